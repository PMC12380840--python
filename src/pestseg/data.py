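"""Dataset I/O: paired image/mask PNGs plus a CSV manifest.

Images are 8-bit RGB PNGs; masks are single-channel PNGs whose pixel values
are the class codes themselves ({0, 1} for the binary pest task).
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image


def write_image_png(path, image: np.ndarray):
    img = np.asarray(image)
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).round().astype(np.uint8)
    Image.fromarray(img, mode="RGB").save(path)


def write_mask_png(path, mask: np.ndarray):
    Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="L").save(path)


def read_image_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def read_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"))


def images_to_float(images: np.ndarray) -> np.ndarray:
    """uint8 [0, 255] -> float [0, 1] network input."""
    return np.asarray(images, dtype=np.float64) / 255.0


def load_directory(data_dir):
    """Load a dataset written by :meth:`SynthDataset.save`.

    Returns (images uint8 [N,H,W,3], masks uint8 [N,H,W], manifest frame).
    Falls back to globbing ``img_*.png`` when no manifest is present.
    """
    data_dir = Path(data_dir)
    manifest_path = data_dir / "manifest.csv"
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path)
        names = list(manifest.filename)
    else:
        names = sorted(p.name for p in data_dir.glob("img_*.png"))
        if not names:
            raise FileNotFoundError(f"no image PNGs found in {data_dir}")
        manifest = pd.DataFrame({"filename": names,
                                 "category": "unknown",
                                 "provenance": "original"})
    images = np.stack([read_image_png(data_dir / n) for n in names])
    masks = np.stack([read_mask_png(data_dir / n.replace("img_", "mask_"))
                      for n in names])
    return images, masks, manifest
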