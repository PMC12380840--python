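"""Synthetic field-scene generation for pest segmentation.

Real field imagery of rice pests has a few statistical signatures that make
segmentation hard: pests are small relative to the frame, appear at several
scales in one image, carry thin appendages (legs, antennae) a pixel or two
wide, and sit on textured, gradually varying vegetation backgrounds with
modest contrast.  Heavy class imbalance (background dominates every image,
and some species are rare) is the norm.  The generator emulates exactly
these signatures with elliptical bodies, protruding polyline appendages,
filtered-noise backgrounds and a category profile with an augmentation
"floor" that tops up rare categories with transformed copies — so the whole
training pipeline can be exercised without any external download.

Everything is deterministic given the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw


@dataclass
class SceneSpec:
    """Parameters of one synthetic pest scene.

    Scales are fractions of the image diagonal; the defaults describe a
    realistic field crop: a few pests occupying a small share of the frame
    (roughly 4-8 percent of pixels in total), moderate pest/background
    contrast, and a noisy green-tinted background with a soft gradient.
    """

    height: int = 64
    width: int = 64
    n_pests: int = 3
    scale_range: tuple = (0.08, 0.20)
    appendage_count: tuple = (3, 6)
    appendage_thickness: tuple = (1, 2)
    eccentricity_range: tuple = (0.40, 0.75)
    background_base: tuple = (0.45, 0.65)
    noise_amplitude: float = 0.06
    gradient_amplitude: float = 0.10
    contrast: float = 0.5
    non_overlap: bool = False
    max_retries: int = 50

    def __post_init__(self):
        if self.n_pests < 0:
            raise ValueError("n_pests must be nonnegative")
        lo, hi = self.scale_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("pest scales must lie in (0, 0.5]")
        if self.appendage_thickness[0] < 1:
            raise ValueError("appendage thickness must be at least 1 px")
        if self.contrast <= 0:
            raise ValueError("contrast factor must be positive")


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    H, W = spec.height, spec.width
    base = rng.uniform(*spec.background_base)
    # green-tinted base colour with a random linear gradient and two noise
    # scales (coarse vegetation clumps + fine sensor grain)
    tint = np.array([0.9, 1.05, 0.85]) * base
    yy, xx = np.mgrid[0:H, 0:W]
    theta = rng.uniform(0, 2 * np.pi)
    ramp = (np.cos(theta) * yy / H + np.sin(theta) * xx / W)
    img = np.tile(tint, (H, W, 1))
    img += spec.gradient_amplitude * (ramp - ramp.mean())[..., None]
    coarse = ndimage.gaussian_filter(rng.standard_normal((H, W)), sigma=4)
    coarse /= max(coarse.std(), 1e-9)
    img += spec.noise_amplitude * coarse[..., None]
    img += 0.3 * spec.noise_amplitude * rng.standard_normal((H, W, 3))
    return img


def _draw_pest(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Render one pest (body + appendages) as a boolean canvas, or raise."""
    H, W = spec.height, spec.width
    diag = float(np.hypot(H, W))
    for _ in range(spec.max_retries):
        major = max(2.0, rng.uniform(*spec.scale_range) * diag / 2.0)
        minor = max(1.0, rng.uniform(*spec.eccentricity_range) * major)
        phi = rng.uniform(0, np.pi)
        cy = rng.uniform(major, H - major) if H > 2 * major else H / 2
        cx = rng.uniform(major, W - major) if W > 2 * major else W / 2
        canvas = np.zeros((H, W), dtype=bool)
        rr, cc = skdraw.ellipse(cy, cx, major, minor, shape=(H, W), rotation=phi)
        if rr.size == 0:
            continue
        canvas[rr, cc] = True
        n_app = rng.integers(spec.appendage_count[0], spec.appendage_count[1] + 1)
        for _ in range(n_app):
            ang = rng.uniform(0, 2 * np.pi)
            # start strictly inside the body (within the minor radius, which
            # every boundary ray exceeds) so the appendage stays connected
            sy = cy + minor * 0.7 * np.sin(ang)
            sx = cx + minor * 0.7 * np.cos(ang)
            length = rng.uniform(0.5, 1.2) * major
            kink = ang + rng.uniform(-0.6, 0.6)
            my, mx = sy + 0.5 * length * np.sin(ang), sx + 0.5 * length * np.cos(ang)
            ey, ex = my + 0.5 * length * np.sin(kink), mx + 0.5 * length * np.cos(kink)
            thick = rng.integers(spec.appendage_thickness[0],
                                 spec.appendage_thickness[1] + 1)
            pts = [(sy, sx), (my, mx), (ey, ex)]
            for (ay, ax), (by, bx) in zip(pts[:-1], pts[1:]):
                for off in range(thick):
                    rr, cc = skdraw.line(int(round(ay)) + off % 2,
                                         int(round(ax)) + off // 2,
                                         int(round(by)) + off % 2,
                                         int(round(bx)) + off // 2)
                    keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
                    canvas[rr[keep], cc[keep]] = True
        return canvas
    raise RuntimeError("could not place a pest inside the canvas")


def generate_scene(spec: SceneSpec, seed: int | np.random.Generator = 0):
    """Render one scene; returns (uint8 RGB image, uint8 {0,1} mask)."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    img = _background(spec, rng)
    mask = np.zeros((spec.height, spec.width), dtype=np.uint8)
    placed = np.zeros_like(mask, dtype=bool)
    for _ in range(spec.n_pests):
        for attempt in range(spec.max_retries):
            canvas = _draw_pest(spec, rng)
            if not spec.non_overlap:
                break
            # one-pixel clearance keeps components separate under 8-connectivity
            grown = ndimage.binary_dilation(canvas, np.ones((3, 3)))
            if not (grown & placed).any():
                break
        else:
            raise RuntimeError("could not place non-overlapping pests")
        placed |= canvas
        body = img[canvas].mean(axis=0)
        pest_col = body * (1.0 - spec.contrast) * rng.uniform(0.85, 1.15, 3)
        img[canvas] = pest_col + 0.02 * rng.standard_normal((canvas.sum(), 3))
        mask[canvas] = 1
    img = np.clip(img, 0.0, 1.0)
    return (img * 255).round().astype(np.uint8), mask


@dataclass
class SynthDataset:
    """In-memory synthetic dataset with a provenance manifest."""

    images: np.ndarray            # [N, H, W, 3] uint8
    masks: np.ndarray             # [N, H, W] uint8 in {0, 1}
    manifest: pd.DataFrame        # filename, category, provenance

    def __len__(self):
        return len(self.images)

    def save(self, out_dir):
        from .data import write_image_png, write_mask_png
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i in range(len(self.images)):
            write_image_png(out / self.manifest.filename[i], self.images[i])
            write_mask_png(out / self.manifest.filename[i].replace("img_", "mask_"),
                           self.masks[i])
        self.manifest.to_csv(out / "manifest.csv", index=False)


def _category_spec(base: SceneSpec, cat_index: int) -> SceneSpec:
    """Deterministic per-category variation (pest count / scale / contrast)."""
    r = np.random.default_rng(1000 + cat_index)
    lo, hi = base.scale_range
    return replace(
        base,
        n_pests=int(1 + (cat_index % 4)),
        scale_range=(lo * r.uniform(0.8, 1.0), hi * r.uniform(0.9, 1.2)),
        contrast=float(np.clip(base.contrast * r.uniform(0.8, 1.2), 0.2, 0.9)),
    )


def generate_dataset(n_images: int | None = None,
                     class_profile: dict | None = None,
                     seed: int = 0,
                     rebalance_floor: int = 0,
                     base_spec: SceneSpec | None = None,
                     out_dir=None) -> SynthDataset:
    """Build a synthetic dataset, optionally rebalancing rare categories.

    ``class_profile`` maps pseudo-category name -> original image count
    (defaults to a single category of ``n_images``).  Categories below
    ``rebalance_floor`` are topped up with augmented copies of their own
    originals; the manifest marks provenance ``original``/``augmented``.
    """
    from .augment import AugmentSpec, augment

    if class_profile is None:
        if n_images is None or n_images < 1:
            raise ValueError("need n_images >= 1 or a class profile")
        class_profile = {"pest": int(n_images)}
    base = base_spec or SceneSpec()
    rng = np.random.default_rng(seed)
    images, masks, rows = [], [], []
    per_cat_indices: dict[str, list[int]] = {}
    for ci, (cat, count) in enumerate(sorted(class_profile.items())):
        spec = _category_spec(base, ci)
        per_cat_indices[cat] = []
        for _ in range(int(count)):
            img, mask = generate_scene(spec, rng)
            per_cat_indices[cat].append(len(images))
            images.append(img)
            masks.append(mask)
            rows.append({"category": cat, "provenance": "original"})
    aug_spec = AugmentSpec()
    for cat, count in sorted(class_profile.items()):
        deficit = rebalance_floor - int(count)
        for _ in range(max(0, deficit)):
            src = per_cat_indices[cat][rng.integers(len(per_cat_indices[cat]))]
            img, mask = augment(images[src], masks[src], aug_spec, rng)
            images.append(img)
            masks.append(mask)
            rows.append({"category": cat, "provenance": "augmented"})
    manifest = pd.DataFrame(rows)
    manifest.insert(0, "filename", [f"img_{i:05d}.png" for i in range(len(rows))])
    ds = SynthDataset(np.stack(images), np.stack(masks), manifest)
    if out_dir is not None:
        ds.save(out_dir)
    return ds


# ----------------------------------------------------------------- splitting
@dataclass
class DatasetSplit:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    ratios: tuple
    seed: int


def split_indices(n: int, ratios=(0.6, 0.2, 0.2), seed: int = 0,
                  provenance=None) -> DatasetSplit:
    """Seeded shuffle + contiguous slicing into train/val/test.

    Slice boundaries are the rounded cumulative ratios, so 10 items at
    6:2:2 give exactly (6, 2, 2).  Augmented items (``provenance[i] ==
    'augmented'``) are confined to the training split: validation and test
    are drawn from originals only, preventing augmentation leakage.
    """
    if n < 3:
        raise ValueError("dataset must contain at least 3 items")
    ratios = np.asarray(ratios, dtype=np.float64)
    if (ratios <= 0).any():
        raise ValueError("ratios must be positive")
    ratios = ratios / ratios.sum()
    bounds = np.round(np.cumsum(ratios) * n).astype(int)
    n_train, n_val = bounds[0], bounds[1] - bounds[0]
    n_test = n - bounds[1]
    rng = np.random.default_rng(seed)
    if provenance is None:
        perm = rng.permutation(n)
        return DatasetSplit(perm[:n_train], perm[n_train:bounds[1]],
                            perm[bounds[1]:], tuple(ratios), seed)
    provenance = np.asarray(provenance)
    orig = np.flatnonzero(provenance != "augmented")
    aug = np.flatnonzero(provenance == "augmented")
    if n_val + n_test > orig.size:
        raise ValueError("not enough original items for validation and test")
    orig = rng.permutation(orig)
    val = orig[:n_val]
    test = orig[n_val:n_val + n_test]
    train = rng.permutation(np.concatenate([orig[n_val + n_test:], aug]))
    return DatasetSplit(train, val, test, tuple(ratios), seed)
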