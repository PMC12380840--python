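"""Paired image/mask augmentation.

Geometric operations (crop, flips, rotation, shift) transform image and
mask with the same parameters; the mask always uses nearest-neighbour
resampling so its codes stay in {0, 1}.  Photometric "enhancement"
(brightness/contrast jitter) touches the image only.  Mixup blends two
scenes and yields a soft probability mask; CutMix transplants a rectangle
jointly in image and mask and keeps labels hard.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize


@dataclass
class AugmentSpec:
    crop: bool = True
    crop_min_area: float = 0.8
    hflip: bool = True
    vflip: bool = True
    enhance: bool = True
    jitter: float = 0.2          # max relative brightness/contrast change
    rotate: bool = True
    max_angle: float = 30.0      # degrees
    shift: bool = True
    max_shift: float = 0.1       # fraction of each dimension
    prob: float = 0.5            # per-op application probability

    def __post_init__(self):
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        if not 0.0 < self.crop_min_area <= 1.0:
            raise ValueError("crop_min_area must lie in (0, 1]")


def _check_pair(image, mask):
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError(f"image {image.shape} and mask {mask.shape} differ")
    return image, mask


def hflip(image, mask):
    """Left-right flip of both image and mask."""
    image, mask = _check_pair(image, mask)
    return image[:, ::-1].copy(), mask[:, ::-1].copy()


def vflip(image, mask):
    """Up-down flip of both image and mask."""
    image, mask = _check_pair(image, mask)
    return image[::-1].copy(), mask[::-1].copy()


def rotate(image, mask, angle: float):
    """Rotate both by ``angle`` degrees about the centre.

    Right-angle rotations on square inputs are exact pixel permutations;
    other angles use bilinear (image) / nearest (mask) interpolation with
    background fill outside the original support.
    """
    image, mask = _check_pair(image, mask)
    if angle % 360 == 0:
        return image.copy(), mask.copy()
    if angle % 90 == 0 and image.shape[0] == image.shape[1]:
        k = int(angle // 90) % 4
        return np.rot90(image, k).copy(), np.rot90(mask, k).copy()
    fill = float(np.asarray(image, dtype=np.float64).mean())
    img = ndimage.rotate(image.astype(np.float64), angle, reshape=False,
                         order=1, mode="constant", cval=fill)
    msk = ndimage.rotate(mask, angle, reshape=False, order=0,
                         mode="constant", cval=0)
    return np.clip(img, 0, 255).astype(image.dtype), msk.astype(mask.dtype)


def shift(image, mask, dy: int, dx: int):
    """Translate both by (dy, dx) pixels with reflection padding."""
    image, mask = _check_pair(image, mask)
    if dy == 0 and dx == 0:
        return image.copy(), mask.copy()
    sh = (dy, dx) + (0,) * (image.ndim - 2)
    img = ndimage.shift(image.astype(np.float64), sh, order=0, mode="reflect")
    msk = ndimage.shift(mask, (dy, dx), order=0, mode="reflect")
    return img.astype(image.dtype), msk.astype(mask.dtype)


def crop_resize(image, mask, top: int, left: int, ch: int, cw: int):
    """Crop a window and resize back to the original resolution."""
    image, mask = _check_pair(image, mask)
    H, W = mask.shape
    if ch < 1 or cw < 1 or top < 0 or left < 0 or top + ch > H or left + cw > W:
        raise ValueError("crop window outside the canvas")
    img = image[top:top + ch, left:left + cw]
    msk = mask[top:top + ch, left:left + cw]
    img = resize(img.astype(np.float64), (H, W), order=1,
                 preserve_range=True, anti_aliasing=False)
    msk = resize(msk, (H, W), order=0, preserve_range=True,
                 anti_aliasing=False)
    return np.clip(img, 0, 255).astype(image.dtype), msk.astype(mask.dtype)


def enhance(image, brightness: float, contrast: float):
    """Photometric jitter: scale brightness, then stretch about the mean."""
    img = np.asarray(image, dtype=np.float64) * brightness
    img = (img - img.mean()) * contrast + img.mean()
    return np.clip(img, 0, 255).astype(np.asarray(image).dtype)


def augment(image, mask, spec: AugmentSpec,
            rng: np.random.Generator | int = 0):
    """Apply the enabled operations, each with probability ``spec.prob``."""
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    image, mask = _check_pair(image, mask)
    image, mask = image.copy(), mask.copy()
    H, W = mask.shape
    if spec.crop and rng.random() < spec.prob:
        area = rng.uniform(spec.crop_min_area, 1.0)
        ch = max(1, int(round(H * np.sqrt(area))))
        cw = max(1, int(round(W * np.sqrt(area))))
        top = rng.integers(0, H - ch + 1)
        left = rng.integers(0, W - cw + 1)
        image, mask = crop_resize(image, mask, top, left, ch, cw)
    if spec.hflip and rng.random() < spec.prob:
        image, mask = hflip(image, mask)
    if spec.vflip and rng.random() < spec.prob:
        image, mask = vflip(image, mask)
    if spec.enhance and rng.random() < spec.prob:
        b = rng.uniform(1 - spec.jitter, 1 + spec.jitter)
        c = rng.uniform(1 - spec.jitter, 1 + spec.jitter)
        image = enhance(image, b, c)
    if spec.rotate and rng.random() < spec.prob:
        image, mask = rotate(image, mask, rng.uniform(-spec.max_angle,
                                                      spec.max_angle))
    if spec.shift and rng.random() < spec.prob:
        dy = int(rng.integers(-int(spec.max_shift * H), int(spec.max_shift * H) + 1))
        dx = int(rng.integers(-int(spec.max_shift * W), int(spec.max_shift * W) + 1))
        image, mask = shift(image, mask, dy, dx)
    return image, mask


def mixup(pair1, pair2, lam: float, num_classes: int = 2):
    """Convex combination of two scenes; returns (image, soft mask).

    The soft mask is the same convex combination of the one-hot masks, a
    valid probability target for the hybrid loss.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    img1, m1 = _check_pair(*pair1)
    img2, m2 = _check_pair(*pair2)
    if img1.shape != img2.shape:
        raise ValueError("mixup pairs must share a shape")
    eye = np.eye(num_classes)
    if lam == 1.0:
        return img1.copy(), eye[m1]
    if lam == 0.0:
        return img2.copy(), eye[m2]
    img = lam * img1.astype(np.float64) + (1 - lam) * img2.astype(np.float64)
    soft = lam * eye[m1] + (1 - lam) * eye[m2]
    if not np.issubdtype(img1.dtype, np.floating):
        img = np.clip(img, 0, 255).round().astype(img1.dtype)
    return img, soft


def cutmix(pair1, pair2, area_frac: float,
           rng: np.random.Generator | int = 0, max_retries: int = 20):
    """Transplant a rectangle of area ≈ ``area_frac``·H·W from pair2 into pair1."""
    if not 0.0 < area_frac < 1.0 + 1e-12:
        raise ValueError("area fraction must lie in (0, 1)")
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    img1, m1 = _check_pair(*pair1)
    img2, m2 = _check_pair(*pair2)
    if img1.shape != img2.shape:
        raise ValueError("cutmix pairs must share a shape")
    H, W = m1.shape
    target = area_frac * H * W
    for _ in range(max_retries):
        aspect = rng.uniform(0.5, 2.0)
        bw = min(W, int(round(np.sqrt(target * aspect))))
        bh = min(H, int(round(target / max(bw, 1))))
        bw = min(W, int(round(target / max(bh, 1))))
        if bh < 1 or bw < 1:
            continue  # degenerate rectangle: resample
        top = int(rng.integers(0, H - bh + 1))
        left = int(rng.integers(0, W - bw + 1))
        img = img1.copy()
        msk = m1.copy()
        img[top:top + bh, left:left + bw] = img2[top:top + bh, left:left + bw]
        msk[top:top + bh, left:left + bw] = m2[top:top + bh, left:left + bw]
        return img, msk, (top, left, bh, bw)
    raise RuntimeError("could not sample a non-degenerate cutmix rectangle")


def make_batch_mixer(num_classes: int = 2, mixup_prob: float = 0.2,
                     cutmix_prob: float = 0.2, mixup_alpha: float = 0.4,
                     cutmix_area: tuple = (0.1, 0.4)):
    """Training-time mixing: returns ``mixer(images, masks, rng)``.

    For each batch the mixer, with the configured probabilities, applies
    mixup (Beta(alpha, alpha) coefficient) or cutmix (uniform area fraction)
    between the batch and a shuffled copy of itself.  The returned targets
    are soft class-probability maps [B, H, W, n], which the hybrid loss
    accepts directly; untouched batches return one-hot targets.
    """

    def mixer(images: np.ndarray, masks: np.ndarray,
              rng: np.random.Generator):
        eye = np.eye(num_classes)
        imgs = np.asarray(images, dtype=np.float64)
        soft = eye[np.asarray(masks)]
        n = len(imgs)
        u = rng.random()
        if n < 2 or u >= mixup_prob + cutmix_prob:
            return imgs, soft
        partner = rng.permutation(n)
        if u < mixup_prob:
            lam = float(rng.beta(mixup_alpha, mixup_alpha))
            imgs = lam * imgs + (1 - lam) * imgs[partner]
            soft = lam * soft + (1 - lam) * soft[partner]
        else:
            frac = float(rng.uniform(*cutmix_area))
            out_i, out_m = imgs.copy(), np.asarray(masks).copy()
            for b in range(n):
                oi, om, _ = cutmix((imgs[b], out_m[b]),
                                   (imgs[partner[b]],
                                    np.asarray(masks)[partner[b]]),
                                   frac, rng)
                out_i[b], out_m[b] = oi, om
            imgs, soft = out_i, eye[out_m]
        return imgs, soft

    return mixer
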