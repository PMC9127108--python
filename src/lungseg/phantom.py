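"""Synthetic chest-radiograph phantoms with known lung-field ground truth.

A phantom emulates the difficulty axes of hard clinical chest films —
blurred/opacified lung fields, device-like occluders, and deformed anatomy —
while keeping an exact ground-truth mask:

* geometry: a bright body ellipse on a dark air background, containing two
  mirrored, tilted superellipse "lungs" of lower intensity (air-filled lungs
  are radiolucent). The mask marks the two lung regions.
* opacity: additive blurred haze localized to one lung, emulating the
  high-intensity turbidity of consolidating disease. Image only.
* occlusion: bright axis-aligned bars crossing a lung (pacemaker-lead /
  catheter analogue). Image only — devices corrupt appearance, not anatomy.
* deformation: a smooth random elastic warp applied identically to image and
  mask (deformed anatomy moves the true lung border with it).
* noise: additive Gaussian intensity noise.

Every random choice draws from its own seeded stream, so toggling one
corruption never changes the others: the mask of an occluded phantom equals
the mask of the clean phantom at the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "PhantomConfig",
    "ImageSample",
    "generate_phantom",
    "generate_dataset",
    "augment",
    "write_dataset",
    "AUGMENTATION_NAMES",
]

AUGMENTATION_NAMES = ("random_gamma", "blur", "horizontal_flip", "normalize")

# fixed anatomy constants, in units of image size
_BODY_CENTER = (0.52, 0.50)  # (row, col)
_BODY_AXES = (0.46, 0.42)
_LUNG_CENTER_ROW = 0.48
_LUNG_CENTER_COLS = (0.32, 0.68)
_LUNG_HALF_WIDTH = 0.115
_SUPERELLIPSE_POWER = 2.5
_AIR, _BODY_TONE, _LUNG_TONE = 0.10, 0.72, 0.28


class PhantomConfigError(ValueError):
    """Invalid phantom configuration; the message names the offending field."""


@dataclass(frozen=True)
class PhantomConfig:
    """Generation knobs for one phantom or a dataset of them.

    Defaults describe a moderately hard case mix: haze on half the samples at
    severity 0.35, a device occluder on a quarter, and a mild (3-pixel)
    elastic deformation everywhere.
    """

    image_size: int = 256
    lung_eccentricity_range: tuple[float, float] = (1.7, 2.3)  # height/width ratio
    opacity_severity: float = 0.35
    opacity_prob: float = 0.5
    occlusion_prob: float = 0.25
    deformation_amplitude: float = 3.0  # pixels
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> "PhantomConfig":
        if self.image_size < 32 or self.image_size % 32 != 0:
            raise PhantomConfigError(
                f"image_size must be >= 32 and divisible by 32, got {self.image_size}"
            )
        lo, hi = self.lung_eccentricity_range
        if not (0 < lo <= hi):
            raise PhantomConfigError(
                f"lung_eccentricity_range must be 0 < lo <= hi, got {self.lung_eccentricity_range}"
            )
        for name in ("opacity_severity", "opacity_prob", "occlusion_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PhantomConfigError(f"{name} must be in [0, 1], got {v}")
        if self.deformation_amplitude < 0:
            raise PhantomConfigError(
                f"deformation_amplitude must be >= 0, got {self.deformation_amplitude}"
            )
        if self.noise_sd < 0:
            raise PhantomConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        return self


@dataclass
class ImageSample:
    """One image/mask pair: H×W×3 image in [0, 1], binary H×W lung mask."""

    image: np.ndarray
    mask: np.ndarray
    sample_id: str
    condition_tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} disagree"
            )
        if self.mask.dtype != bool:
            vals = np.unique(self.mask)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"mask must be binary, found {vals[:10]}")
            self.mask = self.mask.astype(bool)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Independent named RNG streams so corruptions do not interact."""
    names = ("shape", "deform", "opacity", "occlusion", "noise")
    children = np.random.SeedSequence(entropy=int(seed)).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _superellipse(size: int, center, half_axes, tilt: float) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size] / size
    dr, dc = rr - center[0], cc - center[1]
    r = np.cos(tilt) * dr - np.sin(tilt) * dc
    c = np.sin(tilt) * dr + np.cos(tilt) * dc
    p = _SUPERELLIPSE_POWER
    return (np.abs(r / half_axes[0]) ** p + np.abs(c / half_axes[1]) ** p) <= 1.0


def _render_anatomy(size: int, rng: np.random.Generator, ecc_range) -> tuple[np.ndarray, np.ndarray]:
    body = _superellipse(size, _BODY_CENTER, _BODY_AXES, 0.0)
    image = np.full((size, size), _AIR)
    rows = np.linspace(-0.06, 0.06, size)[:, None]  # mild cranio-caudal gradient
    image[body] = (_BODY_TONE + rows + np.zeros((size, size)))[body]
    mask = np.zeros((size, size), dtype=bool)
    for col, sign in zip(_LUNG_CENTER_COLS, (+1, -1)):
        ecc = rng.uniform(*ecc_range)
        width = _LUNG_HALF_WIDTH * rng.uniform(0.9, 1.1)
        tilt = sign * rng.uniform(0.02, 0.10)
        lung = _superellipse(size, (_LUNG_CENTER_ROW, col), (width * ecc, width), tilt)
        mask |= lung
    texture = ndimage.gaussian_filter(rng.normal(0, 1.0, (size, size)), sigma=size / 32)
    image[mask] = (_LUNG_TONE + 0.05 * texture)[mask]
    image = ndimage.gaussian_filter(image, sigma=size / 256)  # soften edges
    return image, mask


def _elastic_warp(image, mask, amplitude: float, rng: np.random.Generator):
    size = image.shape[0]
    sigma = size / 8
    disp = []
    for _ in range(2):
        f = ndimage.gaussian_filter(rng.normal(0, 1.0, (size, size)), sigma=sigma)
        peak = np.abs(f).max()
        disp.append(f * (amplitude / peak if peak > 0 else 0.0))
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    coords = np.array([rr + disp[0], cc + disp[1]])
    warped_img = ndimage.map_coordinates(image, coords, order=1, mode="nearest")
    warped_mask = ndimage.map_coordinates(
        mask.astype(np.uint8), coords, order=0, mode="constant"
    ).astype(bool)
    return warped_img, warped_mask


def _add_opacity(image, mask, severity: float, rng: np.random.Generator):
    size = image.shape[0]
    side = rng.integers(0, 2)  # which lung is diseased
    half = np.zeros_like(mask)
    mid = size // 2
    if side == 0:
        half[:, :mid] = mask[:, :mid]
    else:
        half[:, mid:] = mask[:, mid:]
    blob = ndimage.gaussian_filter(half.astype(np.float64), sigma=size / 20)
    peak = blob.max()
    if peak > 0:
        image = image + severity * 0.55 * (blob / peak)
    return image


def _add_occluders(image, mask, rng: np.random.Generator):
    """Bright axis-aligned bars guaranteed to cross a lung region."""
    size = image.shape[0]
    n_bars = int(rng.integers(1, 3))
    rows_any, cols_any = np.nonzero(mask)
    out = image.copy()
    for _ in range(n_bars):
        i = rng.integers(0, rows_any.size)
        r, c = rows_any[i], cols_any[i]
        thickness = int(rng.integers(2, max(3, size // 64) + 1))
        if rng.random() < 0.5:
            out[max(0, r - thickness // 2) : r + (thickness + 1) // 2, :] = 0.95
        else:
            out[:, max(0, c - thickness // 2) : c + (thickness + 1) // 2] = 0.95
    return out


def generate_phantom(config: PhantomConfig, seed: int) -> ImageSample:
    """Render one phantom; a pure function of (config, seed).

    The mask marks the (possibly deformed) anatomical lung regions only —
    haze and occluders perturb the image, never the mask.
    """
    config.validate()
    rngs = _streams(seed)
    size = config.image_size
    image, mask = _render_anatomy(size, rngs["shape"], config.lung_eccentricity_range)

    tags: set[str] = set()
    if config.deformation_amplitude > 0:
        image, mask = _elastic_warp(image, mask, config.deformation_amplitude, rngs["deform"])
        tags.add("deformed")
    if config.opacity_severity > 0 and rngs["opacity"].random() < config.opacity_prob:
        image = _add_opacity(image, mask, config.opacity_severity, rngs["opacity"])
        tags.add("opacity")
    if rngs["occlusion"].random() < config.occlusion_prob:
        image = _add_occluders(image, mask, rngs["occlusion"])
        tags.add("occluded")
    if config.noise_sd > 0:
        image = image + rngs["noise"].normal(0, config.noise_sd, image.shape)
    if not tags:
        tags.add("clean")

    image = np.clip(image, 0.0, 1.0)
    rgb = np.repeat(image[:, :, None], 3, axis=2)
    return ImageSample(
        image=rgb, mask=mask, sample_id=f"phantom-{seed:010d}", condition_tags=frozenset(tags)
    )


def generate_dataset(n: int, config: PhantomConfig, seed: int | None = None) -> list[ImageSample]:
    """Generate ``n`` phantoms with per-sample seeds derived from the master.

    Per-sample seeds come from a counter-keyed derivation, so growing the
    dataset appends samples without reshuffling earlier ones.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    master = config.seed if seed is None else seed
    samples = []
    for i in range(n):
        child = np.random.SeedSequence(entropy=int(master), spawn_key=(i,))
        sample_seed = int(child.generate_state(1, dtype=np.uint32)[0])
        s = generate_phantom(config, sample_seed)
        s.sample_id = f"phantom-{master:06d}-{i:05d}"
        samples.append(s)
    return samples


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(sample: ImageSample, ops: list[str], seed: int = 0) -> ImageSample:
    """Apply the training augmentations in the order given.

    ``horizontal_flip`` is geometric and applied to image and mask alike
    (and is its own inverse); ``random_gamma``, ``blur`` and ``normalize``
    are photometric and leave the mask untouched. ``normalize`` rescales the
    image to span [0, 1] (min-max).
    """
    unknown = [op for op in ops if op not in AUGMENTATION_NAMES]
    if unknown:
        raise ValueError(
            f"unknown augmentation(s) {unknown}; supported: {list(AUGMENTATION_NAMES)}"
        )
    rng = np.random.default_rng(seed)
    image, mask = sample.image.copy(), sample.mask.copy()
    for op in ops:
        if op == "horizontal_flip":
            image = image[:, ::-1].copy()
            mask = mask[:, ::-1].copy()
        elif op == "random_gamma":
            gamma = rng.uniform(0.7, 1.4)
            image = np.clip(image, 0.0, 1.0) ** gamma
        elif op == "blur":
            sigma = rng.uniform(0.5, 1.5)
            image = ndimage.gaussian_filter(image, sigma=(sigma, sigma, 0))
        elif op == "normalize":
            lo, hi = image.min(), image.max()
            if hi > lo:
                image = (image - lo) / (hi - lo)
    return ImageSample(
        image=image,
        mask=mask,
        sample_id=sample.sample_id,
        condition_tags=sample.condition_tags,
    )


# ---------------------------------------------------------------------------
# on-disk form: 8-bit PNGs plus a CSV manifest
# ---------------------------------------------------------------------------

def write_dataset(samples: list[ImageSample], out_dir: str | Path) -> Path:
    """Write image/mask PNG pairs ({0, 255} masks) and a manifest.csv."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        img_path = out_dir / "images" / f"{s.sample_id}.png"
        mask_path = out_dir / "masks" / f"{s.sample_id}.png"
        Image.fromarray((np.clip(s.image, 0, 1) * 255).round().astype(np.uint8)).save(img_path)
        Image.fromarray((s.mask.astype(np.uint8) * 255)).save(mask_path)
        rows.append(
            {
                "sample_id": s.sample_id,
                "path_image": str(img_path),
                "path_mask": str(mask_path),
                "condition_tags": "|".join(sorted(s.condition_tags)),
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
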