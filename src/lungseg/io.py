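"""Readers/writers for image-mask pairs, manifests, and overlay rendering.

Conventions: row-major arrays, origin top-left, 0-based indices. Images and
masks travel as 8-bit PNG; mask PNGs hold exactly {0, 255} with 255 =
lung-field foreground.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.transform import resize

from .phantom import ImageSample

__all__ = [
    "load_sample",
    "load_mask_png",
    "save_mask_png",
    "read_manifest",
    "write_manifest",
    "load_manifest_samples",
    "render_overlay",
]


def load_mask_png(path: str | Path) -> np.ndarray:
    """Read a {0, 255} PNG mask as a boolean array; reject other values."""
    path = Path(path)
    try:
        arr = np.asarray(Image.open(path).convert("L"))
    except OSError as exc:
        raise OSError(f"cannot read mask PNG {path}: {exc}") from exc
    vals = np.unique(arr)
    if not np.isin(vals, (0, 255)).all():
        raise ValueError(
            f"mask {path} must contain only values {{0, 255}}, found {vals[:10]}"
        )
    return arr == 255


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(mask, dtype=bool).astype(np.uint8) * 255).save(Path(path))


def load_sample(
    image_path: str | Path,
    mask_path: str | Path,
    target_size: int = 256,
    sample_id: str | None = None,
) -> ImageSample:
    """Load a PNG image/mask pair, resizing to the model resolution.

    The image is resized with smooth (anti-aliased bilinear) interpolation
    and scaled to [0, 1]; grayscale inputs are replicated to 3 channels. The
    mask is resized nearest-neighbour and stays strictly binary.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    try:
        img = np.asarray(Image.open(image_path).convert("RGB"), dtype=np.float64) / 255.0
    except OSError as exc:
        raise OSError(f"cannot read image PNG {image_path}: {exc}") from exc
    mask = load_mask_png(mask_path)
    if img.shape[:2] != mask.shape:
        raise OSError(
            f"image {image_path} is {img.shape[:2]} but mask {mask_path} is {mask.shape}"
        )
    if img.shape[:2] != (target_size, target_size):
        img = resize(
            img, (target_size, target_size), order=1, anti_aliasing=True, preserve_range=True
        )
        mask = (
            resize(
                mask.astype(np.uint8),
                (target_size, target_size),
                order=0,
                anti_aliasing=False,
                preserve_range=True,
            )
            > 0.5
        )
    return ImageSample(
        image=np.clip(img, 0.0, 1.0),
        mask=mask,
        sample_id=sample_id or image_path.stem,
    )


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(rows: pd.DataFrame, path: str | Path) -> None:
    rows.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a manifest CSV (unique ids, existing paths)."""
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False)
    required = {"sample_id", "path_image", "path_mask"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest {path} missing columns {required - set(df.columns)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"manifest {path} has duplicate sample_ids: {dupes[:5]}")
    base = path.parent
    for col in ("path_image", "path_mask"):
        for p in df[col]:
            candidate = Path(p)
            if not candidate.is_absolute():
                candidate = base / candidate
            if not candidate.exists():
                raise FileNotFoundError(f"manifest {path} references missing file {p}")
    return df


def load_manifest_samples(path: str | Path, target_size: int = 256) -> list[ImageSample]:
    path = Path(path)
    df = read_manifest(path)
    samples = []
    for _, row in df.iterrows():
        img_p, mask_p = Path(row["path_image"]), Path(row["path_mask"])
        if not img_p.is_absolute():
            img_p, mask_p = path.parent / img_p, path.parent / mask_p
        s = load_sample(img_p, mask_p, target_size, sample_id=row["sample_id"])
        tags = str(row.get("condition_tags", "") or "")
        s.condition_tags = frozenset(t for t in tags.split("|") if t)
        samples.append(s)
    return samples


# ---------------------------------------------------------------------------
# overlays
# ---------------------------------------------------------------------------

def _boundary(mask: np.ndarray) -> np.ndarray:
    """Mask pixels 4-adjacent to background (or to the image border)."""
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~interior


def render_overlay(
    image: np.ndarray, truth_mask: np.ndarray, pred_mask: np.ndarray
) -> np.ndarray:
    """Draw the truth boundary green and the predicted boundary red.

    Returns an 8-bit RGB image; pixels on both boundaries show both channels
    (yellow). The input masks are not modified.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:
        gray = image.mean(axis=2)
    else:
        gray = image
    if gray.shape != np.shape(truth_mask) or gray.shape != np.shape(pred_mask):
        raise ValueError(
            f"shape mismatch: image {gray.shape}, truth {np.shape(truth_mask)}, "
            f"pred {np.shape(pred_mask)}"
        )
    out = np.repeat((np.clip(gray, 0, 1) * 255).round().astype(np.uint8)[:, :, None], 3, axis=2)
    tb, pb = _boundary(truth_mask), _boundary(pred_mask)
    out[tb] = [0, 255, 0]
    out[pb & ~tb] = [255, 0, 0]
    out[pb & tb] = [255, 255, 0]
    return out
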