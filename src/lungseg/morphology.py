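"""Deterministic post-processing for predicted lung masks.

Two operators repair the two characteristic failure modes of a pixel
classifier: stray false-positive fragments outside the lungs, and enclosed
false-negative holes inside them.

* :func:`keep_largest_components` retains the k largest 8-connected
  foreground components (k = 2 for a left and right lung) and discards the
  rest — connected-domain filtering.
* :func:`fill_holes` sets to foreground every background pixel that cannot
  reach the image border through 4-connected background — flood filling.

Foreground uses 8-connectivity and background 4-connectivity; the
complementary pair avoids the topological paradox of a diagonal "gap" that
both sides could claim. :func:`repair` composes them, components first, so a
speckle sitting inside a removed fragment's hole cannot survive.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["keep_largest_components", "fill_holes", "repair", "count_components", "count_holes"]

_STRUCT_8 = np.ones((3, 3), dtype=bool)  # foreground connectivity
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)  # background connectivity


def _as_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.shape[0] < 1 or mask.shape[1] < 1:
        raise ValueError(f"mask must be a non-empty 2-D array, got shape {mask.shape}")
    if mask.dtype != bool:
        vals = np.unique(mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask must be binary, found values {vals[:10]}")
        mask = mask.astype(bool)
    return mask


def keep_largest_components(mask: np.ndarray, k: int = 2) -> np.ndarray:
    """Keep the k largest 8-connected foreground components.

    Area ties are broken in favour of the component whose first pixel comes
    earlier in raster (row-major) order, making the result deterministic.
    Never adds pixels (anti-extensive).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    mask = _as_mask(mask)
    labels, n = ndimage.label(mask, structure=_STRUCT_8)
    if n <= k:
        return mask.copy()
    flat = labels.ravel()
    areas = np.bincount(flat)[1:]  # area per label 1..n
    first_idx = np.full(n, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # first raster occurrence per label (nz is ascending, keep first hit)
    lab_nz = flat[nz]
    order = np.argsort(lab_nz, kind="stable")
    lab_sorted = lab_nz[order]
    pos_sorted = nz[order]
    starts = np.searchsorted(lab_sorted, np.arange(1, n + 1))
    first_idx[:] = pos_sorted[starts]
    rank = sorted(range(n), key=lambda i: (-areas[i], first_idx[i]))
    keep = np.zeros(n + 1, dtype=bool)
    for i in rank[:k]:
        keep[i + 1] = True
    return keep[labels]


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill enclosed holes: background not 4-connected to the border becomes
    foreground. Never removes pixels (extensive); idempotent."""
    mask = _as_mask(mask)
    return ndimage.binary_fill_holes(mask, structure=_STRUCT_4)


def repair(mask: np.ndarray) -> np.ndarray:
    """Full mask repair: keep the two largest components, then fill holes.

    Idempotent; the output has at most 2 foreground components and no
    enclosed background.
    """
    return fill_holes(keep_largest_components(mask, k=2))


# -- small census helpers used by reports and tests -------------------------

def count_components(mask: np.ndarray) -> int:
    """Number of 8-connected foreground components."""
    return int(ndimage.label(_as_mask(mask), structure=_STRUCT_8)[1])


def count_holes(mask: np.ndarray) -> int:
    """Number of 4-connected background components not touching the border."""
    mask = _as_mask(mask)
    labels, n = ndimage.label(~mask, structure=_STRUCT_4)
    border = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    )
    return int(n - np.count_nonzero(border))
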