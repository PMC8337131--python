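"""Grayscale image conventions shared by every stage.

An image is a 2-D ``float64`` array with intensities in ``[0, 1]``,
0-based indices, ``x`` = column, ``y`` = row, origin at the top-left.
"""

from __future__ import annotations

import numpy as np


class DimensionError(ValueError):
    """Two images that must share a shape do not."""


class DegenerateInputError(ValueError):
    """Input is constant (or otherwise information-free) where variation is required."""


def as_gray(img) -> np.ndarray:
    """Coerce ``img`` to a validated 2-D float64 grayscale array.

    Raises
    ------
    ValueError
        If the array is not 2-D, is empty, or contains non-finite values.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={arr.ndim}")
    if arr.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def normalize(img, *, warn_constant: bool = False) -> np.ndarray:
    """Min-max normalize intensities to ``[0, 1]``.

    A constant image has zero dynamic range and maps to all zeros (the
    shared-range convention that makes cross-modality averaging meaningful).
    """
    arr = as_gray(img)
    lo = float(arr.min())
    hi = float(arr.max())
    if hi > lo:
        return (arr - lo) / (hi - lo)
    if warn_constant:
        import logging

        logging.getLogger(__name__).warning(
            "image has zero dynamic range; normalizing to all zeros"
        )
    return np.zeros_like(arr)


def check_same_shape(r: np.ndarray, f: np.ndarray) -> None:
    if r.shape != f.shape:
        raise DimensionError(f"shape mismatch: {r.shape} vs {f.shape}")
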