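"""Similarity measures used to score a registration.

Four classic global measures over an image pair (reference ``R``,
floating ``F``), all computed from intensities normalized to ``[0, 1]``:

* mutual information  MI(R,F) = H(R) + H(F) - H(R,F), entropies in bits,
  estimated from a joint intensity histogram;
* normalized mutual information  NMI(R,F) = (H(R) + H(F)) / H(R,F);
* normalized correlation coefficient (Pearson, signed);
* mean square difference  MSD = sum (R - F)^2 / N.

The joint histogram uses ``bins`` uniform bins over ``[0, 1]`` with the
last bin right-closed at 1.  Empty bins follow the 0 log 0 = 0 convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import DegenerateInputError, as_gray, check_same_shape

DEFAULT_BINS = 64


@dataclass(frozen=True)
class JointHistogram:
    """Joint intensity histogram of a reference/floating pair.

    ``counts[i, j]`` is the number of pixel positions whose reference
    intensity falls in bin ``i`` and floating intensity in bin ``j``;
    marginals are the corresponding row/column sums.
    """

    bins: int
    counts: np.ndarray
    marginal_r: np.ndarray
    marginal_f: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricReport:
    """The four similarity measures of one registration evaluation."""

    mi: float
    nmi: float
    ncc: float
    msd: float

    def as_dict(self) -> dict:
        return {"mi": self.mi, "nmi": self.nmi, "ncc": self.ncc, "msd": self.msd}


def _bin_indices(values: np.ndarray, bins: int) -> np.ndarray:
    # bin i covers [i/bins, (i+1)/bins); the top edge folds into the last bin
    idx = (values * bins).astype(np.int64)
    return np.minimum(idx, bins - 1)


def joint_histogram(r, f, bins: int = DEFAULT_BINS) -> JointHistogram:
    """Bin an image pair into a ``bins`` x ``bins`` joint count matrix."""
    r = as_gray(r)
    f = as_gray(f)
    check_same_shape(r, f)
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    ri = _bin_indices(r.ravel(), bins)
    fi = _bin_indices(f.ravel(), bins)
    flat = np.bincount(ri * bins + fi, minlength=bins * bins)
    counts = flat.reshape(bins, bins)
    return JointHistogram(
        bins=bins,
        counts=counts,
        marginal_r=counts.sum(axis=1),
        marginal_f=counts.sum(axis=0),
    )


def _entropy_bits(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def entropies(hist: JointHistogram) -> tuple[float, float, float]:
    """Return (H(R), H(F), H(R,F)) in bits."""
    return (
        _entropy_bits(hist.marginal_r),
        _entropy_bits(hist.marginal_f),
        _entropy_bits(hist.counts),
    )


def mutual_information(r, f, bins: int = DEFAULT_BINS) -> float:
    """MI(R,F) = H(R) + H(F) - H(R,F), in bits."""
    hr, hf, hrf = entropies(joint_histogram(r, f, bins))
    return hr + hf - hrf


def normalized_mutual_information(r, f, bins: int = DEFAULT_BINS) -> float:
    """NMI(R,F) = (H(R) + H(F)) / H(R,F); 2 for identical, 1 for independent."""
    hr, hf, hrf = entropies(joint_histogram(r, f, bins))
    if hrf == 0.0:
        raise DegenerateInputError("joint entropy is zero (both images constant)")
    return (hr + hf) / hrf


def normalized_correlation(r, f) -> float:
    """Signed Pearson correlation of the two intensity fields."""
    r = as_gray(r)
    f = as_gray(f)
    check_same_shape(r, f)
    dr = r - r.mean()
    df = f - f.mean()
    denom = np.sqrt((dr * dr).sum() * (df * df).sum())
    if denom == 0.0:
        raise DegenerateInputError("zero intensity variance; NCC undefined")
    return float((dr * df).sum() / denom)


def mean_square_difference(r, f) -> float:
    """Mean over pixels of the squared intensity difference."""
    r = as_gray(r)
    f = as_gray(f)
    check_same_shape(r, f)
    d = r - f
    return float((d * d).mean())


def evaluate_pair(r, f, bins: int = DEFAULT_BINS) -> MetricReport:
    """All four measures of one pair, sharing a single histogram pass."""
    r = as_gray(r)
    f = as_gray(f)
    check_same_shape(r, f)
    hr, hf, hrf = entropies(joint_histogram(r, f, bins))
    if hrf == 0.0:
        raise DegenerateInputError("joint entropy is zero (both images constant)")
    return MetricReport(
        mi=hr + hf - hrf,
        nmi=(hr + hf) / hrf,
        ncc=normalized_correlation(r, f),
        msd=mean_square_difference(r, f),
    )
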