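"""Affine estimation from point correspondences and bicubic warping.

The transform maps floating-image coordinates (x', y') to reference-image
coordinates (x, y):

    [x]   [r00 r01 tx] [x']
    [y] = [r10 r11 ty] [y']
    [1]   [0   0   1 ] [1 ]

Warping uses inverse mapping (each output pixel samples the floating image
at the inverse-transformed position) with Keys bicubic interpolation
(a = -0.5), edge replication inside the support and fill value 0 for
points more than half a pixel outside the source image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .image import as_gray


class EstimationError(ValueError):
    """Affine estimation is impossible (too few / collinear / singular)."""


@dataclass(frozen=True)
class AffineTransform:
    r00: float
    r01: float
    r10: float
    r11: float
    tx: float
    ty: float

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.r00, self.r01, self.tx],
                [self.r10, self.r11, self.ty],
                [0.0, 0.0, 1.0],
            ]
        )

    @property
    def det(self) -> float:
        return self.r00 * self.r11 - self.r01 * self.r10

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(1.0, 0.0, 0.0, 1.0, 0.0, 0.0)

    @classmethod
    def from_matrix(cls, m) -> "AffineTransform":
        m = np.asarray(m, dtype=np.float64)
        return cls(m[0, 0], m[0, 1], m[1, 0], m[1, 1], m[0, 2], m[1, 2])

    @classmethod
    def similarity(cls, rot_deg: float, scale: float, tx: float, ty: float,
                   center: tuple[float, float] = (0.0, 0.0)) -> "AffineTransform":
        """Rotation (degrees, about ``center`` = (cx, cy)) + isotropic scale + translation."""
        th = np.deg2rad(rot_deg)
        a = scale * np.cos(th)
        b = scale * np.sin(th)
        cx, cy = center
        tx_eff = cx - (a * cx - b * cy) + tx
        ty_eff = cy - (b * cx + a * cy) + ty
        return cls(a, -b, b, a, tx_eff, ty_eff)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """``self`` after ``other``: (self @ other)(p) = self(other(p))."""
        return AffineTransform.from_matrix(self.matrix @ other.matrix)

    def params(self) -> np.ndarray:
        return np.array([self.r00, self.r01, self.tx, self.r10, self.r11, self.ty])

    def to_line(self) -> str:
        return " ".join(f"{v:.17g}" for v in self.params())

    @classmethod
    def from_line(cls, line: str) -> "AffineTransform":
        v = [float(tok) for tok in line.split()]
        if len(v) != 6:
            raise ValueError(f"expected 6 numbers, got {len(v)}")
        return cls(v[0], v[1], v[3], v[4], v[2], v[5])

    def to_json(self) -> str:
        return json.dumps(
            {k: getattr(self, k) for k in ("r00", "r01", "tx", "r10", "r11", "ty")}
        )

    @classmethod
    def from_json(cls, text: str) -> "AffineTransform":
        d = json.loads(text)
        return cls(d["r00"], d["r01"], d["r10"], d["r11"], d["tx"], d["ty"])


def apply_transform(t: AffineTransform, points) -> np.ndarray:
    """Apply the forward map to an (N, 2) array of (x, y) points."""
    p = np.atleast_2d(np.asarray(points, dtype=np.float64))
    x = t.r00 * p[:, 0] + t.r01 * p[:, 1] + t.tx
    y = t.r10 * p[:, 0] + t.r11 * p[:, 1] + t.ty
    return np.column_stack([x, y])


def invert(t: AffineTransform) -> AffineTransform:
    d = t.det
    if abs(d) < 1e-12:
        raise EstimationError(f"transform is singular (det={d:.3g})")
    i00, i01 = t.r11 / d, -t.r01 / d
    i10, i11 = -t.r10 / d, t.r00 / d
    return AffineTransform(
        i00, i01, i10, i11, -(i00 * t.tx + i01 * t.ty), -(i10 * t.tx + i11 * t.ty)
    )


def _as_pair_arrays(pairs):
    arr = np.asarray([[p[0], p[1]] for p in pairs], dtype=np.float64)
    if arr.ndim != 3 or arr.shape[1:] != (2, 2):
        raise EstimationError("pairs must be ((x', y'), (x, y)) tuples")
    return arr[:, 0, :], arr[:, 1, :]  # floating, reference


def _lstsq_fit(src: np.ndarray, dst: np.ndarray) -> AffineTransform:
    n = src.shape[0]
    if n < 3:
        raise EstimationError(f"need >= 3 correspondences, got {n}")
    # collinearity check on the source configuration
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise EstimationError("source points are collinear")
    A = np.hstack([src, np.ones((n, 1))])
    cx, *_ = np.linalg.lstsq(A, dst[:, 0], rcond=None)
    cy, *_ = np.linalg.lstsq(A, dst[:, 1], rcond=None)
    return AffineTransform(cx[0], cx[1], cy[0], cy[1], cx[2], cy[2])


def _exact_fit(src: np.ndarray, dst: np.ndarray):
    A = np.hstack([src, np.ones((3, 1))])
    if abs(np.linalg.det(A)) < 1e-9:
        return None
    cx = np.linalg.solve(A, dst[:, 0])
    cy = np.linalg.solve(A, dst[:, 1])
    return AffineTransform(cx[0], cx[1], cy[0], cy[1], cx[2], cy[2])


def estimate_affine(
    pairs,
    method: str = "ransac",
    seed: int = 0,
    n_iterations: int = 500,
    inlier_threshold: float = 2.0,
) -> AffineTransform:
    """Fit the floating-to-reference affine map to point correspondences.

    ``lstsq`` minimizes the summed squared transfer error over all pairs;
    ``ransac`` repeatedly fits seeded minimal 3-point samples, keeps the
    hypothesis with the most inliers (transfer error < ``inlier_threshold``
    px, ties broken by smaller inlier error), then refits least squares on
    the inlier set.
    """
    src, dst = _as_pair_arrays(pairs)
    if method == "lstsq":
        return _lstsq_fit(src, dst)
    if method != "ransac":
        raise ValueError(f"unknown estimator {method!r}")
    n = src.shape[0]
    if n < 3:
        raise EstimationError(f"need >= 3 correspondences, got {n}")
    rng = np.random.default_rng(seed)
    best_mask = None
    best_count = 0
    best_err = np.inf
    for _ in range(n_iterations):
        idx = rng.choice(n, size=3, replace=False)
        t = _exact_fit(src[idx], dst[idx])
        if t is None:
            continue
        pred = apply_transform(t, src)
        err = np.sqrt(((pred - dst) ** 2).sum(axis=1))
        mask = err < inlier_threshold
        count = int(mask.sum())
        total = float(err[mask].sum())
        if count > best_count or (count == best_count and total < best_err):
            best_count, best_err, best_mask = count, total, mask
    if best_mask is None or best_count < 3:
        raise EstimationError("RANSAC found no 3-point consensus")
    return _lstsq_fit(src[best_mask], dst[best_mask])


def _keys_kernel(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    at = np.abs(t)
    out = np.zeros_like(at)
    near = at <= 1.0
    far = (at > 1.0) & (at < 2.0)
    out[near] = (a + 2.0) * at[near] ** 3 - (a + 3.0) * at[near] ** 2 + 1.0
    out[far] = a * at[far] ** 3 - 5.0 * a * at[far] ** 2 + 8.0 * a * at[far] - 4.0 * a
    return out


def bicubic_interpolate(img, points, fill: float = 0.0) -> np.ndarray:
    """Sample ``img`` at (x, y) points with the Keys cubic kernel (a = -0.5).

    The 4x4 neighbourhood uses edge replication; points more than 0.5 px
    outside the image bounds return ``fill``.
    """
    arr = as_gray(img)
    h, w = arr.shape
    p = np.atleast_2d(np.asarray(points, dtype=np.float64))
    x, y = p[:, 0], p[:, 1]
    inside = (x >= -0.5) & (x <= w - 0.5) & (y >= -0.5) & (y <= h - 0.5)
    ix = np.floor(x).astype(np.int64)
    iy = np.floor(y).astype(np.int64)
    fx = x - ix
    fy = y - iy
    out = np.zeros(p.shape[0], dtype=np.float64)
    for m in range(-1, 3):  # row offset
        wy = _keys_kernel(fy - m)
        ry = np.clip(iy + m, 0, h - 1)
        acc = np.zeros_like(out)
        for nn in range(-1, 3):  # col offset
            wx = _keys_kernel(fx - nn)
            cx = np.clip(ix + nn, 0, w - 1)
            acc += wx * arr[ry, cx]
        out += wy * acc
    out[~inside] = fill
    return out


def warp(img, t: AffineTransform, out_shape) -> np.ndarray:
    """Resample ``img`` onto the reference grid defined by ``t`` (inverse mapping)."""
    arr = as_gray(img)
    inv = invert(t)
    rows, cols = int(out_shape[0]), int(out_shape[1])
    xs, ys = np.meshgrid(np.arange(cols, dtype=np.float64),
                         np.arange(rows, dtype=np.float64))
    grid = np.column_stack([xs.ravel(), ys.ravel()])
    src = apply_transform(inv, grid)
    vals = bicubic_interpolate(arr, src)
    return np.clip(vals.reshape(rows, cols), 0.0, 1.0)
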