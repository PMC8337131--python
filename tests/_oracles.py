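"""Independent brute-force oracles used by the tests.

Everything here is deliberately slow, loop-based and written without
reference to the package implementation, so agreement is evidence rather
than tautology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import gaussian_filter


def histogram_loop(r: np.ndarray, f: np.ndarray, bins: int) -> np.ndarray:
    counts = np.zeros((bins, bins), dtype=np.int64)
    for y in range(r.shape[0]):
        for x in range(r.shape[1]):
            i = min(int(r[y, x] * bins), bins - 1)
            j = min(int(f[y, x] * bins), bins - 1)
            counts[i, j] += 1
    return counts


def entropy_loop(counts) -> float:
    total = float(np.sum(counts))
    h = 0.0
    for c in np.ravel(counts):
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h


def mi_loop(r, f, bins) -> float:
    joint = histogram_loop(r, f, bins)
    return (
        entropy_loop(joint.sum(axis=1))
        + entropy_loop(joint.sum(axis=0))
        - entropy_loop(joint)
    )


def nmi_loop(r, f, bins) -> float:
    joint = histogram_loop(r, f, bins)
    return (
        entropy_loop(joint.sum(axis=1)) + entropy_loop(joint.sum(axis=0))
    ) / entropy_loop(joint)


def ncc_loop(r, f) -> float:
    rbar = float(np.mean(r))
    fbar = float(np.mean(f))
    num = den_r = den_f = 0.0
    for y in range(r.shape[0]):
        for x in range(r.shape[1]):
            dr = r[y, x] - rbar
            df = f[y, x] - fbar
            num += dr * df
            den_r += dr * dr
            den_f += df * df
    return num / math.sqrt(den_r * den_f)


def msd_loop(r, f) -> float:
    total = 0.0
    for y in range(r.shape[0]):
        for x in range(r.shape[1]):
            total += (r[y, x] - f[y, x]) ** 2
    return total / r.size


def rect_sum_loop(img, top, left, h, w) -> float:
    total = 0.0
    for y in range(max(top, 0), min(top + h, img.shape[0])):
        for x in range(max(left, 0), min(left + w, img.shape[1])):
            total += img[y, x]
    return total


def gaussian_hessian_argmax(img: np.ndarray, sigmas) -> tuple[int, int]:
    """Spatial argmax of the scale-normalized true-Gaussian det(H), best sigma."""
    best = -np.inf
    best_yx = (0, 0)
    for s in sigmas:
        sm = gaussian_filter(img, s, mode="nearest")
        lxx = np.gradient(np.gradient(sm, axis=1), axis=1)
        lyy = np.gradient(np.gradient(sm, axis=0), axis=0)
        lxy = np.gradient(np.gradient(sm, axis=0), axis=1)
        det = (s**4) * (lxx * lyy - lxy**2)
        idx = np.unravel_index(np.argmax(det), det.shape)
        if det[idx] > best:
            best = det[idx]
            best_yx = idx
    return best_yx


def keys_weight(t: float, a: float = -0.5) -> float:
    t = abs(t)
    if t <= 1:
        return (a + 2) * t**3 - (a + 3) * t**2 + 1
    if t < 2:
        return a * t**3 - 5 * a * t**2 + 8 * a * t - 4 * a
    return 0.0


def bicubic_point_loop(img: np.ndarray, x: float, y: float) -> float:
    h, w = img.shape
    ix, iy = math.floor(x), math.floor(y)
    fx, fy = x - ix, y - iy
    val = 0.0
    for m in range(-1, 3):
        ry = min(max(iy + m, 0), h - 1)
        for n in range(-1, 3):
            cx = min(max(ix + n, 0), w - 1)
            val += keys_weight(fy - m) * keys_weight(fx - n) * img[ry, cx]
    return val


def euclid_loop(a, b) -> float:
    total = 0.0
    for u, v in zip(a, b):
        total += (u - v) ** 2
    return math.sqrt(total)
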