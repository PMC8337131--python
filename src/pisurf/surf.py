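"""SURF keypoint detection and description on integral images.

The detector approximates the scale-normalized Hessian determinant with
box filters evaluated on an integral image, builds a scale space from the
canonical filter-size progression (9, 15, 21, 27; 15, 27, 39, 51; ...,
sigma = 1.2 * size / 9), keeps strict maxima over the 26-point
scale-space neighbourhood, refines them with a single quadratic fit, and
describes each keypoint with the 64-d Haar-wavelet statistics vector
(4x4 subregions of a 20-sigma oriented window, each contributing
sum dx, sum dy, sum |dx|, sum |dy|, normalized to unit length).

All maps are computed at full resolution (no stride subsampling), so the
whole stage is deterministic and exactly testable against loop oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .image import as_gray


class BorderError(ValueError):
    """Keypoint too close to the image border for the requested window."""


class DegenerateDescriptorError(ValueError):
    """Descriptor window carries no gradient energy."""


@dataclass(frozen=True)
class IntegralImage:
    """Cumulative-sum table with an exclusive zero first row/column.

    ``table[y, x]`` is the sum of pixels with row < y and col < x, so any
    axis-aligned rectangle sum costs four lookups.
    """

    table: np.ndarray
    source_shape: tuple[int, int]


@dataclass(frozen=True)
class Keypoint:
    x: float
    y: float
    scale: float
    orientation: float = 0.0
    response: float = 0.0
    sign: int = 1


@dataclass(frozen=True)
class ScaleSpace:
    """Hessian-determinant responses per octave/level, full resolution."""

    octaves: int
    levels_per_octave: int
    maps: list  # maps[o][k]: det-response array, source shape
    traces: list  # traces[o][k]: Dxx+Dyy array (laplacian sign source)
    filter_sizes: list  # filter_sizes[o][k]: odd int
    scales: list  # scales[o][k]: sigma in px
    source_shape: tuple[int, int]


@dataclass(frozen=True)
class DetectorParams:
    """Detector/descriptor settings, canonical SURF defaults."""

    threshold: float = 1e-4
    octaves: int = 4
    levels_per_octave: int = 4
    upright: bool = False
    max_keypoints: int | None = None


def integral_image(img) -> IntegralImage:
    arr = as_gray(img)
    h, w = arr.shape
    table = np.zeros((h + 1, w + 1), dtype=np.float64)
    table[1:, 1:] = arr.cumsum(axis=0).cumsum(axis=1)
    return IntegralImage(table=table, source_shape=(h, w))


def box_sum(ii: IntegralImage, top: int, left: int, h: int, w: int) -> float:
    """Sum of the in-bounds part of the rectangle rows [top, top+h), cols [left, left+w)."""
    if h <= 0 or w <= 0:
        raise ValueError("box height and width must be positive")
    rows, cols = ii.source_shape
    a = min(max(top, 0), rows)
    b = min(max(top + h, 0), rows)
    c = min(max(left, 0), cols)
    d = min(max(left + w, 0), cols)
    if b <= a or d <= c:
        return 0.0
    t = ii.table
    return float(t[b, d] - t[a, d] - t[b, c] + t[a, c])


def _rect_sums(ii: IntegralImage, r0, r1, c0, c1) -> np.ndarray:
    """Vectorized clipped rectangle sums, rows r0..r1 and cols c0..c1 inclusive."""
    rows, cols = ii.source_shape
    a = np.clip(r0, 0, rows)
    b = np.clip(np.asarray(r1) + 1, 0, rows)
    c = np.clip(c0, 0, cols)
    d = np.clip(np.asarray(c1) + 1, 0, cols)
    b = np.maximum(a, b)
    d = np.maximum(c, d)
    t = ii.table
    return t[b, d] - t[a, d] - t[b, c] + t[a, c]


def _shift_box(table: np.ndarray, m: int, h: int, w: int, a: int, b: int, c: int, d: int):
    """Box sums rows y+a..y+b, cols x+c..x+d for all centers y in [m, h-m), x in [m, w-m)."""
    return (
        table[m + b + 1 : h - m + b + 1, m + d + 1 : w - m + d + 1]
        - table[m + a : h - m + a, m + d + 1 : w - m + d + 1]
        - table[m + b + 1 : h - m + b + 1, m + c : w - m + c]
        + table[m + a : h - m + a, m + c : w - m + c]
    )


def hessian_response(
    ii: IntegralImage, filter_size: int, with_trace: bool = False
):
    """Box-filter det(H) map for one filter size; borders where the filter
    does not fit are zero.  Responses are normalized by the filter area."""
    L = int(filter_size)
    if L < 9 or L % 2 == 0 or L % 6 != 3:
        raise ValueError(f"filter size must be odd, >= 9 and = 9 (mod 6); got {L}")
    h, w = ii.source_shape
    det = np.zeros((h, w), dtype=np.float64)
    trace = np.zeros((h, w), dtype=np.float64)
    l = L // 3
    m = (L - 1) // 2
    if h - 2 * m <= 0 or w - 2 * m <= 0:
        return (det, trace) if with_trace else det
    t = ii.table
    half = (l - 1) // 2
    # Dyy: three stacked (l x 2l-1) boxes, middle weighted -2
    top = _shift_box(t, m, h, w, -half - l, -half - 1, -(l - 1), l - 1)
    mid = _shift_box(t, m, h, w, -half, half, -(l - 1), l - 1)
    bot = _shift_box(t, m, h, w, half + 1, half + l, -(l - 1), l - 1)
    dyy = top + bot - 2.0 * mid
    # Dxx: transpose layout
    lef = _shift_box(t, m, h, w, -(l - 1), l - 1, -half - l, -half - 1)
    cen = _shift_box(t, m, h, w, -(l - 1), l - 1, -half, half)
    rig = _shift_box(t, m, h, w, -(l - 1), l - 1, half + 1, half + l)
    dxx = lef + rig - 2.0 * cen
    # Dxy: four l x l boxes offset 1 from the centre axes
    ul = _shift_box(t, m, h, w, -l, -1, -l, -1)
    ur = _shift_box(t, m, h, w, -l, -1, 1, l)
    dl = _shift_box(t, m, h, w, 1, l, -l, -1)
    dr = _shift_box(t, m, h, w, 1, l, 1, l)
    dxy = (ul + dr) - (ur + dl)
    area = float(L * L)
    dxx /= area
    dyy /= area
    dxy /= area
    det[m : h - m, m : w - m] = dxx * dyy - (0.9 * dxy) ** 2
    if with_trace:
        trace[m : h - m, m : w - m] = dxx + dyy
        return det, trace
    return det


def octave_filter_sizes(octave: int, levels: int) -> list[int]:
    """Canonical progression: start 9, 15, 27, 51, ...; step 6 * 2**octave."""
    start = 9 + 6 * (2**octave - 1)
    step = 6 * 2**octave
    return [start + k * step for k in range(levels)]


def build_scale_space(
    ii: IntegralImage, octaves: int = 4, levels_per_octave: int = 4
) -> ScaleSpace:
    if octaves < 1:
        raise ValueError("need at least one octave")
    if levels_per_octave < 3:
        raise ValueError("need >= 3 levels per octave for interior maxima")
    h, w = ii.source_shape
    if min(h, w) < 9:
        raise ValueError(f"image {h}x{w} smaller than the smallest (9 px) filter")
    maps, traces, sizes, sigmas = [], [], [], []
    for o in range(octaves):
        fs = octave_filter_sizes(o, levels_per_octave)
        o_maps, o_traces = [], []
        for L in fs:
            det, tr = hessian_response(ii, L, with_trace=True)
            o_maps.append(det)
            o_traces.append(tr)
        maps.append(o_maps)
        traces.append(o_traces)
        sizes.append(fs)
        sigmas.append([1.2 * L / 9.0 for L in fs])
    return ScaleSpace(
        octaves=octaves,
        levels_per_octave=levels_per_octave,
        maps=maps,
        traces=traces,
        filter_sizes=sizes,
        scales=sigmas,
        source_shape=(h, w),
    )


def _strict_maxima_mask(m0, m1, m2, threshold):
    """Pixels of m1 strictly above threshold and all 26 scale-space neighbours."""
    h, w = m1.shape
    mask = m1 > threshold
    core = m1
    for layer, skip_center in ((m0, False), (m1, True), (m2, False)):
        pad = np.full((h + 2, w + 2), -np.inf)
        pad[1:-1, 1:-1] = layer
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if skip_center and dy == 0 and dx == 0:
                    continue
                mask &= core > pad[1 + dy : h + 1 + dy, 1 + dx : w + 1 + dx]
                if not mask.any():
                    return mask
    return mask


def _refine(m0, m1, m2, y, x):
    """One-step 3-D quadratic refinement; returns (dx, dy, ds, value) or None."""
    gx = 0.5 * (m1[y, x + 1] - m1[y, x - 1])
    gy = 0.5 * (m1[y + 1, x] - m1[y - 1, x])
    gs = 0.5 * (m2[y, x] - m0[y, x])
    hxx = m1[y, x + 1] - 2 * m1[y, x] + m1[y, x - 1]
    hyy = m1[y + 1, x] - 2 * m1[y, x] + m1[y - 1, x]
    hss = m2[y, x] - 2 * m1[y, x] + m0[y, x]
    hxy = 0.25 * (m1[y + 1, x + 1] - m1[y + 1, x - 1] - m1[y - 1, x + 1] + m1[y - 1, x - 1])
    hxs = 0.25 * (m2[y, x + 1] - m2[y, x - 1] - m0[y, x + 1] + m0[y, x - 1])
    hys = 0.25 * (m2[y + 1, x] - m2[y - 1, x] - m0[y + 1, x] + m0[y - 1, x])
    H = np.array([[hxx, hxy, hxs], [hxy, hyy, hys], [hxs, hys, hss]])
    g = np.array([gx, gy, gs])
    try:
        offset = -np.linalg.solve(H, g)
    except np.linalg.LinAlgError:
        return None
    if np.any(np.abs(offset) > 0.5):
        return None
    value = m1[y, x] + 0.5 * float(g @ offset)
    return float(offset[0]), float(offset[1]), float(offset[2]), value


def detect_keypoints(ss: ScaleSpace, threshold: float = 1e-4) -> list[Keypoint]:
    """Strict 26-neighbour maxima above threshold, quadratically refined.

    Plateau points (non-strict maxima) and points whose refinement offset
    exceeds 0.5 in any coordinate are discarded; the sign is the sign of
    the Hessian trace (bright vs dark blob) at the detection point.
    """
    h, w = ss.source_shape
    kps: list[Keypoint] = []
    for o in range(ss.octaves):
        maps = ss.maps[o]
        sizes = ss.filter_sizes[o]
        step = sizes[1] - sizes[0]
        for k in range(1, ss.levels_per_octave - 1):
            m0, m1, m2 = maps[k - 1], maps[k], maps[k + 1]
            mask = _strict_maxima_mask(m0, m1, m2, threshold)
            mask[0, :] = mask[-1, :] = False
            mask[:, 0] = mask[:, -1] = False
            ys, xs = np.nonzero(mask)
            for y, x in zip(ys.tolist(), xs.tolist()):
                ref = _refine(m0, m1, m2, y, x)
                if ref is None:
                    continue
                dx, dy, ds, value = ref
                size = sizes[k] + ds * step
                tr = ss.traces[o][k][y, x]
                kps.append(
                    Keypoint(
                        x=x + dx,
                        y=y + dy,
                        scale=1.2 * size / 9.0,
                        response=value,
                        sign=1 if tr >= 0 else -1,
                    )
                )
    kps.sort(key=lambda p: (-p.response, p.y, p.x))
    return kps


def _haar_xy(ii: IntegralImage, px: np.ndarray, py: np.ndarray, s: int):
    """Haar wavelet responses at integer points (px, py), half-width ``s``.

    ``dx`` = right half minus left half, ``dy`` = lower half minus upper half
    of the 2s x 2s window centred at (px, py); boxes are clipped at the image
    boundary.
    """
    r0, r1 = py - s, py + s - 1
    right = _rect_sums(ii, r0, r1, px, px + s - 1)
    left = _rect_sums(ii, r0, r1, px - s, px - 1)
    c0, c1 = px - s, px + s - 1
    lower = _rect_sums(ii, py, py + s - 1, c0, c1)
    upper = _rect_sums(ii, py - s, py - 1, c0, c1)
    return right - left, lower - upper


_ORI_GRID = None


def _orientation_grid():
    global _ORI_GRID
    if _ORI_GRID is None:
        ij = [(i, j) for j in range(-6, 7) for i in range(-6, 7) if i * i + j * j <= 36]
        arr = np.array(ij, dtype=np.int64)
        w = np.exp(-(arr[:, 0] ** 2 + arr[:, 1] ** 2) / (2.0 * 2.5**2))
        _ORI_GRID = (arr, w)
    return _ORI_GRID


def assign_orientation(ii: IntegralImage, kp: Keypoint) -> Keypoint:
    """Dominant direction of Gaussian-weighted Haar responses in a 6-sigma disk.

    A pi/3 sector slides over the response angles in fixed pi/32 steps; the
    sector whose summed response vector is longest wins, with the smaller
    resulting angle breaking exact ties.  Orientation is in [0, 2pi).
    """
    h, w = ii.source_shape
    s = max(1, int(round(kp.scale)))
    xr, yr = int(round(kp.x)), int(round(kp.y))
    margin = 6 * s + 2 * s
    if xr - margin < 0 or xr + margin >= w or yr - margin < 0 or yr + margin >= h:
        raise BorderError(f"keypoint ({kp.x:.1f},{kp.y:.1f}) scale {kp.scale:.2f} too close to border")
    grid, weights = _orientation_grid()
    px = xr + grid[:, 0] * s
    py = yr + grid[:, 1] * s
    dx, dy = _haar_xy(ii, px, py, 2 * s)
    wx = weights * dx
    wy = weights * dy
    ang = np.mod(np.arctan2(wy, wx), 2 * np.pi)
    starts = np.arange(0, 2 * np.pi, np.pi / 32)
    rel = np.mod(ang[None, :] - starts[:, None], 2 * np.pi)
    inside = rel < np.pi / 3
    sx = inside @ wx
    sy = inside @ wy
    norms = sx * sx + sy * sy
    best = norms.max()
    cand = np.nonzero(norms >= best - 1e-15)[0]
    angles = np.mod(np.arctan2(sy[cand], sx[cand]), 2 * np.pi)
    theta = float(angles.min())
    return replace(kp, orientation=theta)


_DESC_GRID = None


def _descriptor_grid():
    global _DESC_GRID
    if _DESC_GRID is None:
        k = np.arange(20) - 9.5  # sample offsets in units of sigma
        u, v = np.meshgrid(k, k, indexing="ij")  # u: x-offset, v: y-offset
        sub = (np.arange(20) // 5)  # subregion index per axis
        su, sv = np.meshgrid(sub, sub, indexing="ij")
        gw = np.exp(-(u**2 + v**2) / (2.0 * 3.3**2))
        _DESC_GRID = (u.ravel(), v.ravel(), (su * 4 + sv).ravel(), gw.ravel())
    return _DESC_GRID


def compute_descriptor(ii: IntegralImage, kp: Keypoint) -> np.ndarray:
    """64-d SURF descriptor over a 20-sigma window aligned to the orientation."""
    h, w = ii.source_shape
    s = max(1, int(round(kp.scale)))
    margin = 10 * s
    if (
        kp.x - margin < 0
        or kp.x + margin >= w
        or kp.y - margin < 0
        or kp.y + margin >= h
    ):
        raise BorderError(f"keypoint ({kp.x:.1f},{kp.y:.1f}) scale {kp.scale:.2f} too close to border")
    u, v, region, gw = _descriptor_grid()
    ct, st = np.cos(kp.orientation), np.sin(kp.orientation)
    px = np.rint(kp.x + (u * ct - v * st) * s).astype(np.int64)
    py = np.rint(kp.y + (u * st + v * ct) * s).astype(np.int64)
    dx, dy = _haar_xy(ii, px, py, s)
    # rotated samples may overshoot the 10-sigma margin; a clipped Haar box
    # has unequal halves and would break contrast invariance, so drop them
    valid = (px - s >= 0) & (px + s <= w) & (py - s >= 0) & (py + s <= h)
    dx = np.where(valid, dx, 0.0)
    dy = np.where(valid, dy, 0.0)
    # rotate gradients into the keypoint frame
    rx = gw * (dx * ct + dy * st)
    ry = gw * (-dx * st + dy * ct)
    vec = np.zeros(64, dtype=np.float64)
    base = region * 4
    np.add.at(vec, base + 0, rx)
    np.add.at(vec, base + 1, ry)
    np.add.at(vec, base + 2, np.abs(rx))
    np.add.at(vec, base + 3, np.abs(ry))
    norm = float(np.linalg.norm(vec))
    if norm < 1e-12:
        raise DegenerateDescriptorError("descriptor window has no gradient energy")
    return vec / norm


def extract(img, params: DetectorParams = DetectorParams()):
    """Detect, orient and describe keypoints of one image.

    Returns aligned ``(keypoints, descriptors)`` lists ordered by response
    descending then (y, x); keypoints whose orientation/descriptor window
    leaves the image are silently dropped.
    """
    arr = as_gray(img)
    if min(arr.shape) < 40:
        raise ValueError(f"image {arr.shape} too small for feature extraction (need 40x40)")
    ii = integral_image(arr)
    ss = build_scale_space(ii, params.octaves, params.levels_per_octave)
    kps = detect_keypoints(ss, params.threshold)
    if params.max_keypoints is not None:
        kps = kps[: params.max_keypoints]
    out_kps: list[Keypoint] = []
    out_desc: list[np.ndarray] = []
    for kp in kps:
        try:
            oriented = kp if params.upright else assign_orientation(ii, kp)
            desc = compute_descriptor(ii, oriented)
        except (BorderError, DegenerateDescriptorError):
            continue
        out_kps.append(oriented)
        out_desc.append(desc)
    return out_kps, out_desc
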