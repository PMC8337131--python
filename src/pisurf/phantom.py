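"""Brain-slice-like phantom images with known ground-truth misalignment.

The phantom is a head-shaped ellipse with a bright rim, filled with
Gaussian blobs of both polarities and varied width, low-frequency cosine
texture and a little sensor noise — not anatomy, but enough blob/edge
structure for a Hessian-based detector to find dozens of stable features.
Misaligned pairs are produced by warping the phantom with the inverse of
a known similarity transform, so registering floating onto reference
should recover exactly that transform; an optional monotone nonlinear
intensity remap emulates a modality change (geometry preserved, intensity
conservation broken).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transform import AffineTransform, invert, warp


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int] = (181, 217)  # paper-sized MR slice grid
    n_blobs: int = 30
    blob_scale_range: tuple[float, float] = (2.5, 8.0)
    texture_amplitude: float = 0.06
    noise_sigma: float = 0.004
    seed: int = 0


@dataclass(frozen=True)
class GroundTruth:
    transform: AffineTransform
    modality_map: str | None = None


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> np.ndarray:
    """Deterministic phantom image in [0, 1] for a given spec."""
    rows, cols = spec.shape
    if rows < 64 or cols < 64:
        raise ValueError(f"phantom shape must be >= (64, 64), got {spec.shape}")
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    ay, ax = 0.44 * rows, 0.44 * cols
    rho = np.sqrt(((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2)
    inside = 1.0 / (1.0 + np.exp((rho - 1.0) / 0.01))  # soft head envelope
    img = 0.10 + 0.35 * inside
    img += 0.30 * np.exp(-(((rho - 0.93) / 0.035) ** 2))  # skull-like rim

    lo, hi = spec.blob_scale_range
    placed = 0
    while placed < spec.n_blobs:
        by = rng.uniform(0.12 * rows, 0.88 * rows)
        bx = rng.uniform(0.12 * cols, 0.88 * cols)
        if ((by - cy) / ay) ** 2 + ((bx - cx) / ax) ** 2 > 0.72:
            continue
        sigma = rng.uniform(lo, hi)
        amp = rng.uniform(0.25, 0.55) * (1 if rng.random() < 0.5 else -1)
        d2 = (yy - by) ** 2 + (xx - bx) ** 2
        img += amp * np.exp(-d2 / (2.0 * sigma**2))
        placed += 1

    if spec.texture_amplitude > 0:
        tex = np.zeros_like(img)
        for _ in range(4):
            fy = rng.uniform(0.01, 0.04)
            fx = rng.uniform(0.01, 0.04)
            phase = rng.uniform(0, 2 * np.pi)
            tex += np.cos(2 * np.pi * (fy * yy + fx * xx) + phase)
        img += spec.texture_amplitude * tex / 4.0 * inside

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def modality_remap(img: np.ndarray) -> np.ndarray:
    """Monotone nonlinear intensity remap emulating a modality change."""
    return np.clip(0.08 + 0.82 * np.power(np.clip(img, 0.0, 1.0), 0.55), 0.0, 1.0)


def make_pair(
    spec: PhantomSpec = PhantomSpec(),
    rot: float = 0.0,
    tx: float = 0.0,
    ty: float = 0.0,
    scale: float = 1.0,
    multimodal: bool = False,
):
    """A (floating, reference, ground-truth) triple.

    The reference is the phantom; the floating image is the phantom warped
    by the inverse of the ground-truth transform (rotation in degrees about
    the image centre, isotropic scale, translation in px), so registering
    floating onto reference should recover the transform.  ``multimodal``
    additionally remaps the floating intensities.
    """
    if abs(rot) > 45:
        raise ValueError(f"|rotation| must be <= 45 degrees, got {rot}")
    if not 0.5 <= scale <= 2.0:
        raise ValueError(f"scale must be in [0.5, 2], got {scale}")
    reference = make_phantom(spec)
    rows, cols = reference.shape
    center = ((cols - 1) / 2.0, (rows - 1) / 2.0)
    truth = AffineTransform.similarity(rot, scale, tx, ty, center=center)
    floating = warp(reference, invert(truth), reference.shape)
    modality = None
    if multimodal:
        floating = modality_remap(floating)
        modality = "affine-compressed gamma curve: v -> 0.08 + 0.82 * v**0.55"
    return floating, reference, GroundTruth(transform=truth, modality_map=modality)


def control_grid(shape, n: int) -> list[tuple[float, float]]:
    """n x n evenly spaced interior (x, y) control points with a 10% margin."""
    if n < 2:
        raise ValueError("need n >= 2 control points per axis")
    rows, cols = int(shape[0]), int(shape[1])
    xs = np.linspace(0.1 * (cols - 1), 0.9 * (cols - 1), n)
    ys = np.linspace(0.1 * (rows - 1), 0.9 * (rows - 1), n)
    return [(float(x), float(y)) for y in ys for x in xs]
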