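"""Coarse-to-fine progressive-image registration driver.

The floating image F and the reference image R are fused into a chain of
progressive images: M0 = (F + R) / 2, then recursively averaged with R
(default) or F.  In the default ``toward_reference`` mode the chain has
the closed form

    M_l = 2**-(l+1) * F + (1 - 2**-(l+1)) * R,

so higher levels lie ever nearer R while retaining a fading imprint of F.
Registration is two-stage: F is registered to M_l with the SURF pipeline
(coarse), the coarse result is registered to R (fine), and the composed
affine is applied once to the original F, so the output is resampled a
single time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .image import as_gray, check_same_shape
from .matching import match_descriptors, matches_to_points
from .metrics import DEFAULT_BINS, MetricReport, evaluate_pair
from .surf import DetectorParams, extract
from .transform import AffineTransform, apply_transform, estimate_affine, warp

DEFAULT_LEVEL = 7

_METRIC_SENSE = {"mi": 1.0, "nmi": 1.0, "ncc": 1.0, "msd": -1.0}


class RegistrationError(RuntimeError):
    """A registration stage could not produce a transform.

    Carries the failing stage name and keypoint/match diagnostics.
    """

    def __init__(self, stage: str, message: str, diagnostics: dict | None = None):
        super().__init__(f"{stage}: {message}")
        self.stage = stage
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class ProgressiveSequence:
    images: list
    level: int
    recursion_mode: str


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the two-stage driver needs; defaults follow the method."""

    level: int | None = DEFAULT_LEVEL  # None = single-stage (plain SURF) registration
    bins: int = DEFAULT_BINS
    detector: DetectorParams = field(default_factory=DetectorParams)
    ratio_threshold: float = 0.7
    estimator: str = "ransac"
    recursion_mode: str = "toward_reference"
    selection_metric: str = "nmi"
    seed: int = 0


@dataclass(frozen=True)
class RegistrationResult:
    warped: np.ndarray
    coarse_transform: AffineTransform
    fine_transform: AffineTransform
    composed_transform: AffineTransform
    level_used: int | None
    report: MetricReport
    stage_match_counts: tuple[int, int]
    seed: int


@dataclass(frozen=True)
class EvaluationRecord:
    report: MetricReport
    mean_tre: float | None
    max_tre: float | None


def average_images(f, r) -> np.ndarray:
    """Pixelwise mean of the floating and reference images."""
    f = as_gray(f)
    r = as_gray(r)
    check_same_shape(f, r)
    return 0.5 * (f + r)


def generate_progressive(f, r, level: int, mode: str = "toward_reference") -> ProgressiveSequence:
    """Build the chain M0..M_level by recursive averaging."""
    if level < 0:
        raise ValueError(f"level must be >= 0, got {level}")
    if mode not in ("toward_reference", "toward_floating"):
        raise ValueError(f"unknown recursion mode {mode!r}")
    f = as_gray(f)
    r = as_gray(r)
    check_same_shape(f, r)
    anchor = r if mode == "toward_reference" else f
    images = [average_images(f, r)]
    for _ in range(level):
        images.append(average_images(images[-1], anchor))
    return ProgressiveSequence(images=images, level=level, recursion_mode=mode)


def register_stage(float_img, target_img, cfg: PipelineConfig, stage: str = "stage",
                   seed: int | None = None):
    """Extract, match, estimate and warp one stage.

    Returns ``(transform, warped, match_count)`` with the transform mapping
    floating coordinates into the target frame.
    """
    float_img = as_gray(float_img)
    target_img = as_gray(target_img)
    try:
        kps_f, desc_f = extract(float_img, cfg.detector)
        kps_t, desc_t = extract(target_img, cfg.detector)
    except ValueError as exc:
        raise RegistrationError(stage, str(exc))
    matches = match_descriptors(desc_f, desc_t, cfg.ratio_threshold)
    diag = {
        "keypoints_float": len(kps_f),
        "keypoints_target": len(kps_t),
        "matches": len(matches),
    }
    if len(matches) < 3:
        raise RegistrationError(stage, f"only {len(matches)} matches (need >= 3)", diag)
    pairs = matches_to_points(matches, kps_f, kps_t)
    try:
        t = estimate_affine(
            pairs,
            method=cfg.estimator,
            seed=cfg.seed if seed is None else seed,
        )
    except Exception as exc:
        raise RegistrationError(stage, f"affine estimation failed: {exc}", diag)
    if abs(t.det) < 1e-6:
        raise RegistrationError(stage, f"estimated transform is degenerate (det={t.det:.3g})", diag)
    warped = warp(float_img, t, target_img.shape)
    return t, warped, len(matches)


def _conform(f: np.ndarray, r: np.ndarray) -> np.ndarray:
    if f.shape == r.shape:
        return f
    from skimage.transform import resize

    return resize(f, r.shape, order=3, anti_aliasing=True, preserve_range=True)


def register(f, r, cfg: PipelineConfig = PipelineConfig()) -> RegistrationResult:
    """Full coarse-to-fine registration of floating F onto reference R.

    With ``cfg.level=None`` the progressive mechanism is disabled and a
    single direct F -> R stage is run (the plain SURF baseline).
    """
    f = as_gray(f)
    r = as_gray(r)
    f = _conform(f, r)
    if cfg.level is None:
        t, warped, n = register_stage(f, r, cfg, stage="direct", seed=cfg.seed)
        return RegistrationResult(
            warped=warped,
            coarse_transform=t,
            fine_transform=AffineTransform.identity(),
            composed_transform=t,
            level_used=None,
            report=evaluate_pair(r, warped, cfg.bins),
            stage_match_counts=(n, 0),
            seed=cfg.seed,
        )
    seq = generate_progressive(f, r, cfg.level, cfg.recursion_mode)
    target = seq.images[-1]
    t_coarse, warped_coarse, n_coarse = register_stage(
        f, target, cfg, stage="coarse", seed=cfg.seed
    )
    t_fine, _, n_fine = register_stage(
        warped_coarse, r, cfg, stage="fine", seed=cfg.seed + 1
    )
    composed = t_fine.compose(t_coarse)
    warped = warp(f, composed, r.shape)  # single resampling of the original F
    return RegistrationResult(
        warped=warped,
        coarse_transform=t_coarse,
        fine_transform=t_fine,
        composed_transform=composed,
        level_used=cfg.level,
        report=evaluate_pair(r, warped, cfg.bins),
        stage_match_counts=(n_coarse, n_fine),
        seed=cfg.seed,
    )


def select_level(f, r, max_level: int, cfg: PipelineConfig = PipelineConfig()):
    """Run the pipeline at every level 0..max_level and pick the best.

    Returns ``(best_level, reports)`` where ``reports[l]`` is the
    MetricReport of level ``l`` or None if that level failed; the best
    level maximizes mi/nmi/ncc or minimizes msd per the config.
    """
    if max_level < 0:
        raise ValueError("max_level must be >= 0")
    metric = cfg.selection_metric
    if metric not in _METRIC_SENSE:
        raise ValueError(f"unknown selection metric {metric!r}")
    sense = _METRIC_SENSE[metric]
    reports: list[MetricReport | None] = []
    best_level = None
    best_score = -np.inf
    for level in range(max_level + 1):
        try:
            res = register(f, r, replace(cfg, level=level))
        except RegistrationError:
            reports.append(None)
            continue
        reports.append(res.report)
        score = sense * getattr(res.report, metric)
        if score > best_score:
            best_score = score
            best_level = level
    if best_level is None:
        raise RegistrationError("sweep", "registration failed at every level")
    return best_level, reports


def evaluate_registration(
    result: RegistrationResult,
    r,
    truth: AffineTransform | None = None,
    grid_n: int = 10,
) -> EvaluationRecord:
    """Similarity metrics vs R, plus target registration error when the
    ground-truth transform is known.

    TRE compares the recovered and true maps on an interior control grid of
    the floating frame: ``|T_est(p) - T_true(p)|`` per control point.
    """
    from .phantom import control_grid

    r = as_gray(r)
    check_same_shape(r, result.warped)
    report = evaluate_pair(r, result.warped)
    if truth is None:
        return EvaluationRecord(report=report, mean_tre=None, max_tre=None)
    pts = np.asarray(control_grid(r.shape, grid_n))
    est = apply_transform(result.composed_transform, pts)
    ref = apply_transform(truth, pts)
    d = np.sqrt(((est - ref) ** 2).sum(axis=1))
    return EvaluationRecord(report=report, mean_tre=float(d.mean()), max_tre=float(d.max()))
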