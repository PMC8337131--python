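"""Model/Results surface over the coarse-to-fine registration pipeline.

``ProgressiveRegistration`` holds the data (floating and reference image)
and configuration; ``fit`` runs the two-stage registration and returns a
``RegistrationResults`` object carrying the estimated affine parameters,
approximate standard errors from the fine-stage correspondence residuals,
similarity diagnostics and a ``summary()`` table, with simulation
(``fit_sweep``) and plotting hanging off the two objects.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .image import normalize
from .matching import match_descriptors, matches_to_points
from .pipeline import (
    PipelineConfig,
    RegistrationResult,
    evaluate_registration,
    register,
    select_level,
)
from .surf import DetectorParams, extract
from .transform import AffineTransform, apply_transform

_PARAM_NAMES = ("r00", "r01", "tx", "r10", "r11", "ty")


class ProgressiveRegistration:
    """Two-stage progressive-image registration model for one image pair.

    Parameters
    ----------
    floating, reference : 2-D arrays
        The image to be moved and the fixed image; intensities are min-max
        normalized to [0, 1] on construction.
    level : int or None
        Progressive-image level l (the coarse target is M_l); ``None``
        disables the mechanism and fits a single direct SURF stage.
    """

    def __init__(
        self,
        floating,
        reference,
        level: int | None = 7,
        bins: int = 64,
        ratio_threshold: float = 0.7,
        estimator: str = "ransac",
        detector: DetectorParams | None = None,
        recursion_mode: str = "toward_reference",
        selection_metric: str = "nmi",
    ):
        self.floating = normalize(floating)
        self.reference = normalize(reference)
        self.config = PipelineConfig(
            level=level,
            bins=bins,
            detector=detector or DetectorParams(),
            ratio_threshold=ratio_threshold,
            estimator=estimator,
            recursion_mode=recursion_mode,
            selection_metric=selection_metric,
        )

    @classmethod
    def from_files(cls, floating_path, reference_path, **kwargs):
        from .io import read_image

        return cls(read_image(floating_path), read_image(reference_path), **kwargs)

    def fit(self, seed: int = 0) -> "RegistrationResults":
        cfg = replace(self.config, seed=seed)
        result = register(self.floating, self.reference, cfg)
        return RegistrationResults(self, result)

    def fit_sweep(self, max_level: int = 9, seed: int = 0):
        """Fit at every level 0..max_level; returns (best_level, reports)."""
        cfg = replace(self.config, seed=seed)
        return select_level(self.floating, self.reference, max_level, cfg)


class RegistrationResults:
    """Fitted registration: estimates, uncertainties, diagnostics."""

    def __init__(self, model: ProgressiveRegistration, result: RegistrationResult):
        self.model = model
        self.result = result
        self.params = result.composed_transform.params()
        self.bse = self._standard_errors()

    @property
    def transform(self) -> AffineTransform:
        return self.result.composed_transform

    @property
    def warped(self):
        return self.result.warped

    @property
    def metrics(self):
        return self.result.report

    @property
    def match_counts(self):
        return self.result.stage_match_counts

    def _standard_errors(self) -> np.ndarray:
        """Approximate parameter standard errors.

        Re-derives the final correspondence set (warped floating vs
        reference features) and propagates its residual variance through
        the least-squares design, sigma^2 (A^T A)^-1; NaN when too few
        correspondences survive.
        """
        cfg = self.model.config
        try:
            kf, df = extract(self.warped, cfg.detector)
            kr, dr = extract(self.model.reference, cfg.detector)
            matches = match_descriptors(df, dr, cfg.ratio_threshold)
            pairs = matches_to_points(matches, kf, kr)
        except ValueError:
            return np.full(6, np.nan)
        if len(pairs) < 4:
            return np.full(6, np.nan)
        src = np.array([p[0] for p in pairs])
        dst = np.array([p[1] for p in pairs])
        # residuals of the identity fit on the already-registered pair
        A = np.hstack([src, np.ones((len(src), 1))])
        se = np.full(6, np.nan)
        try:
            ata_inv = np.linalg.inv(A.T @ A)
        except np.linalg.LinAlgError:
            return se
        for axis, sl in ((0, slice(0, 3)), (1, slice(3, 6))):
            coef, *_ = np.linalg.lstsq(A, dst[:, axis], rcond=None)
            resid = dst[:, axis] - A @ coef
            dof = max(len(src) - 3, 1)
            s2 = float(resid @ resid) / dof
            se[sl] = np.sqrt(s2 * np.diag(ata_inv))
        return se

    def tre(self, truth: AffineTransform, grid_n: int = 10):
        """Mean/max target registration error against a known transform."""
        rec = evaluate_registration(self.result, self.model.reference, truth, grid_n)
        return rec.mean_tre, rec.max_tre

    def predict(self, points):
        """Map floating-frame (x, y) points into the reference frame."""
        return apply_transform(self.transform, points)

    def summary(self) -> str:
        r = self.result
        lines = [
            "Progressive-image SURF registration results",
            "=" * 47,
            f"level used:        {r.level_used if r.level_used is not None else 'none (direct SURF)'}",
            f"matches (coarse):  {r.stage_match_counts[0]}",
            f"matches (fine):    {r.stage_match_counts[1]}",
            f"seed:              {r.seed}",
            "",
            f"{'param':>6} {'estimate':>12} {'std err':>10}",
            "-" * 31,
        ]
        for name, val, se in zip(_PARAM_NAMES, self.params, self.bse):
            se_txt = f"{se:10.4f}" if np.isfinite(se) else "       n/a"
            lines.append(f"{name:>6} {val:12.6f} {se_txt}")
        m = r.report
        lines += [
            "",
            "similarity vs reference",
            "-" * 31,
            f"MI  (bits):  {m.mi:.4f}",
            f"NMI:         {m.nmi:.4f}",
            f"NCC:         {m.ncc:.4f}",
            f"MSD:         {m.msd:.6f}",
        ]
        return "\n".join(lines)

    def plot(self, axes=None):
        """Reference / warped / absolute-difference panel figure."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 3, figsize=(12, 4))
        panels = [
            (self.model.reference, "reference"),
            (self.warped, "warped floating"),
            (np.abs(self.model.reference - self.warped), "absolute difference"),
        ]
        for ax, (img, title) in zip(axes, panels):
            ax.imshow(img, cmap="gray", vmin=0, vmax=1)
            ax.set_title(title)
            ax.axis("off")
        return axes
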