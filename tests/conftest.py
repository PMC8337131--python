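"""Shared fixtures: seeded images, phantoms and the end-to-end suites.

The registration study conditions (40 pairs, |rot| <= 10 deg, |t| <= 15 px,
scale in [0.9, 1.1], phantom defaults) are fixed here once; the heavy
suites are session-scoped and only computed when a test requests them.
"""

from __future__ import annotations

import numpy as np
import pytest

import pisurf as ps

SUITE_SEED = 20250929
N_PAIRS = 40


def random_image(seed: int, shape=(16, 16), levels: int | None = None) -> np.ndarray:
    """Seeded image in [0, 1]; with ``levels`` the values are k/levels
    (dyadic for powers of two, so cumulative sums are exact in float64)."""
    rng = np.random.default_rng(seed)
    if levels is None:
        return rng.random(shape)
    return rng.integers(0, levels + 1, size=shape) / levels


def blob_image(centers, sigmas, amps=None, shape=(96, 96)) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    img = np.zeros(shape)
    amps = amps or [0.9] * len(centers)
    for (cy, cx), s, a in zip(centers, sigmas, amps):
        img += a * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * s**2)))
    return np.clip(img, 0.0, 1.0)


@pytest.fixture(scope="session")
def phantom():
    return ps.make_phantom(ps.PhantomSpec(seed=11))


def draw_pair_params(rng):
    return dict(
        rot=rng.uniform(-10, 10),
        tx=rng.uniform(-15, 15),
        ty=rng.uniform(-15, 15),
        scale=rng.uniform(0.9, 1.1),
    )


def run_suite(multimodal: bool, level: int | None = 7, n_pairs: int = N_PAIRS):
    """Register ``n_pairs`` seeded phantom pairs; returns per-pair records."""
    rng = np.random.default_rng(SUITE_SEED)
    records = []
    for i in range(n_pairs):
        params = draw_pair_params(rng)
        f, r, gt = ps.make_pair(ps.PhantomSpec(seed=i), multimodal=multimodal, **params)
        rec = {"params": params, "initial": ps.evaluate_pair(r, f)}
        try:
            res = ps.ProgressiveRegistration(f, r, level=level).fit(seed=i)
            mean_tre, max_tre = res.tre(gt.transform)
            rec.update(
                ok=True,
                mean_tre=mean_tre,
                max_tre=max_tre,
                report=res.metrics,
                truth=gt.transform,
                transform=res.transform,
            )
        except ps.RegistrationError as exc:
            rec.update(ok=False, error=str(exc))
        records.append(rec)
    return records


@pytest.fixture(scope="session")
def unimodal_suite():
    return run_suite(multimodal=False)


@pytest.fixture(scope="session")
def multimodal_suite():
    return run_suite(multimodal=True)


@pytest.fixture(scope="session")
def single_stage_suite():
    return run_suite(multimodal=False, level=None)
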