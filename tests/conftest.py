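"""Shared fixtures: reference study conditions and expensive cached fits.

The reference tree emulates a maritime-pine-like conifer: two growth cycles
per year, needles retained ~2.5 years (l_g = 5 cycles), moderate carrying
capacity, kappa below one so the trunk sheds pipe area at each ramification,
and distinct sapwood/heartwood pipe areas (c_S > c_H).
"""

import warnings

import numpy as np
import pytest

from trunkmodel import (
    CalibrationSettings,
    GrowthParams,
    TreeMetadata,
    TrunkParams,
    calibrate,
    pipe_model_baseline,
    predict,
    r_squared,
    synthesize_profile,
)


@pytest.fixture(scope="session")
def ref_gp() -> GrowthParams:
    return GrowthParams(alpha=2.0, d=1.6, mu=1.8, l_g=5)


@pytest.fixture(scope="session")
def ref_tp() -> TrunkParams:
    return TrunkParams(kappa=0.85, c_S=0.6, c_H=0.45)


@pytest.fixture(scope="session")
def ref_meta() -> TreeMetadata:
    # 25-year tree, 20 m tall: n = 50 growth cycles, 0.4 m modules.
    return TreeMetadata(age_years=25.0, height=20.0, cycles_per_year=2)


@pytest.fixture(scope="session")
def ref_meta_conspecific() -> TreeMetadata:
    # A younger, shorter conspecific: n = 40, used for cross-validation.
    return TreeMetadata(age_years=20.0, height=17.0, cycles_per_year=2)


@pytest.fixture(scope="session")
def noiseless_profile(ref_gp, ref_tp, ref_meta):
    return synthesize_profile(ref_gp, ref_tp, ref_meta, n_heights=12, noise_sigma=0.0)


@pytest.fixture(scope="session")
def noiseless_cal(noiseless_profile, ref_meta, ref_gp):
    """One full-budget calibration on exact model output, reused across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return calibrate(noiseless_profile, ref_meta, l_g=ref_gp.l_g)


@pytest.fixture(scope="session")
def noisy_study(ref_gp, ref_tp, ref_meta, ref_meta_conspecific):
    """20-seed study: 5 % lognormal noise, fit, cross-validate, baseline.

    Returns per-seed trunk-total R2 for the trunk model and the pipe-model
    baseline, the baseline's topmost residual against the noiseless truth,
    and the cross-validation R2 on a second synthetic tree.
    """
    truth = synthesize_profile(ref_gp, ref_tp, ref_meta, n_heights=12, noise_sigma=0.0)
    truth2 = synthesize_profile(
        ref_gp, ref_tp, ref_meta_conspecific, n_heights=12, noise_sigma=0.0
    )
    out = {"r2_trunk": [], "r2_baseline": [], "top_residual": [], "r2_crossval": []}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(20):
            prof = synthesize_profile(
                ref_gp, ref_tp, ref_meta, n_heights=12, noise_sigma=0.05, seed=seed
            )
            cal = calibrate(prof, ref_meta, l_g=ref_gp.l_g)
            out["r2_trunk"].append(cal.r2["total"])
            base = pipe_model_baseline(prof, cal.growth, ref_meta)
            out["r2_baseline"].append(r_squared(prof.total_areas, base.total_areas))
            out["top_residual"].append(base.total_areas[-1] - truth.total_areas[-1])
            pred = predict(cal, ref_meta_conspecific, truth2.heights)
            out["r2_crossval"].append(r_squared(truth2.total_areas, pred.total_areas))
    return {k: np.asarray(v) for k, v in out.items()}


@pytest.fixture
def quick_settings() -> CalibrationSettings:
    """Reduced search budget for tests that exercise plumbing, not fit quality."""
    return CalibrationSettings(max_iter=80, random_restarts=1, seed=0)


def draw_growth_params(rng: np.random.Generator, n: int, geometric: bool = False) -> GrowthParams:
    """Random parameters; ``geometric=True`` keeps growth below capacity through n."""
    mu = float(rng.uniform(1.3 if geometric else 1.2, 2.0 if geometric else 2.2))
    d = float(rng.uniform(0.8, 1.8))
    l_g = int(rng.integers(0, 5))
    if geometric:
        # capacity far above even unluckily large realised paths: mu**m with
        # an order-of-magnitude headroom stays below alpha*(m+1)**d for m <= n
        alpha_min = max(1.0, max(mu ** m / (m + 1) ** d for m in range(1, n + 1)))
        alpha = float(alpha_min * rng.uniform(10.0, 100.0))
    else:
        alpha = float(rng.uniform(1.0, 2.5))
    return GrowthParams(alpha=alpha, d=d, mu=mu, l_g=l_g)
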