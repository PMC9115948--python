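"""Shared fixtures: a compact single-mediator model and calibrated cohorts.

The compact model (one observed exposure, one latent mediator with three
indicators, one latent outcome with three indicators) is cheap enough to
refit hundreds of times, so bootstrap and calibration studies use it; the
full pathway model is exercised on calibrated synthetic cohorts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from latentmed.sem import SEMSpec

#: ground truth of the compact mediation model
MEDIATION_TRUTH = {
    "a": 0.4,      # M ~ x
    "b": 0.5,      # Y ~ M
    "c": 0.2,      # Y ~ x (direct)
    "loadings_m": (1.0, 0.8, 0.7),
    "loadings_y": (1.0, 0.9, 0.6),
    "resid_ind": 0.5,
    "resid_m": 0.84,   # 1 - a^2
    "resid_y": 0.6,
}


def make_mediation_data(
    n: int, seed: int, mcar: float = 0.0, truth: dict | None = None
) -> pd.DataFrame:
    """Simulate the compact mediation system by explicit recursion."""
    t = dict(MEDIATION_TRUTH)
    if truth:
        t.update(truth)
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    M = t["a"] * x + np.sqrt(t["resid_m"]) * rng.standard_normal(n)
    Y = t["b"] * M + t["c"] * x + np.sqrt(t["resid_y"]) * rng.standard_normal(n)
    cols = {"x": x}
    for j, lam in enumerate(t["loadings_m"], start=1):
        cols[f"m{j}"] = lam * M + np.sqrt(t["resid_ind"]) * rng.standard_normal(n)
    for j, lam in enumerate(t["loadings_y"], start=1):
        cols[f"y{j}"] = lam * Y + np.sqrt(t["resid_ind"]) * rng.standard_normal(n)
    data = pd.DataFrame(cols)
    if mcar > 0:
        mask = rng.random(data.shape) < mcar
        # never blank a full row: keep x observed
        mask[:, 0] = False
        data = data.mask(mask)
    return data


def mediation_spec() -> SEMSpec:
    return SEMSpec(
        latents={"M": ["m1", "m2", "m3"], "Y": ["y1", "y2", "y3"]},
        regressions={"M": ["x"], "Y": ["M", "x"]},
    )


@pytest.fixture(scope="session")
def mediation_data():
    return make_mediation_data(n=800, seed=421)


@pytest.fixture(scope="session")
def mediation_fit(mediation_data):
    from latentmed.sem import fit_sem, standardize_solution

    fit = fit_sem(mediation_spec(), mediation_data)
    standardize_solution(fit)
    return fit


@pytest.fixture(scope="session")
def analysis_cohort():
    """Calibrated analysis-scale cohort with true traits as exposures."""
    from latentmed.synthetic import default_config, simulate_cohort

    cfg = default_config(n_participants=2000, seed=11)
    return simulate_cohort(cfg, scale="analysis")


@pytest.fixture(scope="session")
def pathway_fit(analysis_cohort):
    from latentmed.sem import default_pathway_spec, fit_sem, standardize_solution

    fit = fit_sem(default_pathway_spec(), analysis_cohort.data)
    standardize_solution(fit)
    return fit
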