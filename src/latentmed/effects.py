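"""Direct, indirect and total effects with delta-method standard errors.

For an exposure X, mediator M and outcome Y in a fitted structural model,
the indirect effect through M is the product of the two constituent paths,
``a = M ~ X`` and ``b = Y ~ M``:

.. math::

    \\beta_{ind} = a b, \\qquad
    \\mathrm{SE}^2 = b^2 V_{aa} + a^2 V_{bb} + 2ab\\,V_{ab},

with V the covariance of the estimates (first-order delta method).  The
total effect is the direct path plus the sum of all indirect channels, with
the delta-method gradient ``(1, b_1, a_1, b_2, a_2, ...)`` against the joint
estimate covariance.  By default everything is computed on the standardized
solution, mirroring how such decompositions are reported; the raw scale is
available via ``standardized=False``.

Confidence intervals are normal-approximation ``beta +/- z * SE`` and
p-values two-sided normal.  A parametric bootstrap (refitting simulated
replicates) and a faster Monte-Carlo-over-estimates variant are provided as
checks on the delta approximation, which is known to be slightly
anticonservative for products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sem import SEMFit, fit_sem, standardize_solution

__all__ = [
    "EffectEstimate",
    "indirect_effect",
    "direct_effect",
    "total_effect",
    "effect_table",
    "mediator_residual_correlations",
    "bootstrap_indirect_se",
]


@dataclass(frozen=True)
class EffectEstimate:
    """One row of a mediation decomposition."""

    exposure: str
    outcome: str
    channel: str        # "direct", "total", or the mediator's name
    beta: float
    se: float
    ci_lower: float
    ci_upper: float
    p: float

    def as_dict(self) -> dict:
        return {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "channel": self.channel,
            "beta": self.beta,
            "se": self.se,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "p": self.p,
        }


def _estimates(fit: SEMFit, standardized: bool):
    if standardized:
        if fit.std_theta is None:
            standardize_solution(fit)
        return fit.std_theta, fit.std_cov
    return fit.theta, fit.cov


def _wrap(exposure, outcome, channel, beta, var, ci_level) -> EffectEstimate:
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    zstat = beta / se if se > 0 else np.nan
    return EffectEstimate(
        exposure=exposure,
        outcome=outcome,
        channel=channel,
        beta=float(beta),
        se=se,
        ci_lower=float(beta - z * se),
        ci_upper=float(beta + z * se),
        p=float(2.0 * stats.norm.sf(abs(zstat))) if se > 0 else np.nan,
    )


def direct_effect(
    fit: SEMFit, exposure: str, outcome: str, *,
    standardized: bool = True, ci_level: float = 0.95,
) -> EffectEstimate:
    """The direct path ``outcome ~ exposure`` as an effect row."""
    est, cov = _estimates(fit, standardized)
    k = fit.lookup(outcome, "~", exposure)
    return _wrap(exposure, outcome, "direct", est[k], cov[k, k], ci_level)


def indirect_effect(
    fit: SEMFit, exposure: str, mediator: str, outcome: str, *,
    standardized: bool = True, ci_level: float = 0.95,
) -> EffectEstimate:
    """Product-of-paths indirect effect with its delta-method SE.

    Requires both constituent paths ``mediator ~ exposure`` and
    ``outcome ~ mediator`` to be free parameters of the fitted model.
    """
    est, cov = _estimates(fit, standardized)
    try:
        ka = fit.lookup(mediator, "~", exposure)
    except KeyError as err:
        raise KeyError(f"no path {mediator!r} ~ {exposure!r} in the model") from err
    try:
        kb = fit.lookup(outcome, "~", mediator)
    except KeyError as err:
        raise KeyError(f"no path {outcome!r} ~ {mediator!r} in the model") from err
    a, b = est[ka], est[kb]
    var = (
        b * b * cov[ka, ka]
        + a * a * cov[kb, kb]
        + 2.0 * a * b * cov[ka, kb]
    )
    return _wrap(exposure, outcome, mediator, a * b, var, ci_level)


def total_effect(
    fit: SEMFit, exposure: str, outcome: str, mediators: list[str] | None = None, *,
    standardized: bool = True, ci_level: float = 0.95,
) -> EffectEstimate:
    """Direct plus all indirect channels, delta-method SE on the sum.

    ``mediators`` defaults to every latent with both constituent paths
    present in the model.
    """
    est, cov = _estimates(fit, standardized)
    if mediators is None:
        mediators = _infer_mediators(fit, exposure, outcome)
    kd = fit.lookup(outcome, "~", exposure)
    idx = [kd]
    grad = [1.0]
    beta = est[kd]
    for med in mediators:
        ka = fit.lookup(med, "~", exposure)
        kb = fit.lookup(outcome, "~", med)
        a, b = est[ka], est[kb]
        beta += a * b
        idx.extend([ka, kb])
        grad.extend([b, a])
    g = np.asarray(grad)
    V = cov[np.ix_(idx, idx)]
    return _wrap(exposure, outcome, "total", beta, float(g @ V @ g), ci_level)


def _infer_mediators(fit: SEMFit, exposure: str, outcome: str) -> list[str]:
    meds = []
    for lat in fit.model.spec.latents:
        if lat == outcome:
            continue
        preds_m = fit.model.spec.regressions.get(lat, [])
        preds_y = fit.model.spec.regressions.get(outcome, [])
        if exposure in preds_m and lat in preds_y:
            meds.append(lat)
    return meds


def mediator_residual_correlations(
    fit: SEMFit, *, ci_level: float = 0.95
) -> pd.DataFrame:
    """Residual correlations among the latents with free residual covariances.

    ``r = psi_ij / sqrt(psi_ii psi_jj)`` with the delta-method SE from the
    raw estimate covariance (the ratio is scale-invariant, so raw and
    standardized solutions agree).
    """
    rows = []
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    for a, b in fit.model.spec.covariances:
        kab = fit.lookup(a, "~~", b)
        kaa = fit.lookup(a, "~~", a)
        kbb = fit.lookup(b, "~~", b)
        s_ab, s_aa, s_bb = fit.theta[kab], fit.theta[kaa], fit.theta[kbb]
        r = s_ab / np.sqrt(s_aa * s_bb)
        grad = np.array(
            [1.0 / np.sqrt(s_aa * s_bb), -r / (2.0 * s_aa), -r / (2.0 * s_bb)]
        )
        idx = [kab, kaa, kbb]
        var = float(grad @ fit.cov[np.ix_(idx, idx)] @ grad)
        se = float(np.sqrt(max(var, 0.0)))
        rows.append(
            {
                "var_a": a,
                "var_b": b,
                "r": float(r),
                "se": se,
                "ci_lower": float(r - z * se),
                "ci_upper": float(r + z * se),
                "p": float(2.0 * stats.norm.sf(abs(r / se))) if se > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def effect_table(
    fit: SEMFit,
    exposures: list[str] | None = None,
    outcome: str = "Cognition",
    mediators: list[str] | None = None,
    *,
    standardized: bool = True,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Full mediation decomposition: every exposure/covariate against every
    direct target, indirect channel and the total effect on the outcome.

    ``exposures`` defaults to all predictors of the outcome that are not
    latents (the observed exposures and covariates).  Mediator residual
    correlations are obtainable separately via
    :func:`mediator_residual_correlations`.
    """
    spec = fit.model.spec
    if mediators is None:
        mediators = [lat for lat in spec.latents if lat != outcome]
    if exposures is None:
        exposures = [
            p for p in spec.regressions.get(outcome, []) if p not in spec.latents
        ]
    rows = []
    for exp in exposures:
        for med in mediators:
            rows.append(
                direct_effect(
                    fit, exp, med, standardized=standardized, ci_level=ci_level
                ).as_dict()
            )
        rows.append(
            direct_effect(
                fit, exp, outcome, standardized=standardized, ci_level=ci_level
            ).as_dict()
        )
        for med in mediators:
            rows.append(
                indirect_effect(
                    fit, exp, med, outcome,
                    standardized=standardized, ci_level=ci_level,
                ).as_dict()
            )
        rows.append(
            total_effect(
                fit, exp, outcome, mediators,
                standardized=standardized, ci_level=ci_level,
            ).as_dict()
        )
    return pd.DataFrame(rows)


def effect_table_to_json(table: pd.DataFrame) -> dict:
    """Re-key an effect table as ``{"exposure:channel": {...}}`` for export."""
    out = {}
    for _, row in table.iterrows():
        out[f"{row.exposure}:{row.channel}" + (
            f":{row.outcome}" if row.channel == "direct" else ""
        )] = {
            "beta": float(row.beta),
            "se": float(row.se),
            "ci": [float(row.ci_lower), float(row.ci_upper)],
            "p": float(row.p),
        }
    return out


def bootstrap_indirect_se(
    fit: SEMFit,
    exposure: str,
    mediator: str,
    outcome: str,
    *,
    n_replicates: int = 1000,
    seed: int = 0,
    method: str = "refit",
    standardized: bool = True,
) -> float:
    """Bootstrap SE of an indirect effect, as a check on the delta method.

    ``method="refit"`` is the parametric bootstrap proper: complete data are
    simulated from the fitted model's implied moments, the model is refitted
    and the indirect effect recomputed per replicate.  ``method="mc"`` skips
    refitting and propagates draws of the two path estimates from their
    joint normal sampling distribution (the Monte-Carlo confidence-interval
    method for products).
    """
    rng = np.random.default_rng(seed)
    if method == "mc":
        est, cov = _estimates(fit, standardized)
        ka = fit.lookup(mediator, "~", exposure)
        kb = fit.lookup(outcome, "~", mediator)
        idx = [ka, kb]
        draws = rng.multivariate_normal(est[idx], cov[np.ix_(idx, idx)], n_replicates)
        return float(np.std(draws[:, 0] * draws[:, 1], ddof=1))
    if method != "refit":
        raise ValueError("method must be 'refit' or 'mc'")

    mu, sigma = fit.model.implied(fit.theta)
    cols = fit.model.spec.observed
    vals = np.empty(n_replicates)
    kept = 0
    for r in range(n_replicates):
        X = rng.multivariate_normal(mu, sigma, fit.n_obs)
        data = pd.DataFrame(X, columns=cols)
        refit = fit_sem(
            fit.model.spec,
            data,
            compute_indices=False,
            compute_se=False,
            n_restarts=1,
        )
        if not refit.converged:
            continue
        if standardized:
            # SEs are not needed for the bootstrap statistic itself
            refit.cov = np.zeros((refit.model.n_free, refit.model.n_free))
            standardize_solution(refit)
            est = refit.std_theta
        else:
            est = refit.theta
        a = est[refit.lookup(mediator, "~", exposure)]
        b = est[refit.lookup(outcome, "~", mediator)]
        vals[kept] = a * b
        kept += 1
    if kept < n_replicates // 2:
        raise RuntimeError("too many bootstrap replicates failed to converge")
    return float(np.std(vals[:kept], ddof=1))
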