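"""Synthetic memory-clinic cohorts with known ground truth.

Generates participant tables shaped like the motivating multicentre cohort:
two correlated life-course traits (early-to-midlife social, latelife
lifestyle) drive graded ordinal items; three latent pathology mediators
(small vessel disease, AD pathology, neurodegeneration) and latent cognition
follow linear structural equations with Gaussian residuals; biomarker and
cognitive indicators load on the latents and are inverted to raw measurement
scales (volumes, SUVRs, seconds); and missingness is imposed per acquisition
modality with probabilities depending only on fully observed covariates
(missing at random by construction).

Defaults are calibrated to the reference cohort: item thresholds solved so
marginal category frequencies match the printed baseline table, structural
coefficients set to the published standardized direct effects, mediator
residual correlations to the published values, age/sex/APOE margins to the
printed descriptives, and modality missingness to the published acquisition
fractions (lumbar puncture 18%, amyloid-PET 28%, FDG-PET 57% performed).

Ground truth (latent traits and factors, plus the generating config) rides
along with every simulated cohort so that trait recovery, structural
recovery and mediation decomposition are all directly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import truncnorm

from . import calibration as cal
from .grm import GRMItem, category_probabilities, gauss_hermite_normal
from .sem import SEMMatrices, implied_moments

__all__ = [
    "SimConfig",
    "SimulatedCohort",
    "default_config",
    "simulate_cohort",
    "sample_grm_responses",
    "impose_missingness",
    "thresholds_from_margins",
    "truth_matrices",
    "standardized_truth",
]

AGE_RANGE = (50.0, 95.0)

#: SI-trait items and LI-trait items (the three SNI components are binary
#: graded items; the index itself is derived downstream).
SI_ITEMS = ("education", "occupation", "salary")
LI_ITEMS = ("physical_activity", "leisure_count", "married", "close_ties", "membership")

#: category-label offset: stored code = category index + offset
_ITEM_OFFSET = {
    "education": 1,
    "occupation": 1,
    "salary": 1,
    "physical_activity": 1,
    "leisure_count": 0,
    "married": 0,
    "close_ties": 0,
    "membership": 0,
}

_MODALITY_COLUMNS = {
    "csf": ("csf_ab42", "csf_ab40", "csf_ptau", "ab_ratio", "ptau_t"),
    "amyloid_pet": ("amyloid_suvr", "radioligand", "amyloid_t"),
    "fdg_pet": ("fdg_suvr", "fdg_nd"),
}

#: item-level MCAR rates from the baseline-table footnote (count / 2323)
_ITEM_MISSING_DEFAULT = {
    "education": 5 / cal.COHORT_N,
    "occupation": 26 / cal.COHORT_N,
    "salary": 317 / cal.COHORT_N,
    "physical_activity": 253 / cal.COHORT_N,
    "leisure_count": 129 / cal.COHORT_N,
    "sni_components": 142 / cal.COHORT_N,
    "apoe4": 127 / cal.COHORT_N,
}


@dataclass(frozen=True)
class Indicator:
    """Measurement equation of one analysis-scale indicator."""

    latent: str
    loading: float
    intercept: float
    resid_var: float

    def __post_init__(self):
        if not self.resid_var > 0:
            raise ValueError("indicator residual variance must be > 0")


@dataclass
class SimConfig:
    """Everything needed to generate one cohort; deterministic given seed."""

    n_participants: int = 2000
    seed: int = 12345
    trait_corr: float = 0.3
    item_bank: dict[str, GRMItem] = field(default_factory=dict)
    #: (source, target) -> path coefficient on the unit-latent scale
    structural_coefs: dict[tuple[str, str], float] = field(default_factory=dict)
    mediator_resid_corr: np.ndarray | None = None  # order: svd, ad, neuro
    measurement: dict[str, Indicator] = field(default_factory=dict)
    #: modality -> probability the modality block is MISSING
    missing_rates: dict[str, float] = field(
        default_factory=lambda: {
            "csf": 1.0 - cal.MODALITY_PARTICIPATION["csf"],
            "amyloid_pet": 1.0 - cal.MODALITY_PARTICIPATION["amyloid_pet"],
            "fdg_pet": 1.0 - cal.MODALITY_PARTICIPATION["fdg_pet"],
        }
    )
    item_missing_rates: dict[str, float] = field(
        default_factory=lambda: dict(_ITEM_MISSING_DEFAULT)
    )
    mar_strength: float = 0.5
    age_mean: float = cal.AGE_MEAN
    age_sd: float = cal.AGE_SD
    p_female: float = cal.WOMEN_FREQUENCY
    p_apoe4: float = cal.APOE4_FREQUENCY

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        if not -1.0 < self.trait_corr < 1.0:
            raise ValueError("trait_corr must lie in (-1, 1)")
        for rate in list(self.missing_rates.values()) + list(
            self.item_missing_rates.values()
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("missing rates must lie in [0, 1]")
        R = np.asarray(self.mediator_resid_corr)
        if R.shape != (3, 3) or not np.allclose(R, R.T):
            raise ValueError("mediator_resid_corr must be symmetric 3x3")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("mediator_resid_corr must be positive definite")
        # the full generative model must have a positive-definite implied
        # covariance; residual-variance calibration surfaces violations
        _residual_variances(self)


@dataclass
class SimulatedCohort:
    """Generated data plus the per-participant ground truth."""

    data: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig

    def write(self, prefix) -> None:
        """Write ``<prefix>_cohort.csv``, ``<prefix>_truth.csv`` and a YAML
        sidecar with the generating configuration."""
        self.data.to_csv(f"{prefix}_cohort.csv", index=False)
        self.truth.to_csv(f"{prefix}_truth.csv", index=False)
        cfg = {
            "n_participants": self.config.n_participants,
            "seed": self.config.seed,
            "trait_corr": self.config.trait_corr,
            "mar_strength": self.config.mar_strength,
            "missing_rates": dict(self.config.missing_rates),
            "item_bank": {
                k: {"a": it.discrimination, "b": list(it.thresholds)}
                for k, it in self.config.item_bank.items()
            },
            "structural_coefs": {
                f"{s}->{t}": v for (s, t), v in self.config.structural_coefs.items()
            },
        }
        with open(f"{prefix}_config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh)


# ---------------------------------------------------------------------------
# default calibration


def thresholds_from_margins(a: float, category_probs, n_nodes: int = 101) -> tuple:
    """Thresholds whose N(0,1)-marginal category frequencies match targets.

    For each cut k the marginal exceedance ``integral expit(a(theta - b_k))
    dPhi(theta)`` is matched to the target tail probability by root-finding.
    """
    p = np.asarray(category_probs, dtype=float)
    if np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("category probabilities must be positive and sum to 1")
    nodes, w = gauss_hermite_normal(n_nodes)
    from scipy.special import expit

    tails = 1.0 - np.cumsum(p)[:-1]
    b = []
    for t in tails:
        f = lambda bk: float(w @ expit(a * (nodes - bk))) - t
        b.append(brentq(f, -12.0, 12.0, xtol=1e-12))
    return tuple(b)


def _margin_probs(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    return c / c.sum()


def _leisure_margins() -> np.ndarray:
    """Per-count probabilities for the 0-15 leisure score.

    Only the quartile-block masses (<6, 6-7, 8-9, >9) are published; within
    blocks the mass is spread on a smooth unimodal profile (our choice).
    """
    block = _margin_probs(cal.CATEGORY_MARGINS["leisure_quartile"]["counts"])
    weights = {
        (0, 6): np.array([0.3, 0.6, 1.0, 1.6, 2.2, 2.6]),
        (6, 8): np.array([1.2, 1.0]),
        (8, 10): np.array([1.2, 1.0]),
        (10, 16): np.array([2.4, 1.6, 1.0, 0.6, 0.3, 0.1]),
    }
    p = np.empty(16)
    for bi, (lo, hi) in enumerate([(0, 6), (6, 8), (8, 10), (10, 16)]):
        w = weights[(lo, hi)]
        p[lo:hi] = block[bi] * w / w.sum()
    return p


def _default_item_bank() -> dict[str, GRMItem]:
    margins = {
        "education": (1.8, _margin_probs(cal.CATEGORY_MARGINS["education"]["counts"])),
        "occupation": (1.6, _margin_probs(cal.CATEGORY_MARGINS["occupation"]["counts"])),
        "salary": (1.4, _margin_probs(cal.CATEGORY_MARGINS["salary"]["counts"])),
        "physical_activity": (
            1.0,
            _margin_probs(cal.CATEGORY_MARGINS["physical_activity"]["counts"]),
        ),
        "leisure_count": (1.5, _leisure_margins()),
        # binary SNI components: marginal endorsement rates chosen so the
        # summed index reproduces the printed SNI distribution's mean
        "married": (0.9, np.array([0.35, 0.65])),
        "close_ties": (0.9, np.array([0.45, 0.55])),
        "membership": (0.9, np.array([0.53, 0.47])),
    }
    bank = {}
    for name, (a, p) in margins.items():
        bank[name] = GRMItem(a, thresholds_from_margins(a, p), name)
    return bank


def _default_structural() -> dict[tuple[str, str], float]:
    coefs = {}
    for (src, tgt), entry in cal.DIRECT_EFFECTS.items():
        coefs[(src, tgt)] = entry["beta"]
    return coefs


def _default_measurement() -> dict[str, Indicator]:
    return {
        # small vessel disease
        "wmh_t": Indicator("svd", 1.0, -6.6, 0.60),
        "fazekas_peri": Indicator("svd", 0.55, 1.30, 0.30),
        "fazekas_deep": Indicator("svd", 0.50, 1.10, 0.35),
        # AD pathology (higher latent = more pathology -> lower ratio)
        "ab_ratio": Indicator("ad", -0.015, 0.075, 1.2e-4),
        "ptau_t": Indicator("ad", 0.35, 3.90, 0.08),
        "amyloid_t": Indicator("ad", 0.70, 0.0, 0.50),
        # neurodegeneration (reverse-coded scale: higher = worse)
        "hippo_nd": Indicator("neuro", 1.0, 0.0, 0.50),
        "thickness_nd": Indicator("neuro", 0.80, 0.0, 0.60),
        "bpf_nd": Indicator("neuro", 0.70, 0.0, 0.70),
        "fdg_nd": Indicator("neuro", 0.60, 0.0, 0.80),
        # cognition (raw test scales)
        "verbal_fluency": Indicator("cognition", 6.0, 28.0, 30.0),
        "fcsrt_free_recall": Indicator("cognition", 5.5, 30.0, 25.0),
        "tmtb_t": Indicator("cognition", 0.30, -4.65, 0.10),
        "rey_score": Indicator("cognition", 5.0, 26.0, 28.0),
    }


def default_config(**overrides) -> SimConfig:
    """The calibrated default configuration (see module docstring)."""
    R = np.eye(3)
    R[0, 1] = R[1, 0] = cal.MEDIATOR_RESIDUAL_CORRELATIONS[("ad", "svd")]["r"]
    R[0, 2] = R[2, 0] = cal.MEDIATOR_RESIDUAL_CORRELATIONS[("svd", "neuro")]["r"]
    R[1, 2] = R[2, 1] = cal.MEDIATOR_RESIDUAL_CORRELATIONS[("ad", "neuro")]["r"]
    cfg = SimConfig(
        item_bank=_default_item_bank(),
        structural_coefs=_default_structural(),
        mediator_resid_corr=R,
        measurement=_default_measurement(),
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# covariate and structural algebra


def _age_moments(cfg: SimConfig) -> tuple[float, float]:
    a = (AGE_RANGE[0] - cfg.age_mean) / cfg.age_sd
    b = (AGE_RANGE[1] - cfg.age_mean) / cfg.age_sd
    dist = truncnorm(a, b, loc=cfg.age_mean, scale=cfg.age_sd)
    return float(dist.mean()), float(dist.var())


_PREDICTORS = ("si", "li", "age", "sex", "apoe4")
_MEDIATORS = ("svd", "ad", "neuro")


def _predictor_cov(cfg: SimConfig) -> np.ndarray:
    _, v_age = _age_moments(cfg)
    S = np.diag(
        [
            1.0,
            1.0,
            v_age,
            cfg.p_female * (1 - cfg.p_female),
            cfg.p_apoe4 * (1 - cfg.p_apoe4),
        ]
    )
    S[0, 1] = S[1, 0] = cfg.trait_corr
    return S


def _gamma(cfg: SimConfig, target: str) -> np.ndarray:
    return np.array(
        [cfg.structural_coefs.get((p, target), 0.0) for p in _PREDICTORS]
    )


def _residual_variances(cfg: SimConfig) -> dict[str, float]:
    """Residual variances giving every latent unit marginal variance.

    Raises a configuration error when a latent's systematic variance already
    exceeds 1 (the implied covariance could not be completed positive
    definite on the unit-variance scale).
    """
    Sp = _predictor_cov(cfg)
    resid = {}
    for m in _MEDIATORS:
        g = _gamma(cfg, m)
        explained = float(g @ Sp @ g)
        if explained >= 1.0:
            raise ValueError(
                f"structural coefficients for {m!r} explain variance "
                f"{explained:.3f} >= 1: implied covariance not positive definite"
            )
        resid[m] = 1.0 - explained
    D = np.sqrt([resid[m] for m in _MEDIATORS])
    psi = np.asarray(cfg.mediator_resid_corr) * np.outer(D, D)
    G = np.vstack([_gamma(cfg, m) for m in _MEDIATORS])
    S_med = G @ Sp @ G.T + psi
    S_pm = Sp @ G.T
    S_joint = np.block([[Sp, S_pm], [S_pm.T, S_med]])
    w = np.concatenate(
        [
            _gamma(cfg, "cognition"),
            [cfg.structural_coefs.get((m, "cognition"), 0.0) for m in _MEDIATORS],
        ]
    )
    explained_c = float(w @ S_joint @ w)
    if explained_c >= 1.0:
        raise ValueError(
            f"structural coefficients for cognition explain variance "
            f"{explained_c:.3f} >= 1: implied covariance not positive definite"
        )
    resid["cognition"] = 1.0 - explained_c
    return resid


_LATENT_NAME = {"svd": "SVD", "ad": "ADpath", "neuro": "Neuro", "cognition": "Cognition"}
_EXOG_NAME = {"si": "si_score", "li": "li_score", "age": "age", "sex": "sex",
              "apoe4": "apoe4"}

#: analysis-scale indicator order, matching the default pathway spec
ANALYSIS_ORDER = [
    "wmh_t", "fazekas_peri", "fazekas_deep",
    "ab_ratio", "ptau_t", "amyloid_t",
    "hippo_nd", "thickness_nd", "bpf_nd", "fdg_nd",
    "verbal_fluency", "fcsrt_free_recall", "tmtb_t", "rey_score",
]


def truth_matrices(cfg: SimConfig) -> SEMMatrices:
    """RAM matrices of the full generative model on the analysis scale.

    Variable order: 14 indicators, 5 exogenous predictors, 4 latents —
    identical to the default pathway spec, so the estimator's
    ``implied_moments`` evaluated here is the generator's exact moment
    structure (one shared algebra).
    """
    variables = (
        ANALYSIS_ORDER
        + [_EXOG_NAME[p] for p in _PREDICTORS]
        + [_LATENT_NAME[m] for m in _MEDIATORS + ("cognition",)]
    )
    vi = {v: k for k, v in enumerate(variables)}
    nv = len(variables)
    A = np.zeros((nv, nv))
    S = np.zeros((nv, nv))
    m = np.zeros(nv)

    for ind, eq in cfg.measurement.items():
        A[vi[ind], vi[_LATENT_NAME[eq.latent]]] = eq.loading
        S[vi[ind], vi[ind]] = eq.resid_var
        m[vi[ind]] = eq.intercept

    for (src, tgt), coef in cfg.structural_coefs.items():
        s = vi[_LATENT_NAME.get(src, _EXOG_NAME.get(src, src))]
        t = vi[_LATENT_NAME[tgt]]
        A[t, s] = coef

    resid = _residual_variances(cfg)
    for name, var in resid.items():
        k = vi[_LATENT_NAME[name]]
        S[k, k] = var
    D = np.sqrt([resid[x] for x in _MEDIATORS])
    R = np.asarray(cfg.mediator_resid_corr)
    for i, mi in enumerate(_MEDIATORS):
        for j in range(i + 1, 3):
            cov = R[i, j] * D[i] * D[j]
            a_i, b_j = vi[_LATENT_NAME[mi]], vi[_LATENT_NAME[_MEDIATORS[j]]]
            S[a_i, b_j] = S[b_j, a_i] = cov

    Sp = _predictor_cov(cfg)
    mean_age, _ = _age_moments(cfg)
    means = [0.0, 0.0, mean_age, cfg.p_female, cfg.p_apoe4]
    for i, p in enumerate(_PREDICTORS):
        k = vi[_EXOG_NAME[p]]
        m[k] = means[i]
        for j, q in enumerate(_PREDICTORS):
            S[k, vi[_EXOG_NAME[q]]] = Sp[i, j]

    return SEMMatrices(
        A=A, S=S, m=m, obs_idx=np.arange(len(ANALYSIS_ORDER) + 5), variables=variables
    )


def standardized_truth(cfg: SimConfig) -> dict[tuple[str, str], float]:
    """True structural coefficients on the fully standardized scale.

    Each path is rescaled by sd(source)/sd(target) under the generative
    implied covariance — the scale on which fitted standardized solutions
    are compared.
    """
    mat = truth_matrices(cfg)
    B = np.linalg.inv(np.eye(mat.A.shape[0]) - mat.A)
    V = B @ mat.S @ B.T
    sd = np.sqrt(np.diag(V))
    vi = {v: k for k, v in enumerate(mat.variables)}
    out = {}
    for (src, tgt), coef in cfg.structural_coefs.items():
        s = vi[_LATENT_NAME.get(src, _EXOG_NAME.get(src, src))]
        t = vi[_LATENT_NAME[tgt]]
        out[(src, tgt)] = coef * sd[s] / sd[t]
    return out


# ---------------------------------------------------------------------------
# sampling


def sample_grm_responses(theta, item_bank: dict[str, GRMItem], seed) -> pd.DataFrame:
    """Draw ordinal responses from the GRM given trait values.

    ``seed`` may be an integer or a :class:`numpy.random.Generator`.  Columns
    are coded with each item's conventional offset (e.g. education 1-4,
    leisure count 0-15).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = np.asarray(theta, dtype=float)
    out = {}
    for name, item in item_bank.items():
        probs = category_probabilities(theta, item)
        u = rng.random(theta.size)
        idx = (u[:, None] > np.cumsum(probs, axis=1)[:, :-1]).sum(axis=1)
        out[name] = idx + _ITEM_OFFSET.get(name, 0)
    return pd.DataFrame(out)


def _invert_measurement(analysis: pd.DataFrame, rng: np.random.Generator):
    """Back-transform analysis-scale indicators to raw measurement columns."""
    n = len(analysis)
    raw = pd.DataFrame(index=analysis.index)
    tiv = rng.normal(1.45e6, 1.3e5, n)
    raw["tiv"] = tiv
    raw["wmh_volume"] = np.exp(analysis["wmh_t"]) * tiv
    raw["fazekas_peri"] = analysis["fazekas_peri"]
    raw["fazekas_deep"] = analysis["fazekas_deep"]
    # CSF: pick Abeta40 independently, set Abeta42 from the generated ratio
    ab40 = np.exp(rng.normal(np.log(14000.0), 0.25, n))
    raw["csf_ab40"] = ab40
    raw["csf_ab42"] = analysis["ab_ratio"] * ab40
    raw["csf_ptau"] = np.exp(analysis["ptau_t"])
    ligand = np.where(rng.random(n) < 0.5, "florbetapir", "flutemetamol")
    scale = {"florbetapir": (0.15, 0.12), "flutemetamol": (0.30, 0.18)}
    mvals = np.array([scale[l][0] for l in ligand])
    svals = np.array([scale[l][1] for l in ligand])
    raw["radioligand"] = ligand
    raw["amyloid_suvr"] = np.exp(mvals + svals * analysis["amyloid_t"].to_numpy())
    raw["hippocampus_volume"] = np.exp(-5.99 - 0.15 * analysis["hippo_nd"]) * tiv
    raw["cortical_thickness"] = 2.60 - 0.15 * analysis["thickness_nd"]
    raw["bpf"] = 0.78 - 0.03 * analysis["bpf_nd"]
    raw["fdg_suvr"] = 1.25 - 0.12 * analysis["fdg_nd"]
    raw["verbal_fluency"] = analysis["verbal_fluency"]
    raw["fcsrt_free_recall"] = analysis["fcsrt_free_recall"]
    raw["tmtb_seconds"] = np.exp(-analysis["tmtb_t"])
    raw["rey_score"] = analysis["rey_score"]
    return raw


def simulate_cohort(
    config: SimConfig | None = None,
    *,
    scale: str = "raw",
    apply_missingness: bool = True,
) -> SimulatedCohort:
    """Generate one cohort from the configuration.

    Parameters
    ----------
    config
        Generating configuration; :func:`default_config` when omitted.
    scale
        ``"raw"`` emits the full raw table (ordinal items, volumes, SUVRs,
        seconds) to be run through :mod:`latentmed.preprocess`;
        ``"analysis"`` emits analysis-scale indicator columns directly with
        the true traits as ``si_score``/``li_score`` (no ordinal items, no
        missingness) — the regime for estimator-recovery studies.
    apply_missingness
        Impose modality-block and item-level missingness (raw scale only).
    """
    cfg = config if config is not None else default_config()
    cfg.validate()
    if scale not in ("raw", "analysis"):
        raise ValueError("scale must be 'raw' or 'analysis'")
    n = cfg.n_participants
    streams = np.random.SeedSequence(cfg.seed).spawn(7)
    rngs = [np.random.default_rng(s) for s in streams]
    r_cov, r_trait, r_items, r_struct, r_meas, r_miss, r_raw = rngs

    pid = pd.RangeIndex(n).astype(str).map(lambda s: f"P{int(s):06d}")

    # covariates
    a, b = (
        (AGE_RANGE[0] - cfg.age_mean) / cfg.age_sd,
        (AGE_RANGE[1] - cfg.age_mean) / cfg.age_sd,
    )
    age = truncnorm.rvs(a, b, loc=cfg.age_mean, scale=cfg.age_sd, size=n,
                        random_state=r_cov)
    sex = (r_cov.random(n) < cfg.p_female).astype(float)
    apoe4 = (r_cov.random(n) < cfg.p_apoe4).astype(float)

    # correlated life-course traits
    L = np.linalg.cholesky(np.array([[1.0, cfg.trait_corr], [cfg.trait_corr, 1.0]]))
    traits = r_trait.standard_normal((n, 2)) @ L.T
    si, li = traits[:, 0], traits[:, 1]

    # structural recursion
    pred = np.column_stack([si, li, age, sex, apoe4])
    resid = _residual_variances(cfg)
    D = np.sqrt([resid[m] for m in _MEDIATORS])
    psi = np.asarray(cfg.mediator_resid_corr) * np.outer(D, D)
    e_med = r_struct.multivariate_normal(np.zeros(3), psi, size=n) if n else np.empty((0, 3))
    latents = {}
    for k, m in enumerate(_MEDIATORS):
        latents[m] = pred @ _gamma(cfg, m) + e_med[:, k]
    cog = pred @ _gamma(cfg, "cognition") + np.sqrt(resid["cognition"]) * (
        r_struct.standard_normal(n)
    )
    for m in _MEDIATORS:
        cog = cog + cfg.structural_coefs.get((m, "cognition"), 0.0) * latents[m]
    latents["cognition"] = cog

    # measurement
    analysis = pd.DataFrame(index=pd.RangeIndex(n))
    for ind in ANALYSIS_ORDER:
        eq = cfg.measurement[ind]
        analysis[ind] = (
            eq.intercept
            + eq.loading * latents[eq.latent]
            + np.sqrt(eq.resid_var) * r_meas.standard_normal(n)
        )

    truth = pd.DataFrame(
        {
            "participant_id": pid,
            "si_true": si,
            "li_true": li,
            "svd_true": latents["svd"],
            "ad_true": latents["ad"],
            "neuro_true": latents["neuro"],
            "cognition_true": latents["cognition"],
        }
    )

    if scale == "analysis":
        data = pd.concat(
            [
                pd.DataFrame({"participant_id": pid}),
                analysis,
                pd.DataFrame(
                    {"si_score": si, "li_score": li, "age": age, "sex": sex,
                     "apoe4": apoe4}
                ),
            ],
            axis=1,
        )
        return SimulatedCohort(data=data, truth=truth, config=cfg)

    items = sample_grm_responses(si, {k: cfg.item_bank[k] for k in SI_ITEMS}, r_items)
    items_li = sample_grm_responses(
        li, {k: cfg.item_bank[k] for k in LI_ITEMS}, r_items
    )
    items = pd.concat([items, items_li], axis=1)
    # physical items among the endorsed leisure activities: random subset
    counts = items["leisure_count"].to_numpy(int)
    items["leisure_physical_count"] = r_items.hypergeometric(
        2, 13, counts
    ) if n else np.array([], dtype=int)

    raw = _invert_measurement(analysis, r_raw)
    data = pd.concat(
        [
            pd.DataFrame({"participant_id": pid}),
            items,
            raw,
            pd.DataFrame({"age": age, "sex": sex, "apoe4": apoe4}),
        ],
        axis=1,
    )
    cohort = SimulatedCohort(data=data, truth=truth, config=cfg)
    if apply_missingness:
        cohort = impose_missingness(
            cohort, cfg.missing_rates, cfg.mar_strength, int(r_miss.integers(2**31))
        )
    return cohort


# ---------------------------------------------------------------------------
# missingness


def _mar_probability(
    age: np.ndarray, sex: np.ndarray, rate: float, mar_strength: float, cfg: SimConfig
) -> np.ndarray:
    """Per-participant block-missing probability with marginal mean ``rate``.

    Linear predictor: ``mar_strength * z_age + 0.3 * mar_strength * sex``
    with z-age on the population scale; the intercept is solved so the
    sample-average probability equals the target rate.
    """
    from scipy.special import expit

    if rate <= 0.0:
        return np.zeros_like(age)
    if rate >= 1.0:
        return np.ones_like(age)
    z_age = (age - cfg.age_mean) / cfg.age_sd
    lin = mar_strength * z_age + 0.3 * mar_strength * sex
    f = lambda b0: float(np.mean(expit(b0 + lin))) - rate
    b0 = brentq(f, -30.0, 30.0, xtol=1e-12)
    return expit(b0 + lin)


def impose_missingness(
    cohort: SimulatedCohort,
    missing_rates: dict[str, float] | None = None,
    mar_strength: float | None = None,
    seed: int | None = None,
) -> SimulatedCohort:
    """Blank modality blocks and single items, missing at random.

    Whole modality panels (all CSF columns jointly; each PET block) are set
    missing with probability depending only on the fully observed covariates
    age and sex — MAR by construction.  Item-level missingness (education,
    salary, the SNI components, APOE, ...) is MCAR at the configured rates;
    the three SNI components go missing together, matching how the derived
    index behaves.
    """
    cfg = cohort.config
    rates = cfg.missing_rates if missing_rates is None else missing_rates
    strength = cfg.mar_strength if mar_strength is None else mar_strength
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)

    data = cohort.data.copy()
    n = len(data)
    if n == 0:
        return SimulatedCohort(data=data, truth=cohort.truth.copy(), config=cfg)
    age = data["age"].to_numpy(float)
    sex = data["sex"].to_numpy(float)

    for modality, rate in rates.items():
        cols = [c for c in _MODALITY_COLUMNS.get(modality, ()) if c in data.columns]
        if not cols or rate <= 0:
            continue
        p = _mar_probability(age, sex, rate, strength, cfg)
        gone = rng.random(n) < p
        data.loc[gone, cols] = np.nan

    item_rates = cfg.item_missing_rates
    sni_rate = item_rates.get("sni_components", 0.0)
    if sni_rate > 0 and {"married", "close_ties", "membership"} <= set(data.columns):
        gone = rng.random(n) < sni_rate
        data.loc[gone, ["married", "close_ties", "membership"]] = np.nan
    for item, rate in item_rates.items():
        if item == "sni_components" or rate <= 0 or item not in data.columns:
            continue
        gone = rng.random(n) < rate
        data.loc[gone, item] = np.nan

    return SimulatedCohort(data=data, truth=cohort.truth.copy(), config=cfg)
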