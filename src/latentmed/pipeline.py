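"""End-to-end orchestration: simulate/load -> preprocess -> trait scoring ->
structural model -> mediation decomposition.

One :class:`RunConfig` drives the whole chain deterministically.  The two
sensitivity variants re-specify the latelife trait measurement exactly as in
the source analysis: ``no_sni`` drops the social network index from the
latelife item set; ``no_physical_leisure`` recomputes the leisure score
without its two physical items (re-quartiled at sample quartiles) before
scoring.  Every run writes a manifest (config echo, seed, package versions)
sufficient to reproduce it byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__
from .effects import effect_table, mediator_residual_correlations
from .grm import eap_scores, fit_grm, two_way_margins
from .preprocess import apply_data_dictionary, load_data_dictionary, preprocess
from .sem import default_pathway_spec, fit_sem, standardize_solution
from .synthetic import SI_ITEMS, default_config, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "describe_cohort", "VARIANTS"]

log = logging.getLogger("latentmed")

VARIANTS = ("main", "no_sni", "no_physical_leisure")

#: latelife lifestyle item sets per analysis variant
_LI_ITEMS = {
    "main": ["physical_activity", "leisure_quartile", "sni"],
    "no_sni": ["physical_activity", "leisure_quartile"],
    "no_physical_leisure": ["physical_activity", "leisure_reduced_quartile", "sni"],
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_path: str | None = None
    data_dictionary: str | None = None
    simulate: dict = field(default_factory=dict)  # overrides for default_config
    variant: str = "main"
    n_quadrature: int = 61
    grad_tol: float = 1e-6
    max_iter: int = 5000
    ci_level: float = 0.95
    rmsea_ci_level: float = 0.90
    seed: int = 12345
    output_dir: str = "latentmed_run"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "data_dictionary": self.data_dictionary,
            "simulate": dict(self.simulate),
            "variant": self.variant,
            "n_quadrature": self.n_quadrature,
            "grad_tol": self.grad_tol,
            "max_iter": self.max_iter,
            "ci_level": self.ci_level,
            "rmsea_ci_level": self.rmsea_ci_level,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }


def _reduced_leisure_quartile(table: pd.DataFrame) -> pd.Series:
    """Leisure score without its two physical items, re-quartiled.

    Needs the ``leisure_physical_count`` column; the reduced 0-13 score is
    cut at its own sample quartiles (the published cutpoints apply to the
    full score only).
    """
    if "leisure_physical_count" not in table:
        raise ValueError(
            "variant 'no_physical_leisure' needs a leisure_physical_count column "
            "to recompute the reduced leisure score"
        )
    reduced = table["leisure_count"] - table["leisure_physical_count"]
    qs = np.nanquantile(reduced, [0.25, 0.5, 0.75])
    cat = pd.Series(np.nan, index=reduced.index, dtype=float)
    cat[reduced <= qs[0]] = 1
    cat[(reduced > qs[0]) & (reduced <= qs[1])] = 2
    cat[(reduced > qs[1]) & (reduced <= qs[2])] = 3
    cat[reduced > qs[2]] = 4
    cat[reduced.isna()] = np.nan
    return cat.rename("leisure_reduced_quartile")


def _score_trait(table, items, label, n_quadrature):
    responses = table[items]
    model = fit_grm(responses, n_quadrature=n_quadrature)
    scores = eap_scores(model, responses)
    margins = two_way_margins(model, responses)
    log.info(
        "%s GRM: %d items, loglik %.2f, %d/%d flagged margins",
        label, len(items), model.log_likelihood,
        int(margins["flagged"].sum()), len(margins),
    )
    return model, scores, margins


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Run the full pipeline; returns a dict of in-memory artifacts.

    With ``write=True`` all artifacts are also written under
    ``config.output_dir``: the cohort snapshot, per-trait GRM parameter JSON
    and two-way-margin reports, the structural parameter table (raw and
    standardized), fit indices, the mediation effect table and a run
    manifest.
    """
    # ---- stage 1: data -------------------------------------------------
    if config.input_path:
        raw = pd.read_csv(config.input_path)
        if config.data_dictionary:
            raw = apply_data_dictionary(raw, load_data_dictionary(config.data_dictionary))
        truth = None
    else:
        overrides = dict(config.simulate)
        overrides.setdefault("seed", config.seed)
        cohort = simulate_cohort(default_config(**overrides))
        raw, truth = cohort.data, cohort.truth
    log.info("cohort: %d participants, %d columns", len(raw), raw.shape[1])

    # ---- stage 2: preprocessing ---------------------------------------
    table = preprocess(raw)
    if config.variant == "no_physical_leisure":
        table["leisure_reduced_quartile"] = _reduced_leisure_quartile(table)

    # ---- stage 3: trait scoring ---------------------------------------
    li_items = _LI_ITEMS[config.variant]
    si_model, si_scores, si_margins = _score_trait(
        table, list(SI_ITEMS), "social", config.n_quadrature
    )
    li_model, li_scores, li_margins = _score_trait(
        table, li_items, "lifestyle", config.n_quadrature
    )
    table["si_score"] = si_scores.standardized
    table["li_score"] = li_scores.standardized

    # ---- stage 4: structural model -------------------------------------
    spec = default_pathway_spec()
    fit = fit_sem(
        spec,
        table,
        grad_tol=config.grad_tol,
        max_iter=config.max_iter,
    )
    fit.indices["rmsea_ci_level"] = config.rmsea_ci_level
    standardize_solution(fit)
    log.info(
        "SEM: loglik %.2f, chi2 %.1f (df %d), RMSEA %.3f, CFI %.3f",
        fit.loglik, fit.chi_square, fit.df_model,
        fit.indices["rmsea"], fit.indices["cfi"],
    )

    # ---- stage 5: effects ----------------------------------------------
    effects = effect_table(fit, ci_level=config.ci_level)
    correlations = mediator_residual_correlations(fit, ci_level=config.ci_level)

    artifacts = {
        "cohort": raw,
        "truth": truth,
        "analysis_table": table,
        "si_model": si_model,
        "li_model": li_model,
        "si_margins": si_margins,
        "li_margins": li_margins,
        "fit": fit,
        "effects": effects,
        "mediator_correlations": correlations,
        "fit_indices": fit.indices,
        "li_items": li_items,
    }
    if write:
        _write_artifacts(config, artifacts)
    return artifacts


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_artifacts(config: RunConfig, art: dict) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    art["cohort"].to_csv(out / "cohort.csv", index=False)
    if art["truth"] is not None:
        art["truth"].to_csv(out / "truth.csv", index=False)
    (out / "grm_social.json").write_text(art["si_model"].to_json())
    (out / "grm_lifestyle.json").write_text(art["li_model"].to_json())
    art["si_margins"].to_csv(out / "margins_social.csv", index=False)
    art["li_margins"].to_csv(out / "margins_lifestyle.csv", index=False)
    fit = art["fit"]
    fit.params_frame().to_csv(out / "sem_params.csv", index=False)
    fit.params_frame(standardized=True).to_csv(
        out / "sem_params_standardized.csv", index=False
    )
    with open(out / "fit_indices.json", "w") as fh:
        json.dump({k: _jsonable(v) for k, v in fit.indices.items()}, fh, indent=2)
    art["effects"].to_csv(out / "effects.csv", index=False)
    from .effects import effect_table_to_json

    with open(out / "effects.json", "w") as fh:
        json.dump(effect_table_to_json(art["effects"]), fh, indent=2)
    art["mediator_correlations"].to_csv(out / "mediator_correlations.csv", index=False)
    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "variant": config.variant,
        "lifestyle_items": art["li_items"],
        "n_participants": int(len(art["cohort"])),
        "sem_converged": bool(fit.converged),
        "versions": {
            "latentmed": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


# ---------------------------------------------------------------------------
# descriptive summary


_CATEGORICAL = [
    "education", "occupation", "salary", "physical_activity",
    "leisure_quartile", "sni", "apoe4",
]
_CONTINUOUS = [
    "age", "wmh_volume", "hippocampus_volume", "cortical_thickness", "bpf",
    "fdg_suvr", "amyloid_suvr", "csf_ab42", "csf_ab40", "csf_ptau",
    "fcsrt_free_recall", "verbal_fluency", "tmtb_seconds", "rey_score",
]


def describe_cohort(
    data: pd.DataFrame,
    by: str = "sex",
    age_bins: list[float] | None = None,
) -> pd.DataFrame:
    """Baseline descriptive table, overall and by sex.

    Categorical variables get counts and percentages (of all participants,
    missing included in the denominator) with a chi-square test for the sex
    contrast; continuous variables get mean (SD) with a one-way ANOVA.
    Optional ``age_bins`` adds a grouped summary of the continuous measures
    by age class instead of sex.
    """
    table = preprocess(data) if "leisure_quartile" not in data.columns else data.copy()
    if age_bins is not None:
        by = "_age_group"
        table[by] = pd.cut(table["age"], bins=age_bins)
    groups = table[by].dropna().unique() if by in table else []

    rows = []
    n_total = len(table)
    for var in _CATEGORICAL:
        if var not in table or (by == var):
            continue
        col = table[var]
        levels = sorted(col.dropna().unique())
        if len(levels) < 2:
            rows.append(
                {"variable": var, "level": levels[0] if levels else np.nan,
                 "summary": "constant", "p": np.nan,
                 "n_missing": int(col.isna().sum())}
            )
            continue
        p_val = np.nan
        if by in table:
            ct = pd.crosstab(col, table[by])
            if ct.shape[0] > 1 and ct.shape[1] > 1:
                p_val = sps.chi2_contingency(ct.to_numpy())[1]
        for lev in levels:
            count = int((col == lev).sum())
            row = {
                "variable": var,
                "level": lev,
                "summary": f"{count} ({100.0 * count / n_total:.1f})",
                "p": p_val,
                "n_missing": int(col.isna().sum()),
            }
            for g in groups:
                sub = col[table[by] == g]
                c = int((sub == lev).sum())
                row[f"{by}={g}"] = f"{c} ({100.0 * c / len(sub):.1f})"
            rows.append(row)

    for var in _CONTINUOUS:
        if var not in table:
            continue
        col = pd.to_numeric(table[var], errors="coerce")
        obs = col.dropna()
        if obs.std(ddof=1) == 0 or len(obs) < 2:
            rows.append(
                {"variable": var, "level": "", "summary": "constant",
                 "p": np.nan, "n_missing": int(col.isna().sum())}
            )
            continue
        p_val = np.nan
        if by in table:
            samples = [
                col[table[by] == g].dropna().to_numpy() for g in groups
            ]
            samples = [s for s in samples if len(s) > 1]
            if len(samples) > 1:
                p_val = sps.f_oneway(*samples)[1]
        row = {
            "variable": var,
            "level": "",
            "summary": f"{obs.mean():.1f} ({obs.std(ddof=1):.1f})",
            "p": p_val,
            "n_missing": int(col.isna().sum()),
        }
        for g in groups:
            sub = col[table[by] == g].dropna()
            row[f"{by}={g}"] = (
                f"{sub.mean():.1f} ({sub.std(ddof=1):.1f})" if len(sub) else ""
            )
        rows.append(row)
    return pd.DataFrame(rows)
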