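"""Derived variables and biomarker/cognition transforms.

Turns a raw participant table into the analysis-ready variable set:

* ordinal derivations — leisure-activity quartile category, social network
  index (SNI);
* biomarker transforms — intracranial-volume standardization plus log for
  white-matter-hyperintensity and hippocampal volumes, log p-tau, the CSF
  Abeta42/Abeta40 ratio, and within-radioligand z-scoring of log amyloid-PET
  SUVR;
* cognition coding — TMT-B completion time log-transformed and negated so
  that higher always means better performance;
* reverse coding of the four neurodegeneration indicators (standardized then
  negated) so that higher means more neurodegeneration.

Missing cells propagate through every transform; no step imputes.  All
functions accept and return :class:`pandas.DataFrame` objects using the
canonical column names in :data:`CANONICAL_COLUMNS`; a YAML data dictionary
can map arbitrary input headers onto those names.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CANONICAL_COLUMNS",
    "ANALYSIS_COLUMNS",
    "CohortValidationError",
    "apply_data_dictionary",
    "load_data_dictionary",
    "validate_cohort",
    "derive_leisure_category",
    "derive_sni",
    "transform_biomarkers",
    "code_cognition",
    "reverse_code_neurodegeneration",
    "preprocess",
]


class CohortValidationError(ValueError):
    """Raised when a raw cohort table violates a declared range or coding."""


#: canonical raw column name -> short description (documentation + validation)
CANONICAL_COLUMNS: dict[str, str] = {
    "participant_id": "unique participant identifier",
    "education": "education level, ordinal 1-4",
    "occupation": "occupational complexity, ordinal 1-3",
    "salary": "household income category, ordinal (7 or 8 levels)",
    "physical_activity": "IPAQ physical activity, ordinal 1-3",
    "leisure_count": "weekly leisure activities endorsed, count 0-15",
    "leisure_physical_count": "physical items among the leisure count, 0-2",
    "married": "married / living as couple, 0/1",
    "close_ties": "more than 2 close relatives or friends, 0/1",
    "membership": "membership in community organizations, 0/1",
    "wmh_volume": "white matter hyperintensity volume, mm^3",
    "fazekas_peri": "periventricular Fazekas severity, 0-3 scale",
    "fazekas_deep": "deep white matter Fazekas severity, 0-3 scale",
    "csf_ab42": "CSF amyloid-beta 42, pg/mL",
    "csf_ab40": "CSF amyloid-beta 40, pg/mL",
    "csf_ptau": "CSF phosphorylated tau, pg/mL",
    "amyloid_suvr": "global amyloid-PET SUVR",
    "radioligand": "amyloid-PET tracer: florbetapir or flutemetamol",
    "hippocampus_volume": "hippocampal volume, mm^3",
    "cortical_thickness": "AD-signature cortical thickness, mm",
    "bpf": "brain parenchymal fraction, 0-1",
    "fdg_suvr": "FDG-PET SUVR in AD-signature regions",
    "tiv": "total intracranial volume, mm^3",
    "fcsrt_free_recall": "FCSRT sum of three free recalls, 0-48",
    "verbal_fluency": "animal fluency count",
    "tmtb_seconds": "Trail Making Test B completion time, seconds",
    "rey_score": "Rey complex figure score",
    "age": "age at baseline, years",
    "sex": "sex, 1 = woman (accepts M/F)",
    "apoe4": "APOE-epsilon4 carrier, 0/1",
}

#: columns (besides exposures/covariates) entering the structural model
ANALYSIS_COLUMNS: list[str] = [
    "wmh_t",
    "fazekas_peri",
    "fazekas_deep",
    "ab_ratio",
    "ptau_t",
    "amyloid_t",
    "hippo_nd",
    "thickness_nd",
    "bpf_nd",
    "fdg_nd",
    "verbal_fluency",
    "fcsrt_free_recall",
    "tmtb_t",
    "rey_score",
]

#: ordinal range checks applied by validate_cohort (inclusive bounds)
_ORDINAL_RANGES = {
    "education": (1, 4),
    "occupation": (1, 3),
    "physical_activity": (1, 3),
    "leisure_count": (0, 15),
    "leisure_physical_count": (0, 2),
    "married": (0, 1),
    "close_ties": (0, 1),
    "membership": (0, 1),
    "apoe4": (0, 1),
}


def load_data_dictionary(path) -> dict[str, str]:
    """Read a YAML mapping of user column names to canonical names."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise CohortValidationError("data dictionary must be a flat mapping")
    bad = set(mapping.values()) - set(CANONICAL_COLUMNS)
    if bad:
        raise CohortValidationError(f"unknown canonical names: {sorted(bad)}")
    return {str(k): str(v) for k, v in mapping.items()}


def apply_data_dictionary(df: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    return df.rename(columns=mapping)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check declared ranges/codings; returns the (possibly recoded) table.

    Sex given as M/F is recoded to 0/1 (woman = 1).  Missing cells are always
    allowed.  Raises :class:`CohortValidationError` naming the offending
    column on the first violation.
    """
    df = df.copy()
    if "sex" in df and df["sex"].dtype == object:
        recoded = df["sex"].map({"M": 0, "F": 1, "m": 0, "f": 1})
        if recoded.isna().sum() > df["sex"].isna().sum():
            raise CohortValidationError("sex: expected M/F or 0/1 coding")
        df["sex"] = recoded
    for col, (lo, hi) in _ORDINAL_RANGES.items():
        if col not in df:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        obs = vals.dropna()
        if ((obs < lo) | (obs > hi)).any():
            bad = obs[(obs < lo) | (obs > hi)].index[0]
            raise CohortValidationError(
                f"{col}: value {obs[bad]} at row {bad} outside [{lo}, {hi}]"
            )
    for col in ("tiv", "tmtb_seconds"):
        if col in df:
            obs = pd.to_numeric(df[col], errors="coerce").dropna()
            if (obs <= 0).any():
                raise CohortValidationError(f"{col}: must be > 0 where present")
    return df


def derive_leisure_category(leisure_count) -> pd.Series:
    """Quartile-code the 0-15 leisure count: <6 -> 1, 6-7 -> 2, 8-9 -> 3, >9 -> 4.

    Missing counts propagate.  Out-of-range counts raise.
    """
    s = pd.Series(leisure_count, dtype=float)
    obs = s.dropna()
    if ((obs < 0) | (obs > 15)).any():
        raise CohortValidationError("leisure_count outside 0-15")
    cat = pd.Series(np.nan, index=s.index, dtype=float)
    cat[s < 6] = 1
    cat[(s >= 6) & (s <= 7)] = 2
    cat[(s >= 8) & (s <= 9)] = 3
    cat[s > 9] = 4
    cat[s.isna()] = np.nan
    return cat.rename("leisure_quartile")


def derive_sni(married, close_ties, membership) -> pd.Series:
    """Social network index 0-3: sum of the three 0/1 components.

    Any missing component makes the index missing (no partial credit).
    """
    parts = []
    for name, v in (
        ("married", married),
        ("close_ties", close_ties),
        ("membership", membership),
    ):
        s = pd.Series(v, dtype=float)
        obs = s.dropna()
        if not obs.isin([0, 1]).all():
            raise CohortValidationError(f"{name}: components must be 0/1")
        parts.append(s)
    out = parts[0] + parts[1] + parts[2]
    return out.rename("sni")


def _checked_log(values: pd.Series, col: str) -> pd.Series:
    obs = values.dropna()
    bad = obs[obs <= 0]
    if len(bad):
        raise CohortValidationError(
            f"{col}: non-positive value {bad.iloc[0]} at row {bad.index[0]} "
            "cannot be log-transformed"
        )
    return np.log(values)


def transform_biomarkers(df: pd.DataFrame) -> pd.DataFrame:
    """Add the analysis-scale biomarker columns.

    * ``wmh_t``    = log(wmh_volume / tiv)
    * ``hippo_t``  = log(hippocampus_volume / tiv)
    * ``ptau_t``   = log(csf_ptau)
    * ``ab_ratio`` = csf_ab42 / csf_ab40
    * ``amyloid_t`` = z-score of log(amyloid_suvr), computed within each
      radioligand group (florbetapir and flutemetamol SUVR scales are not
      directly commensurable)

    Missingness propagates cellwise.
    """
    out = df.copy()
    if "wmh_volume" in out and "tiv" in out:
        out["wmh_t"] = _checked_log(out["wmh_volume"] / out["tiv"], "wmh_volume/tiv")
    if "hippocampus_volume" in out and "tiv" in out:
        out["hippo_t"] = _checked_log(
            out["hippocampus_volume"] / out["tiv"], "hippocampus_volume/tiv"
        )
    if "csf_ptau" in out:
        out["ptau_t"] = _checked_log(out["csf_ptau"], "csf_ptau")
    if "csf_ab42" in out and "csf_ab40" in out:
        out["ab_ratio"] = out["csf_ab42"] / out["csf_ab40"]
    if "amyloid_suvr" in out:
        log_suvr = _checked_log(out["amyloid_suvr"], "amyloid_suvr")
        if "radioligand" in out:
            grouped = log_suvr.groupby(out["radioligand"])
            out["amyloid_t"] = (log_suvr - grouped.transform("mean")) / grouped.transform(
                lambda s: s.std(ddof=1)
            )
        else:
            obs = log_suvr.dropna()
            out["amyloid_t"] = (log_suvr - obs.mean()) / obs.std(ddof=1)
    return out


def code_cognition(df: pd.DataFrame) -> pd.DataFrame:
    """Orient the cognitive tests so higher = better.

    TMT-B time is log-transformed and negated (``tmtb_t = -log seconds``);
    the other three tests already point the right way and pass through.
    """
    out = df.copy()
    if "tmtb_seconds" in out:
        out["tmtb_t"] = -_checked_log(out["tmtb_seconds"], "tmtb_seconds")
    return out


def reverse_code_neurodegeneration(df: pd.DataFrame) -> pd.DataFrame:
    """Standardize then negate the four neurodegeneration indicators.

    hippo_t, cortical_thickness, bpf and fdg_suvr all decrease with
    neurodegeneration; after this step ``hippo_nd``, ``thickness_nd``,
    ``bpf_nd`` and ``fdg_nd`` increase with it.
    """
    pairs = [
        ("hippo_t", "hippo_nd"),
        ("cortical_thickness", "thickness_nd"),
        ("bpf", "bpf_nd"),
        ("fdg_suvr", "fdg_nd"),
    ]
    out = df.copy()
    for src, dst in pairs:
        if src not in out:
            continue
        obs = out[src].dropna()
        out[dst] = -(out[src] - obs.mean()) / obs.std(ddof=1)
    return out


def preprocess(df: pd.DataFrame) -> pd.DataFrame:
    """Full derivation chain: validate, derive ordinals, transform, orient.

    Returns the input table augmented with ``leisure_quartile``, ``sni`` and
    every analysis-scale column whose inputs are present.
    """
    out = validate_cohort(df)
    if "leisure_count" in out and "leisure_quartile" not in out:
        out["leisure_quartile"] = derive_leisure_category(out["leisure_count"])
    if {"married", "close_ties", "membership"} <= set(out.columns) and "sni" not in out:
        out["sni"] = derive_sni(out["married"], out["close_ties"], out["membership"])
    out = transform_biomarkers(out)
    out = code_cognition(out)
    out = reverse_code_neurodegeneration(out)
    return out
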