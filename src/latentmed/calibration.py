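"""Reference calibration values for the simulator and identity checks.

These are the standardized effect estimates and baseline cohort margins from
the motivating multicentre memory-clinic cohort analysis (N = 2323) that this
package re-implements as a reusable pipeline.  They serve two purposes:

* simulator defaults — the synthetic cohort generator is calibrated so that
  parameter-recovery tests probe the estimator in the empirically relevant
  regime (effect sizes, category margins, missingness geometry);
* arithmetic-identity checks — a published mediation decomposition must be
  internally consistent: each indirect effect is the product of its two
  constituent direct paths, each total effect the sum of the direct effect and
  all indirect channels, and each category percentage 100 * count / N.

Exposures are the two life-course traits: ``si`` (early-to-midlife social
indicator) and ``li`` (latelife lifestyle indicator).  Mediators are the three
pathology factors ``svd`` (small vessel disease), ``ad`` (AD-specific
pathology) and ``neuro`` (neurodegeneration); the outcome is ``cognition``.
Covariates are ``sex`` (women = 1), ``age`` (years) and ``apoe4`` (carrier).
"""

from __future__ import annotations

COHORT_N = 2323

MEDIATORS = ("svd", "ad", "neuro")
EXPOSURES = ("si", "li")
COVARIATES = ("sex", "age", "apoe4")

#: Standardized direct effects beta with 95% CI, keyed (source, target).
DIRECT_EFFECTS: dict[tuple[str, str], dict] = {
    ("si", "svd"): {"beta": -0.001, "ci": (-0.042, 0.041), "p": 0.968},
    ("si", "ad"): {"beta": -0.034, "ci": (-0.104, 0.036), "p": 0.339},
    ("si", "neuro"): {"beta": -0.030, "ci": (-0.068, 0.008), "p": 0.121},
    ("si", "cognition"): {"beta": 0.364, "ci": (0.322, 0.405), "p": 0.000},
    ("li", "svd"): {"beta": -0.031, "ci": (-0.072, 0.009), "p": 0.129},
    ("li", "ad"): {"beta": -0.036, "ci": (-0.105, 0.032), "p": 0.297},
    ("li", "neuro"): {"beta": -0.116, "ci": (-0.153, -0.079), "p": 0.000},
    ("li", "cognition"): {"beta": 0.076, "ci": (0.033, 0.118), "p": 0.000},
    ("ad", "cognition"): {"beta": -0.264, "ci": (-0.362, -0.165), "p": 0.000},
    ("svd", "cognition"): {"beta": -0.039, "ci": (-0.093, 0.014), "p": 0.149},
    ("neuro", "cognition"): {"beta": -0.574, "ci": (-0.665, -0.483), "p": 0.000},
    ("sex", "svd"): {"beta": 0.016, "ci": (-0.068, 0.100), "p": 0.715},
    ("sex", "ad"): {"beta": -0.129, "ci": (-0.266, 0.008), "p": 0.067},
    ("sex", "neuro"): {"beta": -0.603, "ci": (-0.677, -0.529), "p": 0.000},
    ("sex", "cognition"): {"beta": -0.193, "ci": (-0.296, -0.091), "p": 0.000},
    ("age", "svd"): {"beta": 0.053, "ci": (0.049, 0.057), "p": 0.000},
    ("age", "ad"): {"beta": 0.048, "ci": (0.041, 0.055), "p": 0.000},
    ("age", "neuro"): {"beta": 0.075, "ci": (0.072, 0.078), "p": 0.000},
    ("age", "cognition"): {"beta": 0.015, "ci": (0.007, 0.024), "p": 0.001},
    # The source table prints this CI upper bound inconsistently with the
    # estimate; the value below is the one consistent with beta +/- 1.96 SE.
    ("apoe4", "svd"): {"beta": 0.085, "ci": (-0.004, 0.174), "p": 0.063},
    ("apoe4", "ad"): {"beta": 0.835, "ci": (0.703, 0.967), "p": 0.000},
    ("apoe4", "neuro"): {"beta": 0.199, "ci": (0.117, 0.280), "p": 0.000},
    ("apoe4", "cognition"): {"beta": 0.023, "ci": (-0.097, 0.143), "p": 0.709},
}

#: Published indirect effects on cognition, keyed (source, mediator).
INDIRECT_EFFECTS: dict[tuple[str, str], dict] = {
    ("si", "ad"): {"beta": 0.009, "ci": (-0.010, 0.028), "p": 0.344},
    ("si", "svd"): {"beta": 0.000, "ci": (-0.002, 0.002), "p": 0.968},
    ("si", "neuro"): {"beta": 0.017, "ci": (-0.005, 0.039), "p": 0.124},
    ("li", "ad"): {"beta": 0.010, "ci": (-0.009, 0.028), "p": 0.308},
    ("li", "svd"): {"beta": 0.001, "ci": (-0.001, 0.004), "p": 0.296},
    ("li", "neuro"): {"beta": 0.066, "ci": (0.042, 0.090), "p": 0.000},
    ("sex", "ad"): {"beta": 0.034, "ci": (-0.004, 0.07), "p": 0.085},
    ("sex", "svd"): {"beta": -0.001, "ci": (-0.004, 0.003), "p": 0.724},
    ("sex", "neuro"): {"beta": 0.346, "ci": (0.274, 0.418), "p": 0.000},
    ("age", "ad"): {"beta": -0.013, "ci": (-0.018, -0.007), "p": 0.000},
    ("age", "svd"): {"beta": -0.002, "ci": (-0.005, 0.001), "p": 0.150},
    ("age", "neuro"): {"beta": -0.043, "ci": (-0.050, -0.036), "p": 0.000},
    ("apoe4", "ad"): {"beta": -0.220, "ci": (-0.312, -0.129), "p": 0.000},
    ("apoe4", "svd"): {"beta": -0.003, "ci": (-0.009, 0.002), "p": 0.255},
    ("apoe4", "neuro"): {"beta": -0.114, "ci": (-0.165, -0.064), "p": 0.000},
}

#: Published total effects on cognition (only those printed in the source).
TOTAL_EFFECTS: dict[str, dict] = {
    "si": {"beta": 0.390, "ci": (0.351, 0.429)},
    "li": {"beta": 0.153, "ci": (0.112, 0.193)},
    "sex": {"beta": 0.186, "ci": (0.100, 0.273)},
    "age": {"beta": -0.042, "ci": (-0.047, -0.038)},
}

#: Residual correlations among the three pathology mediators.
MEDIATOR_RESIDUAL_CORRELATIONS: dict[tuple[str, str], dict] = {
    ("ad", "neuro"): {"r": 0.249, "ci": (0.143, 0.355)},
    ("ad", "svd"): {"r": 0.139, "ci": (0.052, 0.227)},
    ("svd", "neuro"): {"r": 0.225, "ci": (0.167, 0.283)},
}

#: Global fit of the published structural model.
FIT_INDICES = {
    "rmsea": 0.049,
    "rmsea_ci": (0.046, 0.052),
    "srmr": 0.047,
    "cfi": 0.942,
    "tli": 0.922,
}

#: Baseline categorical margins: per variable, (counts, printed percentages).
#: Percentages are printed as 100 * count / COHORT_N (missing included in the
#: denominator); missing counts are in CATEGORY_MISSING.
CATEGORY_MARGINS: dict[str, dict] = {
    "education": {
        "counts": (371, 677, 362, 908),
        "percent": (16.0, 29.1, 15.6, 39.1),
    },
    "occupation": {"counts": (469, 1093, 735), "percent": (20.2, 47.1, 31.6)},
    "salary": {
        "counts": (46, 126, 311, 407, 640, 341, 135),
        "percent": (2.0, 5.4, 13.4, 17.5, 27.6, 14.7, 5.8),
    },
    "physical_activity": {
        "counts": (350, 902, 818),
        "percent": (15.1, 38.8, 35.2),
    },
    "leisure_quartile": {
        "counts": (594, 782, 580, 238),
        "percent": (25.6, 33.7, 25.0, 10.2),
    },
    "sni": {"counts": (174, 642, 1085, 280), "percent": (7.5, 27.6, 46.7, 12.1)},
    "apoe4": {"counts": (1538, 658), "percent": (66.2, 28.3)},
    "cdr": {"counts": (933, 1375), "percent": (40.2, 59.2)},
}

#: Item-level missing counts (of COHORT_N) from the baseline table footnote.
CATEGORY_MISSING: dict[str, int] = {
    "apoe4": 127,
    "cdr": 15,
    "education": 5,
    "occupation": 26,
    "salary": 317,
    "physical_activity": 253,
    "leisure_quartile": 129,
    "sni": 142,
}

#: Continuous baseline margins.
AGE_MEAN, AGE_SD = 70.9, 8.7
WOMEN_COUNT = 1438          # 61.9% of 2323
APOE4_FREQUENCY = 0.283     # carriers among genotyped
WOMEN_FREQUENCY = WOMEN_COUNT / COHORT_N

#: Modality participation (fraction of the cohort with the measure acquired).
MODALITY_PARTICIPATION = {"csf": 0.18, "amyloid_pet": 0.28, "fdg_pet": 0.57}


def direct_path(source: str, target: str) -> float:
    """Standardized direct path coefficient from the calibration table."""
    return DIRECT_EFFECTS[(source, target)]["beta"]
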