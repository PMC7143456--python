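"""Bundled watershed land-use / water-quality example models and targets.

These fixtures describe a six-variable system — percent urban and
agricultural land (exogenous), BOD / TN / TP concentrations, and the BMI
stream-health score — used by the demo pipeline, the test suite, and the
synthetic-data generator.

The refined coefficient set is a published standardized solution for this
system; the exogenous urban-agricultural correlation is not published and
defaults to 0.2 (any value keeping the covariance matrix positive definite
works).
"""

from __future__ import annotations

import numpy as np

from .path_model import (
    PathModel,
    SampleMoments,
    parse_model,
    solve_unit_variance_residuals,
)
from .synthetic_data import MarginalTarget

__all__ = [
    "VARIABLES",
    "FULL_MODEL_SPEC",
    "REFINED_MODEL_SPEC",
    "REFINED_COEFFICIENTS",
    "DEFAULT_EXOG_CORR",
    "MARGINAL_TARGETS",
    "LOGNORMAL_VARS",
    "full_model",
    "refined_model",
    "refined_population_model",
    "refined_implied_correlation",
]

VARIABLES = ["urban_pct", "agri_pct", "bod", "tn", "tp", "bmi"]

#: hypothesized model: both land-use shares feed every response,
#: all three water-quality variables feed the biotic index
FULL_MODEL_SPEC = """\
urban_pct -> bod
urban_pct -> tn
urban_pct -> tp
urban_pct -> bmi
agri_pct -> bod
agri_pct -> tn
agri_pct -> tp
agri_pct -> bmi
bod -> bmi
tn -> bmi
tp -> bmi
urban_pct ~~ agri_pct
"""

#: standardized solution of the refined (pruned) model
REFINED_COEFFICIENTS: dict[tuple[str, str], float] = {
    ("agri_pct", "bod"): 0.53,
    ("agri_pct", "tp"): 0.43,
    ("agri_pct", "tn"): 0.35,
    ("agri_pct", "bmi"): -0.23,
    ("urban_pct", "bod"): 0.20,
    ("urban_pct", "tp"): 0.26,
    ("urban_pct", "bmi"): -0.29,
    ("bod", "bmi"): -0.33,
}

DEFAULT_EXOG_CORR = 0.2

REFINED_MODEL_SPEC = "\n".join(
    [f"{s} -> {t}" for (s, t) in REFINED_COEFFICIENTS] + ["urban_pct ~~ agri_pct"]
)

#: raw-scale marginal summaries (units: %, %, mg/L, mg/L, mg/L, score)
MARGINAL_TARGETS: dict[str, MarginalTarget] = {
    "bod": MarginalTarget("bod", mean=1.81, sd=1.05, min=0.50, max=7.60),
    "tn": MarginalTarget("tn", mean=3.85, sd=1.88, min=0.69, max=11.20),
    "tp": MarginalTarget("tp", mean=0.05, sd=0.07, min=0.00, max=0.39),
    "urban_pct": MarginalTarget("urban_pct", mean=5.87, sd=4.58, min=0.00, max=21.57),
    "agri_pct": MarginalTarget("agri_pct", mean=26.75, sd=14.26, min=5.68, max=62.50),
    "bmi": MarginalTarget("bmi", mean=66.71, sd=18.82, min=22.6, max=94.7),
}

#: right-skewed variables get the lognormal back-transform; bmi stays affine
LOGNORMAL_VARS = ("bod", "tn", "tp", "urban_pct", "agri_pct")

DEFAULT_N_SITES = 111


def full_model() -> PathModel:
    """The hypothesized model with all parameters free (p=6, df=3)."""
    return parse_model(FULL_MODEL_SPEC)


def refined_model() -> PathModel:
    """The pruned model with all parameters free (8 paths, df=6)."""
    return parse_model(REFINED_MODEL_SPEC)


def refined_population_model(exog_corr: float = DEFAULT_EXOG_CORR) -> PathModel:
    """The refined model as a fully fixed standardized population.

    Coefficients are fixed at the published standardized values, exogenous
    variances at 1 with correlation ``exog_corr``, and residual variances
    solved so every implied variance is exactly 1.
    """
    model = refined_model()
    values = {f"{s}->{t}": v for (s, t), v in REFINED_COEFFICIENTS.items()}
    values["urban_pct~~urban_pct"] = 1.0
    values["agri_pct~~agri_pct"] = 1.0
    values["urban_pct~~agri_pct"] = float(exog_corr)
    # placeholder residuals, replaced by the unit-variance solve below
    for t in model.endogenous:
        values[f"{t}~~{t}"] = 1.0
    fixed = model.with_values(values)
    B, _ = fixed.matrices()
    exog_idx = [fixed.variables.index(v) for v in fixed.exogenous]
    corr = np.array([[1.0, exog_corr], [exog_corr, 1.0]])
    psi = solve_unit_variance_residuals(B, exog_idx, corr)
    for t in fixed.endogenous:
        values[f"{t}~~{t}"] = float(psi[fixed.variables.index(t), fixed.variables.index(t)])
    return model.with_values(values)


def refined_implied_correlation(
    exog_corr: float = DEFAULT_EXOG_CORR, n: int = DEFAULT_N_SITES
) -> SampleMoments:
    """Population correlation matrix implied by the refined model."""
    model = refined_population_model(exog_corr)
    return SampleMoments(S=model.implied(), n=n, names=list(model.variables))
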