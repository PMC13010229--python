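"""The four regression baselines for the estimator comparison.

Linear regressions of the outcome on the exposure, in the 2x2 grid of
{with, without} confounder adjustment x {with, without} survey weights:

* ``naive`` — unadjusted, unweighted;
* ``weights_only`` — unadjusted, survey-weighted;
* ``confounders_only`` — confounder-adjusted, unweighted;
* ``full`` — confounder-adjusted, survey-weighted.

The exposure coefficient with its design-robust Wald CI is reported. Note
these are *conditional* effects when confounders are in the model: in
linear, no-interaction settings they coincide with the marginal effects the
causal estimators target (collapsibility); the ``estimand`` label carries
this distinction so tables cannot silently mix the two.
"""

from __future__ import annotations

from .results import EstimateResult
from .survey_design import SurveyDataset, fit_weighted_glm

__all__ = ["fit_reference_models", "REFERENCE_LABELS"]

REFERENCE_LABELS = ("naive", "weights_only", "confounders_only", "full")


def _one(
    data: SurveyDataset,
    confounder_formula: str | None,
    weighted: bool,
    label: str,
    ci_level: float,
) -> EstimateResult:
    rhs = data.exposure
    adjusted = confounder_formula is not None
    if adjusted:
        rhs = f"{rhs} + {confounder_formula}"
    fit = fit_weighted_glm(
        data, f"{data.outcome} ~ {rhs}", family="linear",
        weights_mode="survey" if weighted else "none",
    )
    coef = data.exposure
    ci = fit.conf_int(ci_level).loc[coef]
    return EstimateResult(
        method=label,
        estimate=float(fit.params[coef]),
        se=float(fit.bse[coef]),
        ci_lower=float(ci["lower"]),
        ci_upper=float(ci["upper"]),
        ci_method="wald_robust",
        weighted=weighted,
        adjusted=adjusted,
        estimand="conditional",  # regression coefficients are conditional effects
        n=data.n,
        metadata={"formula_rhs": rhs},
    )


def fit_reference_models(
    data: SurveyDataset,
    confounder_formula: str,
    ci_level: float = 0.95,
) -> list[EstimateResult]:
    """Fit all four baselines; returns them in the fixed label order."""
    return [
        _one(data, None, False, "naive", ci_level),
        _one(data, None, True, "weights_only", ci_level),
        _one(data, confounder_formula, False, "confounders_only", ci_level),
        _one(data, confounder_formula, True, "full", ci_level),
    ]
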