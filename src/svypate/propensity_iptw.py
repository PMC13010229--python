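"""Inverse probability of treatment weighting (IPTW) for the PATE.

The estimator proceeds in four steps: (1) fit a logistic propensity model
pi_i = P(A=1 | L); (2) form treatment weights t_i = 1/pi_i for exposed and
1/(1-pi_i) for unexposed units, creating a pseudo-population in which the
measured confounders are balanced across arms; (3) estimate the effect as
the difference in t-weighted mean outcomes between arms; (4) attach
model-robust (sandwich) standard errors.

To target the *population* ATE rather than the sample ATE, the survey
weights omega are multiplied into the treatment weights, w_i = t_i * omega_i,
and the weighted contrast is computed with w. Balance (weighted standardized
mean differences) and positivity diagnostics are included.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
import patsy

from .results import EstimateResult
from .survey_design import (
    SurveyDataset,
    WeightedFit,
    _irls_logistic,
    fit_weighted_glm,
    rao_wu_yue_factors,
)

__all__ = [
    "PropensityResult",
    "CombinedWeights",
    "PositivityWarning",
    "fit_propensity",
    "compute_iptw_weights",
    "estimate_iptw_pate",
    "balance_smd",
]


class PositivityWarning(UserWarning):
    """Estimated propensity scores close to 0 or 1."""


@dataclass
class PropensityResult:
    """Fitted exposure-mechanism scores and the model behind them."""

    pi: np.ndarray  # P(A=1 | L) per row, in (0,1)
    fit: WeightedFit
    survey_weighted: bool

    def __post_init__(self) -> None:
        if ((self.pi <= 0) | (self.pi >= 1)).any():
            raise ValueError("propensity scores must lie strictly inside (0,1)")


@dataclass
class CombinedWeights:
    """Treatment weights, survey weights and their product."""

    treatment: np.ndarray  # t_i = A/pi + (1-A)/(1-pi)
    survey: np.ndarray  # omega_i
    analysis: np.ndarray  # w_i = t_i * omega_i (t possibly truncated)
    cap_quantile: float | None = None
    n_capped: int = 0


def fit_propensity(
    data: SurveyDataset,
    formula: str,
    use_survey_weights: bool = False,
    positivity_bounds: tuple[float, float] = (0.001, 0.999),
) -> PropensityResult:
    """Step 1: logistic regression of exposure on confounders.

    ``formula`` gives the right-hand side only (e.g. ``"age + C(eth)"``);
    the exposure column is taken from the dataset. Whether the fit itself
    uses the survey weights is configurable (default: unweighted fit, with
    omega entering only the final analysis weights). Scores outside
    ``positivity_bounds`` raise a :class:`PositivityWarning`.
    """
    desc = patsy.ModelDesc.from_formula(formula)
    factor_code = " ".join(f.name() for t in desc.rhs_termlist for f in t.factors)
    if data.outcome in factor_code.replace("(", " ").replace(")", " ").split():
        raise ValueError("propensity formula must not reference the outcome")
    full = f"{data.exposure} ~ {formula}"
    fit = fit_weighted_glm(
        data, full, family="logistic",
        weights_mode="survey" if use_survey_weights else "none",
    )
    pi = np.asarray(fit.mu, dtype=float)
    lo, hi = positivity_bounds
    n_out = int(((pi < lo) | (pi > hi)).sum())
    if n_out:
        warnings.warn(
            f"{n_out} propensity scores outside ({lo}, {hi}); "
            "possible positivity violation",
            PositivityWarning,
            stacklevel=2,
        )
    return PropensityResult(pi=pi, fit=fit, survey_weighted=use_survey_weights)


def compute_iptw_weights(
    propensity: PropensityResult,
    data: SurveyDataset,
    truncation_quantile: float | None = None,
    stabilized: bool = False,
) -> CombinedWeights:
    """Steps 2 + PATE extension: t_i = 1/pi (exposed) or 1/(1-pi), w = t * omega.

    With ``stabilized`` the marginal exposure prevalence enters the
    numerator (P(A=1)/pi and P(A=0)/(1-pi)). ``truncation_quantile`` q caps
    t symmetrically at its q and 1-q sample quantiles before the survey
    weights are multiplied in; the number of capped values is reported.
    """
    pi = propensity.pi
    if len(pi) != data.n:
        raise ValueError("propensity scores not aligned with data rows")
    a = data.a
    t = np.where(a == 1, 1.0 / pi, 1.0 / (1.0 - pi))
    if stabilized:
        p1 = float(np.average(a, weights=data.weights))
        t = np.where(a == 1, p1, 1.0 - p1) * t

    n_capped = 0
    if truncation_quantile is not None:
        q = float(truncation_quantile)
        if not 0 < q < 0.5:
            raise ValueError("truncation quantile must be in (0, 0.5)")
        lo, hi = np.quantile(t, [q, 1 - q])
        n_capped = int(((t < lo) | (t > hi)).sum())
        t = np.clip(t, lo, hi)

    omega = data.weights
    return CombinedWeights(
        treatment=t,
        survey=omega,
        analysis=t * omega,
        cap_quantile=truncation_quantile,
        n_capped=n_capped,
    )


def _iptw_array_estimate(
    y: np.ndarray,
    a: np.ndarray,
    xp: np.ndarray,
    w_base: np.ndarray,
    prop_w: np.ndarray,
    truncation_quantile: float | None = None,
    stabilized: bool = False,
) -> float:
    """One full IPTW pass on prebuilt arrays (bootstrap fast path):
    refit propensity, rebuild combined weights, weighted mean difference."""
    _, pi, _ = _irls_logistic(xp, a, prop_w)
    pi = np.clip(pi, 1e-10, 1 - 1e-10)
    t = np.where(a == 1, 1.0 / pi, 1.0 / (1.0 - pi))
    if stabilized:
        p1 = float(np.average(a, weights=np.maximum(w_base, 1e-12)))
        t = np.where(a == 1, p1, 1.0 - p1) * t
    if truncation_quantile is not None:
        lo, hi = np.quantile(t, [truncation_quantile, 1 - truncation_quantile])
        t = np.clip(t, lo, hi)
    w = t * w_base
    w1, w0 = w[a == 1], w[a == 0]
    if w1.sum() <= 0 or w0.sum() <= 0:
        raise RuntimeError("an exposure arm has zero total weight")
    return float(
        y[a == 1] @ w1 / w1.sum() - y[a == 0] @ w0 / w0.sum()
    )


def estimate_iptw_pate(
    data: SurveyDataset,
    propensity_formula: str,
    use_survey_weights: bool = True,
    propensity_survey_weighted: bool = False,
    truncation_quantile: float | None = None,
    stabilized: bool = False,
    ci_level: float = 0.95,
    ci_method: str = "wald_robust",
    bootstrap_reps: int = 1000,
    bootstrap_scheme: str = "rows",
    seed: int | None = None,
) -> EstimateResult:
    """Steps 3-4: weighted mean-difference estimate with robust Wald CI.

    The contrast is computed as the exposure coefficient of a w-weighted
    linear regression of Y on A (identical to the difference in w-weighted
    arm means). The default CI is the design-robust sandwich Wald interval
    (which treats the estimated weights as fixed);
    ``ci_method='percentile_bootstrap'`` instead re-runs the whole
    procedure — propensity fit included — on each resample, putting the CI
    on the same footing as the bootstrap CIs of G-computation and TMLE.
    With ``use_survey_weights`` False, omega is replaced by 1 and the
    estimator targets the sample ATE instead of the PATE.
    """
    if ci_method not in ("wald_robust", "percentile_bootstrap"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    if ci_method == "percentile_bootstrap":
        if bootstrap_reps < 1:
            raise ValueError("percentile bootstrap requires bootstrap_reps >= 1")
        if bootstrap_scheme not in ("rows", "rao_wu_yue"):
            raise ValueError(f"unknown bootstrap scheme {bootstrap_scheme!r}")
    prop = fit_propensity(
        data, propensity_formula, use_survey_weights=propensity_survey_weighted
    )
    cw = compute_iptw_weights(
        prop, data, truncation_quantile=truncation_quantile, stabilized=stabilized
    )
    w = cw.analysis if use_survey_weights else cw.treatment

    a = data.a
    for arm in (0, 1):
        if w[a == arm].sum() <= 0:
            raise RuntimeError(f"exposure arm A={arm} has zero total weight")

    fit = fit_weighted_glm(
        data, f"{data.outcome} ~ {data.exposure}",
        family="linear", weights_mode="supplied", weights=w,
    )
    coef = data.exposure
    est = float(fit.params[coef])
    se = float(fit.bse[coef])

    if ci_method == "wald_robust":
        ci = fit.conf_int(ci_level).loc[coef]
        ci_lo, ci_hi = float(ci["lower"]), float(ci["upper"])
    else:
        rng = np.random.default_rng(seed)
        xp = np.asarray(patsy.dmatrix(propensity_formula, data.data))
        y, n = data.y, data.n
        base = data.weights if use_survey_weights else np.ones(n)
        reps, n_failed = [], 0
        for _ in range(bootstrap_reps):
            if bootstrap_scheme == "rows":
                idx = rng.integers(0, n, size=n)
                args = (y[idx], a[idx], xp[idx], base[idx])
            else:
                factor = rao_wu_yue_factors(data.strata, data.psus, rng)
                args = (y, a, xp, base * factor)
            try:
                w_b = args[3]
                prop_w = w_b if propensity_survey_weighted else (w_b > 0).astype(float)
                reps.append(
                    _iptw_array_estimate(
                        *args, prop_w, truncation_quantile, stabilized
                    )
                )
            except Exception:  # noqa: BLE001 - replicate-level failure
                n_failed += 1
                if n_failed > max(1, bootstrap_reps // 2):
                    raise RuntimeError(
                        f"IPTW failed on {n_failed} bootstrap replicates"
                    ) from None
        arr = np.asarray(reps)
        alpha = 1 - ci_level
        ci_lo = float(np.quantile(arr, alpha / 2))
        ci_hi = float(np.quantile(arr, 1 - alpha / 2))
        se = float(arr.std(ddof=1))
        ci_lo, ci_hi = min(ci_lo, est), max(ci_hi, est)

    return EstimateResult(
        method="IPTW",
        estimate=est,
        se=se,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        ci_method=ci_method,
        weighted=use_survey_weights,
        adjusted=True,
        estimand="marginal",
        n=data.n,
        metadata={
            "propensity_formula": propensity_formula,
            "propensity_survey_weighted": propensity_survey_weighted,
            "stabilized": stabilized,
            "truncation_quantile": truncation_quantile,
            "n_capped": cw.n_capped,
        },
    )


def balance_smd(
    data: SurveyDataset,
    confounders: list[str],
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Standardized mean differences per confounder, before and after weighting.

    SMD = (weighted mean difference between arms) / pooled *unweighted* SD,
    so the denominator is fixed and only the numerator responds to the
    weights. Categorical columns are expanded to level indicators.
    Zero-variance covariates yield NaN rather than an error.
    """
    df = data.data
    a = data.a
    cols: dict[str, np.ndarray] = {}
    for name in confounders:
        col = df[name]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            cols[name] = col.to_numpy(dtype=float)
        else:
            for lvl in sorted(col.unique())[1:] if col.nunique() == 2 else sorted(col.unique()):
                cols[f"{name}=={lvl}"] = (col == lvl).to_numpy(dtype=float)

    def smd(x: np.ndarray, w: np.ndarray) -> float:
        m1 = np.average(x[a == 1], weights=w[a == 1])
        m0 = np.average(x[a == 0], weights=w[a == 0])
        s1, s0 = x[a == 1].var(ddof=1), x[a == 0].var(ddof=1)
        pooled = np.sqrt((s1 + s0) / 2)
        if pooled == 0:
            return float("nan")
        return float((m1 - m0) / pooled)

    ones = np.ones(data.n)
    w_after = ones if weights is None else np.asarray(weights, dtype=float)
    rows = [
        {
            "covariate": name,
            "smd_unweighted": smd(x, ones),
            "smd_weighted": smd(x, w_after),
        }
        for name, x in cols.items()
    ]
    return pd.DataFrame(rows)
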