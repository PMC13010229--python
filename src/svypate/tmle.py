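"""Targeted maximum likelihood estimation (TMLE) of the PATE.

TMLE combines the outcome model of G-computation with the propensity score
of IPTW. Starting from initial predictions Q_hat(A, L), a "clever
covariate"

    H_i = A_i / pi_i - (1 - A_i) / (1 - pi_i)

is built from the propensity scores and used in a one-parameter fluctuation
regression of the residual Y - Q_hat(A, L) on H; the fitted coefficient
eps_hat updates the counterfactual predictions,

    Q*(a, L) = Q_hat(a, L) + eps_hat * H(a),

after which the effect is the (survey-weighted) mean of Q*(1,L) - Q*(0,L).
The update solves the efficient-influence-curve score equation, which is
what gives TMLE its double robustness: the estimate is consistent if either
the outcome model or the propensity model is correctly specified.

Survey weights can enter the targeting step in two algebraically equivalent
ways (they solve the same weighted score equation):

* ``plain`` (default): H is the pure inverse-propensity quantity and omega
  enters as the regression weight of the fluctuation — numerically stabler;
* ``weight_embedded``: H itself is multiplied by omega (the combined
  survey x treatment weight) and the fluctuation regression is unweighted.

Outcomes here are continuous (mmHg scale), so the fluctuation is linear on
the identity link; no bounded-logistic transform is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

import patsy

from .gcomputation import design_arrays, fit_outcome_model, predict_counterfactuals
from .propensity_iptw import fit_propensity
from .results import EstimateResult
from .survey_design import (
    SurveyDataset,
    _irls_logistic,
    _wls_beta,
    rao_wu_yue_factors,
    weighted_mean,
)

__all__ = [
    "CleverCovariate",
    "TargetedFit",
    "clever_covariate",
    "tmle_point_estimate",
    "tmle_pate",
]

_VARIANTS = ("plain", "weight_embedded")


@dataclass
class CleverCovariate:
    """Signed inverse-propensity covariate driving the targeting step.

    ``h`` is evaluated at the observed exposure; ``h1`` and ``h0`` at
    exposure forced to 1 and 0 (needed to update both counterfactuals).
    """

    h: np.ndarray
    h1: np.ndarray
    h0: np.ndarray
    variant: str


@dataclass
class TargetedFit:
    """Initial and targeted (fluctuated) outcome predictions."""

    q_obs: np.ndarray  # Q_hat(A, L) at observed exposure
    q1: np.ndarray  # Q_hat(1, L)
    q0: np.ndarray  # Q_hat(0, L)
    epsilon: float  # fluctuation coefficient
    q1_star: np.ndarray  # Q*(1, L) = Q_hat(1, L) + eps * H(1)
    q0_star: np.ndarray


def clever_covariate(
    exposure: np.ndarray,
    pi: np.ndarray,
    variant: str = "plain",
    survey_weights: np.ndarray | None = None,
) -> CleverCovariate:
    """H_i = A_i/pi_i - (1-A_i)/(1-pi_i), optionally times omega_i."""
    if variant not in _VARIANTS:
        raise ValueError(f"unknown clever-covariate variant {variant!r}")
    pi = np.asarray(pi, dtype=float)
    if ((pi <= 0) | (pi >= 1)).any():
        raise ValueError("propensity scores at 0 or 1: cannot form clever covariate")
    a = np.asarray(exposure, dtype=float)
    h1 = 1.0 / pi
    h0 = -1.0 / (1.0 - pi)
    h = np.where(a == 1, h1, h0)
    if variant == "weight_embedded":
        if survey_weights is None:
            raise ValueError("weight_embedded variant requires survey weights")
        w = np.asarray(survey_weights, dtype=float)
        h, h1, h0 = h * w, h1 * w, h0 * w
    return CleverCovariate(h=h, h1=h1, h0=h0, variant=variant)


def _fluctuate(
    y: np.ndarray,
    q_obs: np.ndarray,
    cc: CleverCovariate,
    fluctuation_weights: np.ndarray,
) -> float:
    """One-parameter no-intercept WLS of (Y - Q_hat) on H."""
    num = float(np.sum(fluctuation_weights * cc.h * (y - q_obs)))
    den = float(np.sum(fluctuation_weights * cc.h**2))
    if den <= 0 or not np.isfinite(num / den):
        raise RuntimeError(
            "non-finite fluctuation coefficient; extreme clever-covariate "
            f"values (max |H| = {np.abs(cc.h).max():.3g})"
        )
    return num / den


def _target(
    data: SurveyDataset,
    outcome_formula: str,
    propensity_formula: str,
    variant: str,
    use_survey_weights: bool,
    propensity_survey_weighted: bool,
) -> TargetedFit:
    model = fit_outcome_model(
        data, outcome_formula, use_survey_weights=use_survey_weights
    )
    q_obs = model.fit.mu
    plug = predict_counterfactuals(model, data, mode="plugin")
    q1, q0 = plug.y1[:, 0], plug.y0[:, 0]

    prop = fit_propensity(
        data, propensity_formula, use_survey_weights=propensity_survey_weighted
    )
    omega = data.weights if use_survey_weights else np.ones(data.n)
    cc = clever_covariate(data.a, prop.pi, variant=variant, survey_weights=omega)
    # plain variant: omega enters as fluctuation regression weight;
    # weight_embedded: omega already lives inside H, regression unweighted
    fw = omega if variant == "plain" else np.ones(data.n)
    eps = _fluctuate(data.y, q_obs, cc, fw)
    return TargetedFit(
        q_obs=q_obs,
        q1=q1,
        q0=q0,
        epsilon=eps,
        q1_star=q1 + eps * cc.h1,
        q0_star=q0 + eps * cc.h0,
    )


def tmle_point_estimate(
    data: SurveyDataset,
    outcome_formula: str,
    propensity_formula: str,
    variant: str = "plain",
    use_survey_weights: bool = True,
    propensity_survey_weighted: bool = False,
) -> float:
    """Omega-weighted mean of Q*(1,L) - Q*(0,L)."""
    tf = _target(
        data, outcome_formula, propensity_formula, variant,
        use_survey_weights, propensity_survey_weighted,
    )
    w = data.weights if use_survey_weights else np.ones(data.n)
    return weighted_mean(tf.q1_star - tf.q0_star, w)


def _tmle_array_estimate(
    y: np.ndarray,
    a: np.ndarray,
    xq: np.ndarray,
    xq1: np.ndarray,
    xq0: np.ndarray,
    xp: np.ndarray,
    w: np.ndarray,
    variant: str,
    propensity_survey_weighted: bool,
) -> float:
    """One full TMLE pass on prebuilt design matrices (bootstrap fast path).

    ``w`` is the analysis weight for this replicate (survey weight, unit
    weight, or Rao-Wu-Yue rescaled weight); zero-weight rows carry no
    information in any of the fits or averages.
    """
    active = w > 0
    prop_w = w if propensity_survey_weighted else active.astype(float)

    beta_q = _wls_beta(xq, y, w)
    q_obs, q1, q0 = xq @ beta_q, xq1 @ beta_q, xq0 @ beta_q
    _, pi, _ = _irls_logistic(xp, a, prop_w)
    pi = np.clip(pi, 1e-10, 1 - 1e-10)

    cc = clever_covariate(a, pi, variant=variant, survey_weights=w)
    flw = w if variant == "plain" else active.astype(float)
    eps = _fluctuate(y, q_obs, cc, flw)
    return weighted_mean(
        (q1 + eps * cc.h1 - (q0 + eps * cc.h0))[active], w[active]
    )


def _influence_curve_se(
    data: SurveyDataset, tf: TargetedFit, cc_h: np.ndarray, w: np.ndarray, psi: float
) -> float:
    """Weighted efficient-influence-curve SE (fast approximation; ignores
    the multi-stage design beyond the weights)."""
    ic = cc_h * (data.y - (tf.q_obs + tf.epsilon * cc_h)) + (
        tf.q1_star - tf.q0_star
    ) - psi
    wn = w / w.sum()
    var = float(np.sum(wn**2 * ic**2))
    return float(np.sqrt(var))


def tmle_pate(
    data: SurveyDataset,
    outcome_formula: str,
    propensity_formula: str,
    variant: str = "plain",
    use_survey_weights: bool = True,
    propensity_survey_weighted: bool = False,
    bootstrap_reps: int = 10_000,
    bootstrap_scheme: str = "rows",
    ci_level: float = 0.95,
    ci_method: str = "percentile_bootstrap",
    seed: int | None = None,
) -> EstimateResult:
    """Full TMLE estimate with percentile-bootstrap CI.

    ``ci_method='influence_curve'`` substitutes the fast weighted
    influence-curve Wald interval (which ignores stratification/clustering).
    Set ``bootstrap_reps=0`` with the bootstrap method to skip the CI.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"unknown clever-covariate variant {variant!r}")
    tf = _target(
        data, outcome_formula, propensity_formula, variant,
        use_survey_weights, propensity_survey_weighted,
    )
    w = data.weights if use_survey_weights else np.ones(data.n)
    point = weighted_mean(tf.q1_star - tf.q0_star, w)

    se = ci_lo = ci_hi = None
    method_used = None
    if ci_method == "influence_curve":
        prop = fit_propensity(
            data, propensity_formula, use_survey_weights=propensity_survey_weighted
        )
        cc = clever_covariate(data.a, prop.pi, variant=variant, survey_weights=w)
        se = _influence_curve_se(data, tf, cc.h, w, point)
        from scipy import stats

        zq = stats.norm.ppf(0.5 + ci_level / 2)
        ci_lo, ci_hi = point - zq * se, point + zq * se
        method_used = "influence_curve_wald"
    elif bootstrap_reps > 0:
        if bootstrap_scheme not in ("rows", "rao_wu_yue"):
            raise ValueError(f"unknown bootstrap scheme {bootstrap_scheme!r}")
        rng = np.random.default_rng(seed)
        y, xq, xq1, xq0 = design_arrays(data, outcome_formula)
        xp = np.asarray(patsy.dmatrix(propensity_formula, data.data))
        a, omega, n = data.a, data.weights, data.n
        reps, n_failed = [], 0
        base_w = omega if use_survey_weights else np.ones(n)
        for _ in range(bootstrap_reps):
            if bootstrap_scheme == "rows":
                idx = rng.integers(0, n, size=n)
                args = (y[idx], a[idx], xq[idx], xq1[idx], xq0[idx], xp[idx],
                        base_w[idx])
            else:
                factor = rao_wu_yue_factors(data.strata, data.psus, rng)
                args = (y, a, xq, xq1, xq0, xp, base_w * factor)
            try:
                reps.append(
                    _tmle_array_estimate(
                        *args, variant, propensity_survey_weighted,
                    )
                )
            except Exception:  # noqa: BLE001 - replicate-level failure
                n_failed += 1
                if n_failed > max(1, bootstrap_reps // 2):
                    raise RuntimeError(
                        f"TMLE failed on {n_failed} bootstrap replicates"
                    ) from None
        arr = np.asarray(reps)
        alpha = 1 - ci_level
        ci_lo = float(np.quantile(arr, alpha / 2))
        ci_hi = float(np.quantile(arr, 1 - alpha / 2))
        se = float(arr.std(ddof=1))
        ci_lo, ci_hi = min(ci_lo, point), max(ci_hi, point)
        method_used = "percentile_bootstrap"

    return EstimateResult(
        method="TMLE",
        estimate=point,
        se=se,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        ci_method=method_used,
        weighted=use_survey_weights,
        adjusted=True,
        estimand="marginal",
        n=data.n,
        metadata={
            "outcome_formula": outcome_formula,
            "propensity_formula": propensity_formula,
            "variant": variant,
            "epsilon": tf.epsilon,
            "propensity_survey_weighted": propensity_survey_weighted,
            "bootstrap_reps": bootstrap_reps,
            "bootstrap_scheme": bootstrap_scheme,
            "seed": seed,
        },
    )
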