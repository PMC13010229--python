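"""Weighted-estimation machinery for complex-survey data.

Everything in this package that touches a survey weight routes through this
module: Horvitz-Thompson style weighted means with design-based (Taylor
linearization) standard errors, probability-weighted generalized linear
models with a stratum/PSU-aware sandwich variance, and percentile-bootstrap
resampling (plain rows or Rao-Wu-Yue rescaling).

Weights are always treated as *probability* weights, i.e. they enter the
estimating equations, never as frequency (case-replication) weights. Point
estimates are therefore invariant to rescaling all weights by a positive
constant, and the variance is the design-robust sandwich rather than the
model-based one.
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import patsy

__all__ = [
    "SurveyDataset",
    "WeightedFit",
    "BootstrapResult",
    "SurveyDesignError",
    "ConvergenceError",
    "SeparationError",
    "SingletonPSUError",
    "weighted_mean",
    "weighted_mean_se",
    "fit_weighted_glm",
    "bootstrap",
]


class SurveyDesignError(ValueError):
    """Invalid survey data or design specification."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the deviance trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(f"{message} (deviance trace: {trace})")
        self.trace = trace


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation in a logistic fit."""


class SingletonPSUError(SurveyDesignError):
    """A stratum contains a single PSU, so its variance contribution is undefined."""


# ---------------------------------------------------------------------------
# SurveyDataset
# ---------------------------------------------------------------------------


@dataclass
class SurveyDataset:
    """One row per sampled unit: outcome, exposure, confounders, design columns.

    Parameters
    ----------
    data:
        Data frame holding the outcome, exposure and confounder columns.
    outcome, exposure, weight:
        Column names for the continuous outcome Y, the binary exposure A and
        the survey weight omega (> 0). If ``weight`` is None a unit weight
        column is attached (self-weighting sample).
    stratum, psu:
        Optional design labels. If PSU labels are present every PSU must map
        to exactly one stratum.
    """

    data: pd.DataFrame
    outcome: str = "Y"
    exposure: str = "A"
    weight: str | None = "weight"
    stratum: str | None = None
    psu: str | None = None
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool = True) -> None:
        df = self.data
        if not validate:
            # trusted construction from already-validated rows (resampling)
            if self.weight is None:
                self.weight = "_unit_weight"
                self.data = df.assign(**{self.weight: 1.0})
            return
        for col in (self.outcome, self.exposure):
            if col not in df.columns:
                raise SurveyDesignError(f"column {col!r} not in data")
            if df[col].isna().any():
                raise SurveyDesignError(f"missing values in required column {col!r}")
        if self.weight is None:
            self.weight = "_unit_weight"
            self.data = df = df.assign(**{self.weight: 1.0})
        if self.weight not in df.columns:
            raise SurveyDesignError(f"weight column {self.weight!r} not in data")
        w = df[self.weight].to_numpy(dtype=float)
        if np.isnan(w).any() or (w <= 0).any():
            raise SurveyDesignError("survey weights must be positive and non-missing")
        a = df[self.exposure].to_numpy()
        if not np.isin(a, (0, 1)).all():
            raise SurveyDesignError("exposure must be coded 0/1")
        if self.psu is not None:
            if self.stratum is None:
                raise SurveyDesignError("PSU labels require stratum labels")
            n_strata = df.groupby(self.psu, observed=True)[self.stratum].nunique()
            if (n_strata > 1).any():
                bad = n_strata[n_strata > 1].index.tolist()
                raise SurveyDesignError(f"PSUs mapped to multiple strata: {bad}")

    # convenience accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def y(self) -> np.ndarray:
        return self.data[self.outcome].to_numpy(dtype=float)

    @property
    def a(self) -> np.ndarray:
        return self.data[self.exposure].to_numpy(dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return self.data[self.weight].to_numpy(dtype=float)

    @property
    def strata(self) -> np.ndarray | None:
        return None if self.stratum is None else self.data[self.stratum].to_numpy()

    @property
    def psus(self) -> np.ndarray | None:
        return None if self.psu is None else self.data[self.psu].to_numpy()

    def replace_data(self, data: pd.DataFrame) -> "SurveyDataset":
        """Same design metadata over new rows (used by resampling)."""
        return SurveyDataset(
            data=data,
            outcome=self.outcome,
            exposure=self.exposure,
            weight=self.weight,
            stratum=self.stratum,
            psu=self.psu,
            validate=False,
        )

    # CSV round trip ---------------------------------------------------------
    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path,
        outcome: str = "Y",
        exposure: str = "A",
        weight: str | None = "weight",
        stratum: str | None = None,
        psu: str | None = None,
    ) -> "SurveyDataset":
        return cls(
            data=pd.read_csv(path),
            outcome=outcome,
            exposure=exposure,
            weight=weight,
            stratum=stratum,
            psu=psu,
        )


# ---------------------------------------------------------------------------
# Weighted means with linearization SE
# ---------------------------------------------------------------------------


def weighted_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    """Hajek (ratio) estimator sum(w*x)/sum(w)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise SurveyDesignError("values and weights must have equal length")
    if (w <= 0).any():
        raise SurveyDesignError("weights must be positive")
    tot = w.sum()
    if tot <= 0:
        raise SurveyDesignError("total weight is zero")
    return float(v @ w / tot)


def _psu_totals(
    z: np.ndarray, strata: np.ndarray | None, psus: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate linearized scores to PSU totals; rows-as-PSUs fallback.

    Returns (stratum id per PSU, PSU totals) with z of shape (n,) or (n, p).
    """
    n = z.shape[0]
    if strata is None:
        strata = np.zeros(n, dtype=int)
    if psus is None:
        psus = np.arange(n)
    key = pd.MultiIndex.from_arrays([strata, psus])
    df = pd.DataFrame(np.atleast_2d(z.T).T, index=key)
    tot = df.groupby(level=[0, 1], observed=True).sum()
    return tot.index.get_level_values(0).to_numpy(), tot.to_numpy()


def _linearized_variance(
    z: np.ndarray,
    strata: np.ndarray | None,
    psus: np.ndarray | None,
    single_psu: str = "error",
) -> np.ndarray:
    """With-replacement first-stage variance of sum(z) from PSU totals.

    V = sum_h n_h/(n_h-1) sum_j (z_hj - zbar_h)(z_hj - zbar_h)'

    ``single_psu='center'`` scores a lone PSU against the grand mean of all
    PSU totals instead of erroring — a conservative convention for designs
    where collapsing strata is not an option.
    """
    h_of_psu, totals = _psu_totals(z, strata, psus)
    p = totals.shape[1]
    v = np.zeros((p, p))
    grand = totals.mean(axis=0)
    for h in pd.unique(h_of_psu):
        sub = totals[h_of_psu == h]
        n_h = len(sub)
        if n_h < 2:
            if single_psu == "center":
                dev = sub - grand
                v += dev.T @ dev
                continue
            raise SingletonPSUError(
                f"stratum {h!r} has a single PSU; variance undefined "
                "(merge strata or opt into single_psu='center')"
            )
        dev = sub - sub.mean(axis=0)
        v += (n_h / (n_h - 1)) * dev.T @ dev
    return v


def weighted_mean_se(
    values: Sequence[float],
    weights: Sequence[float],
    strata: Sequence | None = None,
    psus: Sequence | None = None,
    single_psu: str = "error",
) -> tuple[float, float]:
    """Weighted mean and its design-based (Taylor linearization) SE.

    The SE uses the with-replacement first-stage approximation: the
    linearized score of the ratio mean, z_i = w_i (x_i - mean) / sum(w), is
    summed within PSUs and its between-PSU variance computed per stratum.
    Without design labels every row is its own PSU in one stratum. A
    stratum with a single PSU is an error unless ``single_psu='center'``
    (lone PSU scored against the grand mean).
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    mean = weighted_mean(v, w)
    z = (w * (v - mean) / w.sum())[:, None]
    strata_arr = None if strata is None else np.asarray(strata)
    psus_arr = None if psus is None else np.asarray(psus)
    var = _linearized_variance(z, strata_arr, psus_arr, single_psu)[0, 0]
    return mean, float(np.sqrt(var))


# ---------------------------------------------------------------------------
# Weighted GLM (linear / logistic) with design-robust sandwich
# ---------------------------------------------------------------------------


@dataclass
class WeightedFit:
    """A probability-weighted GLM fit with design-robust covariance."""

    family: str
    formula: str
    params: pd.Series
    cov: pd.DataFrame  # sandwich, stratum/PSU aware when labels given
    weights: np.ndarray
    converged: bool
    design_info: patsy.DesignInfo = field(repr=False)
    mu: np.ndarray = field(repr=False, default=None)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def linpred(self, data: pd.DataFrame) -> np.ndarray:
        x = patsy.build_design_matrices([self.design_info], data)[0]
        return np.asarray(x) @ self.params.to_numpy()

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        eta = self.linpred(data)
        if self.family == "logistic":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        from scipy import stats

        zq = stats.norm.ppf(0.5 + level / 2)
        lo = self.params - zq * self.bse
        hi = self.params + zq * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})


def _wls_beta(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted least-squares coefficients (probability weights)."""
    xtw = x.T * w
    try:
        return np.linalg.solve(xtw @ x, xtw @ y)
    except np.linalg.LinAlgError as exc:
        raise SurveyDesignError("singular design matrix") from exc


def _hc0_cov(x: np.ndarray, resid_w: np.ndarray, bread: np.ndarray) -> np.ndarray:
    """Rows-as-PSUs sandwich; resid_w = w * (y - mu)."""
    score = x * resid_w[:, None]
    n = len(resid_w)
    meat = (n / (n - 1)) * (score - score.mean(axis=0)).T @ (score - score.mean(axis=0))
    return bread @ meat @ bread


def _irls_logistic(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, tol: float = 1e-10, maxit: int = 60
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Weighted logistic MLE by iteratively reweighted least squares."""
    n, p = x.shape
    beta = np.zeros(p)
    # start the intercept at the weighted logit of the mean, if intercept-like
    trace: list[float] = []
    dev_old = np.inf
    for _ in range(maxit):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        s = mu * (1 - mu)
        wls_w = w * s
        z = eta + (y - mu) / s
        xtw = x.T * wls_w
        try:
            beta_new = np.linalg.solve(xtw @ x, xtw @ z)
        except np.linalg.LinAlgError as exc:  # singular information
            raise SeparationError(
                "singular information matrix in logistic fit; "
                "check for separation or collinear covariates"
            ) from exc
        dev = -2.0 * float(w @ (y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        trace.append(dev)
        if not np.isfinite(dev):
            raise ConvergenceError("logistic deviance diverged", trace)
        if abs(dev - dev_old) < tol * (abs(dev) + 0.1):
            beta = beta_new
            break
        beta, dev_old = beta_new, dev
    else:
        raise ConvergenceError("IRLS did not converge", trace)
    eta = x @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    # quasi-separation: fitted probabilities numerically at the boundary
    # (rows with zero weight carry no information and are not checked)
    active = w > 0
    at_edge = ((mu < 1e-8) | (mu > 1 - 1e-8)) & active
    if at_edge.any():
        frac = float(at_edge.sum() / max(active.sum(), 1))
        raise SeparationError(
            f"perfect or quasi-perfect separation: {frac:.1%} of fitted "
            "probabilities at the boundary; review the covariate set"
        )
    return beta, mu, trace


def fit_weighted_glm(
    data: SurveyDataset | pd.DataFrame,
    formula: str,
    family: str = "linear",
    weights_mode: str = "survey",
    weights: np.ndarray | None = None,
) -> WeightedFit:
    """Fit a probability-weighted linear or logistic model.

    The score equations are sum_i w_i x_i (y_i - mu_i) = 0 and the variance
    is the design-robust sandwich B M B with bread B the inverse weighted
    information and meat M the stratified between-PSU covariance of the PSU
    score totals (rows as PSUs when labels are absent — this is HC0-type
    robustness).

    weights_mode: 'none' (unit weights), 'survey' (the dataset's omega) or
    'supplied' (the ``weights`` argument, e.g. combined omega x IPTW weights).
    """
    if isinstance(data, SurveyDataset):
        df, strata, psus = data.data, data.strata, data.psus
        survey_w = data.weights
    else:
        df, strata, psus, survey_w = data, None, None, None

    if family not in ("linear", "logistic"):
        raise SurveyDesignError(f"unknown family {family!r}")
    if weights_mode == "none":
        w = np.ones(len(df))
    elif weights_mode == "survey":
        if survey_w is None:
            raise SurveyDesignError("survey weights requested but data has none")
        w = survey_w.astype(float)
    elif weights_mode == "supplied":
        if weights is None:
            raise SurveyDesignError("weights_mode='supplied' requires weights")
        w = np.asarray(weights, dtype=float)
    else:
        raise SurveyDesignError(f"unknown weights_mode {weights_mode!r}")
    if (w <= 0).any():
        raise SurveyDesignError("analysis weights must be positive")

    ymat, xmat = patsy.dmatrices(formula, df, return_type="dataframe")
    y = ymat.to_numpy(dtype=float).ravel()
    x = xmat.to_numpy(dtype=float)
    names = list(xmat.columns)
    design_info = xmat.design_info

    if family == "logistic":
        uniq = np.unique(y)
        if len(uniq) < 2:
            raise SeparationError(
                "response takes a single value; logistic model is degenerate"
            )
        beta, mu, _ = _irls_logistic(x, y, w)
        s = mu * (1 - mu)
        bread = np.linalg.inv(x.T @ (x * (w * s)[:, None]))
    else:
        xtw = x.T * w
        xtwx = xtw @ x
        try:
            beta = np.linalg.solve(xtwx, xtw @ y)
        except np.linalg.LinAlgError as exc:
            raise SurveyDesignError("singular design matrix") from exc
        mu = x @ beta
        bread = np.linalg.inv(xtwx)

    score = x * (w * (y - mu))[:, None]
    meat = _linearized_variance(score, strata, psus)
    cov = bread @ meat @ bread
    cov = (cov + cov.T) / 2  # symmetrize against round-off

    return WeightedFit(
        family=family,
        formula=formula,
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        weights=w,
        converged=True,
        design_info=design_info,
        mu=mu,
    )


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    estimates: np.ndarray  # replicate statistics (failures dropped)
    ci: tuple[float, float]
    level: float
    scheme: str
    n_failed: int

    @property
    def se(self) -> float:
        return float(np.std(self.estimates, ddof=1))


def _resample_rows(data: SurveyDataset, rng: np.random.Generator) -> SurveyDataset:
    idx = rng.integers(0, data.n, size=data.n)
    return data.replace_data(data.data.iloc[idx].reset_index(drop=True))


def rao_wu_yue_factors(
    strata: np.ndarray, psus: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-row weight rescaling factors for one Rao-Wu-Yue replicate.

    Within each stratum, n_h - 1 of its n_h PSUs are drawn with replacement
    and every row's weight is multiplied by (n_h / (n_h - 1)) x the
    multiplicity of its PSU (0 for PSUs not drawn).
    """
    factor = np.empty(len(strata), dtype=float)
    for h in pd.unique(strata):
        in_h = strata == h
        psu_h = psus[in_h]
        psu_ids = pd.unique(psu_h)
        n_h = len(psu_ids)
        if n_h < 2:
            raise SingletonPSUError(
                f"stratum {h!r} has a single PSU; Rao-Wu-Yue bootstrap undefined"
            )
        draw = rng.choice(n_h, size=n_h - 1, replace=True)
        mult = np.bincount(draw, minlength=n_h)
        lookup = dict(zip(psu_ids, (n_h / (n_h - 1)) * mult))
        factor[in_h] = [lookup[p] for p in psu_h]
    return factor


def _resample_rao_wu_yue(
    data: SurveyDataset, rng: np.random.Generator
) -> SurveyDataset:
    """Rao-Wu-Yue rescaling bootstrap as a dataset transform."""
    factor = rao_wu_yue_factors(data.strata, data.psus, rng)
    keep = factor > 0
    df = data.data.loc[keep].copy()
    df[data.weight] = df[data.weight].to_numpy() * factor[keep]
    return data.replace_data(df.reset_index(drop=True))


def bootstrap(
    data: SurveyDataset,
    statistic: Callable[[SurveyDataset], float],
    b: int = 1000,
    scheme: str = "rows",
    seed: int | np.random.Generator | None = None,
    level: float = 0.95,
) -> BootstrapResult:
    """Percentile bootstrap of an arbitrary statistic of a SurveyDataset.

    ``rows`` resamples records with replacement (weights carried along);
    ``rao_wu_yue`` resamples n_h - 1 PSUs per stratum with the standard
    weight rescaling and requires stratum+PSU labels. Replicates on which
    the statistic raises are dropped; more than 50% failures aborts.
    """
    if b < 1:
        raise SurveyDesignError("bootstrap requires B >= 1")
    if scheme not in ("rows", "rao_wu_yue"):
        raise SurveyDesignError(f"unknown bootstrap scheme {scheme!r}")
    if scheme == "rao_wu_yue" and (data.stratum is None or data.psu is None):
        raise SurveyDesignError("rao_wu_yue bootstrap requires stratum and PSU labels")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    resample = _resample_rows if scheme == "rows" else _resample_rao_wu_yue
    estimates, failures = [], []
    for _ in range(b):
        rep = resample(data, rng)
        try:
            estimates.append(float(statistic(rep)))
        except Exception as exc:  # noqa: BLE001 - replicate-level failure is data
            failures.append(exc)
            if len(failures) > max(1, b // 2):
                raise RuntimeError(
                    f"statistic failed on {len(failures)} of {b} replicates; "
                    f"last error: {failures[-1]!r}"
                ) from failures[-1]
    est = np.asarray(estimates)
    alpha = 1 - level
    ci = (
        float(np.quantile(est, alpha / 2)),
        float(np.quantile(est, 1 - alpha / 2)),
    )
    return BootstrapResult(
        estimates=est, ci=ci, level=level, scheme=scheme, n_failed=len(failures)
    )
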