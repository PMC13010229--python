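"""Synthetic superpopulations and informative survey samples with known truth.

The generator emulates the qualitative features of a national health survey
(NHANES-style) needed to exercise PATE estimators without any download:

* a superpopulation with mixed confounders — an age-like and an income-like
  continuous covariate, a binary sex-like covariate, and a three-level
  ethnicity-like covariate;
* a binary exposure assigned by a logistic model on the confounders
  (confounding by construction, positivity by construction);
* continuous potential outcomes on a blood-pressure-like mmHg scale, with a
  heterogeneous treatment effect (effect modification);
* stratified sampling with unequal inclusion probabilities keyed to the
  ethnicity-like stratum (minority oversampling), optional covariate-
  dependent selection and optional nonresponse — so the sample is not a
  simple random sample and the sample ATE differs from the population ATE.

Both potential outcomes are stored on the Population, so the true PATE,
PATT and expected SATE are computable exactly; the drawn SurveyDataset has
the potential-outcome columns stripped, so estimators can never peek.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .survey_design import SurveyDataset

__all__ = [
    "GeneratorConfig",
    "Population",
    "EstimandTruth",
    "ConfigError",
    "DegenerateSampleError",
    "generate_population",
    "draw_survey_sample",
    "true_estimands",
    "default_config",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


class DegenerateSampleError(RuntimeError):
    """A sampling draw produced no rows."""


# Features available to the linear predictors. ``age_c`` is age centered at
# 10 years, ``income_c`` the income-to-needs ratio centered at 1; ``eth_1``
# and ``eth_2`` are dummies for the two minority levels of ``eth``.
_FEATURES = ("age_c", "income_c", "sex", "eth_1", "eth_2")


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic superpopulation and its survey design.

    Defaults define the package's reference scenario: four confounders, a
    ~28% prevalent exposure, a heterogeneous effect (stronger in the
    oversampled minority strata, so SATE != PATE), mmHg-scale outcomes with
    sd-8 noise, and NHANES-style minority oversampling by stratum.
    """

    n_population: int = 400_000
    # exposure-assignment logistic model: logit P(A=1|L)
    exposure_intercept: float = -1.2
    exposure_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "age_c": 0.15,
            "income_c": -0.8,
            "sex": 0.2,
            "eth_1": 0.6,
            "eth_2": 0.4,
        }
    )
    # untreated outcome model: E[Y^0 | L]
    outcome_intercept: float = 100.0
    outcome_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "age_c": 1.0,
            "income_c": -3.0,
            "sex": -1.0,
            "eth_1": 2.0,
            "eth_2": 1.0,
        }
    )
    # treatment effect: y1 - y0 (systematic) = tau0 + sum tau_l[f] * f
    tau0: float = 2.0
    tau_l: dict[str, float] = field(
        default_factory=lambda: {"eth_1": 2.0, "eth_2": 1.0}
    )
    noise_sd: float = 8.0
    # covariate distributions
    eth_probs: tuple[float, ...] = (0.55, 0.25, 0.20)
    age_range: tuple[float, float] = (8.0, 12.0)
    income_lognorm_sd: float = 0.5
    # sampling design: strata are the eth levels
    stratum_inclusion: dict[int, float] = field(
        default_factory=lambda: {0: 0.0025, 1: 0.01, 2: 0.0075}
    )
    # logit-scale tilt of selection on centered income (informativeness dial
    # beyond the strata themselves); 0 keeps selection constant per stratum
    selection_income_coef: float = 0.0
    # optional nonresponse: response probability per stratum (None = full response)
    response_rates: dict[int, float] | None = None
    n_psus_per_stratum: int = 12
    seed: int = 20_250_714

    def __post_init__(self) -> None:
        if self.n_population < 2:
            raise ConfigError("population size must be at least 2")
        for key in set(self.exposure_coefs) | set(self.outcome_coefs) | set(self.tau_l):
            if key not in _FEATURES:
                raise ConfigError(f"unknown feature {key!r}; allowed: {_FEATURES}")
        for lvl, p in self.stratum_inclusion.items():
            if not 0 < p <= 1:
                raise ConfigError(f"inclusion probability for stratum {lvl} not in (0,1]")
        if self.response_rates is not None:
            for lvl, p in self.response_rates.items():
                if not 0 < p <= 1:
                    raise ConfigError(f"response rate for stratum {lvl} not in (0,1]")
        if not np.isclose(sum(self.eth_probs), 1.0):
            raise ConfigError("eth_probs must sum to 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if self.n_psus_per_stratum < 2:
            raise ConfigError("need at least 2 PSUs per stratum")

    # ------------------------------------------------------------------ YAML
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["eth_probs"] = list(d["eth_probs"])
        d["age_range"] = list(d["age_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("eth_probs", "age_range"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("stratum_inclusion", "response_rates"):
            if d.get(key):
                d[key] = {int(k): float(v) for k, v in d[key].items()}
        return cls(**d)


def default_config(**overrides) -> GeneratorConfig:
    """The package's reference scenario, with keyword overrides."""
    return GeneratorConfig(**overrides)


@dataclass
class Population:
    """Synthetic superpopulation with both potential outcomes stored.

    Columns: ``id``; confounders ``age`` (years), ``income``
    (income-to-needs ratio), ``sex`` (0/1), ``eth`` (0/1/2); exposure ``A``;
    potential outcomes ``y0``/``y1`` and observed ``Y`` (outcome units);
    ``stratum`` (= eth level); ``p_sel`` (selection probability); ``psu``.
    """

    data: pd.DataFrame
    config: GeneratorConfig

    @property
    def n(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class EstimandTruth:
    """Exact causal estimands of a Population, in outcome units (mmHg)."""

    pate: float
    patt: float
    sate_expected: float | None = None


def _features(df: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        "age_c": df["age"].to_numpy() - 10.0,
        "income_c": df["income"].to_numpy() - 1.0,
        "sex": df["sex"].to_numpy(dtype=float),
        "eth_1": (df["eth"].to_numpy() == 1).astype(float),
        "eth_2": (df["eth"].to_numpy() == 2).astype(float),
    }


def _linpred(
    intercept: float, coefs: Mapping[str, float], feats: Mapping[str, np.ndarray]
) -> np.ndarray:
    eta = np.full_like(feats["sex"], intercept, dtype=float)
    for name, c in coefs.items():
        eta = eta + c * feats[name]
    return eta


def generate_population(config: GeneratorConfig) -> Population:
    """Draw a superpopulation from the configured structural model.

    Exposure follows the logistic assignment model; y0 is the untreated
    outcome model plus Gaussian noise; y1 adds the (possibly heterogeneous)
    treatment effect to y0's systematic part, with an independent noise
    draw; the observed Y satisfies Y = A*y1 + (1-A)*y0 row by row.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_population

    age = rng.uniform(*config.age_range, size=n)
    income = rng.lognormal(mean=0.0, sigma=config.income_lognorm_sd, size=n)
    sex = rng.binomial(1, 0.5, size=n)
    eth = rng.choice(len(config.eth_probs), size=n, p=np.asarray(config.eth_probs))
    df = pd.DataFrame(
        {"id": np.arange(n), "age": age, "income": income, "sex": sex, "eth": eth}
    )
    feats = _features(df)

    pi = 1.0 / (1.0 + np.exp(-_linpred(config.exposure_intercept,
                                       config.exposure_coefs, feats)))
    a = rng.binomial(1, pi)

    mu0 = _linpred(config.outcome_intercept, config.outcome_coefs, feats)
    effect = _linpred(config.tau0, config.tau_l, feats)
    y0 = mu0 + rng.normal(0.0, config.noise_sd, size=n)
    y1 = mu0 + effect + rng.normal(0.0, config.noise_sd, size=n)

    df["A"] = a
    df["y0"] = y0
    df["y1"] = y1
    df["Y"] = np.where(a == 1, y1, y0)
    df["stratum"] = eth

    # selection probability: per-stratum base, optionally tilted by income
    missing = set(np.unique(eth)) - set(config.stratum_inclusion)
    if missing:
        raise ConfigError(f"strata without inclusion probability: {sorted(missing)}")
    base = df["stratum"].map(config.stratum_inclusion).to_numpy(dtype=float)
    if config.selection_income_coef != 0.0:
        logit = np.log(base / (1 - base)) + config.selection_income_coef * feats["income_c"]
        p_sel = 1.0 / (1.0 + np.exp(-logit))
    else:
        p_sel = base
    df["p_sel"] = p_sel

    # pseudo-PSU labels within stratum (design labels for variance machinery;
    # assignment is random, so there is no real intra-cluster correlation)
    df["psu"] = [
        f"{s}-{p}"
        for s, p in zip(eth, rng.integers(0, config.n_psus_per_stratum, size=n))
    ]
    return Population(data=df, config=config)


def draw_survey_sample(
    population: Population,
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SurveyDataset:
    """Poisson-sample the population under its design; return observed data.

    Each unit enters independently with its selection probability p_sel; a
    sampled unit carries survey weight 1/p_sel. With nonresponse enabled, a
    second Bernoulli thinning is applied and the weight becomes
    1/(p_sel * response rate) — the standard inverse response-propensity
    adjustment. Potential-outcome columns are stripped.
    """
    config = config or population.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    df = population.data
    if len(df) == 0:
        raise DegenerateSampleError("population is empty")

    keep = rng.random(len(df)) < df["p_sel"].to_numpy()
    sample = df.loc[keep].copy()
    sample["weight"] = 1.0 / sample["p_sel"].to_numpy()

    if config.response_rates is not None:
        missing = set(sample["stratum"].unique()) - set(config.response_rates)
        if missing:
            raise ConfigError(f"strata without response rate: {sorted(missing)}")
        r = sample["stratum"].map(config.response_rates).to_numpy(dtype=float)
        respond = rng.random(len(sample)) < r
        sample = sample.loc[respond].copy()
        sample["weight"] = sample["weight"].to_numpy() * (1.0 / r[respond])

    if len(sample) == 0:
        raise DegenerateSampleError("sampling produced an empty dataset")

    cols = ["id", "age", "income", "sex", "eth", "A", "Y", "weight", "stratum", "psu"]
    return SurveyDataset(
        data=sample[cols].reset_index(drop=True),
        outcome="Y",
        exposure="A",
        weight="weight",
        stratum="stratum",
        psu="psu",
    )


def true_estimands(
    population: Population,
    n_sate_replicates: int = 0,
    seed: int | None = None,
) -> EstimandTruth:
    """Exact PATE and PATT; optionally the design-expected SATE.

    pate = mean(y1 - y0) over the population, patt the same among A=1. With
    ``n_sate_replicates`` > 0, sate_expected averages the unweighted sample
    mean of (y1 - y0) over replicate survey draws — the effect an unweighted
    analysis targets under the design.
    """
    df = population.data
    if "y1" not in df.columns or "y0" not in df.columns:
        raise ValueError("population lacks potential-outcome columns y1/y0")
    diff = df["y1"].to_numpy() - df["y0"].to_numpy()
    pate = float(diff.mean())
    exposed = df["A"].to_numpy() == 1
    patt = float(diff[exposed].mean()) if exposed.any() else float("nan")

    sate = None
    if n_sate_replicates > 0:
        rng = np.random.default_rng(
            population.config.seed + 7 if seed is None else seed
        )
        p = df["p_sel"].to_numpy()
        means = []
        for _ in range(n_sate_replicates):
            keep = rng.random(len(df)) < p
            if keep.any():
                means.append(diff[keep].mean())
        sate = float(np.mean(means))
    return EstimandTruth(pate=pate, patt=patt, sate_expected=sate)
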