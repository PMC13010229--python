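"""Orchestration: the ten-estimator comparison and Monte-Carlo simulation study.

The comparison mirrors the standard forest-plot layout for this problem:
four regression baselines (naive, survey weights only, confounders only,
fully adjusted) followed by the three causal estimators (IPTW,
G-computation, TMLE), each without and with survey weights — ten rows in a
fixed order. All methods share the same exposure and outcome model
specifications for comparability.

The simulation study repeatedly draws survey samples from a synthetic
superpopulation with known truth and summarises each estimator's bias,
empirical SE, mean CI width and CI coverage of the true PATE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gcomputation import gcomp_pate
from .propensity_iptw import estimate_iptw_pate
from .reference_models import fit_reference_models
from .results import EstimateResult, results_table
from .survey_design import SurveyDataset
from .synthetic_data import (
    GeneratorConfig,
    draw_survey_sample,
    generate_population,
    true_estimands,
)
from .tmle import tmle_pate

__all__ = [
    "AnalysisConfig",
    "COMPARISON_ORDER",
    "run_comparison",
    "simulation_study",
]

# fixed forest-plot row order
COMPARISON_ORDER = (
    "naive",
    "weights_only",
    "confounders_only",
    "full",
    "iptw_unweighted",
    "iptw_weighted",
    "gcomp_unweighted",
    "gcomp_weighted",
    "tmle_unweighted",
    "tmle_weighted",
)


@dataclass
class AnalysisConfig:
    """Shared analysis settings for the comparison.

    ``confounder_formula`` is the patsy right-hand side used (identically)
    for the propensity model, the outcome model's confounder part and the
    adjusted reference models. ``outcome_rhs`` optionally overrides the
    outcome model's right-hand side, e.g. to add exposure-confounder
    interaction terms when the effect is heterogeneous (regression
    standardization is only consistent for the PATE when the outcome model
    captures the effect modification).
    """

    confounder_formula: str = "age + income + sex + C(eth)"
    outcome_rhs: str | None = None
    n_mc_iterations: int = 250
    mc_mode: str = "parameter_draw"
    bootstrap_reps: int = 10_000
    bootstrap_scheme: str = "rows"
    tmle_variant: str = "plain"
    iptw_ci_method: str = "wald_robust"  # or 'percentile_bootstrap'
    propensity_survey_weighted: bool = False
    ci_level: float = 0.95
    seed: int = 0

    def outcome_formula(self, data: SurveyDataset) -> str:
        rhs = self.outcome_rhs or f"{data.exposure} + {self.confounder_formula}"
        return f"{data.outcome} ~ {rhs}"


def _child_seeds(master: int, n: int) -> list[int]:
    """Deterministic per-estimator/per-replicate seed fan-out (< 2**31)."""
    ss = np.random.SeedSequence(master)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def run_comparison(
    data: SurveyDataset | GeneratorConfig,
    config: AnalysisConfig | None = None,
    include: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """All ten estimators on one dataset, in the fixed row order.

    A failing estimator is recorded in its row (``error`` column) without
    aborting the rest. Accepts either a ready SurveyDataset or a generator
    config (in which case a population is generated and sampled first).
    ``include`` restricts computation to a subset of the labels (rows keep
    the fixed order).
    """
    config = config or AnalysisConfig()
    wanted = set(COMPARISON_ORDER if include is None else include)
    unknown = wanted - set(COMPARISON_ORDER)
    if unknown:
        raise ValueError(f"unknown estimator labels: {sorted(unknown)}")
    if isinstance(data, GeneratorConfig):
        data = draw_survey_sample(generate_population(data))

    seeds = dict(zip(COMPARISON_ORDER, _child_seeds(config.seed, len(COMPARISON_ORDER))))
    out_formula = config.outcome_formula(data)

    runners = {
        "iptw_unweighted": lambda: estimate_iptw_pate(
            data, config.confounder_formula, use_survey_weights=False,
            propensity_survey_weighted=config.propensity_survey_weighted,
            ci_level=config.ci_level, ci_method=config.iptw_ci_method,
            bootstrap_reps=config.bootstrap_reps,
            bootstrap_scheme=config.bootstrap_scheme,
            seed=seeds["iptw_unweighted"],
        ),
        "iptw_weighted": lambda: estimate_iptw_pate(
            data, config.confounder_formula, use_survey_weights=True,
            propensity_survey_weighted=config.propensity_survey_weighted,
            ci_level=config.ci_level, ci_method=config.iptw_ci_method,
            bootstrap_reps=config.bootstrap_reps,
            bootstrap_scheme=config.bootstrap_scheme,
            seed=seeds["iptw_weighted"],
        ),
        "gcomp_unweighted": lambda: gcomp_pate(
            data, out_formula, use_survey_weights=False,
            n_iterations=config.n_mc_iterations, mode=config.mc_mode,
            bootstrap_reps=config.bootstrap_reps,
            bootstrap_scheme=config.bootstrap_scheme,
            ci_level=config.ci_level, seed=seeds["gcomp_unweighted"],
        ),
        "gcomp_weighted": lambda: gcomp_pate(
            data, out_formula, use_survey_weights=True,
            n_iterations=config.n_mc_iterations, mode=config.mc_mode,
            bootstrap_reps=config.bootstrap_reps,
            bootstrap_scheme=config.bootstrap_scheme,
            ci_level=config.ci_level, seed=seeds["gcomp_weighted"],
        ),
        "tmle_unweighted": lambda: tmle_pate(
            data, out_formula, config.confounder_formula,
            variant=config.tmle_variant, use_survey_weights=False,
            propensity_survey_weighted=config.propensity_survey_weighted,
            bootstrap_reps=config.bootstrap_reps,
            bootstrap_scheme=config.bootstrap_scheme,
            ci_level=config.ci_level, seed=seeds["tmle_unweighted"],
        ),
        "tmle_weighted": lambda: tmle_pate(
            data, out_formula, config.confounder_formula,
            variant=config.tmle_variant, use_survey_weights=True,
            propensity_survey_weighted=config.propensity_survey_weighted,
            bootstrap_reps=config.bootstrap_reps,
            bootstrap_scheme=config.bootstrap_scheme,
            ci_level=config.ci_level, seed=seeds["tmle_weighted"],
        ),
    }

    rows: list[dict] = []

    def record(label: str, result: EstimateResult | None, error: str | None) -> None:
        row = {"label": label, "error": error}
        if result is not None:
            row.update(result.to_row())
        rows.append(row)

    reference_labels = [l for l in COMPARISON_ORDER[:4] if l in wanted]
    if reference_labels:
        try:
            for label, res in zip(
                COMPARISON_ORDER[:4],
                fit_reference_models(data, config.confounder_formula,
                                     config.ci_level),
            ):
                if label in wanted:
                    record(label, res, None)
        except Exception as exc:  # noqa: BLE001 - partial-results contract
            for label in reference_labels:
                record(label, None, repr(exc))

    for label in COMPARISON_ORDER[4:]:
        if label not in wanted:
            continue
        try:
            record(label, runners[label](), None)
        except Exception as exc:  # noqa: BLE001
            record(label, None, repr(exc))

    df = pd.DataFrame(rows)
    order = [l for l in COMPARISON_ORDER if l in wanted]
    return df.set_index("label").loc[order].reset_index()


@dataclass
class SimulationSummary:
    """Per-estimator Monte-Carlo performance against the known truth."""

    table: pd.DataFrame
    truth: float
    n_replicates: int
    estimates: pd.DataFrame = field(repr=False, default=None)


def simulation_study(
    generator_config: GeneratorConfig,
    n_replicates: int,
    analysis_config: AnalysisConfig | None = None,
    estimators: tuple[str, ...] = COMPARISON_ORDER,
    master_seed: int = 0,
) -> SimulationSummary:
    """Repeated-sampling evaluation of the estimators against the true PATE.

    One superpopulation is generated (truth fixed); ``n_replicates`` survey
    samples are drawn and every requested estimator run on each. Summaries:
    bias, Monte-Carlo SE of the bias, empirical SE, mean CI width, and CI
    coverage of the true PATE (NaN when an estimator has no CI in this run).
    """
    if n_replicates < 2:
        raise ValueError("simulation study needs at least 2 replicates")
    analysis_config = analysis_config or AnalysisConfig()
    population = generate_population(generator_config)
    truth = true_estimands(population).pate

    rep_seeds = _child_seeds(master_seed, n_replicates)
    records: list[dict] = []
    for r, s in enumerate(rep_seeds):
        rng = np.random.default_rng(s)
        sample = draw_survey_sample(population, rng=rng)
        cfg = AnalysisConfig(**{**analysis_config.__dict__, "seed": s})
        table = run_comparison(sample, cfg, include=estimators)
        for _, row in table.iterrows():
            records.append(
                {
                    "replicate": r,
                    "label": row["label"],
                    "estimate": row.get("estimate"),
                    "ci_lower": row.get("ci_lower"),
                    "ci_upper": row.get("ci_upper"),
                    "error": row.get("error"),
                }
            )

    est = pd.DataFrame(records)
    summaries = []
    for label, sub in est.groupby("label", sort=False):
        ok = sub[sub["error"].isna() & sub["estimate"].notna()]
        e = ok["estimate"].to_numpy(dtype=float)
        has_ci = ok["ci_lower"].notna() & ok["ci_upper"].notna()
        cover = width = float("nan")
        if has_ci.any():
            lo = ok.loc[has_ci, "ci_lower"].to_numpy(dtype=float)
            hi = ok.loc[has_ci, "ci_upper"].to_numpy(dtype=float)
            cover = float(((lo <= truth) & (truth <= hi)).mean())
            width = float((hi - lo).mean())
        summaries.append(
            {
                "label": label,
                "n_ok": len(ok),
                "mean_estimate": float(e.mean()) if len(e) else float("nan"),
                "bias": float(e.mean() - truth) if len(e) else float("nan"),
                "mc_se": float(e.std(ddof=1) / np.sqrt(len(e))) if len(e) > 1 else float("nan"),
                "empirical_se": float(e.std(ddof=1)) if len(e) > 1 else float("nan"),
                "mean_ci_width": width,
                "coverage": cover,
            }
        )
    order = [lab for lab in estimators if lab in set(est["label"])]
    table = pd.DataFrame(summaries).set_index("label").loc[order].reset_index()
    return SimulationSummary(
        table=table, truth=truth, n_replicates=n_replicates, estimates=est
    )
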