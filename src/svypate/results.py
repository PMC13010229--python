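"""Labelled effect estimates shared by all estimator modules.

Every estimator returns an :class:`EstimateResult` carrying, besides the
point estimate and interval, the metadata needed to read a comparison table
safely: whether survey weights entered the analysis, whether confounders
were adjusted for, and — because marginal and conditional effects coincide
only in collapsible settings — whether the estimand is marginal (IPTW,
G-computation, TMLE) or conditional (covariate-adjusted regression).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["EstimateResult", "results_table"]


@dataclass
class EstimateResult:
    """A single labelled treatment-effect estimate, in outcome units."""

    method: str
    estimate: float
    se: float | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None
    ci_method: str | None = None  # 'wald_robust' | 'percentile_bootstrap' | ...
    weighted: bool = False  # survey weights used anywhere in the analysis
    adjusted: bool = True  # confounders adjusted for
    estimand: str = "marginal"  # 'marginal' | 'conditional'
    n: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.estimand not in ("marginal", "conditional"):
            raise ValueError(f"unknown estimand type {self.estimand!r}")
        if (
            self.ci_lower is not None
            and self.ci_upper is not None
            and not (self.ci_lower <= self.estimate <= self.ci_upper)
        ):
            raise ValueError(
                f"point estimate {self.estimate} outside CI "
                f"[{self.ci_lower}, {self.ci_upper}] for {self.method}"
            )

    @property
    def ci_width(self) -> float | None:
        if self.ci_lower is None or self.ci_upper is None:
            return None
        return self.ci_upper - self.ci_lower

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "estimate": self.estimate,
            "se": self.se,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "ci_method": self.ci_method,
            "weighted": self.weighted,
            "adjusted": self.adjusted,
            "estimand": self.estimand,
            "n": self.n,
        }


def results_table(results: list[EstimateResult]) -> pd.DataFrame:
    """Forest-plot-ready table, one row per estimator (stable column schema)."""
    return pd.DataFrame([r.to_row() for r in results])
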