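import numpy as np
import pandas as pd
import pytest

import svypate as sp
from svypate.survey_design import SurveyDataset


@pytest.fixture(scope="session")
def default_population() -> sp.Population:
    """The reference scenario's superpopulation (shared; treat as read-only)."""
    return sp.generate_population(sp.default_config())


@pytest.fixture(scope="session")
def default_sample(default_population) -> SurveyDataset:
    return sp.draw_survey_sample(default_population)


def make_discrete_dataset(
    counts: dict[tuple[int, int], int],
    means: dict[tuple[int, int], float],
    weights: dict[tuple[int, int], float] | None = None,
    y_spread: float = 1.0,
) -> SurveyDataset:
    """Hand-built discrete dataset: cells indexed by (A, L).

    Outcomes in each cell are mean +/- y_spread in alternation so every cell
    has the exact specified mean and nonzero variance (even counts required).
    """
    rows = []
    for (a, l), n in counts.items():
        assert n % 2 == 0, "use even cell counts so the +/- spread cancels"
        m = means[(a, l)]
        w = 1.0 if weights is None else weights[(a, l)]
        for i in range(n):
            rows.append(
                {"A": a, "L": l, "Y": m + (y_spread if i % 2 else -y_spread), "weight": w}
            )
    return SurveyDataset(data=pd.DataFrame(rows))


def standardization_oracle(data: SurveyDataset) -> float:
    """Brute-force standardization over the discrete confounder L.

    sum_l [ mean_w(Y | A=1, l) - mean_w(Y | A=0, l) ] * P_w(l), with all
    means and the confounder distribution weighted by the survey weights.
    Independent of every estimator implementation: plain pandas arithmetic.
    """
    df = data.data
    total_w = df["weight"].sum()
    est = 0.0
    for l, sub in df.groupby("L"):
        p_l = sub["weight"].sum() / total_w
        m1 = np.average(sub.loc[sub.A == 1, "Y"], weights=sub.loc[sub.A == 1, "weight"])
        m0 = np.average(sub.loc[sub.A == 0, "Y"], weights=sub.loc[sub.A == 0, "weight"])
        est += (m1 - m0) * p_l
    return float(est)


@pytest.fixture
def discrete_data() -> SurveyDataset:
    """Binary confounder, all four cell means fixed, equal weights."""
    counts = {(0, 0): 40, (1, 0): 10, (0, 1): 20, (1, 1): 30}
    means = {(0, 0): 100.0, (1, 0): 104.0, (0, 1): 95.0, (1, 1): 97.0}
    return make_discrete_dataset(counts, means)


@pytest.fixture
def discrete_data_weighted() -> SurveyDataset:
    """Same cells but with unequal survey weights by (A, L) cell."""
    counts = {(0, 0): 40, (1, 0): 10, (0, 1): 20, (1, 1): 30}
    means = {(0, 0): 100.0, (1, 0): 104.0, (0, 1): 95.0, (1, 1): 97.0}
    weights = {(0, 0): 1.0, (1, 0): 3.0, (0, 1): 2.0, (1, 1): 0.5}
    return make_discrete_dataset(counts, means, weights)
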