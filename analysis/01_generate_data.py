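#!/usr/bin/env python
"""Generate the reference synthetic superpopulation and one survey sample.

Writes the generator configuration, the drawn sample (observed columns
only) and the exact causal estimands of the population to results/.
The headline numbers: the true PATE sits near 2.66 mmHg while the expected
unweighted sample ATE is near 3.2 mmHg — the gap the survey weights exist
to close.
"""

import json
from pathlib import Path

import numpy as np

import svypate as sp

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    config = sp.default_config()
    config.to_yaml(RESULTS / "scenario.yaml")

    population = sp.generate_population(config)
    truth = sp.true_estimands(population, n_sate_replicates=200)
    sample = sp.draw_survey_sample(population)
    sample.to_csv(RESULTS / "sample.csv")

    summary = {
        "population_size": population.n,
        "sample_size": sample.n,
        "true_pate_mmhg": round(truth.pate, 4),
        "true_patt_mmhg": round(truth.patt, 4),
        "expected_unweighted_sate_mmhg": round(truth.sate_expected, 4),
        "exposure_prevalence_unweighted": round(float(sample.a.mean()), 4),
        "exposure_prevalence_weighted": round(
            float(np.average(sample.a, weights=sample.weights)), 4
        ),
    }
    with open(RESULTS / "scenario_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    print("reference scenario written to results/")
    for k, v in summary.items():
        print(f"  {k}: {v}")
    gap = truth.sate_expected - truth.pate
    print(
        f"\nThe oversampled strata carry the larger treatment effect, so an\n"
        f"unweighted analysis targets {truth.sate_expected:.2f} mmHg instead of "
        f"the population's {truth.pate:.2f} mmHg (gap {gap:+.2f})."
    )


if __name__ == "__main__":
    main()
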