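#!/usr/bin/env python
"""Repeated-sampling evaluation of all ten estimators against the truth.

Draws replicate survey samples from the reference superpopulation and
summarises bias, empirical SE, mean CI width and CI coverage per estimator.
This is the quantitative backbone for the package's three claims:

* survey-weighted IPTW, G-computation and TMLE are unbiased for the PATE
  under informative sampling with effect modification, their unweighted
  twins are not;
* G-computation yields the narrowest confidence intervals; IPTW's, inflated
  by the variance of the combined weights, are the widest on average (its
  margin over TMLE is small in this scenario — see docs/methods.md);
* ignoring the weights produces deceptively narrow intervals.

Writes results/simulation_study.csv. Replicate count and bootstrap size are
module constants; the defaults (150 x B=300) run in a few minutes.
"""

from pathlib import Path

import svypate as sp
from svypate.pipeline import AnalysisConfig, simulation_study

RESULTS = Path(__file__).resolve().parents[1] / "results"

N_REPLICATES = 150
BOOTSTRAP_B = 300


def main() -> None:
    gen = sp.default_config()
    cfg = AnalysisConfig(
        confounder_formula="age + income + sex + C(eth)",
        outcome_rhs="A + age + income + sex + C(eth) + A:C(eth)",
        bootstrap_reps=BOOTSTRAP_B,
        mc_mode="plugin",
        # same percentile-bootstrap CI for all three causal estimators, so
        # CI widths compare estimator efficiency rather than CI machinery
        iptw_ci_method="percentile_bootstrap",
    )
    summary = simulation_study(
        gen, n_replicates=N_REPLICATES, analysis_config=cfg, master_seed=7
    )
    summary.table.to_csv(RESULTS / "simulation_study.csv", index=False)

    print(f"true PATE: {summary.truth:.4f} mmHg over {N_REPLICATES} replicates\n")
    cols = ["label", "bias", "mc_se", "empirical_se", "mean_ci_width", "coverage"]
    print(summary.table[cols].to_string(index=False,
                                        float_format=lambda v: f"{v:.3f}"))
    tab = summary.table.set_index("label")
    print(
        f"\nMean CI widths (weighted): gcomp "
        f"{tab.loc['gcomp_weighted','mean_ci_width']:.2f}, TMLE "
        f"{tab.loc['tmle_weighted','mean_ci_width']:.2f}, IPTW "
        f"{tab.loc['iptw_weighted','mean_ci_width']:.2f} mmHg; "
        f"empirical SEs "
        f"{tab.loc['gcomp_weighted','empirical_se']:.2f} / "
        f"{tab.loc['tmle_weighted','empirical_se']:.2f} / "
        f"{tab.loc['iptw_weighted','empirical_se']:.2f}."
    )


if __name__ == "__main__":
    main()
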