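# svypate

**Survey-weight-aware causal estimators of the population average treatment
effect (PATE).**

Epidemiologists routinely estimate exposure effects from national health
surveys — NHANES-style designs with stratification, minority oversampling
and nonresponse adjustment. Standard causal inference machinery (propensity
weighting, standardization, doubly robust estimation) deals with
*confounding*, but the survey's unequal selection probabilities are a
second, independent source of bias: the sample average treatment effect
(SATE) generalises to the population only if the sample is a simple random
sample, which these surveys never are. When the estimand is the **PATE** —
the effect in the population the survey represents — the survey weights
`ω = 1/P(selection)` must enter the estimator itself.

`svypate` implements the three standard estimators in survey-aware form,
for analysts of complex-survey health data and for methodologists who want
a tested simulation bench:

| estimator | confounding handled by | survey weights enter via |
|---|---|---|
| **IPTW** | treatment weights `t = A/π + (1−A)/(1−π)`, `π(L) = P(A=1\|L)` | combined analysis weights `w = t·ω` |
| **G-computation** | outcome model `Q(A,L) = E[Y\|A,L]`, standardization `Σᵢ ωᵢ[Q̂(1,Lᵢ) − Q̂(0,Lᵢ)]/Σᵢ ωᵢ` | ω-weighted model fit and ω-weighted averaging |
| **TMLE** | both, fluctuated along the clever covariate `H = A/π − (1−A)/(1−π)`: `Q* = Q̂ + ε̂·H` | ω-weighted fluctuation and averaging (or ω inside `H`) |

plus the four regression baselines (naive; weights-only; confounders-only;
fully adjusted), design-based (Taylor linearization) standard errors with
stratum/PSU support, percentile and Rao-Wu-Yue bootstraps, balance and
positivity diagnostics, a synthetic survey generator with exactly known
causal truth, and an adapter that builds analysis datasets from NHANES
public-release files (XPT or CSV) you supply.

## Worked example

The reference synthetic scenario has four confounders, a ~30%-prevalence
exposure, a heterogeneous effect concentrated in the minority strata that
the design oversamples, and mmHg-scale outcomes. The truth is computable
exactly:

```python
import svypate as sp

config = sp.default_config()
population = sp.generate_population(config)       # N = 400,000, both POs stored
truth = sp.true_estimands(population, n_sate_replicates=200)
sample = sp.draw_survey_sample(population)        # n ≈ 2,100, POs stripped
```

prints (via `analysis/01_generate_data.py`):

```
true_pate_mmhg: 2.6625
expected_unweighted_sate_mmhg: 3.1884
exposure_prevalence_unweighted: 0.3274
exposure_prevalence_weighted: 0.2939
```

The oversampled strata carry the larger effect, so an unweighted analysis
targets 3.19 mmHg instead of the population's 2.66 mmHg. Running all ten
estimators on the drawn sample (`analysis/02_compare_estimators.py`):

```
           label  estimate  ci_lower  ci_upper    estimand
           naive     3.519     2.917     4.121 conditional
    weights_only     3.068     2.378     3.758 conditional
confounders_only     2.572     2.059     3.085 conditional
            full     2.082     1.488     2.676 conditional
 iptw_unweighted     2.591     2.016     3.167    marginal
   iptw_weighted     2.056     1.430     2.683    marginal
gcomp_unweighted     2.517     1.818     3.217    marginal
  gcomp_weighted     1.992     1.109     2.900    marginal
 tmle_unweighted     2.643     1.929     3.369    marginal
   tmle_weighted     2.027     1.163     2.961    marginal
```

Reading the table: the naive regression (3.52) is pushed up by both
confounding and the design; adjusting confounders alone (2.57–2.64) still
targets the sample, not the population; the three weighted causal
estimators agree (1.99–2.06 on this draw, CIs covering the true 2.66) and
are the only rows whose estimand is the PATE. Conditional-vs-marginal
labels are carried on every row because the two only coincide in
collapsible (linear, no-interaction) settings.

`analysis/03_simulation_study.py` repeats this over 150 replicate samples:
the three weighted estimators are unbiased for the PATE (|bias| ≤ 0.10
mmHg, each within 3 Monte-Carlo SEs) while every unweighted estimator is
biased upward by ≈ +0.5 mmHg; G-computation has the narrowest intervals
(mean width 1.88 vs 2.0–2.1 mmHg for TMLE/IPTW) and the unweighted
intervals are deceptively narrow (coverage as low as 2% for the naive
model, versus 91–96% for the weighted causal estimators).

A thin CLI wraps the same functions:

```bash
svypate compare --data sample.csv --stratum stratum --psu psu --out results.csv
svypate simulate --config scenario.yaml --reps 200
svypate tmle --data sample.csv --variant plain -B 2000
```

## NHANES data

`svypate.nhanes_adapter.build_analysis_dataset` merges demographics,
blood-pressure, household-smoking and income files (SAS transport or CSV),
applies eligibility and complete-case filters in a fixed logged order, and
returns a `SurveyDataset` with MEC weights and design columns. Variable
names and codings are configuration (`NhanesMapping`, YAML-loadable), since
they change between survey cycles. The package downloads nothing; point it
at files obtained from the CDC website.

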