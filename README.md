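# asymrepro

Reproducibility of paired left–right brain asymmetry effects across many
datasets, in an idealized reporting environment.

## The problem

Multi-site consortia measure the same within-subject contrast — say, the
left-minus-right cortical thickness of the parahippocampal gyrus — in dozens
of independent datasets and pool the per-dataset results by meta-analysis.
Because every dataset reports its summary statistics regardless of outcome,
such collections are free of publication bias and p-hacking, and they allow
an empirical question that the published literature cannot answer: *if the
same study were honestly run 99 times at typical sample sizes, how often
would a given effect "replicate"?*

`asymrepro` implements that analysis end-to-end for paired (left/right)
designs, plus a synthetic-data generator that emulates the statistical
structure of a 99-dataset, 70-measure cortical asymmetry study (sample sizes
14–2,326; true |d| from ~0 to 1.76, median 0.30). It is aimed at
biostatisticians and neuroimaging methodologists studying replication,
power, and heterogeneity in multi-site summary data.

## The model

Per dataset and measure, the hemispheric effect is the paired-samples
standardized mean difference

> d_z = mean(L−R) / SD(L−R) = t/√n,  with sampling variance v = 1/n + d²/(2n),

tested by the paired t-test (df = n−1). Across k datasets the effects follow
the random-effects model dᵢ ~ N(μ, vᵢ + τ²); τ² is estimated by
DerSimonian–Laird (closed form) or REML (default), and pooling uses weights
wᵢ* = 1/(vᵢ + τ²) with z = μ̂/SE against the standard normal.

A dataset **reproduces** an effect relative to the leave-one-out
meta-analysis of the other k−1 datasets:

* pooled effect significant (p ≤ α_meta): same sign of d *and* single-dataset
  p ≤ .05;
* pooled effect nonsignificant: single-dataset p > .05.

The reproducibility rate of an effect is the proportion of datasets
reproducing it. Supporting analyses: minimum-sample-size stratification
(thresholds 15–500), |pooled d| bins ([0,.2), …, [.8,1.8)), subgroup
comparisons (field strength, software version, child/adult), analytic power
from the noncentral t distribution, PPV = (1−β)R/((1−β)R+α), and
test–retest ICC (two-way model, absolute agreement or consistency).

## Worked example

```python
from asymrepro import (tau2_dl, random_effects_meta, reproducibility_rate,
                       paired_t_power, ppv)
from asymrepro.synthetic import simulate_measure

# three studies, hand-checkable pooling
print(tau2_dl([0.2, 0.5, 0.8], [0.04, 0.04, 0.04]))   # 0.05

# one simulated measure across 99 datasets of size 72, true d = 0.3
recs = simulate_measure(0.3, tau=0.0, sizes=[72]*99, seed=1)
print(random_effects_meta(recs, method="DL").pooled_d)  # 0.2879...
print(reproducibility_rate(recs, method="DL").rate)     # 0.7677...
print(paired_t_power(0.3, 72))                          # 0.7090...
print(ppv(0.8, 0.25, 0.05))                             # 0.8
```

The simulated reproducibility rate (0.77 in this single draw, ~0.71 on
average over seeds) matches the correct-direction
power of the paired t-test at n = 72 — at the median dataset size of the
emulated study, a d = 0.3 effect replicates in only ~71% of honest attempts.

The full analysis is a sequence of drivers:

```bash
python analysis/01_simulate_multiverse.py --seed 1   # 99 x 70 study set
python analysis/02_meta_analysis.py                  # pooled "true" effects
python analysis/03_reproducibility.py                # LOO rates + strata
python analysis/04_power_ppv.py                      # power / PPV landscape
python analysis/05_heterogeneity_subgroups.py        # subgroup contrasts
python analysis/06_reliability.py                    # ICC correlates
```

With seed 1 the pipeline prints a mean reproducibility rate of 70.1%
(SD 25.7%, range 18.4–100%), 62 of 70 pooled effects significant at p ≤ .05
(58 at .05/70), thickness mean 49.6% vs area 90.7%, and rates rising from
45% in the |d| < 0.2 bin to 99% for |d| ≥ 0.8 — even with no selective
reporting, small effects at typical sample sizes reproduce in less than half
of datasets. A `asymrepro` CLI (`simulate`, `effects`, `meta`, `repro`,
`power`, `reliability`, `run`) wraps the same library.

## Layout

```
src/asymrepro/    library (effects, meta, reproducibility, power_ppv,
                  reliability, synthetic, io, pipeline, cli)
analysis/         numbered narrative drivers over the library
tests/            pytest suite (unit, property, and end-to-end checks)
scripts/          acceptance recomputation
docs/methods.md   modelling and design notes
```
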