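# Methods and design notes

## Effects

The per-dataset hemispheric effect is the paired-samples standardized mean
difference d_z = mean(L−R)/SD(L−R), equal to t/√n for the paired t-test.
This is the only standardized effect recoverable when a deposited table
carries just t and n, and it makes summary tables self-consistent under the
round trip d ↔ t. The sampling variance is the standard large-sample form
var(d_z) ≈ 1/n + d²/(2n); inverse-variance pooling needs a per-study
variance, and this is the convention this package uses throughout. The sign
convention is left minus right (positive d = leftward asymmetry); all
direction matching uses sign(d). No Hedges small-sample correction is
applied by default (a `hedges=True` flag exists); with the smallest
admitted dataset at n = 14 the correction factor is ≥ 0.98 and immaterial
next to between-dataset variability.

## Meta-analysis

Effects are pooled under the normal-normal random-effects model
dᵢ ~ N(μ, vᵢ + τ²). Two τ² estimators are implemented:

* **DL** (DerSimonian–Laird): closed-form moment estimator, exactly
  hand-checkable, truncated at 0 (Q is reported untruncated);
* **REML** (default): the score equation of the restricted log-likelihood is
  solved by bracketed Brent root finding (`xtol` = 1e-10); a non-positive
  score at τ² = 0 returns the boundary exactly. REML is the default because
  it is the default of the reference R implementation used by multi-site
  consortium analyses of this kind.

Pooled inference uses z = μ̂/SE against the standard normal (no
Knapp–Hartung adjustment), matching how such consortium meta-analyses
report their test statistics. A pool of one study returns that study with
τ² = 0. In leave-one-out pooling, τ² is re-estimated inside every reduced
pool — each LOO result is exactly the meta-analysis a team would have run
on the remaining datasets, not an approximation holding τ² fixed. A
vectorized DL path (`loo_meta_arrays_dl`) serves simulation studies and is
tested for exact equality against the looped route.

## Reproduction criterion

With the pooled (LOO) effect significant at α_meta, a dataset reproduces
iff its d has the same sign and its own p ≤ α_single; with the pooled
effect nonsignificant, iff its own p > α_single. All significance
comparisons use ≤. d exactly 0 never reproduces a significant pooled
effect (no direction to match); this is logged. The Bonferroni variant
divides only α_meta by the number of effects (70 by default) — the
single-dataset level stays at .05 because it models what an individual
study would have reported.

`min_n` (default 15) filters which datasets enter the *rate denominator*;
the LOO pools always use all other datasets. Whether the main-analysis
denominator excludes the sub-threshold datasets is genuinely ambiguous in
this design (a 99-dataset collection with two datasets of n = 14 yields a
97-dataset denominator); both `min_n` and the pool filtering are
configurable and recorded in the output manifest. The minimum-sample-size
stratification is different by intent: there both the pools and the
denominator are restricted to qualifying datasets (a subgroup re-analysis),
and thresholds leaving fewer than 3 datasets are flagged unavailable.
Effect-size bins use the full-pool |pooled d| with half-open [lo, hi)
edges; out-of-range magnitudes go to an overflow bin with a warning.

Subgroup rate comparisons use the Welch t-test plus the Mann–Whitney U
(asymptotic p) when groups are unpaired; the matched area-vs-thickness
contrast across the 34 regions uses the paired t-test (df = 33) and
additionally reports both the Mann–Whitney U treating the two vectors as
independent samples and the Wilcoxon signed-rank — published analyses of
this kind report a U for matched vectors without stating the convention, so
both are computed.

## Power and PPV

Power of the two-sided paired t-test uses the exact noncentral-t
formulation: reject regions at t_crit(α/2, n−1) evaluated under
noncentrality |d|√n. The far-tail term can underflow to NaN in scipy's
noncentral-t CDF at large noncentrality; it is then exactly the term that
is numerically 0 and is clamped. Directional power — the probability of a
*correct-sign* rejection, which is what drives reproduction of a
significant pooled effect — is the matching single tail; at d = 0 it is
α/2 by convention (no correct direction exists, either tail is "wrong";
the convention makes the function continuous from both sides in the mean).
Monte-Carlo oracles (10⁶ simulated paired t-tests, frozen before the
implementation) anchor both functions in the tests, so no package's
convention is taken on faith. PPV is the exact formula
(1−β)R/((1−β)R+α); (1−β)R = 0 returns 0 with a warning.

## Reliability

ICC comes from the mean squares of the subjects × sessions two-way layout.
The default is absolute agreement, single measurement (ICC(A,1), two-way
random effects): scan–rescan with possible scanner drift is an
absolute-agreement question, so a constant session offset should (and
does) lower it. The consistency form ICC(C,1) is selectable and is
invariant to session offsets; both are exercised in tests, with pingouin
as an independent cross-check. Spearman correlations use average ranks for
ties with the large-sample p-value. Subjects scanned on different
hardware across sessions are retained (a metadata filter is left to the
caller), since hardware change is part of what absolute agreement is
meant to capture.

## Synthetic data

The generator emulates a 99-dataset, 70-measure paired-asymmetry study
with known ground truth; it is the package's test bed, not a model of any
particular cohort.

* **Sizes** are log-uniform on [14, 2326] by default (median ≈ 180),
  reproducing the heavy right skew of multi-site sample sizes between the
  observed extremes; an explicit size list is also accepted. Every size is
  ≥ 2 (the paired test needs df ≥ 1).
* **True effects**: each measure has a true d and a between-dataset SD τ.
  The default 70-measure profile places |d| on a deterministic split
  log-normal quantile grid anchored at the observed minimum/median/maximum
  magnitudes (0.0015 / 0.30 / 1.76). The split (wider log-scale spread
  below the median) is what allows a handful of essentially-null measures
  to coexist with a median of 0.30 — the nonsignificant branch of the
  criterion is only exercised if near-null effects exist. Signs alternate;
  area measures take the larger half of the magnitudes (area asymmetries
  are generally stronger than thickness asymmetries), so the
  area-vs-thickness contrast is planted. Default τ = 0.10 for every
  measure: the emulated study does not publish its heterogeneity, and
  moderate between-dataset SD of this order is typical for anatomical
  effects across scanners and cohorts. Chosen once; documented here.
* **Summary mode** (default): δᵢ ~ N(true d, τ²), observed
  dᵢ ~ N(δᵢ, 1/nᵢ + δᵢ²/(2nᵢ)) — the same normal approximation
  inverse-variance pooling assumes — with the per-dataset p computed from
  the implied t = d√n against the t distribution with nᵢ−1 df, so
  single-dataset significance behaves correctly at small n. **Individual
  mode** draws nᵢ paired differences ~ N(δᵢ, 1) and feeds them through the
  paired t-test itself, giving exact finite-n behaviour; the two modes
  agree in mean and variance at matched parameters (tested), and the
  power-link checks use individual-mode sampling because the noncentral-t
  power formula is exact there.
* **Covariates** (field strength 3T:1.5T ≈ 63:29, software 5.3:5.1:5.0 ≈
  91:6:2, age group child/adult/mixed ≈ 18:36:45) are assigned
  independently of size and of the effects — subgroup analyses on default
  synthetic data are negative controls.
* **Determinism**: all randomness flows from `SeedSequence([seed, stream,
  measure])`, so identical configs give byte-identical tables and measures
  are independent streams.

What the generator does *not* emulate: spatial correlation between the 70
measures within a dataset (measures are generated independently; the
emulated study's within-dataset covariance is unpublished), covariate
effects on the measures, non-normal measurement error, and
dataset-specific processing artifacts. Passing tests therefore demonstrate
the statistical machinery under the stated model, not robustness to those
real-data features.

## Problem sizes and numerical choices

Monte-Carlo checks run at sizes chosen so a 3σ binomial band is decisive:
null calibration uses 200 simulated 99-dataset multiverses; the
power-link check 500 replicates per effect size; monotonicity checks 40–80
replicates with a 3-SE noise allowance on each adjacent difference (mean
rates estimated by simulation are noisy; adjacent differences high in the
threshold ladder are genuinely tiny, and the allowance keeps the check
sharp against real violations while tolerating sampling error). Heavy
loops use the DL estimator (closed form, vectorizable; at τ = 0 the
estimator choice is immaterial), while single fits and the pipeline
default to REML. REML tolerance is 1e-10 on τ²; frozen cross-checks
against the R reference implementation agree to its own convergence
tolerance (~1e-5).

## Known limitations

* The criterion treats p ≤ .05 in a tiny dataset and p ≤ 10⁻¹⁵ in a large
  one identically; reproducibility is a binary-agreement rate, not an
  evidence measure.
* With k = 98 in every LOO pool, pooled significance is nearly certain for
  |d| ≳ 0.05, so the nonsignificant branch is driven by truly tiny
  effects, as intended — but this makes rate estimates for that branch
  sensitive to exactly how many near-null measures the profile contains.
* The deposited summary statistics of the emulated study are fetched by
  the user if desired (the reader accepts any conforming TSV/CSV with a
  column map); no downloader is shipped.
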