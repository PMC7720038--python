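# Methods

This note records the models, estimators and design decisions behind the
package, in the order the pipeline runs them.

## Inputs and conventions

The expression input is a genes × samples matrix of nonnegative,
already-summarized values on a log2-like scale (e.g. RMA output from a
microarray platform); the package deliberately does not touch probe-level
data. Clinical covariates arrive as one CSV row per subject; ventilation
courses as one CSV row per invasive-ventilation interval. Days are
real-valued and measured from ARDS onset (day 0); intervals are half-open
`[start, end)`. Missing values in modeling columns are rejected rather
than imputed — silent imputation in a 96-subject cohort would do more
harm than a loud error.

## Clinical scores and ventilation outcomes

* Oxygenation index OI = (mean airway pressure × FiO2 × 100) / PaO2
  (unitless; mean airway pressure in cmH2O, PaO2 in mmHg).
* Vasopressor score = dopamine + dobutamine (µg/kg/min each, ×1)
  + epinephrine, norepinephrine, phenylephrine (×100) + milrinone (×10)
  + vasopressin (U/kg/min, ×10,000).
* Ventilator days: an extubation gap of ≤ 24 h does not count as
  liberation and merges the adjacent intervals; a gap of exactly 24 h is
  therefore still one episode (liberation requires *more* than 24 h).
  Re-intubation after a sustained gap adds its days to the total.
* VFD at 28 days: survivors get 28 − total ventilator days, with partial
  days rounded up before subtraction so VFDs are integers (whether a
  study counts partial days as whole days is rarely stated; the rounding
  is configurable via `round_up_partial_days`); PICU nonsurvivors and
  subjects ventilated ≥ 28 days get 0.
* The competing-risk observation for the extubation analysis is the end
  of the *first sustained* liberation (> 24 h off the ventilator), event
  1 if the subject was alive at that point, event 2 (death) if death
  occurred while still on the ventilator, and administrative censoring at
  day 28 for subjects still ventilated. Later re-intubation episodes do
  not re-enter the risk set.

## Subtype discovery

Subjects are clustered with k-means (k-means++ initialization, Lloyd
iterations, best of `n_init` restarts by total within-cluster sum of
squares) in the full gene space of the values as given — no per-gene
rescaling, since the matrix is already on a common normalized scale and
rescaling would inflate uninformative genes.

The number of clusters is chosen with the gap statistic over k = 1..10.
The pooled within-cluster dispersion is W_k = Σ_r D_r / (2 n_r) with D_r
the sum of pairwise squared Euclidean distances in cluster r (computed
from the pairwise form; it equals the sum of squared distances to
centroids, and the test suite checks that identity numerically).
Reference datasets are drawn uniformly and independently per gene over
that gene's observed range — the simple axis-aligned reference; the
PCA-rotated variant is omitted because with p ≫ n it is costly and adds
little for this design. Zero-range genes carry no positional information
and are dropped from reference generation with a warning. With B
references (default 50; the bundled experiments use 20, which was ample
for a 96 × 2,000 problem), s_k = sd_b(log W*) · √(1 + 1/B) and the 95% CI
is gap ± 1.96 s_k (normal approximation; a bootstrap-percentile CI would
also be defensible, but with B ≥ 20 the reference log-dispersions are
very nearly Gaussian).

**Selection rule.** All k whose CI overlaps the CI of the globally
maximal gap are treated as statistically similar candidates. Candidates
leaving any cluster with fewer than `min_cluster_size` subjects (default
11, i.e. strictly more than 10, ~10% of a 96-subject cohort) are
eliminated. Among the survivors the *smallest* k is returned. Parsimony
here is load-bearing, not cosmetic: on structureless data the gap curve
is flat and its argmax is essentially a draw from correlated noise, so a
maximal-gap rule returns arbitrary k while the parsimonious rule
correctly returns k = 1 (the test suite checks exactly this null
behavior). On planted-subtype data the gap at the true k is far above the
smaller candidates, their CIs do not overlap, and both rules agree. The
literal maximal-gap-subject-to-size rule remains available as
`rule="max_gap"`. An audit trail (global maximum, candidate set, size
eliminations) is recorded in the pipeline manifest.

PCA projections for visualization use the centered SVD; variance
fractions are singular values squared over total centered sum of squares.

## Characterization statistics

Categorical subtype associations use the Freeman–Halton generalization of
Fisher's exact test: the p-value is the total multivariate-
hypergeometric probability of all r×c tables with the observed margins
whose probability does not exceed the observed table's, with a 1 + 1e-7
relative tolerance absorbing floating-point ties. Enumeration is exact
(recursive over rows, last row forced by the margins) and capped by an
explicit budget; the 2×3 tables of a ~100-subject cohort enumerate in
milliseconds. Continuous variables use tie-corrected Kruskal–Wallis
tests. The reported effect size is the rank-based η²_H = (H − k + 1) /
(n − k), floored at 0, consistent with the nonparametric testing
framework; the classical ANOVA-based η² is available behind a flag. Note
the rank-based η² has a ceiling below 1 for fixed k: with k equal groups
on perfectly separated rank blocks it converges to 1 − 1/k² (8/9 for
k = 3), which the tests assert. No multiplicity adjustment is applied
across characterization rows (raw p-values are reported);
Benjamini–Hochberg q-values are reserved for the gene-level gates.

## Outcome models

Mortality: logistic regression by maximum likelihood (IRLS), Wald
standard errors, 95% CIs exp(β ± 1.96 SE). Perfect or quasi-perfect
separation is detected (fitted probabilities pinned at 0/1 or runaway
coefficients) and raised as an explicit error; the pipeline skips and
logs such fits — with an 8% mortality subtype of n ≈ 36, a simulated
cohort occasionally has zero deaths in a cluster, and a silent
infinite-odds-ratio row would be worse than a gap in the table.

Extubation: Fine–Gray subdistribution-hazard regression, treating death
as competing. The weighted partial likelihood keeps subjects with a prior
competing event in later risk sets with IPCW weights
G(t−)/G(T_i−), where G is the Kaplan–Meier estimate of the censoring
survival; ties use the Breslow convention; Newton iterations run to a
gradient norm below 1e-8; the variance is a sandwich over per-subject
score residuals. Under purely administrative censoring at day 28 — this
package's default study design — G is 1 before the horizon and the
weights reduce to keeping competing-event subjects in the risk set with
weight 1, which is why the implementation reproduces an independent
implementation (`cmprsk::crr`) to ~1e-7 in both coefficients and robust
standard errors on a frozen fixture, and collapses exactly onto the Cox
partial likelihood when no competing events exist (the Cox fit, delegated
to statsmodels with Breslow ties, doubles as the reduction oracle).

Kaplan–Meier estimation and log-rank tests (overall and pairwise,
unadjusted) delegate to lifelines. The Aalen–Johansen cumulative
incidence estimator is implemented directly from the product formula so
that per-cause incidences plus overall survival sum to 1 to 1e-12 at
every jump time (a library implementation that jitters tied times would
break that identity and the hand-checked examples).

Subtype indicator designs use cluster 1 as the reference level, with
named adjustment presets: none, PRISM III, immunocompromised, both, and
both plus ANC or ALC. The models are always fit on *discovered* labels;
planted labels never leave the test suite.

## Differential expression

Quantile normalization maps every sample onto the mean of the per-sample
sorted vectors; within-column ties receive the mean of their tied
quantile targets, and the operation is idempotent. Genes pass the
expression filter when ≥ `min_value` (default 10) in ≥ `min_samples`
(default 10) samples, boundaries inclusive. The per-gene one-vs-rest
contrast is a Welch two-sample t on the log2-scale values with the
fold change as the plain mean difference. A count-model (negative
binomial) test is intentionally not emulated: the values are continuous
intensities, and the Welch t keeps the surrounding filter, twofold and
q < 0.1 gates identical while remaining honest about the data's scale.
"Twofold" is inclusive: |log2FC| ≥ 1. BH q-values are computed across the
filtered genes of each contrast.

## Synthetic cohorts

The generator produces the structure the analysis assumes, at
configurable size; the defaults describe a 96-subject cohort with three
subtypes of sizes 31/29/36, immunocompromise prevalences 0.32/0.48/0.14,
28-day death probabilities 0.32/0.24/0.08, a baseline extubation rate of
0.10/day (median ~7 ventilator days) and a 2,000-gene matrix with 200
informative genes shifted by +2.0 log2 units (noise SD 1.0).

* Subjects are apportioned to subtypes by largest remainder, so group
  sizes are exact and tests can pin them.
* Expression is Gaussian on the log2 scale around per-gene baselines
  uniform on [4, 12], with disjoint informative blocks per subtype
  (orthogonal signatures) and independence across genes — within-subtype
  co-expression is *not* modeled, so passing recovery tests speak to the
  planted mean structure, not to correlated real transcriptomes.
* Clinical covariates: immunocompromise Bernoulli per subtype; ANC/ALC
  lognormal with modest subtype location shifts (chosen to give
  single-digit-percent rank η², the regime of interest); PRISM III
  Poisson and subtype-independent; 24-h P/F and OI medians reproduce a
  persistent-hypoxemia first subtype.
* Outcomes: death by day 28 with the subtype's probability (optionally
  tilted by covariates via 1 − (1 − p)^exp(βᵀx)), death times from a
  truncated exponential on (0, 28]; extubation times for the remainder
  are exponential, censored administratively at day 28; a 10% fraction of
  extubated survivors is re-intubated after a sustained gap. Censoring is
  administrative only — no random loss to follow-up.
* For parameter-recovery and coverage studies,
  `simulate_fine_gray_cohort` generates data directly under the
  proportional subdistribution-hazards model via the standard indirect
  parameterization F₁(t|x) = 1 − (1 − p(1 − e^{−rt}))^{exp(βᵀx)}, so a
  planted log-SHR is the exact estimand of the fitted model. The cohort
  generator above parameterizes *death* probabilities instead (that is
  what a clinical table reports), under which the extubation
  subdistribution is only approximately proportional — hence the two
  generators coexist with different jobs.

All randomness flows from the config seed through named substreams
(expression / clinical / outcomes), so identical configs give
byte-identical cohorts regardless of which tables are generated.

## Experiment sizes and numerical choices

The bundled experiments (test suite and `scripts/acceptance.py`) use:
20-seed end-to-end recovery at 96 × 2,000 with B = 20 references and 5
k-means restarts; 100 simulations at n = 2,000 for SHR recovery
(planted SHR 2.39, the cohort-scale effect, with ~75% ultimately
extubated); 500 simulations at n = 500 for CI coverage of both
regression models; 10⁴ simulations for the Fisher and Kruskal–Wallis
null calibrations. Newton/IRLS tolerances are 1e-8 on the gradient;
k-means ties and equal gaps break toward smaller k; degenerate inputs
(zero margins, empty clusters, constant matrices, separation) raise
structured errors rather than returning numbers.

## Known limitations

* The expression model is spherical-Gaussian with orthogonal subtype
  signatures; correlated gene modules, batch effects and heavy-tailed
  intensities are out of scope, and real-data gap curves will be less
  clean than the simulated ones.
* The Welch-t DE stage is a deliberate simplification; its gene lists
  feed downstream tooling but are not a count-model reanalysis.
* The Fine–Gray sandwich variance omits the correction for an estimated
  censoring distribution; under the administrative-censoring designs
  generated here that term is exactly zero, but with random censoring
  the standard errors would be mildly approximate.
* Pathway enrichment, probe annotation and severity-score internals
  (PRISM III) are consumed as inputs, never computed.
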