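# Methods

This note documents the models, estimators and numerical choices behind
`microcompare`, what the synthetic-cohort generator does and does not
emulate, and the design decisions that were genuinely open.

## The synthetic-cohort generator

Every sample is a Dirichlet-multinomial draw: a component (an
"enterotype") is chosen from the cohort's mixture weights, a proportion
vector from Dirichlet(α), a sequencing depth uniformly from 10,000–60,000
reads (so rarefaction is a meaningful step), and counts from a multinomial.
Default cohort sizes are 75 (TR) and 80 (UR), the shape of the motivating
two-cohort gut study.

Component concentrations default to a lognormal shape (σ = 1.5) scaled to a
total concentration of 40: a handful of dominant taxa, a long rare tail,
and strong sample-to-sample overdispersion — the texture of stool 16S
profiles.  Planted structure:

* **Diversity gap** — `diversity_gap_spec` raises each concentration to the
  power 1/scale.  Skewed components become more even and richer, raising
  Shannon, Simpson and Chao1 in expectation; the power rule makes repeated
  application compose multiplicatively (scale a then b ≡ a·b), and the
  shared-component spec shape is preserved by appending the flattened
  copies and re-pointing only the high cohort's mixture weights at them.
* **Fold-change effects** — the target feature's α is multiplied by the
  fold in the enriched cohort, preserving the Dirichlet form so mixture
  recovery stays well-posed.
* **Core features** — a Dirichlet-coupled feature with mean 1% has so much
  between-sample variance that its prevalence *at a detection threshold* is
  far below its presence rate, so cores are implanted directly: with
  probability `prevalence` the feature's proportion is drawn from a tight
  lognormal band (σ = 0.35) around the target mean abundance, otherwise set
  to zero; remaining features are renormalized.  `mean_abundance` is the
  mean *when present*.
* **Metadata links** — covariates are generated from their marginals (age
  uniform 18–60, BMI uniform 15–35, sex balanced, diet with a cohort-typical
  vegetarian share) and then re-ordered through a Gaussian copula so their
  ranks track a chosen feature's abundance ranks at the requested Spearman
  ρ (default 0.5); a rank link, not a parametric regression, because the
  downstream analyses are rank-based.

What the generator does **not** emulate: sequencing error, chimeras and
taxonomy-assignment noise; phylogenetic correlation between features;
zero-inflation beyond the planted cores; batch effects.  Passing tests
therefore demonstrate that the estimators recover the statistical structure
they target — not robustness to artifacts upstream of the abundance table.

## Preprocessing

Rarefaction is subsampling **without replacement** (multivariate
hypergeometric), one substream per sample keyed by (seed, CRC32 of the
sample id) so results are reproducible and invariant to column order.  The
sparse filter drops features whose total count is below a fraction
(default 0.002%) of the grand total.  The prevalence rule (default 51%
non-zero, i.e. a non-zero median) is enforced within *every* declared
group: a feature must clear the fraction in each cohort separately.
Subsetting a relative table renormalizes the remaining features (closure of
the subcomposition).

## Alpha diversity

Shannon uses the natural log (the vegan convention; base exposed), Simpson
is the Gini–Simpson probability 1 − Σpᵢ², and Chao1 is always the
bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)), defined even when no
doubletons exist.  Group tests are two-sided Wilcoxon rank-sum: exact
enumeration for small tie-free samples, mid-ranks with normal approximation
and continuity correction otherwise (scipy's automatic rule, validated
against a brute-force enumeration oracle in the tests).  BH correction is
applied across all (metric × group-pair) rows emitted together.

## Enterotyping

**Distance route.**  The distance is √JSD with natural logs — a true
metric, the convention of classic enterotyping — computed after replacing
zeros by a pseudocount (default 1e-6) and renormalizing; raw JSD is
available (`sqrt=False`).  PCoA is classical scaling; negative eigenvalues
(inevitable for raw JSD) are reported, with zero coordinates on those axes
— this is why the eigendecomposition is done in-package rather than through
a library that clamps them.  PAM is BUILD + steepest-descent SWAP; because
single-swap descent can stall, a few seeded random restarts are run and the
cheapest solution kept (the tests verify agreement with exhaustive search
at n ≤ 8).  The CH index is evaluated on the PCoA embedding restricted to
positive-eigenvalue axes, since CH needs centroids and JSD space has none;
ties in assignment break toward the lowest medoid slot.

**Model route.**  The DMM is fitted by EM: responsibilities ∝
π_k·DirMult(x|α_k); mixture weights from responsibility means; α_k by
responsibility-weighted Minka fixed-point iterations (3 inner steps per
M-step).  The fit is MAP under a weak Exp(rate = 1) prior on every
concentration — the prior's rate simply adds to the Minka denominator.
This regularization is load-bearing for model selection: at a pure MLE,
features absent from a component sit on the α → 0 boundary with zero
curvature, and a bare Laplace criterion then rewards every extra component
for its flat directions, so the selected K climbs to the top of the range
regardless of the truth.  With the prior, the reported score is the
Laplace-approximated negative log evidence

    score = −[log posterior + (d/2)·ln 2π − ½·ln|H|]

with H the observed information approximated block-diagonally per component
(responsibilities fixed), and each curvature direction contributing
max(0, ½·ln(h/2π)): weakly-determined directions are carried by their prior
mass and cannot inflate the evidence.  `prior_rate=0` restores plain ML.
Initialization: one soft k-means start (on log-proportions) plus random
soft partitions; convergence at relative objective change < 1e-8, at most
500–1000 iterations; the EM objective trace is monotone by construction and
asserted in the tests.  By default only the 500 most abundant features
enter the fit (tractability on OTU tables); the full-table mode is a flag.

## Core taxa

The qualification rule — relative abundance ≥ 0.1% in ≥ 70% of samples —
is re-evaluated on bootstrap resamples (default: 1000 draws of n samples
*with replacement*, the standard bootstrap; subset size and replacement are
exposed since other resampling conventions exist).  The score is the
percentage of resamples in which the feature qualified; core requires
≥ 80.  With this scheme the score of a feature whose presence is a clean
Bernoulli equals the binomial tail P(Binom(n, p̂)/n ≥ 0.7), which the tests
check against scipy's binomial distribution.  Function-abundance tables are
scored by the same machinery — they are just another abundance table.

## Differential abundance

Samples are scaled to a fixed total of 10⁶ before the LDA stage (the
LEfSe convention), making the score invariant to global depth rescaling.
Stage 1 is a per-feature Kruskal–Wallis test on raw p (no FDR, matching
the original tool; BH is a flag); constant features get p = 1.  Stage 2
averages, over 30 bootstrap rounds of 2/3-per-class subsampling, the
per-feature effect

    e_f = ½·(|w_f|·d + |Δ_f|)

where w is the unit-norm ridge-regularized (1e-6) Fisher discriminant
direction, d the separation of the projected class means, and Δ_f the
feature's class-mean difference; the score is sign(Δ_f)·log₁₀(1 + mean e_f).
Taking absolute values inside the average makes the magnitude exactly
invariant under swapping the class labels, so scores negate exactly — the
sign convention ties to the lexicographically first class label, not to
sample order.  Subsamples are drawn per class in a partition-canonical
order for the same reason.  There is no subclass (within-class) stage: the
two-cohort design has none.  Default gates: |LDA| > 4 at p < 0.05 for taxa,
|LDA| > 2.5 at p < 0.001 for function tables; the clade rollup repeats the
analysis on the table collapsed at each taxonomic rank.

## Metadata associations

Age is binned into six contiguous 5-year intervals anchored at the observed
minimum floored to a multiple of 5 (anchor exposed), last bin closed; ages
outside the span keep NA bins and are flagged.  BMI cuts are the WHO
values 18.5/25.0, with the upper category labelled "obese" since the design
has exactly three groups; boundary values go up (18.5 → normal,
25.0 → obese).  White's-style two-group comparison is realized as a seeded
permutation test of the mean difference (default 1000 permutations,
p ≥ 1/(n_perm+1)) with a bootstrap 95% CI; the original tool's sparse-data
heuristic is omitted because filtered abundance tables here are dense.
Multi-group tests use Kruskal–Wallis with η² = (H−k+1)/(n−k) and classic
Tukey–Kramer post hocs (studentized-range p, unequal-n correction).  Trend
labels (increasing/decreasing/none) formalize qualitative monotone
statements: Spearman ρ against the ordinal bin index, BH across the feature
family.

## Co-occurrence networks

The null is a randomization walk: at each of 10,000 steps, every feature
row independently swaps one uniformly chosen pair of sample values, and all
pairwise Spearman correlations of the walking table are pooled.  Because
swaps accumulate, the walk's stationary law is an independent per-row
permutation — the exact permutation null; a `fresh` mode (each step one
swap from the observed table) is kept for comparison but is *not* a
meaningful null, since single swaps barely perturb the observed
correlations.  Implementation note: swapping values within a row permutes
its ranks identically, so the walk runs on standardized ranks and each
step's correlation matrix is one matrix product.  The critical r is the
two-sided |r| quantile at 99% confidence (type-7 linear interpolation),
pooled over all pairs (one global threshold; per-pair nulls would need far
more steps per pair).  Edges require both |r| > critical r and BH-corrected
p < 0.01.  Diversity indices and numeric metadata enter as extra rows;
categorical metadata is excluded from correlation.  The null mean is
reported as the "expectancy value".

## Classification

The stratified 70:30 split takes ⌊frac·n_c⌋ per class and assigns leftover
slots (to reach round(frac·N)) by largest fractional part — for 80 + 75
samples this gives 56 + 52 or 53 in training.  Repeated CV is 10-fold
× 10 repeats, stratified, out-of-fold scores pooled per repeat into one
AUC.  ROC uses a threshold sweep with mid-rank tie handling, so the
trapezoid AUC equals the normalized Mann–Whitney U exactly (asserted to
1e-12).  The learner is any `fit(X, y) → score_fn` callable; the default is
a random forest (200 trees), chosen because the module's contract is the
split/CV/ROC machinery, not the learner.

## Problem sizes used in the checks

The test-suite and `scripts/acceptance.py` exercise the pipeline at the
study's natural scale where that is cheap (75/80 samples, 200–300 features
for diversity, effect sizes, classification, clustering) and at 150 samples
× 100 features for the DMM selection sweep (k = 1..7, 3 restarts, 20
seeded replicates) — sizes chosen so the full acceptance run completes in
a few minutes on one CPU while keeping every statistical margin wide.

## Known limitations

* The DMM Laplace score depends on the block-diagonal curvature
  approximation and the weak prior; it selects the component count reliably
  for well-separated components but, like all evidence approximations, can
  prefer an extra component when clusters are small and heavily
  overdispersed.
* The LDA effect-size formula matches the original tool in sign, scale and
  thresholds, and in ranking behaviour — not bit-for-bit, since the
  original's exact expression is folklore.
* White's test is a permutation realization, not the original closed-form
  heuristic.
* Compositional effects are not modelled away: correlations between
  relative abundances carry the usual closure-induced bias, as in the
  methods this package mirrors (no SparCC-style correction).
* PAM restarts make the clustering robust in practice but global optimality
  is only guaranteed where the tests enumerate (n ≤ 8).
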