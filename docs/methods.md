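# Methods

This note documents the models, the statistical choices, and the
synthetic-data design behind `prosig`, including the places where the
design was genuinely open and what was decided.

## Gene-set scoring

Scoring is a per-sample, rank-based running sum.  Genes are
mean-centered across the cohort (so only deviations from a gene's
cohort-typical level matter), each sample's centered values are sorted
in descending order, and for each gene set the walk steps up at in-set
genes and down otherwise.  `Score+` is the walk's maximum over
positions 1..N, `Score−` its minimum.

**Walk increments.**  The default increments are
`d_in = sqrt((N−S)/S)`, `d_out = −sqrt(S/(N−S))` — the classic
unweighted Kolmogorov–Smirnov-style statistic, whose defining property
is that the walk terminates at exactly zero, making the max/min
excursions interpretable and comparable across set sizes.  A `literal`
variant with increments `(N−S)/S` and `−S/(N−S)` is retained behind a
flag; its walk terminates at `N−2S`, which systematically inflates
small sets, so it is not the default.

**Direction.**  `Score+ − Score−` (the `total` statistic) is blind to
direction: a strongly depleted set scores exactly as high as a strongly
enriched one.  Observed pathway signatures in tumor cohorts are
directional — depleted Polycomb-target programs appear as *low*
signature values in poorly differentiated cancers, not high ones — and
a direction-blind score also poisons downstream averaging: the mean
normal signature would be elevated on sets that are merely *absent*
from normal tissue, making the composition correction subtract signal
it should preserve.  The pipeline therefore defaults to the `signed`
statistic: the dominant excursion with its sign (`Score+` if
`Score+ ≥ |Score−|`, else `Score−`).  Both statistics are exposed at
every API level; the walk primitive itself always reports
`(Score+, Score−, total)`.

**Ties** in the ranking are broken by input gene order via a stable
sort, so results are bit-reproducible across platforms.

**Normalisation.**  Three strategies: min-max to [0, 1] per sample (the
default — it matches a clinical setting where a fixed panel is applied
to each new patient separately), min-max per set across samples, and an
empirical p-value against size-matched random gene sets drawn without
replacement from the scored genes, with add-one smoothing
(`p = (1 + #{null ≥ obs}) / (B + 1)`, so p is never zero).  A constant
score vector cannot be min-max scaled and maps to 0.5 with a warning —
one degenerate sample should not abort a cohort run; downstream
correlation then fails explicitly for that sample.

**Set hygiene.**  Gene identifiers are matched as exact case-sensitive
strings.  Sets are intersected with the matrix genes before scoring;
sets retaining fewer than 5 genes trigger a robustness warning and sets
retaining none are dropped with an error-level log.

## Subtype assignment

Pearson correlation of an n-dimensional signature (n = 15 gene sets in
a full panel) against each reference subtype row gives dependent
correlations — they share the sample vector.  Comparing two of them
uses Steiger's Z with the averaged-correlation covariance form (the
variant using `r̄ = (r_jk + r_jh)/2`; several variants exist in the
literature and one must be pinned for reproducibility):

    s = [r_kh(1 − 2r̄²) − ½ r̄²(1 − 2r̄² − r_kh²)] / (1 − r̄²)²
    Z = sqrt(n − 3)(z_jk − z_jh) / sqrt(2 − 2s)

with Fisher transforms z.  The test is **one-sided** by default: the
assignment criterion is directional ("significantly *better*
correlated"), and thresholds up to 0.5 are only coherent one-sided
(at alpha = 0.5 the rule degenerates to "whichever correlation is
larger", which is the intended limiting behaviour).  A two-sided option
exists.  Preconditions: n ≥ 4 (the statistic needs `sqrt(n − 3)` and a
meaningful covariance), |r| < 1 (Fisher transform), and a feasible
correlation triple (an infeasible `(r_jk, r_jh, r_kh)` — one no joint
distribution can produce — raises rather than returning a complex Z;
correlations computed from actual data are always feasible).

Exclusive mode assigns a sample to the one subtype that beats every
other subtype at alpha; at most one subtype can do so, because the two
one-sided p-values of a pair sum to one.  Prognosis mode pools the
subtypes: *bad* iff some bad subtype beats both good subtypes, *good*
by the mirrored rule; the same sum-to-one argument makes the two calls
mutually exclusive at any alpha ≤ 0.5.  No multiple-testing correction
is applied across samples — thresholds are deliberately per-sample, and
cohort-level error control is out of scope.

Gene sets with undefined scores in a sample are dropped from its
correlations with a warning and n adjusted; below n = 4 the sample is
unassignable.  Samples with constant signatures are unassignable, never
silently zero-correlated.

## Composition correction

The correction is the algebraic inverse of an additive contamination
model in signature space: if an observed signature is
`PR_true + SE_AVG·frac/(1−frac)`, subtraction recovers `PR_true` to
machine precision.  On real mixtures (and on the simulator's
expression-space mixtures) the model is only approximate, which is
exactly the regime the pipeline must tolerate.  Decisions:

* `frac` is the fraction of **normal** tissue.  Histopathology reports
  often state percent *cancer*; the metadata reader accepts either
  column (`frac_normal` or `percent_cancer`) and converts explicitly,
  because silently confusing the two inverts the correction.
* `frac` is capped at 0.95: the factor `frac/(1−frac)` is unbounded and
  a "cancer" sample that is nearly pure normal tissue has no meaningful
  cancer signature to recover (the strongest factor in actual use is 9,
  at frac = 0.9, which is also the diagnostic factor applied to normal
  samples via `include_normals`).
* Correction operates on normalised signatures and the output is *not*
  renormalised; corrected values may leave [0, 1].  Renormalising would
  distort inter-sample comparability, and Pearson correlation
  downstream is location/scale-invariant anyway.
* Correction runs after per-sample normalisation, not before.  SE_AVG
  is only meaningful as an average of comparable (normalised) vectors.

## Cohort analysis

Within/between splits enumerate each unordered sample pair exactly
once: `patient` and `gleason` groupings over cancer samples only,
`sample_type` over all pairs (same-type vs cross-type), and
`normal_vs_cancer_patient` over normal–cancer pairs split by shared
patient.  Group comparison uses the two-sided Mann–Whitney rank-sum
test: correlations are bounded and non-normal, so a rank-based test is
the safe default.

Clustering is agglomerative on correlation distance `1 − r` with
single linkage by default (the default of the standard scientific
Python clustering package, configurable to average/complete/ward), and
the dendrogram leaf order is recorded for matrix export.  The
same-patient neighbour statistic counts samples whose immediate left or
right neighbour in leaf order shares their patient; its null
expectation and p-value come from uniform random permutations of the
labels with add-one smoothing.  Adjacency is strictly immediate
neighbours — the most conservative reading of "cluster neighbour".

## Synthetic cohorts

The generator produces the structure the pipeline is designed to
detect, with full ground truth.  Defaults (all overridable) describe a
realistic prostatectomy cohort:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 500 | scored gene universe |
| `n_sets` × `set_size` | 15 × 20 | disjoint gene sets; 3 characteristic sets per subtype, 3 neutral |
| `n_patients`, `samples_per_patient` | 40, 3 | 120 cancer samples |
| `normal_sample_fraction` | 0.25 | 40 pure-normal samples |
| `effect_size` | 3.0 | mean characteristic-gene shift, in noise-SD units |
| `effect_strength_sd` | 0.5 | per-sample lognormal program-strength spread (mean 1) |
| `patient_effect_sd` | 3.0 | per-patient per-gene shift shared by the patient's samples |
| `noise_sd` | 1.0 | iid measurement noise |
| `frac_bounds` | (0, 0.6) | uniform normal-tissue fractions of cancer samples |
| `normal_goodlike_weight` | 0.5 | strength of good-prognosis programs in benign tissue |
| `normal_heterogeneity_sd` | 1.5 | per-sample variability of the contaminating benign tissue |

Design choices, with the reasoning:

* **Subtype effects are gene-set-level mean shifts**, not a full
  covariance model — that is precisely the structure the signature
  statistic targets; richer models are out of scope.  Each sample
  expresses its program at a lognormal strength with mean 1
  (`effect_strength_sd`), because real tumors vary in program activity
  and a cohort in which every tumor carries a uniform 3-SD shift is
  unrealistically easy to classify.
* **Patient effect** is an additive per-patient Gaussian gene shift
  shared by the patient's cancer samples.  Its default is calibrated at
  cohort level: rank-based scoring strongly attenuates gene-level
  correlation (a gene-level r of 0.5 between two samples yields nearly
  uncorrelated signatures), and 3 noise-SD units is what makes the
  synthetic cohort show both clear within-patient signature homogeneity
  and a realistic minority of unassignable samples.
* **Mixing is linear in expression space** — the standard two-component
  bulk assumption — so the signature-space correction faces a
  deliberately imperfect contamination model, as it does on real data.
  The benign-tissue profile carries the good-prognosis subtypes'
  characteristic programs at half strength (`normal_goodlike_weight`):
  benign prostate tissue is molecularly far closer to the indolent
  subtypes than to the aggressive ones.  This is what makes normal
  samples classify on the good-prognosis side, makes contamination
  *mask* aggressive signatures, and gives the correction its
  directional effect (it adds bad-prognosis calls and removes none).
  The contaminating tissue also varies per sample
  (`normal_heterogeneity_sd`), so samples with more normal content have
  noisier profiles — the mechanism behind the elevated unassignment of
  samples with similar cancer/normal proportions.
* **References from truth** score each subtype's noise-free prototype
  against the neutral normal baseline in a two-column panel and use the
  prototype's normalised signature as the reference row.  Scoring all
  four prototypes jointly would be wrong under rank statistics: every
  *other* subtype's genes would form a maximal bottom-of-list block (a
  rank statistic cannot distinguish mild from strong depletion), and
  the rows would collapse onto each other.  Rows are then rescaled to
  [−1, 1] and rounded to half units — the five levels a heatmap color
  code distinguishes — because reference matrices in this field are
  typically digitized by eye from published figures and that
  quantization error is part of the operating conditions.  Zero effect
  size yields a degenerate (constant) prototype signature and is
  rejected.

**What the generator does and does not emulate.**  It reproduces:
latent subtype structure expressed through gene sets, within-patient
homogeneity, two-component tissue mixing with histopathology-style
`frac` metadata, good-prognosis/normal similarity, and seeded
determinism.  It does **not** model probe- or batch-level microarray
noise, gene–gene correlation within sets beyond the shared shift,
survival outcomes, or intra-patient clonal divergence.  Passing
recovery tests on these cohorts shows the pipeline correctly inverts
the structure it assumes; it does not certify performance on data whose
contamination or noise departs qualitatively from these models.

## Numerical and testing notes

* All randomness flows through seeded numpy generators; the same seed
  reproduces cohorts bit-for-bit.
* The zero-sum walk's terminal value is checked to |sum| < 1e−9; the
  exhaustive walk oracle (all placements for N ≤ 8, S ≤ 4, both weight
  variants) is enumerated by an independent cumulative-sum loop.
* Steiger-test calibration is verified against a simulated
  trivariate-normal null (type-I error within two binomial standard
  errors of nominal at 0.05 and 0.25, n = 15).
* Composition-dependence of assignability is measured pooled over
  several cohort realisations: at the default conditions only a handful
  of samples per cohort are unassignable, so per-cohort bin rates are
  too noisy to rank.
* Test problem sizes (cohorts of 160 samples, 500 genes; thousands of
  null replicates) are chosen so the full suite runs in well under a
  minute of CPU apiece while keeping Monte-Carlo error far below the
  asserted margins.

## Known limitations

* The direction question is resolved by this package in favour of the
  signed statistic; analyses built on the direction-blind total will
  differ for strongly depleted sets.
* The Steiger variant, its sidedness, and the rank-sum group test are
  pinned choices among defensible alternatives; all are configurable.
* `frac` is taken from histopathology as given; estimating tumor purity
  from expression is explicitly out of scope, as are raw microarray
  preprocessing, survival analysis, and interpretation of individual
  gene sets.
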