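# prosig

Signature-based molecular subtyping for prostate-cancer expression
cohorts: per-sample gene-set enrichment signatures, statistical subtype
assignment against reference profiles, normal-tissue composition
correction, and cohort-structure analysis — with a fully seeded
synthetic-cohort generator for end-to-end validation.

## The problem

Bulk prostate tissue samples are mixtures of cancer and benign
(stromal/epithelial) tissue, tumors are molecularly heterogeneous
between patients, and single-gene markers have proven fragile.  A
robust alternative characterizes each sample by a small vector of
pathway-level scores (a *signature*) and classifies it against
reference subtype profiles — here two aggressive, bad-prognosis
subtypes (ESC/PTEN−/Proliferation-driven `BP-E/P/Pr` and ERG-fusion
driven `BP-ERG`) and two indolent, good-prognosis subtypes (`GP1`,
`GP2`).  The pipeline is aimed at computational biologists analysing
microarray-style expression matrices with histopathology metadata.

## The method

**Per-sample scoring.**  Each gene is mean-centered across samples;
each sample's centered values are ranked in descending order, and every
gene set `GS` (size `S` of `N` scored genes) is scored by a running
sum that steps up by `d_in = sqrt((N−S)/S)` at in-set genes and down by
`d_out = −sqrt(S/(N−S))` otherwise:

    Score+ = max_{1≤k≤N} Σ_{j≤k} d(j),   Score− = min_{1≤k≤N} Σ_{j≤k} d(j)

The increments telescope to zero, so the excursions are meaningful.
The pipeline reports the *signed* dominant excursion (enriched sets
positive, depleted sets negative); the direction-blind total
`Score+ − Score−` is available as an option.  Related sets can be
averaged (21 → 15 in the motivating use case) and scores are min-max
normalised to [0, 1] per sample.

**Assignment.**  A sample's signature is Pearson-correlated with each
reference row over the n = 15 gene sets.  Two correlations sharing the
sample (`r_jk` vs `r_jh`, with reference inter-correlation `r_kh`) are
compared by Steiger's one-sided Z for dependent correlations:

    s = [r_kh(1 − 2r̄²) − ½ r̄²(1 − 2r̄² − r_kh²)] / (1 − r̄²)²
    Z = sqrt(n − 3) · (z_jk − z_jh) / sqrt(2 − 2s)

A sample is called *bad prognosis* iff some bad subtype's correlation
significantly beats **both** good subtypes' (the two bad subtypes need
not differ), and symmetrically for *good*; exclusive single-subtype
mode is also provided.

**Composition correction.**  With `SE_AVG` the average normal-sample
signature and `frac` a sample's histopathological normal-tissue
fraction:

    PR_corrected = PR − SE_AVG · frac / (1 − frac)

**Cohort analysis.**  Within/between-group signature correlations
(patient, Gleason, sample type) compared by rank-sum test; hierarchical
clustering on correlation distance (1 − r) with leaf ordering; and a
permutation statistic for same-patient adjacency in the dendrogram.

## Worked example

```bash
python examples/03_composition_correction.py
```

prints, for a seeded synthetic cohort of 120 cancer + 40 normal
samples:

```
alpha=0.05: bad-prognosis calls 52 -> 64 after correction; every initial call retained: True
alpha=0.25: bad-prognosis calls 63 -> 70 after correction; every initial call retained: True
```

Subtracting the normal-tissue component unmasks aggressive signatures
that benign tissue had diluted: the number of bad-prognosis calls rises
and no existing call is lost.  The other examples cover scoring
(`01`), assignment across thresholds (`02`, where pure normal samples
land on the good-prognosis side), cohort structure (`04`, within-patient
median signature correlation ≈ 0.8 versus ≈ −0.07 between patients, and
72 of 120 samples adjacent to a same-patient sample in the dendrogram
against 4 expected by chance), and reference-matrix configuration
(`05`).

A thin CLI mirrors the library:
`prosig simulate | score | correct | assign | cluster | groupcorr`.

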