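"""Synthetic expression cohorts with known subtype ground truth.

The generator emulates the statistical structure the signature pipeline
is built for: a cohort of ~40 patients contributing several prostate
samples each, where

* every patient carries one latent molecular subtype (two bad-prognosis
  subtypes, two good-prognosis subtypes), shared by all of the
  patient's cancer samples;
* a subtype expresses itself as a mean shift (``effect_size``, in
  noise-SD units) on the genes of its characteristic gene sets; each
  sample expresses the program at its own strength (lognormal with
  mean 1 around the cohort mean), reflecting the program-activity
  heterogeneity real tumors show;
* each patient additionally has a private per-gene Gaussian shift
  (``patient_effect_sd``) shared by all their cancer samples — the
  source of within-patient signature homogeneity;
* every cancer sample is a linear two-component mixture of its cancer
  expression profile and a normal-tissue profile, weighted by the
  sample's fraction of normal tissue ``frac``; the normal component is
  itself perturbed per sample (``normal_heterogeneity_sd``) because the
  contaminating benign tissue varies in stromal/epithelial composition
  — so the more normal tissue a sample carries, the noisier its
  expression profile;
* the normal-tissue profile carries a half-strength version of the
  good-prognosis subtypes' characteristic-set elevation — benign
  prostate tissue is molecularly much closer to the indolent subtypes
  than to the aggressive ones, which is why normal contamination masks
  aggressive signatures and pure normal samples classify as
  good-prognosis-like;
* pure normal samples are the normal profile plus noise; and
* independent Gaussian noise (``noise_sd``) is added per gene per
  sample.

Everything is reproducible from the seed: the same seed yields a
bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    ReferenceSubtypes,
    SampleMetadata,
)
from .scoring import compute_raw_scores, normalize_signatures

__all__ = [
    "SUBTYPES",
    "PROGNOSIS",
    "CohortSimulationParams",
    "GroundTruth",
    "simulate_gene_set_collection",
    "simulate_cohort",
    "make_reference_from_truth",
]

SUBTYPES = ("BP-E/P/Pr", "BP-ERG", "GP1", "GP2")
PROGNOSIS = {"BP-E/P/Pr": "bad", "BP-ERG": "bad", "GP1": "good", "GP2": "good"}


@dataclass(frozen=True)
class CohortSimulationParams:
    """Study conditions for a synthetic cohort.

    Defaults mirror a realistic prostatectomy cohort: ~40 patients with
    three cancer samples each plus pure-normal samples making up about a
    quarter of the cohort; 500 scored genes carrying 15 gene sets of 20
    genes (three characteristic sets per subtype, three neutral);
    characteristic-set genes shifted by 3 noise-SD units; unit
    measurement noise; and normal tissue fractions of cancer samples
    spread uniformly between 0 and 0.6, as histopathology typically
    reports for macrodissected samples.

    ``patient_effect_sd`` is calibrated at cohort level, not gene
    level: rank-based scoring attenuates gene-level correlation, and a
    per-gene patient shift of 3 noise-SD units is what makes the
    synthetic cohort behave like a real prostatectomy cohort on two
    observable scales at once — clear within-patient signature
    homogeneity (within-patient correlations far above between-patient
    ones) together with a realistic fraction of samples (roughly a
    quarter to a third) whose subtype cannot be called at moderate
    thresholds.  Much smaller values make classification nearly
    perfect, which real expression cohorts never are.
    """

    n_genes: int = 500
    n_sets: int = 15
    set_size: int = 20
    overlap_fraction: float = 0.0
    sets_per_subtype: int = 3
    n_patients: int = 40
    samples_per_patient: tuple[int, int] = (3, 3)
    subtype_prevalences: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    effect_size: float = 3.0
    effect_strength_sd: float = 0.5
    patient_effect_sd: float = 3.0
    noise_sd: float = 1.0
    frac_bounds: tuple[float, float] = (0.0, 0.6)
    normal_sample_fraction: float = 0.25
    normal_goodlike_weight: float = 0.5
    normal_heterogeneity_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.subtype_prevalences) - 1.0) > 1e-9:
            raise ValueError("subtype prevalences must sum to 1")
        if len(self.subtype_prevalences) != len(SUBTYPES):
            raise ValueError(f"need one prevalence per subtype {SUBTYPES}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0 <= self.frac_bounds[0] <= self.frac_bounds[1] < 1):
            raise ValueError("frac_bounds must satisfy 0 <= lo <= hi < 1")
        if self.sets_per_subtype * len(SUBTYPES) > self.n_sets:
            raise ValueError("more characteristic sets than gene sets")
        if not 0 <= self.normal_sample_fraction < 1:
            raise ValueError("normal_sample_fraction must be in [0, 1)")
        if not 0 <= self.normal_goodlike_weight <= 1:
            raise ValueError("normal_goodlike_weight must be in [0, 1]")
        if self.effect_strength_sd < 0:
            raise ValueError("effect_strength_sd must be >= 0")
        if self.normal_heterogeneity_sd < 0:
            raise ValueError("normal_heterogeneity_sd must be >= 0")


@dataclass
class GroundTruth:
    """Latent structure behind a simulated cohort."""

    sample_subtype: dict[str, str | None]  # None for pure normal samples
    sample_frac: dict[str, float]
    sample_patient: dict[str, str]
    patient_subtype: dict[str, str]
    characteristic_map: dict[str, str | None]  # gene set -> subtype (or neutral)
    gene_sets: GeneSetCollection = field(repr=False)

    def prognosis_of(self, sample_id: str) -> str | None:
        sub = self.sample_subtype[sample_id]
        return None if sub is None else PROGNOSIS[sub]


def simulate_gene_set_collection(
    n_genes: int,
    sizes: list[int],
    overlap_fraction: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> GeneSetCollection:
    """Draw gene sets from a gene universe, optionally sharing a gene pool.

    With ``overlap_fraction`` = 0 the sets are disjoint; otherwise each
    set draws that fraction of its genes from one shared pool (so any
    two sets overlap in expectation) and the rest exclusively.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = np.array([f"g{i:04d}" for i in range(n_genes)])
    n_shared = max(int(round(overlap_fraction * s)) for s in sizes) if sizes else 0
    n_exclusive = sum(s - int(round(overlap_fraction * s)) for s in sizes)
    if n_shared + n_exclusive > n_genes:
        raise ValueError(
            f"gene sets need {n_shared + n_exclusive} genes but the universe has {n_genes}"
        )
    perm = rng.permutation(n_genes)
    pool = genes[perm[:n_shared]]
    rest = genes[perm[n_shared:]]
    sets, start = [], 0
    for i, size in enumerate(sizes):
        k_shared = int(round(overlap_fraction * size))
        members = list(rest[start : start + size - k_shared])
        start += size - k_shared
        if k_shared:
            members += list(rng.choice(pool, size=k_shared, replace=False))
        sets.append(GeneSet(f"set{i + 1:02d}", frozenset(members)))
    return GeneSetCollection(sets)


def _characteristic_map(params: CohortSimulationParams, names: list[str]) -> dict[str, str | None]:
    cmap: dict[str, str | None] = {}
    for i, name in enumerate(names):
        k = i // params.sets_per_subtype
        cmap[name] = SUBTYPES[k] if k < len(SUBTYPES) else None
    return cmap


def _model_components(params: CohortSimulationParams):
    """Seeded structural pieces shared by the cohort and its references."""
    rng = np.random.default_rng([params.seed, 1])
    sets = simulate_gene_set_collection(
        params.n_genes, [params.set_size] * params.n_sets, params.overlap_fraction, rng
    )
    cmap = _characteristic_map(params, sets.names)
    rng = np.random.default_rng([params.seed, 2])
    cancer_baseline = rng.normal(0.0, 1.0, params.n_genes)
    normal_baseline = rng.normal(0.0, 1.0, params.n_genes)
    gene_index = {g: i for i, g in enumerate(f"g{i:04d}" for i in range(params.n_genes))}
    effect = {}
    for sub in SUBTYPES:
        ind = np.zeros(params.n_genes)
        for s in sets:
            if cmap[s.name] == sub:
                for g in s.genes:
                    ind[gene_index[g]] = 1.0
        effect[sub] = ind * params.effect_size
    # benign tissue expresses the indolent subtypes' programs at reduced
    # strength: normal contamination therefore masks aggressive signatures
    # and pulls mixed samples toward the good-prognosis side
    normal_profile = normal_baseline + params.normal_goodlike_weight * (
        effect["GP1"] + effect["GP2"]
    )
    return sets, cmap, cancer_baseline, normal_baseline, normal_profile, effect


def simulate_cohort(
    params: CohortSimulationParams,
) -> tuple[ExpressionMatrix, list[SampleMetadata], GroundTruth]:
    """Generate a full cohort: expression, metadata and ground truth."""
    sets, cmap, cancer_base, _normal_base, normal_profile, effect = _model_components(params)
    rng = np.random.default_rng([params.seed, 3])

    patients = [f"P{i + 1:02d}" for i in range(params.n_patients)]
    prev = np.asarray(params.subtype_prevalences)
    patient_subtype = {
        p: SUBTYPES[i] for p, i in zip(patients, rng.choice(len(SUBTYPES), size=len(patients), p=prev))
    }
    patient_shift = {
        p: rng.normal(0.0, params.patient_effect_sd, params.n_genes) for p in patients
    }

    lo, hi = params.samples_per_patient
    columns: dict[str, np.ndarray] = {}
    metadata: list[SampleMetadata] = []
    sample_subtype: dict[str, str | None] = {}
    sample_frac: dict[str, float] = {}
    sample_patient: dict[str, str] = {}

    for p in patients:
        k = int(rng.integers(lo, hi + 1))
        for j in range(k):
            sid = f"{p}_c{j + 1}"
            sub = patient_subtype[p]
            frac = float(rng.uniform(*params.frac_bounds))
            # per-sample program strength: lognormal, mean exactly 1
            sd = params.effect_strength_sd
            strength = (
                float(np.exp(rng.normal(0.0, sd) - 0.5 * sd * sd)) if sd > 0 else 1.0
            )
            cancer_comp = cancer_base + strength * effect[sub] + patient_shift[p]
            noise = rng.normal(0.0, params.noise_sd, params.n_genes)
            # the contaminating benign tissue has its own per-sample makeup
            normal_comp = normal_profile + rng.normal(
                0.0, params.normal_heterogeneity_sd, params.n_genes
            )
            columns[sid] = (1.0 - frac) * cancer_comp + frac * normal_comp + noise
            gleason = int(rng.choice([6, 7, 8, 9], p=[0.25, 0.40, 0.20, 0.15]))
            metadata.append(
                SampleMetadata(sid, p, "cancer", gleason=gleason, frac_normal=frac)
            )
            sample_subtype[sid] = sub
            sample_frac[sid] = frac
            sample_patient[sid] = p

    n_cancer = len(columns)
    f = params.normal_sample_fraction
    n_normals = int(round(n_cancer * f / (1.0 - f))) if f > 0 else 0
    for i in range(n_normals):
        p = patients[i % len(patients)]
        sid = f"{p}_n{i // len(patients) + 1}"
        noise = rng.normal(0.0, params.noise_sd, params.n_genes)
        normal_comp = normal_profile + rng.normal(
            0.0, params.normal_heterogeneity_sd, params.n_genes
        )
        columns[sid] = normal_comp + noise
        metadata.append(SampleMetadata(sid, p, "normal", gleason=None, frac_normal=1.0))
        sample_subtype[sid] = None
        sample_frac[sid] = 1.0
        sample_patient[sid] = p

    genes = [f"g{i:04d}" for i in range(params.n_genes)]
    X = ExpressionMatrix(pd.DataFrame(columns, index=genes))
    truth = GroundTruth(
        sample_subtype=sample_subtype,
        sample_frac=sample_frac,
        sample_patient=sample_patient,
        patient_subtype=patient_subtype,
        characteristic_map=cmap,
        gene_sets=sets,
    )
    return X, metadata, truth


def make_reference_from_truth(
    params: CohortSimulationParams,
    weights_variant: str = "zero_sum_ks",
    statistic: str = "signed",
    digitize: bool = True,
) -> ReferenceSubtypes:
    """Build a reference subtype matrix by scoring noise-free prototypes.

    For each subtype a noise-free prototype expression profile (baseline
    plus the subtype's characteristic-set shift) is scored through the
    standard pipeline alongside the noise-free normal-tissue profile,
    and the prototype's normalised signature becomes that subtype's
    reference row.  Scoring each prototype against the normal profile —
    rather than against the other prototypes — keeps the other subtypes'
    genes at background level, so a reference row is high only on its
    own characteristic sets; rank-based scoring cannot distinguish mild
    from strong depletion, and a joint prototype panel would therefore
    score every *other* subtype's sets as maximal bottom-of-list
    excursions, collapsing the rows onto each other.

    With ``digitize`` (the default) each row is rescaled to span [-1, 1]
    and rounded to the nearest half unit — the five levels a heatmap
    color code distinguishes.  Reference subtype matrices in this field
    are typically digitized by eye from published figures, and the
    quantization error that introduces is part of the operating
    conditions the pipeline faces; without it, classification against
    the references is unrealistically clean.  The rows carry the
    bad/good prognosis designation of their subtypes.
    """
    if params.effect_size <= 0:
        raise ValueError(
            "effect_size = 0 gives a constant (degenerate) prototype signature; "
            "references are undefined"
        )
    sets, _cmap, cancer_base, normal_base, _normal_profile, effect = _model_components(params)
    genes = [f"g{i:04d}" for i in range(params.n_genes)]
    rows = {}
    for sub in SUBTYPES:
        panel = ExpressionMatrix(
            pd.DataFrame(
                {"prototype": cancer_base + effect[sub], "normal": normal_base},
                index=genes,
            )
        )
        raw = compute_raw_scores(
            panel, sets, weights_variant=weights_variant, statistic=statistic
        )
        sig = normalize_signatures(raw, mode="per_sample")
        row = sig["prototype"]
        if digitize:
            row = 2.0 * (row - row.min()) / (row.max() - row.min()) - 1.0
            row = (row * 2.0).round() / 2.0  # heatmap color-code levels
        rows[sub] = row
    df = pd.DataFrame(rows).T
    return ReferenceSubtypes(df, prognosis=dict(PROGNOSIS))
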