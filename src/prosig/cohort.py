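"""Cohort-level signature structure: group correlations and clustering.

Signature similarity between samples is measured with Pearson
correlation of their gene-set signature vectors.  Pairs of samples are
split into "within" and "between" sets under a chosen grouping (same
patient vs different patients, same Gleason score vs different, ...) and
the two sets compared with a rank-sum test.  Samples are also clustered
hierarchically on correlation distance (1 - r), and a permutation
statistic asks how often a sample sits next to a same-patient sample in
the dendrogram leaf order, versus chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import SampleMetadata

__all__ = [
    "GroupCorrelationReport",
    "ClusteringResult",
    "pairwise_signature_correlations",
    "within_between_split",
    "compare_groups",
    "cluster_signatures",
    "neighbor_same_patient_stat",
]

GROUPINGS = ("patient", "gleason", "sample_type", "normal_vs_cancer_patient")


def pairwise_signature_correlations(signatures: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Pearson correlation matrix of signature columns."""
    if signatures.shape[1] < 2:
        raise ValueError("need at least two samples")
    arr = signatures.to_numpy(dtype=float)
    spans = np.ptp(arr, axis=0)
    if np.any(spans == 0.0):
        bad = signatures.columns[int(np.argmax(spans == 0.0))]
        raise ValueError(f"sample {bad!r} has a constant signature")
    corr = np.corrcoef(arr.T)
    return pd.DataFrame(corr, index=signatures.columns, columns=signatures.columns)


@dataclass
class GroupCorrelationReport:
    grouping: str
    within_values: list[float]
    between_values: list[float]
    p: float

    @property
    def within_median(self) -> float:
        return float(np.median(self.within_values))

    @property
    def between_median(self) -> float:
        return float(np.median(self.between_values))


def _pairs(ids: list[str]):
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            yield ids[i], ids[j]


def within_between_split(
    corr: pd.DataFrame,
    metadata: dict[str, SampleMetadata],
    grouping: str,
) -> GroupCorrelationReport:
    """Split pairwise correlations into within- and between-group sets.

    Groupings:

    * ``patient`` — cancer samples only; within = same patient.
    * ``gleason`` — cancer samples only; within = same Gleason score.
    * ``sample_type`` — all samples; within = same type (cancer-cancer
      or normal-normal), between = cancer-normal pairs.
    * ``normal_vs_cancer_patient`` — normal-cancer pairs only; within =
      the two samples come from the same patient.

    Every eligible unordered pair lands in exactly one of the two sets.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; choose from {GROUPINGS}")
    ids = [s for s in corr.index if s in metadata]
    if len(ids) != len(corr.index):
        missing = [s for s in corr.index if s not in metadata]
        raise ValueError(f"samples without metadata: {missing}")

    within, between = [], []
    if grouping == "normal_vs_cancer_patient":
        normals = [s for s in ids if metadata[s].sample_type == "normal"]
        cancers = [s for s in ids if metadata[s].sample_type == "cancer"]
        for a in normals:
            for b in cancers:
                r = float(corr.loc[a, b])
                (within if metadata[a].patient_id == metadata[b].patient_id else between).append(r)
    else:
        if grouping in ("patient", "gleason"):
            ids = [s for s in ids if metadata[s].sample_type == "cancer"]
        if grouping == "gleason":
            missing = [s for s in ids if metadata[s].gleason is None]
            if missing:
                raise ValueError(f"cancer samples without Gleason score: {missing}")
        key = {
            "patient": lambda m: m.patient_id,
            "gleason": lambda m: m.gleason,
            "sample_type": lambda m: m.sample_type,
        }[grouping]
        for a, b in _pairs(ids):
            r = float(corr.loc[a, b])
            (within if key(metadata[a]) == key(metadata[b]) else between).append(r)

    if not within or not between:
        raise ValueError(
            f"grouping {grouping!r}: within ({len(within)}) and between "
            f"({len(between)}) pair sets must both be non-empty"
        )
    return GroupCorrelationReport(
        grouping=grouping,
        within_values=within,
        between_values=between,
        p=compare_groups(within, between),
    )


def compare_groups(within_values, between_values) -> float:
    """Two-sided Mann-Whitney rank-sum p-value comparing the two sets.

    Correlations are bounded and generally non-normal, so a rank-based
    comparison is the safe default.
    """
    if len(within_values) == 0 or len(between_values) == 0:
        raise ValueError("both groups must be non-empty")
    return float(
        stats.mannwhitneyu(within_values, between_values, alternative="two-sided").pvalue
    )


@dataclass
class ClusteringResult:
    """Agglomerative clustering of samples on correlation distance."""

    linkage: np.ndarray  # scipy linkage matrix (merge history with heights)
    leaf_order: list[str]  # sample ids, dendrogram left to right
    linkage_method: str
    sample_ids: list[str]

    def ordered(self, signatures: pd.DataFrame) -> pd.DataFrame:
        """Reorder signature columns by leaf order (for heatmap export)."""
        return signatures[self.leaf_order]


def cluster_signatures(
    signatures: pd.DataFrame, linkage_method: str = "single"
) -> ClusteringResult:
    """Hierarchically cluster samples using correlation distance 1 - r.

    The default linkage is single (the default of scipy's hierarchical
    clustering); average/complete/ward are accepted.  The leaf order is
    recorded for ordering exported matrices so similar samples sit next
    to each other.
    """
    corr = pairwise_signature_correlations(signatures)
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # exact symmetry for squareform
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    leaves = hierarchy.leaves_list(Z)
    ids = list(signatures.columns)
    return ClusteringResult(
        linkage=Z,
        leaf_order=[ids[i] for i in leaves],
        linkage_method=linkage_method,
        sample_ids=ids,
    )


def _count_same_label_neighbors(labels: np.ndarray) -> int:
    """#positions whose immediate left or right neighbor shares the label."""
    n = labels.size
    hit = np.zeros(n, dtype=bool)
    same = labels[:-1] == labels[1:]
    hit[:-1] |= same
    hit[1:] |= same
    return int(hit.sum())


def neighbor_same_patient_stat(
    leaf_order: list[str],
    patient_labels: dict[str, str],
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> tuple[int, float, float]:
    """How many samples sit next to a same-patient sample in leaf order?

    Adjacency means immediate left/right neighbour only.  Returns
    (observed count, chance expectation under uniform random ordering of
    the same labels, add-one-smoothed upper-tail permutation p-value).
    """
    if len(leaf_order) < 2:
        raise ValueError("need at least two leaves")
    missing = [s for s in leaf_order if s not in patient_labels]
    if missing:
        raise ValueError(f"leaves without a patient label: {missing}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray([patient_labels[s] for s in leaf_order], dtype=object)
    observed = _count_same_label_neighbors(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        counts[b] = _count_same_label_neighbors(rng.permutation(labels))
    expected = float(counts.mean())
    p = float((1 + int((counts >= observed).sum())) / (n_perm + 1))
    return observed, expected, p
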