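"""Per-sample gene-set enrichment scoring.

For each sample, genes are mean-centered across samples, the sample's
centered values are sorted in descending order, and a running-sum
(Kolmogorov–Smirnov style) walk is taken down the ranked list for every
gene set: the sum is incremented by ``d_in`` when the next gene belongs
to the set and by ``d_out`` otherwise.  The positive score is the walk's
maximum, the negative score its minimum, and the total score their
difference — one total per gene set per sample.  Related sets are then
averaged into a reduced signature (21 -> 15 in the motivating study) and
the reduced scores normalised to a per-sample [0, 1] scale.

Two increment variants are provided.  The default ``zero_sum_ks`` uses

    d_in = sqrt((N - S) / S),   d_out = -sqrt(S / (N - S)),

which telescopes to exactly zero at the end of the list, so the max/min
scores measure genuine excursions.  The ``literal`` variant uses
(N - S)/S and -S/(N - S); its walk terminates at N - 2S, which inflates
small sets, and it is retained behind a flag for comparison only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "WalkWeights",
    "WalkScores",
    "gsea_walk",
    "compute_raw_scores",
    "reduce_related_sets",
    "normalize_signatures",
]

NORMALIZATION_MODES = ("per_sample", "per_set", "random_set_pvalue")


@dataclass(frozen=True)
class WalkWeights:
    """Running-sum increments for a set of size S in a list of N genes."""

    variant: str  # "zero_sum_ks" | "literal"
    N: int
    S: int

    def __post_init__(self) -> None:
        if self.variant not in ("zero_sum_ks", "literal"):
            raise ValueError(f"unknown weight variant {self.variant!r}")
        if not 1 <= self.S < self.N:
            raise ValueError(
                f"set size S={self.S} must satisfy 1 <= S < N={self.N}; "
                f"walk increments are undefined otherwise"
            )

    @property
    def d_in(self) -> float:
        N, S = self.N, self.S
        if self.variant == "zero_sum_ks":
            return float(np.sqrt((N - S) / S))
        return (N - S) / S

    @property
    def d_out(self) -> float:
        N, S = self.N, self.S
        if self.variant == "zero_sum_ks":
            return -float(np.sqrt(S / (N - S)))
        return -S / (N - S)


@dataclass(frozen=True)
class WalkScores:
    """Positive (max), negative (min) and total running-sum scores."""

    positive: float
    negative: float

    @property
    def total(self) -> float:
        """Score+ - Score-: direction-blind excursion size.

        A strongly depleted set scores as high as a strongly enriched
        one under this statistic.
        """
        return self.positive - self.negative

    @property
    def signed(self) -> float:
        """The larger excursion, with its sign.

        Score+ if the upward excursion dominates, Score- otherwise, so
        enriched sets score positive and depleted sets negative.  This
        direction-sensitive statistic is what lets a depleted pathway
        appear as a *low* signature value downstream.
        """
        return self.positive if self.positive >= -self.negative else self.negative


def gsea_walk(membership: Sequence[bool] | np.ndarray, weights: WalkWeights) -> WalkScores:
    """Score one gene set on one ranked gene list.

    ``membership[k]`` says whether the gene at rank k (0-based, best
    first) belongs to the set.  Returns the maximum and minimum of the
    partial sums over k = 1..N.
    """
    m = np.asarray(membership, dtype=bool)
    if m.ndim != 1 or m.size < 2:
        raise ValueError("membership must be a 1-D vector of length >= 2")
    S = int(m.sum())
    if m.size != weights.N or S != weights.S:
        raise ValueError(
            f"membership (N={m.size}, S={S}) inconsistent with weights "
            f"(N={weights.N}, S={weights.S})"
        )
    steps = np.where(m, weights.d_in, weights.d_out)
    sums = np.cumsum(steps)
    return WalkScores(positive=float(sums.max()), negative=float(sums.min()))


def _membership_matrix(gene_ids: Sequence[str], sets: GeneSetCollection) -> np.ndarray:
    idx = {g: i for i, g in enumerate(gene_ids)}
    M = np.zeros((len(sets), len(gene_ids)), dtype=bool)
    for si, s in enumerate(sets):
        for g in s.genes:
            M[si, idx[g]] = True
    return M


def _walk_scores_for_ranking(
    order: np.ndarray, M: np.ndarray, d_in: np.ndarray, d_out: np.ndarray, statistic: str
) -> np.ndarray:
    """Walk score of every set for one sample's gene ranking."""
    ranked = M[:, order]  # sets x genes, in rank order
    steps = np.where(ranked, d_in[:, None], d_out[:, None])
    sums = np.cumsum(steps, axis=1)
    hi, lo = sums.max(axis=1), sums.min(axis=1)
    if statistic == "total":
        return hi - lo
    if statistic == "signed":
        return np.where(hi >= -lo, hi, lo)
    raise ValueError(f"unknown score statistic {statistic!r}")


def compute_raw_scores(
    X: ExpressionMatrix,
    sets: GeneSetCollection,
    weights_variant: str = "zero_sum_ks",
    statistic: str = "total",
) -> pd.DataFrame:
    """Walk scores for every gene set in every sample.

    Each gene is first mean-centered across all samples; each sample's
    centered values are then ranked in descending order (ties broken by
    input gene order, so results are deterministic across platforms) and
    every set is scored by :func:`gsea_walk`.

    ``statistic`` selects what is stored per set and sample: ``"total"``
    is Score+ - Score- (direction-blind); ``"signed"`` reports the
    dominant excursion with its sign, so depletion shows up as a low
    (negative) raw score.

    Returns a sets x samples DataFrame.
    """
    if len(sets) == 0:
        raise ValueError("empty gene-set collection")
    sets = sets.intersect(X.gene_ids)
    N = X.n_genes
    weights = [WalkWeights(weights_variant, N, s.size) for s in sets]
    d_in = np.array([w.d_in for w in weights])
    d_out = np.array([w.d_out for w in weights])
    M = _membership_matrix(X.gene_ids, sets)

    vals = X.values
    centered = vals - vals.mean(axis=1, keepdims=True)
    out = np.empty((len(sets), vals.shape[1]))
    for j in range(vals.shape[1]):
        order = np.argsort(-centered[:, j], kind="stable")
        out[:, j] = _walk_scores_for_ranking(order, M, d_in, d_out, statistic)
    return pd.DataFrame(out, index=sets.names, columns=X.sample_ids)


def reduce_related_sets(
    raw: pd.DataFrame, mapping: Mapping[str, Sequence[str]] | None
) -> pd.DataFrame:
    """Average scores of related gene sets into reduced signature rows.

    ``mapping`` maps each output name to the group of raw set names it
    averages; raw sets not mentioned pass through unchanged after the
    mapped groups, in their original order.  ``None`` is the identity.
    """
    if mapping is None:
        return raw.copy()
    used: set[str] = set()
    rows = {}
    for out_name, group in mapping.items():
        unknown = [g for g in group if g not in raw.index]
        if unknown:
            raise ValueError(f"group {out_name!r} references unknown set(s): {unknown}")
        dup = used.intersection(group)
        if dup:
            raise ValueError(f"set(s) {sorted(dup)} appear in more than one group")
        used.update(group)
        rows[out_name] = raw.loc[list(group)].mean(axis=0)
    for name in raw.index:
        if name not in used:
            if name in rows:
                raise ValueError(f"pass-through set {name!r} collides with a group name")
            rows[name] = raw.loc[name]
    return pd.DataFrame(rows).T[raw.columns]


def _minmax(arr: np.ndarray, axis: int) -> np.ndarray:
    lo = arr.min(axis=axis, keepdims=True)
    hi = arr.max(axis=axis, keepdims=True)
    span = hi - lo
    degenerate = span == 0
    if degenerate.any():
        warnings.warn(
            "constant score vector(s) during min-max normalization; set to 0.5",
            stacklevel=3,
        )
    span = np.where(degenerate, 1.0, span)
    out = (arr - lo) / span
    return np.where(np.broadcast_to(degenerate, out.shape), 0.5, out)


def normalize_signatures(
    raw: pd.DataFrame,
    mode: str = "per_sample",
    *,
    expression: ExpressionMatrix | None = None,
    sets: GeneSetCollection | None = None,
    weights_variant: str = "zero_sum_ks",
    statistic: str = "total",
    n_random_sets: int = 99,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Normalise raw total scores into comparable sample signatures.

    Three strategies: ``per_sample`` min-max rescales each sample's score
    vector to [0, 1] (the default — it best matches a clinical setting
    where a fixed gene-set panel is applied to new patients one at a
    time); ``per_set`` rescales each set's scores across samples; and
    ``random_set_pvalue`` replaces each score with an empirical p-value
    against ``n_random_sets`` size-matched random gene sets drawn without
    replacement from the scored genes (add-one smoothing, so p is always
    in (0, 1]).  A constant vector cannot be min-max scaled; it maps to
    0.5 with a warning so one degenerate sample cannot abort a cohort run.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    arr = raw.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("raw score matrix contains non-finite values")
    if mode == "per_sample":
        return pd.DataFrame(_minmax(arr, axis=0), index=raw.index, columns=raw.columns)
    if mode == "per_set":
        return pd.DataFrame(_minmax(arr, axis=1), index=raw.index, columns=raw.columns)

    if expression is None or sets is None:
        raise ValueError("random_set_pvalue mode needs the expression matrix and gene sets")
    sets = sets.intersect(expression.gene_ids)
    if list(raw.index) != sets.names:
        raise ValueError("raw score rows must match the gene-set collection for p-value mode")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    N = expression.n_genes
    sizes = sorted({s.size for s in sets})
    # one shared pool of random memberships per distinct set size
    null_members = {
        size: np.stack(
            [
                np.isin(
                    np.arange(N), gen.choice(N, size=size, replace=False)
                )
                for _ in range(n_random_sets)
            ]
        )
        for size in sizes
    }
    vals = expression.values
    centered = vals - vals.mean(axis=1, keepdims=True)
    out = np.empty_like(arr)
    size_by_row = np.array([s.size for s in sets])
    for j in range(arr.shape[1]):
        order = np.argsort(-centered[:, j], kind="stable")
        null_totals = {}
        for size in sizes:
            w = WalkWeights(weights_variant, N, size)
            null_totals[size] = _walk_scores_for_ranking(
                order, null_members[size], np.full(n_random_sets, w.d_in),
                np.full(n_random_sets, w.d_out), statistic,
            )
        for i in range(arr.shape[0]):
            null = null_totals[size_by_row[i]]
            out[i, j] = (1.0 + np.sum(null >= arr[i, j])) / (n_random_sets + 1.0)
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)
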