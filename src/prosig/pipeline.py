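"""End-to-end conveniences tying the pipeline stages together."""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assignment import AssignmentResult, assign_exclusive, assign_prognosis
from .io import ExpressionMatrix, GeneSetCollection, ReferenceSubtypes
from .references import ConstantSignatureError, correlate_cohort
from .scoring import compute_raw_scores, normalize_signatures, reduce_related_sets

__all__ = ["score_cohort", "assign_cohort"]


def score_cohort(
    X: ExpressionMatrix,
    sets: GeneSetCollection,
    mapping: Mapping[str, Sequence[str]] | None = None,
    mode: str = "per_sample",
    weights_variant: str = "zero_sum_ks",
    statistic: str = "signed",
    rng: np.random.Generator | int | None = None,
    n_random_sets: int = 99,
) -> pd.DataFrame:
    """Expression matrix -> normalised sample-signature matrix.

    Runs raw gene-set scoring, optional related-set averaging, and
    normalisation; returns reduced gene sets x samples.

    The default score ``statistic`` is the direction-sensitive
    ``"signed"`` excursion: an enriched pathway scores high and a
    depleted one low, which is the behaviour signature heatmaps of
    tumor cohorts display (depleted repressive-complex targets appear
    as low values).  The direction-blind ``"total"`` (Score+ - Score-)
    is available for comparison.
    """
    raw = compute_raw_scores(X, sets, weights_variant=weights_variant, statistic=statistic)
    reduced = reduce_related_sets(raw, mapping)
    return normalize_signatures(
        reduced,
        mode=mode,
        expression=X,
        sets=sets if mapping is None else None,
        weights_variant=weights_variant,
        statistic=statistic,
        rng=rng,
        n_random_sets=n_random_sets,
    )


def assign_cohort(
    signatures: pd.DataFrame,
    refs: ReferenceSubtypes,
    alphas: Sequence[float] = (0.05, 0.15, 0.25, 0.5),
    mode: str = "prognosis",
    sided: str = "one",
) -> dict[float, list[AssignmentResult]]:
    """Assign every sample at every threshold.

    Samples whose correlations are undefined (constant signature) or
    degenerate (|r| = 1) are reported unassigned with a warning rather
    than aborting the cohort.
    """
    if mode not in ("exclusive", "prognosis"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    bad, good = refs.bad_subtypes(), refs.good_subtypes()
    if mode == "prognosis" and (len(bad) != 2 or len(good) != 2):
        raise ValueError(
            "prognosis mode needs a reference matrix with two bad- and two "
            "good-prognosis subtypes designated"
        )
    out: dict[float, list[AssignmentResult]] = {a: [] for a in alphas}
    corrs = {}
    for sid in signatures.columns:
        try:
            corrs[sid] = correlate_cohort(signatures[[sid]], refs)[0]
        except (ConstantSignatureError, ValueError) as exc:
            warnings.warn(f"sample {sid!r} unassignable: {exc}", stacklevel=2)
            corrs[sid] = None
    for alpha in alphas:
        for sid in signatures.columns:
            c = corrs[sid]
            if c is None:
                out[alpha].append(AssignmentResult(sid, mode, "unassigned", alpha, {}))
                continue
            try:
                if mode == "exclusive":
                    out[alpha].append(assign_exclusive(c, alpha, sided=sided))
                else:
                    out[alpha].append(assign_prognosis(c, alpha, bad, good, sided=sided))
            except ValueError as exc:
                warnings.warn(f"sample {sid!r} unassignable: {exc}", stacklevel=2)
                out[alpha].append(AssignmentResult(sid, mode, "unassigned", alpha, {}))
    return out
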