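"""Pearson correlation of sample signatures to reference subtype profiles."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ReferenceSubtypes

__all__ = ["SubtypeCorrelations", "correlate_to_references", "correlate_cohort"]

MIN_GENESETS = 4  # the dependent-correlations test needs n >= 4


class ConstantSignatureError(ValueError):
    """Signature has zero variance: Pearson correlation is undefined."""


@dataclass
class SubtypeCorrelations:
    """One sample's correlations to every reference subtype.

    ``n`` is the number of gene sets the correlations were computed over
    (after dropping sets undefined in the sample); it is the sample size
    of the dependent-correlations test downstream.
    ``inter_reference`` is the subtype x subtype correlation matrix of
    the reference rows themselves (r_kh in the test), which depends only
    on the references and is shared across samples.
    """

    sample_id: str
    r_by_subtype: pd.Series
    inter_reference: pd.DataFrame
    n: int


def inter_reference_correlations(refs: ReferenceSubtypes) -> pd.DataFrame:
    """Subtype x subtype Pearson correlation matrix of the reference rows."""
    return refs.data.T.corr(method="pearson")


def correlate_to_references(
    signature: pd.Series,
    refs: ReferenceSubtypes,
    sample_id: str = "",
    *,
    _inter: pd.DataFrame | None = None,
) -> SubtypeCorrelations:
    """Correlate one sample signature against every reference subtype.

    The signature must be indexed by the same gene-set names as the
    reference columns.  Gene sets with undefined (NaN) values in the
    sample are dropped with a warning and n adjusted; below n = 4 the
    sample cannot be tested and an error is raised.  A constant
    signature raises :class:`ConstantSignatureError` (the sample is
    reported unassignable rather than silently given r = 0).
    """
    if set(signature.index) != set(refs.geneset_names):
        raise ValueError("signature gene sets do not match reference gene sets")
    sig = signature.reindex(refs.geneset_names)
    keep = sig.notna()
    if not keep.all():
        warnings.warn(
            f"sample {sample_id!r}: {int((~keep).sum())} gene set(s) undefined; "
            f"correlating on the remaining {int(keep.sum())}",
            stacklevel=2,
        )
    n = int(keep.sum())
    if n < MIN_GENESETS:
        raise ValueError(
            f"sample {sample_id!r}: only {n} usable gene sets; need >= {MIN_GENESETS}"
        )
    x = sig[keep].to_numpy(dtype=float)
    if np.ptp(x) == 0.0:
        raise ConstantSignatureError(
            f"sample {sample_id!r} has a constant signature; correlation undefined"
        )
    R = refs.data.loc[:, keep[keep].index].to_numpy(dtype=float)
    xc = x - x.mean()
    Rc = R - R.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum()) * np.sqrt((Rc ** 2).sum(axis=1))
    if np.any(denom == 0.0):
        raise ConstantSignatureError(
            f"a reference row is constant on the usable gene sets of {sample_id!r}"
        )
    r = (Rc @ xc) / denom
    inter = _inter if _inter is not None else inter_reference_correlations(refs)
    return SubtypeCorrelations(
        sample_id=sample_id,
        r_by_subtype=pd.Series(r, index=refs.subtype_names),
        inter_reference=inter,
        n=n,
    )


def correlate_cohort(
    signatures: pd.DataFrame, refs: ReferenceSubtypes
) -> list[SubtypeCorrelations]:
    """Correlate every sample (column) of a signature matrix to the references.

    The inter-reference correlation matrix is computed once and shared.
    """
    inter = inter_reference_correlations(refs)
    return [
        correlate_to_references(signatures[s], refs, sample_id=s, _inter=inter)
        for s in signatures.columns
    ]
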