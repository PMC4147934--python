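"""Normal-tissue component subtraction in signature space.

Prostate cancer tissue samples are mixtures of cancer and benign
(stromal/epithelial) tissue.  To emphasise the cancer component, the
average signature of the pure-normal samples (SE_AVG) is subtracted from
each cancer sample's signature PR in proportion to the sample's
histopathological fraction of normal tissue ``frac``:

    PR_corrected = PR - SE_AVG * frac / (1 - frac)

``frac`` is the fraction of NORMAL tissue: a sample that is 90% cancer
has frac = 0.1.  The subtraction factor frac/(1-frac) grows without
bound as frac -> 1; frac is capped at 0.95 (the strongest factor used in
practice is 9, at frac = 0.9).  The correction operates on normalised
signatures and the corrected values may leave [0, 1]; they are NOT
renormalised, which would distort inter-sample comparability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SampleMetadata

__all__ = [
    "NormalReferenceSignature",
    "CorrectedSignature",
    "average_normal_signature",
    "subtract_normal_component",
    "correct_cohort",
]

FRAC_MAX = 0.95


@dataclass
class NormalReferenceSignature:
    """Element-wise mean signature of the pure-normal samples (SE_AVG)."""

    values: pd.Series
    n_normals: int

    def __post_init__(self) -> None:
        if self.n_normals < 1:
            raise ValueError("need at least one normal sample")


@dataclass
class CorrectedSignature:
    sample_id: str
    frac: float
    original: pd.Series
    values: pd.Series


def average_normal_signature(normal_signatures: pd.DataFrame) -> NormalReferenceSignature:
    """Average the normal samples' signatures (gene sets x samples)."""
    if normal_signatures.shape[1] < 1:
        raise ValueError("need at least one normal sample to build SE_AVG")
    if normal_signatures.isna().any().any():
        raise ValueError("normal signatures contain undefined values")
    return NormalReferenceSignature(
        values=normal_signatures.mean(axis=1),
        n_normals=normal_signatures.shape[1],
    )


def subtract_normal_component(
    signature: pd.Series,
    normal_ref: NormalReferenceSignature,
    frac: float,
    sample_id: str = "",
) -> CorrectedSignature:
    """Subtract the scaled average normal signature from one sample."""
    if not 0.0 <= frac <= FRAC_MAX:
        raise ValueError(
            f"frac = {frac} outside [0, {FRAC_MAX}]; the subtraction factor "
            f"frac/(1-frac) is unbounded near 1"
        )
    if not signature.index.equals(normal_ref.values.index):
        raise ValueError("signature and normal reference have different gene sets")
    factor = frac / (1.0 - frac)
    corrected = signature - normal_ref.values * factor
    return CorrectedSignature(
        sample_id=sample_id, frac=frac, original=signature, values=corrected
    )


def correct_cohort(
    signatures: pd.DataFrame,
    metadata: dict[str, SampleMetadata],
    include_normals: bool = False,
    normal_frac: float = 0.9,
) -> pd.DataFrame:
    """Composition-correct a whole cohort of signatures.

    SE_AVG is built from the normal samples only; each cancer sample is
    corrected with its own histopathological frac.  With
    ``include_normals`` the normal samples are themselves corrected at
    ``normal_frac`` (default 0.9, the strongest factor otherwise in
    use) — a diagnostic for whether the subtraction manufactures cancer
    signal where there is none.  Normal samples are otherwise passed
    through unchanged.
    """
    missing_meta = [s for s in signatures.columns if s not in metadata]
    if missing_meta:
        raise ValueError(f"samples without metadata: {missing_meta}")
    normal_ids = [s for s in signatures.columns if metadata[s].sample_type == "normal"]
    cancer_ids = [s for s in signatures.columns if metadata[s].sample_type == "cancer"]
    if not normal_ids:
        raise ValueError("no normal samples: cannot build the average normal signature")
    missing_frac = [
        s for s in cancer_ids if metadata[s].frac_normal is None or np.isnan(metadata[s].frac_normal)
    ]
    if missing_frac:
        raise ValueError(f"cancer samples without frac_normal: {missing_frac}")

    se_avg = average_normal_signature(signatures[normal_ids])
    out = signatures.copy()
    for s in cancer_ids:
        out[s] = subtract_normal_component(
            signatures[s], se_avg, metadata[s].frac_normal, sample_id=s
        ).values
    if include_normals:
        for s in normal_ids:
            out[s] = subtract_normal_component(
                signatures[s], se_avg, normal_frac, sample_id=s
            ).values
    return out
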