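"""Domain types and TSV/GMT readers and writers.

The pipeline works on four kinds of input: a genes x samples expression
matrix (tab-separated, log-scale values), gene-set collections in GMT
format, per-sample metadata (patient, cancer/normal, Gleason score,
histopathological fraction of normal tissue), and a reference subtype
matrix (subtypes x gene sets, values in [-1, 1]).

Gene identifiers are matched as exact, case-sensitive strings; symbol
aliasing is a user preprocessing step, never done here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "SampleMetadata",
    "ReferenceSubtypes",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_reference_matrix",
    "write_reference_matrix",
    "validate_cohort",
]


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with unique identifiers.

    Values are expression units on whatever scale the upstream
    normalisation produced (log scale assumed but not enforced).
    """

    data: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        if df.shape[0] < 2 or df.shape[1] < 1:
            raise ValueError(
                f"expression matrix needs >= 2 genes and >= 1 sample, got {df.shape}"
            )
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if not np.all(np.isfinite(arr)):
            gi, sj = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene {df.index[gi]!r}, "
                f"sample {df.columns[sj]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]


@dataclass
class GeneSet:
    """A named set of gene identifiers (size S after intersection)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        self.genes = frozenset(self.genes)

    @property
    def size(self) -> int:
        return len(self.genes)

    def intersect(self, gene_ids) -> "GeneSet":
        """Restrict to genes present in an expression matrix."""
        kept = self.genes & set(gene_ids)
        if not kept:
            raise ValueError(f"gene set {self.name!r} has no genes in the matrix")
        return GeneSet(self.name, frozenset(kept))


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        _check_unique([s.name for s in self.sets], "gene-set")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def intersect(self, gene_ids, min_size: int = 5) -> "GeneSetCollection":
        """Intersect every set with the matrix genes.

        Sets retaining fewer than `min_size` genes trigger a warning
        (scores from very small sets lack robustness); sets retaining no
        genes are dropped with an error-level log message.
        """
        gene_ids = set(gene_ids)
        kept: list[GeneSet] = []
        for s in self.sets:
            inter = s.genes & gene_ids
            if not inter:
                logger.error("gene set %r has no genes in the matrix; dropped", s.name)
                continue
            if len(inter) < min_size:
                warnings.warn(
                    f"gene set {s.name!r} retains only {len(inter)} gene(s) "
                    f"after intersection; its scores may lack robustness",
                    stacklevel=2,
                )
            kept.append(GeneSet(s.name, frozenset(inter)))
        if not kept:
            raise ValueError("no gene set retains any gene after intersection")
        return GeneSetCollection(kept)


@dataclass
class SampleMetadata:
    """Histopathology-derived annotation for one sample.

    frac_normal is the fraction of NORMAL (benign stromal/epithelial)
    tissue in the sample, in [0, 1]. Pure normal samples have
    frac_normal = 1 by convention. Gleason score may be absent only for
    normal samples.
    """

    sample_id: str
    patient_id: str
    sample_type: str  # "cancer" | "normal"
    gleason: int | None = None
    frac_normal: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_type not in ("cancer", "normal"):
            raise ValueError(
                f"sample {self.sample_id!r}: sample_type must be 'cancer' or "
                f"'normal', got {self.sample_type!r}"
            )
        if not 0.0 <= self.frac_normal <= 1.0:
            raise ValueError(
                f"sample {self.sample_id!r}: frac_normal {self.frac_normal} "
                f"outside [0, 1]"
            )
        if self.gleason is None and self.sample_type == "cancer":
            warnings.warn(
                f"cancer sample {self.sample_id!r} has no Gleason score",
                stacklevel=2,
            )


@dataclass
class ReferenceSubtypes:
    """Subtype x gene-set matrix of reference signature values in [-1, 1].

    Rows are molecular subtypes (in this problem domain: two bad-prognosis
    subtypes, BP-E/P/Pr and BP-ERG, and two good-prognosis subtypes, GP1
    and GP2); columns are the reduced gene sets. ``prognosis`` optionally
    maps each subtype name to "bad" or "good" for the combined-category
    assignment mode.
    """

    data: pd.DataFrame  # index = subtype names, columns = gene-set names
    prognosis: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "subtype")
        _check_unique(df.columns, "gene-set")
        arr = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("reference matrix contains non-finite values")
        if arr.min() < -1.0 or arr.max() > 1.0:
            bad = np.argwhere((arr < -1.0) | (arr > 1.0))[0]
            raise ValueError(
                f"reference value {arr[bad[0], bad[1]]} outside [-1, 1] at "
                f"subtype {df.index[bad[0]]!r}, set {df.columns[bad[1]]!r}"
            )
        for name, row in zip(df.index, arr):
            if np.ptp(row) == 0.0:
                raise ValueError(
                    f"reference subtype {name!r} is constant; correlation undefined"
                )
        for k, v in self.prognosis.items():
            if k not in df.index:
                raise ValueError(f"prognosis label for unknown subtype {k!r}")
            if v not in ("bad", "good"):
                raise ValueError(f"prognosis must be 'bad' or 'good', got {v!r}")

    @property
    def subtype_names(self) -> list[str]:
        return list(self.data.index)

    @property
    def geneset_names(self) -> list[str]:
        return list(self.data.columns)

    def bad_subtypes(self) -> list[str]:
        return [s for s in self.subtype_names if self.prognosis.get(s) == "bad"]

    def good_subtypes(self) -> list[str]:
        return [s for s in self.subtype_names if self.prognosis.get(s) == "good"]


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str), dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & ~df[col].isna()
        if bad.any() or df[col].isna().any():
            i = int(np.argmax((converted.isna()).to_numpy()))
            raise ValueError(
                f"{path}: non-numeric cell at row {df.index[i]!r}, column {col!r}"
            )
        out[col] = converted.to_numpy(dtype=float)
    return out


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first row sample ids, first column gene ids)."""
    return ExpressionMatrix(_read_tsv_matrix(path))


def write_expression_matrix(X: ExpressionMatrix, path) -> None:
    X.data.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_sets_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>gene...``.

    Within-set duplicate genes are removed with a warning; a duplicate set
    name or a line with no genes is an error.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT line has no genes")
            name, genes = fields[0], [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{ln}: gene set {name!r} has no genes")
            uniq = list(dict.fromkeys(genes))
            if len(uniq) < len(genes):
                warnings.warn(
                    f"{path}:{ln}: gene set {name!r} lists duplicate genes; "
                    f"kept {len(uniq)} unique",
                    stacklevel=2,
                )
            sets.append(GeneSet(name, frozenset(uniq)))
    return GeneSetCollection(sets)


def write_gene_sets_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, "na", *sorted(s.genes)]) + "\n")


_META_COLS = ["sample_id", "patient_id", "sample_type", "gleason", "frac_normal"]


def read_sample_metadata(path) -> list[SampleMetadata]:
    """Read per-sample metadata TSV.

    Accepts either a ``frac_normal`` column (fraction of normal tissue) or
    a ``percent_cancer`` column, which is converted explicitly via
    frac_normal = 1 - percent_cancer/100. The two conventions are easy to
    confuse and silently swapping them inverts the composition correction,
    so only these two exact column names are accepted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = set(df.columns)
    if "percent_cancer" in cols and "frac_normal" not in cols:
        df["frac_normal"] = 1.0 - pd.to_numeric(df["percent_cancer"]) / 100.0
    missing = set(_META_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        gleason = row["gleason"]
        gleason = None if pd.isna(gleason) or str(gleason).strip() == "" else int(float(gleason))
        records.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                patient_id=str(row["patient_id"]),
                sample_type=str(row["sample_type"]),
                gleason=gleason,
                frac_normal=float(row["frac_normal"]),
            )
        )
    _check_unique([r.sample_id for r in records], "sample")
    return records


def write_sample_metadata(records: list[SampleMetadata], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "patient_id": r.patient_id,
                "sample_type": r.sample_type,
                "gleason": "" if r.gleason is None else r.gleason,
                "frac_normal": r.frac_normal,
            }
            for r in records
        ],
        columns=_META_COLS,
    ).to_csv(path, sep="\t", index=False)


def read_reference_matrix(path, prognosis: dict[str, str] | None = None) -> ReferenceSubtypes:
    """Read a subtypes x gene-sets reference TSV (values in [-1, 1])."""
    return ReferenceSubtypes(_read_tsv_matrix(path), prognosis=prognosis or {})


def write_reference_matrix(refs: ReferenceSubtypes, path) -> None:
    refs.data.to_csv(path, sep="\t", index_label="subtype")


def validate_cohort(X: ExpressionMatrix, metadata: list[SampleMetadata]) -> dict[str, SampleMetadata]:
    """Check that every sample in the matrix has exactly one metadata record.

    Returns a sample_id -> record mapping. Samples missing a record, or
    records duplicated, raise rather than being silently ignored.
    """
    by_id: dict[str, SampleMetadata] = {}
    for r in metadata:
        if r.sample_id in by_id:
            raise ValueError(f"duplicate metadata record for sample {r.sample_id!r}")
        by_id[r.sample_id] = r
    missing = [s for s in X.sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    return {s: by_id[s] for s in X.sample_ids}
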