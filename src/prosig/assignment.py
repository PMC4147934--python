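"""Subtype assignment by a test of dependent (overlapping) correlations.

A sample's signature is Pearson-correlated to each reference subtype.
Two correlations that share the sample vector (r_jk and r_jh, against
references k and h) are compared with Steiger's Z test for dependent
correlations, using the averaged-correlation covariance form: with
Fisher transforms z_jk, z_jh, r_bar = (r_jk + r_jh)/2 and the reference
inter-correlation r_kh,

    s = [r_kh (1 - 2 r_bar^2) - 0.5 r_bar^2 (1 - 2 r_bar^2 - r_kh^2)]
        / (1 - r_bar^2)^2
    Z = sqrt(n - 3) (z_jk - z_jh) / sqrt(2 - 2 s)

The default test is one-sided ("is r_jk significantly better than
r_jh?"), which is the only reading under which an alpha of 0.5 is a
coherent threshold; a two-sided option is provided.

Assignment modes:

* exclusive — the sample is called one subtype only if its correlation
  to that subtype beats every other subtype's at the chosen alpha.
* prognosis — subtypes are pooled into bad- and good-prognosis pairs;
  a bad call needs one bad subtype to beat BOTH good subtypes (the two
  bad subtypes need not differ from each other), and symmetrically for
  a good call.  At any alpha <= 0.5 the two calls are mutually
  exclusive.

No multiple-testing correction is applied across samples: thresholds
are per-sample by design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleMetadata
from .references import SubtypeCorrelations

__all__ = [
    "SteigerResult",
    "AssignmentResult",
    "steiger_test",
    "assign_exclusive",
    "assign_prognosis",
    "summarize_assignments",
]


@dataclass(frozen=True)
class SteigerResult:
    """Dependent-correlations comparison of r_jk vs r_jh sharing vector j."""

    r_jk: float
    r_jh: float
    r_kh: float
    n: int
    z_jk: float
    z_jh: float
    r_bar: float
    s: float
    Z: float
    p: float  # one-sided: P(r_jk > r_jh rejected in favour) upper tail
    sided: str = "one"


def steiger_test(
    r_jk: float, r_jh: float, r_kh: float, n: int, sided: str = "one"
) -> SteigerResult:
    """Test whether r_jk is larger than r_jh given their dependence r_kh.

    ``n`` is the number of paired observations the correlations were
    computed over — here the number of gene sets in the signature (15 in
    a full panel), not the number of genes or samples.  One-sided p is
    the upper-tail normal probability of Z; r_jk = r_jh gives Z = 0 and
    p = 0.5 exactly.
    """
    if sided not in ("one", "two"):
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")
    if n < 4:
        raise ValueError(f"dependent-correlations test needs n >= 4, got {n}")
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name} = {r} outside [-1, 1]")
    if abs(r_jk) >= 1.0 or abs(r_jh) >= 1.0:
        raise ValueError("|r| = 1: Fisher transform infinite, test undefined")
    z_jk = math.atanh(r_jk)
    z_jh = math.atanh(r_jh)
    r_bar = 0.5 * (r_jk + r_jh)
    rb2 = r_bar * r_bar
    s = (r_kh * (1.0 - 2.0 * rb2) - 0.5 * rb2 * (1.0 - 2.0 * rb2 - r_kh * r_kh)) / (
        (1.0 - rb2) ** 2
    )
    if s >= 1.0:
        # only reachable for (r_jk, r_jh, r_kh) that no actual trivariate
        # data can produce (non-PSD correlation structure)
        raise ValueError(
            f"correlation triple (r_jk={r_jk}, r_jh={r_jh}, r_kh={r_kh}) is "
            f"infeasible: no joint distribution has this structure"
        )
    Z = math.sqrt(n - 3) * (z_jk - z_jh) / math.sqrt(2.0 - 2.0 * s)
    if sided == "one":
        p = float(stats.norm.sf(Z))
    else:
        p = float(2.0 * stats.norm.sf(abs(Z)))
    return SteigerResult(r_jk, r_jh, r_kh, n, z_jk, z_jh, r_bar, s, Z, p, sided)


@dataclass
class AssignmentResult:
    """A per-sample subtype (or prognosis-category) call at one alpha."""

    sample_id: str
    mode: str  # "exclusive" | "prognosis"
    call: str  # subtype name | "bad" | "good" | "unassigned"
    alpha: float
    supporting_pvalues: dict[str, float] = field(default_factory=dict)

    @property
    def assigned(self) -> bool:
        return self.call != "unassigned"


def _pairwise_p(corrs: SubtypeCorrelations, a: str, b: str, sided: str) -> float:
    """p-value for 'sample correlates better with subtype a than with b'."""
    return steiger_test(
        float(corrs.r_by_subtype[a]),
        float(corrs.r_by_subtype[b]),
        float(corrs.inter_reference.loc[a, b]),
        corrs.n,
        sided=sided,
    ).p


def assign_exclusive(
    corrs: SubtypeCorrelations, alpha: float, sided: str = "one"
) -> AssignmentResult:
    """Call the one subtype whose correlation beats every other subtype.

    At most one subtype can win all its pairwise comparisons at
    alpha <= 0.5 (the comparison p-values of a pair sum to 1), so the
    call is unambiguous; if no subtype wins all, the sample is
    unassigned.
    """
    names = list(corrs.r_by_subtype.index)
    pvals: dict[str, float] = {}
    call = "unassigned"
    for x in names:
        ps = {f"{x}>{y}": _pairwise_p(corrs, x, y, sided) for y in names if y != x}
        if all(p < alpha for p in ps.values()):
            call = x
            pvals = ps
            break
    result = AssignmentResult(corrs.sample_id, "exclusive", call, alpha, pvals)
    return result


def assign_prognosis(
    corrs: SubtypeCorrelations,
    alpha: float,
    bad_subtypes: list[str],
    good_subtypes: list[str],
    sided: str = "one",
) -> AssignmentResult:
    """Call bad or good prognosis by pooling subtype pairs.

    bad: some bad subtype B beats BOTH good subtypes at alpha (B need
    not beat the other bad subtype); good: mirrored.
    """
    if len(bad_subtypes) != 2 or len(good_subtypes) != 2:
        raise ValueError("prognosis mode needs exactly two bad and two good subtypes")
    for s in bad_subtypes + good_subtypes:
        if s not in corrs.r_by_subtype.index:
            raise ValueError(f"unknown subtype {s!r}")

    def _wins(candidates: list[str], opponents: list[str]) -> dict[str, float] | None:
        for c in candidates:
            ps = {f"{c}>{o}": _pairwise_p(corrs, c, o, sided) for o in opponents}
            if all(p < alpha for p in ps.values()):
                return ps
        return None

    bad_ps = _wins(bad_subtypes, good_subtypes)
    good_ps = _wins(good_subtypes, bad_subtypes)
    if bad_ps is not None and good_ps is not None:
        # impossible at alpha <= 0.5: p(a>b) + p(b>a) = 1
        raise AssertionError("bad and good prognosis conditions cannot co-hold")
    if bad_ps is not None:
        return AssignmentResult(corrs.sample_id, "prognosis", "bad", alpha, bad_ps)
    if good_ps is not None:
        return AssignmentResult(corrs.sample_id, "prognosis", "good", alpha, good_ps)
    return AssignmentResult(corrs.sample_id, "prognosis", "unassigned", alpha, {})


def _frac_bin(frac: float) -> str:
    edges = [0.2, 0.4, 0.6, 0.8]
    lo = 0.0
    for e in edges:
        if frac < e:
            return f"[{lo:.1f},{e:.1f})"
        lo = e
    return "[0.8,1.0]"


def _gleason_group(g: int | None) -> str:
    if g is None:
        return "none"
    return "6-7" if g <= 7 else "8-9"


def summarize_assignments(
    results: dict[float, list[AssignmentResult]],
    metadata: dict[str, SampleMetadata] | None = None,
) -> pd.DataFrame:
    """Tabulate call counts per alpha, stratified by sample annotations.

    ``results`` maps each alpha to one AssignmentResult per sample.
    Strata: overall, sample type, frac_normal bins (width 0.2), and
    Gleason groups 6–7 vs 8–9.  An empty cohort yields an all-zero
    overall table.
    """
    rows = []
    for alpha in sorted(results):
        res = results[alpha]
        calls = sorted({r.call for r in res} | {"bad", "good", "unassigned"})
        strata: dict[tuple[str, str], list[AssignmentResult]] = {("overall", "all"): list(res)}
        if metadata is not None:
            for r in res:
                m = metadata[r.sample_id]
                strata.setdefault(("sample_type", m.sample_type), []).append(r)
                strata.setdefault(("frac_bin", _frac_bin(m.frac_normal)), []).append(r)
                if m.sample_type == "cancer":
                    strata.setdefault(("gleason", _gleason_group(m.gleason)), []).append(r)
        for (stratum, level), group in sorted(strata.items()):
            counts = {c: 0 for c in calls}
            for r in group:
                counts[r.call] = counts.get(r.call, 0) + 1
            for call, count in counts.items():
                rows.append(
                    {
                        "alpha": alpha,
                        "stratum": stratum,
                        "level": level,
                        "call": call,
                        "count": count,
                    }
                )
    if not rows:  # empty cohort and no alphas
        return pd.DataFrame(columns=["alpha", "stratum", "level", "call", "count"])
    return pd.DataFrame(rows)
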