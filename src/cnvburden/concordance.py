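"""Cross-callset concordance under 1-bp and fractional-overlap criteria.

Concordance here is directional recall: the fraction of a *primary*
callset's CNVs that a *secondary* callset recovers.  A primary CNV is
recalled either when any secondary CNV overlaps it by at least one base
("1bp" criterion) or when the union of secondary overlap covers at least
a fraction f of the primary CNV's length (fractional criterion, f = 0.5
by default).  Because the fractional criterion measures coverage of the
primary call, every comparison is asymmetric: a short call inside a huge
one is fully covered, while the huge call is barely covered by the short
one.  Matching is type-agnostic by default (plain intervals), with an
optional type-aware mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import CnvCall, CnvError, GenomicInterval, ValidationError

__all__ = ["ConcordanceResult", "pairwise_concordance", "concordance_matrix",
           "matrix_to_frame"]


@dataclass(frozen=True)
class ConcordanceResult:
    primary: str
    secondary: str
    criterion: str
    fraction_recalled: float
    n_primary: int


def _as_intervals(calls) -> list[tuple[str, int, int, str]]:
    out = []
    for c in calls:
        if isinstance(c, CnvCall):
            out.append((c.chrom, c.start, c.end, c.svtype))
        elif isinstance(c, GenomicInterval):
            out.append((c.chrom, c.start, c.end, ""))
        else:
            chrom, start, end = c[0], int(c[1]), int(c[2])
            svtype = c[3] if len(c) > 3 else ""
            out.append((chrom, start, end, svtype))
    return out


def _merged_by_chrom(items, type_aware: bool):
    """dict (chrom[, svtype]) -> merged sorted (starts, ends) arrays."""
    groups: dict = {}
    for chrom, s, e, t in items:
        key = (chrom, t) if type_aware else (chrom, "")
        groups.setdefault(key, []).append((s, e))
    merged = {}
    for key, ivs in groups.items():
        ivs.sort()
        ms, me = [], []
        for s, e in ivs:
            if ms and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        merged[key] = (np.asarray(ms), np.asarray(me))
    return merged


def _parse_criterion(criterion) -> tuple[str, float]:
    if criterion == "1bp":
        return "1bp", 0.0
    if isinstance(criterion, (int, float)):
        f = float(criterion)
        if not (0 < f <= 1):
            raise ValidationError("fractional criterion must lie in (0, 1]")
        return f"frac{f:g}", f
    if isinstance(criterion, str) and criterion.startswith("frac"):
        return _parse_criterion(float(criterion[4:]))
    raise ValidationError(f"unknown criterion {criterion!r}")


def pairwise_concordance(primary, secondary, criterion="1bp",
                         primary_label: str = "primary",
                         secondary_label: str = "secondary",
                         type_aware: bool = False) -> ConcordanceResult:
    """Fraction of primary CNVs recalled by the secondary callset.

    ``criterion`` is ``"1bp"`` (any overlap) or a fraction in (0, 1]
    (union of secondary overlap must cover at least that fraction of the
    primary call; also accepted as a string like ``"frac0.5"``). Coverage
    uses the merged union of secondary calls, so splitting a secondary
    call into book-ended pieces changes nothing.
    """
    name, frac = _parse_criterion(criterion)
    prim = _as_intervals(primary)
    if not prim:
        raise CnvError("empty primary callset: recall undefined")
    merged = _merged_by_chrom(_as_intervals(secondary), type_aware)
    recalled = 0
    for chrom, s, e, t in prim:
        key = (chrom, t) if type_aware else (chrom, "")
        if key not in merged:
            continue
        ms, me = merged[key]
        lo = np.searchsorted(me, s, side="right")
        hi = np.searchsorted(ms, e, side="left")
        if lo >= hi:
            continue
        if frac == 0.0:
            recalled += 1
            continue
        cov = np.minimum(me[lo:hi], e) - np.maximum(ms[lo:hi], s)
        if cov.sum() >= frac * (e - s):
            recalled += 1
    return ConcordanceResult(primary_label, secondary_label, name,
                             recalled / len(prim), len(prim))


def concordance_matrix(callsets: Sequence[tuple[str, Iterable]],
                       criteria: Sequence = ("1bp", 0.5),
                       type_aware: bool = False) -> list[ConcordanceResult]:
    """All ordered pairwise comparisons (including self) per criterion.

    ``callsets`` is a sequence of (label, calls) pairs with unique labels.
    Every callset serves as the primary against every other, so each pair
    is evaluated twice per criterion and the diagonal is 1.0.
    """
    labels = [lab for lab, _ in callsets]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate callset labels in {labels}")
    if len(callsets) < 2:
        raise ValidationError("need at least two callsets")
    results = []
    for crit in criteria:
        for p_lab, p_calls in callsets:
            for s_lab, s_calls in callsets:
                results.append(
                    pairwise_concordance(p_calls, s_calls, crit,
                                         p_lab, s_lab, type_aware)
                )
    return results


def matrix_to_frame(results: Sequence[ConcordanceResult]) -> pd.DataFrame:
    """Pivot results into one matrix per criterion (primary in columns)."""
    frame = pd.DataFrame([r.__dict__ for r in results])
    return frame.pivot_table(index=["criterion", "secondary"],
                             columns="primary", values="fraction_recalled")
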