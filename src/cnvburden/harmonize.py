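"""Multi-caller merging and per-sample CNV consolidation.

Different callers report the same event with slightly different
breakpoints, and a joint-genotyped callset leaves many overlapping or
adjacent segments per sample that association tools will not accept.  Two
steps fix this:

1. :func:`merge_caller_callsets` — a proximity merge that collapses
   same-type calls whose breakpoints agree within a tolerance, keeping
   provenance of the contributing callers.
2. :func:`consolidate_sample_cnvs` — merges overlapping/book-ended
   same-type segments into their union and drops *both* members of any
   DEL/DUP conflict, yielding non-overlapping per-sample segments suitable
   for burden analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .model import (
    DEL,
    DUP,
    CnvCall,
    GenomicInterval,
    PhenotypeTable,
    SampleCallset,
    ValidationError,
    calls_to_frame,
)

__all__ = [
    "MergeParameters",
    "merge_caller_callsets",
    "consolidate_sample_cnvs",
    "build_cohort_table",
]


@dataclass(frozen=True)
class MergeParameters:
    """max_breakpoint_distance: calls of one type merge when both their
    start and end positions differ by at most this many bp (transitively).
    adjacency_gap: segments whose gap is <= this merge during
    consolidation; 0 means only overlapping or book-ended segments merge."""

    max_breakpoint_distance: int = 100
    adjacency_gap: int = 0

    def __post_init__(self) -> None:
        if self.max_breakpoint_distance < 0 or self.adjacency_gap < 0:
            raise ValidationError("merge distances must be >= 0")


class _DisjointSet:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_caller_callsets(callsets: Sequence[SampleCallset],
                          params: MergeParameters = MergeParameters()
                          ) -> SampleCallset:
    """Collapse near-identical calls reported by several callers.

    Two calls of the same type on the same chromosome merge when their
    starts differ by at most ``max_breakpoint_distance`` and their ends do
    too; merging is transitive (single linkage). A merged call spans the
    earliest start to the latest end of its members, its copy number is the
    most extreme reported state (minimum for DEL, maximum for DUP) and its
    source lists the contributing callers. DEL never merges with DUP.
    """
    if not callsets:
        raise ValidationError("no callsets given")
    sample_ids = {cs.sample_id for cs in callsets}
    if len(sample_ids) != 1:
        raise ValidationError(f"mixed sample ids: {sorted(sample_ids)}")
    sample_id = callsets[0].sample_id
    calls = [c for cs in callsets for c in cs]
    merged: list[CnvCall] = []
    d = params.max_breakpoint_distance
    # cluster within (chrom, svtype) groups
    groups: dict[tuple[str, str], list[CnvCall]] = {}
    for c in calls:
        groups.setdefault((c.chrom, c.svtype), []).append(c)
    for (chrom, svtype), members in sorted(groups.items()):
        members.sort(key=CnvCall.sort_key)
        ds = _DisjointSet(len(members))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if members[j].start - members[i].start > d:
                    break
                if abs(members[j].end - members[i].end) <= d:
                    ds.union(i, j)
        clusters: dict[int, list[CnvCall]] = {}
        for i, c in enumerate(members):
            clusters.setdefault(ds.find(i), []).append(c)
        for _, clust in sorted(clusters.items()):
            start = min(c.start for c in clust)
            end = max(c.end for c in clust)
            cns = [c.copy_number for c in clust]
            cn = min(cns) if svtype == DEL else min(max(cns), 4)
            sources = sorted({s for c in clust for s in c.source.split(",") if s})
            merged.append(
                CnvCall(
                    GenomicInterval(chrom, start, end),
                    svtype,
                    cn,
                    sample_id,
                    ",".join(sources),
                    all(c.filter_pass for c in clust),
                )
            )
    return SampleCallset(sample_id, tuple(merged))


def _merge_same_type(calls: list[CnvCall], gap: int) -> list[CnvCall]:
    """Union-merge sorted same-type calls that overlap or sit within gap."""
    out: list[CnvCall] = []
    for c in sorted(calls, key=CnvCall.sort_key):
        if out and c.chrom == out[-1].chrom and c.start <= out[-1].end + gap:
            prev = out[-1]
            svtype = prev.svtype
            cn = (min(prev.copy_number, c.copy_number) if svtype == DEL
                  else min(max(prev.copy_number, c.copy_number), 4))
            sources = sorted(
                {s for x in (prev, c) for s in x.source.split(",") if s}
            )
            out[-1] = CnvCall(
                GenomicInterval(prev.chrom, prev.start, max(prev.end, c.end)),
                svtype, cn, prev.sample_id, ",".join(sources),
                prev.filter_pass and c.filter_pass,
            )
        else:
            out.append(c)
    return out


def consolidate_sample_cnvs(callset: SampleCallset,
                            params: MergeParameters = MergeParameters()
                            ) -> SampleCallset:
    """Resolve a sample's overlapping segments into a clean CNV list.

    Same-type segments that overlap or are book-ended are merged into
    their union (copy number: minimum for DEL, maximum capped at 4 for
    DUP). Wherever a merged deletion and a merged duplication still
    overlap, the copy state is contradictory and *both entire segments*
    are removed. The result is non-overlapping and sorted; the operation
    is idempotent and never increases the event count.
    """
    dels = _merge_same_type([c for c in callset if c.svtype == DEL],
                            params.adjacency_gap)
    dups = _merge_same_type([c for c in callset if c.svtype == DUP],
                            params.adjacency_gap)
    drop_del = set()
    drop_dup = set()
    for i, dcall in enumerate(dels):
        for j, pcall in enumerate(dups):
            if dcall.interval.overlaps(pcall.interval):
                drop_del.add(i)
                drop_dup.add(j)
    kept = [c for i, c in enumerate(dels) if i not in drop_del]
    kept += [c for j, c in enumerate(dups) if j not in drop_dup]
    return SampleCallset(callset.sample_id, tuple(kept))


def build_cohort_table(callsets: Sequence[SampleCallset],
                       phenotypes: PhenotypeTable) -> pd.DataFrame:
    """Concatenate consolidated per-sample callsets into one sorted table.

    Rows are sorted by (chrom, start, end, sample_id). Every sample in the
    callsets must appear in the phenotype table; the error lists missing
    samples. The returned frame has columns chrom, start, end, svtype,
    copy_number, sample_id, source.
    """
    known = set(phenotypes.sample_ids)
    missing = sorted({cs.sample_id for cs in callsets} - known)
    if missing:
        raise ValidationError(f"samples absent from phenotype table: {missing}")
    frame = calls_to_frame(c for cs in callsets for c in cs)
    frame = frame.sort_values(["chrom", "start", "end", "sample_id"],
                              kind="mergesort").reset_index(drop=True)
    return frame


def per_sample_event_counts(cohort: pd.DataFrame) -> pd.Series:
    """Events per sample in a cohort table (all types combined)."""
    return cohort.groupby("sample_id").size()
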