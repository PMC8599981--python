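"""Core data model for CNV segments, masks and phenotypes.

All coordinates are 0-based half-open (`[start, end)`), the BED convention.
Format-specific conversions (VCF 1-based POS, PLINK 1-based inclusive
BP1/BP2) happen at the I/O boundary in :mod:`cnvburden.io`, never here.

Copy-number status is restricted to the alphabet {0, 1, 3, 4}: deletions
carry 0 (homozygous) or 1 (heterozygous) copies, duplications 3
(heterozygous) or 4, where 4 stands for four *or more* copies.  Two copies
is the diploid reference state and is not a CNV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

DEL = "DEL"
DUP = "DUP"
SVTYPES = (DEL, DUP)

#: valid copy-number states; 4 means >= 4 copies
COPY_NUMBERS = (0, 1, 3, 4)

#: accessibility-mask class alphabet: P passed, N ambiguous base, L low
#: coverage, H high coverage, Z zero mapping quality
MASK_CLASSES = ("P", "N", "L", "H", "Z")

#: ancestry/ethnicity group labels used in the burden analysis grid
GROUPS = ("AA", "Hispanic", "NHW", "Other")


class CnvError(Exception):
    """Base class for all toolkit errors."""


class ParseError(CnvError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(CnvError):
    """Input violated a model invariant."""


class OverlappingSegmentsError(ValidationError):
    """A sample carried overlapping segments where none are allowed."""


def svtype_for_copy_number(copy_number: int) -> str:
    """Infer DEL/DUP from a copy-number status.

    Raises :class:`ValidationError` for copy number 2 (diploid, not a CNV)
    or any value outside the {0, 1, 3, 4} alphabet.
    """
    if copy_number in (0, 1):
        return DEL
    if copy_number in (3, 4):
        return DUP
    if copy_number == 2:
        raise ValidationError("copy number 2 is the diploid state, not a CNV")
    raise ValidationError(f"copy number {copy_number} outside {{0,1,3,4}}")


def clamp_copy_number(copy_number: int) -> int:
    """Clamp out-of-range integer copy numbers into the status alphabet.

    Values above 4 become 4 (the ">=4 copies" state); negatives become 0.
    Copy number 2 is *not* clamped and still fails validation downstream.
    """
    if copy_number > 4:
        return 4
    if copy_number < 0:
        return 0
    return copy_number


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class CnvCall:
    """One deletion or duplication segment in one sample.

    ``source`` is a free-form provenance label (caller name or pipeline
    stage); merged calls carry a comma-joined, sorted list of contributors.
    ``filter_pass`` records whether the call survived upstream filtering;
    readers keep failing calls so that filtering decisions stay explicit.
    """

    interval: GenomicInterval
    svtype: str
    copy_number: int
    sample_id: str
    source: str = ""
    filter_pass: bool = True

    def __post_init__(self) -> None:
        if self.svtype not in SVTYPES:
            raise ValidationError(f"svtype must be DEL or DUP, got {self.svtype!r}")
        if svtype_for_copy_number(self.copy_number) != self.svtype:
            raise ValidationError(
                f"copy number {self.copy_number} inconsistent with {self.svtype}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.svtype, self.sample_id)


@dataclass
class SampleCallset:
    """All CNV calls of one sample, kept sorted by (chrom, start, end)."""

    sample_id: str
    calls: tuple[CnvCall, ...] = ()

    def __post_init__(self) -> None:
        calls = tuple(sorted(self.calls, key=CnvCall.sort_key))
        for c in calls:
            if c.sample_id != self.sample_id:
                raise ValidationError(
                    f"call for sample {c.sample_id!r} in callset of "
                    f"{self.sample_id!r}"
                )
        object.__setattr__(self, "calls", calls)

    def __iter__(self) -> Iterator[CnvCall]:
        return iter(self.calls)

    def __len__(self) -> int:
        return len(self.calls)

    def has_overlaps(self) -> bool:
        """True when any two calls of the sample share a base."""
        by_chrom: dict[str, int] = {}
        for c in self.calls:
            prev_end = by_chrom.get(c.chrom, -1)
            if c.start < prev_end:
                return True
            by_chrom[c.chrom] = max(prev_end, c.end)
        return False


def _merge_sorted(starts: np.ndarray, ends: np.ndarray, gap: int = 0):
    """Merge sorted intervals allowing a join gap (0 = book-ended merge)."""
    if len(starts) == 0:
        return starts, ends
    out_s = [int(starts[0])]
    out_e = [int(ends[0])]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1] + gap:
            out_e[-1] = max(out_e[-1], int(e))
        else:
            out_s.append(int(s))
            out_e.append(int(e))
    return np.asarray(out_s), np.asarray(out_e)


class MaskTrack:
    """Genome accessibility partition into classes P/N/L/H/Z.

    Holds per-chromosome sorted, non-overlapping labeled intervals exactly
    as read (adjacent same-label rows are not auto-merged).
    """

    def __init__(self, frame: pd.DataFrame):
        required = ["chrom", "start", "end", "label"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValidationError(f"mask frame missing columns {missing}")
        frame = frame[required].copy()
        bad = ~frame["label"].isin(MASK_CLASSES)
        if bad.any():
            raise ValidationError(
                f"unknown mask class labels: {sorted(frame.loc[bad, 'label'].unique())}"
            )
        if (frame["start"] >= frame["end"]).any():
            raise ValidationError("mask contains empty or inverted intervals")
        frame = frame.sort_values(["chrom", "start", "end"], kind="mergesort")
        frame = frame.reset_index(drop=True)
        for chrom, grp in frame.groupby("chrom", sort=False):
            ends = grp["end"].to_numpy()
            starts = grp["start"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                raise ValidationError(f"overlapping mask intervals on {chrom}")
        self.frame = frame

    def composition(self) -> dict[str, float]:
        """Fraction of masked bases per class; fractions sum to 1."""
        lengths = self.frame["end"] - self.frame["start"]
        total = float(lengths.sum())
        if total == 0:
            raise ValidationError("mask is empty")
        by_class = lengths.groupby(self.frame["label"]).sum()
        return {str(label): float(v) / total for label, v in by_class.items()}

    def class_union(self, chrom: str, label: str = "P"):
        """Merged (book-ended joined) intervals of one class on one chromosome.

        Returns ``(starts, ends)`` numpy arrays sorted by position.
        """
        sub = self.frame[(self.frame["chrom"] == chrom) & (self.frame["label"] == label)]
        return _merge_sorted(sub["start"].to_numpy(), sub["end"].to_numpy(), gap=0)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.frame["chrom"].unique())


class PhenotypeTable:
    """Per-sample phenotype/bookkeeping table.

    Columns: ``sample_id``, ``family_id`` (defaults to the sample id, for
    cohorts without family structure), ``status`` in {case, control} and
    ``group`` in {AA, Hispanic, NHW, Other}.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if "sample_id" not in frame.columns or "status" not in frame.columns:
            raise ValidationError("phenotype table needs sample_id and status columns")
        if "family_id" not in frame.columns:
            frame["family_id"] = frame["sample_id"]
        else:
            frame["family_id"] = frame["family_id"].fillna(frame["sample_id"])
        if "group" not in frame.columns:
            frame["group"] = "Other"
        if frame["sample_id"].duplicated().any():
            dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        bad_status = ~frame["status"].isin(["case", "control"])
        if bad_status.any():
            raise ValidationError(
                f"status must be case/control, got {sorted(frame.loc[bad_status, 'status'].unique())}"
            )
        bad_group = ~frame["group"].isin(GROUPS)
        if bad_group.any():
            raise ValidationError(
                f"group must be one of {GROUPS}, got {sorted(frame.loc[bad_group, 'group'].unique())}"
            )
        self.frame = frame[["sample_id", "family_id", "status", "group"]].reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def family_of(self) -> Mapping[str, str]:
        return dict(zip(self.frame["sample_id"], self.frame["family_id"]))

    def is_case(self) -> pd.Series:
        """Boolean Series indexed by sample_id; True for cases."""
        return pd.Series(
            (self.frame["status"] == "case").to_numpy(),
            index=self.frame["sample_id"],
        )

    def samples_in_group(self, group: str) -> list[str]:
        """Sample ids belonging to a group; ``"ALL"`` selects every sample."""
        if group == "ALL":
            return self.sample_ids
        return self.frame.loc[self.frame["group"] == group, "sample_id"].tolist()

    def __len__(self) -> int:
        return len(self.frame)


def calls_to_frame(calls: Iterable[CnvCall]) -> pd.DataFrame:
    """Tabulate CnvCalls into the cohort-table column layout."""
    rows = [
        (c.chrom, c.start, c.end, c.svtype, c.copy_number, c.sample_id, c.source)
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "svtype", "copy_number", "sample_id", "source"],
    )


def frame_to_calls(frame: pd.DataFrame) -> list[CnvCall]:
    """Inverse of :func:`calls_to_frame` (source column optional)."""
    has_source = "source" in frame.columns
    return [
        CnvCall(
            GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            str(r.svtype),
            int(r.copy_number),
            str(r.sample_id),
            str(getattr(r, "source", "")) if has_source else "",
        )
        for r in frame.itertuples(index=False)
    ]
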