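"""Rare-CNV identification: cohort-frequency exclusion and mask residence.

Rarity is defined by overlap frequency across the cohort, mirroring the
``--cnv-freq-exclude-above N --cnv-overlap 0.5`` semantics of the classic
association toolkit: a CNV is *excluded* when more than half of its length
lies on bases covered by more than N cohort events.  With N =
floor(0.01 x n_samples) this removes events whose local frequency exceeds
1%.  Rare CNVs are additionally required to reside entirely within the
accessible ("P"-classified) portion of the genome mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MaskTrack, ValidationError

__all__ = [
    "RareFilterParameters",
    "frequency_threshold",
    "frequency_filter",
    "apply_accessibility_mask",
    "mask_composition",
    "rare_cnvs",
]


@dataclass(frozen=True)
class RareFilterParameters:
    """frequency: cohort frequency above which a region is "common"
    (default 1%). overlap_fraction: a CNV is excluded when more than this
    fraction of its length lies on common bases (default 0.5, strict >).
    count_threshold: explicit event-count threshold; when None it is
    derived as floor(frequency x n_samples)."""

    frequency: float = 0.01
    overlap_fraction: float = 0.5
    count_threshold: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.frequency < 1):
            raise ValidationError("frequency must lie in (0, 1)")
        if not (0 < self.overlap_fraction <= 1):
            raise ValidationError("overlap_fraction must lie in (0, 1]")
        if self.count_threshold is not None and self.count_threshold < 1:
            raise ValidationError("count_threshold must be >= 1")


def frequency_threshold(n_samples: int, frequency: float = 0.01) -> int:
    """Event-count threshold floor(frequency x n_samples).

    E.g. 3,800 samples at 1% -> 38. Raises when the result would be 0
    (every event would be excluded).
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    t = math.floor(frequency * n_samples)
    if t < 1:
        raise ValidationError(
            f"threshold floor({frequency} x {n_samples}) = 0 would exclude everything"
        )
    return t


def _per_base_counts(starts: np.ndarray, ends: np.ndarray):
    """Coordinate-compressed per-base event counts for one chromosome.

    Returns (breakpoints, counts): counts[i] events cover every base in
    [breakpoints[i], breakpoints[i+1]).
    """
    bp = np.unique(np.concatenate([starts, ends]))
    delta = np.zeros(len(bp), dtype=np.int64)
    np.add.at(delta, np.searchsorted(bp, starts), 1)
    np.add.at(delta, np.searchsorted(bp, ends), -1)
    return bp, np.cumsum(delta)


def frequency_filter(cohort: pd.DataFrame,
                     params: RareFilterParameters = RareFilterParameters(),
                     n_samples: int | None = None) -> pd.DataFrame:
    """Remove CNVs that overlap a common region of the cohort.

    For every base, the number of cohort events covering it is counted —
    any type, any sample, *including the event under test itself*, so a
    threshold of 38 tolerates 38 carriers. A CNV is excluded iff the
    fraction of its length on bases with count > threshold exceeds
    ``overlap_fraction`` (strict). Retained rows are returned unchanged.

    ``n_samples`` (for deriving the threshold from ``params.frequency``)
    defaults to the number of distinct samples in the table.
    """
    if len(cohort) == 0:
        return cohort.copy()
    if params.count_threshold is not None:
        threshold = params.count_threshold
    else:
        if n_samples is None:
            n_samples = cohort["sample_id"].nunique()
        threshold = frequency_threshold(n_samples, params.frequency)
    keep = np.ones(len(cohort), dtype=bool)
    for chrom, grp in cohort.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        bp, counts = _per_base_counts(starts, ends)
        common = counts > threshold
        # prefix sum of common bases per elementary segment
        seg_len = np.diff(bp, append=bp[-1])
        common_len = np.concatenate([[0], np.cumsum(seg_len * common)])
        for row_idx, s, e in zip(grp.index, starts, ends):
            i = np.searchsorted(bp, s, side="right") - 1
            j = np.searchsorted(bp, e, side="left")
            frac = (common_len[j] - common_len[i]) / (e - s)
            if frac > params.overlap_fraction:
                keep[cohort.index.get_loc(row_idx)] = False
    return cohort[keep].copy()


def apply_accessibility_mask(cohort: pd.DataFrame, mask: MaskTrack,
                             label: str = "P") -> pd.DataFrame:
    """Keep only CNVs residing entirely in accessible (P) regions.

    A CNV is retained iff 100% of its span is covered by the union of
    P-labeled mask intervals; events on chromosomes absent from the mask
    are excluded (and counted in the ``.attrs['excluded_no_mask']`` of the
    result).
    """
    if len(cohort) == 0:
        out = cohort.copy()
        out.attrs["excluded_no_mask"] = 0
        return out
    keep = np.zeros(len(cohort), dtype=bool)
    no_mask = 0
    mask_chroms = set(mask.chromosomes)
    pos = 0
    unions: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for row in cohort.itertuples(index=False):
        chrom = row.chrom
        if chrom not in mask_chroms:
            no_mask += 1
            pos += 1
            continue
        if chrom not in unions:
            unions[chrom] = mask.class_union(chrom, label)
        starts, ends = unions[chrom]
        # containment in the union <=> containment in one merged interval
        i = np.searchsorted(starts, row.start, side="right") - 1
        keep[pos] = i >= 0 and ends[i] >= row.end
        pos += 1
    out = cohort[keep].copy()
    out.attrs["excluded_no_mask"] = no_mask
    return out


def mask_composition(mask: MaskTrack) -> dict[str, float]:
    """Fraction of masked bases per class (sums to 1 over the masked span)."""
    return mask.composition()


def rare_cnvs(cohort: pd.DataFrame, mask: MaskTrack | None,
              params: RareFilterParameters = RareFilterParameters(),
              n_samples: int | None = None,
              order: str = "mask-then-frequency") -> pd.DataFrame:
    """Full rare-CNV pipeline: accessibility mask + frequency exclusion.

    ``order`` selects whether the mask is applied before or after the
    frequency filter ("mask-then-frequency", the default, or
    "frequency-then-mask"); the retained set can differ because masking
    changes nothing about per-base counts but frequency filtering changes
    which events reach the mask step only in reporting, so the default
    applies the mask first.
    """
    if order not in ("mask-then-frequency", "frequency-then-mask"):
        raise ValidationError(f"unknown order {order!r}")
    out = cohort
    if order == "mask-then-frequency":
        if mask is not None:
            out = apply_accessibility_mask(out, mask)
        out = frequency_filter(out, params, n_samples=n_samples)
    else:
        out = frequency_filter(out, params, n_samples=n_samples)
        if mask is not None:
            out = apply_accessibility_mask(out, mask)
    return out
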