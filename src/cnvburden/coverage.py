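"""Across-chromosome alignment-coverage quality control.

Uneven coverage across chromosomes causes false-positive CNV calls, so
samples are screened before CNV analysis.  The check estimates each
chromosome's fold-coverage from *repetitive-free regions* — windows in
which every constituent k-mer (default 25-mer) occurs exactly once in the
whole reference, counting both strands — so read depth there reflects true
coverage without mapping ambiguity.  Chromosomes whose coverage deviates
strongly from the sample median are flagged as outliers (trisomy ~1.5x,
monosomy ~0.5x); the sample itself fails QC when the standard deviation of
the remaining chromosome coverages exceeds a fraction (default 15%) of
their mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import CnvError, GenomicInterval, ValidationError

__all__ = [
    "QcParameters",
    "CoverageProfile",
    "DepthTrack",
    "find_repetitive_free_regions",
    "chromosome_coverage",
    "detect_outlier_chromosomes",
    "OutlierResult",
    "sample_qc",
    "QcVerdict",
    "coverage_profile",
]


@dataclass(frozen=True)
class QcParameters:
    """Tunables of the coverage check.

    k
        k-mer length used for the uniqueness census (bp).
    region_length
        length of each repetitive-free region (bp).
    regions_per_chromosome
        number of regions sought per chromosome (best effort: short or
        repeat-dense chromosomes may yield fewer).
    sd_fraction
        a sample fails QC when the sd of its non-outlier chromosome
        coverages exceeds this fraction of their mean.
    outlier_fraction
        a chromosome is an outlier when its coverage deviates from the
        across-chromosome median by more than this fraction of the median;
        use ``math.inf`` to disable outlier detection.
    """

    k: int = 25
    region_length: int = 20_000
    regions_per_chromosome: int = 20
    sd_fraction: float = 0.15
    outlier_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.region_length < self.k:
            raise ValidationError("region_length must be >= k")
        if self.regions_per_chromosome < 1:
            raise ValidationError("regions_per_chromosome must be >= 1")
        if not (0 < self.sd_fraction < 1):
            raise ValidationError("sd_fraction must lie in (0, 1)")
        if not (0 < self.outlier_fraction):
            raise ValidationError("outlier_fraction must be positive")


# ---------------------------------------------------------------------------
# k-mer uniqueness and region finding

_CODE = np.full(256, -1, dtype=np.int64)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to integer codes A=0 C=1 G=2 T=3, anything else -1."""
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def _canonical_kmer_hashes(codes: np.ndarray, k: int):
    """Per-position canonical k-mer hash and validity mask.

    The canonical hash is the minimum of the 2-bit polynomial hash of the
    k-mer and of its reverse complement, so a k-mer and its reverse
    complement collapse to one object. Positions whose window contains an
    ambiguous base are invalid.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    valid = ~(windows < 0).any(axis=1)
    fwd = (windows * powers).sum(axis=1)
    # reverse complement read 3'->5': complement codes, reversed weight order
    rev = ((3 - windows) * powers[::-1]).sum(axis=1)
    canon = np.minimum(fwd, rev)
    canon[~valid] = -1
    return canon, valid


def genome_kmer_uniqueness(reference: Mapping[str, str], k: int) -> dict[str, np.ndarray]:
    """Boolean per-position array per chromosome: k-mer occurs exactly once.

    Occurrence counting is genome-wide and strand-agnostic. Positions whose
    k-mer contains an N are False.
    """
    if not reference:
        raise CnvError("empty reference")
    hashes = {}
    for chrom, seq in reference.items():
        hashes[chrom] = _canonical_kmer_hashes(_encode(seq), k)
    all_valid = [h[v] for h, v in hashes.values()]
    if all_valid:
        pool = np.concatenate(all_valid) if all_valid else np.empty(0, np.int64)
    else:  # pragma: no cover - degenerate
        pool = np.empty(0, np.int64)
    values, counts = np.unique(pool, return_counts=True)
    unique_once = values[counts == 1]
    out = {}
    for chrom, (h, valid) in hashes.items():
        idx = np.searchsorted(unique_once, h)
        idx = np.clip(idx, 0, max(len(unique_once) - 1, 0))
        hit = np.zeros(len(h), dtype=bool)
        if len(unique_once):
            hit = unique_once[idx] == h
        out[chrom] = hit & valid
    return out


def _qualifying_window_starts(unique: np.ndarray, region_length: int, k: int,
                              chrom_length: int) -> np.ndarray:
    """Boolean array over window starts: all fully-contained k-mers unique."""
    n_windows = chrom_length - region_length + 1
    if n_windows <= 0:
        return np.empty(0, dtype=bool)
    span = region_length - k + 1  # k-mer starts fully inside the window
    bad = (~unique).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(bad)])
    starts = np.arange(n_windows)
    return csum[starts + span] - csum[starts] == 0


def _place_regions(ok: np.ndarray, chrom_length: int, params: QcParameters) -> list[tuple[int, int]]:
    """Deterministic region placement.

    The chromosome is partitioned into ``regions_per_chromosome`` equal
    bins; each bin contributes the leftmost qualifying window starting in
    it that does not overlap an already chosen region. Remaining slots are
    filled by a greedy left-to-right scan.
    """
    L = params.region_length
    n_target = params.regions_per_chromosome
    if len(ok) == 0:
        return []
    ok_starts = np.flatnonzero(ok)
    if len(ok_starts) == 0:
        return []
    edges = [round(i * chrom_length / n_target) for i in range(n_target + 1)]
    chosen: list[tuple[int, int]] = []
    cursor = 0
    for i in range(n_target):
        lo = max(edges[i], cursor)
        hi = edges[i + 1]
        if lo >= hi:
            continue
        j = np.searchsorted(ok_starts, lo)
        if j < len(ok_starts) and ok_starts[j] < hi:
            s = int(ok_starts[j])
            chosen.append((s, s + L))
            cursor = s + L
    if len(chosen) < n_target:
        # greedy left-to-right fill of leftover slots
        import bisect

        res = sorted(chosen)
        idx = 0
        while len(res) < n_target and idx < len(ok_starts):
            s = int(ok_starts[idx])
            e = s + L
            i = bisect.bisect_left(res, (s, s))
            if i > 0 and res[i - 1][1] > s:  # overlaps previous chosen region
                idx = int(np.searchsorted(ok_starts, res[i - 1][1]))
                continue
            if i < len(res) and res[i][0] < e:  # overlaps next chosen region
                idx = int(np.searchsorted(ok_starts, res[i][1]))
                continue
            res.insert(i, (s, e))
            idx = int(np.searchsorted(ok_starts, e))
        chosen = res
    return sorted(chosen)


def find_repetitive_free_regions(reference: Mapping[str, str],
                                 params: QcParameters = QcParameters()
                                 ) -> dict[str, list[GenomicInterval]]:
    """Locate repetitive-free regions on every chromosome.

    Each returned interval has length exactly ``params.region_length`` and
    every k-mer fully contained in it occurs exactly once in the whole
    reference (both strands). Regions of one chromosome never overlap and
    at most ``params.regions_per_chromosome`` are returned per chromosome;
    chromosomes shorter than the region length yield an empty list.
    """
    uniq = genome_kmer_uniqueness(reference, params.k)
    out: dict[str, list[GenomicInterval]] = {}
    for chrom, seq in reference.items():
        ok = _qualifying_window_starts(uniq[chrom], params.region_length,
                                       params.k, len(seq))
        spans = _place_regions(ok, len(seq), params)
        out[chrom] = [GenomicInterval(chrom, s, e) for s, e in spans]
    return out


# ---------------------------------------------------------------------------
# depth tracks and chromosome coverage

class DepthTrack:
    """Read-depth over the genome as per-chromosome step functions.

    Stored as sorted, non-overlapping (start, end, depth) runs per
    chromosome — the in-memory equivalent of a bedGraph. Positions not
    covered by any run have depth 0.
    """

    def __init__(self, runs: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.runs = {}
        for chrom, (starts, ends, depths) in runs.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            depths = np.asarray(depths, dtype=float)
            order = np.argsort(starts, kind="stable")
            self.runs[chrom] = (starts[order], ends[order], depths[order])

    @classmethod
    def from_array(cls, per_base: Mapping[str, np.ndarray]) -> "DepthTrack":
        """Build from per-base depth arrays, run-length encoding each."""
        runs = {}
        for chrom, arr in per_base.items():
            arr = np.asarray(arr)
            if len(arr) == 0:
                runs[chrom] = (np.empty(0, np.int64),) * 2 + (np.empty(0),)
                continue
            change = np.flatnonzero(np.diff(arr) != 0) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            runs[chrom] = (starts, ends, arr[starts].astype(float))
        return cls(runs)

    @classmethod
    def from_bedgraph(cls, path) -> "DepthTrack":
        frame = pd.read_csv(path, sep=r"\s+", header=None,
                            names=["chrom", "start", "end", "depth"],
                            comment="#")
        runs = {
            chrom: (g["start"].to_numpy(), g["end"].to_numpy(), g["depth"].to_numpy())
            for chrom, g in frame.groupby("chrom", sort=False)
        }
        return cls(runs)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.runs):
                starts, ends, depths = self.runs[chrom]
                for s, e, d in zip(starts, ends, depths):
                    d_str = f"{d:g}"
                    fh.write(f"{chrom}\t{s}\t{e}\t{d_str}\n")

    def mean_over(self, intervals: Sequence[GenomicInterval]) -> float:
        """Mean per-base depth over the union of the given intervals."""
        total_bases = 0
        total_depth = 0.0
        for iv in intervals:
            if iv.chrom not in self.runs:
                total_bases += iv.length
                continue
            starts, ends, depths = self.runs[iv.chrom]
            lo = np.searchsorted(ends, iv.start, side="right")
            hi = np.searchsorted(starts, iv.end, side="left")
            for s, e, d in zip(starts[lo:hi], ends[lo:hi], depths[lo:hi]):
                ov = min(e, iv.end) - max(s, iv.start)
                if ov > 0:
                    total_depth += d * ov
            total_bases += iv.length
        if total_bases == 0:
            raise ValidationError("mean depth over an empty interval set")
        return total_depth / total_bases


def chromosome_coverage(depth: DepthTrack,
                        regions: Mapping[str, Sequence[GenomicInterval]]
                        ) -> dict[str, float]:
    """Fold-coverage per chromosome: mean depth over its repetitive-free
    regions. Chromosomes without regions get NaN (undefined; excluded from
    downstream statistics)."""
    out = {}
    for chrom, ivs in regions.items():
        out[chrom] = depth.mean_over(ivs) if ivs else math.nan
    return out


# ---------------------------------------------------------------------------
# outlier chromosomes and sample verdict

@dataclass(frozen=True)
class OutlierResult:
    outliers: frozenset
    undefined: frozenset
    overall_mean: float
    sd: float
    median: float


def detect_outlier_chromosomes(coverages: Mapping[str, float],
                               params: QcParameters = QcParameters()
                               ) -> OutlierResult:
    """Flag chromosomes with unexpectedly high or low coverage.

    A chromosome is an outlier when its coverage deviates from the median
    (over defined coverages) by more than ``outlier_fraction`` times the
    median — e.g. trisomy (~1.5x) or monosomy (~0.5x). The overall mean and
    (population) sd are computed over non-outlier chromosomes only.
    """
    defined = {c: v for c, v in coverages.items() if not math.isnan(v)}
    undefined = frozenset(set(coverages) - set(defined))
    if len(defined) < 2:
        raise CnvError("need >= 2 chromosomes with defined coverage")
    values = np.array(list(defined.values()))
    med = float(np.median(values))
    names = list(defined)
    if math.isinf(params.outlier_fraction):
        flag = np.zeros(len(values), dtype=bool)
    else:
        flag = np.abs(values - med) > params.outlier_fraction * med
    if flag.all():
        raise CnvError("all chromosomes flagged as outliers; no baseline")
    kept = values[~flag]
    return OutlierResult(
        outliers=frozenset(n for n, f in zip(names, flag) if f),
        undefined=undefined,
        overall_mean=float(kept.mean()),
        sd=float(kept.std()),  # population sd: chromosomes are the population
        median=med,
    )


@dataclass(frozen=True)
class QcVerdict:
    passed: bool
    sd: float
    overall_mean: float
    threshold: float


@dataclass(frozen=True)
class CoverageProfile:
    """Per-sample coverage summary with QC verdict."""

    sample_id: str
    coverages: dict[str, float]
    regions: dict[str, tuple[GenomicInterval, ...]]
    outliers: frozenset
    undefined: frozenset
    overall_mean: float
    sd: float
    passed: bool


def sample_qc(profile: CoverageProfile | OutlierResult,
              params: QcParameters = QcParameters()) -> QcVerdict:
    """Pass/fail verdict for a sample: fail iff sd > sd_fraction x mean.

    The comparison is strict (> fails, == passes) and uses the mean/sd
    computed over non-outlier chromosomes.
    """
    if profile.overall_mean <= 0:
        raise CnvError("overall mean coverage must be positive")
    threshold = params.sd_fraction * profile.overall_mean
    return QcVerdict(profile.sd <= threshold, profile.sd, profile.overall_mean,
                     threshold)


def coverage_profile(sample_id: str, depth: DepthTrack,
                     regions: Mapping[str, Sequence[GenomicInterval]],
                     params: QcParameters = QcParameters()) -> CoverageProfile:
    """Full per-sample QC: coverage per chromosome, outliers, verdict."""
    cov = chromosome_coverage(depth, regions)
    res = detect_outlier_chromosomes(cov, params)
    verdict = sample_qc(res, params)
    return CoverageProfile(
        sample_id=sample_id,
        coverages=cov,
        regions={c: tuple(v) for c, v in regions.items()},
        outliers=res.outliers,
        undefined=res.undefined,
        overall_mean=res.overall_mean,
        sd=res.sd,
        passed=verdict.passed,
    )


def profile_to_frame(profiles: Sequence[CoverageProfile]) -> pd.DataFrame:
    """Tabulate QC results, one row per (sample, chromosome)."""
    rows = []
    for p in profiles:
        for chrom, cov in sorted(p.coverages.items()):
            rows.append(
                (p.sample_id, chrom, cov, chrom in p.outliers,
                 p.overall_mean, p.sd, "pass" if p.passed else "fail")
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "coverage", "outlier",
                 "overall_mean", "sd", "verdict"],
    )
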