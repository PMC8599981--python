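"""Synthetic data for exercising the whole pipeline end to end.

Generates every input the toolkit consumes: a random reference (with
optional implanted duplicated blocks so that repetitive-free-region
finding has something to avoid), a cohort of CNV genotypes drawn from a
population pool with allele frequencies, caller-style noisy observations
(breakpoint jitter, missed calls, split calls), per-base depth tracks
with optional whole-chromosome gain/loss, an accessibility mask, and a
phenotype table with an injectable case/control duplication-burden
effect.

Everything is driven by one integer seed; each generator draws from its
own deterministic stream, so the individual functions are reproducible
both standalone and in combination.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import DepthTrack
from .model import (
    DEL,
    DUP,
    CnvCall,
    CnvError,
    GenomicInterval,
    MaskTrack,
    PhenotypeTable,
    SampleCallset,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "simulate_reference",
    "simulate_cohort",
    "simulate_caller_observations",
    "simulate_depth_profile",
    "simulate_mask",
    "write_fixtures",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults describe a desk-scale version of a WGS CNV study: a cohort
    of 200 samples (100 cases) on a 700-kb two-chromosome genome, a
    120-CNV population pool with log-normally distributed lengths (median
    ~1 kb) and rarity-skewed Beta allele frequencies, three pseudo-callers
    with 50-bp breakpoint jitter / 5% missed calls / 5% split calls,
    37-fold mean depth (the coverage scale of large WGS efforts), and an
    accessibility mask split 89 / 5.3 / 1.4 / 0.6 / 3.7 percent across
    the P/N/L/H/Z classes. ``burden_effect`` is the expected number of
    extra private duplications per case (0 = null cohort).
    """

    seed: int = 0
    n_samples: int = 200
    n_cases: int = 100
    chromosome_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 400_000, "chr2": 300_000})
    n_pool_cnvs: int = 120
    length_log_mean: float = math.log(1_000)
    length_log_sd: float = 1.0
    min_length: int = 200
    max_length_fraction: float = 0.05  # cap: fraction of the largest chromosome
    af_alpha: float = 0.4
    af_beta: float = 3.6
    dup_fraction: float = 0.45
    callers: tuple[str, ...] = ("rdcaller", "largecaller", "splitread")
    jitter_sd: float = 50.0
    fn_rate: float = 0.05
    split_rate: float = 0.05
    burden_effect: float = 0.0
    effect_svtype: str = DUP
    effect_length: int = 2_000
    depth_mean: float = 37.0
    aneuploid_multipliers: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict)
    group_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"AA": 0.25, "Hispanic": 0.30,
                                 "NHW": 0.40, "Other": 0.05})
    mask_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"P": 0.890, "N": 0.053, "L": 0.014,
                                 "H": 0.006, "Z": 0.037})
    n_implanted_duplications: int = 0
    implant_length: int = 5_000
    depth_window: int = 100
    n_depth_samples: int = 2

    def __post_init__(self) -> None:
        if self.n_cases > self.n_samples:
            raise ValidationError("n_cases must not exceed n_samples")
        for r in (self.fn_rate, self.split_rate, self.dup_fraction):
            if not (0 <= r <= 1):
                raise ValidationError("rates must lie in [0, 1]")
        if self.burden_effect < 0:
            raise ValidationError("burden_effect must be >= 0")

    def sample_ids(self) -> list[str]:
        width = len(str(self.n_samples))
        return [f"S{i:0{width}d}" for i in range(1, self.n_samples + 1)]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# reference

def simulate_reference(config: SimulationConfig) -> dict[str, str]:
    """i.i.d. random reference with optional implanted duplicated blocks.

    Each implanted duplication copies a block of ``implant_length`` bases
    from one locus to another (possibly across chromosomes), so every
    k-mer inside either copy occurs at least twice genome-wide.
    """
    rng = _rng(config, 1)
    seqs = {}
    for chrom, length in config.chromosome_lengths.items():
        codes = rng.integers(0, 4, size=length)
        seqs[chrom] = _BASES[codes].tobytes().decode()
    L = config.implant_length
    chroms = list(seqs)
    for _ in range(config.n_implanted_duplications):
        if any(len(seqs[c]) < 3 * L for c in chroms):
            raise CnvError("chromosomes too short for requested duplications")
        src_chrom = chroms[rng.integers(len(chroms))]
        dst_chrom = chroms[rng.integers(len(chroms))]
        src = int(rng.integers(0, len(seqs[src_chrom]) - L))
        block = seqs[src_chrom][src:src + L]
        dst = int(rng.integers(0, len(seqs[dst_chrom]) - L))
        if dst_chrom == src_chrom:
            # keep the two copies disjoint
            while abs(dst - src) < L:
                dst = int(rng.integers(0, len(seqs[dst_chrom]) - L))
        s = seqs[dst_chrom]
        seqs[dst_chrom] = s[:dst] + block + s[dst + L:]
    return seqs


# ---------------------------------------------------------------------------
# cohort truth

def _draw_disjoint_intervals(rng, chrom_lengths: Mapping[str, int], n: int,
                             lengths: np.ndarray,
                             occupied: dict[str, list[tuple[int, int]]],
                             max_tries: int = 10_000):
    """Place n intervals of the given lengths without mutual overlap."""
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed = []
    for length in lengths:
        for _ in range(max_tries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            limit = chrom_lengths[chrom] - int(length)
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            end = start + int(length)
            clashes = any(start < e and s < end for s, e in occupied.get(chrom, []))
            if not clashes:
                occupied.setdefault(chrom, []).append((start, end))
                placed.append((chrom, start, end))
                break
        else:
            raise CnvError("could not place non-overlapping interval; "
                           "genome too crowded")
    return placed


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, PhenotypeTable]:
    """Draw the truth cohort: pool CNVs, genotypes, phenotypes, effect.

    Pool CNVs are mutually non-overlapping (so per-sample truth is free of
    DEL/DUP conflicts by construction) with log-normal lengths and
    Beta-distributed allele frequencies. Each sample's genotype at each
    pool CNV is Binomial(2, af): heterozygous carriers get CN 1 (DEL) or
    3 (DUP), homozygous carriers CN 0 or 4. When ``burden_effect`` > 0
    every case additionally receives Poisson(burden_effect) private
    duplications placed outside all pool CNVs.

    Returns the truth cohort table (one row per planted event) and the
    phenotype table. The pool itself is attached as ``table.attrs["pool"]``.
    """
    rng = _rng(config, 2)
    lengths = np.exp(rng.normal(config.length_log_mean, config.length_log_sd,
                                size=config.n_pool_cnvs))
    cap = max(config.min_length,
              int(config.max_length_fraction * max(config.chromosome_lengths.values())))
    lengths = np.clip(lengths, config.min_length, cap).astype(int)
    occupied: dict[str, list[tuple[int, int]]] = {}
    placed = _draw_disjoint_intervals(rng, config.chromosome_lengths,
                                      config.n_pool_cnvs, lengths, occupied)
    svtypes = np.where(rng.random(config.n_pool_cnvs) < config.dup_fraction,
                       DUP, DEL)
    afs = rng.beta(config.af_alpha, config.af_beta, size=config.n_pool_cnvs)
    pool = pd.DataFrame(
        [(c, s, e, t, af) for (c, s, e), t, af in zip(placed, svtypes, afs)],
        columns=["chrom", "start", "end", "svtype", "allele_frequency"],
    )

    samples = config.sample_ids()
    status = ["case"] * config.n_cases + ["control"] * (config.n_samples - config.n_cases)
    groups = list(config.group_proportions)
    probs = np.array([config.group_proportions[g] for g in groups], dtype=float)
    probs /= probs.sum()
    group_assign = [groups[i] for i in rng.choice(len(groups), size=config.n_samples, p=probs)]
    phenotypes = PhenotypeTable(pd.DataFrame(
        {"sample_id": samples, "family_id": samples,
         "status": status, "group": group_assign}))

    rows = []
    genotypes = rng.binomial(2, afs[None, :].repeat(config.n_samples, axis=0))
    for i, sample in enumerate(samples):
        carried = np.flatnonzero(genotypes[i])
        for j in carried:
            g = genotypes[i, j]
            svtype = pool.at[j, "svtype"]
            cn = (1 if g == 1 else 0) if svtype == DEL else (3 if g == 1 else 4)
            rows.append((pool.at[j, "chrom"], pool.at[j, "start"],
                         pool.at[j, "end"], svtype, cn, sample, "truth"))

    if config.burden_effect > 0:
        for i, sample in enumerate(samples):
            if status[i] != "case":
                continue
            k = int(rng.poisson(config.burden_effect))
            if k == 0:
                continue
            extra_lengths = np.full(k, config.effect_length)
            sample_occupied = {c: list(v) for c, v in occupied.items()}
            extra = _draw_disjoint_intervals(rng, config.chromosome_lengths,
                                             k, extra_lengths, sample_occupied)
            cn = 3 if config.effect_svtype == DUP else 1
            for chrom, s, e in extra:
                rows.append((chrom, s, e, config.effect_svtype, cn, sample,
                             "truth-effect"))

    truth = pd.DataFrame(rows, columns=["chrom", "start", "end", "svtype",
                                        "copy_number", "sample_id", "source"])
    truth = truth.sort_values(["chrom", "start", "end", "sample_id"],
                              kind="mergesort").reset_index(drop=True)
    truth.attrs["pool"] = pool
    return truth, phenotypes


# ---------------------------------------------------------------------------
# caller noise

def simulate_caller_observations(truth: pd.DataFrame, config: SimulationConfig
                                 ) -> dict[str, dict[str, SampleCallset]]:
    """Noisy per-caller views of the truth cohort.

    Each pseudo-caller independently drops events (Bernoulli
    ``fn_rate``), jitters both breakpoints with rounded Gaussian noise of
    sd ``jitter_sd`` (clamped so length stays >= 1 and start >= 0), and
    with probability ``split_rate`` emits an event as two book-ended
    pieces — the behaviour of read-depth callers that fragment large
    CNVs. Returns ``{caller: {sample_id: SampleCallset}}``.
    """
    out: dict[str, dict[str, SampleCallset]] = {}
    for ci, caller in enumerate(config.callers):
        rng = _rng(config, 100 + ci)
        per_sample: dict[str, list[CnvCall]] = {}
        for row in truth.itertuples(index=False):
            if rng.random() < config.fn_rate:
                continue
            start = row.start
            end = row.end
            if config.jitter_sd > 0:
                start = start + int(round(rng.normal(0, config.jitter_sd)))
                end = end + int(round(rng.normal(0, config.jitter_sd)))
            start = max(0, start)
            if end <= start:
                end = start + 1
            pieces = [(start, end)]
            if end - start >= 2 and rng.random() < config.split_rate:
                cut = int(rng.integers(start + 1, end))
                pieces = [(start, cut), (cut, end)]
            for s, e in pieces:
                per_sample.setdefault(row.sample_id, []).append(
                    CnvCall(GenomicInterval(row.chrom, s, e), row.svtype,
                            int(row.copy_number), row.sample_id, caller))
        out[caller] = {
            sample: SampleCallset(sample, tuple(calls))
            for sample, calls in per_sample.items()
        }
    return out


# ---------------------------------------------------------------------------
# depth

def simulate_depth_profile(reference: Mapping[str, str],
                           config: SimulationConfig,
                           multipliers: Mapping[str, float] | None = None,
                           stream: int = 0) -> DepthTrack:
    """Per-base Poisson depth with per-chromosome multipliers.

    Mean depth is ``depth_mean`` times the chromosome's multiplier
    (1.0 = euploid, 1.5 = trisomy-like gain, 0.5 = monosomy-like loss).
    ``stream`` separates samples deterministically.
    """
    rng = _rng(config, 200 + stream)
    multipliers = multipliers or {}
    arrays = {}
    for chrom, seq in reference.items():
        mu = config.depth_mean * float(multipliers.get(chrom, 1.0))
        arrays[chrom] = rng.poisson(mu, size=len(seq))
    return DepthTrack.from_array(arrays)


# ---------------------------------------------------------------------------
# mask

def simulate_mask(config: SimulationConfig) -> MaskTrack:
    """Accessibility mask matching the configured class proportions.

    Each chromosome is tiled into 200 equal tiles; tiles are assigned to
    classes by largest-remainder apportionment of the configured
    proportions and shuffled, so class fractions are exact to tile
    rounding and classes are interleaved along the chromosome.
    """
    rng = _rng(config, 3)
    classes = list(config.mask_proportions)
    props = np.array([config.mask_proportions[c] for c in classes], dtype=float)
    props /= props.sum()
    rows = []
    n_tiles = 200
    for chrom, length in config.chromosome_lengths.items():
        ideal = props * n_tiles
        counts = np.floor(ideal).astype(int)
        remainder = n_tiles - counts.sum()
        order = np.argsort(-(ideal - counts), kind="stable")
        counts[order[:remainder]] += 1
        labels = np.repeat(classes, counts)
        rng.shuffle(labels)
        edges = np.linspace(0, length, n_tiles + 1).astype(int)
        for i, label in enumerate(labels):
            if edges[i] < edges[i + 1]:
                rows.append((chrom, int(edges[i]), int(edges[i + 1]), label))
    return MaskTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


# ---------------------------------------------------------------------------
# fixture writing

_VCF_GT = {(DEL, 1): "0/1", (DEL, 0): "1/1", (DUP, 3): "0/1", (DUP, 4): "1/1"}


def _write_vcf(path, records, samples: Sequence[str],
               chrom_lengths: Mapping[str, int]) -> None:
    """Write symbolic-ALT CNV records as a VCF 4.2 text file.

    ``records`` iterates (chrom, start, end, svtype, {sample: copy_number}).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=FT,Number=1,Type=String,Description="Genotype filter">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, start, end, svtype, cns in records:
            gts = []
            for s in samples:
                cn = cns.get(s)
                gt = _VCF_GT.get((svtype, cn), "0/0") if cn is not None else "0/0"
                gts.append(f"{gt}:PASS")
            fh.write(f"{chrom}\t{start + 1}\t.\tN\t<{svtype}>\t.\tPASS\t"
                     f"SVTYPE={svtype};END={end}\tGT:FT\t" + "\t".join(gts) + "\n")


def _truth_to_records(truth: pd.DataFrame):
    grouped: dict[tuple, dict[str, int]] = {}
    for row in truth.itertuples(index=False):
        key = (row.chrom, row.start, row.end, row.svtype)
        grouped.setdefault(key, {})[row.sample_id] = int(row.copy_number)
    for (chrom, start, end, svtype) in sorted(grouped):
        yield chrom, start, end, svtype, grouped[(chrom, start, end, svtype)]


def write_fixtures(config: SimulationConfig, directory) -> dict[str, object]:
    """Materialize a complete, self-consistent fixture directory.

    Writes the reference FASTA, the truth cohort table (TSV), a
    multi-sample genotyped CNV VCF, per-caller per-sample VCFs, windowed
    depth bedGraphs for the first ``n_depth_samples`` samples, the mask
    BED, the phenotype TSV, and a manifest recording seed and config.
    Identical config (including seed) reproduces the directory
    byte-for-byte. Returns the paths plus the in-memory objects.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    reference = simulate_reference(config)
    truth, phenotypes = simulate_cohort(config)
    observations = simulate_caller_observations(truth, config)
    mask = simulate_mask(config)

    fasta = directory / "reference.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")

    truth_path = directory / "truth_cohort.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    vcf_path = directory / "cohort.vcf"
    _write_vcf(vcf_path, _truth_to_records(truth), phenotypes.sample_ids,
               config.chromosome_lengths)

    caller_dir = directory / "callers"
    caller_paths: dict[str, dict[str, Path]] = {}
    for caller, per_sample in observations.items():
        cdir = caller_dir / caller
        cdir.mkdir(parents=True, exist_ok=True)
        caller_paths[caller] = {}
        for sample, cs in sorted(per_sample.items()):
            p = cdir / f"{sample}.vcf"
            records = [(c.chrom, c.start, c.end, c.svtype, {sample: c.copy_number})
                       for c in cs]
            _write_vcf(p, records, [sample], config.chromosome_lengths)
            caller_paths[caller][sample] = p

    depth_paths = {}
    for i, sample in enumerate(phenotypes.sample_ids[:config.n_depth_samples]):
        mult = config.aneuploid_multipliers.get(sample, {})
        track = simulate_depth_profile(reference, config, mult, stream=i)
        windowed = _window_track(track, config.depth_window)
        p = directory / f"depth_{sample}.bedgraph"
        windowed.to_bedgraph(p)
        depth_paths[sample] = p

    mask_path = directory / "mask.bed"
    mask.frame.to_csv(mask_path, sep="\t", header=False, index=False)

    pheno_path = directory / "phenotypes.tsv"
    phenotypes.frame.to_csv(pheno_path, sep="\t", index=False)

    manifest = directory / "manifest.json"
    cfg = dataclasses.asdict(config)
    cfg["chromosome_lengths"] = dict(cfg["chromosome_lengths"])
    with open(manifest, "w") as fh:
        json.dump({"seed": config.seed, "config": cfg}, fh, indent=2,
                  default=str, sort_keys=True)

    return {
        "reference": fasta, "truth": truth_path, "vcf": vcf_path,
        "callers": caller_paths, "depth": depth_paths, "mask": mask_path,
        "phenotypes": pheno_path, "manifest": manifest,
        "objects": {"reference": reference, "truth": truth,
                    "phenotypes": phenotypes, "mask": mask,
                    "observations": observations},
    }


def _window_track(track: DepthTrack, window: int) -> DepthTrack:
    """Average a per-base track into fixed windows (for compact output)."""
    runs = {}
    for chrom, (starts, ends, depths) in track.runs.items():
        length = int(ends[-1]) if len(ends) else 0
        if length == 0:
            continue
        per_base = np.zeros(length)
        for s, e, d in zip(starts, ends, depths):
            per_base[s:e] = d
        n_win = math.ceil(length / window)
        ws = np.arange(n_win) * window
        we = np.minimum(ws + window, length)
        means = np.array([per_base[s:e].mean() for s, e in zip(ws, we)])
        runs[chrom] = (ws, we, np.round(means, 3))
    return DepthTrack(runs)
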