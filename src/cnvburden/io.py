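"""Readers and writers for the formats the pipeline consumes and produces.

Conventions at the boundary:

* BED is read and written 0-based half-open, as is.
* VCF ``POS`` (1-based) becomes ``start = POS - 1``; ``INFO/END`` is taken
  as the half-open end, so internal length equals ``END - POS + 1`` in
  1-based inclusive terms.
* The PLINK six-column CNV format is written 1-based inclusive:
  ``BP1 = start + 1``, ``BP2 = end``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .model import (
    CnvCall,
    GenomicInterval,
    MaskTrack,
    OverlappingSegmentsError,
    ParseError,
    PhenotypeTable,
    SampleCallset,
    ValidationError,
    clamp_copy_number,
    svtype_for_copy_number,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_bed",
    "write_bed",
    "read_cnv_vcf",
    "vcf_to_sample_calls",
    "to_plink_cnv",
    "read_plink_cnv",
    "read_mask",
    "read_phenotypes",
    "write_phenotypes",
    "read_fasta",
    "CnvVcfRecord",
    "VcfReadResult",
]


# ---------------------------------------------------------------------------
# BED

def read_bed(path, sample_id: str = "", source: str = "bed") -> list[CnvCall]:
    """Read a CNV BED file (chrom, start, end, copy-number status, ...).

    Coordinates are 0-based half-open. The fourth column is the copy-number
    status in {0, 1, 3, 4}; the DEL/DUP type is inferred from it. Values
    above 4 / below 0 are clamped into the alphabet; copy number 2 is
    rejected (a diploid segment is not a CNV).
    """
    calls: list[CnvCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 columns, got {len(fields)}")
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                cn = clamp_copy_number(int(fields[3]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            try:
                svtype = svtype_for_copy_number(cn)
                interval = GenomicInterval(chrom, start, end)
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            calls.append(CnvCall(interval, svtype, cn, sample_id, source))
    return calls


def write_bed(calls: Iterable[CnvCall], path) -> None:
    """Write calls as 4-column BED (chrom, start, end, copy-number)."""
    ordered = sorted(calls, key=CnvCall.sort_key)
    with open(path, "w") as fh:
        for c in ordered:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.copy_number}\n")


# ---------------------------------------------------------------------------
# VCF

@dataclass(frozen=True)
class CnvVcfRecord:
    """One genotyped CNV site: interval, type, site filter and genotypes.

    ``genotypes`` maps sample id to ``(alt_allele_count, genotype_pass)``
    where alt_allele_count is 0/1/2 (or None for a missing genotype) and
    genotype_pass reflects the per-genotype FORMAT/FT field when present
    (True otherwise).
    """

    interval: GenomicInterval
    svtype: str
    filter_pass: bool
    genotypes: dict[str, tuple[int | None, bool]] = field(default_factory=dict)


@dataclass
class VcfReadResult:
    """Records kept from a CNV VCF plus bookkeeping on skipped ALTs."""

    records: list[CnvVcfRecord]
    samples: list[str]
    skipped: Counter = field(default_factory=Counter)

    def __iter__(self) -> Iterator[CnvVcfRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


_SYMBOLIC = {"<DEL>": "DEL", "DEL": "DEL", "<DUP>": "DUP", "DUP": "DUP",
             "<DUP:TANDEM>": "DUP"}


def read_cnv_vcf(path) -> VcfReadResult:
    """Read a (possibly multi-sample) genotyped CNV VCF.

    Keeps only symbolic ``<DEL>``/``<DUP>`` ALTs; other symbolic types
    (e.g. ``<INV>``) are skipped and counted. Multi-allelic records are
    split into one record per ALT. ``POS`` is converted to a 0-based start;
    ``INFO/END`` is the half-open end and is required.
    """
    from cyvcf2 import VCF  # deferred: import cost and optional at runtime

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[CnvVcfRecord] = []
    skipped: Counter = Counter()
    for var in vcf:
        alts = var.ALT or []
        sv_by_alt = {}
        for j, alt in enumerate(alts, start=1):
            svtype = _SYMBOLIC.get(alt)
            if svtype is None:
                skipped[alt] += 1
                continue
            sv_by_alt[j] = svtype
        if not sv_by_alt:
            continue
        end = var.INFO.get("END")
        if end is None:
            raise ParseError(f"{path}: record {var.CHROM}:{var.POS} lacks INFO/END")
        start = var.POS - 1
        filter_pass = var.FILTER is None  # cyvcf2: None means PASS
        ft = None
        if samples:
            try:
                ft = var.format("FT")
            except KeyError:
                ft = None
        gts = var.genotypes if samples else []
        for j, svtype in sv_by_alt.items():
            genotypes: dict[str, tuple[int | None, bool]] = {}
            for i, sample in enumerate(samples):
                alleles = [a for a in gts[i][:-1]]
                if all(a < 0 for a in alleles):
                    count: int | None = None
                else:
                    count = sum(1 for a in alleles if a == j)
                gt_pass = True
                if ft is not None:
                    val = ft[i]
                    if isinstance(val, bytes):
                        val = val.decode()
                    gt_pass = str(val) in ("PASS", ".", "None")
                genotypes[sample] = (count, gt_pass)
            records.append(
                CnvVcfRecord(
                    GenomicInterval(var.CHROM, start, int(end)),
                    svtype,
                    filter_pass,
                    genotypes,
                )
            )
    if skipped:
        logger.info("skipped non-DEL/DUP ALTs: %s", dict(skipped))
    return VcfReadResult(records, samples, skipped)


#: genotype (svtype, alt-allele count) -> copy-number status
GT_TO_CN = {("DEL", 1): 1, ("DEL", 2): 0, ("DUP", 1): 3, ("DUP", 2): 4}


def vcf_to_sample_calls(result: VcfReadResult, sample_id: str,
                        source: str = "vcf") -> SampleCallset:
    """Extract one sample's passing, non-reference calls from a read VCF.

    A call is emitted only when the genotype is non-reference *and* passes:
    both the site FILTER and the per-genotype FT field (when present) must
    be PASS. The genotype maps to copy number as DEL 0/1 -> 1, DEL 1/1 -> 0,
    DUP 0/1 -> 3, DUP 1/1 -> 4. Missing genotypes (./.) emit nothing.
    """
    if sample_id not in result.samples:
        raise ValidationError(f"sample {sample_id!r} absent from VCF")
    calls = []
    for rec in result.records:
        count, gt_pass = rec.genotypes[sample_id]
        if count is None or count == 0:
            continue
        if not (rec.filter_pass and gt_pass):
            continue
        key = (rec.svtype, count)
        if key not in GT_TO_CN:
            raise ValidationError(
                f"unsupported genotype encoding: {count} alt alleles at "
                f"{rec.interval}"
            )
        calls.append(
            CnvCall(rec.interval, rec.svtype, GT_TO_CN[key], sample_id, source)
        )
    return SampleCallset(sample_id, tuple(calls))


# ---------------------------------------------------------------------------
# PLINK six-column CNV format

def _chr_sort_key(chrom: str):
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


def _strip_chr(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def to_plink_cnv(callsets: Sequence[SampleCallset], phenotypes: PhenotypeTable | None,
                 path) -> None:
    """Write consolidated callsets in the six-column CNV layout.

    Columns are FID IID CHR BP1 BP2 CN with BP1/BP2 1-based inclusive
    (BP1 = start+1, BP2 = end) and the ``chr`` prefix stripped from CHR.
    Rows are sorted by (CHR, BP1, BP2). Family ids come from the phenotype
    table; without one the sample id doubles as family id. Refuses input
    in which any sample still carries overlapping segments, since the
    downstream association tools reject such files.
    """
    fam = phenotypes.family_of() if phenotypes is not None else {}
    rows = []
    for cs in callsets:
        if cs.has_overlaps():
            raise OverlappingSegmentsError(
                f"sample {cs.sample_id} has overlapping segments; "
                "consolidate before PLINK export"
            )
        fid = fam.get(cs.sample_id, cs.sample_id)
        for c in cs:
            rows.append(
                (fid, cs.sample_id, _strip_chr(c.chrom), c.start + 1, c.end,
                 c.copy_number, _chr_sort_key(c.chrom))
            )
    rows.sort(key=lambda r: (r[6], r[3], r[4], r[1]))
    with open(path, "w") as fh:
        for fid, iid, chrom, bp1, bp2, cn, _ in rows:
            fh.write(f"{fid}\t{iid}\t{chrom}\t{bp1}\t{bp2}\t{cn}\n")


def read_plink_cnv(path, chrom_prefix: str = "chr") -> list[SampleCallset]:
    """Parse a six-column CNV file back into per-sample callsets.

    ``chrom_prefix`` restores the naming used internally (the writer strips
    it); pass ``""`` to keep bare chromosome names.
    """
    per_sample: dict[str, list[CnvCall]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns")
            fid, iid, chrom, bp1, bp2, cn = fields
            cn_i = int(cn)
            interval = GenomicInterval(chrom_prefix + chrom, int(bp1) - 1, int(bp2))
            call = CnvCall(interval, svtype_for_copy_number(cn_i), cn_i, iid, "plink")
            per_sample.setdefault(iid, []).append(call)
    return [SampleCallset(s, tuple(cs)) for s, cs in sorted(per_sample.items())]


# ---------------------------------------------------------------------------
# Mask / phenotypes / reference / depth

def read_mask(path) -> MaskTrack:
    """Read an accessibility mask BED whose label column is in {P,N,L,H,Z}.

    The label is taken from the fourth column if it is one of the five
    class letters, otherwise from the fifth (masks in the wild often keep
    a name in column 4 and the class in column 5).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 columns")
            label = fields[3]
            if label not in ("P", "N", "L", "H", "Z") and len(fields) >= 5:
                label = fields[4]
            try:
                rows.append((fields[0], int(fields[1]), int(fields[2]), label))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return MaskTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


def read_phenotypes(path) -> PhenotypeTable:
    """Read a phenotype TSV with columns sample_id, family_id, status, group."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return PhenotypeTable(frame)


def write_phenotypes(table: PhenotypeTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA reference into an upper-cased dict of sequences."""
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}
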