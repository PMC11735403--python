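"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions are fixed here and nowhere else: VCF positions are
1-based; every interval elsewhere in the package is 0-based half-open (BED
convention). Chromosome names are taken verbatim from input — no "chr"
normalization is applied (an aliasing map can be supplied where needed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from cyvcf2 import VCF

from .errors import ConfigurationError, FormatError
from .intervals import GenomicInterval, sort_intervals

PHASE_HAPA_REF = "hapA=REF"
PHASE_HAPA_ALT = "hapA=ALT"
PHASE_UNPHASED = "unphased"


@dataclass(frozen=True)
class VariantRecord:
    """One germline variant with tumor/normal per-allele depths.

    pos is 1-based (VCF convention). phase records which allele the first
    haplotype carries, taken from a pipe-separated genotype; slash-separated
    genotypes are unphased.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    tumor_ref_depth: int
    tumor_alt_depth: int
    normal_ref_depth: int
    normal_alt_depth: int
    phase: str = PHASE_UNPHASED
    filter_pass: bool = True
    is_biallelic: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.key}")
        for d in (
            self.tumor_ref_depth,
            self.tumor_alt_depth,
            self.normal_ref_depth,
            self.normal_alt_depth,
        ):
            if d < 0:
                raise ValueError(f"negative depth at {self.key}")
        if self.phase not in (PHASE_HAPA_REF, PHASE_HAPA_ALT, PHASE_UNPHASED):
            raise ValueError(f"unknown phase {self.phase!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def indel_length(self) -> int:
        """Number of inserted or deleted bases; 0 for SNVs."""
        return abs(len(self.ref_allele) - len(self.alt_allele))


@dataclass(frozen=True)
class LoopRecord:
    """A chromatin loop: two anchors with a supporting read count and Q-value."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    read_count: int
    q_value: float

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError("loop read_count must be >= 0")
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError(f"q_value outside [0,1]: {self.q_value}")

    @property
    def intrachromosomal(self) -> bool:
        return self.anchor1.chrom == self.anchor2.chrom

    @property
    def distance(self) -> float:
        """Distance between anchor midpoints (intrachromosomal only)."""
        if not self.intrachromosomal:
            raise ValueError("distance undefined for interchromosomal loop")
        return abs(self.anchor2.midpoint - self.anchor1.midpoint)

    def normalized(self) -> "LoopRecord":
        """Return the loop with anchors in genome order."""
        a, b = self.anchor1, self.anchor2
        if (b.chrom, b.start, b.end) < (a.chrom, a.start, a.end):
            return LoopRecord(b, a, self.read_count, self.q_value)
        return self


def _phase_from_genotype(gt_allele_a: int, gt_allele_b: int, phased: bool) -> str:
    if not phased:
        return PHASE_UNPHASED
    if {gt_allele_a, gt_allele_b} != {0, 1}:
        return PHASE_UNPHASED  # hom or multi-allelic genotype carries no het phase
    return PHASE_HAPA_REF if gt_allele_a == 0 else PHASE_HAPA_ALT


def read_variant_table(
    path: str | Path,
    tumor_sample: str | None = None,
    normal_sample: str | None = None,
) -> list[VariantRecord]:
    """Read a two-sample (tumor + matched normal) VCF into VariantRecords.

    Per-allele depths come from the standard AD FORMAT field; records
    lacking it are rejected rather than imputed. Germline haplotype phase is
    taken from the normal-sample genotype (pipe separator). Multi-allelic
    sites are kept but flagged is_biallelic=False, with depths taken for the
    first ALT allele.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if tumor_sample is None and normal_sample is None:
        if len(samples) != 2:
            raise ConfigurationError(
                f"VCF has {len(samples)} samples; pass tumor_sample/normal_sample "
                f"explicitly (found: {samples})"
            )
        tumor_sample, normal_sample = samples
    for name in (tumor_sample, normal_sample):
        if name not in samples:
            raise ConfigurationError(
                f"sample column {name!r} not in VCF header (has {samples})"
            )
    t_idx = samples.index(tumor_sample)
    n_idx = samples.index(normal_sample)

    records: list[VariantRecord] = []
    for v in vcf:
        ad = v.format("AD")
        if ad is None:
            raise FormatError(
                f"record {v.CHROM}:{v.POS} lacks the AD (allele depth) FORMAT field"
            )
        alts = list(v.ALT)
        if not alts:
            continue  # no alternate allele: not a variant site for our purposes
        gt = v.genotypes[n_idx]  # [allele_a, allele_b, phased_flag]
        phase = _phase_from_genotype(int(gt[0]), int(gt[1]), bool(gt[-1]))
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref_allele=v.REF,
                alt_allele=alts[0],
                tumor_ref_depth=max(int(ad[t_idx][0]), 0),
                tumor_alt_depth=max(int(ad[t_idx][1]), 0),
                normal_ref_depth=max(int(ad[n_idx][0]), 0),
                normal_alt_depth=max(int(ad[n_idx][1]), 0),
                phase=phase,
                filter_pass=v.FILTER is None,  # cyvcf2: None means PASS/'.'
                is_biallelic=len(alts) == 1,
            )
        )
    return records


def read_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file into sorted GenomicIntervals.

    Zero-length and inverted intervals are rejected with the offending line
    number; track/browser/comment lines are skipped.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has < 3 fields")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise FormatError(
                    f"{path}:{lineno}: end ({end}) must exceed start ({start})"
                )
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            out.append(GenomicInterval(chrom, start, end, strand))
    return sort_intervals(out)


def read_named_intervals(path: str | Path) -> dict[str, GenomicInterval]:
    """Read a BED4+ file into an ordered name -> interval mapping.

    Lines lacking a name field get an autogenerated "feature<N>" name.
    """
    out: dict[str, GenomicInterval] = {}
    with open(path) as fh:
        n = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has < 3 fields")
            start, end = int(fields[1]), int(fields[2])
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end must exceed start")
            n += 1
            name = fields[3] if len(fields) >= 4 else f"feature{n}"
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            out[name] = GenomicInterval(fields[0], start, end, strand)
    return out


def write_intervals(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    """Write intervals as BED3 (or BED6 when names are given)."""
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_loops(
    path: str | Path, count_col: int = 7, q_col: int = 8
) -> list[LoopRecord]:
    """Read a BEDPE file with read-count and Q-value columns.

    count_col/q_col are 0-based column indices (defaults follow the layout
    written by write_loops: six coordinates, name, count, Q). Anchors are
    normalized so anchor1 precedes anchor2 in genome order.
    """
    out: list[LoopRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) <= max(count_col, q_col):
                raise ConfigurationError(
                    f"{path}:{lineno}: BEDPE line has {len(fields)} columns; "
                    f"count_col={count_col}, q_col={q_col} not present"
                )
            try:
                a1 = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                a2 = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
                count = int(fields[count_col])
                q = float(fields[q_col])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            out.append(LoopRecord(a1, a2, count, q).normalized())
    return out


def write_loops(loops: Iterable[LoopRecord], path: str | Path) -> None:
    """Write loops as BEDPE: six coordinates, name '.', count, Q-value."""
    with open(path, "w") as fh:
        for lp in loops:
            a1, a2 = lp.anchor1, lp.anchor2
            fh.write(
                f"{a1.chrom}\t{a1.start}\t{a1.end}\t{a2.chrom}\t{a2.start}\t{a2.end}"
                f"\t.\t{lp.read_count}\t{lp.q_value:g}\n"
            )


# --- tabular helpers -------------------------------------------------------

ALLELE_COUNT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "library_id", "mark", "ref_n", "alt_n", "other_n",
]


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated table with a header row."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, quoting=csv.QUOTE_NONE)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix whose first column is the row identifier."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True)
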