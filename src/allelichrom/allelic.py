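"""Per-library allele counting at het SNPs and the imbalance statistic r.

For a het SNP covered by one sequencing library, AF_REF = ref/(ref+alt) and
r = |AF_REF - AF_ALT| = |ref - alt| / (ref + alt): r = 0 is perfectly
balanced, r = 1 fully skewed toward one allele. Bases matching neither
germline allele accumulate in other_n and never enter the AF denominator;
a count whose other-base fraction exceeds max_other_fraction should be
treated as unreliable by callers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import UsageError
from .io import VariantRecord

logger = logging.getLogger(__name__)

MARKS = ("H3K27ac", "H3K27me3", "RNA", "WGS")

#: minimum REF+ALT reads for a count to be informative where the
#: ten-read library rule applies
DEFAULT_MIN_READS = 10

#: counts with other_n/(ref+alt+other) above this are flagged unreliable
DEFAULT_MAX_OTHER_FRACTION = 0.2


@dataclass(frozen=True)
class AlleleCount:
    """REF/ALT/other read counts at one SNP in one sequencing library."""

    chrom: str
    pos: int  # 1-based, matching the SNP record
    ref_allele: str
    alt_allele: str
    library_id: str
    mark: str
    ref_n: int
    alt_n: int
    other_n: int = 0

    def __post_init__(self) -> None:
        if min(self.ref_n, self.alt_n, self.other_n) < 0:
            raise ValueError(f"negative read count at {self.key}")
        if self.mark not in MARKS:
            raise UsageError(f"mark must be one of {MARKS}, got {self.mark!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @property
    def total(self) -> int:
        """Informative (REF+ALT) reads; other bases are excluded."""
        return self.ref_n + self.alt_n

    @property
    def af_ref(self) -> float:
        if self.total == 0:
            return math.nan
        return self.ref_n / self.total

    @property
    def af_alt(self) -> float:
        return 1.0 - self.af_ref

    def informative(self, min_reads: int = DEFAULT_MIN_READS) -> bool:
        return self.total >= min_reads

    def reliable(self, max_other_fraction: float = DEFAULT_MAX_OTHER_FRACTION) -> bool:
        """False when too many covering reads match neither germline allele."""
        grand = self.total + self.other_n
        if grand == 0:
            return False
        return self.other_n / grand <= max_other_fraction


def allelic_imbalance(count: AlleleCount) -> float:
    """The imbalance statistic r = |AF_REF - AF_ALT| in [0, 1].

    Returns NaN when there are zero informative reads; callers must treat
    NaN as uninformative.
    """
    if count.total == 0:
        return math.nan
    return abs(count.ref_n - count.alt_n) / count.total


def biased_allele(count: AlleleCount) -> str:
    """Which allele carries the majority of reads: 'REF', 'ALT' or 'none'."""
    if count.ref_n > count.alt_n:
        return "REF"
    if count.alt_n > count.ref_n:
        return "ALT"
    return "none"


def count_alleles_from_pileup(
    snps: Sequence[VariantRecord],
    pileups: Mapping[str, str],
    library_id: str,
    mark: str,
) -> list[AlleleCount]:
    """Tally REF/ALT/other from per-SNP pileup base strings.

    pileups maps "chrom:pos" to the string of read bases covering that
    position. SNPs absent from the mapping yield all-zero counts (logged),
    not an error. Only single-nucleotide alleles can be tallied from a base
    string; InDel SNPs must come from a counts table instead.
    """
    out: list[AlleleCount] = []
    for snp in snps:
        bases = pileups.get(snp.key, "")
        if not bases:
            logger.debug("no pileup for %s in %s; zero counts", snp.key, library_id)
        ref_n = sum(1 for b in bases.upper() if b == snp.ref_allele.upper())
        alt_n = sum(1 for b in bases.upper() if b == snp.alt_allele.upper())
        other_n = len(bases) - ref_n - alt_n
        out.append(
            AlleleCount(
                snp.chrom, snp.pos, snp.ref_allele, snp.alt_allele,
                library_id, mark, ref_n, alt_n, other_n,
            )
        )
    return out


def count_alleles_from_bam(
    snps: Sequence[VariantRecord],
    bam_path: str,
    library_id: str,
    mark: str,
    min_base_quality: int = 20,
) -> list[AlleleCount]:
    """Count alleles at SNV positions directly from an alignment file.

    Uses pysam's per-base coverage counts with a base-quality floor of 20
    (mirroring the variant-caller settings). Duplicate reads are assumed
    removed upstream. InDel SNPs are reported with zero counts.
    """
    import pysam  # deferred: BAM support is optional at runtime

    out: list[AlleleCount] = []
    with pysam.AlignmentFile(bam_path) as bam:
        contigs = set(bam.references)
        for snp in snps:
            if not snp.is_snv or snp.chrom not in contigs:
                logger.debug("skipping non-SNV or missing contig at %s", snp.key)
                out.append(
                    AlleleCount(snp.chrom, snp.pos, snp.ref_allele, snp.alt_allele,
                                library_id, mark, 0, 0, 0)
                )
                continue
            cov = bam.count_coverage(
                snp.chrom, snp.pos - 1, snp.pos, quality_threshold=min_base_quality
            )
            by_base = {b: int(cov[i][0]) for i, b in enumerate("ACGT")}
            ref_n = by_base.get(snp.ref_allele.upper(), 0)
            alt_n = by_base.get(snp.alt_allele.upper(), 0)
            other_n = sum(by_base.values()) - ref_n - alt_n
            out.append(
                AlleleCount(snp.chrom, snp.pos, snp.ref_allele, snp.alt_allele,
                            library_id, mark, ref_n, alt_n, other_n)
            )
    return out


def counts_from_table(df, library_id: str | None = None) -> list[AlleleCount]:
    """Build AlleleCounts from a counts table (see io.ALLELE_COUNT_COLUMNS)."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            AlleleCount(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref_allele=str(row.ref),
                alt_allele=str(row.alt),
                library_id=library_id or str(row.library_id),
                mark=str(row.mark),
                ref_n=int(row.ref_n),
                alt_n=int(row.alt_n),
                other_n=int(getattr(row, "other_n", 0)),
            )
        )
    return out


def counts_to_rows(counts: Iterable[AlleleCount]) -> list[dict]:
    """Rows for io.write_table, including r and the biased allele."""
    rows = []
    for c in counts:
        rows.append(
            {
                "chrom": c.chrom, "pos": c.pos, "ref": c.ref_allele,
                "alt": c.alt_allele, "library_id": c.library_id, "mark": c.mark,
                "ref_n": c.ref_n, "alt_n": c.alt_n, "other_n": c.other_n,
                "r": allelic_imbalance(c), "biased_allele": biased_allele(c),
            }
        )
    return rows
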