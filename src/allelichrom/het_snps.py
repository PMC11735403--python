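"""Germline heterozygous-SNP filtering on tumor/normal variant records.

A usable het SNP must be well covered in both compartments, close to 50/50
in the normal (blood) sample, not grossly skewed in the tumor, bi-allelic,
and at most a 2-bp insertion/deletion. Ratio intervals are OPEN: a blood
alt-fraction of exactly 0.3 or 0.7 is rejected. Depth thresholds are
inclusive. The variant caller's own quality filters are consumed as a
boolean pass flag; re-running the caller is out of scope here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

from .errors import DataError
from .io import (
    PHASE_HAPA_ALT,
    PHASE_HAPA_REF,
    PHASE_UNPHASED,
    VariantRecord,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HetSNPFilterConfig:
    """Thresholds for germline het-SNP selection.

    Defaults: tumor total allele depth >= 10, normal >= 7, normal
    alt-fraction in the open interval (0.3, 0.7), tumor alt-fraction in
    (0.2, 0.8), bi-allelic sites only, InDels shorter than three
    nucleotides (at most 2 inserted/deleted bases).
    """

    min_tumor_depth: int = 10
    min_normal_depth: int = 7
    normal_ratio_range: tuple[float, float] = (0.3, 0.7)
    tumor_ratio_range: tuple[float, float] = (0.2, 0.8)
    max_indel_len: int = 2
    biallelic_only: bool = True
    require_filter_pass: bool = True

    def __post_init__(self) -> None:
        for lo, hi in (self.normal_ratio_range, self.tumor_ratio_range):
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"ratio range must satisfy 0 <= lo < hi <= 1: ({lo}, {hi})")
        if self.min_tumor_depth < 0 or self.min_normal_depth < 0:
            raise ValueError("depth thresholds must be >= 0")


def alt_fraction(ref_depth: int, alt_depth: int) -> float | None:
    """ALT read fraction alt/(ref+alt); None when no informative reads."""
    total = ref_depth + alt_depth
    if total == 0:
        return None
    return alt_depth / total


def failure_reason(record: VariantRecord, cfg: HetSNPFilterConfig) -> str | None:
    """Name of the first filter the record violates, or None if it passes."""
    if cfg.require_filter_pass and not record.filter_pass:
        return "caller_qc_fail"
    if cfg.biallelic_only and not record.is_biallelic:
        return "multi_allelic"
    if record.indel_length > cfg.max_indel_len:
        return "indel_too_long"
    if record.tumor_ref_depth + record.tumor_alt_depth < cfg.min_tumor_depth:
        return "tumor_depth"
    if record.normal_ref_depth + record.normal_alt_depth < cfg.min_normal_depth:
        return "normal_depth"
    normal_af = alt_fraction(record.normal_ref_depth, record.normal_alt_depth)
    if normal_af is None:
        return "normal_zero_depth"
    lo, hi = cfg.normal_ratio_range
    if not (lo < normal_af < hi):  # open interval
        return "normal_ratio"
    tumor_af = alt_fraction(record.tumor_ref_depth, record.tumor_alt_depth)
    if tumor_af is None:
        return "tumor_zero_depth"
    lo, hi = cfg.tumor_ratio_range
    if not (lo < tumor_af < hi):
        return "tumor_ratio"
    return None


def filter_het_snps(
    records: Iterable[VariantRecord],
    cfg: HetSNPFilterConfig | None = None,
) -> list[VariantRecord]:
    """Return the records passing every het-SNP filter, order preserved.

    Records with zero informative reads in either compartment are dropped
    with a logged reason rather than raising.
    """
    cfg = cfg or HetSNPFilterConfig()
    kept: list[VariantRecord] = []
    for rec in records:
        reason = failure_reason(rec, cfg)
        if reason is None:
            kept.append(rec)
        else:
            logger.debug("dropping %s: %s", rec.key, reason)
    return kept


@dataclass(frozen=True)
class PhasedHetSNP:
    """A het SNP with each haplotype assigned one of the germline alleles."""

    record: VariantRecord
    hapA_allele: str  # "REF" or "ALT"
    hapB_allele: str

    def __post_init__(self) -> None:
        if {self.hapA_allele, self.hapB_allele} != {"REF", "ALT"}:
            raise ValueError("haplotype alleles must be exactly {REF, ALT}")

    @property
    def key(self) -> str:
        return self.record.key

    @property
    def phased(self) -> bool:
        return self.record.phase != PHASE_UNPHASED


def attach_phase(
    snps: Iterable[VariantRecord],
    phased_genotypes: Mapping[str, str] | None = None,
) -> list[PhasedHetSNP]:
    """Assign REF/ALT to haplotypes A/B from phased genotypes.

    phased_genotypes maps "chrom:pos" to a genotype string ("0|1", "1|0",
    "0/1", ...); when omitted, the phase already carried on each record is
    used. Unphased SNPs get the conventional hapA=REF orientation but are
    marked unphased (phased=False) and must be excluded from pooled
    multi-SNP haplotype computations by callers; they remain usable for
    single-SNP statistics.
    """
    out: list[PhasedHetSNP] = []
    for snp in snps:
        if phased_genotypes is not None:
            if snp.key not in phased_genotypes:
                raise DataError(f"no phased genotype supplied for {snp.key}")
            gt = phased_genotypes[snp.key]
            if gt == "0|1":
                phase = PHASE_HAPA_REF
            elif gt == "1|0":
                phase = PHASE_HAPA_ALT
            else:
                phase = PHASE_UNPHASED
            snp = replace(snp, phase=phase)
        if snp.phase == PHASE_HAPA_ALT:
            out.append(PhasedHetSNP(snp, hapA_allele="ALT", hapB_allele="REF"))
        else:
            out.append(PhasedHetSNP(snp, hapA_allele="REF", hapB_allele="ALT"))
    return out
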