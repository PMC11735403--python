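"""Trans hemizygous chromatin-state inference from paired histone marks.

H3K27ac (active) and H3K27me3 (Polycomb-repressive) are normally mutually
exclusive at a locus. When a sample carries peaks for BOTH marks over the
same region — the per-sample "hemizygous region", the base-wise intersection
of the two peak sets — the marks may sit on different alleles (in trans). A
het SNP supports that trans configuration when both libraries are strongly
imbalanced (r >= 0.6), with at least ten reads each, toward OPPOSITE
alleles. A locus is called hemizygous_trans when at least one SNP supports
trans and none supports the same-allele configuration; mixtures are
surfaced as ambiguous rather than resolved by guesswork.

SNPs below the r threshold in either library establish only that the site
is heterozygous; they are never counted as trans evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .allelic import AlleleCount, allelic_imbalance, biased_allele
from .errors import UsageError
from .intervals import GenomicInterval, intersect_intervals

R_THRESHOLD = 0.6
MIN_READS = 10

# SNP-level configurations
TRANS_BIASED = "trans_biased"
SAME_ALLELE_BIASED = "same_allele_biased"
BALANCED = "balanced"
UNINFORMATIVE = "uninformative"

# locus-level states
HEMIZYGOUS_TRANS = "hemizygous_trans"
BIALLELIC_ACTIVE = "biallelic_active"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class SNPConfiguration:
    """Joint H3K27ac/H3K27me3 allelic configuration at one het SNP."""

    snp_key: str
    r_ac: float
    r_me3: float
    bias_ac: str
    bias_me3: str
    call: str


@dataclass(frozen=True)
class LocusStateCall:
    """Per sample x locus chromatin-state classification."""

    sample_id: str
    locus: GenomicInterval
    state: str
    supporting_snps: tuple[SNPConfiguration, ...] = ()


def hemizygous_regions(
    ac_peaks: Iterable[GenomicInterval],
    me3_peaks: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Per-sample H3K27ac–H3K27me3 hemizygous region.

    The base-wise intersection of the two peak sets, merged into maximal
    intervals and sorted. Empty inputs yield an empty list.
    """
    return intersect_intervals(ac_peaks, me3_peaks)


def classify_snp_configuration(
    ac: AlleleCount,
    me3: AlleleCount,
    r_threshold: float = R_THRESHOLD,
    min_reads: int = MIN_READS,
) -> SNPConfiguration:
    """Classify one SNP from its paired H3K27ac and H3K27me3 counts.

    Decision table: (i) either library below min_reads -> uninformative;
    (ii) both r >= r_threshold (inclusive) with opposite biases ->
    trans_biased; (iii) both r >= r_threshold with the same bias ->
    same_allele_biased; (iv) otherwise -> balanced.
    """
    if ac.mark != "H3K27ac" or me3.mark != "H3K27me3":
        raise UsageError(
            f"expected marks H3K27ac/H3K27me3, got {ac.mark!r}/{me3.mark!r}"
        )
    if ac.key != me3.key:
        raise UsageError(f"counts refer to different SNPs: {ac.key} vs {me3.key}")
    r_ac = allelic_imbalance(ac)
    r_me3 = allelic_imbalance(me3)
    bias_ac = biased_allele(ac)
    bias_me3 = biased_allele(me3)
    if not (ac.informative(min_reads) and me3.informative(min_reads)):
        call = UNINFORMATIVE
    elif r_ac >= r_threshold and r_me3 >= r_threshold:
        # r >= threshold implies counts differ, so neither bias is "none"
        call = TRANS_BIASED if bias_ac != bias_me3 else SAME_ALLELE_BIASED
    else:
        call = BALANCED
    return SNPConfiguration(ac.key, r_ac, r_me3, bias_ac, bias_me3, call)


def call_locus_state(
    sample_id: str,
    locus: GenomicInterval,
    configs: Sequence[SNPConfiguration],
    ac_peak_present: bool = True,
    me3_peak_present: bool = True,
) -> LocusStateCall:
    """Aggregate SNP configurations into a per-sample locus state.

    hemizygous_trans requires peaks for both marks at the locus, >= 1
    trans_biased SNP and 0 same_allele_biased SNPs; uninformative when no
    SNP is informative; ambiguous when trans and same-allele evidence
    coexist; biallelic_active otherwise.
    """
    configs = tuple(configs)
    n_trans = sum(1 for c in configs if c.call == TRANS_BIASED)
    n_same = sum(1 for c in configs if c.call == SAME_ALLELE_BIASED)
    n_informative = sum(1 for c in configs if c.call != UNINFORMATIVE)
    if n_informative == 0:
        state = UNINFORMATIVE
    elif n_trans > 0 and n_same > 0:
        state = AMBIGUOUS
    elif n_trans > 0 and n_same == 0 and ac_peak_present and me3_peak_present:
        state = HEMIZYGOUS_TRANS
    else:
        state = BIALLELIC_ACTIVE
    return LocusStateCall(sample_id, locus, state, configs)
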