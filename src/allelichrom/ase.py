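"""Mono- vs bi-allelic expression calls and cohort-level summaries.

A gene is expressed mono-allelically in a sample when the RNA-seq reads at
its exonic germline het SNPs, pooled onto haplotypes via phase, derive at
least 90% from one haplotype (the same pooled-major-fraction rule used for
super-enhancers, inclusive at the boundary). Phase is required to pool more
than one SNP; a single covered SNP is classifiable without phase because
its major allele IS the major haplotype. Cohort summaries count assessable
(informative) samples per subgroup x gene and report the mono-allelic
percentage under an explicit rounding spec, so that printed percentages are
reproducible to the digit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .allelic import AlleleCount
from .errors import UsageError
from .het_snps import PhasedHetSNP
from .stats import enrichment_fisher, fisher_exact_2x2, group_comparison  # noqa: F401

AF_THRESHOLD = 0.9
MIN_TOTAL_READS = 10

MONOALLELIC = "monoallelic"
BIALLELIC = "biallelic"
UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class AllelicExpressionCall:
    """Per sample x gene allelic-expression classification."""

    sample_id: str
    gene_id: str
    hapA_reads: int
    hapB_reads: int
    major_af: float  # max(hapA,hapB)/total; NaN when uninformative
    call: str
    reason: str = ""


def classify_allelic_expression(
    sample_id: str,
    gene_id: str,
    phased_exonic_snps: Sequence[PhasedHetSNP],
    rna_counts: Mapping[str, AlleleCount],
    af_threshold: float = AF_THRESHOLD,
    min_total_reads: int = MIN_TOTAL_READS,
) -> AllelicExpressionCall:
    """Classify one gene in one sample from exonic het-SNP RNA counts.

    SNPs must already be restricted to the gene's exons. With a single
    covered SNP, phase is unnecessary (major allele = major haplotype);
    with several covered SNPs only phased ones can be pooled — if none are
    phased the call is uninformative rather than guessing a haplotype
    assignment.
    """
    covered = [
        (snp, rna_counts[snp.key])
        for snp in phased_exonic_snps
        if snp.key in rna_counts and rna_counts[snp.key].total > 0
    ]
    if not covered:
        return AllelicExpressionCall(
            sample_id, gene_id, 0, 0, math.nan, UNINFORMATIVE,
            reason="no exonic het SNP with RNA coverage",
        )
    if len(covered) == 1:
        snp, count = covered[0]
        if snp.hapA_allele == "REF" or not snp.phased:
            hapA, hapB = count.ref_n, count.alt_n
        else:
            hapA, hapB = count.alt_n, count.ref_n
    else:
        phased = [(s, c) for s, c in covered if s.phased]
        if not phased:
            return AllelicExpressionCall(
                sample_id, gene_id, 0, 0, math.nan, UNINFORMATIVE,
                reason="multiple covered SNPs but none phased; cannot pool",
            )
        hapA = hapB = 0
        for snp, count in phased:
            if snp.hapA_allele == "REF":
                hapA += count.ref_n
                hapB += count.alt_n
            else:
                hapA += count.alt_n
                hapB += count.ref_n
    total = hapA + hapB
    if total < min_total_reads:
        return AllelicExpressionCall(
            sample_id, gene_id, hapA, hapB, math.nan, UNINFORMATIVE,
            reason=f"pooled reads {total} < {min_total_reads}",
        )
    major_af = max(hapA, hapB) / total
    call = MONOALLELIC if major_af >= af_threshold else BIALLELIC
    return AllelicExpressionCall(sample_id, gene_id, hapA, hapB, major_af, call)


def round_percent(value: float, decimals: int | None) -> float:
    """Half-up rounding of a percentage.

    decimals=None (or 0) rounds to the nearest integer; decimals=1 to one
    decimal place. Half-up (36/65 -> 55.38 -> 55; 0.5 always rounds away
    from zero) matches how percentages are conventionally printed.
    """
    d = decimals or 0
    scale = 10 ** d
    rounded = math.floor(value * scale + 0.5) / scale
    return float(rounded)


def cohort_summary(
    calls: Sequence[AllelicExpressionCall],
    subgroup_labels: Mapping[str, str],
    rounding: Mapping[tuple[str, str], int] | int | None = None,
) -> pd.DataFrame:
    """Per subgroup x gene counts of assessable and mono-allelic samples.

    Uninformative calls are excluded from n_assessable. rounding gives the
    number of decimal places for percent_monoallelic, either globally or
    per (subgroup, gene); percentages recompute exactly from the reported
    counts.
    """
    rows: dict[tuple[str, str], dict[str, int]] = {}
    for call in calls:
        sg = subgroup_labels.get(call.sample_id)
        if sg is None:
            raise UsageError(f"no subgroup label for sample {call.sample_id!r}")
        key = (sg, call.gene_id)
        entry = rows.setdefault(key, {"n_assessable": 0, "n_monoallelic": 0})
        if call.call == UNINFORMATIVE:
            continue
        entry["n_assessable"] += 1
        if call.call == MONOALLELIC:
            entry["n_monoallelic"] += 1
    records = []
    for (sg, gene), entry in sorted(rows.items()):
        n_a = entry["n_assessable"]
        n_m = entry["n_monoallelic"]
        if isinstance(rounding, Mapping):
            decimals = rounding.get((sg, gene), 0)
        else:
            decimals = rounding
        pct = round_percent(100.0 * n_m / n_a, decimals) if n_a else 0.0
        records.append(
            {
                "subgroup": sg, "gene_id": gene,
                "n_assessable": n_a, "n_monoallelic": n_m,
                "percent_monoallelic": pct,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["subgroup", "gene_id", "n_assessable", "n_monoallelic",
                 "percent_monoallelic"],
    )


def summary_from_counts(
    n_monoallelic: int, n_assessable: int, decimals: int | None = None
) -> float:
    """Percentage mono-allelic from printed counts under the stated rounding."""
    if n_monoallelic > n_assessable:
        raise UsageError("n_monoallelic cannot exceed n_assessable")
    if n_assessable == 0:
        return 0.0
    return round_percent(100.0 * n_monoallelic / n_assessable, decimals)
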