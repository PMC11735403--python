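"""Super-enhancer stitching, ranking, consensus merging and allelic calls.

Super-enhancers (SEs) are clusters of enhancer peaks stitched together when
inter-peak gaps are at most 12.5 kb, ranked by background-adjusted H3K27ac
signal, and separated from typical enhancers at the point of the scaled
rank-signal curve where the tangent slope reaches 1 (the hockey-stick
cutoff). An SE is mono-allelic in a sample when the sample's phased het
SNPs inside the SE, pooled onto haplotypes, show at least 90% of the
informative H3K27ac reads on one haplotype — heterozygous in the genome but
effectively homozygous in the chromatin mark.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .allelic import AlleleCount
from .errors import UsageError
from .het_snps import PhasedHetSNP
from .intervals import (
    GenomicInterval,
    merge_intervals,
    stitch_clusters,
    union_length,
)

logger = logging.getLogger(__name__)

STITCH_DISTANCE = 12_500
AF_THRESHOLD = 0.9
MIN_TOTAL_READS = 10
SUBGROUPS = ("WNT", "SHH", "G3", "G4")

MONOALLELIC = "monoallelic"
BIALLELIC = "biallelic"
UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class StitchedRegion:
    """A stitched enhancer region and its constituent peaks."""

    region: GenomicInterval
    constituent_peaks: tuple[GenomicInterval, ...]


@dataclass(frozen=True)
class SuperEnhancer:
    """A ranked stitched region; rank 1 is the strongest signal."""

    region: GenomicInterval
    constituent_peaks: tuple[GenomicInterval, ...]
    signal: float
    rank: int
    is_super: bool


@dataclass(frozen=True)
class MonoallelicSECall:
    """Per-sample allelic status of one SE from pooled phased H3K27ac reads."""

    sample_id: str
    region: GenomicInterval
    hapA_reads: int
    hapB_reads: int
    normalized_af: float  # max(hapA,hapB)/(hapA+hapB); NaN when uninformative
    call: str
    reason: str = ""


def stitch_peaks(
    peaks: Iterable[GenomicInterval], stitch_distance: int = STITCH_DISTANCE
) -> list[StitchedRegion]:
    """Stitch peaks whose gaps are <= stitch_distance into regions.

    Two peaks share a region iff a chain of peaks links them with every
    inter-peak gap at most stitch_distance (gap = next.start - prev.end on
    half-open intervals, inclusive boundary). The region spans
    [min start, max end] of its members.
    """
    out = []
    for members in stitch_clusters(list(peaks), stitch_distance):
        region = GenomicInterval(
            members[0].chrom,
            min(p.start for p in members),
            max(p.end for p in members),
        )
        out.append(StitchedRegion(region, tuple(members)))
    return out


def rank_cutoff_index(signals_sorted: np.ndarray) -> int:
    """Index of the slope-1 tangent point on the scaled rank-signal curve.

    Signals must be sorted ascending. Both axes are scaled to [0, 1]; the
    cutoff is where the curve's tangent slope equals 1, located as the point
    of maximum gap below the diagonal (argmin of scaled_signal - scaled_rank).
    """
    n = len(signals_sorted)
    lo, hi = float(signals_sorted[0]), float(signals_sorted[-1])
    if hi == lo:
        # flat curve: slope never exceeds 1; by convention no region is super
        return n - 1
    y = (signals_sorted - lo) / (hi - lo)
    x = np.arange(n) / (n - 1)
    return int(np.argmin(y - x))


def rank_superenhancers(
    stitched: Sequence[StitchedRegion],
    signal_per_region: Sequence[float],
) -> list[SuperEnhancer]:
    """Rank stitched regions by signal and flag those above the knee.

    signal_per_region aligns with stitched and should already be
    input-subtracted where a background library is available. Regions with
    signal strictly above the cutoff signal are super. With fewer than 3
    regions the curve is undefined and all regions are flagged super with a
    warning.
    """
    if len(stitched) != len(signal_per_region):
        raise UsageError("one signal value per stitched region is required")
    n = len(stitched)
    if n == 0:
        return []
    signals = np.asarray(signal_per_region, dtype=float)
    order_desc = np.argsort(-signals, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order_desc] = np.arange(1, n + 1)
    if n < 3:
        logger.warning("fewer than 3 regions: rank curve undefined, all flagged super")
        super_flags = np.ones(n, dtype=bool)
    else:
        asc = np.sort(signals)
        cutoff_signal = asc[rank_cutoff_index(asc)]
        super_flags = signals > cutoff_signal
    return [
        SuperEnhancer(
            region=sr.region,
            constituent_peaks=sr.constituent_peaks,
            signal=float(signals[i]),
            rank=int(ranks[i]),
            is_super=bool(super_flags[i]),
        )
        for i, sr in enumerate(stitched)
    ]


def merge_subgroup_ses(
    per_sample_ses: Mapping[str, Sequence[GenomicInterval]],
    min_recurrence: int = 2,
) -> list[GenomicInterval]:
    """Consensus SE regions recurrent within one subgroup.

    SEs from all samples are clustered by genomic overlap (transitive);
    clusters supported by at least min_recurrence distinct samples are
    reported as the genomic union of their members.
    """
    tagged: list[tuple[GenomicInterval, str]] = []
    for sample_id, ses in per_sample_ses.items():
        for se in ses:
            tagged.append((se, sample_id))
    if not tagged:
        return []
    intervals = [iv for iv, _ in tagged]
    by_identity: dict[tuple, list[str]] = {}
    for iv, sample in tagged:
        by_identity.setdefault((iv.chrom, iv.start, iv.end), []).append(sample)
    out: list[GenomicInterval] = []
    # max_gap=-1 makes the chain condition next.start < prev.end: true overlap
    for members in stitch_clusters(intervals, max_gap=-1):
        samples = set()
        for m in members:
            samples.update(by_identity[(m.chrom, m.start, m.end)])
        if len(samples) >= min_recurrence:
            out.extend(merge_intervals(members))
    return out


def classify_monoallelic_se(
    sample_id: str,
    se_region: GenomicInterval,
    phased_snps: Sequence[PhasedHetSNP],
    ac_counts: Mapping[str, AlleleCount],
    af_threshold: float = AF_THRESHOLD,
    min_total_reads: int = MIN_TOTAL_READS,
) -> MonoallelicSECall:
    """Call an SE mono-allelic from pooled phased H3K27ac allele counts.

    Phased WGS-heterozygous SNPs inside the SE contribute their REF/ALT
    H3K27ac reads to haplotypes A/B via their phase; counts are summed
    across SNPs and normalized_af = max(hapA, hapB) / (hapA + hapB). The
    call is monoallelic iff normalized_af >= af_threshold (inclusive),
    uninformative when no phased SNP has coverage or the pooled total is
    below min_total_reads.
    """
    hapA = hapB = 0
    n_used = 0
    for snp in phased_snps:
        if not snp.phased:
            continue
        if not se_region.contains_point(snp.record.chrom, snp.record.pos - 1):
            continue
        count = ac_counts.get(snp.key)
        if count is None or count.total == 0:
            continue
        if snp.hapA_allele == "REF":
            hapA += count.ref_n
            hapB += count.alt_n
        else:
            hapA += count.alt_n
            hapB += count.ref_n
        n_used += 1
    total = hapA + hapB
    if n_used == 0:
        return MonoallelicSECall(
            sample_id, se_region, 0, 0, math.nan, UNINFORMATIVE,
            reason="no phased het SNP with H3K27ac coverage in SE",
        )
    if total < min_total_reads:
        return MonoallelicSECall(
            sample_id, se_region, hapA, hapB, math.nan, UNINFORMATIVE,
            reason=f"pooled reads {total} < {min_total_reads}",
        )
    af = max(hapA, hapB) / total
    call = MONOALLELIC if af >= af_threshold else BIALLELIC
    return MonoallelicSECall(sample_id, se_region, hapA, hapB, af, call)


def recurrent_monoallelic_ses(
    calls: Sequence[MonoallelicSECall],
    subgroup_labels: Mapping[str, str],
    n_g4: int = 3,
    n_other: int = 2,
    subgroups: Sequence[str] = SUBGROUPS,
) -> dict[str, list[GenomicInterval]]:
    """SEs recurrently mono-allelic per subgroup.

    An SE is reported for a subgroup when it is called monoallelic in at
    least n_g4 samples for G4 and n_other samples for every other subgroup.
    """
    counts: dict[str, dict[tuple, int]] = {sg: {} for sg in subgroups}
    regions: dict[tuple, GenomicInterval] = {}
    for call in calls:
        sg = subgroup_labels.get(call.sample_id)
        if sg not in subgroups:
            raise UsageError(
                f"unknown subgroup label {sg!r} for sample {call.sample_id!r}"
            )
        if call.call != MONOALLELIC:
            continue
        key = (call.region.chrom, call.region.start, call.region.end)
        regions[key] = call.region
        counts[sg][key] = counts[sg].get(key, 0) + 1
    out: dict[str, list[GenomicInterval]] = {}
    for sg in subgroups:
        threshold = n_g4 if sg == "G4" else n_other
        out[sg] = sorted(
            (regions[k] for k, n in counts[sg].items() if n >= threshold),
            key=lambda iv: (iv.chrom, iv.start, iv.end),
        )
    return out


def genome_coverage(
    peaks: Iterable[GenomicInterval], genome_length: int
) -> tuple[int, float]:
    """Number of peaks and the fraction of the genome their union covers."""
    peaks = list(peaks)
    if genome_length <= 0:
        raise UsageError("genome_length must be positive")
    return len(peaks), union_length(peaks) / genome_length
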