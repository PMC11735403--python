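"""Subgroup-specific peak categorization across a labeled cohort.

Two complementary notions of subgroup specificity: a subgroup-ENRICHED peak
carries significantly higher normalized read counts in the target subgroup
than in each comparison subgroup (one-sided rank-sum per comparison, BH
across peaks, q < 0.05, median fold-change >= 2 by default); a
subgroup-RECURRENT peak is simply called in enough target samples and in
(almost) no samples of any other subgroup, regardless of average signal.
Shared categories (e.g. SHH/WNT) are peaks enriched against the two distant
subgroups but not against the partner subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UsageError
from .intervals import GenomicInterval
from .stats import bh_adjust

SUBGROUPS = ("WNT", "SHH", "G3", "G4")


@dataclass
class PeakPresenceMatrix:
    """Consensus peaks x samples: boolean presence plus normalized counts.

    presence and counts share index (peak keys "chrom:start-end") and
    columns (sample ids); labels maps each sample to its subgroup.
    """

    peaks: list[GenomicInterval]
    presence: pd.DataFrame
    counts: pd.DataFrame
    labels: dict[str, str]

    def __post_init__(self) -> None:
        if list(self.presence.index) != [str(p) for p in self.peaks]:
            raise UsageError("presence index must match peak keys in order")
        if list(self.presence.columns) != list(self.counts.columns):
            raise UsageError("presence and counts must share sample columns")
        if (self.counts.to_numpy() < 0).any():
            raise UsageError("counts must be non-negative")
        unknown = set(self.labels.values()) - set(SUBGROUPS)
        if unknown:
            raise UsageError(f"unknown subgroup labels: {sorted(unknown)}")

    def samples_in(self, subgroup: str) -> list[str]:
        return [s for s in self.presence.columns if self.labels.get(s) == subgroup]

    def subset(self, peak_keys: Sequence[str]) -> "PeakPresenceMatrix":
        keep = set(peak_keys)
        mask = [str(p) in keep for p in self.peaks]
        return PeakPresenceMatrix(
            peaks=[p for p, m in zip(self.peaks, mask) if m],
            presence=self.presence.loc[mask],
            counts=self.counts.loc[mask],
            labels=dict(self.labels),
        )


@dataclass(frozen=True)
class EnrichmentTestConfig:
    """Parameters of the subgroup-enrichment test.

    The test itself is swappable; the default is a one-sided rank-sum per
    comparison subgroup with BH correction across peaks and a median
    fold-change floor. A pseudocount stabilizes fold changes at zero
    medians. cpm_normalize converts raw counts to counts-per-million within
    the peak universe before testing.
    """

    q_threshold: float = 0.05
    min_fold_change: float = 2.0
    pseudocount: float = 0.5
    cpm_normalize: bool = True
    min_group_size: int = 3


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million library-size normalization within the peak universe."""
    totals = counts.sum(axis=0)
    totals = totals.replace(0, 1)
    return counts.div(totals, axis=1) * 1e6


def global_peak_filter(
    matrix: PeakPresenceMatrix, min_samples: int = 2
) -> PeakPresenceMatrix:
    """Drop peaks called in fewer than min_samples samples cohort-wide."""
    n_present = matrix.presence.sum(axis=1)
    keep = n_present[n_present >= min_samples].index
    return matrix.subset(list(keep))


def _rank_sum_greater(target: np.ndarray, other: np.ndarray) -> float:
    if np.unique(np.concatenate([target, other])).size == 1:
        return 1.0  # all values identical: no evidence either way
    return float(sps.mannwhitneyu(target, other, alternative="greater").pvalue)


def enrichment_qvalues(
    matrix: PeakPresenceMatrix,
    target_subgroup: str,
    cfg: EnrichmentTestConfig | None = None,
) -> pd.DataFrame:
    """Per-peak BH q-values and fold changes of target vs each other subgroup.

    Returns a DataFrame indexed by peak key with columns q_<sg> and fc_<sg>
    for every non-target subgroup present in the cohort.
    """
    cfg = cfg or EnrichmentTestConfig()
    target_samples = matrix.samples_in(target_subgroup)
    if len(target_samples) < cfg.min_group_size:
        raise UsageError(
            f"subgroup {target_subgroup} has {len(target_samples)} samples; "
            f">= {cfg.min_group_size} required"
        )
    counts = cpm(matrix.counts) if cfg.cpm_normalize else matrix.counts
    tgt = counts[target_samples].to_numpy()
    out = pd.DataFrame(index=counts.index)
    for sg in SUBGROUPS:
        if sg == target_subgroup:
            continue
        comp_samples = matrix.samples_in(sg)
        if not comp_samples:
            continue
        if len(comp_samples) < cfg.min_group_size:
            raise UsageError(
                f"comparison subgroup {sg} has {len(comp_samples)} samples; "
                f">= {cfg.min_group_size} required"
            )
        comp = counts[comp_samples].to_numpy()
        pvals = np.array(
            [_rank_sum_greater(tgt[i], comp[i]) for i in range(counts.shape[0])]
        )
        fc = (np.median(tgt, axis=1) + cfg.pseudocount) / (
            np.median(comp, axis=1) + cfg.pseudocount
        )
        out[f"q_{sg}"] = bh_adjust(pvals)
        out[f"fc_{sg}"] = fc
    return out


def subgroup_enriched_peaks(
    matrix: PeakPresenceMatrix,
    target_subgroup: str,
    cfg: EnrichmentTestConfig | None = None,
) -> list[str]:
    """Peaks enriched in the target subgroup against EVERY other subgroup."""
    cfg = cfg or EnrichmentTestConfig()
    table = enrichment_qvalues(matrix, target_subgroup, cfg)
    comparisons = [c[2:] for c in table.columns if c.startswith("q_")]
    if not comparisons:
        return []
    mask = pd.Series(True, index=table.index)
    for sg in comparisons:
        mask &= (table[f"q_{sg}"] < cfg.q_threshold) & (
            table[f"fc_{sg}"] >= cfg.min_fold_change
        )
    return list(table.index[mask])


def shared_subgroup_peaks(
    matrix: PeakPresenceMatrix,
    target_subgroup: str,
    partner_subgroup: str,
    cfg: EnrichmentTestConfig | None = None,
) -> list[str]:
    """Peaks shared by a subgroup pair (e.g. SHH/WNT or G3/G4).

    Enriched in the target against every subgroup except the partner, but
    NOT enriched against the partner.
    """
    cfg = cfg or EnrichmentTestConfig()
    table = enrichment_qvalues(matrix, target_subgroup, cfg)
    comparisons = [c[2:] for c in table.columns if c.startswith("q_")]
    if partner_subgroup not in comparisons:
        raise UsageError(f"partner subgroup {partner_subgroup} not in cohort")
    mask = pd.Series(True, index=table.index)
    for sg in comparisons:
        enriched_vs_sg = (table[f"q_{sg}"] < cfg.q_threshold) & (
            table[f"fc_{sg}"] >= cfg.min_fold_change
        )
        mask &= ~enriched_vs_sg if sg == partner_subgroup else enriched_vs_sg
    return list(table.index[mask])


def subgroup_recurrent_peaks(
    matrix: PeakPresenceMatrix,
    target_subgroup: str,
    min_in: int = 3,
    max_out: int = 0,
) -> list[str]:
    """Peaks present in >= min_in target samples and <= max_out samples of
    every other subgroup."""
    target_samples = matrix.samples_in(target_subgroup)
    in_count = matrix.presence[target_samples].sum(axis=1)
    mask = in_count >= min_in
    for sg in SUBGROUPS:
        if sg == target_subgroup:
            continue
        other_samples = matrix.samples_in(sg)
        if other_samples:
            mask &= matrix.presence[other_samples].sum(axis=1) <= max_out
    return list(matrix.presence.index[mask])


def build_presence_matrix(
    peaks: Sequence[GenomicInterval],
    per_sample_peaks: Mapping[str, Sequence[GenomicInterval]],
    counts: pd.DataFrame,
    labels: Mapping[str, str],
) -> PeakPresenceMatrix:
    """Assemble the presence matrix from per-sample peak calls.

    A consensus peak is present in a sample when it overlaps any of the
    sample's called peaks.
    """
    samples = list(counts.columns)
    presence = pd.DataFrame(
        False, index=[str(p) for p in peaks], columns=samples, dtype=bool
    )
    for sample, sample_peaks in per_sample_peaks.items():
        if sample not in presence.columns:
            continue
        for i, peak in enumerate(peaks):
            if any(peak.overlaps(sp) for sp in sample_peaks):
                presence.iloc[i, presence.columns.get_loc(sample)] = True
    return PeakPresenceMatrix(list(peaks), presence, counts, dict(labels))
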