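"""Enhancer-promoter loop filtering and significantly correlated loop calls.

High-confidence chromatin loops (intrachromosomal, Q < 0.01, more than 5
supporting reads, anchor distance between 5 kb and 20 Mb) are linked to
(enhancer, gene) pairs when an enhancer interval overlaps one anchor and a
gene promoter (TSS +/- 2 kb) overlaps the other. A pair becomes a
significantly correlated loop (SCL) when the enhancer's H3K27ac signal
correlates POSITIVELY with the target gene's expression across samples at
Benjamini-Hochberg adjusted P < 0.1; significant negative correlations are
reported but never flagged as SCLs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, UsageError
from .intervals import GenomicInterval
from .io import LoopRecord
from .stats import bh_adjust

Q_MAX = 0.01
MIN_COUNT_EXCLUSIVE = 5
MIN_DIST = 5_000
MAX_DIST = 20_000_000
PROMOTER_HALFWIDTH = 2_000
SCL_ALPHA = 0.1


@dataclass(frozen=True)
class GeneAnnotation:
    """Minimal gene model: the TSS locates the promoter."""

    gene_id: str
    chrom: str
    tss: int  # 0-based position of the transcription start site
    strand: str = "."

    def promoter(self, halfwidth: int = PROMOTER_HALFWIDTH) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, max(self.tss - halfwidth, 0), self.tss + halfwidth, self.strand
        )


@dataclass(frozen=True)
class EnhancerPromoterPair:
    loop: LoopRecord
    enhancer: GenomicInterval
    gene_id: str
    promoter: GenomicInterval

    @property
    def distance(self) -> float:
        return self.loop.distance

    @property
    def key(self) -> str:
        return f"{self.enhancer}|{self.gene_id}"


@dataclass(frozen=True)
class SCLCall:
    pair: EnhancerPromoterPair
    pearson_r: float
    p_raw: float
    p_adjusted: float
    is_scl: bool


def filter_loops(
    loops: Iterable[LoopRecord],
    q_max: float = Q_MAX,
    min_count_exclusive: int = MIN_COUNT_EXCLUSIVE,
    min_dist: int = MIN_DIST,
    max_dist: int = MAX_DIST,
) -> list[LoopRecord]:
    """High-confidence loop filter.

    Survivors are intrachromosomal with Q strictly below q_max, read count
    strictly above min_count_exclusive, and anchor-midpoint distance within
    [min_dist, max_dist].
    """
    out = []
    for lp in loops:
        if not lp.intrachromosomal:
            continue
        if not (lp.q_value < q_max):
            continue
        if not (lp.read_count > min_count_exclusive):
            continue
        if not (min_dist <= lp.distance <= max_dist):
            continue
        out.append(lp)
    return out


def link_enhancer_promoter(
    loops: Sequence[LoopRecord],
    enhancers: Sequence[GenomicInterval],
    gene_annotations: Sequence[GeneAnnotation],
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
) -> list[EnhancerPromoterPair]:
    """Emit one pair per (enhancer, gene) bridged by a loop.

    The enhancer must overlap one anchor and the gene promoter the OTHER
    anchor; a feature pair sharing a single anchor is not an interaction.
    One enhancer may target several genes and one gene may receive several
    enhancers. Both anchor orientations are tried.
    """
    promoters = [(g, g.promoter(promoter_halfwidth)) for g in gene_annotations]
    pairs: list[EnhancerPromoterPair] = []
    for lp in loops:
        for enh in enhancers:
            on_a1 = enh.overlaps(lp.anchor1)
            on_a2 = enh.overlaps(lp.anchor2)
            if not (on_a1 or on_a2):
                continue
            for gene, prom in promoters:
                if on_a1 and prom.overlaps(lp.anchor2):
                    pairs.append(EnhancerPromoterPair(lp, enh, gene.gene_id, prom))
                elif on_a2 and prom.overlaps(lp.anchor1):
                    pairs.append(EnhancerPromoterPair(lp, enh, gene.gene_id, prom))
    return pairs


def _pair_vectors(
    pair: EnhancerPromoterPair,
    enhancer_signal: pd.DataFrame,
    expression: pd.DataFrame,
    samples: list[str],
) -> tuple[np.ndarray, np.ndarray] | None:
    enh_key = str(pair.enhancer)
    if enh_key not in enhancer_signal.index or pair.gene_id not in expression.index:
        return None
    x = enhancer_signal.loc[enh_key, samples].to_numpy(dtype=float)
    y = expression.loc[pair.gene_id, samples].to_numpy(dtype=float)
    return x, y


def call_scl(
    pairs: Sequence[EnhancerPromoterPair],
    enhancer_signal: pd.DataFrame,
    expression: pd.DataFrame,
    alpha: float = SCL_ALPHA,
    min_samples: int = 5,
) -> list[SCLCall]:
    """Correlate enhancer signal with target-gene expression across samples.

    Pearson correlation per pair over the shared sample columns, two-sided
    p-values, BH adjustment across all TESTED pairs; is_scl iff r > 0 and
    adjusted p < alpha. Pairs with a zero-variance vector (or missing rows)
    are untestable: reported with NaN statistics and excluded from the BH
    family.
    """
    samples = [s for s in enhancer_signal.columns if s in set(expression.columns)]
    if len(samples) < min_samples:
        raise DataError(
            f"only {len(samples)} shared samples between matrices; "
            f">= {min_samples} required"
        )
    testable_idx: list[int] = []
    r_vals: list[float] = []
    p_vals: list[float] = []
    per_pair: list[tuple[float, float] | None] = []
    for i, pair in enumerate(pairs):
        vecs = _pair_vectors(pair, enhancer_signal, expression, samples)
        if vecs is None or np.std(vecs[0]) == 0 or np.std(vecs[1]) == 0:
            per_pair.append(None)
            continue
        r, p = sps.pearsonr(vecs[0], vecs[1])
        per_pair.append((float(r), float(p)))
        testable_idx.append(i)
        r_vals.append(float(r))
        p_vals.append(float(p))
    adjusted = bh_adjust(p_vals)
    adj_by_idx = {i: float(q) for i, q in zip(testable_idx, adjusted)}
    calls: list[SCLCall] = []
    for i, pair in enumerate(pairs):
        stats_i = per_pair[i]
        if stats_i is None:
            calls.append(SCLCall(pair, math.nan, math.nan, math.nan, False))
            continue
        r, p = stats_i
        q = adj_by_idx[i]
        calls.append(SCLCall(pair, r, p, q, bool(r > 0 and q < alpha)))
    return calls


def read_gene_annotations(df: pd.DataFrame) -> list[GeneAnnotation]:
    """Gene table with columns gene_id, chrom, tss[, strand]."""
    required = {"gene_id", "chrom", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise UsageError(f"gene table missing columns: {sorted(missing)}")
    has_strand = "strand" in df.columns
    return [
        GeneAnnotation(
            str(row.gene_id), str(row.chrom), int(row.tss),
            str(row.strand) if has_strand else ".",
        )
        for row in df.itertuples(index=False)
    ]
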