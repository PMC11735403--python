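"""End-to-end orchestration: from a file bundle to per-sample locus reports.

The pipeline runs the allele-specific stages sample by sample — het-SNP
filtering, phased allele counts, chromatin-state inference at each assessed
locus, mono-allelic SE calls, mono-allelic expression calls — and then
aggregates per-subgroup proportions. Evidence channels are reported side by
side, never collapsed into a single label: the chromatin, SE and RNA calls
for a sample can legitimately disagree (a gene may show mono-allelic
expression without detectable repressive-mark deposition), so the combined
category simply concatenates the three channels at the focal locus.

Every threshold actually applied is logged once at run start so the
provenance of each decision is auditable from the log alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ase, chromatin, superenhancers as se_mod
from .allelic import AlleleCount, counts_from_table
from .errors import ConfigurationError, DataError
from .het_snps import HetSNPFilterConfig, attach_phase, filter_het_snps
from .intervals import GenomicInterval
from .io import read_named_intervals, read_table, read_variant_table, write_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the end-to-end run, with their defaults.

    Thresholds restate the per-module defaults: r >= 0.6 with >= 10 reads
    per library for trans SNP evidence; pooled major-haplotype fraction
    >= 0.9 with >= 10 pooled reads for mono-allelic SE and RNA calls.
    """

    input_dir: str = "."
    output_dir: str = "out"
    seed: int = 0
    r_threshold: float = 0.6
    min_reads_per_library: int = 10
    af_threshold_se: float = 0.9
    af_threshold_rna: float = 0.9
    min_pooled_reads: int = 10
    het_filter: HetSNPFilterConfig = field(default_factory=HetSNPFilterConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "het_filter" in raw:
            raw["het_filter"] = HetSNPFilterConfig(**raw["het_filter"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (0.0 <= self.r_threshold <= 1.0):
            raise ConfigurationError("r_threshold must lie in [0,1]")
        for t in (self.af_threshold_se, self.af_threshold_rna):
            if not (0.5 <= t <= 1.0):
                raise ConfigurationError("AF thresholds must lie in [0.5,1]")
        if self.min_reads_per_library < 0 or self.min_pooled_reads < 0:
            raise ConfigurationError("read minimums must be >= 0")


@dataclass
class PipelineReport:
    per_sample: pd.DataFrame  # focal-locus channel summary, one row per sample
    calls: pd.DataFrame  # long table: every sample x feature x channel call
    cohort: pd.DataFrame  # per-subgroup proportions per channel

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(self.per_sample, outdir / "report_per_sample.tsv")
        write_table(self.calls, outdir / "report_calls.tsv")
        write_table(self.cohort, outdir / "report_cohort.tsv")


def _counts_by_key(counts: list[AlleleCount]) -> dict[str, AlleleCount]:
    return {c.key: c for c in counts}


def _log_thresholds(cfg: PipelineConfig) -> None:
    logger.info("threshold r_threshold=%s (trans SNP evidence)", cfg.r_threshold)
    logger.info("threshold min_reads_per_library=%s", cfg.min_reads_per_library)
    logger.info("threshold af_threshold_se=%s", cfg.af_threshold_se)
    logger.info("threshold af_threshold_rna=%s", cfg.af_threshold_rna)
    logger.info("threshold min_pooled_reads=%s", cfg.min_pooled_reads)
    logger.info("het filter %s", cfg.het_filter)


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Run every stage over the bundle in cfg.input_dir and write reports.

    Expects the bundle layout written by the synthetic-cohort generator (or
    assembled by hand to match): samples.tsv plus per-sample VCF, peak BEDs
    and per-mark count TSVs, with chromatin_loci.bed, se_regions.bed and
    gene_exons.bed naming the assessed features.
    """
    cfg.validate()
    _log_thresholds(cfg)
    indir = Path(cfg.input_dir)
    samples_path = indir / "samples.tsv"
    if not samples_path.exists():
        raise DataError(f"samples table not found: {samples_path}")
    samples = read_table(samples_path)
    if samples.empty:
        logger.warning("empty cohort: emitting empty report")
        empty_cols_ps = ["sample_id", "subgroup", "chromatin_state", "se_call",
                         "rna_call", "combined"]
        report = PipelineReport(
            per_sample=pd.DataFrame(columns=empty_cols_ps),
            calls=pd.DataFrame(columns=["sample_id", "subgroup", "channel",
                                        "feature", "call"]),
            cohort=pd.DataFrame(columns=["subgroup", "channel", "n_informative",
                                         "n_positive", "proportion"]),
        )
        report.write(cfg.output_dir)
        return report

    loci = read_named_intervals(indir / "chromatin_loci.bed")
    ses = read_named_intervals(indir / "se_regions.bed")
    genes = read_named_intervals(indir / "gene_exons.bed")
    focal_locus = next(iter(loci), None)
    focal_se = next(iter(ses), None)
    focal_gene = next(iter(genes), None)

    call_rows = []
    per_sample_rows = []
    for row in samples.itertuples(index=False):
        sid, subgroup = str(row.sample_id), str(row.subgroup)
        try:
            channel_calls = _run_sample(cfg, indir, sid, loci, ses, genes)
        except Exception as exc:
            raise DataError(f"stage failure for sample {sid}: {exc}") from exc
        for channel, feature, call in channel_calls:
            call_rows.append({"sample_id": sid, "subgroup": subgroup,
                              "channel": channel, "feature": feature, "call": call})
        by_cf = {(c, f): call for c, f, call in channel_calls}
        ch = by_cf.get(("chromatin", focal_locus), "uninformative")
        se = by_cf.get(("se", focal_se), "uninformative")
        rna = by_cf.get(("rna", focal_gene), "uninformative")
        per_sample_rows.append({
            "sample_id": sid, "subgroup": subgroup, "chromatin_state": ch,
            "se_call": se, "rna_call": rna,
            "combined": f"chromatin:{ch}|SE:{se}|RNA:{rna}",
        })

    calls = pd.DataFrame.from_records(call_rows)
    per_sample = pd.DataFrame.from_records(per_sample_rows)
    cohort = _cohort_proportions(calls)
    report = PipelineReport(per_sample, calls, cohort)
    report.write(cfg.output_dir)
    return report


def _run_sample(
    cfg: PipelineConfig,
    indir: Path,
    sid: str,
    loci: dict[str, GenomicInterval],
    ses: dict[str, GenomicInterval],
    genes: dict[str, GenomicInterval],
) -> list[tuple[str, str, str]]:
    variants = read_variant_table(indir / f"{sid}.vcf", "TUMOR", "NORMAL")
    het = filter_het_snps(variants, cfg.het_filter)
    phased = attach_phase(het)
    ac_peaks = _read_bed_plain(indir / f"{sid}.h3k27ac_peaks.bed")
    me3_peaks = _read_bed_plain(indir / f"{sid}.h3k27me3_peaks.bed")
    ac_counts = _counts_by_key(counts_from_table(read_table(indir / f"{sid}.h3k27ac_counts.tsv")))
    me3_counts = _counts_by_key(counts_from_table(read_table(indir / f"{sid}.h3k27me3_counts.tsv")))
    rna_counts = _counts_by_key(counts_from_table(read_table(indir / f"{sid}.rna_counts.tsv")))

    out: list[tuple[str, str, str]] = []
    for name, locus in loci.items():
        ac_present = any(locus.overlaps(p) for p in ac_peaks)
        me3_present = any(locus.overlaps(p) for p in me3_peaks)
        configs = []
        if ac_present and me3_present:
            hemi = chromatin.hemizygous_regions(
                [p for p in ac_peaks if locus.overlaps(p)],
                [p for p in me3_peaks if locus.overlaps(p)],
            )
            for snp in het:
                pos0 = snp.pos - 1
                if not any(h.contains_point(snp.chrom, pos0) for h in hemi):
                    continue
                ac = ac_counts.get(snp.key)
                me3 = me3_counts.get(snp.key)
                if ac is None or me3 is None:
                    continue
                configs.append(
                    chromatin.classify_snp_configuration(
                        ac, me3, cfg.r_threshold, cfg.min_reads_per_library
                    )
                )
        state = chromatin.call_locus_state(sid, locus, configs, ac_present, me3_present)
        out.append(("chromatin", name, state.state))

    for name, region in ses.items():
        call = se_mod.classify_monoallelic_se(
            sid, region, phased, ac_counts,
            cfg.af_threshold_se, cfg.min_pooled_reads,
        )
        out.append(("se", name, call.call))

    for name, exon in genes.items():
        exonic = [
            s for s in phased
            if exon.contains_point(s.record.chrom, s.record.pos - 1)
        ]
        call = ase.classify_allelic_expression(
            sid, name, exonic, rna_counts,
            cfg.af_threshold_rna, cfg.min_pooled_reads,
        )
        out.append(("rna", name, call.call))
    return out


def _read_bed_plain(path: Path) -> list[GenomicInterval]:
    from .io import read_intervals

    return read_intervals(path)


_POSITIVE = {"chromatin": chromatin.HEMIZYGOUS_TRANS, "se": se_mod.MONOALLELIC,
             "rna": ase.MONOALLELIC}


def _cohort_proportions(calls: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (subgroup, channel), grp in calls.groupby(["subgroup", "channel"], sort=True):
        informative = grp[~grp["call"].isin(["uninformative", "ambiguous"])]
        n_inf = len(informative)
        n_pos = int((informative["call"] == _POSITIVE[channel]).sum())
        rows.append({
            "subgroup": subgroup, "channel": channel, "n_informative": n_inf,
            "n_positive": n_pos,
            "proportion": (n_pos / n_inf) if n_inf else float("nan"),
        })
    return pd.DataFrame.from_records(
        rows, columns=["subgroup", "channel", "n_informative", "n_positive", "proportion"]
    )
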