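"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates a tumor cohort profiled with WGS (tumor + matched
blood), H3K27ac and H3K27me3 ChIP-seq, RNA-seq, and an enhancer-promoter
loop set, on a toy diploid genome. Reads at het SNPs are binomially sampled
around a per-haplotype allele fraction: 0.5 for balanced (bi-allelic)
features, 0.95 for skewed (mono-allelic / trans hemizygous) ones — no
overdispersion by default, so recovery benchmarks have tight, predictable
operating characteristics (real ChIP data are noisier; see the methods
note). All randomness flows from a single integer seed and the emitted
files are byte-identical across runs with the same config.

Layout of the toy genome (2 x 1 Mb by default): chromatin-state loci and
gene exons live on the first chromosome, super-enhancers on the second;
the loop/correlation block carries its own enhancer and promoter features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import chromatin, superenhancers as se_mod, ase
from .errors import ConfigurationError, DataError
from .intervals import GenomicInterval
from .io import (
    PHASE_HAPA_ALT,
    PHASE_HAPA_REF,
    LoopRecord,
    VariantRecord,
    write_intervals,
    write_loops,
    write_matrix,
    write_table,
)
from .allelic import AlleleCount
from .het_snps import PhasedHetSNP

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SCLBlockConfig:
    """The loop-correlation block: independent of the ChIP cohort samples."""

    n_pairs: int = 1000
    n_planted: int = 100
    r_true: float = 0.8
    n_samples: int = 30


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_samples_per_subgroup: Mapping[str, int] = field(
        default_factory=lambda: {"WNT": 4, "SHH": 8, "G3": 8, "G4": 10}
    )
    toy_genome: tuple[tuple[str, int], ...] = (("chr1", 1_000_000), ("chr2", 1_000_000))
    n_chromatin_loci: int = 4
    n_ses: int = 10
    n_genes: int = 10
    locus_width: int = 40_000
    n_snps_per_locus: int = 3
    n_snps_per_gene: int = 2
    p_hemizygous_trans: float = 0.5
    p_mono_se: float = 0.5
    p_mono_rna: float = 0.5
    balanced_af: float = 0.5
    skewed_af: float = 0.95
    lambda_wgs: float = 60.0
    lambda_chip: float = 30.0
    lambda_rna: float = 30.0
    scl: SCLBlockConfig = field(default_factory=SCLBlockConfig)

    def validate(self) -> None:
        for p in (self.p_hemizygous_trans, self.p_mono_se, self.p_mono_rna):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"probability outside [0,1]: {p}")
        for lam in (self.lambda_wgs, self.lambda_chip, self.lambda_rna):
            if lam <= 0:
                raise ConfigurationError(f"depth parameter must be > 0: {lam}")
        if not (0.5 <= self.skewed_af <= 1.0):
            raise ConfigurationError("skewed_af must lie in [0.5, 1]")
        chrom_len = dict(self.toy_genome)
        if len(chrom_len) < 2:
            raise ConfigurationError("toy genome needs at least 2 chromosomes")
        c1, c2 = list(chrom_len)[:2]
        if self.n_chromatin_loci * 100_000 + 50_000 > min(chrom_len[c1], 500_000):
            raise ConfigurationError(
                "chromatin loci do not fit before the gene block on the first chromosome"
            )
        if 500_000 + self.n_genes * 40_000 > chrom_len[c1]:
            raise ConfigurationError("gene exons do not fit on first chromosome")
        if 50_000 + self.n_ses * 80_000 > chrom_len[c2]:
            raise ConfigurationError("SE regions do not fit on second chromosome")


@dataclass
class TruthTable:
    """Ground-truth labels for every simulated entity."""

    chromatin: dict[tuple[str, str], str]  # (sample, locus) -> state
    se: dict[tuple[str, str], str]  # (sample, se key) -> mono/bi
    rna: dict[tuple[str, str], str]  # (sample, gene) -> mono/bi
    scl: dict[str, bool]  # pair key -> planted correlation


@dataclass
class SampleBundle:
    sample_id: str
    subgroup: str
    variants: list[VariantRecord]
    ac_peaks: list[GenomicInterval]
    me3_peaks: list[GenomicInterval]
    ac_counts: list[AlleleCount]
    me3_counts: list[AlleleCount]
    rna_counts: list[AlleleCount]


@dataclass
class SimulatedCohort:
    """In-memory cohort bundle; write() materializes the file bundle."""

    config: SimulationConfig
    samples: list[SampleBundle]
    chromatin_loci: dict[str, GenomicInterval]
    se_regions: dict[str, GenomicInterval]
    gene_exons: dict[str, GenomicInterval]
    loops: list[LoopRecord]
    scl_enhancers: list[GenomicInterval]
    scl_genes: pd.DataFrame  # gene_id, chrom, tss, strand
    enhancer_signal: pd.DataFrame
    expression: pd.DataFrame
    truth: TruthTable

    def labels(self) -> dict[str, str]:
        return {s.sample_id: s.subgroup for s in self.samples}

    def scl_pairs(self):
        """The simulated enhancer-gene pairs, one per loop, in loop order."""
        from .loops import EnhancerPromoterPair, GeneAnnotation

        pairs = []
        for lp, enh, row in zip(
            self.loops, self.scl_enhancers, self.scl_genes.itertuples(index=False)
        ):
            gene = GeneAnnotation(str(row.gene_id), str(row.chrom), int(row.tss))
            pairs.append(EnhancerPromoterPair(lp, enh, gene.gene_id, gene.promoter()))
        return pairs

    def write(self, outdir: str | Path) -> None:
        write_cohort(self, outdir)


def _plant_snps(rng: np.random.Generator, region: GenomicInterval, n: int) -> list[tuple[int, str, str]]:
    """n distinct (1-based pos, ref, alt) SNVs inside a region."""
    pos0 = rng.choice(np.arange(region.start, region.end), size=n, replace=False)
    out = []
    for p in sorted(int(x) for x in pos0):
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        out.append((p + 1, str(ref), str(alt)))
    return out


def _binom(rng: np.random.Generator, n: int, p: float) -> int:
    return int(rng.binomial(n, p)) if n > 0 else 0


def _hap_counts(
    rng: np.random.Generator, depth: int, hap_a_fraction: float, phase: str
) -> tuple[int, int]:
    """Draw (ref_n, alt_n) given the hapA read fraction and SNP phase."""
    hap_a = _binom(rng, depth, hap_a_fraction)
    hap_b = depth - hap_a
    if phase == PHASE_HAPA_REF:
        return hap_a, hap_b
    return hap_b, hap_a


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Generate the full cohort; deterministic for a fixed config."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chrom1, len1 = cfg.toy_genome[0]
    chrom2, len2 = cfg.toy_genome[1]

    loci = {
        f"locus{i + 1}": GenomicInterval(chrom1, 50_000 + i * 100_000,
                                         50_000 + i * 100_000 + cfg.locus_width)
        for i in range(cfg.n_chromatin_loci)
    }
    ses = {
        f"SE{i + 1}": GenomicInterval(chrom2, 50_000 + i * 80_000,
                                      50_000 + i * 80_000 + cfg.locus_width)
        for i in range(cfg.n_ses)
    }
    genes = {
        f"gene{i + 1}": GenomicInterval(chrom1, 500_000 + i * 40_000,
                                        500_000 + i * 40_000 + 10_000)
        for i in range(cfg.n_genes)
    }

    # fixed SNP positions shared by all samples (as dbSNP sites would be)
    locus_snps = {name: _plant_snps(rng, iv, cfg.n_snps_per_locus) for name, iv in loci.items()}
    se_snps = {name: _plant_snps(rng, iv, cfg.n_snps_per_locus) for name, iv in ses.items()}
    gene_snps = {name: _plant_snps(rng, iv, cfg.n_snps_per_gene) for name, iv in genes.items()}

    truth = TruthTable(chromatin={}, se={}, rna={}, scl={})
    samples: list[SampleBundle] = []
    sample_index = 0
    for subgroup in ("WNT", "SHH", "G3", "G4"):
        for _ in range(int(cfg.n_samples_per_subgroup.get(subgroup, 0))):
            sample_index += 1
            sid = f"S{sample_index:03d}"
            samples.append(
                _simulate_sample(rng, cfg, sid, subgroup, loci, ses, genes,
                                 locus_snps, se_snps, gene_snps, truth)
            )

    loops, enhancers, gene_df, sig, expr = _simulate_scl_block(rng, cfg, chrom2, len2, truth)

    return SimulatedCohort(
        config=cfg, samples=samples, chromatin_loci=loci, se_regions=ses,
        gene_exons=genes, loops=loops, scl_enhancers=enhancers,
        scl_genes=gene_df, enhancer_signal=sig, expression=expr, truth=truth,
    )


def _simulate_sample(
    rng, cfg, sid, subgroup, loci, ses, genes, locus_snps, se_snps, gene_snps, truth
) -> SampleBundle:
    variants: list[VariantRecord] = []
    ac_counts: list[AlleleCount] = []
    me3_counts: list[AlleleCount] = []
    rna_counts: list[AlleleCount] = []
    ac_peaks: list[GenomicInterval] = []
    me3_peaks: list[GenomicInterval] = []

    def make_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantRecord:
        t_depth = int(rng.poisson(cfg.lambda_wgs))
        n_depth = int(rng.poisson(cfg.lambda_wgs))
        t_alt = _binom(rng, t_depth, 0.5)
        n_alt = _binom(rng, n_depth, 0.5)
        phase = PHASE_HAPA_REF if rng.random() < 0.5 else PHASE_HAPA_ALT
        return VariantRecord(
            chrom, pos, ref, alt,
            tumor_ref_depth=t_depth - t_alt, tumor_alt_depth=t_alt,
            normal_ref_depth=n_depth - n_alt, normal_alt_depth=n_alt,
            phase=phase,
        )

    def chip_count(v: VariantRecord, mark: str, lam: float, hap_a_fraction: float) -> AlleleCount:
        depth = int(rng.poisson(lam))
        ref_n, alt_n = _hap_counts(rng, depth, hap_a_fraction, v.phase)
        return AlleleCount(v.chrom, v.pos, v.ref_allele, v.alt_allele, sid, mark, ref_n, alt_n)

    # chromatin-state loci: both marks deposited; trans loci skew the two
    # marks toward opposite haplotypes, bi-allelic loci are balanced in both
    for name, iv in loci.items():
        is_trans = rng.random() < cfg.p_hemizygous_trans
        truth.chromatin[(sid, name)] = (
            chromatin.HEMIZYGOUS_TRANS if is_trans else chromatin.BIALLELIC_ACTIVE
        )
        ac_peaks.append(iv)
        me3_peaks.append(iv)
        ac_frac = cfg.skewed_af if is_trans else cfg.balanced_af
        me3_frac = (1.0 - cfg.skewed_af) if is_trans else cfg.balanced_af
        for pos, ref, alt in locus_snps[name]:
            v = make_variant(iv.chrom, pos, ref, alt)
            variants.append(v)
            ac_counts.append(chip_count(v, "H3K27ac", cfg.lambda_chip, ac_frac))
            me3_counts.append(chip_count(v, "H3K27me3", cfg.lambda_chip, me3_frac))

    # super-enhancers: H3K27ac only; mono-allelic SEs skew toward one haplotype
    for name, iv in ses.items():
        is_mono = rng.random() < cfg.p_mono_se
        truth.se[(sid, name)] = se_mod.MONOALLELIC if is_mono else se_mod.BIALLELIC
        ac_peaks.append(iv)
        major_hap_a = rng.random() < 0.5
        if is_mono:
            frac = cfg.skewed_af if major_hap_a else 1.0 - cfg.skewed_af
        else:
            frac = cfg.balanced_af
        for pos, ref, alt in se_snps[name]:
            v = make_variant(iv.chrom, pos, ref, alt)
            variants.append(v)
            ac_counts.append(chip_count(v, "H3K27ac", cfg.lambda_chip, frac))

    # gene expression: RNA reads at exonic SNPs
    for name, iv in genes.items():
        is_mono = rng.random() < cfg.p_mono_rna
        truth.rna[(sid, name)] = ase.MONOALLELIC if is_mono else ase.BIALLELIC
        major_hap_a = rng.random() < 0.5
        if is_mono:
            frac = cfg.skewed_af if major_hap_a else 1.0 - cfg.skewed_af
        else:
            frac = cfg.balanced_af
        for pos, ref, alt in gene_snps[name]:
            v = make_variant(iv.chrom, pos, ref, alt)
            variants.append(v)
            rna_counts.append(chip_count(v, "RNA", cfg.lambda_rna, frac))

    variants.sort(key=lambda v: (v.chrom, v.pos))
    return SampleBundle(sid, subgroup, variants, sorted(ac_peaks), sorted(me3_peaks),
                        ac_counts, me3_counts, rna_counts)


def _simulate_scl_block(rng, cfg, chrom: str, chrom_len: int, truth: TruthTable):
    scl = cfg.scl
    stride = max((chrom_len - 13_000) // max(scl.n_pairs, 1), 1)
    if stride < 1:
        raise ConfigurationError("too many SCL pairs for the toy chromosome")
    enhancers: list[GenomicInterval] = []
    gene_rows = []
    loops: list[LoopRecord] = []
    sample_cols = [f"C{i + 1:03d}" for i in range(scl.n_samples)]
    sig_rows = {}
    expr_rows = {}
    planted_flags = np.zeros(scl.n_pairs, dtype=bool)
    planted_flags[: scl.n_planted] = True
    rng.shuffle(planted_flags)
    for i in range(scl.n_pairs):
        start = i * stride
        enh = GenomicInterval(chrom, start, start + 400)
        tss = start + 10_000
        gene_id = f"scl_gene{i + 1}"
        enhancers.append(enh)
        gene_rows.append({"gene_id": gene_id, "chrom": chrom, "tss": tss, "strand": "+"})
        anchor2 = GenomicInterval(chrom, tss - 500, tss + 500)
        loops.append(
            LoopRecord(enh, anchor2, read_count=6 + int(rng.poisson(20)),
                       q_value=float(rng.uniform(0, 0.009)))
        )
        x = rng.standard_normal(scl.n_samples)
        if planted_flags[i]:
            noise = rng.standard_normal(scl.n_samples)
            y = scl.r_true * x + np.sqrt(1.0 - scl.r_true**2) * noise
        else:
            y = rng.standard_normal(scl.n_samples)
        sig_rows[str(enh)] = x
        expr_rows[gene_id] = y
        truth.scl[f"{enh}|{gene_id}"] = bool(planted_flags[i])
    sig = pd.DataFrame.from_dict(sig_rows, orient="index", columns=sample_cols)
    expr = pd.DataFrame.from_dict(expr_rows, orient="index", columns=sample_cols)
    gene_df = pd.DataFrame.from_records(gene_rows)
    return loops, enhancers, gene_df, sig, expr


# --- file bundle -----------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL
"""


def write_sample_vcf(path: str | Path, variants: list[VariantRecord],
                     toy_genome: tuple[tuple[str, int], ...]) -> None:
    """Write a two-sample (TUMOR, NORMAL) VCF 4.2 for one simulated sample."""
    contigs = "".join(
        f"##contig=<ID={chrom},length={length}>\n" for chrom, length in toy_genome
    )
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs))
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
            gt = "0|1" if v.phase == PHASE_HAPA_REF else (
                "1|0" if v.phase == PHASE_HAPA_ALT else "0/1"
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t.\t"
                f"GT:AD\t{gt}:{v.tumor_ref_depth},{v.tumor_alt_depth}\t"
                f"{gt}:{v.normal_ref_depth},{v.normal_alt_depth}\n"
            )


def _counts_df(counts: list[AlleleCount]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {"chrom": c.chrom, "pos": c.pos, "ref": c.ref_allele, "alt": c.alt_allele,
             "library_id": c.library_id, "mark": c.mark, "ref_n": c.ref_n,
             "alt_n": c.alt_n, "other_n": c.other_n}
            for c in counts
        ],
        columns=["chrom", "pos", "ref", "alt", "library_id", "mark",
                 "ref_n", "alt_n", "other_n"],
    )


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Materialize the cohort as the file bundle the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config

    sample_rows = []
    for s in cohort.samples:
        write_sample_vcf(outdir / f"{s.sample_id}.vcf", s.variants, cfg.toy_genome)
        write_intervals(s.ac_peaks, outdir / f"{s.sample_id}.h3k27ac_peaks.bed")
        write_intervals(s.me3_peaks, outdir / f"{s.sample_id}.h3k27me3_peaks.bed")
        write_table(_counts_df(s.ac_counts), outdir / f"{s.sample_id}.h3k27ac_counts.tsv")
        write_table(_counts_df(s.me3_counts), outdir / f"{s.sample_id}.h3k27me3_counts.tsv")
        write_table(_counts_df(s.rna_counts), outdir / f"{s.sample_id}.rna_counts.tsv")
        sample_rows.append({"sample_id": s.sample_id, "subgroup": s.subgroup})
    write_table(pd.DataFrame.from_records(sample_rows), outdir / "samples.tsv")

    write_intervals(list(cohort.chromatin_loci.values()), outdir / "chromatin_loci.bed",
                    names=list(cohort.chromatin_loci))
    write_intervals(list(cohort.se_regions.values()), outdir / "se_regions.bed",
                    names=list(cohort.se_regions))
    write_intervals(list(cohort.gene_exons.values()), outdir / "gene_exons.bed",
                    names=list(cohort.gene_exons))
    write_loops(cohort.loops, outdir / "loops.bedpe")
    write_intervals(cohort.scl_enhancers, outdir / "scl_enhancers.bed")
    write_table(cohort.scl_genes, outdir / "scl_genes.tsv")
    write_matrix(cohort.enhancer_signal, outdir / "enhancer_signal.tsv")
    write_matrix(cohort.expression, outdir / "expression.tsv")

    write_table(
        pd.DataFrame.from_records(
            [{"sample_id": k[0], "locus": k[1], "true_state": v}
             for k, v in sorted(cohort.truth.chromatin.items())]
        ),
        outdir / "truth_chromatin.tsv",
    )
    write_table(
        pd.DataFrame.from_records(
            [{"sample_id": k[0], "se": k[1], "true_call": v}
             for k, v in sorted(cohort.truth.se.items())]
        ),
        outdir / "truth_se.tsv",
    )
    write_table(
        pd.DataFrame.from_records(
            [{"sample_id": k[0], "gene_id": k[1], "true_call": v}
             for k, v in sorted(cohort.truth.rna.items())]
        ),
        outdir / "truth_rna.tsv",
    )
    write_table(
        pd.DataFrame.from_records(
            [{"pair": k, "is_planted": v} for k, v in sorted(cohort.truth.scl.items())]
        ),
        outdir / "truth_scl.tsv",
    )
    _write_config_echo(cfg, outdir / "config_resolved.yaml")


def _write_config_echo(cfg: SimulationConfig, path: Path) -> None:
    import yaml

    d = {
        "seed": cfg.seed,
        "n_samples_per_subgroup": dict(cfg.n_samples_per_subgroup),
        "toy_genome": [list(t) for t in cfg.toy_genome],
        "n_chromatin_loci": cfg.n_chromatin_loci,
        "n_ses": cfg.n_ses,
        "n_genes": cfg.n_genes,
        "locus_width": cfg.locus_width,
        "n_snps_per_locus": cfg.n_snps_per_locus,
        "n_snps_per_gene": cfg.n_snps_per_gene,
        "p_hemizygous_trans": cfg.p_hemizygous_trans,
        "p_mono_se": cfg.p_mono_se,
        "p_mono_rna": cfg.p_mono_rna,
        "balanced_af": cfg.balanced_af,
        "skewed_af": cfg.skewed_af,
        "lambda_wgs": cfg.lambda_wgs,
        "lambda_chip": cfg.lambda_chip,
        "lambda_rna": cfg.lambda_rna,
        "scl": {"n_pairs": cfg.scl.n_pairs, "n_planted": cfg.scl.n_planted,
                "r_true": cfg.scl.r_true, "n_samples": cfg.scl.n_samples},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


# --- recovery scoring ------------------------------------------------------

@dataclass(frozen=True)
class RecoveryScore:
    sensitivity: float
    specificity: float
    accuracy: float
    n_true_positive: int
    n_true_negative: int
    n_uninformative: int


def score_recovery(
    calls: Mapping, truth: Mapping, positive_label: str,
    uninformative_labels: tuple[str, ...] = ("uninformative",),
) -> RecoveryScore:
    """Confusion-matrix rates of calls against ground truth.

    calls and truth must share keys exactly (error lists the mismatch).
    Uninformative calls are counted separately and excluded from the
    sensitivity/specificity/accuracy denominators.
    """
    missing = set(truth) - set(calls)
    extra = set(calls) - set(truth)
    if missing or extra:
        raise DataError(
            f"call/truth key mismatch; missing from calls: {sorted(missing)[:5]}, "
            f"unexpected in calls: {sorted(extra)[:5]}"
        )
    tp = tn = fp = fn = n_unf = 0
    for key, true_label in truth.items():
        call = calls[key]
        if call in uninformative_labels:
            n_unf += 1
            continue
        truly_pos = true_label == positive_label
        called_pos = call == positive_label
        if truly_pos and called_pos:
            tp += 1
        elif truly_pos:
            fn += 1
        elif called_pos:
            fp += 1
        else:
            tn += 1
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    acc = (tp + tn) / (tp + tn + fp + fn) if (tp + tn + fp + fn) else float("nan")
    return RecoveryScore(sens, spec, acc, tp + fn, tn + fp, n_unf)
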