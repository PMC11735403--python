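"""Recovery benchmarks: run the pipeline stages against generator truth.

Each function takes a simulated cohort, executes the corresponding inference
stage exactly as the pipeline would, and scores the calls against the
ground-truth labels the generator recorded. These are the operating
characteristics quoted in the docs: they describe performance under the
generator's binomial read model, not on real (overdispersed) data.
"""

from __future__ import annotations

from . import ase, chromatin, superenhancers as se_mod
from .het_snps import attach_phase, filter_het_snps
from .loops import call_scl, filter_loops
from .synthetic import RecoveryScore, SimulatedCohort, score_recovery


def chromatin_state_calls(cohort: SimulatedCohort) -> dict[tuple[str, str], str]:
    """Per sample x locus hemizygous-trans / bi-allelic calls."""
    calls: dict[tuple[str, str], str] = {}
    for s in cohort.samples:
        het = filter_het_snps(s.variants)
        ac = {c.key: c for c in s.ac_counts}
        me3 = {c.key: c for c in s.me3_counts}
        for name, locus in cohort.chromatin_loci.items():
            configs = [
                chromatin.classify_snp_configuration(ac[snp.key], me3[snp.key])
                for snp in het
                if locus.contains_point(snp.chrom, snp.pos - 1)
                and snp.key in ac and snp.key in me3
            ]
            calls[(s.sample_id, name)] = chromatin.call_locus_state(
                s.sample_id, locus, configs
            ).state
    return calls


def benchmark_chromatin(cohort: SimulatedCohort) -> RecoveryScore:
    return score_recovery(
        chromatin_state_calls(cohort), cohort.truth.chromatin,
        chromatin.HEMIZYGOUS_TRANS,
    )


def mono_se_calls(cohort: SimulatedCohort) -> dict[tuple[str, str], str]:
    calls: dict[tuple[str, str], str] = {}
    for s in cohort.samples:
        phased = attach_phase(filter_het_snps(s.variants))
        ac = {c.key: c for c in s.ac_counts}
        for name, region in cohort.se_regions.items():
            call = se_mod.classify_monoallelic_se(s.sample_id, region, phased, ac)
            calls[(s.sample_id, name)] = call.call
    return calls


def benchmark_mono_se(cohort: SimulatedCohort) -> RecoveryScore:
    return score_recovery(mono_se_calls(cohort), cohort.truth.se, se_mod.MONOALLELIC)


def mono_rna_calls(cohort: SimulatedCohort) -> dict[tuple[str, str], str]:
    calls: dict[tuple[str, str], str] = {}
    for s in cohort.samples:
        phased = attach_phase(filter_het_snps(s.variants))
        rna = {c.key: c for c in s.rna_counts}
        for name, exon in cohort.gene_exons.items():
            exonic = [
                p for p in phased
                if exon.contains_point(p.record.chrom, p.record.pos - 1)
            ]
            call = ase.classify_allelic_expression(s.sample_id, name, exonic, rna)
            calls[(s.sample_id, name)] = call.call
    return calls


def benchmark_mono_rna(cohort: SimulatedCohort) -> RecoveryScore:
    return score_recovery(mono_rna_calls(cohort), cohort.truth.rna, ase.MONOALLELIC)


def benchmark_scl(cohort: SimulatedCohort) -> RecoveryScore:
    """Sensitivity on planted pairs; (1 - specificity) is the null FP fraction."""
    pairs = cohort.scl_pairs()
    kept = set(id(lp) for lp in filter_loops(cohort.loops))
    pairs = [p for p in pairs if id(p.loop) in kept]
    calls = call_scl(pairs, cohort.enhancer_signal, cohort.expression)
    call_map = {c.pair.key: ("scl" if c.is_scl else "null") for c in calls}
    truth = {
        k: ("scl" if v else "null")
        for k, v in cohort.truth.scl.items()
        if k in call_map
    }
    return score_recovery(call_map, truth, "scl")
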