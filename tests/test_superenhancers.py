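"""Stitching, hockey-stick ranking, consensus merging, mono-allelic SEs."""

import math

import numpy as np
import pytest

from allelichrom.allelic import AlleleCount
from allelichrom.errors import UsageError
from allelichrom.het_snps import PhasedHetSNP
from allelichrom.intervals import GenomicInterval, merge_intervals
from allelichrom.io import PHASE_HAPA_ALT, PHASE_HAPA_REF, VariantRecord
from allelichrom.superenhancers import (
    BIALLELIC,
    MONOALLELIC,
    UNINFORMATIVE,
    MonoallelicSECall,
    classify_monoallelic_se,
    genome_coverage,
    merge_subgroup_ses,
    rank_superenhancers,
    recurrent_monoallelic_ses,
    stitch_peaks,
)

from conftest import coverage_vector, random_intervals


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestStitching:
    def test_single_peak_is_its_own_region(self):
        (sr,) = stitch_peaks([iv(0, 100)])
        assert sr.region == iv(0, 100)
        assert sr.constituent_peaks == (iv(0, 100),)

    def test_gap_boundary_at_12500(self):
        # 12,400 bp gap stitches; 13,000 bp gap does not
        one = stitch_peaks([iv(0, 100), iv(12_500, 12_600)])
        assert len(one) == 1 and one[0].region == iv(0, 12_600)
        two = stitch_peaks([iv(0, 100), iv(13_100, 13_200)])
        assert len(two) == 2

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(13)
        peaks = random_intervals(rng, 200, genome_length=200_000, max_len=3_000)
        gap = 5_000
        got = {(sr.region.chrom, sr.region.start, sr.region.end)
               for sr in stitch_peaks(peaks, gap)}
        # O(n^2) oracle: union-find over the pairwise "gap <= threshold" relation
        n = len(peaks)
        parent = list(range(n))
        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i
        for i in range(n):
            for j in range(i + 1, n):
                a, b = peaks[i], peaks[j]
                if a.chrom != b.chrom:
                    continue
                g = max(a.start, b.start) - min(a.end, b.end)
                if g <= gap:
                    parent[find(i)] = find(j)
        groups = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(peaks[i])
        expected = {
            (ms[0].chrom, min(p.start for p in ms), max(p.end for p in ms))
            for ms in groups.values()
        }
        assert got == expected

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(17)
        peaks = random_intervals(rng, 60, genome_length=100_000, max_len=2_000)
        regions = [sr.region for sr in stitch_peaks(peaks)]
        again = [sr.region for sr in stitch_peaks(regions)]
        assert regions == again
        shuffled = list(peaks)
        rng.shuffle(shuffled)
        assert [sr.region for sr in stitch_peaks(shuffled)] == regions


class TestRanking:
    def regions(self, n):
        return [type("SR", (), {})() for _ in range(n)]

    def test_flat_signal_has_no_super(self):
        stitched = stitch_peaks([iv(i * 50_000, i * 50_000 + 100) for i in range(5)])
        ranked = rank_superenhancers(stitched, [3.0] * 5)
        assert not any(se.is_super for se in ranked)
        assert sorted(se.rank for se in ranked) == [1, 2, 3, 4, 5]

    def test_single_outlier_is_the_only_super(self):
        stitched = stitch_peaks([iv(i * 50_000, i * 50_000 + 100) for i in range(5)])
        ranked = rank_superenhancers(stitched, [1, 1, 1, 1, 100])
        supers = [se for se in ranked if se.is_super]
        assert len(supers) == 1 and supers[0].signal == 100
        assert supers[0].rank == 1

    def test_planted_knee_recovered_within_one_rank(self):
        # piecewise-linear curve: 40 background regions with tiny slope, then
        # 10 regions rising steeply — knee planted at rank boundary 40/41
        stitched = stitch_peaks([iv(i * 50_000, i * 50_000 + 100) for i in range(50)])
        signals = [1 + 0.01 * i for i in range(40)] + [10 + 10 * i for i in range(10)]
        ranked = rank_superenhancers(stitched, signals)
        n_super = sum(se.is_super for se in ranked)
        assert abs(n_super - 10) <= 1

    def test_fewer_than_three_regions_all_super(self):
        stitched = stitch_peaks([iv(0, 100), iv(50_000, 50_100)])
        ranked = rank_superenhancers(stitched, [1.0, 2.0])
        assert all(se.is_super for se in ranked)


class TestConsensusMerge:
    def test_singleton_excluded(self):
        per_sample = {f"s{i}": [] for i in range(10)}
        per_sample["s0"] = [iv(0, 1000)]
        assert merge_subgroup_ses(per_sample, min_recurrence=2) == []

    def test_identical_in_three_samples_is_one_region(self):
        per_sample = {f"s{i}": [iv(0, 1000)] for i in range(3)}
        assert merge_subgroup_ses(per_sample) == [iv(0, 1000)]

    def test_staggered_overlap_gives_union(self):
        per_sample = {"s1": [iv(0, 600)], "s2": [iv(400, 1000)]}
        assert merge_subgroup_ses(per_sample) == [iv(0, 1000)]

    def test_never_shrinks_when_recurrence_loosens(self):
        rng = np.random.default_rng(23)
        per_sample = {
            f"s{i}": random_intervals(rng, 8, genome_length=50_000, max_len=4_000)
            for i in range(6)
        }
        covered = {}
        for k in (1, 2, 3, 4):
            covered[k] = sum(r.length for r in merge_subgroup_ses(per_sample, k))
        assert covered[4] <= covered[3] <= covered[2] <= covered[1]


def make_phased(pos, hap_a="REF", chrom="chr2"):
    phase = PHASE_HAPA_REF if hap_a == "REF" else PHASE_HAPA_ALT
    rec = VariantRecord(chrom, pos, "A", "T", 20, 20, 15, 15, phase=phase)
    return PhasedHetSNP(rec, hapA_allele=hap_a,
                        hapB_allele="ALT" if hap_a == "REF" else "REF")


def ac_count(pos, ref_n, alt_n, chrom="chr2"):
    return AlleleCount(chrom, pos, "A", "T", "s", "H3K27ac", ref_n, alt_n)


class TestMonoallelicSE:
    se = GenomicInterval("chr2", 0, 10_000)

    def test_exact_threshold_is_monoallelic(self):
        # pooled 27 vs 3 -> normalized AF exactly 0.9, inclusive boundary
        call = classify_monoallelic_se(
            "s", self.se, [make_phased(100)], {"chr2:100": ac_count(100, 27, 3)}
        )
        assert call.normalized_af == pytest.approx(0.9)
        assert call.call == MONOALLELIC

    def test_balanced_is_biallelic(self):
        call = classify_monoallelic_se(
            "s", self.se, [make_phased(100)], {"chr2:100": ac_count(100, 15, 15)}
        )
        assert call.normalized_af == pytest.approx(0.5)
        assert call.call == BIALLELIC

    def test_three_snp_pooling(self):
        # (10,1), (8,0), (9,2) on consistent haplotypes -> 27/30 = 0.9
        snps = [make_phased(100), make_phased(200), make_phased(300)]
        counts = {
            "chr2:100": ac_count(100, 10, 1),
            "chr2:200": ac_count(200, 8, 0),
            "chr2:300": ac_count(300, 9, 2),
        }
        call = classify_monoallelic_se("s", self.se, snps, counts)
        assert (call.hapA_reads, call.hapB_reads) == (27, 3)
        assert call.normalized_af == pytest.approx(0.9)
        assert call.call == MONOALLELIC

    def test_phase_routes_counts_onto_haplotypes(self):
        # same raw counts, opposite phases: pooled totals must agree
        snps = [make_phased(100, "REF"), make_phased(200, "ALT")]
        counts = {
            "chr2:100": ac_count(100, 9, 1),
            "chr2:200": ac_count(200, 1, 9),
        }
        call = classify_monoallelic_se("s", self.se, snps, counts)
        assert (call.hapA_reads, call.hapB_reads) == (18, 2)

    def test_unphased_only_is_uninformative(self):
        rec = VariantRecord("chr2", 100, "A", "T", 20, 20, 15, 15)
        snp = PhasedHetSNP(rec, "REF", "ALT")
        call = classify_monoallelic_se(
            "s", self.se, [snp], {"chr2:100": ac_count(100, 30, 0)}
        )
        assert call.call == UNINFORMATIVE and call.reason

    def test_low_pooled_depth_is_uninformative(self):
        call = classify_monoallelic_se(
            "s", self.se, [make_phased(100)], {"chr2:100": ac_count(100, 6, 1)}
        )
        assert call.call == UNINFORMATIVE

    def test_haplotype_label_swap_invariance(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            ref_n, alt_n = (int(x) for x in rng.integers(0, 40, 2))
            c = {"chr2:100": ac_count(100, ref_n, alt_n)}
            a = classify_monoallelic_se("s", self.se, [make_phased(100, "REF")], c)
            b = classify_monoallelic_se("s", self.se, [make_phased(100, "ALT")], c)
            assert a.call == b.call
            if not math.isnan(a.normalized_af):
                assert a.normalized_af == pytest.approx(b.normalized_af)


class TestRecurrentSEs:
    def make_call(self, sample, region, call):
        return MonoallelicSECall(sample, region, 20, 0, 1.0 if call == MONOALLELIC else 0.5, call)

    def test_g4_needs_three_samples(self):
        region = iv(0, 1000)
        calls = [self.make_call(f"g4_{i}", region, MONOALLELIC) for i in range(2)]
        labels = {f"g4_{i}": "G4" for i in range(2)}
        assert recurrent_monoallelic_ses(calls, labels)["G4"] == []

    def test_other_subgroups_need_two(self):
        region = iv(0, 1000)
        calls = [self.make_call(f"g3_{i}", region, MONOALLELIC) for i in range(2)]
        labels = {f"g3_{i}": "G3" for i in range(2)}
        assert recurrent_monoallelic_ses(calls, labels)["G3"] == [region]

    def test_unknown_label_rejected(self):
        calls = [self.make_call("x", iv(0, 1000), MONOALLELIC)]
        with pytest.raises(UsageError):
            recurrent_monoallelic_ses(calls, {"x": "G5"})

    def test_random_matrix_matches_count_threshold_oracle(self):
        rng = np.random.default_rng(37)
        regions = [iv(i * 2000, i * 2000 + 1000) for i in range(12)]
        samples = [f"s{i}" for i in range(16)]
        labels = {s: ("G4" if i < 8 else "G3") for i, s in enumerate(samples)}
        calls = []
        mono = {}
        for region in regions:
            for s in samples:
                is_mono = bool(rng.random() < 0.3)
                mono[(str(region), s)] = is_mono
                calls.append(self.make_call(s, region, MONOALLELIC if is_mono else BIALLELIC))
        got = recurrent_monoallelic_ses(calls, labels)
        for sg, threshold in (("G4", 3), ("G3", 2)):
            expected = [
                r for r in regions
                if sum(mono[(str(r), s)] for s in samples if labels[s] == sg) >= threshold
            ]
            assert got[sg] == expected


class TestGenomeCoverage:
    def test_no_peaks(self):
        assert genome_coverage([], 10_000) == (0, 0.0)

    def test_full_coverage(self):
        assert genome_coverage([iv(0, 10_000, "chrA")], 10_000) == (1, 1.0)

    def test_overlaps_counted_once_vs_per_base_oracle(self):
        rng = np.random.default_rng(41)
        peaks = random_intervals(rng, 40, chroms=("chrA",))
        n, frac = genome_coverage(peaks, 10_000)
        assert n == 40
        assert frac == pytest.approx(coverage_vector(peaks, "chrA").sum() / 10_000)
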