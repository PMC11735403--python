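"""Allelic-expression calls, cohort summaries, Fisher/Hochberg/Mann-Whitney."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import comb

from allelichrom.allelic import AlleleCount
from allelichrom.ase import (
    BIALLELIC,
    MONOALLELIC,
    UNINFORMATIVE,
    AllelicExpressionCall,
    classify_allelic_expression,
    cohort_summary,
    summary_from_counts,
)
from allelichrom.het_snps import PhasedHetSNP
from allelichrom.io import PHASE_HAPA_ALT, PHASE_HAPA_REF, VariantRecord
from allelichrom.stats import (
    fisher_exact_2x2,
    group_comparison,
    hochberg_adjust,
)


def phased_snp(pos, hap_a="REF", phased=True):
    if phased:
        phase = PHASE_HAPA_REF if hap_a == "REF" else PHASE_HAPA_ALT
    else:
        phase = "unphased"
    rec = VariantRecord("chr1", pos, "A", "T", 20, 20, 15, 15, phase=phase)
    if hap_a == "REF":
        return PhasedHetSNP(rec, "REF", "ALT")
    return PhasedHetSNP(rec, "ALT", "REF")


def rna(pos, ref_n, alt_n):
    return AlleleCount("chr1", pos, "A", "T", "s", "RNA", ref_n, alt_n)


class TestClassification:
    def test_single_snp_strong_skew_is_monoallelic(self):
        call = classify_allelic_expression(
            "s", "g", [phased_snp(100)], {"chr1:100": rna(100, 19, 1)}
        )
        assert call.major_af == pytest.approx(0.95)
        assert call.call == MONOALLELIC

    def test_single_snp_balanced_is_biallelic(self):
        call = classify_allelic_expression(
            "s", "g", [phased_snp(100)], {"chr1:100": rna(100, 11, 9)}
        )
        assert call.major_af == pytest.approx(0.55)
        assert call.call == BIALLELIC

    def test_two_phased_snps_pool_onto_haplotypes(self):
        # (9,1) and (10,0) on consistent haplotypes -> 19/20 = 0.95
        snps = [phased_snp(100, "REF"), phased_snp(200, "ALT")]
        counts = {"chr1:100": rna(100, 9, 1), "chr1:200": rna(200, 0, 10)}
        call = classify_allelic_expression("s", "g", snps, counts)
        assert (call.hapA_reads, call.hapB_reads) == (19, 1)
        assert call.major_af == pytest.approx(0.95)
        assert call.call == MONOALLELIC

    def test_single_covered_snp_classifiable_without_phase(self):
        call = classify_allelic_expression(
            "s", "g", [phased_snp(100, phased=False)], {"chr1:100": rna(100, 19, 1)}
        )
        assert call.call == MONOALLELIC

    def test_multiple_unphased_snps_uninformative(self):
        snps = [phased_snp(100, phased=False), phased_snp(200, phased=False)]
        counts = {"chr1:100": rna(100, 10, 0), "chr1:200": rna(200, 0, 10)}
        call = classify_allelic_expression("s", "g", snps, counts)
        assert call.call == UNINFORMATIVE and "phase" in call.reason

    def test_no_coverage_uninformative(self):
        call = classify_allelic_expression("s", "g", [phased_snp(100)], {})
        assert call.call == UNINFORMATIVE

    def test_haplotype_relabeling_invariance(self):
        rng = np.random.default_rng(89)
        for _ in range(50):
            a, b = (int(x) for x in rng.integers(0, 30, 2))
            c1 = classify_allelic_expression(
                "s", "g", [phased_snp(100, "REF")], {"chr1:100": rna(100, a, b)}
            )
            c2 = classify_allelic_expression(
                "s", "g", [phased_snp(100, "ALT")], {"chr1:100": rna(100, a, b)}
            )
            assert c1.call == c2.call
            if not math.isnan(c1.major_af):
                assert c1.major_af == pytest.approx(c2.major_af)


def make_calls(subgroup_counts):
    """subgroup_counts: {(subgroup, gene): (n_mono, n_bi, n_uninf)}"""
    calls, labels = [], {}
    i = 0
    for (sg, gene), (n_mono, n_bi, n_unf) in subgroup_counts.items():
        for call_type, n in [(MONOALLELIC, n_mono), (BIALLELIC, n_bi), (UNINFORMATIVE, n_unf)]:
            for _ in range(n):
                sid = f"{sg}_{i}"
                i += 1
                labels[sid] = sg
                calls.append(
                    AllelicExpressionCall(sid, gene, 10, 10, 0.5, call_type)
                )
    return calls, labels


class TestCohortSummary:
    def test_counts_and_rounding(self):
        calls, labels = make_calls({("G4", "ZIC1"): (36, 29, 4)})
        df = cohort_summary(calls, labels, rounding=0)
        row = df.iloc[0]
        assert (row.n_monoallelic, row.n_assessable) == (36, 65)
        assert row.percent_monoallelic == 55.0

    def test_uninformative_excluded_from_assessable(self):
        calls, labels = make_calls({("G3", "g"): (2, 3, 10)})
        df = cohort_summary(calls, labels)
        assert df.iloc[0].n_assessable == 5

    def test_zero_positive(self):
        calls, labels = make_calls({("WNT", "g"): (0, 12, 0)})
        assert cohort_summary(calls, labels).iloc[0].percent_monoallelic == 0.0

    def test_percentages_self_consistent(self):
        rng = np.random.default_rng(97)
        spec = {
            (sg, g): (int(rng.integers(0, 20)), int(rng.integers(1, 20)), int(rng.integers(0, 5)))
            for sg in ("G3", "G4") for g in ("ZIC1", "ZIC4")
        }
        calls, labels = make_calls(spec)
        df = cohort_summary(calls, labels, rounding=1)
        for row in df.itertuples():
            assert row.percent_monoallelic == summary_from_counts(
                row.n_monoallelic, row.n_assessable, 1
            )


class TestFisher:
    def test_flat_table(self):
        odds, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration_oracle(self):
        # enumerate all tables with the margins of [[10,0],[0,10]]
        table = [[10, 0], [0, 10]]
        _, p = fisher_exact_2x2(table)
        r1, r2 = 10, 10
        c1 = 10
        n = r1 + r2
        def table_prob(a):
            return comb(r1, a) * comb(r2, c1 - a) / comb(n, c1)
        p_obs = table_prob(10)
        expected = sum(
            table_prob(a)
            for a in range(max(0, c1 - r2), min(r1, c1) + 1)
            if table_prob(a) <= p_obs * (1 + 1e-9)
        )
        assert p == pytest.approx(expected)

    def test_negative_cell_rejected(self):
        from allelichrom.errors import UsageError

        with pytest.raises(UsageError):
            fisher_exact_2x2([[1, -2], [3, 4]])


class TestHochberg:
    def test_matches_step_up_hand_computation(self):
        # sorted p: 0.01, 0.02, 0.9 -> adj(3)=0.9; adj(2)=min(0.9, 2*0.02)=0.04;
        # adj(1)=min(0.04, 3*0.01)=0.03
        adj = hochberg_adjust([0.01, 0.02, 0.9])
        assert np.allclose(adj, [0.03, 0.04, 0.9])

    def test_random_vectors_match_oracle(self):
        rng = np.random.default_rng(101)
        for _ in range(20):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 15)))
            m = len(p)
            order = np.argsort(p)
            # Hochberg step-up: q_(i) = min_{j >= i} (m - j + 1) p_(j), capped at 1
            factors = (m - np.arange(1, m + 1) + 1) * p[order]
            q_sorted = np.minimum.accumulate(factors[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(q_sorted, 1.0)
            assert np.allclose(hochberg_adjust(p), expected)


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        assert group_comparison([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0, abs=0.05)

    def test_fully_separated_three_vs_three(self):
        # all 3 target ranks above: 2/C(6,3) = 2/20 = 0.1 two-tailed
        assert group_comparison([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_permutation_enumeration_for_small_n(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=4)
        b = rng.normal(size=5)
        got = group_comparison(a, b)
        # enumerate all C(9,4) assignments of pooled values to group A
        pooled = np.concatenate([a, b])
        def u_stat(a_vals, b_vals):
            return sum((x > y) + 0.5 * (x == y) for x in a_vals for y in b_vals)
        u_obs = u_stat(a, b)
        mu = len(a) * len(b) / 2
        count = total = 0
        for idx in itertools.combinations(range(9), 4):
            sel = np.zeros(9, dtype=bool)
            sel[list(idx)] = True
            u = u_stat(pooled[sel], pooled[~sel])
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
        assert got == pytest.approx(count / total)

    def test_empty_group_rejected(self):
        from allelichrom.errors import UsageError

        with pytest.raises(UsageError):
            group_comparison([], [1.0])
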