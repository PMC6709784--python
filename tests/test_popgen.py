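"""Diversity/neutrality statistics against independent naive oracles, plus
column annotation, enrichment, correlation and expression thresholds."""

import math

import numpy as np
import pytest
from scipy.special import comb

from conftest import random_alignment
from oracles import naive_stats
from pannlrome.models import CodonAlignment, DomainInterval as DI
from pannlrome.popgen import (annotate_columns, domain_subset_stats,
                              expression_threshold, flag_enrichment,
                              invariable_codons, neutrality_stats,
                              pair_correlation, strobeck_s, tajima_d_null)


class TestNeutralityStats:
    def test_three_row_worked_example(self):
        aln = CodonAlignment(["a", "b", "c"], ["AAA", "AAT", "ATT"])
        st = neutrality_stats(aln)
        assert st.pi == pytest.approx((4 / 3) / 3)
        assert st.S == 2
        assert st.K == 3
        assert st.hap_div == pytest.approx(1.0)

    def test_identical_rows_give_sentinels(self):
        aln = CodonAlignment(["a", "b"], ["ATGATG", "ATGATG"])
        st = neutrality_stats(aln)
        assert st.S == 0 and st.pi == 0.0 and st.hap_div == 0.0
        assert math.isnan(st.tajima_d)
        assert math.isnan(st.r2)

    def test_r2_single_singleton_site_hand_value(self):
        # n=4, one site 1-vs-3: pi_count=0.5, U=(1,0,0,0)
        aln = CodonAlignment(list("abcd"),
                             ["TAA", "AAA", "AAA", "AAA"])
        st = neutrality_stats(aln)
        assert st.r2 == pytest.approx(math.sqrt(0.75 / 4) / 1)
        assert st.r2 == pytest.approx(0.4330127, abs=1e-6)

    def test_oracle_equivalence_on_random_alignments(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            n = int(rng.integers(2, 12))
            aln = random_alignment(rng, n, int(rng.integers(2, 40)))
            st = neutrality_stats(aln)
            ref = naive_stats(aln.seqs)
            for fld in ("S", "L", "K", "eta_s"):
                assert getattr(st, fld) == ref[fld]
            for fld in ("pi", "hap_div"):
                assert getattr(st, fld) == pytest.approx(ref[fld], abs=1e-12)
            for fld in ("tajima_d", "r2"):
                ours, theirs = getattr(st, fld), ref[fld]
                assert (math.isnan(ours) and math.isnan(theirs)) or \
                    ours == pytest.approx(theirs, abs=1e-10)

    def test_gapped_columns_completely_deleted(self):
        aln = CodonAlignment(["a", "b"], ["A-GATG", "ATGTTG"])
        st = neutrality_stats(aln)
        assert st.L == 5
        assert st.S == 1

    def test_all_gap_columns_rejected(self):
        aln = CodonAlignment(["a", "b"], ["---", "AT-"])
        with pytest.raises(ValueError):
            neutrality_stats(aln)

    def test_hap_div_bounds_and_k1_iff_zero(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            aln = random_alignment(rng, int(rng.integers(2, 10)), 10)
            st = neutrality_stats(aln)
            assert 0.0 <= st.hap_div <= 1.0
            assert (st.hap_div == 0.0) == (st.K == 1)
            assert st.K <= st.n

    def test_strobeck_bounds_and_theta_zero(self):
        assert strobeck_s(10, 1, 0.0) == 1.0
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(2, 15))
            k = int(rng.integers(1, n + 1))
            s = strobeck_s(n, k, float(rng.uniform(0.01, 10)))
            assert 0.0 <= s <= 1.0 + 1e-12
        # at K=n the cumulative Ewens probability is 1
        assert strobeck_s(6, 6, 2.5) == pytest.approx(1.0)

    def test_tajima_d_sign_on_extreme_genealogies(self):
        # star-like: every sequence carries private singletons -> D < 0
        n, L = 12, 120
        base = ["A"] * L
        rows = []
        for i in range(n):
            s = base.copy()
            for j in range(5):
                s[(i * 5 + j) % L] = "T"
            rows.append("".join(s))
        star = neutrality_stats(
            CodonAlignment([f"s{i}" for i in range(n)], rows))
        assert star.tajima_d < 0

        # deep balanced split: two haplotype groups at intermediate
        # frequency -> D > 0
        hap1 = "A" * L
        hap2 = "T" * 30 + "A" * (L - 30)
        rows = [hap1] * 6 + [hap2] * 6
        deep = neutrality_stats(
            CodonAlignment([f"s{i}" for i in range(n)], rows))
        assert deep.tajima_d > 0


class TestTajimaDNull:
    def test_neutral_mean_near_zero(self):
        out = tajima_d_null(20, 5 / 300, reps=400, seed=3, length=300)
        se = out["sd"] / math.sqrt(out["n_defined"])
        # slightly negative in finite samples; must be within 3 SE of 0
        assert abs(out["mean"]) < 3 * se + 0.15

    def test_theta_zero_reported_undefined(self):
        out = tajima_d_null(10, 0.0, reps=200, seed=1)
        assert math.isnan(out["mean"])
        assert out["n_undefined"] == 200

    def test_deterministic_given_seed(self):
        a = tajima_d_null(8, 0.02, reps=200, seed=9, length=120)
        b = tajima_d_null(8, 0.02, reps=200, seed=9, length=120)
        assert a == b


class TestAnnotateColumns:
    def _aln(self, rows):
        return CodonAlignment(list(rows), list(rows.values()))

    def test_unanimous_and_majority(self):
        aln = self._aln({f"g{i}": "ATGATGATG" for i in range(5)})
        doms = {f"g{i}": [DI(f"g{i}", "NB", 1, 3)] for i in range(3)}
        doms.update({f"g{i}": [DI(f"g{i}", "LRR", 1, 3)] for i in range(3, 5)})
        labels = annotate_columns(aln, doms)
        assert labels == ["NB", "NB", "NB"]

    def test_even_split_gives_none(self):
        aln = self._aln({f"g{i}": "ATGATG" for i in range(4)})
        doms = {"g0": [DI("g0", "NB", 1, 2)], "g1": [DI("g1", "NB", 1, 2)],
                "g2": [DI("g2", "LRR", 1, 2)], "g3": [DI("g3", "LRR", 1, 2)]}
        assert annotate_columns(aln, doms) == ["none", "none"]

    def test_interval_beyond_protein_rejected(self):
        aln = self._aln({"g0": "ATGATG", "g1": "ATGATG"})
        with pytest.raises(ValueError):
            annotate_columns(aln, {"g0": [DI("g0", "NB", 1, 99)]})


class TestDomainSubsetStats:
    def test_all_columns_one_domain_equals_full_stats(self):
        rng = np.random.default_rng(21)
        aln = random_alignment(rng, 6, 20)
        full = neutrality_stats(aln)
        sub = domain_subset_stats(aln, ["NB"] * 20, "NB")
        assert sub.pi == pytest.approx(full.pi)
        assert sub.S == full.S

    def test_absent_domain_gives_sentinel(self):
        rng = np.random.default_rng(22)
        aln = random_alignment(rng, 4, 10)
        sub = domain_subset_stats(aln, ["NB"] * 10, "TIR")
        assert sub.L == 0 and math.isnan(sub.pi)

    def test_variable_lrr_vs_constant_nb(self):
        # mutations only in the LRR half -> pi(LRR) > pi(NB) = 0
        n, half = 6, 10
        rows = []
        for i in range(n):
            nb = "ATG" * half
            lrr = "".join("ATC" if (j + i) % 3 else "AGG"
                          for j in range(half))
            rows.append(nb + lrr)
        aln = CodonAlignment([f"g{i}" for i in range(n)], rows)
        labels = ["NB"] * half + ["LRR"] * half
        assert domain_subset_stats(aln, labels, "NB").pi == 0.0
        assert domain_subset_stats(aln, labels, "LRR").pi > 0.0


class TestInvariableCodons:
    def test_identical_rows_all_invariable(self):
        aln = CodonAlignment(["a", "b"], ["ATGATGATGATGATGATGATGATGATGATG"] * 2)
        count, pos = invariable_codons(aln)
        assert count == 10 and pos == list(range(10))

    def test_one_variable_codon(self):
        aln = CodonAlignment(["a", "b"], ["ATGATGATGATG", "ATGATGATGTTG"])
        count, _ = invariable_codons(aln)
        assert count == 3

    def test_gapped_codon_not_invariable(self):
        aln = CodonAlignment(["a", "b"], ["ATG---", "ATGATG"])
        count, pos = invariable_codons(aln)
        assert count == 1 and pos == [0]


class TestFlagEnrichment:
    def test_og_equal_to_universe_gives_p_one(self):
        df = flag_enrichment({("OG1", "paired"): 5}, {"OG1": 20},
                             {"paired": 5}, universe_size=20)
        assert df["p"].iloc[0] == pytest.approx(1.0)

    def test_exact_hypergeometric_fully_flagged_og(self):
        df = flag_enrichment({("OG1", "paired"): 5}, {"OG1": 5},
                             {"paired": 5}, universe_size=20)
        assert df["p"].iloc[0] == pytest.approx(1 / comb(20, 5, exact=True))

    def test_bh_matches_reference_step_up(self):
        rng = np.random.default_rng(31)
        counts = {}
        sizes = {}
        for i in range(12):
            sizes[f"OG{i}"] = 10
            counts[(f"OG{i}", "clustered")] = int(rng.integers(0, 6))
        df = flag_enrichment(counts, sizes, {"clustered": 40}, 200)
        p = df["p"].to_numpy()
        # independent step-up BH
        m = len(p)
        order = np.argsort(p)
        q_ref = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, p[order[rank]] * m / (rank + 1))
            q_ref[order[rank]] = running
        assert df["q"].to_numpy() == pytest.approx(q_ref)
        # q monotone in p
        qs = df.sort_values("p")["q"].to_numpy()
        assert (np.diff(qs) >= -1e-12).all()

    def test_inconsistent_totals_rejected(self):
        with pytest.raises(ValueError):
            flag_enrichment({("OG1", "f"): 6}, {"OG1": 5}, {"f": 5}, 20)


class TestPairCorrelation:
    def test_identical_vectors(self):
        assert pair_correlation([1, 2, 3], [1, 2, 3])["r"] == pytest.approx(1)

    def test_negated_vectors(self):
        out = pair_correlation([1, 2, 3], [-1, -2, -3])
        assert out["r"] == pytest.approx(-1)

    def test_matches_direct_covariance_formula(self):
        a, b = [1, 2, 3], [2, 4, 6.5]
        out = pair_correlation(a, b)
        am, bm = np.mean(a), np.mean(b)
        cov = np.sum((np.array(a) - am) * (np.array(b) - bm))
        r = cov / np.sqrt(np.sum((np.array(a) - am) ** 2)
                          * np.sum((np.array(b) - bm) ** 2))
        assert out["r"] == pytest.approx(r)
        assert out["slope"] == pytest.approx(
            cov / np.sum((np.array(a) - am) ** 2))

    def test_zero_variance_sentinel(self):
        out = pair_correlation([1, 1, 1], [1, 2, 3])
        assert math.isnan(out["r"])


class TestExpressionThreshold:
    def test_separated_supports(self):
        rng = np.random.default_rng(41)
        intron = rng.integers(0, 11, size=300)
        nlr = rng.integers(1000, 5000, size=300)
        t = expression_threshold(nlr, intron)
        assert 10 < t <= 1000

    def test_identical_distributions_sentinel(self):
        x = np.arange(1, 100)
        assert math.isnan(expression_threshold(x, x))

    def test_mixture_threshold_between_modes(self):
        rng = np.random.default_rng(42)
        bg = np.exp(rng.normal(np.log(20), 0.3, size=2000))
        sig = np.exp(rng.normal(np.log(500), 0.3, size=2000))
        t = expression_threshold(sig, bg)
        assert 20 < t < 500
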