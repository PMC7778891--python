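"""Enrichment statistics against exact-rational brute-force oracles, the
independent scipy/statsmodels implementations, and simulation calibration."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from phylograft import synthetic_data as synth
from phylograft.enrichment import (
    adjust_pvalues,
    binomial_term_test,
    fisher_exact_2x2,
    run_overrepresentation,
    run_value_enrichment,
)


def fisher_oracle(k, n, K, N) -> float:
    """Exact rational hypergeometric minimum-likelihood two-sided p."""
    denom = comb(N, n)
    pmf = {
        x: Fraction(comb(K, x) * comb(N - K, n - x), denom)
        for x in range(max(0, n - (N - K)), min(n, K) + 1)
    }
    pk = pmf[k]
    return float(sum(p for p in pmf.values() if p <= pk * (1 + Fraction(1, 10**7))))


def binom_oracle(k, n, p0) -> float:
    pmf = [comb(n, x) * p0**x * (1 - p0) ** (n - x) for x in range(n + 1)]
    return min(1.0, sum(p for p in pmf if p <= pmf[k] * (1 + 1e-7)))


class TestFisher:
    def test_proportional_table_gives_one(self):
        assert fisher_exact_2x2(2, 4, 5, 10) == pytest.approx(1.0, abs=1e-12)

    def test_empty_list_gives_one(self):
        assert fisher_exact_2x2(0, 0, 5, 10) == 1.0

    def test_matches_direct_enumeration(self):
        assert fisher_exact_2x2(5, 10, 10, 100) == pytest.approx(
            fisher_oracle(5, 10, 10, 100), rel=1e-10
        )

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(6, 5, 10, 100)
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 50, 10, 40)  # n-k > N-K impossible

    def test_exhaustive_small_tables_match_oracle(self):
        """All consistent tables with n <= 12, N <= 16 match the exact
        rational enumeration oracle."""
        for N in (4, 9, 16):
            for n in range(0, min(N, 12) + 1):
                for K in range(0, N + 1):
                    for k in range(max(0, n - (N - K)), min(n, K) + 1):
                        got = fisher_exact_2x2(k, n, K, N)
                        want = fisher_oracle(k, n, K, N)
                        assert got == pytest.approx(want, rel=1e-9), (k, n, K, N)

    @pytest.mark.parametrize("k,n,K,N", [(5, 10, 10, 100), (1, 30, 40, 200), (12, 20, 30, 60)])
    def test_agrees_with_scipy_fisher(self, k, n, K, N):
        """Independent cross-check: scipy's two-sided Fisher on the same 2x2."""
        from scipy.stats import fisher_exact as scipy_fisher

        table = [[k, n - k], [K - k, (N - K) - (n - k)]]
        assert fisher_exact_2x2(k, n, K, N) == pytest.approx(
            scipy_fisher(table)[1], rel=1e-6
        )


class TestBinomial:
    def test_degenerate_null_gives_one(self):
        assert binomial_term_test(0, 0, 0.0) == 1.0
        assert binomial_term_test(0, 5, 0.0) == 1.0

    def test_symmetric_center_gives_one(self):
        assert binomial_term_test(5, 10, 0.5) == pytest.approx(1.0, abs=1e-12)

    def test_exhaustive_small_cases_match_oracle(self):
        for n in range(0, 13):
            for p0 in (0.1, 0.3, 0.5, 0.77):
                for k in range(n + 1):
                    assert binomial_term_test(k, n, p0) == pytest.approx(
                        binom_oracle(k, n, p0), rel=1e-9
                    ), (k, n, p0)


class TestAdjustPvalues:
    def test_bonferroni(self):
        assert adjust_pvalues([0.01] * 5, "bonferroni")[0] == pytest.approx(0.05)

    def test_bh_stepup_hand_computed(self):
        got = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "fdr_bh")
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_none_is_identity(self):
        p = [0.5, 0.01, 0.99]
        assert adjust_pvalues(p, "none") == pytest.approx(p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "fdr_bh")

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_statsmodels_on_random_vectors(self, seed):
        """BH and Bonferroni agree with the independent statsmodels
        implementation, order preserved."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = list(rng.random(int(rng.integers(1, 40))))
        for ours, theirs in (("fdr_bh", "fdr_bh"), ("bonferroni", "bonferroni")):
            got = adjust_pvalues(p, ours)
            want = multipletests(p, method=theirs)[1]
            assert got == pytest.approx(list(want), rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_ordering_invariants(self, seed):
        rng = np.random.default_rng(seed)
        p = np.sort(rng.random(20))
        bh = adjust_pvalues(list(p), "fdr_bh")
        bon = adjust_pvalues(list(p), "bonferroni")
        # tolerances absorb one-ULP rounding in p * m / rank
        assert all(b >= r - 1e-12 for b, r in zip(bh, p))  # BH >= raw
        assert all(bo >= b - 1e-12 for bo, b in zip(bon, bh))  # BH <= Bonferroni
        assert bh == sorted(bh)  # monotone in raw-p rank


class TestOverrepresentation:
    def test_list_equals_reference_all_null(self):
        genes = [f"G{i}" for i in range(50)]
        tm = {"T1": set(genes[:10]), "T2": set(genes[5:30])}
        rows = run_overrepresentation(genes, genes, tm, correction="none")
        for r in rows:
            assert r.p_raw == pytest.approx(1.0)
            assert r.fold_enrichment == pytest.approx(1.0)

    def test_out_of_reference_gene_requires_union(self):
        with pytest.raises(ValueError, match="union"):
            run_overrepresentation(["X"], ["A", "B"], {"T": {"A"}})
        rows = run_overrepresentation(["X"], ["A", "B"], {"T": {"A"}}, union=True)
        assert rows[0].ref_size == 3

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty reference"):
            run_overrepresentation([], [], {"T": {"A"}})

    def test_terms_without_reference_genes_skipped(self):
        rows = run_overrepresentation(["A"], ["A", "B"], {"T": {"Z"}})
        assert rows == []

    def test_planted_enrichment_detected(self):
        """A term sampled with 5x odds has the smallest raw p in >= 95 of 100
        seeded replicates (list 100 of 2000)."""
        genes = [f"G{i + 1:05d}" for i in range(2000)]
        tm = synth.simulate_term_map(genes, n_terms=10, genes_per_term=200, seed=11)
        target = "TERM0001"
        wins = 0
        for seed in range(100):
            lst, ref = synth.simulate_gene_list(
                2000, 100, tm, target, odds=5.0, seed=seed, genes=genes
            )
            rows = run_overrepresentation(lst, ref, tm, correction="none")
            if rows[0].term_id == target:
                wins += 1
        assert wins >= 95

    def test_null_rejections_valid_never_anticonservative(self):
        """Uniform random lists: the exact test's rejection rate at 0.05 is
        at most nominal (validity) and not grossly conservative at this
        discreteness (the acceptance suite checks the calibrated band at a
        near-continuous scale)."""
        genes = [f"G{i + 1:05d}" for i in range(2000)]
        tm = synth.simulate_term_map(genes, n_terms=10, genes_per_term=200, seed=42)
        rng = np.random.default_rng(123)
        hits = total = 0
        for _ in range(400):
            lst = list(rng.choice(genes, size=100, replace=False))
            for r in run_overrepresentation(lst, genes, tm, correction="none"):
                hits += r.p_raw < 0.05
                total += 1
        rate = hits / total
        assert 0.02 <= rate <= 0.06


class TestValueEnrichment:
    def test_identical_distributions_p_near_one(self):
        rng = np.random.default_rng(0)
        vals = {f"G{i}": float(v) for i, v in enumerate(rng.normal(size=200))}
        tm = {"T": set(list(vals)[:50])}
        rows, skipped = run_value_enrichment(vals, tm, correction="none")
        assert not skipped
        assert rows[0].p_raw > 0.05

    def test_shifted_term_strongly_significant(self):
        """In-term values shifted by +3 SD (50 vs 500 genes) give p < 1e-6."""
        rng = np.random.default_rng(0)
        vals = {}
        for i in range(500):
            vals[f"BG{i}"] = float(rng.normal())
        for i in range(50):
            vals[f"IN{i}"] = float(rng.normal(loc=3.0))
        rows, _ = run_value_enrichment(vals, {"T": {f"IN{i}" for i in range(50)}}, "none")
        assert rows[0].p_raw < 1e-6
        assert rows[0].direction == "over"

    def test_degenerate_terms_skipped_with_note(self):
        vals = {"A": 1.0, "B": 2.0, "C": 3.0}
        rows, skipped = run_value_enrichment(vals, {"ALL": {"A", "B", "C"}, "NONE": set()})
        assert rows == []
        assert len(skipped) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_u_statistic_matches_pair_enumeration(self, seed):
        """U equals the exhaustive count of (in, out) pairs where the in-term
        value wins (ties half), for groups <= 8."""
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 9)), int(rng.integers(2, 9))
        x = rng.integers(0, 6, n1).astype(float)  # small ints force ties
        y = rng.integers(0, 6, n2).astype(float)
        vals = {f"A{i}": float(v) for i, v in enumerate(x)}
        vals.update({f"B{i}": float(v) for i, v in enumerate(y)})
        rows, _ = run_value_enrichment(vals, {"T": {f"A{i}" for i in range(n1)}}, "none")
        u_brute = sum(
            1.0 if xi > yi else (0.5 if xi == yi else 0.0)
            for xi, yi in itertools.product(x, y)
        )
        assert rows[0].u_statistic == pytest.approx(u_brute)
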