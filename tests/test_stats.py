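"""Exact and permutation association tests against enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from ohnoshift.stats import (
    complex_label_permutation,
    fisher_exact,
    fractionation_bias_test,
    pathway_enrichment,
    spearman_correlation,
    wilcoxon_signed_rank,
)


def wilcoxon_enumeration(d, alternative):
    """Oracle: exhaustive 2^n sign enumeration with average ranks."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ge = le = total = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        total += 1
        ge += w >= w_obs - 1e-9
        le += w <= w_obs + 1e-9
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2 * min(ge, le) / total)


class TestWilcoxon:
    def test_all_positive_n5_one_sided(self):
        x = np.array([1.0, 2.0, 0.5, 3.0, 1.5])
        w, p = wilcoxon_signed_rank(x, np.zeros(5), alternative="greater")
        assert p == pytest.approx(1 / 32)
        assert w == 15.0

    def test_identical_vectors_degenerate(self):
        with pytest.warns(UserWarning):
            _, p = wilcoxon_signed_rank(np.ones(4), np.ones(4))
        assert p == 1.0

    @pytest.mark.parametrize("alternative", ["greater", "less", "two-sided"])
    def test_matches_enumeration_random(self, alternative):
        rng = np.random.default_rng(7)
        for _ in range(15):
            n = int(rng.integers(3, 13))
            d = np.round(rng.normal(0.3, 1, n), 2)
            # include exact ties in |d| sometimes
            if n > 4 and rng.random() < 0.5:
                d[1] = -d[0]
            d = d[d != 0]
            if len(d) == 0:
                continue
            _, p = wilcoxon_signed_rank(d, alternative=alternative)
            assert p == pytest.approx(wilcoxon_enumeration(d, alternative), abs=1e-12)

    def test_normal_approximation_above_cutoff(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.5, 1, 60)
        _, p_approx = wilcoxon_signed_rank(x, alternative="greater", exact_max_n=25)
        from scipy.stats import wilcoxon as scipy_wilcoxon
        ref = scipy_wilcoxon(x, alternative="greater", correction=True,
                             method="approx").pvalue
        assert p_approx == pytest.approx(ref, rel=1e-6)


def hypergeom_tail(a, b, c, d):
    """Oracle: one-sided Fisher p by direct hypergeometric enumeration."""
    n1, n2, m = a + b, c + d, a + c
    def pr(k):
        return (math.comb(n1, k) * math.comb(n2, m - k)) / math.comb(n1 + n2, m)
    return sum(pr(k) for k in range(a, min(n1, m) + 1))


class TestFisher:
    def test_worked_example(self):
        assert fisher_exact([[3, 1], [1, 3]], "greater") == pytest.approx(17 / 70)

    def test_closed_form_antidiagonal(self):
        # the most extreme anti-diagonal table: p = 1/C(2n, n) at n = 2
        assert fisher_exact([[0, 2], [2, 0]], "less") == pytest.approx(1 / 6)

    def test_matches_enumeration_random(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum(0).min() == 0 or t.sum(1).min() == 0:
                continue
            assert fisher_exact(t, "greater") == pytest.approx(
                hypergeom_tail(*t.ravel()), abs=1e-12)

    def test_transpose_symmetry_two_sided(self):
        t = np.array([[5, 2], [1, 7]])
        assert fisher_exact(t) == pytest.approx(fisher_exact(t.T))

    def test_empty_margin(self):
        assert fisher_exact([[0, 0], [3, 4]]) == 1.0

    def test_monotone_in_diagonal_excess(self):
        # fixed margins (10, 10) x (10, 10): p decreases as a grows
        ps = [fisher_exact([[a, 10 - a], [10 - a, a]], "greater") for a in range(5, 11)]
        assert all(x > y for x, y in zip(ps, ps[1:]))


class TestEnrichment:
    def test_gene_set_equals_background(self):
        ann = pd.DataFrame({"gene": ["g1", "g2", "g3"], "term": ["A", "A", "B"]})
        bg = {"g1", "g2", "g3"}
        out = pathway_enrichment(bg, bg, ann)
        assert (out["p"] == 1.0).all()

    def test_hand_computed_toy(self):
        # background 10 genes; term T covers 4; set of 5 hits 3 of them
        bg = {f"g{i}" for i in range(10)}
        ann = pd.DataFrame({"gene": [f"g{i}" for i in range(4)], "term": ["T"] * 4})
        gs = {"g0", "g1", "g2", "g8", "g9"}
        out = pathway_enrichment(gs, bg, ann).set_index("term")
        # P(X >= 3), X ~ Hypergeom(N=10, K=4, n=5)
        expect = (math.comb(4, 3) * math.comb(6, 2) + math.comb(4, 4) * math.comb(6, 1)) \
            / math.comb(10, 5)
        assert out.loc["T", "p"] == pytest.approx(expect, abs=1e-12)
        assert (out.loc["T", ["k", "K", "n", "N"]] == [3, 4, 5, 10]).all()

    def test_planted_term_attains_min_p(self, cohort):
        from ohnoshift.stats import pathway_enrichment as pe
        truth = cohort.truth
        ann = cohort.pathway_annotation
        down_ogs = set(truth.pairs[truth.pairs["category"].str.contains("down")]["orthogroup"])
        og_of = dict(zip(truth.genes["gene"], truth.genes["orthogroup"]))
        og_ann = (ann.assign(og=ann["gene"].map(og_of))
                  .drop_duplicates(["og", "term"])[["og", "term"]]
                  .rename(columns={"og": "gene"}))
        bg = set(truth.pairs["orthogroup"])
        out = pe(down_ogs & bg, bg, og_ann)
        best = out.sort_values("p").iloc[0]
        assert best["term"] == truth.planted_pathway

    def test_set_outside_background_rejected(self):
        with pytest.raises(ValueError):
            pathway_enrichment({"x"}, {"y"}, pd.DataFrame({"gene": [], "term": []}))


class TestComplexPermutation:
    def test_exhaustive_small_case(self):
        """Empirical p within 3 SE of the exact enumeration over all
        distinct label arrangements (6 genes, 2 complexes)."""
        genes = [f"g{i}" for i in range(6)]
        labels = dict(zip(genes, ["singleton"] * 3 + ["ohnolog"] * 3))
        complexes = {"c1": {"g0", "g1"}, "c2": {"g3", "g4", "g5"}}
        lab = np.array(list(labels.values()))
        members = [np.array([0, 1]), np.array([3, 4, 5])]
        obs = sum(np.all(lab[m] == "singleton") for m in members)
        hits = total = 0
        for perm in itertools.permutations(range(6)):
            pl = lab[list(perm)]
            stat = sum(np.all(pl[m] == "singleton") for m in members)
            total += 1
            hits += stat >= obs
        exact = hits / total
        n_perm = 4000
        _, p = complex_label_permutation(complexes, labels, n_perm=n_perm,
                                         statistic="n_only_singleton", seed=3)
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(p - exact) < 3 * se + 1 / n_perm

    def test_single_one_gene_complex_constant(self):
        labels = {"g0": "singleton", "g1": "ohnolog"}
        obs, p = complex_label_permutation({"c": {"g0"}}, labels, n_perm=200,
                                           statistic="n_only_ohnolog", seed=0)
        # statistic is 0 or 1 with equal chance under permutation; observed 0
        assert obs == 0 and p == 1.0

    def test_small_nperm_warns(self):
        with pytest.warns(UserWarning):
            complex_label_permutation({"c": {"g0"}}, {"g0": "singleton"}, n_perm=10)

    def test_super_uniform_under_null(self):
        """The (b+1)/(n+1) estimator is conservative: under label
        exchange, P(p <= q) <= q + slack."""
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(12)]
        complexes = {f"c{j}": set(rng.choice(genes, 3, replace=False)) for j in range(4)}
        ps = []
        for rep in range(60):
            lab = rng.permutation(["singleton"] * 6 + ["ohnolog"] * 6)
            labels = dict(zip(genes, lab))
            _, p = complex_label_permutation(complexes, labels, n_perm=400,
                                             statistic="n_only_singleton", seed=rep)
            ps.append(p)
        ps = np.array(ps)
        for q in (0.1, 0.25, 0.5):
            assert (ps <= q).mean() <= q + 0.12


class TestFractionation:
    def test_symmetric_block(self):
        df, n = fractionation_bias_test(pd.DataFrame({"losses_a": [5], "losses_b": [5]}))
        assert df.iloc[0]["p"] == pytest.approx(1.0)
        assert n == 0

    def test_extreme_block_closed_form(self):
        df, n = fractionation_bias_test(pd.DataFrame({"losses_a": [10], "losses_b": [0]}))
        assert df.iloc[0]["p"] == pytest.approx(2 / 1024)
        assert n == 1

    def test_matches_tail_summation(self):
        rng = np.random.default_rng(11)
        rows = [{"losses_a": int(rng.integers(0, 15)), "losses_b": int(rng.integers(0, 15))}
                for _ in range(20)]
        df, _ = fractionation_bias_test(pd.DataFrame(rows))
        for row, rec in zip(rows, df.itertuples(index=False)):
            a, b = row["losses_a"], row["losses_b"]
            if a + b == 0:
                assert not rec.tested
                continue
            n = a + b
            probs = np.array([math.comb(n, k) for k in range(n + 1)], dtype=float) / 2 ** n
            # two-sided: sum of outcomes no more probable than observed
            expect = probs[probs <= probs[a] + 1e-12].sum()
            assert rec.p == pytest.approx(expect, abs=1e-10)

    def test_empty_block_untested(self):
        df, n = fractionation_bias_test(pd.DataFrame({"losses_a": [0], "losses_b": [0]}))
        assert not df.iloc[0]["tested"] and n == 0


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(8.0)
        assert spearman_correlation(x, x ** 3)[0] == pytest.approx(1.0)
        assert spearman_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_exact_permutation_n8(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(size=8), rng.normal(size=8)
        rho, p = spearman_correlation(x, y)
        rx, ry = rankdata(x), rankdata(y)
        def rho_of(a, b):
            a, b = a - a.mean(), b - b.mean()
            return a @ b / math.sqrt((a @ a) * (b @ b))
        hits = total = 0
        for perm in itertools.permutations(range(8)):
            total += 1
            hits += abs(rho_of(rx, ry[list(perm)])) >= abs(rho) - 1e-12
        assert p == pytest.approx(hits / total, abs=1e-12)

    def test_large_n_uses_t_approximation(self):
        from scipy.stats import spearmanr
        rng = np.random.default_rng(14)
        x, y = rng.normal(size=40), rng.normal(size=40)
        rho, p = spearman_correlation(x, y)
        ref = spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_correlation(np.ones(5), np.arange(5.0))
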