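"""Association tests: paired signed-rank, Fisher, hypergeometric
enrichment, label permutation, per-block binomial fractionation bias,
and Spearman rank correlation.

The signed-rank test is exact (full sign-assignment distribution,
average ranks on ties) up to n = 25 and falls back to the normal
approximation with tie and continuity corrections above that.  Spearman
p-values are exact by permutation enumeration at n <= 10.  Permutation
p-values use the (b + 1) / (n + 1) estimator so they are never exactly
zero.  No multiple-testing correction is applied unless the caller asks
for it, matching the raw-p reporting convention of the analysis.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "wilcoxon_signed_rank",
    "fisher_exact",
    "pathway_enrichment",
    "complex_label_permutation",
    "fractionation_bias_test",
    "spearman_correlation",
]


def _exact_wplus_tail(ranks: np.ndarray, w_obs: float) -> tuple[float, float]:
    """P(W+ >= w_obs) and P(W+ <= w_obs) under random signs.

    Ranks may be half-integer (average ranks on ties); they are doubled
    to integers and the distribution of the doubled statistic is built
    by dynamic programming over all 2^n sign assignments.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2 * w_obs))
    return float(counts[w2:].sum()), float(counts[: w2 + 1].sum())


def wilcoxon_signed_rank(
    x: np.ndarray,
    y: np.ndarray | None = None,
    alternative: str = "two-sided",
    exact_max_n: int = 25,
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (W+, p).

    ``alternative="greater"`` tests for x > y (positive differences).
    Zero differences are dropped; if all are zero the test is degenerate
    and p = 1.  Exact sign enumeration up to ``exact_max_n`` informative
    pairs, then the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero", stacklevel=2)
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        p_ge, p_le = _exact_wplus_tail(ranks, w_plus)
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
        sd = math.sqrt(var)
        p_ge = float(sps.norm.sf((w_plus - mean - 0.5) / sd))
        p_le = float(sps.norm.cdf((w_plus - mean + 0.5) / sd))

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return w_plus, float(p)


def fisher_exact(table, alternative: str = "two-sided") -> float:
    """Fisher's exact test p-value for a 2x2 table.

    One-sided p is the hypergeometric tail; the two-sided p sums the
    probabilities of tables no more probable than the observed one.
    Empty margins give p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return 1.0
    return float(sps.fisher_exact(t, alternative=alternative)[1])


def pathway_enrichment(
    gene_set: set[str],
    background: set[str],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term.

    ``annotation`` columns: gene, term.  Only background genes count;
    terms with no background gene are skipped; terms with no gene-set hit
    are reported with p = 1.  Returns columns (term, k, K, n, N, p) where
    k of the n set genes hit the term's K background genes out of N.
    """
    gene_set = set(gene_set)
    background = set(background)
    if not gene_set <= background:
        raise ValueError("gene_set must be a subset of background")
    ann = annotation[annotation["gene"].isin(background)]
    N, n = len(background), len(gene_set)
    rows = []
    for term, sub in ann.groupby("term", sort=True):
        term_genes = set(sub["gene"])
        K = len(term_genes)
        k = len(term_genes & gene_set)
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    return pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])


def complex_label_permutation(
    complexes: dict[str, set[str]],
    labels: dict[str, str],
    n_perm: int = 10_000,
    statistic: str = "n_only_singleton",
    seed: int = 0,
) -> tuple[int, float]:
    """Empirical test for label-homogeneous protein complexes.

    Counts complexes whose members all carry one label ("singleton" or
    "ohnolog"), then permutes the gene labels ``n_perm`` times; the
    empirical p is (1 + #{permuted >= observed}) / (1 + n_perm).
    """
    if statistic not in ("n_only_singleton", "n_only_ohnolog"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} is small; empirical p will be coarse", stacklevel=2)
    target = "singleton" if statistic == "n_only_singleton" else "ohnolog"
    genes = sorted(labels)
    lab = np.array([labels[g] for g in genes])
    gi = {g: i for i, g in enumerate(genes)}
    members = []
    for name in sorted(complexes):
        idx = [gi[g] for g in complexes[name] if g in gi]
        if idx:
            members.append(np.array(idx))

    def count(lab_vec: np.ndarray) -> int:
        return sum(1 for idx in members if np.all(lab_vec[idx] == target))

    observed = count(lab)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += count(rng.permutation(lab)) >= observed
    return observed, (1 + hits) / (1 + n_perm)


def fractionation_bias_test(
    blocks: pd.DataFrame, threshold: float = 0.05
) -> tuple[pd.DataFrame, int]:
    """Per-duplicate-block exact binomial test of gene-loss symmetry.

    ``blocks`` columns: losses_a, losses_b.  Each block with at least
    one loss is tested two-sided against Binomial(losses_a + losses_b,
    1/2); blocks with no losses are untested.  Returns the per-block
    table (with p and tested flag) and the number of blocks significant
    at ``threshold``.
    """
    rows = []
    n_sig = 0
    for rec in blocks.itertuples(index=False):
        a, b = int(rec.losses_a), int(rec.losses_b)
        if a < 0 or b < 0:
            raise ValueError("loss counts must be nonnegative")
        if a + b == 0:
            rows.append({"losses_a": a, "losses_b": b, "p": np.nan, "tested": False})
            continue
        p = float(sps.binomtest(a, a + b, 0.5, alternative="two-sided").pvalue)
        n_sig += p < threshold
        rows.append({"losses_a": a, "losses_b": b, "p": p, "tested": True})
    return pd.DataFrame(rows), int(n_sig)


def spearman_correlation(x: np.ndarray, y: np.ndarray, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with average ranks on ties.

    p-value by exhaustive permutation of one margin for n <= ``exact_max_n``
    (two-sided on |rho|), else the t-distribution approximation.
    Constant input is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rx, ry = sps.rankdata(x), sps.rankdata(y)

    def rho_of(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    rho = rho_of(rx, ry)
    n = len(x)
    if n <= exact_max_n:
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            hits += abs(rho_of(rx, ry[list(perm)])) >= abs(rho) - 1e-12
        return rho, hits / total
    return rho, float(sps.spearmanr(x, y).pvalue)
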