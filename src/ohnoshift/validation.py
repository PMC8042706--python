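"""Validation harness: the package's own end-to-end checks.

Each function here recomputes a headline property of the method from
scratch — likelihood correctness against direct multivariate-normal
evaluation, null calibration and power of the shift test, planted-truth
recovery by the full pipeline, TMM agreement with an independent
reference implementation, and exact-test agreement with enumeration
oracles.  The acceptance script and the acceptance test suite both call
these, so the reported numbers are always produced by live computation.
"""

from __future__ import annotations

import itertools
import json
import math
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal, rankdata

from . import eve
from .intervals import overlap_fraction
from .normalization import tmm_factor
from .pipeline import PipelineConfig, run_pipeline
from .stats import fisher_exact, fractionation_bias_test, wilcoxon_signed_rank
from .synthetic import SimConfig, make_roles, simulate_species_tree
from .trees import parse_newick

__all__ = [
    "loglik_oracle_dev",
    "type1_simulation",
    "recovery_simulation",
    "cohort_recovery",
    "tmm_reference_dev",
    "overlap_bitmap_dev",
    "exact_test_devs",
    "determinism_check",
]


def _random_newick(rng: np.random.Generator, n_tips: int) -> str:
    nodes = [f"T{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        la, lb = rng.uniform(0.05, 1.5, size=2)
        merged = f"({nodes[i]}:{la:.6f},{nodes[j]}:{lb:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"


def loglik_oracle_dev(seed: int, n_cases: int = 100) -> float:
    """Max |log L - direct MVN log density| over random trees (<= 6 tips,
    <= 3 replicates/species) with random regimes and parameters."""
    rng = np.random.default_rng([seed, 101])
    worst = 0.0
    for _ in range(n_cases):
        t = parse_newick(_random_newick(rng, int(rng.integers(2, 7))))
        sm = {lbl: int(rng.integers(1, 4)) for lbl in t.tip_labels}
        tip = rng.choice(t.tip_labels)
        painting = (eve.paint_ingroup_clade(t, [tip])
                    if t.parent[t.tip_index(tip)] != -1
                    else np.zeros(t.n_nodes, dtype=np.int64))
        nreg = int(painting.max()) + 1
        params = eve.OUParams(
            tuple(rng.normal(3, 2, nreg)), float(rng.uniform(0.2, 3)),
            float(rng.uniform(0.3, 2)), float(rng.uniform(0.1, 1)))
        y = rng.normal(3, 1.5, sum(sm.values()))
        mu = eve.ou_mean_vector(t, painting, params)
        idx = np.concatenate([[i] * sm[lbl] for i, lbl in enumerate(t.tip_labels)]).astype(int)
        C = eve.ou_covariance(t, params, sm)
        ref = multivariate_normal(mu[idx], C).logpdf(y)
        worst = max(worst, abs(eve.log_likelihood(y, t, painting, params, sm) - ref))
    return float(worst)


def _default_tree_setup(seed: int):
    cfg = SimConfig(seed=seed)
    tree = simulate_species_tree(cfg)
    roles = make_roles(cfg)
    painting = eve.paint_ingroup_clade(tree, sorted(roles.ingroup))
    sm = {l: cfg.replicates_per_species for l in tree.tip_labels}
    return cfg, tree, painting, sm


def type1_simulation(seed: int, n_genes: int = 500) -> float:
    """Fraction of null genes (no shift) called significant by the
    two-optima test at the chi2(1) 95% cutoff, on the default 7-taxon
    tree with 4 replicates per species."""
    cfg, tree, painting, sm = _default_tree_setup(seed)
    params = eve.OUParams((cfg.theta_mean,), cfg.alpha, cfg.sigma2, cfg.beta)
    C = eve.ou_covariance(tree, params, sm)
    L = np.linalg.cholesky(C)
    rng = np.random.default_rng([seed, 102])
    sig = 0
    for g in range(n_genes):
        y = cfg.theta_mean + L @ rng.standard_normal(len(L))
        sig += eve.two_theta_test(y, tree, painting, sm, seed=g).significant
    return sig / n_genes


def recovery_simulation(seed: int, deltas=(0.5, 1.0, 2.0), n_genes: int = 200) -> dict:
    """Power, direction accuracy and optimum-estimate error at planted
    shift sizes (alpha * root depth = 2, beta = 0.3, 4 replicates)."""
    cfg, tree, painting, sm = _default_tree_setup(seed)
    rng = np.random.default_rng([seed, 103])
    out = {"power": {}, "direction_accuracy": {}, "median_theta_shift_error": {}}
    for delta in deltas:
        params = eve.OUParams((cfg.theta_mean, cfg.theta_mean + delta),
                              cfg.alpha, cfg.sigma2, cfg.beta)
        mu = eve.ou_mean_vector(tree, painting, params)
        idx = np.repeat(np.arange(tree.n_tips), cfg.replicates_per_species)
        C = eve.ou_covariance(tree, params, sm)
        L = np.linalg.cholesky(C)
        sig = ok_dir = 0
        errs = []
        for g in range(n_genes):
            y = mu[idx] + L @ rng.standard_normal(len(idx))
            call = eve.two_theta_test(y, tree, painting, sm, seed=g)
            sig += call.significant
            ok_dir += call.theta_shift > call.theta_base
            errs.append(call.theta_shift - (cfg.theta_mean + delta))
        out["power"][delta] = sig / n_genes
        out["direction_accuracy"][delta] = ok_dir / n_genes
        out["median_theta_shift_error"][delta] = float(np.median(errs))
    return out


def cohort_recovery(seed: int, outdir: str | None = None, **sim_kw) -> dict:
    """Run the full pipeline on a synthetic cohort and score recovery of
    the planted pair categories and study-level summaries."""
    sim = SimConfig(seed=seed, **sim_kw)
    with tempfile.TemporaryDirectory() as tmp:
        cfg = PipelineConfig(sim=sim, outdir=outdir or f"{tmp}/run", force=True)
        d = run_pipeline(cfg)
        pairs = pd.read_csv(d / "pairs.tsv", sep="\t")
        calls = pd.read_csv(d / "shift_calls.tsv", sep="\t")
        truth_pairs = pd.read_csv(d / "cohort" / "truth_pairs.tsv", sep="\t")
        truth_trees = pd.read_csv(d / "cohort" / "truth_trees.tsv", sep="\t")

    ok = pairs[(pairs["excluded"].isna()) | (pairs["excluded"] == "")].copy()
    merged = ok.merge(truth_pairs, on="orthogroup", suffixes=("_called", "_true"))
    confusion = pd.crosstab(merged["category_true"], merged["category_called"])
    cc = merged[merged["category_true"] == "cons+cons"]
    specificity = float((cc["category_called"] == "cons+cons").mean()) if len(cc) else np.nan
    accuracy = float((merged["category_true"] == merged["category_called"]).mean())

    tested = calls[calls["status"] == "tested"].merge(
        truth_trees[["orthogroup", "kind"]], on="orthogroup")
    sig_frac = {
        kind: float(sub.groupby("orthogroup")["significant"].any().mean())
        for kind, sub in tested.groupby("kind")
    }
    shifted = ok[ok["category"] != "cons+cons"]
    down_bias = float(shifted["category"].str.contains("down").mean()) if len(shifted) else np.nan
    dc = ok[(ok["category"] == "down+cons") & (ok["n_tissues_lower"] >= 0)]
    concordance = float((dc["n_tissues_lower"] > dc["n_tissues_higher"]).mean()) \
        if len(dc) else np.nan
    return {
        "confusion": confusion,
        "cons_cons_specificity": specificity,
        "category_accuracy": accuracy,
        "n_pairs": len(merged),
        "n_cons_cons_true": len(cc),
        "sig_tree_fraction": sig_frac,
        "down_bias_fraction": down_bias,
        "n_shifted_pairs": len(shifted),
        "concordance_majority_fraction": concordance,
        "n_down_cons_pairs": len(dc),
    }


# --------------------------------------------------------------------------
# oracle deviations


def tmm_reference(test, ref, logratio_trim=0.30, abs_expr_trim=0.05):
    """Independently coded textbook TMM (pandas-based ranking and
    explicit loops) serving as the reference implementation.  Ties in
    the M/A distributions take average ranks, as in the original
    definition."""
    t = pd.Series(np.asarray(test, dtype=float))
    r = pd.Series(np.asarray(ref, dtype=float))
    Nt, Nr = t.sum(), r.sum()
    keep = (t > 0) & (r > 0)
    t, r = t[keep], r[keep]
    M = np.log2(t) - np.log2(r)
    A = 0.5 * (np.log2(t) + np.log2(r))
    w = pd.Series([1.0 / ((Nt - tv) / (Nt * tv) + (Nr - rv) / (Nr * rv))
                   for tv, rv in zip(t, r)], index=M.index)
    n = len(M)
    lo = math.floor(n * logratio_trim) + 1
    loA = math.floor(n * abs_expr_trim) + 1
    rM, rA = M.rank(), A.rank()
    sel = (rM >= lo) & (rM <= n + 1 - lo) & (rA >= loA) & (rA <= n + 1 - loA)
    return float(2.0 ** ((w[sel] * M[sel]).sum() / w[sel].sum()))


def tmm_reference_dev(seed: int, n_cases: int = 50) -> tuple[float, float]:
    """(max |factor - reference| over random matrices with planted
    asymmetric DE, max |factor - 1| for identical columns)."""
    rng = np.random.default_rng([seed, 104])
    worst = 0.0
    for _ in range(n_cases):
        n = int(rng.integers(200, 800))
        base = rng.lognormal(4, 1.5, n)
        # continuous TPM-like values: exact ties (which make rank-based
        # trimming boundary-sensitive) have probability zero
        a = base * rng.lognormal(0, 0.15, n)
        b = base * rng.lognormal(0, 0.15, n)
        de = rng.choice(n, int(n * 0.1), replace=False)
        a[de] *= rng.uniform(2, 6)
        worst = max(worst, abs(tmm_factor(a, b) - tmm_reference(a, b)))
    x = rng.lognormal(4, 1.5, 500)
    ident = abs(tmm_factor(x, x) - 1.0)
    return float(worst), float(ident)


def overlap_bitmap_dev(seed: int, n_cases: int = 200) -> float:
    """Max |overlap fraction - per-base bitmap count| over random
    promoter/feature fixtures on sequences up to 10 kb."""
    rng = np.random.default_rng([seed, 105])
    worst = 0.0
    for _ in range(n_cases):
        L = int(rng.integers(200, 10_000))
        prom = pd.DataFrame([{"chrom": "c", "start": 0, "end": L, "strand": "+",
                              "gene": "g"}])
        iv = []
        for _ in range(int(rng.integers(0, 15))):
            s = int(rng.integers(0, L))
            iv.append({"chrom": "c", "start": s,
                       "end": s + int(rng.integers(1, 900)), "strand": ".",
                       "label": "TE"})
        feats = pd.DataFrame(iv, columns=["chrom", "start", "end", "strand", "label"])
        got = overlap_fraction(prom, feats)["g"]
        bitmap = np.zeros(L, dtype=bool)
        for rec in iv:
            bitmap[rec["start"]:min(rec["end"], L)] = True
        worst = max(worst, abs(got - bitmap.sum() / L))
    return float(worst)


def exact_test_devs(seed: int) -> dict:
    """Max deviations of the exact tests from direct enumeration."""
    rng = np.random.default_rng([seed, 106])

    # signed-rank vs 2^n sign enumeration
    worst_w = 0.0
    for _ in range(30):
        n = int(rng.integers(3, 13))
        d = np.round(rng.normal(0.3, 1, n), 2)
        d = d[d != 0]
        if len(d) == 0:
            continue
        ranks = rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ge = total = 0
        for signs in itertools.product((0, 1), repeat=len(d)):
            w = sum(r for s, r in zip(signs, ranks) if s)
            total += 1
            ge += w >= w_obs - 1e-9
        _, p = wilcoxon_signed_rank(d, alternative="greater")
        worst_w = max(worst_w, abs(p - ge / total))

    # Fisher vs hypergeometric tail
    worst_f = 0.0
    for _ in range(30):
        t = rng.integers(0, 12, size=(2, 2))
        if t.sum(0).min() == 0 or t.sum(1).min() == 0:
            continue
        a, b, c, d2 = map(int, t.ravel())
        n1, n2, m = a + b, c + d2, a + c
        tail = sum(math.comb(n1, k) * math.comb(n2, m - k) for k in range(a, min(n1, m) + 1)) \
            / math.comb(n1 + n2, m)
        worst_f = max(worst_f, abs(fisher_exact(t, "greater") - tail))

    # per-block binomial vs tail summation
    worst_b = 0.0
    rows = [{"losses_a": int(rng.integers(0, 15)), "losses_b": int(rng.integers(0, 15))}
            for _ in range(25)]
    df, _ = fractionation_bias_test(pd.DataFrame(rows))
    for row, rec in zip(rows, df.itertuples(index=False)):
        a, b = row["losses_a"], row["losses_b"]
        if a + b == 0:
            continue
        n = a + b
        probs = np.array([math.comb(n, k) for k in range(n + 1)], dtype=float) / 2 ** n
        expect = probs[probs <= probs[a] + 1e-12].sum()
        worst_b = max(worst_b, abs(rec.p - expect))

    return {"wilcoxon": float(worst_w), "fisher": float(worst_f), "binomial": float(worst_b)}


def determinism_check(seed: int) -> bool:
    """Two pipeline runs with identical config and seed produce
    bit-identical output files (compared by SHA-256 manifest)."""
    sim = dict(seed=seed, n_singleton_trees=8, n_ohnolog_trees=12)
    manifests = []
    for _ in range(2):
        with tempfile.TemporaryDirectory() as tmp:
            cfg = PipelineConfig(sim=SimConfig(**sim), outdir=f"{tmp}/run",
                                 n_perm=500, force=True)
            d = run_pipeline(cfg)
            manifests.append(json.loads((d / "manifest.json").read_text()))
    return manifests[0]["files"] == manifests[1]["files"]
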