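"""End-to-end pipeline: simulate -> filter -> normalize -> shift-test ->
classify -> genomic context -> association tests -> report.

Every stage writes its table under the run directory and logs row counts
in and out, so the funnel from emitted gene trees to tested units is
auditable.  A manifest (config hash, seeds, per-stage counts, SHA-256 of
every output file) makes reproducibility checkable: identical configs
and seeds give bit-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import eve, intervals, stats
from . import normalization as norm
from . import synthetic
from .trees import classify_tree, expression_filters, extract_test_units

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "summarize_run"]

ALL_STAGES = ("simulate", "filter", "normalize", "shift_test", "classify",
              "context", "stats", "report")


@dataclass
class PipelineConfig:
    """Run settings; the printed analysis thresholds are all surfaced here
    with their standard defaults."""

    sim: synthetic.SimConfig = field(default_factory=synthetic.SimConfig)
    outdir: str = "runs/default"
    chi2_quantile: float = 0.95     # LRT significance quantile (chi2, 1 df)
    enrichment_alpha: float = 0.05  # pathway enrichment cutoff
    tau_min: float = 0.6            # tissue-specificity threshold
    liver_fraction: float = 0.9     # focal expression >= this fraction of max
    network_min_targets: int = 20
    n_perm: int = 10_000            # complex label permutations
    n_restarts: int = 5             # OU fit multi-starts
    focal_tissue: str = "liver"
    stages: tuple = ALL_STAGES
    force: bool = False

    def __post_init__(self):
        for t in (self.chi2_quantile, self.enrichment_alpha, self.tau_min, self.liver_fraction):
            if not 0 < t < 1:
                raise ValueError("thresholds must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw:
            sim_raw = raw.pop("sim")
            for key in ("shift_spec", "singleton_shift_spec"):
                if key in sim_raw:
                    sim_raw[key] = tuple(tuple(t) for t in sim_raw[key])
            if "promoter_window" in sim_raw:
                sim_raw["promoter_window"] = tuple(sim_raw["promoter_window"])
            raw["sim"] = synthetic.SimConfig(**sim_raw)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the enabled stages and return the run directory.

    Re-running over a completed directory is a no-op unless
    ``config.force`` is set.  A stage failure raises with the stage name;
    outputs of completed stages stay on disk.
    """
    outdir = Path(config.outdir)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not config.force:
        log.info("run directory %s already complete; skipping (force=False)", outdir)
        return outdir
    if outdir.exists() and config.force:
        shutil.rmtree(outdir)  # stale outputs must not leak into the manifest
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    enabled = set(config.stages)

    state: dict = {}
    try:
        if "simulate" in enabled:
            _stage_simulate(config, outdir, counts, state)
        if "filter" in enabled:
            _stage_filter(config, outdir, counts, state)
        if "normalize" in enabled:
            _stage_normalize(config, outdir, counts, state)
        if "shift_test" in enabled:
            _stage_shift_test(config, outdir, counts, state)
        if "classify" in enabled:
            _stage_classify(config, outdir, counts, state)
        if "context" in enabled:
            if "classify" not in enabled:
                log.warning("context stage needs classify output; skipped")
            else:
                _stage_context(config, outdir, counts, state)
        if "stats" in enabled:
            if "classify" not in enabled:
                log.warning("stats stage needs classify output; skipped")
            else:
                _stage_stats(config, outdir, counts, state)
        if "report" in enabled:
            summarize_run(outdir).to_csv(outdir / "report.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed in {outdir}: {exc}") from exc

    files = sorted(p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.sim.seed,
        "stage_counts": counts,
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config, outdir, counts, state):
    cohort = synthetic.simulate_cohort(config.sim)
    synthetic.write_cohort(cohort, outdir / "cohort")
    state["cohort"] = cohort
    counts["simulate.trees"] = len(cohort.gene_trees)
    counts["simulate.genes"] = len(cohort.truth.genes)


def _stage_filter(config, outdir, counts, state):
    cohort = state["cohort"]
    rows = []
    for og in sorted(cohort.gene_trees):
        tree = cohort.gene_trees[og]
        tc = classify_tree(tree, cohort.roles)
        tc = expression_filters(tree, tc, cohort.panel, cohort.roles)
        rows.append({"orthogroup": og, "status": tc.status, "reason": tc.reason or ""})
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "tree_classes.tsv", sep="\t", index=False)
    state["tree_classes"] = df
    counts["filter.in"] = len(df)
    counts["filter.accepted"] = int((df["status"] != "rejected").sum())
    counts["filter.rejected"] = int((df["status"] == "rejected").sum())


def _stage_normalize(config, outdir, counts, state):
    cohort = state["cohort"]
    tc = state["tree_classes"]
    singleton_ogs = tc[tc["status"].str.startswith("singleton")]["orthogroup"]
    g = cohort.truth.genes
    singles = g[g["orthogroup"].isin(singleton_ogs)]
    singleton_table = singles.rename(columns={})[["orthogroup", "species", "gene"]]
    panel = norm.normalize_within_species(cohort.panel)
    panel = norm.normalize_between_species(panel, singleton_table)
    panel = norm.log_transform(panel)
    panel.write(outdir / "expression_logged.tsv", outdir / "sample_map.tsv")
    panel.write_factors(outdir / "norm_factors.tsv")
    state["panel"] = panel
    counts["normalize.singleton_orthogroups"] = int(singleton_table["orthogroup"].nunique())


def _stage_shift_test(config, outdir, counts, state):
    cohort = state["cohort"]
    tc = state["tree_classes"]
    panel = state["panel"]
    accepted = tc[tc["status"] != "rejected"]
    rows = []
    for rec in accepted.itertuples(index=False):
        tree = cohort.gene_trees[rec.orthogroup]
        for unit in extract_test_units(tree, cohort.roles):
            call = eve.run_orthogroup(
                unit, panel, cohort.species_tree, cohort.roles,
                seed=config.sim.seed, n_restarts=config.n_restarts,
                chi2_quantile=config.chi2_quantile,
            )
            gene = sorted(unit.ingroup_genes)[0] if unit.ingroup_genes else ""
            copy = gene.rsplit("_", 1)[-1] if gene.rsplit("_", 1)[-1] in ("a", "b") else ""
            rows.append({
                "orthogroup": rec.orthogroup, "clade": unit.clade_id, "copy": copy,
                "tree_status": rec.status, "lrt": call.lrt, "p": call.p,
                "significant": call.significant, "direction": call.direction,
                "theta_base": call.theta_base, "theta_shift": call.theta_shift,
                "alpha": call.alpha, "sigma2": call.sigma2, "beta": call.beta,
                "status": call.status, "reason": call.reason or "",
            })
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "shift_calls.tsv", sep="\t", index=False)
    state["shift_calls"] = df
    counts["shift_test.units"] = len(df)
    counts["shift_test.tested"] = int((df["status"] == "tested").sum())
    counts["shift_test.significant"] = int(df["significant"].sum())


def _calls_by_pair(state) -> dict[str, dict[str, eve.ShiftCall]]:
    calls = {}
    for rec in state["shift_calls"].itertuples(index=False):
        call = eve.ShiftCall(
            lrt=rec.lrt, p=rec.p, significant=bool(rec.significant),
            direction=rec.direction, theta_base=rec.theta_base,
            theta_shift=rec.theta_shift, alpha=rec.alpha, sigma2=rec.sigma2,
            beta=rec.beta, status=rec.status, reason=rec.reason or None,
        )
        calls.setdefault(rec.orthogroup, {})[rec.copy or str(rec.clade)] = call
    return calls


def _stage_classify(config, outdir, counts, state):
    cohort = state["cohort"]
    panel = state["panel"]
    focal_sp = sorted(cohort.roles.ingroup)[0]
    calls = _calls_by_pair(state)
    rows = []
    for og, by_copy in calls.items():
        if set(by_copy) != {"a", "b"}:
            continue
        ca, cb = by_copy["a"], by_copy["b"]
        if ca.status != "tested" or cb.status != "tested":
            rows.append({"orthogroup": og, "category": "", "excluded": "untested_copy"})
            continue
        category = cls.classify_pair(ca, cb)
        # asymmetry pooled over every ingroup species carrying both copies
        g = cohort.truth.genes
        sub = g[(g["orthogroup"] == og) & g["copy"].isin(["a", "b"])]
        copies = {
            c: dict(zip(sub[sub["copy"] == c]["species"], sub[sub["copy"] == c]["gene"]))
            for c in ("a", "b")
        }
        ga, gb = f"g{og[2:]}_{focal_sp}_a", f"g{og[2:]}_{focal_sp}_b"
        try:
            asym = cls.pair_asymmetry(copies["a"], copies["b"], panel,
                                      sorted(cohort.roles.ingroup))
        except ValueError:
            asym = np.nan
        n_lower = n_higher = -1
        states = {"a": cls.call_state(ca), "b": cls.call_state(cb)}
        shifted = [c for c, s in states.items() if s != "cons"]
        if len(shifted) == 1 and ga in cohort.tissue_atlas.index and gb in cohort.tissue_atlas.index:
            sg = ga if shifted[0] == "a" else gb
            cg = gb if shifted[0] == "a" else ga
            n_lower, n_higher = cls.tissue_concordance(
                sg, cg, cohort.tissue_atlas, config.focal_tissue)
        rows.append({
            "orthogroup": og, "category": category, "excluded": "",
            "state_a": states["a"], "state_b": states["b"],
            "gene_a": ga, "gene_b": gb, "asymmetry": asym,
            "n_tissues_lower": n_lower, "n_tissues_higher": n_higher,
        })
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    state["pairs"] = df
    counts["classify.pairs"] = len(df)
    for cat in cls.CATEGORIES:
        counts[f"classify.{cat}"] = int((df.get("category", pd.Series(dtype=str)) == cat).sum())


def _stage_context(config, outdir, counts, state):
    cohort = state["cohort"]
    pairs = state["pairs"]
    pairs = pairs[pairs["excluded"] == ""]
    te_frac = intervals.overlap_fraction(cohort.promoters, cohort.te_intervals)
    te_frac.rename("te_fraction").to_csv(outdir / "te_load.tsv", sep="\t",
                                         index_label="gene")
    state["te_fraction"] = te_frac

    # paired TE load: down-shifted copy vs conserved partner
    down = pairs[pairs["category"] == "down+cons"]
    rows = []
    for rec in down.itertuples(index=False):
        sg = rec.gene_a if rec.state_a == "down" else rec.gene_b
        cg = rec.gene_b if rec.state_a == "down" else rec.gene_a
        if sg in te_frac.index and cg in te_frac.index:
            rows.append({"orthogroup": rec.orthogroup,
                         "te_down": te_frac[sg], "te_cons": te_frac[cg]})
    te_pairs = pd.DataFrame(rows, columns=["orthogroup", "te_down", "te_cons"])
    te_pairs.to_csv(outdir / "te_paired.tsv", sep="\t", index=False)
    state["te_pairs"] = te_pairs

    # liver-specific up+cons pairs and the TF network
    up = pairs[pairs["category"] == "up+cons"]
    up_genes, cons_genes = [], []
    for rec in up.itertuples(index=False):
        ug = rec.gene_a if rec.state_a == "up" else rec.gene_b
        cg = rec.gene_b if rec.state_a == "up" else rec.gene_a
        if ug in cohort.tissue_atlas.index:
            keep = cls.liver_specific_filter(
                [ug], cohort.tissue_atlas, config.focal_tissue,
                max_fraction=config.liver_fraction, tau_min=config.tau_min)
            if keep:
                up_genes.append(ug)
                cons_genes.append(cg)
    tf_cands = pd.DataFrame([
        {"tf": tf, "motif": f"{tf}_M1", "evalue": 1e-30, "aln_length": 200}
        for tf in sorted(set(cohort.sites["tf"]))
    ])
    tf_lrt = {tf: 0.0 for tf in tf_cands["tf"]}
    net = intervals.build_liver_network(
        up_genes, cons_genes, cohort.sites, tf_cands, cohort.tissue_atlas,
        config.focal_tissue, tf_lrt,
        min_targets=min(config.network_min_targets, max(1, len(up_genes) // 2)),
    )
    if net.edges is not None:
        net.edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
        net.nodes.to_csv(outdir / "network_nodes.tsv", sep="\t", index=False)
    state["network"] = net
    state["liver_pairs"] = list(zip(up_genes, cons_genes))
    te_by_copy = intervals.te_site_overlap_by_copy(
        state["liver_pairs"], cohort.sites, tf_set=set(synthetic.LIVER_TFS))
    te_by_copy.to_csv(outdir / "te_site_overlap.tsv", sep="\t", index=False)
    state["te_by_copy"] = te_by_copy
    counts["context.liver_pairs"] = len(up_genes)
    counts["context.network_tfs"] = 0 if net.nodes is None else len(net.nodes)


def _stage_stats(config, outdir, counts, state):
    cohort = state["cohort"]
    pairs = state["pairs"]
    pairs = pairs[pairs["excluded"] == ""]
    results = []

    te_pairs = state.get("te_pairs")
    if te_pairs is not None and len(te_pairs) >= 3:
        w, p = stats.wilcoxon_signed_rank(
            te_pairs["te_down"].to_numpy(), te_pairs["te_cons"].to_numpy(),
            alternative="greater")
        results.append({"test": "te_load_down_vs_cons", "statistic": w, "p": p,
                        "n": len(te_pairs), "alternative": "greater"})

    te_by_copy = state.get("te_by_copy")
    if te_by_copy is not None and len(te_by_copy) >= 3:
        w, p = stats.wilcoxon_signed_rank(
            te_by_copy["count_up"].to_numpy(dtype=float),
            te_by_copy["count_cons"].to_numpy(dtype=float), alternative="greater")
        results.append({"test": "liver_bTFBS_te_up_vs_cons", "statistic": w, "p": p,
                        "n": len(te_by_copy), "alternative": "greater"})

    # pathway enrichment per shift category against all tested pairs
    genes = cohort.truth.genes
    og_of_gene = dict(zip(genes["gene"], genes["orthogroup"]))
    ann = cohort.pathway_annotation.copy()
    ann["term_og"] = ann["gene"].map(og_of_gene)
    og_ann = (ann.drop_duplicates(["term_og", "term"])[["term_og", "term"]]
              .rename(columns={"term_og": "gene"}))
    background = set(pairs["orthogroup"])
    enrich_frames = []
    for label, sub in [("down", pairs[pairs["category"].str.contains("down")]),
                       ("up", pairs[pairs["category"].str.contains("up")])]:
        gene_set = set(sub["orthogroup"]) & background
        if gene_set:
            e = stats.pathway_enrichment(gene_set, background, og_ann)
            e.insert(0, "category", label)
            enrich_frames.append(e)
    if enrich_frames:
        enrichment = pd.concat(enrich_frames, ignore_index=True)
        enrichment.to_csv(outdir / "pathway_enrichment.tsv", sep="\t", index=False)
        state["enrichment"] = enrichment

    # protein-complex label homogeneity
    focal_sp = sorted(cohort.roles.ingroup)[0]
    fg = genes[genes["species"] == focal_sp]
    labels = {g: ("ohnolog" if c in ("a", "b") else "singleton")
              for g, c in zip(fg["gene"], fg["copy"])}
    for statname in ("n_only_singleton", "n_only_ohnolog"):
        obs, p = stats.complex_label_permutation(
            cohort.complexes, labels, n_perm=config.n_perm,
            statistic=statname, seed=config.sim.seed)
        results.append({"test": f"complex_{statname}", "statistic": obs, "p": p,
                        "n": len(cohort.complexes), "alternative": "greater"})

    # fractionation bias over synthetic syntenic blocks: consecutive
    # ohnolog orthogroups grouped into blocks, losses = dropped tips per copy
    tt = cohort.truth.trees
    ohno = tt[tt["kind"] == "ohnolog"].reset_index(drop=True)
    n_blocks = max(1, len(ohno) // 25)
    blocks = []
    for b in range(n_blocks):
        sub = ohno.iloc[b * 25:(b + 1) * 25]
        blocks.append({
            "losses_a": int(((sub["partial_copy"] == "a") * sub["n_dropped"]).sum()),
            "losses_b": int(((sub["partial_copy"] == "b") * sub["n_dropped"]).sum()),
        })
    block_df, n_sig = stats.fractionation_bias_test(pd.DataFrame(blocks))
    block_df.to_csv(outdir / "fractionation_blocks.tsv", sep="\t", index=False)
    results.append({"test": "fractionation_significant_blocks", "statistic": n_sig,
                    "p": np.nan, "n": len(block_df), "alternative": "two-sided"})

    res = pd.DataFrame(results, columns=["test", "statistic", "p", "n", "alternative"])
    res.to_csv(outdir / "assoc_tests.tsv", sep="\t", index=False)
    state["assoc"] = res
    counts["stats.tests"] = len(res)


def summarize_run(run_dir: Path) -> pd.DataFrame:
    """Report tables for a completed run: shift proportions per tree
    class, pair-category counts, asymmetry and concordance summaries."""
    run_dir = Path(run_dir)
    calls = pd.read_csv(run_dir / "shift_calls.tsv", sep="\t")
    rows = []
    tested = calls[calls["status"] == "tested"]
    for status, sub in tested.groupby("tree_status"):
        by_og = sub.groupby("orthogroup")["significant"].any()
        rows.append({"table": "shift_proportion", "key": status,
                     "value": float(by_og.mean()), "n": int(by_og.size)})
        for direction in ("up", "down"):
            frac = float((sub["direction"] == direction).mean())
            rows.append({"table": "direction_fraction", "key": f"{status}:{direction}",
                         "value": frac, "n": len(sub)})
    pairs_path = run_dir / "pairs.tsv"
    if pairs_path.exists():
        pairs = pd.read_csv(pairs_path, sep="\t")
        ok = pairs[pairs["excluded"].isna() | (pairs["excluded"] == "")]
        for cat in cls.CATEGORIES:
            sub = ok[ok["category"] == cat]
            rows.append({"table": "category_count", "key": cat,
                         "value": float(len(sub)), "n": len(ok)})
            if len(sub):
                rows.append({"table": "median_asymmetry", "key": cat,
                             "value": float(sub["asymmetry"].median()), "n": len(sub)})
        conc = ok[(ok.get("n_tissues_lower", -1) >= 0)]
        if len(conc):
            down_conc = conc[conc["category"] == "down+cons"]
            if len(down_conc):
                frac = float((down_conc["n_tissues_lower"] >
                              down_conc["n_tissues_higher"]).mean())
                rows.append({"table": "concordance", "key": "down_majority_lower",
                             "value": frac, "n": len(down_conc)})
            up_conc = conc[conc["category"] == "up+cons"]
            if len(up_conc):
                frac = float((up_conc["n_tissues_higher"] >
                              up_conc["n_tissues_lower"]).mean())
                rows.append({"table": "concordance", "key": "up_majority_higher",
                             "value": frac, "n": len(up_conc)})
    return pd.DataFrame(rows, columns=["table", "key", "value", "n"])
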