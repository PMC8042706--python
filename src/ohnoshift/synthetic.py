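"""Synthetic study cohort with known ground truth.

Generates everything the pipeline consumes — a 7-taxon ultrametric
species tree with a marked WGD-descendant (salmonid-role) clade,
singleton and ohnolog gene trees (complete and partial), replicate
expression evolving under the stationary OU model with planted optimum
shifts, promoter/TE/bound-TFBS interval tables, a tissue atlas, and
pathway/complex annotations with planted enrichments — together with a
``SimTruth`` record of every planted label, so recovery of the truth by
the pipeline can be measured.

Randomness comes from a single seed; each stage derives its own
deterministic sub-stream, so identical configs reproduce every output
byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import eve
from .normalization import ExpressionPanel
from .trees import PhyloTree, SpeciesRoles, parse_newick

log = logging.getLogger(__name__)

__all__ = ["SimConfig", "SimTruth", "Cohort", "simulate_species_tree",
           "simulate_orthogroups", "simulate_expression",
           "simulate_genomic_context", "simulate_cohort"]

PAIR_CATEGORIES = ("up+cons", "down+cons", "up+up", "down+down", "up+down")

LIVER_TFS = ("HNF4A", "FOXA1", "RXRA", "KLF15", "PPARG", "NR1H3", "CEBPA", "ONECUT1")
OTHER_TFS = ("SOX2", "PAX6", "GATA1", "MYOD1", "NEUROD1", "TBX5")
TE_SUPERFAMILIES = ("TC1-Mariner", "hAT", "Gypsy", "LINE-L2")


@dataclass
class SimConfig:
    """Knobs of the synthetic study.

    Defaults mirror the study design: four ingroup (salmonid-role)
    species and three outgroups with four replicates each; roughly 65%
    of orthogroups carry a retained ohnolog pair; 40% of pairs have a
    planted shift with a strong down bias, and 20% of singletons shift
    with a slight up bias.  ``delta_theta`` is in log2-expression units.
    """

    seed: int = 0
    n_species_ingroup: int = 4
    n_outgroups: int = 3
    replicates_per_species: int = 4
    n_singleton_trees: int = 120
    n_ohnolog_trees: int = 220
    frac_partial: float = 0.25
    # (category, fraction of ohnolog pairs, delta_theta in log2 units)
    shift_spec: tuple = (
        ("up+cons", 0.08, 1.5),
        ("down+cons", 0.20, 1.5),
        ("up+up", 0.03, 1.5),
        ("down+down", 0.06, 1.5),
        ("up+down", 0.03, 1.5),
    )
    # (direction, fraction of singleton trees, delta_theta)
    singleton_shift_spec: tuple = (("up", 0.11, 1.5), ("down", 0.09, 1.5))
    alpha: float = 2.0       # OU pull, per unit tree depth (root depth = 1)
    sigma2: float = 1.0      # drift variance rate, log2^2 per unit time
    beta: float = 0.3        # within/between species variance ratio
    theta_mean: float = 4.0  # grand mean of base optima (log2 TPM)
    theta_sd: float = 1.5
    promoter_window: tuple = (2000, 200)  # upstream, downstream of TSS
    te_rate: float = 1.0       # TE insertions per promoter
    te_load_bias: float = 2.5  # TE-rate multiplier for down-shifted copies
    tfbs_rate: float = 10.0    # motif sites per promoter
    n_tissues: int = 15
    frac_tissue_specific: float = 0.25  # share of shifts confined to the focal tissue
    n_pathways: int = 10
    pathway_rate: float = 0.25        # chance an orthogroup gets any pathway
    planted_pathway_bias: float = 4.0  # enrichment of pathway 0 in down-shifted pairs
    n_complexes: int = 40
    complex_homogeneity: float = 0.7  # chance a complex draws from one label pool

    def __post_init__(self):
        if self.n_species_ingroup < 2 or self.n_outgroups < 1:
            raise ValueError("need at least 2 ingroup species and 1 outgroup")
        if self.replicates_per_species < 2:
            raise ValueError("need at least 2 replicates per species")
        if self.alpha <= 0 or self.sigma2 <= 0 or self.beta <= 0:
            raise ValueError("OU rate/variance parameters must be positive")
        for frac_set in (self.shift_spec, self.singleton_shift_spec):
            total = sum(f for _, f, _ in frac_set)
            if total > 1 + 1e-12:
                raise ValueError("shift fractions must sum to at most 1")
        if not 0 <= self.frac_partial <= 1:
            self.frac_partial = min(1.0, max(0.0, self.frac_partial))
            log.warning("frac_partial clamped to %s", self.frac_partial)

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic per-stage sub-stream."""
        return np.random.default_rng([self.seed, stage])

    @classmethod
    def from_yaml(cls, path: Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("shift_spec", "singleton_shift_spec"):
            if key in raw:
                raw[key] = tuple(tuple(t) for t in raw[key])
        if "promoter_window" in raw:
            raw["promoter_window"] = tuple(raw["promoter_window"])
        return cls(**raw)

    def to_yaml(self, path: Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort.

    ``genes``: one row per emitted gene (gene, orthogroup, species, copy,
    category, theta_base, theta_shift).  ``pairs``: one row per ohnolog
    pair with the planted category and asymmetry sign.  ``trees``: per
    orthogroup kind/completeness.
    """

    genes: pd.DataFrame = None
    pairs: pd.DataFrame = None
    trees: pd.DataFrame = None
    planted_pathway: str = ""
    te_load_bias: float = 1.0
    n_floor_events: int = 0
    atlas: pd.DataFrame = None  # per-gene tissue-specificity of planted shifts


@dataclass
class Cohort:
    config: SimConfig
    species_tree: PhyloTree
    roles: SpeciesRoles
    gene_trees: dict  # orthogroup -> PhyloTree
    panel: ExpressionPanel
    truth: SimTruth
    promoters: pd.DataFrame = None
    te_intervals: pd.DataFrame = None
    sites: pd.DataFrame = None
    tissue_atlas: pd.DataFrame = None
    pathway_annotation: pd.DataFrame = None
    complexes: dict = None


# ---------------------------------------------------------------------------
# species tree


def _species_names(config: SimConfig) -> tuple[list[str], list[str]]:
    ingroup = [f"SAL{i + 1}" for i in range(config.n_species_ingroup)]
    outgroups = ["PIKE", "ZEB", "MED"] + [f"OUT{i + 1}" for i in range(3, config.n_outgroups)]
    return ingroup, outgroups[: config.n_outgroups]


def make_roles(config: SimConfig) -> SpeciesRoles:
    ingroup, outgroups = _species_names(config)
    return SpeciesRoles(
        ingroup=ingroup,
        sister_anchor=outgroups[0],
        distant_anchors=[s for s in outgroups[1:3]],
        other_outgroups=[s for s in outgroups[3:]],
    )


def _subtree(labels: list[str], crown: float) -> tuple[str, float]:
    """Balanced ultrametric subtree over the given tip labels (tips at
    depth 1).  Returns (clause without stem length, depth of its root);
    for a single tip the clause is the tip itself at depth 1."""
    if len(labels) == 1:
        return labels[0], 1.0
    mid = len(labels) // 2
    child_crown = crown + (1.0 - crown) / 2.0
    lc, ld = _subtree(labels[:mid], child_crown)
    rc, rd = _subtree(labels[mid:], child_crown)
    return f"({lc}:{ld - crown:.10g},{rc}:{rd - crown:.10g})", crown


def _backbone(outgroups: list[str], clause: str, clause_depth: float) -> str:
    """Wrap an ingroup clause in the outgroup ladder (root depth 0, tips
    at 1).  ``outgroups[0]`` (sister role) splits deepest, at
    ``STEM_PARENT_DEPTH``; the rest join at evenly spaced shallower
    depths down to the root."""
    k = len(outgroups)
    if k == 1:
        return f"({clause}:{clause_depth:.10g},{outgroups[0]}:1);"
    cur = f"({clause}:{clause_depth - STEM_PARENT_DEPTH:.10g},{outgroups[0]}:{1.0 - STEM_PARENT_DEPTH:.10g})"
    cur_depth = STEM_PARENT_DEPTH
    for j, sp in enumerate(outgroups[1:], start=1):
        new_depth = STEM_PARENT_DEPTH * (k - 1 - j) / (k - 1)
        cur = f"({cur}:{cur_depth - new_depth:.10g},{sp}:{1.0 - new_depth:.10g})"
        cur_depth = new_depth
    return cur + ";"


STEM_PARENT_DEPTH = 0.5   # depth where the sister outgroup splits off
WGD_DEPTH = 0.7           # depth of the WGD node on the ingroup stem
CROWN_DEPTH = 0.8         # depth of each (duplicate) ingroup crown


def simulate_species_tree(config: SimConfig) -> PhyloTree:
    """Ultrametric species tree, root depth 1.0, ingroup monophyletic.

    The ingroup stem branch (flagged on the returned tree as
    ``wgd_branch``) runs from depth 0.5 to the ingroup crown at 0.8; the
    WGD is dated at 0.7 of root depth on that branch.
    """
    ingroup, outgroups = _species_names(config)
    clause, depth = _subtree(ingroup, CROWN_DEPTH)
    tree = parse_newick(_backbone(outgroups, clause, depth))
    tip_ids = [tree.tip_index(s) for s in ingroup]
    tree.wgd_branch = tree.mrca(tip_ids) if len(tip_ids) > 1 else tip_ids[0]
    return tree


# ---------------------------------------------------------------------------
# gene trees


def _gene_label(species: str, og: str, copy: str | None) -> str:
    gid = f"g{og[2:]}_{species}" + (f"_{copy}" if copy else "")
    return f"{species}|{gid}", gid


def _gene_tree_newick(config: SimConfig, og: str, kind: str,
                      dropped: dict[str, set]) -> str:
    """Newick for one orthogroup; ``dropped`` maps copy label ('a'/'b' or
    '' for singletons) to the set of ingroup species deleted from it."""
    ingroup, outgroups = _species_names(config)

    def clade(copy: str | None, crown: float) -> tuple[str, float] | None:
        sp = [s for s in ingroup if s not in dropped.get(copy or "", set())]
        if not sp:
            return None
        labels = [_gene_label(s, og, copy)[0] for s in sp]
        return _subtree(labels, crown)

    if kind == "singleton":
        clause, depth = clade(None, CROWN_DEPTH)
    else:
        parts = [clade(c, CROWN_DEPTH) for c in ("a", "b")]
        parts = [p for p in parts if p is not None]
        if len(parts) == 2:
            (ca, da), (cb, db) = parts
            clause = f"({ca}:{da - WGD_DEPTH:.10g},{cb}:{db - WGD_DEPTH:.10g})"
            depth = WGD_DEPTH
        else:
            clause, depth = parts[0]  # degenerate: a whole clade deleted
    out_labels = [_gene_label(s, og, None)[0] for s in outgroups]
    return _backbone(out_labels, clause, depth)


def simulate_orthogroups(config: SimConfig, tree: PhyloTree) -> tuple[dict, SimTruth]:
    """Emit singleton and ohnolog gene trees plus the tree-level truth.

    A ``frac_partial`` share of trees has 1..(n_ingroup - 1) tips deleted
    from one (duplicate) clade, never breaking monophyly.
    """
    rng = config.rng(1)
    ingroup, _ = _species_names(config)
    trees: dict[str, PhyloTree] = {}
    rows = []
    n_total = config.n_singleton_trees + config.n_ohnolog_trees
    kinds = ["singleton"] * config.n_singleton_trees + ["ohnolog"] * config.n_ohnolog_trees
    for i, kind in enumerate(kinds):
        og = f"OG{i:05d}"
        partial = bool(rng.random() < config.frac_partial)
        dropped: dict[str, set] = {}
        if partial:
            n_drop = int(rng.integers(1, len(ingroup)))
            victims = set(rng.choice(ingroup, size=n_drop, replace=False))
            copy = "" if kind == "singleton" else str(rng.choice(["a", "b"]))
            dropped[copy] = victims
        trees[og] = parse_newick(_gene_tree_newick(config, og, kind, dropped))
        rows.append({
            "orthogroup": og, "kind": kind,
            "complete": not partial,
            "partial_copy": next(iter(dropped), ""),
            "n_dropped": sum(len(v) for v in dropped.values()),
        })
    truth = SimTruth(trees=pd.DataFrame(rows))
    return trees, truth


# ---------------------------------------------------------------------------
# expression


def _assign_categories(rng, n: int, spec) -> list[str]:
    cats, bounds = [], []
    acc = 0.0
    for cat, frac, _ in spec:
        acc += frac
        cats.append(cat)
        bounds.append(acc)
    u = rng.random(n)
    out = []
    for ui in u:
        cat = None
        for c, b in zip(cats, bounds):
            if ui < b:
                cat = c
                break
        out.append(cat)
    return out


def _copy_deltas(category: str, delta: float, rng) -> tuple[float, float]:
    """Per-copy optimum shifts for a pair category; which physical copy
    carries the asymmetric shift is randomized."""
    table = {
        "cons+cons": (0.0, 0.0),
        "up+cons": (delta, 0.0),
        "down+cons": (-delta, 0.0),
        "up+up": (delta, delta),
        "down+down": (-delta, -delta),
        "up+down": (delta, -delta),
    }
    da, db = table[category]
    if rng.random() < 0.5:
        da, db = db, da
    return da, db


def simulate_expression(
    gene_trees: dict, species_tree: PhyloTree, config: SimConfig, truth: SimTruth
) -> tuple[ExpressionPanel, SimTruth]:
    """Species means drawn from the OU multivariate normal on each gene
    tree with the planted regime painting; replicates add independent
    within-species noise of variance beta * sigma2 / (2 alpha).

    Values are emitted on the TPM scale through the inverse of
    log2(x + 0.01), floored at zero (expression cannot be negative);
    floor events are counted in the truth record.
    """
    rng = config.rng(2)
    ingroup, outgroups = _species_names(config)
    species = ingroup + outgroups
    reps = config.replicates_per_species
    samples = [f"{s}_r{k + 1}" for s in species for k in range(reps)]
    sample_species = pd.Series({f"{s}_r{k + 1}": s for s in species for k in range(reps)})

    delta_of = {cat: d for cat, _, d in config.shift_spec}
    sdelta_of = {cat: d for cat, _, d in config.singleton_shift_spec}
    tree_rows = truth.trees.set_index("orthogroup")
    ohno_ogs = [og for og in gene_trees if tree_rows.loc[og, "kind"] == "ohnolog"]
    single_ogs = [og for og in gene_trees if tree_rows.loc[og, "kind"] == "singleton"]
    pair_cats = _assign_categories(rng, len(ohno_ogs), config.shift_spec)
    single_cats = _assign_categories(rng, len(single_ogs), config.singleton_shift_spec)
    cat_of = dict(zip(ohno_ogs, pair_cats))
    cat_of.update({og: c for og, c in zip(single_ogs, single_cats)})

    gene_rows, pair_rows = [], []
    data = {}
    n_floor = 0
    var_within = config.beta * config.sigma2 / (2.0 * config.alpha)

    for og, gtree in gene_trees.items():
        kind = tree_rows.loc[og, "kind"]
        theta0 = float(rng.normal(config.theta_mean, config.theta_sd))
        category = cat_of[og] or ("cons+cons" if kind == "ohnolog" else "cons")

        painting = np.zeros(gtree.n_nodes, dtype=np.int64)
        thetas = [theta0]
        copy_delta: dict[str, float] = {}
        if kind == "ohnolog":
            da, db = _copy_deltas(category, delta_of.get(category, 0.0), rng)
            copy_delta = {"a": da, "b": db}
            for r, (copy, d) in enumerate(copy_delta.items(), start=1):
                tips = [lbl for lbl in gtree.tip_labels if lbl.endswith(f"_{copy}")]
                if not tips:
                    continue
                ids = [gtree.tip_index(t) for t in tips]
                stem = gtree.mrca(ids) if len(ids) > 1 else ids[0]
                for nd in gtree.clade_nodes(stem):
                    painting[nd] = len(thetas)
                thetas.append(theta0 + d)
        else:
            d = sdelta_of.get(category, 0.0) * (1 if category == "up" else -1 if category == "down" else 0)
            copy_delta = {"": d}
            if d != 0.0:
                tips = [lbl for lbl in gtree.tip_labels if lbl.split("|")[0] in ingroup]
                ids = [gtree.tip_index(t) for t in tips]
                stem = gtree.mrca(ids) if len(ids) > 1 else ids[0]
                for nd in gtree.clade_nodes(stem):
                    painting[nd] = 1
                thetas.append(theta0 + d)

        params = eve.OUParams(
            thetas=tuple(thetas), alpha=config.alpha, sigma2=config.sigma2, beta=config.beta
        )
        mu = eve.ou_mean_vector(gtree, painting, params)
        V = params.stationary_var * np.exp(-config.alpha * gtree.tip_distance_matrix())
        L = np.linalg.cholesky(V + 1e-12 * np.eye(len(mu)))
        species_means = mu + L @ rng.standard_normal(len(mu))

        genes_of_pair: dict[str, str] = {}
        for t, lbl in enumerate(gtree.tip_labels):
            sp, gid = lbl.split("|")
            vals = species_means[t] + np.sqrt(var_within) * rng.standard_normal(reps)
            tpm = np.maximum(np.exp2(vals) - 0.01, 0.0)
            n_floor += int(np.sum(np.exp2(vals) - 0.01 < 0))
            row = np.full(len(samples), np.nan)
            for k in range(reps):
                row[samples.index(f"{sp}_r{k + 1}")] = tpm[k]
            data[gid] = row
            copy = gid.rsplit("_", 1)[-1] if gid.rsplit("_", 1)[-1] in ("a", "b") else ""
            if sp in ingroup and copy in copy_delta and copy:
                genes_of_pair.setdefault(copy, gid.rsplit("_", 2)[0])
            d = copy_delta.get(copy, 0.0) if sp in ingroup else 0.0
            state = "cons" if d == 0 else ("up" if d > 0 else "down")
            gene_rows.append({
                "gene": gid, "orthogroup": og, "species": sp, "copy": copy,
                "category": state if sp in ingroup else "outgroup",
                "theta_base": theta0, "theta_shift": theta0 + d,
            })
        if kind == "ohnolog":
            da, db = copy_delta.get("a", 0.0), copy_delta.get("b", 0.0)
            pair_rows.append({
                "orthogroup": og, "category": category,
                "delta_a": da, "delta_b": db,
                "asym_sign": int(np.sign(da - db)),
            })

    values = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    panel = ExpressionPanel(values, sample_species, state="raw")
    truth.genes = pd.DataFrame(gene_rows)
    truth.pairs = pd.DataFrame(pair_rows)
    truth.n_floor_events = n_floor
    if truth.genes["gene"].duplicated().any():
        raise AssertionError("truth bookkeeping: duplicate gene emitted")
    return panel, truth


# ---------------------------------------------------------------------------
# genomic context, tissue atlas, annotations


def simulate_genomic_context(config: SimConfig, truth: SimTruth) -> dict:
    """Promoters, TE insertions, bound-TFBS rows, tissue atlas, and
    pathway/complex annotations for the ingroup copy genes.

    Planted signal: down-shifted copies carry ``te_load_bias`` times more
    promoter TE insertions; up-shifted copies gain bound liver-TF sites
    (often TE-overlapping, biased to the TC1-Mariner superfamily); the
    first pathway is enriched among down-shifted pairs; protein
    complexes are biased towards label homogeneity.
    """
    rng = config.rng(3)
    up_len, down_len = config.promoter_window
    plen = up_len + down_len

    # one focal ingroup species carries the annotation (first ingroup species)
    focal_sp = _species_names(config)[0][0]
    genes = truth.genes[truth.genes["species"] == focal_sp].reset_index(drop=True)
    spacing = 10 * plen
    tss_rows, te_rows, site_rows = [], [], []
    chrom = "chr1"
    chrom_sizes = {chrom: spacing * (len(genes) + 2)}

    tissues = [f"tissue{i + 1}" for i in range(config.n_tissues - 1)]
    atlas_cols = ["liver"] + tissues
    atlas = {}
    og_profiles: dict[str, np.ndarray] = {}
    atlas_rows: list[dict] = []

    for i, rec in genes.iterrows():
        pos = spacing * (i + 1)
        strand = "+" if i % 2 == 0 else "-"
        tss_rows.append({"gene": rec["gene"], "chrom": chrom, "pos": pos, "strand": strand})
        start = pos - up_len if strand == "+" else pos - down_len
        start = max(0, start)
        end = start + plen

        shifted_down = rec["category"] == "down"
        shifted_up = rec["category"] == "up"
        te_rate = config.te_rate * (config.te_load_bias if shifted_down else 1.0)
        for _ in range(rng.poisson(te_rate)):
            te_len = int(rng.integers(50, 500))
            s = int(rng.integers(start, max(start + 1, end - te_len)))
            fam = TE_SUPERFAMILIES[int(rng.integers(len(TE_SUPERFAMILIES)))]
            te_rows.append({"chrom": chrom, "start": s, "end": min(s + te_len, end),
                            "strand": ".", "label": fam})

        n_sites = rng.poisson(config.tfbs_rate)
        extra_liver = rng.poisson(4.0) if shifted_up else 0
        for j in range(n_sites + extra_liver):
            liver_site = j >= n_sites or rng.random() < 0.3
            tf_pool = LIVER_TFS if liver_site else OTHER_TFS
            tf = tf_pool[int(rng.integers(len(tf_pool)))]
            bound = bool(rng.random() < (0.8 if j >= n_sites else 0.4))
            te_ov = bool(rng.random() < (0.5 if j >= n_sites else 0.15))
            fam = ""
            if te_ov:
                fam = "TC1-Mariner" if (j >= n_sites and rng.random() < 0.7) else \
                    TE_SUPERFAMILIES[int(rng.integers(len(TE_SUPERFAMILIES)))]
            site_rows.append({
                "gene": rec["gene"], "motif": f"{tf}_M1", "tf": tf,
                "bound": bound, "te_overlap": te_ov, "te_superfamily": fam,
            })

        # tissue atlas row: ohnolog copies share their orthogroup's
        # ancestral profile (they are duplicates of one gene) plus small
        # copy noise; shifted copies move in liver and, concordantly, in
        # most other tissues
        og = rec["orthogroup"]
        if og not in og_profiles:
            og_profiles[og] = np.exp2(rng.normal(4.0, 1.0)) * rng.lognormal(
                0.0, 0.3, size=config.n_tissues)
        prof = og_profiles[og] * rng.lognormal(0.0, 0.1, size=config.n_tissues)
        shift = 2.0 ** (1.5 if shifted_up else -1.5 if shifted_down else 0.0)
        tissue_specific = False
        if shifted_up or shifted_down:
            tissue_specific = bool(rng.random() < config.frac_tissue_specific)
            if tissue_specific:
                # focal-only shift, amplified: the atlas sees a clearly
                # tissue-specific gain/loss (tau pushed past the filter)
                prof[0] *= shift ** 2
            else:
                prof[0] *= shift
                concordant = rng.random(config.n_tissues - 1) < 0.77
                prof[1:][concordant] *= shift
        atlas[rec["gene"]] = prof
        atlas_rows.append({"gene": rec["gene"], "tissue_specific": tissue_specific})

    # liver-specific TF expression rows for the network filter
    for tf in LIVER_TFS:
        prof = np.full(config.n_tissues, 1.0) * rng.lognormal(0.0, 0.2, config.n_tissues)
        prof[0] = 40.0
        atlas[tf] = prof
    for tf in OTHER_TFS:
        atlas[tf] = np.exp2(rng.normal(3.0, 0.5)) * rng.lognormal(0.0, 0.3, config.n_tissues)

    # pathway annotation with a planted enrichment in pathway 0 for
    # down-shifted pairs
    pathways = [f"pw{str(i).zfill(2)}" for i in range(config.n_pathways)]
    ann_rows = []
    down_ogs = set()
    if truth.pairs is not None and len(truth.pairs):
        down_ogs = set(truth.pairs[truth.pairs["category"].str.contains("down")]["orthogroup"])
    for og in sorted(truth.genes["orthogroup"].unique()):
        r = rng.random()
        biased = og in down_ogs
        p_any = min(1.0, config.pathway_rate * (config.planted_pathway_bias if biased else 1.0))
        if r < p_any:
            if biased and rng.random() < 0.8:
                term = pathways[0]
            else:
                term = pathways[int(rng.integers(1, len(pathways)))]
            for g in truth.genes[truth.genes["orthogroup"] == og]["gene"]:
                ann_rows.append({"gene": g, "term": term})

    # protein complexes over ingroup genes, biased towards one-label pools
    is_ohno = truth.genes["copy"].isin(["a", "b"])
    focal_mask = truth.genes["species"] == focal_sp
    ohno_genes = list(truth.genes[focal_mask & is_ohno]["gene"])
    single_genes = list(truth.genes[focal_mask & ~is_ohno]["gene"])
    complexes = {}
    for c in range(config.n_complexes):
        size = int(rng.integers(2, 6))
        if rng.random() < config.complex_homogeneity:
            pool = ohno_genes if rng.random() < 0.5 else single_genes
        else:
            pool = ohno_genes + single_genes
        members = rng.choice(pool, size=min(size, len(pool)), replace=False)
        complexes[f"cplx{c:03d}"] = set(members)

    return {
        "tss": pd.DataFrame(tss_rows),
        "chrom_sizes": chrom_sizes,
        "te_intervals": pd.DataFrame(te_rows, columns=["chrom", "start", "end", "strand", "label"]),
        "sites": pd.DataFrame(site_rows),
        "tissue_atlas": pd.DataFrame.from_dict(atlas, orient="index", columns=atlas_cols),
        "pathway_annotation": pd.DataFrame(ann_rows, columns=["gene", "term"]),
        "complexes": complexes,
        "planted_pathway": pathways[0],
        "atlas_truth": pd.DataFrame(atlas_rows, columns=["gene", "tissue_specific"]),
    }


def simulate_cohort(config: SimConfig) -> Cohort:
    """Run all simulation stages and bundle the results."""
    from .intervals import make_promoters

    species_tree = simulate_species_tree(config)
    roles = make_roles(config)
    gene_trees, truth = simulate_orthogroups(config, species_tree)
    panel, truth = simulate_expression(gene_trees, species_tree, config, truth)
    ctx = simulate_genomic_context(config, truth)
    truth.planted_pathway = ctx["planted_pathway"]
    truth.te_load_bias = config.te_load_bias
    truth.atlas = ctx["atlas_truth"]
    promoters = make_promoters(ctx["tss"], config.promoter_window, ctx["chrom_sizes"])
    return Cohort(
        config=config, species_tree=species_tree, roles=roles,
        gene_trees=gene_trees, panel=panel, truth=truth,
        promoters=promoters, te_intervals=ctx["te_intervals"], sites=ctx["sites"],
        tissue_atlas=ctx["tissue_atlas"], pathway_annotation=ctx["pathway_annotation"],
        complexes=ctx["complexes"],
    )


def write_cohort(cohort: Cohort, outdir: Path) -> dict[str, Path]:
    """Write every cohort table in its plain-text interchange format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["species_tree"] = outdir / "species_tree.nwk"
    paths["species_tree"].write_text(cohort.species_tree.to_newick() + "\n")

    paths["gene_trees"] = outdir / "gene_trees.nwk"
    with open(paths["gene_trees"], "w") as fh:
        for og in sorted(cohort.gene_trees):
            fh.write(f"{og}\t{cohort.gene_trees[og].to_newick()}\n")

    paths["expression"] = outdir / "expression_tpm.tsv"
    paths["sample_map"] = outdir / "sample_map.tsv"
    cohort.panel.write(paths["expression"], paths["sample_map"])

    for name, df in [
        ("promoters", cohort.promoters), ("te_intervals", cohort.te_intervals),
        ("bound_sites", cohort.sites), ("pathways", cohort.pathway_annotation),
        ("truth_genes", cohort.truth.genes), ("truth_pairs", cohort.truth.pairs),
        ("truth_trees", cohort.truth.trees),
    ]:
        paths[name] = outdir / f"{name}.tsv"
        df.to_csv(paths[name], sep="\t", index=False)

    paths["tissue_atlas"] = outdir / "tissue_atlas.tsv"
    cohort.tissue_atlas.to_csv(paths["tissue_atlas"], sep="\t", index_label="gene")

    paths["complexes"] = outdir / "complexes.tsv"
    rows = [{"complex": c, "gene": g} for c in sorted(cohort.complexes)
            for g in sorted(cohort.complexes[c])]
    pd.DataFrame(rows).to_csv(paths["complexes"], sep="\t", index=False)

    paths["config"] = outdir / "sim_config.yaml"
    cohort.config.to_yaml(paths["config"])
    return paths
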