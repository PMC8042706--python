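"""Interval arithmetic for promoters, TE load, and bound-TFBS tables.

Coordinates are 0-based half-open (BED convention) throughout; GFF-style
1-based inputs must be converted at the boundary.  Overlap is
strand-blind and requires at least one shared base.

The liver-network builder reproduces a filter cascade over candidate
transcription factors: motif-hit quality filters, a minimum bound-target
count, a tissue-specificity filter, then a reduction that keeps one TF
per motif (strongest expression shift), merges motifs with highly
overlapping target sets, collapses multi-motif TFs, and ranks TFs by
their bias towards binding up-shifted ohnolog copies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "make_promoters",
    "merge_intervals",
    "overlap_fraction",
    "count_bound_sites",
    "rank_pair_by_shift",
    "LiverNetwork",
    "build_liver_network",
    "te_site_overlap_by_copy",
]


def make_promoters(
    tss: pd.DataFrame,
    window: tuple[int, int],
    chrom_sizes: dict[str, int],
) -> pd.DataFrame:
    """Strand-aware promoter windows around transcription start sites.

    ``tss`` columns: gene, chrom, pos, strand.  ``window`` is
    (upstream, downstream) in bases; on the minus strand upstream extends
    to higher coordinates.  Windows are clipped to [0, chrom length];
    records on unknown chromosomes are skipped with a warning.
    """
    up, down = window
    rows = []
    for rec in tss.itertuples(index=False):
        if rec.chrom not in chrom_sizes:
            log.warning("unknown chromosome %s for gene %s; skipped", rec.chrom, rec.gene)
            continue
        if rec.strand == "+":
            start, end = rec.pos - up, rec.pos + down
        elif rec.strand == "-":
            start, end = rec.pos - down, rec.pos + up
        else:
            raise ValueError(f"TSS records must be stranded (gene {rec.gene})")
        start = max(0, start)
        end = min(chrom_sizes[rec.chrom], end)
        if end > start:
            rows.append((rec.chrom, start, end, rec.strand, rec.gene))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene"])


def merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent half-open intervals given as an (n, 2)
    array; returns the merged (m, 2) array sorted by start."""
    if len(iv) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def overlap_fraction(promoters: pd.DataFrame, features: pd.DataFrame, by: str = "gene") -> pd.Series:
    """Fraction of each promoter covered by the (merged) features.

    Overlapping feature intervals are merged before measuring, so a base
    covered twice counts once.  Zero-length promoters are excluded.
    """
    feats_by_chrom = {}
    if len(features):
        feats_by_chrom = {
            c: sub[["start", "end"]].to_numpy(dtype=np.int64)
            for c, sub in features.groupby("chrom")
        }
    out = {}
    for rec in promoters.itertuples(index=False):
        length = rec.end - rec.start
        if length <= 0:
            continue
        fv = feats_by_chrom.get(rec.chrom)
        covered = 0
        if fv is not None and len(fv):
            clipped = np.column_stack(
                (np.clip(fv[:, 0], rec.start, rec.end), np.clip(fv[:, 1], rec.start, rec.end))
            )
            clipped = clipped[clipped[:, 1] > clipped[:, 0]]
            merged = merge_intervals(clipped)
            covered = int((merged[:, 1] - merged[:, 0]).sum()) if len(merged) else 0
        out[getattr(rec, by)] = covered / length
    return pd.Series(out, dtype=float)


def count_bound_sites(
    sites: pd.DataFrame,
    genes: list[str],
    tf_filter: set[str] | None = None,
    mode: str = "sites",
) -> pd.Series:
    """Per-gene bound-site counts.

    ``mode="sites"`` counts bound rows; ``mode="tfs"`` counts distinct
    TFs with at least one bound row.  ``tf_filter`` restricts to a TF
    set (None = all TFs).
    """
    sub = sites[sites["bound"]]
    if tf_filter is not None:
        sub = sub[sub["tf"].isin(tf_filter)]
    sub = sub[sub["gene"].isin(genes)]
    if mode == "sites":
        counts = sub.groupby("gene").size()
    elif mode == "tfs":
        counts = sub.groupby("gene")["tf"].nunique()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return counts.reindex(genes, fill_value=0).astype(int)


def rank_pair_by_shift(pair) -> tuple[str, str]:
    """Order a pair's genes by their shift-test p-value (lowest first);
    ties broken lexicographically by gene id."""
    a = (pair.call_a.p, pair.gene_a)
    b = (pair.call_b.p, pair.gene_b)
    if a == b:
        return tuple(sorted((pair.gene_a, pair.gene_b)))
    lo, hi = sorted((a, b))
    return lo[1], hi[1]


@dataclass
class LiverNetwork:
    """Filter-cascade audit trail plus the reduced TF-target network."""

    stages: dict = field(default_factory=dict)  # stage name -> kept TF set
    edges: pd.DataFrame = None
    nodes: pd.DataFrame = None
    empty_at: str | None = None


def _target_overlap(a: set, b: set) -> float:
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def build_liver_network(
    up_genes: list[str],
    cons_genes: list[str],
    sites: pd.DataFrame,
    tf_candidates: pd.DataFrame,
    tissues: pd.DataFrame,
    focal: str,
    tf_shift_lrt: dict[str, float],
    min_targets: int = 20,
    evalue_max: float = 1e-10,
    aln_min: int = 100,
    top_hits: int = 4,
    motif_overlap: float = 0.8,
    top_display: int = 9,
) -> LiverNetwork:
    """Build the focal-tissue regulatory network over up+cons ohnolog
    pairs with a tissue-specific up-shifted copy.

    ``tf_candidates`` columns: tf, motif, evalue, aln_length.  Stages:
    (1) per motif keep the ``top_hits`` best hits passing the E-value and
    alignment-length cutoffs; (2) keep TFs bound in at least
    ``min_targets`` target promoters; (3) keep TFs passing the
    focal-tissue specificity filter.  Reduction: one TF per motif
    (largest |LRT|), merge motifs whose target sets overlap by more than
    ``motif_overlap``, collapse multi-motif TFs into single nodes, rank
    by up-shift bias (bound up-copies minus bound cons-copies) and keep
    the ``top_display`` strongest for display.
    """
    from .classify import liver_specific_filter

    net = LiverNetwork()
    targets = list(up_genes) + list(cons_genes)
    bound = sites[sites["bound"] & sites["gene"].isin(targets)]

    # stage 1: motif-hit quality filter
    cand = tf_candidates[
        (tf_candidates["evalue"] < evalue_max) & (tf_candidates["aln_length"] > aln_min)
    ]
    cand = (
        cand.sort_values(["motif", "evalue", "tf"], kind="mergesort")
        .groupby("motif", sort=True)
        .head(top_hits)
    )
    tfs1 = set(cand["tf"])
    net.stages["hit_quality"] = tfs1
    if not tfs1:
        net.empty_at = "hit_quality"
        return net

    # stage 2: bound in enough target promoters
    per_tf_targets = {
        tf: set(bound[bound["tf"] == tf]["gene"]) for tf in tfs1
    }
    tfs2 = {tf for tf in tfs1 if len(per_tf_targets[tf]) >= min_targets}
    net.stages["min_bound_targets"] = tfs2
    if not tfs2:
        net.empty_at = "min_bound_targets"
        return net

    # stage 3: focal-tissue-specific expression
    present = [tf for tf in sorted(tfs2) if tf in tissues.index]
    tfs3 = set(liver_specific_filter(present, tissues, focal))
    net.stages["tissue_specific"] = tfs3
    if not tfs3:
        net.empty_at = "tissue_specific"
        return net

    # reduction (a): per motif, TF with the strongest expression shift
    cand3 = cand[cand["tf"].isin(tfs3)]
    motif_tf = {}
    for motif, sub in cand3.groupby("motif", sort=True):
        motif_tf[motif] = max(
            sorted(sub["tf"]), key=lambda tf: (abs(tf_shift_lrt.get(tf, 0.0)), tf)
        )

    # reduction (b): merge motifs with highly overlapping target sets
    motif_targets = {
        m: per_tf_targets[tf] & set(targets) for m, tf in motif_tf.items()
    }
    kept_motifs: list[str] = []
    for m in sorted(motif_tf, key=lambda m: (-abs(tf_shift_lrt.get(motif_tf[m], 0.0)), m)):
        if any(
            _target_overlap(motif_targets[m], motif_targets[k]) > motif_overlap
            for k in kept_motifs
        ):
            continue
        kept_motifs.append(m)

    # reduction (c): collapse multi-motif TFs into one node
    tf_motifs: dict[str, list[str]] = {}
    for m in kept_motifs:
        tf_motifs.setdefault(motif_tf[m], []).append(m)

    up_set, cons_set = set(up_genes), set(cons_genes)
    rows = []
    for tf, motifs in tf_motifs.items():
        tg = per_tf_targets[tf] & set(targets)
        n_up = len(tg & up_set)
        n_cons = len(tg & cons_set)
        rows.append({
            "tf": tf, "motifs": ",".join(sorted(motifs)),
            "n_up_targets": n_up, "n_cons_targets": n_cons,
            "up_bias": n_up - n_cons, "n_targets": len(tg),
            "lrt": tf_shift_lrt.get(tf, 0.0),
        })
    nodes = pd.DataFrame(rows).sort_values(
        ["up_bias", "n_targets", "tf"], ascending=[False, False, True], kind="mergesort"
    )
    nodes["display"] = False
    nodes.iloc[: min(top_display, len(nodes)), nodes.columns.get_loc("display")] = True
    net.stages["reduced"] = set(nodes["tf"])

    edge_rows = []
    for tf in nodes["tf"]:
        for g in sorted(per_tf_targets[tf] & set(targets)):
            for m in sorted(tf_motifs[tf]):
                edge_rows.append({"tf": tf, "gene": g, "motif": m})
    net.edges = pd.DataFrame(edge_rows, columns=["tf", "gene", "motif"])
    net.nodes = nodes.reset_index(drop=True)
    return net


def te_site_overlap_by_copy(
    pairs: list[tuple[str, str]],
    sites: pd.DataFrame,
    tf_set: set[str] | None = None,
    group_by: str | None = None,
) -> pd.DataFrame:
    """Per up+cons pair: counts of bound sites overlapping a TE in the
    up-shifted vs the conserved copy.

    ``group_by="superfamily"`` splits counts per TE superfamily (the
    grouped counts partition the ungrouped total).  Feeds the paired
    Wilcoxon test downstream.
    """
    sub = sites[sites["bound"] & sites["te_overlap"]]
    if tf_set is not None:
        sub = sub[sub["tf"].isin(tf_set)]
    rows = []
    if group_by is None:
        for up_g, cons_g in pairs:
            rows.append({
                "up_gene": up_g, "cons_gene": cons_g,
                "count_up": int((sub["gene"] == up_g).sum()),
                "count_cons": int((sub["gene"] == cons_g).sum()),
            })
    elif group_by == "superfamily":
        fams = sorted(sub["te_superfamily"].dropna().unique())
        for up_g, cons_g in pairs:
            for fam in fams:
                fs = sub[sub["te_superfamily"] == fam]
                rows.append({
                    "up_gene": up_g, "cons_gene": cons_g, "superfamily": fam,
                    "count_up": int((fs["gene"] == up_g).sum()),
                    "count_cons": int((fs["gene"] == cons_g).sum()),
                })
    else:
        raise ValueError(f"unknown group_by {group_by!r}")
    return pd.DataFrame(rows)
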