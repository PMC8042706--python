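"""Phylogenetic trees and gene-tree filtering.

Trees are parsed from Newick with dendropy and converted to a compact
array representation (preorder node list with parent pointers) that the
Ornstein-Uhlenbeck likelihood machinery can traverse cheaply.

Gene trees follow the ``SPECIES|geneid`` tip-label convention.  A gene
tree is classified by the number of maximal ingroup (salmonid) clades it
contains: one clade means the whole-genome-duplication copy was lost
(singleton), two clades mean a retained ohnolog pair, anything else is
rejected.  Additional filters reject trees with within-clade paralogs,
duplicated outgroup species, unexpressed duplicate clades, or missing
outgroup anchor species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "SpeciesRoles",
    "TreeClass",
    "TestUnit",
    "NewickParseError",
    "parse_newick",
    "split_label",
    "classify_tree",
    "duplicate_clades",
    "expression_filters",
    "extract_test_units",
    "prune_species_tree",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


def split_label(label: str, sep: str = "|") -> tuple[str, str]:
    """Split a ``SPECIES|geneid`` tip label into (species, gene id).

    Labels without the separator are treated as species-only (the gene id
    equals the label), which is the convention for species trees.
    """
    if sep in label:
        species, gene = label.split(sep, 1)
        return species, gene
    return label, label


class PhyloTree:
    """Rooted tree with branch lengths in a flat preorder layout.

    Attributes
    ----------
    parent : (n_nodes,) int array, ``parent[0] == -1`` for the root.
    edge_len : (n_nodes,) float array, length of the edge above each node
        (0.0 for the root).
    labels : list of tip labels (``None`` on internal nodes).
    """

    def __init__(self, parent: np.ndarray, edge_len: np.ndarray, labels: list[str | None]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.edge_len = np.asarray(edge_len, dtype=float)
        self.labels = list(labels)
        n = len(self.labels)
        if self.parent.shape != (n,) or self.edge_len.shape != (n,):
            raise ValueError("inconsistent array sizes")
        self._children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self._children[self.parent[i]].append(i)
        self.tip_idx = np.array([i for i in range(n) if not self._children[i]], dtype=np.int64)
        self.tip_labels = [self.labels[i] for i in self.tip_idx]
        if any(lbl is None for lbl in self.tip_labels):
            raise ValueError("every tip must be labelled")
        # root-to-node depths
        self.depth = np.zeros(n)
        for i in range(1, n):
            self.depth[i] = self.depth[self.parent[i]] + self.edge_len[i]

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dt = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        nodes = list(dt.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        edge_len = np.zeros(len(nodes))
        labels: list[str | None] = [None] * len(nodes)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                edge_len[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label is None:
                    raise NewickParseError("unlabelled tip")
                labels[i] = nd.taxon.label
        return cls(parent, edge_len, labels)

    def to_newick(self) -> str:
        def fmt(i: int) -> str:
            if not self._children[i]:
                body = self.labels[i]
            else:
                body = "(" + ",".join(fmt(c) for c in self._children[i]) + ")"
            if self.parent[i] == -1:
                return body
            return f"{body}:{self.edge_len[i]:.10g}"

        return fmt(0) + ";"

    # -- basic queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_tips(self) -> int:
        return len(self.tip_idx)

    def children(self, i: int) -> list[int]:
        return self._children[i]

    def is_tip(self, i: int) -> bool:
        return not self._children[i]

    def tip_index(self, label: str) -> int:
        for i in self.tip_idx:
            if self.labels[i] == label:
                return int(i)
        raise KeyError(label)

    def root_depth(self) -> float:
        """Maximum root-to-tip path length."""
        return float(self.depth[self.tip_idx].max())

    def is_ultrametric(self, rel_tol: float = 1e-9) -> bool:
        d = self.depth[self.tip_idx]
        return bool(np.ptp(d) <= rel_tol * max(d.max(), 1.0))

    def ancestors(self, i: int) -> list[int]:
        """Path from node *i* up to and including the root."""
        path = []
        while i != -1:
            path.append(i)
            i = int(self.parent[i])
        return path

    def mrca(self, node_ids: list[int]) -> int:
        paths = [set(self.ancestors(i)) for i in node_ids]
        common = set.intersection(*paths)
        return max(common, key=lambda j: self.depth[j])

    def clade_nodes(self, stem: int) -> list[int]:
        """Stem node plus all descendants (preorder)."""
        out, stack = [], [stem]
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(self._children[i])
        return out

    def tip_distance_matrix(self) -> np.ndarray:
        """Patristic distances between tips, ordered as ``tip_labels``."""
        k = self.n_tips
        D = np.zeros((k, k))
        anc = [self.ancestors(int(i)) for i in self.tip_idx]
        anc_sets = [set(a) for a in anc]
        for a in range(k):
            for b in range(a + 1, k):
                common = anc_sets[a] & anc_sets[b]
                m = max(common, key=lambda j: self.depth[j])
                d = self.depth[self.tip_idx[a]] + self.depth[self.tip_idx[b]] - 2 * self.depth[m]
                D[a, b] = D[b, a] = d
        return D

    def tip_path_segments(self, tip: int) -> list[tuple[int, float, float]]:
        """Edges on the root-to-tip path as (node, start_depth, end_depth).

        ``start_depth``/``end_depth`` are distances from the root to the
        top and bottom of the edge above ``node``; used for the OU
        regime-weighted expectation.
        """
        segs = []
        for i in self.ancestors(tip):
            if self.parent[i] == -1:
                continue
            segs.append((i, float(self.depth[self.parent[i]]), float(self.depth[i])))
        segs.reverse()
        return segs

    def prune_to(self, keep_labels: set[str]) -> "PhyloTree":
        """Restrict to the given tips, collapsing unary nodes.

        Patristic distances among kept tips are preserved exactly; the
        edge above the new root (if any) is discarded.
        """
        missing = keep_labels - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        # mark retained nodes: tips kept + their ancestors
        retain = np.zeros(self.n_nodes, dtype=bool)
        for i in self.tip_idx:
            if self.labels[i] in keep_labels:
                for a in self.ancestors(int(i)):
                    retain[a] = True
        # new root: deepest retained node that is an ancestor of all kept tips
        kept_tips = [int(i) for i in self.tip_idx if self.labels[i] in keep_labels]
        new_root = self.mrca(kept_tips) if len(kept_tips) > 1 else kept_tips[0]

        parent_out: list[int] = []
        len_out: list[float] = []
        labels_out: list[str | None] = []

        def rec(i: int, new_parent: int, acc_len: float) -> None:
            kids = [c for c in self._children[i] if retain[c]]
            if i != new_root and len(kids) == 1 and self.is_tip(i) is False:
                # unary internal node: collapse, accumulating length
                rec(kids[0], new_parent, acc_len + self.edge_len[kids[0]])
                return
            j = len(parent_out)
            parent_out.append(new_parent)
            len_out.append(acc_len)
            labels_out.append(self.labels[i])
            for c in kids:
                rec(c, j, float(self.edge_len[c]))

        rec(new_root, -1, 0.0)
        return PhyloTree(np.array(parent_out), np.array(len_out), labels_out)


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Round-trips: ``parse_newick(t.to_newick())`` preserves topology and
    branch lengths.
    """
    return PhyloTree.from_newick(text)


@dataclass(frozen=True)
class SpeciesRoles:
    """Species role map for a study design.

    ``ingroup`` are the WGD-descendant (salmonid-role) species;
    ``sister_anchor`` is the closest outgroup whose ortholog must be
    present and expressed (pike role); ``distant_anchors`` are far
    outgroups of which at least one must be present and expressed
    (zebrafish/medaka roles).
    """

    ingroup: frozenset
    sister_anchor: str = ""
    distant_anchors: frozenset = frozenset()
    other_outgroups: frozenset = frozenset()

    def __init__(self, ingroup, sister_anchor="", distant_anchors=(), other_outgroups=()):
        object.__setattr__(self, "ingroup", frozenset(ingroup))
        object.__setattr__(self, "sister_anchor", sister_anchor)
        object.__setattr__(self, "distant_anchors", frozenset(distant_anchors))
        object.__setattr__(self, "other_outgroups", frozenset(other_outgroups))

    @property
    def outgroup(self) -> frozenset:
        out = set(self.distant_anchors) | set(self.other_outgroups)
        if self.sister_anchor:
            out.add(self.sister_anchor)
        return frozenset(out)

    def role(self, species: str) -> str:
        if species in self.ingroup:
            return "ingroup"
        if species in self.outgroup:
            return "outgroup"
        raise KeyError(f"species {species!r} has no assigned role")


@dataclass(frozen=True)
class TreeClass:
    """Classification outcome for one gene tree."""

    status: str  # singleton-complete | singleton-partial | ohnolog-complete | ohnolog-partial | rejected
    reason: str | None = None  # exactly one machine-readable reason when rejected

    @property
    def accepted(self) -> bool:
        return self.status != "rejected"

    @property
    def is_ohnolog(self) -> bool:
        return self.status.startswith("ohnolog")


@dataclass(frozen=True)
class TestUnit:
    """One duplicate clade plus all outgroup genes: the unit the OU shift
    test runs on."""

    clade_id: int  # 0 for singletons; 0/1 for the two duplicate clades
    genes: dict = field(default_factory=dict)  # gene id -> species
    ingroup_genes: tuple = ()


def _tip_species(tree: PhyloTree) -> dict[int, str]:
    return {int(i): split_label(tree.labels[i])[0] for i in tree.tip_idx}


def maximal_ingroup_clades(tree: PhyloTree, roles: SpeciesRoles) -> list[int]:
    """Stem nodes of maximal subtrees whose tips are all ingroup species."""
    sp = _tip_species(tree)
    pure = np.zeros(tree.n_nodes, dtype=bool)
    # postorder = reversed preorder
    for i in range(tree.n_nodes - 1, -1, -1):
        kids = tree.children(i)
        if not kids:
            pure[i] = roles.role(sp[i]) == "ingroup"
        else:
            pure[i] = all(pure[c] for c in kids)
    stems = []
    for i in range(tree.n_nodes):
        if pure[i] and (tree.parent[i] == -1 or not pure[tree.parent[i]]):
            stems.append(i)
    return stems


def duplicate_clades(tree: PhyloTree, roles: SpeciesRoles) -> tuple[list[int], str | None]:
    """Split maximal ingroup subtrees into duplicate clades.

    A maximal pure-ingroup subtree with each species at most once is one
    clade.  One in which species recur is split once at its root (the
    WGD duplication node); if a child still contains a species twice the
    tree carries within-clade paralogs and is rejected.  Returns
    (clade stem nodes, rejection reason or None).
    """
    sp = _tip_species(tree)

    def species_multiset(stem: int) -> list[str]:
        return [sp[i] for i in tree.clade_nodes(stem) if tree.is_tip(i)]

    stems: list[int] = []
    for m in maximal_ingroup_clades(tree, roles):
        members = species_multiset(m)
        if len(members) == len(set(members)):
            stems.append(m)
            continue
        for c in tree.children(m):
            cm = species_multiset(c)
            if len(cm) != len(set(cm)):
                return [], "ingroup_paralogs"
            stems.append(c)
    return stems, None


def classify_tree(tree: PhyloTree, roles: SpeciesRoles) -> TreeClass:
    """Apply the topology filters and label the tree.

    Rejection reasons: ``excess_clades`` (more than two maximal ingroup
    clades), ``no_ingroup_clade``, ``ingroup_paralogs`` (one species twice
    inside a duplicate clade), ``outgroup_paralogs`` (an outgroup species
    appearing more than once).  Otherwise the tree is a singleton (one
    clade) or ohnolog (two clades), and complete iff every expected
    ingroup species occurs in every clade.
    """
    sp = _tip_species(tree)
    for s in set(sp.values()):
        roles.role(s)  # raises on unknown species

    stems, reason = duplicate_clades(tree, roles)
    if reason is not None:
        return TreeClass("rejected", reason)
    if len(stems) > 2:
        return TreeClass("rejected", "excess_clades")
    if len(stems) == 0:
        return TreeClass("rejected", "no_ingroup_clade")

    out_species = [sp[int(i)] for i in tree.tip_idx if roles.role(sp[int(i)]) == "outgroup"]
    if len(out_species) != len(set(out_species)):
        return TreeClass("rejected", "outgroup_paralogs")

    complete = True
    for stem in stems:
        clade_sp = [sp[i] for i in tree.clade_nodes(stem) if tree.is_tip(i)]
        if set(clade_sp) != set(roles.ingroup):
            complete = False

    kind = "singleton" if len(stems) == 1 else "ohnolog"
    return TreeClass(f"{kind}-{'complete' if complete else 'partial'}")


def extract_test_units(tree: PhyloTree, roles: SpeciesRoles) -> list[TestUnit]:
    """One unit per duplicate clade: its ingroup genes plus all outgroup
    genes (shared between the two units of an ohnolog tree)."""
    sp = _tip_species(tree)
    stems, reason = duplicate_clades(tree, roles)
    if reason is not None:
        raise ValueError(f"cannot extract units from a rejected tree ({reason})")
    out_genes = {
        split_label(tree.labels[int(i)])[1]: sp[int(i)]
        for i in tree.tip_idx
        if roles.role(sp[int(i)]) == "outgroup"
    }
    units = []
    for k, stem in enumerate(sorted(stems)):
        in_genes = {
            split_label(tree.labels[i])[1]: sp[i]
            for i in tree.clade_nodes(stem)
            if tree.is_tip(i)
        }
        genes = dict(out_genes)
        genes.update(in_genes)
        units.append(TestUnit(clade_id=k, genes=genes, ingroup_genes=tuple(sorted(in_genes))))
    return units


def expression_filters(
    tree: PhyloTree,
    tree_class: TreeClass,
    panel,
    roles: SpeciesRoles,
    zero_threshold: float = 0.0,
) -> TreeClass:
    """Expression-based exclusions applied after the topology filters.

    A gene is "not expressed" when all its replicates are at or below
    ``zero_threshold`` on the TPM scale.  The tree is rejected when (1) a
    duplicate clade has no expressed gene, (2) the sister-outgroup anchor
    is missing or unexpressed, or (3) every distant-outgroup anchor is
    missing or unexpressed.
    """
    if not tree_class.accepted:
        return tree_class

    def expressed(gene: str) -> bool:
        vals = panel.gene_values(gene)
        return bool(np.any(vals > zero_threshold))

    sp = _tip_species(tree)
    genes_by_species: dict[str, list[str]] = {}
    for i in tree.tip_idx:
        genes_by_species.setdefault(sp[int(i)], []).append(split_label(tree.labels[int(i)])[1])

    for unit in extract_test_units(tree, roles):
        if not any(expressed(g) for g in unit.ingroup_genes):
            return TreeClass("rejected", "unexpressed_clade")

    sister = genes_by_species.get(roles.sister_anchor, [])
    if not sister or not any(expressed(g) for g in sister):
        return TreeClass("rejected", "missing_sister_anchor")

    ok = False
    for s in roles.distant_anchors:
        if any(expressed(g) for g in genes_by_species.get(s, [])):
            ok = True
    if roles.distant_anchors and not ok:
        return TreeClass("rejected", "missing_distant_anchors")

    return tree_class


def prune_species_tree(tree: PhyloTree, keep: set[str]) -> PhyloTree:
    """Prune the species tree to ``keep``, preserving patristic distances.

    Refuses fewer than 3 species: the OU shift model is unidentifiable
    below that.
    """
    if len(keep) < 3:
        raise ValueError("need at least 3 species to fit the OU model")
    return tree.prune_to(set(keep))
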