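"""Ohnolog pair classification and tissue statistics.

Per-copy shift calls combine into the six unordered pair categories
(cons+cons, up+cons, down+cons, up+up, down+down, up+down); "cons" means
the copy's shift test was not significant.  Pair-level statistics:
expression asymmetry (absolute mean log2 difference between copies over
all ingroup samples), tissue concordance counts against an independent
tissue atlas, the tau tissue-specificity index, and the focal-tissue
(liver role) specificity filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eve import ShiftCall
from .normalization import ExpressionPanel

log = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "OhnologPair",
    "call_state",
    "classify_pair",
    "expression_asymmetry",
    "pair_asymmetry",
    "tissue_concordance",
    "tau_score",
    "liver_specific_filter",
]

_RANK = {"up": 0, "down": 1, "cons": 2}
CATEGORIES = ("cons+cons", "up+cons", "down+cons", "up+up", "down+down", "up+down")


@dataclass
class OhnologPair:
    gene_a: str
    gene_b: str
    call_a: ShiftCall
    call_b: ShiftCall
    category: str | None = None
    asymmetry: float = np.nan


def call_state(call: ShiftCall) -> str:
    """Reduce a shift call to its category state: up/down if significant,
    cons otherwise."""
    if call.status != "tested":
        raise ValueError(f"untested call ({call.reason}); pair must be excluded")
    return call.direction if call.significant else "cons"


def classify_pair(call_a: ShiftCall, call_b: ShiftCall) -> str:
    """Unordered category of a pair of per-copy shift calls."""
    states = sorted((call_state(call_a), call_state(call_b)), key=_RANK.__getitem__)
    return "+".join(states)


def expression_asymmetry(
    gene_a: str, gene_b: str, panel: ExpressionPanel, ingroup_samples: list[str]
) -> float:
    """|mean over ingroup samples of (x_a - x_b)| on the logged scale."""
    cols = [s for s in ingroup_samples if s in panel.samples]
    if len(cols) < len(ingroup_samples):
        log.info("asymmetry for (%s, %s) computed over %d shared samples",
                 gene_a, gene_b, len(cols))
    if not cols:
        raise ValueError("no ingroup samples available")
    xa = panel.values.loc[gene_a, cols].to_numpy(dtype=float)
    xb = panel.values.loc[gene_b, cols].to_numpy(dtype=float)
    return float(abs(np.mean(xa - xb)))


def pair_asymmetry(
    copies_a: dict[str, str],
    copies_b: dict[str, str],
    panel: ExpressionPanel,
    ingroup_species: list[str],
) -> float:
    """Pair-level asymmetry across all ingroup species.

    ``copies_a``/``copies_b`` map species to that species' gene id for
    each copy; the per-sample differences of all species with both
    copies are pooled before taking |mean|.
    """
    diffs: list[float] = []
    for s in ingroup_species:
        if s in copies_a and s in copies_b:
            xa = panel.species_values(copies_a[s], s)
            xb = panel.species_values(copies_b[s], s)
            diffs.extend(xa - xb)
    if not diffs:
        raise ValueError("no species carries both copies")
    return float(abs(np.mean(diffs)))


def tissue_concordance(
    shifted_gene: str,
    conserved_gene: str,
    tissues: pd.DataFrame,
    focal: str,
) -> tuple[int, int]:
    """Count non-focal tissues where the shifted copy is strictly lower /
    strictly higher than its conserved partner.  Ties count in neither."""
    if focal not in tissues.columns:
        raise KeyError(f"focal tissue {focal!r} not in matrix")
    others = [t for t in tissues.columns if t != focal]
    s = tissues.loc[shifted_gene, others].to_numpy(dtype=float)
    c = tissues.loc[conserved_gene, others].to_numpy(dtype=float)
    n_lower = int(np.sum(s < c))
    n_higher = int(np.sum(s > c))
    if n_lower + n_higher < len(others):
        log.debug("%d tied tissues for (%s, %s)",
                  len(others) - n_lower - n_higher, shifted_gene, conserved_gene)
    return n_lower, n_higher


def tau_score(x: np.ndarray) -> float:
    """Tissue-specificity index: tau = sum_i (1 - x_i/max) / (N - 1).

    0 for a uniform profile, 1 for single-tissue expression.  Computed on
    linear nonnegative values; all-zero profiles are undefined.
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("tau requires nonnegative values")
    m = x.max()
    if m == 0:
        raise ValueError("tau undefined for an all-zero profile")
    return float(np.sum(1.0 - x / m) / (len(x) - 1))


def liver_specific_filter(
    genes: list[str],
    tissues: pd.DataFrame,
    focal: str,
    max_fraction: float = 0.9,
    tau_min: float = 0.6,
    rule: str = "fraction_of_max",
) -> list[str]:
    """Keep genes whose focal-tissue expression is at least
    ``max_fraction`` of their across-tissue maximum and whose tau exceeds
    ``tau_min``.

    ``rule="quantile"`` instead requires focal expression at or above the
    ``max_fraction`` quantile of the gene's own tissue profile.
    """
    if focal not in tissues.columns:
        raise KeyError(f"focal tissue {focal!r} not in matrix")
    kept = []
    for g in genes:
        x = tissues.loc[g].to_numpy(dtype=float)
        if x.max() == 0:
            continue
        fx = float(tissues.loc[g, focal])
        if rule == "fraction_of_max":
            passes_level = fx >= max_fraction * x.max()
        elif rule == "quantile":
            passes_level = fx >= np.quantile(x, max_fraction)
        else:
            raise ValueError(f"unknown rule {rule!r}")
        if passes_level and tau_score(x) > tau_min:
            kept.append(g)
    return kept
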