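"""Cross-species expression normalization.

Two-stage trimmed-mean-of-M-values (TMM) scaling applied to TPM
matrices: replicates are first normalized within each species, then the
species are normalized against each other using only genes from
singleton orthogroups (one gene per species), whose per-species replicate
means form the between-species comparison matrix.  Finally expression is
log transformed as ``log2(TPM + 0.01)``.

The TMM factor is re-implemented here on TPM values directly: M-values
are log2 ratios test/reference, A-values the average log2 abundance;
genes with a zero in either column are dropped, the extremes of the M-
and A-distributions are rank-trimmed, and the factor is two to the power
of the precision-weighted mean of the surviving M-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionPanel",
    "TMMParams",
    "tmm_factor",
    "normalize_within_species",
    "normalize_between_species",
    "log_transform",
]

_STATES = ("raw", "within-normalized", "between-normalized", "logged")


@dataclass(frozen=True)
class TMMParams:
    """Trim and reference-selection settings for the TMM factor."""

    logratio_trim: float = 0.30
    abs_expr_trim: float = 0.05
    min_genes: int = 10  # below this, fall back to the untrimmed mean

    def __post_init__(self):
        if not (0 <= self.logratio_trim < 0.5 and 0 <= self.abs_expr_trim < 0.5):
            raise ValueError("trims must lie in [0, 0.5)")


class ExpressionPanel:
    """Genes x samples expression matrix with species bookkeeping.

    The ``state`` flag enforces the normalization order
    raw -> within-normalized -> between-normalized -> logged; each stage
    refuses input in the wrong state, so a panel can never be normalized
    twice.
    """

    def __init__(self, values: pd.DataFrame, sample_species: pd.Series, state: str = "raw"):
        if state not in _STATES:
            raise ValueError(f"unknown state {state!r}")
        missing = set(values.columns) - set(sample_species.index)
        if missing:
            raise ValueError(f"samples without species assignment: {sorted(missing)}")
        # NaN marks genes a species does not have; negatives are invalid
        if state != "logged" and np.nanmin(values.to_numpy(), initial=0.0) < 0:
            raise ValueError("TPM-scale values must be nonnegative")
        self.values = values
        self.sample_species = sample_species.loc[values.columns]
        self.state = state
        self.factors: list[dict] = []  # (sample, species, stage, factor) records

    # -- queries -------------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def species_of(self, sample: str) -> str:
        return self.sample_species[sample]

    def samples_for(self, species: str) -> list[str]:
        return [s for s in self.samples if self.sample_species[s] == species]

    def gene_values(self, gene: str) -> np.ndarray:
        if gene not in self.values.index:
            raise KeyError(f"gene {gene!r} not in panel")
        return self.values.loc[gene].to_numpy(dtype=float)

    def species_values(self, gene: str, species: str) -> np.ndarray:
        cols = self.samples_for(species)
        if not cols:
            raise KeyError(f"no samples for species {species!r}")
        return self.values.loc[gene, cols].to_numpy(dtype=float)

    def _advance(self, new_values: pd.DataFrame, new_state: str) -> "ExpressionPanel":
        if _STATES.index(new_state) != _STATES.index(self.state) + 1:
            raise ValueError(f"cannot go from state {self.state!r} to {new_state!r}")
        out = ExpressionPanel(new_values, self.sample_species, new_state)
        out.factors = list(self.factors)
        return out

    # -- I/O -----------------------------------------------------------

    def write(self, matrix_path: Path, map_path: Path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene")
        self.sample_species.rename("species").to_csv(map_path, sep="\t", index_label="sample")

    @classmethod
    def read(cls, matrix_path: Path, map_path: Path, state: str = "raw") -> "ExpressionPanel":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        sm = pd.read_csv(map_path, sep="\t", index_col=0)["species"]
        return cls(values, sm, state=state)

    def write_factors(self, path: Path) -> None:
        pd.DataFrame(self.factors, columns=["sample", "species", "stage", "factor"]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# TMM


def _ref_column(mat: pd.DataFrame) -> str:
    """Reference = column whose upper quartile is closest to the mean
    upper quartile (computed over nonzero values)."""
    uq = {}
    for c in mat.columns:
        col = mat[c].to_numpy(dtype=float)
        nz = col[col > 0]
        uq[c] = np.quantile(nz, 0.75) if nz.size else 0.0
    target = np.mean(list(uq.values()))
    return min(mat.columns, key=lambda c: (abs(uq[c] - target), str(c)))


def tmm_factor(test_col: np.ndarray, ref_col: np.ndarray, params: TMMParams | None = None) -> float:
    """Scale factor for ``test_col`` relative to ``ref_col``.

    Returns ``2**f`` where ``f`` is the weighted trimmed mean of
    M-values; dividing the test column by the factor aligns it with the
    reference.  Weights are the inverse asymptotic binomial variance of
    M computed from the column totals.
    """
    params = params or TMMParams()
    t = np.asarray(test_col, dtype=float)
    r = np.asarray(ref_col, dtype=float)
    if t.shape != r.shape:
        raise ValueError("columns must have equal length")
    if np.all(t == 0) or np.all(r == 0):
        raise ValueError("column is all zero")
    Nt, Nr = t.sum(), r.sum()
    keep = (t > 0) & (r > 0)
    t, r = t[keep], r[keep]
    M = np.log2(t / r)
    A = 0.5 * np.log2(t * r)
    w = 1.0 / ((Nt - t) / (Nt * t) + (Nr - r) / (Nr * r))

    n = len(M)
    if n == 0:
        return 1.0
    loL = np.floor(n * params.logratio_trim) + 1
    hiL = n + 1 - loL
    loS = np.floor(n * params.abs_expr_trim) + 1
    hiS = n + 1 - loS
    rM = rankdata(M)
    rA = rankdata(A)
    sel = (rM >= loL) & (rM <= hiL) & (rA >= loS) & (rA <= hiS)
    if sel.sum() < params.min_genes:
        warnings.warn(
            f"only {int(sel.sum())} genes survive TMM trimming; using untrimmed mean",
            stacklevel=2,
        )
        sel = np.ones(n, dtype=bool)
    f = np.sum(w[sel] * M[sel]) / np.sum(w[sel])
    return float(2.0 ** f)


def _geo_center(factors: dict[str, float]) -> dict[str, float]:
    logs = np.log([max(v, 1e-300) for v in factors.values()])
    gm = np.exp(logs.mean())
    return {k: v / gm for k, v in factors.items()}


def normalize_within_species(panel: ExpressionPanel, params: TMMParams | None = None) -> ExpressionPanel:
    """TMM-normalize replicates within each species.

    Each sample is divided by its TMM factor against a per-species
    reference sample; factors are geometric-mean-centered to 1 within
    each species so the species-level scale is untouched.
    """
    params = params or TMMParams()
    if panel.state != "raw":
        raise ValueError(f"expected raw panel, got state {panel.state!r}")
    out = panel.values.copy()
    records = []
    for species in sorted(set(panel.sample_species)):
        cols = panel.samples_for(species)
        if len(cols) == 1:
            log.info("species %s has a single replicate; factor = 1", species)
            records.append({"sample": cols[0], "species": species,
                            "stage": "within", "factor": 1.0})
            continue
        # genes absent from this species (NaN rows) do not inform its factors
        sub = panel.values[cols].dropna(axis=0, how="any")
        ref = _ref_column(sub)
        raw = {
            c: 1.0 if c == ref else tmm_factor(sub[c].to_numpy(), sub[ref].to_numpy(), params)
            for c in cols
        }
        centered = _geo_center(raw)
        for c in cols:
            out[c] = out[c] / centered[c]
            records.append({"sample": c, "species": species,
                            "stage": "within", "factor": centered[c]})
    res = panel._advance(out, "within-normalized")
    res.factors.extend(records)
    return res


def normalize_between_species(
    panel: ExpressionPanel,
    singleton_table: pd.DataFrame,
    params: TMMParams | None = None,
) -> ExpressionPanel:
    """TMM-normalize species against each other on singleton orthogroups.

    ``singleton_table`` has columns (orthogroup, species, gene), one gene
    per species per orthogroup.  Per-species replicate means over these
    genes form a species-per-column matrix; one TMM factor per species is
    computed against a reference species, geometric-mean-centered across
    species, and applied to every replicate of that species.
    """
    params = params or TMMParams()
    if panel.state != "within-normalized":
        raise ValueError(f"expected within-normalized panel, got {panel.state!r}")
    if singleton_table.empty:
        raise ValueError("singleton orthogroup set is empty")
    dup = singleton_table.groupby(["orthogroup", "species"]).size()
    if (dup > 1).any():
        raise ValueError("singleton orthogroups must have one gene per species")

    species_list = sorted(set(panel.sample_species))
    ogs = sorted(singleton_table["orthogroup"].unique())
    mat = pd.DataFrame(0.0, index=ogs, columns=species_list)
    for _, row in singleton_table.iterrows():
        if row["gene"] in panel.values.index and row["species"] in species_list:
            mat.loc[row["orthogroup"], row["species"]] = panel.values.loc[
                row["gene"], panel.samples_for(row["species"])
            ].mean()
    # TMM on composition-normalized columns; the column total carries the
    # species' overall scale.  This makes a per-species rescaling cancel
    # exactly (up to the global geometric-mean centering).
    totals = mat.sum(axis=0)
    comp = mat / totals * 1e6
    ref = _ref_column(comp)
    raw = {
        s: (1.0 if s == ref else tmm_factor(comp[s].to_numpy(), comp[ref].to_numpy(), params))
        * totals[s]
        for s in species_list
    }
    centered = _geo_center(raw)
    out = panel.values.copy()
    records = []
    for s in species_list:
        for c in panel.samples_for(s):
            out[c] = out[c] / centered[s]
            records.append({"sample": c, "species": s, "stage": "between",
                            "factor": centered[s]})
    res = panel._advance(out, "between-normalized")
    res.factors.extend(records)
    return res


def log_transform(panel: ExpressionPanel, pseudo: float = 0.01) -> ExpressionPanel:
    """log2(TPM + 0.01) transform."""
    if panel.state != "between-normalized":
        raise ValueError(f"expected between-normalized panel, got {panel.state!r}")
    if (panel.values.to_numpy() < 0).any():
        raise ValueError("negative expression values")
    return panel._advance(np.log2(panel.values + pseudo), "logged")
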