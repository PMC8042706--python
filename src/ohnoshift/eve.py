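"""Phylogenetic Ornstein-Uhlenbeck model of expression evolution.

The model: a gene's (log2) expression level evolves along the species
tree as an OU process with pull strength ``alpha`` towards an optimum
``theta`` and drift variance rate ``sigma2``.  At stationarity the
between-species covariance for tips at patristic distance ``d`` is

    Cov(i, j) = (sigma2 / 2 alpha) * exp(-alpha * d)

Biological replicates within a species scatter around the species mean
with variance ``beta * sigma2 / (2 alpha)``, i.e. ``beta`` is the
within-/between-species variance ratio.

The shift test compares a two-optima model (one optimum painted on the
WGD-descendant clade, stem branch included, another on the rest of the
tree) against a single-optimum null by a likelihood-ratio test referred
to the chi-squared distribution with one degree of freedom; LRT scores
above the 95% quantile are called significant and the sign of
``theta_shift - theta_base`` gives the shift direction.

Fitting profiles the likelihood: for fixed (alpha, beta) the optima and
the stationary variance have closed-form generalized-least-squares
estimates, so numerical optimization runs over (log alpha, log beta)
only, from several deterministic and seeded random starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.stats import chi2

from .trees import PhyloTree

__all__ = [
    "OUParams",
    "EVEFit",
    "ShiftCall",
    "CHI2_95",
    "paint_ingroup_clade",
    "ou_mean_vector",
    "ou_covariance",
    "log_likelihood",
    "fit_single_theta",
    "fit_two_theta",
    "two_theta_test",
    "run_orthogroup",
]

# 95% quantile of chi-squared with 1 df: the significance cutoff for the LRT
CHI2_95: float = float(chi2.ppf(0.95, df=1))


@dataclass(frozen=True)
class OUParams:
    """OU parameters; ``thetas`` has one entry per regime (base first)."""

    thetas: tuple
    alpha: float
    sigma2: float
    beta: float

    def __post_init__(self):
        if self.alpha <= 0 or self.sigma2 <= 0 or self.beta <= 0:
            raise ValueError("alpha, sigma2 and beta must be positive")
        if not np.all(np.isfinite(self.thetas)):
            raise ValueError("thetas must be finite")

    @property
    def stationary_var(self) -> float:
        return self.sigma2 / (2.0 * self.alpha)


@dataclass
class EVEFit:
    params: OUParams
    logL: float
    converged: bool
    n_restarts_used: int = 0


@dataclass
class ShiftCall:
    """Outcome of the two-optima test for one (orthogroup, clade) unit."""

    lrt: float
    p: float
    significant: bool
    direction: str  # "up" | "down" | "none"
    theta_base: float
    theta_shift: float
    alpha: float
    sigma2: float
    beta: float
    status: str = "tested"  # "tested" | "untested"
    reason: str | None = None

    @classmethod
    def untested(cls, reason: str) -> "ShiftCall":
        return cls(
            lrt=np.nan, p=np.nan, significant=False, direction="none",
            theta_base=np.nan, theta_shift=np.nan, alpha=np.nan,
            sigma2=np.nan, beta=np.nan, status="untested", reason=reason,
        )


def paint_ingroup_clade(tree: PhyloTree, ingroup_tips: list[str]) -> np.ndarray:
    """Regime painting: 1 on the stem branch of the MRCA of the given
    tips and on all its descendant branches, 0 elsewhere."""
    painting = np.zeros(tree.n_nodes, dtype=np.int64)
    tip_ids = [tree.tip_index(lbl) for lbl in ingroup_tips]
    stem = tip_ids[0] if len(tip_ids) == 1 else tree.mrca(tip_ids)
    for i in tree.clade_nodes(stem):
        painting[i] = 1
    if painting[0] == 1:
        raise ValueError("shifted regime cannot include the root")
    return painting


def _check_painting(tree: PhyloTree, painting: np.ndarray) -> np.ndarray:
    painting = np.asarray(painting, dtype=np.int64)
    if painting.shape != (tree.n_nodes,):
        raise ValueError("painting must cover every branch")
    return painting


def ou_mean_vector(tree: PhyloTree, painting: np.ndarray, params: OUParams) -> np.ndarray:
    """Expected value at each tip under the regime painting.

    The root state sits at the base optimum; along the root-to-tip path
    each branch segment with optimum theta_r contributes
    ``theta_r * (exp(-a*(T-s_end)) - exp(-a*(T-s_start)))`` where s is
    the distance from the root and T the tip depth.  With a single
    regime this collapses to theta exactly.
    """
    painting = _check_painting(tree, painting)
    a = params.alpha
    thetas = np.asarray(params.thetas, dtype=float)
    out = np.empty(tree.n_tips)
    for t, tip in enumerate(tree.tip_idx):
        T = tree.depth[tip]
        mu = thetas[painting[0]] * np.exp(-a * T)
        for node, s0, s1 in tree.tip_path_segments(int(tip)):
            w = np.exp(-a * (T - s1)) - np.exp(-a * (T - s0))
            mu += thetas[painting[node]] * w
        out[t] = mu
    return out


def _expand_to_individuals(tree: PhyloTree, sample_map: dict[str, int]) -> np.ndarray:
    """Tip index of each individual, replicates consecutive in tip order."""
    idx = []
    for t, lbl in enumerate(tree.tip_labels):
        n = sample_map[lbl]
        if n < 1:
            raise ValueError(f"species {lbl!r} needs at least one replicate")
        idx.extend([t] * n)
    return np.asarray(idx, dtype=np.int64)


def ou_covariance(tree: PhyloTree, params: OUParams, sample_map: dict[str, int]) -> np.ndarray:
    """Individual-level covariance matrix.

    Between individuals of species i and j (any replicates, not the same
    individual): ``(sigma2/2a) * exp(-a * d_ij)``; the diagonal adds the
    within-species component ``beta * sigma2/(2a)``.
    """
    v = params.stationary_var
    D = tree.tip_distance_matrix()
    idx = _expand_to_individuals(tree, sample_map)
    C = v * np.exp(-params.alpha * D)[np.ix_(idx, idx)]
    C[np.diag_indices_from(C)] += params.beta * v
    return C


def log_likelihood(
    y: np.ndarray,
    tree: PhyloTree,
    painting: np.ndarray,
    params: OUParams,
    sample_map: dict[str, int],
) -> float:
    """Multivariate-normal log density of the replicate vector ``y``.

    ``y`` is ordered species-by-species following ``tree.tip_labels``,
    replicates consecutive.  Returns ``-inf`` if the covariance is
    numerically singular.
    """
    y = np.asarray(y, dtype=float)
    idx = _expand_to_individuals(tree, sample_map)
    if y.shape != idx.shape:
        raise ValueError("y length must equal total replicate count")
    mu = ou_mean_vector(tree, painting, params)[idx]
    C = ou_covariance(tree, params, sample_map)
    n = len(y)
    try:
        cho = cho_factor(C, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    r = y - mu
    quad = float(r @ cho_solve(cho, r))
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)


# ---------------------------------------------------------------------------
# fitting


class _UnitModel:
    """Precomputed structures for one (tree, painting, sample_map) unit so
    repeated likelihood evaluations during optimization stay cheap."""

    def __init__(self, tree: PhyloTree, painting: np.ndarray, sample_map: dict[str, int]):
        self.tree = tree
        self.painting = _check_painting(tree, painting)
        self.n_regimes = int(self.painting.max()) + 1
        self.idx = _expand_to_individuals(tree, sample_map)
        self.n = len(self.idx)
        D = tree.tip_distance_matrix()
        self.D_ind = D[np.ix_(self.idx, self.idx)]
        self.tipT = tree.depth[tree.tip_idx]
        # flatten root-to-tip segments for vectorized design evaluation
        seg_tip, seg_reg, seg_s0, seg_s1 = [], [], [], []
        for t, tip in enumerate(tree.tip_idx):
            for node, s0, s1 in tree.tip_path_segments(int(tip)):
                seg_tip.append(t)
                seg_reg.append(self.painting[node])
                seg_s0.append(s0)
                seg_s1.append(s1)
        self.seg_tip = np.asarray(seg_tip)
        self.seg_reg = np.asarray(seg_reg)
        self.seg_s0 = np.asarray(seg_s0)
        self.seg_s1 = np.asarray(seg_s1)
        self.root_regime = int(self.painting[0])
        self.root_depth = tree.root_depth()

    def design(self, alpha: float) -> np.ndarray:
        """Tip-level regime weight matrix A(alpha); rows sum to 1."""
        A = np.zeros((self.tree.n_tips, self.n_regimes))
        A[:, self.root_regime] += np.exp(-alpha * self.tipT)
        T = self.tipT[self.seg_tip]
        w = np.exp(-alpha * (T - self.seg_s1)) - np.exp(-alpha * (T - self.seg_s0))
        np.add.at(A, (self.seg_tip, self.seg_reg), w)
        return A

    def profile_nll(self, x: np.ndarray):
        """Negative log-likelihood profiled over thetas and sigma2.

        ``x = (log alpha, log beta)``.  Returns (nll, thetas, v_hat).
        """
        alpha, beta = np.exp(x)
        R = np.exp(-alpha * self.D_ind)
        R[np.diag_indices_from(R)] += beta
        A = self.design(alpha)[self.idx]
        try:
            cho = cho_factor(R, lower=True)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        Ri_A = cho_solve(cho, A)
        Ri_y = cho_solve(cho, self._y)
        G = A.T @ Ri_A
        try:
            thetas = np.linalg.solve(G, A.T @ Ri_y)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        r = self._y - A @ thetas
        quad = float(r @ cho_solve(cho, r))
        v = max(quad / self.n, 1e-12)
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        nll = 0.5 * (self.n * np.log(2.0 * np.pi) + logdet + self.n * np.log(v) + self.n)
        return nll, thetas, v

    def fit(self, y: np.ndarray, seed: int = 0, n_restarts: int = 5) -> EVEFit:
        self._y = np.asarray(y, dtype=float)
        T = self.root_depth
        lo = np.log([1e-3 / T, 1e-4])
        hi = np.log([5e2 / T, 1e4])
        bounds = list(zip(lo, hi))

        # deterministic heuristic start: alpha = 1/root depth, beta from a
        # crude within/between variance decomposition
        within, between = _variance_components(self._y, self.idx)
        beta0 = np.clip(within / max(between, 1e-8), 1e-3, 1e3)
        starts = [np.log([1.0 / T, beta0]), np.log([4.0 / T, beta0]), np.log([0.25 / T, 1.0])]
        rng = np.random.default_rng(seed)
        while len(starts) < max(n_restarts, 1):
            starts.append(lo + (hi - lo) * rng.random(2))

        best = None
        used = 0
        for x0 in starts[: max(n_restarts, 1)]:
            used += 1
            res = minimize(
                lambda x: self.profile_nll(x)[0],
                np.clip(x0, lo, hi),
                method="L-BFGS-B",
                bounds=bounds,
            )
            if best is None or res.fun < best.fun:
                best = res
        nll, thetas, v = self.profile_nll(best.x)
        if not np.isfinite(nll) or thetas is None:
            return EVEFit(
                OUParams(thetas=(np.nan,) * self.n_regimes, alpha=1.0, sigma2=1.0, beta=1.0),
                logL=-np.inf, converged=False, n_restarts_used=used,
            )
        alpha, beta = np.exp(best.x)
        params = OUParams(
            thetas=tuple(float(t) for t in thetas),
            alpha=float(alpha),
            sigma2=float(2.0 * alpha * v),
            beta=float(beta),
        )
        return EVEFit(params=params, logL=float(-nll), converged=True, n_restarts_used=used)


def _variance_components(y: np.ndarray, idx: np.ndarray) -> tuple[float, float]:
    """One-way within/between variance decomposition over species groups."""
    means, within = [], []
    for t in np.unique(idx):
        g = y[idx == t]
        means.append(g.mean())
        if len(g) > 1:
            within.append(g.var(ddof=1))
    w = float(np.mean(within)) if within else 0.1
    b = float(np.var(means, ddof=1)) if len(means) > 1 else 1.0
    return w, b


def fit_single_theta(
    y: np.ndarray, tree: PhyloTree, sample_map: dict[str, int],
    seed: int = 0, n_restarts: int = 5,
) -> EVEFit:
    """Fit the single-optimum null model by maximum likelihood."""
    painting = np.zeros(tree.n_nodes, dtype=np.int64)
    return _UnitModel(tree, painting, sample_map).fit(y, seed=seed, n_restarts=n_restarts)


def fit_two_theta(
    y: np.ndarray, tree: PhyloTree, painting: np.ndarray,
    sample_map: dict[str, int], seed: int = 0, n_restarts: int = 5,
) -> EVEFit:
    """Fit the two-optima model (base + shifted regime)."""
    painting = _check_painting(tree, painting)
    if set(np.unique(painting)) != {0, 1}:
        raise ValueError("painting must have exactly regimes {0, 1}")
    return _UnitModel(tree, painting, sample_map).fit(y, seed=seed, n_restarts=n_restarts)


def two_theta_test(
    y: np.ndarray, tree: PhyloTree, painting: np.ndarray,
    sample_map: dict[str, int], seed: int = 0, n_restarts: int = 5,
    chi2_quantile: float = 0.95,
) -> ShiftCall:
    """Likelihood-ratio test of the two-optima model against the
    single-optimum null.

    LRT = 2 (logL_alt - logL_null), clamped at 0; p from the upper tail
    of chi-squared with 1 df; significant above its 95% quantile.  The
    direction is the sign of ``theta_shift - theta_base``, reported only
    for significant calls.
    """
    null = fit_single_theta(y, tree, sample_map, seed=seed, n_restarts=n_restarts)
    alt = fit_two_theta(y, tree, painting, sample_map, seed=seed, n_restarts=n_restarts)
    if not (null.converged and alt.converged):
        return ShiftCall.untested("fit_not_converged")
    lrt = max(0.0, 2.0 * (alt.logL - null.logL))
    p = float(chi2.sf(lrt, df=1))
    significant = lrt > float(chi2.ppf(chi2_quantile, df=1))
    d = alt.params.thetas[1] - alt.params.thetas[0]
    direction = "none"
    if significant and d != 0.0:
        direction = "up" if d > 0 else "down"
    return ShiftCall(
        lrt=float(lrt), p=p, significant=bool(significant), direction=direction,
        theta_base=float(alt.params.thetas[0]), theta_shift=float(alt.params.thetas[1]),
        alpha=alt.params.alpha, sigma2=alt.params.sigma2, beta=alt.params.beta,
    )


def run_orthogroup(unit, panel, species_tree: PhyloTree, roles, seed: int = 0,
                   n_restarts: int = 5, chi2_quantile: float = 0.95) -> ShiftCall:
    """Run the shift test for one test unit (one duplicate clade plus the
    outgroup genes).

    Prunes the species tree to the species with data in the unit, paints
    the ingroup stem branch and its descendants as the shifted regime,
    and tests.  Units with fewer than 3 species (or no ingroup species)
    are returned untested with a reason.
    """
    species_with_data = sorted(set(unit.genes.values()))
    if len(species_with_data) < 3:
        return ShiftCall.untested("too_few_species")
    pruned = species_tree.prune_to(set(species_with_data))
    ingroup_sp = sorted({sp for g, sp in unit.genes.items() if roles.role(sp) == "ingroup"})
    if not ingroup_sp:
        return ShiftCall.untested("no_ingroup_species")
    painting = paint_ingroup_clade(pruned, ingroup_sp)
    gene_of = {sp: g for g, sp in unit.genes.items()}
    y, sample_map = [], {}
    for sp in pruned.tip_labels:
        vals = panel.species_values(gene_of[sp], sp)
        sample_map[sp] = len(vals)
        y.extend(vals)
    return two_theta_test(np.asarray(y), pruned, painting, sample_map,
                          seed=seed, n_restarts=n_restarts, chi2_quantile=chi2_quantile)
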