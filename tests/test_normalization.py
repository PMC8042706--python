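"""Two-stage TMM normalization and the log transform."""

import math
import subprocess

import numpy as np
import pandas as pd
import pytest

from ohnoshift.normalization import (
    ExpressionPanel,
    TMMParams,
    log_transform,
    normalize_between_species,
    normalize_within_species,
    tmm_factor,
)


def tmm_reference(test, ref, logratio_trim=0.30, abs_expr_trim=0.05):
    """Independently coded textbook TMM (sorting-based trimming via
    pandas ranks, loop-based weighting) used as the oracle."""
    t = pd.Series(test, dtype=float)
    r = pd.Series(ref, dtype=float)
    Nt, Nr = t.sum(), r.sum()
    keep = (t > 0) & (r > 0)
    t, r = t[keep], r[keep]
    M = np.log2(t / r)
    A = 0.5 * np.log2(t * r)
    w = []
    for tv, rv in zip(t, r):
        w.append(1.0 / ((Nt - tv) / (Nt * tv) + (Nr - rv) / (Nr * rv)))
    w = pd.Series(w, index=M.index)
    n = len(M)
    loL = math.floor(n * logratio_trim) + 1
    loS = math.floor(n * abs_expr_trim) + 1
    rM, rA = M.rank(), A.rank()
    sel = (rM >= loL) & (rM <= n + 1 - loL) & (rA >= loS) & (rA <= n + 1 - loS)
    return 2.0 ** (float((w[sel] * M[sel]).sum() / w[sel].sum()))


def random_tpm(rng, n=500, de_frac=0.1, de_fold=4.0):
    # continuous TPM-like values; ties would make rank trimming
    # boundary-sensitive to floating-point noise between implementations
    base = rng.lognormal(4, 1.5, n)
    a = base * rng.lognormal(0, 0.15, n)
    b = base * rng.lognormal(0, 0.15, n)
    de = rng.choice(n, int(n * de_frac), replace=False)
    a[de] *= de_fold  # asymmetric differential expression
    return a, b


class TestTMMFactor:
    def test_identical_columns_give_one(self):
        x = np.array([5.0, 80.0, 3.0, 40.0, 7.0, 12.0, 1.0, 9.0, 25.0, 60.0, 33.0])
        assert tmm_factor(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_doubled_column_gives_two(self):
        x = np.array([5.0, 80.0, 3.0, 40.0, 7.0, 12.0, 1.0, 9.0, 25.0, 60.0, 33.0])
        assert tmm_factor(2 * x, x) == pytest.approx(2.0, rel=1e-9)

    def test_matches_independent_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            a, b = random_tpm(rng)
            assert tmm_factor(a, b) == pytest.approx(tmm_reference(a, b), abs=1e-6)

    def test_matches_edger(self, tmp_path):
        """Cross-check against edgeR's calcNormFactors on equal-sum
        (TPM-like) columns, where the library-size scaling cancels."""
        rng = np.random.default_rng(3)
        a, b = random_tpm(rng)
        tpm = np.column_stack([a, b])
        tpm = tpm / tpm.sum(0) * 1e6
        path = tmp_path / "m.tsv"
        pd.DataFrame(tpm, columns=["s1", "s2"]).to_csv(path, sep="\t", index=False)
        res = subprocess.run(
            ["Rscript", "-e",
             f'suppressMessages(library(edgeR));'
             f'm <- as.matrix(read.delim("{path}"));'
             f'f <- calcNormFactors(m, method="TMM", refColumn=2);'
             f'cat(sprintf("%.12f", f[1]/f[2]))'],
            capture_output=True, text=True, timeout=120)
        if res.returncode != 0:
            pytest.skip(f"edgeR unavailable: {res.stderr[-200:]}")
        assert tmm_factor(tpm[:, 0], tpm[:, 1]) == pytest.approx(
            float(res.stdout.strip()), abs=1e-6)

    def test_few_genes_falls_back_untrimmed(self):
        a = np.array([4.0, 9.0, 2.0])
        b = np.array([2.0, 3.0, 8.0])
        with pytest.warns(UserWarning, match="untrimmed"):
            f = tmm_factor(a, b)
        assert f > 0

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError):
            tmm_factor(np.zeros(5), np.ones(5))


def make_panel(rng, n_genes=300, species=("X", "Y"), reps=3, state="raw"):
    base = rng.lognormal(4, 1, n_genes)
    cols, smap = {}, {}
    for sp in species:
        for r in range(1, reps + 1):
            cols[f"{sp}_r{r}"] = rng.poisson(base).astype(float)
            smap[f"{sp}_r{r}"] = sp
    genes = [f"g{i}" for i in range(n_genes)]
    return ExpressionPanel(pd.DataFrame(cols, index=genes), pd.Series(smap), state=state)


class TestWithinSpecies:
    def test_identical_replicates_unchanged(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(4, 1, 200)
        vals = pd.DataFrame({f"X_r{r}": base for r in (1, 2, 3)},
                            index=[f"g{i}" for i in range(200)])
        panel = ExpressionPanel(vals, pd.Series({f"X_r{r}": "X" for r in (1, 2, 3)}))
        out = normalize_within_species(panel)
        assert np.allclose(out.values.to_numpy(), vals.to_numpy(), rtol=1e-12)

    def test_scaled_replicate_cv_reduced(self):
        rng = np.random.default_rng(2)
        panel = make_panel(rng)
        scaled = panel.values.copy()
        scaled["X_r1"] = scaled["X_r1"] * 3.0
        panel = ExpressionPanel(scaled, panel.sample_species)
        out = normalize_within_species(panel)
        xcols = ["X_r1", "X_r2", "X_r3"]
        cv = lambda df: (df[xcols].std(axis=1) / df[xcols].mean(axis=1)).median()
        assert cv(out.values) < cv(panel.values)

    def test_factors_geometric_mean_one_per_species(self):
        rng = np.random.default_rng(3)
        out = normalize_within_species(make_panel(rng))
        fac = pd.DataFrame(out.factors)
        for _, sub in fac.groupby("species"):
            assert np.exp(np.log(sub["factor"]).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_single_replicate_species_gets_factor_one(self):
        vals = pd.DataFrame({"X_r1": [1.0, 5.0], "Y_r1": [2.0, 3.0], "Y_r2": [2.0, 3.1]},
                            index=["g0", "g1"])
        panel = ExpressionPanel(vals, pd.Series({"X_r1": "X", "Y_r1": "Y", "Y_r2": "Y"}))
        out = normalize_within_species(panel)
        fac = pd.DataFrame(out.factors)
        assert fac.loc[fac["sample"] == "X_r1", "factor"].iloc[0] == 1.0


def singleton_table(n, species=("X", "Y")):
    rows = []
    for i in range(n):
        for sp in species:
            rows.append({"orthogroup": f"og{i}", "species": sp, "gene": f"g{i}_{sp}"})
    return pd.DataFrame(rows)


def species_panel(rng, n=300, scale={"X": 1.0, "Y": 1.0}, reps=3, state="within-normalized"):
    """Panel where gene g{i}_{sp} belongs to species sp (NaN elsewhere)."""
    base = rng.lognormal(4, 1, n)
    genes = [f"g{i}_{sp}" for i in range(n) for sp in scale]
    cols = {f"{sp}_r{r}": pd.Series(np.nan, index=genes)
            for sp in scale for r in range(1, reps + 1)}
    smap = {f"{sp}_r{r}": sp for sp in scale for r in range(1, reps + 1)}
    for i in range(n):
        for sp in scale:
            for r in range(1, reps + 1):
                cols[f"{sp}_r{r}"][f"g{i}_{sp}"] = rng.poisson(base[i]) * scale[sp]
    return ExpressionPanel(pd.DataFrame(cols), pd.Series(smap), state=state)


class TestBetweenSpecies:
    def test_identical_profiles_factors_one(self):
        rng = np.random.default_rng(4)
        n = 200
        base = rng.lognormal(4, 1, n)
        genes = [f"g{i}_{sp}" for i in range(n) for sp in ("X", "Y")]
        cols = {}
        smap = {}
        for sp in ("X", "Y"):
            for r in (1, 2):
                col = pd.Series(np.nan, index=genes)
                for i in range(n):
                    col[f"g{i}_{sp}"] = base[i]
                cols[f"{sp}_r{r}"] = col
                smap[f"{sp}_r{r}"] = sp
        panel = ExpressionPanel(pd.DataFrame(cols), pd.Series(smap),
                                state="within-normalized")
        out = normalize_between_species(panel, singleton_table(n))
        fac = pd.DataFrame(out.factors)
        assert np.allclose(fac["factor"], 1.0, atol=1e-9)

    def test_global_scaling_removed(self):
        rng = np.random.default_rng(5)
        panel = species_panel(rng, scale={"X": 1.0, "Y": 4.0})
        out = normalize_between_species(panel, singleton_table(300))
        fac = pd.DataFrame(out.factors).set_index("sample")["factor"]
        ratio = fac["Y_r1"] / fac["X_r1"]
        assert ratio == pytest.approx(4.0, rel=0.05)
        # the x4 scale is gone from the singleton means
        xm = out.values.loc["g0_X", ["X_r1", "X_r2", "X_r3"]].mean()
        ym = out.values.loc["g0_Y", ["Y_r1", "Y_r2", "Y_r3"]].mean()
        assert ym / xm == pytest.approx(1.0, rel=0.3)

    def test_scale_equivariance_up_to_global_constant(self):
        """Multiplying every sample of one species by c leaves the
        between-normalized panel unchanged up to one global scalar (the
        geometric-mean centering of the factors spreads c^(1/S) over all
        species; a shared scalar cancels in every downstream contrast)."""
        rng = np.random.default_rng(6)
        panel = species_panel(rng)
        out1 = normalize_between_species(panel, singleton_table(300))
        scaled = panel.values.copy()
        for c in ["Y_r1", "Y_r2", "Y_r3"]:
            scaled[c] = scaled[c] * 7.0
        panel2 = ExpressionPanel(scaled, panel.sample_species, state="within-normalized")
        out2 = normalize_between_species(panel2, singleton_table(300))
        a, b = out1.values.to_numpy(), out2.values.to_numpy()
        mask = ~np.isnan(a) & (a > 0)
        ratio = b[mask] / a[mask]
        assert np.nanmax(np.abs(ratio / np.median(ratio) - 1)) < 1e-9

    def test_empty_singleton_set_refused(self):
        rng = np.random.default_rng(7)
        panel = species_panel(rng, n=20)
        with pytest.raises(ValueError):
            normalize_between_species(panel, pd.DataFrame(columns=["orthogroup", "species", "gene"]))


class TestLogTransformAndStates:
    def test_log_transform_values(self):
        vals = pd.DataFrame({"X_r1": [0.0, 0.99, 7.99]}, index=["a", "b", "c"])
        panel = ExpressionPanel(vals, pd.Series({"X_r1": "X"}), state="between-normalized")
        out = log_transform(panel)
        assert out.values.loc["a", "X_r1"] == pytest.approx(np.log2(0.01), abs=1e-4)
        assert out.values.loc["b", "X_r1"] == pytest.approx(0.0, abs=1e-12)
        assert out.values.loc["c", "X_r1"] == pytest.approx(3.0, abs=1e-12)
        assert out.values.loc["a", "X_r1"] == pytest.approx(-6.6439, abs=1e-4)

    def test_state_machine_refuses_wrong_order(self):
        rng = np.random.default_rng(8)
        panel = make_panel(rng, n_genes=50)
        with pytest.raises(ValueError):
            log_transform(panel)  # raw -> logged is not allowed
        out = normalize_within_species(panel)
        with pytest.raises(ValueError):
            normalize_within_species(out)  # idempotence guard

    def test_rank_order_preserved_through_stages(self):
        rng = np.random.default_rng(9)
        panel = species_panel(rng, n=100, state="raw")
        within = normalize_within_species(panel)
        between = normalize_between_species(within, singleton_table(100))
        logged = log_transform(between)
        col = "X_r1"
        raw_rank = panel.values[col].dropna().rank()
        for stage in (within, between, logged):
            assert (stage.values[col].dropna().rank() == raw_rank).all()

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            ExpressionPanel(pd.DataFrame({"X_r1": [-1.0]}, index=["g"]),
                            pd.Series({"X_r1": "X"}))
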