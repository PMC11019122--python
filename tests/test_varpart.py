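import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from islandbeta.beta import beta_taxonomic
from islandbeta.core_io import CommunityMatrix, DomainError
from islandbeta.mem import build_graph, mem_eigenvectors
from islandbeta.ordination import adjusted_r2, drop_constant_columns, pcoa_axes
from islandbeta.synthetic import ScenarioConfig, generate
from islandbeta.varpart import (
    FRACTION_KEYS,
    dbrda,
    fractions_from_r2,
    permutation_test,
    run_table1,
    varpart3,
)

from conftest import make_sites, random_community


def distance_from_coords(Y):
    """Squared Euclidean distances; PCoA with the sqrt transform then
    recovers the centered coordinates exactly."""
    Y = np.atleast_2d(np.asarray(Y, float))
    if Y.shape[0] == 1:
        Y = Y.T
    G = Y @ Y.T
    d = np.diag(G)
    return d[:, None] + d[None, :] - 2 * G


def frame(X, prefix):
    X = np.atleast_2d(X)
    if X.shape[0] < X.shape[1]:
        X = X.T
    return pd.DataFrame(X, columns=[f"{prefix}{i}" for i in range(X.shape[1])])


class TestDbrda:
    def test_adjustment_formula(self):
        assert adjusted_r2(0.5, 10, 2) == pytest.approx(1 - 0.5 * 9 / 7)

    def test_perfect_fit(self, rng):
        X = rng.normal(size=(12, 2))
        D = distance_from_coords(X)
        model = dbrda(D, frame(X, "x"))
        assert model.r2 == pytest.approx(1.0, abs=1e-9)
        assert model.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_column_rejected(self, rng):
        D = distance_from_coords(rng.normal(size=(10, 2)))
        with pytest.raises(DomainError, match="collinear|constant"):
            dbrda(D, pd.DataFrame({"c": np.ones(10)}))

    def test_collinear_columns_named(self, rng):
        x = rng.normal(size=10)
        D = distance_from_coords(rng.normal(size=(10, 2)))
        with pytest.raises(DomainError, match="dup"):
            dbrda(D, pd.DataFrame({"a": x, "dup": 2 * x}))

    def test_too_many_predictors_rejected(self, rng):
        D = distance_from_coords(rng.normal(size=(5, 2)))
        with pytest.raises(DomainError):
            dbrda(D, frame(rng.normal(size=(5, 4)), "x"))

    def test_r2_matches_least_squares_oracle(self, rng):
        # brute-force multivariate regression on the exact coordinates
        n = 14
        Y = rng.normal(size=(n, 3))
        X = rng.normal(size=(n, 2))
        D = distance_from_coords(Y)
        model = dbrda(D, frame(X, "x"))
        Yc = Y - Y.mean(axis=0)
        Xc = np.column_stack([np.ones(n), X])
        beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        fitted = Xc @ beta
        oracle = np.sum(fitted**2) / np.sum(Yc**2)
        assert model.r2 == pytest.approx(oracle, abs=1e-9)


class TestFractions:
    def test_worked_inclusion_exclusion(self):
        fr, resid, totals = fractions_from_r2(
            {"S": 0.4, "E": 0.3, "H": 0.2, "SE": 0.55, "SH": 0.45, "EH": 0.35, "SEH": 0.6}
        )
        assert fr["S|(E∩H)"] == pytest.approx(0.25)
        assert fr["E|(S∩H)"] == pytest.approx(0.15)
        assert fr["H|(S∩E)"] == pytest.approx(0.05)
        assert fr["S∩E|H"] == pytest.approx(0.0)
        assert fr["S∩H|E"] == pytest.approx(0.0)
        assert fr["E∩H|S"] == pytest.approx(0.0)
        assert fr["E∩S∩H"] == pytest.approx(0.15)
        assert resid == pytest.approx(0.4)
        assert totals == {"Total S": 0.4, "Total E": 0.3, "Total H": 0.2}

    def test_closure_on_random_data(self, rng):
        for _ in range(5):
            n = 30
            D = distance_from_coords(rng.normal(size=(n, 4)))
            res = varpart3(
                D,
                frame(rng.normal(size=(n, 3)), "s"),
                frame(rng.normal(size=(n, 2)), "e"),
                frame(rng.normal(size=(n, 2)), "h"),
            )
            assert sum(res.fractions.values()) == pytest.approx(
                1.0 - res.residual, abs=1e-9
            )

    def test_duplicated_sets_share_everything(self, rng):
        n = 40
        X = rng.normal(size=(n, 2))
        Y = X @ rng.normal(size=(2, 2)) + 0.1 * rng.normal(size=(n, 2))
        D = distance_from_coords(Y)
        XS = frame(X, "s")
        XE = frame(X + 1e-9 * rng.normal(size=X.shape), "e")  # near-duplicate
        XH = frame(rng.normal(size=(n, 2)), "h")
        res = varpart3(D, XS, XE, XH)
        assert abs(res.fractions["S|(E∩H)"]) < 0.01
        assert abs(res.fractions["E|(S∩H)"]) < 0.01
        assert res.fractions["S∩E|H"] + res.fractions["E∩S∩H"] == pytest.approx(
            res.totals["Total S"], abs=0.02
        )

    def test_orthogonal_history_gets_nothing(self, rng):
        n = 40
        XS = rng.normal(size=(n, 2))
        XE = rng.normal(size=(n, 2))
        Y = XS @ rng.normal(size=(2, 2)) + XE @ rng.normal(size=(2, 2))
        # build H orthogonal to Y, XS and XE
        B = np.column_stack([np.ones(n), Y, XS, XE])
        Q, _ = np.linalg.qr(B)
        raw = rng.normal(size=(n, 2))
        XH = raw - Q @ (Q.T @ raw)
        res = varpart3(distance_from_coords(Y), frame(XS, "s"), frame(XE, "e"), frame(XH, "h"))
        for key in ("H|(S∩E)", "S∩H|E", "E∩H|S", "E∩S∩H"):
            assert abs(res.fractions[key]) < 0.05


class TestPermutation:
    def setup_blocks(self, rng, n=30):
        XS = frame(rng.normal(size=(n, 2)), "s")
        XE = frame(rng.normal(size=(n, 2)), "e")
        XH = frame(rng.normal(size=(n, 2)), "h")
        return XS, XE, XH

    def test_floor_p_value_under_strong_signal(self, rng):
        n = 30
        XS, XE, XH = self.setup_blocks(rng, n)
        Y = XS.to_numpy() @ rng.normal(size=(2, 2))
        res = permutation_test(distance_from_coords(Y), XS, XE, XH, nperm=999, seed=0)
        assert res.p_values["Total S"] == pytest.approx(1 / 1000)

    def test_deterministic_given_seed(self, rng):
        n = 25
        XS, XE, XH = self.setup_blocks(rng, n)
        D = distance_from_coords(rng.normal(size=(n, 3)))
        a = permutation_test(D, XS, XE, XH, nperm=99, seed=7)
        b = permutation_test(D, XS, XE, XH, nperm=99, seed=7)
        assert a.p_values == b.p_values

    def test_invalid_nperm(self, rng):
        XS, XE, XH = self.setup_blocks(rng)
        D = distance_from_coords(rng.normal(size=(30, 2)))
        with pytest.raises(DomainError):
            permutation_test(D, XS, XE, XH, nperm=0)

    def test_joint_permutation_equals_community_recomputation(self, rng):
        """Permuting community rows then recomputing beta gives exactly the
        jointly permuted dissimilarity matrix, so the two permutation
        routes yield identical fractions."""
        cm = random_community(rng, n_sites=15, n_species=10)
        perm = rng.permutation(15)
        D = beta_taxonomic(cm).total.to_numpy()
        occ_perm = cm.occurrence.iloc[perm].set_axis(cm.occurrence.index)
        D_rebuilt = beta_taxonomic(CommunityMatrix(occ_perm)).total.to_numpy()
        assert np.allclose(D[np.ix_(perm, perm)], D_rebuilt, atol=1e-12)
        XS = frame(rng.normal(size=(15, 2)), "s")
        XE = frame(rng.normal(size=(15, 2)), "e")
        XH = frame(rng.normal(size=(15, 2)), "h")
        a = varpart3(D[np.ix_(perm, perm)], XS, XE, XH)
        b = varpart3(D_rebuilt, XS, XE, XH)
        for k in FRACTION_KEYS:
            assert a.fractions[k] == pytest.approx(b.fractions[k], abs=1e-9)

    def test_relabeling_invariance(self, rng):
        n = 20
        XS, XE, XH = self.setup_blocks(rng, n)
        D = distance_from_coords(rng.normal(size=(n, 3)))
        perm = rng.permutation(n)
        a = varpart3(D, XS, XE, XH)
        b = varpart3(
            D[np.ix_(perm, perm)],
            XS.iloc[perm].reset_index(drop=True),
            XE.iloc[perm].reset_index(drop=True),
            XH.iloc[perm].reset_index(drop=True),
        )
        for k in FRACTION_KEYS:
            assert a.fractions[k] == pytest.approx(b.fractions[k], abs=1e-9)

    def test_null_p_values_super_uniform(self, rng):
        """Under a response independent of all predictors the permutation
        p-values must not be anti-conservative (Kolmogorov-Smirnov against
        the uniform, one-sided, alpha = 0.01)."""
        n = 30
        XS, XE, XH = self.setup_blocks(rng, n)
        pvals = []
        for r in range(200):
            D = distance_from_coords(np.random.default_rng(50_000 + r).normal(size=(n, 3)))
            res = permutation_test(D, XS, XE, XH, nperm=99, seed=60_000 + r)
            pvals.append(res.p_values["Total E"])
        assert kstest(pvals, "uniform", alternative="greater").pvalue > 0.01


def test_run_table1_shape_contract():
    data = generate(ScenarioConfig(scenario="MIXED", seed=0))
    table, log = run_table1(
        data.community,
        data.sites,
        data.traits,
        data.factors,
        nperm=19,
        swm_nperm=49,
        seed=0,
    )
    # 2 scales x 6 responses x (7 fractions + 3 totals + residual)
    assert len(table) == 2 * 6 * 11
    assert np.isfinite(table["adj_r2"]).all()
    fractions = table[~table["fraction"].isin(["Residuals"])]
    assert np.isfinite(fractions["p"]).all()
    assert set(log) == {"entire", "main_islands"}
    # the Tokara indicator is constant at the main-islands scale
    assert "tokara" in log["main_islands"]["dropped_hist"]
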