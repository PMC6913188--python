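"""Incidence building, kernel expansion, likelihood fitting and BLUP prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from deepkern import (
    KernelMixedModel,
    KernelMixedModelResults,
    PhenotypeTable,
    build_incidence,
    expand_main_kernel,
    fit_multi_kernel,
    fit_single_kernel,
    gxe_kernel,
    heritability,
    predict_cells,
)


def make_pheno(lines, envs, values=None, rng=None):
    rows = [(l, e) for e in envs for l in lines]
    if values is None:
        values = rng.normal(size=len(rows))
    df = pd.DataFrame(rows, columns=["line", "env"])
    df["value"] = np.asarray(values, dtype=float)
    return PhenotypeTable(records=df, envs=list(envs))


def random_psd(rng, n, rank=None):
    A = rng.normal(size=(n, rank or n))
    return A @ A.T / (rank or n)


class TestIncidence:
    def test_complete_two_by_two(self, rng):
        pheno = make_pheno(["A", "B"], ["E1", "E2"], rng=rng)
        inc = build_incidence(pheno, ["A", "B"], ["E1", "E2"])
        assert inc.Zg.shape == (4, 2)
        np.testing.assert_array_equal(inc.Zg.sum(axis=0), [2, 2])
        np.testing.assert_array_equal(inc.Zg.sum(axis=1), np.ones(4))
        np.testing.assert_array_equal(inc.ZE.sum(axis=1), np.ones(4))

    def test_single_environment_column_of_ones(self, rng):
        pheno = make_pheno(["A", "B", "C"], ["E1"], rng=rng)
        inc = build_incidence(pheno, ["A", "B", "C"], ["E1"])
        np.testing.assert_array_equal(inc.ZE, np.ones((3, 1)))

    def test_unknown_line_rejected(self, rng):
        pheno = make_pheno(["A", "B"], ["E1"], rng=rng)
        with pytest.raises(ValueError, match="unknown line"):
            build_incidence(pheno, ["A"], ["E1"])


class TestKernelExpansion:
    def test_identity_ordering_recovers_g(self, rng):
        G = random_psd(rng, 3)
        pheno = make_pheno(["A", "B", "C"], ["E1"], rng=rng)
        inc = build_incidence(pheno, ["A", "B", "C"], ["E1"])
        np.testing.assert_allclose(expand_main_kernel(G, inc), G)

    def test_repeated_line_block(self, rng):
        G = random_psd(rng, 2)
        df = pd.DataFrame({"line": ["A", "A", "B"], "env": ["E1", "E2", "E1"],
                           "value": [0.0, 1.0, 2.0]})
        inc = build_incidence(PhenotypeTable(records=df, envs=["E1", "E2"]), ["A", "B"], ["E1", "E2"])
        K1 = expand_main_kernel(G, inc)
        assert K1[0, 1] == G[0, 0]  # two observations of line A

    def test_matches_index_lookup_oracle(self, rng):
        G = random_psd(rng, 4)
        lines = ["L0", "L1", "L2", "L3"]
        df = pd.DataFrame({"line": ["L2", "L0", "L2", "L3", "L1", "L0"],
                           "env": ["E1", "E1", "E2", "E2", "E1", "E2"],
                           "value": np.zeros(6)})
        inc = build_incidence(PhenotypeTable(records=df, envs=["E1", "E2"]), lines, ["E1", "E2"])
        K1 = expand_main_kernel(G, inc)
        li = [2, 0, 2, 3, 1, 0]
        for a in range(6):
            for b in range(6):
                assert K1[a, b] == G[li[a], li[b]]

    def test_gxe_kernel_structure(self, rng):
        G = random_psd(rng, 3)
        pheno = make_pheno(["A", "B", "C"], ["E1", "E2"], rng=rng)
        inc = build_incidence(pheno, ["A", "B", "C"], ["E1", "E2"])
        K1 = expand_main_kernel(G, inc)
        K2 = gxe_kernel(K1, inc)
        ei = inc.env_index
        same = ei[:, None] == ei[None, :]
        np.testing.assert_array_equal(K2[~same], 0.0)
        np.testing.assert_allclose(K2[same], K1[same])
        w = np.linalg.eigvalsh(K2)
        assert w[0] >= -1e-8 * max(1.0, w[-1])

    def test_single_env_gxe_equals_main(self, rng):
        G = random_psd(rng, 4)
        pheno = make_pheno(list("ABCD"), ["E1"], rng=rng)
        inc = build_incidence(pheno, list("ABCD"), ["E1"])
        K1 = expand_main_kernel(G, inc)
        np.testing.assert_allclose(gxe_kernel(K1, inc), K1)


class TestSingleKernelFit:
    def test_constant_response_degenerates(self, rng):
        K = random_psd(rng, 10)
        res = fit_single_kernel(np.full(10, 3.7), K, compute_se=False)
        assert res.params[0] == pytest.approx(3.7, abs=1e-6)
        assert res.var_components["residual"] <= 1e-8
        assert res.var_components["genomic"] <= 1e-8

    def test_logml_matches_dense_density(self, rng):
        n = 8
        K = random_psd(rng, n)
        y = rng.normal(size=n)
        res = fit_single_kernel(y, K)
        vc = res.var_components
        V = vc["genomic"] * K + vc["residual"] * np.eye(n)
        dense = multivariate_normal(mean=np.full(n, float(res.params[0])), cov=V).logpdf(y)
        assert res.logml == pytest.approx(dense, abs=1e-6)

    def test_parameter_recovery_with_standard_errors(self, rng):
        # sigma_u^2 = 2, sigma_e^2 = 1; estimates should sit within 3 SE
        n, hits = 200, 0
        for _ in range(5):
            K = random_psd(rng, n, rank=400)
            d, U = np.linalg.eigh(K)
            u = U @ (np.sqrt(np.maximum(d, 0) * 2.0) * rng.normal(size=n))
            y = 1.0 + u + rng.normal(size=n)
            res = fit_single_kernel(y, K)
            assert res.var_se is not None
            if abs(res.var_components["genomic"] - 2.0) <= 3 * res.var_se["genomic"]:
                hits += 1
        assert hits >= 4

    def test_nonfinite_y_rejected(self, rng):
        K = random_psd(rng, 4)
        with pytest.raises(ValueError):
            fit_single_kernel(np.array([1.0, np.nan, 0.0, 2.0]), K)


class TestMultiKernelFit:
    def test_logml_matches_dense_density(self, rng):
        nl, m = 6, 2
        G = random_psd(rng, nl)
        li = np.tile(np.arange(nl), m)
        ei = np.repeat(np.arange(m), nl)
        K1 = G[np.ix_(li, li)]
        K2 = K1 * (ei[:, None] == ei[None, :])
        ZE = np.zeros((nl * m, m))
        ZE[np.arange(nl * m), ei] = 1.0
        y = rng.normal(size=nl * m)
        res = fit_multi_kernel(y, ZE, [K1, K2])
        vc = res.var_components
        V = vc["genomic"] * K1 + vc["gxe"] * K2 + vc["residual"] * np.eye(nl * m)
        dense = multivariate_normal(mean=ZE @ res.params, cov=V).logpdf(y)
        assert res.logml == pytest.approx(dense, abs=1e-6)

    def test_single_env_multi_nests_single(self, rng):
        n = 15
        K = random_psd(rng, n)
        y = rng.normal(size=n)
        res_single = fit_single_kernel(y, K)  # eigendecomposition path
        res_multi = KernelMixedModel(y, {"genomic": K}).fit(method="nm")  # gradient path
        assert res_multi.logml == pytest.approx(res_single.logml, abs=1e-6)

    def test_null_gxe_variance_stays_small(self, rng):
        nl, m, ok = 40, 3, 0
        for _ in range(10):
            G = random_psd(rng, nl, rank=80)
            li = np.tile(np.arange(nl), m)
            ei = np.repeat(np.arange(m), nl)
            K1 = G[np.ix_(li, li)]
            K2 = K1 * (ei[:, None] == ei[None, :])
            ZE = np.zeros((nl * m, m))
            ZE[np.arange(nl * m), ei] = 1.0
            d, U = np.linalg.eigh(G)
            u1 = U @ (np.sqrt(np.maximum(d, 0)) * rng.normal(size=nl))
            y = ZE @ np.array([1.0, 2.0, 0.5]) + u1[li] + rng.normal(size=nl * m) * 0.7
            res = fit_multi_kernel(y, ZE, [K1, K2], compute_se=False)
            share = res.var_components["gxe"] / sum(res.var_components.values())
            if share <= 0.05:
                ok += 1
        assert ok >= 8

    def test_nesting_monotonicity(self, rng):
        nl, m = 10, 2
        G = random_psd(rng, nl)
        li = np.tile(np.arange(nl), m)
        ei = np.repeat(np.arange(m), nl)
        K1 = G[np.ix_(li, li)]
        K2 = K1 * (ei[:, None] == ei[None, :])
        ZE = np.zeros((nl * m, m))
        ZE[np.arange(nl * m), ei] = 1.0
        y = rng.normal(size=nl * m)
        small = fit_multi_kernel(y, ZE, [K1], compute_se=False)
        big = fit_multi_kernel(y, ZE, [K1, K2], compute_se=False)
        assert big.logml >= small.logml - 1e-6

    def test_observation_reordering_invariance(self, rng):
        n = 18
        K = random_psd(rng, n)
        y = rng.normal(size=n)
        res = fit_single_kernel(y, K, compute_se=False)
        perm = rng.permutation(n)
        res_p = fit_single_kernel(y[perm], K[np.ix_(perm, perm)], compute_se=False)
        assert res_p.logml == pytest.approx(res.logml, abs=1e-8)
        np.testing.assert_allclose(res_p.blups["genomic"], res.blups["genomic"][perm], atol=1e-6)

    def test_singular_fixed_design_rejected(self, rng):
        K = random_psd(rng, 6)
        F = np.ones((6, 2))  # two identical columns
        with pytest.raises(ValueError, match="singular"):
            KernelMixedModel(rng.normal(size=6), {"genomic": K}, fixed=F)


class TestPrediction:
    def test_training_cells_interpolated_when_noiseless(self, rng):
        # additive noiseless signal with p < n_train: prediction is exact
        n, p = 40, 15
        X = rng.normal(size=(n, p))
        y = 2.0 + X @ rng.normal(size=p) * 0.3
        G = X @ X.T / p
        res = fit_single_kernel(y, G, compute_se=False)
        lines = [f"L{i}" for i in range(n)]
        cells = [(l, "E1") for l in lines]
        ps = predict_cells(res, G, lines, ["E1"], cells, y, cells[:5])
        np.testing.assert_allclose(ps.y_hat, y[:5], atol=1e-3)

    def test_matches_block_matrix_oracle(self, rng):
        # fixed variance components, hand-built conditional-Gaussian oracle
        n_all = 8
        G = random_psd(rng, n_all)
        lines = [f"L{i}" for i in range(n_all)]
        train = [(l, "E1") for l in lines[:6]]
        target = [(l, "E1") for l in lines[6:]]
        y_tr = rng.normal(size=6)
        s2g, s2e, mu = 1.3, 0.4, 0.8
        model = KernelMixedModel(y_tr, {"genomic": G[:6, :6]})
        res = KernelMixedModelResults(
            model=model, params=np.array([mu]),
            var_components={"genomic": s2g, "residual": s2e}, var_se=None,
            logml=0.0, blups={}, converged=True, n_iter=0,
        )
        ps = predict_cells(res, G, lines, ["E1"], train, y_tr, target)
        C_TT = s2g * G[:6, :6]
        C_UT = s2g * G[6:, :6]
        oracle = mu + C_UT @ np.linalg.solve(C_TT + s2e * np.eye(6), y_tr - mu)
        np.testing.assert_allclose(ps.y_hat, oracle, atol=1e-10)

    def test_predictions_track_genetic_values(self, rng):
        # h2 ~ 0.6: correlation with the true genetic value is clearly positive
        n, p = 80, 120
        cors = []
        for _ in range(5):
            X = rng.normal(size=(n, p))
            X = (X - X.mean(0)) / X.std(0)
            G = X @ X.T / p
            d, U = np.linalg.eigh(G)
            u = U @ (np.sqrt(np.maximum(d, 0) * 1.5) * rng.normal(size=n))
            y = u + rng.normal(size=n)
            res = fit_single_kernel(y[:60], G[:60, :60], compute_se=False)
            lines = [f"L{i}" for i in range(n)]
            ps = predict_cells(res, G, lines, ["E1"],
                               [(l, "E1") for l in lines[:60]], y[:60],
                               [(l, "E1") for l in lines[60:]])
            cors.append(np.corrcoef(ps.y_hat, u[60:])[0, 1])
        assert np.mean(cors) > 0.2

    def test_unknown_target_line_rejected(self, rng):
        G = random_psd(rng, 3)
        lines = ["A", "B", "C"]
        res = fit_single_kernel(rng.normal(size=3), G, compute_se=False)
        with pytest.raises(ValueError, match="absent"):
            predict_cells(res, G, lines, ["E1"], [(l, "E1") for l in lines],
                          np.zeros(3), [("Z", "E1")])


class TestCompleteTrialFastPath:
    def test_matches_dense_multi_kernel_fit(self, rng):
        from deepkern.mixed_model import fit_complete_gxe

        n, m = 25, 3
        G = random_psd(rng, n, rank=40)
        Y = rng.normal(size=(n, m)) + np.array([1.0, 3.0, 2.0])
        li = np.tile(np.arange(n), m)
        ei = np.repeat(np.arange(m), n)
        K1 = G[np.ix_(li, li)]
        K2 = K1 * (ei[:, None] == ei[None, :])
        ZE = np.zeros((n * m, m))
        ZE[np.arange(n * m), ei] = 1.0
        dense = fit_multi_kernel(Y.ravel(order="F"), ZE, [K1, K2], compute_se=False)
        fast = fit_complete_gxe(Y, G, compute_se=False)
        assert fast.logml == pytest.approx(dense.logml, abs=1e-6)
        for k in ("genomic", "gxe", "residual"):
            assert fast.var_components[k] == pytest.approx(dense.var_components[k], abs=1e-6)
        np.testing.assert_allclose(fast.params, dense.params, atol=1e-6)

    def test_diagonal_kernels_match_dense_diagonal(self, rng):
        n = 12
        dk = rng.uniform(0.2, 2.0, size=n)
        y = rng.normal(size=n)
        diag_fit = KernelMixedModel(y, {"genomic": dk}).fit(compute_se=False)
        dense_fit = KernelMixedModel(y, {"genomic": np.diag(dk)}).fit(
            method="nm", compute_se=False)
        assert diag_fit.logml == pytest.approx(dense_fit.logml, abs=1e-6)


class TestHeritability:
    def test_arithmetic(self, rng):
        K = random_psd(rng, 5)
        model = KernelMixedModel(rng.normal(size=5), {"genomic": K, "gxe": K})
        res = KernelMixedModelResults(
            model=model, params=np.zeros(1),
            var_components={"genomic": 1.0, "gxe": 0.0, "residual": 1.0},
            var_se=None, logml=0.0, blups={}, converged=True, n_iter=0,
        )
        assert heritability(res) == pytest.approx(0.5)

    def test_monotone_in_residual_variance(self, rng):
        K = random_psd(rng, 5)
        model = KernelMixedModel(rng.normal(size=5), {"genomic": K})
        h2 = []
        for s2e in (0.5, 1.0, 2.0):
            res = KernelMixedModelResults(
                model=model, params=np.zeros(1),
                var_components={"genomic": 1.0, "residual": s2e},
                var_se=None, logml=0.0, blups={}, converged=True, n_iter=0,
            )
            h2.append(res.heritability())
        assert h2[0] > h2[1] > h2[2]
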