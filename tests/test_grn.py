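import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diurnet import (SeriesMatrix, build_lagged_design, fit_group_scad,
                     generate_arx_tensor, infer_network_single, lambda_max,
                     scad_penalty, scad_threshold, select_lambda)


def random_series(n_genes, T, seed, sd=1.0):
    rng = np.random.default_rng(seed)
    return SeriesMatrix([f"g{i}" for i in range(n_genes)],
                        np.arange(T, dtype=float) * 4.0,
                        rng.normal(0, sd, size=(n_genes, T)))


def scad_objective(beta, z, lam, a):
    return 0.5 * (z - beta) ** 2 + scad_penalty(np.abs(beta), lam, a)


class TestLaggedDesign:
    def test_dimensions_order1(self):
        d = build_lagged_design(random_series(2, 4, 0), "g0", 1)
        assert d.y.shape == (3,)
        assert d.X.shape == (3, 2)
        assert d.n_groups == 2

    def test_dimensions_order2_groups(self):
        d = build_lagged_design(random_series(2, 4, 0), "g1", 2)
        assert d.y.shape == (2,)
        assert d.X.shape == (2, 4)
        assert d.group_cols(0) == slice(0, 2)
        assert d.group_cols(1) == slice(2, 4)

    def test_manual_lagging_two_genes(self):
        s = SeriesMatrix(["a", "b"], np.arange(5.0),
                         np.array([[1.0, 2.0, 3.0, 4.0, 5.0],
                                   [10.0, 20.0, 30.0, 40.0, 50.0]]))
        d = build_lagged_design(s, "a", 2)
        # rows correspond to times 3..5 (1-based); column g*p+(l-1) = lag l
        expected = np.array([[2.0, 1.0, 20.0, 10.0],
                             [3.0, 2.0, 30.0, 20.0],
                             [4.0, 3.0, 40.0, 30.0]])
        np.testing.assert_allclose(d.lagged, expected)
        np.testing.assert_allclose(d.y + d.y_mean, [3.0, 4.0, 5.0])

    def test_orthonormalization(self):
        d = build_lagged_design(random_series(3, 30, 1), "g0", 3)
        n = d.n_obs
        for g in range(d.n_groups):
            Xg = d.X[:, d.group_cols(g)]
            np.testing.assert_allclose(Xg.T @ Xg / n, np.eye(3), atol=1e-10)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            build_lagged_design(random_series(2, 2, 0), "g0", 2)

    def test_unknown_target(self):
        with pytest.raises(KeyError):
            build_lagged_design(random_series(2, 5, 0), "nope", 1)


class TestScadThreshold:
    @pytest.mark.parametrize("z,lam,a,expected", [
        (0.5, 1.0, 3.7, 0.0),                 # sub-threshold
        (1.5, 1.0, 3.7, 0.5),                 # soft-threshold region
        (3.0, 1.0, 3.7, (2.7 * 3 - 3.7) / 1.7),  # interpolating region
        (5.0, 1.0, 3.7, 5.0),                 # unbiasedness region
        (0.0, 0.0, 3.7, 0.0),
    ])
    def test_piecewise_values(self, z, lam, a, expected):
        assert scad_threshold(z, lam, a) == pytest.approx(expected, abs=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            scad_threshold(1.0, 1.0, a=2.0)
        with pytest.raises(ValueError):
            scad_threshold(-1.0, 1.0)
        with pytest.raises(ValueError):
            scad_threshold(1.0, -0.5)

    @given(st.floats(min_value=0.0, max_value=6.0),
           st.sampled_from([0.5, 1.0, 2.0]),
           st.sampled_from([2.5, 3.7, 5.0]))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_brute_force_objective(self, z, lam, a):
        # the thresholding operator is the argmin of ½(z−β)² + p_λ(|β|)
        grid = np.arange(0.0, 6.5, 1e-4)
        best = scad_objective(grid, z, lam, a).min()
        beta = scad_threshold(z, lam, a)
        assert scad_objective(np.array([beta]), z, lam, a)[0] <= best + 1e-8

    def test_continuity_at_breakpoints(self):
        for lam, a in [(0.5, 2.5), (1.0, 3.7), (2.0, 5.0)]:
            for brk in (lam, 2 * lam, a * lam):
                lo = scad_threshold(brk - 1e-9, lam, a)
                hi = scad_threshold(brk + 1e-9, lam, a)
                assert hi - lo == pytest.approx(0.0, abs=1e-6)


class TestFitGroupScad:
    def test_ols_limit(self):
        s = random_series(5, 202, 3)
        d = build_lagged_design(s, "g0", 2)          # n=200, 5 groups × 2
        fit = fit_group_scad(d, lam=0.0)
        Xs = (d.lagged - d.lagged.mean(0)) / d.lagged.std(0)
        ols, *_ = np.linalg.lstsq(Xs, d.y, rcond=None)
        np.testing.assert_allclose(fit.coefficients, ols, atol=1e-6)
        assert fit.converged

    def test_lambda_max_empty_model(self):
        for seed in range(10):
            d = build_lagged_design(random_series(6, 20, seed), "g0", 1)
            fit = fit_group_scad(d, lam=lambda_max(d) * 1.0001)
            assert fit.selected == []
            assert not fit.coefficients.any()

    def test_single_group_one_step_closed_form(self):
        s = random_series(1, 40, 4)
        d = build_lagged_design(s, "g0", 2)
        z = np.linalg.norm(d.X.T @ d.y) / d.n_obs
        for lam in (0.1 * z, 0.6 * z, 1.5 * z):
            fit = fit_group_scad(d, lam=lam)
            norm = np.linalg.norm(fit.beta_ortho)
            assert norm == pytest.approx(scad_threshold(z, lam), abs=1e-9)

    def test_group_lasso_limit_large_a(self):
        # as a → ∞ the SCAD group update approaches the group-lasso
        # soft-threshold on the single-group closed form
        s = random_series(1, 40, 5)
        d = build_lagged_design(s, "g0", 2)
        z = np.linalg.norm(d.X.T @ d.y) / d.n_obs
        lam = 0.7 * z
        fit = fit_group_scad(d, lam=lam, a=1e8)
        assert np.linalg.norm(fit.beta_ortho) == pytest.approx(z - lam, rel=1e-6)

    def test_objective_non_increasing(self):
        tensor, _ = generate_arx_tensor(8, 2, 3, order=1, innovation_sd=0.5,
                                        grid_or_length=40, seed=6)
        s = SeriesMatrix(tensor.genes, tensor.grid.hours, tensor.values[:, :, 0])
        d = build_lagged_design(s, s.genes[3], 1)
        fit = fit_group_scad(d, lam=0.3 * lambda_max(d), track_objective=True)
        assert fit.converged

    def test_nonconvergence_flag_not_exception(self):
        d = build_lagged_design(random_series(10, 30, 7), "g0", 1)
        fit = fit_group_scad(d, lam=1e-8, max_iter=1)
        assert isinstance(fit.converged, bool)


class TestSelectLambda:
    def test_path_empty_at_lambda_max(self):
        d = build_lagged_design(random_series(5, 30, 8), "g0", 1)
        lam, path = select_lambda(d)
        assert path["n_groups"].iloc[0] == 0

    def test_decreasing_grid_required(self):
        d = build_lagged_design(random_series(3, 20, 9), "g0", 1)
        with pytest.raises(ValueError):
            select_lambda(d, grid=np.array([0.1, 0.5]))
        with pytest.raises(ValueError):
            select_lambda(d, grid=np.array([]))

    def test_pure_noise_selects_nothing(self):
        hits = 0
        for seed in range(100):
            d = build_lagged_design(random_series(8, 101, 200 + seed), "g0", 1)
            lam, path = select_lambda(d)
            n_sel = int(path.loc[path["lam"] == lam, "n_groups"].iloc[0])
            hits += n_sel <= 1
        assert hits >= 90

    def test_strong_regressor_selected(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(500 + seed)
            T = 101
            x = rng.normal(size=(5, T))
            x[1, 1:] = 0.9 * x[0, :-1] + 0.3 * rng.normal(size=T - 1)
            s = SeriesMatrix([f"g{i}" for i in range(5)],
                             np.arange(T, dtype=float), x)
            d = build_lagged_design(s, "g1", 1)
            lam, _ = select_lambda(d)
            fit = fit_group_scad(d, lam=lam)
            hits += "g0" in fit.selected
        assert hits >= 95


class TestInferNetwork:
    def test_output_contract(self):
        net = infer_network_single(random_series(6, 30, 10), 1)
        assert net.matrix.shape == (6, 6)
        assert set(net.matrix.ravel()) <= {0, 1}
        assert all(s != t for s, t in net.edge_set())

    def test_null_edge_density(self):
        densities = []
        for seed in range(5):
            s = random_series(10, 101, 300 + seed)
            net = infer_network_single(s, 1)
            off = net.matrix.copy()
            np.fill_diagonal(off, 0)
            densities.append(off.sum() / (10 * 9))
        assert np.mean(densities) <= 0.05

    def test_directional_recovery_two_genes(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(700 + seed)
            T = 100
            x = np.zeros((2, T))
            x[0] = rng.normal(size=T)
            x[1, 1:] = 0.8 * x[0, :-1]
            x[1] += 0.3 * rng.normal(size=T)
            s = SeriesMatrix(["g0", "g1"], np.arange(T, dtype=float), x)
            net = infer_network_single(s, 1)
            hits += (net.matrix[0, 1] == 1) and (net.matrix[1, 0] == 0)
        assert hits >= 0.9 * n_seeds

    def test_permutation_equivariance(self):
        tensor, _ = generate_arx_tensor(8, 2, 2, order=1, innovation_sd=0.2,
                                        grid_or_length=60, seed=11)
        s = SeriesMatrix(tensor.genes, tensor.grid.hours, tensor.values[:, :, 0])
        net = infer_network_single(s, 1)
        perm = [3, 1, 4, 0, 7, 6, 2, 5]
        s2 = SeriesMatrix([s.genes[i] for i in perm], s.hours, s.values[perm])
        net2 = infer_network_single(s2, 1)
        assert net2.edge_set() == net.edge_set()

    def test_constant_gene_rejected(self):
        s = random_series(4, 20, 12)
        s.values[2] = 5.0
        with pytest.raises(ValueError, match="constant"):
            build_lagged_design(s, "g0", 1)
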