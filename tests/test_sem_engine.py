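import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from usem.data_model import RoiTimeSeries, center
from usem.sem_engine import (
    LaggedCovariance,
    ModelSpec,
    ParamMatrixSet,
    block_toeplitz_cov,
    fit_indices,
    fit_ml,
    implied_sigma,
    model_df,
    modification_indices,
    wald_prune,
)
from usem.synthesis import SimulationSpec, second_order_scenario, simulate_usem
from usem.usem_family import candidate_set


class TestBlockToeplitz:
    def test_order_zero_is_sample_covariance(self, white_series):
        cov = block_toeplitz_cov(white_series, 0)
        Y = white_series.values
        np.testing.assert_allclose(cov.S, Y @ Y.T / Y.shape[1], atol=1e-12)

    def test_equal_offset_blocks_identical(self, scen_series):
        cov = block_toeplitz_cov(scen_series, 2)
        p = 3
        np.testing.assert_array_equal(cov.S[0:p, p : 2 * p], cov.S[p : 2 * p, 2 * p : 3 * p])
        assert cov.n_eff == scen_series.T - 2

    def test_iid_lagged_blocks_near_zero(self):
        rng = np.random.default_rng(5)
        ts = center(RoiTimeSeries(rng.standard_normal((3, 10000)), ("a", "b", "c")))
        cov = block_toeplitz_cov(ts, 2)
        assert np.abs(cov.S[:3, 3:]).max() < 0.05  # 4 / sqrt(T) sampling bound

    def test_uncentered_series_rejected(self):
        ts = RoiTimeSeries(np.random.default_rng(0).standard_normal((2, 50)), ("a", "b"))
        with pytest.raises(ValueError, match="centered"):
            block_toeplitz_cov(ts, 1)

    def test_too_short_series_rejected(self, white_series):
        with pytest.raises(ValueError, match="too short"):
            block_toeplitz_cov(white_series, 101)


class TestImpliedSigma:
    def test_empty_model_gives_psi_and_zero_cross(self):
        spec = ModelSpec.null(2, 1)
        params = ParamMatrixSet(
            spec=spec, A=np.zeros((2, 2)), phi=np.zeros((1, 2, 2)), psi=np.array([1.5, 2.0])
        )
        Sigma = implied_sigma(spec, params, np.eye(2))
        np.testing.assert_allclose(Sigma[:2, :2], np.diag([1.5, 2.0]))
        np.testing.assert_allclose(Sigma[:2, 2:], 0.0)

    def test_ar1_stationary_variance_closed_form(self):
        # phi = 0.5, psi = 1, sigma_xx = 4/3: implied variance 0.25*4/3 + 1 = 4/3
        spec = ModelSpec.null(1, 1).with_freed(("Phi", 1, 0, 0))
        phi = np.zeros((1, 1, 1))
        phi[0, 0, 0] = 0.5
        params = ParamMatrixSet(spec=spec, A=np.zeros((1, 1)), phi=phi, psi=np.array([1.0]))
        Sigma = implied_sigma(spec, params, np.array([[4.0 / 3.0]]))
        assert Sigma[0, 0] == pytest.approx(4.0 / 3.0)
        assert Sigma[0, 1] == pytest.approx(0.5 * 4.0 / 3.0)

    def test_singular_i_minus_a_rejected(self):
        spec = ModelSpec.null(2, 0, f=None)
        spec = spec.with_freed(("A", 0, 1)).with_freed(("A", 1, 0))
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        params = ParamMatrixSet(spec=spec, A=A, phi=np.zeros((0, 2, 2)), psi=np.ones(2))
        with pytest.raises(ValueError, match="singular"):
            implied_sigma(spec, params, np.eye(0).reshape(0, 0))


class TestModelDf:
    @pytest.mark.parametrize(
        "p,a,k,expected",
        [(3, 1, 5, 7), (3, 2, 4, 17), (3, 2, 6, 15), (3, 2, 0, 21)],
    )
    def test_published_df_values(self, p, a, k, expected):
        assert model_df(p, a, k) == expected

    def test_overparameterized_rejected(self):
        with pytest.raises(ValueError, match="over-parameterized"):
            model_df(2, 1, 20)

    @given(st.integers(1, 4), st.integers(0, 3), st.integers(0, 4))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_df_equals_moments_minus_free_parameters(self, p, a, k):
        m = p * (a + 1)
        n_x = m - p
        expected = m * (m + 1) // 2 - (n_x * (n_x + 1) // 2 + p + k)
        if expected < 0:
            return
        assert model_df(p, a, k) == expected


class TestFitMl:
    def test_just_identified_equals_covariance_regression(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        cov = LaggedCovariance(
            S=S, order=1, n_eff=101, p=1, var_names=("y", "x"), block_labels=("lag0", "lag1")
        )
        spec = ModelSpec.null(1, 1).with_freed(("Phi", 1, 0, 0))
        params, fr = fit_ml(cov, spec)
        assert params.estimate(("Phi", 1, 0, 0)) == pytest.approx(0.5, abs=1e-6)
        assert params.psi[0] == pytest.approx(0.75, abs=1e-6)
        assert fr.chi2 == pytest.approx(0.0, abs=1e-6)
        assert fr.df == 0

    def test_saturated_recursive_model_chi2_zero(self, scen_series):
        cov = block_toeplitz_cov(scen_series, 1)
        spec = ModelSpec.null(3, 1)
        for k in range(3):
            for j in range(k):
                spec = spec.with_freed(("A", k, j))
            for j in range(3):
                spec = spec.with_freed(("Phi", 1, k, j))
        params, fr = fit_ml(cov, spec)
        assert fr.df == 0
        assert fr.chi2 == pytest.approx(0.0, abs=1e-5)

    def test_freeing_never_increases_chi2(self, scen_series):
        cov = block_toeplitz_cov(scen_series, 1)
        spec = ModelSpec.null(3, 1)
        params, fr = fit_ml(cov, spec)
        for pid in [("A", 0, 2), ("Phi", 1, 1, 0), ("Phi", 1, 0, 0)]:
            spec2 = spec.with_freed(pid)
            params2, fr2 = fit_ml(cov, spec2, start=params)
            assert fr2.chi2 <= fr.chi2 + 1e-6 * max(fr.chi2, 1.0)
            spec, params, fr = spec2, params2, fr2

    def test_estimates_permute_with_variable_order(self, scen_series):
        cov = block_toeplitz_cov(scen_series, 1)
        spec = ModelSpec.null(3, 1).with_freed(("A", 0, 2)).with_freed(("Phi", 1, 1, 0))
        params, _ = fit_ml(cov, spec)
        perm = [2, 0, 1]  # new index -> old index
        vals = scen_series.values[perm]
        ts2 = RoiTimeSeries(vals, tuple(scen_series.labels[i] for i in perm), centered=True)
        cov2 = block_toeplitz_cov(ts2, 1)
        inv = np.empty(3, dtype=int)
        inv[perm] = np.arange(3)
        spec2 = ModelSpec.null(3, 1).with_freed(("A", int(inv[0]), int(inv[2]))).with_freed(
            ("Phi", 1, int(inv[1]), int(inv[0]))
        )
        params2, _ = fit_ml(cov2, spec2)
        assert params2.estimate(("A", int(inv[0]), int(inv[2]))) == pytest.approx(
            params.estimate(("A", 0, 2)), abs=1e-8
        )


class TestFitIndices:
    def test_chi2_equal_df_gives_rmsea_zero_cfi_one(self):
        S = np.eye(3)
        fr = fit_indices(10.0, 10, 50.0, 3, 200, S, S)
        assert fr.rmsea == 0.0
        assert fr.cfi == 1.0

    def test_published_white_noise_row(self):
        # chi2 below df: RMSEA 0.00 and CFI 1.00
        S = np.eye(12)
        fr = fit_indices(64.07, 72, 200.0, 66, 197, S, S)
        assert fr.rmsea == pytest.approx(0.0)
        assert fr.cfi == pytest.approx(1.0)

    def test_exact_reproduction_gives_zero_srmr(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((4, 100))
        S = X @ X.T / 100
        fr = fit_indices(0.0, 5, 80.0, 6, 100, S, S.copy())
        assert fr.srmr == 0.0

    def test_nnfi_missing_when_df_zero(self):
        S = np.eye(2)
        fr = fit_indices(0.0, 0, 10.0, 1, 50, S, S)
        assert fr.nnfi is None


class TestModificationIndices:
    def test_mi_matches_refit_oracle(self):
        phi = np.zeros((1, 3, 3))
        phi[0] = np.array([[0.4, 0.0, 0.2], [0.0, 0.3, 0.0], [0.0, 0.2, 0.4]])
        sim = SimulationSpec(p=3, T=400, order=1, A=np.zeros((3, 3)), phi=phi, seed=8)
        ts = center(simulate_usem(sim))
        cov = block_toeplitz_cov(ts, 1)
        base = ModelSpec.null(3, 1).with_freed(("Phi", 1, 0, 0)).with_freed(("Phi", 1, 1, 1))
        params, fr = fit_ml(cov, base)
        cands = [c for c in candidate_set(base) if not base.is_free(c)]
        table = modification_indices(cov, base, params, cands)
        assert all(row.mi >= 0 for row in table)
        for row in list(table)[:6]:
            _, fr2 = fit_ml(cov, base.with_freed(row.param), start=params)
            drop = fr.chi2 - fr2.chi2
            assert abs(row.mi - drop) / max(drop, 1.0) < 0.25

    def test_already_free_candidate_excluded(self, scen_series):
        cov = block_toeplitz_cov(scen_series, 1)
        base = ModelSpec.null(3, 1).with_freed(("A", 0, 2))
        params, _ = fit_ml(cov, base)
        with pytest.warns(UserWarning, match="already free"):
            table = modification_indices(cov, base, params, [("A", 0, 2)])
        assert len(table) == 0

    def test_saturated_model_has_empty_table(self, white_series):
        cov = block_toeplitz_cov(white_series, 0)
        spec = ModelSpec.null(3, 0)
        params, _ = fit_ml(cov, spec)
        table = modification_indices(cov, spec, params, [])
        assert len(table) == 0


class TestWaldPrune:
    def test_spurious_zero_parameter_is_pruned(self):
        phi = np.zeros((1, 3, 3))
        phi[0] = np.diag([0.5, 0.5, 0.5])
        sim = SimulationSpec(p=3, T=2000, order=1, A=np.zeros((3, 3)), phi=phi, seed=11)
        ts = center(simulate_usem(sim))
        cov = block_toeplitz_cov(ts, 1)
        spec = ModelSpec.null(3, 1)
        for k in range(3):
            spec = spec.with_freed(("Phi", 1, k, k))
        spec = spec.with_freed(("A", 0, 1))  # true value 0
        params, _ = fit_ml(cov, spec)
        pruned, pparams, _ = wald_prune(cov, spec, params)
        assert not pruned.is_free(("A", 0, 1))
        for k in range(3):
            assert pruned.is_free(("Phi", 1, k, k))

    def test_all_significant_model_unchanged(self, scen_series):
        cov = block_toeplitz_cov(scen_series, 2)
        spec = ModelSpec.null(3, 2)
        for pid, _ in second_order_scenario().nonzero_coefficients():
            spec = spec.with_freed(pid)
        params, _ = fit_ml(cov, spec)
        pruned, _, _ = wald_prune(cov, spec, params)
        assert set(pruned.free_params()) == set(spec.free_params())

    def test_empty_model_passes_through(self, white_series):
        cov = block_toeplitz_cov(white_series, 1)
        spec = ModelSpec.null(3, 1)
        params, _ = fit_ml(cov, spec)
        pruned, _, _ = wald_prune(cov, spec, params)
        assert pruned.k_free == 0


class TestModelSpec:
    def test_diagonal_a_cannot_be_freed(self):
        with pytest.raises(ValueError, match="diagonal"):
            ModelSpec.null(3, 1).with_freed(("A", 1, 1))

    def test_json_round_trip(self):
        spec = ModelSpec.null(3, 2).with_freed(("A", 0, 2)).with_freed(("Phi", 2, 2, 2))
        back = ModelSpec.from_json_dict(spec.to_json_dict())
        assert back.key() == spec.key()
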