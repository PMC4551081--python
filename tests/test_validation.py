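import numpy as np
import pytest

from usem.data_model import RoiTimeSeries, center
from usem.sem_engine import ModelSpec, ParamMatrixSet
from usem.synthesis import SimulationSpec, second_order_scenario, simulate_usem
from usem.usem_family import SearchConfig, usem_confirmatory, usem_search
from usem.validation import (
    Decision,
    DecisionPolicy,
    ResidualSeries,
    WhiteNoiseResult,
    decide_option,
    prediction_errors,
    validate,
    white_noise_df,
    white_noise_test,
)


class TestPredictionErrors:
    def test_zero_coefficients_return_centered_data(self, scen_series):
        spec = ModelSpec.null(3, 1)
        params = ParamMatrixSet(
            spec=spec, A=np.zeros((3, 3)), phi=np.zeros((1, 3, 3)), psi=np.ones(3)
        )
        res = prediction_errors(scen_series, params)
        assert res.length == scen_series.T - 1
        np.testing.assert_allclose(res.values, scen_series.values[:, 1:])

    def test_true_parameters_whiten_to_identity(self):
        sim = second_order_scenario(T=5000, seed=21)
        ts = center(simulate_usem(sim))
        spec = ModelSpec.null(3, 2)
        for pid, _ in sim.nonzero_coefficients():
            spec = spec.with_freed(pid)
        phi = np.zeros((2, 3, 3))
        phi[0], phi[1] = sim.phi[0], sim.phi[1]
        params = ParamMatrixSet(spec=spec, A=sim.A, phi=phi, psi=np.ones(3))
        res = prediction_errors(ts, params)
        C = res.values @ res.values.T / res.length
        assert np.abs(C - np.eye(3)).max() < 0.1

    def test_dimension_mismatch_rejected(self, white_series):
        spec = ModelSpec.null(2, 1)
        params = ParamMatrixSet(
            spec=spec, A=np.zeros((2, 2)), phi=np.zeros((1, 2, 2)), psi=np.ones(2)
        )
        with pytest.raises(ValueError, match="mismatch"):
            prediction_errors(white_series, params)


class TestWhiteNoiseDf:
    @pytest.mark.parametrize("p,L,expected", [(3, 3, 72), (4, 3, 126), (7, 3, 378), (1, 0, 0)])
    def test_published_values(self, p, L, expected):
        assert white_noise_df(p, L) == expected


class TestWhiteNoiseTest:
    cfg = SearchConfig()

    def test_df_is_structural_not_data_dependent(self):
        for seed in (0, 1):
            rng = np.random.default_rng(seed)
            res = ResidualSeries(rng.standard_normal((3, 150)), "m", 0, 1)
            wn = white_noise_test(res, 3, self.cfg)
            assert wn.fit.df == 72

    def test_iid_residuals_usually_pass(self):
        passed = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            res = ResidualSeries(rng.standard_normal((3, 200)), "m", 0, 1)
            passed += white_noise_test(res, 3, self.cfg).passed
        assert passed >= 14

    def test_autocorrelated_residuals_fail(self):
        failed = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            Z = rng.standard_normal((3, 200))
            for t in range(1, 200):
                Z[0, t] += 0.5 * Z[0, t - 1]
            failed += not white_noise_test(ResidualSeries(Z, "m", 0, 1), 3, self.cfg).passed
        assert failed == 10

    def test_mi_table_flags_the_lagged_dependency(self):
        rng = np.random.default_rng(4)
        Z = rng.standard_normal((3, 400))
        for t in range(1, 400):
            Z[1, t] += 0.4 * Z[1, t - 1]
        wn = white_noise_test(ResidualSeries(Z, "m", 0, 1), 3, self.cfg)
        top = wn.mi.rows[0]
        assert top.param == ("Phi", 1, 1, 1)
        assert top.mi > 3.8415

    def test_too_short_series_rejected(self):
        res = ResidualSeries(np.random.default_rng(0).standard_normal((3, 12)), "m", 0, 1)
        with pytest.raises(ValueError, match="too short"):
            white_noise_test(res, 3, self.cfg)


def _wn_stub(passed, mi_rows, model_order=1):
    from usem.sem_engine import ModIndexRow, ModIndexTable
    from usem.sem_engine import FitResult

    fr = FitResult(
        chi2=100.0, df=72, p_value=0.01, rmsea=0.08, srmr=0.1, cfi=0.5, nnfi=0.5,
        baseline_chi2=120.0, baseline_df=66, converged=True, n_eff=197,
    )
    table = ModIndexTable(rows=tuple(ModIndexRow(param=p, mi=m, epc=0.1) for p, m in mi_rows))
    return WhiteNoiseResult(fit=fr, mi=table, passed=passed, L=3, p=3, model_order=model_order)


class TestDecideOption:
    def test_few_indices_map_to_confirmatory_parameters(self):
        wn = _wn_stub(False, [(("Phi", 2, 2, 2), 20.0), (("Phi", 1, 1, 0), 8.0), (("Phi", 1, 0, 1), 1.0)])
        d = decide_option(wn, DecisionPolicy())
        assert d.action == "option_a"
        assert d.mapped_params == (("Phi", 2, 2, 2), ("Phi", 1, 1, 0))

    def test_already_free_dependency_escalates_one_lag(self):
        spec = ModelSpec.null(3, 1).with_freed(("Phi", 1, 2, 2))
        wn = _wn_stub(False, [(("Phi", 1, 2, 2), 15.0)])
        d = decide_option(wn, DecisionPolicy(), current_spec=spec)
        assert d.action == "option_a"
        assert d.mapped_params == (("Phi", 2, 2, 2),)

    def test_no_significant_indices_fall_back_to_search(self):
        wn = _wn_stub(False, [(("Phi", 1, 0, 0), 2.0)])
        assert decide_option(wn, DecisionPolicy()).action == "option_b"

    def test_diffuse_pattern_triggers_search(self):
        rows = [(("Phi", l, k, j), 6.0) for l in (1, 2, 3) for k in range(3) for j in range(2)]
        assert decide_option(_wn_stub(False, rows), DecisionPolicy()).action == "option_b"

    def test_passed_test_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            decide_option(_wn_stub(True, []), DecisionPolicy())

    def test_subdivision_only_on_explicit_request(self):
        wn = _wn_stub(False, [(("Phi", 2, 0, 0), 9.0)])
        d = decide_option(wn, DecisionPolicy(allow_subdivision=True))
        assert d.action == "option_c"


class TestValidate:
    def test_correct_first_order_model_accepted_in_one_pass(self):
        accepted = 0
        for seed in range(10):
            phi = np.zeros((1, 3, 3))
            phi[0] = np.diag([0.5, 0.4, 0.5])
            A = np.zeros((3, 3))
            A[1, 0] = 0.4
            sim = SimulationSpec(p=3, T=200, order=1, A=A, phi=phi, seed=seed)
            ts = center(simulate_usem(sim))
            spec, params, fr = usem_search(ts, SearchConfig(order=1))
            trace = validate(ts, params, SearchConfig(order=1), fit=fr)
            accepted += trace.accepted and trace.final_order == 1 and len(trace.records) == 1
        assert accepted >= 8

    def test_second_order_truth_recovered_from_first_order_start(self, scen_truth):
        # representative seeded realization of the 3-ROI second-order scenario
        ts = center(simulate_usem(second_order_scenario(seed=0)))
        cfg = SearchConfig(order=1)
        spec, params, fr = usem_search(ts, cfg)
        trace = validate(ts, params, cfg, fit=fr)
        assert trace.accepted
        assert trace.final_order == 2
        assert set(trace.final_spec.free_params()) == scen_truth
        assert not trace.records[0].white_noise.passed
        assert trace.records[-1].white_noise.passed

    def test_order_budget_exhaustion_gives_up(self):
        ts = center(simulate_usem(second_order_scenario(seed=3)))
        cfg = SearchConfig(order=1)
        spec, params, fr = usem_search(ts, cfg)
        trace = validate(ts, params, cfg, max_order=1, fit=fr)
        if not trace.records[0].white_noise.passed:
            assert not trace.accepted
            assert trace.records[-1].action == "give_up"
            assert trace.final_order == 1

    def test_orders_non_decreasing_along_trace(self):
        ts = center(simulate_usem(second_order_scenario(seed=5)))
        cfg = SearchConfig(order=1)
        spec, params, fr = usem_search(ts, cfg)
        trace = validate(ts, params, cfg, fit=fr)
        orders = [r.spec.order for r in trace.records]
        assert orders == sorted(orders)

    def test_accepted_trace_residuals_reconfirm_white(self):
        ts = center(simulate_usem(second_order_scenario(seed=0)))
        cfg = SearchConfig(order=1)
        spec, params, fr = usem_search(ts, cfg)
        trace = validate(ts, params, cfg, fit=fr)
        assert trace.accepted
        res = prediction_errors(ts, trace.final_params)
        assert white_noise_test(res, 3, cfg).passed

    def test_trace_serializes_and_reports(self, tmp_path):
        ts = center(simulate_usem(second_order_scenario(seed=0)))
        cfg = SearchConfig(order=1)
        spec, params, fr = usem_search(ts, cfg)
        trace = validate(ts, params, cfg, fit=fr)
        trace.to_json(tmp_path / "trace.json")
        assert (tmp_path / "trace.json").stat().st_size > 100
        rep = trace.report()
        assert "MODEL FIT" in rep and "WHITE NOISE TEST" in rep
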