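"""Vector fields, bolus event, simulation and the model (i) closed form."""

import numpy as np
import pytest

from scnlme import (
    CellParameters,
    MODELS,
    analytic_model_i,
    apply_bolus,
    get_model,
    observable_map,
    simulate_cell,
    simulate_observable,
    vector_field,
)
from scnlme.models import model_i_observable

from conftest import random_model_i_params


MODEL_PARAMS = {
    "i": {"delta": 0.3, "gamma": 0.9, "kappa": 50.0, "t0": 1.0, "offset": 5.0},
    "ii": {
        "delta": 0.3,
        "gamma": 0.9,
        "k1m0": 0.5,
        "k2": 2.0,
        "k2m0scale": 60.0,
        "r0m0": 3.0,
        "t0": 1.0,
        "offset": 5.0,
    },
    "iii": {
        "delta1m0": 0.4,
        "delta2": 1.5,
        "e0m0": 2.0,
        "kappa": 50.0,
        "gamma": 0.9,
        "t0": 1.0,
        "offset": 5.0,
    },
    "iv": {
        "delta": 0.3,
        "gamma": 0.9,
        "k1m0": 0.5,
        "k2": 2.0,
        "k2m0scale": 60.0,
        "r0m0": 3.0,
        "delta1m0": 0.4,
        "delta2": 1.5,
        "e0m0": 2.0,
        "t0": 1.0,
        "offset": 5.0,
    },
}


class TestVectorField:
    def test_zero_state_is_fixed_point_before_bolus(self):
        # without mRNA nothing moves (pools at their initial values)
        assert np.allclose(vector_field("i", MODEL_PARAMS["i"], [0.0, 0.0]), 0.0)
        assert np.allclose(vector_field("ii", MODEL_PARAMS["ii"], [0.0, 3.0, 0.0, 0.0]), 0.0)

    def test_model_i_direct_substitution(self):
        dv = vector_field("i", {"delta": 1.0, "gamma": 2.0, "kappa": 3.0, "t0": 1.0, "offset": 1.0}, [1.0, 0.0])
        assert np.allclose(dv, [-1.0, 3.0])

    @pytest.mark.parametrize("model_id", ["ii", "iii", "iv"])
    def test_pool_conservation_by_construction(self, model_id):
        rng = np.random.default_rng(5)
        model = get_model(model_id)
        for _ in range(10):
            state = rng.uniform(0.0, 2.0, size=model.n_states)
            dv = vector_field(model, MODEL_PARAMS[model_id], state)
            if "r" in model.state_names:
                assert dv[model.state_index("r")] + dv[model.state_index("c")] == pytest.approx(0.0, abs=1e-12)
            if "e" in model.state_names:
                assert dv[model.state_index("e")] + dv[model.state_index("em")] == pytest.approx(0.0, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="unknown model_id"):
            vector_field("v", MODEL_PARAMS["i"], [0.0, 0.0])
        with pytest.raises(ValueError, match="missing parameter"):
            vector_field("i", {"delta": 1.0}, [0.0, 0.0])
        with pytest.raises(ValueError, match="negative state"):
            vector_field("i", MODEL_PARAMS["i"], [-0.1, 0.0])


class TestBolus:
    def test_normalized_bolus_increments_m_by_one(self):
        assert np.allclose(apply_bolus("i", [0.0, 0.0]), [1.0, 0.0])
        assert np.allclose(apply_bolus("ii", [0.0, 3.0, 0.0, 0.0]), [1.0, 3.0, 0.0, 0.0])

    def test_bolus_is_additive(self):
        once = apply_bolus("i", [0.0, 0.0])
        twice = apply_bolus("i", once)
        assert twice[0] == pytest.approx(2.0)


class TestObservableMap:
    def test_values(self):
        assert observable_map(0.0, 1.0) == pytest.approx(0.0)
        assert observable_map(np.e - 1.0, 1.0) == pytest.approx(1.0)

    def test_monotone_in_g(self):
        g = np.linspace(0.0, 10.0, 50)
        y = observable_map(g, 2.0)
        assert np.all(np.diff(y) > 0)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            observable_map(1.0, 0.0)
        with pytest.raises(ValueError):
            observable_map(-1.0, 1.0)


class TestSimulateCell:
    def test_flat_at_log_offset_up_to_bolus(self, model_i_params):
        # no mRNA before t0, and g(t0) = 0 exactly at the bolus
        times = np.append(np.linspace(0.0, 0.9, 10), 0.95)
        params = CellParameters({**model_i_params.values, "t0": 0.95})
        tr = simulate_cell("i", params, times)
        assert np.allclose(tr.observable, np.log(params["offset"]))

    def test_closed_form_value_at_unit_time(self):
        # delta=1, gamma=2, kappa=1, t0->0, offset=1 at t=1: g=(e^-1-e^-2)/1
        params = {"delta": 1.0, "gamma": 2.0, "kappa": 1.0, "t0": 1e-9, "offset": 1.0}
        tr = simulate_cell("i", params, np.array([0.5, 1.0]))
        g_expect = np.exp(-1.0) - np.exp(-2.0)
        assert tr.states["g"][1] == pytest.approx(g_expect, abs=1e-7)
        assert tr.observable[1] == pytest.approx(np.log(1.0 + g_expect), abs=1e-7)

    def test_delta_gamma_swap_leaves_observable_unchanged(self, grid181):
        params = MODEL_PARAMS["i"]
        swapped = {**params, "delta": params["gamma"], "gamma": params["delta"]}
        y1 = simulate_cell("i", params, grid181).observable
        y2 = simulate_cell("i", swapped, grid181).observable
        assert np.max(np.abs(y1 - y2)) < 1e-7

    @pytest.mark.parametrize("model_id", ["ii", "iii", "iv"])
    def test_conservation_and_nonnegativity_along_trajectory(self, model_id, grid181):
        model = get_model(model_id)
        tr = simulate_cell(model, MODEL_PARAMS[model_id], grid181)
        for s in tr.states.values():
            assert np.all(s >= -1e-8)
        if "r" in tr.states:
            total = tr.states["r"] + tr.states["c"]
            assert np.allclose(total, MODEL_PARAMS[model_id]["r0m0"], atol=1e-6)
        if "e" in tr.states:
            total = tr.states["e"] + tr.states["em"]
            assert np.allclose(total, MODEL_PARAMS[model_id]["e0m0"], atol=1e-6)

    def test_t0_outside_window_rejected(self, model_i_params):
        bad = CellParameters({**model_i_params.values, "t0": 40.0})
        with pytest.raises(ValueError, match="t0"):
            simulate_cell("i", bad, np.linspace(0, 30, 10))


class TestAnalyticModelI:
    def test_continuity_at_bolus(self, model_i_params):
        tr = analytic_model_i(model_i_params, np.array([model_i_params["t0"]]))
        assert tr.states["g"][0] == pytest.approx(0.0)
        assert tr.observable[0] == pytest.approx(np.log(model_i_params["offset"]))

    def test_equal_rates_limit_form(self):
        params = {"delta": 1.0, "gamma": 1.0, "kappa": 1.0, "t0": 1e-12, "offset": 1.0}
        tr = analytic_model_i(params, np.array([1.0]))
        assert tr.states["g"][0] == pytest.approx(np.exp(-1.0), rel=1e-9)

    def test_limit_form_is_continuous_across_the_switch(self):
        # gamma approaching delta from both sides agrees with the limit form
        base = {"delta": 0.5, "kappa": 30.0, "t0": 0.8, "offset": 4.0}
        t = np.linspace(0.0, 30.0, 181)
        y_eq = analytic_model_i({**base, "gamma": 0.5}, t).observable
        for eps in (1e-7, -1e-7):
            y = analytic_model_i({**base, "gamma": 0.5 + eps}, t).observable
            assert np.max(np.abs(y - y_eq)) < 1e-5

    def test_oracle_equivalence_with_numerical_integrator(self, grid181):
        rng = np.random.default_rng(17)
        worst = 0.0
        for _ in range(20):
            params = random_model_i_params(rng)
            y_a = analytic_model_i(params, grid181).observable
            y_n = simulate_cell("i", params, grid181).observable
            worst = max(worst, float(np.max(np.abs(y_a - y_n))))
        assert worst < 1e-6

    def test_jacobian_matches_finite_differences(self, grid181):
        rng = np.random.default_rng(3)
        params = random_model_i_params(rng)
        theta = params.vector(("delta", "gamma", "kappa", "t0", "offset"))
        y, jac = model_i_observable(theta, grid181, with_jac=True)
        for k in range(5):
            h = 1e-6 * max(1.0, theta[k])
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            fd = (model_i_observable(tp, grid181) - model_i_observable(tm, grid181)) / (2 * h)
            # ignore the grid point straddling t0 where y is non-differentiable
            mask = np.abs(grid181 - theta[3]) > 1e-3
            assert np.max(np.abs(jac[mask, k] - fd[mask])) < 1e-4


class TestRibosomeNonLimitingReduction:
    def test_model_ii_reduces_to_model_i_when_ribosomes_saturate(self, grid181):
        # strong binding (k1m0*r0m0 >> k2 >> gamma): essentially all mRNA is
        # ribosome-bound, translation proceeds at k2m0scale per total mRNA and
        # free-mRNA decay is suppressed by the bound fraction
        k2 = 0.5
        rho = 2000.0  # k1m0*r0m0 / k2
        delta = 1e-5
        p_ii = {
            "delta": delta,
            "gamma": 0.25,
            "k1m0": rho * k2 / 1e5,
            "k2": k2,
            "k2m0scale": 40.0,
            "r0m0": 1e5,
            "t0": 1.0,
            "offset": 5.0,
        }
        p_i = {
            "delta": delta / (1.0 + rho),
            "gamma": 0.25,
            "kappa": 40.0 * rho / (1.0 + rho),
            "t0": 1.0,
            "offset": 5.0,
        }
        y_ii = simulate_cell("ii", p_ii, grid181).observable
        y_i = simulate_observable("i", p_i, grid181)
        # transient equilibration right after the bolus is excluded
        settled = grid181 > 1.5
        assert np.max(np.abs(y_ii[settled] - y_i[settled])) < 5e-3
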