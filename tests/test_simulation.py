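"""Integration, steady-state solving, and fold-change classification."""

import numpy as np
import pytest

from eicokin.model import STATE_IDS, build_paper_model, make_rhs_function
from eicokin.simulate import (
    NotConvergedError,
    SteadyStateResult,
    classify_ratio,
    fold_changes,
    integrate,
    simulate_condition,
    steady_state,
)


class TestIntegrate:
    def test_zero_pc_zero_trajectory(self, model):
        t, y = integrate(model, t_end=1e4, pc_nM=0.0)
        assert np.all(y == 0.0)

    def test_invalid_arguments(self, model):
        with pytest.raises(ValueError):
            integrate(model, t_end=-1.0)
        with pytest.raises(ValueError):
            integrate(model, t_end=10.0, rel_tol=-1e-3)
        with pytest.raises(ValueError):
            integrate(model, initial_state=np.zeros(3), t_end=10.0)

    def test_agrees_with_fixed_step_euler(self, model, conditions):
        """Adaptive integration matches a brute-force explicit Euler oracle
        (dt = 1e-3 s) within 1% per species on t in [0, 100]."""
        cond = conditions[("B6", "control")]
        f = make_rhs_function(model, activities=cond.activity_ratios, pc_nM=cond.pc_nM)
        dt = 1e-3
        y = np.zeros(len(STATE_IDS))
        for _ in range(100_000):
            y = np.maximum(y + dt * f(0.0, y), 0.0)
        t, traj = integrate(
            model, t_end=100.0, activities=cond.activity_ratios,
            pc_nM=cond.pc_nM, t_eval=[100.0],
        )
        adaptive = traj[-1]
        scale = np.maximum(np.abs(y), 1e-12)
        assert np.all(np.abs(adaptive - y) / scale <= 0.01)


class TestSteadyState:
    def test_zero_pc_gives_zero_state(self, model):
        res = steady_state(model, pc_nM=0.0)
        assert res.converged
        assert all(v == 0.0 for v in res.concentrations.values())

    def test_all_conditions_converge(self, steady_states):
        for key, res in steady_states.items():
            assert res.converged, key
            assert res.residual_norm <= 1e-6, key
            assert all(v >= 0.0 for v in res.concentrations.values()), key

    def test_start_state_independence(self, model, conditions):
        """The attracting steady state does not depend on whether species
        start at 0 or at 10 nM (within 0.1% per species)."""
        for key, cond in conditions.items():
            a = simulate_condition(model, cond)
            b = simulate_condition(
                model, cond, initial_state=np.full(len(STATE_IDS), 10.0)
            )
            for m in STATE_IDS:
                va, vb = a.concentrations[m], b.concentrations[m]
                assert vb == pytest.approx(va, rel=1e-3), (key, m)

    def test_ptgds_branch_responds_to_ptgs1(self, model, conditions, steady_states):
        """Doubling only the PTGS1 ratio raises steady-state PGD2."""
        cond = conditions[("B6", "control")]
        ratios = dict(cond.activity_ratios)
        ratios["PTGS1"] = 2.0
        res = steady_state(model, activities=ratios, pc_nM=cond.pc_nM)
        base = steady_states[("B6", "control")]
        assert res.converged
        assert res.concentrations["PGD2"] > base.concentrations["PGD2"]

    def test_original_model_unmodified(self, model, conditions):
        before = model.activity_map()
        pc_before = model.pc_nM
        simulate_condition(model, conditions[("PWD", "DDC")])
        assert model.activity_map() == before
        assert model.pc_nM == pc_before

    def test_invalid_tolerance(self, model):
        with pytest.raises(ValueError):
            steady_state(model, tol=0.0)


def _fake_result(concs, converged=True):
    return SteadyStateResult(concs, 0.0, converged, 1.0)


class TestFoldChanges:
    def test_identical_states_all_unchanged(self, steady_states):
        ctl = steady_states[("B6", "control")]
        fc = fold_changes(ctl, ctl)
        assert all(r == 1.0 for r in fc.ratios.values())
        assert all(c == "unchanged" for c in fc.classification.values())

    def test_classification_band(self):
        assert classify_ratio(1.5) == "up"
        assert classify_ratio(1.0 / 1.5) == "down"
        assert classify_ratio(1.49) == "unchanged"
        assert classify_ratio(0.7) == "unchanged"
        assert classify_ratio(3.0, threshold=4.0) == "unchanged"
        with pytest.raises(ValueError):
            classify_ratio(1.0, threshold=1.0)

    def test_requires_convergence(self, steady_states):
        ctl = steady_states[("B6", "control")]
        bad = _fake_result(dict(ctl.concentrations), converged=False)
        with pytest.raises(NotConvergedError):
            fold_changes(ctl, bad)

    def test_zero_control_reported_undefined(self):
        a = _fake_result({"AA": 0.0, "PGD2": 1.0})
        b = _fake_result({"AA": 2.0, "PGD2": 3.0})
        fc = fold_changes(a, b)
        assert np.isnan(fc.ratios["AA"])
        assert fc.classification["AA"] == "undefined"
        assert fc.ratios["PGD2"] == 3.0

    def test_to_frame_layout(self, steady_states):
        fc = fold_changes(
            steady_states[("AJ", "control")], steady_states[("AJ", "DDC")]
        )
        df = fc.to_frame()
        assert list(df.columns) == ["metabolite", "ratio", "classification"]
        assert set(df["metabolite"]) == set(STATE_IDS)
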