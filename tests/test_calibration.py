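"""Objective function and genetic-algorithm fitting."""

import numpy as np
import pytest

from eicokin.calibrate import (
    METABOLITE_SET_M,
    FitResult,
    ObjectiveSpec,
    default_parameter_space,
    fit_genetic,
    objective,
)
from eicokin.model import build_paper_model
from eicokin.simulate import simulate_condition
from eicokin.synth import generate_scenario, make_objective_spec, simulate_measurements


@pytest.fixture(scope="module")
def noise_free():
    """Scenario at the published constants with exact (noise-free) data."""
    scenario = generate_scenario(seed=11, perturbation_scale=0.0, noise_cv=0.0)
    measurements = simulate_measurements(scenario)
    return scenario, measurements


@pytest.fixture(scope="module")
def b6_spec(noise_free):
    scenario, measurements = noise_free
    return make_objective_spec(scenario, measurements, strain="B6")


def _truth_vector(scenario, spec):
    return [scenario.true_parameters[(r, n)] for (r, n, _, _) in spec.parameter_space]


class TestObjective:
    def test_zero_at_self_consistent_data(self, noise_free, b6_spec):
        """f = 0 when the experimental values equal the model's own steady
        states at the true parameters."""
        scenario, _ = noise_free
        assert objective(_truth_vector(scenario, b6_spec), b6_spec) == 0.0

    def test_single_perturbed_value_gives_delta_squared(self, noise_free, b6_spec):
        scenario, _ = noise_free
        delta = 0.37
        bumped = ObjectiveSpec(
            experimental_control={
                m: v + (delta if m == "PGD2" else 0.0)
                for m, v in b6_spec.experimental_control.items()
            },
            experimental_ddc=dict(b6_spec.experimental_ddc),
            control_condition=b6_spec.control_condition,
            ddc_condition=b6_spec.ddc_condition,
            parameter_space=b6_spec.parameter_space,
        )
        f = objective(_truth_vector(scenario, bumped), bumped)
        assert f == pytest.approx(delta**2, rel=1e-6)

    def test_truth_beats_perturbed_vmax(self, noise_free, b6_spec):
        """Doubling one V_max can only worsen the fit to self-consistent data."""
        scenario, _ = noise_free
        truth = _truth_vector(scenario, b6_spec)
        worse = list(truth)
        for k, (r, n, _, _) in enumerate(b6_spec.parameter_space):
            if (r, n) == ("R9", "v_max"):
                worse[k] = truth[k] * 2.0
        assert objective(truth, b6_spec) <= objective(worse, b6_spec)

    def test_metabolite_set_is_fixed(self, b6_spec):
        with pytest.raises(ValueError):
            ObjectiveSpec(
                experimental_control=b6_spec.experimental_control,
                experimental_ddc=b6_spec.experimental_ddc,
                control_condition=b6_spec.control_condition,
                ddc_condition=b6_spec.ddc_condition,
                parameter_space=b6_spec.parameter_space,
                metabolite_set=("AA", "PGD2"),
            )

    def test_bad_bounds_rejected(self, b6_spec):
        with pytest.raises(ValueError):
            ObjectiveSpec(
                experimental_control=b6_spec.experimental_control,
                experimental_ddc=b6_spec.experimental_ddc,
                control_condition=b6_spec.control_condition,
                ddc_condition=b6_spec.ddc_condition,
                parameter_space=(("R9", "v_max", 2.0, 1.0),),
            )

    def test_default_space_excludes_literature_km(self):
        space = default_parameter_space()
        assert ("R1", "k_m") not in {(r, n) for r, n, _, _ in space}
        # every bound brackets its published value
        model = build_paper_model()
        for r, n, lo, hi in space:
            v = getattr(model.reaction(r).rate_law, n)
            assert lo < v < hi


class TestFitGenetic:
    def test_truth_in_population_is_kept(self, noise_free, b6_spec):
        """With the ground truth injected, one generation suffices for f=0."""
        scenario, _ = noise_free
        fit = fit_genetic(
            b6_spec, population_size=6, generations=1, seed=4,
            initial_population=[_truth_vector(scenario, b6_spec)],
        )
        # the log-scale gene encoding re-represents the injected values, so
        # "zero" is zero to machine precision, not bitwise
        assert fit.best_objective == pytest.approx(0.0, abs=1e-18)

    def test_seeded_determinism(self, b6_spec):
        kw = dict(population_size=8, generations=4, seed=123)
        a = fit_genetic(b6_spec, **kw)
        b = fit_genetic(b6_spec, **kw)
        assert a.best_parameters == b.best_parameters
        assert a.generation_trace == b.generation_trace
        assert a.best_objective == b.best_objective

    def test_elitist_trace_non_increasing(self, b6_spec):
        fit = fit_genetic(b6_spec, population_size=10, generations=12, seed=7)
        trace = np.asarray(fit.generation_trace)
        assert len(trace) == 12
        assert np.all(np.diff(trace) <= 0.0)
        assert fit.best_objective == trace[-1]

    def test_best_parameters_within_bounds(self, b6_spec):
        fit = fit_genetic(b6_spec, population_size=8, generations=3, seed=2)
        bounds = {(r, n): (lo, hi) for r, n, lo, hi in b6_spec.parameter_space}
        for key, v in fit.best_parameters.items():
            lo, hi = bounds[key]
            assert lo <= v <= hi

    def test_argument_validation(self, b6_spec):
        with pytest.raises(ValueError):
            fit_genetic(b6_spec, population_size=1, generations=5, seed=0)
        with pytest.raises(ValueError):
            fit_genetic(b6_spec, population_size=4, generations=0, seed=0)

    def test_result_invariant_rejects_increasing_trace(self):
        with pytest.raises(ValueError):
            FitResult({}, 1.0, (3.0, 1.0, 2.0), seed=0)
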