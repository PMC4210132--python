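"""Model construction, rate-law evaluation, and the ODE right-hand side."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eicokin.model import (
    ENZYME_IDS,
    STATE_IDS,
    KineticModel,
    ModelConsistencyError,
    StrainCondition,
    build_paper_model,
    evaluate_rate,
    load_constants,
    rhs,
)

# published kinetic constants, keyed (reaction, parameter) -> (value, unit)
PUBLISHED_CONSTANTS = {
    ("R1", "v_max"): (20.56, "nM^2.s^-1"),
    ("R1", "k_m"): (2500.0, "uM"),
    ("R1", "k_i"): (100.0, "nM"),
    ("R2", "v_max"): (0.01, "nM^2.s^-1"),
    ("R2", "k_m"): (0.0107, "nM"),
    ("R2", "k_i"): (8.603, "nM"),
    ("R3", "k_cat"): (0.0012, "s^-1"),
    ("R4", "v_max"): (9.7953, "nM^2.s^-1"),
    ("R4", "k_m"): (99.913, "nM"),
    ("R4", "k_i"): (0.709, "nM"),
    ("R5", "k_cat"): (0.0012, "s^-1"),
    ("R6", "v_max"): (0.003, "nM^3.s^-1"),
    ("R6", "k_m"): (0.067, "nM"),
    ("R6", "k_i"): (1.004, "nM"),
    ("R7", "v_max"): (1.098, "nM.s^-1"),
    ("R7", "k_m"): (1.58, "nM"),
    ("R7", "k_i"): (0.0106, "nM"),
    ("R8", "k_cat"): (0.00127, "s^-1"),
    ("R9", "v_max"): (0.168, "nM.s^-1"),
    ("R9", "k_m"): (3.876, "nM"),
    ("R9", "k_i"): (0.013, "nM"),
    ("R10", "v_max"): (0.067, "s^-1"),
    ("R11", "k_cat"): (0.052, "s^-1"),
    ("R12", "k_cat"): (0.00096, "s^-1"),
}

SINKS = {"R3", "R5", "R8", "R11", "R12"}


class TestModelAudit:
    def test_constants_match_published_values(self, model):
        """Every kinetic constant matches the published table, unit-annotated.

        µM-scale entries (R1's Michaelis constant for PC) are stored in nM
        internally, so the audit applies the declared unit conversion.
        """
        seen = set()
        for rxn in model.reactions:
            rl = rxn.rate_law
            for name in ("v_max", "k_m", "k_i", "k_cat"):
                v = getattr(rl, name)
                if v is None:
                    continue
                key = (rxn.id, name)
                assert key in PUBLISHED_CONSTANTS, f"unexpected constant {key}"
                ref, unit = PUBLISHED_CONSTANTS[key]
                scale = 1000.0 if unit == "uM" else 1.0
                assert v == ref * scale, key
                assert rl.units[name] == unit, key
                seen.add(key)
        assert seen == set(PUBLISHED_CONSTANTS)

    def test_counts(self, model):
        assert len(model.metabolites) == 8
        assert len(model.reactions) == 12
        assert len(model.activities) == 10
        assert model.fixed_ids == ("PC",)
        assert len(model.state_ids) == 7

    def test_sink_reactions(self, model):
        sinks = {r.id for r in model.reactions if r.product is None}
        assert sinks == SINKS
        for rid in sinks:
            assert model.reaction(rid).rate_law.form == "first_order_decay"

    def test_regulatory_topology(self, model):
        r = model.reaction
        assert r("R1").rate_law.activators == ("PLA2", "PERK")
        assert r("R1").rate_law.inhibitor == "AA"
        assert r("R2").rate_law.activators == ("ALOX5", "ALOX5AP")
        assert r("R2").rate_law.inhibitor == "5-HPETE"
        assert r("R4").rate_law.inhibitor == "LTA4"
        assert r("R6").rate_law.activators == ("ALOX15", "PKCD", "PSTAT3")
        assert r("R6").rate_law.inhibitor == "15-HPETE"
        assert r("R7").rate_law.activators == ("GPX",)
        assert r("R7").rate_law.inhibitor == "15-HETE"
        assert r("R9").rate_law.activators == ("PTGS1",)
        assert r("R9").rate_law.inhibitor == "PGH2"
        assert r("R10").rate_law.activators == ("PTGDS",)

    def test_r7_catalyst_switch(self):
        alt = build_paper_model(r7_catalyst="ALOX15")
        assert alt.reaction("R7").rate_law.activators == ("ALOX15",)
        with pytest.raises(ValueError):
            build_paper_model(r7_catalyst="nonsense")


class TestEvaluateRate:
    def test_first_order_decay_value(self, model):
        # k_cat * [S] = 0.0012 * 100
        v = evaluate_rate(model.reaction("R3"), {"5-HPETE": 100.0}, {})
        assert v == pytest.approx(0.12)

    @pytest.mark.parametrize("rid", [f"R{i}" for i in range(1, 13)])
    def test_zero_substrate_zero_flux(self, model, rid):
        rxn = model.reaction(rid)
        conc = {m.id: 0.0 for m in model.metabolites}
        acts = {a: 2.0 for a in ENZYME_IDS}
        assert evaluate_rate(rxn, conc, acts) == 0.0

    def test_product_inhibition_of_release(self, model):
        """Doubling AA strictly lowers the AA-release flux, all else equal."""
        rxn = model.reaction("R1")
        base = {"PC": 249000.0, "AA": 50.0}
        acts = {"PLA2": 1.0, "PERK": 1.0}
        v_lo = evaluate_rate(rxn, base, acts)
        v_hi = evaluate_rate(rxn, {**base, "AA": 100.0}, acts)
        assert v_hi < v_lo

    def test_negative_concentration_rejected(self, model):
        with pytest.raises(ValueError):
            evaluate_rate(model.reaction("R3"), {"5-HPETE": -1.0}, {})

    def test_unresolved_id_rejected(self, model):
        with pytest.raises(ModelConsistencyError):
            evaluate_rate(model.reaction("R9"), {"AA": 1.0, "PGH2": 1.0}, {})

    @settings(max_examples=50, deadline=None)
    @given(
        s=st.floats(0.0, 1e6),
        i=st.floats(0.0, 1e4),
        u=st.floats(0.01, 50.0),
        c=st.floats(0.01, 100.0),
    )
    def test_activator_linearity_and_nonnegativity(self, model, s, i, u, c):
        """Flux is non-negative and exactly linear in each activator ratio."""
        rxn = model.reaction("R9")
        conc = {"AA": s, "PGH2": i}
        v1 = evaluate_rate(rxn, conc, {"PTGS1": u})
        v2 = evaluate_rate(rxn, conc, {"PTGS1": u * c})
        assert v1 >= 0.0
        assert v2 == pytest.approx(v1 * c, rel=1e-12, abs=1e-300)

    @settings(max_examples=50, deadline=None)
    @given(i=st.floats(0.0, 1e4), delta=st.floats(1e-6, 1e4))
    def test_inhibitor_monotonicity(self, model, i, delta):
        rxn = model.reaction("R6")
        acts = {"ALOX15": 1.0, "PKCD": 1.0, "PSTAT3": 1.0}
        v1 = evaluate_rate(rxn, {"AA": 10.0, "15-HPETE": i}, acts)
        v2 = evaluate_rate(rxn, {"AA": 10.0, "15-HPETE": i + delta}, acts)
        assert v2 < v1


class TestRhs:
    def test_all_zero_with_pc_zero(self, model):
        d = rhs(model, np.zeros(7), pc_nM=0.0)
        assert np.all(d == 0.0)

    def test_pc_clamp_drives_only_aa(self, model):
        d = rhs(model, np.zeros(7), pc_nM=249000.0)
        by_id = dict(zip(STATE_IDS, d))
        assert by_id["AA"] > 0.0
        for mid, v in by_id.items():
            if mid != "AA":
                assert v == 0.0

    def test_dimension_mismatch(self, model):
        with pytest.raises(ValueError):
            rhs(model, np.zeros(5))

    def test_residual_vanishes_at_solver_steady_state(self, model, conditions, steady_states):
        res = steady_states[("B6", "control")]
        cond = conditions[("B6", "control")]
        d = rhs(
            model,
            res.vector(model.state_ids),
            activities=cond.activity_ratios,
            pc_nM=cond.pc_nM,
        )
        assert np.max(np.abs(d)) <= 1e-6


class TestConditions:
    def test_control_conditions_all_unity(self, conditions):
        for strain in ("AJ", "B6", "PWD"):
            cond = conditions[(strain, "control")]
            assert set(cond.activity_ratios) == set(ENZYME_IDS)
            assert all(v == 1.0 for v in cond.activity_ratios.values())

    def test_published_ddc_values(self, conditions):
        aj = conditions[("AJ", "DDC")]
        assert aj.activity_ratios["ALOX5AP"] == 4.81
        assert aj.activity_ratios["PTGS1"] == 2.13
        assert aj.pc_concentration == 206.0
        assert conditions[("PWD", "DDC")].activity_ratios["GPX"] == 19.42
        assert conditions[("B6", "DDC")].activity_ratios["GPX"] == 11.70
        assert conditions[("B6", "control")].pc_concentration == 249.0

    def test_perk_mirrors_the_pla2_row(self, conditions):
        """The p-ERK activity carries the same RPPA-derived fold change that
        the initial-values table prints in its PLA2 row."""
        for strain in ("AJ", "B6", "PWD"):
            ddc = conditions[(strain, "DDC")]
            assert ddc.activity_ratios["PERK"] == ddc.activity_ratios["PLA2"]

    def test_control_condition_rejects_non_unit_ratio(self):
        ratios = {e: 1.0 for e in ENZYME_IDS}
        ratios["GPX"] = 2.0
        with pytest.raises(ValueError):
            StrainCondition("B6", "control", ratios, 249.0)

    def test_missing_enzyme_rejected(self):
        ratios = {e: 1.0 for e in ENZYME_IDS if e != "GPX"}
        with pytest.raises(ModelConsistencyError):
            StrainCondition("B6", "control", ratios, 249.0)
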