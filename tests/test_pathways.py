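"""Reaction network balancing, theoretical yields, extent decomposition."""

import pytest
import sympy
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from lactoferm.compounds import REGISTRY
from lactoferm.pathways import (
    PathwayExtents,
    Reaction,
    StoichiometryError,
    builtin_network,
    co2_recycled,
    decompose_cycle,
    decompose_extents,
    fermentation_only_ratio,
    predicted_ratio,
    reconstruct_deltas,
    theoretical_combined_yields,
)
from lactoferm.simulate import (
    LogisticExtent,
    SimCycle,
    SimulationParams,
    simulate_batch,
)


def oracle_balanced(rxn: Reaction) -> bool:
    """Independent atom-count oracle: a reaction over CcHhOo species (plus
    cathodic e- arriving as H+ + e-) is balanced iff integer H2O and H+
    coefficients exist that close C, H, O and charge simultaneously.

    Solved symbolically from the raw atom counts, without using the
    degree-of-reduction shortcut the implementation relies on.
    """
    c_net = h_net = o_net = 0
    for sp, coeff in rxn.stoichiometry.items():
        comp = REGISTRY.get(sp)
        c_net += coeff * comp.c_atoms
        h_net += coeff * comp.h_atoms
        o_net += coeff * comp.o_atoms
    w, p = sympy.symbols("w p")  # H2O produced, H+ consumed
    sol = sympy.solve(
        [
            sympy.Eq(o_net + w, 0),
            sympy.Eq(h_net + 2 * w - p, 0),
            sympy.Eq(p, rxn.electrons),  # each cathodic e- reduces one H+
        ],
        [w, p],
        dict=True,
    )
    return c_net == 0 and len(sol) == 1


class TestNetwork:
    def test_every_builtin_reaction_balances(self):
        for rxn in builtin_network():
            assert oracle_balanced(rxn), rxn.name

    def test_fermentation_coefficients(self):
        ferm = builtin_network()[0]
        assert ferm.stoichiometry == {
            "lactate": -3, "propionate": 2, "acetate": 1, "CO2": 1,
        }

    def test_chain_elongation_carbon_count(self):
        ce = {r.name: r for r in builtin_network()}["chain_elongation"]
        consumed = sum(
            -coeff * REGISTRY.get(sp).carbon_equiv
            for sp, coeff in ce.stoichiometry.items()
            if coeff < 0
        )
        produced = sum(
            coeff * REGISTRY.get(sp).carbon_equiv
            for sp, coeff in ce.stoichiometry.items()
            if coeff > 0
        )
        assert consumed == produced == 5

    def test_unbalanced_reaction_rejected(self):
        with pytest.raises(StoichiometryError, match="imbalance"):
            Reaction(name="bogus", stoichiometry={"lactate": -1, "acetate": 1})


class TestTheoreticalYields:
    def test_combined_mode(self):
        prop, ace, ratio = theoretical_combined_yields()
        assert prop == pytest.approx(2.0 / 3.0)
        assert ace == pytest.approx(0.5)
        assert ratio == pytest.approx(4.0 / 3.0)
        assert round(ratio, 2) == 1.33

    def test_fermentation_only(self):
        assert fermentation_only_ratio() == pytest.approx(2.0)

    def test_acetogenic_share_of_acetate(self):
        prop, ace, _ = theoretical_combined_yields()
        assert (ace - 1.0 / 3.0) / ace == pytest.approx(1.0 / 3.0)


class TestDecomposition:
    def test_hand_algebra(self):
        ext = decompose_extents(
            {"propionate": 12.0, "acetate": 9.0, "butyrate": 0.0}
        )
        assert ext.xi_ferm == pytest.approx(6.0)
        assert ext.xi_acet == pytest.approx(3.0)
        assert ext.co2_net == pytest.approx(0.0)
        assert ext.h2_demand == pytest.approx(12.0)
        assert ext.charge_demand == pytest.approx(24.0)

    def test_all_zero(self):
        ext = decompose_extents({})
        assert (ext.xi_ferm, ext.xi_acet, ext.xi_ce) == (0.0, 0.0, 0.0)

    def test_published_outlet_decomposition(self):
        """The high-substrate cell's outlet mmol decompose to the extents
        implied by its carbon ledger."""
        ext = decompose_extents(
            {"propionate": 9.7, "acetate": 6.2, "butyrate": 1.825}
        )
        assert ext.xi_ferm == pytest.approx(4.85)
        assert ext.xi_acet == pytest.approx(3.175)
        assert ext.xi_ce == pytest.approx(1.825)

    def test_negative_product_delta_rejected(self):
        with pytest.raises(StoichiometryError, match="window"):
            decompose_extents({"propionate": -1.0})

    def test_acetate_deficit_floors_acetogenesis(self):
        ext = decompose_extents({"propionate": 12.0, "acetate": 4.0})
        assert ext.xi_acet == 0.0
        assert ext.residual["acetate"] == pytest.approx(-2.0)
        assert ext.flags

    def test_lactate_residual_exposes_other_fates(self):
        ext = decompose_extents(
            {"propionate": 12.0, "acetate": 9.0, "lactate": -20.0}
        )
        # network demands 18 mmol; 2 more vanished (growth, aerobic loss)
        assert ext.residual["lactate"] == pytest.approx(-2.0)

    @settings(deadline=None, max_examples=200)
    @given(
        xi_ferm=st.floats(min_value=0.0, max_value=100.0),
        xi_acet=st.floats(min_value=0.0, max_value=100.0),
        xi_ce=st.floats(min_value=0.0, max_value=100.0),
    )
    def test_round_trip_identity(self, xi_ferm, xi_acet, xi_ce):
        """Reconstructing deltas from extents and re-decomposing recovers
        the extents exactly."""
        truth = PathwayExtents(xi_ferm=xi_ferm, xi_acet=xi_acet, xi_ce=xi_ce)
        deltas = reconstruct_deltas(truth)
        assume(deltas["acetate"] >= 0)
        ext = decompose_extents(
            {k: v for k, v in deltas.items() if k not in ("H2", "CO2")}
        )
        assert ext.xi_ferm == pytest.approx(xi_ferm, abs=1e-9)
        assert ext.xi_acet == pytest.approx(xi_acet, abs=1e-6)
        assert ext.xi_ce == pytest.approx(xi_ce, abs=1e-9)
        assert ext.residual["lactate"] == pytest.approx(0.0, abs=1e-6)


class TestPredictedRatio:
    def test_combined_mode_identity(self):
        ext = PathwayExtents(xi_ferm=6.0, xi_acet=3.0, xi_ce=0.0)
        assert predicted_ratio(ext) == pytest.approx(4.0 / 3.0)

    def test_fermentation_only_identity(self):
        ext = PathwayExtents(xi_ferm=6.0, xi_acet=0.0, xi_ce=0.0)
        assert predicted_ratio(ext) == pytest.approx(2.0)

    @settings(deadline=None, max_examples=50)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        a = PathwayExtents(xi_ferm=6.0, xi_acet=2.0, xi_ce=1.0)
        b = PathwayExtents(
            xi_ferm=6.0 * scale, xi_acet=2.0 * scale, xi_ce=1.0 * scale
        )
        assert predicted_ratio(b) == pytest.approx(predicted_ratio(a), rel=1e-9)

    def test_zero_denominator_rejected(self):
        with pytest.raises(StoichiometryError):
            predicted_ratio(PathwayExtents(xi_ferm=1.0, xi_acet=0.0, xi_ce=2.0))


class TestCO2Recycling:
    def test_two_co2_per_acetate(self):
        recycled, external, flag = co2_recycled(
            PathwayExtents(xi_ferm=6.0, xi_acet=3.0, xi_ce=0.0)
        )
        assert recycled == pytest.approx(6.0)
        assert external == 0.0
        assert not flag

    def test_zero_acetogenesis(self):
        recycled, external, flag = co2_recycled(
            PathwayExtents(xi_ferm=6.0, xi_acet=0.0, xi_ce=0.0)
        )
        assert recycled == external == 0.0

    def test_external_co2_capped_and_flagged(self):
        recycled, external, flag = co2_recycled(
            PathwayExtents(xi_ferm=6.0, xi_acet=4.0, xi_ce=0.0)
        )
        assert recycled == pytest.approx(6.0)
        assert external == pytest.approx(2.0)
        assert flag


class TestCycleDecomposition:
    def test_chain_elongation_cycle_recovered(self):
        params = SimulationParams(
            noise_sd_mm=0.0,
            cycles=(
                SimCycle(
                    duration_h=168.0,
                    lactate_restore_mm=30.0,
                    extents={
                        "fermentation": LogisticExtent(0.9),
                        "acetogenesis": LogisticExtent(0.3),
                        "chain_elongation": LogisticExtent(
                            0.2, midpoint_h=120.0
                        ),
                    },
                ),
            ),
        )
        exp, truth = simulate_batch(params)
        ext = decompose_cycle(exp, exp.cycles[0])
        assert ext.xi_ferm == pytest.approx(truth[0].xi_ferm, abs=1e-9)
        assert ext.xi_acet == pytest.approx(truth[0].xi_acet, abs=1e-6)
        assert ext.xi_ce == pytest.approx(truth[0].xi_ce, abs=1e-9)
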