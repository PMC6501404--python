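"""FBA/FVA correctness against analytic results, vertex enumeration, and cobrapy."""

import numpy as np
import pytest

from _oracles import lp_optimum_by_enumeration, to_cobra
from conftest import build_chain, build_diamond
from seraflux import fba, io, synthetic
from seraflux.model import MediumSpec


def _mass_balance_residual(model, solution):
    S, _ = model.stoichiometric_matrix()
    v = np.array([solution.fluxes[r.id] for r in model.reactions])
    return float(np.max(np.abs(S @ v))) if S.size else 0.0


class TestSolveFba:
    def test_linear_chain_has_unit_yield(self, chain3):
        sol = fba.solve_fba(chain3)
        assert sol.optimal
        assert sol.objective == pytest.approx(10.0)

    def test_no_inputs_no_growth(self, chain3):
        for rxn in chain3.exchange_reactions():
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
        sol = fba.solve_fba(chain3)
        assert sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_mass_balance_of_optimum(self, toy_core):
        sol = fba.solve_fba(toy_core)
        assert _mass_balance_residual(toy_core, sol) <= 1e-6

    def test_fluxes_within_bounds(self, toy_core):
        sol = fba.solve_fba(toy_core)
        for r in toy_core.reactions:
            assert r.lower_bound - 1e-6 <= sol.fluxes[r.id] <= r.upper_bound + 1e-6

    def test_doubling_uptake_doubles_growth(self):
        z1 = fba.solve_fba(build_chain(3, uptake=10.0)).objective
        z2 = fba.solve_fba(build_chain(3, uptake=20.0)).objective
        assert z2 == pytest.approx(2 * z1)

    def test_missing_objective_raises(self, chain3):
        chain3.objective_reaction_id = None
        with pytest.raises(ValueError):
            fba.solve_fba(chain3)

    @pytest.mark.parametrize(
        "builder", [lambda: build_chain(2), lambda: build_chain(4), build_diamond]
    )
    def test_optimum_matches_vertex_enumeration(self, builder):
        """On <= 8-reaction toys, the LP optimum equals the best vertex of
        the flux polytope found by exhaustive enumeration."""
        model = builder()
        assert len(model.reactions) <= 8
        sol = fba.solve_fba(model, minimize_total_flux=False)
        oracle = lp_optimum_by_enumeration(model, model.objective_reaction_id)
        assert sol.objective == pytest.approx(oracle, abs=1e-6)

    def test_optimum_matches_cobrapy(self, toy_core):
        cm = to_cobra(toy_core)
        cobra_sol = cm.optimize()
        ours = fba.solve_fba(toy_core)
        assert ours.objective == pytest.approx(cobra_sol.objective_value, rel=1e-6)

    def test_flux_minimised_vector_attains_same_optimum(self, toy_core):
        raw = fba.solve_fba(toy_core, minimize_total_flux=False)
        parsimonious = fba.solve_fba(toy_core, minimize_total_flux=True)
        assert parsimonious.objective == pytest.approx(raw.objective)
        total_raw = sum(abs(v) for v in raw.fluxes.values())
        total_min = sum(abs(v) for v in parsimonious.fluxes.values())
        assert total_min <= total_raw + 1e-6


class TestSolveFva:
    def test_single_path_ranges_collapse(self, chain3):
        res = fba.solve_fva(chain3, objective_fraction=1.0)
        z = res.objective
        for rid, (lo, hi) in res.ranges.items():
            if rid == "EX_s":
                assert (lo, hi) == pytest.approx((-z, -z))
            else:
                assert (lo, hi) == pytest.approx((z, z))

    def test_diamond_branches_span_zero_to_optimum(self, diamond):
        res = fba.solve_fva(diamond, objective_fraction=1.0)
        z = res.objective
        for rid in ("RA", "RB"):
            assert res.ranges[rid] == pytest.approx((0.0, z), abs=1e-6)

    def test_fraction_zero_recovers_reachable_bounds(self):
        """At objective fraction 0 the ranges equal what is reachable under
        S v = 0 alone, checked by vertex enumeration."""
        from _oracles import enumerate_vertices

        model = build_diamond()
        res = fba.solve_fva(model, objective_fraction=0.0)
        S, _ = model.stoichiometric_matrix()
        bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
        verts = enumerate_vertices(S, bounds)
        for j, rxn in enumerate(model.reactions):
            lo = min(v[j] for v in verts)
            hi = max(v[j] for v in verts)
            assert res.ranges[rxn.id] == pytest.approx((lo, hi), abs=1e-6)

    def test_fva_sandwiches_fba_fluxes(self, toy_core):
        sol = fba.solve_fba(toy_core)
        res = fba.solve_fva(toy_core, objective_fraction=1.0)
        for rid, (lo, hi) in res.ranges.items():
            assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6
            assert lo <= hi + 1e-9

    @pytest.mark.parametrize("fraction", [-0.1, 1.5])
    def test_fraction_outside_unit_interval_rejected(self, chain3, fraction):
        with pytest.raises(ValueError):
            fba.solve_fva(chain3, objective_fraction=fraction)


class TestMedium:
    def test_components_open_and_others_close(self, toy_core):
        medium = MediumSpec(components={"glc": 5.0}, carbon_source="glc")
        constrained = fba.apply_medium(toy_core, medium)
        assert constrained.get_reaction("EX_glc").lower_bound == -5.0
        sol = fba.solve_fba(constrained)
        assert sol.objective == pytest.approx(synthetic.TOY_CORE_OPTIMUM / 2)

    def test_empty_medium_closes_all_uptakes(self, toy_core):
        constrained = fba.apply_medium(toy_core, MediumSpec())
        sol = fba.solve_fba(constrained)
        assert sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_unconsumed_component_leaves_growth_unchanged(self, toy_core):
        base = fba.apply_medium(toy_core, MediumSpec(components={"glc": 10.0}))
        # carbon dioxide uptake is never useful to this network
        extra = fba.apply_medium(
            toy_core, MediumSpec(components={"glc": 10.0, "co2": 10.0})
        )
        assert fba.solve_fba(extra).objective == pytest.approx(
            fba.solve_fba(base).objective
        )

    def test_component_without_exchange_is_an_error(self, toy_core):
        with pytest.raises(KeyError, match="unobtainium"):
            fba.apply_medium(toy_core, MediumSpec(components={"unobtainium": 1.0}))


class TestMeasuredExchanges:
    def test_zero_tolerance_pins_flux(self, toy_core):
        sol = fba.solve_fba(toy_core)
        pinned = fba.constrain_measured_exchanges(
            toy_core, {"EX_glc": (sol.fluxes["EX_glc"], 0.0)}
        )
        res = fba.solve_fva(pinned, objective_fraction=1.0, reactions=["EX_glc"])
        lo, hi = res.ranges["EX_glc"]
        assert lo == pytest.approx(hi)

    def test_progressive_constraints_narrow_secretion_ranges(self, toy_core):
        """Pinning one by-product narrows (never widens) the FVA ranges of
        the others, mirroring the progressively-constrained protocol."""
        free = fba.solve_fva(toy_core, objective_fraction=1.0,
                             reactions=["EX_ac", "EX_etoh"])
        mid_ac = sum(free.ranges["EX_ac"]) / 2
        pinned = fba.constrain_measured_exchanges(toy_core, {"EX_ac": (mid_ac, 0.0)})
        after = fba.solve_fva(pinned, objective_fraction=1.0, reactions=["EX_etoh"])
        w_before = free.ranges["EX_etoh"][1] - free.ranges["EX_etoh"][0]
        w_after = after.ranges["EX_etoh"][1] - after.ranges["EX_etoh"][0]
        assert w_after <= w_before + 1e-6

    def test_conservation_violating_measurements_are_infeasible(self, chain3):
        # 10 units in but 0 allowed out at the biomass drain
        bad = fba.constrain_measured_exchanges(
            chain3, {"EX_s": (-10.0, 0.0), "BIOMASS": (0.0, 0.0)}
        )
        sol = fba.solve_fba(bad)
        assert sol.status == "infeasible"

    def test_negative_tolerance_rejected(self, chain3):
        with pytest.raises(ValueError):
            fba.constrain_measured_exchanges(chain3, {"EX_s": (0.0, -1.0)})


class TestGapDetection:
    def test_chain_missing_sink_flags_dead_end_and_blocks_upstream(self):
        m = io.parse_model_file(
            "EX_a: a_e <=> a_b\nT: a_e --> b_c\nR1: b_c --> c_c\n"
        )
        assert fba.find_dead_end_metabolites(m) == ["c_c"]
        # the dead end propagates: nothing upstream, exchange included,
        # can carry steady-state flux
        blocked = fba.find_blocked_reactions(m)
        assert set(blocked) == {"EX_a", "T", "R1"}

    def test_fully_connected_toy_has_no_gaps(self, toy_core):
        assert fba.find_dead_end_metabolites(toy_core) == []
        assert fba.find_blocked_reactions(toy_core) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_blocked_reactions_agree_with_cobrapy(self, seed):
        """Random ~20-reaction networks: blocked-reaction calls match the
        independent cobrapy implementation."""
        from cobra.flux_analysis import find_blocked_reactions as cobra_blocked

        model = synthetic.make_random_model(
            synthetic.SyntheticSpec(seed=seed, n_reactions=20)
        )
        opened = model.copy()
        for rxn in opened.exchange_reactions():
            rxn.lower_bound, rxn.upper_bound = -1000.0, 1000.0
        ours = set(fba.find_blocked_reactions(model, open_exchanges=True))
        theirs = set(cobra_blocked(to_cobra(opened), open_exchanges=False))
        assert ours == theirs
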