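"""Expression discretization, the geometric cutoff grid, and flux integration."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import imat_brute_force
from conftest import build_chain
from seraflux import expression as expr, fba, synthetic
from seraflux.model import Gpr


def _table(values: dict[str, dict[str, float]]) -> expr.ExpressionTable:
    return expr.ExpressionTable(pd.DataFrame(values))


class TestBinGrid:
    def test_first_cutoff_is_one_and_ratio_constant(self):
        grid = expr.build_bin_grid(base=1.2, n=58)
        assert grid.cutoffs[0] == 1.0
        assert len(grid.cutoffs) == 58
        ratios = np.diff(np.log(grid.cutoffs))
        assert np.allclose(ratios, np.log(1.2))

    def test_cutoff_37_matches_upper_threshold(self):
        grid = expr.build_bin_grid(base=1.2, n=58)
        assert round(grid.cutoffs[37], 2) == 850.56

    @pytest.mark.parametrize("base,n", [(1.0, 58), (0.9, 58), (1.2, 1)])
    def test_degenerate_grids_rejected(self, base, n):
        with pytest.raises(ValueError):
            expr.build_bin_grid(base=base, n=n)


class TestLowerCutoffSelection:
    def test_planted_decile_selects_grid_value_near_three(self):
        genes = [f"g{i}" for i in range(2000)]
        spec = synthetic.SyntheticSpec(seed=5, conditions=("c1", "c2"))
        table = synthetic.make_expression_table(genes, spec)
        gamma, achieved = expr.select_lower_cutoff(table, target_excluded_fraction=0.10)
        grid = expr.build_bin_grid()
        # the generator plants ~10% of genes below 3.00 in every condition
        assert gamma in grid.cutoffs
        assert 1.2**4 <= gamma <= 1.2**9
        assert achieved >= 0.10

    def test_target_zero_returns_first_cutoff(self):
        table = _table({"c": {"g1": 5.0, "g2": 10.0}})
        gamma, achieved = expr.select_lower_cutoff(table, target_excluded_fraction=0.0)
        assert gamma == 1.0 and achieved == 0.0

    def test_empty_table_rejected(self):
        table = _table({"c": {"g1": 1.0}})
        table.data = table.data.iloc[0:0]
        with pytest.raises(ValueError):
            expr.select_lower_cutoff(table)


class TestDiscretization:
    thresholds = expr.DiscretizationThresholds(3.00, 850.56)

    @pytest.mark.parametrize(
        "g,state",
        [
            (0.0, -1),          # unexpressed is always low
            (2.99, -1),
            (3.00, 0),          # boundary inclusive to moderate
            (850.56, 0),
            (967.20, 1),        # the GlcNAc transporter level is high
            (1e6, 1),
        ],
    )
    def test_state_assignment(self, g, state):
        assert expr.discretize_gene(g, self.thresholds) == state

    def test_negative_rpkm_rejected(self):
        with pytest.raises(ValueError):
            expr.discretize_gene(-1.0, self.thresholds)

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            expr.DiscretizationThresholds(10.0, 5.0)

    def test_discretization_partitions_genes(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([[0.0] * 10, rng.lognormal(4, 2, 500)])
        states = [expr.discretize_gene(g, self.thresholds) for g in values]
        counts = {s: states.count(s) for s in (-1, 0, 1)}
        assert sum(counts.values()) == len(values)

    @given(st.floats(min_value=0.0, max_value=1e9, allow_nan=False))
    @settings(deadline=None, derandomize=True, max_examples=300)
    def test_every_rpkm_maps_to_exactly_one_state(self, g):
        th = expr.DiscretizationThresholds()
        state = expr.discretize_gene(g, th)
        assert state in (-1, 0, 1)
        assert (state == -1) == (g < th.gamma_low)
        assert (state == 1) == (g > th.gamma_high)

    @given(
        st.floats(min_value=0.0, max_value=1e6, allow_nan=False),
        st.floats(min_value=1e-3, max_value=1e3),
        st.floats(min_value=1.0, max_value=1e3),
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_state_is_monotone_in_the_expression_level(self, g, lo, span):
        th = expr.DiscretizationThresholds(lo, lo + span)
        assert expr.discretize_gene(g, th) <= expr.discretize_gene(g + 1.0, th)

    def test_raising_gamma_high_never_adds_high_genes(self):
        rng = np.random.default_rng(1)
        values = rng.lognormal(4, 2, 500)
        n_high_prev = None
        for gamma_high in (100.0, 850.56, 5000.0):
            th = expr.DiscretizationThresholds(3.00, gamma_high)
            n_high = sum(expr.discretize_gene(g, th) == 1 for g in values)
            if n_high_prev is not None:
                assert n_high <= n_high_prev
            n_high_prev = n_high


class TestClampMode:
    def test_all_moderate_states_change_nothing(self, toy_core):
        states = {g: 0 for g in toy_core.genes}
        constrained = expr.apply_expression_constraints(toy_core, states, mode="clamp")
        z0 = fba.solve_fba(toy_core).objective
        z1 = fba.solve_fba(constrained).objective
        assert z1 == pytest.approx(z0)
        for r in toy_core.reactions:
            rc = constrained.get_reaction(r.id)
            assert (rc.lower_bound, rc.upper_bound) == (r.lower_bound, r.upper_bound)

    def test_low_state_on_sole_path_kills_growth(self, chain3):
        states = {g: 0 for g in chain3.genes}
        states["g2"] = -1
        constrained = expr.apply_expression_constraints(chain3, states, mode="clamp")
        assert fba.solve_fba(constrained).objective == pytest.approx(0.0, abs=1e-9)

    def test_low_state_reactions_carry_zero_flux_in_any_solution(self, toy_core, core_rpkm):
        """Soundness of the clamp: a state -1 reaction has FVA range {0}."""
        states = expr.gene_states_for_condition(core_rpkm, "glcnac")
        constrained = expr.apply_expression_constraints(toy_core, states, mode="clamp")
        rstates = constrained.annotations["expression_states"]
        low = [rid for rid, s in rstates.items() if s == -1]
        assert low  # the profile plants at least the TCA entry gene low
        res = fba.solve_fva(constrained, objective_fraction=0.0, reactions=low)
        for rid in low:
            lo, hi = res.ranges[rid]
            assert abs(lo) <= 1e-9 and abs(hi) <= 1e-9

    def test_high_state_extends_capacity_without_forcing_flux(self):
        model = build_chain(2)
        model.get_reaction("R1").upper_bound = 50.0
        states = {"g1": 1}
        constrained = expr.apply_expression_constraints(model, states, mode="clamp")
        assert constrained.get_reaction("R1").upper_bound == 1000.0
        assert constrained.get_reaction("R1").lower_bound == 0.0  # irreversible stays

    def test_biomass_never_clamped(self, chain3):
        chain3.get_reaction("BIOMASS").gpr = Gpr.gene_("gBM")
        states = {"gBM": -1}
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            constrained = expr.apply_expression_constraints(chain3, states, mode="clamp")
        assert any("biomass" in str(w.message).lower() for w in caught)
        assert constrained.get_reaction("BIOMASS").upper_bound > 0


class TestImatMode:
    @pytest.mark.parametrize("seed", range(4))
    def test_agreement_matches_brute_force_on_small_networks(self, seed):
        rng = np.random.default_rng(seed)
        model = build_chain(3)
        genes = model.genes
        states = {g: int(rng.integers(-1, 2)) for g in genes}
        problem = expr.apply_expression_constraints(model, states, mode="imat")
        n_constrained = len(problem.high_reactions) + len(problem.low_reactions)
        solution = problem.solve()
        assert solution.optimal
        assert solution.agreement <= n_constrained
        assert solution.agreement == imat_brute_force(problem)

    def test_satisfiable_constraints_all_rewarded(self, chain3):
        states = {g: 1 for g in chain3.genes}  # all on one feasible path
        problem = expr.apply_expression_constraints(chain3, states, mode="imat")
        solution = problem.solve()
        assert solution.agreement == len(problem.high_reactions)
        # every rewarded reaction really carries >= epsilon flux
        for rid in problem.high_reactions:
            assert abs(solution.fluxes[rid]) >= problem.epsilon - 1e-6

    def test_boundary_flux_satisfies_high_and_low_at_once(self):
        """At |v| = epsilon a reaction counts as both 'carrying flux' and
        'nearly silent', so a mixed chain is fully satisfiable."""
        model = build_chain(3)
        states = {"gT": 1, "g1": 1, "g2": -1, "g3": 1}
        problem = expr.apply_expression_constraints(model, states, mode="imat")
        solution = problem.solve()
        assert solution.agreement == 4
        assert solution.agreement == imat_brute_force(problem)

    def test_forced_throughput_sacrifices_minority_constraint(self):
        """When the chain must carry flux well above epsilon, the low state
        on the middle step cannot be honoured and the MILP drops it."""
        model = build_chain(3)
        model.get_reaction("BIOMASS").lower_bound = 5.0
        states = {"gT": 1, "g1": 1, "g2": -1, "g3": 1}
        problem = expr.apply_expression_constraints(model, states, mode="imat")
        solution = problem.solve()
        assert solution.agreement == 3
        assert solution.indicators["R2"] == 0
        assert solution.agreement == imat_brute_force(problem)

    def test_unknown_mode_rejected(self, chain3):
        with pytest.raises(ValueError):
            expr.apply_expression_constraints(chain3, {}, mode="gimme")


class TestActiveReactionReport:
    def test_zero_solution_has_no_active_reactions(self, toy_core):
        sol = fba.FluxSolution("optimal", 0.0, {r.id: 0.0 for r in toy_core.reactions})
        report = expr.active_reaction_report(toy_core, sol)
        assert report.total == 0 and report.subsystem_counts == {}

    def test_counts_partition_total(self, toy_core):
        sol = fba.solve_fba(toy_core)
        report = expr.active_reaction_report(toy_core, sol)
        assert report.total == sum(report.subsystem_counts.values())
        assert report.total == len(report.active)

    def test_exchanges_and_biomass_excluded(self, toy_core):
        sol = fba.solve_fba(toy_core)
        report = expr.active_reaction_report(toy_core, sol)
        assert "Exchange" not in report.subsystem_counts
        assert "Biomass" not in report.subsystem_counts


class TestFoldChange:
    table = _table(
        {
            "glucose": {"SMDB11_4022": 59.20, "SMDB11_3886": 28.10, "SMDB11_0473": 80.23},
            "glcnac": {"SMDB11_4022": 71.28, "SMDB11_3886": 30.78, "SMDB11_0473": 967.20},
            "glycerol": {"SMDB11_4022": 4535.25, "SMDB11_3886": 1683.89, "SMDB11_0473": 188.36},
        }
    )

    def test_glycerol_kinase_fold_change(self):
        fc = expr.fold_change(self.table, "SMDB11_4022", "glycerol", "glucose")
        assert fc.value == 76.6 and not fc.infinite

    def test_g3p_dehydrogenase_fold_change(self):
        fc = expr.fold_change(self.table, "SMDB11_3886", "glycerol", "glucose")
        assert fc.value == 59.9

    def test_nag_transporter_fold_change_two_decimals(self):
        fc = expr.fold_change(self.table, "SMDB11_0473", "glcnac", "glycerol", ndigits=2)
        assert fc.value == 5.13

    def test_self_ratio_is_one(self):
        fc = expr.fold_change(self.table, "SMDB11_4022", "glucose", "glucose")
        assert fc.value == 1.0

    def test_zero_denominator_flagged_infinite(self):
        t = _table({"a": {"g": 5.0}, "b": {"g": 0.0}})
        fc = expr.fold_change(t, "g", "a", "b")
        assert fc.infinite and fc.value == float("inf")
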