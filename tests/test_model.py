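"""FBA core: optima vs the exact vertex-enumeration oracle, knockout
semantics, constraint satisfaction of reported solutions."""

from fractions import Fraction

import numpy as np
import pytest

from lp_oracle import fba_exact, min_at_fixed_exact
from warburgflux.model import (
    InfeasibleModelError,
    Reaction,
    StoichiometricModel,
    Metabolite,
    flux_extremum,
    flux_variability,
    knockout_gene,
    knockout_reaction,
    solve_fba,
)


def test_micro3_bottleneck(micro3):
    sol = solve_fba(micro3)
    assert sol.optimal
    assert sol.objective_value == pytest.approx(10.0, abs=1e-9)


def test_micro3_broken_chain(micro3):
    assert solve_fba(knockout_reaction(micro3, "AB")).objective_value == pytest.approx(0.0, abs=1e-9)


def test_objectives_match_exact_oracle(micro3, parallel_path, warburg_mini):
    """scipy optima equal brute-force vertex enumeration on all small fixtures."""
    for model in (micro3, parallel_path, warburg_mini):
        expected = float(fba_exact(model))
        assert solve_fba(model).objective_value == pytest.approx(expected, abs=1e-8)


def test_warburg_mini_forced_lactate_vs_oracle(warburg_mini):
    mu = solve_fba(warburg_mini).objective_value
    assert mu == pytest.approx(5.0, abs=1e-9)
    lac = flux_extremum(warburg_mini, "EX_lac", "min", fixed={"EX_biomass": (mu, 1e-9)})
    expected = float(min_at_fixed_exact(warburg_mini, "EX_lac", {"EX_biomass": 5}))
    assert expected == 15.0
    assert lac == pytest.approx(expected, abs=1e-6)


def test_unconstrained_oxygen_removes_forcing(warburg_mini):
    free = warburg_mini.with_reaction_bounds("EX_o2", 0, 1000)
    mu = solve_fba(free).objective_value
    assert mu == pytest.approx(float(Fraction(110, 7)), abs=1e-8)
    lac = flux_extremum(free, "EX_lac", "min", fixed={"EX_biomass": (mu, 1e-9)})
    assert lac == pytest.approx(0.0, abs=1e-6)


def test_optimal_solutions_satisfy_constraints(micro3, parallel_path, warburg_mini, toy_core):
    for model in (micro3, parallel_path, warburg_mini, toy_core):
        sol = solve_fba(model)
        balance, violation = model.check_fluxes(sol.fluxes)
        assert balance <= 1e-6
        assert violation <= 1e-9


def test_flux_extremum_min_le_max(warburg_mini):
    mu = solve_fba(warburg_mini).objective_value
    fixed = {"EX_biomass": (mu, 1e-9)}
    for rid in warburg_mini.reaction_ids:
        lo = flux_extremum(warburg_mini, rid, "min", fixed=fixed)
        hi = flux_extremum(warburg_mini, rid, "max", fixed=fixed)
        assert lo <= hi + 1e-9


def test_fixing_to_infeasible_value_names_constraint(warburg_mini):
    with pytest.raises(InfeasibleModelError, match="EX_biomass"):
        flux_extremum(warburg_mini, "EX_lac", "min", fixed={"EX_biomass": (50.0, 1e-9)})


def test_min_of_knocked_out_reaction_is_zero(warburg_mini):
    ko = knockout_reaction(warburg_mini, "TCA")
    assert flux_extremum(ko, "TCA", "min") == pytest.approx(0.0, abs=1e-12)


class TestKnockouts:
    def test_ldh_knockout_matches_oracle(self, warburg_mini):
        ko = knockout_reaction(warburg_mini, "LDH")
        expected = float(fba_exact(ko))
        assert expected == pytest.approx(55 / 26)
        assert solve_fba(ko).objective_value == pytest.approx(expected, abs=1e-8)

    def test_gly_knockout_kills_growth(self, warburg_mini):
        ko = knockout_reaction(warburg_mini, "GLY")
        assert solve_fba(ko).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_original_model_untouched(self, warburg_mini):
        before = warburg_mini.get_reaction("LDH").upper_bound
        knockout_reaction(warburg_mini, "LDH")
        assert warburg_mini.get_reaction("LDH").upper_bound == before

    def test_idempotent_on_closed_reaction(self, warburg_mini):
        once = knockout_reaction(warburg_mini, "TCA")
        twice = knockout_reaction(once, "TCA")
        assert [r.upper_bound for r in once.reactions] == [r.upper_bound for r in twice.reactions]

    def test_unknown_reaction_raises(self, warburg_mini):
        with pytest.raises(KeyError):
            knockout_reaction(warburg_mini, "NOPE")

    def test_knockout_never_increases_optimum(self, warburg_mini, toy_core):
        for model in (warburg_mini, toy_core):
            wt = solve_fba(model).objective_value
            for r in model.reactions:
                if r.id == model.objective_reaction:
                    continue
                sol = solve_fba(knockout_reaction(model, r.id))
                ko = sol.objective_value if sol.optimal else 0.0
                assert ko <= wt + 1e-6


class TestGeneKnockouts:
    def test_isoenzyme_backup_keeps_reaction_open(self, warburg_mini):
        m = knockout_gene(warburg_mini, {"gLDH1"})
        assert m.get_reaction("LDH").upper_bound > 0

    def test_both_isoenzymes_close_reaction(self, warburg_mini):
        m = knockout_gene(warburg_mini, {"gLDH1", "gLDH2"})
        assert m.get_reaction("LDH").upper_bound == 0

    def test_and_rule_single_gene_closes(self, toy_core):
        m = knockout_gene(toy_core, {"gENO"})
        assert m.get_reaction("PYK").upper_bound == 0

    def test_unknown_gene_warns_and_is_noop(self, warburg_mini):
        with pytest.warns(UserWarning, match="gNOT_A_GENE"):
            m = knockout_gene(warburg_mini, {"gNOT_A_GENE"})
        assert [r.upper_bound for r in m.reactions] == [r.upper_bound for r in warburg_mini.reactions]


def test_medium_only_tightens_exchange_bounds():
    base = StoichiometricModel(
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("EX_A", {"A": 1}, 0, 10, is_exchange=True),
            Reaction("AB", {"A": -1, "B": 1}),
            Reaction("EX_B", {"B": -1}, 0, 1000, is_exchange=True),
        ],
        objective_reaction="EX_B",
        medium={"EX_A": 4},
    )
    assert base.get_reaction("EX_A").upper_bound == 4
    wide = StoichiometricModel(
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("EX_A", {"A": 1}, 0, 10, is_exchange=True),
            Reaction("AB", {"A": -1, "B": 1}),
            Reaction("EX_B", {"B": -1}, 0, 1000, is_exchange=True),
        ],
        objective_reaction="EX_B",
        medium={"EX_A": 50},
    )
    assert wide.get_reaction("EX_A").upper_bound == 10  # cannot loosen


def test_invalid_reactions_rejected():
    with pytest.raises(ValueError):
        Reaction("r", {"A": 1}, lower_bound=1, upper_bound=0)
    with pytest.raises(ValueError):
        Reaction("r", {"A": 0})
    with pytest.raises(ValueError):
        Reaction("r", {"A": 1, "B": -1}, is_exchange=True)


def test_flux_variability_brackets_optimal_vertex(parallel_path):
    mu = solve_fba(parallel_path).objective_value
    fva = flux_variability(parallel_path, ["PATH_X"], fixed={"EX_B": (mu, 1e-9)})
    lo, hi = fva["PATH_X"]
    assert lo == pytest.approx(0.0, abs=1e-6)
    assert hi == pytest.approx(10.0, abs=1e-6)
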