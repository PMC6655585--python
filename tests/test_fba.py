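"""Growth, viability, essentiality and flux-variability behaviour."""

import itertools

import numpy as np
import pytest

from syntro import fba
from syntro.model import Metabolism, Reaction, Metabolite
from syntro.synthdata import _module_reactions_from_universe

from conftest import make_toy_universe


class TestGrowth:
    def test_growth_equals_uptake_bound_on_linear_toy(self, toy_universe, toy_metabolism):
        assert fba.growth(toy_metabolism, toy_universe, "S_e") == pytest.approx(10.0)
        assert fba.growth(
            toy_metabolism, toy_universe, "S_e", carbon_uptake_bound=2.5
        ) == pytest.approx(2.5)

    def test_growth_at_threshold_is_zero(self, toy_universe, toy_metabolism):
        # the toy's yield equals the uptake bound, so a bound of exactly
        # 0.001 puts the optimum at the threshold: strict exceedance fails
        assert fba.growth(toy_metabolism, toy_universe, "S_e",
                          carbon_uptake_bound=0.001) == 0.0
        assert not fba.is_viable(toy_metabolism, toy_universe, "S_e",
                                 carbon_uptake_bound=0.001)
        assert fba.is_viable(toy_metabolism, toy_universe, "S_e",
                             carbon_uptake_bound=0.002)

    def test_no_transport_means_no_growth(self, default_universe):
        spec, universe, seeds = default_universe
        # the seed for C1 has no transport for C4: no carbon influx
        assert fba.growth(seeds["C1_e"], universe, "C4_e") == 0.0

    def test_biomass_only_metabolism_not_viable(self, toy_universe):
        m = Metabolism(frozenset({"BIO"}), primary_carbon_source="S_e")
        assert not fba.is_viable(m, toy_universe, "S_e")


class TestViabilityProfile:
    def test_profile_contains_primary_for_seeds(self, default_universe):
        spec, universe, seeds = default_universe
        for source, seed in seeds.items():
            profile = fba.viability_profile(seed, universe, spec.carbon_sources)
            assert source in profile.viable_sources

    def test_engineered_profile_of_exactly_two_sources(self, default_universe):
        spec, universe, seeds = default_universe
        m = seeds["C1_e"]
        extra = _module_reactions_from_universe(universe, 2)
        m2 = m.replace(reaction_ids=m.reaction_ids | extra)
        profile = fba.viability_profile(m2, universe, spec.carbon_sources)
        # C1 and C2 share hub H1; the added module makes exactly C2 viable
        assert profile.viable_sources == {"C1_e", "C2_e"}
        assert profile.additional_sources == {"C2_e"}

    def test_empty_profile_for_biomass_only(self, default_universe):
        spec, universe, _ = default_universe
        m = Metabolism(frozenset({universe.biomass_reaction_id}))
        profile = fba.viability_profile(m, universe, spec.carbon_sources)
        assert profile.viable_sources == frozenset()

    def test_viability_monotone_under_addition(self, default_universe, rng):
        spec, universe, seeds = default_universe
        m = seeds["C2_e"]
        absent = sorted(universe.reactions.keys() - m.reaction_ids)
        for _ in range(10):
            extra = rng.choice(absent, size=5, replace=False)
            bigger = m.replace(reaction_ids=m.reaction_ids | set(map(str, extra)))
            assert fba.is_viable(bigger, universe, "C2_e")


class TestEssentialReactions:
    def test_every_reaction_essential_on_linear_toy(self, toy_universe, toy_metabolism):
        essential = fba.essential_reactions(toy_metabolism, toy_universe, "S_e")
        assert essential == {"T", "R", "BIO"}

    def test_parallel_route_reactions_not_essential(self, default_universe):
        spec, universe, seeds = default_universe
        m = seeds["C1_e"]
        essential = fba.essential_reactions(m, universe, "C1_e")
        # step 0 of C1 has a direct route and a two-reaction detour: no
        # single chain reaction is essential, but the sole transport is
        assert "R_C1_s0_r0" not in essential
        assert "T_C1_1" in essential
        assert universe.biomass_reaction_id in essential

    def test_nonviable_input_raises(self, default_universe):
        spec, universe, seeds = default_universe
        with pytest.raises(fba.NonviableError):
            fba.essential_reactions(seeds["C1_e"], universe, "C4_e")

    def test_deleting_essential_reaction_is_lethal(self, default_universe):
        spec, universe, seeds = default_universe
        m = seeds["C2_e"]
        essential = fba.essential_reactions(m, universe, "C2_e")
        essential = essential - {universe.biomass_reaction_id}
        for rid in sorted(essential)[:5]:
            smaller = m.replace(reaction_ids=m.reaction_ids - {rid})
            assert not fba.is_viable(smaller, universe, "C2_e")


class TestZeroFluxReactions:
    def test_linear_toy_has_none(self, toy_universe, toy_metabolism):
        assert fba.zero_flux_reactions(toy_metabolism, toy_universe, "S_e") == frozenset()

    def test_dangling_branch_is_zero_flux(self):
        universe = make_toy_universe(
            extra_reactions=[Reaction("SIDE", {"P": -1.0, "W": 1.0})],
            extra_metabolites=[Metabolite("W")],
        )
        m = Metabolism(frozenset({"T", "R", "BIO", "SIDE"}), primary_carbon_source="S_e")
        # W is a dead end: any flux into it would strand mass
        assert fba.zero_flux_reactions(m, universe, "S_e") == {"SIDE"}

    def test_decoys_are_zero_flux_in_seeds(self, default_universe):
        spec, universe, seeds = default_universe
        m = seeds["C1_e"]
        zero = fba.zero_flux_reactions(m, universe, "C1_e")
        decoys = {rid for rid in m.reaction_ids if rid.startswith("DK")}
        assert decoys <= zero

    def test_deleting_zero_flux_preserves_viability(self, default_universe):
        spec, universe, seeds = default_universe
        m = seeds["C3_e"]
        zero = fba.zero_flux_reactions(m, universe, "C3_e")
        for rid in sorted(zero):
            smaller = m.replace(reaction_ids=m.reaction_ids - {rid})
            assert fba.is_viable(smaller, universe, "C3_e")

    def test_disjoint_from_essential(self, default_universe):
        spec, universe, seeds = default_universe
        m = seeds["C5_e"]
        zero = fba.zero_flux_reactions(m, universe, "C5_e")
        essential = fba.essential_reactions(m, universe, "C5_e")
        assert zero & essential == frozenset()


def _reachability_viable(universe, reaction_ids, carbon_source):
    """Independent viability oracle for irreversible tree-like universes:
    iteratively close the producible-metabolite set and require every
    biomass substrate to be reachable."""
    available = {carbon_source} | set(universe.medium_metabolites)
    changed = True
    while changed:
        changed = False
        for rid in reaction_ids:
            rxn = universe.reactions[rid]
            if rxn.is_biomass:
                continue
            consumed = {m for m, c in rxn.stoichiometry.items() if c < 0}
            produced = {m for m, c in rxn.stoichiometry.items() if c > 0}
            if consumed <= available and not produced <= available:
                available |= produced
                changed = True
    bio = universe.reactions[universe.biomass_reaction_id]
    needed = {m for m, c in bio.stoichiometry.items() if c < 0}
    return universe.biomass_reaction_id in reaction_ids and needed <= available


def test_lp_viability_matches_reachability_oracle(tiny_universe, rng):
    """On a small acyclic universe, FBA viability equals set-reachability."""
    spec, universe, seeds = tiny_universe
    all_ids = sorted(universe.reactions)
    assert len(all_ids) <= 20
    bio = universe.biomass_reaction_id
    agree = 0
    for _ in range(100):
        k = int(rng.integers(1, len(all_ids)))
        subset = set(map(str, rng.choice(all_ids, size=k, replace=False))) | {bio}
        m = Metabolism(frozenset(subset), primary_carbon_source="C1_e")
        lp = fba.is_viable(m, universe, "C1_e")
        oracle = _reachability_viable(universe, subset, "C1_e")
        assert lp == oracle
        agree += 1
    assert agree == 100
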