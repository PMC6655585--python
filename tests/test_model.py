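"""Domain types, stoichiometric assembly, and universe serialization."""

import numpy as np
import pytest

from syntro import fba
from syntro.model import (
    EXCHANGE_PREFIX,
    Environment,
    Metabolism,
    Metabolite,
    ModelError,
    Reaction,
    ReactionUniverse,
    ResolutionError,
    UniverseFormatError,
    build_system,
    metabolism_from_dict,
    metabolism_to_dict,
    read_population,
    read_universe,
    write_population,
    write_universe,
)


class TestDomainTypes:
    def test_empty_stoichiometry_rejected(self):
        with pytest.raises(ModelError):
            Reaction("bad", {})

    def test_duplicate_reaction_ids_rejected(self):
        r = Reaction("r", {"a": -1.0, "b": 1.0})
        with pytest.raises(ModelError, match="duplicate"):
            ReactionUniverse(
                [r, Reaction("r", {"a": -1.0, "b": 1.0}, is_biomass=True)],
                [Metabolite("a"), Metabolite("b")],
            )

    def test_two_biomass_reactions_rejected(self):
        with pytest.raises(ModelError, match="multiple biomass"):
            ReactionUniverse(
                [
                    Reaction("b1", {"a": -1.0}, is_biomass=True),
                    Reaction("b2", {"a": -1.0}, is_biomass=True),
                ],
                [Metabolite("a")],
            )

    def test_transport_must_touch_extracellular(self):
        with pytest.raises(ModelError, match="transport"):
            ReactionUniverse(
                [
                    Reaction("t", {"a": -1.0, "b": 1.0}, is_transport=True),
                    Reaction("bio", {"b": -1.0}, is_biomass=True),
                ],
                [Metabolite("a"), Metabolite("b")],
            )

    def test_unknown_metabolite_rejected(self):
        with pytest.raises(ResolutionError):
            ReactionUniverse(
                [Reaction("bio", {"ghost": -1.0}, is_biomass=True)], [Metabolite("a")]
            )

    def test_environment_invariants(self):
        with pytest.raises(ModelError):
            Environment(carbon_source="c", carbon_uptake_bound=-1.0)
        with pytest.raises(ModelError):
            Environment(carbon_source="c", medium_metabolites={"c"})

    def test_metabolism_validate(self, toy_universe):
        Metabolism(frozenset({"T", "R", "BIO"})).validate(toy_universe)
        with pytest.raises(ModelError):
            Metabolism(frozenset({"T", "R"})).validate(toy_universe)
        with pytest.raises(ResolutionError):
            Metabolism(frozenset({"T", "R", "BIO", "ghost"})).validate(toy_universe)


class TestBuildSystem:
    def test_toy_system_structure(self, toy_universe, toy_metabolism):
        env = toy_universe.environment("S_e")
        system = build_system(toy_metabolism, toy_universe, env)
        # 3 reaction columns + one exchange column per extracellular metabolite
        assert len(system.col_ids) == 3 + len(toy_universe.extracellular_ids)
        assert system.col_ids[system.objective_col] == "BIO"
        j = system.col_index[EXCHANGE_PREFIX + "S_e"]
        assert system.lb[j] == -env.carbon_uptake_bound  # bounded uptake
        j_bio = system.col_index[EXCHANGE_PREFIX + "BIO_e"]
        assert system.lb[j_bio] == 0.0  # secretion only

    def test_missing_transport_blocks_carbon_influx(self, toy_universe):
        m = Metabolism(frozenset({"R", "BIO"}), primary_carbon_source="S_e")
        system = build_system(m, toy_universe, toy_universe.environment("S_e"))
        # no reaction column carries the carbon source inward; only its
        # environment exchange column touches it
        row = toy_universe.metabolite_index("S_e")
        touching = [
            system.col_ids[j]
            for j in range(len(system.col_ids))
            if system.A[row, j] != 0
        ]
        assert touching == [EXCHANGE_PREFIX + "S_e"]
        assert fba.growth(m, toy_universe, "S_e") == 0.0

    def test_seed_optimum_matches_hand_computed_yield(self, default_universe):
        # one unit of carbon traverses the chain 1:1 into the hub; biomass
        # consumes one unit of each precursor, so 10 carbon units support a
        # biomass flux of 10 / n_precursors
        spec, universe, seeds = default_universe
        g = fba.growth(seeds["C1_e"], universe, "C1_e")
        assert g == pytest.approx(10.0 / spec.n_biomass_precursors, abs=1e-9)

    def test_mass_balance_at_optimum(self, default_universe):
        spec, universe, seeds = default_universe
        system = build_system(seeds["C2_e"], universe, universe.environment("C2_e"))
        sol = fba.solve_system(system)
        assert sol.status == "optimal"
        v = np.array([sol.fluxes[c] for c in system.col_ids])
        residual = system.A @ v
        assert np.max(np.abs(residual)) <= 1e-6

    def test_deletion_never_increases_growth(self, default_universe):
        # LP restriction monotonicity on 100 random single deletions
        spec, universe, seeds = default_universe
        m = seeds["C3_e"]
        base = fba.growth(m, universe, "C3_e")
        rng = np.random.default_rng(42)
        candidates = sorted(m.reaction_ids - {universe.biomass_reaction_id})
        for rid in rng.choice(candidates, size=100, replace=True):
            smaller = m.replace(reaction_ids=m.reaction_ids - {str(rid)})
            assert fba.growth(smaller, universe, "C3_e") <= base + 1e-9


class TestUniverseSerialization:
    def test_round_trip_identity(self, default_universe, tmp_path):
        spec, universe, _ = default_universe
        path = tmp_path / "universe.tsv"
        write_universe(universe, path)
        again = read_universe(path)
        assert set(again.reactions) == set(universe.reactions)
        for rid, rxn in universe.reactions.items():
            back = again.reactions[rid]
            assert back.stoichiometry == rxn.stoichiometry
            assert back.reversible == rxn.reversible
            assert back.is_transport == rxn.is_transport
            assert back.is_biomass == rxn.is_biomass
        assert again.biomass_reaction_id == universe.biomass_reaction_id
        assert again.medium_metabolites == universe.medium_metabolites
        for mid, met in universe.metabolites.items():
            assert again.metabolites[mid].is_extracellular == met.is_extracellular

    def test_duplicate_id_in_table_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "@metabolite\ta\tint\t-\n@metabolite\tb\tint\t-\n"
            "r1\ta => b\t-\nr1\ta => b\tbiomass\n"
        )
        with pytest.raises(UniverseFormatError, match="duplicate"):
            read_universe(path)

    def test_missing_biomass_rejected(self, tmp_path):
        path = tmp_path / "nobio.tsv"
        path.write_text("@metabolite\ta\tint\t-\n@metabolite\tb\tint\t-\nr1\ta => b\t-\n")
        with pytest.raises(UniverseFormatError, match="biomass"):
            read_universe(path)

    def test_bad_equation_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("@metabolite\ta\tint\t-\nr1\ta -- b\tbiomass\n")
        with pytest.raises(UniverseFormatError, match="arrow"):
            read_universe(path)

    def test_sbml_import_counts(self, tmp_path):
        cobra = pytest.importorskip("cobra")
        model = cobra.Model("toy")
        met_e = cobra.Metabolite("glc_e", compartment="e")
        met_c = cobra.Metabolite("glc_c", compartment="c")
        bio = cobra.Metabolite("bio_c", compartment="c")
        t = cobra.Reaction("T_glc")
        t.add_metabolites({met_e: -1, met_c: 1})
        growth_rxn = cobra.Reaction("GROWTH")
        growth_rxn.add_metabolites({met_c: -1, bio: 1})
        model.add_reactions([t, growth_rxn])
        model.objective = "GROWTH"
        path = tmp_path / "toy.xml"
        cobra.io.write_sbml_model(model, str(path))
        universe = read_universe(path, format="sbml")
        assert len(universe) == 2  # cross-checked against the cobra record count
        assert universe.biomass_reaction_id == "GROWTH"
        assert universe.reactions["T_glc"].is_transport
        assert universe.metabolites["glc_e"].is_extracellular


class TestMetabolismSerialization:
    def test_json_round_trip(self):
        m = Metabolism(frozenset({"a", "b"}), primary_carbon_source="c", label=(2, 7))
        assert metabolism_from_dict(metabolism_to_dict(m)) == m

    def test_population_round_trip(self, tmp_path, default_universe):
        _, _, seeds = default_universe
        path = tmp_path / "pop.jsonl"
        write_population(seeds.values(), path)
        back = read_population(path)
        assert back == list(seeds.values())
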