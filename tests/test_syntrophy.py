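"""Pooling, syntrophy detection, explicit exchange and minimal exchange."""

import pytest

from syntro import fba, syntrophy
from syntro.model import Metabolism
from syntro.syntrophy import (
    NoSyntrophyError,
    detect_syntrophy,
    explicit_exchange_growth,
    joint_growth,
    min_exchanged_metabolites,
    pool,
    restore_transport,
    syntrophy_essential_reactions,
)
from syntro.synthdata import _module_reactions_from_universe, plant_complementarity


@pytest.fixture(scope="module")
def planted(deep_universe):
    spec, universe, _ = deep_universe
    return plant_complementarity(universe, "C3_e", n_cuts=2)


class TestPool:
    def test_idempotent_and_symmetric(self, default_universe):
        _, _, seeds = default_universe
        a, b = seeds["C1_e"], seeds["C2_e"]
        assert pool(a, a).reaction_ids == a.reaction_ids
        assert pool(a, b).reaction_ids == pool(b, a).reaction_ids

    def test_size_bound_with_equality_iff_disjoint(self, default_universe):
        _, universe, seeds = default_universe
        a, b = seeds["C1_e"], seeds["C2_e"]
        assert len(pool(a, b)) <= len(a) + len(b)
        disjoint = Metabolism(
            frozenset({"T_C1_1", universe.biomass_reaction_id}), primary_carbon_source="C1_e"
        )
        other = Metabolism(frozenset({"T_C2_1", "R_C2_s0_r0"}) | {universe.biomass_reaction_id})
        overlap_only_bio = pool(disjoint, other)
        assert len(overlap_only_bio) == len(disjoint) + len(other) - 1  # shared biomass

    def test_complementary_halves_viable_only_pooled(self, planted, deep_universe):
        _, universe, _ = deep_universe
        a, b = planted.metabolism_a, planted.metabolism_b
        source = planted.carbon_source
        assert fba.growth(a, universe, source) == 0.0
        assert fba.growth(b, universe, source) == 0.0
        assert joint_growth(a, b, universe, source) > 0.0


class TestJointGrowth:
    def test_self_pair_equals_single_growth(self, default_universe):
        _, universe, seeds = default_universe
        m = seeds["C1_e"]
        assert joint_growth(m, m, universe, "C1_e") == fba.growth(m, universe, "C1_e")

    def test_symmetric(self, default_universe):
        _, universe, seeds = default_universe
        a, b = seeds["C1_e"], seeds["C3_e"]
        for c in ("C1_e", "C3_e", "C5_e"):
            assert joint_growth(a, b, universe, c) == joint_growth(b, a, universe, c)


class TestDetectSyntrophy:
    def test_identical_pair_empty(self, default_universe, default_spec):
        _, universe, seeds = default_universe
        m = seeds["C1_e"]
        rec = detect_syntrophy(m, m, universe, default_spec.carbon_sources)
        assert rec.syntrophic_sources == frozenset()
        assert rec.s == 0

    def test_planted_pair_detected_on_designed_source(self, planted, deep_universe):
        spec, universe, _ = deep_universe
        rec = detect_syntrophy(
            planted.metabolism_a, planted.metabolism_b, universe, spec.carbon_sources
        )
        assert rec.syntrophic_sources == {planted.carbon_source}
        assert rec.n_joint_additional == 1

    def test_symmetry_in_pair_order(self, planted, deep_universe):
        spec, universe, _ = deep_universe
        r1 = detect_syntrophy(
            planted.metabolism_a, planted.metabolism_b, universe, spec.carbon_sources
        )
        r2 = detect_syntrophy(
            planted.metabolism_b, planted.metabolism_a, universe, spec.carbon_sources
        )
        assert r1.syntrophic_sources == r2.syntrophic_sources

    def test_source_excluded_if_one_member_viable(self, default_universe, default_spec):
        _, universe, seeds = default_universe
        # give A the complete module for C2: the pair can grow on C2 but it
        # is A's own ability, not a syntrophy
        a = seeds["C1_e"].replace(
            reaction_ids=seeds["C1_e"].reaction_ids
            | _module_reactions_from_universe(universe, 2)
        )
        b = seeds["C3_e"]
        rec = detect_syntrophy(a, b, universe, default_spec.carbon_sources)
        assert "C2_e" not in rec.syntrophic_sources


class TestExplicitExchange:
    def test_no_exchange_decouples_to_best_individual(self, default_universe):
        _, universe, seeds = default_universe
        a, b = seeds["C1_e"], seeds["C2_e"]
        g = explicit_exchange_growth(a, b, universe, "C1_e", allowed_exchange=set())
        best = max(fba.growth(a, universe, "C1_e"), fba.growth(b, universe, "C1_e"))
        assert g == pytest.approx(best, abs=1e-6)

    def test_all_exchange_equals_pooling(self, planted, deep_universe):
        _, universe, _ = deep_universe
        a, b = planted.metabolism_a, planted.metabolism_b
        for source in (planted.carbon_source, a.primary_carbon_source):
            jg = joint_growth(a, b, universe, source)
            eg = explicit_exchange_growth(a, b, universe, source, None)
            assert eg == pytest.approx(jg, abs=1e-6)

    def test_designed_cut_set_suffices(self, planted, deep_universe):
        _, universe, _ = deep_universe
        g = explicit_exchange_growth(
            planted.metabolism_a,
            planted.metabolism_b,
            universe,
            planted.carbon_source,
            planted.cut_metabolites,
        )
        assert g > 0.0

    def test_monotone_in_allowed_set(self, planted, deep_universe):
        _, universe, _ = deep_universe
        a, b = planted.metabolism_a, planted.metabolism_b
        source = planted.carbon_source
        partial = planted.cut_metabolites[:1]  # one of two cuts: still blocked
        g_none = explicit_exchange_growth(a, b, universe, source, set())
        g_partial = explicit_exchange_growth(a, b, universe, source, partial)
        g_cut = explicit_exchange_growth(a, b, universe, source, planted.cut_metabolites)
        g_all = explicit_exchange_growth(a, b, universe, source, None)
        assert g_none <= g_partial <= g_cut <= g_all + 1e-9
        assert g_partial == 0.0 and g_cut > 0.0


class TestMinExchange:
    def test_planted_cut_size_recovered(self, deep_universe):
        spec, universe, _ = deep_universe
        for n_cuts in (1, 2, 3):
            pair = plant_complementarity(universe, "C4_e", n_cuts=n_cuts)
            sol = min_exchanged_metabolites(
                pair.metabolism_a, pair.metabolism_b, universe, "C4_e"
            )
            assert sol.count == n_cuts
            assert sol.exchanged_metabolites == set(pair.cut_metabolites)

    def test_milp_matches_enumeration_on_tiny_universe(self, tiny_universe):
        spec, universe, _ = tiny_universe
        pair = plant_complementarity(universe, "C1_e", n_cuts=1, with_primaries=False)
        milp = min_exchanged_metabolites(
            pair.metabolism_a, pair.metabolism_b, universe, "C1_e", method="milp"
        )
        enum = min_exchanged_metabolites(
            pair.metabolism_a, pair.metabolism_b, universe, "C1_e", method="enumerate"
        )
        assert milp.count == enum.count == 1

    def test_requires_syntrophy(self, default_universe):
        _, universe, seeds = default_universe
        with pytest.raises(NoSyntrophyError):
            min_exchanged_metabolites(
                seeds["C1_e"], seeds["C2_e"], universe, "C1_e"
            )


class TestRestoreTransport:
    def test_identity_when_transports_present(self, default_universe, default_spec):
        _, universe, seeds = default_universe
        m = seeds["C1_e"]
        assert restore_transport(m, universe, ["C1_e"]) == m

    def test_restores_viability_lost_to_transport_alone(self, default_universe, default_spec):
        _, universe, seeds = default_universe
        # full C2 machinery but no C2 transport: nonviable on C2 until restored
        module = _module_reactions_from_universe(universe, 2)
        transports = set(universe.transports_for("C2_e"))
        m = seeds["C1_e"].replace(
            reaction_ids=(seeds["C1_e"].reaction_ids | module) - transports
        )
        assert not fba.is_viable(m, universe, "C2_e")
        restored = restore_transport(m, universe, default_spec.carbon_sources)
        assert fba.is_viable(restored, universe, "C2_e")
        before = fba.viability_profile(m, universe, default_spec.carbon_sources)
        after = fba.viability_profile(restored, universe, default_spec.carbon_sources)
        assert before.viable_sources <= after.viable_sources


class TestSyntrophyEssentiality:
    def test_biomass_and_cut_producer_essential(self, planted, deep_universe):
        _, universe, _ = deep_universe
        ess = syntrophy_essential_reactions(
            planted.metabolism_a, planted.metabolism_b, universe, planted.carbon_source
        )
        assert universe.biomass_reaction_id in ess.essential
        for met, producer in planted.cut_producers.items():
            assert producer in ess.essential

    def test_removing_cut_producer_destroys_syntrophy(self, planted, deep_universe):
        _, universe, _ = deep_universe
        producer = planted.cut_producers[planted.cut_metabolites[0]]
        if producer in planted.metabolism_a.reaction_ids:
            owner, other = planted.metabolism_a, planted.metabolism_b
        else:
            owner, other = planted.metabolism_b, planted.metabolism_a
        pruned = owner.replace(reaction_ids=owner.reaction_ids - {producer})
        rec = detect_syntrophy(pruned, other, universe, [planted.carbon_source])
        assert rec.syntrophic_sources == frozenset()

    def test_cross_tags_and_bookkeeping(self, planted, deep_universe):
        _, universe, _ = deep_universe
        ess = syntrophy_essential_reactions(
            planted.metabolism_a, planted.metabolism_b, universe, planted.carbon_source
        )
        assert ess.primary_essential_a == fba.essential_reactions(
            planted.metabolism_a, universe, planted.metabolism_a.primary_carbon_source
        )
        s = ess.summary()
        assert s["n_essential"] == (
            s["n_essential_in_both"] + s["n_essential_single"]
        )
        assert s["n_essential_in_both_primary_essential_both"] <= s[
            "n_essential_in_both_primary_essential_either"
        ] <= s["n_essential_in_both"]
        assert ess.membership(universe.biomass_reaction_id) == "both"
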