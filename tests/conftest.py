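"""Shared fixtures: hand-checkable toy models and synthetic universes.

The toy universe is a three-reaction linear chain (uptake -> conversion ->
biomass) whose growth equals the carbon uptake bound, so every LP result
has a pencil-and-paper oracle. Synthetic universes come from the package's
own generator at several scales; expensive ones are session-scoped.
"""

import numpy as np
import pytest

from syntro.model import Metabolism, Metabolite, Reaction, ReactionUniverse
from syntro.synthdata import UniverseSpec, generate_universe


def make_toy_universe(extra_reactions=(), extra_metabolites=()):
    """Linear chain: S_e --T--> S --R--> P --BIO--> BIO_e, all 1:1.

    Growth on carbon source S_e with uptake bound b is exactly b.
    """
    metabolites = [
        Metabolite("S_e", is_extracellular=True),
        Metabolite("S"),
        Metabolite("P"),
        Metabolite("BIO_e", is_extracellular=True),
        *extra_metabolites,
    ]
    reactions = [
        Reaction("T", {"S_e": -1.0, "S": 1.0}, is_transport=True),
        Reaction("R", {"S": -1.0, "P": 1.0}),
        Reaction("BIO", {"P": -1.0, "BIO_e": 1.0}, is_biomass=True),
        *extra_reactions,
    ]
    return ReactionUniverse(reactions, metabolites, biomass_reaction_id="BIO")


@pytest.fixture
def toy_universe():
    return make_toy_universe()


@pytest.fixture
def toy_metabolism():
    return Metabolism(frozenset({"T", "R", "BIO"}), primary_carbon_source="S_e")


@pytest.fixture(scope="session")
def default_spec():
    return UniverseSpec()


@pytest.fixture(scope="session")
def default_universe(default_spec):
    """(spec, universe, seeds) at the generator's default study conditions."""
    universe, seeds = generate_universe(default_spec)
    return default_spec, universe, seeds


@pytest.fixture(scope="session")
def deep_universe():
    """Longer source-specific pathways (room for multi-metabolite cuts)."""
    spec = UniverseSpec(pathway_length=4, n_decoy_reactions=10)
    universe, seeds = generate_universe(spec)
    return spec, universe, seeds


@pytest.fixture(scope="session")
def single_route_universe():
    """No redundant routes: every pathway reaction is essential in seeds."""
    spec = UniverseSpec(pathway_length=4, n_branch_redundancy=1, n_decoy_reactions=10)
    universe, seeds = generate_universe(spec)
    return spec, universe, seeds


def make_tiny_spec(pathway_length=2):
    """Universe with <= 12 metabolites, for exhaustive-subset oracles."""
    return UniverseSpec(
        n_carbon_sources=2,
        pathway_length=pathway_length,
        n_branch_redundancy=1,
        n_shared_intermediates=1,
        n_biomass_precursors=1,
        n_decoy_reactions=0,
        with_medium=False,
    )


@pytest.fixture(scope="session")
def tiny_universe():
    spec = make_tiny_spec()
    universe, seeds = generate_universe(spec)
    assert universe.n_metabolites <= 12
    return spec, universe, seeds


@pytest.fixture(scope="session")
def short_walk_population(default_universe):
    """Ten quickly walked metabolisms (2 per source, 150 steps) plus profiles."""
    from syntro import fba, sampler

    spec, universe, seeds = default_universe
    population, walks = sampler.sample_population(
        universe, spec.carbon_sources, seeds, per_source=2, n_steps=150, base_seed=11
    )
    profiles = [
        fba.viability_profile(m, universe, spec.carbon_sources) for m in population
    ]
    return population, walks, profiles


@pytest.fixture
def rng():
    return np.random.default_rng(0)
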