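"""Synthetic reaction universes with the structure the analysis assumes.

The generator emulates, at desk scale, the features of a genome-scale
reaction universe that the pipeline relies on: multiple carbon sources,
each connected by linear-plus-branched pathways through shared hub
intermediates to a single biomass reaction; gain/loss-able transport
reactions; redundant alternative routes (so randomized metabolisms can be
pathway-complementary); and mass-balanced off-pathway "decoy" reactions
that can never carry flux and therefore give size reduction room to work.

Topology for carbon source ``Ci`` (all coefficients are 1)::

    Ci_e --T--> Ci --s0--> Ci_x1 --s1--> ... --s(L-1)--> H{hub(i)}
                 +--detour routes (2 reactions each) parallel to every step
    H{h} --> P{q}   for every biomass precursor q
    P1 + ... + PnP (+ NH4) --> BIOMASS_e    (the biomass reaction)

Hubs are shared between carbon sources (``hub(i) = i mod n_shared``), so
different sources' lower pathways overlap — one of the structural reasons
pairs of randomized metabolisms can unlock carbon sources neither can use
alone. Decoy reactions form an acyclic chain among dedicated decoy
metabolites with no connection to any carbon source, which makes them
provably flux-free in every environment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import fba
from .model import Metabolism, Metabolite, Reaction, ReactionUniverse, SyntroError

__all__ = [
    "GenerationError",
    "UniverseSpec",
    "PlantedPair",
    "generate_universe",
    "plant_complementarity",
    "generate_null_population",
]


class GenerationError(SyntroError):
    """The generator produced (or would produce) an invalid universe."""


@dataclass(frozen=True)
class UniverseSpec:
    """Parameters of a synthetic reaction universe.

    ``pathway_length`` is the number of source-specific reactions funneling
    a carbon source into its hub — kept short by default, as peripheral
    catabolic pathways feeding shared central metabolism are.
    ``n_branch_redundancy`` counts parallel routes per pathway step (the
    direct reaction plus two-reaction detours); ``n_shared_intermediates``
    is the number of hub metabolites the carbon-source pathways converge
    on; ``n_biomass_precursors`` sets the biomass yield (10 carbon units
    give a biomass flux of 10 / n_biomass_precursors).
    """

    n_carbon_sources: int = 5
    pathway_length: int = 2
    n_branch_redundancy: int = 2
    n_shared_intermediates: int = 2
    n_decoy_reactions: int = 30
    transport_per_source: int = 1
    n_biomass_precursors: int = 3
    seed_size: int | None = None  # default: core pathway + up to 12 decoys
    with_medium: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "n_carbon_sources": self.n_carbon_sources,
            "pathway_length": self.pathway_length,
            "n_branch_redundancy": self.n_branch_redundancy,
            "n_shared_intermediates": self.n_shared_intermediates,
            "transport_per_source": self.transport_per_source,
            "n_biomass_precursors": self.n_biomass_precursors,
        }
        for name, value in positive.items():
            if value < 1:
                raise GenerationError(f"{name} must be >= 1, got {value}")
        if self.n_decoy_reactions < 0:
            raise GenerationError("n_decoy_reactions must be >= 0")

    def hub(self, source_index: int) -> int:
        """Hub index (1-based) the pathway of source ``source_index`` feeds."""
        return (source_index - 1) % self.n_shared_intermediates + 1

    @property
    def carbon_sources(self) -> list[str]:
        return [f"C{i}_e" for i in range(1, self.n_carbon_sources + 1)]


BIOMASS_ID = "BIOMASS"
MEDIUM_MET = "NH4_e"
MEDIUM_TRANSPORT = "T_NH4"


def _chain_metabolite(i: int, step: int, pathway_length: int, hub: int) -> str:
    """Metabolite entering pathway step ``step`` (0-based) of source i."""
    if step == 0:
        return f"C{i}"
    if step == pathway_length:
        return f"H{hub}"
    return f"C{i}_x{step}"


def _route0_id(i: int, step: int) -> str:
    return f"R_C{i}_s{step}_r0"


def _module_reactions(spec: UniverseSpec, i: int, all_routes: bool) -> set[str]:
    """Reaction ids of source i's full pathway module (transports included)."""
    ids = {f"T_C{i}_{t}" for t in range(1, spec.transport_per_source + 1)}
    for s in range(spec.pathway_length):
        ids.add(_route0_id(i, s))
        if all_routes:
            for r in range(1, spec.n_branch_redundancy):
                ids.add(f"R_C{i}_s{s}_r{r}a")
                ids.add(f"R_C{i}_s{s}_r{r}b")
    hub = spec.hub(i)
    ids |= {f"R_H{hub}_P{q}" for q in range(1, spec.n_biomass_precursors + 1)}
    return ids


def generate_universe(spec: UniverseSpec) -> tuple[ReactionUniverse, dict[str, Metabolism]]:
    """Build the universe and one verified-viable seed metabolism per source.

    Deterministic given ``spec.seed``. Every seed metabolism is self-checked
    by FBA to be viable on its primary carbon source.
    """
    rng = np.random.default_rng(spec.seed)
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []

    for q in range(1, spec.n_biomass_precursors + 1):
        metabolites.append(Metabolite(f"P{q}"))
    for h in range(1, spec.n_shared_intermediates + 1):
        metabolites.append(Metabolite(f"H{h}"))
    metabolites.append(Metabolite("BIOMASS_e", is_extracellular=True))
    if spec.with_medium:
        metabolites.append(Metabolite(MEDIUM_MET, is_extracellular=True))
        metabolites.append(Metabolite("NH4"))
        reactions.append(
            Reaction(MEDIUM_TRANSPORT, {MEDIUM_MET: -1.0, "NH4": 1.0}, is_transport=True)
        )

    for i in range(1, spec.n_carbon_sources + 1):
        hub = spec.hub(i)
        metabolites.append(Metabolite(f"C{i}_e", is_extracellular=True))
        metabolites.append(Metabolite(f"C{i}"))
        for s in range(1, spec.pathway_length):
            metabolites.append(Metabolite(f"C{i}_x{s}"))
        for t in range(1, spec.transport_per_source + 1):
            reactions.append(
                Reaction(f"T_C{i}_{t}", {f"C{i}_e": -1.0, f"C{i}": 1.0}, is_transport=True)
            )
        for s in range(spec.pathway_length):
            a = _chain_metabolite(i, s, spec.pathway_length, hub)
            b = _chain_metabolite(i, s + 1, spec.pathway_length, hub)
            reactions.append(Reaction(_route0_id(i, s), {a: -1.0, b: 1.0}))
            for r in range(1, spec.n_branch_redundancy):
                v = f"C{i}_d{s}_{r}"
                metabolites.append(Metabolite(v))
                reactions.append(Reaction(f"R_C{i}_s{s}_r{r}a", {a: -1.0, v: 1.0}))
                reactions.append(Reaction(f"R_C{i}_s{s}_r{r}b", {v: -1.0, b: 1.0}, reversible=True))

    for h in range(1, spec.n_shared_intermediates + 1):
        for q in range(1, spec.n_biomass_precursors + 1):
            reactions.append(Reaction(f"R_H{h}_P{q}", {f"H{h}": -1.0, f"P{q}": 1.0}))

    biomass_stoich: dict[str, float] = {
        f"P{q}": -1.0 for q in range(1, spec.n_biomass_precursors + 1)
    }
    if spec.with_medium:
        biomass_stoich["NH4"] = -1.0
    biomass_stoich["BIOMASS_e"] = 1.0
    reactions.append(Reaction(BIOMASS_ID, biomass_stoich, is_biomass=True))

    # decoys: acyclic (low index -> high index) chain fragments among decoy
    # metabolites, unreachable from any carbon source, hence always flux-free
    n_decoy_mets = max(2, spec.n_decoy_reactions // 2 + 2) if spec.n_decoy_reactions else 0
    for d in range(1, n_decoy_mets + 1):
        metabolites.append(Metabolite(f"D{d}"))
    possible_edges = list(itertools.combinations(range(1, n_decoy_mets + 1), 2))
    if spec.n_decoy_reactions > 0:
        replace = spec.n_decoy_reactions > len(possible_edges)
        picks = rng.choice(len(possible_edges), size=spec.n_decoy_reactions, replace=replace)
        for d, e in enumerate(np.atleast_1d(picks), start=1):
            a, b = possible_edges[int(e)]
            reactions.append(Reaction(f"DK{d}", {f"D{a}": -1.0, f"D{b}": 1.0}))

    universe = ReactionUniverse(
        reactions,
        metabolites,
        biomass_reaction_id=BIOMASS_ID,
        medium_metabolites={MEDIUM_MET} if spec.with_medium else (),
    )

    decoy_ids = sorted(rid for rid in universe.reactions if rid.startswith("DK"))
    seeds: dict[str, Metabolism] = {}
    for i in range(1, spec.n_carbon_sources + 1):
        core = _module_reactions(spec, i, all_routes=True)
        core.add(BIOMASS_ID)
        if spec.with_medium:
            core.add(MEDIUM_TRANSPORT)
        target = spec.seed_size
        if target is None:
            target = len(core) + min(12, len(decoy_ids))
        if target < len(core):
            raise GenerationError(
                f"seed_size {target} below core pathway size {len(core)} for source {i}"
            )
        n_fill = min(target - len(core), len(decoy_ids))
        fill = rng.choice(decoy_ids, size=n_fill, replace=False) if n_fill else []
        seed = Metabolism(
            reaction_ids=frozenset(core) | frozenset(str(x) for x in fill),
            primary_carbon_source=f"C{i}_e",
            label=(i - 1, 0),
        )
        if not fba.is_viable(seed, universe, seed.primary_carbon_source):
            raise GenerationError(f"seed metabolism for C{i}_e failed its viability self-check")
        seeds[f"C{i}_e"] = seed
    return universe, seeds


def _infer_spec_dims(universe: ReactionUniverse, i: int) -> tuple[int, int]:
    """(pathway_length, hub index) of source i, recovered from reaction ids."""
    steps = set()
    for rid in universe.reactions:
        if rid.startswith(f"R_C{i}_s") and rid.endswith("_r0"):
            steps.add(int(rid.split("_s")[1].split("_")[0]))
    if not steps:
        raise GenerationError(f"universe has no pathway for source index {i}")
    length = max(steps) + 1
    last = universe.reactions[_route0_id(i, length - 1)]
    hub_mets = [m for m, c in last.stoichiometry.items() if c > 0 and m.startswith("H")]
    return length, int(hub_mets[0][1:])


@dataclass(frozen=True)
class PlantedPair:
    """A designed pathway-complementary pair of metabolisms.

    Neither partner is viable on ``carbon_source`` alone, the pooled pair
    is, and the minimum metabolite exchange equals ``len(cut_metabolites)``.
    ``cut_producers`` maps each cut metabolite to the reaction (held by the
    upstream partner) that produces it; deleting that reaction destroys the
    syntrophy.
    """

    metabolism_a: Metabolism
    metabolism_b: Metabolism
    carbon_source: str
    cut_metabolites: tuple[str, ...]
    cut_producers: Mapping[str, str] = field(default_factory=dict)


def plant_complementarity(
    universe: ReactionUniverse,
    carbon_source: str,
    n_cuts: int = 1,
    with_primaries: bool = True,
) -> PlantedPair:
    """Split source ``carbon_source``'s sole (route-0) pathway into two
    metabolisms that are individually nonviable on it but viable pooled.

    The chain is cut after steps 1..n_cuts; segments alternate between the
    partners (A first), so the pair must exchange exactly the ``n_cuts``
    boundary metabolites — some flowing A→B, some B→A. With
    ``with_primaries`` each partner additionally carries the complete
    single-route pathway of its own, distinct primary carbon source, so it
    is viable in isolation on that source (required for essentiality
    cross-classification).
    """
    if not carbon_source.startswith("C") or not carbon_source.endswith("_e"):
        raise GenerationError(f"not a synthetic carbon source id: {carbon_source!r}")
    k = int(carbon_source[1:-2])
    length, hub_k = _infer_spec_dims(universe, k)
    if not 1 <= n_cuts <= length - 1:
        raise GenerationError(f"n_cuts must be in [1, {length - 1}], got {n_cuts}")

    boundaries = list(range(1, n_cuts + 1))  # cut after steps 0..n_cuts-1
    owner_of_step: dict[int, str] = {}
    seg = 0
    for s in range(length):
        if seg < len(boundaries) and s == boundaries[seg]:
            seg += 1
        owner_of_step[s] = "A" if seg % 2 == 0 else "B"

    a_rxns: set[str] = set(universe.transports_for(carbon_source))
    b_rxns: set[str] = set()
    for s, owner in owner_of_step.items():
        (a_rxns if owner == "A" else b_rxns).add(_route0_id(k, s))
    hub_to_p = {rid for rid in universe.reactions if rid.startswith(f"R_H{hub_k}_P")}
    last_owner = owner_of_step[length - 1]
    (a_rxns if last_owner == "A" else b_rxns).update(hub_to_p)

    shared = {universe.biomass_reaction_id}
    if MEDIUM_TRANSPORT in universe.reactions:
        shared.add(MEDIUM_TRANSPORT)
    a_rxns |= shared
    b_rxns |= shared

    primary_a = primary_b = None
    if with_primaries:
        others = [
            i
            for i in range(1, _count_sources(universe) + 1)
            if i != k
        ]
        if len(others) < 2:
            raise GenerationError("with_primaries needs a universe with >= 3 carbon sources")
        pa, pb = others[0], others[1]
        a_rxns |= _module_reactions_from_universe(universe, pa)
        b_rxns |= _module_reactions_from_universe(universe, pb)
        primary_a, primary_b = f"C{pa}_e", f"C{pb}_e"

    cut_mets = tuple(f"C{k}_x{b}" for b in boundaries)
    producers = {f"C{k}_x{b}": _route0_id(k, b - 1) for b in boundaries}
    pair = PlantedPair(
        metabolism_a=Metabolism(frozenset(a_rxns), primary_carbon_source=primary_a),
        metabolism_b=Metabolism(frozenset(b_rxns), primary_carbon_source=primary_b),
        carbon_source=carbon_source,
        cut_metabolites=cut_mets,
        cut_producers=producers,
    )
    pair.metabolism_a.validate(universe)
    pair.metabolism_b.validate(universe)
    return pair


def _count_sources(universe: ReactionUniverse) -> int:
    n = 0
    while f"C{n + 1}_e" in universe.metabolites:
        n += 1
    return n


def _module_reactions_from_universe(universe: ReactionUniverse, i: int) -> set[str]:
    """Source i's single-route pathway module as present in the universe."""
    length, hub = _infer_spec_dims(universe, i)
    ids = set(universe.transports_for(f"C{i}_e"))
    ids |= {_route0_id(i, s) for s in range(length)}
    ids |= {rid for rid in universe.reactions if rid.startswith(f"R_H{hub}_P")}
    return ids


def generate_null_population(
    universe: ReactionUniverse,
    p_extra: float,
    n_per_source: int,
    rng: np.random.Generator,
) -> tuple[list[Metabolism], dict[tuple[int, int], frozenset[str]]]:
    """Population with *known* per-metabolism extra-viability probability.

    Each metabolism holds its primary source's complete pathway module and,
    independently with probability ``p_extra``, the complete module of each
    other carbon source. Modules are included atomically, so pooling two
    members can never unlock a source neither holds — pairs from this
    population are exactly the no-exchange null.

    Returns the population and a map label -> the extra sources planted in
    that metabolism (its realized viability beyond the primary).
    """
    if not 0.0 <= p_extra <= 1.0:
        raise GenerationError("p_extra must lie in [0, 1]")
    n_sources = _count_sources(universe)
    shared = {universe.biomass_reaction_id}
    if MEDIUM_TRANSPORT in universe.reactions:
        shared.add(MEDIUM_TRANSPORT)
    population: list[Metabolism] = []
    extras: dict[tuple[int, int], frozenset[str]] = {}
    for i in range(1, n_sources + 1):
        for x in range(n_per_source):
            rxns = set(shared) | _module_reactions_from_universe(universe, i)
            extra_sources = []
            for j in range(1, n_sources + 1):
                if j != i and rng.random() < p_extra:
                    rxns |= _module_reactions_from_universe(universe, j)
                    extra_sources.append(f"C{j}_e")
            label = (i - 1, x)
            population.append(
                Metabolism(frozenset(rxns), primary_carbon_source=f"C{i}_e", label=label)
            )
            extras[label] = frozenset(extra_sources)
    return population, extras
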