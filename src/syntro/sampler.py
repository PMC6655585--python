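"""Viability-constrained MCMC sampling of random viable metabolisms.

One Markov-chain step deletes a uniformly chosen non-biomass reaction and
inserts a uniformly chosen universe reaction that is not currently
present; the swap is accepted iff the resulting metabolism stays viable
on its primary carbon source, otherwise it is reverted. Long walks
(50,000 steps at genome scale) effectively randomize the reaction
complement while preserving primary-source viability and metabolism size.

Also provided: size reduction by repeated removal of dispensable
reactions, the random-augmentation control (add reactions with no
viability constraint), and population sampling with one derived RNG seed
per walk so an entire population reproduces from a single integer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fba
from .model import Metabolism, ReactionUniverse, SyntroError

__all__ = [
    "SaturationError",
    "ReductionError",
    "WalkResult",
    "swap_step",
    "random_walk",
    "reduce_metabolism",
    "augment_with_random_reactions",
    "sample_population",
]


class SaturationError(SyntroError):
    """The metabolism already contains every universe reaction."""


class ReductionError(SyntroError):
    """Size reduction cannot reach the requested target."""


@dataclass
class WalkResult:
    final: Metabolism
    steps: int
    accepted: int
    divergence_trace: list[tuple[int, float]] | None = None

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / self.steps if self.steps else 0.0


def swap_step(
    metabolism: Metabolism,
    universe: ReactionUniverse,
    rng: np.random.Generator,
    carbon_uptake_bound: float = 10.0,
    threshold: float = fba.VIABILITY_THRESHOLD,
) -> tuple[Metabolism, bool]:
    """One reaction swap; returns (new metabolism, accepted?).

    The biomass reaction is never deleted. The replacement is drawn from
    universe reactions not currently in the metabolism, so the swap always
    preserves metabolism size.
    """
    removable = sorted(metabolism.reaction_ids - {universe.biomass_reaction_id})
    absent = sorted(universe.reactions.keys() - metabolism.reaction_ids)
    if not absent:
        raise SaturationError("no universe reactions left to insert")
    out = removable[rng.integers(len(removable))]
    new = absent[rng.integers(len(absent))]
    proposal = metabolism.replace(
        reaction_ids=(metabolism.reaction_ids - {out}) | {new}
    )
    if fba.is_viable(
        proposal, universe, metabolism.primary_carbon_source, carbon_uptake_bound, threshold
    ):
        return proposal, True
    return metabolism, False


def random_walk(
    metabolism: Metabolism,
    universe: ReactionUniverse,
    n_steps: int = 50000,
    rng: np.random.Generator | int | None = None,
    carbon_uptake_bound: float = 10.0,
    threshold: float = fba.VIABILITY_THRESHOLD,
    trace_every: int | None = None,
    check_invariants: bool = False,
) -> WalkResult:
    """Run ``n_steps`` swap steps from a viable start.

    ``trace_every`` records (step, fraction of reactions shared with the
    start) at that interval. ``check_invariants`` re-asserts, after every
    accepted step, primary-source viability and constant size (slow; meant
    for validation runs).
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    if metabolism.primary_carbon_source is None:
        raise SyntroError("random_walk requires a primary carbon source")
    if not fba.is_viable(metabolism, universe, metabolism.primary_carbon_source,
                         carbon_uptake_bound, threshold):
        raise fba.NonviableError("walk start is not viable on its primary carbon source")
    start_ids = metabolism.reaction_ids
    size = len(start_ids)
    current = metabolism
    accepted = 0
    trace: list[tuple[int, float]] | None = [] if trace_every else None
    for step in range(1, n_steps + 1):
        current, ok = swap_step(current, universe, rng, carbon_uptake_bound, threshold)
        if ok:
            accepted += 1
            if check_invariants:
                assert len(current.reaction_ids) == size, "metabolism size changed"
                assert fba.is_viable(
                    current, universe, current.primary_carbon_source,
                    carbon_uptake_bound, threshold,
                ), "accepted step lost primary-source viability"
        if trace is not None and step % trace_every == 0:
            shared = len(current.reaction_ids & start_ids) / size
            trace.append((step, shared))
    return WalkResult(final=current, steps=n_steps, accepted=accepted, divergence_trace=trace)


def reduce_metabolism(
    metabolism: Metabolism,
    universe: ReactionUniverse,
    target_size: int,
    carbon_source: str | None = None,
    rng: np.random.Generator | int | None = None,
    carbon_uptake_bound: float = 10.0,
    threshold: float = fba.VIABILITY_THRESHOLD,
) -> Metabolism:
    """Shrink to ``target_size`` reactions while staying viable.

    Removals are drawn uniformly from the currently removable (dispensable,
    i.e. flux-free in some viable flux distribution) reactions; removability
    is re-established by an FBA deletion test as redundancy is consumed,
    and reactions found essential stay essential under further deletions,
    so they are cached.
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    carbon_source = carbon_source or metabolism.primary_carbon_source
    if carbon_source is None:
        raise SyntroError("reduce_metabolism needs a carbon source")
    if target_size > len(metabolism):
        raise ReductionError(
            f"target_size {target_size} exceeds current size {len(metabolism)}"
        )
    if not fba.is_viable(metabolism, universe, carbon_source, carbon_uptake_bound, threshold):
        raise fba.NonviableError("reduce_metabolism requires a viable metabolism")
    current = metabolism
    essential: set[str] = {universe.biomass_reaction_id}
    while len(current) > target_size:
        candidates = sorted(current.reaction_ids - essential)
        removed = False
        while candidates:
            idx = int(rng.integers(len(candidates)))
            rid = candidates.pop(idx)
            trial = current.replace(reaction_ids=current.reaction_ids - {rid})
            if fba.is_viable(trial, universe, carbon_source, carbon_uptake_bound, threshold):
                current = trial
                removed = True
                break
            essential.add(rid)
        if not removed:
            raise ReductionError(
                f"cannot reduce below {len(current)} reactions "
                f"(all remaining are essential); target was {target_size}"
            )
    return current


def augment_with_random_reactions(
    metabolism: Metabolism,
    k: int,
    universe: ReactionUniverse,
    rng: np.random.Generator | int | None = None,
) -> Metabolism:
    """Add ``k`` distinct absent universe reactions, uniformly at random.

    No viability constraint is applied — this is the control for whether
    reaction count alone, rather than two functional metabolisms, explains
    syntrophy.
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    absent = sorted(universe.reactions.keys() - metabolism.reaction_ids)
    if k > len(absent):
        raise SaturationError(f"cannot add {k} reactions; only {len(absent)} absent")
    if k == 0:
        return metabolism
    picks = rng.choice(len(absent), size=k, replace=False)
    added = {absent[int(i)] for i in picks}
    return metabolism.replace(reaction_ids=metabolism.reaction_ids | added)


def sample_population(
    universe: ReactionUniverse,
    primary_sources: list[str],
    seeds: dict[str, Metabolism],
    per_source: int = 20,
    n_steps: int = 50000,
    base_seed: int = 0,
    carbon_uptake_bound: float = 10.0,
    threshold: float = fba.VIABILITY_THRESHOLD,
    reduce_first_target: int | None = None,
) -> tuple[list[Metabolism], list[WalkResult]]:
    """Sample ``per_source`` random viable metabolisms per primary source.

    Each walk uses its own RNG seeded with ``base_seed + walk_index`` so the
    whole population is reproducible from one integer. Labels are (i, x):
    0-based source index and replicate index. ``reduce_first_target``
    enables the alternative reduce-then-walk mode (off by default; it is
    more constrained and accepts fewer swaps).
    """
    population: list[Metabolism] = []
    walks: list[WalkResult] = []
    for i, source in enumerate(primary_sources):
        try:
            seed_metabolism = seeds[source]
        except KeyError:
            raise SyntroError(f"no seed metabolism for carbon source {source!r}") from None
        for x in range(per_source):
            idx = i * per_source + x
            rng = np.random.default_rng(base_seed + idx)
            start = seed_metabolism.replace(primary_carbon_source=source, label=(i, x))
            if reduce_first_target is not None:
                start = reduce_metabolism(
                    start, universe, reduce_first_target, source, rng,
                    carbon_uptake_bound, threshold,
                )
            result = random_walk(
                start, universe, n_steps, rng, carbon_uptake_bound, threshold
            )
            population.append(result.final.replace(label=(i, x)))
            walks.append(result)
    return population, walks
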