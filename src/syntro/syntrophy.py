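"""Pairwise syntrophy detection and metabolite-exchange modelling.

A pair of metabolisms interacts syntrophically on carbon source C_k when
neither grows on C_k alone but the pair does when allowed to exchange
metabolites. Two equivalent formulations are implemented:

* **Pooling** — the unique reactions of the pair form one joint
  metabolism whose FBA growth is the pair growth G(A, B, C_k). This is
  the cheap formulation used for detection.
* **Explicit exchange** — the two metabolisms are kept as separate
  compartments (every metabolite duplicated) coupled only by reversible
  transfer reactions for an allowed set of metabolites, with the carbon
  uptake bound shared between the compartments. With every metabolite
  transferable this is mathematically equivalent to pooling; with an
  empty allowed set the compartments are fully decoupled. The explicit
  model is what the minimal-exchange computation constrains.

The minimum number of exchanged metabolites is found by a MILP with one
binary per metabolite gating its transfer fluxes (big-M), minimizing the
number of open transfers subject to joint growth above the viability
threshold; an exhaustive subset search over the same explicit model is
available for tiny universes and serves as an independent oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from . import fba
from .model import (
    Environment,
    Metabolism,
    ReactionUniverse,
    SolverError,
    SyntroError,
)

__all__ = [
    "NoSyntrophyError",
    "SyntrophyRecord",
    "ExchangeSolution",
    "SyntrophyEssentiality",
    "pool",
    "joint_growth",
    "detect_syntrophy",
    "explicit_exchange_growth",
    "min_exchanged_metabolites",
    "restore_transport",
    "syntrophy_essential_reactions",
]


class NoSyntrophyError(SyntroError):
    """The pair is not syntrophic on the requested carbon source."""


def pool(mA: Metabolism, mB: Metabolism) -> Metabolism:
    """Joint metabolism: the union of the pair's reaction sets."""
    return Metabolism(
        reaction_ids=mA.reaction_ids | mB.reaction_ids,
        primary_carbon_source=None,
        label=None,
    )


def joint_growth(
    mA: Metabolism,
    mB: Metabolism,
    universe: ReactionUniverse,
    carbon_source: Environment | str,
    carbon_uptake_bound: float = 10.0,
    threshold: float = fba.VIABILITY_THRESHOLD,
) -> float:
    """G(A, B, C_k): FBA growth of the pooled pair. G(m, m, C) is the
    single-metabolism growth."""
    return fba.growth(pool(mA, mB), universe, carbon_source, carbon_uptake_bound, threshold)


@dataclass(frozen=True)
class SyntrophyRecord:
    """Syntrophy outcome for one unordered pair of metabolisms.

    ``syntrophic_sources`` are the carbon sources with S = 1 (both
    individual growths zero, pair growth positive). ``n_joint_additional``
    counts sources where the pooled pair is viable beyond both individual
    viability profiles; because pooling can only add viability, this count
    equals ``len(syntrophic_sources)`` — both are kept for explicitness.
    """

    labels: tuple[tuple[int, int] | None, tuple[int, int] | None]
    primaries: tuple[str | None, str | None]
    syntrophic_sources: frozenset[str]
    n_joint_additional: int

    @property
    def s(self) -> int:
        """The syntrophy indicator S for the pair."""
        return 1 if self.syntrophic_sources else 0


def detect_syntrophy(
    mA: Metabolism,
    mB: Metabolism,
    universe: ReactionUniverse,
    carbon_sources: Sequence[str],
    profiles: tuple[fba.ViabilityProfile, fba.ViabilityProfile] | None = None,
    carbon_uptake_bound: float = 10.0,
    threshold: float = fba.VIABILITY_THRESHOLD,
) -> SyntrophyRecord:
    """Carbon sources on which the pair, but neither member, is viable.

    ``profiles`` may carry precomputed viability profiles (over the same
    ``carbon_sources``) for the two members to avoid redundant LPs. A
    metabolism forms no syntrophy with itself.
    """
    labels = (mA.label, mB.label)
    primaries = (mA.primary_carbon_source, mB.primary_carbon_source)
    if mA.reaction_ids == mB.reaction_ids:
        return SyntrophyRecord(labels, primaries, frozenset(), 0)
    if profiles is not None:
        viable_a = set(profiles[0].viable_sources)
        viable_b = set(profiles[1].viable_sources)
    else:
        viable_a = {
            c for c in carbon_sources
            if fba.is_viable(mA, universe, c, carbon_uptake_bound, threshold)
        }
        viable_b = {
            c for c in carbon_sources
            if fba.is_viable(mB, universe, c, carbon_uptake_bound, threshold)
        }
    joint = pool(mA, mB)
    syntrophic = set()
    for c in carbon_sources:
        if c in viable_a or c in viable_b:
            continue
        if fba.growth(joint, universe, c, carbon_uptake_bound, threshold) > 0.0:
            syntrophic.add(c)
    return SyntrophyRecord(labels, primaries, frozenset(syntrophic), len(syntrophic))


# ---------------------------------------------------------------------------
# explicit two-compartment exchange model
# ---------------------------------------------------------------------------


@dataclass
class _ExplicitSystem:
    A_eq: sp.csc_matrix
    A_ub: sp.csc_matrix | None
    b_ub: np.ndarray | None
    lb: np.ndarray
    ub: np.ndarray
    col_ids: list[str]
    bio_cols: tuple[int, int]
    transfer_cols: dict[str, int]


def _explicit_system(
    mA: Metabolism,
    mB: Metabolism,
    universe: ReactionUniverse,
    env: Environment,
    exchange_mets: Sequence[str],
) -> _ExplicitSystem:
    """Two duplicated compartments coupled only by transfer columns.

    Each compartment has its own metabolite copies and its own environment
    exchange columns; the carbon-source uptake bound is shared between the
    compartments (one inequality row), so opening all transfers reproduces
    the pooled model exactly.
    """
    for m in (mA, mB):
        m.validate(universe)
    n = universe.n_metabolites
    rows_parts, cols_parts, data_parts = [], [], []
    lb, ub, col_ids = [], [], []
    bio_cols = [-1, -1]
    carbon_cols = []

    j = 0
    for side, (m, offset) in enumerate([(mA, 0), (mB, n)]):
        tag = "AB"[side]
        for rid in sorted(m.reaction_ids):
            rows, coefs = universe.column(rid)
            rows_parts.append(rows + offset)
            cols_parts.append(np.full(rows.shape, j, dtype=np.int32))
            data_parts.append(coefs)
            rxn = universe.reactions[rid]
            lb.append(-np.inf if rxn.reversible else 0.0)
            ub.append(np.inf)
            if rid == universe.biomass_reaction_id:
                bio_cols[side] = j
            col_ids.append(f"{tag}::{rid}")
            j += 1
        for met_id in universe.extracellular_ids:
            rows_parts.append(
                np.array([universe.metabolite_index(met_id) + offset], dtype=np.int32)
            )
            cols_parts.append(np.array([j], dtype=np.int32))
            data_parts.append(np.array([-1.0]))
            if met_id == env.carbon_source:
                lb.append(-env.carbon_uptake_bound)
                carbon_cols.append(j)
            elif met_id in env.medium_metabolites:
                lb.append(-np.inf)
            else:
                lb.append(0.0)
            ub.append(np.inf)
            col_ids.append(f"EX{tag}::{met_id}")
            j += 1

    transfer_cols: dict[str, int] = {}
    for met_id in exchange_mets:
        r = universe.metabolite_index(met_id)
        rows_parts.append(np.array([r, r + n], dtype=np.int32))
        cols_parts.append(np.array([j, j], dtype=np.int32))
        data_parts.append(np.array([-1.0, 1.0]))  # positive flux: A -> B
        lb.append(-np.inf)
        ub.append(np.inf)
        col_ids.append(f"TR::{met_id}")
        transfer_cols[met_id] = j
        j += 1

    A_eq = sp.csc_matrix(
        (np.concatenate(data_parts), (np.concatenate(rows_parts), np.concatenate(cols_parts))),
        shape=(2 * n, j),
    )
    A_ub = b_ub = None
    if carbon_cols:
        # shared carbon budget: uptake_A + uptake_B <= bound
        A_ub = sp.csr_matrix(
            (np.full(len(carbon_cols), -1.0), (np.zeros(len(carbon_cols), dtype=int), carbon_cols)),
            shape=(1, j),
        )
        b_ub = np.array([env.carbon_uptake_bound])
    return _ExplicitSystem(
        A_eq=A_eq, A_ub=A_ub, b_ub=b_ub,
        lb=np.array(lb), ub=np.array(ub), col_ids=col_ids,
        bio_cols=(bio_cols[0], bio_cols[1]), transfer_cols=transfer_cols,
    )


def _solve_explicit(system: _ExplicitSystem) -> tuple[float, np.ndarray | None]:
    c = np.zeros(len(system.col_ids))
    c[list(system.bio_cols)] = -1.0  # maximize total biomass flux
    res = linprog(
        c,
        A_eq=system.A_eq,
        b_eq=np.zeros(system.A_eq.shape[0]),
        A_ub=system.A_ub,
        b_ub=system.b_ub,
        bounds=np.column_stack([system.lb, system.ub]),
        method="highs",
    )
    if res.status == 2:
        return 0.0, None
    if res.status != 0:
        raise SolverError(f"explicit-exchange LP failed (status {res.status}): {res.message}")
    v = np.asarray(res.x)
    v[np.abs(v) < fba.NUMERIC_TOL] = 0.0
    return float(v[system.bio_cols[0]] + v[system.bio_cols[1]]), v


def explicit_exchange_growth(
    mA: Metabolism,
    mB: Metabolism,
    universe: ReactionUniverse,
    carbon_source: Environment | str,
    allowed_exchange: Iterable[str] | None = None,
    carbon_uptake_bound: float = 10.0,
    threshold: float = fba.VIABILITY_THRESHOLD,
) -> float:
    """Pair growth with metabolite transfer restricted to ``allowed_exchange``.

    ``allowed_exchange=None`` opens every metabolite (equivalent to
    pooling); an empty set fully decouples the pair. Growth at or below
    the viability threshold is reported as 0.
    """
    env = fba._resolve_env(universe, carbon_source, carbon_uptake_bound)
    if allowed_exchange is None:
        mets = sorted(universe.metabolites)
    else:
        mets = sorted(set(allowed_exchange))
        for m in mets:
            universe.metabolite_index(m)  # raise on unknown ids
    system = _explicit_system(mA, mB, universe, env, mets)
    value, _ = _solve_explicit(system)
    return 0.0 if value <= threshold else value


@dataclass(frozen=True)
class ExchangeSolution:
    """A minimum-cardinality exchanged-metabolite set for one syntrophy."""

    carbon_source: str
    exchanged_metabolites: frozenset[str]
    count: int


def _require_syntrophy(mA, mB, universe, env, threshold) -> None:
    gA = fba.growth(mA, universe, env, threshold=threshold)
    gB = fba.growth(mB, universe, env, threshold=threshold)
    if gA > 0.0 or gB > 0.0:
        raise NoSyntrophyError("a member is individually viable on this carbon source")
    if joint_growth(mA, mB, universe, env, threshold=threshold) <= 0.0:
        raise NoSyntrophyError("the pooled pair is not viable on this carbon source")


def min_exchanged_metabolites(
    mA: Metabolism,
    mB: Metabolism,
    universe: ReactionUniverse,
    carbon_source: str,
    method: str = "milp",
    carbon_uptake_bound: float = 10.0,
    threshold: float = fba.VIABILITY_THRESHOLD,
    big_m: float | None = None,
) -> ExchangeSolution:
    """Minimum number of metabolites the pair must exchange to grow.

    ``method="milp"`` solves the gated-transfer MILP (big-M default: 1000x
    the carbon uptake bound); ``method="enumerate"`` searches subsets of
    metabolites in order of increasing size (independent of the MILP, and
    feasible only for small universes). The returned set is re-verified by
    an explicit-exchange LP restricted to it.
    """
    env = fba._resolve_env(universe, carbon_source, carbon_uptake_bound)
    _require_syntrophy(mA, mB, universe, env, threshold)
    if method == "enumerate":
        exchanged = _min_exchange_enumerate(mA, mB, universe, env, threshold)
    elif method == "milp":
        exchanged = _min_exchange_milp(mA, mB, universe, env, threshold, big_m)
    else:
        raise ValueError(f"unknown method {method!r}")
    check = explicit_exchange_growth(
        mA, mB, universe, env, exchanged, carbon_uptake_bound, threshold
    )
    if check <= 0.0:
        raise SolverError("minimal exchange set failed its verification LP")
    return ExchangeSolution(
        carbon_source=env.carbon_source,
        exchanged_metabolites=frozenset(exchanged),
        count=len(exchanged),
    )


def _min_exchange_milp(
    mA, mB, universe, env: Environment, threshold: float, big_m: float | None
) -> set[str]:
    mets = sorted(universe.metabolites)
    system = _explicit_system(mA, mB, universe, env, mets)
    n_flux = len(system.col_ids)
    n_z = len(mets)
    if big_m is None:
        big_m = env.carbon_uptake_bound * 1e3

    c = np.concatenate([np.zeros(n_flux), np.ones(n_z)])
    constraints = [
        LinearConstraint(
            sp.hstack([system.A_eq, sp.csc_matrix((system.A_eq.shape[0], n_z))], format="csc"),
            0.0,
            0.0,
        )
    ]
    if system.A_ub is not None:
        constraints.append(
            LinearConstraint(
                sp.hstack([system.A_ub, sp.csc_matrix((1, n_z))], format="csc"),
                -np.inf,
                system.b_ub,
            )
        )
    # |t_m| <= big_m * z_m
    rows, cols, data = [], [], []
    for zi, met in enumerate(mets):
        t = system.transfer_cols[met]
        rows += [2 * zi, 2 * zi, 2 * zi + 1, 2 * zi + 1]
        cols += [t, n_flux + zi, t, n_flux + zi]
        data += [1.0, -big_m, -1.0, -big_m]
    gate = sp.csc_matrix((data, (rows, cols)), shape=(2 * n_z, n_flux + n_z))
    constraints.append(LinearConstraint(gate, -np.inf, 0.0))
    # joint growth strictly above the viability threshold
    grow = sp.csc_matrix(
        (np.array([1.0, 1.0]), (np.array([0, 0]), np.array(list(system.bio_cols)))),
        shape=(1, n_flux + n_z),
    )
    constraints.append(LinearConstraint(grow, threshold + 1e-6, np.inf))

    lb = np.concatenate([system.lb, np.zeros(n_z)])
    ub = np.concatenate([system.ub, np.ones(n_z)])
    integrality = np.concatenate([np.zeros(n_flux), np.ones(n_z)])

    # Big-M gating can leak a little flux through "closed" transfers within
    # the solver's integrality tolerance, so the rounded set is re-verified
    # by an exact LP; an insufficient set S is excluded by the valid cut
    # sum_{m not in S} z_m >= 1 (any sufficient set must leave S, because
    # exchange feasibility is monotone in the allowed set) and re-solved.
    for _ in range(25):
        res = milp(c, constraints=constraints, bounds=Bounds(lb, ub), integrality=integrality)
        if res.status != 0 or res.x is None:
            raise SolverError(f"minimal-exchange MILP failed: {res.message}")
        z = res.x[n_flux:]
        selected = {mets[i] for i in range(n_z) if z[i] > 0.5}
        g = explicit_exchange_growth(
            mA, mB, universe, env, selected, env.carbon_uptake_bound, threshold
        )
        if g > 0.0:
            return selected
        outside = np.zeros(n_flux + n_z)
        for i, met in enumerate(mets):
            if met not in selected:
                outside[n_flux + i] = 1.0
        constraints.append(LinearConstraint(sp.csc_matrix(outside), 1.0, np.inf))
    raise SolverError("minimal-exchange MILP did not converge to a verified set")


def _min_exchange_enumerate(
    mA, mB, universe, env: Environment, threshold: float
) -> set[str]:
    mets = sorted(universe.metabolites)
    for size in range(len(mets) + 1):
        for combo in itertools.combinations(mets, size):
            g = explicit_exchange_growth(
                mA, mB, universe, env, combo, env.carbon_uptake_bound, threshold
            )
            if g > 0.0:
                return set(combo)
    raise NoSyntrophyError("no exchanged-metabolite set yields growth")  # pragma: no cover


def restore_transport(
    metabolism: Metabolism,
    universe: ReactionUniverse,
    carbon_sources: Iterable[str],
) -> Metabolism:
    """Add every universe transport reaction for the listed carbon sources.

    Models guaranteed carbon transport: the resulting metabolism is a
    superset, so its viability profile can only grow.
    """
    added = set()
    for source in carbon_sources:
        added.update(universe.transports_for(source))
    return metabolism.replace(reaction_ids=metabolism.reaction_ids | added)


@dataclass(frozen=True)
class SyntrophyEssentiality:
    """Reactions essential for one syntrophy, cross-tagged with parent
    primary-source essentiality."""

    carbon_source: str
    essential: frozenset[str]  # pooled reactions whose deletion kills the syntrophy
    in_a: frozenset[str]
    in_b: frozenset[str]
    primary_essential_a: frozenset[str] | None
    primary_essential_b: frozenset[str] | None

    def membership(self, reaction_id: str) -> str:
        in_a, in_b = reaction_id in self.in_a, reaction_id in self.in_b
        if in_a and in_b:
            return "both"
        if in_a:
            return "A"
        if in_b:
            return "B"
        raise KeyError(reaction_id)

    def summary(self) -> dict[str, int]:
        """Bookkeeping counts for the shared-machinery cross-classification."""
        both = {r for r in self.essential if r in self.in_a and r in self.in_b}
        single = self.essential - both
        ess_a = self.primary_essential_a or frozenset()
        ess_b = self.primary_essential_b or frozenset()
        return {
            "n_pooled": len(self.in_a | self.in_b),
            "n_essential": len(self.essential),
            "n_essential_in_both": len(both),
            "n_essential_in_both_primary_essential_both": len(both & ess_a & ess_b),
            "n_essential_in_both_primary_essential_either": len(both & (ess_a | ess_b)),
            "n_essential_single": len(single),
            "n_essential_single_primary_essential": len(
                {r for r in single if (r in self.in_a and r in ess_a)
                 or (r in self.in_b and r in ess_b)}
            ),
        }


def syntrophy_essential_reactions(
    mA: Metabolism,
    mB: Metabolism,
    universe: ReactionUniverse,
    carbon_source: str,
    carbon_uptake_bound: float = 10.0,
    threshold: float = fba.VIABILITY_THRESHOLD,
) -> SyntrophyEssentiality:
    """Partition pooled reactions by whether their deletion kills the
    syntrophy, cross-tagged with essentiality on each parent's primary.

    Parent primary-source essentiality is computed only for parents that
    declare a primary carbon source and are viable on it; otherwise the
    corresponding cross-tag is None.
    """
    env = fba._resolve_env(universe, carbon_source, carbon_uptake_bound)
    _require_syntrophy(mA, mB, universe, env, threshold)
    joint = pool(mA, mB)
    essential = fba.essential_reactions(joint, universe, env, threshold)

    def primary_ess(m: Metabolism) -> frozenset[str] | None:
        if m.primary_carbon_source is None:
            return None
        if not fba.is_viable(m, universe, m.primary_carbon_source,
                             carbon_uptake_bound, threshold):
            return None
        return fba.essential_reactions(m, universe, m.primary_carbon_source, threshold)

    return SyntrophyEssentiality(
        carbon_source=env.carbon_source,
        essential=essential,
        in_a=frozenset(mA.reaction_ids),
        in_b=frozenset(mB.reaction_ids),
        primary_essential_a=primary_ess(mA),
        primary_essential_b=primary_ess(mB),
    )
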