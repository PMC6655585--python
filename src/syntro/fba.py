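"""Viability prediction and essentiality analysis via flux balance analysis.

Growth is the optimum of a steady-state LP maximizing biomass flux; a
metabolism is *viable* in an environment when that optimum strictly
exceeds the viability threshold (0.001 by default). Growth rates at or
below the threshold are reported as 0.

Numerics: solver fluxes with magnitude below 1e-9 are clamped to zero
before the threshold comparison, so the viability decision is a strict,
reproducible exceedance test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model import (
    Environment,
    FluxSolution,
    Metabolism,
    ReactionUniverse,
    StoichiometricSystem,
    SolverError,
    SyntroError,
    build_system,
)

__all__ = [
    "VIABILITY_THRESHOLD",
    "NUMERIC_TOL",
    "NonviableError",
    "ViabilityProfile",
    "solve_system",
    "growth",
    "is_viable",
    "viability_profile",
    "essential_reactions",
    "zero_flux_reactions",
    "write_profiles_csv",
]

#: growth at or below this value counts as no growth (strict exceedance rule)
VIABILITY_THRESHOLD = 0.001
#: fluxes below this magnitude are numerical zero
NUMERIC_TOL = 1e-9


class NonviableError(SyntroError):
    """An operation requiring a viable metabolism was given a nonviable one."""


def _resolve_env(universe: ReactionUniverse, env: Environment | str,
                 carbon_uptake_bound: float = 10.0) -> Environment:
    if isinstance(env, Environment):
        return env
    return universe.environment(env, carbon_uptake_bound)


def solve_system(
    system: StoichiometricSystem,
    objective_col: int | None = None,
    sense: float = -1.0,
    extra_A_ub: sp.spmatrix | None = None,
    extra_b_ub: np.ndarray | None = None,
) -> FluxSolution:
    """Optimize ``sense * v[objective_col]`` (sense=-1 maximizes) over the system.

    Returns a :class:`FluxSolution` with status ``"optimal"`` or
    ``"infeasible"``; any other solver outcome raises :class:`SolverError`.
    """
    n = len(system.col_ids)
    c = np.zeros(n)
    j = system.objective_col if objective_col is None else objective_col
    c[j] = sense
    res = linprog(
        c,
        A_eq=system.A,
        b_eq=np.zeros(system.A.shape[0]),
        A_ub=extra_A_ub,
        b_ub=extra_b_ub,
        bounds=np.column_stack([system.lb, system.ub]),
        method="highs",
    )
    if res.status == 2:
        return FluxSolution(status="infeasible", objective=0.0, fluxes={})
    if res.status != 0:
        raise SolverError(f"LP solver failed (status {res.status}): {res.message}")
    v = np.asarray(res.x)
    v[np.abs(v) < NUMERIC_TOL] = 0.0
    return FluxSolution(
        status="optimal",
        objective=float(v[j]),
        fluxes=dict(zip(system.col_ids, v.tolist())),
    )


def growth(
    metabolism: Metabolism,
    universe: ReactionUniverse,
    env: Environment | str,
    carbon_uptake_bound: float = 10.0,
    threshold: float = VIABILITY_THRESHOLD,
) -> float:
    """Optimal biomass flux; values at or below ``threshold`` are reported as 0.

    ``env`` may be an :class:`Environment` or a carbon-source metabolite id
    (the universe's minimal medium is then used).
    """
    env = _resolve_env(universe, env, carbon_uptake_bound)
    system = build_system(metabolism, universe, env)
    sol = solve_system(system)
    if sol.status != "optimal" or sol.objective <= threshold:
        return 0.0
    return sol.objective


def is_viable(
    metabolism: Metabolism,
    universe: ReactionUniverse,
    carbon_source: Environment | str,
    carbon_uptake_bound: float = 10.0,
    threshold: float = VIABILITY_THRESHOLD,
) -> bool:
    """True iff biomass flux strictly exceeds the viability threshold."""
    return growth(metabolism, universe, carbon_source, carbon_uptake_bound, threshold) > 0.0


@dataclass(frozen=True)
class ViabilityProfile:
    """Carbon sources on which one metabolism is viable."""

    label: tuple[int, int] | None
    primary_carbon_source: str | None
    viable_sources: frozenset[str]

    @property
    def additional_sources(self) -> frozenset[str]:
        """Viable sources beyond the primary."""
        if self.primary_carbon_source is None:
            return self.viable_sources
        return self.viable_sources - {self.primary_carbon_source}


def viability_profile(
    metabolism: Metabolism,
    universe: ReactionUniverse,
    carbon_sources: Sequence[str],
    carbon_uptake_bound: float = 10.0,
    threshold: float = VIABILITY_THRESHOLD,
) -> ViabilityProfile:
    viable = frozenset(
        c
        for c in carbon_sources
        if is_viable(metabolism, universe, c, carbon_uptake_bound, threshold)
    )
    return ViabilityProfile(
        label=metabolism.label,
        primary_carbon_source=metabolism.primary_carbon_source,
        viable_sources=viable,
    )


def essential_reactions(
    metabolism: Metabolism,
    universe: ReactionUniverse,
    carbon_source: Environment | str,
    threshold: float = VIABILITY_THRESHOLD,
) -> frozenset[str]:
    """Reactions whose single deletion abolishes viability on ``carbon_source``.

    Only reactions carrying flux in one optimal solution are deletion-tested:
    a reaction with zero flux in some optimum is provably non-essential
    (that optimum remains feasible after its deletion).
    """
    env = _resolve_env(universe, carbon_source)
    system = build_system(metabolism, universe, env)
    sol = solve_system(system)
    if sol.status != "optimal" or sol.objective <= threshold:
        raise NonviableError("essential_reactions requires a viable metabolism")
    candidates = [
        rid for rid in metabolism.reaction_ids if abs(sol.fluxes.get(rid, 0.0)) > 0.0
    ]
    essential = set()
    for rid in candidates:
        if rid == universe.biomass_reaction_id:
            essential.add(rid)
            continue
        reduced = metabolism.replace(reaction_ids=metabolism.reaction_ids - {rid})
        if growth(reduced, universe, env, threshold=threshold) == 0.0:
            essential.add(rid)
    return frozenset(essential)


def zero_flux_reactions(
    metabolism: Metabolism,
    universe: ReactionUniverse,
    carbon_source: Environment | str,
    threshold: float = VIABILITY_THRESHOLD,
    optimum_fraction: float = 1.0 - 1e-6,
) -> frozenset[str]:
    """Reactions that carry zero flux in *every* optimal flux distribution.

    Identified by flux variability over the optimal face (max |v| subject to
    biomass >= optimum_fraction * optimum), which avoids false positives from
    degenerate alternative optima. Deleting any returned reaction preserves
    both the optimum and viability.
    """
    env = _resolve_env(universe, carbon_source)
    system = build_system(metabolism, universe, env)
    sol = solve_system(system)
    if sol.status != "optimal" or sol.objective <= threshold:
        raise NonviableError("zero_flux_reactions requires a viable metabolism")
    # pin the optimal face: -v_bio <= -optimum_fraction * optimum
    row = sp.csr_matrix(
        (np.array([-1.0]), (np.array([0]), np.array([system.objective_col]))),
        shape=(1, len(system.col_ids)),
    )
    b = np.array([-optimum_fraction * sol.objective])
    zero = set()
    for rid in metabolism.reaction_ids:
        if rid == universe.biomass_reaction_id:
            continue
        if abs(sol.fluxes.get(rid, 0.0)) > 0.0:
            continue  # carries flux in this optimum, not robustly zero
        j = system.col_index[rid]
        try:
            hi = solve_system(system, objective_col=j, sense=-1.0, extra_A_ub=row, extra_b_ub=b)
            vmax = abs(hi.fluxes.get(rid, 0.0)) if hi.status == "optimal" else np.inf
            if vmax <= NUMERIC_TOL and system.lb[j] < 0:
                lo = solve_system(system, objective_col=j, sense=+1.0, extra_A_ub=row, extra_b_ub=b)
                vmax = abs(lo.fluxes.get(rid, 0.0)) if lo.status == "optimal" else np.inf
        except SolverError:
            # unbounded variability (e.g. a free internal cycle) is not zero
            continue
        if vmax <= NUMERIC_TOL:
            zero.add(rid)
    return frozenset(zero)


def write_profiles_csv(profiles: Iterable[ViabilityProfile], path) -> None:
    """CSV export: label, primary source, semicolon-joined viable sources."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source_index", "replicate_index", "primary_carbon_source", "viable_sources"])
        for p in profiles:
            i, x = p.label if p.label is not None else ("", "")
            w.writerow([i, x, p.primary_carbon_source or "", ";".join(sorted(p.viable_sources))])
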