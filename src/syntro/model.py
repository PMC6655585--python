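"""Domain types for reactions, metabolisms and environments, plus the
stoichiometric-system assembly handed to the linear-programming layer.

The central objects are:

* :class:`ReactionUniverse` — the global pool of mass-balanced candidate
  reactions (one of which is the biomass pseudo-reaction) together with a
  metabolite registry and the universe's minimal-medium definition.
* :class:`Metabolism` — a subset of universe reactions (always containing
  the biomass reaction) tagged with its primary carbon source.
* :class:`Environment` — a minimal medium plus a single bounded carbon
  source; the carbon uptake bound defaults to 10 flux units.
* :func:`build_system` — assembles the steady-state stoichiometric matrix,
  flux bounds and exchange columns for one metabolism in one environment.

Exchange conventions: every extracellular metabolite gets one exchange
column with coefficient -1 (positive flux = secretion, negative = uptake).
Medium metabolites exchange freely, the carbon source may be taken up to
its bound, and all other extracellular metabolites are secretion-only, so
a metabolism that has lost the transport reaction for a carbon source
genuinely cannot use it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import scipy.sparse as sp

__all__ = [
    "SyntroError",
    "ResolutionError",
    "ModelError",
    "UniverseFormatError",
    "SolverError",
    "Metabolite",
    "Reaction",
    "ReactionUniverse",
    "Metabolism",
    "Environment",
    "FluxSolution",
    "StoichiometricSystem",
    "build_system",
    "read_universe",
    "write_universe",
    "metabolism_to_dict",
    "metabolism_from_dict",
    "write_population",
    "read_population",
]


class SyntroError(Exception):
    """Base class for all package errors."""


class ResolutionError(SyntroError, KeyError):
    """A reaction or metabolite id could not be resolved in the universe."""


class ModelError(SyntroError):
    """Structural model problem (e.g. missing biomass reaction)."""


class UniverseFormatError(SyntroError):
    """Malformed universe file."""


class SolverError(SyntroError):
    """The LP/MILP solver failed for a reason other than infeasibility."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str | None = None
    is_extracellular: bool = False


@dataclass(frozen=True)
class Reaction:
    """A mass-balanced reaction.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed, positive = produced). ``is_transport`` marks
    reactions that move a metabolite across the cell boundary; such a
    reaction must touch at least one extracellular metabolite.
    """

    id: str
    stoichiometry: Mapping[str, float]
    reversible: bool = False
    is_transport: bool = False
    is_biomass: bool = False

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r} has empty stoichiometry")
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))


class ReactionUniverse:
    """The global pool of candidate reactions and its metabolite registry.

    Parameters
    ----------
    reactions :
        Iterable of :class:`Reaction`; ids must be unique and exactly one
        reaction must carry ``is_biomass=True`` (or be named by
        ``biomass_reaction_id``).
    metabolites :
        Iterable of :class:`Metabolite` covering every id referenced by a
        reaction.
    medium_metabolites :
        Extracellular metabolite ids that the universe's minimal medium
        supplies without bound (non-carbon components).
    """

    def __init__(
        self,
        reactions: Iterable[Reaction],
        metabolites: Iterable[Metabolite],
        biomass_reaction_id: str | None = None,
        medium_metabolites: Iterable[str] = (),
    ) -> None:
        self.reactions: dict[str, Reaction] = {}
        for rxn in reactions:
            if rxn.id in self.reactions:
                raise ModelError(f"duplicate reaction id {rxn.id!r}")
            self.reactions[rxn.id] = rxn
        self.metabolites: dict[str, Metabolite] = {}
        for met in metabolites:
            if met.id in self.metabolites:
                raise ModelError(f"duplicate metabolite id {met.id!r}")
            self.metabolites[met.id] = met

        flagged = [r.id for r in self.reactions.values() if r.is_biomass]
        if len(flagged) > 1:
            raise ModelError(f"multiple biomass reactions: {flagged}")
        if biomass_reaction_id is None:
            if not flagged:
                raise ModelError("universe has no biomass reaction")
            biomass_reaction_id = flagged[0]
        if biomass_reaction_id not in self.reactions:
            raise ModelError(f"biomass reaction {biomass_reaction_id!r} not in universe")
        self.biomass_reaction_id = biomass_reaction_id
        self.medium_metabolites = frozenset(medium_metabolites)

        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ResolutionError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )
            if rxn.is_transport and not any(
                self.metabolites[m].is_extracellular for m in rxn.stoichiometry
            ):
                raise ModelError(
                    f"transport reaction {rxn.id!r} touches no extracellular metabolite"
                )
        for met_id in self.medium_metabolites:
            if met_id not in self.metabolites:
                raise ResolutionError(f"medium metabolite {met_id!r} not registered")

        # --- caches for fast LP assembly -----------------------------------
        self._met_ids: list[str] = sorted(self.metabolites)
        self._met_index: dict[str, int] = {m: i for i, m in enumerate(self._met_ids)}
        self._columns: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for rid, rxn in self.reactions.items():
            rows = np.array([self._met_index[m] for m in rxn.stoichiometry], dtype=np.int32)
            coefs = np.array(list(rxn.stoichiometry.values()), dtype=float)
            self._columns[rid] = (rows, coefs)
        self.extracellular_ids: list[str] = [
            m for m in self._met_ids if self.metabolites[m].is_extracellular
        ]

    # -- convenience -------------------------------------------------------

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self.reactions

    def __len__(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    def metabolite_index(self, met_id: str) -> int:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise ResolutionError(f"unknown metabolite {met_id!r}") from None

    def column(self, reaction_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(row indices, coefficients) of one reaction's stoichiometric column."""
        try:
            return self._columns[reaction_id]
        except KeyError:
            raise ResolutionError(f"unknown reaction {reaction_id!r}") from None

    def transports_for(self, metabolite_id: str) -> list[str]:
        """Ids of transport reactions touching the given (extracellular) metabolite."""
        return [
            rid
            for rid, rxn in self.reactions.items()
            if rxn.is_transport and metabolite_id in rxn.stoichiometry
        ]

    def environment(self, carbon_source: str, carbon_uptake_bound: float = 10.0) -> "Environment":
        """Minimal-medium environment with a single bounded carbon source."""
        if carbon_source not in self.metabolites:
            raise ResolutionError(f"unknown carbon source {carbon_source!r}")
        return Environment(
            carbon_source=carbon_source,
            carbon_uptake_bound=carbon_uptake_bound,
            medium_metabolites=self.medium_metabolites - {carbon_source},
        )


@dataclass(frozen=True)
class Metabolism:
    """A reaction subset of one universe, always including biomass.

    ``label`` is an (i, x) index pair: carbon-source index and replicate
    index within that source, mirroring the M_{i,x} bookkeeping of the
    sampled population.
    """

    reaction_ids: frozenset[str]
    primary_carbon_source: str | None = None
    label: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "reaction_ids", frozenset(self.reaction_ids))

    def __len__(self) -> int:
        return len(self.reaction_ids)

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self.reaction_ids

    def replace(self, **kwargs) -> "Metabolism":
        data = {
            "reaction_ids": self.reaction_ids,
            "primary_carbon_source": self.primary_carbon_source,
            "label": self.label,
        }
        data.update(kwargs)
        return Metabolism(**data)

    def validate(self, universe: ReactionUniverse) -> None:
        missing = self.reaction_ids - universe.reactions.keys()
        if missing:
            raise ResolutionError(f"reactions not in universe: {sorted(missing)[:5]}")
        if universe.biomass_reaction_id not in self.reaction_ids:
            raise ModelError("metabolism lacks the biomass reaction")


@dataclass(frozen=True)
class Environment:
    """A minimal medium plus one bounded carbon source."""

    carbon_source: str
    carbon_uptake_bound: float = 10.0
    medium_metabolites: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "medium_metabolites", frozenset(self.medium_metabolites))
        if self.carbon_uptake_bound <= 0:
            raise ModelError("carbon_uptake_bound must be positive")
        if self.carbon_source in self.medium_metabolites:
            raise ModelError("carbon source must not be part of the unbounded medium")


@dataclass(frozen=True)
class FluxSolution:
    status: str  # "optimal" | "infeasible"
    objective: float
    fluxes: dict[str, float]


@dataclass
class StoichiometricSystem:
    """Assembled steady-state LP: A @ v = 0, lb <= v <= ub, maximize v[objective]."""

    A: sp.csc_matrix
    lb: np.ndarray
    ub: np.ndarray
    col_ids: list[str]
    row_ids: list[str]
    objective_col: int
    col_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.col_index:
            self.col_index = {c: i for i, c in enumerate(self.col_ids)}


EXCHANGE_PREFIX = "EX::"


def build_system(
    metabolism: Metabolism,
    universe: ReactionUniverse,
    env: Environment,
) -> StoichiometricSystem:
    """Assemble the FBA system for one metabolism in one environment.

    Columns are the metabolism's reactions (sorted by id, biomass objective)
    followed by one exchange column per extracellular metabolite of the
    universe. Irreversible reactions get bounds [0, inf); reversible
    (-inf, inf). The carbon-source exchange is bounded below by minus the
    uptake bound, medium exchanges are free, and every other extracellular
    metabolite is secretion-only.
    """
    metabolism.validate(universe)
    rxn_ids = sorted(metabolism.reaction_ids)
    n_mets = universe.n_metabolites

    rows_parts: list[np.ndarray] = []
    cols_parts: list[np.ndarray] = []
    data_parts: list[np.ndarray] = []
    lb: list[float] = []
    ub: list[float] = []
    for j, rid in enumerate(rxn_ids):
        rows, coefs = universe.column(rid)
        rows_parts.append(rows)
        cols_parts.append(np.full(rows.shape, j, dtype=np.int32))
        data_parts.append(coefs)
        rxn = universe.reactions[rid]
        lb.append(-np.inf if rxn.reversible else 0.0)
        ub.append(np.inf)

    col_ids = list(rxn_ids)
    j = len(rxn_ids)
    for met_id in universe.extracellular_ids:
        rows_parts.append(np.array([universe.metabolite_index(met_id)], dtype=np.int32))
        cols_parts.append(np.array([j], dtype=np.int32))
        data_parts.append(np.array([-1.0]))
        if met_id == env.carbon_source:
            lb.append(-env.carbon_uptake_bound)
        elif met_id in env.medium_metabolites:
            lb.append(-np.inf)
        else:
            lb.append(0.0)  # secretion only
        ub.append(np.inf)
        col_ids.append(EXCHANGE_PREFIX + met_id)
        j += 1

    A = sp.csc_matrix(
        (
            np.concatenate(data_parts),
            (np.concatenate(rows_parts), np.concatenate(cols_parts)),
        ),
        shape=(n_mets, len(col_ids)),
    )
    try:
        objective_col = rxn_ids.index(universe.biomass_reaction_id)
    except ValueError:  # pragma: no cover - excluded by Metabolism.validate
        raise ModelError("metabolism lacks the biomass reaction") from None
    return StoichiometricSystem(
        A=A,
        lb=np.array(lb),
        ub=np.array(ub),
        col_ids=col_ids,
        row_ids=list(universe._met_ids),
        objective_col=objective_col,
    )


# ---------------------------------------------------------------------------
# reaction-table (TSV) serialization
# ---------------------------------------------------------------------------


def _format_equation(rxn: Reaction) -> str:
    lhs, rhs = [], []
    for met, coef in sorted(rxn.stoichiometry.items()):
        side = lhs if coef < 0 else rhs
        mag = abs(coef)
        term = met if mag == 1 else f"{_fmt_num(mag)} {met}"
        side.append(term)
    arrow = "<=>" if rxn.reversible else "=>"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def _parse_equation(eq: str, rxn_id: str) -> tuple[dict[str, float], bool]:
    if "<=>" in eq:
        reversible = True
        lhs_s, rhs_s = eq.split("<=>")
    elif "=>" in eq:
        reversible = False
        lhs_s, rhs_s = eq.split("=>")
    else:
        raise UniverseFormatError(f"reaction {rxn_id!r}: no arrow in equation {eq!r}")
    stoich: dict[str, float] = {}

    def add_terms(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            parts = term.strip().split()
            if len(parts) == 1:
                met, coef = parts[0], 1.0
            elif len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError:
                    raise UniverseFormatError(
                        f"reaction {rxn_id!r}: bad coefficient in term {term!r}"
                    ) from None
                met = parts[1]
            else:
                raise UniverseFormatError(f"reaction {rxn_id!r}: bad term {term!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_terms(lhs_s, -1.0)
    add_terms(rhs_s, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise UniverseFormatError(f"reaction {rxn_id!r}: empty stoichiometry")
    return stoich, reversible


def write_universe(universe: ReactionUniverse, path: str | Path) -> None:
    """Write the tab-separated reaction-table format (round-trip exact)."""
    lines = ["# syntro universe-tsv v1"]
    for met_id in sorted(universe.metabolites):
        met = universe.metabolites[met_id]
        comp = "ext" if met.is_extracellular else "int"
        lines.append(f"@metabolite\t{met.id}\t{comp}\t{met.name or '-'}")
    for met_id in sorted(universe.medium_metabolites):
        lines.append(f"@medium\t{met_id}")
    lines.append(f"@biomass\t{universe.biomass_reaction_id}")
    for rid in sorted(universe.reactions):
        rxn = universe.reactions[rid]
        flags = ",".join(
            f for f, on in [("transport", rxn.is_transport), ("biomass", rxn.is_biomass)] if on
        )
        lines.append(f"{rid}\t{_format_equation(rxn)}\t{flags or '-'}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_universe_tsv(path: str | Path) -> ReactionUniverse:
    metabolites: dict[str, Metabolite] = {}
    medium: set[str] = set()
    biomass_id: str | None = None
    reactions: list[Reaction] = []
    seen_rxn: set[str] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "@metabolite":
            _, mid, comp, name = fields
            if mid in metabolites:
                raise UniverseFormatError(f"line {lineno}: duplicate metabolite {mid!r}")
            metabolites[mid] = Metabolite(
                id=mid, name=None if name == "-" else name, is_extracellular=comp == "ext"
            )
        elif fields[0] == "@medium":
            medium.add(fields[1])
        elif fields[0] == "@biomass":
            biomass_id = fields[1]
        else:
            if len(fields) != 3:
                raise UniverseFormatError(f"line {lineno}: expected 3 tab-separated fields")
            rid, eq, flag_s = fields
            if rid in seen_rxn:
                raise UniverseFormatError(f"line {lineno}: duplicate reaction id {rid!r}")
            seen_rxn.add(rid)
            stoich, reversible = _parse_equation(eq, rid)
            flags = set() if flag_s in ("-", "") else set(flag_s.split(","))
            reactions.append(
                Reaction(
                    id=rid,
                    stoichiometry=stoich,
                    reversible=reversible,
                    is_transport="transport" in flags,
                    is_biomass="biomass" in flags,
                )
            )
    if biomass_id is None and not any(r.is_biomass for r in reactions):
        raise UniverseFormatError("universe file declares no biomass reaction")
    return ReactionUniverse(
        reactions, metabolites.values(), biomass_reaction_id=biomass_id, medium_metabolites=medium
    )


def _read_universe_sbml(path: str | Path, biomass_reaction_id: str | None) -> ReactionUniverse:
    """Import a user-supplied SBML model via cobrapy (optional dependency)."""
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover
        raise SyntroError("SBML import requires the optional 'cobra' dependency") from exc
    model = cobra.io.read_sbml_model(str(path))
    compartments = {m.compartment for m in model.metabolites}
    ext_comps = {c for c in compartments if str(c).lower() in ("e", "ext", "extracellular")}
    metabolites = [
        Metabolite(id=m.id, name=m.name or None, is_extracellular=m.compartment in ext_comps)
        for m in model.metabolites
    ]
    if biomass_reaction_id is None:
        objs = [r.id for r in model.reactions if r.objective_coefficient]
        biomass_reaction_id = objs[0] if objs else None
    reactions = []
    for r in model.reactions:
        if r.boundary:  # exchange pseudo-reactions are supplied by Environment
            continue
        comps = {m.compartment for m in r.metabolites}
        reactions.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: c for m, c in r.metabolites.items()},
                reversible=r.lower_bound < 0,
                is_transport=len(comps) > 1 and bool(comps & ext_comps),
                is_biomass=r.id == biomass_reaction_id,
            )
        )
    return ReactionUniverse(reactions, metabolites, biomass_reaction_id=biomass_reaction_id)


def read_universe(
    path: str | Path,
    format: str = "reaction-table",
    biomass_reaction_id: str | None = None,
) -> ReactionUniverse:
    """Read a reaction universe from disk.

    ``format`` is ``"reaction-table"`` (the package's TSV format) or
    ``"sbml"`` (SBML Level 3, via cobrapy).
    """
    if format == "reaction-table":
        return _read_universe_tsv(path)
    if format == "sbml":
        return _read_universe_sbml(path, biomass_reaction_id)
    raise ValueError(f"unknown universe format {format!r}")


# ---------------------------------------------------------------------------
# metabolism serialization (JSON / JSON-lines populations)
# ---------------------------------------------------------------------------


def metabolism_to_dict(m: Metabolism) -> dict:
    return {
        "reaction_ids": sorted(m.reaction_ids),
        "primary_carbon_source": m.primary_carbon_source,
        "label": list(m.label) if m.label is not None else None,
    }


def metabolism_from_dict(d: Mapping) -> Metabolism:
    label = d.get("label")
    return Metabolism(
        reaction_ids=frozenset(d["reaction_ids"]),
        primary_carbon_source=d.get("primary_carbon_source"),
        label=tuple(label) if label is not None else None,
    )


def write_population(metabolisms: Iterable[Metabolism], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in metabolisms:
            fh.write(json.dumps(metabolism_to_dict(m), sort_keys=True) + "\n")


def read_population(path: str | Path) -> list[Metabolism]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(metabolism_from_dict(json.loads(line)))
    return out


def iter_pairs(population: list[Metabolism]) -> Iterator[tuple[Metabolism, Metabolism]]:
    """All unique unordered pairs of distinct population members."""
    for a in range(len(population)):
        for b in range(a + 1, len(population)):
            yield population[a], population[b]
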