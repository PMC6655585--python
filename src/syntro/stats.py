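"""Population statistics for syntrophy: syntrophic potential, the
carbon-source pair syntrophic potential, the no-exchange null model, and
the significance tests used alongside them.

Denominators generalize the fixed-size population of 1,000 metabolisms
(20 per each of 50 carbon sources): a metabolism has N - 1 potential
partners (999 at N = 1000); a pair of distinct primary carbon sources
has per_source^2 metabolism pairings (400 at 20 per source) and a single
source has C(per_source, 2) (190). The fixed constants are recovered at
the published population sizes.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .fba import ViabilityProfile
from .model import SyntroError
from .syntrophy import SyntrophyRecord

__all__ = [
    "PotentialTable",
    "NullExpectation",
    "population_pair_count",
    "carbon_source_pair_count",
    "partner_count",
    "within_source_pair_count",
    "cross_source_pair_count",
    "syntrophic_potential",
    "pair_syntrophic_potential",
    "potential_table",
    "estimate_viability_probability",
    "null_expected_additional",
    "null_expectations",
    "sign_test_observed_vs_null",
    "two_proportion_test",
    "incidence_by_carbon_source",
]


# -- combinatorial bookkeeping ----------------------------------------------

def population_pair_count(n: int) -> int:
    """Unique unordered pairs of distinct metabolisms in a population of n."""
    return n * (n - 1) // 2


def carbon_source_pair_count(n_sources: int) -> int:
    """Unordered carbon-source combinations, same-source pairs included."""
    return n_sources * (n_sources - 1) // 2 + n_sources


def partner_count(n: int) -> int:
    """Partners available to one metabolism in a population of n."""
    return n - 1


def within_source_pair_count(per_source: int) -> int:
    """Metabolism pairings within one primary-carbon-source class."""
    return per_source * (per_source - 1) // 2


def cross_source_pair_count(per_source: int) -> int:
    """Metabolism pairings between two distinct primary-source classes."""
    return per_source * per_source


# -- syntrophic potential ----------------------------------------------------

def _pair_key(record: SyntrophyRecord) -> frozenset:
    return frozenset(record.labels)


def syntrophic_potential(
    label: tuple[int, int],
    records: Iterable[SyntrophyRecord],
    population_size: int,
) -> float:
    """Fraction of a metabolism's pairings that produce a syntrophy:
    sum of S over its N - 1 partners, divided by N - 1."""
    if population_size < 2:
        raise SyntroError("syntrophic potential needs a population of >= 2")
    hits = sum(r.s for r in records if label in r.labels)
    return hits / partner_count(population_size)


def pair_syntrophic_potential(
    c_i: str,
    c_j: str,
    records: Iterable[SyntrophyRecord],
    per_source: int,
) -> float:
    """Fraction of metabolism pairings between primary-source classes C_i
    and C_j that produce a syntrophy (symmetric in its arguments)."""
    want = frozenset((c_i, c_j))
    hits = sum(r.s for r in records if frozenset(r.primaries) == want)
    denom = (
        within_source_pair_count(per_source)
        if c_i == c_j
        else cross_source_pair_count(per_source)
    )
    return hits / denom


@dataclass
class PotentialTable:
    """s-bar per metabolism and pair potential per carbon-source pair."""

    s_bar: dict[tuple[int, int], float]
    sp_bar: dict[tuple[str, str], float]  # keys sorted (C_i, C_j), C_i <= C_j
    s_denominator: int
    sp_denominators: dict[tuple[str, str], int] = field(default_factory=dict)

    def sp(self, c_i: str, c_j: str) -> float:
        return self.sp_bar[tuple(sorted((c_i, c_j)))]


def potential_table(
    records: Sequence[SyntrophyRecord],
    labels: Sequence[tuple[int, int]],
    sources: Sequence[str],
    per_source: int,
) -> PotentialTable:
    """Compute every s-bar and pair potential from a full set of pair records."""
    n = len(labels)
    hits_by_label: dict[tuple[int, int], int] = defaultdict(int)
    hits_by_pair: dict[tuple[str, str], int] = defaultdict(int)
    for r in records:
        if r.s:
            for lab in r.labels:
                hits_by_label[lab] += 1
            hits_by_pair[tuple(sorted(r.primaries))] += 1
    s_bar = {lab: hits_by_label.get(lab, 0) / partner_count(n) for lab in labels}
    sp_bar = {}
    sp_den = {}
    for a in range(len(sources)):
        for b in range(a, len(sources)):
            key = tuple(sorted((sources[a], sources[b])))
            den = (
                within_source_pair_count(per_source)
                if a == b
                else cross_source_pair_count(per_source)
            )
            sp_bar[key] = hits_by_pair.get(key, 0) / den
            sp_den[key] = den
    return PotentialTable(
        s_bar=s_bar,
        sp_bar=sp_bar,
        s_denominator=partner_count(n),
        sp_denominators=sp_den,
    )


# -- no-exchange null model --------------------------------------------------

@dataclass(frozen=True)
class NullExpectation:
    """Null (no-exchange) expectation for one pair of metabolisms."""

    labels: tuple[tuple[int, int] | None, tuple[int, int] | None]
    p_i: float
    p_j: float
    same_primary: bool
    expected_additional: float


def estimate_viability_probability(profile: ViabilityProfile, n_sources: int) -> float:
    """p_i: the metabolism's additional viable sources over the n - 1
    non-primary candidates."""
    return len(profile.additional_sources) / (n_sources - 1)


def null_expected_additional(
    p_i: float,
    p_j: float,
    same_primary: bool,
    n_sources: int = 50,
) -> float:
    """Expected additional carbon sources for a non-interacting pair.

    With no exchange, a pair is viable on a source iff at least one member
    is: probability 1 - (1 - p_i)(1 - p_j) per source, times the n - 2
    candidate sources (n - 1 when the primaries coincide).
    """
    for p in (p_i, p_j):
        if not 0.0 <= p <= 1.0:
            raise SyntroError(f"viability probability {p} outside [0, 1]")
    n_candidates = n_sources - 1 if same_primary else n_sources - 2
    return n_candidates * (1.0 - (1.0 - p_i) * (1.0 - p_j))


def null_expectations(
    profiles: Sequence[ViabilityProfile],
    n_sources: int,
) -> list[NullExpectation]:
    """Null expectation for every unordered pair of profiled metabolisms."""
    out = []
    ps = [estimate_viability_probability(p, n_sources) for p in profiles]
    for a in range(len(profiles)):
        for b in range(a + 1, len(profiles)):
            pa, pb = profiles[a], profiles[b]
            same = (
                pa.primary_carbon_source is not None
                and pa.primary_carbon_source == pb.primary_carbon_source
            )
            out.append(
                NullExpectation(
                    labels=(pa.label, pb.label),
                    p_i=ps[a],
                    p_j=ps[b],
                    same_primary=same,
                    expected_additional=null_expected_additional(
                        ps[a], ps[b], same, n_sources
                    ),
                )
            )
    return out


# -- significance tests ------------------------------------------------------

def sign_test_observed_vs_null(
    observed: Sequence[float],
    expected: Sequence[float],
) -> float:
    """Exact two-sided binomial sign test on paired differences, ties dropped.

    Returns 1.0 when every pair ties.
    """
    if len(observed) != len(expected):
        raise SyntroError("observed and expected must have equal length")
    diffs = np.asarray(observed, dtype=float) - np.asarray(expected, dtype=float)
    pos = int(np.sum(diffs > 0))
    neg = int(np.sum(diffs < 0))
    n = pos + neg
    if n == 0:
        return 1.0
    return float(sps.binomtest(pos, n, 0.5, alternative="two-sided").pvalue)


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided test that two binomial proportions differ (2x2 chi-squared
    without continuity correction, identical to the pooled z-test)."""
    for k, n in ((k1, n1), (k2, n2)):
        if not 0 <= k <= n:
            raise SyntroError("need 0 <= k <= n for both samples")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return 1.0  # identical degenerate proportions
    _, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(p)


# -- per-carbon-source incidence ---------------------------------------------

def incidence_by_carbon_source(
    records: Iterable[SyntrophyRecord],
    sources: Sequence[str] | None = None,
) -> tuple[dict[str, int], dict[str, float]]:
    """Count of syntrophic pairs per carbon source and each source's share
    of all syntrophies (shares sum to 1 when any exist)."""
    counts: dict[str, int] = defaultdict(int)
    for r in records:
        for c in r.syntrophic_sources:
            counts[c] += 1
    if sources is not None:
        for c in sources:
            counts.setdefault(c, 0)
    total = sum(counts.values())
    shares = {c: (k / total if total else 0.0) for c, k in counts.items()}
    return dict(counts), shares
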