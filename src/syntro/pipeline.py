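"""End-to-end pipeline: universe -> population -> profiles -> pair records
-> potentials -> network -> report, with deterministic seeding and
diff-able tabular outputs.

All randomness flows from ``RunConfig.seed`` through a fixed hierarchy
(universe generation, then one derived seed per walk), recorded in the
run manifest, so re-running an identical configuration reproduces every
output byte for byte. Stages whose outputs already exist under an
unchanged configuration are reloaded instead of recomputed.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import fba, netanalysis, sampler, stats, synthdata, syntrophy
from .model import (
    Metabolism,
    ReactionUniverse,
    SyntroError,
    metabolism_from_dict,
    metabolism_to_dict,
    read_population,
    read_universe,
    write_population,
    write_universe,
)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "build_report",
    "format_report",
    "write_pairs_csv",
    "read_pairs_csv",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Defaults mirror the published study parameters (20 metabolisms per
    source, 50,000-step walks, viability threshold 0.001, carbon uptake
    bound 10); desk-scale runs override the sizes. Either ``universe_path``
    (a reaction-table TSV plus ``seeds_path``) or ``synth`` (synthetic
    universe parameters) supplies the reaction universe.
    """

    outdir: str = "syntro_run"
    universe_path: str | None = None
    seeds_path: str | None = None
    synth: dict = field(default_factory=dict)
    sources: list[str] | None = None
    per_source: int = 20
    n_steps: int = 50000
    reduction_target: int | None = None
    viability_threshold: float = 0.001
    carbon_uptake_bound: float = 10.0
    min_exchange: bool = False
    min_exchange_max_pairs: int = 200
    restore_transport: bool = False
    network_threshold: float = 0.55
    core_periphery_restarts: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.viability_threshold <= 0 or self.carbon_uptake_bound <= 0:
            raise SyntroError("thresholds and bounds must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# tabular writers / readers
# ---------------------------------------------------------------------------


def write_pairs_csv(records, null_by_pair, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([
            "i_a", "x_a", "i_b", "x_b", "primary_a", "primary_b",
            "s", "n_joint_additional", "syntrophic_sources", "expected_additional",
        ])
        for r in records:
            (ia, xa), (ib, xb) = r.labels
            exp = null_by_pair.get(frozenset(r.labels), float("nan"))
            w.writerow([
                ia, xa, ib, xb, r.primaries[0], r.primaries[1],
                r.s, r.n_joint_additional,
                ";".join(sorted(r.syntrophic_sources)), repr(float(exp)),
            ])


def read_pairs_csv(path) -> list[syntrophy.SyntrophyRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            sources = frozenset(s for s in row["syntrophic_sources"].split(";") if s)
            records.append(
                syntrophy.SyntrophyRecord(
                    labels=((int(row["i_a"]), int(row["x_a"])), (int(row["i_b"]), int(row["x_b"]))),
                    primaries=(row["primary_a"], row["primary_b"]),
                    syntrophic_sources=sources,
                    n_joint_additional=int(row["n_joint_additional"]),
                )
            )
    return records


def _write_csv(path, header, rows) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _pair_records(population, profiles, universe, sources, config):
    by_label = {p.label: p for p in profiles}
    records = []
    for a in range(len(population)):
        for b in range(a + 1, len(population)):
            ma, mb = population[a], population[b]
            records.append(
                syntrophy.detect_syntrophy(
                    ma, mb, universe, sources,
                    profiles=(by_label[ma.label], by_label[mb.label]),
                    carbon_uptake_bound=config.carbon_uptake_bound,
                    threshold=config.viability_threshold,
                )
            )
    return records


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the result bundle under ``config.outdir``.

    Returns a dict with the in-memory objects (universe, population,
    profiles, records, potentials, network, partition, report) plus the
    output paths.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest_path = out / "manifest.json"
    reuse = False
    if manifest_path.exists():
        try:
            reuse = json.loads(manifest_path.read_text()).get("config_hash") == chash
        except json.JSONDecodeError:
            reuse = False

    # --- stage 1: universe --------------------------------------------------
    universe_file = out / "universe.tsv"
    seeds_file = out / "seeds.jsonl"
    if config.universe_path is not None:
        universe = read_universe(config.universe_path)
        if config.seeds_path is None:
            raise SyntroError("universe_path requires seeds_path (viable seed metabolisms)")
        seeds = {m.primary_carbon_source: m for m in read_population(config.seeds_path)}
        write_universe(universe, universe_file)
    elif reuse and universe_file.exists() and seeds_file.exists():
        universe = read_universe(universe_file)
        seeds = {m.primary_carbon_source: m for m in read_population(seeds_file)}
    else:
        spec = synthdata.UniverseSpec(**{**config.synth, "seed": config.seed})
        universe, seeds = synthdata.generate_universe(spec)
        write_universe(universe, universe_file)
        write_population(seeds.values(), seeds_file)
    sources = config.sources or sorted(seeds)

    # --- stage 2: population ------------------------------------------------
    population_file = out / "population.jsonl"
    walks_file = out / "walks.csv"
    walks = None
    if reuse and population_file.exists() and walks_file.exists():
        population = read_population(population_file)
        acceptance = []
        with open(walks_file, newline="") as fh:
            for row in csv.DictReader(fh):
                acceptance.append(float(row["acceptance_rate"]))
    else:
        population, walks = sampler.sample_population(
            universe, sources, seeds,
            per_source=config.per_source,
            n_steps=config.n_steps,
            base_seed=config.seed + 1,
            carbon_uptake_bound=config.carbon_uptake_bound,
            threshold=config.viability_threshold,
        )
        if config.reduction_target is not None:
            population = [
                sampler.reduce_metabolism(
                    m, universe, config.reduction_target,
                    rng=config.seed + 100_000 + idx,
                    carbon_uptake_bound=config.carbon_uptake_bound,
                    threshold=config.viability_threshold,
                )
                for idx, m in enumerate(population)
            ]
        write_population(population, population_file)
        _write_csv(
            walks_file,
            ["i", "x", "steps", "accepted", "acceptance_rate"],
            [
                [m.label[0], m.label[1], w.steps, w.accepted, repr(w.acceptance_rate)]
                for m, w in zip(population, walks)
            ],
        )
        acceptance = [w.acceptance_rate for w in walks]

    # --- stage 3: viability profiles ----------------------------------------
    profiles = [
        fba.viability_profile(
            m, universe, sources, config.carbon_uptake_bound, config.viability_threshold
        )
        for m in population
    ]
    fba.write_profiles_csv(profiles, out / "profiles.csv")

    # --- stage 4: pair records + null model ----------------------------------
    records = _pair_records(population, profiles, universe, sources, config)
    null = stats.null_expectations(profiles, n_sources=len(sources))
    null_by_pair = {frozenset(n.labels): n.expected_additional for n in null}
    write_pairs_csv(records, null_by_pair, out / "pairs.csv")

    min_exchange_counts: list[int] = []
    if config.min_exchange:
        by_label = {m.label: m for m in population}
        done = 0
        for r in records:
            if done >= config.min_exchange_max_pairs:
                break
            if not r.s:
                continue
            ma, mb = by_label[r.labels[0]], by_label[r.labels[1]]
            for source in sorted(r.syntrophic_sources):
                try:
                    sol = syntrophy.min_exchanged_metabolites(
                        ma, mb, universe, source,
                        carbon_uptake_bound=config.carbon_uptake_bound,
                        threshold=config.viability_threshold,
                    )
                except SyntroError:
                    continue  # skip unsolved instances; n_min_exchange_solved records coverage
                min_exchange_counts.append(sol.count)
            done += 1
        _write_csv(
            out / "min_exchange.csv", ["count"], [[c] for c in min_exchange_counts]
        )

    restored_records = restored_profiles = None
    if config.restore_transport:
        restored = [
            syntrophy.restore_transport(m, universe, sources) for m in population
        ]
        restored_profiles = [
            fba.viability_profile(
                m, universe, sources, config.carbon_uptake_bound, config.viability_threshold
            )
            for m in restored
        ]
        restored_records = _pair_records(
            restored, restored_profiles, universe, sources, config
        )

    # --- stage 5: potentials --------------------------------------------------
    labels = [m.label for m in population]
    table = stats.potential_table(records, labels, sources, config.per_source)
    _write_csv(
        out / "s_bar.csv",
        ["i", "x", "s_bar"],
        [[i, x, repr(table.s_bar[(i, x)])] for (i, x) in labels],
    )
    _write_csv(
        out / "sp_bar.csv",
        ["c_i", "c_j", "sp_bar", "denominator"],
        [
            [a, b, repr(table.sp_bar[(a, b)]), table.sp_denominators[(a, b)]]
            for (a, b) in sorted(table.sp_bar)
        ],
    )
    counts, shares = stats.incidence_by_carbon_source(records, sources)
    _write_csv(
        out / "incidence.csv",
        ["carbon_source", "n_syntrophic_pairs", "share"],
        [[c, counts[c], repr(shares.get(c, 0.0))] for c in sorted(counts)],
    )

    # --- stage 6: network ------------------------------------------------------
    network = netanalysis.build_network(table, config.network_threshold)
    _write_csv(
        out / "network_edges.tsv",
        ["c_i", "c_j", "weight"],
        [[a, b, repr(w)] for (a, b), w in sorted(network.weights.items())],
    )
    partition = None
    if len(network.nodes) >= 3:
        partition = netanalysis.core_periphery(
            network, n_restarts=config.core_periphery_restarts, seed=config.seed
        )
        _write_csv(
            out / "partition.csv",
            ["carbon_source", "role"],
            [[c, partition.role(c)] for c in sorted(network.nodes)],
        )

    # --- stage 7: report -------------------------------------------------------
    report = build_report(
        profiles=profiles,
        records=records,
        null=null,
        table=table,
        network=network,
        partition=partition,
        acceptance=acceptance,
        sources=sources,
        min_exchange_counts=min_exchange_counts or None,
        restored_records=restored_records,
        restored_profiles=restored_profiles,
    )
    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    (out / "report.txt").write_text(format_report(report))
    manifest_path.write_text(
        json.dumps(
            {"config": asdict(config), "config_hash": chash, "package": "syntro 0.1.0"},
            sort_keys=True,
            indent=1,
        )
    )
    return {
        "universe": universe,
        "seeds": seeds,
        "population": population,
        "walks": walks,
        "profiles": profiles,
        "records": records,
        "null": null,
        "potentials": table,
        "network": network,
        "partition": partition,
        "report": report,
        "outdir": str(out),
    }


def build_report(
    profiles,
    records,
    null,
    table,
    network,
    partition,
    acceptance,
    sources,
    min_exchange_counts=None,
    restored_records=None,
    restored_profiles=None,
) -> dict:
    """Headline quantities of one run, all recomputable from the raw CSVs."""
    individual = [len(p.additional_sources) for p in profiles]
    observed = [r.n_joint_additional for r in records]
    expected = [n.expected_additional for n in null]
    s_values = sorted(table.s_bar.values())
    counts, shares = stats.incidence_by_carbon_source(records, sources)
    top = max(sorted(counts), key=lambda c: counts[c]) if counts else None
    exp_mean = float(np.mean(expected)) if expected else 0.0
    obs_mean = float(np.mean(observed)) if observed else 0.0
    report = {
        "n_population": len(profiles),
        "n_sources": len(sources),
        "n_pairs": len(records),
        "mean_individual_additional_sources": float(np.mean(individual)),
        "sd_individual_additional_sources": float(np.std(individual)),
        "mean_null_expected_additional": exp_mean,
        "sd_null_expected_additional": float(np.std(expected)) if expected else 0.0,
        "mean_pair_additional_sources": obs_mean,
        "sd_pair_additional_sources": float(np.std(observed)) if observed else 0.0,
        "fold_over_null": (obs_mean / exp_mean) if exp_mean > 0 else None,
        "sign_test_p": stats.sign_test_observed_vs_null(observed, expected),
        "fraction_pairs_syntrophic": float(np.mean([r.s for r in records])) if records else 0.0,
        "median_syntrophic_potential": float(np.median(s_values)) if s_values else 0.0,
        "min_syntrophic_potential": float(min(s_values)) if s_values else 0.0,
        "mean_swap_acceptance_rate": float(np.mean(acceptance)) if acceptance else None,
        "min_swap_acceptance_rate": float(min(acceptance)) if acceptance else None,
        "max_swap_acceptance_rate": float(max(acceptance)) if acceptance else None,
        "top_carbon_source": top,
        "top_carbon_source_share": float(shares[top]) if top else 0.0,
        "assortativity": netanalysis.assortativity(network) if network else None,
        "core_size": len(partition.core) if partition else None,
        "periphery_size": len(partition.periphery) if partition else None,
        "n_outliers": len(partition.outliers) if partition else None,
    }
    if min_exchange_counts:
        report["mean_min_exchanged_metabolites"] = float(np.mean(min_exchange_counts))
        report["n_min_exchange_solved"] = len(min_exchange_counts)
    if restored_records is not None:
        r_obs = [r.n_joint_additional for r in restored_records]
        r_ind = [len(p.additional_sources) for p in restored_profiles]
        report["restored_mean_pair_additional_sources"] = float(np.mean(r_obs))
        report["restored_mean_individual_additional_sources"] = float(np.mean(r_ind))
    return report


def format_report(report: dict) -> str:
    """Human-readable run summary."""
    lines = [
        "syntro run summary",
        "==================",
        f"population: {report['n_population']} metabolisms, "
        f"{report['n_sources']} carbon sources, {report['n_pairs']} pairs",
        "",
        "additional carbon sources (beyond individual viability):",
        f"  single metabolisms : {report['mean_individual_additional_sources']:.3f}"
        f" +/- {report['sd_individual_additional_sources']:.3f}",
        f"  null (no exchange) : {report['mean_null_expected_additional']:.3f}"
        f" +/- {report['sd_null_expected_additional']:.3f}",
        f"  interacting pairs  : {report['mean_pair_additional_sources']:.3f}"
        f" +/- {report['sd_pair_additional_sources']:.3f}",
    ]
    fold = report.get("fold_over_null")
    lines.append(
        f"  fold over null     : {fold:.2f}" if fold is not None
        else "  fold over null     : undefined (null expectation is zero)"
    )
    lines += [
        f"  sign test p        : {report['sign_test_p']:.3g}",
        "",
        f"syntrophic potential: median {report['median_syntrophic_potential']:.3f}, "
        f"minimum {report['min_syntrophic_potential']:.3f}; "
        f"{100 * report['fraction_pairs_syntrophic']:.1f}% of pairs syntrophic",
    ]
    if report.get("mean_swap_acceptance_rate") is not None:
        lines.append(
            f"swap acceptance: mean {report['mean_swap_acceptance_rate']:.3f} "
            f"(range {report['min_swap_acceptance_rate']:.3f}"
            f"-{report['max_swap_acceptance_rate']:.3f})"
        )
    if report.get("top_carbon_source"):
        lines.append(
            f"most syntrophic carbon source: {report['top_carbon_source']} "
            f"({100 * report['top_carbon_source_share']:.1f}% of all syntrophies)"
        )
    if report.get("mean_min_exchanged_metabolites") is not None:
        lines.append(
            f"minimum exchanged metabolites: mean "
            f"{report['mean_min_exchanged_metabolites']:.2f} "
            f"over {report['n_min_exchange_solved']} syntrophies"
        )
    if report.get("restored_mean_pair_additional_sources") is not None:
        lines.append(
            "with restored carbon transport: pairs viable on "
            f"{report['restored_mean_pair_additional_sources']:.3f} additional sources"
        )
    if report.get("core_size") is not None:
        assort = report.get("assortativity")
        assort_s = f"{assort:.3f}" if assort is not None and not np.isnan(assort) else "nan"
        lines.append(
            f"carbon-source network: core {report['core_size']}, "
            f"periphery {report['periphery_size']}, outliers {report['n_outliers']}, "
            f"assortativity {assort_s}"
        )
    return "\n".join(lines) + "\n"
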