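# syntro

**De novo syntrophy in randomly sampled viable metabolisms.**

Syntrophy lets a microbial community grow on a substrate that no member
can use alone, through the exchange of metabolites. It is usually
explained as the endpoint of sustained co-evolution; `syntro` asks the
complementary question: how often does syntrophy arise *spontaneously*,
between metabolisms that share no history at all?

The package answers it in silico, for people who work with
constraint-based metabolic models:

1. **Sample** random viable metabolisms: a viability-constrained MCMC
   walk swaps one reaction at a time against a reaction universe,
   accepting a swap iff flux balance analysis (FBA) still predicts
   growth on the metabolism's *primary* carbon source. Long walks
   randomize the reaction complement while preserving that one ability.
2. **Pair** the sampled metabolisms and let them exchange metabolites.
   Pair growth on carbon source C_k is the FBA optimum of the pooled
   reaction set, G(M_i,x, M_j,y, C_k); a pair is *syntrophic* on C_k
   when G(M_i,x, M_i,x, C_k) = 0, G(M_j,y, M_j,y, C_k) = 0 and
   G(M_i,x, M_j,y, C_k) > 0 (growth below the 0.001 viability threshold
   counts as 0). An explicit two-compartment model with gated transfer
   reactions yields the minimum number of metabolites that must be
   exchanged (MILP, with an exhaustive-subset oracle).
3. **Summarize**: the syntrophic potential s̄(M) (fraction of a
   metabolism's pairings that produce a syntrophy), the carbon-source
   pair potential s̄p(C_i, C_j), the no-exchange null expectation
   (n−2)·(1−(1−p_i)(1−p_j)) with an exact sign test against it,
   per-carbon-source syntrophy incidence, syntrophy-essential reactions
   cross-classified against primary-source essentiality, and the
   carbon-source network with core–periphery detection.

Everything runs on synthetic reaction universes built by the package's
own generator (multiple carbon sources funneling into shared hub
intermediates, redundant routes, gain/loss-able transports, flux-free
decoys), so no external model downloads are needed; genome-scale models
can be supplied as a reaction-table TSV or SBML (via `cobra`).
See `docs/methods.md` for the model, assumptions and limitations.

## Worked example

```python
from syntro import (
    UniverseSpec, generate_universe, plant_complementarity,
    growth, joint_growth, detect_syntrophy, min_exchanged_metabolites,
)

spec = UniverseSpec()                      # 5 carbon sources, ~100 reactions
universe, seeds = generate_universe(spec)

print(growth(seeds["C1_e"], universe, "C1_e"))
# 3.3333333333333335  -> 10 carbon units / 3 biomass precursors

pair = plant_complementarity(universe, "C3_e", n_cuts=1)
a, b = pair.metabolism_a, pair.metabolism_b
print(growth(a, universe, "C3_e"), growth(b, universe, "C3_e"))
# 0.0 0.0             -> neither half grows on C3 alone
print(joint_growth(a, b, universe, "C3_e"))
# 3.3333333333333335  -> together they do: a syntrophy

rec = detect_syntrophy(a, b, universe, spec.carbon_sources)
print(sorted(rec.syntrophic_sources))
# ['C3_e']
sol = min_exchanged_metabolites(a, b, universe, "C3_e")
print(sol.count, sorted(sol.exchanged_metabolites))
# 1 ['C3_x1']         -> one cross-fed intermediate suffices
```

The full pipeline (sampling, pairing, potentials, network, report) runs
from a YAML config:

```bash
syntro synth --out universe.tsv --seeds seeds.jsonl --seed 1
syntro sample --universe universe.tsv --seeds seeds.jsonl \
    --per-source 5 --steps 2000 --seed 1 --out pop.jsonl
syntro pair --universe universe.tsv --population pop.jsonl --out pairs.csv
# or everything at once:
syntro run --config config.yaml
```

`syntro run` prints a summary such as mean additional carbon sources for
single metabolisms, for the no-exchange null, and for interacting pairs,
with the sign-test p-value and the syntrophic-potential distribution.

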