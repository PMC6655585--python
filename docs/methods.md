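# Methods

## The question the package answers

Syntrophy — a pair (or community) of organisms growing on a substrate
none of them can use alone, mediated by metabolite exchange — is usually
explained as the product of sustained co-evolution. The alternative is
that it arises *de novo*: two metabolisms with no shared history happen
to be pathway-complementary the moment they meet. `syntro` quantifies
that possibility in silico. It samples metabolisms with no evolutionary
history but a guaranteed ability to grow on one primary carbon source,
pairs them, lets the pairs exchange metabolites, and measures how often
the pair unlocks carbon sources neither member can use alone.

## Model and procedure

### Viability by flux balance analysis

A metabolism is a subset of a fixed reaction universe, always containing
the single biomass pseudo-reaction. In an environment consisting of a
minimal medium plus one carbon source bounded at 10 flux units, growth is
the optimum of the standard FBA linear program: maximize biomass flux
subject to steady-state mass balance `S v = 0` and flux bounds
(irreversible reactions `[0, inf)`, reversible `(-inf, inf)`). Exchange
columns exist for every extracellular metabolite: medium components are
unbounded, the carbon source may be taken up to its bound, and everything
else is secretion-only — so losing the transport reaction for a carbon
source genuinely blocks it. A metabolism is *viable* when the optimum
strictly exceeds 0.001; growth at or below the threshold is reported as
zero. Solver fluxes below 1e-9 are clamped to zero before the comparison,
making the threshold test reproducible.

The biomass reaction demands all precursors jointly; viability is judged
on that single aggregate objective (the simplest reading of "all essential
biomass molecules"), not per-compound.

### Sampling random viable metabolisms

One MCMC step deletes a uniformly chosen non-biomass reaction and inserts
a uniformly chosen universe reaction not currently present (drawing from
the absent set keeps the metabolism size exactly constant); the swap is
accepted iff the result remains viable on the primary carbon source.
Repeating for many steps (50,000 at genome scale; 2,000 at the package's
desk scale, where the universe is ~50x smaller) randomizes the reaction
complement while preserving primary-source viability. Each walk runs on
its own RNG seeded `base_seed + walk_index`, so a whole population
reproduces from one integer.

Size reduction removes, one at a time, reactions that are dispensable —
equivalently, flux-free in some viable flux distribution — chosen
uniformly by rejection sampling with a cache of reactions already proven
essential (essentiality is monotone under further deletion, so the cache
stays valid). Removability is thereby recomputed as redundancy is
consumed. The alternative reduce-then-walk mode is available but off by
default; it constrains the walk more and accepts fewer swaps.

The `zero_flux_reactions` diagnostic is stricter than "dispensable": it
reports reactions with zero flux in *every* optimal solution, established
by flux variability over the optimal face, which is robust to degenerate
alternative optima.

### Syntrophy detection and metabolite exchange

Pair growth `G(A, B, C_k)` is the FBA optimum of the *pooled* metabolism
(union of reaction sets). A pair is syntrophic on `C_k` when both
individual growths are zero and the pair growth is positive; `S = 1` if
that holds for any carbon source. A metabolism never forms a syntrophy
with itself.

Pooling is mathematically equivalent to an explicit two-compartment model
in which every metabolite is duplicated, each compartment keeps its own
environment exchanges, the carbon uptake bound is shared between the
compartments (one inequality row), and reversible transfer reactions
couple the copies. The package implements both; with all transfers open
they agree to 1e-6 (verified on 200 pairs per test run), with no
transfers the compartments decouple.

The minimum number of exchanged metabolites is a MILP over the explicit
model: one binary per metabolite gates its transfer flux through a big-M
pair of inequalities (`big_m = 1000 x` the carbon uptake bound), the
objective minimizes the number of open gates, and joint growth must
exceed the viability threshold. Because big-M gating can leak flux within
the solver's integrality tolerance, every candidate set is re-verified by
an exact LP restricted to it; an insufficient set `S` is excluded with
the valid cut "open at least one metabolite outside `S`" (valid because
feasibility is monotone in the allowed-exchange set) and the MILP is
re-solved. An exhaustive subset search over the same explicit model is
the independent oracle on universes of at most 12 metabolites.

### Statistics

* Syntrophic potential `s̄(M)`: fraction of a metabolism's `N - 1`
  pairings with `S = 1`.
* Carbon-source pair potential `s̄p(C_i, C_j)`: fraction of pairings
  between the two primary-source classes with `S = 1`; denominators are
  `per_source^2` for distinct sources and `C(per_source, 2)` within one
  source. The published constants (999, 400, 190 at 20-per-source,
  50-source populations) are recovered and asserted in tests.
* No-exchange null: with per-metabolism extra-viability probabilities
  `p_i` (estimated as additional viable sources over the `n - 1`
  non-primary candidates), a non-interacting pair is expected viable on
  `(n - 2)(1 - (1 - p_i)(1 - p_j))` additional sources (`n - 1` when the
  primaries coincide).
* Observed-vs-null significance: exact two-sided binomial sign test on
  paired differences, ties dropped.
* The augmentation comparison uses a two-proportion test implemented as
  the 2x2 chi-squared statistic without continuity correction.

### Carbon-source network

Nodes are carbon sources, edge weights the pair potentials; the 0.55
threshold only filters the *displayed* edges, analysis uses all weights.
Core-periphery structure maximizes the Pearson correlation between the
off-diagonal weights and the ideal two-role pattern (periphery-periphery
ties absent, all others present) by greedy single-node flips from 50
seeded random restarts. Since the ideal pattern gives every node core
ties at least as strong as its periphery ties, a node whose mean weight
to the periphery exceeds its mean weight to the core by more than 0.1
fits neither role and is reported as an outlier. An equal-weight network
is returned flagged `degenerate`. Weighted degree assortativity (NaN when
undefined, e.g. zero degree variance) summarizes disassortativity.

## The synthetic universe

Real curated universes (thousands of reactions) are inputs the package
can read, not data it ships; all tests and the acceptance run use the
generator. It emulates the structural features the analysis relies on:

* several carbon sources, each with its own transport reaction and a
  short source-specific pathway (default 2 reactions) funneling into one
  of a small number of shared hub metabolites — peripheral catabolism
  feeding shared central metabolism;
* hub-to-precursor reactions and a single biomass reaction consuming all
  precursors (plus the medium's nitrogen source when enabled);
* redundant parallel routes (two-reaction detours) at every pathway step,
  so randomized metabolisms can lose one route and stay viable, and two
  metabolisms can be complementary;
* mass-balanced decoy reactions on an acyclic private metabolite set,
  provably flux-free in every environment, which gives swaps neutral
  material and size reduction room to work.

All stoichiometric coefficients are 1, so every LP optimum has a
pencil-and-paper oracle (10 carbon units yield biomass flux
`10 / n_biomass_precursors`). Default seed metabolisms hold their full
pathway module plus 12 decoys — about a third of the universe, matching
the reaction-complement-to-universe ratio of genome-scale models. Every
emitted seed is self-checked viable on its primary source, and generation
is deterministic given the spec seed.

`plant_complementarity` splits one source's single-route pathway between
two partners at chosen cut points (segments alternate, so exchange flows
both ways); each partner optionally carries a complete single-route
pathway for its own distinct primary source. By construction neither
partner grows on the split source, the pair does, and the minimal
exchange set is exactly the cut metabolites. `generate_null_population`
includes complete pathway modules atomically (each with probability
`p_extra`), so pooling can never unlock anything — pairs from it realize
the no-exchange null with known `p_i`.

What the generator does *not* emulate: cofactor and energy coupling,
non-unit stoichiometry, reversible central pathways, compartments beyond
in/out, and the sheer redundancy of real biochemistry. Passing tests
therefore demonstrate correctness of the machinery and the qualitative
emergence of de novo syntrophy under the modeled structure, not
quantitative rates for any real organism.

## Problem sizes and numerical choices

The package's standard analysis scale (used by `scripts/acceptance.py`
and the heaviest test) is 5 carbon sources x 5 metabolisms per source
with 2,000-step walks on the default ~100-reaction universe — a
deliberate desk-scale choice that keeps a full run in minutes while
leaving every pipeline stage nontrivial. LPs use HiGHS via
`scipy.optimize.linprog`; MILPs use `scipy.optimize.milp`. Solver
tolerance 1e-9, viability threshold 0.001 (strict exceedance), pooling
equivalence asserted at 1e-6, MILP growth constraint at threshold + 1e-6.
Ties in the sign test are dropped; the two-proportion test returns 1.0
for degenerate all-zero or all-one tables.

## Known limitations

* The sampler makes no claim of uniformity over the viable genotype
  space; it matches the stated swap procedure, and only divergence from
  the start is monitored.
* Whether a replacement reaction already present should be redrawn is
  ambiguous in the procedure's prose; drawing from absent reactions only
  (preserving size exactly) is the implemented reading.
* The minimal-exchange MILP may return a different minimum-cardinality
  set than other formalizations when several minima tie; only the count
  is uniquely defined.
* Restoring carbon transport extends individual viability profiles by
  construction; the *pair-additional* count is relative to those profiles
  and need not increase at desk scale, where transport is often the only
  missing piece for individuals too.
* With very sparse syntrophy (few or all-equal pair potentials) the
  carbon-source network can be flagged degenerate; partitions are then
  not meaningful and are reported as such.
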