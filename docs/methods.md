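# Methods

## Problem

A genome-scale metabolic network (GSMN) `G = {R, M, S}` has reactions `R`
(with flux bounds `v_min`, `v_max` and gene–protein–reaction rules),
metabolites `M`, and the m×n stoichiometric matrix `S`. Context-specific
reconstruction selects the sub-network most consistent with condition-specific
expression evidence under steady state (`S·v = 0`). Because the selection is
discrete and the constraints underdetermine it, many sub-networks fit the data
*equally well*; this package treats the set of co-optimal sub-networks as the
object of study and provides four strategies to enumerate diverse samples of
it, plus the downstream analyses (diversity metrics, ensemble gene
essentiality, pathway over-representation) that make the enumeration useful.

## The base MILP

The reconstruction objective is the iMAT score. Reactions are split into R_H
(associated with highly expressed enzymes) and R_L (lowly expressed), and the
MILP maximizes the number of R_H reactions carrying at least ε flux plus the
number of R_L reactions carrying none:

```
max  Σ_{i∈R_H} (x⁺_i + x⁻_i) + Σ_{i∈R_L} xᵒ_i
s.t. S·v = 0,  v_min ≤ v ≤ v_max
     v_i + x⁺_i (v_min,i − ε) ≥ v_min,i      i ∈ R_H
     v_i + x⁻_i (v_max,i + ε) ≤ v_max,i      i ∈ R_H (reversible; x⁺+x⁻ ≤ 1)
     v_i + xᵒ_i v_min,i ≥ v_min,i            i ∈ R_L
     v_i + xᵒ_i v_max,i ≤ v_max,i            i ∈ R_L
```

`build_imat` constructs exactly this constraint set. ε (default 1e-3 in
`EnumerationConfig`) is the minimal flux magnitude for a reaction to count as
active; it must be chosen per model (see *Numerical choices*).

### Consolidated activity indicators

The enumeration layer reasons about a single direction-insensitive 0/1
activity vector per solution — the object that integer cuts, distances and
the dissimilarity objective operate on. `add_activity_indicators` augments the
MILP with one binary `a_i` per reaction such that `a_i = 1 ⟺ |v_i| ≥ ε` and
`a_i = 0 ⟺ v_i = 0`, tied to the iMAT binaries (`a = x⁺ + x⁻` on R_H,
`xᵒ = 1 − a` on R_L) and to fresh directional indicators elsewhere. Two
consequences, both deliberate:

* fluxes strictly between 0 and ε are excluded for **every** reaction, so the
  activity vector is a well-defined function of the MILP solution and two
  solutions are "the same network" exactly when their active-reaction sets
  coincide (direction-only flips are not counted as distinct networks);
* the enumeration optimum z* is the optimum of this ε-quantized formulation.
  On well-scaled models (bounds ≫ ε, scalable fluxes) it coincides with the
  plain formulation's optimum; on models where an optimal solution *requires*
  a sub-ε flux it can be lower.

Without this quantization the plain formulation is numerically treacherous:
MILP solvers accept binaries within an integrality tolerance (~1e-6), and a
binary resting at 1−1e-6 relaxes its big-M constraint by (bound × tolerance).
With bounds of 1000 that is a leak of order 1e-3 — indistinguishable from a
small ε, which lets "inactive" reactions patch broken routes and yields
phantom optimal networks. We observed exactly this on the benchmark before
quantizing (the solver returned a better-than-true objective, and cut-based
enumeration produced more "distinct" solutions than the ground-truth count).

## Enumeration strategies

All four return a deduplicated, ordered `SolutionSet` whose members share the
optimal score z*; completeness (`complete=True`) means exhaustion was proved
by infeasibility, not that a limit was hit.

**reaction_enum** — solve once for a reference optimum, then flip each
reaction's state relative to it in model file order: active reactions are
blocked (bounds `[0,0]`), inactive ones are forced forward (lower bound ε),
with an additional backward trial (upper bound −ε) for reversible reactions.
A perturbed solution is kept iff it still scores z*. With `track_states` on, a
trial is skipped when some retained solution already exhibits the target state
for that reaction (the skip test consults retained solutions only). Fast and
systematic, but blind to combinations of changes.

**icut_enum** — exhaustive enumeration. After the reference solve the
objective is pinned (`Σx = z*`) and each found solution `x*` is excluded by
the linearized integer cut

```
Σ_{i∈A} a_i − Σ_{i∈B} a_i ≤ (Σ_i x*_i) − 1,   A = {i | x*_i=1}, B = {i | x*_i=0}
```

over the activity indicators. Iterating solve → cut until infeasibility
provably yields the complete optimal set Ω*.

**maxdist_enum** — repeatedly minimizes `g(x, x*) = Σ_{i: x*_i=1} a_i`, the
overlap of ones with the previous solution, under the optimality equality and
all accumulated cuts. At fixed score, minimal overlap is maximal Hamming
distance, so the search jumps to the far boundary of the solution polytope
first and works inward.

**diversity_enum** — phase 1 seeds the set via the reaction-enum scan and
installs a cut per seed. Phase 2 iterates from the last seed: at step
i = 0, 1, 2, … each active reaction of the current solution enters the
dissimilarity target independently with probability `1 − d_s^i`, and the MILP
minimizes overlap with that target under the cuts. The schedule starts local
(empty target at i=0: the cut alone forces novelty) and converges to full
maxdist behaviour; `d_s` (default 0.995) sets the transition speed, e.g.
`1 − 0.99^70 ≈ 0.5`. `d_s = 0` is defined as probability 1 at every step, so
the post-seed phase is exactly a maxdist continuation (the limit case, not
`0^0 = 1` arithmetic, is the intended semantics, and a test pins it).
One RNG stream per run (`numpy` PCG64, seeded from the config) is consumed in
reaction-index order, making runs bit-reproducible.

## Benchmark with known ground truth

`build_dag_model(DagSpec(L, N))` builds a layered DAG: source metabolite m_s
feeds N layer-1 metabolites, every layer-k metabolite feeds every layer-(k+1)
metabolite, layer L drains into sink m_t, plus one import and one export
exchange. Counts: `2 + N·L` metabolites and `2N + N²(L−1) + 2` reactions, all
irreversible with bounds [0, 1000]. Under the scenario "R_H = ∅, R_L = R,
export flux ≥ ε", an optimal network is a minimum-cardinality flux route: a
single source-to-sink path (L+1 internal reactions) plus both exchanges, and
there are exactly `N^L` of them — `enumerate_ground_truth` materializes all
of them combinatorially as the oracle the enumeration strategies are tested
against. For L=5, N=4: 74 reactions, 22 metabolites, 1,024 optimal networks.

## Diversity metrics

Normalized Hamming distance `δh(x,y) = (1/n) Σ|x_i − y_i|` over **all** n
reactions (not only partitioned ones), so values are comparable across
partitions. δ̄h averages over all unordered pairs; δ̄hnn averages each
solution's distance to its nearest neighbour and measures spread (two tight
clusters far apart: large δ̄h, small δ̄hnn). `diversity_trace` reports both
for every prefix of an ordered set, tracking how diversity evolves during a
run.

## Ensemble essentiality

For each enumerated network, the generic model is bound-silenced down to the
network's active reactions (reactions are never removed, keeping indices
stable), and every gene is deleted in turn: reactions whose GPR evaluates
false without the gene are silenced and the biomass optimum recomputed by
FBA. A gene is essential for a network when the knockout optimum falls below
`threshold_ratio` (default 0.01) of that network's own wild-type optimum —
each submodel is its own reference, so essentiality means "this context
cannot reroute". Per-network calls are OR-combined: the ensemble calls a gene
essential if any member network does, trading false positives for
sensitivity. Networks with zero wild-type objective are excluded and
reported. TPR/FPR are computed against a curated truth table; genes absent
from the table are skipped and counted.

## Pathway over-representation

Per network, each pathway's 2×2 table (active membership vs pathway
membership) is tested with the one-sided Fisher's exact test (hypergeometric
right tail), BH-adjusted across pathways *within* that network; the union
summary marks pathways enriched (adjusted p < α, default 0.05) in at least
one network. The background defaults to all reactions of the generic model —
the only universe shared by every network, keeping p-values comparable; a
flag allows passing a restricted background instead.

## Expression preprocessing

Genes are classed on their own expression distribution with
linear-interpolation empirical quantiles: strictly below the lower quantile →
−1 (lowly expressed), strictly above the upper → +1, ties with a threshold →
0 (so a constant profile classifies everything 0). Classes propagate to
reactions through GPR trees with AND = min and OR = max on the {−1, 0, +1}
lattice (a complex needs all subunits; isoenzymes rescue each other);
reactions at +1 form R_H, at −1 form R_L. `random_partition_fixture` samples
disjoint random R_H/R_L reaction sets directly for benchmark-style runs on
models without usable expression data.

## Numerical choices

* Solver: HiGHS through `scipy.optimize.milp`, behind a named-backend
  registry. Solves are deterministic; the `seed` in `SolverConfig` is recorded
  for provenance. Default `mip_gap = 0`: a solution counts as optimal only at
  score exactly z*, which the cut and equality semantics require; the gap is a
  config knob for exploratory use.
* ε must satisfy ε ≫ max|bound| × 1e-6 (the solver's integrality tolerance),
  or inactive reactions can leak flux (see above). The DAG benchmark uses
  ε = 1 against bounds [0, 1000]; a runtime warning fires when fluxes near
  ε/2 appear on reactions marked inactive. The general default ε = 1e-3 is
  appropriate for models whose relevant bounds are O(1)–O(10).
* Fluxes below 1e-9 are snapped to zero before activity derivation; without
  the indicator layer, activity falls back to flux thresholds (|v| ≥
  ε(1−1e-6) on R_H, |v| > 1e-6 elsewhere).
* Degenerate inputs: blocked reactions get a fixed-zero indicator; an R_H
  reaction that can never reach |v| ≥ ε is reported as a warning finding but
  still modelled (its binary is simply forced 0); reversible R_L reactions
  get a single xᵒ, not a split pair.
* Ties in nearest-neighbour distances are handled by `min` naturally; BH uses
  the standard step-up recursion (via statsmodels).

## What the tests do and do not show

The synthetic instances (the layered DAG, the parallel-path knockout toys,
random R_H/R_L draws) have unit stoichiometry, generous bounds, no
thermodynamically infeasible loops, and fully scalable fluxes. They exercise
the enumeration semantics exactly (the DAG's optimal set is known in closed
form), but passing them does not certify behaviour on genome-scale models
with ill-scaled bounds, large loops, or dense GPR overlap — there, per-solve
timeouts, the ε scale rule above, and the completeness flag matter. Problem
sizes in the test suite are chosen so the full suite runs on one CPU in
minutes: complete enumerations up to 1,024 solutions (the 5×4 DAG), oracle
cross-checks up to 64 solutions, metric oracles up to 200 vectors.

## Known limitations

* Only the iMAT objective is implemented behind the enumeration layer; the
  MILP interface is pluggable but no alternative reconstruction objective
  ships.
* No solver-internal solution pools or custom branch-and-cut callbacks; every
  solution costs one MILP solve.
* Enumeration identity is ε-quantized reaction activity; direction of flux
  through reversible reactions does not distinguish solutions.
* `icut_enum`'s completeness proof assumes exact integer optimality; with a
  nonzero `mip_gap` the "complete" flag must not be trusted, and the per-solve
  timeout can truncate any strategy (flagged in `stats` and warnings).
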