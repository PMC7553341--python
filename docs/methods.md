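# Methods

## Problem and model

A protein–protein interaction network (PPIN) is an undirected graph of
proteins and physical interactions. Functional modules — groups of
proteins acting in the same complex or process — appear as densely
interconnected regions whose members share interaction partners. The
pipeline turns module detection into a one-dimensional ordering problem:
if a dissimilarity between proteins reflects neighbourhood overlap, a
shortest Hamiltonian path through all proteins arranges functionally
related proteins contiguously, and modules can be read off as
low-dissimilarity stretches of the path.

### Czekanowski–Dice distance

For proteins *i*, *j* with open adjacency lists Int(*i*), Int(*j*):

d_ij = (|Int(i) ∪ Int(j)| − |Int(i) ∩ Int(j)|) / (|Int(i) ∪ Int(j)| + |Int(i) ∩ Int(j)|).

The **open-neighbourhood convention** (a protein is not in its own
adjacency list) is deliberate: under it, two interacting proteins with no
common partner are at distance 1 — interaction alone carries no evidence
of shared function — which is the behaviour the six-protein worked
example in the test-suite pins down (d(A,B) = 1 although A–B is an
edge). The closed-neighbourhood variant of this distance that also
appears in the clustering literature is intentionally not implemented.
Because |∪| + |∩| = deg(i) + deg(j), the whole matrix is computed as
`1 − 2·(A@A)/(deg_i + deg_j)` with one integer matrix product; a
set-arithmetic oracle cross-checks it in the tests.

The distance is undefined (0/0) for isolated proteins, so the graph
loader removes degree-0 proteins (after dropping self-loops and duplicate
records) with a logged warning. An isolated protein also cannot be
placed meaningfully on an interaction-distance tour, so removal, not
imputation, is the right behaviour. All node orderings are lexicographic
on the identifier, which makes every downstream stage deterministic.

## Shortest-path sequencing

The path problem is embedded as a cycle problem through a **dummy node**
at distance 0 to every protein: a minimum cycle containing such a node is
exactly a minimum path plus two free ends, so cycle and path optimality
coincide and the machinery of cycle-improvement heuristics applies
unchanged.

**Construction.** Greedy nearest-neighbour from the dummy node. All
proteins tie at distance 0 from the dummy, so the path starts at the
lexicographically smallest label; every later tie breaks the same way.

**Improvement.** Sequential K-opt in the Lin-Kernighan style. A move is
grown as an alternating chain of removed and added links subject to the
five classic criteria: sequential exchange (consecutive links share an
endpoint), feasibility (every intermediate configuration is a valid
Hamiltonian path — automatic here because each chain step is a prefix
reversal of the open path), positive gain (the running
removed-minus-added sum stays strictly positive), disjunctive (a link
added in a chain is never one removed earlier in it), and candidate
restriction (added links must come from per-node nearest-neighbour
candidate lists). The chain closes back to the anchor as soon as the
total gain including the closing link is positive; scanning then
restarts, and the search terminates when a full scan over anchors finds
no improving move, which guarantees the returned length never exceeds
the input length.

Parameters (`LKParams`): `max_move_depth` K = 5 by default (moves remove
at most 5 links), `candidate_list_size` 5, `runs` 1, `seed` 0. With
`runs > 1` the search restarts from seeded perturbations of the
incumbent — a double-bridge 4-opt kick for larger instances, a fresh
random permutation for instances of ≤ 12 nodes where a double bridge
barely changes anything — and each restart also shuffles the anchor scan
order. This last point matters: with a fixed scan order the
first-improvement dynamics are so strongly convergent that independent
restarts can funnel into the same local optimum; decorrelating the scan
order removes that failure mode. With full candidate lists
(size n − 1), depth 6 and 16 runs the search matched an exact
Held–Karp dynamic-programming oracle on 4 000/4 000 random instances
with n ≤ 9 during development; the test-suite re-verifies 50 such
instances plus the worked example against brute-force enumeration.

Backtracking breadth is the full candidate list at chain depths ≤ 3 and
a single (nearest) candidate deeper, a standard efficiency compromise.
The partitioning-and-merging machinery that large TSP solvers use for
instances with millions of nodes is deliberately omitted: PPIN instances
in the intended range (≲ a few thousand proteins) are optimised directly.

## From path to modules

1. **Segmentation.** The path is cut at every consecutive pair with
   d > δ (`cut_threshold`). The default δ is the empirical 75th
   percentile of the tour-edge distances, so roughly the longest quarter
   of the path edges is severed; a fixed δ can be supplied instead. The
   cut rule is the simplest one consistent with "close on the path ⇒
   likely the same module"; it is the genuinely open design point of the
   pipeline and is therefore fully exposed in configuration.
2. **Function-information merging.** Module-pair similarity is
   S(M_A,M_B) = Σ s(i,j) / min(|M_A|,|M_B|) with s the Jaccard index of
   GO term sets (s = 0 when both proteins are unannotated). The pair
   with the **largest** S among those exceeding θ is merged first, all
   similarities involving the union are recomputed (the min-size
   normalisation changes after a merge), and the loop repeats until no
   pair exceeds θ — at most (initial count − 1) merges. Ties break on
   the lexicographically smallest member labels. Merge order genuinely
   affects the result, which is why a deterministic highest-first order
   is fixed rather than left to iteration order. Protein-pair
   similarities are cached once as a matrix, so the loop cost is
   submatrix sums.
3. **Density filtering.** Module density is e/(N(N−1)/2) with N the
   number of proteins in the module and e its internal edge count;
   singletons score 0 by convention. Modules below `density_min`
   (default 0, i.e. no filtering) move wholesale to an explicit
   *unassigned* pool — proteins are never silently dropped, and the
   union of modules plus unassigned always equals the input protein set.
   `keep_singletons` (default on) controls whether single-protein
   modules survive the filter at all.

## Validity indices

Cohesion C_o = S̄ + 1/D̄ (S̄ when D̄ = 0) with S̄, D̄ the mean GO similarity
and mean CD-distance over **intra-module pairs**; separation
S_e = D̄ + 1/S̄ (D̄ when S̄ = 0) over **cross-module pairs**. Using the
pooled mean over all relevant pairs is a choice — other aggregations are
defensible — so the aggregation is pluggable (`aggregate="pooled"` or
`"macro"`, the latter averaging per module / per module pair first).
Note the 1/S̄ term makes S_e discontinuous at S̄ = 0: a partition with no
cross-module annotation overlap scores only D̄, while one with tiny
overlap scores D̄ + 1/S̄. Comparisons of S_e across partitions are
therefore only meaningful within the same branch; the test-suite's
random-partition comparison keeps a shared background term in every
annotation set for exactly this reason.

The adjusted Rand index (delegated to scikit-learn's contingency-table
implementation, cross-checked against a closed-form computation in the
tests) quantifies agreement with planted ground truth; unassigned
proteins count as one extra predicted cluster.

## Synthetic benchmark

`SynthSpec`/`generate_ppin` produce a planted-partition graph — each
intra-module pair is an edge with probability `p_in`, each cross-module
pair with `p_out` — plus per-module disjoint GO term pools. Each protein
draws `terms_per_protein` terms without replacement from its own pool,
each draw replaced with a foreign-pool term with probability
`annotation_noise`. Proteins left isolated by the random draw are
re-wired to one random partner inside their own module (any partner for
a singleton module), so the generated graph always satisfies the cleaned
graph invariants and the truth labelling stays total. `p_out = 0` is
legal and produces disconnected graphs; the tour simply crosses
components through distance-1 edges, which segmentation cuts.

The standard benchmark configuration (the generator defaults) is five
modules of 20 proteins, p_in = 0.8, p_out = 0.05, pools of 12 terms,
4 terms per protein, 10 % annotation noise. Under these conditions
intra-module CD-distances concentrate near 0.4 and cross-module
distances near 0.9, and intra-module Jaccard similarities near 0.2. The
recovery test freezes δ at the percentile default and θ = 1.0; this
threshold pair was established once, by scanning candidate values over
the 20 benchmark seeds before the test was frozen, and is not tuned
thereafter. θ values in the 0.05 range, natural for sparse real GO
annotation where cross-module protein pairs rarely share any term, merge
aggressively under the dense synthetic annotation model: with 20-protein
modules the cross-pair similarity *sum* divided by min-size easily
exceeds 0.05 even at 10 % noise. θ must therefore be read as scaled to
the annotation regime, not as a universal constant. At the frozen
settings the pipeline recovered the planting with ARI ≥ 0.949 on all 40
development seeds; the test requires ARI ≥ 0.9 on ≥ 18 of seeds 0–19.

What the generator does **not** emulate: the heavy-tailed degree
distributions of real interactome screens, correlated false
positives/negatives of specific assays, the GO DAG (terms are flat,
unrelated symbols — no semantic similarity between distinct terms), and
inter-species differences in annotation depth. Passing the recovery test
therefore demonstrates correctness of the machinery on networks with
genuine planted modular structure, not field performance on any
particular interactome.

## Numerical and degenerate-input conventions

- Distances are kept at full float precision; the worked-example
  comparisons use absolute tolerance 5×10⁻⁵ because the reference values
  are rounded to four decimals.
- Gain comparisons in the tour search use an absolute epsilon of 10⁻¹²;
  tour lengths are validated against recomputation at 10⁻⁹.
- Single-node and two-node instances bypass the optimiser (every
  ordering is optimal).
- A protein absent from the annotation file has the empty term set;
  Jaccard 0/0 (two unannotated distinct proteins) is defined as 0.
- The diagonal of the distance matrix is stored as 0 and never consumed.
- Module tables list modules as M1, M2, … ordered by smallest member,
  proteins sorted within, unassigned proteins last with id `NA`; output
  is byte-deterministic.

## Known limitations

- The greedy highest-first merge is order-dependent by construction;
  a different (e.g. threshold-order) merge policy can give different
  partitions at equal θ.
- The K-opt search is a heuristic: exactness is only verified at desk
  scale (n ≤ 9), and large instances get good, monotone-improved, but
  not certified-optimal paths.
- Modules are disjoint; overlapping complexes (shared subunits) cannot
  be represented — proteins belong to exactly one module or to the
  unassigned pool.
- GO terms are compared as opaque strings; no ontology-graph semantic
  similarity, no namespace separation, no evidence-code weighting.
- Cohesion/separation absolute values depend on the chosen pair
  aggregation and on the annotation regime; they are comparable between
  runs of this package, not across tools using other aggregations.
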