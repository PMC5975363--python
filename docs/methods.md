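# Methods

## Model

A regulatory network is a signed digraph on nodes `V = {1..N}` with at most
one edge per ordered pair.  Each node carries product-of-sums logic over
its inputs.  The associated switching system is

    dx_i/dt = −γ_i x_i + M_i(σ_i(x)),   γ_i > 0,

where `M_i` is the product over sum-groups of step-function values: the
step for input `j` sits at its low value `l_{i,j}` below the threshold
`θ_{i,j}` and at its high value `u_{i,j}` above it (the comparison is
reversed for repressors), with `0 < l < u` and all thresholds of a given
source node distinct.  The dynamics of such a system are captured, domain
by domain, by a discrete surrogate:

* **State lattice.**  Node `i` has integer levels `0..m_i`, `m_i` = its
  number of targets (one threshold per target).  States stand for the
  rectangular phase-space domains cut out by the thresholds; the geometric
  domains themselves are never materialized.
* **Combinatorial parameter `(O, D)`.**  `O_i` is the total order of node
  `i`'s outgoing thresholds (a permutation of its targets).  `D` is the
  multi-level map: node `i` reads, for each input `j`, the bit
  `s_j ≥ rank_{O_j}(i)` (negated for repression, so the bit always means
  "step function high"), and applies its logic map
  `c_i : {0,1}^{n_i} → {0..m_i}`, which counts how many of its own
  thresholds lie below `M_i/γ_i` for that input combination.
* **Asynchronous update.**  The state transition graph (STG) has a
  self-loop at `s` iff `D(s) = s`, and otherwise one edge per coordinate
  with `D(s)_i ≠ s_i`, moving that coordinate one step toward its target.
  Out-degree therefore equals the number of disagreeing coordinates (or 1
  for a fixed state).

Two continuous parameter sets are equivalent when they induce the same
`(O, D)`; the finitely many classes are the nodes of the **parameter
graph**, and each class is analyzed once.

## Enumerating factor parameters

Per node, candidate logic maps are all monotone nondecreasing tables
`{0,1}^n → {0..m}` (monotone because the input bit already absorbs the
edge sign).  A candidate is **realizable** iff positive values
`0 < l_j < u_j` exist with `f(b) < f(b')` whenever `c(b) < c(b')`, where
`f(b)` is the product over groups of the selected low/high sums — strictly
increasing thresholds separating the level sets can then always be
interleaved, and `γ` is fixed to 1 throughout since only `M/γ` is compared
with thresholds.  The oracle has two tiers:

* **Pure sums (single group, includes every 1-input node).**  Exact
  strict-feasibility LP over `{l_j, u_j, θ_k}` with a maximized margin
  variable (scipy HiGHS); realizable iff the optimal margin exceeds 1e−7.
  Variables are bounded above (scale invariance) so the LP is bounded.
* **Products of groups.**  First, 4,000 log-uniform witness draws over
  `log l, log(u−l) ∈ [−6, 6]` (seed 0): any candidate whose required
  strict inequalities hold at a sampled point is certified realizable with
  that witness.  Candidates still undecided get multi-start Nelder–Mead
  (32 starts, staged hinge margins 0.05 then 1e−3) minimizing
  `Σ max(0, μ − (log f(b') − log f(b)))²` in the same log-parameterization,
  declared realizable only if a point satisfies every inequality with
  relative margin ≥ 1e−9.  On the shapes exercised here the sampling stage
  alone certifies every feasible candidate and optimization serves to
  (fail to) rescue the infeasible ones, which is what makes the decision
  robust to optimizer quirks.

Results are cached in-process keyed by `(group sizes, m, seed)`;
realizability depends only on that shape, not on edge signs or on which
node supplies which input.  For the 3-input logic `(a+b)(~c)` with two
outputs this yields 155 realizable maps out of 168 monotone candidates;
for the 2-input product `a·b` all 20 monotone candidates are realizable.
These two counts multiply out to the published parameter totals of the
bundled benchmark networks and act as regression anchors for the oracle.

**Essential restriction** (`: E`): keep only maps in which every input is
essential — for each input bit some pair of combinations differing only in
that bit changes the output.  Output-level surjectivity is *not* required;
the compatibility definition constrains inputs only, and the test suite
verifies that every essential parameter's `D` indeed carries a
sign-correct witness per edge.

**Threshold orders** enumerate independently of logic maps (feasibility
sees only the sorted threshold values), as rank vectors in lexicographic
order.  The factor list is the Cartesian product, logic-map-major, giving
every parameter a stable mixed-radix index (node 0 least significant).

**Factor adjacency** (parameter-graph edges): two entries of one node are
adjacent iff they share the logic map and the orders differ by one
adjacent transposition, or share the order and the tables differ at
exactly one combination by exactly one level.  Read literally on the
induced map `D : V → V`, a "single-state unit change" would almost never
fire (one table cell affects every state sharing that input combination),
so the neighbor relation is defined at the factor level; global adjacency
is "exactly one node's entry replaced by an intra-factor neighbor".

## Morse graphs and canonical forms

Recurrent components are SCCs of the STG carrying a nonempty path (size
≥ 2, or a fixed state).  Components are ordered by minimal state index;
reachability between them, reduced to its transitive reduction, gives the
Hasse diagram (source upstream).  Labels:

* singleton: `FP(v_1,...,v_N)`, suffixed ` OFF` when all coordinates are
  zero and ` ON` when none is — so the SQL pattern `like "FP%"` matches
  every fixed point;
* larger components: `FC` when internal edges change every coordinate
  belonging to a node with at least one target (strong connectivity then
  supplies a single path crossing a threshold in each such variable),
  otherwise `XC(...)` listing the changing variables in network order.
  Nodes without targets have a single level and are excluded from the
  coverage requirement.

Morse graphs are deduplicated by a canonical string: color refinement
seeded by (longest-path level from the sources, label) and refined by
sorted successor/predecessor colors, followed by individualization that
minimizes the rendered string (exhaustive for graphs ≤ 16 nodes; beyond
that the refined order is used directly, which can at worst store an
isomorphic duplicate — never merge distinct graphs, since the string
encodes the full labeled graph).  Vertex numbers in the database are
positions in this canonical order; Morse graph indices are assigned in
first-seen parameter order.  Both choices make re-runs byte-identical.

## Database

SQLite tables `Signatures(ParameterIndex, MorseGraphIndex)`,
`MorseGraphAnnotations(MorseGraphIndex, Vertex, Label)`,
`MorseGraphEdges(MorseGraphIndex, Source, Target)`, plus a provenance
table `MorseGraphs(MorseGraphIndex, CanonicalString)`.  The stable-FC and
stable-FP queries are embedded verbatim as SQL (label match minus edge
sources) rather than re-expressed through the API, so any schema drift
breaks the tests.  Files are written to a temporary path and renamed, so
an interrupted run leaves no partially valid database.

Two sweep engines produce identical bytes: a pure-Python reference path
(networkx SCCs and condensation) and a numba-compiled kernel that decodes
each parameter, builds `D` over packed arrays, runs iterative Tarjan on
the implicit STG, accumulates reachability over the SCC completion order,
and emits a compact record that the Python side canonicalizes and
deduplicates.  `engine="auto"` picks the kernel when the sweep exceeds a
few hundred thousand state evaluations.  The equivalence of the two paths
is asserted table-for-table in the tests; the full five-node sweep
(803,520 parameters, 108 states each) runs in well under a minute on one
core.

## Synthetic fixtures

`fixtures.random_network(n_nodes, max_indegree, seed)` draws, per node, a
random set of distinct signed inputs and a random composition into sum
groups.  It emulates the *structural* variety of small regulatory networks
(mixed signs, shared inputs, product/sum logic, self-loops) and is sized
so the closure oracle stays exact; it does not emulate degree
distributions, sign biases or module structure of real transcriptional
networks, so passing property tests demonstrates algorithmic correctness
on the model class, not biological fidelity.  Property tests run 200
random networks of up to 3 nodes (in-degree ≤ 2), checking all parameters
when a network has at most 24 and a seeded sample of 24 otherwise — sizes
chosen to keep the dense transitive-closure oracle (cubic in the ≤ 27
states) the clear bottleneck-free referee.

## Numerical and design choices

* Oracle seeds are method constants (seed 0), not experiment randomness:
  enumeration is part of the model definition and must not vary run to run.
* LP margin threshold 1e−7, numerical margin 1e−9 (relative): strict
  inequalities over an open feasible set, so any positive margin suffices;
  the thresholds guard against solver round-off.
* Thresholds for returned witnesses are placed midway between consecutive
  level-set extremes (or one unit above, when a level is unattained).
* A node with no targets contributes one level and one (empty) threshold
  order; a network line must have a nonempty right-hand side, so every
  node has at least one input.
* The parser resolves undeclared name tokens by greedy longest-match
  splitting into declared names, which reproduces both `XY` (= `X·Y`) and
  multi-character names without ambiguity; products are not allowed inside
  sum groups.

## Limitations

* The product-logic feasibility decision is numerical, not symbolic; an
  extremely thin feasible region could in principle be missed.  The
  published factor counts covered by the tests bound this risk for the
  shapes used here.
* Only the asynchronous, nearest-neighbor semantics is implemented; no
  trajectory-level (ODE) information is produced.
* The sweep is single-process; the design keeps the sequential result the
  specification, and the compiled kernel makes parallelism unnecessary at
  the scales handled here.
* SBML import and graphical browsing are out of scope; the network file
  dialect and SQL interface are the contract.
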