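# switchdyn

Qualitative dynamics databases for switching (Glass) models of gene
regulatory networks.

## The problem

Given a regulatory network — genes connected by activating (→) and
repressing (⊣) edges, with product-of-sums interaction logic at each node —
a switching system models each concentration by

    dx_i/dt = −γ_i x_i + M_i(σ(x)),

where every interaction is a step function that switches between a low
value `l` and a high value `u` at a threshold `θ`, and `M_i` combines a
node's inputs as a product of sums (e.g. `(Chk2 + ATM)(~Mdm2)`).  The
continuous parameters (γ, l, u, θ) are rarely known.  The key fact this
package exploits is that they do not need to be: parameter space decomposes
into **finitely many regions**, each inducing the same *combinatorial
parameter* — a threshold order `O_i` per node plus a multi-level discrete
map `D` on the integer state lattice `∏_i {0, …, m_i}` (`m_i` = number of
targets of node `i`).

For **every** combinatorial parameter, `switchdyn` computes the
asynchronous state transition graph of `D`, its Morse decomposition
(recurrent strongly connected components ordered by reachability), and the
annotated Morse graph — fixed points `FP` (with `ON`/`OFF` variants), full
cycles `FC`, partial oscillations `XC(...)` — and stores the whole sweep
in an SQLite database.  Counting how many parameters produce a behavior is
a proxy for that behavior's robustness across all of parameter space.  The
intended users are systems biologists screening network hypotheses against
observed dynamics (bistability, oscillation) without fitting rate
constants.

Enumeration per node is *exact*: all monotone candidate maps
`c: {0,1}^n → {0..m}` are generated, and a feasibility oracle keeps those
realizable by positive continuous parameters (a strict-feasibility linear
program for pure-sum logic; witness sampling plus multi-start optimization
for products of sums).

## Worked example

Network files have one line per node; `~` is repression, `+` groups
OR-like sums, juxtaposition multiplies, and a trailing `: E` restricts a
node to *essential* logic maps (every input matters).  The essential
toggle switch:

```
X : ~Y : E
Y : ~X : E
```

has a single combinatorial parameter.  Inspecting it:

```
$ parameter-inspect toggle.txt 0
parameter 0 of 1
D:
  (0, 0) -> (1, 1)
  (1, 0) -> (1, 0)
  (0, 1) -> (0, 1)
  (1, 1) -> (0, 0)
STG edges: 6
Morse graph:
  0: FP(0,1) (attractor)
  1: FP(1,0) (attractor)
```

Two incomparable fixed-point attractors: the classic bistability of the
toggle switch, derived without a single rate constant.

A full database sweep for the two-node multiplicative network
(`X : XY` / `Y : XY`):

```
$ signatures a.txt a.db --quiet
>>> import switchdyn as sd
>>> sd.count_parameters("a.db")
1600
>>> sd.count_stable("a.db", "FP%")   # parameters with a stable fixed point
1600
>>> sd.count_stable("a.db", "FC")    # parameters with a stable full cycle
0
```

1,600 combinatorial parameters (40 per node: 20 realizable logic maps × 2
threshold orders), collapsing to 77 distinct Morse graphs; every parameter
has at least one stable fixed point and none sustains a stable
oscillation.  The stable-FC / stable-FP counts are computed by SQL directly
against the three tables `Signatures`, `MorseGraphAnnotations` and
`MorseGraphEdges` (a stable node is a labeled Morse graph vertex with no
outgoing Hasse edge).

The same pipeline on the bundled five-node p53 damage-response network
enumerates 803,520 parameters; `compute_database` switches to a compiled
sweep kernel for networks of that size (about half a minute on one core).

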