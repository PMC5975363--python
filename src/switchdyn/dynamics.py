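"""Dynamics at one combinatorial parameter: discrete map, STG, Morse graph.

The multi-level map ``D`` updates every node synchronously: node ``i``
reads, for each input ``j``, whether the source level ``s_j`` has passed
the threshold that source ``j`` dedicates to ``i`` (position of ``i`` in
``j``'s threshold order), flips the comparison for repressors, and feeds
the resulting input combination to its logic map.  The asynchronous update
turns ``D`` into a state transition graph: a self-loop where ``D`` fixes
the state, otherwise one unit step toward ``D(s)`` per disagreeing
coordinate.

Recurrent components of the STG (strongly connected sets carrying a
nonempty path) form the Morse decomposition; their reachability order,
reduced to its Hasse diagram and annotated, is the Morse graph — the
dynamical signature stored in the database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import networkx as nx

from .network import RegulatoryNetwork, StateSpace, state_space
from .parameter_graph import CombinatorialParameter

__all__ = [
    "MultiLevelMap",
    "StateTransitionGraph",
    "MorseDecomposition",
    "AnnotatedMorseGraph",
    "multilevel_map",
    "async_stg",
    "morse_decomposition",
    "annotate",
    "morse_graph",
    "canonical_form",
]


@dataclass(frozen=True)
class MultiLevelMap:
    """Synchronous discrete map on the state lattice, as a full table."""

    network: RegulatoryNetwork
    space: StateSpace
    table: dict  # state tuple -> state tuple

    def __call__(self, state):
        return self.table[tuple(state)]

    def items(self):
        return self.table.items()


def multilevel_map(net: RegulatoryNetwork, param: CombinatorialParameter) -> MultiLevelMap:
    """Build ``D`` for one combinatorial parameter.

    Input bit for edge ``j -> i``: 1 iff ``s_j >= rank_j(i)`` for an
    activation, ``s_j < rank_j(i)`` for a repression, where ``rank_j(i)``
    is the 1-based position of ``i``'s threshold in ``j``'s order.
    """
    space = state_space(net)
    n_nodes = net.n_nodes
    # per node: list of (source index, is_activation, rank)
    slots: list[list[tuple[int, bool, int]]] = []
    for i in range(n_nodes):
        expr = net.logic[i]
        row = []
        for name, sign in zip(expr.inputs, expr.signs):
            j = net.index(name)
            row.append((j, sign == "activation", param.rank(j, i)))
        slots.append(row)
    table = {}
    for s in space.states():
        out = []
        for i in range(n_nodes):
            idx = 0
            for j, act, rank in slots[i]:
                bit = (s[j] >= rank) if act else (s[j] < rank)
                idx = (idx << 1) | bit
            out.append(param.logic_maps[i].table[idx])
        table[s] = tuple(out)
    return MultiLevelMap(net, space, table)


@dataclass(frozen=True)
class StateTransitionGraph:
    """Asynchronous-update digraph on the state lattice (networkx DiGraph,
    nodes are state tuples; a self-loop marks a fixed state)."""

    network: RegulatoryNetwork
    space: StateSpace
    graph: nx.DiGraph
    fixed: frozenset

    def out_degree(self, s):
        return self.graph.out_degree(s)


def async_stg(D: MultiLevelMap) -> StateTransitionGraph:
    """Asynchronous update of ``D``: self-loop where ``D(s) = s``; else one
    unit step toward the target per coordinate with ``D(s)_i != s_i``."""
    g = nx.DiGraph()
    g.add_nodes_from(D.table)
    fixed = set()
    for s, t in D.items():
        if s == t:
            g.add_edge(s, s)
            fixed.add(s)
            continue
        for i, (a, b) in enumerate(zip(s, t)):
            if a != b:
                step = 1 if b > a else -1
                g.add_edge(s, s[:i] + (a + step,) + s[i + 1:])
    return StateTransitionGraph(D.network, D.space, g, frozenset(fixed))


@dataclass
class MorseDecomposition:
    """Recurrent components (listed by ascending minimal state index) and
    their reachability relation ``reaches`` (a, b): a path runs from
    component a to component b."""

    stg: StateTransitionGraph
    components: list[frozenset]
    reaches: set[tuple[int, int]]


def morse_decomposition(stg: StateTransitionGraph) -> MorseDecomposition:
    """SCCs filtered to recurrent ones (size >= 2, or a fixed state), with
    the reachability partial order via the condensation."""
    g = stg.graph
    cond = nx.condensation(g)  # members in cond.nodes[c]["members"]
    rec = []
    for c in cond.nodes:
        members = cond.nodes[c]["members"]
        if len(members) > 1 or next(iter(members)) in stg.fixed:
            rec.append(c)
    space = stg.space
    rec.sort(key=lambda c: min(space.state_index(s) for s in cond.nodes[c]["members"]))
    comp_of = {c: k for k, c in enumerate(rec)}
    reaches = set()
    for k, c in enumerate(rec):
        for d in nx.descendants(cond, c):
            if d in comp_of:
                reaches.add((k, comp_of[d]))
    components = [frozenset(cond.nodes[c]["members"]) for c in rec]
    return MorseDecomposition(stg, components, reaches)


def annotate(component: frozenset, stg: StateTransitionGraph,
             net: RegulatoryNetwork) -> str:
    """Label one recurrent component.

    Singletons are fixed points ``FP(v_1,...,v_N)`` with `` OFF`` when all
    coordinates are zero and `` ON`` when none is.  Larger components cross
    a threshold in variable ``i`` when some internal edge changes
    coordinate ``i``: crossing every variable (with at least one target)
    gives ``FC``, otherwise ``XC(...)`` lists the oscillating variables.
    """
    if len(component) == 1:
        v = next(iter(component))
        if v not in stg.fixed:
            raise ValueError("singleton component is not recurrent")
        label = "FP(" + ",".join(str(x) for x in v) + ")"
        if all(x == 0 for x in v):
            label += " OFF"
        elif all(x != 0 for x in v):
            label += " ON"
        return label
    changed = set()
    g = stg.graph
    for s in component:
        for t in g.successors(s):
            if t in component and t != s:
                for i, (a, b) in enumerate(zip(s, t)):
                    if a != b:
                        changed.add(i)
    required = {i for i in range(net.n_nodes) if net.out_degree(i) >= 1}
    if required <= changed:
        return "FC"
    names = [net.nodes[i] for i in sorted(changed)]
    return "XC(" + ",".join(names) + ")"


@dataclass(frozen=True)
class AnnotatedMorseGraph:
    """Hasse diagram of recurrent components with labels, in canonical
    vertex order (equal canonical strings iff isomorphic as labeled DAGs)."""

    labels: tuple[str, ...]
    edges: frozenset  # (source upstream, target downstream) vertex pairs
    components: tuple  # state sets aligned with labels; may be empty tuples

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @cached_property
    def attractors(self) -> tuple[int, ...]:
        srcs = {a for a, _ in self.edges}
        return tuple(v for v in range(self.n_nodes) if v not in srcs)

    @cached_property
    def canonical_string(self) -> str:
        return _render(self.labels, self.edges)


def _hasse(reaches: set[tuple[int, int]], k: int) -> set[tuple[int, int]]:
    """Transitive reduction of a strict partial order given as pairs."""
    return {
        (a, b)
        for a, b in reaches
        if not any((a, c) in reaches and (c, b) in reaches for c in range(k))
    }


def _render(labels, edges) -> str:
    el = ",".join(f"{a}>{b}" for a, b in sorted(edges))
    return "|".join(labels) + ";" + el


def _canonical_order(labels, edges):
    """Vertex order making (labels, edges) a canonical form of the labeled
    DAG: color refinement seeded by (level, label), then individualization
    minimizing the rendered string (full search for <= 16 nodes)."""
    k = len(labels)
    succ = [set() for _ in range(k)]
    pred = [set() for _ in range(k)]
    for a, b in edges:
        succ[a].add(b)
        pred[b].add(a)
    # longest-path level from the top (sources at level 0)
    level = [0] * k
    for v in _topo(succ, k):
        for w in succ[v]:
            level[w] = max(level[w], level[v] + 1)

    def refine(colors):
        while True:
            sig = [
                (colors[v], tuple(sorted(colors[w] for w in succ[v])),
                 tuple(sorted(colors[w] for w in pred[v])))
                for v in range(k)
            ]
            ranks = {s: r for r, s in enumerate(sorted(set(sig)))}
            new = [ranks[s] for s in sig]
            if len(set(new)) == len(set(colors)):
                return new
            colors = new

    init_sig = sorted(set((level[v], labels[v]) for v in range(k)))
    ranks = {s: r for r, s in enumerate(init_sig)}
    colors = refine([ranks[(level[v], labels[v])] for v in range(k)])

    def order_of(colors):
        return sorted(range(k), key=lambda v: (colors[v], v))

    def rendered(order):
        pos = {v: p for p, v in enumerate(order)}
        return _render(
            tuple(labels[v] for v in order),
            frozenset((pos[a], pos[b]) for a, b in edges),
        )

    def search(colors):
        cells: dict[int, list[int]] = {}
        for v in range(k):
            cells.setdefault(colors[v], []).append(v)
        target = None
        for c in sorted(cells):
            if len(cells[c]) > 1:
                target = cells[c]
                break
        if target is None:
            order = order_of(colors)
            return rendered(order), order
        best = None
        for v in target:
            c2 = list(colors)
            c2[v] = -1  # individualize: strictly smallest color
            got = search(refine(c2))
            if best is None or got[0] < best[0]:
                best = got
        return best

    if len(set(colors)) == k or k > 16:
        return order_of(colors)
    _, order = search(colors)
    return order


def _topo(succ, k):
    indeg = [0] * k
    for v in range(k):
        for w in succ[v]:
            indeg[w] += 1
    stack = [v for v in range(k) if indeg[v] == 0]
    out = []
    while stack:
        v = stack.pop()
        out.append(v)
        for w in succ[v]:
            indeg[w] -= 1
            if indeg[w] == 0:
                stack.append(w)
    return out


def build_annotated(labels, edges, components=None) -> AnnotatedMorseGraph:
    """Canonicalize raw (labels, Hasse edges) into an AnnotatedMorseGraph."""
    k = len(labels)
    order = _canonical_order(tuple(labels), frozenset(edges))
    pos = {v: p for p, v in enumerate(order)}
    comps = components if components is not None else [frozenset()] * k
    return AnnotatedMorseGraph(
        labels=tuple(labels[v] for v in order),
        edges=frozenset((pos[a], pos[b]) for a, b in edges),
        components=tuple(comps[v] for v in order),
    )


def morse_graph(decomp: MorseDecomposition) -> AnnotatedMorseGraph:
    """Annotated Hasse diagram of the Morse decomposition.

    Morse node indices follow the canonical order (topological level, then
    label, refined); leaves are exactly the attractors.
    """
    k = len(decomp.components)
    net = decomp.stg.network
    labels = [annotate(c, decomp.stg, net) for c in decomp.components]
    edges = _hasse(decomp.reaches, k)
    return build_annotated(labels, edges, decomp.components)


def canonical_form(mg: AnnotatedMorseGraph) -> str:
    """Relabeling-invariant string; equal iff the annotated Morse graphs
    are isomorphic as labeled DAGs (the string encodes the full graph, so
    false merges are impossible; the canonical search makes matching
    isomorphic graphs render identically)."""
    return mg.canonical_string
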