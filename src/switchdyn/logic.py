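"""Per-node factor parameters: monotone logic maps, threshold orders, realizability.

A node with ``n`` inputs and ``m`` targets contributes a *factor* to the
global combinatorial parameter: a pair ``(logic map, threshold order)``.
The logic map ``c: {0,1}^n -> {0..m}`` gives the number of the node's own
thresholds lying below the production/decay ratio for each combination of
input step-function values (bit 1 = the step function sits at its high
value ``u``, which already absorbs the edge sign).  The threshold order is
a total order on the node's outgoing thresholds.

Not every monotone candidate map is induced by some choice of positive
continuous parameters ``0 < l_j < u_j`` (with thresholds interleaved).  A
candidate ``c`` is realizable iff there are ``l, u`` with

    f(b) < f(b')   whenever c(b) < c(b'),

where ``f(b)`` is the product over sum-groups of the selected low/high
values; strictly increasing thresholds separating the level sets then
always exist.  For single-group (pure-sum) expressions this is decided
exactly by a strict-feasibility linear program; for products of groups it
is decided numerically (witness sampling plus multi-start hinge-loss
minimization over log-parameters).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog, minimize

from .network import LogicExpression, RegulatoryNetwork

__all__ = [
    "LogicMap",
    "RealizationWitness",
    "FactorParameterList",
    "candidate_logic_maps",
    "combinations",
    "evaluate_expression",
    "induced_logic_map",
    "is_essential_map",
    "is_realizable",
    "realizable_logic_maps",
    "threshold_orders",
    "factor_parameters",
]


@dataclass(frozen=True)
class LogicMap:
    """Monotone map ``{0,1}^n -> {0..m}`` stored as a table.

    ``table[k]`` is the value on the k-th input combination in
    lexicographic order (first input most significant); see
    :func:`combinations`.
    """

    table: tuple[int, ...]
    n: int
    m: int

    def value(self, bits: tuple[int, ...]) -> int:
        return self.table[combo_index(bits)]


@dataclass(frozen=True)
class RealizationWitness:
    """Continuous parameters realizing a logic map: decay rate ``gamma``,
    low/high step values ``l_j < u_j`` per input, increasing thresholds."""

    gamma: float
    l: tuple[float, ...]
    u: tuple[float, ...]
    theta: tuple[float, ...]

    def __post_init__(self) -> None:
        assert self.gamma > 0
        assert all(0 < a < b for a, b in zip(self.l, self.u))
        assert all(a > 0 for a in self.theta)
        assert all(a < b for a, b in zip(self.theta, self.theta[1:]))


def combinations(n: int) -> list[tuple[int, ...]]:
    """Input combinations in lexicographic order (first input major)."""
    return list(itertools.product((0, 1), repeat=n))


def combo_index(bits) -> int:
    idx = 0
    for b in bits:
        idx = (idx << 1) | int(b)
    return idx


def candidate_logic_maps(n: int, m: int) -> list[LogicMap]:
    """All monotone nondecreasing maps ``{0,1}^n -> {0..m}``, in
    lexicographic table order.  For ``n = 0`` these are the ``m + 1``
    constants."""
    if n < 0 or m < 0:
        raise ValueError("n and m must be nonnegative")
    combos = combinations(n)
    # covering pairs: flip one 0-bit to 1
    covers = []
    for i, b in enumerate(combos):
        for j in range(n):
            if not b[j]:
                covers.append((i, combo_index(b[:j] + (1,) + b[j + 1:])))
    out = []
    for table in itertools.product(range(m + 1), repeat=2 ** n):
        if all(table[i] <= table[j] for i, j in covers):
            out.append(LogicMap(table, n, m))
    return out


def is_essential_map(c: LogicMap) -> bool:
    """True iff every input matters: for each input j there are
    combinations differing only in bit j with different map values."""
    combos = combinations(c.n)
    for j in range(c.n):
        hit = False
        for b in combos:
            if b[j]:
                continue
            b1 = b[:j] + (1,) + b[j + 1:]
            if c.table[combo_index(b)] != c.table[combo_index(b1)]:
                hit = True
                break
        if not hit:
            return False
    return True


def evaluate_expression(
    expr: LogicExpression, bits, w: RealizationWitness
) -> float:
    """Value of the multi-affine term at one input combination:
    product over groups of the sum of selected low/high values."""
    if len(bits) != expr.n_inputs or len(w.l) != expr.n_inputs:
        raise ValueError("arity mismatch")
    val, j = 1.0, 0
    for g in expr.groups:
        s = 0.0
        for _ in g:
            s += w.u[j] if bits[j] else w.l[j]
            j += 1
        val *= s
    return val


def induced_logic_map(expr: LogicExpression, w: RealizationWitness, m: int) -> LogicMap:
    """Logic map induced by a concrete witness: count thresholds below
    ``f(b) / gamma`` for each combination."""
    table = []
    for b in combinations(expr.n_inputs):
        f = evaluate_expression(expr, b, w) / w.gamma
        table.append(sum(1 for t in w.theta[:m] if t < f))
    return LogicMap(tuple(table), expr.n_inputs, m)


# -- feasibility oracle ----------------------------------------------------

_REALIZABLE_CACHE: dict = {}


def _group_value_matrix(group_sizes, combos, L, U):
    """f values for a batch of (l, u) draws.  L, U: (ns, n).  Returns (ns, B)."""
    ns = L.shape[0]
    V = np.ones((ns, len(combos)))
    for bi, b in enumerate(combos):
        j = 0
        prod = np.ones(ns)
        for gs in group_sizes:
            s = np.zeros(ns)
            for _ in range(gs):
                s += U[:, j] if b[j] else L[:, j]
                j += 1
            prod = prod * s
        V[:, bi] = prod
    return V


def _required_pairs(table):
    B = len(table)
    return [(i, j) for i in range(B) for j in range(B) if table[i] < table[j]]


def _f_log(x, group_sizes, combos):
    """log f(b) for all combos at packed point x = (log l, log(u - l))."""
    n = len(x) // 2
    l = np.exp(x[:n])
    u = l + np.exp(x[n:])
    out = np.empty(len(combos))
    for bi, b in enumerate(combos):
        j, acc = 0, 0.0
        for gs in group_sizes:
            s = 0.0
            for _ in range(gs):
                s += u[j] if b[j] else l[j]
                j += 1
            acc += np.log(s)
        out[bi] = acc
    return out


def _optimize_feasible(group_sizes, combos, pairs, rng, n_starts=32):
    """Multi-start hinge minimization; returns (l, u) or None."""
    n = sum(group_sizes)
    ip = np.array([p[0] for p in pairs])
    jp = np.array([p[1] for p in pairs])

    def loss(x, mu):
        lv = _f_log(x, group_sizes, combos)
        h = np.maximum(0.0, mu - (lv[jp] - lv[ip]))
        return float(np.dot(h, h))

    def extract(x):
        l = np.exp(x[:n])
        u = l + np.exp(x[n:])
        vals = np.exp(_f_log(x, group_sizes, combos))
        if all(vals[j] - vals[i] > 1e-9 * max(vals[j], 1.0) for i, j in pairs):
            return l, u, vals
        return None

    for s in range(n_starts):
        x0 = np.zeros(2 * n) if s == 0 else rng.uniform(-4.0, 4.0, 2 * n)
        for mu in (0.05, 1e-3):
            res = minimize(
                loss, x0, args=(mu,), method="Nelder-Mead",
                options={"maxiter": 2000, "fatol": 1e-14, "xatol": 1e-10},
            )
            x0 = res.x
            if loss(res.x, 0.0) == 0.0:
                got = extract(res.x)
                if got is not None:
                    return got
    return None


def _lp_pure_sum(table, n, m, combos):
    """Exact strict-feasibility LP for single-group expressions, gamma = 1.

    Variables: l_1..l_n, u_1..u_n, th_1..th_m, margin; maximize the margin.
    Feasible with positive margin iff the map is realizable.
    """
    nv = 2 * n + m + 1
    MU = nv - 1
    A, bvec = [], []

    def ub_row(coeffs, rhs=0.0):  # sum coeffs . x <= rhs
        row = [0.0] * nv
        for k, v in coeffs:
            row[k] += v
        A.append(row)
        bvec.append(rhs)

    for j in range(n):
        ub_row([(MU, 1.0), (j, -1.0)])              # mu <= l_j
        ub_row([(MU, 1.0), (n + j, -1.0), (j, 1.0)])  # mu <= u_j - l_j
    if m:
        ub_row([(MU, 1.0), (2 * n, -1.0)])          # mu <= th_1
        for k in range(m - 1):
            ub_row([(MU, 1.0), (2 * n + k + 1, -1.0), (2 * n + k, 1.0)])
    for bi, b in enumerate(combos):
        fcoef = [(n + j if b[j] else j, 1.0) for j in range(n)]
        c = table[bi]
        if c >= 1:  # f(b) - th_c >= mu
            ub_row([(MU, 1.0), (2 * n + c - 1, 1.0)] + [(k, -v) for k, v in fcoef])
        if c < m:  # th_{c+1} - f(b) >= mu
            ub_row([(MU, 1.0)] + fcoef + [(2 * n + c, -1.0)])

    cost = np.zeros(nv)
    cost[MU] = -1.0
    bounds = [(0.0, float(max(n, 1) + m + 1))] * (nv - 1) + [(0.0, 1.0)]
    res = linprog(cost, A_ub=np.array(A), b_ub=np.array(bvec), bounds=bounds,
                  method="highs")
    if not res.success or -res.fun <= 1e-7:
        return None
    x = res.x
    l = tuple(x[:n])
    u = tuple(x[n:2 * n])
    theta = tuple(x[2 * n:2 * n + m])
    return l, u, theta


def _interleave_thresholds(table, vals, m):
    """Strictly increasing thresholds separating the level sets of a
    feasible point; theta_k lies between max{f : c < k} and min{f : c >= k}."""
    theta = []
    prev = 0.0
    for k in range(1, m + 1):
        below = [v for v, c in zip(vals, table) if c < k]
        above = [v for v, c in zip(vals, table) if c >= k]
        lo = max([prev] + below)
        if above:
            hi = min(above)
            assert hi > lo
            t = 0.5 * (lo + hi)
        else:
            t = lo + 1.0
        theta.append(t)
        prev = t
    return tuple(theta)


def _decide_shape(group_sizes, m, seed=0):
    """Classify every monotone candidate for an expression shape.

    Returns an ordered dict table -> witness-or-None for realizable maps
    only.  Cached per (shape, m): realizability depends only on the group
    sizes, not on edge signs or on which node supplies which input.
    """
    key = (tuple(group_sizes), m, seed)
    if key in _REALIZABLE_CACHE:
        return _REALIZABLE_CACHE[key]
    n = sum(group_sizes)
    combos = combinations(n)
    cands = candidate_logic_maps(n, m)
    result: dict = {}
    if n == 0:
        for c in cands:
            result[c.table] = ((), (), _interleave_thresholds(c.table, [1.0], m))
        _REALIZABLE_CACHE[key] = result
        return result

    if len(group_sizes) == 1:
        for c in cands:
            got = _lp_pure_sum(c.table, n, m, combos)
            if got is not None:
                result[c.table] = got
        _REALIZABLE_CACHE[key] = result
        return result

    rng = np.random.default_rng(seed)
    # Stage 1: witness sampling.  Every induced ordering certifies all maps
    # whose required strict inequalities it satisfies.
    ns = 4000
    L = np.exp(rng.uniform(-6.0, 6.0, (ns, n)))
    U = L + np.exp(rng.uniform(-6.0, 6.0, (ns, n)))
    V = _group_value_matrix(group_sizes, combos, L, U)
    undecided = []
    for c in cands:
        pairs = _required_pairs(c.table)
        if not pairs:
            row = 0
        else:
            ip = np.array([p[0] for p in pairs])
            jp = np.array([p[1] for p in pairs])
            ok = np.all(V[:, ip] < V[:, jp], axis=1)
            row = int(np.argmax(ok)) if ok.any() else -1
        if row >= 0:
            l, u = L[row], U[row]
            vals = V[row]
            theta = _interleave_thresholds(c.table, vals, m)
            result[c.table] = (tuple(l), tuple(u), theta)
        else:
            undecided.append(c)
    # Stage 2: multi-start optimization on the remainder.
    for c in undecided:
        pairs = _required_pairs(c.table)
        got = _optimize_feasible(group_sizes, combos, pairs, rng)
        if got is not None:
            l, u, vals = got
            result[c.table] = (tuple(l), tuple(u),
                               _interleave_thresholds(c.table, vals, m))
    # preserve candidate (lexicographic) order
    ordered = {c.table: result[c.table] for c in cands if c.table in result}
    _REALIZABLE_CACHE[key] = ordered
    return ordered


def is_realizable(
    expr: LogicExpression, c: LogicMap, seed: int = 0
) -> tuple[bool, RealizationWitness | None]:
    """Decide whether continuous parameters induce the candidate map ``c``.

    Returns ``(True, witness)`` with a concrete witness (gamma fixed to 1;
    gamma only rescales the threshold comparison) or ``(False, None)``.
    """
    covers_ok = all(
        c.table[i] <= c.table[j]
        for i, j in itertools.combinations(range(len(c.table)), 2)
        if _dominates(j, i, c.n)
    )
    if not covers_ok:
        raise ValueError("logic map is not monotone")
    decided = _decide_shape(expr.group_sizes, c.m, seed=seed)
    if c.table not in decided:
        return False, None
    l, u, theta = decided[c.table]
    if len(theta) == 0:
        theta = ()
    return True, RealizationWitness(1.0, tuple(l), tuple(u), tuple(theta))


def _dominates(j: int, i: int, n: int) -> bool:
    """combo j >= combo i componentwise (indices in lexicographic order)."""
    return (i & j) == i


def realizable_logic_maps(
    expr: LogicExpression, m: int, seed: int = 0
) -> list[LogicMap]:
    """Realizable monotone logic maps for an expression, candidate order."""
    decided = _decide_shape(expr.group_sizes, m, seed=seed)
    n = expr.n_inputs
    return [LogicMap(t, n, m) for t in decided]


# -- threshold orders and the per-node factor ------------------------------


def threshold_orders(m: int) -> list[tuple[int, ...]]:
    """All rank vectors over a node's target list: entry ``t`` is the rank
    (1-based; 1 = lowest threshold) of the t-th target.  Lexicographic."""
    if m == 0:
        return [()]
    return list(itertools.permutations(range(1, m + 1)))


def _orders_adjacent(r1, r2) -> bool:
    diff = [t for t in range(len(r1)) if r1[t] != r2[t]]
    if len(diff) != 2:
        return False
    p, q = diff
    return r1[p] == r2[q] and r1[q] == r2[p] and abs(r1[p] - r1[q]) == 1


def _maps_adjacent(t1, t2) -> bool:
    diff = [k for k in range(len(t1)) if t1[k] != t2[k]]
    return len(diff) == 1 and abs(t1[diff[0]] - t2[diff[0]]) == 1


@dataclass
class FactorParameterList:
    """All (logic map, threshold order) pairs of one node.

    Entry order is deterministic: logic-map index major (candidate
    lexicographic order restricted to realizable, optionally essential,
    maps), threshold-order index minor (rank-vector lexicographic order).
    """

    node: int
    maps: list[LogicMap]
    orders: list[tuple[int, ...]]

    def __len__(self) -> int:
        return len(self.maps) * len(self.orders)

    def entry(self, e: int) -> tuple[LogicMap, tuple[int, ...]]:
        mi, oi = divmod(e, len(self.orders))
        return self.maps[mi], self.orders[oi]

    def entry_index(self, logic_map: LogicMap, order: tuple[int, ...]) -> int:
        return self.maps.index(logic_map) * len(self.orders) + self.orders.index(order)

    def adjacency(self) -> dict[int, list[int]]:
        """Intra-factor neighbors: same map and adjacent-transposed orders,
        or same order and tables differing at one combination by 1."""
        n_o = len(self.orders)
        out: dict[int, list[int]] = {e: [] for e in range(len(self))}
        order_adj = [
            (a, b)
            for a in range(n_o)
            for b in range(a + 1, n_o)
            if _orders_adjacent(self.orders[a], self.orders[b])
        ]
        map_adj = [
            (a, b)
            for a in range(len(self.maps))
            for b in range(a + 1, len(self.maps))
            if _maps_adjacent(self.maps[a].table, self.maps[b].table)
        ]
        for mi in range(len(self.maps)):
            for a, b in order_adj:
                out[mi * n_o + a].append(mi * n_o + b)
                out[mi * n_o + b].append(mi * n_o + a)
        for a, b in map_adj:
            for oi in range(n_o):
                out[a * n_o + oi].append(b * n_o + oi)
                out[b * n_o + oi].append(a * n_o + oi)
        for e in out:
            out[e].sort()
        return out


def factor_parameters(
    net: RegulatoryNetwork, node: int, essential: bool | None = None, seed: int = 0
) -> FactorParameterList:
    """Factor parameter list of one node.

    ``essential=None`` uses the network's per-node flag.  Essential
    enumeration keeps only logic maps in which every input is essential.
    """
    if essential is None:
        essential = net.essential[node]
    m = net.out_degree(node)
    maps = realizable_logic_maps(net.logic[node], m, seed=seed)
    if essential:
        maps = [c for c in maps if is_essential_map(c)]
    return FactorParameterList(node, maps, threshold_orders(m))
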