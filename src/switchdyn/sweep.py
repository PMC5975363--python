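"""Compiled full-database sweep.

Recomputes, per combinatorial parameter, the multi-level map, the
asynchronous state transition graph, its strongly connected components
(iterative Tarjan over the implicit edge structure), the recurrent
components with their reachability order, Hasse edges and annotation —
exactly the pure-Python :mod:`switchdyn.dynamics` pipeline, restated over
packed integer arrays so that numba can compile it.  The two paths are
cross-checked byte-for-byte in the test suite; this one exists because a
full sweep visits close to a million parameters on realistic networks.

Each parameter yields a compact integer record (component annotations in
ascending-minimal-state order plus Hasse edges); records are deduplicated
in Python through the same canonicalization used by the reference path.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .dynamics import build_annotated
from .parameter_graph import ParameterGraph

__all__ = ["sweep_signatures"]


def _pack(pg: ParameterGraph):
    net = pg.network
    N = net.n_nodes
    shape = [net.out_degree(i) + 1 for i in range(N)]
    strides, acc = [], 1
    for k in shape:
        strides.append(acc)
        acc *= k
    S = acc
    coords = np.empty((S, N), np.int8)
    for s in range(S):
        x = s
        for i in range(N):
            coords[s, i] = x % shape[i]
            x //= shape[i]

    m_arr = np.array([net.out_degree(i) for i in range(N)], np.int64)
    F = np.array(pg.factor_sizes(), np.int64)
    P = np.array([len(f.orders) for f in pg.factors], np.int64)
    radix = np.array(pg._radix, np.int64)

    table_off, table_row, tbl = [], [], []
    for f in pg.factors:
        n = net.in_degree(f.node)
        table_off.append(len(tbl))
        table_row.append(2 ** n)
        for c in f.maps:
            tbl.extend(c.table)
    tables = np.array(tbl, np.int8)
    table_off = np.array(table_off, np.int64)
    table_row = np.array(table_row, np.int64)

    order_off, odata = [], []
    for f in pg.factors:
        order_off.append(len(odata))
        for r in f.orders:
            odata.extend(r)
    orders = np.array(odata if odata else [0], np.int8)
    order_off = np.array(order_off, np.int64)

    n_in, input_off, in_src, in_act, in_tpos = [], [], [], [], []
    for i in range(N):
        expr = net.logic[i]
        input_off.append(len(in_src))
        n_in.append(expr.n_inputs)
        for name, sign in zip(expr.inputs, expr.signs):
            v = net.index(name)
            in_src.append(v)
            in_act.append(1 if sign == "activation" else 0)
            in_tpos.append(net.target_rank_position(v, i))
    n_in = np.array(n_in, np.int64)
    input_off = np.array(input_off, np.int64)
    in_src = np.array(in_src if in_src else [0], np.int64)
    in_act = np.array(in_act if in_act else [0], np.int8)
    in_tpos = np.array(in_tpos if in_tpos else [0], np.int64)

    req_mask = 0
    for i in range(N):
        if net.out_degree(i) >= 1:
            req_mask |= 1 << i

    strides = np.array(strides, np.int64)
    return (
        N, S, radix, F, P, m_arr, strides, coords, tables, table_off,
        table_row, orders, order_off, n_in, input_off, in_src, in_act,
        in_tpos, req_mask, tuple(shape),
    )


@njit(cache=True)
def _sweep_range(p0, p1, N, S, radix, F, P, m_arr, strides, coords,
                 tables, table_off, table_row, orders, order_off,
                 n_in, input_off, in_src, in_act, in_tpos, req_mask,
                 buf, offsets):
    D = np.empty((S, N), np.int8)
    fixed = np.empty(S, np.uint8)
    mi = np.empty(N, np.int64)
    oi = np.empty(N, np.int64)
    num = np.empty(S, np.int32)
    low = np.empty(S, np.int32)
    on = np.empty(S, np.uint8)
    sccid = np.empty(S, np.int32)
    stk = np.empty(S, np.int32)
    fv = np.empty(S, np.int32)
    fcs = np.empty(S, np.int32)
    scc_size = np.empty(S, np.int32)
    scc_start = np.empty(S + 1, np.int32)
    fillp = np.empty(S, np.int32)
    members = np.empty(S, np.int32)
    rec_idx = np.empty(S, np.int32)
    rec_scc = np.empty(S, np.int32)
    reach = np.zeros((S, S), np.uint8)
    rel = np.empty((S, S), np.uint8)

    pos = 0
    count = 0
    offsets[0] = 0
    for p in range(p0, p1):
        for i in range(N):
            e = (p // radix[i]) % F[i]
            mi[i] = e // P[i]
            oi[i] = e % P[i]
        # multi-level map
        for s in range(S):
            fx = 1
            for i in range(N):
                bits = 0
                off = input_off[i]
                for t in range(n_in[i]):
                    v = in_src[off + t]
                    r = orders[order_off[v] + oi[v] * m_arr[v] + in_tpos[off + t]]
                    sv = coords[s, v]
                    if in_act[off + t] == 1:
                        b = 1 if sv >= r else 0
                    else:
                        b = 1 if sv < r else 0
                    bits = (bits << 1) | b
                d = tables[table_off[i] + mi[i] * table_row[i] + bits]
                D[s, i] = d
                if d != coords[s, i]:
                    fx = 0
            fixed[s] = fx
        # Tarjan SCC over the implicit asynchronous STG
        for s in range(S):
            num[s] = -1
            on[s] = 0
        idx_counter = 0
        ncc = 0
        sp = 0
        for root in range(S):
            if num[root] >= 0:
                continue
            num[root] = idx_counter
            low[root] = idx_counter
            idx_counter += 1
            stk[sp] = root
            sp += 1
            on[root] = 1
            fv[0] = root
            fcs[0] = 0
            fp = 1
            while fp > 0:
                v = fv[fp - 1]
                if fcs[fp - 1] < N:
                    c = fcs[fp - 1]
                    fcs[fp - 1] += 1
                    d = D[v, c]
                    cv = coords[v, c]
                    if d != cv:
                        w = v + strides[c] if d > cv else v - strides[c]
                        if num[w] < 0:
                            num[w] = idx_counter
                            low[w] = idx_counter
                            idx_counter += 1
                            stk[sp] = w
                            sp += 1
                            on[w] = 1
                            fv[fp] = w
                            fcs[fp] = 0
                            fp += 1
                        elif on[w] == 1:
                            if num[w] < low[v]:
                                low[v] = num[w]
                else:
                    fp -= 1
                    if fp > 0:
                        u = fv[fp - 1]
                        if low[v] < low[u]:
                            low[u] = low[v]
                    if low[v] == num[v]:
                        while True:
                            w = stk[sp - 1]
                            sp -= 1
                            on[w] = 0
                            sccid[w] = ncc
                            if w == v:
                                break
                        ncc += 1
        # member lists (states ascending within each SCC)
        for c in range(ncc):
            scc_size[c] = 0
        for s in range(S):
            scc_size[sccid[s]] += 1
        scc_start[0] = 0
        for c in range(ncc):
            scc_start[c + 1] = scc_start[c] + scc_size[c]
            fillp[c] = scc_start[c]
        for s in range(S):
            c = sccid[s]
            members[fillp[c]] = s
            fillp[c] += 1
        # recurrent components, ordered by minimal state
        n_rec = 0
        for c in range(ncc):
            rec_idx[c] = -1
            if scc_size[c] > 1 or fixed[members[scc_start[c]]] == 1:
                rec_scc[n_rec] = c
                n_rec += 1
        # insertion sort by minimal state (= first member)
        for a in range(1, n_rec):
            key = rec_scc[a]
            kmin = members[scc_start[key]]
            b = a - 1
            while b >= 0 and members[scc_start[rec_scc[b]]] > kmin:
                rec_scc[b + 1] = rec_scc[b]
                b -= 1
            rec_scc[b + 1] = key
        for x in range(n_rec):
            rec_idx[rec_scc[x]] = x
        # reachability: SCC completion order is reverse topological
        for c in range(ncc):
            for x in range(n_rec):
                reach[c, x] = 0
        for c in range(ncc):
            for q in range(scc_start[c], scc_start[c + 1]):
                v = members[q]
                for i in range(N):
                    d = D[v, i]
                    cv = coords[v, i]
                    if d == cv:
                        continue
                    w = v + strides[i] if d > cv else v - strides[i]
                    b = sccid[w]
                    if b != c:
                        for x in range(n_rec):
                            if reach[b, x] == 1:
                                reach[c, x] = 1
                        if rec_idx[b] >= 0:
                            reach[c, rec_idx[b]] = 1
        for x in range(n_rec):
            cx = rec_scc[x]
            for y in range(n_rec):
                rel[x, y] = reach[cx, y]
        # record: k, (type, payload) * k, nE, (src, tgt) * nE
        n_edges = 0
        for x in range(n_rec):
            for y in range(n_rec):
                if rel[x, y] == 1:
                    direct = True
                    for z in range(n_rec):
                        if rel[x, z] == 1 and rel[z, y] == 1:
                            direct = False
                            break
                    if direct:
                        n_edges += 1
        need = 2 + 2 * n_rec + 2 * n_edges
        if pos + need > buf.shape[0]:
            break
        buf[pos] = n_rec
        q = pos + 1
        for x in range(n_rec):
            c = rec_scc[x]
            if scc_size[c] == 1:
                buf[q] = 0
                buf[q + 1] = members[scc_start[c]]
            else:
                mask = 0
                for t in range(scc_start[c], scc_start[c + 1]):
                    v = members[t]
                    for i in range(N):
                        d = D[v, i]
                        cv = coords[v, i]
                        if d == cv:
                            continue
                        w = v + strides[i] if d > cv else v - strides[i]
                        if sccid[w] == c:
                            mask |= 1 << i
                if (mask & req_mask) == req_mask:
                    buf[q] = 1
                    buf[q + 1] = mask
                else:
                    buf[q] = 2
                    buf[q + 1] = mask
            q += 2
        buf[q] = n_edges
        q += 1
        for x in range(n_rec):
            for y in range(n_rec):
                if rel[x, y] == 1:
                    direct = True
                    for z in range(n_rec):
                        if rel[x, z] == 1 and rel[z, y] == 1:
                            direct = False
                            break
                    if direct:
                        buf[q] = x
                        buf[q + 1] = y
                        q += 2
        pos = q
        count += 1
        offsets[count] = pos
    return count


def _decode(rec, shape, names, out_degrees):
    k = int(rec[0])
    labels = []
    for x in range(k):
        typ = int(rec[1 + 2 * x])
        pay = int(rec[2 + 2 * x])
        if typ == 0:
            cs = []
            for dim in shape:
                cs.append(pay % dim)
                pay //= dim
            label = "FP(" + ",".join(str(c) for c in cs) + ")"
            if all(c == 0 for c in cs):
                label += " OFF"
            elif all(c != 0 for c in cs):
                label += " ON"
            labels.append(label)
        elif typ == 1:
            labels.append("FC")
        else:
            osc = [names[i] for i in range(len(names)) if pay >> i & 1]
            labels.append("XC(" + ",".join(osc) + ")")
    q = 1 + 2 * k
    n_edges = int(rec[q])
    q += 1
    edges = set()
    for _ in range(n_edges):
        edges.add((int(rec[q]), int(rec[q + 1])))
        q += 2
    return labels, edges


def sweep_signatures(pg: ParameterGraph, stop: int, progress=None):
    """Numba-path equivalent of the pure-Python signature sweep."""
    packed = _pack(pg)
    shape = packed[-1]
    args = packed[:-1]
    net = pg.network
    names = list(net.nodes)
    out_degrees = [net.out_degree(i) for i in range(net.n_nodes)]
    chunk = 8192
    cap = chunk * 64 + 65536
    buf = np.empty(cap, np.int32)
    offsets = np.empty(chunk + 1, np.int64)
    signatures: list[tuple[int, int]] = []
    graphs = []
    index_of: dict[str, int] = {}
    memo: dict[bytes, int] = {}
    p = 0
    while p < stop:
        p1 = min(p + chunk, stop)
        count = _sweep_range(p, p1, *args, buf, offsets)
        if count == 0:
            # a single record larger than the buffer: grow and retry
            cap *= 4
            buf = np.empty(cap, np.int32)
            continue
        for t in range(count):
            key = buf[offsets[t]:offsets[t + 1]].tobytes()
            mgi = memo.get(key)
            if mgi is None:
                labels, edges = _decode(buf[offsets[t]:offsets[t + 1]], shape, names, out_degrees)
                mg = build_annotated(labels, edges)
                ck = mg.canonical_string
                mgi = index_of.get(ck)
                if mgi is None:
                    mgi = len(graphs)
                    index_of[ck] = mgi
                    graphs.append(mg)
                memo[key] = mgi
            signatures.append((p + t, mgi))
        p += count
        if progress is not None:
            progress(p, stop)
    return signatures, graphs
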