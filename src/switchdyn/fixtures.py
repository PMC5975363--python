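"""Test inputs and brute-force oracles.

Ships the two networks printed in the source publication's example section
(the five-node p53 damage-response network and the two-node multiplicative
example, plus its essential variant), a few canonical toy circuits, a
seeded random-network generator, and a transitive-closure oracle for the
Morse decomposition.
"""

from __future__ import annotations

import random

import numpy as np

from .dynamics import MorseDecomposition, StateTransitionGraph
from .network import parse_network

__all__ = ["printed_networks", "random_network", "brute_force_recurrent"]

_NETWORKS = {
    "5D_2015_10_21_VA": (
        "p53 : (Chk2 + ATM)(~Mdm2)\n"
        "ATM : ~Wip1\n"
        "Chk2 : ATM (~Wip1)\n"
        "Wip1 : p53\n"
        "Mdm2 : p53\n"
    ),
    "2D_Example_A": "X : XY\nY : XY\n",
    "2D_Example_A_essential": "X : XY : E\nY : XY : E\n",
    "toggle": "X : ~Y\nY : ~X\n",
    "toggle_essential": "X : ~Y : E\nY : ~X : E\n",
    "negative_loop": "X : ~Y\nY : X\n",
    "self_activator": "X : X\n",
}


def printed_networks() -> dict[str, str]:
    """Map of fixture name to network file text (all texts parse)."""
    return dict(_NETWORKS)


def random_network(n_nodes: int, max_indegree: int, seed: int) -> str:
    """Deterministic random network text: every node gets 1..max_indegree
    distinct signed inputs grouped into a random product of sums.  Always
    parses and round-trips through the parser."""
    if n_nodes < 1:
        raise ValueError("need at least one node")
    rng = random.Random(seed)
    names = [f"N{i}" for i in range(n_nodes)]
    lines = []
    for i in range(n_nodes):
        k = rng.randint(1, min(max_indegree, n_nodes))
        inputs = rng.sample(names, k)
        terms = [(n, rng.random() < 0.5) for n in inputs]  # (name, repressed)
        # random composition of k into group sizes
        groups, rest = [], terms
        while rest:
            g = rng.randint(1, len(rest))
            groups.append(rest[:g])
            rest = rest[g:]
        parts = []
        for g in groups:
            body = " + ".join(("~" + n if rep else n) for n, rep in g)
            if len(g) == 1 and not g[0][1]:
                parts.append(body)
            else:
                parts.append(f"({body})")
        lines.append(f"{names[i]} : {' '.join(parts)}")
    text = "\n".join(lines) + "\n"
    parse_network(text)
    return text


def brute_force_recurrent(stg: StateTransitionGraph) -> MorseDecomposition:
    """Morse decomposition via dense transitive closure (independent of the
    SCC-based path): states u, v are equivalent iff nonempty paths run both
    ways; a state is recurrent iff it reaches itself."""
    space = stg.space
    S = space.size
    if S > 4096:
        raise ValueError("state space too large for the closure oracle")
    A = np.zeros((S, S), dtype=bool)
    for s, t in stg.graph.edges:
        A[space.state_index(s), space.state_index(t)] = True
    # closure over nonempty paths: R = A + A@A + ...
    R = A.copy()
    while True:
        R2 = R | (R @ A)
        if (R2 == R).all():
            break
        R = R2
    recurrent = [i for i in range(S) if R[i, i]]
    comps: list[list[int]] = []
    assigned = {}
    for i in recurrent:
        for k, rep in enumerate(comps):
            j = rep[0]
            if R[i, j] and R[j, i]:
                comps[k].append(i)
                assigned[i] = k
                break
        else:
            assigned[i] = len(comps)
            comps.append([i])
    comps.sort(key=min)
    components = [
        frozenset(space.state_at(i) for i in comp) for comp in comps
    ]
    reaches = set()
    for a, ca in enumerate(comps):
        for b, cb in enumerate(comps):
            if a != b and R[ca[0], cb[0]]:
                reaches.add((a, b))
    return MorseDecomposition(stg, components, reaches)
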