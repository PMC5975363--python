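"""Global parameter graph: combinatorial parameters and their adjacency.

A combinatorial parameter assembles one factor entry (logic map, threshold
order) per node.  Parameters are indexed by a mixed-radix integer with
node 0 least significant, so indices are stable across runs.  Two
parameters are adjacent when they differ in exactly one node's factor
entry and the two entries are intra-factor adjacent (one adjacent
threshold transposition, or one logic-table entry changed by one).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

from .logic import FactorParameterList, LogicMap, factor_parameters
from .network import RegulatoryNetwork

__all__ = ["CombinatorialParameter", "ParameterGraph"]


@dataclass(frozen=True)
class CombinatorialParameter:
    """One (order, logic-map) datum per node; a node of the parameter graph."""

    network: RegulatoryNetwork
    logic_maps: tuple[LogicMap, ...]
    orders: tuple[tuple[int, ...], ...]

    def rank(self, source: int, target: int) -> int:
        """Rank (1-based) of ``target``'s threshold within ``source``'s order."""
        pos = self.network.target_rank_position(source, target)
        return self.orders[source][pos]


class ParameterGraph:
    """Lazy container for all combinatorial parameters of a network."""

    def __init__(self, network: RegulatoryNetwork,
                 factors: list[FactorParameterList]):
        self.network = network
        self.factors = factors
        self._sizes = [len(f) for f in factors]
        self._radix = []
        acc = 1
        for s in self._sizes:
            self._radix.append(acc)
            acc *= s
        self._size = acc

    @classmethod
    def build(cls, network: RegulatoryNetwork,
              essential: bool | None = None, seed: int = 0) -> "ParameterGraph":
        """Enumerate per-node factors.  ``essential=None`` follows the
        network file's per-node flags; True/False overrides all nodes."""
        if network.n_nodes == 0:
            raise ValueError("network has no nodes")
        factors = [
            factor_parameters(network, i, essential=essential, seed=seed)
            for i in range(network.n_nodes)
        ]
        return cls(network, factors)

    @property
    def size(self) -> int:
        return self._size

    def __len__(self) -> int:
        return self._size

    def factor_sizes(self) -> tuple[int, ...]:
        return tuple(self._sizes)

    def entry_indices(self, index: int) -> tuple[int, ...]:
        """Mixed-radix decode to per-node factor entry indices."""
        if not 0 <= index < self._size:
            raise IndexError(f"parameter index {index} out of range [0, {self._size})")
        out = []
        for s in self._sizes:
            out.append(index % s)
            index //= s
        return tuple(out)

    def index_of_entries(self, entries) -> int:
        return sum(e * r for e, r in zip(entries, self._radix))

    def parameter_at(self, index: int) -> CombinatorialParameter:
        es = self.entry_indices(index)
        maps, orders = [], []
        for f, e in zip(self.factors, es):
            c, o = f.entry(e)
            maps.append(c)
            orders.append(o)
        return CombinatorialParameter(self.network, tuple(maps), tuple(orders))

    def index_of(self, param: CombinatorialParameter) -> int:
        entries = [
            f.entry_index(c, o)
            for f, c, o in zip(self.factors, param.logic_maps, param.orders)
        ]
        return self.index_of_entries(entries)

    @cached_property
    def _factor_adjacency(self) -> list[dict[int, list[int]]]:
        return [f.adjacency() for f in self.factors]

    def adjacencies(self, index: int) -> list[int]:
        """Indices adjacent to ``index``: exactly one node's entry replaced
        by an intra-factor neighbor.  Symmetric by construction."""
        es = self.entry_indices(index)
        out = []
        for i, (e, radix) in enumerate(zip(es, self._radix)):
            for e2 in self._factor_adjacency[i][e]:
                out.append(index + (e2 - e) * radix)
        return sorted(out)
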