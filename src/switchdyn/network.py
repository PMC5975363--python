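"""Regulatory-network specification files and the integer state lattice.

A network file has one line per node::

    Name : logic-expression [: E]

The right-hand side is a product of factors.  A factor is ``name``,
``~name`` (repression), or a parenthesized ``+``-separated sum of such
terms; juxtaposition means product, e.g. ``(Chk2 + ATM)(~Mdm2)``.  A bare
token that is not a declared node name is split greedily into declared
names (so ``XY`` is the product ``X * Y`` when ``X`` and ``Y`` are nodes
and ``XY`` is not).  The trailing ``: E`` marks the node's parameters as
*essential*: only logic maps in which every input matters are enumerated.

Blank lines and lines starting with ``#`` are ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product as _iproduct

__all__ = [
    "NetworkParseError",
    "LogicExpression",
    "RegulatoryNetwork",
    "StateSpace",
    "parse_network",
    "state_space",
]

ACTIVATION = "activation"
REPRESSION = "repression"

_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")


class NetworkParseError(ValueError):
    """Raised for malformed network specification text."""


@dataclass(frozen=True)
class LogicExpression:
    """Product-of-sums input logic of one node.

    ``groups`` is an ordered tuple of sum-groups; each group is a tuple of
    ``(source_name, sign)`` pairs with ``sign`` one of :data:`ACTIVATION`
    or :data:`REPRESSION`.  The multi-affine interaction term is the
    product over groups of the sum of the step-function values of the
    group's members.
    """

    groups: tuple[tuple[tuple[str, str], ...], ...]

    def __post_init__(self) -> None:
        if not self.groups or any(not g for g in self.groups):
            raise NetworkParseError("logic expression needs at least one nonempty group")
        seen: set[str] = set()
        for g in self.groups:
            for name, sign in g:
                if name in seen:
                    raise NetworkParseError(f"variable {name!r} appears twice in one expression")
                seen.add(name)
                if sign not in (ACTIVATION, REPRESSION):
                    raise NetworkParseError(f"bad sign {sign!r}")

    @property
    def inputs(self) -> tuple[str, ...]:
        """Input names in expression order (group-major)."""
        return tuple(name for g in self.groups for name, _ in g)

    @property
    def signs(self) -> tuple[str, ...]:
        return tuple(sign for g in self.groups for _, sign in g)

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    @property
    def group_sizes(self) -> tuple[int, ...]:
        return tuple(len(g) for g in self.groups)

    def serialize(self) -> str:
        parts = []
        for g in self.groups:
            terms = [("~" + n if s == REPRESSION else n) for n, s in g]
            if len(g) == 1 and g[0][1] == ACTIVATION:
                parts.append(terms[0])
            else:
                parts.append("(" + " + ".join(terms) + ")")
        return " ".join(parts)


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Signed directed network with per-node product-of-sums logic.

    Node order is the order of first definition in the file and fixes every
    integer index used downstream (state coordinates, factor lists,
    parameter indices).
    """

    nodes: tuple[str, ...]
    logic: tuple[LogicExpression, ...]
    essential: tuple[bool, ...]

    def __post_init__(self) -> None:
        declared = set(self.nodes)
        if len(declared) != len(self.nodes):
            raise NetworkParseError("duplicate node definition")
        for expr in self.logic:
            for name in expr.inputs:
                if name not in declared:
                    raise NetworkParseError(f"unknown variable {name!r}")

    # -- basic graph structure -------------------------------------------

    def index(self, name: str) -> int:
        return self.nodes.index(name)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str, str]]:
        """Set of (source, target, sign) triples inferred from the logic."""
        out = set()
        for target, expr in zip(self.nodes, self.logic):
            for name, sign in zip(expr.inputs, expr.signs):
                out.add((name, target, sign))
        return frozenset(out)

    def sources(self, i: int) -> tuple[int, ...]:
        """Indices of inputs of node ``i`` in expression order (may repeat never)."""
        return tuple(self.index(n) for n in self.logic[i].inputs)

    def targets(self, i: int) -> tuple[int, ...]:
        """Indices of targets of node ``i``, ascending."""
        name = self.nodes[i]
        return tuple(
            j for j in range(self.n_nodes) if name in self.logic[j].inputs
        )

    def in_degree(self, i: int) -> int:
        return self.logic[i].n_inputs

    def out_degree(self, i: int) -> int:
        return len(self.targets(i))

    @property
    def sink_nodes(self) -> tuple[str, ...]:
        """Nodes with no targets (single-level state coordinate); permitted,
        and vacuously excluded from full-cycle coverage."""
        return tuple(n for i, n in enumerate(self.nodes) if self.out_degree(i) == 0)

    def target_rank_position(self, source: int, target: int) -> int:
        """Position of ``target`` within ``targets(source)`` (0-based)."""
        return self.targets(source).index(target)

    def serialize(self) -> str:
        lines = []
        for name, expr, ess in zip(self.nodes, self.logic, self.essential):
            line = f"{name} : {expr.serialize()}"
            if ess:
                line += " : E"
            lines.append(line)
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class StateSpace:
    """Integer state lattice ``prod_i {0..m_i}`` with ``m_i`` = out-degree."""

    shape: tuple[int, ...]  # (m_1 + 1, ..., m_N + 1)

    @property
    def size(self) -> int:
        out = 1
        for k in self.shape:
            out *= k
        return out

    @property
    def strides(self) -> tuple[int, ...]:
        """Mixed-radix strides, node 0 least significant."""
        st, acc = [], 1
        for k in self.shape:
            st.append(acc)
            acc *= k
        return tuple(st)

    def states(self):
        """All states as tuples, in index order (node 0 fastest)."""
        ranges = [range(k) for k in self.shape]
        for rev in _iproduct(*reversed(ranges)):
            yield tuple(reversed(rev))

    def state_index(self, state: tuple[int, ...]) -> int:
        return sum(s * st for s, st in zip(state, self.strides))

    def state_at(self, index: int) -> tuple[int, ...]:
        out = []
        for k in self.shape:
            out.append(index % k)
            index //= k
        return tuple(out)


# -- parsing ---------------------------------------------------------------


def _tokenize(rhs: str, lineno: int):
    tokens = []
    i = 0
    while i < len(rhs):
        ch = rhs[i]
        if ch.isspace():
            i += 1
        elif ch in "()+~":
            tokens.append(ch)
            i += 1
        else:
            match = _NAME_RE.match(rhs, i)
            if not match:
                raise NetworkParseError(f"line {lineno}: unexpected character {ch!r}")
            tokens.append(match.group())
            i = match.end()
    return tokens


def _split_token(token: str, declared: set[str], lineno: int) -> list[str]:
    """Resolve a bare token into one or more declared names (longest match)."""
    if token in declared:
        return [token]
    names, i = [], 0
    while i < len(token):
        for j in range(len(token), i, -1):
            if token[i:j] in declared:
                names.append(token[i:j])
                i = j
                break
        else:
            raise NetworkParseError(f"line {lineno}: unknown variable {token!r}")
    return names


def _parse_rhs(rhs: str, declared: set[str], lineno: int) -> LogicExpression:
    tokens = _tokenize(rhs, lineno)
    if not tokens:
        raise NetworkParseError(f"line {lineno}: empty right-hand side")
    groups: list[tuple[tuple[str, str], ...]] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok == "(":
            group: list[tuple[str, str]] = []
            i += 1
            expect_term = True
            while i < len(tokens) and tokens[i] != ")":
                if tokens[i] == "+":
                    if expect_term:
                        raise NetworkParseError(f"line {lineno}: misplaced '+'")
                    expect_term = True
                    i += 1
                    continue
                if not expect_term:
                    raise NetworkParseError(f"line {lineno}: missing '+' in sum")
                sign = ACTIVATION
                if tokens[i] == "~":
                    sign = REPRESSION
                    i += 1
                if i >= len(tokens) or tokens[i] in "()+~":
                    raise NetworkParseError(f"line {lineno}: '~' must precede a name")
                names = _split_token(tokens[i], declared, lineno)
                if len(names) > 1:
                    raise NetworkParseError(
                        f"line {lineno}: product {tokens[i]!r} not allowed inside a sum"
                    )
                group.append((names[0], sign))
                expect_term = False
                i += 1
            if i >= len(tokens):
                raise NetworkParseError(f"line {lineno}: unbalanced parentheses")
            if expect_term:
                raise NetworkParseError(f"line {lineno}: empty or trailing term in sum")
            groups.append(tuple(group))
            i += 1  # consume ')'
        elif tok == ")":
            raise NetworkParseError(f"line {lineno}: unbalanced parentheses")
        elif tok == "+":
            raise NetworkParseError(f"line {lineno}: '+' outside parentheses")
        elif tok == "~":
            i += 1
            if i >= len(tokens) or tokens[i] in "()+~":
                raise NetworkParseError(f"line {lineno}: '~' must precede a name")
            names = _split_token(tokens[i], declared, lineno)
            if len(names) > 1:
                raise NetworkParseError(
                    f"line {lineno}: cannot apply '~' to the product {tokens[i]!r}"
                )
            groups.append(((names[0], REPRESSION),))
            i += 1
        else:
            for name in _split_token(tok, declared, lineno):
                groups.append(((name, ACTIVATION),))
            i += 1
    return LogicExpression(tuple(groups))


def parse_network(text: str) -> RegulatoryNetwork:
    """Parse network specification text into a :class:`RegulatoryNetwork`.

    Edges are inferred from the logic expressions; ``~x`` contributes a
    repression edge, a bare name an activation edge.
    """
    if not text or not text.strip():
        raise NetworkParseError("empty network specification")
    raw_lines = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        raw_lines.append((lineno, stripped))

    names: list[str] = []
    for lineno, line in raw_lines:
        parts = [p.strip() for p in line.split(":")]
        if len(parts) < 2:
            raise NetworkParseError(f"line {lineno}: expected 'Name : expression'")
        if not _NAME_RE.fullmatch(parts[0]):
            raise NetworkParseError(f"line {lineno}: bad node name {parts[0]!r}")
        if parts[0] in names:
            raise NetworkParseError(f"line {lineno}: duplicate node definition {parts[0]!r}")
        names.append(parts[0])

    declared = set(names)
    logic: list[LogicExpression] = []
    essential: list[bool] = []
    for lineno, line in raw_lines:
        parts = [p.strip() for p in line.split(":")]
        if len(parts) > 3 or (len(parts) == 3 and parts[2] != "E"):
            raise NetworkParseError(f"line {lineno}: trailing annotation must be ': E'")
        if not parts[1]:
            raise NetworkParseError(f"line {lineno}: empty right-hand side")
        logic.append(_parse_rhs(parts[1], declared, lineno))
        essential.append(len(parts) == 3)
    return RegulatoryNetwork(tuple(names), tuple(logic), tuple(essential))


def state_space(net: RegulatoryNetwork) -> StateSpace:
    """State lattice of ``net``; node ``i`` has levels ``0..out_degree(i)``."""
    return StateSpace(tuple(net.out_degree(i) + 1 for i in range(net.n_nodes)))
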