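"""SQLite persistence of dynamical signatures and the headline queries.

One row per combinatorial parameter maps the parameter index to a
deduplicated annotated Morse graph.  Schema::

    Signatures(ParameterIndex INTEGER, MorseGraphIndex INTEGER)
    MorseGraphAnnotations(MorseGraphIndex INTEGER, Vertex INTEGER, Label TEXT)
    MorseGraphEdges(MorseGraphIndex INTEGER, Source INTEGER, Target INTEGER)

plus a provenance table ``MorseGraphs(MorseGraphIndex, CanonicalString)``.
The stable-FC / stable-FP queries are embedded verbatim so that schema
drift is caught by tests: a Morse graph vertex is a stable match when its
label matches and it has no outgoing Hasse edge.
"""

from __future__ import annotations

import os
import sqlite3
import tempfile

from .dynamics import (
    AnnotatedMorseGraph,
    async_stg,
    morse_decomposition,
    morse_graph,
    multilevel_map,
)
from .network import RegulatoryNetwork
from .parameter_graph import ParameterGraph

__all__ = [
    "SQL_COUNT_PARAMETERS",
    "SQL_STABLE_FC",
    "SQL_STABLE_FP",
    "compute_database",
    "compute_signatures",
    "count_parameters",
    "count_stable",
]

SQL_COUNT_PARAMETERS = "select count(*) from Signatures"

SQL_STABLE_FC = (
    'select count(*) from Signatures natural join '
    '(select distinct(MorseGraphIndex) from '
    '(select MorseGraphIndex,Vertex from MorseGraphAnnotations where Label="FC" '
    'except select MorseGraphIndex,Source from MorseGraphEdges))'
)

SQL_STABLE_FP = (
    'select count(*) from Signatures natural join '
    '(select distinct(MorseGraphIndex) from '
    '(select MorseGraphIndex,Vertex from MorseGraphAnnotations where Label like '
    '"FP%" except select MorseGraphIndex,Source from MorseGraphEdges))'
)


def compute_signatures(
    pg: ParameterGraph,
    limit: int | None = None,
    engine: str = "auto",
    progress=None,
) -> tuple[list[tuple[int, int]], list[AnnotatedMorseGraph]]:
    """Morse-graph signature of every parameter (or the first ``limit``).

    Returns ``(signatures, graphs)``: parameter-index/Morse-graph-index
    pairs and the deduplicated annotated Morse graphs, indices assigned in
    first-seen parameter order.  ``engine`` selects the pure-Python path
    (``"python"``), the compiled sweep kernel (``"numba"``), or picks by
    problem size (``"auto"``); both paths produce identical output.
    """
    stop = pg.size if limit is None else min(limit, pg.size)
    if engine == "auto":
        engine = "numba" if stop * pg.network.n_nodes > 200_000 else "python"
    if engine == "numba":
        from .sweep import sweep_signatures

        return sweep_signatures(pg, stop, progress=progress)
    if engine != "python":
        raise ValueError(f"unknown engine {engine!r}")

    signatures: list[tuple[int, int]] = []
    graphs: list[AnnotatedMorseGraph] = []
    index_of: dict[str, int] = {}
    for p in range(stop):
        mg = morse_graph(
            morse_decomposition(async_stg(multilevel_map(pg.network, pg.parameter_at(p))))
        )
        key = mg.canonical_string
        mgi = index_of.get(key)
        if mgi is None:
            mgi = len(graphs)
            index_of[key] = mgi
            graphs.append(mg)
        signatures.append((p, mgi))
        if progress is not None and p % 10000 == 0:
            progress(p, stop)
    return signatures, graphs


def _write(path: str, signatures, graphs) -> None:
    """Write-then-rename: an interrupted run never leaves a partial file."""
    directory = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(suffix=".db.tmp", dir=directory)
    os.close(fd)
    try:
        conn = sqlite3.connect(tmp)
        cur = conn.cursor()
        cur.execute("create table Signatures (ParameterIndex INTEGER, MorseGraphIndex INTEGER)")
        cur.execute(
            "create table MorseGraphAnnotations (MorseGraphIndex INTEGER, Vertex INTEGER, Label TEXT)"
        )
        cur.execute(
            "create table MorseGraphEdges (MorseGraphIndex INTEGER, Source INTEGER, Target INTEGER)"
        )
        cur.execute("create table MorseGraphs (MorseGraphIndex INTEGER, CanonicalString TEXT)")
        cur.executemany("insert into Signatures values (?,?)", signatures)
        cur.executemany(
            "insert into MorseGraphAnnotations values (?,?,?)",
            (
                (mgi, v, label)
                for mgi, mg in enumerate(graphs)
                for v, label in enumerate(mg.labels)
            ),
        )
        cur.executemany(
            "insert into MorseGraphEdges values (?,?,?)",
            (
                (mgi, a, b)
                for mgi, mg in enumerate(graphs)
                for a, b in sorted(mg.edges)
            ),
        )
        cur.executemany(
            "insert into MorseGraphs values (?,?)",
            ((mgi, mg.canonical_string) for mgi, mg in enumerate(graphs)),
        )
        conn.commit()
        conn.close()
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def compute_database(
    net: RegulatoryNetwork,
    out_path: str,
    essential: bool | None = None,
    limit: int | None = None,
    engine: str = "auto",
    seed: int = 0,
    progress=None,
) -> str:
    """Sweep every combinatorial parameter of ``net`` and persist the
    signature database at ``out_path`` (deterministic; re-runs overwrite
    with identical contents)."""
    pg = ParameterGraph.build(net, essential=essential, seed=seed)
    signatures, graphs = compute_signatures(pg, limit=limit, engine=engine, progress=progress)
    _write(out_path, signatures, graphs)
    return out_path


def _connect(db):
    if isinstance(db, sqlite3.Connection):
        return db, False
    return sqlite3.connect(db), True


def count_parameters(db) -> int:
    """Row count of Signatures via the verbatim count statement."""
    conn, close = _connect(db)
    try:
        return conn.execute(SQL_COUNT_PARAMETERS).fetchone()[0]
    finally:
        if close:
            conn.close()


def count_stable(db, label_pattern: str) -> int:
    """Parameters whose Morse graph has a stable (leaf) node matching the
    pattern: ``"FC"`` (exact) or ``"FP%"`` (prefix)."""
    sql = {"FC": SQL_STABLE_FC, "FP%": SQL_STABLE_FP}.get(label_pattern)
    if sql is None:
        raise ValueError('label_pattern must be "FC" or "FP%"')
    conn, close = _connect(db)
    try:
        return conn.execute(sql).fetchone()[0]
    finally:
        if close:
            conn.close()
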