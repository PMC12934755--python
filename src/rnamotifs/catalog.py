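"""Relational motif store, conformation classification and export.

The store is a single-file SQLite database with one row per motif
occurrence: id, class, source structure id, size, member keys and both graph
views (JSON).  Conformation classification partitions the stored motifs of
one (class, size) bin into exact attribute-isomorphism classes — two motifs
are the same conformation only if their graphs (including non-WC edges) are
isomorphic with identical edge-attribute vectors.  The canonical key is
computed by color refinement with individualization, so it is invariant
under node relabeling and identical exactly for isomorphic graphs.
"""

from __future__ import annotations

import io
import json
import sqlite3
import zipfile
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import IntegrityError_
from .graphs import RNAGraph
from .motifs import MotifMatch
from .rna_io import Structure, write_motif_pdb

SCHEMA_VERSION = "1"

_SCHEMA = """
CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS motifs (
    motif_id INTEGER PRIMARY KEY,
    motif_class TEXT NOT NULL,
    pdb_id TEXT NOT NULL,
    size INTEGER NOT NULL CHECK (size >= 0),
    members TEXT NOT NULL,
    graph_with_nonwc TEXT NOT NULL,
    graph_without_nonwc TEXT NOT NULL,
    coords_ref TEXT
);
CREATE INDEX IF NOT EXISTS idx_motifs_class_size ON motifs (motif_class, size);
"""


@dataclass
class MotifRow:
    motif_id: int
    motif_class: str
    pdb_id: str
    size: int
    members: list  # [[chain, number, icode], ...]
    graph_with_nonwc: dict
    graph_without_nonwc: dict
    coords_ref: str | None = None

    @classmethod
    def from_match(
        cls, match: MotifMatch, motif_id: int, pdb_id: str | None = None, coords_ref=None
    ) -> "MotifRow":
        if match.graph_with_nonwc is None or match.graph_without_nonwc is None:
            raise ValueError("match must carry both graph views (extract with enrich=True)")
        return cls(
            motif_id=motif_id,
            motif_class=match.motif_class,
            pdb_id=pdb_id or match.structure_id or "",
            size=match.size,
            members=[list(k) for k in match.members],
            graph_with_nonwc=match.graph_with_nonwc.to_json(),
            graph_without_nonwc=match.graph_without_nonwc.to_json(),
            coords_ref=coords_ref,
        )

    def member_keys(self) -> list[tuple[str, int, str]]:
        return [tuple(m) for m in self.members]


@dataclass
class ConformationClass:
    canonical_key: str
    representative: dict  # graph JSON
    frequency: int


class MotifStore:
    """SQLite-backed motif catalog."""

    def __init__(self, path: str = ":memory:"):
        self.conn = sqlite3.connect(path)
        self.conn.executescript(_SCHEMA)
        self.conn.execute(
            "INSERT OR IGNORE INTO meta (key, value) VALUES ('schema_version', ?)",
            (SCHEMA_VERSION,),
        )
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    def store_motifs(self, rows: list[MotifRow]) -> int:
        try:
            with self.conn:
                self.conn.executemany(
                    "INSERT INTO motifs VALUES (?, ?, ?, ?, ?, ?, ?, ?)",
                    [
                        (
                            r.motif_id,
                            r.motif_class,
                            r.pdb_id,
                            r.size,
                            json.dumps(r.members),
                            json.dumps(r.graph_with_nonwc, sort_keys=True),
                            json.dumps(r.graph_without_nonwc, sort_keys=True),
                            r.coords_ref,
                        )
                        for r in rows
                    ],
                )
        except sqlite3.IntegrityError as exc:
            raise IntegrityError_(str(exc)) from exc
        return len(rows)

    def query_motifs(self, motif_class: str | None = None, size: int | None = None):
        sql = "SELECT * FROM motifs"
        clauses, params = [], []
        if motif_class is not None:
            clauses.append("motif_class = ?")
            params.append(motif_class)
        if size is not None:
            clauses.append("size = ?")
            params.append(size)
        if clauses:
            sql += " WHERE " + " AND ".join(clauses)
        sql += " ORDER BY motif_id"
        rows = []
        for rec in self.conn.execute(sql, params):
            rows.append(
                MotifRow(
                    motif_id=rec[0],
                    motif_class=rec[1],
                    pdb_id=rec[2],
                    size=rec[3],
                    members=json.loads(rec[4]),
                    graph_with_nonwc=json.loads(rec[5]),
                    graph_without_nonwc=json.loads(rec[6]),
                    coords_ref=rec[7],
                )
            )
        return rows

    def __len__(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM motifs").fetchone()[0]


# ---------------------------------------------------------------------------
# export


def export_csv(rows: list[MotifRow]) -> str:
    """CSV with exactly the columns (ID, motif type, PDB ID, nucleotide number)."""
    lines = ["ID,motif type,PDB ID,nucleotide number"]
    for r in rows:
        lines.append(f"{r.motif_id},{r.motif_class},{r.pdb_id},{r.size}")
    return "\n".join(lines) + "\n"


def export_zip(rows: list[MotifRow], structures: dict[str, Structure]) -> bytes:
    """ZIP archive with one PDB file per row, named ``<motif_id>.pdb``."""
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED) as zf:
        for r in rows:
            structure = structures[r.pdb_id]
            text = write_motif_pdb(structure, r.member_keys())
            zf.writestr(f"{r.motif_id}.pdb", text)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# canonical labeling (exact, for attribute-isomorphism classes)


def _refine(graph: nx.Graph, colors: dict) -> dict:
    while True:
        signatures = {
            node: (
                colors[node],
                tuple(
                    sorted(
                        (graph.edges[node, nb]["attr"], colors[nb]) for nb in graph[node]
                    )
                ),
            )
            for node in graph
        }
        palette = {sig: i for i, sig in enumerate(sorted(set(signatures.values())))}
        new_colors = {node: palette[signatures[node]] for node in graph}
        if len(set(new_colors.values())) == len(set(colors.values())) and all(
            new_colors[a] == new_colors[b]
            for a in graph
            for b in graph
            if colors[a] == colors[b]
        ):
            return new_colors
        colors = new_colors


def _serialize(graph: nx.Graph, order: dict) -> tuple:
    edges = sorted(
        (min(order[a], order[b]), max(order[a], order[b]), graph.edges[a, b]["attr"])
        for a, b in graph.edges
    )
    return (graph.number_of_nodes(), tuple(edges))


def _canonical_tuple(graph: nx.Graph, colors: dict) -> tuple:
    colors = _refine(graph, colors)
    classes: dict[int, list] = {}
    for node, color in colors.items():
        classes.setdefault(color, []).append(node)
    non_singleton = [c for c in sorted(classes) if len(classes[c]) > 1]
    if not non_singleton:
        order = {node: colors[node] for node in graph}
        # colors are distinct; normalize to ranks 0..n-1
        rank = {c: i for i, c in enumerate(sorted(order.values()))}
        return _serialize(graph, {node: rank[c] for node, c in order.items()})
    target = non_singleton[0]
    best = None
    fresh = max(colors.values()) + 1
    for node in classes[target]:
        branched = dict(colors)
        branched[node] = fresh
        candidate = _canonical_tuple(graph, branched)
        if best is None or candidate < best:
            best = candidate
    return best


def canonical_key(graph: RNAGraph | nx.Graph) -> str:
    """Relabeling-invariant key, identical iff graphs are attribute-isomorphic."""
    g = graph.graph if isinstance(graph, RNAGraph) else graph
    if g.number_of_nodes() == 0:
        return "0;"
    n, edges = _canonical_tuple(g, {node: 0 for node in g})
    return f"{n};" + ";".join(f"{a}-{b}:{''.join(map(str, attr))}" for a, b, attr in edges)


# ---------------------------------------------------------------------------
# conformation classification


def classify_conformations(
    store: MotifStore,
    motif_class: str | None = None,
    size: int | None = None,
    use_nonwc: bool = True,
) -> list[ConformationClass]:
    """Partition the fetched motifs into unique graph conformations.

    Fetch by class/size, group the chosen graph view by canonical key and
    count occurrences.  Output sorted by frequency descending, ties broken
    by canonical key; frequencies always sum to the number fetched and the
    partition is independent of insertion order.
    """
    rows = store.query_motifs(motif_class=motif_class, size=size)
    buckets: dict[str, ConformationClass] = {}
    for row in rows:
        payload = row.graph_with_nonwc if use_nonwc else row.graph_without_nonwc
        key = canonical_key(RNAGraph.from_json(payload))
        if key in buckets:
            buckets[key].frequency += 1
        else:
            buckets[key] = ConformationClass(canonical_key=key, representative=payload, frequency=1)
    return sorted(buckets.values(), key=lambda c: (-c.frequency, c.canonical_key))


def distributions(store: MotifStore):
    """Class share table (percent) and per-class size histograms."""
    rows = store.query_motifs()
    if not rows:
        return pd.Series(dtype=float, name="share_percent"), {}
    frame = pd.DataFrame({"motif_class": [r.motif_class for r in rows], "size": [r.size for r in rows]})
    shares = (frame["motif_class"].value_counts(normalize=True) * 100.0).rename("share_percent")
    hists = {
        cls: grp["size"].value_counts().sort_index()
        for cls, grp in frame.groupby("motif_class")
    }
    return shares, hists
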