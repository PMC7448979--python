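"""Tripartite compound–target–disease interaction network: data model and I/O.

The network is a typed, undirected multipartite graph.  Nodes are compounds,
proteins (targets) or diseases; edges are one of four pair types:

* ``CT`` — compound–target
* ``CD`` — compound–disease
* ``DT`` — disease–target
* ``TT`` — protein–protein

Each edge carries a provenance tag (``known``, ``sim_inferred`` or
``ctcs_predicted``) and, for inferred edges, a support count (number of
distinct inference routes).  Edge identity is the unordered node pair plus
the pair type; provenance and support are attributes resolved on merge
(strongest provenance wins, supports are maximised).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

KINDS = ("compound", "protein", "disease")
PAIR_TYPES = ("CT", "CD", "DT", "TT")
PROVENANCES = ("known", "sim_inferred", "ctcs_predicted")

#: endpoint kinds admissible for each pair type (as an unordered multiset)
PAIR_KINDS = {
    "CT": ("compound", "protein"),
    "CD": ("compound", "disease"),
    "DT": ("disease", "protein"),
    "TT": ("protein", "protein"),
}

# higher rank = stronger provenance; known beats any prediction
_PROV_RANK = {"known": 2, "sim_inferred": 1, "ctcs_predicted": 1}


@dataclass
class Entity:
    """A node: a compound, protein or disease with optional identifier labels."""

    id: str
    kind: str
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown entity kind {self.kind!r} for {self.id!r}")

    def __eq__(self, other):
        return (
            isinstance(other, Entity)
            and self.id == other.id
            and self.kind == other.kind
            and self.labels == other.labels
        )

    def __hash__(self):
        return hash((self.id, self.kind))


@dataclass
class Interaction:
    """An undirected typed edge; identity is (unordered pair, pair_type)."""

    a: str
    b: str
    pair_type: str
    provenance: str = "known"
    support: int = 0
    routes: list = field(default_factory=list)

    def __post_init__(self):
        if self.pair_type not in PAIR_TYPES:
            raise ValueError(f"unknown pair_type {self.pair_type!r}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.a == self.b:
            raise ValueError(f"self-edge {self.a!r} is not allowed")
        if self.support < 0:
            raise ValueError("support must be nonnegative")

    @property
    def key(self):
        """Canonical identity: (sorted endpoint pair, pair_type)."""
        lo, hi = sorted((self.a, self.b))
        return (lo, hi, self.pair_type)


class TripartiteNetwork:
    """Container of entities and interactions with validation on insert."""

    def __init__(self):
        self.entities: dict[str, Entity] = {}
        self._edges: dict[tuple, Interaction] = {}

    # -- construction -------------------------------------------------

    def add_entity(self, entity: Entity) -> None:
        existing = self.entities.get(entity.id)
        if existing is not None and existing.kind != entity.kind:
            raise ValueError(
                f"entity {entity.id!r} redeclared with kind {entity.kind!r}, "
                f"was {existing.kind!r}"
            )
        if existing is None:
            self.entities[entity.id] = entity
        else:
            existing.labels.update(entity.labels)

    def add_interaction(self, inter: Interaction, merge: bool = True) -> bool:
        """Insert an edge; returns True if the edge was new.

        On collision the strongest provenance and the maximum support are
        kept (``merge=True``); with ``merge=False`` a collision is an error.
        """
        for end in (inter.a, inter.b):
            if end not in self.entities:
                raise ValueError(f"interaction endpoint {end!r} is not a known entity")
        kinds = tuple(sorted((self.entities[inter.a].kind, self.entities[inter.b].kind)))
        if kinds != tuple(sorted(PAIR_KINDS[inter.pair_type])):
            raise ValueError(
                f"pair_type {inter.pair_type} incompatible with endpoint kinds "
                f"{kinds} for edge {inter.a!r}-{inter.b!r}"
            )
        key = inter.key
        old = self._edges.get(key)
        if old is None:
            self._edges[key] = inter
            return True
        if not merge:
            raise ValueError(f"duplicate interaction {key}")
        if _PROV_RANK[inter.provenance] > _PROV_RANK[old.provenance]:
            old.provenance = inter.provenance
        old.support = max(old.support, inter.support)
        if inter.routes:
            seen = set(map(tuple, map(_route_key, old.routes)))
            for r in inter.routes:
                if _route_key(r) not in seen:
                    old.routes.append(r)
        return False

    # -- queries ------------------------------------------------------

    @property
    def interactions(self) -> list[Interaction]:
        return list(self._edges.values())

    def has_pair(self, a: str, b: str, pair_type: str) -> bool:
        lo, hi = sorted((a, b))
        return (lo, hi, pair_type) in self._edges

    def get(self, a: str, b: str, pair_type: str) -> Interaction | None:
        lo, hi = sorted((a, b))
        return self._edges.get((lo, hi, pair_type))

    def edges_of_type(self, pair_type: str, provenance: str | None = None):
        out = [e for e in self._edges.values() if e.pair_type == pair_type]
        if provenance is not None:
            out = [e for e in out if e.provenance == provenance]
        return sorted(out, key=lambda e: e.key)

    def partners(self, entity_id: str, pair_type: str, provenance: str | None = None):
        """Sorted ids of neighbors of ``entity_id`` over edges of one type."""
        out = set()
        for e in self._edges.values():
            if e.pair_type != pair_type:
                continue
            if provenance is not None and e.provenance != provenance:
                continue
            if e.a == entity_id:
                out.add(e.b)
            elif e.b == entity_id:
                out.add(e.a)
        return sorted(out)

    def n_entities(self) -> int:
        return len(self.entities)

    def n_interactions(self) -> int:
        return len(self._edges)

    def kinds_count(self) -> dict:
        out = {k: 0 for k in KINDS}
        for e in self.entities.values():
            out[e.kind] += 1
        return out

    def copy(self) -> "TripartiteNetwork":
        new = TripartiteNetwork()
        for ent in self.entities.values():
            new.add_entity(Entity(ent.id, ent.kind, dict(ent.labels)))
        for e in self._edges.values():
            new.add_interaction(
                Interaction(e.a, e.b, e.pair_type, e.provenance, e.support, list(e.routes))
            )
        return new

    def to_networkx(self) -> nx.Graph:
        """Simple undirected graph view (parallel pair types collapse)."""
        g = nx.Graph()
        for ent in self.entities.values():
            g.add_node(ent.id, kind=ent.kind)
        for e in self._edges.values():
            g.add_edge(e.a, e.b, pair_type=e.pair_type, provenance=e.provenance)
        return g

    def __eq__(self, other):
        if not isinstance(other, TripartiteNetwork):
            return NotImplemented
        if self.entities != other.entities:
            return False
        if set(self._edges) != set(other._edges):
            return False
        for k, e in self._edges.items():
            o = other._edges[k]
            if (e.provenance, e.support) != (o.provenance, o.support):
                return False
        return True

    def __repr__(self):
        c = self.kinds_count()
        return (
            f"TripartiteNetwork({c['compound']} compounds, {c['protein']} proteins, "
            f"{c['disease']} diseases, {self.n_interactions()} interactions)"
        )


def _route_key(route):
    if isinstance(route, str):
        return ("s", route)
    return ("t", tuple(route))


# -- I/O ---------------------------------------------------------------


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype=str).fillna("")


def load_network(node_table, edge_table) -> TripartiteNetwork:
    """Load a network from a node table and an edge table.

    Node table columns: ``id``, ``kind`` plus any label columns.  Edge table
    columns: ``a``, ``b``, ``pair_type`` and optionally ``provenance`` and
    ``support``.  Duplicate rows are collapsed; the duplicate count is
    logged.  Edges referencing undeclared entities are hard errors.
    """
    net = TripartiteNetwork()
    nodes = _read_table(node_table)
    if len(nodes) and not {"id", "kind"}.issubset(nodes.columns):
        raise ValueError("node table must have columns 'id' and 'kind'")
    dup_nodes = 0
    for _, row in nodes.iterrows():
        labels = {
            c: row[c] for c in nodes.columns if c not in ("id", "kind") and row[c] != ""
        }
        if row["id"] in net.entities:
            dup_nodes += 1
        net.add_entity(Entity(str(row["id"]), str(row["kind"]), labels))

    edges = _read_table(edge_table)
    if len(edges) and not {"a", "b", "pair_type"}.issubset(edges.columns):
        raise ValueError("edge table must have columns 'a', 'b' and 'pair_type'")
    dup_edges = 0
    for i, row in edges.iterrows():
        prov = row.get("provenance", "") or "known"
        support = int(row.get("support", "") or 0)
        for end in (row["a"], row["b"]):
            if end not in net.entities:
                raise ValueError(f"edge row {i}: endpoint {end!r} missing from node table")
        inter = Interaction(str(row["a"]), str(row["b"]), str(row["pair_type"]), prov, support)
        if not net.add_interaction(inter):
            dup_edges += 1
    if dup_nodes or dup_edges:
        log.warning("collapsed %d duplicate node rows, %d duplicate edge rows",
                    dup_nodes, dup_edges)
    return net


def merge_interactions(net: TripartiteNetwork, new_edges, dedupe_against_known: bool = True):
    """Merge predicted/inferred edges into a network.

    Returns ``(merged_network, counts)`` with counts ``added``,
    ``dropped_existing`` (edge already present with provenance *known* while
    deduplication is on) and ``dropped_duplicate`` (repeated within
    ``new_edges`` or already present as a non-known edge).
    """
    out = net.copy()
    counts = {"added": 0, "dropped_existing": 0, "dropped_duplicate": 0}
    for e in new_edges:
        for end, kind_attr in ((e.a, None), (e.b, None)):
            if end not in out.entities:
                raise ValueError(
                    f"merge endpoint {end!r} unknown; declare it in the node set first"
                )
        existing = out.get(e.a, e.b, e.pair_type)
        if existing is not None:
            if dedupe_against_known and existing.provenance == "known":
                counts["dropped_existing"] += 1
            else:
                out.add_interaction(
                    Interaction(e.a, e.b, e.pair_type, e.provenance, e.support, list(e.routes))
                )
                counts["dropped_duplicate"] += 1
            continue
        out.add_interaction(
            Interaction(e.a, e.b, e.pair_type, e.provenance, e.support, list(e.routes))
        )
        counts["added"] += 1
    return out, counts


def write_network(net: TripartiteNetwork, edge_path, node_path=None, format: str = "edge-tsv"):
    """Write a network as edge/node TSV tables or Cytoscape SIF.

    ``edge-tsv`` writes the edge table to ``edge_path`` and, when
    ``node_path`` is given, the node table alongside (both are needed for a
    lossless round trip through :func:`load_network`).  ``sif`` writes
    whitespace-delimited ``a <pair_type> b`` lines; isolated nodes appear as
    bare ids on their own line.
    """
    edge_path = Path(edge_path)
    if format == "edge-tsv":
        rows = [
            {"a": e.a, "b": e.b, "pair_type": e.pair_type,
             "provenance": e.provenance, "support": e.support}
            for e in sorted(net.interactions, key=lambda e: (e.pair_type, e.key))
        ]
        pd.DataFrame(rows, columns=["a", "b", "pair_type", "provenance", "support"]).to_csv(
            edge_path, sep="\t", index=False
        )
        if node_path is not None:
            label_cols = sorted({k for ent in net.entities.values() for k in ent.labels})
            nrows = []
            for ent in sorted(net.entities.values(), key=lambda x: x.id):
                row = {"id": ent.id, "kind": ent.kind}
                row.update({c: ent.labels.get(c, "") for c in label_cols})
                nrows.append(row)
            pd.DataFrame(nrows, columns=["id", "kind", *label_cols]).to_csv(
                Path(node_path), sep="\t", index=False
            )
    elif format == "sif":
        touched = set()
        lines = []
        for e in sorted(net.interactions, key=lambda e: (e.pair_type, e.key)):
            lines.append(f"{e.a} {e.pair_type} {e.b}")
            touched.update((e.a, e.b))
        for ent_id in sorted(net.entities):
            if ent_id not in touched:
                lines.append(ent_id)
        edge_path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unknown format {format!r}")


def induced_subgraph(net: TripartiteNetwork, node_ids) -> TripartiteNetwork:
    """Subnetwork on ``node_ids`` with exactly the edges internal to the set."""
    node_ids = set(node_ids)
    unknown = node_ids - set(net.entities)
    if unknown:
        raise ValueError(f"unknown entity ids: {sorted(unknown)}")
    sub = TripartiteNetwork()
    for nid in sorted(node_ids):
        ent = net.entities[nid]
        sub.add_entity(Entity(ent.id, ent.kind, dict(ent.labels)))
    for e in net.interactions:
        if e.a in node_ids and e.b in node_ids:
            sub.add_interaction(
                Interaction(e.a, e.b, e.pair_type, e.provenance, e.support, list(e.routes))
            )
    return sub
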