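"""Network topology statistics and disease-seeded module extraction.

Statistics follow the Cytoscape NetworkAnalyzer conventions for simple
undirected graphs: shortest-path quantities are evaluated inside each
connected component (so a disconnected network still has a finite diameter
and its radius is taken over components independently), density counts
unordered pairs, and heterogeneity/centralization are degree-distribution
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .network import TripartiteNetwork, induced_subgraph


@dataclass
class NetworkStats:
    nodes: int
    edges: int
    connected_components: int
    diameter: int
    radius: int
    density: float
    heterogeneity: float
    centralization: float
    characteristic_path_length: float
    avg_neighbors: float
    isolated_nodes: int
    centralization_defined: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SeedModule:
    seed: str
    path_length: int
    counts: dict
    subnetwork: TripartiteNetwork


def compute_stats(net: TripartiteNetwork) -> NetworkStats:
    """Topology summary of the (simple, undirected) network view.

    * density = 2E / (N(N-1))
    * avg_neighbors = mean degree
    * heterogeneity = population sd(degree) / mean(degree)
    * centralization = N/(N-2) * (max_degree/(N-1) - density)
    * characteristic path length = mean shortest path over all connected
      ordered pairs; diameter = max finite eccentricity; radius = min
      eccentricity over non-isolated nodes, components evaluated
      independently.
    """
    g = net.to_networkx()
    n = g.number_of_nodes()
    e = g.number_of_edges()
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    isolated = int((degrees == 0).sum()) if n else 0
    density = 2 * e / (n * (n - 1)) if n > 1 else 0.0
    mean_deg = degrees.mean() if n else 0.0
    heterogeneity = float(degrees.std(ddof=0) / mean_deg) if mean_deg > 0 else 0.0
    centralization_defined = n >= 3
    if centralization_defined:
        centralization = float(n / (n - 2) * (degrees.max() / (n - 1) - density))
    else:
        centralization = 0.0

    diameter = 0
    radius_candidates = []
    path_sum = 0.0
    path_pairs = 0
    components = list(nx.connected_components(g)) if n else []
    for comp in components:
        if len(comp) == 1:
            continue
        sub = g.subgraph(comp)
        ecc = nx.eccentricity(sub)
        diameter = max(diameter, max(ecc.values()))
        radius_candidates.append(min(ecc.values()))
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            path_sum += sum(dists.values())
            path_pairs += len(dists) - 1  # exclude self
    cpl = path_sum / path_pairs if path_pairs else 0.0
    radius = min(radius_candidates) if radius_candidates else 0
    return NetworkStats(
        nodes=n,
        edges=e,
        connected_components=len(components),
        diameter=int(diameter),
        radius=int(radius),
        density=float(density),
        heterogeneity=heterogeneity,
        centralization=centralization,
        characteristic_path_length=float(cpl),
        avg_neighbors=float(mean_deg),
        isolated_nodes=isolated,
        centralization_defined=centralization_defined,
    )


def extract_seed_module(net: TripartiteNetwork, seed: str, path_length: int = 2) -> SeedModule:
    """Induced subnetwork of every node within ``path_length`` of ``seed``."""
    if seed not in net.entities:
        raise ValueError(f"unknown seed node {seed!r}")
    g = net.to_networkx()
    reach = nx.single_source_shortest_path_length(g, seed, cutoff=path_length)
    members = set(reach)
    sub = induced_subgraph(net, members)
    counts = {"compounds": 0, "diseases": 0, "targets": 0}
    for m in members:
        kind = net.entities[m].kind
        if kind == "compound":
            counts["compounds"] += 1
        elif kind == "disease":
            counts["diseases"] += 1
        else:
            counts["targets"] += 1
    return SeedModule(seed=seed, path_length=path_length, counts=counts, subnetwork=sub)


def compare_stats(a: NetworkStats, b: NetworkStats) -> pd.DataFrame:
    """Side-by-side table of two stat sets with a delta column."""
    fields = [f for f in a.as_dict() if f != "centralization_defined"]
    da, db = a.as_dict(), b.as_dict()
    return pd.DataFrame(
        {
            "parameter": fields,
            "a": [da[f] for f in fields],
            "b": [db[f] for f in fields],
            "delta": [db[f] - da[f] for f in fields],
        }
    ).set_index("parameter")
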