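"""Shared fixtures: the published evaluation network, random tripartite
networks, and an exhaustive premise-pair enumeration oracle for the simple
inference model (independent of the package's rule implementation)."""

import itertools

import numpy as np
import pytest

from sipa import Entity, Interaction, TripartiteNetwork, evaluation_network


@pytest.fixture
def benchmark_net():
    return evaluation_network()


def make_random_network(n_compounds=10, n_proteins=10, n_diseases=5,
                        edge_prob=0.2, seed=0, with_tt=True) -> TripartiteNetwork:
    """Seeded random tripartite network over all four edge types."""
    rng = np.random.default_rng(seed)
    net = TripartiteNetwork()
    compounds = [f"C{i}" for i in range(n_compounds)]
    proteins = [f"T{i}" for i in range(n_proteins)]
    diseases = [f"D{i}" for i in range(n_diseases)]
    for c in compounds:
        net.add_entity(Entity(c, "compound"))
    for t in proteins:
        net.add_entity(Entity(t, "protein"))
    for d in diseases:
        net.add_entity(Entity(d, "disease"))
    for c, t in itertools.product(compounds, proteins):
        if rng.random() < edge_prob:
            net.add_interaction(Interaction(c, t, "CT"))
    for c, d in itertools.product(compounds, diseases):
        if rng.random() < edge_prob:
            net.add_interaction(Interaction(c, d, "CD"))
    for d, t in itertools.product(diseases, proteins):
        if rng.random() < edge_prob:
            net.add_interaction(Interaction(d, t, "DT"))
    if with_tt:
        for ta, tb in itertools.combinations(proteins, 2):
            if rng.random() < edge_prob / 2:
                net.add_interaction(Interaction(ta, tb, "TT"))
    return net


def brute_force_sim(net: TripartiteNetwork, family: str):
    """O(E^2) oracle: enumerate every ordered pair of known edges and match
    it against the rule patterns directly.

    Returns {(a, b, pair_type, rule): set of intermediates} with (a, b) the
    canonical sorted pair.
    """
    edges = [e for e in net.interactions if e.provenance == "known"]
    kind = {eid: ent.kind for eid, ent in net.entities.items()}
    out: dict[tuple, set] = {}

    def orientations(e):
        return [(e.a, e.b), (e.b, e.a)]

    def emit(a, b, pair_type, rule, mid):
        if a == b:
            return
        lo, hi = sorted((a, b))
        out.setdefault((lo, hi, pair_type, rule), set()).add(mid)

    for e1, e2 in itertools.product(edges, edges):
        for (x1, y1), (x2, y2) in itertools.product(orientations(e1), orientations(e2)):
            if y1 != x2:
                continue
            mid = y1
            k1, km, k2 = kind[x1], kind[mid], kind[y2]
            if family == "target":
                if k1 == "compound" and km == "protein" and k2 == "disease" \
                        and e1.pair_type == "CT" and e2.pair_type == "DT":
                    emit(x1, y2, "CD", "R1_CD", mid)
                if k1 == "compound" and km == "protein" and k2 == "protein" \
                        and e1.pair_type == "CT" and e2.pair_type == "TT":
                    emit(x1, y2, "CT", "R2_CT", mid)
                if k1 == "protein" and km == "protein" and k2 == "disease" \
                        and e1.pair_type == "TT" and e2.pair_type == "DT":
                    emit(y2, x1, "DT", "R3_DT", mid)
            else:
                if k1 == "disease" and km == "compound" and k2 == "protein" \
                        and e1.pair_type == "CD" and e2.pair_type == "CT":
                    emit(x1, y2, "DT", "R4_DT", mid)
                if k1 == "compound" and km == "disease" and k2 == "protein" \
                        and e1.pair_type == "CD" and e2.pair_type == "DT":
                    emit(x1, y2, "CT", "R5_CT", mid)
    return out


def as_oracle_dict(inferred):
    """Package output -> the oracle's {(a, b, pair_type, rule): mids} form."""
    return {
        (*x.key, x.rule): {r.intermediate for r in x.routes}
        for x in inferred
    }
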