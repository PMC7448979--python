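"""Simple inference model (SIM): one-hop logical link inference.

Five rules infer a candidate edge from two known edges that share an
intermediate node.  Target-centered rules (principle A):

* R1_CD — compound–target and target–disease imply compound–disease;
* R2_CT — compound–target and target–target imply compound–target;
* R3_DT — target–target and target–disease imply (other) target–disease.

Compound/disease-centered rules (principle B):

* R4_DT — compound–disease and compound–target imply disease–target
  (intermediate = the compound);
* R5_CT — compound–disease and disease–target imply compound–target
  (intermediate = the disease).

Each inferred pair aggregates its inference routes; the support is the
number of distinct intermediates.  The compound/disease-centered family is
noisier, so its output is filtered by a minimum support (default 2).
Inference is a single pass: inferred edges are never reused as premises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import Interaction, TripartiteNetwork

TARGET_CENTERED_RULES = ("R1_CD", "R2_CT", "R3_DT")
ENTITY_CENTERED_RULES = ("R4_DT", "R5_CT")

#: pair type emitted by each rule
RULE_PAIR_TYPE = {
    "R1_CD": "CD",
    "R2_CT": "CT",
    "R3_DT": "DT",
    "R4_DT": "DT",
    "R5_CT": "CT",
}


@dataclass
class InferenceRoute:
    """One (premise, premise) chain producing an inferred pair.

    ``chain`` uses the a–intermediate–b notation, e.g. ``D2-C29-T8``.
    """

    intermediate: str
    used_edges: tuple
    chain: str


@dataclass
class InferredInteraction:
    a: str
    b: str
    pair_type: str
    rule: str
    routes: list = field(default_factory=list)
    novel: bool = False

    @property
    def support(self) -> int:
        return len({r.intermediate for r in self.routes})

    @property
    def key(self):
        lo, hi = sorted((self.a, self.b))
        return (lo, hi, self.pair_type)

    def to_interaction(self) -> Interaction:
        return Interaction(
            self.a, self.b, self.pair_type, "sim_inferred", self.support,
            [r.chain for r in self.routes],
        )


def _known(net: TripartiteNetwork, pair_type: str):
    return net.edges_of_type(pair_type, provenance="known")


def _directed(edges, net, kind_first):
    """Yield (x, y) orientations of undirected edges with x of ``kind_first``."""
    for e in edges:
        ka = net.entities[e.a].kind
        if ka == kind_first:
            yield e.a, e.b, e
        if net.entities[e.b].kind == kind_first:
            yield e.b, e.a, e


def _collect(instances, net):
    """Group (a, b, pair_type, rule, intermediate, edges) into inferred pairs."""
    grouped: dict[tuple, InferredInteraction] = {}
    for a, b, pair_type, rule, mid, used in instances:
        if a == b:
            continue
        lo, hi = sorted((a, b))
        key = (lo, hi, pair_type, rule)
        item = grouped.get(key)
        if item is None:
            item = InferredInteraction(a, b, pair_type, rule)
            grouped[key] = item
        if any(r.intermediate == mid for r in item.routes):
            continue
        item.routes.append(InferenceRoute(mid, used, f"{item.a}-{mid}-{item.b}"))
    out = list(grouped.values())
    for item in out:
        item.novel = not net.has_pair(item.a, item.b, item.pair_type)
    out.sort(key=lambda x: (x.pair_type, x.key, x.rule))
    return out


def target_centered_inference(net: TripartiteNetwork) -> list[InferredInteraction]:
    """Principle A: infer edges through a shared target (rules R1–R3)."""
    ct = _known(net, "CT")
    dt = _known(net, "DT")
    tt = _known(net, "TT")

    # partner maps keyed by the shared target
    comp_by_t: dict[str, list] = {}
    for c, t, e in _directed(ct, net, "compound"):
        comp_by_t.setdefault(t, []).append((c, e))
    dis_by_t: dict[str, list] = {}
    for d, t, e in _directed(dt, net, "disease"):
        dis_by_t.setdefault(t, []).append((d, e))

    instances = []
    # R1: C–Ta & Ta–D => C–D
    for t, comps in comp_by_t.items():
        for d, de in dis_by_t.get(t, []):
            for c, ce in comps:
                instances.append((c, d, "CD", "R1_CD", t, (ce, de)))
    # R2: C–Ta & Ta–Tb => C–Tb
    for e in tt:
        for ta, tb in ((e.a, e.b), (e.b, e.a)):
            for c, ce in comp_by_t.get(ta, []):
                instances.append((c, tb, "CT", "R2_CT", ta, (ce, e)))
    # R3: Tb–Ta & Ta–D => Tb–D
    for e in tt:
        for ta, tb in ((e.a, e.b), (e.b, e.a)):
            for d, de in dis_by_t.get(ta, []):
                instances.append((d, tb, "DT", "R3_DT", ta, (e, de)))
    return _collect(instances, net)


def entity_centered_inference(net: TripartiteNetwork) -> list[InferredInteraction]:
    """Principle B: infer edges through a shared compound or disease (R4, R5)."""
    cd = _known(net, "CD")
    ct = _known(net, "CT")
    dt = _known(net, "DT")

    dis_by_c: dict[str, list] = {}
    for c, d, e in _directed(cd, net, "compound"):
        dis_by_c.setdefault(c, []).append((d, e))
    tgt_by_c: dict[str, list] = {}
    for c, t, e in _directed(ct, net, "compound"):
        tgt_by_c.setdefault(c, []).append((t, e))
    tgt_by_d: dict[str, list] = {}
    for d, t, e in _directed(dt, net, "disease"):
        tgt_by_d.setdefault(d, []).append((t, e))

    instances = []
    # R4: C–D & C–T => D–T (intermediate compound)
    for c, diseases in dis_by_c.items():
        for t, te in tgt_by_c.get(c, []):
            for d, de in diseases:
                instances.append((d, t, "DT", "R4_DT", c, (de, te)))
    # R5: C–D & D–T => C–T (intermediate disease)
    for c, diseases in dis_by_c.items():
        for d, de in diseases:
            for t, te in tgt_by_d.get(d, []):
                instances.append((c, t, "CT", "R5_CT", d, (de, te)))
    return _collect(instances, net)


def apply_support_filter(inferred, min_support: int):
    """Keep inferred pairs with support >= ``min_support`` (stable order)."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    return [x for x in inferred if x.support >= min_support]


def run_sim(
    net: TripartiteNetwork,
    min_support_entity_centered: int = 2,
    min_support_target_centered: int = 1,
    evaluation_mode: bool = False,
) -> dict:
    """Run both SIM inference families over the known edges of ``net``.

    In production mode (default) both families run, the per-family support
    filters apply and pairs already known are dropped: the output is the
    novel-edge expansion set.  Evaluation mode mirrors the published
    benchmark of the noisier compound/disease-centered family: only that
    family runs, support filters are relaxed to 1 and known pairs are
    retained (flagged ``novel=False``) so the full inference table can be
    compared against a held-back test set.

    Returns ``{"inferred": [...], "novel": [...]}``, both deterministically
    ordered by (pair_type, pair ids).
    """
    if evaluation_mode:
        min_support_entity_centered = 1
        tc = []
    else:
        tc = apply_support_filter(
            target_centered_inference(net), min_support_target_centered)
    ec = apply_support_filter(entity_centered_inference(net), min_support_entity_centered)
    inferred = tc + ec
    if not evaluation_mode:
        inferred = [x for x in inferred if x.novel]
    inferred.sort(key=lambda x: (x.pair_type, x.key, x.rule))
    novel = [x for x in inferred if x.novel]
    return {"inferred": inferred, "novel": novel}
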