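"""Compound–target correlation-space interaction prediction (CTCS-IPM).

For every target, the compounds known to act on it form the *compound
space* of that target in the selected-descriptor coordinates (and
symmetrically the *target space* of a compound).  All pairwise Euclidean
distances inside a space define a per-anchor threshold — by default the
upper limit of the 95 % confidence interval of the mean distance — and a
candidate is predicted to interact when its distances to the members
satisfy the decision rule (default: every distance within the threshold).

No negative training examples are needed; evaluation is by recall of
held-out known interactions under per-target stratified splitting and
k-fold cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist, pdist
from sklearn.base import BaseEstimator

from .cca import (
    FeatureSelection,
    build_paired_sample,
    fit_cca,
    select_feature_descriptors,
)
from .preprocess import DescriptorCleaner
from .network import TripartiteNetwork

log = logging.getLogger(__name__)

THRESHOLD_METHODS = ("ci_mean_t95", "percentile95", "mean_plus_1p96sd")
DECISION_RULES = ("all", "any", "mean")


@dataclass
class EntitySpace:
    """The member cloud of one anchor plus its distance threshold."""

    anchor: str
    anchor_kind: str
    member_ids: list
    features: np.ndarray
    pairwise_distances: np.ndarray
    threshold: float
    threshold_method: str
    degenerate: bool = False


@dataclass
class SpaceSkipped:
    anchor: str
    reason: str


@dataclass
class PredictionRecord:
    compound: str
    protein: str
    direction: str
    n_members: int
    d_max: float
    d_mean: float
    d_min: float
    threshold: float
    decision: bool
    rule: str
    agreement: bool | None = None


@dataclass
class RecallReport:
    folds: list
    average_recall: float
    config: dict
    seed: int


# -- primitives --------------------------------------------------------


def standardize_features(dm: pd.DataFrame, columns, reference_stats=None):
    """Z-score the selected columns; returns (standardised frame, stats).

    With ``reference_stats`` (a ``(means, sds)`` pair of Series, typically
    from the training entities) the given statistics are applied; otherwise
    they are computed from ``dm`` and returned for later reuse.
    """
    if isinstance(columns, FeatureSelection):
        raise TypeError("pass an explicit column list (compound or protein side)")
    missing = [c for c in columns if c not in dm.columns]
    if missing:
        raise ValueError(f"selected columns missing from matrix: {missing}")
    sub = dm[list(columns)].astype(float)
    if reference_stats is None:
        means = sub.mean()
        sds = sub.std(ddof=1)
    else:
        means, sds = reference_stats
        means = means[list(columns)]
        sds = sds[list(columns)]
    if (sds == 0).any():
        bad = list(sds.index[sds == 0])
        raise ValueError(f"zero-sd columns under reference stats: {bad}")
    return (sub - means) / sds, (means, sds)


def euclidean_distance(u, v) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.linalg.norm(u - v))


def compute_threshold(distances, method: str = "ci_mean_t95", level: float = 0.95) -> float:
    """Per-anchor distance threshold from the member pairwise distances.

    * ``ci_mean_t95`` — upper limit of the t-based confidence interval of
      the mean distance: mean + t_{(1+level)/2, m-1} * sd / sqrt(m);
    * ``percentile95`` — empirical ``level`` percentile (linear
      interpolation);
    * ``mean_plus_1p96sd`` — normal upper tail of the distance
      distribution: mean + z_{(1+level)/2} * sd.

    A single distance is its own threshold under any method.
    """
    d = np.asarray(list(distances), dtype=float)
    m = len(d)
    if m == 0:
        raise ValueError("cannot compute a threshold from zero distances")
    if m == 1:
        return float(d[0])
    if method == "ci_mean_t95":
        t = stats.t.ppf((1 + level) / 2, m - 1)
        return float(d.mean() + t * d.std(ddof=1) / np.sqrt(m))
    if method == "percentile95":
        return float(np.percentile(d, 100 * level))
    if method == "mean_plus_1p96sd":
        z = stats.norm.ppf((1 + level) / 2)
        return float(d.mean() + z * d.std(ddof=1))
    raise ValueError(f"unknown threshold method {method!r}")


def build_space(
    anchor: str,
    net: TripartiteNetwork,
    features: pd.DataFrame,
    min_members: int = 3,
    threshold_method: str = "ci_mean_t95",
    level: float = 0.95,
):
    """Build the member space of ``anchor`` from its training CT partners.

    ``features`` is the standardised selected-descriptor frame for the
    member side (compound features for a protein anchor and vice versa).
    Returns :class:`SpaceSkipped` when fewer than ``min_members`` partners
    have feature rows.
    """
    if anchor not in net.entities:
        raise ValueError(f"unknown anchor {anchor!r}")
    anchor_kind = net.entities[anchor].kind
    members = [m for m in net.partners(anchor, "CT") if m in features.index]
    if len(members) < min_members:
        return SpaceSkipped(anchor, f"insufficient members ({len(members)} < {min_members})")
    mat = features.loc[members].to_numpy(dtype=float)
    dists = pdist(mat)
    threshold = compute_threshold(dists, threshold_method, level)
    return EntitySpace(
        anchor=anchor,
        anchor_kind=anchor_kind,
        member_ids=members,
        features=mat,
        pairwise_distances=dists,
        threshold=threshold,
        threshold_method=threshold_method,
        degenerate=len(dists) == 1,
    )


def predict_pair(candidate, space: EntitySpace, decision_rule: str = "all",
                 candidate_id: str = "?") -> PredictionRecord:
    """Score one candidate against a space.

    ``all`` requires every candidate-to-member distance within the
    threshold; ``any`` at least one; ``mean`` the mean distance.
    """
    cand = np.asarray(candidate, dtype=float).reshape(1, -1)
    if cand.shape[1] != space.features.shape[1]:
        raise ValueError("candidate dimension does not match space features")
    d = cdist(cand, space.features)[0]
    if decision_rule == "all":
        decision = bool(d.max() <= space.threshold)
    elif decision_rule == "any":
        decision = bool(d.min() <= space.threshold)
    elif decision_rule == "mean":
        decision = bool(d.mean() <= space.threshold)
    else:
        raise ValueError(f"unknown decision rule {decision_rule!r}")
    if space.anchor_kind == "protein":
        compound, protein, direction = candidate_id, space.anchor, "compound_to_target"
    else:
        compound, protein, direction = space.anchor, candidate_id, "target_to_compound"
    return PredictionRecord(
        compound=compound,
        protein=protein,
        direction=direction,
        n_members=len(space.member_ids),
        d_max=float(d.max()),
        d_mean=float(d.mean()),
        d_min=float(d.min()),
        threshold=space.threshold,
        decision=decision,
        rule=decision_rule,
    )


# -- estimator ---------------------------------------------------------


class CorrelationSpacePredictor(BaseEstimator):
    """Scikit-learn-style estimator for correlation-space link prediction.

    ``fit`` builds per-anchor spaces from the training network's known CT
    edges and standardised feature frames; ``predict`` scores candidate
    (compound, protein) pairs and ``predict_all`` enumerates every
    non-training combination.

    Parameters
    ----------
    threshold_method : {'ci_mean_t95', 'percentile95', 'mean_plus_1p96sd'}
    decision_rule : {'all', 'any', 'mean'}
    min_members : int, default 3
        Minimum member count for a usable space (two distances are needed
        for a confidence interval).
    level : float, default 0.95
        Confidence level of the threshold.
    direction : {'compound_to_target', 'target_to_compound', 'union'}
        Which spaces to score against: target-anchored compound spaces,
        compound-anchored target spaces, or both.
    """

    def __init__(self, threshold_method: str = "ci_mean_t95",
                 decision_rule: str = "all", min_members: int = 3,
                 level: float = 0.95, direction: str = "compound_to_target"):
        self.threshold_method = threshold_method
        self.decision_rule = decision_rule
        self.min_members = min_members
        self.level = level
        self.direction = direction

    def fit(self, net: TripartiteNetwork, compound_features: pd.DataFrame,
            protein_features: pd.DataFrame):
        """Build anchor spaces from training CT edges and feature frames."""
        if self.threshold_method not in THRESHOLD_METHODS:
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if self.decision_rule not in DECISION_RULES:
            raise ValueError(f"unknown decision rule {self.decision_rule!r}")
        self.net_ = net
        self.compound_features_ = compound_features
        self.protein_features_ = protein_features
        self.target_spaces_ = {}
        self.compound_spaces_ = {}
        self.skipped_ = []
        targets = sorted(
            e.id for e in net.entities.values() if e.kind == "protein"
        )
        compounds = sorted(
            e.id for e in net.entities.values() if e.kind == "compound"
        )
        if self.direction in ("compound_to_target", "union"):
            for t in targets:
                sp = build_space(t, net, compound_features, self.min_members,
                                 self.threshold_method, self.level)
                if isinstance(sp, SpaceSkipped):
                    self.skipped_.append(sp)
                else:
                    self.target_spaces_[t] = sp
        if self.direction in ("target_to_compound", "union"):
            for c in compounds:
                sp = build_space(c, net, protein_features, self.min_members,
                                 self.threshold_method, self.level)
                if isinstance(sp, SpaceSkipped):
                    self.skipped_.append(sp)
                else:
                    self.compound_spaces_[c] = sp
        return self

    def _score(self, compound: str, protein: str):
        records = []
        sp = self.target_spaces_.get(protein)
        if sp is not None and compound in self.compound_features_.index:
            records.append(predict_pair(
                self.compound_features_.loc[compound].to_numpy(float),
                sp, self.decision_rule, candidate_id=compound))
        sp = self.compound_spaces_.get(compound)
        if sp is not None and protein in self.protein_features_.index:
            records.append(predict_pair(
                self.protein_features_.loc[protein].to_numpy(float),
                sp, self.decision_rule, candidate_id=protein))
        return records

    def predict(self, pairs) -> np.ndarray:
        """Boolean interaction call for each (compound, protein) pair.

        A pair with no usable space in the configured direction is False.
        Under ``union`` a pair interacts when either direction says so.
        """
        out = []
        for compound, protein in pairs:
            recs = self._score(compound, protein)
            out.append(any(r.decision for r in recs))
        return np.asarray(out, dtype=bool)

    def predict_records(self, pairs):
        """Per-pair :class:`PredictionRecord` list (merged under union)."""
        out = []
        for compound, protein in pairs:
            recs = self._score(compound, protein)
            if not recs:
                continue
            if len(recs) == 1:
                out.append(recs[0])
            else:
                merged = recs[0]
                merged.direction = "union"
                merged.decision = recs[0].decision or recs[1].decision
                merged.agreement = recs[0].decision == recs[1].decision
                out.append(merged)
        return out

    def predict_all(self):
        """Score every candidate/space combination not in the training edges.

        Known training CT pairs are never re-emitted.  Output is ordered by
        (compound, protein).
        """
        pairs = set()
        for t in self.target_spaces_:
            for c in self.compound_features_.index:
                pairs.add((c, t))
        for c in self.compound_spaces_:
            for t in self.protein_features_.index:
                pairs.add((c, t))
        pairs = sorted(
            (c, t) for c, t in pairs if not self.net_.has_pair(c, t, "CT")
        )
        return self.predict_records(pairs)


def predict_all(net, compound_features, protein_features,
                direction: str = "compound_to_target", **kwargs):
    """Functional wrapper over :class:`CorrelationSpacePredictor`."""
    est = CorrelationSpacePredictor(direction=direction, **kwargs)
    est.fit(net, compound_features, protein_features)
    return est.predict_all()


# -- evaluation --------------------------------------------------------


def _parse_ratio(ratio) -> float:
    """'4:1' -> test fraction 0.2; floats are taken as the test fraction."""
    if isinstance(ratio, str) and ":" in ratio:
        train, test = (Fraction(part) for part in ratio.split(":"))
        return float(test / (train + test))
    return float(ratio)


def _ct_edges_by_target(net, edges=None):
    by_target: dict[str, list] = {}
    edges = net.edges_of_type("CT", provenance="known") if edges is None else edges
    for e in edges:
        c, t = (e.a, e.b) if net.entities[e.a].kind == "compound" else (e.b, e.a)
        by_target.setdefault(t, []).append((c, t))
    return by_target


def stratified_split(ct_edges, ratio="4:1", seed: int = 0, net=None):
    """Per-target random split of CT edges at the given train:test ratio.

    ``ct_edges`` may be (compound, protein) tuples or Interaction objects
    (with ``net`` supplied to orient them).  Each target's edges are
    shuffled with the seed and ``round(n * test_fraction)`` go to the test
    set; a target with a single edge keeps it in training.
    """
    test_frac = _parse_ratio(ratio)
    if not 0 < test_frac < 1:
        raise ValueError("ratio must leave both splits non-empty fractions")
    pairs = []
    for e in ct_edges:
        if isinstance(e, tuple):
            pairs.append(e)
        else:
            c, t = (e.a, e.b) if net.entities[e.a].kind == "compound" else (e.b, e.a)
            pairs.append((c, t))
    by_target: dict[str, list] = {}
    for c, t in sorted(set(pairs)):
        by_target.setdefault(t, []).append((c, t))
    rng = np.random.default_rng(seed)
    train, test = [], []
    for t in sorted(by_target):
        edges = by_target[t]
        if len(edges) == 1:
            train.extend(edges)
            continue
        idx = rng.permutation(len(edges))
        n_test = int(round(len(edges) * test_frac))
        n_test = min(n_test, len(edges) - 1)
        test.extend(edges[i] for i in idx[:n_test])
        train.extend(edges[i] for i in idx[n_test:])
    return sorted(train), sorted(test)


def _stratified_folds(by_target: dict, k: int, seed: int):
    """Round-robin deal of each target's shuffled edges into k folds."""
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(k)]
    for t in sorted(by_target):
        edges = by_target[t]
        idx = rng.permutation(len(edges))
        offset = int(rng.integers(k))
        for j, i in enumerate(idx):
            folds[(j + offset) % k].append(edges[i])
    return folds


def _training_network(net, train_pairs):
    """Known-CT-only network restricted to the training pairs."""
    from .network import Entity, Interaction as Inter, TripartiteNetwork as Net

    sub = Net()
    for ent in net.entities.values():
        sub.add_entity(Entity(ent.id, ent.kind, dict(ent.labels)))
    for c, t in train_pairs:
        sub.add_interaction(Inter(c, t, "CT", "known"))
    return sub


def cross_validate(
    net: TripartiteNetwork,
    compound_dm: pd.DataFrame,
    protein_dm: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    min_members: int = 3,
    threshold_method: str = "ci_mean_t95",
    decision_rule: str = "mean",
    level: float = 0.95,
    r_min: float = 0.8,
    alpha: float = 0.01,
    loading_cutoff: float = 0.3,
    ridge: float = 0.0,
    max_mode_fraction: float = 0.80,
    min_rsd: float = 0.05,
    max_abs_r: float = 0.9,
) -> RecallReport:
    """Per-target stratified k-fold recall of the full CTCS-IPM pipeline.

    For each fold the whole pipeline — descriptor cleaning, CCA, feature
    selection, feature standardisation and space construction — is fitted
    on the training edges only.  A held-out edge counts as recovered when
    the candidate compound is predicted to interact with its target; edges
    whose target space was skipped (too few training members) count as not
    recovered.

    The evaluation default compares the candidate's *mean* member distance
    to the threshold: the default threshold is an upper confidence limit of
    the mean pairwise distance, so the mean-distance comparison is the
    scale-consistent one.  The stricter ``all`` rule (production default of
    :class:`CorrelationSpacePredictor`) compares a maximum against that
    mean-scale bound and is deliberately conservative.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    by_target = _ct_edges_by_target(net)
    folds = _stratified_folds(by_target, k, seed)
    all_pairs = sorted(p for edges in folds for p in edges)
    config = dict(
        k=k, min_members=min_members, threshold_method=threshold_method,
        decision_rule=decision_rule, level=level, r_min=r_min, alpha=alpha,
        loading_cutoff=loading_cutoff, ridge=ridge,
        max_mode_fraction=max_mode_fraction, min_rsd=min_rsd, max_abs_r=max_abs_r,
    )
    fold_reports = []
    for f in range(k):
        test = sorted(folds[f])
        if not test:
            log.warning("fold %d has an empty test set; skipped", f)
            continue
        train = sorted(set(all_pairs) - set(test))
        train_net = _training_network(net, train)
        train_compounds = sorted({c for c, _ in train})
        train_proteins = sorted({t for _, t in train})

        cleaner_c = DescriptorCleaner(max_mode_fraction, min_rsd, max_abs_r).fit(
            compound_dm.loc[train_compounds])
        cleaner_p = DescriptorCleaner(max_mode_fraction, min_rsd, max_abs_r).fit(
            protein_dm.loc[train_proteins])
        comp_clean = cleaner_c.transform(compound_dm)
        prot_clean = cleaner_p.transform(protein_dm)

        sample = build_paired_sample(train_net, comp_clean, prot_clean)
        model = fit_cca(sample, ridge=ridge)
        try:
            selection = select_feature_descriptors(model, r_min, alpha, loading_cutoff)
        except ValueError as err:
            # no usable correlation space on this training fold: the model
            # can predict nothing, so every held-out edge is a miss
            log.warning("fold %d: %s; recall scored 0", f, err)
            fold_reports.append({
                "fold": f, "train_size": len(train), "test_size": len(test),
                "predicted_consistent": 0, "recall": 0.0,
                "note": str(err),
            })
            continue

        comp_z, comp_stats = standardize_features(
            comp_clean.loc[train_compounds], selection.compound_descriptors)
        prot_z, prot_stats = standardize_features(
            prot_clean.loc[train_proteins], selection.protein_descriptors)
        comp_all, _ = standardize_features(
            comp_clean, selection.compound_descriptors, comp_stats)
        prot_all, _ = standardize_features(
            prot_clean, selection.protein_descriptors, prot_stats)

        est = CorrelationSpacePredictor(
            threshold_method=threshold_method, decision_rule=decision_rule,
            min_members=min_members, level=level, direction="compound_to_target",
        ).fit(train_net, comp_all, prot_all)
        hits = int(est.predict(test).sum())
        fold_reports.append({
            "fold": f,
            "train_size": len(train),
            "test_size": len(test),
            "predicted_consistent": hits,
            "recall": hits / len(test),
        })
    if not fold_reports:
        raise ValueError("no usable folds")
    avg = float(np.mean([fr["recall"] for fr in fold_reports]))
    return RecallReport(folds=fold_reports, average_recall=avg, config=config, seed=seed)
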