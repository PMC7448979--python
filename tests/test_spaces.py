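"""Correlation-space predictor: thresholds, decision rules, splitting and
cross-validated recall."""

import numpy as np
import pandas as pd
import pytest

from sipa import (
    CorrelationSpacePredictor,
    Entity,
    Interaction,
    TripartiteNetwork,
    build_space,
    compute_threshold,
    cross_validate,
    euclidean_distance,
    predict_pair,
    simulate_study,
    standardize_features,
    stratified_split,
)
from sipa.spaces import SpaceSkipped


def _ct_net(pairs, compounds=None, proteins=None):
    net = TripartiteNetwork()
    compounds = compounds or sorted({c for c, _ in pairs})
    proteins = proteins or sorted({t for _, t in pairs})
    for c in compounds:
        net.add_entity(Entity(c, "compound"))
    for t in proteins:
        net.add_entity(Entity(t, "protein"))
    for c, t in pairs:
        net.add_interaction(Interaction(c, t, "CT"))
    return net


class TestStandardize:
    def test_fit_then_apply_centers_and_scales(self):
        rng = np.random.default_rng(0)
        dm = pd.DataFrame(rng.standard_normal((20, 3)) * 5 + 2, columns=list("abc"))
        z, stats = standardize_features(dm, ["a", "b"])
        assert np.allclose(z.mean(), 0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1, atol=1e-12)

    def test_reference_stats_shift_exactly(self):
        dm = pd.DataFrame({"a": [0.0, 1, 2, 3]})
        _, stats = standardize_features(dm, ["a"])
        shifted, _ = standardize_features(dm + 1.0, ["a"], stats)
        base, _ = standardize_features(dm, ["a"], stats)
        sd = dm["a"].std(ddof=1)
        assert np.allclose(shifted - base, 1.0 / sd)

    def test_zero_sd_reference_is_hard_error(self):
        dm = pd.DataFrame({"a": [1.0, 1, 1]})
        stats = (pd.Series({"a": 1.0}), pd.Series({"a": 0.0}))
        with pytest.raises(ValueError, match="zero-sd"):
            standardize_features(dm, ["a"], stats)


class TestDistanceAndThreshold:
    def test_three_four_five(self):
        assert euclidean_distance([0, 0], [3, 4]) == 5.0
        assert euclidean_distance([1.5, -2], [1.5, -2]) == 0.0

    def test_matches_plain_python_sum(self):
        rng = np.random.default_rng(9)
        u, v = rng.standard_normal(7), rng.standard_normal(7)
        ref = sum((a - b) ** 2 for a, b in zip(u, v)) ** 0.5
        assert euclidean_distance(u, v) == pytest.approx(ref, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            euclidean_distance([1, 2], [1, 2, 3])

    @pytest.mark.parametrize("method", ["ci_mean_t95", "percentile95",
                                        "mean_plus_1p96sd"])
    def test_identical_distances_return_the_value(self, method):
        assert compute_threshold([2.5, 2.5, 2.5], method) == pytest.approx(2.5)

    def test_t_interval_closed_form(self):
        # mean 2, sd 1, t_{0.975, 2} = 4.3027: 2 + 4.3027/sqrt(3)
        assert compute_threshold([1, 2, 3], "ci_mean_t95") == \
            pytest.approx(4.4842, abs=1e-4)

    def test_normal_upper_tail_closed_form(self):
        assert compute_threshold([1, 2, 3], "mean_plus_1p96sd") == \
            pytest.approx(3.96, abs=1e-3)

    def test_single_distance_is_its_own_threshold(self):
        assert compute_threshold([1.7], "ci_mean_t95") == 1.7

    def test_empty_is_hard_error(self):
        with pytest.raises(ValueError):
            compute_threshold([])


@pytest.fixture
def triangle_space():
    """Target T1 with members at (0,0), (3,0), (0,4): distances {3,4,5}."""
    net = _ct_net([("C1", "T1"), ("C2", "T1"), ("C3", "T1")],
                  compounds=["C1", "C2", "C3", "C9"])
    feats = pd.DataFrame([[0.0, 0], [3, 0], [0, 4], [1, 1]],
                         index=["C1", "C2", "C3", "C9"], columns=["f1", "f2"])
    return net, feats


class TestBuildSpace:
    def test_insufficient_members_yields_skip_marker(self):
        net = _ct_net([("C1", "T1"), ("C2", "T1")])
        feats = pd.DataFrame([[0.0], [1.0]], index=["C1", "C2"], columns=["f"])
        sp = build_space("T1", net, feats, min_members=3)
        assert isinstance(sp, SpaceSkipped)
        assert "insufficient" in sp.reason

    def test_triangle_distances_and_threshold(self, triangle_space):
        net, feats = triangle_space
        sp = build_space("T1", net, feats)
        assert sorted(sp.pairwise_distances) == [3, 4, 5]
        assert sp.threshold == pytest.approx(4 + 4.3027 / np.sqrt(3), abs=1e-4)

    def test_compound_anchored_space_is_symmetric(self):
        net = _ct_net([("C1", "T1"), ("C1", "T2"), ("C1", "T3")])
        feats = pd.DataFrame([[0.0, 0], [3, 0], [0, 4]],
                             index=["T1", "T2", "T3"], columns=["f1", "f2"])
        sp = build_space("C1", net, feats)
        assert sp.anchor_kind == "compound"
        assert sorted(sp.pairwise_distances) == [3, 4, 5]

    def test_unknown_anchor(self, triangle_space):
        net, feats = triangle_space
        with pytest.raises(ValueError, match="unknown anchor"):
            build_space("T9", net, feats)


class TestPredictPair:
    def test_inside_candidate_interacts_under_all(self, triangle_space):
        net, feats = triangle_space
        sp = build_space("T1", net, feats)
        rec = predict_pair(feats.loc["C9"], sp, "all", candidate_id="C9")
        assert rec.decision
        assert rec.d_max == pytest.approx(np.sqrt(10), abs=1e-12)
        assert rec.d_min == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_distant_candidate_rejected(self, triangle_space):
        net, feats = triangle_space
        sp = build_space("T1", net, feats)
        rec = predict_pair([100.0, 100.0], sp, "all")
        assert not rec.decision

    def test_member_clone_interacts_under_any(self, triangle_space):
        net, feats = triangle_space
        sp = build_space("T1", net, feats)
        rec = predict_pair(feats.loc["C2"], sp, "any")
        assert rec.decision and rec.d_min == 0.0

    def test_dimension_mismatch(self, triangle_space):
        net, feats = triangle_space
        sp = build_space("T1", net, feats)
        with pytest.raises(ValueError):
            predict_pair([1.0], sp)


class TestPredictor:
    def _toy(self):
        """T1's members cluster near the origin; C4 sits inside the cluster
        (the planted novel pair), C5 far away.  T2 has too few members."""
        net = _ct_net([("C1", "T1"), ("C2", "T1"), ("C3", "T1"), ("C1", "T2")],
                      compounds=["C1", "C2", "C3", "C4", "C5"])
        comp = pd.DataFrame(
            [[0.0, 0], [1, 0], [0, 1], [0.5, 0.5], [50, 50]],
            index=["C1", "C2", "C3", "C4", "C5"], columns=["f1", "f2"])
        prot = pd.DataFrame([[0.0, 0], [1, 1]], index=["T1", "T2"],
                            columns=["g1", "g2"])
        return net, comp, prot

    def test_planted_novel_pair_is_the_only_prediction(self):
        net, comp, prot = self._toy()
        est = CorrelationSpacePredictor(decision_rule="all").fit(net, comp, prot)
        records = est.predict_all()
        hits = [(r.compound, r.protein) for r in records if r.decision]
        assert hits == [("C4", "T1")]

    def test_known_edges_never_reemitted(self):
        net, comp, prot = self._toy()
        est = CorrelationSpacePredictor().fit(net, comp, prot)
        emitted = {(r.compound, r.protein) for r in est.predict_all()}
        assert emitted.isdisjoint({("C1", "T1"), ("C2", "T1"), ("C3", "T1"),
                                   ("C1", "T2")})

    def test_no_usable_space_gives_empty_output(self):
        net = _ct_net([("C1", "T1")], compounds=["C1", "C2"])
        comp = pd.DataFrame([[0.0], [1.0]], index=["C1", "C2"], columns=["f"])
        prot = pd.DataFrame([[0.0]], index=["T1"], columns=["g"])
        est = CorrelationSpacePredictor().fit(net, comp, prot)
        assert est.predict_all() == []

    def test_scale_invariance_of_decisions(self):
        net, comp, prot = self._toy()
        base = CorrelationSpacePredictor().fit(net, comp, prot)
        scaled = CorrelationSpacePredictor().fit(net, comp * 7.0, prot * 7.0)
        for t, sp in base.target_spaces_.items():
            assert scaled.target_spaces_[t].threshold == \
                pytest.approx(7.0 * sp.threshold, rel=1e-12)
        pairs = [("C4", "T1"), ("C5", "T1")]
        assert (base.predict(pairs) == scaled.predict(pairs)).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_decision_rule_nesting(self, seed):
        rng = np.random.default_rng(seed)
        comp_ids = [f"C{i}" for i in range(12)]
        net = _ct_net([(c, "T1") for c in comp_ids[:6]], compounds=comp_ids)
        comp = pd.DataFrame(rng.standard_normal((12, 3)), index=comp_ids,
                            columns=["f1", "f2", "f3"])
        prot = pd.DataFrame(rng.standard_normal((1, 3)), index=["T1"],
                            columns=["g1", "g2", "g3"])
        preds = {}
        for rule in ("all", "mean", "any"):
            est = CorrelationSpacePredictor(decision_rule=rule).fit(net, comp, prot)
            preds[rule] = {(r.compound, r.protein)
                           for r in est.predict_all() if r.decision}
        assert preds["all"] <= preds["mean"] <= preds["any"]

    def test_sklearn_params_roundtrip(self):
        from sklearn.base import clone
        est = CorrelationSpacePredictor(decision_rule="mean", min_members=4)
        c = clone(est)
        assert c.get_params()["min_members"] == 4


class TestStratifiedSplit:
    def test_five_edges_split_four_one(self):
        edges = [(f"C{i}", "T1") for i in range(5)]
        train, test = stratified_split(edges, "4:1", seed=0)
        assert len(train) == 4 and len(test) == 1
        assert sorted(train + test) == sorted(edges)

    def test_singleton_target_stays_in_training(self):
        train, test = stratified_split([("C1", "T1")], "4:1", seed=0)
        assert train == [("C1", "T1")] and test == []

    def test_deterministic_and_seed_sensitive(self):
        edges = [(f"C{i}", f"T{j}") for j in range(4) for i in range(10)]
        a = stratified_split(edges, "4:1", seed=5)
        b = stratified_split(edges, "4:1", seed=5)
        c = stratified_split(edges, "4:1", seed=6)
        assert a == b
        assert a != c
        # per-target counts identical across seeds
        for split_a, split_c in zip(a, c):
            counts_a = pd.Series([t for _, t in split_a]).value_counts()
            counts_c = pd.Series([t for _, t in split_c]).value_counts()
            assert counts_a.sort_index().equals(counts_c.sort_index())


class TestCrossValidate:
    def test_recall_on_latent_proximity_study(self):
        comp, prot, net, _ = simulate_study()
        rep = cross_validate(net, comp, prot, k=10, seed=7)
        assert rep.average_recall >= 0.85
        assert len(rep.folds) == 10
        assert rep.average_recall == pytest.approx(
            np.mean([f["recall"] for f in rep.folds]))

    def test_any_rule_recall_dominates_all_rule(self):
        comp, prot, net, _ = simulate_study()
        rec_any = cross_validate(net, comp, prot, k=5, seed=3,
                                 decision_rule="any").average_recall
        rec_all = cross_validate(net, comp, prot, k=5, seed=3,
                                 decision_rule="all").average_recall
        assert rec_any >= rec_all

    def test_training_on_itself_recalls_everything_under_any(self):
        """Degenerate check: every training edge is its own-space member at
        distance 0, so the any-rule recalls the training set entirely."""
        comp, prot, net, _ = simulate_study()
        pairs = [(e.a, e.b) if net.entities[e.a].kind == "compound"
                 else (e.b, e.a) for e in net.edges_of_type("CT")]
        comp_z, _ = standardize_features(
            comp, [c for c in comp.columns if "_" not in c])
        prot_z, _ = standardize_features(
            prot, [c for c in prot.columns if "_" not in c])
        est = CorrelationSpacePredictor(decision_rule="any").fit(net, comp_z, prot_z)
        assert est.predict(pairs).all()

    def test_no_leakage_spaces_ignore_test_edges(self):
        comp, prot, net, _ = simulate_study()
        pairs = [(e.a, e.b) if net.entities[e.a].kind == "compound"
                 else (e.b, e.a) for e in net.edges_of_type("CT")]
        train, test = stratified_split(pairs, "4:1", seed=1)
        from sipa.spaces import _training_network
        cols = [c for c in comp.columns if c.startswith("x") and "x_" not in c]
        pcols = [c for c in prot.columns if c.startswith("y") and "y_" not in c]
        comp_z, _ = standardize_features(comp, cols)
        prot_z, _ = standardize_features(prot, pcols)
        full = CorrelationSpacePredictor().fit(
            _training_network(net, train), comp_z, prot_z)
        # delete a held-out edge from the source network: the fitted model
        # must not notice
        pruned = net.copy()
        pruned._edges.pop(
            tuple(sorted(test[0])) + ("CT",))
        reduced = CorrelationSpacePredictor().fit(
            _training_network(pruned, train), comp_z, prot_z)
        assert set(full.target_spaces_) == set(reduced.target_spaces_)
        for t in full.target_spaces_:
            assert full.target_spaces_[t].threshold == \
                reduced.target_spaces_[t].threshold

    def test_report_invariant_to_edge_input_order(self):
        comp, prot, net, _ = simulate_study()
        rep1 = cross_validate(net, comp, prot, k=5, seed=2)
        rep2 = cross_validate(net, comp, prot, k=5, seed=2)
        assert rep1.folds == rep2.folds

    def test_k_below_two_rejected(self):
        comp, prot, net, _ = simulate_study()
        with pytest.raises(ValueError):
            cross_validate(net, comp, prot, k=1)
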