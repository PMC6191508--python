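"""Training-sample assembly, balanced subset selection, forests, Eq-style
vote-fraction probabilities, and the probabilistic segmentation map."""

import numpy as np
import pytest

import atlasfuse as af
from atlasfuse.errors import DegenerateTrainingSetError
from atlasfuse.features import PatchParams, extract_feature_vector, feature_length
from atlasfuse.preprocess import compute_bounding_box, majority_vote
from atlasfuse.rf_fusion import (
    RFParams,
    TrainingSet,
    assemble_candidates,
    predict_probability,
    rf_segment,
    select_balanced_subset,
    train_forest,
    tree_votes,
)


def _pair(rng, shape=(10, 10, 10), fg=slice(3, 7), pid="a"):
    data = rng.random(shape) * 100
    lab = np.zeros(shape, dtype=np.uint8)
    lab[fg, fg, fg] = 1
    return af.AtlasPair(
        af.Volume(data, np.eye(4)), af.LabelVolume(lab, np.eye(4)), id=pid
    )


def _training(rng, n_pos=60, n_neg=60, dim=12, sep=3.0):
    pos = rng.normal(sep, 1, (n_pos, dim))
    neg = rng.normal(0, 1, (n_neg, dim))
    x = np.vstack([pos, neg]).astype(np.float32)
    y = np.r_[np.ones(n_pos), np.zeros(n_neg)].astype(np.uint8)
    return TrainingSet(x, y)


class TestAssembleCandidates:
    def test_sample_count_is_neighborhood_times_atlases(self, rng):
        atlases = [_pair(rng, pid=f"a{i}") for i in range(4)]
        ts = assemble_candidates(atlases, (5, 5, 5), PatchParams(r_s=2, r=1))
        assert len(ts) == 27 * 4
        assert ts.features.shape[1] == feature_length(PatchParams(r_s=2))

    def test_r0_single_atlas_single_candidate(self, rng):
        atlases = [_pair(rng)]
        ts = assemble_candidates(atlases, (5, 5, 5), PatchParams(r_s=2, r=0))
        assert len(ts) == 1
        assert ts.labels[0] == atlases[0].label.data[5, 5, 5]
        np.testing.assert_array_equal(
            ts.features[0],
            extract_feature_vector(atlases[0].intensity, (5, 5, 5),
                                   PatchParams(r_s=2, r=0)),
        )

    def test_labels_follow_atlas_masks(self, rng):
        atlases = [_pair(rng, pid=f"a{i}") for i in range(3)]
        ts = assemble_candidates(atlases, (5, 5, 5), PatchParams(r_s=2, r=1))
        # voxel (5,5,5) sits deep inside every atlas foreground
        assert np.all(ts.labels == 1)

    def test_provenance_records_atlas_and_voxel(self, rng):
        atlases = [_pair(rng, pid="left"), _pair(rng, pid="right")]
        ts = assemble_candidates(atlases, (4, 4, 4), PatchParams(r_s=2, r=1))
        assert ts.provenance[0] == ("left", (3, 3, 3))
        assert ts.provenance[27] == ("right", (3, 3, 3))


class TestBalancedSubset:
    def _brute_force(self, features, labels, target, k):
        """Oracle: full sort of every distance, stable by candidate order."""
        d = np.sqrt(((features.astype(np.float64) - target) ** 2).sum(1))
        picked = []
        for cls in (1, 0):
            idx = [i for i in np.argsort(d, kind="stable") if labels[i] == cls]
            picked.extend(idx[:k])
        return picked

    def test_matches_exhaustive_sort_on_random_sets(self, rng):
        for _ in range(100):
            n_pos = int(rng.integers(5, 120))
            n_neg = int(rng.integers(5, 120))
            dim = int(rng.integers(2, 16))
            ts = _training(rng, n_pos, n_neg, dim)
            target = rng.normal(1.5, 1, dim)
            k = int(rng.integers(1, 60))
            sub = select_balanced_subset(ts, target, k)
            expect = self._brute_force(ts.features, ts.labels, target, k)
            got = [ts.provenance[i] if ts.provenance else i for i in expect]
            # compare feature rows (provenance empty here): order and content
            np.testing.assert_array_equal(sub.features, ts.features[expect])
            np.testing.assert_array_equal(sub.labels, ts.labels[expect])

    def test_class_shortage_truncates(self, rng):
        ts = _training(rng, n_pos=40, n_neg=500)
        sub = select_balanced_subset(ts, np.zeros(12), k=100)
        assert int((sub.labels == 1).sum()) == 40
        assert int((sub.labels == 0).sum()) == 100

    def test_exact_match_candidate_is_selected(self, rng):
        ts = _training(rng, 30, 30)
        target = ts.features[7].astype(np.float64)
        sub = select_balanced_subset(ts, target, k=5)
        assert any(np.array_equal(row, ts.features[7]) for row in sub.features)

    def test_single_class_raises(self, rng):
        x = rng.normal(0, 1, (20, 5)).astype(np.float32)
        ts = TrainingSet(x, np.ones(20, dtype=np.uint8))
        with pytest.raises(DegenerateTrainingSetError):
            select_balanced_subset(ts, np.zeros(5), k=5)


class TestForest:
    def test_separable_data_perfect_training_accuracy(self, rng):
        ts = _training(rng, sep=6.0)
        model = train_forest(ts, RFParams(n_tree=30, n_split=4, seed=0))
        preds = [predict_probability(model, f) > 0.5 for f in ts.features]
        assert np.array_equal(preds, ts.labels == 1)

    def test_same_seed_same_predictions(self, rng):
        ts = _training(rng)
        q = rng.normal(1.5, 1, (20, 12)).astype(np.float32)
        m1 = train_forest(ts, RFParams(n_tree=25, n_split=4, seed=9))
        m2 = train_forest(ts, RFParams(n_tree=25, n_split=4, seed=9))
        p1 = [predict_probability(m1, f) for f in q]
        p2 = [predict_probability(m2, f) for f in q]
        assert p1 == p2

    def test_different_seeds_differ(self, rng):
        ts = _training(rng, sep=1.0)
        q = rng.normal(1.5, 1, (40, 12)).astype(np.float32)
        m1 = train_forest(ts, RFParams(n_tree=25, n_split=4, seed=1))
        m2 = train_forest(ts, RFParams(n_tree=25, n_split=4, seed=2))
        assert any(
            predict_probability(m1, f) != predict_probability(m2, f) for f in q
        )

    def test_single_class_raises(self, rng):
        x = rng.normal(0, 1, (20, 5)).astype(np.float32)
        with pytest.raises(DegenerateTrainingSetError):
            train_forest(TrainingSet(x, np.zeros(20, dtype=np.uint8)),
                         RFParams(n_tree=5, n_split=2, seed=0))

    def test_permuted_labels_give_chance_level_accuracy(self, rng):
        # Monte-Carlo under the permutation null: accuracy on held-out
        # balanced data should hover around 0.5
        accs = []
        for rep in range(100):
            x = rng.normal(0, 1, (80, 8)).astype(np.float32)
            y = np.r_[np.ones(40), np.zeros(40)].astype(np.uint8)
            rng.shuffle(y)
            model = train_forest(TrainingSet(x[:60], y[:60]),
                                 RFParams(n_tree=15, n_split=3, seed=rep))
            preds = np.array(
                [predict_probability(model, f) > 0.5 for f in x[60:]]
            )
            accs.append(np.mean(preds == (y[60:] == 1)))
        assert abs(np.mean(accs) - 0.5) < 0.05

    def test_vote_fraction_equals_tree_by_tree_count(self, rng):
        # Eq-style probability is exactly the fraction of per-tree votes
        ts = _training(rng, sep=1.5)
        model = train_forest(ts, RFParams(n_tree=20, n_split=4, seed=3))
        for f in rng.normal(1.5, 2, (15, 12)).astype(np.float32):
            votes = [tree.predict_one(f) for tree in model.trees]
            p = predict_probability(model, f)
            assert p == pytest.approx(sum(votes) / 20)
            assert p * 20 == int(round(p * 20))  # on the 1/N_Tree lattice
            np.testing.assert_array_equal(tree_votes(model, f), votes)

    def test_agrees_with_sklearn_reference_on_separable_data(self, rng):
        # independent cross-check: scikit-learn's Breiman forest reaches the
        # same decisions on clearly separable data
        from sklearn.ensemble import RandomForestClassifier

        ts = _training(rng, n_pos=80, n_neg=80, sep=4.0)
        q = np.vstack([
            rng.normal(4.0, 1, (30, 12)), rng.normal(0.0, 1, (30, 12))
        ]).astype(np.float32)
        truth = np.r_[np.ones(30), np.zeros(30)]
        ours = train_forest(ts, RFParams(n_tree=40, n_split=4, seed=5))
        ref = RandomForestClassifier(
            n_estimators=40, max_features=4, random_state=5
        ).fit(ts.features, ts.labels)
        ours_pred = np.array([predict_probability(ours, f) > 0.5 for f in q])
        ref_pred = ref.predict(q).astype(bool)
        assert np.mean(ours_pred == ref_pred) == 1.0
        assert np.array_equal(ours_pred, truth == 1)

    def test_dimension_mismatch_raises(self, rng):
        ts = _training(rng)
        model = train_forest(ts, RFParams(n_tree=5, n_split=3, seed=0))
        with pytest.raises(ValueError, match="dimension"):
            predict_probability(model, np.zeros(5))


class TestRFSegment:
    def test_identical_atlases_reproduce_their_label(self, rng):
        shape = (14, 14, 14)
        data = rng.random(shape) * 100
        lab = np.zeros(shape, dtype=np.uint8)
        lab[4:9, 4:9, 4:9] = 1
        atlases = [
            af.AtlasPair(af.Volume(data.copy(), np.eye(4)),
                         af.LabelVolume(lab.copy(), np.eye(4)), id=f"a{i}")
            for i in range(5)
        ]
        target = af.Volume(data, np.eye(4))
        box = compute_bounding_box([a.label for a in atlases], margin=3)
        part = majority_vote([a.label for a in atlases], box)
        assert not part.ambiguous.any()
        prob = rf_segment(target, atlases, part,
                          PatchParams(), RFParams(n_tree=10, seed=0))
        np.testing.assert_array_equal(prob.data >= 0.5, lab > 0)
        assert set(np.unique(prob.data)) <= {0.0, 1.0}

    def test_probabilities_on_vote_lattice_and_beats_mv(self, small_subject):
        vol, truth, atlases = small_subject
        box = compute_bounding_box([a.label for a in atlases], margin=10)
        part = majority_vote([a.label for a in atlases], box)
        assert part.ambiguous.any()
        n_tree = 25
        prob = rf_segment(vol, atlases, part,
                          PatchParams(), RFParams(n_tree=n_tree, seed=7))
        assert prob.data.min() >= 0 and prob.data.max() <= 1
        amb_values = prob.data[part.ambiguous]
        lattice = np.round(amb_values * n_tree)
        np.testing.assert_allclose(amb_values * n_tree, lattice, atol=1e-6)
        # learned fusion should not fall behind plain majority voting
        rf_lab = af.LabelVolume((prob.data >= 0.5).astype(np.uint8), vol.affine)
        mv_lab = af.LabelVolume(part.hard_segmentation(), vol.affine)
        dice_rf = af.evaluate(truth, rf_lab).dice
        dice_mv = af.evaluate(truth, mv_lab).dice
        assert dice_rf >= dice_mv

    def test_bit_reproducible_for_fixed_seed(self, small_subject):
        vol, _, atlases = small_subject
        box = compute_bounding_box([a.label for a in atlases], margin=10)
        part = majority_vote([a.label for a in atlases], box)
        # restrict to a small ambiguous subset to keep this quick
        amb = np.argwhere(part.ambiguous)[:40]
        mask = np.zeros_like(part.ambiguous)
        mask[amb[:, 0], amb[:, 1], amb[:, 2]] = True
        part.ambiguous = mask
        kw = dict(patch_params=PatchParams(), rf_params=RFParams(n_tree=10, seed=3))
        p1 = rf_segment(vol, atlases, part, **kw)
        p2 = rf_segment(vol, atlases, part, **kw)
        np.testing.assert_array_equal(p1.data, p2.data)
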