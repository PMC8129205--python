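"""SVM-ensemble domain demarcation: training, voting, dense maps."""

import numpy as np
import pytest

from tracemap import boundary
from tracemap.boundary import (
    CLASS_ORDER,
    BoundaryMap,
    LabeledPoints,
    SvmEnsemble,
    SvmMember,
    agreement,
    build_training_set,
    demarcate,
    ensemble_predict,
    train_ensemble,
)

SMALL_C = (0.5, 2.0)
SMALL_GAMMA = (0.25, 1.0)


def brute_force_vote(members, points):
    """Independent oracle for the accuracy-weighted vote: explicit loop."""
    out = []
    for x in np.asarray(points, dtype=float):
        tallies = {c: 0.0 for c in CLASS_ORDER}
        for m in members:
            pred = m.predict_one(x)
            tallies[pred] += m.accuracy
        best = max(tallies.values())
        winners = [c for c in CLASS_ORDER if tallies[c] == best]
        out.append(winners[0])
    return np.array(out, dtype=object)


class FixedMember:
    """Stub ensemble member with a constant prediction (unit-test double)."""

    def __init__(self, label, accuracy):
        self._label = label
        self.accuracy = accuracy
        self.classifier = self
        self.C = 1.0
        self.gamma = 1.0

    def predict(self, X):
        return np.array([self._label] * len(X), dtype=object)

    def predict_one(self, x):
        return self._label


def fixed_ensemble(members):
    return SvmEnsemble(
        level_id="L0",
        members=list(members),
        classes=CLASS_ORDER,
        scale_mean=np.zeros(2),
        scale_std=np.ones(2),
    )


class TestTrainingSet:
    def make(self, n, level="L1", label="medial"):
        rng = np.random.default_rng(n)
        return LabeledPoints(level, rng.random((n, 2)), np.array([label] * n))

    def test_single_section_is_identity(self):
        s = self.make(20)
        out = build_training_set([s])
        assert np.array_equal(out.points, s.points)

    def test_sections_concatenate(self):
        out = build_training_set([self.make(100), self.make(50, label="lateral")])
        assert out.n_points == 150

    def test_three_sections_three_classes(self):
        out = build_training_set(
            [self.make(10, label=c) for c in CLASS_ORDER]
        )
        assert set(out.labels) == set(CLASS_ORDER)

    def test_mixed_levels_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            build_training_set([self.make(10), self.make(10, level="L2")])


class TestTraining:
    def test_small_grid_member_count(self, separable_points):
        ens = train_ensemble(
            separable_points, c_grid=SMALL_C, gamma_grid=SMALL_GAMMA,
            cv_repeats=2, seed=0,
        )
        assert len(ens.members) == 4

    def test_separable_data_reaches_high_accuracy(self, separable_points):
        ens = train_ensemble(
            separable_points, c_grid=SMALL_C, gamma_grid=SMALL_GAMMA,
            cv_repeats=2, seed=0,
        )
        assert ens.accuracies.max() >= 0.99

    def test_accuracies_deterministic_under_seed(self, separable_points):
        a = train_ensemble(
            separable_points, c_grid=SMALL_C, gamma_grid=SMALL_GAMMA,
            cv_repeats=2, seed=42,
        )
        b = train_ensemble(
            separable_points, c_grid=SMALL_C, gamma_grid=SMALL_GAMMA,
            cv_repeats=2, seed=42,
        )
        assert np.array_equal(a.accuracies, b.accuracies)

    def test_thin_class_rejected(self):
        pts = LabeledPoints(
            "L1",
            np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float),
            np.array(["medial", "medial", "medial", "lateral"], dtype=object),
        )
        with pytest.raises(ValueError, match="lateral"):
            train_ensemble(pts)

    def test_stratified_folds_preserve_class_proportions(self, separable_points):
        from sklearn.model_selection import RepeatedStratifiedKFold

        y = separable_points.labels.astype(str)
        cv = RepeatedStratifiedKFold(n_splits=3, n_repeats=2, random_state=0)
        _, full_counts = np.unique(y, return_counts=True)
        full_prop = full_counts / full_counts.sum()
        for _, te in cv.split(separable_points.points, y):
            _, c = np.unique(y[te], return_counts=True)
            assert np.all(np.abs(c - full_prop * len(te)) <= 1.0)


class TestVoting:
    def test_single_member_matches_member(self, separable_points):
        ens = train_ensemble(
            separable_points, c_grid=(1.0,), gamma_grid=(0.5,), cv_repeats=1,
            seed=0,
        )
        pts = separable_points.points[:20]
        member_pred = ens.members[0].classifier.predict(
            (pts - ens.scale_mean) / ens.scale_std
        )
        assert np.array_equal(ensemble_predict(ens, pts), member_pred)

    def test_equal_weights_reduce_to_majority(self):
        ens = fixed_ensemble(
            [
                FixedMember("medial", 0.5),
                FixedMember("medial", 0.5),
                FixedMember("lateral", 0.5),
            ]
        )
        assert ensemble_predict(ens, np.zeros((3, 2)))[0] == "medial"

    def test_strong_minority_member_wins(self):
        # accuracies (0.9, 0.2, 0.2): the 0.9 member beats the 2-vote 0.4
        ens = fixed_ensemble(
            [
                FixedMember("caudal", 0.9),
                FixedMember("lateral", 0.2),
                FixedMember("lateral", 0.2),
            ]
        )
        assert ensemble_predict(ens, np.zeros((1, 2)))[0] == "caudal"

    def test_tie_breaks_by_class_order(self):
        ens = fixed_ensemble(
            [FixedMember("lateral", 0.5), FixedMember("medial", 0.5)]
        )
        assert ensemble_predict(ens, np.zeros((1, 2)))[0] == "medial"

    def test_untrained_ensemble_rejected(self):
        with pytest.raises(ValueError, match="untrained"):
            ensemble_predict(fixed_ensemble([]), np.zeros((1, 2)))

    @pytest.mark.parametrize("seed", range(5))
    def test_vote_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(1, 6)
        members = [
            FixedMember(CLASS_ORDER[rng.integers(3)], float(rng.random()))
            for _ in range(k)
        ]
        # heterogeneous members: prediction depends on the point
        class HalfPlane(FixedMember):
            def __init__(self, accuracy, flip):
                super().__init__("medial", accuracy)
                self.flip = flip

            def predict_one(self, x):
                return "medial" if (x[0] > 0) ^ self.flip else "lateral"

            def predict(self, X):
                return np.array([self.predict_one(x) for x in X], dtype=object)

        members.append(HalfPlane(float(rng.random()), bool(rng.integers(2))))
        pts = rng.normal(0, 1, (20, 2))
        ens = fixed_ensemble(members)
        assert np.array_equal(
            ensemble_predict(ens, pts), brute_force_vote(members, pts)
        )

    def test_duplicating_winning_member_is_stable(self):
        members = [
            FixedMember("caudal", 0.9),
            FixedMember("lateral", 0.2),
        ]
        before = ensemble_predict(fixed_ensemble(members), np.zeros((1, 2)))
        after = ensemble_predict(
            fixed_ensemble(members + [FixedMember("caudal", 0.9)]),
            np.zeros((1, 2)),
        )
        assert np.array_equal(before, after)

    def test_duplicating_whole_ensemble_is_invariant(self, separable_points):
        ens = train_ensemble(
            separable_points, c_grid=SMALL_C, gamma_grid=SMALL_GAMMA,
            cv_repeats=1, seed=1,
        )
        doubled = fixed_ensemble(ens.members + ens.members)
        doubled.scale_mean, doubled.scale_std = ens.scale_mean, ens.scale_std
        pts = separable_points.points[::7]
        assert np.array_equal(
            ensemble_predict(ens, pts), ensemble_predict(doubled, pts)
        )


class TestDenseMaps:
    def test_training_points_self_consistent(self, separable_points):
        ens = train_ensemble(
            separable_points, c_grid=SMALL_C, gamma_grid=SMALL_GAMMA,
            cv_repeats=1, seed=3,
        )
        pred = ensemble_predict(ens, separable_points.points)
        assert np.mean(pred == separable_points.labels) >= 0.99

    def test_domains_contain_their_centers(self, small_cloud):
        pts, truth = small_cloud
        ens = train_ensemble(
            pts, c_grid=SMALL_C, gamma_grid=SMALL_GAMMA, cv_repeats=1, seed=0
        )
        pred = ensemble_predict(ens, truth.centers)
        assert np.array_equal(pred, np.array(truth.domains, dtype=object))

    def test_demarcate_labels_every_mask_pixel(self, small_cloud):
        pts, truth = small_cloud
        ens = train_ensemble(
            pts, c_grid=SMALL_C, gamma_grid=SMALL_GAMMA, cv_repeats=1, seed=0
        )
        # coarse raster keeps the dense classification fast
        small = truth.label_raster((60, 80))
        auto = demarcate(ens, small.mask)
        assert np.all(auto.raster[auto.mask] >= 0)
        assert np.all(auto.raster[~auto.mask] == -1)

    def test_empty_mask_rejected(self, small_cloud):
        pts, _ = small_cloud
        ens = train_ensemble(
            pts, c_grid=(1.0,), gamma_grid=(0.5,), cv_repeats=1, seed=0
        )
        with pytest.raises(ValueError, match="empty"):
            demarcate(ens, np.zeros((10, 10), dtype=bool))


class TestAgreement:
    def maps(self, a_vals, b_vals):
        mask = np.ones((10, 10), dtype=bool)
        a = BoundaryMap("L1", np.array(a_vals).reshape(10, 10), mask)
        b = BoundaryMap("L1", np.array(b_vals).reshape(10, 10), mask)
        return a, b

    def test_identical_maps(self):
        a, b = self.maps([0] * 100, [0] * 100)
        assert agreement(a, b).fraction == 1.0

    def test_complementary_maps(self):
        a, b = self.maps([0] * 100, [1] * 100)
        assert agreement(a, b).fraction == 0.0

    def test_eight_of_hundred_disagree(self):
        vals = [0] * 100
        other = [0] * 92 + [1] * 8
        a, b = self.maps(vals, other)
        rep = agreement(a, b)
        assert rep.fraction == pytest.approx(0.92)
        # reference says lateral on the 8 disagreeing pixels, auto medial
        assert rep.confusion.loc["lateral", "medial"] == 8

    def test_mask_mismatch_rejected(self):
        mask1 = np.ones((10, 10), dtype=bool)
        mask2 = mask1.copy()
        mask2[0, 0] = False
        raster2 = np.zeros((10, 10), int)
        raster2[0, 0] = -1
        a = BoundaryMap("L1", np.zeros((10, 10), int), mask1)
        b = BoundaryMap("L1", raster2, mask2)
        with pytest.raises(ValueError, match="masks"):
            agreement(a, b)
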