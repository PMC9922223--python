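"""Ensemble scheme: severity levels, splits, polling, ROI retention and the
two-stage severity pipeline."""

import numpy as np
import pytest

from csednn.cse import CseMatrix, CseParams, CohortStandardizer
from csednn.nets import ClassifierSpec, RegressorSpec, TrainConfig
from csednn.prep import RoiTimeSeriesSet
from csednn.scheme import (
    DdnModel,
    SeverityLevels,
    Split,
    ddn_predict,
    dspn_predict,
    evaluate_ddn,
    evaluate_rmse,
    prepare_cohort,
    rank_rois_by_rmse,
    round_half_away,
    select_rois,
    split_cohort,
    train_ddn,
    train_dspn,
)
from csednn.synthetic import LabelVolume, SimConfig, Subject, SyntheticCohort, make_toy_atlas, simulate_cohort


class TestSeverityLevels:
    levels = SeverityLevels()

    @pytest.mark.parametrize(
        "hamd,expected",
        [(14, "severe"), (20, "severe"), (13, "moderate"), (11, "moderate"),
         (10, "mild"), (8, "mild")],
    )
    def test_classification_ranges(self, hamd, expected):
        assert self.levels.classify(hamd) == expected

    def test_hamd_below_depressed_range_rejected(self):
        with pytest.raises(ValueError):
            self.levels.classify(5)

    @pytest.mark.parametrize(
        "hamd,expected",
        [
            (12, {"severe", "moderate", "mild"}),  # overlap covers all three
            (20, {"severe"}),
            (8, {"mild"}),
            (13, {"severe", "moderate"}),
            (9, {"moderate", "mild"}),
        ],
    )
    def test_overlapped_training_ranges(self, hamd, expected):
        assert set(self.levels.training_levels(hamd)) == expected

    def test_class_ranges_partition_the_depressed_scale(self):
        for hamd in range(8, 53):
            members = [
                lvl for lvl, rng in self.levels.class_ranges.items()
                if self.levels._contains(rng, hamd)
            ]
            assert len(members) == 1


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(12.5, 13), (12.4, 12), (-12.5, -13), (12.733, 13), (0.0, 0)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_half_away(value) == expected


class TestSelectRois:
    def test_threshold_retention(self):
        sel = select_rois({1: 0.90, 2: 0.80, 3: 0.86}, threshold=0.85)
        assert sel.retained_rois == [1, 3]

    def test_all_below_threshold(self):
        sel = select_rois({1: 0.5, 2: 0.6})
        assert sel.retained_rois == []

    def test_zero_threshold_retains_all(self):
        sel = select_rois({3: 0.1, 1: 0.2, 2: 0.0}, threshold=0.0)
        assert sel.retained_rois == [1, 2, 3]


class TestRmse:
    def test_perfect_predictions(self):
        assert evaluate_rmse([3, 4, 5], [3, 4, 5]) == 0.0

    def test_closed_form_example(self):
        assert evaluate_rmse([1, 2], [2, 2]) == pytest.approx(np.sqrt(0.5))

    def test_matches_direct_formula(self, rng):
        p, t = rng.normal(size=(2, 30))
        assert evaluate_rmse(p, t) == pytest.approx(
            float(np.sqrt(np.mean((p - t) ** 2)))
        )

    def test_ranking_ascending_with_label_ties(self):
        truths = [10, 12]
        ranked = rank_rois_by_rmse(
            {3: [10, 12], 1: [11, 13], 2: [11, 13]}, truths
        )
        assert [roi for roi, _ in ranked] == [3, 1, 2]


def _toy_subjects(n_ctrl, hamds):
    subs = []
    for k in range(n_ctrl):
        subs.append(Subject(f"c{k:02d}", "control", 3, None))
    for k, h in enumerate(hamds):
        subs.append(Subject(f"d{k:02d}", "depressed", h, None))
    return subs


class TestSplit:
    def test_sizes_and_disjointness(self):
        subs = _toy_subjects(10, [8, 9, 10, 11, 12, 13, 14, 15, 16, 17])
        split = split_cohort(subs, (12, 4, 4), seed=0)
        ids = split.train + split.val + split.test
        assert len(split.train) == 12 and len(split.val) == 4 and len(split.test) == 4
        assert len(set(ids)) == len(ids)

    def test_both_groups_in_every_set(self):
        subs = _toy_subjects(10, list(range(8, 18)))
        split = split_cohort(subs, (12, 4, 4), seed=1)
        by_id = {s.subject_id: s for s in subs}
        for part in (split.train, split.val, split.test):
            assert {by_id[i].group for i in part} == {"control", "depressed"}

    def test_deterministic_given_seed(self):
        subs = _toy_subjects(8, list(range(8, 16)))
        a = split_cohort(subs, (10, 3, 3), seed=5)
        b = split_cohort(subs, (10, 3, 3), seed=5)
        assert a == b

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(_toy_subjects(2, [9, 10]), (4, 2, 2), seed=0)


class _FixedNet:
    """Stands in for a trained classifier/regressor: constant output."""

    def __init__(self, output):
        self.output = np.asarray(output, dtype=np.float32)

    def forward(self, x, train=False):
        return np.tile(self.output, (len(x), 1))


def _stub_ddn(votes):
    """A DdnModel whose seed classifiers produce predetermined votes.

    ``votes`` maps roi -> 'depressed' | 'control'.
    """
    n = len(votes)
    roi_ids = np.array(sorted(votes))
    std = CohortStandardizer(
        mean=np.zeros((n, n)), sd=np.ones((n, n)), roi_ids=roi_ids
    )
    classifiers = {
        roi: _FixedNet([0.0, 4.0] if votes[roi] == "depressed" else [4.0, 0.0])
        for roi in votes
    }
    return DdnModel(
        classifiers=classifiers, standardizer=std,
        split=Split([], [], []), validation_accuracy={r: 1.0 for r in votes},
        spec=ClassifierSpec(), params=CseParams(),
    )


def _dummy_matrices(roi_ids):
    n = len(roi_ids)
    return [CseMatrix(np.zeros((n, n)), CseParams(), roi_ids) for _ in range(3)]


class TestPolling:
    def _atlas(self, n):
        return make_toy_atlas((4, 4, 4), n)

    def test_unanimous_vote(self):
        votes = {r: "depressed" for r in range(1, 9)}
        model = _stub_ddn(votes)
        res = ddn_predict(model, _dummy_matrices(list(range(1, 9))), self._atlas(8))
        assert res.final == "depressed"
        assert res.vote_margin == 1.0

    def test_margin_arithmetic_fifty_forty(self):
        votes = {r: ("depressed" if r <= 50 else "control") for r in range(1, 91)}
        model = _stub_ddn(votes)
        res = ddn_predict(
            model, _dummy_matrices(list(range(1, 91))),
            make_toy_atlas((5, 6, 5), 90),
        )
        assert res.final == "depressed"
        assert res.vote_margin == pytest.approx(10 / 90)

    def test_tie_breaks_toward_depressed(self):
        votes = {r: ("depressed" if r % 2 else "control") for r in range(1, 9)}
        model = _stub_ddn(votes)
        res = ddn_predict(model, _dummy_matrices(list(range(1, 9))), self._atlas(8))
        assert res.final == "depressed"

    def test_polling_deterministic(self):
        votes = {r: ("depressed" if r <= 3 else "control") for r in range(1, 9)}
        model = _stub_ddn(votes)
        mats = _dummy_matrices(list(range(1, 9)))
        a = ddn_predict(model, mats, self._atlas(8))
        b = ddn_predict(model, mats, self._atlas(8))
        assert a.final == b.final == "control"
        assert a.per_seed_votes == b.per_seed_votes

    def test_missing_seed_rejected(self):
        model = _stub_ddn({1: "depressed", 2: "control"})
        with pytest.raises(ValueError):
            ddn_predict(
                model, _dummy_matrices([1, 2]), self._atlas(2), seeds=[1, 2, 3]
            )


SMOKE_CLF = ClassifierSpec(
    input_shape=(10, 12, 10), conv_filters=(2, 3, 2), conv_kernels=(3, 3, 1),
    avgpool_kernel=1, maxpool_kernels=(2, 2), fc_widths=(8, 2),
)
SMOKE_REG = RegressorSpec(
    input_shape=(10, 12, 10), conv_filters=(2, 3, 2), conv_kernels=(3, 3, 1),
    avgpool_kernel=1, maxpool_kernels=(2, 2), fc_widths=(8, 8, 8, 4, 4, 4, 1),
)


@pytest.fixture(scope="module")
def smoke_setup():
    """A tiny end-to-end cohort shared by the pipeline smoke tests."""
    coupling = np.eye(4)
    coupling[0, 1] = coupling[1, 0] = 0.05
    cfg = SimConfig(n_roi=4, n_timepoints=120, coupling_matrix=coupling,
                    effect_pairs=((1, 2),), effect_size=0.9, seed=31)
    cohort = simulate_cohort(cfg, 10, 14, hamd_range=(8, 20), seed=31,
                             atlas_shape=(10, 12, 10))
    prep = prepare_cohort(cohort, CseParams())
    clf_cfg = TrainConfig(learning_rate=1e-3, epochs=8, batch_size=8,
                          patience=4, seed=0)
    model = train_ddn(prep, SMOKE_CLF, clf_cfg, split_sizes=(16, 4, 4), seed=0)
    return cohort, prep, model, clf_cfg


class TestDdnPipeline:
    def test_one_classifier_and_accuracy_per_seed(self, smoke_setup):
        _, _, model, _ = smoke_setup
        assert sorted(model.classifiers) == [1, 2, 3, 4]
        assert all(0.0 <= a <= 1.0 for a in model.validation_accuracy.values())

    def test_standardizer_fitted_on_training_controls_only(self, smoke_setup):
        _, prep, model, _ = smoke_setup
        n_train_controls = sum(
            prep.subject(i).group == "control" for i in model.split.train
        )
        assert model.standardizer.n_matrices == 3 * n_train_controls

    def test_subject_level_splits_are_disjoint(self, smoke_setup):
        _, _, model, _ = smoke_setup
        ids = model.split.train + model.split.val + model.split.test
        assert len(set(ids)) == len(ids) == 24

    def test_prediction_consistent_with_majority_vote(self, smoke_setup):
        _, prep, model, _ = smoke_setup
        for sid in model.split.test:
            res = ddn_predict(model, prep.matrices[sid], prep.atlas)
            n_dep = sum(v == "depressed" for v in res.per_seed_votes.values())
            expected = "depressed" if n_dep >= len(res.per_seed_votes) - n_dep else "control"
            assert res.final == expected

    def test_evaluate_ddn_returns_fraction(self, smoke_setup):
        _, prep, model, _ = smoke_setup
        acc, results = evaluate_ddn(model, prep)
        assert 0.0 <= acc <= 1.0
        assert set(results) == set(model.split.test)


class TestDspnPipeline:
    def test_routing_and_prediction_contract(self, smoke_setup):
        cohort, prep, ddn, clf_cfg = smoke_setup
        reg_cfg = TrainConfig(loss="mse", learning_rate=1e-3, epochs=8,
                              batch_size=8, patience=4, seed=0)
        model = train_dspn(
            prep, ddn.standardizer, [1, 2], SMOKE_CLF, SMOKE_REG,
            clf_cfg, reg_cfg, split_sizes=(10, 2, 2), seed=0,
        )
        assert sorted(model.stage1) == [1, 2]
        assert set(model.regressors) == {"severe", "moderate", "mild"}
        for sid in model.split.test:
            hp = dspn_predict(model, prep.matrices[sid], prep.atlas)
            assert hp.level in ("severe", "moderate", "mild")
            # one estimate per retained seed, rounded mean as the final score
            assert len(hp.per_volume_estimates) == 2
            assert hp.final_score == round_half_away(
                float(np.mean(hp.per_volume_estimates))
            )

    def test_empty_training_range_is_reported(self, smoke_setup):
        cohort, prep, ddn, clf_cfg = smoke_setup
        # a split whose training half contains only severe subjects cannot
        # populate the mild range
        severe_ids = [
            s.subject_id for s in cohort.subjects
            if s.group == "depressed" and s.hamd > 15
        ]
        other = [
            s.subject_id for s in cohort.subjects
            if s.group == "depressed" and s.hamd <= 15
        ]
        split = Split(train=severe_ids, val=other[:1], test=other[1:2])
        with pytest.raises(ValueError, match="moderate|mild"):
            train_dspn(
                prep, ddn.standardizer, [1, 2], SMOKE_CLF, SMOKE_REG,
                clf_cfg, clf_cfg, split=split,
            )

    def test_empty_retained_set_rejected(self, smoke_setup):
        _, prep, ddn, clf_cfg = smoke_setup
        with pytest.raises(ValueError):
            train_dspn(
                prep, ddn.standardizer, [], SMOKE_CLF, SMOKE_REG,
                clf_cfg, clf_cfg,
            )
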