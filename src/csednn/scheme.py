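"""End-to-end scheme: per-seed classifier ensemble with polling (DDN),
validation-accuracy ROI retention, and the two-stage severity + per-level
regression pipeline (DSPN).

DDN trains one classification network per seed ROI on that seed's CSE
volumes and diagnoses a subject by majority poll over the seed votes.
Seeds whose classifier reaches the validation-accuracy threshold (0.85)
are retained for DSPN, which first polls per-seed weak classifiers to
split depressed subjects into high/low severity, sends the low group
through a single moderate-vs-mild classifier, and finally predicts the
HAM-D score with the matching level's regression network (estimates from
every retained seed averaged and rounded to the nearest integer).

Severity levels on the 17-item HAM-D: severe > 13, moderate 11-13,
mild 8-10.  The regression networks are trained on *overlapped* ranges
(> 11, 9-15, 8-12) for fault tolerance against level misclassification.

Splits are subject-level and stratified by group with HAM-D spread evenly
across sets, so the three augmented segments of a subject never straddle
splits.  The control standardisation statistics are fitted on training
controls only; test subjects are touched exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cse import (
    CseMatrix,
    CseParams,
    CohortStandardizer,
    build_cse_volume,
    fit_standardizer,
    segment_cse_matrices,
    standardize,
)
from .nets import (
    ClassifierSpec,
    RegressorSpec,
    Sequential,
    TrainConfig,
    build_classifier,
    build_regressor,
    predict_proba,
    train,
)
from .synthetic import LabelVolume, Subject, SyntheticCohort

__all__ = [
    "SeverityLevels",
    "DiagnosisResult",
    "SeveritySelection",
    "HamdPrediction",
    "Split",
    "split_cohort",
    "prepare_cohort",
    "PreparedCohort",
    "DdnModel",
    "train_ddn",
    "ddn_predict",
    "evaluate_ddn",
    "select_rois",
    "DspnModel",
    "train_dspn",
    "dspn_predict",
    "evaluate_rmse",
    "rank_rois_by_rmse",
    "round_half_away",
]

#: fraction of seed votes a diagnosis is decided by in the study protocol
DEFAULT_SELECTION_THRESHOLD = 0.85
#: split proportions for diagnosis (train/val/test participant counts)
DDN_SPLIT = (51, 7, 13)
#: split proportions for severity prediction
DSPN_SPLIT = (29, 10, 10)


@dataclass(frozen=True)
class SeverityLevels:
    """Classification ranges partition [8, inf); training ranges overlap to
    give the per-level regressors fault tolerance."""

    class_ranges: Mapping[str, tuple[int, int | None]] = field(
        default_factory=lambda: {
            "severe": (14, None),
            "moderate": (11, 13),
            "mild": (8, 10),
        }
    )
    training_ranges: Mapping[str, tuple[int, int | None]] = field(
        default_factory=lambda: {
            "severe": (12, None),
            "moderate": (9, 15),
            "mild": (8, 12),
        }
    )

    @staticmethod
    def _contains(rng: tuple[int, int | None], hamd: int) -> bool:
        low, high = rng
        return hamd >= low and (high is None or hamd <= high)

    def classify(self, hamd: int) -> str:
        for level, rng in self.class_ranges.items():
            if self._contains(rng, hamd):
                return level
        raise ValueError(f"HAM-D {hamd} outside the depressed range (>= 8)")

    def training_levels(self, hamd: int) -> list[str]:
        return [
            level
            for level, rng in self.training_ranges.items()
            if self._contains(rng, hamd)
        ]

    def is_high(self, hamd: int) -> bool:
        """Stage-1 boundary: high = the severe class range."""
        return self.classify(hamd) == "severe"


@dataclass
class DiagnosisResult:
    per_seed_votes: dict[int, str]
    vote_margin: float
    final: str


@dataclass
class SeveritySelection:
    retained_rois: list[int]
    validation_accuracy: dict[int, float]
    threshold: float


@dataclass
class HamdPrediction:
    level: str
    per_volume_estimates: list[float]
    final_score: int


@dataclass
class Split:
    train: list[str]
    val: list[str]
    test: list[str]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (avoids
    platform banker's-rounding drift)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def _spread_assign(n: int, counts: Sequence[int]) -> list[int]:
    """Assignment sequence of length n where set k appears counts[k] times,
    each spread evenly along the sequence."""
    entries = []
    for k, c in enumerate(counts):
        for i in range(c):
            entries.append(((i + 0.5) / c, k))
    entries.sort()
    assert len(entries) == n
    return [k for _, k in entries]


def _allocate(total_counts: Sequence[int], group_sizes: Sequence[int]) -> list[list[int]]:
    """Largest-remainder allocation of per-set counts across groups.

    Sets are processed smallest first against each group's remaining
    capacity, so no group is ever over-drawn.
    """
    n_groups = len(group_sizes)
    remaining = list(group_sizes)
    out = [[0] * len(total_counts) for _ in group_sizes]
    for s in sorted(range(len(total_counts)), key=lambda i: total_counts[i]):
        c = total_counts[s]
        tot = sum(remaining)
        quotas = [c * r / tot if tot else 0.0 for r in remaining]
        base = [min(int(math.floor(q)), remaining[g]) for g, q in enumerate(quotas)]
        short = c - sum(base)
        order = sorted(range(n_groups), key=lambda g: base[g] - quotas[g])
        while short > 0:
            progressed = False
            for g in order:
                if short == 0:
                    break
                if base[g] < remaining[g]:
                    base[g] += 1
                    short -= 1
                    progressed = True
            if not progressed:
                raise ValueError("split sizes exceed available subjects")
        for g, b in enumerate(base):
            out[g][s] = b
            remaining[g] -= b
    return out


def split_cohort(
    subjects: Sequence[Subject],
    sizes: tuple[int, int, int],
    seed: int = 0,
) -> Split:
    """Subject-level train/val/test split, stratified by group and with
    HAM-D spread approximately evenly across the three sets."""
    n_train, n_val, n_test = sizes
    if n_train + n_val + n_test > len(subjects):
        raise ValueError(
            f"split sizes {sizes} exceed cohort size {len(subjects)}"
        )
    rng = np.random.default_rng(seed)
    groups: dict[str, list[Subject]] = {}
    for s in subjects:
        groups.setdefault(s.group, []).append(s)
    group_names = sorted(groups)
    alloc = _allocate(
        (n_train, n_val, n_test), [len(groups[g]) for g in group_names]
    )
    sets: list[list[str]] = [[], [], []]
    for g_idx, g in enumerate(group_names):
        members = groups[g]
        counts = alloc[g_idx]
        used = sum(counts)
        pick = rng.choice(len(members), size=used, replace=False)
        jitter = rng.permutation(len(members))
        order = sorted(pick, key=lambda i: (members[i].hamd, jitter[i]))
        chosen = [members[i] for i in order]
        # spread each set across the HAM-D-sorted members
        for pos, set_idx in enumerate(_spread_assign(len(chosen), counts)):
            sets[set_idx].append(chosen[pos].subject_id)
    return Split(train=sorted(sets[0]), val=sorted(sets[1]), test=sorted(sets[2]))


@dataclass
class PreparedCohort:
    """Cohort metadata plus per-subject segment CSE matrices (raw scale)."""

    subjects: list[Subject]
    atlas: LabelVolume
    params: CseParams
    matrices: dict[str, list[CseMatrix]]

    def subject(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


def prepare_cohort(
    cohort: SyntheticCohort, params: CseParams = CseParams()
) -> PreparedCohort:
    """Compute the three augmented-segment CSE matrices for every subject."""
    matrices = {
        s.subject_id: segment_cse_matrices(s.series.values, s.series.roi_ids, params)
        for s in cohort.subjects
    }
    return PreparedCohort(
        subjects=list(cohort.subjects),
        atlas=cohort.label_volume,
        params=params,
        matrices=matrices,
    )


def _volumes(
    matrices: Iterable[CseMatrix], seed_roi: int, atlas: np.ndarray
) -> np.ndarray:
    """Stack segment CSE volumes as (n_segments, 1, x, y, z) float32."""
    vols = [
        build_cse_volume(m, seed_roi, atlas).grid[None, ...] for m in matrices
    ]
    return np.stack(vols).astype(np.float32)


def _onehot(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    out = np.zeros((len(labels), n_classes), dtype=np.float32)
    out[np.arange(len(labels)), labels] = 1.0
    return out


@dataclass
class DdnModel:
    """Per-seed diagnosis classifiers plus the control standardizer."""

    classifiers: dict[int, Sequential]
    standardizer: CohortStandardizer
    split: Split
    validation_accuracy: dict[int, float]
    spec: ClassifierSpec
    params: CseParams


def _standardized(prep: PreparedCohort, std: CohortStandardizer, subject_id: str):
    return [standardize(m, std) for m in prep.matrices[subject_id]]


def _seed_probs(
    model: Sequential, std_mats: list[CseMatrix], seed_roi: int, atlas: np.ndarray
) -> np.ndarray:
    """Class probabilities for one subject and one seed: softmax outputs of
    the subject's augmented volumes, averaged."""
    x = _volumes(std_mats, seed_roi, atlas)
    return predict_proba(model, x).mean(axis=0)


def train_ddn(
    prep: PreparedCohort,
    spec: ClassifierSpec,
    cfg: TrainConfig,
    split: Split | None = None,
    split_sizes: tuple[int, int, int] | None = None,
    seed: int = 0,
    seeds: Sequence[int] | None = None,
) -> DdnModel:
    """Train one diagnosis classifier per seed ROI.

    The control standardizer is fitted on training-split controls only.
    Augmented segments are independent training samples; validation
    accuracy is subject-level (segment probabilities averaged per subject).
    """
    if split is None:
        if split_sizes is None:
            n = len(prep.subjects)
            total = sum(DDN_SPLIT)
            n_val = max(2, round(n * DDN_SPLIT[1] / total))
            n_test = max(2, round(n * DDN_SPLIT[2] / total))
            split_sizes = (n - n_val - n_test, n_val, n_test)
        split = split_cohort(prep.subjects, split_sizes, seed=seed)
    for name, ids in (("train", split.train), ("val", split.val), ("test", split.test)):
        grps = {prep.subject(i).group for i in ids}
        if ids and grps != {"control", "depressed"}:
            raise ValueError(f"{name} split lacks one of the two groups")
    train_controls = [
        i for i in split.train if prep.subject(i).group == "control"
    ]
    std = fit_standardizer(
        [m for i in train_controls for m in prep.matrices[i]]
    )
    std_mats = {
        i: _standardized(prep, std, i) for i in (*split.train, *split.val)
    }
    atlas = prep.atlas.data
    roi_list = [int(r) for r in (seeds if seeds is not None else prep.atlas.roi_ids)]
    y_map = {"control": 0, "depressed": 1}
    classifiers: dict[int, Sequential] = {}
    val_acc: dict[int, float] = {}
    for k, roi in enumerate(roi_list):
        x_train = np.concatenate(
            [_volumes(std_mats[i], roi, atlas) for i in split.train]
        )
        y_train = np.repeat(
            [y_map[prep.subject(i).group] for i in split.train], 3
        )
        x_val = np.concatenate([_volumes(std_mats[i], roi, atlas) for i in split.val])
        y_val = np.repeat([y_map[prep.subject(i).group] for i in split.val], 3)
        net = build_classifier(spec, seed=seed + 1000 * (k + 1))
        net_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + k})
        train(net, x_train, _onehot(y_train), x_val, _onehot(y_val), net_cfg)
        correct = 0
        for i in split.val:
            probs = _seed_probs(net, std_mats[i], roi, atlas)
            pred = 1 if probs[1] >= probs[0] else 0
            correct += int(pred == y_map[prep.subject(i).group])
        val_acc[roi] = correct / len(split.val)
        classifiers[roi] = net
    return DdnModel(
        classifiers=classifiers,
        standardizer=std,
        split=split,
        validation_accuracy=val_acc,
        spec=spec,
        params=prep.params,
    )


def ddn_predict(
    model: DdnModel,
    segment_matrices: list[CseMatrix],
    atlas: LabelVolume,
    seeds: Sequence[int] | None = None,
) -> DiagnosisResult:
    """Diagnose one subject by polling the per-seed classifiers.

    Per seed, the three augmented volumes' class probabilities are averaged
    and arg-maxed into a vote; the final label is the vote majority, with
    ties broken toward "depressed" (screening favours sensitivity).
    """
    std_mats = [standardize(m, model.standardizer) for m in segment_matrices]
    roi_list = list(seeds) if seeds is not None else sorted(model.classifiers)
    missing = [r for r in roi_list if r not in model.classifiers]
    if missing:
        raise ValueError(f"no trained classifier for seeds {missing}")
    votes: dict[int, str] = {}
    for roi in roi_list:
        probs = _seed_probs(model.classifiers[roi], std_mats, roi, atlas.data)
        votes[roi] = "depressed" if probs[1] >= probs[0] else "control"
    n_dep = sum(v == "depressed" for v in votes.values())
    n_ctl = len(votes) - n_dep
    final = "depressed" if n_dep >= n_ctl else "control"
    margin = abs(n_dep - n_ctl) / len(votes)
    return DiagnosisResult(per_seed_votes=votes, vote_margin=margin, final=final)


def evaluate_ddn(
    model: DdnModel,
    prep: PreparedCohort,
    subject_ids: Sequence[str] | None = None,
) -> tuple[float, dict[str, DiagnosisResult]]:
    """Polling accuracy over a subject set (default: the held-out test split)."""
    ids = list(subject_ids) if subject_ids is not None else model.split.test
    results = {}
    correct = 0
    for i in ids:
        res = ddn_predict(model, prep.matrices[i], prep.atlas)
        results[i] = res
        correct += int(res.final == prep.subject(i).group)
    return correct / len(ids), results


def seed_accuracy(
    model: DdnModel,
    prep: PreparedCohort,
    subject_ids: Sequence[str],
) -> dict[int, tuple[int, int]]:
    """Per-seed (correct, total) subject-level diagnosis counts over a
    subject set — the single-seed analogue of the polling accuracy, used
    for effect localisation."""
    y_map = {"control": 0, "depressed": 1}
    out: dict[int, tuple[int, int]] = {}
    for roi, net in model.classifiers.items():
        correct = 0
        for i in subject_ids:
            std_mats = [standardize(m, model.standardizer) for m in prep.matrices[i]]
            probs = _seed_probs(net, std_mats, roi, prep.atlas.data)
            pred = 1 if probs[1] >= probs[0] else 0
            correct += int(pred == y_map[prep.subject(i).group])
        out[roi] = (correct, len(subject_ids))
    return out


def select_rois(
    validation_accuracy: Mapping[int, float],
    threshold: float = DEFAULT_SELECTION_THRESHOLD,
) -> SeveritySelection:
    """Retain the seed ROIs whose diagnosis classifier reached the
    validation-accuracy threshold (ordering stable by ROI label)."""
    retained = sorted(r for r, a in validation_accuracy.items() if a >= threshold)
    return SeveritySelection(
        retained_rois=retained,
        validation_accuracy=dict(validation_accuracy),
        threshold=threshold,
    )


@dataclass
class DspnModel:
    """Two-stage severity classifiers plus per-level regression networks."""

    stage1: dict[int, Sequential]
    stage2: Sequential
    regressors: dict[str, Sequential]
    retained_rois: list[int]
    levels: SeverityLevels
    standardizer: CohortStandardizer
    split: Split
    clf_spec: ClassifierSpec
    reg_spec: RegressorSpec


def train_dspn(
    prep: PreparedCohort,
    standardizer: CohortStandardizer,
    retained_rois: Sequence[int],
    clf_spec: ClassifierSpec,
    reg_spec: RegressorSpec,
    clf_cfg: TrainConfig,
    reg_cfg: TrainConfig,
    levels: SeverityLevels | None = None,
    split: Split | None = None,
    split_sizes: tuple[int, int, int] | None = None,
    seed: int = 0,
) -> DspnModel:
    """Train the severity pipeline on the depressed subjects.

    Stage 1: one weak high/low classifier per retained seed (high = severe
    class range).  Stage 2: a single moderate-vs-mild classifier pooled
    over all retained seeds.  Regressors: one per level, trained only on
    subjects whose HAM-D lies in that level's overlapped training range.
    """
    levels = levels or SeverityLevels()
    retained = sorted(retained_rois)
    if not retained:
        raise ValueError("no retained seed ROIs: cannot train DSPN")
    depressed = [s for s in prep.subjects if s.group == "depressed"]
    if any(s.hamd < 8 for s in depressed):
        raise ValueError("depressed subjects must have HAM-D >= 8")
    if split is None:
        if split_sizes is None:
            n = len(depressed)
            total = sum(DSPN_SPLIT)
            n_val = max(2, round(n * DSPN_SPLIT[1] / total))
            n_test = max(2, round(n * DSPN_SPLIT[2] / total))
            split_sizes = (n - n_val - n_test, n_val, n_test)
        split = split_cohort(depressed, split_sizes, seed=seed)
    for level, rng in levels.training_ranges.items():
        in_range = [
            i for i in split.train
            if levels._contains(rng, prep.subject(i).hamd)
        ]
        if not in_range:
            raise ValueError(
                f"training range of level {level!r} contains no subjects"
            )
    std_mats = {
        i: _standardized(prep, standardizer, i)
        for i in (*split.train, *split.val)
    }
    atlas = prep.atlas.data
    hamd = {i: prep.subject(i).hamd for i in (*split.train, *split.val)}

    # --- stage 1: per-seed high/low weak classifiers -----------------------
    stage1: dict[int, Sequential] = {}
    y1 = {i: int(levels.is_high(hamd[i])) for i in hamd}
    for k, roi in enumerate(retained):
        x_tr = np.concatenate([_volumes(std_mats[i], roi, atlas) for i in split.train])
        y_tr = np.repeat([y1[i] for i in split.train], 3)
        x_va = np.concatenate([_volumes(std_mats[i], roi, atlas) for i in split.val])
        y_va = np.repeat([y1[i] for i in split.val], 3)
        net = build_classifier(clf_spec, seed=seed + 2000 + k)
        cfg_k = TrainConfig(**{**clf_cfg.__dict__, "seed": clf_cfg.seed + k})
        train(net, x_tr, _onehot(y_tr), x_va, _onehot(y_va), cfg_k)
        stage1[roi] = net

    # --- stage 2: single moderate-vs-mild classifier -----------------------
    def low_ids(ids):
        return [i for i in ids if not levels.is_high(hamd[i])]

    def stacked(ids, target_fn):
        xs, ys = [], []
        for i in ids:
            for roi in retained:
                xs.append(_volumes(std_mats[i], roi, atlas))
                ys.extend([target_fn(i)] * 3)
        return np.concatenate(xs), np.array(ys)

    is_moderate = lambda i: int(levels.classify(hamd[i]) == "moderate")
    lo_tr, lo_va = low_ids(split.train), low_ids(split.val)
    if not lo_tr or not lo_va:
        raise ValueError("low-severity subjects missing from train or val split")
    x_tr, y_tr = stacked(lo_tr, is_moderate)
    x_va, y_va = stacked(lo_va, is_moderate)
    stage2 = build_classifier(clf_spec, seed=seed + 3000)
    train(
        stage2, x_tr, _onehot(y_tr), x_va, _onehot(y_va),
        TrainConfig(**{**clf_cfg.__dict__, "seed": clf_cfg.seed + 101}),
    )

    # --- per-level regressors on overlapped training ranges ----------------
    regressors: dict[str, Sequential] = {}
    for k, (level, rng_) in enumerate(levels.training_ranges.items()):
        tr_ids = [i for i in split.train if levels._contains(rng_, hamd[i])]
        va_ids = [i for i in split.val if levels._contains(rng_, hamd[i])] or tr_ids
        x_tr, y_tr = stacked(tr_ids, lambda i: float(hamd[i]))
        x_va, y_va = stacked(va_ids, lambda i: float(hamd[i]))
        net = build_regressor(reg_spec, seed=seed + 4000 + k)
        cfg_k = TrainConfig(**{**reg_cfg.__dict__, "seed": reg_cfg.seed + k})
        train(net, x_tr, y_tr[:, None], x_va, y_va[:, None], cfg_k)
        regressors[level] = net

    return DspnModel(
        stage1=stage1,
        stage2=stage2,
        regressors=regressors,
        retained_rois=retained,
        levels=levels,
        standardizer=standardizer,
        split=split,
        clf_spec=clf_spec,
        reg_spec=reg_spec,
    )


def dspn_predict(
    model: DspnModel,
    segment_matrices: list[CseMatrix],
    atlas: LabelVolume,
) -> HamdPrediction:
    """Predict one depressed subject's HAM-D score.

    Stage-1 votes (one per retained seed) decide high/low; low subjects go
    through the stage-2 moderate/mild classifier; exactly one per-level
    regressor then scores every retained-seed volume (segment estimates
    averaged per seed), and the seed estimates are averaged and rounded to
    the nearest integer.
    """
    if not model.retained_rois:
        raise ValueError("empty retained ROI set")
    std_mats = [standardize(m, model.standardizer) for m in segment_matrices]
    grid = atlas.data
    high_votes = 0
    for roi in model.retained_rois:
        probs = _seed_probs(model.stage1[roi], std_mats, roi, grid)
        high_votes += int(probs[1] >= probs[0])
    n = len(model.retained_rois)
    if high_votes * 2 >= n:  # ties go to the more severe branch
        level = "severe"
    else:
        mod_votes = 0
        for roi in model.retained_rois:
            probs = _seed_probs(model.stage2, std_mats, roi, grid)
            mod_votes += int(probs[1] >= probs[0])
        level = "moderate" if mod_votes * 2 >= n else "mild"
    reg = model.regressors[level]
    estimates = []
    for roi in model.retained_rois:
        x = _volumes(std_mats, roi, grid)
        estimates.append(float(reg.forward(x, train=False).mean()))
    final = round_half_away(float(np.mean(estimates)))
    return HamdPrediction(
        level=level, per_volume_estimates=estimates, final_score=final
    )


def evaluate_rmse(predictions: Sequence[float], truths: Sequence[float]) -> float:
    """Root-mean-square error between predicted and true HAM-D scores."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truths, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("predictions and truths must be equal-length, non-empty")
    return float(np.sqrt(np.mean((p - t) ** 2)))


def rank_rois_by_rmse(
    per_roi_predictions: Mapping[int, Sequence[float]],
    truths: Sequence[float],
) -> list[tuple[int, float]]:
    """Rank seed ROIs by the RMSE of their single-seed predictions,
    ascending; ties broken by ROI label."""
    scored = [
        (roi, evaluate_rmse(preds, truths))
        for roi, preds in per_roi_predictions.items()
    ]
    return sorted(scored, key=lambda rv: (rv[1], rv[0]))
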