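"""On-disk round-tripping of trained DDN/DSPN models.

Layout: one directory per model; each network is an ``.npz`` (state
arrays) plus ``.json`` (spec) pair, with a ``meta.json`` holding the
standardizer, split and validation accuracies.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .cse import CseParams, CohortStandardizer
from .nets import ClassifierSpec, RegressorSpec, load_model, save_model
from .scheme import DdnModel, DspnModel, SeverityLevels, Split

__all__ = ["save_ddn", "load_ddn", "save_dspn", "load_dspn"]


def _save_standardizer(std: CohortStandardizer, path: Path) -> None:
    np.savez(
        path, mean=std.mean, sd=std.sd, roi_ids=std.roi_ids,
        n_matrices=np.array(std.n_matrices),
    )


def _load_standardizer(path: Path) -> CohortStandardizer:
    data = np.load(path)
    return CohortStandardizer(
        mean=data["mean"], sd=data["sd"], roi_ids=data["roi_ids"],
        n_matrices=int(data["n_matrices"]),
    )


def save_ddn(model: DdnModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for roi, net in model.classifiers.items():
        save_model(net, model.spec, out / f"seed_{roi:03d}")
    _save_standardizer(model.standardizer, out / "standardizer.npz")
    meta = {
        "kind": "ddn",
        "rois": [int(r) for r in sorted(model.classifiers)],
        "validation_accuracy": {
            str(int(k)): float(v) for k, v in model.validation_accuracy.items()
        },
        "split": model.split.__dict__,
        "cse_params": model.params.__dict__,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))


def load_ddn(model_dir: str | Path) -> DdnModel:
    out = Path(model_dir)
    meta = json.loads((out / "meta.json").read_text())
    classifiers = {}
    spec = None
    for roi in meta["rois"]:
        net, spec = load_model(out / f"seed_{roi:03d}")
        classifiers[roi] = net
    return DdnModel(
        classifiers=classifiers,
        standardizer=_load_standardizer(out / "standardizer.npz"),
        split=Split(**meta["split"]),
        validation_accuracy={int(k): v for k, v in meta["validation_accuracy"].items()},
        spec=spec,
        params=CseParams(**meta["cse_params"]),
    )


def save_dspn(model: DspnModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for roi, net in model.stage1.items():
        save_model(net, model.clf_spec, out / f"stage1_{roi:03d}")
    save_model(model.stage2, model.clf_spec, out / "stage2")
    for level, net in model.regressors.items():
        save_model(net, model.reg_spec, out / f"reg_{level}")
    _save_standardizer(model.standardizer, out / "standardizer.npz")
    meta = {
        "kind": "dspn",
        "retained_rois": [int(r) for r in model.retained_rois],
        "levels": {
            "class_ranges": {k: list(v) for k, v in model.levels.class_ranges.items()},
            "training_ranges": {
                k: list(v) for k, v in model.levels.training_ranges.items()
            },
        },
        "split": model.split.__dict__,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))


def load_dspn(model_dir: str | Path) -> DspnModel:
    out = Path(model_dir)
    meta = json.loads((out / "meta.json").read_text())
    stage1 = {}
    clf_spec = None
    for roi in meta["retained_rois"]:
        net, clf_spec = load_model(out / f"stage1_{roi:03d}")
        stage1[roi] = net
    stage2, clf_spec = load_model(out / "stage2")
    regressors = {}
    reg_spec = None
    for level in meta["levels"]["class_ranges"]:
        regressors[level], reg_spec = load_model(out / f"reg_{level}")
    levels = SeverityLevels(
        class_ranges={
            k: (v[0], v[1]) for k, v in meta["levels"]["class_ranges"].items()
        },
        training_ranges={
            k: (v[0], v[1]) for k, v in meta["levels"]["training_ranges"].items()
        },
    )
    return DspnModel(
        stage1=stage1,
        stage2=stage2,
        regressors=regressors,
        retained_rois=meta["retained_rois"],
        levels=levels,
        standardizer=_load_standardizer(out / "standardizer.npz"),
        split=Split(**meta["split"]),
        clf_spec=clf_spec,
        reg_spec=reg_spec,
    )
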