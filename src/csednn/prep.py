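"""ROI time-series preparation: detrend, bandpass, nuisance regression,
atlas averaging.

The cleaning sequence follows the standard resting-state pipeline:
frame exclusion (optional motion scrubbing) -> linear detrend -> 0.01-0.08 Hz
zero-phase bandpass -> nuisance regression -> (atlas averaging).  All steps
are linear, so averaging voxels into ROI means commutes with them; when only
ROI-level series are available the same cleaning is applied after averaging
with identical results.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "Bold4D",
    "NuisanceSet",
    "RoiTimeSeriesSet",
    "detrend",
    "bandpass",
    "regress_nuisance",
    "extract_roi_series",
    "prepare_roi_series",
    "read_roi_tsv",
    "write_roi_tsv",
]


@dataclass
class Bold4D:
    """A preprocessed 4D BOLD volume (x, y, z, t) on a common spatial grid."""

    data: np.ndarray
    tr_seconds: float = 2.0
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("need at least two time points")


@dataclass
class NuisanceSet:
    """t x k matrix of nuisance regressors (WM mean, CSF mean, six motion
    parameters, or any user-supplied columns)."""

    regressors: np.ndarray

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.ndim != 2:
            raise ValueError("regressors must be a 2-D matrix")


@dataclass
class RoiTimeSeriesSet:
    """n_roi x t matrix of ROI-mean BOLD series."""

    values: np.ndarray
    roi_ids: np.ndarray
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi_ids = np.asarray(self.roi_ids, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be n_roi x t")
        if len(self.roi_ids) != self.values.shape[0]:
            raise ValueError("roi_ids length must match number of rows")

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


def detrend(series: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend (slope and intercept)."""
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 2:
        raise ValueError("need at least two samples to detrend")
    return signal.detrend(series, axis=-1, type="linear")


def bandpass(
    series: np.ndarray,
    tr_seconds: float,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (applied forward-backward, so no
    temporal shift). Default band is the resting-state 0.01-0.08 Hz."""
    series = np.asarray(series, dtype=float)
    nyquist = 0.5 / tr_seconds
    if not 0 < low_hz < high_hz:
        raise ValueError(f"need 0 < low_hz < high_hz, got {low_hz}, {high_hz}")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz {high_hz} must be below the Nyquist frequency {nyquist}"
        )
    sos = signal.butter(
        order, [low_hz / nyquist, high_hz / nyquist], btype="bandpass", output="sos"
    )
    return signal.sosfiltfilt(sos, series, axis=-1)


def regress_nuisance(series: np.ndarray, nuisance: NuisanceSet | None) -> np.ndarray:
    """Least-squares residual after projecting out the nuisance columns plus
    an intercept. Rank-deficient designs are handled by the pseudo-inverse.
    With no regressors this reduces to mean-centering."""
    series = np.asarray(series, dtype=float)
    t = series.shape[-1]
    cols = [np.ones((t, 1))]
    if nuisance is not None and nuisance.regressors.size:
        if nuisance.regressors.shape[0] != t:
            raise ValueError(
                f"nuisance rows {nuisance.regressors.shape[0]} != series length {t}"
            )
        cols.append(nuisance.regressors)
    design = np.hstack(cols)
    beta, *_ = np.linalg.lstsq(design, series.T if series.ndim > 1 else series)
    fitted = design @ beta
    return series - (fitted.T if series.ndim > 1 else fitted)


def extract_roi_series(
    bold: Bold4D, atlas: np.ndarray, tr_seconds: float | None = None
) -> RoiTimeSeriesSet:
    """Average the voxel series within each atlas label, per time point.

    ROI order is ascending label; label 0 is background.  An ROI present in
    the atlas must occupy at least one voxel (guaranteed by construction);
    a requested label with no voxels raises naming the label.
    """
    atlas = np.asarray(atlas)
    if atlas.shape != bold.data.shape[:3]:
        raise ValueError(
            f"atlas shape {atlas.shape} != spatial dims {bold.data.shape[:3]}"
        )
    labels = np.unique(atlas)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("atlas contains no labelled voxels")
    rows = []
    for label in labels:
        mask = atlas == label
        if not mask.any():  # pragma: no cover - unique() precludes this
            raise ValueError(f"ROI label {label} has no voxels")
        rows.append(bold.data[mask].mean(axis=0))
    return RoiTimeSeriesSet(
        values=np.stack(rows),
        roi_ids=labels.astype(int),
        tr_seconds=tr_seconds if tr_seconds is not None else bold.tr_seconds,
    )


def prepare_roi_series(
    ts: RoiTimeSeriesSet,
    nuisance: NuisanceSet | None = None,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    frame_mask: np.ndarray | None = None,
) -> RoiTimeSeriesSet:
    """Full cleaning pipeline on ROI series: drop excluded frames, detrend,
    bandpass, regress nuisance.

    ``frame_mask`` is a boolean keep-mask (True = keep) implementing motion
    scrubbing; excluded frames are dropped before detrending, and nuisance
    rows are subset to match.
    """
    values = ts.values
    if frame_mask is not None:
        frame_mask = np.asarray(frame_mask, dtype=bool)
        if frame_mask.shape[0] != values.shape[1]:
            raise ValueError("frame_mask length must match n_timepoints")
        values = values[:, frame_mask]
        if nuisance is not None:
            nuisance = NuisanceSet(nuisance.regressors[frame_mask])
    values = detrend(values)
    values = bandpass(values, ts.tr_seconds, low_hz, high_hz)
    values = regress_nuisance(values, nuisance)
    if np.any(values.std(axis=1) == 0):
        raise ValueError("preparation produced a constant ROI series")
    return RoiTimeSeriesSet(values, ts.roi_ids, ts.tr_seconds)


def read_roi_tsv(path: str | Path, tr_seconds: float = 2.0) -> RoiTimeSeriesSet:
    """Read ROI series from TSV: one column per ROI (header = ROI label),
    one row per time point."""
    df = pd.read_csv(path, sep="\t")
    roi_ids = np.array([int(c) for c in df.columns])
    return RoiTimeSeriesSet(df.to_numpy(dtype=float).T, roi_ids, tr_seconds)


def write_roi_tsv(ts: RoiTimeSeriesSet, path: str | Path) -> None:
    df = pd.DataFrame(ts.values.T, columns=[str(r) for r in ts.roi_ids])
    df.to_csv(path, sep="\t", index=False)
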