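"""Synthetic cohorts: toy atlases and coupled ROI time series with injected
group and severity effects.

The simulator emulates ROI-mean BOLD series *after* preprocessing.  Each ROI
has a private first-order autoregressive latent signal; a subject's observed
series are mixtures of these latents weighted by a symmetric coupling matrix
(unit diagonal), plus white observation noise:

    x_i(t) = sum_j C_ij u_j(t) + noise_sd * eps_i(t)

Coupling raises shared temporal structure between ROI pairs and therefore
lowers their cross-sample entropy.  For depressed subjects the coupling of
the designated effect pairs is shifted by ``effect_size`` scaled linearly by
symptom severity, (hamd - 7) / 13, so a HAM-D of 20 carries the full effect
and scores near the diagnostic threshold carry almost none.  This gives the
severity regression a recoverable monotone signal.

HAM-D conventions follow the 17-item scale: controls score <= 7, depressed
subjects (non-remitted) score >= 8; the depressed scores are drawn uniformly
over ``hamd_range`` (the study population observed 8-20).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .prep import RoiTimeSeriesSet, write_roi_tsv

__all__ = [
    "SimConfig",
    "Subject",
    "SyntheticCohort",
    "LabelVolume",
    "make_toy_atlas",
    "simulate_subject",
    "simulate_cohort",
    "save_cohort",
]

#: AR(1) coefficient of the latent ROI signals
AR_COEF = 0.4
#: HAM-D threshold separating remitted/controls (<= 7) from depressed (>= 8)
HAMD_THRESHOLD = 7
#: linear severity scaling denominator: full effect at HAM-D 20
HAMD_SCALE = 13


@dataclass
class LabelVolume:
    """3D integer atlas grid mapping voxels to ROI identifiers (0 = background)."""

    data: np.ndarray
    affine: np.ndarray = field(
        default_factory=lambda: np.diag([2.0, 2.0, 2.0, 1.0])
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("atlas must be a 3D grid")

    @property
    def roi_ids(self) -> np.ndarray:
        labels = np.unique(self.data)
        return labels[labels > 0].astype(int)

    def to_nifti(self, path: str | Path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.data.astype(np.int16), self.affine), str(path))


@dataclass
class SimConfig:
    """Cohort simulation parameters.

    ``n_timepoints`` must be divisible by 4 because the three-segment
    augmentation uses offsets of N/4.  ``coupling_matrix`` is symmetric with
    unit diagonal and entries in [0, 1]; if omitted it defaults to the
    identity (independent ROIs).
    """

    n_roi: int = 90
    n_timepoints: int = 180
    tr_seconds: float = 2.0
    coupling_matrix: np.ndarray | None = None
    effect_pairs: tuple[tuple[int, int], ...] = ()
    effect_size: float = 0.0
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_roi < 1:
            raise ValueError("n_roi must be positive")
        if self.n_timepoints % 4 != 0:
            raise ValueError(
                f"n_timepoints {self.n_timepoints} must be divisible by 4 "
                "(augmentation uses N/4 offsets)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.coupling_matrix is None:
            self.coupling_matrix = np.eye(self.n_roi)
        self.coupling_matrix = np.asarray(self.coupling_matrix, dtype=float)
        c = self.coupling_matrix
        if c.shape != (self.n_roi, self.n_roi):
            raise ValueError("coupling_matrix must be n_roi x n_roi")
        if not np.allclose(c, c.T):
            raise ValueError("coupling_matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("coupling_matrix must have unit diagonal")
        if c.min() < 0 or c.max() > 1:
            raise ValueError("coupling strengths must lie in [0, 1]")
        for i, j in self.effect_pairs:
            if not (1 <= i <= self.n_roi and 1 <= j <= self.n_roi) or i == j:
                raise ValueError(f"invalid effect pair ({i}, {j})")


@dataclass
class Subject:
    subject_id: str
    group: str  # "control" | "depressed"
    hamd: int
    series: RoiTimeSeriesSet


@dataclass
class SyntheticCohort:
    subjects: list[Subject]
    label_volume: LabelVolume
    config: SimConfig

    def by_group(self, group: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == group]


def make_toy_atlas(
    shape: tuple[int, int, int], n_roi: int, seed: int = 0
) -> LabelVolume:
    """Partition a 3D grid into ``n_roi`` contiguous axis-aligned blocks
    labelled 1..n_roi (leftover blocks stay background 0)."""
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 1:
        raise ValueError(f"invalid grid shape {shape}")
    if int(np.prod(shape)) < n_roi:
        raise ValueError(
            f"grid {shape} has {int(np.prod(shape))} voxels, fewer than "
            f"{n_roi} ROIs"
        )
    if n_roi < 1:
        raise ValueError("n_roi must be positive")
    # split axes until the block grid can host every ROI
    divisions = [1, 1, 1]
    while int(np.prod(divisions)) < n_roi:
        axis = int(np.argmax([shape[a] / divisions[a] for a in range(3)]))
        if divisions[axis] >= shape[axis]:
            order = np.argsort([shape[a] / divisions[a] for a in range(3)])[::-1]
            for a in order:
                if divisions[a] < shape[a]:
                    axis = int(a)
                    break
        divisions[axis] += 1
    edges = [
        np.linspace(0, shape[a], divisions[a] + 1).round().astype(int)
        for a in range(3)
    ]
    grid = np.zeros(shape, dtype=np.int32)
    label = 1
    for ix in range(divisions[0]):
        for iy in range(divisions[1]):
            for iz in range(divisions[2]):
                if label > n_roi:
                    break
                grid[
                    edges[0][ix] : edges[0][ix + 1],
                    edges[1][iy] : edges[1][iy + 1],
                    edges[2][iz] : edges[2][iz + 1],
                ] = label
                label += 1
    return LabelVolume(grid)


def _subject_coupling(cfg: SimConfig, group: str, hamd: int) -> np.ndarray:
    c = cfg.coupling_matrix.copy()
    if group == "depressed" and cfg.effect_pairs:
        scale = (hamd - HAMD_THRESHOLD) / HAMD_SCALE
        for i, j in cfg.effect_pairs:
            shifted = np.clip(c[i - 1, j - 1] + cfg.effect_size * scale, 0.0, 1.0)
            c[i - 1, j - 1] = c[j - 1, i - 1] = shifted
    return c


def _ar1(rng: np.random.Generator, n_series: int, n_t: int) -> np.ndarray:
    """Stationary AR(1) latents with unit marginal variance."""
    innov_sd = np.sqrt(1.0 - AR_COEF**2)
    u = np.empty((n_series, n_t))
    u[:, 0] = rng.normal(0.0, 1.0, n_series)
    eps = rng.normal(0.0, innov_sd, (n_series, n_t))
    for t in range(1, n_t):
        u[:, t] = AR_COEF * u[:, t - 1] + eps[:, t]
    return u


def simulate_subject(
    cfg: SimConfig, group: str, hamd: int, seed: int | None = None
) -> RoiTimeSeriesSet:
    """One subject's ROI series under the latent-mixing model (reproducible
    for a given seed)."""
    if group not in ("control", "depressed"):
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    c = _subject_coupling(cfg, group, hamd)
    latents = _ar1(rng, cfg.n_roi, cfg.n_timepoints)
    values = c @ latents
    if cfg.noise_sd > 0:
        values = values + rng.normal(
            0.0, cfg.noise_sd, (cfg.n_roi, cfg.n_timepoints)
        )
    roi_ids = np.arange(1, cfg.n_roi + 1)
    return RoiTimeSeriesSet(values, roi_ids, cfg.tr_seconds)


def simulate_cohort(
    cfg: SimConfig,
    n_control: int,
    n_depressed: int,
    hamd_range: tuple[int, int] = (8, 20),
    seed: int | None = None,
    atlas_shape: tuple[int, int, int] = (16, 20, 16),
) -> SyntheticCohort:
    """A labelled cohort: controls with HAM-D <= 7, depressed subjects with
    HAM-D drawn uniformly over ``hamd_range`` (17-item scale, so within
    [8, 52])."""
    low, high = hamd_range
    if not (HAMD_THRESHOLD + 1 <= low <= high <= 52):
        raise ValueError(f"hamd_range {hamd_range} must lie within [8, 52]")
    master = np.random.default_rng(cfg.seed if seed is None else seed)
    atlas = make_toy_atlas(atlas_shape, cfg.n_roi, seed=0)
    subjects: list[Subject] = []
    for k in range(n_control):
        hamd = int(master.integers(0, HAMD_THRESHOLD + 1))
        sseed = int(master.integers(0, 2**31 - 1))
        subjects.append(
            Subject(
                f"ctrl{k:03d}",
                "control",
                hamd,
                simulate_subject(cfg, "control", hamd, seed=sseed),
            )
        )
    for k in range(n_depressed):
        hamd = int(master.integers(low, high + 1))
        sseed = int(master.integers(0, 2**31 - 1))
        subjects.append(
            Subject(
                f"dep{k:03d}",
                "depressed",
                hamd,
                simulate_subject(cfg, "depressed", hamd, seed=sseed),
            )
        )
    return SyntheticCohort(subjects, atlas, cfg)


def save_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write atlas (NIfTI), per-subject series (TSV) and metadata (TSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.label_volume.to_nifti(out / "atlas.nii.gz")
    rows = []
    for s in cohort.subjects:
        write_roi_tsv(s.series, out / f"{s.subject_id}.tsv")
        rows.append({"subject_id": s.subject_id, "group": s.group, "hamd": s.hamd})
    pd.DataFrame(rows).to_csv(out / "participants.tsv", sep="\t", index=False)
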