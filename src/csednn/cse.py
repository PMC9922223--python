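"""Cross-sample entropy (CSE) between ROI time series.

CSE(m, r, L) = -ln(p^{m+1} / p^m) measures the asynchrony of two time
series: p^l is the probability that an l-point template from one series
matches (Chebyshev distance < r) an l-point template from the other.
Low CSE means the two series share temporal structure; high CSE means
they evolve independently.

Two match-counting conventions are supported:

``paper``
    both template indices run over 1..L-l at every template length, so the
    normalisation at length m+1 uses L-(m+1) templates.  Small-L values can
    be negative.
``richman_moorman``
    both index ranges are truncated to L-m templates at both lengths, so
    every (m+1)-match is nested inside an m-match and CSE >= 0.

This module also provides the surrounding machinery: per-series
z-normalisation, the three-segment overlapping augmentation, the ROI x ROI
CSE matrix, control-cohort standardisation, and painting a seed ROI's CSE
column onto an atlas grid to form a 3D CSE volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "CseParams",
    "CseMatrix",
    "CohortStandardizer",
    "CseVolume",
    "UndefinedEntropyError",
    "normalize_series",
    "chebyshev_distance",
    "match_fraction",
    "cross_sample_entropy",
    "augment_segments",
    "augment_roi_set",
    "build_cse_matrix",
    "segment_cse_matrices",
    "fit_standardizer",
    "standardize",
    "build_cse_volume",
]

#: standard deviation floor applied when standardising against controls
SD_FLOOR = 1e-6


class UndefinedEntropyError(ValueError):
    """Raised when a template length yields zero matches, so -ln(p) diverges."""


@dataclass(frozen=True)
class CseParams:
    """Template length ``m``, tolerance ``r`` (in SD units of the normalised
    series) and the match-counting convention."""

    m: int = 2
    r: float = 0.6
    convention: str = "paper"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"template length m must be >= 1, got {self.m}")
        if self.r <= 0:
            raise ValueError(f"tolerance r must be > 0, got {self.r}")
        if self.convention not in ("paper", "richman_moorman"):
            raise ValueError(f"unknown convention {self.convention!r}")


@dataclass
class CseMatrix:
    """Symmetric ROI x ROI matrix of CSE values.

    The diagonal holds each ROI's CSE with itself (self-matches included).
    Undefined entries (no template matches) are stored as NaN and imputed
    with the control-cohort mean at standardisation time.
    """

    values: np.ndarray
    params: CseParams
    roi_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi_ids = np.asarray(self.roi_ids, dtype=int)
        n = len(self.roi_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} ROI ids"
            )

    def column(self, roi: int) -> np.ndarray:
        idx = int(np.flatnonzero(self.roi_ids == roi)[0])
        return self.values[:, idx]


@dataclass
class CohortStandardizer:
    """Entrywise mean/SD of the control subjects' CSE matrices."""

    mean: np.ndarray
    sd: np.ndarray
    roi_ids: np.ndarray
    n_matrices: int = 0


@dataclass
class CseVolume:
    """A seed ROI's CSE column painted onto the atlas geometry."""

    grid: np.ndarray
    seed_roi: int
    source_segment: int | None = None

    def to_nifti(self, path, affine: np.ndarray | None = None) -> None:
        """Write as NIfTI, inheriting the atlas affine when given."""
        import nibabel as nib

        affine = np.eye(4) if affine is None else np.asarray(affine)
        nib.save(
            nib.Nifti1Image(self.grid.astype(np.float32), affine), str(path)
        )


def normalize_series(x: np.ndarray) -> np.ndarray:
    """Z-normalise to mean 0, population SD 1."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot normalize a zero-variance series")
    return (x - x.mean()) / sd


def chebyshev_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Maximum absolute componentwise difference."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.abs(u - v).max())


def _count_matches(
    x: np.ndarray, y: np.ndarray, l: int, r: float, n_templates: int
) -> int:
    """Number of (i, j) template pairs with Chebyshev distance < r.

    Both index ranges are truncated to the first ``n_templates`` templates.
    Chunked over i so series of length 10^4 stay within a small memory
    footprint.
    """
    tx = sliding_window_view(x, l)[:n_templates]
    ty = sliding_window_view(y, l)[:n_templates]
    total = 0
    chunk = max(1, (1 << 22) // max(1, n_templates * l))
    for s in range(0, n_templates, chunk):
        d = np.abs(tx[s : s + chunk, None, :] - ty[None, :, :]).max(axis=2)
        total += int((d < r).sum())
    return total


def match_fraction(
    x: np.ndarray,
    y: np.ndarray,
    l: int,
    r: float,
    convention: str = "paper",
    m: int | None = None,
) -> float:
    """Template-match probability p^l between series ``x`` and ``y``.

    Under ``paper`` both template indices run over the first L-l positions
    and p^l = sum_i n_i^l / (L-l)^2.  Under ``richman_moorman`` the index
    ranges at both lengths are truncated to L-m templates (``m`` defaults to
    ``l``), which keeps (m+1)-matches nested inside m-matches.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValueError("x and y must be 1-D series of equal length")
    L = len(x)
    if L <= l:
        raise ValueError(f"series length {L} must exceed template length {l}")
    if convention == "paper":
        n_templates = L - l
    elif convention == "richman_moorman":
        base = l if m is None else m
        n_templates = L - base
        if l > base + 1 or n_templates + l - 1 > L:
            raise ValueError(f"inconsistent l={l}, m={base} for length {L}")
    else:
        raise ValueError(f"unknown convention {convention!r}")
    count = _count_matches(x, y, l, r, n_templates)
    return count / (n_templates * n_templates)


def cross_sample_entropy(
    x: np.ndarray, y: np.ndarray, params: CseParams = CseParams()
) -> float:
    """CSE(m, r, L) = -ln(p^{m+1} / p^m); symmetric in its arguments.

    Expects z-normalised inputs (``r`` is in SD units).  Raises
    :class:`UndefinedEntropyError` when either template length has no
    matches, rather than returning an infinity.
    """
    m, r = params.m, params.r
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(x) <= m + 1:
        raise ValueError(f"series length {len(x)} must exceed m+1={m + 1}")
    p_m = match_fraction(x, y, m, r, params.convention, m=m)
    p_m1 = match_fraction(x, y, m + 1, r, params.convention, m=m)
    if p_m == 0 or p_m1 == 0:
        raise UndefinedEntropyError(
            f"no template matches at m={m} (p^m={p_m}, p^(m+1)={p_m1}); "
            "CSE is undefined for this pair"
        )
    return float(-np.log(p_m1 / p_m))


def augment_segments(x: np.ndarray) -> list[np.ndarray]:
    """Partition a length-N series into three length-N/2 segments
    overlapping by N/4 (offsets 0, N/4, N/2), tripling the sample count."""
    x = np.asarray(x)
    n = x.shape[-1]
    if n % 4 != 0:
        raise ValueError(f"series length {n} must be divisible by 4")
    half, quarter = n // 2, n // 4
    return [
        x[..., :half].copy(),
        x[..., quarter : quarter + half].copy(),
        x[..., half:].copy(),
    ]


def augment_roi_set(values: np.ndarray) -> list[np.ndarray]:
    """Apply the three-segment augmentation to every row of an
    (n_roi, n_timepoints) matrix at once."""
    return augment_segments(np.asarray(values, dtype=float))


def build_cse_matrix(
    values: np.ndarray,
    roi_ids: Sequence[int],
    params: CseParams = CseParams(),
) -> CseMatrix:
    """Pairwise CSE between every pair of ROI series (rows of ``values``).

    Each row is z-normalised independently before matching.  The matrix is
    symmetric; the diagonal is each ROI's CSE with itself.  Pairs with no
    matches become NaN with a warning and are imputed by the control mean
    when standardised.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("ROI series contain non-finite values")
    n_roi = values.shape[0]
    roi_ids = np.asarray(roi_ids, dtype=int)
    if len(roi_ids) != n_roi:
        raise ValueError("roi_ids length does not match number of rows")
    normed = np.stack([normalize_series(row) for row in values])
    out = np.empty((n_roi, n_roi), dtype=float)
    for i in range(n_roi):
        for j in range(i, n_roi):
            try:
                v = cross_sample_entropy(normed[i], normed[j], params)
            except UndefinedEntropyError:
                warnings.warn(
                    f"CSE undefined for ROI pair ({roi_ids[i]}, {roi_ids[j]}); "
                    "recorded as missing",
                    RuntimeWarning,
                    stacklevel=2,
                )
                v = np.nan
            out[i, j] = out[j, i] = v
    return CseMatrix(out, params, roi_ids)


def segment_cse_matrices(
    values: np.ndarray,
    roi_ids: Sequence[int],
    params: CseParams = CseParams(),
) -> list[CseMatrix]:
    """Augment an (n_roi, N) series matrix into three overlapping segments
    and build one CSE matrix per segment (each segment row re-normalised)."""
    return [
        build_cse_matrix(seg, roi_ids, params) for seg in augment_roi_set(values)
    ]


def fit_standardizer(control_matrices: Iterable[CseMatrix]) -> CohortStandardizer:
    """Entrywise mean and sample SD (ddof=1) over the control cohort's CSE
    matrices, with the SD floored at ``SD_FLOOR``."""
    mats = list(control_matrices)
    if len(mats) < 2:
        raise ValueError("need at least two control matrices")
    roi_ids = mats[0].roi_ids
    params = mats[0].params
    for m in mats[1:]:
        if not np.array_equal(m.roi_ids, roi_ids) or m.params != params:
            raise ValueError("control matrices differ in shape or parameters")
    stack = np.stack([m.values for m in mats])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    sd = np.where(np.isfinite(sd), sd, SD_FLOOR)
    mean = np.where(np.isfinite(mean), mean, 0.0)
    sd = np.maximum(sd, SD_FLOOR)
    return CohortStandardizer(mean=mean, sd=sd, roi_ids=roi_ids, n_matrices=len(mats))


def standardize(matrix: CseMatrix, std: CohortStandardizer) -> CseMatrix:
    """Entrywise (value - control mean) / control SD.

    Missing (NaN) entries map to 0, i.e. the control mean — the neutral
    value after standardisation.
    """
    if not np.array_equal(matrix.roi_ids, std.roi_ids):
        raise ValueError("ROI ids of matrix and standardizer differ")
    z = (matrix.values - std.mean) / std.sd
    z = np.where(np.isnan(z), 0.0, z)
    return CseMatrix(z, matrix.params, matrix.roi_ids)


def build_cse_volume(
    matrix: CseMatrix,
    seed_roi: int,
    atlas: np.ndarray,
    fill: float = 0.0,
    source_segment: int | None = None,
) -> CseVolume:
    """Paint the seed ROI's CSE column onto the atlas grid.

    Every voxel labelled j receives CSE(j, seed); voxels of the seed ROI
    itself receive the diagonal entry; background (label 0 or any label not
    in ``roi_ids``) receives ``fill`` (0 = the control mean after
    standardisation, a neutral input for convolution).
    """
    atlas = np.asarray(atlas)
    if seed_roi not in matrix.roi_ids:
        raise ValueError(f"seed ROI {seed_roi} not among matrix ROI ids")
    column = matrix.column(seed_roi)
    max_label = int(atlas.max()) if atlas.size else 0
    lut = np.full(max(max_label, int(matrix.roi_ids.max())) + 1, fill, dtype=float)
    lut[matrix.roi_ids] = column
    grid = lut[atlas]
    return CseVolume(grid=grid, seed_roi=int(seed_roi), source_segment=source_segment)
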