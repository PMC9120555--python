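"""Single-subject feature extraction from post-processed BOLD images.

Six features: task GLM activation, seed-based connectivity, dual
regression against network templates, atlas-based connectivity matrices,
regional homogeneity (ReHo), and fractional amplitude of low-frequency
fluctuations (fALFF).

Per-feature preprocessing constraints are enforced here: atlas matrices
must not be computed on spatially smoothed data, and ReHo / fALFF are
computed on unsmoothed data with smoothing (if any) deferred to the
resulting statistical maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .postproc import Bold4D, DEFAULT_FALFF_BAND

__all__ = [
    "RoiImage",
    "EventTable",
    "StatMap",
    "extract_mean_series",
    "seed_connectivity",
    "dual_regression",
    "atlas_matrix",
    "reho",
    "falff",
    "task_glm",
    "double_gamma_hrf",
    "MISSING",
]

#: Sentinel returned when a region fails its minimum-coverage threshold.
MISSING = None

DEFAULT_MIN_COVERAGE = 0.5


@dataclass
class RoiImage:
    """A region-of-interest image on the BOLD grid.

    ``kind`` is one of ``seed-mask`` (3D boolean), ``atlas-labels`` (3D
    positive-integer labels, 0 = background), or ``network-maps`` (4D stack
    of spatial maps, last axis indexes networks).  ``min_coverage`` is the
    minimum fraction of ROI voxels that must fall inside the subject's
    brain mask for the region to be usable.
    """

    kind: str
    data: np.ndarray
    min_coverage: float = DEFAULT_MIN_COVERAGE

    def __post_init__(self) -> None:
        if self.kind not in ("seed-mask", "atlas-labels", "network-maps"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        self.data = np.asarray(self.data)
        if self.kind == "seed-mask":
            self.data = self.data.astype(bool)
            if self.data.ndim != 3:
                raise ValueError("seed mask must be 3D")
        elif self.kind == "atlas-labels":
            self.data = self.data.astype(int)
            if self.data.ndim != 3 or (self.data < 0).any():
                raise ValueError("atlas labels must be 3D non-negative integers")
        else:
            self.data = self.data.astype(float)
            if self.data.ndim != 4 or self.data.shape[3] < 1:
                raise ValueError("network maps must be a 4D stack with >= 1 map")
        if not 0 <= self.min_coverage <= 1:
            raise ValueError("min_coverage must be in [0, 1]")


@dataclass
class EventTable:
    """Task events: onsets and durations in seconds, grouped by condition."""

    onsets: np.ndarray
    durations: np.ndarray
    conditions: list[str]

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.conditions = list(self.conditions)
        if not (len(self.onsets) == len(self.durations) == len(self.conditions)):
            raise ValueError("onsets, durations, conditions must align")
        if (self.onsets < 0).any():
            raise ValueError("onsets must be non-negative")
        if (self.durations < 0).any():
            raise ValueError("durations must be non-negative")

    @property
    def condition_names(self) -> list[str]:
        seen: list[str] = []
        for c in self.conditions:
            if c not in seen:
                seen.append(c)
        return seen

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EventTable":
        """Build from a BIDS-style events table (onset, duration, trial_type)."""
        return cls(
            onsets=frame["onset"].to_numpy(),
            durations=frame["duration"].to_numpy(),
            conditions=list(frame["trial_type"]),
        )


@dataclass
class StatMap:
    """A per-voxel effect estimate with its variance and coverage.

    The unit of exchange between single-subject features and group-level
    statistics: ``effect`` and ``variance`` are defined only where
    ``coverage`` is true (NaN elsewhere); ``dof`` is the residual degrees
    of freedom of the first-level fit.
    """

    effect: np.ndarray
    variance: np.ndarray
    dof: float
    coverage: np.ndarray
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.effect = np.asarray(self.effect, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=bool)
        if self.effect.shape != self.variance.shape or self.effect.shape != self.coverage.shape:
            raise ValueError("effect, variance, coverage must share a shape")
        inside = self.variance[self.coverage]
        if inside.size and np.nanmin(inside) < 0:
            raise ValueError("variance must be non-negative inside coverage")


# ---------------------------------------------------------------------------
# shared least-squares helper


def _ols_fit(design: np.ndarray, responses: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS of responses (t, n_series) on design (t, p).

    Returns (beta (p, n), per-coefficient sampling variances (p, n), dof).
    """
    t, p = design.shape
    rank = np.linalg.matrix_rank(design)
    if rank < p:
        raise ValueError(f"design matrix is rank deficient (rank {rank} < {p})")
    if t <= p:
        raise ValueError("need more time points than regressors")
    beta, *_ = np.linalg.lstsq(design, responses, rcond=None)
    resid = responses - design @ beta
    dof = t - p
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    var = np.outer(np.diag(xtx_inv), sigma2)
    return beta, var, dof


# ---------------------------------------------------------------------------
# ROI extraction


def extract_mean_series(
    img: Bold4D,
    roi: np.ndarray,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
):
    """Mean time series over an ROI, or :data:`MISSING` on poor coverage.

    Coverage is the fraction of ROI voxels inside the subject's brain
    mask; below ``min_coverage`` the region is reported missing rather
    than estimated from too few voxels.  Returns ``(series, coverage)``.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != img.spatial_shape:
        raise ValueError("ROI grid does not match the image grid")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    inside = roi & img.mask
    coverage = inside.sum() / n_roi
    if coverage < min_coverage:
        return MISSING, coverage
    return img.data[inside].mean(axis=0), coverage


# ---------------------------------------------------------------------------
# seed-based connectivity


def seed_connectivity(img: Bold4D, seed_series: np.ndarray, tags: dict | None = None) -> StatMap:
    """First-level GLM of every voxel on a seed time series.

    Design is [intercept, seed]; the map's effect is the seed coefficient,
    its variance the OLS sampling variance, dof = t - 2.
    """
    seed_series = np.asarray(seed_series, dtype=float)
    t = img.n_volumes
    if seed_series.shape != (t,):
        raise ValueError("seed series length must equal the number of volumes")
    if np.ptp(seed_series) == 0:
        raise ValueError("seed series is constant")
    design = np.column_stack([np.ones(t), seed_series])
    responses = img.data[img.mask].T  # (t, v)
    beta, var, dof = _ols_fit(design, responses)
    effect = np.full(img.spatial_shape, np.nan)
    variance = np.full(img.spatial_shape, np.nan)
    effect[img.mask] = beta[1]
    variance[img.mask] = var[1]
    return StatMap(effect, variance, dof, img.mask.copy(), tags=dict(tags or {}))


# ---------------------------------------------------------------------------
# dual regression


def dual_regression(img: Bold4D, networks: RoiImage) -> tuple[list[StatMap], np.ndarray]:
    """Dual regression of network template maps against individual data.

    Stage 1 regresses, frame by frame, the in-mask voxel vector on the
    spatially demeaned template maps plus an intercept, yielding one time
    series per network.  Stage 2 regresses each voxel's time series on
    those network time series plus an intercept, yielding per-network
    effect and variance maps (dof = t - k - 1).

    A map that is spatially constant in-mask would duplicate the
    intercept; in that case the raw map replaces the intercept column for
    stage 1, so a single all-ones map yields the global mean signal.

    Returns ``(list of k StatMaps, (k, t) array of network time series)``.
    """
    if networks.kind != "network-maps":
        raise ValueError("dual regression requires a network-maps ROI image")
    if networks.data.shape[:3] != img.spatial_shape:
        raise ValueError("network map grid does not match the image grid")
    k = networks.data.shape[3]
    t = img.n_volumes
    if t <= k + 1:
        raise ValueError("need more time points than networks")
    maps = networks.data[img.mask]  # (v, k)
    demeaned = maps - maps.mean(axis=0, keepdims=True)
    constant = np.ptp(maps, axis=0) == 0
    design_cols = np.where(constant[None, :], maps, demeaned)
    v = maps.shape[0]
    if constant.any():
        stage1_design = design_cols  # constant map plays the intercept role
    else:
        stage1_design = np.column_stack([np.ones(v), design_cols])
    rank = np.linalg.matrix_rank(stage1_design)
    if rank < stage1_design.shape[1]:
        raise ValueError("network maps are collinear over in-mask voxels")

    frames = img.data[img.mask]  # (v, t)
    coef, *_ = np.linalg.lstsq(stage1_design, frames, rcond=None)
    timeseries = coef[stage1_design.shape[1] - k :]  # (k, t)

    stage2_design = np.column_stack([np.ones(t), timeseries.T])
    beta, var, dof = _ols_fit(stage2_design, frames.T)
    statmaps = []
    for j in range(k):
        effect = np.full(img.spatial_shape, np.nan)
        variance = np.full(img.spatial_shape, np.nan)
        effect[img.mask] = beta[1 + j]
        variance[img.mask] = var[1 + j]
        statmaps.append(
            StatMap(effect, variance, dof, img.mask.copy(), tags={"network": j})
        )
    return statmaps, timeseries


# ---------------------------------------------------------------------------
# atlas connectivity matrix


def atlas_matrix(
    img: Bold4D,
    atlas: RoiImage,
    min_coverage: float | None = None,
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Pairwise Pearson correlation matrix between atlas region mean series.

    Regions whose brain-mask coverage falls below the threshold get NaN
    rows/columns (missing, not zero).  Returns ``(matrix, coverage per
    label)``; the matrix is symmetric with unit diagonal for present
    regions.
    """
    if atlas.kind != "atlas-labels":
        raise ValueError("atlas_matrix requires an atlas-labels ROI image")
    if atlas.data.shape != img.spatial_shape:
        raise ValueError("atlas grid does not match the image grid")
    if min_coverage is None:
        min_coverage = atlas.min_coverage
    labels = sorted(int(l) for l in np.unique(atlas.data) if l > 0)
    if len(labels) < 2:
        raise ValueError("need at least 2 labelled regions")
    series: dict[int, np.ndarray | None] = {}
    coverage: dict[int, float] = {}
    for lab in labels:
        s, cov = extract_mean_series(img, atlas.data == lab, min_coverage)
        series[lab] = s
        coverage[lab] = cov
    present = [lab for lab in labels if series[lab] is not None]
    if len(present) < 2:
        raise ValueError("fewer than 2 regions survive the coverage threshold")
    frame = pd.DataFrame(
        {lab: (series[lab] if series[lab] is not None else np.full(img.n_volumes, np.nan))
         for lab in labels}
    )
    corr = frame.corr()  # pairwise Pearson; NaN rows stay NaN
    for lab in labels:
        if series[lab] is None:
            corr.loc[lab, :] = np.nan
            corr.loc[:, lab] = np.nan
    return corr, coverage


# ---------------------------------------------------------------------------
# regional homogeneity (ReHo)


_NEIGHBORHOOD_OFFSETS = {
    7: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) <= 1],
    19: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
         if abs(dx) + abs(dy) + abs(dz) <= 2],
    27: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)],
}


def kendall_w(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance of m series over n time points.

    Ranks use midranks for ties; the denominator carries the standard tie
    correction m^2 (n^3 - n) - m * sum(t_j^3 - t_j) over tie groups.
    """
    series = np.asarray(series, dtype=float)
    m, n = series.shape
    if m < 2:
        raise ValueError("need at least 2 series")
    ranks = np.apply_along_axis(stats.rankdata, 1, series)
    rank_sums = ranks.sum(axis=0)
    s = ((rank_sums - rank_sums.mean()) ** 2).sum()
    tie_term = 0.0
    for row in series:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * tie_term
    if denom <= 0:
        return np.nan
    return float(12.0 * s / denom)


def reho(img: Bold4D, neighborhood: int = 27) -> np.ndarray:
    """Regional homogeneity map: Kendall's W of each voxel with its neighbours.

    ``neighborhood`` is 7 (faces), 19 (faces+edges), or 27 (full cube).
    Neighbours outside the brain mask are dropped; a voxel with fewer than
    2 in-mask series is NaN.  Must be run on spatially *unsmoothed* data —
    smoothing, if requested, is applied to the resulting map afterwards.
    """
    if neighborhood not in _NEIGHBORHOOD_OFFSETS:
        raise ValueError("neighborhood must be one of 7, 19, 27")
    if img.n_volumes < 3:
        raise ValueError("need at least 3 time points for ReHo")
    offsets = _NEIGHBORHOOD_OFFSETS[neighborhood]
    mask = img.mask
    nx, ny, nz = img.spatial_shape
    # rank the time series once per voxel, then only rank sums are needed
    n = img.n_volumes
    out = np.full(img.spatial_shape, np.nan)
    coords = np.argwhere(mask)
    data = img.data
    for (x, y, z) in coords:
        members = []
        for dx, dy, dz in offsets:
            xx, yy, zz = x + dx, y + dy, z + dz
            if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz and mask[xx, yy, zz]:
                members.append(data[xx, yy, zz])
        if len(members) < 2:
            continue
        out[x, y, z] = kendall_w(np.asarray(members))
    return out


# ---------------------------------------------------------------------------
# fALFF


def falff(
    img: Bold4D,
    band: tuple[float, float] = DEFAULT_FALFF_BAND,
) -> tuple[np.ndarray, np.ndarray]:
    """fALFF and ALFF maps from the amplitude spectrum of each voxel.

    ALFF is the sum of spectral amplitudes of the demeaned series in the
    low-frequency band (inclusive bounds, default 0.01-0.1 Hz); fALFF
    divides it by the amplitude sum over *all* positive frequencies, so it
    lies in [0, 1].  Voxels with zero total power are NaN.  Like ReHo,
    computed before any spatial smoothing.
    """
    low, high = band
    nyquist = 0.5 / img.repetition_time
    if not 0 < low < high <= nyquist + 1e-12:
        raise ValueError(f"band {band} must satisfy 0 < low < high <= Nyquist={nyquist:g}")
    series = img.data[img.mask]
    demeaned = series - series.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(demeaned, axis=1))
    freqs = np.fft.rfftfreq(img.n_volumes, d=img.repetition_time)
    positive = freqs > 0
    in_band = (freqs >= low - 1e-12) & (freqs <= high + 1e-12) & positive
    alff_vals = spec[:, in_band].sum(axis=1)
    total = spec[:, positive].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        falff_vals = np.where(total > 0, alff_vals / np.where(total > 0, total, 1.0), np.nan)
    alff_map = np.full(img.spatial_shape, np.nan)
    falff_map = np.full(img.spatial_shape, np.nan)
    alff_map[img.mask] = alff_vals
    falff_map[img.mask] = falff_vals
    return falff_map, alff_map


# ---------------------------------------------------------------------------
# task GLM


def double_gamma_hrf(times: np.ndarray, peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                     peak_disp: float = 1.0, undershoot_disp: float = 1.0,
                     undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, normalized to peak 1."""
    times = np.asarray(times, dtype=float)
    peak = stats.gamma.pdf(times, peak_delay / peak_disp, scale=peak_disp)
    under = stats.gamma.pdf(times, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    h = peak - undershoot_ratio * under
    m = h.max()
    if m > 0:
        h = h / m
    return h


def _condition_regressors(events: EventTable, t: int, tr: float) -> tuple[np.ndarray, list[str]]:
    names = events.condition_names
    frame_times = np.arange(t) * tr
    hrf = double_gamma_hrf(np.arange(0, min(32.0, t * tr), tr))
    regs = np.zeros((t, len(names)))
    for j, name in enumerate(names):
        boxcar = np.zeros(t)
        for onset, dur, cond in zip(events.onsets, events.durations, events.conditions):
            if cond != name:
                continue
            active = (frame_times >= onset) & (frame_times < onset + max(dur, tr / 2))
            boxcar[active] = 1.0
        regs[:, j] = np.convolve(boxcar, hrf)[:t]
    return regs, names


def task_glm(
    img: Bold4D,
    events: EventTable,
    contrasts: dict[str, dict[str, float]],
) -> dict[str, StatMap]:
    """First-level task GLM with double-gamma HRF convolution and OLS fit.

    Each condition's boxcar (sampled on the frame grid) is convolved with
    the canonical HRF; the design adds an intercept.  For each named
    contrast (a mapping condition -> weight) the map holds effect c'beta,
    variance sigma^2 c'(X'X)^-1 c, and dof = t - rank(X).
    """
    t = img.n_volumes
    regs, names = _condition_regressors(events, t, img.repetition_time)
    for cname, weights in contrasts.items():
        unknown = set(weights) - set(names)
        if unknown:
            raise ValueError(f"contrast {cname!r} references unknown conditions {sorted(unknown)}")
    design = np.column_stack([np.ones(t), regs])
    responses = img.data[img.mask].T
    p = design.shape[1]
    rank = np.linalg.matrix_rank(design)
    if rank < p:
        raise ValueError("task design matrix is rank deficient")
    if t <= p:
        raise ValueError("need more time points than regressors")
    beta, *_ = np.linalg.lstsq(design, responses, rcond=None)
    resid = responses - design @ beta
    dof = t - p
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    out: dict[str, StatMap] = {}
    for cname, weights in contrasts.items():
        c = np.zeros(p)
        for cond, w in weights.items():
            c[1 + names.index(cond)] = w
        eff = c @ beta
        var = float(c @ xtx_inv @ c) * sigma2
        effect = np.full(img.spatial_shape, np.nan)
        variance = np.full(img.spatial_shape, np.nan)
        effect[img.mask] = eff
        variance[img.mask] = var
        out[cname] = StatMap(effect, variance, dof, img.mask.copy(), tags={"contrast": cname})
    return out
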