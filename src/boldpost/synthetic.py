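"""Synthetic data with known ground truth for every stage of the workflow.

The BOLD generator builds images as a sum of smooth spatial network maps
times latent time courses, plus low-frequency drift and white noise; the
drift regressors double as labelled noise components of a synthetic ICA
decomposition and as confound columns.  The group generator draws
subject effects from the two-level mixed model the group stage assumes,
with configurable voxel-wise MCAR missingness.  All generators are pure
functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import StatMap
from .group_stats import CovariateTable
from .postproc import Bold4D, ConfoundTable, IcaDecomposition

__all__ = ["SyntheticTruth", "make_bold", "make_group", "make_layout"]

DEFAULT_SHAPE = (16, 16, 12)
DEFAULT_T = 120
DEFAULT_TR = 2.0


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic dataset, serializable to JSON."""

    seed: int
    params: dict = field(default_factory=dict)
    network_series: np.ndarray | None = None
    network_maps: np.ndarray | None = None
    drift: np.ndarray | None = None
    betas: np.ndarray | None = None
    sigma_b2: float | None = None
    within_vars: np.ndarray | None = None
    design: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {"seed": self.seed, "params": self.params}
        for name in ("network_series", "network_maps", "drift", "betas",
                     "within_vars", "design"):
            val = getattr(self, name)
            if val is not None:
                payload[name] = np.asarray(val).tolist()
        if self.sigma_b2 is not None:
            payload["sigma_b2"] = self.sigma_b2
        Path(path).write_text(json.dumps(payload))


def _gaussian_bump(shape: tuple[int, int, int], centre: np.ndarray, width: float) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
    return np.exp(-d2 / (2.0 * width**2))


def make_bold(
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    t: int = DEFAULT_T,
    tr: float = DEFAULT_TR,
    networks: int = 3,
    drift_amplitude: float = 2.0,
    noise_sd: float = 1.0,
    baseline: float = 100.0,
    seed: int = 0,
) -> tuple[Bold4D, ConfoundTable, IcaDecomposition, SyntheticTruth]:
    """Generate a BOLD image with known network structure, drift, and noise.

    ``data = baseline + sum_k map_k * series_k + drift + white noise``.
    The drift mixes a linear trend and slow cosines (1/f-flavoured), so
    both the frequency and the Gaussian-weighted highpass have work to
    do.  The returned ICA decomposition stacks the true network series
    (signal) and the drift regressors (labelled noise); the confound
    table carries the drift regressors and six synthetic motion
    parameters.
    """
    if t <= 10:
        raise ValueError("need t > 10")
    if any(s < 8 for s in shape):
        raise ValueError("each spatial axis must have at least 8 voxels")
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)

    # brain mask: central ellipsoid
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    centre = [(s - 1) / 2 for s in shape]
    radii = [0.45 * s for s in shape]
    mask = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centre, radii)) <= 1.0

    # smooth spatial maps (Gaussian bumps) and latent series
    maps = np.zeros(shape + (networks,))
    for k in range(networks):
        c = np.array([rng.uniform(0.25 * s, 0.75 * s) for s in shape])
        maps[..., k] = _gaussian_bump(shape, c, width=rng.uniform(1.5, 3.0))
        maps[..., k] *= mask
    series = rng.standard_normal((networks, t))

    # drift: linear trend plus slow cosines
    times = np.arange(t) * tr
    n_drift = 2
    drift = np.zeros((n_drift, t))
    drift[0] = np.linspace(-1.0, 1.0, t)
    drift[1] = np.cos(2 * np.pi * times / (times[-1] + tr) * 1.5)
    drift_maps = rng.uniform(0.5, 1.0, size=(n_drift,))

    data = np.full(shape + (t,), float(baseline))
    data += np.einsum("xyzk,kt->xyzt", maps, series)
    for d in range(n_drift):
        data += drift_amplitude * drift_maps[d] * drift[d]
    data += noise_sd * rng.standard_normal(shape + (t,))
    data[~mask] = 0.0

    img = Bold4D(data=data, repetition_time=tr, mask=mask, voxel_size=(3.0, 3.0, 3.0))

    motion = np.cumsum(0.01 * rng.standard_normal((t, 6)), axis=0)
    conf = pd.DataFrame(
        {f"drift_{d}": drift_amplitude * drift_maps[d] * drift[d] for d in range(n_drift)}
    )
    for j, name in enumerate(["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]):
        conf[name] = motion[:, j]
    confounds = ConfoundTable(conf)

    mixing = np.column_stack([series.T, drift.T])
    ica = IcaDecomposition(mixing=mixing, noise_indices=tuple(range(networks, networks + n_drift)))

    truth = SyntheticTruth(
        seed=seed,
        params={
            "shape": list(shape), "t": t, "tr": tr, "networks": networks,
            "drift_amplitude": drift_amplitude, "noise_sd": noise_sd,
            "baseline": baseline,
        },
        network_series=series,
        network_maps=maps,
        drift=drift,
    )
    return img, confounds, ica, truth


def make_group(
    n: int = 40,
    shape: tuple[int, int, int] = (8, 8, 6),
    betas: np.ndarray | float = 0.0,
    design: np.ndarray | None = None,
    covariates: CovariateTable | None = None,
    sigma_b2: float = 1.0,
    within_var_range: tuple[float, float] = (0.2, 1.0),
    missing_fraction: float = 0.0,
    dof: float = 100.0,
    seed: int = 0,
) -> tuple[list[StatMap], CovariateTable, SyntheticTruth]:
    """Generate per-subject effect maps under the two-level mixed model.

    At every voxel, subject i's effect is ``x_i' beta + b_i + e_i`` with
    ``b_i ~ N(0, sigma_b2)`` and ``e_i ~ N(0, s_i^2)``, where ``s_i^2``
    is drawn uniformly from ``within_var_range`` and reported as the
    subject's first-level variance.  Coverage is knocked out voxel-wise,
    independently per subject, with probability ``missing_fraction``
    (missing completely at random); patterns leaving a voxel with fewer
    than p + 1 subjects everywhere raise an error.
    """
    rng = np.random.default_rng(seed)
    if design is None:
        design = np.ones((n, 1))
    design = np.asarray(design, dtype=float)
    if design.shape[0] != n:
        raise ValueError("design rows must equal n")
    p = design.shape[1]
    if n < p + 2:
        raise ValueError("need n >= p + 2")
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    if betas.shape != (p,):
        raise ValueError(f"betas must have length {p}")

    shape = tuple(int(s) for s in shape)
    n_vox = int(np.prod(shape))
    mean = design @ betas  # (n,)
    within = rng.uniform(*within_var_range, size=n)

    effects = (
        mean[:, None]
        + np.sqrt(sigma_b2) * rng.standard_normal((n, n_vox))
        + np.sqrt(within)[:, None] * rng.standard_normal((n, n_vox))
    )
    coverage = rng.random((n, n_vox)) >= missing_fraction
    per_voxel = coverage.sum(axis=0)
    if (per_voxel < p + 1).any():
        raise ValueError(
            "infeasible missingness: some voxel has fewer than p + 1 subjects"
        )

    maps: list[StatMap] = []
    for i in range(n):
        eff = np.where(coverage[i], effects[i], np.nan).reshape(shape)
        var = np.where(coverage[i], within[i], np.nan).reshape(shape)
        maps.append(
            StatMap(
                effect=eff,
                variance=var,
                dof=dof,
                coverage=coverage[i].reshape(shape),
                tags={"subject": f"{i:03d}"},
            )
        )
    if covariates is None:
        covariates = CovariateTable(
            pd.DataFrame(index=[f"{i:03d}" for i in range(n)]), types={}
        )
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n": n, "shape": list(shape), "sigma_b2": sigma_b2,
            "within_var_range": list(within_var_range),
            "missing_fraction": missing_fraction,
        },
        betas=betas,
        sigma_b2=sigma_b2,
        within_vars=within,
        design=design,
    )
    return maps, covariates, truth


def make_layout(
    tmpdir: str | Path,
    subjects: tuple[str, ...] = ("subject01", "subject02", "subject03"),
    sessions: int = 1,
    include_phantom: bool = True,
    include_subfolder_trap: bool = True,
    tr: float = 2.0,
    broken_sidecar_tr: float | None = None,
) -> list[Path]:
    """Write a miniature file tree exercising the template matcher.

    Produces ``data/<subject>/bold_rest.nii.gz`` for each subject plus,
    by default, a rest scan for a phantom, a task scan for the first
    subject, and a decoy in a subfolder — the classic traps a template
    must navigate.  Tiny valid NIfTI files and JSON sidecars are written;
    ``broken_sidecar_tr`` deliberately mis-states the repetition time so
    metadata override paths can be exercised.
    """
    import nibabel as nib

    tmpdir = Path(tmpdir)
    written: list[Path] = []

    def write_scan(rel: str, session_tag: str = "") -> None:
        path = tmpdir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        data = np.zeros((4, 4, 4, 3), dtype=np.float32)
        nifti = nib.Nifti1Image(data, affine=np.eye(4))
        nifti.header["pixdim"][4] = tr
        nib.save(nifti, str(path))
        written.append(path)
        sidecar = path.with_name(path.name.replace(".nii.gz", ".json"))
        sidecar.write_text(
            json.dumps({"RepetitionTime": broken_sidecar_tr if broken_sidecar_tr else tr})
        )

    names = []
    for subject in subjects:
        if sessions > 1:
            for ses in range(1, sessions + 1):
                names.append(f"data/{subject}/ses{ses:02d}/bold_rest.nii.gz")
        else:
            names.append(f"data/{subject}/bold_rest.nii.gz")
    if subjects:
        if sessions > 1:
            names.append(f"data/{subjects[0]}/ses01/bold_task.nii.gz")
        else:
            names.append(f"data/{subjects[0]}/bold_task.nii.gz")
    if include_phantom:
        names.append("data/phantom/bold_rest.nii.gz")
    if include_subfolder_trap and subjects:
        names.append(f"data/subfolder/{subjects[0]}/bold_rest.nii.gz")
    for rel in names:
        write_scan(rel)
    return written
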