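"""Quantitative quality metrics and rating-based exclusion logic.

Metrics: framewise displacement (Power convention), DVARS (raw units),
temporal SNR, and the fraction of ICA components classified as noise.
Visual ratings (good / uncertain / bad) from one or more raters are
merged with a lower-rating-wins rule; a bad rating on an anatomical-class
report excludes the whole subject, a bad rating on a functional-class
report excludes only that scan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .postproc import Bold4D, IcaDecomposition

__all__ = [
    "MotionParams",
    "QualityRating",
    "RATING_ORDER",
    "framewise_displacement",
    "dvars",
    "tsnr",
    "noise_component_fraction",
    "merge_ratings",
    "exclusion_decisions",
    "load_rating_files",
]

DEFAULT_HEAD_RADIUS_MM = 50.0

#: Rating lattice: higher is better.  Conflicts resolve to the minimum.
RATING_ORDER = {"bad": 0, "uncertain": 1, "good": 2}


@dataclass
class MotionParams:
    """Rigid-body motion parameters: t x 6 (3 translations mm, 3 rotations rad)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError("motion parameters must be a t x 6 array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("motion parameters contain non-finite values")


@dataclass(frozen=True)
class QualityRating:
    """One rater's verdict on one report image."""

    subject: str
    rating: str
    image_type: str = "functional"  # "anatomical" or "functional" class
    scan: str | None = None
    rater: str | None = None

    def __post_init__(self) -> None:
        if self.rating not in RATING_ORDER:
            raise ValueError(f"rating must be one of {sorted(RATING_ORDER)}, got {self.rating!r}")
        if self.image_type not in ("anatomical", "functional"):
            raise ValueError("image_type must be 'anatomical' or 'functional'")


def framewise_displacement(
    motion: MotionParams, radius_mm: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Framewise displacement (Power convention), one value per frame pair.

    FD_i = sum |Delta translations| + radius * sum |Delta rotations|,
    with rotations converted to arc length on a sphere of ``radius_mm``.
    """
    if not radius_mm > 0:
        raise ValueError("head radius must be positive")
    vals = motion.values
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    diffs = np.abs(np.diff(vals, axis=0))
    return diffs[:, :3].sum(axis=1) + radius_mm * diffs[:, 3:].sum(axis=1)


def dvars(img: Bold4D) -> np.ndarray:
    """DVARS: RMS over in-mask voxels of the backward temporal difference."""
    series = img.in_mask_series()
    if series.shape[0] == 0:
        raise ValueError("empty mask")
    d = np.diff(series, axis=1)
    return np.sqrt((d**2).mean(axis=0))


def tsnr(img: Bold4D, tissue_mask: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Temporal SNR map (mean / sample sd over time) and its tissue-mask mean.

    Voxels with zero temporal variance are NaN.  ``tissue_mask`` defaults
    to the brain mask; typically a gray-matter mask is supplied.
    """
    if img.n_volumes < 3:
        raise ValueError("need at least 3 time points for tSNR")
    mean = img.data.mean(axis=3)
    sd = img.data.std(axis=3, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tmap = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.nan)
    tmap[~img.mask] = np.nan
    if tissue_mask is None:
        tissue_mask = img.mask
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    vals = tmap[tissue_mask & img.mask]
    summary = float(np.nanmean(vals)) if vals.size else float("nan")
    return tmap, summary


def noise_component_fraction(ica: IcaDecomposition) -> float:
    """Percentage of ICA components classified as noise."""
    return 100.0 * len(ica.noise_indices) / ica.n_components


# ---------------------------------------------------------------------------
# rating merge and exclusion


def merge_ratings(ratings: list[QualityRating]) -> dict[tuple, str]:
    """Consolidate ratings per (subject, scan, image_type): lower wins.

    The merge is the meet of the good > uncertain > bad lattice, so it is
    associative, commutative, and idempotent regardless of how many rating
    files or raters contributed.
    """
    merged: dict[tuple, str] = {}
    for r in ratings:
        key = (r.subject, r.scan, r.image_type)
        if key in merged:
            if RATING_ORDER[r.rating] < RATING_ORDER[merged[key]]:
                merged[key] = r.rating
        else:
            merged[key] = r.rating
    return merged


def exclusion_decisions(merged: dict[tuple, str]) -> dict[tuple[str, str | None], tuple[bool, str]]:
    """Turn consolidated ratings into per-scan include/exclude decisions.

    A bad anatomical-class rating excludes every scan of that subject; a
    bad functional-class rating excludes only that scan.  Good and
    uncertain ratings are included.  Returns a mapping (subject, scan) ->
    (included, reason).
    """
    bad_anat = {subj for (subj, _scan, itype), rating in merged.items()
                if itype == "anatomical" and rating == "bad"}
    decisions: dict[tuple[str, str | None], tuple[bool, str]] = {}
    for (subj, scan, itype), rating in merged.items():
        if itype != "functional":
            continue
        key = (subj, scan)
        if subj in bad_anat:
            decisions[key] = (False, "bad anatomical rating excludes the subject")
        elif rating == "bad":
            decisions[key] = (False, "bad functional rating excludes this scan")
        else:
            decisions[key] = (True, f"rated {rating}")
    # subjects with only anatomical ratings: record the subject-level verdict
    for subj in bad_anat:
        if not any(k[0] == subj for k in decisions):
            decisions[(subj, None)] = (False, "bad anatomical rating excludes the subject")
    return decisions


def load_rating_files(directory: str | Path) -> list[QualityRating]:
    """Read every rating JSON in a working directory.

    Ingests ``ratings.json`` plus any file whose name starts with
    ``exclude``, so multiple raters can drop their exports side by side.
    Each file holds a JSON array of {subject, scan, type, rating} objects.
    """
    directory = Path(directory)
    ratings: list[QualityRating] = []
    paths = sorted(
        p for p in directory.glob("*.json")
        if p.name.startswith("exclude") or p.name == "ratings.json"
    )
    for path in paths:
        for entry in json.loads(path.read_text()):
            ratings.append(
                QualityRating(
                    subject=str(entry["subject"]),
                    rating=str(entry["rating"]),
                    image_type=str(entry.get("type", "functional")),
                    scan=entry.get("scan"),
                    rater=entry.get("rater", path.stem),
                )
            )
    return ratings
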