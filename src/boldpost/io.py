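"""Reading and writing the standard on-disk formats.

NIfTI images go through nibabel; confounds and events are plain TSV
tables with a header row; setting chains serialize to JSON so an
analysis plan can be scripted and shared.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .features import StatMap
from .postproc import Bold4D, ConfoundTable, IcaDecomposition, SettingChain, TemporalFilterSpec

__all__ = [
    "load_bold",
    "save_bold",
    "load_confounds",
    "save_confounds",
    "load_ica",
    "load_setting_chain",
    "save_setting_chain",
    "save_statmap",
]


def load_bold(
    bold_path: str | Path,
    mask_path: str | Path | None = None,
    repetition_time: float | None = None,
) -> Bold4D:
    """Load a 4D NIfTI (and optional mask) into a :class:`Bold4D`.

    The repetition time defaults to the header ``pixdim[4]``; pass an
    explicit value to override a stale header.
    """
    img = nib.load(str(bold_path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{bold_path} is not a 4D image")
    zooms = img.header.get_zooms()
    tr = repetition_time if repetition_time is not None else float(zooms[3])
    if mask_path is not None:
        mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    return Bold4D(
        data=data,
        repetition_time=tr,
        mask=mask,
        voxel_size=tuple(float(z) for z in zooms[:3]),
    )


def save_bold(img: Bold4D, path: str | Path, affine: np.ndarray | None = None) -> None:
    affine = affine if affine is not None else np.diag(list(img.voxel_size) + [1.0])
    nifti = nib.Nifti1Image(img.data.astype(np.float32), affine)
    nifti.header.set_zooms(tuple(img.voxel_size) + (img.repetition_time,))
    nib.save(nifti, str(path))


def load_confounds(path: str | Path) -> ConfoundTable:
    return ConfoundTable(pd.read_csv(path, sep="\t"))


def save_confounds(confounds: ConfoundTable, path: str | Path) -> None:
    confounds.frame.to_csv(path, sep="\t", index=False)


def load_ica(mixing_path: str | Path, noise_path: str | Path) -> IcaDecomposition:
    """Load a mixing matrix (TSV, t rows x c columns) and noise labels.

    The noise file lists one component index per line (0-based).
    """
    mixing = pd.read_csv(mixing_path, sep="\t", header=None).to_numpy(dtype=float)
    text = Path(noise_path).read_text().split()
    noise = tuple(int(tok) for tok in text)
    return IcaDecomposition(mixing=mixing, noise_indices=noise)


def load_setting_chain(path: str | Path) -> SettingChain:
    spec = json.loads(Path(path).read_text())
    filt = spec.get("filter")
    return SettingChain(
        smoothing_fwhm=spec.get("smoothing_fwhm"),
        grand_mean=spec.get("grand_mean"),
        ica_denoise=bool(spec.get("ica_denoise", False)),
        filter=TemporalFilterSpec(**filt) if filt else None,
        confound_selection=tuple(spec.get("confound_selection", ())),
    )


def save_setting_chain(chain: SettingChain, path: str | Path) -> None:
    payload = {
        "smoothing_fwhm": chain.smoothing_fwhm,
        "grand_mean": chain.grand_mean,
        "ica_denoise": chain.ica_denoise,
        "filter": (
            {
                "type": chain.filter.type,
                "low_cutoff_hz": chain.filter.low_cutoff_hz,
                "high_cutoff_hz": chain.filter.high_cutoff_hz,
                "highpass_fwhm_s": chain.filter.highpass_fwhm_s,
            }
            if chain.filter
            else None
        ),
        "confound_selection": list(chain.confound_selection),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def save_statmap(statmap: StatMap, effect_path: str | Path, variance_path: str | Path,
                 affine: np.ndarray | None = None) -> None:
    affine = affine if affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(statmap.effect.astype(np.float32), affine), str(effect_path))
    nib.save(nib.Nifti1Image(statmap.variance.astype(np.float32), affine), str(variance_path))
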