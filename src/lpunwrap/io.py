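"""Phase-image readers and writers (CSV matrix, float TIFF, NIfTI).

Phase is stored in radians everywhere; there is no degree support.  CSV and
NIfTI round trips are lossless (64-bit), TIFF is single-channel float32.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional

import numpy as np

from .phase_core import PhaseImage, wrap

__all__ = ["infer_format", "read_phase", "write_phase"]

log = logging.getLogger("lpunwrap")

_SUFFIXES = {
    ".csv": "csv",
    ".tif": "tiff",
    ".tiff": "tiff",
    ".nii": "nifti",
}


def infer_format(path, fmt: Optional[str] = None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "tiff", "nifti"):
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    p = Path(path)
    name = p.name.lower()
    if name.endswith(".nii.gz"):
        return "nifti"
    try:
        return _SUFFIXES[p.suffix.lower()]
    except KeyError:
        raise ValueError(f"cannot infer format from {p.name!r}") from None


def read_phase(
    path,
    fmt: Optional[str] = None,
    slice_index: Optional[int] = None,
    wrapped: bool = True,
) -> PhaseImage:
    """Read a 2D phase image in radians.

    Values outside (-pi, pi] in a nominally wrapped image are wrapped on
    load with a warning.  NaNs become masked pixels.  Multi-slice NIfTI
    volumes require an explicit ``slice_index`` — there is no silent
    first-slice default.
    """
    fmt = infer_format(path, fmt)
    affine = None
    if fmt == "csv":
        data = np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=float))
    elif fmt == "tiff":
        import tifffile

        data = np.asarray(tifffile.imread(path), dtype=float)
    else:
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
        affine = img.affine
        data = np.squeeze(data) if data.ndim > 2 and slice_index is None else data
    if data.ndim == 3:
        if slice_index is None:
            raise ValueError(
                f"{path}: 3D volume; select a plane with an explicit slice index"
            )
        if not (0 <= slice_index < data.shape[2]):
            raise ValueError(f"slice index {slice_index} out of range")
        data = data[:, :, slice_index]
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a 2D image, got shape {data.shape}")

    mask = None
    if np.isnan(data).any():
        mask = ~np.isnan(data)
        warnings.warn(f"{path}: NaN pixels masked out", stacklevel=2)
        data = np.where(mask, data, 0.0)
    if wrapped and np.any((data <= -np.pi) | (data > np.pi)):
        warnings.warn(
            f"{path}: values outside (-pi, pi] wrapped on load", stacklevel=2
        )
        data = wrap(data)
    return PhaseImage(values=data, is_wrapped=wrapped, mask=mask, affine=affine)


def write_phase(img: PhaseImage, path, fmt: Optional[str] = None) -> None:
    """Write a phase image; CSV/NIfTI keep full double precision."""
    fmt = infer_format(path, fmt)
    if fmt == "csv":
        np.savetxt(path, img.values, delimiter=",", fmt="%.17g")
    elif fmt == "tiff":
        import tifffile

        tifffile.imwrite(path, img.values.astype(np.float32))
    else:
        import nibabel as nib

        affine = img.affine if img.affine is not None else np.eye(4)
        nib.save(nib.Nifti1Image(img.values.astype(np.float64), affine), str(path))
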