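"""NIfTI-1 volume I/O with the package's voxel-centre convention.

The affine is diagonal in the voxel spacing with a half-voxel offset so that
world mm = (index + 0.5) * spacing, matching the phantom's coordinate system.
Complex volumes are stored as paired ``*_real.nii`` / ``*_imag.nii`` float32
files.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = 0.5 * np.asarray(spacing)
    return aff


def save_volume(path, data: np.ndarray, spacing) -> None:
    img = nib.Nifti1Image(np.asarray(data), _affine(spacing))
    img.header.set_zooms(tuple(float(s) for s in spacing))
    nib.save(img, str(path))


def load_volume(path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def save_complex(prefix, data: np.ndarray, spacing) -> None:
    save_volume(str(prefix) + "_real.nii", np.real(data).astype(np.float32), spacing)
    save_volume(str(prefix) + "_imag.nii", np.imag(data).astype(np.float32), spacing)


def load_complex(prefix):
    re, spacing = load_volume(str(prefix) + "_real.nii")
    im, _ = load_volume(str(prefix) + "_imag.nii")
    return re.astype(np.float64) + 1j * im.astype(np.float64), spacing
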