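"""bSSFP image formation, k-space assembly, and banding removal.

Signal model
------------
The balanced-SSFP steady state, demodulated at TE = TR/2, traces an ellipse
in the complex plane as a function of the effective per-TR precession phase
``phi = theta - delta`` (off-resonance ``theta`` minus the RF phase-cycle
increment ``delta``)::

    I(phi) = M * (1 - a e^{i phi}) / (1 - b cos phi) * e^{i theta / 2}

with, for E1 = exp(-TR/T1), E2 = exp(-TR/T2), flip angle alpha and proton
density M0::

    d = 1 - E1 cos(alpha) - E2^2 (E1 - cos(alpha))
    a = E2
    b = E2 (1 - E1)(1 + cos(alpha)) / d
    M = M0 (1 - E1) sin(alpha) / d * sqrt(E2)

``M`` (the geometric cross-point of the ellipse) is independent of ``phi``:
it is the band-free signal. Signal nulls ("bands") occur near phi = 0.

Band removal
------------
Four phase-cycled images (delta = 0/90/180/270 degrees) are combined per
voxel by intersecting the complex-plane line through (I_0, I_180) with the
line through (I_90, I_270). Because points half a cycle apart sit on opposite
sides of the cross-point, both lines pass through M (up to a voxelwise common
phase) and the intersection magnitude is band-free. Near-parallel or
degenerate line pairs (an on-resonance pathology of the geometric solution)
fall back to the quadrature mean of the four magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from crbssfp.errors import InvalidParameterError
from crbssfp.gating import CORRUPT_REACQUIRED, AcquisitionLog, SequenceParams
from crbssfp.phantom import LABEL_BACKGROUND, PhantomScene, TissueParams

#: |sin(angle between lines)| below which the cross-point solve is abandoned.
PARALLEL_TOL = 1e-3


@dataclass(frozen=True)
class EllipseModel:
    """Ellipse parameterisation of one tissue's bSSFP steady state."""

    M: float
    a: float
    b: float

    def signal(self, theta, phase_cycle_deg: float = 0.0) -> np.ndarray:
        """Complex TE-demodulated signal at off-resonance ``theta`` (rad/TR)."""
        theta = np.asarray(theta, dtype=float)
        phi = theta - np.deg2rad(phase_cycle_deg)
        ell = (1.0 - self.a * np.exp(1j * phi)) / (1.0 - self.b * np.cos(phi))
        return self.M * ell * np.exp(0.5j * theta)


def ellipse_model(tissue: TissueParams, seq: SequenceParams) -> EllipseModel:
    """Ellipse constants (M, a, b) for a tissue under a sequence."""
    if tissue.T1 <= 0 or tissue.T2 <= 0:
        raise InvalidParameterError("relaxation times must be positive")
    E1 = np.exp(-seq.TR / tissue.T1)
    E2 = np.exp(-seq.TR / tissue.T2)
    alpha = np.deg2rad(seq.flip_angle_deg)
    d = 1.0 - E1 * np.cos(alpha) - E2**2 * (E1 - np.cos(alpha))
    a = E2
    b = E2 * (1.0 - E1) * (1.0 + np.cos(alpha)) / d
    M = tissue.proton_density * (1.0 - E1) * np.sin(alpha) / d * np.sqrt(E2)
    return EllipseModel(M=float(M), a=float(a), b=float(b))


def band_free_signal(tissue: TissueParams, seq: SequenceParams) -> float:
    """|M|: the magnitude the four-cycle combination recovers for a tissue."""
    return abs(ellipse_model(tissue, seq).M)


def bssfp_signal(
    tissue: TissueParams,
    seq: SequenceParams,
    phase_cycle_deg: float = 0.0,
    off_resonance=None,
):
    """Steady-state complex bSSFP signal for one tissue.

    ``off_resonance`` (rad/TR) defaults to the tissue's own value; an array
    input returns an array of signals (used for voxel maps).
    """
    theta = tissue.off_resonance if off_resonance is None else off_resonance
    sig = ellipse_model(tissue, seq).signal(theta, phase_cycle_deg)
    if np.isscalar(theta) or np.asarray(theta).ndim == 0:
        return complex(sig)
    return sig


@dataclass(frozen=True)
class ComplexVolume:
    """A reconstructed complex 3D volume at one RF phase cycle."""

    data: np.ndarray
    spacing: tuple
    phase_cycle_deg: float

    def __post_init__(self):
        if np.asarray(self.data).ndim != 3:
            raise InvalidParameterError("volume must be 3-D")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)


def ideal_image(scene: PhantomScene, seq: SequenceParams,
                phase_cycle_deg: float) -> np.ndarray:
    """Noise-free voxelwise bSSFP image of a scene at one phase cycle."""
    if tuple(scene.shape) != tuple(seq.matrix):
        raise InvalidParameterError(
            f"scene grid {scene.shape} does not match matrix {tuple(seq.matrix)}"
        )
    out = np.zeros(scene.shape, dtype=np.complex128)
    for label in np.unique(scene.label_volume):
        if label == LABEL_BACKGROUND:
            continue
        where = scene.label_volume == label
        model = ellipse_model(scene.tissue_for_label(int(label)), seq)
        out[where] = model.signal(scene.off_resonance_map[where], phase_cycle_deg)
    return out


def _line_to_kspace_indices(line: int, seq: SequenceParams):
    return line // seq.matrix[2], line % seq.matrix[2]


def acquire_volume(
    scene: PhantomScene,
    log: AcquisitionLog,
    seq: SequenceParams,
    phase_cycle_deg: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    keep_corrupted: bool = False,
) -> ComplexVolume:
    """Simulate one gated acquisition and reconstruct the complex volume.

    The ideal image is transformed to k-space (orthonormal FFT), complex
    Gaussian noise of per-channel sd ``noise_sd`` is added to every sample,
    and the inverse transform returns the image. Because the scheduler
    guarantees every line's final acquisition is motion-free, the default
    reconstruction uses clean data everywhere. With ``keep_corrupted=True``
    the lines whose blocks were flagged CORRUPT_REACQUIRED are instead taken
    from a motion-displaced copy of the object (the scene's respiratory bulk
    displacement), emulating a scan without reacquisition.
    """
    log.assert_line_conservation()
    image = ideal_image(scene, seq, phase_cycle_deg)
    kspace = np.fft.fftn(image, norm="ortho")

    if keep_corrupted:
        disp = np.asarray(scene.motion_model["respiratory_mm"], float)
        shift_vox = disp / np.asarray(scene.spacing, float)
        moved = ndimage.shift(image.real, shift_vox, order=1, mode="constant") + 1j * (
            ndimage.shift(image.imag, shift_vox, order=1, mode="constant")
        )
        k_moved = np.fft.fftn(moved, norm="ortho")
        for rec in log.records:
            if rec.status == CORRUPT_REACQUIRED:
                for line in range(rec.line_start, rec.line_stop):
                    ky, kz = _line_to_kspace_indices(line, seq)
                    kspace[:, ky, kz] = k_moved[:, ky, kz]

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, kspace.shape) + 1j * rng.normal(
            0.0, noise_sd, kspace.shape
        )
        kspace = kspace + noise

    recon = np.fft.ifftn(kspace, norm="ortho")
    return ComplexVolume(recon, scene.spacing, phase_cycle_deg)


def combine_phase_cycles(volumes) -> np.ndarray:
    """Band-free magnitude from four phase-cycled complex volumes.

    Expects exactly the 0/90/180/270 degree cycles on a common grid (any
    order). Returns the magnitude of the per-voxel cross-point of the line
    through (I_0, I_180) and the line through (I_90, I_270); voxels where the
    lines are within ``PARALLEL_TOL`` of parallel (or a pair coincides) use
    the quadrature-mean magnitude fallback.
    """
    if len(volumes) != 4:
        raise InvalidParameterError("exactly four phase-cycled volumes are required")
    cycles = sorted(round(v.phase_cycle_deg) % 360 for v in volumes)
    if cycles != [0, 90, 180, 270]:
        raise InvalidParameterError(f"need phase cycles 0/90/180/270, got {cycles}")
    shapes = {v.data.shape for v in volumes}
    spacings = {tuple(v.spacing) for v in volumes}
    if len(shapes) != 1 or len(spacings) != 1:
        raise InvalidParameterError("volumes must share grid and spacing")

    by_cycle = {round(v.phase_cycle_deg) % 360: v.data for v in volumes}
    i0, i90, i180, i270 = (by_cycle[c] for c in (0, 90, 180, 270))

    d1 = i180 - i0
    d2 = i270 - i90
    rhs = i90 - i0
    det = d1.real * (-d2.imag) - (-d2.real) * d1.imag
    norms = np.abs(d1) * np.abs(d2)
    with np.errstate(divide="ignore", invalid="ignore"):
        sin_angle = np.abs(det) / norms
    degenerate = (norms == 0) | ~np.isfinite(sin_angle) | (sin_angle < PARALLEL_TOL)

    with np.errstate(divide="ignore", invalid="ignore"):
        s = (rhs.real * (-d2.imag) - (-d2.real) * rhs.imag) / det
        cross = i0 + s * d1
        out = np.abs(cross)
    fallback = np.sqrt(
        (np.abs(i0) ** 2 + np.abs(i90) ** 2 + np.abs(i180) ** 2 + np.abs(i270) ** 2)
        / 4.0
    )
    out[degenerate] = fallback[degenerate]
    return out
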