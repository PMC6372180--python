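"""Rigid ICP registration of lung masks with Dice quality control.

The earlier timepoint's lung mask is the moving image: it is aligned to the
later (fixed) mask by iterative closest point on surface-voxel point clouds,
then resampled into the fixed grid by nearest neighbour for the Dice check.
Rigid alignment is used because it retains volumetric detail; tumour volumes
are always measured in each image's native frame, so registration aids
correspondence, not volumetry.

QC tiers: Dice above 0.800 is good enough for fully shared-seed tracking
(AUTO); 0.778-0.800 still permits tracking with manually repositioned seeds
(MANUAL); below that individual tracking is abandoned (FAIL), although
aggregate volumetry remains possible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from crbssfp.errors import InvalidParameterError
from crbssfp.quantify import Mask

AUTO = "AUTO"
MANUAL = "MANUAL"
FAIL = "FAIL"

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class RigidTransform:
    """x_fixed = rotation @ x_moving + translation (mm coordinates)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise InvalidParameterError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or np.linalg.det(R) < 0:
            raise InvalidParameterError("rotation must be orthonormal with det +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self.compose(other)).apply(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def save(self, path) -> None:
        np.savetxt(str(path), self.as_matrix(), fmt="%.12g")

    @staticmethod
    def load(path) -> "RigidTransform":
        m = np.loadtxt(str(path))
        return RigidTransform(m[:3, :3], m[:3, 3])


@dataclass(frozen=True)
class QCThresholds:
    """Dice thresholds for the tracking tiers (config values)."""

    auto_tier: float = 0.800
    manual_tier: float = 0.778
    auto_inclusive: bool = False  # default: strict > for AUTO

    def __post_init__(self):
        if not (0 <= self.manual_tier <= self.auto_tier <= 1):
            raise InvalidParameterError("need 0 <= manual_tier <= auto_tier <= 1")


def surface_points(mask: Mask) -> np.ndarray:
    """mm coordinates of the mask's surface voxels (6-connectivity erosion)."""
    if mask.n_voxels == 0:
        raise InvalidParameterError("mask is empty")
    interior = ndimage.binary_erosion(mask.data, structure=_STRUCT6, border_value=0)
    surf = mask.data & ~interior
    idx = np.argwhere(surf)
    return (idx + 0.5) * np.asarray(mask.spacing)


def _kabsch(src: np.ndarray, dst: np.ndarray):
    """Least-squares rigid transform mapping src onto dst (SVD, det-corrected)."""
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = cd - R @ cs
    return R, t


def icp_register(
    moving: Mask,
    fixed: Mask,
    max_iter: int = 100,
    tol: float = 1e-4,
    full_output: bool = False,
):
    """Iterative closest point between two masks' surface point clouds.

    Initialised by centroid alignment; each iteration matches every moving
    surface point to its nearest fixed surface point (ties broken by lowest
    point index) and re-estimates the rigid transform by the SVD solution.
    Stops when the RMS correspondence distance improves by less than ``tol``
    mm or ``max_iter`` is reached; returns ``(transform, converged)`` with the
    best transform seen (``(transform, converged, rms_history)`` with
    ``full_output=True``). Convergence says nothing about anatomical success —
    that is the Dice QC's job.
    """
    src = surface_points(moving)
    dst = surface_points(fixed)
    tree = cKDTree(dst)

    R = np.eye(3)
    t = dst.mean(axis=0) - src.mean(axis=0)
    best = (np.inf, R, t)
    prev_rms = np.inf
    converged = False
    history = []
    for _ in range(max_iter):
        cur = src @ R.T + t
        dists, nn = tree.query(cur, k=1)
        rms = float(np.sqrt(np.mean(dists**2)))
        history.append(rms)
        if rms < best[0]:
            best = (rms, R, t)
        if prev_rms - rms < tol:
            converged = True
            break
        prev_rms = rms
        R, t = _kabsch(src, dst[nn])
    _, R, t = best
    if full_output:
        return RigidTransform(R, t), converged, history
    return RigidTransform(R, t), converged


def resample_mask(moving: Mask, transform: RigidTransform, fixed: Mask) -> Mask:
    """Nearest-neighbour resampling of ``moving`` into the fixed grid."""
    sp_f = np.asarray(fixed.spacing, float)
    sp_m = np.asarray(moving.spacing, float)
    inv = transform.inverse()
    # index_moving = diag(1/sp_m) @ (R^-1 @ (diag(sp_f) @ (i + .5) - t)) - .5
    A = (inv.rotation * sp_f[np.newaxis, :]) / sp_m[:, np.newaxis]
    offset = (inv.rotation @ (0.5 * sp_f) + inv.translation) / sp_m - 0.5
    out = ndimage.affine_transform(
        moving.data.astype(np.uint8),
        A,
        offset=offset,
        output_shape=fixed.data.shape,
        order=0,
        mode="constant",
        cval=0,
    )
    return Mask(out.astype(bool), fixed.spacing, label=moving.label,
                seed_points=moving.seed_points)


def dice(a: Mask, b: Mask) -> float:
    """Dice overlap 2|A^B| / (|A|+|B|); undefined (error) when both empty."""
    if a.data.shape != b.data.shape:
        raise InvalidParameterError("masks must share a grid")
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise InvalidParameterError("Dice of two empty masks is undefined")
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)


def qc_tier(d: float, thresholds: QCThresholds = QCThresholds()) -> str:
    """Classify a Dice value into AUTO / MANUAL / FAIL."""
    if not (0.0 <= d <= 1.0):
        raise InvalidParameterError("Dice value must lie in [0, 1]")
    if (d >= thresholds.auto_tier) if thresholds.auto_inclusive else (d > thresholds.auto_tier):
        return AUTO
    if d >= thresholds.manual_tier:
        return MANUAL
    return FAIL


def register_and_qc(moving: Mask, fixed: Mask,
                    thresholds: QCThresholds = QCThresholds(),
                    max_iter: int = 100, tol: float = 1e-4):
    """Convenience: ICP, resample, Dice and tier in one call.

    Returns ``(transform, dice_value, tier, resampled_moving)``.
    """
    transform, _ = icp_register(moving, fixed, max_iter=max_iter, tol=tol)
    warped = resample_mask(moving, transform, fixed)
    d = dice(warped, fixed)
    return transform, d, qc_tier(d, thresholds), warped
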