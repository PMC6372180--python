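"""Digital mouse-thorax phantom with exactly countable tumour ground truth.

The phantom stands in for the urethane-induced lung-tumour mouse: a body
ellipsoid enclosing two lung lobes (right larger than left, which also breaks
the left-right symmetry that would otherwise make rigid registration
ambiguous), a heart between the lobes, optional anaesthesia-atelectasis
patches, and ellipsoidal tumours embedded in lung parenchyma. Lung tissue is
assigned low proton density (air-tissue signal loss) while tumours are
assigned high proton density, reproducing the tumour-to-parenchyma contrast
that makes lung MRI volumetry viable.

Ground truth is exact by construction: each tumour is rasterised as exactly
``n`` voxels (the ``n`` grid points of smallest ellipsoidal norm around its
centre), so truth volume = voxel count x voxel volume and voxel-count
volumetry can recover it with zero error.

Coordinates: 0-based voxel indices, axis order (readout, phase1, phase2);
world position of a voxel centre is ``(index + 0.5) * spacing`` mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from crbssfp.errors import InfeasiblePlacementError, InvalidParameterError
from crbssfp.nifti_io import load_volume, save_volume

LABEL_BACKGROUND = 0
LABEL_BODY = 1
LABEL_LUNG = 2
LABEL_HEART = 3
LABEL_ATELECTASIS = 4
TUMOUR_LABEL_BASE = 10

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class TissueParams:
    """Relaxation times, proton density and off-resonance of one tissue.

    ``off_resonance`` is the per-TR precession angle theta in radians; for
    scene voxels it is overridden by the scene's smooth off-resonance map.
    """

    T1: float
    T2: float
    proton_density: float
    off_resonance: float = 0.0

    def __post_init__(self):
        if self.T1 <= 0 or self.T2 <= 0:
            raise InvalidParameterError("T1 and T2 must be positive")
        if self.T2 > self.T1:
            raise InvalidParameterError("T2 must not exceed T1")
        if self.proton_density < 0:
            raise InvalidParameterError("proton_density must be non-negative")


#: Phantom tissue conventions (not measured values): lung parenchyma has low
#: proton density, tumours high; T1/T2 are plausible 7 T orders of magnitude.
DEFAULT_TISSUES = {
    LABEL_BODY: TissueParams(T1=1.2, T2=0.025, proton_density=0.70),
    LABEL_LUNG: TissueParams(T1=1.1, T2=0.010, proton_density=0.15),
    LABEL_HEART: TissueParams(T1=1.3, T2=0.030, proton_density=0.80),
    LABEL_ATELECTASIS: TissueParams(T1=1.4, T2=0.040, proton_density=0.60),
}
TUMOUR_TISSUE = TissueParams(T1=1.5, T2=0.060, proton_density=0.90)

#: Bulk displacement amplitudes (mm) applied when simulating corrupted blocks:
#: respiration is cranio-caudal (readout axis), cardiac motion is small.
DEFAULT_MOTION_MODEL = {
    "respiratory_mm": (1.0, 0.0, 0.0),
    "cardiac_mm": (0.15, 0.15, 0.15),
}


@dataclass(frozen=True)
class TumourTruth:
    """Ground truth for one tumour: centre (mm), volume (mm^3), voxel count."""

    centre_mm: tuple
    volume_mm3: float
    n_voxels: int


@dataclass(frozen=True)
class _Ellipsoid:
    centre_mm: tuple
    semi_mm: tuple


@dataclass(frozen=True)
class _TumourSpec:
    centre_mm: tuple
    ratios: tuple
    n_voxels: int


@dataclass(frozen=True)
class _GenRecord:
    """Generative parameters retained so a scene can be evolved exactly."""

    body: _Ellipsoid
    lobes: tuple
    heart: _Ellipsoid
    atelectasis: object  # _Ellipsoid or None
    tumours: dict  # id -> _TumourSpec
    rotation: tuple  # 3x3, row tuples
    margin_vox: int
    lung_volume_target: float


@dataclass(frozen=True)
class PhantomScene:
    """A labelled 3D thorax with tissue table, truth and motion model."""

    label_volume: np.ndarray
    spacing: tuple
    tissue_table: dict
    tumour_truth: dict
    off_resonance_map: np.ndarray
    motion_model: dict = field(default_factory=lambda: dict(DEFAULT_MOTION_MODEL))
    _gen: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise InvalidParameterError("spacing must be strictly positive")
        labels = set(np.unique(self.label_volume))
        for tid in self.tumour_truth:
            if tid not in labels:
                raise InvalidParameterError(f"tumour {tid} missing from label volume")

    @property
    def shape(self) -> tuple:
        return self.label_volume.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def tumour_mask(self, tumour_id: int) -> np.ndarray:
        return self.label_volume == tumour_id

    def lung_mask(self, include_tumours: bool = True) -> np.ndarray:
        """Anatomical lung extent; tumours (and atelectasis) lie within it."""
        m = self.label_volume == LABEL_LUNG
        if include_tumours:
            m = m | (self.label_volume >= TUMOUR_LABEL_BASE)
            m = m | (self.label_volume == LABEL_ATELECTASIS)
        return m

    def lung_volume_mm3(self, include_tumours: bool = True) -> float:
        return float(self.lung_mask(include_tumours).sum() * self.voxel_volume_mm3)

    def tissue_for_label(self, label: int) -> TissueParams:
        if label >= TUMOUR_LABEL_BASE:
            return self.tissue_table.get(label, TUMOUR_TISSUE)
        return self.tissue_table[label]

    def save(self, prefix) -> None:
        """Write the labels as NIfTI-1 plus a JSON truth sidecar."""
        prefix = str(prefix)
        save_volume(prefix + ".nii", self.label_volume.astype(np.int16), self.spacing)
        save_volume(prefix + "_offres.nii", self.off_resonance_map.astype(np.float32),
                    self.spacing)
        sidecar = {
            "spacing_mm": list(self.spacing),
            "motion_model": {k: list(v) for k, v in self.motion_model.items()},
            "tumours": {
                str(tid): {
                    "centre_mm": list(t.centre_mm),
                    "volume_mm3": t.volume_mm3,
                    "n_voxels": t.n_voxels,
                }
                for tid, t in self.tumour_truth.items()
            },
            "tissues": {
                str(lbl): {
                    "T1": tp.T1, "T2": tp.T2,
                    "proton_density": tp.proton_density,
                }
                for lbl, tp in self.tissue_table.items()
            },
        }
        with open(prefix + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @staticmethod
    def load(prefix) -> "PhantomScene":
        prefix = str(prefix)
        labels, spacing = load_volume(prefix + ".nii")
        offres, _ = load_volume(prefix + "_offres.nii")
        with open(prefix + ".json") as fh:
            sidecar = json.load(fh)
        tissues = {
            int(lbl): TissueParams(**tp) for lbl, tp in sidecar["tissues"].items()
        }
        truth = {
            int(tid): TumourTruth(tuple(t["centre_mm"]), t["volume_mm3"], t["n_voxels"])
            for tid, t in sidecar["tumours"].items()
        }
        motion = {k: tuple(v) for k, v in sidecar["motion_model"].items()}
        return PhantomScene(labels.astype(np.int16), tuple(sidecar["spacing_mm"]),
                            tissues, truth, offres, motion)


# ---------------------------------------------------------------------------
# rasterisation


def _voxel_centres_bbox(shape, lo, hi):
    """Index grids for the box [lo, hi) (clipped to the volume)."""
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, shape)
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    return grids, lo, hi


def _ellipsoid_mask(shape, spacing, ell: _Ellipsoid, rotation=None) -> np.ndarray:
    """Boolean mask of voxel centres with ellipsoidal norm <= 1."""
    spacing = np.asarray(spacing, float)
    c = np.asarray(ell.centre_mm, float)
    semi = np.asarray(ell.semi_mm, float)
    R = np.eye(3) if rotation is None else np.asarray(rotation, float)
    half = np.abs(R) @ semi  # bounding half-extent in grid axes
    lo = np.floor((c - half) / spacing - 0.5).astype(int) - 1
    hi = np.ceil((c + half) / spacing - 0.5).astype(int) + 2
    (gi, gj, gk), lo, hi = _voxel_centres_bbox(shape, lo, hi)
    pts = np.stack([(gi + 0.5) * spacing[0] - c[0],
                    (gj + 0.5) * spacing[1] - c[1],
                    (gk + 0.5) * spacing[2] - c[2]], axis=-1)
    local = pts @ R  # R^T applied to each row
    norm = np.sum((local / semi) ** 2, axis=-1)
    mask = np.zeros(shape, dtype=bool)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = norm <= 1.0
    return mask


def _exact_blob(shape, spacing, centre_mm, ratios, n_voxels, rotation=None):
    """The ``n_voxels`` grid points of smallest ellipsoidal norm around a centre.

    Deterministic (ties broken by raster order) and exactly countable; the
    result approximates an axis-ratio ``ratios`` ellipsoid of n voxels.
    Returns an (n, 3) integer index array.
    """
    spacing = np.asarray(spacing, float)
    c = np.asarray(centre_mm, float)
    ratios = np.asarray(ratios, float)
    R = np.eye(3) if rotation is None else np.asarray(rotation, float)
    vox = float(np.prod(spacing))
    r_eq = (3.0 * n_voxels * vox / (4.0 * np.pi)) ** (1.0 / 3.0)
    half = r_eq * float(ratios.max() / np.power(ratios.prod(), 1 / 3)) * 2.5 + 2 * spacing.max()
    lo = np.floor((c - half) / spacing - 0.5).astype(int)
    hi = np.ceil((c + half) / spacing - 0.5).astype(int) + 1
    (gi, gj, gk), lo, hi = _voxel_centres_bbox(shape, lo, hi)
    pts = np.stack([(gi + 0.5) * spacing[0] - c[0],
                    (gj + 0.5) * spacing[1] - c[1],
                    (gk + 0.5) * spacing[2] - c[2]], axis=-1)
    local = pts @ R
    norm = np.sum((local / ratios) ** 2, axis=-1).ravel()
    if norm.size < n_voxels:
        raise InfeasiblePlacementError("blob does not fit inside the grid")
    order = np.argsort(norm, kind="stable")[:n_voxels]
    ii = np.stack([g.ravel()[order] for g in (gi, gj, gk)], axis=1)
    return ii


def _blob_connected(shape, idx) -> bool:
    box_lo = idx.min(axis=0)
    local = idx - box_lo
    m = np.zeros(local.max(axis=0) + 1, dtype=bool)
    m[tuple(local.T)] = True
    _, n = ndimage.label(m, structure=_STRUCT26)
    return n == 1


def _off_resonance_map(shape, spacing) -> np.ndarray:
    """Smooth linear+quadratic field spanning about +/- pi rad per TR."""
    axes = [np.linspace(-1.0, 1.0, s, dtype=np.float32) for s in shape]
    u0, u1, u2 = np.meshgrid(*axes, indexing="ij")
    theta = 0.6 * u0 + 0.8 * u2 + 0.5 * (u1**2 - 0.3)
    theta *= np.pi / np.abs(theta).max()
    return theta.astype(np.float32)


def _rotation_about_axis(angle_deg: float, axis: int = 0) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    ca, sa = np.cos(a), np.sin(a)
    R = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    R[i, i] = ca
    R[i, j] = -sa
    R[j, i] = sa
    R[j, j] = ca
    return R


# ---------------------------------------------------------------------------
# scene construction


def _rasterise(shape, spacing, gen: _GenRecord, tissue_table):
    R = np.asarray(gen.rotation, float)
    labels = np.zeros(shape, dtype=np.int16)
    labels[_ellipsoid_mask(shape, spacing, gen.body, R)] = LABEL_BODY
    for lobe in gen.lobes:
        lung = _ellipsoid_mask(shape, spacing, lobe, R)
        labels[lung & (labels == LABEL_BODY)] = LABEL_LUNG
    heart = _ellipsoid_mask(shape, spacing, gen.heart, R)
    labels[heart & (labels > LABEL_BACKGROUND)] = LABEL_HEART
    if gen.atelectasis is not None:
        patch = _ellipsoid_mask(shape, spacing, gen.atelectasis, R)
        labels[patch & (labels == LABEL_LUNG)] = LABEL_ATELECTASIS

    truth = {}
    for tid in sorted(gen.tumours):
        spec = gen.tumours[tid]
        idx = _exact_blob(shape, spacing, spec.centre_mm, spec.ratios,
                          spec.n_voxels, R)
        inside = labels[tuple(idx.T)] == LABEL_LUNG
        if not inside.all():
            raise InfeasiblePlacementError(
                f"tumour {tid} no longer fits inside the lung"
            )
        labels[tuple(idx.T)] = tid
        truth[tid] = TumourTruth(
            centre_mm=tuple(np.asarray(spec.centre_mm, float)),
            volume_mm3=float(spec.n_voxels * np.prod(spacing)),
            n_voxels=int(spec.n_voxels),
        )
    return labels, truth


def _allowed_region(labels, margin_vox: int) -> np.ndarray:
    lung = labels == LABEL_LUNG
    if margin_vox > 0:
        lung = ndimage.binary_erosion(lung, iterations=margin_vox)
    return lung


def _place_tumours(shape, spacing, labels, rng, n_tumours, volume_range,
                   margin_vox, start_id, growth_headroom=4.0, max_tries=200):
    """Sample non-overlapping tumour specs inside the (eroded) lung label.

    Placement additionally requires headroom for ~4x later growth so evolved
    scenes remain feasible. Returns {id: _TumourSpec}; mutates ``labels``
    bookkeeping only via the returned specs (caller rasterises).
    """
    vox = float(np.prod(spacing))
    allowed = _allowed_region(labels, margin_vox)
    specs = {}
    occupied = np.zeros(shape, dtype=bool)
    for k in range(n_tumours):
        tid = start_id + k
        nominal = float(rng.uniform(*volume_range))
        n_vox = max(1, int(round(nominal / vox)))
        ratios = tuple(np.exp(rng.uniform(-0.3, 0.3, size=3)))
        placed = False
        for _ in range(max_tries):
            cand = np.argwhere(allowed & ~occupied)
            if len(cand) == 0:
                break
            centre_idx = cand[rng.integers(len(cand))]
            centre_mm = tuple((centre_idx + 0.5) * np.asarray(spacing))
            n_head = max(n_vox, int(round(n_vox * growth_headroom)))
            try:
                big = _exact_blob(shape, spacing, centre_mm, ratios, n_head)
                idx = big[:n_vox]
            except InfeasiblePlacementError:
                continue
            ok = allowed[tuple(big.T)].all() and not occupied[tuple(big.T)].any()
            if ok and _blob_connected(shape, idx):
                specs[tid] = _TumourSpec(centre_mm, ratios, n_vox)
                # block the headroom region plus a 1-voxel moat so components
                # stay 26-disjoint
                occ = np.zeros(shape, dtype=bool)
                occ[tuple(big.T)] = True
                occupied |= ndimage.binary_dilation(occ, structure=_STRUCT26)
                placed = True
                break
        if not placed:
            raise InfeasiblePlacementError(
                f"could not place tumour {tid} after {max_tries} tries"
            )
    return specs


def make_scene(
    n_tumours: int = 5,
    tumour_volume_range: tuple = (0.056, 0.7),
    lung_volume_target: float = 440.0,
    seed: int = 0,
    shape: tuple = (256, 128, 128),
    spacing: tuple = (0.2, 0.2, 0.2),
    atelectasis: bool = False,
    tissue_table: dict = None,
    margin_vox: int = 2,
    growth_headroom: float = 4.0,
) -> PhantomScene:
    """Generate a thorax phantom with ``n_tumours`` non-overlapping tumours.

    The two lung lobes are scaled so the lung label volume lands within 10%
    of ``lung_volume_target`` (mm^3, the scale of an adult mouse lung).
    Tumour nominal volumes are drawn uniformly from ``tumour_volume_range``
    (mm^3) and realised as exact voxel counts. Deterministic for fixed seed.

    Raises
    ------
    InfeasiblePlacementError
        If the lung cannot host the requested tumours without overlap.
    """
    if n_tumours < 0:
        raise InvalidParameterError("n_tumours must be >= 0")
    vox = float(np.prod(spacing))
    if n_tumours > 0 and tumour_volume_range[0] < vox:
        raise InvalidParameterError(
            f"tumour_volume_range lower bound must be >= one voxel volume ({vox} mm^3)"
        )
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    spacing = tuple(float(s) for s in spacing)
    fov = np.asarray(shape) * np.asarray(spacing)
    centre = fov / 2.0

    body = _Ellipsoid(tuple(centre), tuple(fov * np.array([0.42, 0.40, 0.40])))
    lobe_offset = 0.215 * fov[2]
    lobe_ratio = np.array([2.2, 1.0, 1.0])
    lobes = []
    for sign, share in ((+1, 0.55), (-1, 0.45)):  # right lobe larger
        target = share * lung_volume_target
        s3 = 3.0 * target / (4.0 * np.pi * np.prod(lobe_ratio))
        semi = lobe_ratio * s3 ** (1.0 / 3.0)
        c = centre + np.array([0.0, 0.0, sign * lobe_offset])
        lobes.append(_Ellipsoid(tuple(c), tuple(semi)))
    heart = _Ellipsoid(tuple(centre + np.array([3.0, 0.0, 0.0])),
                       (4.0, 3.0, 0.45 * lobe_offset))
    at = None
    if atelectasis:
        right = lobes[0]
        c = np.asarray(right.centre_mm) + np.array([-0.5 * right.semi_mm[0], 0.0, 0.0])
        at = _Ellipsoid(tuple(c), (2.5, 1.8, 1.8))

    gen = _GenRecord(body=body, lobes=tuple(lobes), heart=heart, atelectasis=at,
                     tumours={}, rotation=tuple(map(tuple, np.eye(3))),
                     margin_vox=margin_vox, lung_volume_target=lung_volume_target)
    labels, _ = _rasterise(shape, spacing, gen, None)

    # one corrective rescale brings the realised lung volume within 10%
    realised = float((labels == LABEL_LUNG).sum() * vox)
    scale = (lung_volume_target / realised) ** (1.0 / 3.0)
    lobes = [
        _Ellipsoid(l.centre_mm, tuple(np.asarray(l.semi_mm) * scale)) for l in lobes
    ]
    gen = replace(gen, lobes=tuple(lobes))
    labels, _ = _rasterise(shape, spacing, gen, None)
    realised = float((labels == LABEL_LUNG).sum() * vox)
    if abs(realised - lung_volume_target) > 0.10 * lung_volume_target:
        raise InfeasiblePlacementError(
            f"lung volume {realised:.1f} mm^3 missed target {lung_volume_target} by >10%"
        )

    specs = _place_tumours(shape, spacing, labels, rng, n_tumours,
                           tumour_volume_range, margin_vox, TUMOUR_LABEL_BASE,
                           growth_headroom=growth_headroom)
    gen = replace(gen, tumours=specs)
    labels, truth = _rasterise(shape, spacing, gen, None)

    table = dict(DEFAULT_TISSUES if tissue_table is None else tissue_table)
    for tid in truth:
        table.setdefault(tid, TUMOUR_TISSUE)
    return PhantomScene(
        label_volume=labels,
        spacing=spacing,
        tissue_table=table,
        tumour_truth=truth,
        off_resonance_map=_off_resonance_map(shape, spacing),
        motion_model=dict(DEFAULT_MOTION_MODEL),
        _gen=gen,
    )


def evolve_scene(
    scene: PhantomScene,
    growth_factors: dict = None,
    new_tumours: int = 0,
    seed: int = 0,
    shift_mm: tuple = (0.0, 0.0, 0.0),
    rotation_deg: float = 0.0,
    rotation_axis: int = 0,
    new_tumour_volume_range: tuple = None,
    lung_scale: float = 1.0,
) -> PhantomScene:
    """Produce a later-timepoint scene: grown tumours, new tumours, repose.

    Each existing tumour's voxel count is scaled by its multiplier (realised
    exactly on the grid, so within one voxel volume of the continuous
    target); new tumours are placed as in :func:`make_scene`. The whole
    thorax may be rigidly repositioned (``shift_mm``, ``rotation_deg`` about
    ``rotation_axis`` through the grid centre) to emulate inter-session
    placement differences; anatomy is re-rasterised in the new pose so truth
    volumes stay exact.

    Raises
    ------
    InfeasiblePlacementError
        If growth pushes a tumour outside the lung or into a neighbour.
    """
    if scene._gen is None:
        raise InvalidParameterError("scene lacks generative parameters; rebuild it")
    growth_factors = dict(growth_factors or {})
    for tid, f in growth_factors.items():
        if f <= 0:
            raise InvalidParameterError("growth multipliers must be positive")
        if tid not in scene.tumour_truth:
            raise InvalidParameterError(f"unknown tumour id {tid}")
    rng = np.random.default_rng(seed)
    gen: _GenRecord = scene._gen
    shape = scene.shape
    spacing = scene.spacing
    centre = np.asarray(shape) * np.asarray(spacing) / 2.0
    R_new = _rotation_about_axis(rotation_deg, rotation_axis)
    R = R_new @ np.asarray(gen.rotation, float)
    shift = np.asarray(shift_mm, float)

    def move(c):
        return tuple(R_new @ (np.asarray(c, float) - centre) + centre + shift)

    def move_ell(e: _Ellipsoid, scale=1.0):
        return _Ellipsoid(move(e.centre_mm), tuple(np.asarray(e.semi_mm) * scale))

    lobes = tuple(move_ell(l, lung_scale ** (1.0 / 3.0)) for l in gen.lobes)
    tumours = {}
    for tid, spec in gen.tumours.items():
        f = growth_factors.get(tid, 1.0)
        n_new = max(1, int(round(spec.n_voxels * f)))
        tumours[tid] = _TumourSpec(move(spec.centre_mm), spec.ratios, n_new)

    gen2 = _GenRecord(
        body=move_ell(gen.body),
        lobes=lobes,
        heart=move_ell(gen.heart),
        atelectasis=None if gen.atelectasis is None else move_ell(gen.atelectasis),
        tumours=tumours,
        rotation=tuple(map(tuple, R)),
        margin_vox=gen.margin_vox,
        lung_volume_target=gen.lung_volume_target * lung_scale,
    )

    # rasterise anatomy without tumours first, then check/paint tumours
    anat = replace(gen2, tumours={})
    labels, _ = _rasterise(shape, spacing, anat, None)
    occupied = np.zeros(shape, dtype=bool)
    vox = float(np.prod(spacing))
    allowed = _allowed_region(labels, max(1, gen.margin_vox - 1))
    for tid in sorted(tumours):
        spec = tumours[tid]
        idx = _exact_blob(shape, spacing, spec.centre_mm, spec.ratios,
                          spec.n_voxels, R)
        ok = allowed[tuple(idx.T)].all() and not occupied[tuple(idx.T)].any()
        if not ok:
            raise InfeasiblePlacementError(
                f"growth of tumour {tid} overlaps a neighbour or exits the lung"
            )
        occ = np.zeros(shape, dtype=bool)
        occ[tuple(idx.T)] = True
        occupied |= ndimage.binary_dilation(occ, structure=_STRUCT26)

    if new_tumours > 0:
        if new_tumour_volume_range is None:
            vols = [t.n_voxels * vox for t in scene.tumour_truth.values()]
            new_tumour_volume_range = (max(vox, min(vols, default=0.056)),
                                       max(vols, default=0.7))
        blocked = labels.copy()
        blocked[occupied] = LABEL_BACKGROUND  # keep clear of existing tumours
        start = max(tumours, default=TUMOUR_LABEL_BASE - 1) + 1
        # tumours appearing at the later timepoint need no growth headroom
        new_specs = _place_tumours(shape, spacing, blocked, rng, new_tumours,
                                   new_tumour_volume_range, gen.margin_vox, start,
                                   growth_headroom=1.0)
        tumours.update(new_specs)

    gen2 = replace(gen2, tumours=tumours)
    labels, truth = _rasterise(shape, spacing, gen2, None)
    table = dict(scene.tissue_table)
    for tid in truth:
        table.setdefault(tid, TUMOUR_TISSUE)
    return PhantomScene(
        label_volume=labels,
        spacing=spacing,
        tissue_table=table,
        tumour_truth=truth,
        off_resonance_map=scene.off_resonance_map,
        motion_model=dict(scene.motion_model),
        _gen=gen2,
    )
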