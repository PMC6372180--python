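"""Seeded threshold segmentation and voxel-count volumetry.

Segmentation mirrors the interactive workflow it replaces: an operator picks
an intensity band and seed points, and the mask is the union of the
26-connected components of the thresholded volume that contain a seed. For
reproducibility the band is an explicit numeric interval, either supplied or
derived from the phantom's tissue signal model (midpoints between modal
intensities); there is no GUI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from crbssfp.errors import BadSeedError, InvalidParameterError
from crbssfp.gating import SequenceParams
from crbssfp.phantom import (
    LABEL_ATELECTASIS,
    LABEL_BODY,
    LABEL_HEART,
    LABEL_LUNG,
    TUMOUR_LABEL_BASE,
    PhantomScene,
)
from crbssfp.recon import band_free_signal

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class Mask:
    """A boolean 3D mask with its spacing, semantic label and seeds."""

    data: np.ndarray
    spacing: tuple
    label: str = "mask"
    seed_points: tuple = ()

    def __post_init__(self):
        d = np.asarray(self.data, dtype=bool)
        if d.ndim != 3:
            raise InvalidParameterError("mask must be 3-D")
        object.__setattr__(self, "data", d)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def centroid_voxel(self) -> tuple:
        """Nearest voxel index to the mask's centre of mass."""
        if self.n_voxels == 0:
            raise InvalidParameterError("centroid of an empty mask is undefined")
        com = np.asarray(ndimage.center_of_mass(self.data))
        return tuple(int(round(c)) for c in com)


def segment(
    volume: np.ndarray,
    spacing,
    seeds,
    threshold_low: float,
    threshold_high: float = np.inf,
    label: str = "mask",
    fill_holes: bool = False,
    connectivity: int = 26,
) -> Mask:
    """Seeded threshold segmentation.

    Returns the union over ``seeds`` of the connected components (default
    26-neighbour) of ``threshold_low <= volume <= threshold_high`` containing
    each seed. ``fill_holes`` closes internal cavities, which for lung masks
    folds the bright tumours back into the (dark) lung — matching the burden
    definition of tumour volume per *total* lung volume.

    Raises
    ------
    BadSeedError
        If a seed's intensity lies outside the band (reported with the value).
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise InvalidParameterError("volume must be 3-D")
    seeds = [tuple(int(c) for c in s) for s in seeds]
    if not seeds:
        raise InvalidParameterError("at least one seed point is required")
    for s in seeds:
        if any(c < 0 or c >= n for c, n in zip(s, volume.shape)):
            raise BadSeedError(f"seed {s} outside the grid", seed=s)
    band = (volume >= threshold_low) & (volume <= threshold_high)
    for s in seeds:
        if not band[s]:
            raise BadSeedError(
                f"seed {s} has intensity {volume[s]:.6g}, outside "
                f"[{threshold_low:.6g}, {threshold_high:.6g}]",
                seed=s,
                intensity=float(volume[s]),
            )
    structure = _STRUCT26 if connectivity == 26 else _STRUCT6
    comp, _ = ndimage.label(band, structure=structure)
    keep = {comp[s] for s in seeds}
    mask = np.isin(comp, sorted(keep))
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return Mask(mask, tuple(spacing), label=label, seed_points=tuple(seeds))


def volume_mm3(mask: Mask) -> float:
    """Voxel-count volumetry: count x voxel volume, reported to 3 decimals."""
    return round(mask.n_voxels * mask.voxel_volume_mm3, 3)


def split_tumours(mask: Mask, connectivity: int = 26) -> list:
    """Split a tumour mask into per-tumour component masks.

    Components are numbered 1..n in raster order of their first voxel, so IDs
    are stable across re-runs. Returns a list of (id, Mask) pairs.
    """
    structure = _STRUCT26 if connectivity == 26 else _STRUCT6
    comp, n = ndimage.label(mask.data, structure=structure)
    out = []
    for i in range(1, n + 1):
        out.append((i, Mask(comp == i, mask.spacing, label=f"{mask.label}_{i}")))
    return out


@dataclass(frozen=True)
class ThresholdBands:
    """Lung and tumour intensity bands derived from the tissue signal model."""

    lung: tuple
    tumour: tuple


def suggest_thresholds(scene: PhantomScene, seq: SequenceParams) -> ThresholdBands:
    """Bands from modal (band-free) tissue intensities.

    The lung band runs from zero to the midpoint of the lung-parenchyma and
    body intensities; the tumour band from the midpoint of the parenchyma and
    tumour intensities upward. This replaces interactive threshold picking
    with a reproducible rule.
    """
    lung_i = band_free_signal(scene.tissue_table[LABEL_LUNG], seq)
    body_i = band_free_signal(scene.tissue_table[LABEL_BODY], seq)
    tum_labels = [l for l in scene.tissue_table if l >= TUMOUR_LABEL_BASE]
    if tum_labels:
        tum_i = float(np.median(
            [band_free_signal(scene.tissue_table[l], seq) for l in tum_labels]
        ))
    else:
        from crbssfp.phantom import TUMOUR_TISSUE

        tum_i = band_free_signal(TUMOUR_TISSUE, seq)
    return ThresholdBands(
        lung=(0.0, 0.5 * (lung_i + body_i)),
        tumour=(0.5 * (lung_i + tum_i), np.inf),
    )


def lung_seeds_from_scene(scene: PhantomScene) -> list:
    """One seed voxel per lung-label connected component (each lobe)."""
    comp, n = ndimage.label(scene.label_volume == LABEL_LUNG, structure=_STRUCT26)
    seeds = []
    for i in range(1, n + 1):
        com = ndimage.center_of_mass(comp == i)
        idx = tuple(int(round(c)) for c in com)
        if comp[idx] != i:  # centre of mass fell outside (thin lobe): pick a voxel
            idx = tuple(np.argwhere(comp == i)[0])
        seeds.append(idx)
    return seeds


def tumour_seeds_from_scene(scene: PhantomScene) -> list:
    """Seed voxels at each truth tumour centre (the shared-seed workflow)."""
    seeds = []
    for tid in sorted(scene.tumour_truth):
        c = np.asarray(scene.tumour_truth[tid].centre_mm) / np.asarray(scene.spacing)
        idx = tuple(int(round(x - 0.5)) for x in c)
        if scene.label_volume[idx] != tid:
            idx = tuple(np.argwhere(scene.label_volume == tid)[0])
        seeds.append(idx)
    return seeds


def seeds_to_csv(seeds, path, label: str = "") -> None:
    pd.DataFrame(
        [(s[0], s[1], s[2], label) for s in seeds], columns=["x", "y", "z", "label"]
    ).to_csv(path, index=False)


def seeds_from_csv(path) -> list:
    df = pd.read_csv(path)
    return [tuple(int(v) for v in row) for row in df[["x", "y", "z"]].to_numpy()]
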