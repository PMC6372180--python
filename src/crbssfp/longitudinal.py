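"""Longitudinal tumour tracking, growth tables and cohort statistics.

After the two timepoints' lung masks are rigidly registered, each late-
timepoint tumour's seed (its mass-centroid voxel) is mapped through the
inverse transform into the early frame; if it lands inside (or within a small
radius of) an early tumour, the pair is linked and shares an identity. Late
tumours with no early partner are NEW — they first became visible at the
later timepoint — and are rendered "-" in the early column of the growth
table.

Per mouse and timepoint the table carries TTV (total tumour volume), AVT
(average volume per tumour) and SDV (population standard deviation of the
present volumes); absent entries are excluded from all three. Tumour burden
is 100 x TTV / lung volume. Group comparisons use the two-tailed,
unequal-variance (Welch) t-test, and all descriptive spreads are population
standard deviations (divisor n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from crbssfp.errors import InvalidParameterError, UntrackableError
from crbssfp.quantify import Mask, volume_mm3
from crbssfp.register import FAIL, RigidTransform

ABSENT = None
#: default link radius around the transformed seed, in voxels
LINK_RADIUS_VOX = 2.0


def population_sd(values) -> float:
    """Standard deviation with divisor n (population convention)."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise InvalidParameterError("population SD of an empty set is undefined")
    return float(np.std(v, ddof=0))


@dataclass(frozen=True)
class Correspondence:
    """Tracking outcome: late-timepoint id -> early id (or NEW)."""

    links: dict  # t2_id -> t1_id
    new_t2: tuple  # t2 ids with no early partner
    unmatched_t1: tuple  # early ids with no late partner (regressions)


def _seed_in_mm(mask: Mask) -> np.ndarray:
    c = np.asarray(mask.centroid_voxel(), dtype=float)
    return (c + 0.5) * np.asarray(mask.spacing)


def track_tumours(
    masks_t1,
    masks_t2,
    transform: RigidTransform,
    tier: str,
    link_radius_vox: float = LINK_RADIUS_VOX,
    manual_links: dict = None,
) -> Correspondence:
    """Link per-tumour masks across timepoints through a shared seed point.

    ``masks_t1``/``masks_t2`` are lists of ``(id, Mask)`` pairs in their
    native frames; ``transform`` maps early-frame mm coordinates to the late
    frame. Each late tumour's centroid seed is carried through the inverse
    transform; the nearest early tumour within ``link_radius_vox`` voxels is
    linked (greedy nearest-first, one-to-one). In the MANUAL tier,
    ``manual_links`` (t2_id -> t1_id or None) overrides the automatic pairing
    — the operator repositioning seeds by hand.

    Raises
    ------
    UntrackableError
        For the FAIL tier: individual tumours cannot be identified across
        timepoints, although aggregate volumetry remains possible.
    """
    if tier == FAIL:
        raise UntrackableError(
            "registration QC failed; individual tumour tracking is not possible "
            "(aggregate volumetry still is)"
        )
    t1 = list(masks_t1)
    t2 = list(masks_t2)
    inv = transform.inverse()
    radius_mm = link_radius_vox * float(
        np.min([np.min(m.spacing) for _, m in t1]) if t1 else 1.0
    )

    # distance from each back-transformed t2 seed to each t1 tumour surface/volume
    candidates = []
    t1_points = {tid: (np.argwhere(m.data) + 0.5) * np.asarray(m.spacing)
                 for tid, m in t1}
    for tid2, m2 in t2:
        seed_mm = inv.apply(_seed_in_mm(m2)[np.newaxis, :])[0]
        for tid1, pts in t1_points.items():
            d = float(np.min(np.linalg.norm(pts - seed_mm, axis=1)))
            if d <= radius_mm:
                candidates.append((d, tid2, tid1))

    links = {}
    used_t1 = set()
    for d, tid2, tid1 in sorted(candidates):
        if tid2 in links or tid1 in used_t1:
            continue
        links[tid2] = tid1
        used_t1.add(tid1)

    if manual_links:
        for tid2, tid1 in manual_links.items():
            old = links.pop(tid2, None)
            if old is not None:
                used_t1.discard(old)
            if tid1 is not None:
                links = {k: v for k, v in links.items() if v != tid1}
                links[tid2] = tid1
                used_t1.add(tid1)

    new_t2 = tuple(tid for tid, _ in t2 if tid not in links)
    unmatched_t1 = tuple(tid for tid, _ in t1 if tid not in set(links.values()))
    return Correspondence(links=links, new_t2=new_t2, unmatched_t1=unmatched_t1)


@dataclass(frozen=True)
class MouseGrowthRecord:
    """One mouse's tracked volumes: rows are tumours, two timepoints each."""

    mouse: str
    volumes: tuple  # ((name, v_t1_or_None, v_t2), ...) in table row order
    lung_volume_t1: float
    lung_volume_t2: float

    def present(self, timepoint: int):
        return [row[1 + timepoint] for row in self.volumes if row[1 + timepoint] is not None]

    def ttv(self, timepoint: int) -> float:
        return round(sum(self.present(timepoint)), 3)

    def avt(self, timepoint: int):
        vals = self.present(timepoint)
        return round(sum(vals) / len(vals), 3) if vals else None

    def sdv(self, timepoint: int):
        vals = self.present(timepoint)
        return round(population_sd(vals), 3) if vals else None

    def burden_percent(self, timepoint: int) -> float:
        lung = (self.lung_volume_t1, self.lung_volume_t2)[timepoint]
        if lung <= 0:
            raise InvalidParameterError("tumour burden undefined for zero lung volume")
        return 100.0 * self.ttv(timepoint) / lung


def build_growth_table(
    correspondence: Correspondence,
    volumes_t1: dict,
    volumes_t2: dict,
    lung_volumes: tuple,
    mouse: str = "M1",
) -> MouseGrowthRecord:
    """Assemble one mouse's growth record from tracking output and volumes.

    Linked tumours come first (ordered by their early-timepoint id), then NEW
    tumours (by late id); rows are renamed T1..Tn. Volumes are rounded to
    three decimals; ABSENT early entries stay ``None``.
    """
    for v in list(volumes_t1.values()) + list(volumes_t2.values()):
        if v < 0:
            raise InvalidParameterError("volumes must be non-negative")
    rows = []
    linked = sorted(correspondence.links.items(), key=lambda kv: kv[1])
    for tid2, tid1 in linked:
        rows.append((round(volumes_t1[tid1], 3), round(volumes_t2[tid2], 3)))
    for tid2 in correspondence.new_t2:
        rows.append((None, round(volumes_t2[tid2], 3)))
    named = tuple((f"T{i+1}", v1, v2) for i, (v1, v2) in enumerate(rows))
    return MouseGrowthRecord(
        mouse=mouse,
        volumes=named,
        lung_volume_t1=float(lung_volumes[0]),
        lung_volume_t2=float(lung_volumes[1]),
    )


class GrowthTable:
    """Cohort growth table: per-tumour rows, (mouse x timepoint) columns."""

    TIMEPOINT_NAMES = ("w13", "w18")

    def __init__(self, records):
        self.records = list(records)

    def to_frame(self) -> pd.DataFrame:
        """Wide layout with TTV/AVT/SDV summary rows; ABSENT rendered '-'."""
        n_rows = max((len(r.volumes) for r in self.records), default=0)
        index = [f"T{i+1}" for i in range(n_rows)] + ["TTV", "AVT", "SDV"]
        data = {}
        for rec in self.records:
            for tp, tp_name in enumerate(self.TIMEPOINT_NAMES):
                col = []
                for i in range(n_rows):
                    if i < len(rec.volumes):
                        v = rec.volumes[i][1 + tp]
                        col.append("-" if v is None else f"{v:.3f}")
                    else:
                        col.append("")
                col.append(f"{rec.ttv(tp):.3f}")
                avt, sdv = rec.avt(tp), rec.sdv(tp)
                col.append("" if avt is None else f"{avt:.3f}")
                col.append("" if sdv is None else f"{sdv:.3f}")
                data[(rec.mouse, tp_name)] = col
        return pd.DataFrame(data, index=index)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def burden_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mouse": [r.mouse for r in self.records],
                "burden_w13_percent": [r.burden_percent(0) for r in self.records],
                "burden_w18_percent": [r.burden_percent(1) for r in self.records],
            }
        )


@dataclass(frozen=True)
class SummaryStats:
    """Welch comparison of two groups, population-SD descriptives."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    df: float
    p_value: float

    def as_dict(self) -> dict:
        return {
            "mean_a": self.mean_a, "sd_a": self.sd_a, "n_a": self.n_a,
            "mean_b": self.mean_b, "sd_b": self.sd_b, "n_b": self.n_b,
            "t": self.t_statistic, "df": self.df, "p": self.p_value,
        }


def group_stats(values_a, values_b) -> SummaryStats:
    """Two-tailed, unequal-variance (Welch) t-test with population SDs.

    The t statistic uses sample variances (Satterthwaite degrees of freedom,
    the standard Welch construction); the *reported* descriptive SDs use
    divisor n, matching how cohort results are conventionally printed here.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("each group needs at least two values")
    if np.std(a) == 0 and np.std(b) == 0 and a.mean() == b.mean():
        # identical constant groups: t = 0, p = 1 (scipy returns nan here)
        t_stat, p, df = 0.0, 1.0, float(a.size + b.size - 2)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t_stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
        if math.isnan(t_stat):
            t_stat, p = 0.0, 1.0
    return SummaryStats(
        mean_a=float(a.mean()), sd_a=population_sd(a), n_a=int(a.size),
        mean_b=float(b.mean()), sd_b=population_sd(b), n_b=int(b.size),
        t_statistic=t_stat, df=df, p_value=p,
    )
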