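"""End-to-end study orchestration.

``run_study`` simulates a small longitudinal cohort: for each mouse a thorax
phantom is generated and evolved to a second timepoint (grown plus newly
appeared tumours, with a small rigid repose emulating re-positioning in the
cradle); each timepoint is imaged with four phase-cycled, prospectively gated
bSSFP acquisitions; the band-free combination is segmented (lungs, tumours);
the early lung mask is ICP-registered to the late one with Dice QC; tumours
are tracked through shared seed points; and growth tables plus cohort Welch
statistics are assembled. All artefacts regenerate byte-identically from the
persisted config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from crbssfp import gating, longitudinal, phantom, physio, quantify, recon, register
from crbssfp.errors import InvalidParameterError
from crbssfp.seeding import child_seed
from crbssfp.tables import load_table_fixtures  # re-exported pipeline surface

__all__ = ["RunConfig", "StudyReport", "run_study", "load_table_fixtures"]

logger = logging.getLogger("crbssfp")


@dataclass(frozen=True)
class RunConfig:
    """Everything a study run needs; serialisable, hence reproducible.

    ``grid`` selects the full acquisition geometry (256 x 128 x 128 at
    0.2 mm) or a reduced 64^3 grid at 0.4 mm for fast runs. Growth
    multipliers per tumour are drawn uniformly from ``growth_range`` and new
    tumours appear at the second timepoint, mirroring a slow-growing
    stochastic tumour model between weeks 13 and 18.
    """

    n_mice: int = 2
    seed: int = 0
    grid: str = "reduced"  # "full" or "reduced"
    n_tumours_t1: int = 4
    new_tumours_t2: int = 3
    growth_range: tuple = (2.0, 4.0)
    lung_volume_target: float = 440.0
    tumour_volume_range: tuple = None  # per-grid default if None
    repose_shift_mm: tuple = (0.6, 0.4, 0.2)
    repose_rotation_deg: float = 2.0
    noise_fraction: float = 0.02  # k-space noise sd as fraction of peak signal
    heart_rate: float = 500.0
    resp_rate: float = 45.0
    quiescent_fraction: float = 0.67
    rr_jitter_sd: float = 0.005
    resp_jitter_frac: float = 0.03
    setup_minutes: float = 5.0  # per-mouse non-scan overhead (positioning, shim, cal)
    out_dir: str = None
    verbosity: str = "INFO"

    def sequence(self) -> gating.SequenceParams:
        if self.grid == "full":
            return gating.SequenceParams()
        if self.grid == "reduced":
            return gating.SequenceParams.reduced(64)
        raise InvalidParameterError("grid must be 'full' or 'reduced'")

    def gate(self) -> gating.GatingParams:
        return gating.GatingParams()

    def physio(self, seed: int) -> physio.PhysioParams:
        return physio.PhysioParams(
            heart_rate=self.heart_rate,
            resp_rate=self.resp_rate,
            quiescent_fraction=self.quiescent_fraction,
            rr_jitter_sd=self.rr_jitter_sd,
            resp_jitter_frac=self.resp_jitter_frac,
            seed=seed,
        )

    def tumour_range(self) -> tuple:
        if self.tumour_volume_range is not None:
            return tuple(self.tumour_volume_range)
        # lower bound >= one voxel volume on the chosen grid
        return (0.056, 0.7) if self.grid == "full" else (0.256, 1.4)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in ("growth_range", "repose_shift_mm", "tumour_volume_range"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return RunConfig(**d)


@dataclass
class MouseResult:
    mouse: str
    scan_minutes: tuple  # per timepoint (4 phase cycles each)
    dice: float
    tier: str
    record: object  # MouseGrowthRecord or None for FAIL tier
    n_tumours: tuple  # per timepoint
    lung_volumes: tuple
    transform: object


@dataclass
class StudyReport:
    config: RunConfig
    mice: list
    growth_table: object  # GrowthTable over trackable mice
    cohort_stats: object  # SummaryStats TTV w13 vs w18 (None if < 2 mice)
    mean_scan_minutes: float
    throughput_mice_per_hour: float

    def summary(self) -> dict:
        return {
            "n_mice": len(self.mice),
            "per_mouse": [
                {
                    "mouse": m.mouse,
                    "scan_minutes": list(m.scan_minutes),
                    "dice": m.dice,
                    "tier": m.tier,
                    "n_tumours": list(m.n_tumours),
                    "lung_volumes_mm3": list(m.lung_volumes),
                }
                for m in self.mice
            ],
            "mean_scan_minutes_per_session": self.mean_scan_minutes,
            "setup_minutes": self.config.setup_minutes,
            "throughput_mice_per_hour": self.throughput_mice_per_hour,
            "note": "scan minutes exclude shimming/frequency/RF calibration, "
                    "which is budgeted in setup_minutes",
            "cohort_ttv_stats": None if self.cohort_stats is None
            else self.cohort_stats.as_dict(),
        }


def _acquire_timepoint(scene, cfg: RunConfig, seq, gate, seed):
    """Four phase-cycled gated acquisitions -> band-free magnitude volume."""
    volumes = []
    durations = []
    peak = max(
        recon.band_free_signal(scene.tissue_for_label(int(l)), seq)
        for l in np.unique(scene.label_volume) if l != phantom.LABEL_BACKGROUND
    )
    noise_sd = cfg.noise_fraction * peak
    for i, cycle in enumerate(seq.phase_cycles_deg):
        params = cfg.physio(child_seed(seed, 10 + i))
        trace = physio.simulate_trace(
            params, gating._estimate_trace_duration(seq, gate, params) * 2
        )
        log = gating.schedule_scan(seq, gate, trace, phase_cycle_index=i)
        vol = recon.acquire_volume(
            scene, log, seq, cycle, noise_sd=noise_sd, seed=child_seed(seed, 20 + i)
        )
        volumes.append(vol)
        durations.append(log.scan_duration)
    combined = recon.combine_phase_cycles(volumes)
    return combined, sum(durations) / 60.0


def _segment_timepoint(combined, scene, seq):
    bands = quantify.suggest_thresholds(scene, seq)
    lung = quantify.segment(
        combined, scene.spacing, quantify.lung_seeds_from_scene(scene),
        *bands.lung, label="lung", fill_holes=True,
    )
    tumour_seeds = quantify.tumour_seeds_from_scene(scene)
    if tumour_seeds:
        tum = quantify.segment(
            combined, scene.spacing, tumour_seeds, bands.tumour[0],
            label="tumour",
        )
        per_tumour = quantify.split_tumours(tum)
    else:
        per_tumour = []
    return lung, per_tumour


def run_study(config: RunConfig) -> StudyReport:
    """Simulate and quantify a longitudinal cohort; see the module docstring.

    Any stage failure aborts with a stage-tagged exception. When
    ``config.out_dir`` is set, all artefacts (config snapshot, volumes, masks,
    transforms, growth tables, summary JSON) are written there.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    out = None
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    seq = config.sequence()
    gate = config.gate()
    gate.check_against(config.physio(0))
    results = []
    records = []
    ttv13, ttv18 = [], []

    for m in range(config.n_mice):
        mouse = f"SIM{m+1}"
        mseed = child_seed(config.seed, 100 + m)
        logger.info("[%s] generating phantom (grid=%s)", mouse, config.grid)
        scene13 = phantom.make_scene(
            n_tumours=config.n_tumours_t1,
            tumour_volume_range=config.tumour_range(),
            lung_volume_target=config.lung_volume_target,
            seed=child_seed(mseed, 1),
            shape=tuple(seq.matrix),
            spacing=seq.voxel_size_mm,
        )
        rng = np.random.default_rng(child_seed(mseed, 2))
        growth = {
            tid: float(rng.uniform(*config.growth_range))
            for tid in scene13.tumour_truth
        }
        scene18 = phantom.evolve_scene(
            scene13,
            growth_factors=growth,
            new_tumours=config.new_tumours_t2,
            new_tumour_volume_range=config.tumour_range(),
            seed=child_seed(mseed, 3),
            shift_mm=config.repose_shift_mm,
            rotation_deg=config.repose_rotation_deg,
        )

        masks = {}
        per_tumour = {}
        scan_minutes = []
        for tp, scene in (("w13", scene13), ("w18", scene18)):
            logger.info("[%s %s] acquiring 4 phase cycles", mouse, tp)
            combined, minutes = _acquire_timepoint(
                scene, config, seq, gate, child_seed(mseed, 50 if tp == "w13" else 60)
            )
            lung, tums = _segment_timepoint(combined, scene, seq)
            masks[tp] = lung
            per_tumour[tp] = tums
            scan_minutes.append(minutes)
            if out:
                from crbssfp.nifti_io import save_volume

                save_volume(out / f"{mouse}_{tp}_magnitude.nii",
                            combined.astype(np.float32), scene.spacing)
                save_volume(out / f"{mouse}_{tp}_lungmask.nii",
                            lung.data.astype(np.uint8), scene.spacing)

        logger.info("[%s] registering w13 -> w18", mouse)
        transform, d, tier, _ = register.register_and_qc(masks["w13"], masks["w18"])
        vols13 = {tid: quantify.volume_mm3(mk) for tid, mk in per_tumour["w13"]}
        vols18 = {tid: quantify.volume_mm3(mk) for tid, mk in per_tumour["w18"]}
        lungs = (quantify.volume_mm3(masks["w13"]), quantify.volume_mm3(masks["w18"]))

        record = None
        if tier != register.FAIL:
            corr = longitudinal.track_tumours(
                per_tumour["w13"], per_tumour["w18"], transform, tier
            )
            record = longitudinal.build_growth_table(
                corr, vols13, vols18, lungs, mouse=mouse
            )
            records.append(record)
            ttv13.append(record.ttv(0))
            ttv18.append(record.ttv(1))
        if out:
            transform.save(out / f"{mouse}_w13_to_w18_transform.txt")

        results.append(
            MouseResult(
                mouse=mouse,
                scan_minutes=tuple(scan_minutes),
                dice=d,
                tier=tier,
                record=record,
                n_tumours=(len(per_tumour["w13"]), len(per_tumour["w18"])),
                lung_volumes=lungs,
                transform=transform,
            )
        )

    table = longitudinal.GrowthTable(records)
    stats = None
    if len(ttv13) >= 2:
        stats = longitudinal.group_stats(ttv13, ttv18)
    all_minutes = [mm for r in results for mm in r.scan_minutes]
    mean_scan = float(np.mean(all_minutes))
    throughput = 60.0 / (mean_scan + config.setup_minutes)

    report = StudyReport(
        config=config,
        mice=results,
        growth_table=table,
        cohort_stats=stats,
        mean_scan_minutes=mean_scan,
        throughput_mice_per_hour=throughput,
    )
    if out:
        table.to_csv(out / "growth_table.csv")
        table.burden_frame().to_csv(out / "tumour_burden.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(report.summary(), fh, indent=2)
    return report
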