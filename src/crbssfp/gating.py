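"""Prospective cardio-respiratory gating scheduler.

The scan alternates between two sections: a steady-state maintenance loop
that plays RF at constant TR while polling a 0/5 V control signal, and a data
section that acquires one block of N phase-encode lines whenever the control
signal fires. The control signal is generated only from interbreath R-waves,
so blocks are acquired exclusively during respiratory quiescence. A breath is
detected when the time since the previous valid trigger exceeds a counter
threshold (~250 ms: longer than two heartbeats, shorter than a breath); the
two blocks acquired immediately before that gap are presumed corrupted by
early chest motion and their lines are re-enqueued at the head of the pending
queue, so reacquisition happens immediately after the same breath ends.

The maintenance loop is modelled as elapsed time only: its observable effect
(constant TR, no transient between blocks) is inherited by the reconstruction
module's steady-state assumption.
"""

from __future__ import annotations

import json
import math
from collections import Counter, deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from crbssfp.errors import InsufficientTraceError, InvalidParameterError
from crbssfp.physio import PhysioParams, PhysioTrace, simulate_trace
from crbssfp.seeding import child_seed

CLEAN = "CLEAN"
CORRUPT_REACQUIRED = "CORRUPT_REACQUIRED"


@dataclass(frozen=True)
class SequenceParams:
    """bSSFP acquisition constants.

    Defaults reproduce the 7 T protocol this package models: TR 2.8 ms,
    TE 1.4 ms, 16 us hard pulse, 30 degree flip, FOV 51.2 x 25.6 x 25.6 mm^3,
    matrix 256 x 128 x 128 (200 um isotropic), 32 k-lines per R-wave, and four
    RF phase-cycle increments 0/90/180/270 degrees. The readout direction
    (axis 0) is fully sampled each excitation; only the matrix[1] x matrix[2]
    phase-encode grid is scheduled.
    """

    TR: float = 2.8e-3
    TE: float = 1.4e-3
    flip_angle_deg: float = 30.0
    rf_duration: float = 16e-6
    FOV_mm: tuple = (51.2, 25.6, 25.6)
    matrix: tuple = (256, 128, 128)
    lines_per_block: int = 32
    phase_cycles_deg: tuple = (0.0, 90.0, 180.0, 270.0)

    def __post_init__(self):
        if self.TR <= 0 or self.TE <= 0:
            raise InvalidParameterError("TR and TE must be positive")
        if abs(self.TE - self.TR / 2.0) > 1e-12:
            raise InvalidParameterError("balanced SSFP requires TE = TR/2")
        if self.lines_per_block < 1:
            raise InvalidParameterError("lines_per_block must be >= 1")
        if len(self.FOV_mm) != 3 or len(self.matrix) != 3:
            raise InvalidParameterError("FOV and matrix must be length-3")
        if any(m < 1 for m in self.matrix) or any(f <= 0 for f in self.FOV_mm):
            raise InvalidParameterError("matrix and FOV entries must be positive")

    @property
    def n_phase_lines(self) -> int:
        return int(self.matrix[1] * self.matrix[2])

    @property
    def n_blocks(self) -> int:
        return math.ceil(self.n_phase_lines / self.lines_per_block)

    @property
    def voxel_size_mm(self) -> tuple:
        return tuple(f / m for f, m in zip(self.FOV_mm, self.matrix))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @classmethod
    def reduced(cls, n: int = 64) -> "SequenceParams":
        """A small-grid preset (default 64^3 at 0.4 mm) for fast runs."""
        return cls(FOV_mm=(0.4 * n,) * 3, matrix=(n,) * 3)


@dataclass(frozen=True)
class GatingParams:
    """Breath-detection counter threshold and reacquisition depth.

    The 250 ms default sits between two cardiac R-R intervals and one breath
    at the maintained physiology (500 bpm heart, 40-60 bpm respiration).
    """

    breath_counter_threshold: float = 0.250
    reacquire_blocks: int = 2

    def __post_init__(self):
        if self.breath_counter_threshold <= 0:
            raise InvalidParameterError("breath_counter_threshold must be positive")
        if self.reacquire_blocks < 0:
            raise InvalidParameterError("reacquire_blocks must be >= 0")

    def check_against(self, physio: PhysioParams) -> None:
        """Raise unless the counter separates heartbeats from breaths."""
        if self.breath_counter_threshold <= 2 * physio.rr_interval:
            raise InvalidParameterError("counter must exceed 2 cardiac R-R intervals")
        if self.breath_counter_threshold >= physio.resp_period:
            raise InvalidParameterError("counter must be shorter than one breath cycle")


@dataclass
class BlockRecord:
    """One acquired block: which lines, when, and its final status."""

    trigger_time: float
    block_index: int
    line_start: int
    line_stop: int  # exclusive
    status: str = CLEAN

    @property
    def n_lines(self) -> int:
        return self.line_stop - self.line_start


@dataclass
class AcquisitionLog:
    """Ordered record of one gated 3D acquisition."""

    seq: SequenceParams
    records: list = field(default_factory=list)
    scan_duration: float = 0.0
    n_triggers_used: int = 0
    n_breaths: int = 0
    n_reacquired_blocks: int = 0
    first_trigger_time: float = 0.0
    phase_cycle_index: int = 0

    def clean_records(self) -> list:
        return [r for r in self.records if r.status == CLEAN]

    def assert_line_conservation(self) -> None:
        """Every phase-encode line must be CLEAN exactly once."""
        counts = Counter()
        for r in self.clean_records():
            for line in range(r.line_start, r.line_stop):
                counts[line] += 1
        expected = set(range(self.seq.n_phase_lines))
        if set(counts) != expected or any(v != 1 for v in counts.values()):
            raise AssertionError("phase-encode lines are not CLEAN exactly once")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.trigger_time, r.block_index, r.line_start, r.line_stop, r.status)
                for r in self.records
            ],
            columns=["trigger_time", "block_index", "line_start", "line_stop", "status"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "scan_duration_s": self.scan_duration,
            "n_triggers_used": self.n_triggers_used,
            "n_breaths": self.n_breaths,
            "n_reacquired_blocks": self.n_reacquired_blocks,
            "duty_cycle": duty_cycle(self),
            "phase_cycle_index": self.phase_cycle_index,
        }

    def summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def _block_table(seq: SequenceParams) -> list:
    """Pending blocks in linear line order: (block_index, start, stop)."""
    n = seq.lines_per_block
    return [
        (i, i * n, min((i + 1) * n, seq.n_phase_lines)) for i in range(seq.n_blocks)
    ]


def schedule_scan(
    seq: SequenceParams,
    gate: GatingParams,
    trace: PhysioTrace,
    phase_cycle_index: int = 0,
) -> AcquisitionLog:
    """Run the gating controller over a physiological trace.

    On each VALID (interbreath) R-wave one block of ``lines_per_block``
    consecutive lines is dequeued and acquired. When the gap since the
    previous valid trigger exceeds the breath counter threshold, the last
    ``reacquire_blocks`` still-clean blocks are marked CORRUPT_REACQUIRED and
    their lines re-enqueued at the queue head, so they are the first blocks
    acquired after the breath. The scan terminates when every line is clean.

    ``scan_duration`` is the elapsed time from the first used trigger to the
    completion of the final block (trigger time + lines x TR).

    Raises
    ------
    InsufficientTraceError
        If the trace ends before all blocks are clean; carries progress.
    """
    queue = deque(_block_table(seq))
    total_blocks = seq.n_blocks
    log = AcquisitionLog(seq=seq, phase_cycle_index=phase_cycle_index)
    valid_times = trace.r_wave_times[trace.r_wave_valid()]

    last_valid_t = None
    finish_time = None
    for t in valid_times:
        if last_valid_t is not None and (t - last_valid_t) > gate.breath_counter_threshold:
            log.n_breaths += 1
            # Corrupt the blocks of the last `reacquire_blocks` R-waves that
            # preceded the breath; ones already flagged by an earlier breath
            # are still pending reacquisition and count toward the quota.
            quota = gate.reacquire_blocks
            to_requeue = []
            for rec in reversed(log.records):
                if quota == 0:
                    break
                quota -= 1
                if rec.status == CLEAN:
                    rec.status = CORRUPT_REACQUIRED
                    log.n_reacquired_blocks += 1
                    to_requeue.append(rec)
            for rec in to_requeue:  # earliest-corrupted block re-acquired first
                queue.appendleft((rec.block_index, rec.line_start, rec.line_stop))
        block_index, start, stop = queue.popleft()
        rec = BlockRecord(trigger_time=float(t), block_index=block_index,
                          line_start=start, line_stop=stop)
        log.records.append(rec)
        log.n_triggers_used += 1
        last_valid_t = t
        if not queue:
            finish_time = float(t) + rec.n_lines * seq.TR
            break

    if finish_time is None:
        raise InsufficientTraceError(
            f"trace exhausted with {len(queue)} of {total_blocks} blocks pending",
            blocks_done=total_blocks - len(queue),
            blocks_total=total_blocks,
        )

    log.first_trigger_time = float(log.records[0].trigger_time)
    log.scan_duration = finish_time - log.first_trigger_time
    log.assert_line_conservation()
    return log


def duty_cycle(log: AcquisitionLog) -> float:
    """Fraction of the scan spent acquiring clean data.

    ``(clean line count x TR) / scan_duration``; strictly below the no-breath
    ceiling ``N x TR / RR`` whenever reacquisition occurred.
    """
    if not log.records:
        raise InvalidParameterError("duty cycle of an empty log is undefined")
    clean_lines = sum(r.n_lines for r in log.clean_records())
    return clean_lines * log.seq.TR / log.scan_duration


@dataclass(frozen=True)
class ProtocolTiming:
    """Per-phase-cycle scan durations and their total, in seconds."""

    per_cycle_s: tuple
    total_s: float
    logs: tuple = ()

    @property
    def total_minutes(self) -> float:
        return self.total_s / 60.0


def _estimate_trace_duration(seq: SequenceParams, gate: GatingParams,
                             params: PhysioParams) -> float:
    valid_per_s = params.quiescent_fraction * params.heart_rate / 60.0
    lost_per_s = gate.reacquire_blocks / params.resp_period
    net = max(valid_per_s - lost_per_s, 0.5)
    return seq.n_blocks / net * 1.5 + 3 * params.resp_period


def full_protocol_time(
    seq: SequenceParams,
    gate: GatingParams,
    params: PhysioParams,
    seed: int = 0,
    inter_scan_gap: float = 0.0,
    keep_logs: bool = False,
) -> ProtocolTiming:
    """Simulate one gated scan per RF phase cycle and total the durations.

    Each cycle runs on a freshly simulated trace (child seed per cycle); the
    total is the sum of per-cycle durations plus any configured inter-scan
    gaps. Calibration overhead (shimming, frequency and RF calibration) is
    not part of the scan time and is reported separately by the pipeline.
    """
    if len(seq.phase_cycles_deg) < 1:
        raise InvalidParameterError("at least one phase cycle is required")
    durations = []
    logs = []
    for i in range(len(seq.phase_cycles_deg)):
        cycle_params = params.reseeded(child_seed(seed, i))
        duration_est = _estimate_trace_duration(seq, gate, cycle_params)
        log = None
        for _ in range(6):
            trace = simulate_trace(cycle_params, duration_est)
            try:
                log = schedule_scan(seq, gate, trace, phase_cycle_index=i)
                break
            except InsufficientTraceError:
                duration_est *= 2.0
        if log is None:
            raise InsufficientTraceError(
                "could not complete scan within a bounded trace length"
            )
        durations.append(log.scan_duration)
        if keep_logs:
            logs.append(log)
    total = float(sum(durations) + inter_scan_gap * (len(durations) - 1))
    return ProtocolTiming(tuple(durations), total, tuple(logs))
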