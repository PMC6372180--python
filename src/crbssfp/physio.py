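"""Synthetic cardio-respiratory traces for prospective gating.

The scanner's gating controller consumes two monitored signals: ECG R-waves
(cardiac triggers) and a respiration signal that partitions each breathing
cycle into a quiescent segment, during which the chest is still and data may
be acquired, and a motion segment around the breath itself. This module
synthesises both as event streams.

Conventions
-----------
* Each respiration cycle is a triple ``(quiescent_start, motion_start,
  cycle_end)``; cycles tile time without gaps.
* Window membership is half-open, ``[start, end)``: an R-wave falling exactly
  on ``motion_start`` belongs to the motion segment and is suppressed; one
  falling exactly on ``cycle_end`` belongs to the next cycle's quiescent
  segment.
* Jitter draws are Gaussian, truncated at +/-3 sd; R-R intervals are floored
  at 10 ms so pathological draws cannot produce non-physical event orderings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from crbssfp.errors import InvalidParameterError

VALID = "VALID"
SUPPRESSED = "SUPPRESSED"

#: Physiology maintained in the animal protocol this simulator emulates:
#: respiration held at 40-60 breaths/min with ~60-70% of each cycle quiescent.
PRESET_RESP_RANGE = (40.0, 60.0)
PRESET_QUIESCENT_RANGE = (0.60, 0.70)


@dataclass(frozen=True)
class PhysioParams:
    """Rates and variability of the simulated animal.

    Parameters
    ----------
    heart_rate : float
        Beats per minute. The anaesthetised-mouse default is 500 bpm.
    resp_rate : float
        Breaths per minute. The maintained protocol range is 40-60.
    quiescent_fraction : float
        Fraction of each respiration cycle available for imaging (0, 1].
        A value of 1.0 is the degenerate no-motion limit (motion length 0).
    rr_jitter_sd : float
        Standard deviation of the R-R interval jitter, seconds.
    resp_jitter_frac : float
        Cycle-length jitter sd as a fraction of the nominal period; exercises
        the controller's adaptation to instantaneous respiration-rate changes.
    seed : int
        Seed for the jitter random stream.
    """

    heart_rate: float = 500.0
    resp_rate: float = 45.0
    quiescent_fraction: float = 0.67
    rr_jitter_sd: float = 0.005
    resp_jitter_frac: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.heart_rate <= 0 or self.resp_rate <= 0:
            raise InvalidParameterError("heart_rate and resp_rate must be positive")
        if not (0.0 < self.quiescent_fraction <= 1.0):
            raise InvalidParameterError("quiescent_fraction must be in (0, 1]")
        if self.heart_rate <= self.resp_rate:
            raise InvalidParameterError("heart_rate must exceed resp_rate")
        if self.rr_jitter_sd < 0 or self.resp_jitter_frac < 0:
            raise InvalidParameterError("jitter parameters must be non-negative")
        if not self.in_preset_range:
            warnings.warn(
                "physiology outside the maintained protocol ranges "
                f"(resp {PRESET_RESP_RANGE} bpm, quiescent {PRESET_QUIESCENT_RANGE}); "
                "simulation proceeds",
                stacklevel=2,
            )

    @property
    def in_preset_range(self) -> bool:
        lo, hi = PRESET_RESP_RANGE
        qlo, qhi = PRESET_QUIESCENT_RANGE
        return lo <= self.resp_rate <= hi and qlo <= self.quiescent_fraction <= qhi

    @property
    def rr_interval(self) -> float:
        """Nominal R-R interval in seconds."""
        return 60.0 / self.heart_rate

    @property
    def resp_period(self) -> float:
        """Nominal respiration cycle length in seconds."""
        return 60.0 / self.resp_rate

    @property
    def quiescent_length(self) -> float:
        """Nominal quiescent-segment length in seconds."""
        return self.quiescent_fraction * self.resp_period

    def reseeded(self, seed: int) -> "PhysioParams":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class PhysioTrace:
    """Timestamped R-wave events plus respiration windows.

    Attributes
    ----------
    r_wave_times : ndarray, shape (n_beats,)
        Strictly increasing event times, seconds.
    breath_windows : ndarray, shape (n_cycles, 3)
        Columns ``(quiescent_start, motion_start, cycle_end)``; rows tile time.
    """

    r_wave_times: np.ndarray
    breath_windows: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.r_wave_times, dtype=float)
        w = np.asarray(self.breath_windows, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise InvalidParameterError("r_wave_times must be strictly increasing 1-D")
        if w.ndim != 2 or w.shape[1] != 3:
            raise InvalidParameterError("breath_windows must have shape (n, 3)")
        if np.any(w[:, 0] > w[:, 1]) or np.any(w[:, 1] > w[:, 2]):
            raise InvalidParameterError("each window must satisfy qs <= ms <= ce")
        if w.shape[0] > 1 and not np.allclose(w[:-1, 2], w[1:, 0]):
            raise InvalidParameterError("breath windows must tile time without gaps")
        object.__setattr__(self, "r_wave_times", t)
        object.__setattr__(self, "breath_windows", w)

    @property
    def duration(self) -> float:
        return float(self.breath_windows[-1, 2])

    def r_wave_valid(self) -> np.ndarray:
        """Boolean array: True where an R-wave lies in a quiescent segment."""
        starts = self.breath_windows[:, 0]
        idx = np.searchsorted(starts, self.r_wave_times, side="right") - 1
        idx = np.clip(idx, 0, len(starts) - 1)
        t = self.r_wave_times
        in_cycle = (t >= self.breath_windows[idx, 0]) & (t < self.breath_windows[idx, 2])
        quiescent = t < self.breath_windows[idx, 1]
        return in_cycle & quiescent

    def to_csv(self, path) -> None:
        """Serialise as an (event_time, event_type) table."""
        classify_triggers(self)  # validates
        rows = [(t, "r_wave") for t in self.r_wave_times]
        for qs, ms, ce in self.breath_windows:
            rows.append((qs, "quiescent_start"))
            rows.append((ms, "motion_start"))
            rows.append((ce, "cycle_end"))
        df = pd.DataFrame(sorted(rows), columns=["event_time", "event_type"])
        df.to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "PhysioTrace":
        df = pd.read_csv(path)
        r = df.loc[df.event_type == "r_wave", "event_time"].to_numpy(float)
        qs = df.loc[df.event_type == "quiescent_start", "event_time"].to_numpy(float)
        ms = df.loc[df.event_type == "motion_start", "event_time"].to_numpy(float)
        ce = df.loc[df.event_type == "cycle_end", "event_time"].to_numpy(float)
        windows = np.column_stack([np.sort(qs), np.sort(ms), np.sort(ce)])
        return PhysioTrace(np.sort(r), windows)


def _truncated_normal(rng: np.random.Generator, sd: float, n: int) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    return np.clip(rng.normal(0.0, sd, size=n), -3.0 * sd, 3.0 * sd)


def simulate_trace(params: PhysioParams, duration: float) -> PhysioTrace:
    """Simulate an ECG/respiration trace of at least ``duration`` seconds.

    R-wave intervals are ``60 / heart_rate`` with truncated Gaussian jitter
    (floor 10 ms); respiration cycles are ``60 / resp_rate`` with fractional
    jitter, each split into a quiescent then a motion segment. Deterministic
    for a fixed ``params.seed``.
    """
    if duration <= params.resp_period:
        raise InvalidParameterError("duration must exceed one respiration cycle")
    rng = np.random.default_rng(params.seed)

    n_cycles = int(np.ceil(duration / params.resp_period)) + 3
    jit = _truncated_normal(rng, params.resp_jitter_frac, n_cycles)
    lengths = np.maximum(params.resp_period * (1.0 + jit), 0.1 * params.resp_period)
    ends = np.cumsum(lengths)
    starts = ends - lengths
    motion_starts = starts + params.quiescent_fraction * lengths
    windows = np.column_stack([starts, motion_starts, ends])
    windows = windows[starts < duration]

    total = float(windows[-1, 2])
    n_beats = int(np.ceil(total / params.rr_interval)) + 3
    gaps = params.rr_interval + _truncated_normal(rng, params.rr_jitter_sd, n_beats)
    gaps = np.maximum(gaps, 0.010)
    times = np.concatenate([[0.0], np.cumsum(gaps)])
    times = times[times < total]
    return PhysioTrace(times, windows)


def classify_triggers(trace: PhysioTrace) -> pd.DataFrame:
    """Label every R-wave VALID (quiescent) or SUPPRESSED (motion segment).

    Returns a DataFrame with columns ``time`` and ``label``; the two labels
    partition all R-waves.
    """
    valid = trace.r_wave_valid()
    labels = np.where(valid, VALID, SUPPRESSED)
    return pd.DataFrame({"time": trace.r_wave_times, "label": labels})
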