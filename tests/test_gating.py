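"""Gating scheduler: queue arithmetic, breath handling, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crbssfp import gating, physio
from crbssfp.errors import InsufficientTraceError, InvalidParameterError
from tests.oracles import replay_schedule

GATE = gating.GatingParams()


def no_breath_trace(rr=0.12, duration=120.0):
    """Degenerate trace: motion length zero, so every R-wave is valid."""
    r = np.arange(0.0, duration, rr)
    windows = np.array([[0.0, duration, duration]])
    return physio.PhysioTrace(r, windows)


def test_default_geometry_gives_512_pending_blocks(seq_full):
    assert seq_full.n_phase_lines == 128 * 128
    assert seq_full.n_blocks == 512


def test_te_must_be_half_tr():
    with pytest.raises(InvalidParameterError):
        gating.SequenceParams(TR=2.8e-3, TE=1.0e-3)


def test_no_breath_limit_duration_and_duty(seq_full):
    """Without breaths the scan is 512 consecutive triggers at the RR."""
    log = gating.schedule_scan(seq_full, GATE, no_breath_trace())
    assert log.n_breaths == 0
    assert log.n_reacquired_blocks == 0
    expected = 511 * 0.12 + 32 * seq_full.TR
    assert log.scan_duration == pytest.approx(expected, abs=1e-9)
    # duty cycle approaches N*TR/RR
    assert gating.duty_cycle(log) == pytest.approx(
        32 * 0.0028 / 0.12, rel=0.01
    )


def test_scan_duration_under_protocol_physiology(seq_full, gate, quiet_physio):
    """~125 s per volume at 500 bpm / 45 bpm / 67% quiescent; < 150 s."""
    trace = physio.simulate_trace(quiet_physio, 200.0)
    log = gating.schedule_scan(seq_full, gate, trace)
    assert log.scan_duration < 150.0
    assert log.scan_duration == pytest.approx(125.0, rel=0.05)
    # exact agreement with the brute-force replay oracle
    oracle_blocks, oracle_duration = replay_schedule(seq_full, gate, trace)
    assert log.scan_duration == oracle_duration
    assert len(log.records) == len(oracle_blocks)
    for rec, blk in zip(log.records, oracle_blocks):
        assert rec.trigger_time == blk["time"]
        assert tuple(range(rec.line_start, rec.line_stop)) == blk["lines"]
        assert (rec.status == gating.CORRUPT_REACQUIRED) == blk["corrupt"]


def test_four_phase_cycle_protocol_time(seq_full, gate, quiet_physio):
    timing = gating.full_protocol_time(seq_full, gate, quiet_physio, seed=1)
    assert len(timing.per_cycle_s) == 4
    assert timing.total_s == pytest.approx(sum(timing.per_cycle_s))
    assert timing.total_s < 600.0
    assert timing.total_s == pytest.approx(4 * 125.0, rel=0.05)
    # jitter-free physiology: the four cycles are identical
    assert len(set(timing.per_cycle_s)) == 1


def test_single_phase_cycle_total_is_that_scan(gate, quiet_physio):
    seq = gating.SequenceParams(phase_cycles_deg=(0.0,))
    timing = gating.full_protocol_time(seq, gate, quiet_physio, seed=1)
    assert timing.total_s == timing.per_cycle_s[0]


def test_reacquisition_bookkeeping(seq_full, gate, quiet_physio):
    """Jitter-free: exactly reacquire_blocks blocks redone per breath."""
    trace = physio.simulate_trace(quiet_physio, 200.0)
    log = gating.schedule_scan(seq_full, gate, trace)
    assert log.n_breaths > 0
    assert log.n_reacquired_blocks == gate.reacquire_blocks * log.n_breaths
    assert gating.duty_cycle(log) < 32 * 0.0028 / 0.12


def test_monotone_in_quiescent_fraction_and_heart_rate(seq64, gate):
    def duration(hr, qf):
        p = physio.PhysioParams(heart_rate=hr, quiescent_fraction=qf,
                                rr_jitter_sd=0, resp_jitter_frac=0, seed=1)
        return gating.schedule_scan(seq64, gate, physio.simulate_trace(p, 120.0)
                                    ).scan_duration

    d = [duration(500, qf) for qf in (0.60, 0.65, 0.70)]
    assert d[0] >= d[1] >= d[2]
    d = [duration(hr, 0.67) for hr in (400, 500, 600)]
    assert d[0] >= d[1] >= d[2]


def test_insufficient_trace_reports_progress(seq_full, gate, quiet_physio):
    trace = physio.simulate_trace(quiet_physio, 10.0)
    with pytest.raises(InsufficientTraceError) as exc:
        gating.schedule_scan(seq_full, gate, trace)
    assert 0 < exc.value.blocks_done < exc.value.blocks_total == 512


def test_duty_cycle_of_empty_log_rejected(seq_full):
    with pytest.raises(InvalidParameterError):
        gating.duty_cycle(gating.AcquisitionLog(seq=seq_full))


def test_counter_threshold_validated_against_physiology(quiet_physio):
    gating.GatingParams().check_against(quiet_physio)  # fine at presets
    with pytest.raises(InvalidParameterError):
        gating.GatingParams(breath_counter_threshold=0.1).check_against(quiet_physio)
    with pytest.raises(InvalidParameterError):
        gating.GatingParams(breath_counter_threshold=2.0).check_against(quiet_physio)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    heart_rate=st.floats(350, 650),
    resp_rate=st.floats(40, 60),
    quiescent_fraction=st.floats(0.60, 0.70),
    rr_jitter_ms=st.floats(0, 10),
    seed=st.integers(0, 2**20),
)
def test_line_conservation_and_oracle_equivalence(
    seq64, gate, heart_rate, resp_rate, quiescent_fraction, rr_jitter_ms, seed
):
    """Across random physiology: every line CLEAN exactly once, and the
    scheduler agrees exactly with the independent event-replay oracle."""
    p = physio.PhysioParams(
        heart_rate=heart_rate,
        resp_rate=resp_rate,
        quiescent_fraction=quiescent_fraction,
        rr_jitter_sd=rr_jitter_ms / 1000.0,
        resp_jitter_frac=0.03,
        seed=seed,
    )
    trace = physio.simulate_trace(p, 150.0)
    log = gating.schedule_scan(seq64, gate, trace)
    log.assert_line_conservation()  # CLEAN multiset == full grid
    blocks, duration = replay_schedule(seq64, gate, trace)
    assert log.scan_duration == duration
    assert [(r.trigger_time, r.line_start, r.line_stop, r.status == "CORRUPT_REACQUIRED")
            for r in log.records] == [
        (b["time"], b["lines"][0], b["lines"][-1] + 1, b["corrupt"]) for b in blocks
    ]


def test_log_csv_and_summary_roundtrip(tmp_path, seq64, gate, quiet_physio):
    trace = physio.simulate_trace(quiet_physio, 120.0)
    log = gating.schedule_scan(seq64, gate, trace)
    log.to_csv(tmp_path / "log.csv")
    log.summary_json(tmp_path / "summary.json")
    import json
    import pandas as pd

    df = pd.read_csv(tmp_path / "log.csv")
    assert len(df) == len(log.records)
    s = json.load(open(tmp_path / "summary.json"))
    assert s["scan_duration_s"] == pytest.approx(log.scan_duration)
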