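"""Schedule one prospectively gated 3D bSSFP acquisition and time it.

The controller acquires 32 k-space lines per interbreath R-wave, detects
breaths with a 250 ms inter-trigger counter, and immediately reacquires the
two blocks collected just before each breath.
"""

from crbssfp.gating import GatingParams, SequenceParams, duty_cycle, full_protocol_time, schedule_scan
from crbssfp.physio import PhysioParams, simulate_trace

params = PhysioParams(heart_rate=500, resp_rate=45, quiescent_fraction=0.67,
                      rr_jitter_sd=0.0, resp_jitter_frac=0.0, seed=1)
seq = SequenceParams()  # 256x128x128 at 0.2 mm, TR 2.8 ms, N=32
gate = GatingParams()   # 250 ms breath counter, 2 blocks reacquired

log = schedule_scan(seq, gate, simulate_trace(params, 300.0))
print(f"single 3D volume: {log.scan_duration:.1f} s "
      f"({log.scan_duration / 60:.2f} min)")
print(f"  breaths detected: {log.n_breaths}, blocks reacquired: "
      f"{log.n_reacquired_blocks}, duty cycle: {duty_cycle(log):.3f}")

timing = full_protocol_time(seq, gate, params, seed=1)
print(f"four phase cycles: {timing.total_s:.1f} s ({timing.total_minutes:.2f} min)")
print("a banding-free volume therefore costs well under ten minutes of scanning,")
print("which is what makes >4 mice/hour throughput possible.")
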