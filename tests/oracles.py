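"""Independent oracles used only by the tests.

These re-derive expected behaviour through deliberately different routes from
the package implementation: a naive per-line event replay of the gating
controller, and a time-stepped Bloch simulation of the bSSFP steady state.
They must never import logic from the modules they check beyond plain data
containers.
"""

from __future__ import annotations

import numpy as np


def replay_schedule(seq, gate, trace):
    """Brute-force event replay of the gated acquisition.

    Walks every R-wave, resolves its respiration segment by scanning the
    window list, and maintains the pending k-space lines as a plain Python
    list. Returns (acquisitions, scan_duration) where each acquisition is a
    dict with keys time, lines (tuple), corrupt (bool).
    """
    pending = list(range(seq.n_phase_lines))
    acquired = []
    last_t = None
    windows = [tuple(w) for w in trace.breath_windows]
    for t in trace.r_wave_times:
        quiescent = False
        for qs, ms, ce in windows:
            if qs <= t < ce:
                quiescent = t < ms
                break
        if not quiescent:
            continue
        if last_t is not None and (t - last_t) > gate.breath_counter_threshold:
            quota = gate.reacquire_blocks
            requeue = []
            for blk in reversed(acquired):
                if quota == 0:
                    break
                quota -= 1
                if not blk["corrupt"]:
                    blk["corrupt"] = True
                    requeue.append(list(blk["lines"]))
            for lines in requeue:
                pending = lines + pending
        n = min(seq.lines_per_block, len(pending))
        block = pending[:n]
        pending = pending[n:]
        acquired.append({"time": float(t), "lines": tuple(block), "corrupt": False})
        last_t = t
        if not pending:
            duration = float(t) + n * seq.TR - acquired[0]["time"]
            return acquired, duration
    raise RuntimeError("oracle: trace exhausted before completion")


def _rot_z(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def bloch_steady_state_magnitude(
    tissue, seq, phase_cycle_deg: float, theta: float, n_iter: int = 6000
) -> float:
    """|signal| at TE from an iterated Bloch simulation.

    Repeats (RF pulse with linearly incremented phase, free precession theta
    with relaxation over TR) until steady state, then evolves half a TR and
    reads the transverse magnitude. Independent of the ellipse closed form.
    """
    alpha = np.deg2rad(seq.flip_angle_deg)
    delta = np.deg2rad(phase_cycle_deg)
    E1, E2 = np.exp(-seq.TR / tissue.T1), np.exp(-seq.TR / tissue.T2)
    E1e, E2e = np.exp(-seq.TE / tissue.T1), np.exp(-seq.TE / tissue.T2)
    m0 = tissue.proton_density

    def evolve(m, ang, e1, e2):
        c, s = np.cos(ang), np.sin(ang)
        return np.array(
            [e2 * (c * m[0] - s * m[1]), e2 * (s * m[0] + c * m[1]),
             e1 * m[2] + m0 * (1.0 - e1)]
        )

    m = np.array([0.0, 0.0, m0])
    for n in range(n_iter):
        psi = n * delta
        rf = _rot_z(psi) @ _rot_x(alpha) @ _rot_z(-psi)
        m = evolve(rf @ m, theta, E1, E2)
    psi = n_iter * delta
    rf = _rot_z(psi) @ _rot_x(alpha) @ _rot_z(-psi)
    m = evolve(rf @ m, theta * seq.TE / seq.TR, E1e, E2e)
    return float(np.hypot(m[0], m[1]))
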