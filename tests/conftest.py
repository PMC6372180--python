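import numpy as np
import pytest

from crbssfp import gating, phantom, physio


@pytest.fixture(scope="session")
def seq64():
    """Reduced 64^3 grid at 0.4 mm for fast tests."""
    return gating.SequenceParams.reduced(64)


@pytest.fixture(scope="session")
def seq_full():
    return gating.SequenceParams()


@pytest.fixture(scope="session")
def gate():
    return gating.GatingParams()


@pytest.fixture(scope="session")
def quiet_physio():
    """Jitter-free physiology at the maintained protocol rates."""
    return physio.PhysioParams(rr_jitter_sd=0.0, resp_jitter_frac=0.0, seed=1)


@pytest.fixture(scope="session")
def scene64(seq64):
    return phantom.make_scene(
        n_tumours=3,
        tumour_volume_range=(0.256, 1.4),
        lung_volume_target=440.0,
        seed=3,
        shape=tuple(seq64.matrix),
        spacing=seq64.voxel_size_mm,
    )


@pytest.fixture(scope="session")
def evolved64(scene64):
    return phantom.evolve_scene(
        scene64,
        growth_factors={tid: 3.0 for tid in scene64.tumour_truth},
        new_tumours=2,
        seed=5,
        shift_mm=(0.8, 0.5, 0.3),
        rotation_deg=3.0,
    )


@pytest.fixture(scope="session")
def log64(seq64, gate, quiet_physio):
    trace = physio.simulate_trace(quiet_physio, 120.0)
    return gating.schedule_scan(seq64, gate, trace)


@pytest.fixture(scope="session")
def combined64(scene64, seq64, log64):
    """Noiseless four-cycle band-free magnitude of the base scene."""
    from crbssfp import recon

    vols = [
        recon.acquire_volume(scene64, log64, seq64, c, noise_sd=0.0)
        for c in (0.0, 90.0, 180.0, 270.0)
    ]
    return recon.combine_phase_cycles(vols)


@pytest.fixture(scope="session")
def combined64_evolved(evolved64, seq64, log64):
    from crbssfp import recon

    vols = [
        recon.acquire_volume(evolved64, log64, seq64, c, noise_sd=0.0)
        for c in (0.0, 90.0, 180.0, 270.0)
    ]
    return recon.combine_phase_cycles(vols)
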