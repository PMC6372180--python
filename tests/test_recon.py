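"""bSSFP signal model, acquisition transform identity, band removal."""

import numpy as np
import pytest

from crbssfp import recon
from crbssfp.errors import InvalidParameterError
from crbssfp.gating import SequenceParams
from crbssfp.phantom import TissueParams
from tests.oracles import bloch_steady_state_magnitude

SEQ = SequenceParams()
TISSUE = TissueParams(T1=1.0, T2=0.08, proton_density=1.0)


def test_zero_flip_angle_gives_zero_signal():
    seq = SequenceParams(flip_angle_deg=0.0)
    assert recon.bssfp_signal(TISSUE, seq, 0.0, off_resonance=0.3) == 0


def test_zero_proton_density_gives_zero_signal():
    t = TissueParams(T1=1.0, T2=0.08, proton_density=0.0)
    assert recon.bssfp_signal(t, SEQ, 0.0, off_resonance=0.3) == 0


def test_invalid_relaxation_rejected():
    with pytest.raises(InvalidParameterError):
        TissueParams(T1=-1.0, T2=0.08, proton_density=1.0)
    with pytest.raises(InvalidParameterError):
        TissueParams(T1=0.05, T2=0.08, proton_density=1.0)  # T2 > T1


@pytest.mark.parametrize("phase_cycle", [0.0, 90.0, 180.0, 270.0])
@pytest.mark.parametrize("theta", [np.pi / 2, -np.pi / 2, 1.1, 2.7])
def test_magnitude_matches_bloch_oracle(phase_cycle, theta):
    """Closed-form steady state vs iterated Bloch simulation, within 1%."""
    ours = abs(recon.bssfp_signal(TISSUE, SEQ, phase_cycle, off_resonance=theta))
    oracle = bloch_steady_state_magnitude(TISSUE, SEQ, phase_cycle, theta)
    assert ours == pytest.approx(oracle, rel=0.01)


def test_band_null_shifts_half_period_between_0_and_180():
    """Phase cycling moves the signal null from theta=0 to theta=pi."""
    theta = np.linspace(-np.pi, np.pi, 721)
    m0 = np.abs(recon.bssfp_signal(TISSUE, SEQ, 0.0, off_resonance=theta))
    m180 = np.abs(recon.bssfp_signal(TISSUE, SEQ, 180.0, off_resonance=theta))
    null0 = theta[np.argmin(m0)]
    null180 = theta[np.argmin(m180)]
    assert null0 == pytest.approx(0.0, abs=0.02)
    assert abs(abs(null180) - np.pi) < 0.02


def test_noiseless_reconstruction_is_transform_exact(scene64, seq64, log64):
    vol = recon.acquire_volume(scene64, log64, seq64, 0.0, noise_sd=0.0)
    ideal = recon.ideal_image(scene64, seq64, 0.0)
    err = np.max(np.abs(np.abs(vol.data) - np.abs(ideal)))
    assert err < 1e-8 * np.abs(ideal).max()


def test_noise_realisation_is_seed_deterministic(scene64, seq64, log64):
    a = recon.acquire_volume(scene64, log64, seq64, 0.0, noise_sd=1e-3, seed=5)
    b = recon.acquire_volume(scene64, log64, seq64, 0.0, noise_sd=1e-3, seed=5)
    c = recon.acquire_volume(scene64, log64, seq64, 0.0, noise_sd=1e-3, seed=6)
    assert np.array_equal(a.data, b.data)
    assert not np.array_equal(a.data, c.data)


def test_corrupted_lines_change_image_only_when_kept(scene64, seq64, log64):
    assert any(r.status == "CORRUPT_REACQUIRED" for r in log64.records)
    clean = recon.acquire_volume(scene64, log64, seq64, 0.0)
    ghosted = recon.acquire_volume(scene64, log64, seq64, 0.0, keep_corrupted=True)
    assert not np.allclose(clean.data, ghosted.data)


def _analytic_volumes(theta):
    """Four phase-cycled single-voxel 'volumes' from the ellipse form."""
    vols = []
    for c in (0.0, 90.0, 180.0, 270.0):
        data = np.asarray(
            recon.bssfp_signal(TISSUE, SEQ, c, off_resonance=theta)
        ).reshape(1, 1, -1)
        vols.append(recon.ComplexVolume(data, (1, 1, 1), c))
    return vols


def test_four_identical_inputs_fall_back_to_magnitude():
    data = np.full((2, 2, 2), 0.3 - 0.4j)
    vols = [recon.ComplexVolume(data, (1, 1, 1), c) for c in (0, 90, 180, 270)]
    out = recon.combine_phase_cycles(vols)
    assert np.allclose(out, 0.5)


def test_combination_recovers_band_free_magnitude_any_theta():
    """Cross-point magnitude equals |M| regardless of off-resonance."""
    theta = np.linspace(-np.pi, np.pi, 257)
    out = recon.combine_phase_cycles(_analytic_volumes(theta)).ravel()
    M = recon.band_free_signal(TISSUE, SEQ)
    assert np.allclose(out, M, rtol=1e-6)


def test_band_flatness_versus_single_cycle_variation():
    """Combined CV < 1% over a full off-resonance sweep; each input > 50%."""
    theta = np.linspace(-np.pi, np.pi, 721)
    vols = _analytic_volumes(theta)
    combined = recon.combine_phase_cycles(vols).ravel()
    cv = combined.std() / combined.mean()
    assert cv < 0.01
    for v in vols:
        mag = np.abs(v.data).ravel()
        assert (mag.max() - mag.min()) / mag.max() > 0.50


def test_combination_invariant_to_global_phase():
    theta = np.linspace(-2.0, 2.0, 64)
    vols = _analytic_volumes(theta)
    ref = recon.combine_phase_cycles(vols)
    phase = np.exp(1j * 1.234)
    rotated = [
        recon.ComplexVolume(v.data * phase, v.spacing, v.phase_cycle_deg) for v in vols
    ]
    assert np.allclose(recon.combine_phase_cycles(rotated), ref, rtol=1e-9)


def test_combination_is_linear_in_signal_scale():
    theta = np.linspace(-2.0, 2.0, 64)
    vols = _analytic_volumes(theta)
    ref = recon.combine_phase_cycles(vols)
    scaled = [
        recon.ComplexVolume(3.5 * v.data, v.spacing, v.phase_cycle_deg) for v in vols
    ]
    assert np.allclose(recon.combine_phase_cycles(scaled), 3.5 * ref, rtol=1e-9)


def test_combination_validates_inputs():
    data = np.zeros((2, 2, 2), dtype=complex)
    vols3 = [recon.ComplexVolume(data, (1, 1, 1), c) for c in (0, 90, 180)]
    with pytest.raises(InvalidParameterError):
        recon.combine_phase_cycles(vols3)
    wrong = [recon.ComplexVolume(data, (1, 1, 1), c) for c in (0, 45, 180, 270)]
    with pytest.raises(InvalidParameterError):
        recon.combine_phase_cycles(wrong)


def test_no_nulls_in_combined_phantom_image(scene64, seq64, combined64, log64):
    """Each single-cycle image contains deep nulls in body tissue; the
    combined image does not."""
    from crbssfp.phantom import LABEL_BODY

    body = scene64.label_volume == LABEL_BODY
    single = np.abs(recon.acquire_volume(scene64, log64, seq64, 0.0).data)
    M_body = recon.band_free_signal(scene64.tissue_table[LABEL_BODY], seq64)
    assert single[body].min() < 0.2 * M_body  # banding null present
    assert combined64[body].min() > 0.9 * M_body  # removed after combination
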