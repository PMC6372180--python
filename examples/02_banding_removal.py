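"""Show bSSFP banding and its removal by four-cycle combination.

Sweeps the off-resonance angle across a full cycle: each single phase-cycle
magnitude passes through a deep null (the band), while the elliptical-model
cross-point of the four cycles stays flat at the band-free signal |M|.
"""

import numpy as np

from crbssfp.gating import SequenceParams
from crbssfp.phantom import TUMOUR_TISSUE
from crbssfp.recon import ComplexVolume, band_free_signal, bssfp_signal, combine_phase_cycles

seq = SequenceParams()
theta = np.linspace(-np.pi, np.pi, 721)

vols = []
for cycle in (0.0, 90.0, 180.0, 270.0):
    sig = np.asarray(bssfp_signal(TUMOUR_TISSUE, seq, cycle, off_resonance=theta))
    vols.append(ComplexVolume(sig.reshape(1, 1, -1), (1, 1, 1), cycle))
    mag = np.abs(sig)
    print(f"cycle {cycle:5.0f} deg: magnitude range "
          f"[{mag.min():.5f}, {mag.max():.5f}]  (deep null = band)")

combined = combine_phase_cycles(vols).ravel()
cv = combined.std() / combined.mean()
print(f"\ncombined magnitude: mean {combined.mean():.5f}, CV {cv:.2e}")
print(f"band-free |M| from the closed form: {band_free_signal(TUMOUR_TISSUE, seq):.5f}")
print("the combination is flat across all off-resonance, so banding cannot")
print("masquerade as (or hide) a tumour anywhere in the field of view.")
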