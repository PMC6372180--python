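"""Acquire a phantom, segment it, and compare volumes against ground truth.

Uses the reduced 64^3 grid (0.4 mm voxels) so it runs in seconds; a noiseless
four-cycle acquisition recovers every tumour's voxel count exactly.
"""

from crbssfp.gating import GatingParams, SequenceParams, schedule_scan
from crbssfp.phantom import make_scene
from crbssfp.physio import PhysioParams, simulate_trace
from crbssfp.quantify import (
    segment, split_tumours, suggest_thresholds, tumour_seeds_from_scene, volume_mm3,
)
from crbssfp.recon import acquire_volume, combine_phase_cycles

seq = SequenceParams.reduced(64)
scene = make_scene(n_tumours=3, tumour_volume_range=(0.256, 1.4),
                   lung_volume_target=440.0, seed=3,
                   shape=tuple(seq.matrix), spacing=seq.voxel_size_mm)

params = PhysioParams(rr_jitter_sd=0.0, resp_jitter_frac=0.0, seed=1)
log = schedule_scan(seq, GatingParams(), simulate_trace(params, 120.0))
vols = [acquire_volume(scene, log, seq, c) for c in (0.0, 90.0, 180.0, 270.0)]
image = combine_phase_cycles(vols)

import numpy as np

bands = suggest_thresholds(scene, seq)
mask = segment(image, scene.spacing, tumour_seeds_from_scene(scene), bands.tumour[0])
print("tumour  measured mm^3  truth mm^3")
for tid, m in split_tumours(mask):
    label = int(scene.label_volume[tuple(np.argwhere(m.data)[0])])
    truth = scene.tumour_truth[label].volume_mm3
    print(f"  T{tid}        {volume_mm3(m):7.3f}     {truth:7.3f}")
print("measured volumes are voxel counts x 0.064 mm^3 and match truth exactly")
print("because the band-free image has perfect tumour/parenchyma contrast.")
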