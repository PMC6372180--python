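# Methods

This note documents what the simulator computes, the assumptions and defaults
behind every stage, and what the passing tests do and do not establish about
real data.

## Physiology

R-waves are a renewal process with nominal interval 60/heart-rate and
truncated-Gaussian jitter (±3 sd, interval floored at 10 ms). Respiration is
a sequence of cycles of nominal length 60/resp-rate with fractional length
jitter; each cycle is a quiescent segment (the fraction available for
imaging) followed by a motion segment. Window membership is half-open
[start, end): an R-wave exactly at motion onset is suppressed, one exactly at
a cycle boundary belongs to the next quiescent segment. Defaults: heart rate
500 beats/min (a typical anaesthetised-mouse value — the protocol being
modelled does not fix it, so it is exposed in config), respiration 45
breaths/min and 67% quiescent fraction (the middle of the maintained 40–60
breaths/min, 60–70% ranges), R-R jitter sd 5 ms, cycle-length jitter sd 3% of
the period. The jitters exist to exercise the controller's adaptation to
instantaneous rate changes, not to model any particular animal. Parameters
outside the maintained ranges are allowed but flagged with a warning.

## Gating controller

The scheduler is event-driven. Pending phase-encode lines (matrix[1]×matrix[2]
of them; the readout direction is fully sampled each excitation) form a FIFO
queue of blocks of N consecutive lines in linear order (centric ordering is
not implemented; linear was chosen as the simplest convention consistent with
"N k-lines per R-wave"). Each valid (interbreath) trigger dequeues one block;
a trigger arriving with fewer than N lines remaining acquires a final short
block, which only matters for matrices where N does not divide the line
count. A breath is detected when the gap since the previous valid trigger
exceeds the counter threshold (default 250 ms — longer than two cardiac R-R
intervals, shorter than a breath at the preset rates; validated by
`GatingParams.check_against`). On detection, the blocks of the last two
R-waves before the gap that are still clean are flagged corrupt and their
lines re-enqueued at the *head* of the queue, so they are the first blocks
acquired after the breath ("immediate" reacquisition). Blocks already flagged
by an earlier breath count toward the quota but are not re-flagged. When
several breaths occur in quick succession the head-of-queue choice means
reacquisitions always precede fresh lines; this is a convention — the order
is not observable in the final image since every line ends up clean.

Scan duration is measured from the first used trigger to the completion of
the final block (trigger time + lines×TR). The steady-state maintenance loop
between blocks is modelled as elapsed time only; its observable effect
(constant TR, no transient) is inherited by the reconstruction's steady-state
assumption. Calibration overhead (shimming, frequency, RF calibration) is
excluded from scan time and budgeted separately as a per-mouse setup
allowance (default 5 min) in throughput figures.

Every scheduled scan asserts line conservation (each line clean exactly
once), and the test suite checks exact agreement with an independent
brute-force event-replay oracle across random physiology draws.

## Phantom

The thorax is a body ellipsoid enclosing two lung lobes (right larger than
left, which also breaks the mirror symmetry that would make rigid
registration ambiguous), a heart between the lobes, optional atelectasis
patches, and tumours inside the lung. The lobes are rescaled once so the lung
label volume lands within 10% of the requested target (default 440 mm³, an
adult-mouse scale). Tumours are sampled as ellipsoids with mild random axis
ratios, but rasterised as the *n* grid voxels of smallest ellipsoidal norm
around the centre, where n = round(volume / voxel volume). This makes ground
truth exact by construction (truth volume = voxel count × voxel volume), lets
growth multipliers be realised within one voxel volume, and reproduces the
7-voxel = 0.056 mm³ minimum-size case at 200 µm spacing. Placement requires a
2-voxel margin inside the lung, a one-voxel moat between tumours (so
26-connected components never merge), and head-room for ~4× growth; an
infeasible request raises rather than silently degrading.

Tissue parameters are phantom conventions, not measured values: proton
densities 0.15 (parenchyma), 0.70 (body), 0.80 (heart), 0.90 (tumour), 0.60
(atelectasis), with plausible 7 T relaxation times. Off-resonance is a smooth
linear+quadratic 3D map rescaled to span ±π per TR so that banding is visible
across the thorax. Motion is piecewise-rigid bulk displacement (respiratory:
1 mm cranio-caudal) applied only when corrupted blocks are deliberately kept.
Inter-session repositioning is a rigid shift/rotation of the whole scene,
re-rasterised in the new pose so truth volumes stay exact.

Deliberate non-goals: airway trees, deformable respiratory mechanics,
perfusion, B1 inhomogeneity, tumour shape heterogeneity (real tumours are not
ellipsoids; nothing downstream depends on shape beyond connectedness).

## Signal model and band removal

The bSSFP steady state is the standard ellipse in the complex plane (see the
README for the closed form), demodulated at TE = TR/2 (magnitude factor √E2,
phase factor e^{iθ/2}). Banding nulls sit at φ = θ − Δ = 0. Acquisition is an
orthonormal 3D FFT of the ideal voxelwise image; complex Gaussian noise
(default per-channel sd 2% of the peak ideal signal) is added per k-space
sample. Because the scheduler guarantees each line's final acquisition is
motion-free, the default reconstruction uses clean data only; a
`keep_corrupted` switch substitutes motion-displaced data for the flagged
lines to visualise what reacquisition prevents.

Band removal intersects the line through (I₀, I₁₈₀) with the line through
(I₉₀, I₂₇₀) per voxel via a 2×2 real solve. The geometric solution is
ill-posed when the two lines are near-parallel (on-resonance pathology), so
voxels with |sin(angle)| < 1e−3 — or with a coincident pair — fall back to
the quadrature mean of the four magnitudes; four identical inputs therefore
return |I|. Only this first-pass geometric solution is implemented; the
second-pass weighted smoothing described in the elliptical-model literature
is out of scope. The phase-cycle increments {0, 90, 180, 270}° are the
standard four-cycle scheme. Noiseless, the combination recovers |M| to 1e−6
relative at any off-resonance; with noise it *amplifies* error at low-SNR
voxels (the intersection of two short noisy chords is unstable), which in
practice can flip a boundary voxel of a mask — visible in the test that
segments at protocol noise.

## Segmentation and volumetry

Seeded threshold segmentation: the mask is the union of the 26-connected
components (connectivity configurable) of the in-band voxels containing each
seed; a seed outside the band is an error reporting the offending intensity.
Interactive threshold picking is replaced by bands derived from the phantom's
modal tissue intensities (midpoint between parenchyma and body for the lung
band, midpoint between parenchyma and tumour for the tumour band), and seed
points are taken from phantom truth (lung lobe centroids; tumour centres),
standing in for the operator. Lung masks are hole-filled so tumours count
toward lung volume, matching the burden definition 100×TTV/lung volume — the
workflow being modelled does not state whether its lung volumes include
tumours, and inclusion is the assumption consistent with that definition.
Volumes are voxel count × voxel volume, reported to 3 decimals.

## Registration and QC

ICP runs on surface voxels (6-connectivity erosion difference — surfaces
only, for speed), centroid-initialised, with nearest-neighbour
correspondences (kd-tree; ties resolved deterministically) and the SVD/Kabsch
det-corrected update; it stops when the RMS correspondence distance improves
by < 1e−4 mm or after 100 iterations, returning the best transform seen. The
earlier timepoint is always the moving image, resampled by nearest neighbour
into the later frame only for the Dice computation; volumes are always
measured in native frames, so registration never touches volumetry. Tiers:
Dice > 0.800 AUTO, ≥ 0.778 MANUAL, else FAIL; both thresholds are config
values (whether the 0.778 tier was pre hoc or descriptive in the workflow
being modelled is unknowable, so neither is hard-coded).

## Tracking and statistics

Each late tumour's mass-centroid seed is mapped through the inverse transform
into the early frame and linked to the nearest early tumour within 2 voxels
(greedy nearest-first, one-to-one; the radius is config-exposed — the value
is a tolerance for centroid shift under growth, not a measured quantity).
Unlinked late tumours are NEW; a FAIL tier raises instead of guessing.
MANUAL-tier correspondences accept a user override map. Growth tables list
linked tumours first (by early id) then NEW ones; TTV/AVT/SDV are computed
over present entries only, and SDV — like every descriptive spread in the
package — is the population SD (divisor n), validated against the packaged
reference tables (e.g. 434.18 ± 111.311 mm³ control, 444.31 ± 45.34 mm³
tumour-bearing week-18 lung volumes). Group comparisons use the two-tailed
Welch t-test (Satterthwaite df, sample variances in the statistic); two
identical constant groups return t = 0, p = 1 by convention.

## Study orchestration and problem sizes

`run_study` fans a single seed out to per-stage child seeds by fixed offsets,
so any stage can be reproduced in isolation and a repeated run is
byte-identical. Defaults simulate 2 mice, 4 tumours at the first timepoint,
2–4× growth plus 3 new tumours at the second, a 0.6/0.4/0.2 mm shift + 2°
repose between sessions, and 2% noise. Two grid presets exist: the full
256×128×128 geometry at 0.2 mm, and a reduced 64³ grid at 0.4 mm used by most
tests and examples; the reduced grid keeps a full study to seconds while the
full geometry completes in well under a minute per mouse on one CPU. The
packaged reference tables (18-mouse QC table; 9-mouse per-tumour growth
table) are checksummed CSVs used for validation, not inputs to simulation.

## What passing tests do and do not show

The phantom has crisp labels, no partial volume, no B0 drift, no receive-coil
shading, and its "operator" places seeds at truth locations, so exact-volume
recovery here demonstrates the *pipeline's* correctness (scheduling, signal
model, combination, segmentation arithmetic, registration and bookkeeping),
not the accuracy of threshold segmentation on real images. Scan-time figures
are simulated event timings under idealised physiology; they exclude setup
and calibration, which enter only via the fixed per-mouse allowance in
throughput estimates. The Welch/permutation agreement is checked at moderate
group sizes where the t approximation is good; it is not a small-sample
guarantee.
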