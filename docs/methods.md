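# Methods

`mocolge` implements a complete free-breathing 3D Dixon late-gadolinium-
enhancement (LGE) reconstruction chain and a digital moving cardiac
phantom on which every stage can be exercised and verified without any
scanner data.  The same simulated raw acquisition is reconstructed two
ways — image-navigator (iNAV) translational correction with iterative
SENSE ("TC") and respiratory-binned non-rigid motion-compensated
iterative SENSE ("NRC") — followed by two-point Dixon water–fat
separation and FWHM scar quantification, mirroring a paired clinical
comparison design.

## Coordinate and numeric conventions

* Axis 0 = foot–head (FH, head positive), axis 1 = anterior–posterior
  (AP, anterior positive), axis 2 = right–left (RL, right positive).
  Voxel indices are 0-based.
* All FFTs are centered (DC at index `n//2` on every axis) and
  orthonormal.
* A deformation field `d` is a per-voxel displacement in voxel units;
  warping an image `I` with `d` yields `J(r) = I(r − d(r))`, so a
  positive FH component moves anatomy toward the head.  The adjoint of
  the warp in the encoding operator is the exact transpose of its
  sparse interpolation matrix (a scatter of interpolation weights), not
  the inverse warp.
* k-space translational correction multiplies the centered spectrum by
  `exp(+2πi f Δ)` per axis (`f` in cycles/voxel, `Δ = measured − target`
  in voxels), which moves the anatomy from its measured position to the
  target exactly (Fourier shift theorem; the DC sample is untouched).

## Digital phantom

An ellipsoidal-shell left-ventricular myocardium (default epicardial
radii 28/26/22 mm, 8 mm wall) with interior blood pool, a
subendocardial scar sector (default: 75° sector, 26 mm FH extent, 55%
transmural), an epicardial fat rim (4 mm) and an anterior chest wall
(muscle slab plus subcutaneous fat).  Post-inversion tissue contrast is
baked into the water/fat maps as effective magnetizations — a full
Bloch simulation of the inversion-recovery spoiled-gradient-echo
readout is out of scope because the reconstruction problem under study
is motion, not signal modelling.  The water intensities (scar 0.9,
blood 0.7, chest wall 0.45, fat's water component 0.25, myocardium
0.15) reproduce clinically reported post-contrast contrast ratios:
LGE-to-myocardium ≈ 6 and blood-to-myocardium ≈ 4.7, i.e. scar is the
brightest tissue, slightly above blood.  Maps are smoothed by a 0.8-
voxel Gaussian so edges are not voxel-sharp; labels stay crisp and
provide ground truth (scar mass = voxel count × voxel volume ×
1.05 g/mL).

The desk-scale grid is 64×64×32 at 2 mm isotropic voxels with 8
analytic surface coils (Gaussian magnitude lobes on the AP–RL
circumference with linear phase).  The acquisition-scale protocol
(240×240 matrix, 1.3 mm, TR 7.2 ms, TE 2.38/4.76 ms, flip 20°,
TI ≈ 245 ms) is supported but not required by the tests.

### Respiratory motion model

Pseudo-periodic breathing: within cycle j the normalized waveform is
`A_j sin²(π(t−t_j)/T_j)` (end-expiration baseline 0), with per-cycle
amplitude and period jittered by the `irregularity` fraction
(default 0.1).  Default amplitudes: FH 10 mm, RL 3 mm, AP 2 mm, period
4 s, heart rate 69 bpm.  The non-rigid component converts
`nonrigid_gain` (default 0.5) of the FH displacement into a smooth
spatially varying field: full FH displacement at the diaphragm (foot
edge) tapering linearly toward the head, plus an AP chest-expansion
term growing anteriorly.  One motion state applies per heartbeat
(intra-beat motion is ignored), matching the beat-to-beat granularity
of navigator-driven correction.  Ground-truth warps in the simulator
use cubic-spline interpolation: linear interpolation would blur the
moving anatomy by an amount that depends on the fractional
displacement, biasing any comparison referenced to a sub-voxel
position.

### Acquisition simulation

Per heartbeat: deform the phantom by that beat's truth field, form both
echo images as `W + F·exp(2πi·Δf_fat·TE_e)` (the fat chemical shift
defaults to `1/(2·TE1) ≈ 210 Hz` so TE1 is exactly opposed-phase and
TE2 exactly in-phase, making the Dixon step testable in closed form; a
1.5 T value of −220 Hz can be configured), multiply by each coil map,
apply the centered FFT and sample the beat's trajectory lines for both
echoes; complex Gaussian noise (default SD 0.01 per sample) is added to
all samples.  A low-resolution coronal projection navigator is formed
per beat and echo from the same deformed anatomy (the iNAV shares the
beat's motion state, consistent with k-space centers adjacent in time);
nav frames are 1/4 in-plane resolution with a 16-pixel floor per axis
so they stay informative on desk grids, and carry per-axis pixel sizes.
An optional smooth B0 map exercises the Dixon phase correction; it
defaults to zero.

## VD-CASPR trajectory

Each heartbeat acquires one spiral-like interleaf of Cartesian
phase-encode points, emitted center-outward (centric in-out: the first
line of every beat is the exact k-space center), with radial candidate
density ∝ (1−r) and golden-step (137.508°) azimuthal rotation between
beats.  Two design choices matter:

* **Dense low-k core.**  Cells within normalized radius 0.12 of the
  center are re-acquired by every interleaf; outside the core each cell
  is acquired at most once over the whole scan (a cell already taken is
  skipped and the walk continues outward; a beat whose arm is exhausted
  falls back to the nearest unacquired cells, so full sampling is
  reachable in the accel = 1 limit).  The repeatedly sampled core is
  what gives every respiratory bin a fully sampled k-space center —
  without it the half-resolution bin images alias so badly that
  registration is hopeless.  Re-acquiring everything (dedup within one
  beat only) was rejected: reaching 3.3× unique coverage then requires
  ~5.7× line overlap, an implausible ~140 lines per beat at the
  722-beat acquisition budget.
* **Budget calibration.**  When only the acceleration is prescribed,
  the total line budget is found by a deterministic bisection so the
  unique-coverage acceleration matches the prescription — this is the
  sequence-design step, and it lands within a fraction of a percent.
  At the acquisition-scale configuration (240×240, 722 beats) this
  yields ≈25–45 lines per beat depending on the core overhead.

The construction contains no randomness: identical arguments give
identical trajectories.

## Navigator tracking

The opposed-echo iNAV of each beat is matched against a template from a
fixed reference frame (beat 0, end-expiration) by normalized
cross-correlation; the integer peak is refined to sub-pixel precision
by Fourier-upsampled phase correlation between the template and the
matched patch.  The default template covers the central three quarters
of the frame — larger templates track these low-resolution frames with
visibly less scatter.  A correlation peak on the search-window border
flags the estimate as unreliable.  Only FH and RL are observable in a
coronal projection; AP motion is invisible to the navigator by
geometry.  Sign convention: a positive FH estimate means the heart
moved toward the head relative to the reference.

## Respiratory binning and motion-field estimation

Lines are sorted into five equal-count (quantile) FH bins — quantile
edges guarantee nonempty, comparably conditioned bins; per-bin center =
median FH of its lines; the central bin is the one whose center is
nearest the overall median (the average breathing position).

For the opposed echo, per-bin images are reconstructed at half
resolution (central k-space crop in all three dimensions, consistent
with Fourier acquisition semantics) after correcting each line to its
bin center, histogram-equalized, and registered to the central bin.
Several choices here departed from the obvious defaults after the
obvious defaults failed on undersampled bin images:

* **Equalization with a background floor.**  Rank-based equalization of
  the raw magnitudes stretches background noise across half the output
  range and lets the registration metric chase it; intensities below
  half the Otsu threshold are therefore tied to exactly zero before
  ranking.
* **Registration = known translation + single-level diffeomorphic
  demons.**  The inter-bin bulk translation is already known from the
  navigator bin centers and initializes the transform exactly (when it
  is not supplied, an LBFGSB translation stage estimates it).  The
  residual deformation is estimated by diffeomorphic demons with
  Gaussian field regularization.  A B-spline FFD with LBFGSB — the
  textbook default — produced 15–35-voxel field excursions on the flat
  plateau regions of equalized bin images (the aperture problem, with
  no bending-energy term available), and multi-resolution demons
  pyramids injected spurious large-scale deformation from the coarse
  levels of artifact-laden images; a single level is used in the
  pipeline (the generic `register_nonrigid` keeps 3 levels for clean
  images, where large warps need the pyramid).
* **Residual smoothing and a data-consistency gate.**  The demons
  residual is smoothed over the joint foreground (σ = 6 half-grid
  voxels, boundary-trimmed — genuine respiratory deformation varies
  over the whole volume, while artifact-chasing components are
  mid-frequency).  Each bin's residual field must then pass a
  data-consistency test before entering the final solve: warping a
  quick pooled reconstruction by the field has to fit that bin's own
  k-space samples at least 2% better than the identity warp does,
  otherwise the bin keeps its bulk translation only.  Registration can
  extract pseudo-deformation from blur/point-spread differences between
  bin images (each bin owns a different share of the periphery of
  k-space), and that pseudo-motion — unlike genuine motion — does not
  explain the measured data.  A demons stage that does not improve its
  own metric is likewise discarded.

Fields are trilinearly interpolated back to the full grid with
displacements scaled by the grid ratio.

## Reconstruction

Both pipelines solve unregularized least squares over all acquired
lines with preconditioned conjugate gradients on the normal equations
(intensity preconditioning by the inverse coil-power map; default 30
iterations, tolerance 1e−6).  Since duplicate acquisitions of a cell
are averaged onto the Cartesian grid, each cell carries its acquisition
count as least-squares weight — this keeps the pooled TC problem and
the multi-bin NRC problem exactly consistent: with identity fields the
per-bin weighted normal equations sum to the pooled ones, so NRC
degenerates to TC when no deformation is detected.

* **TC**: every line is corrected beat-wise toward the average global
  breathing position (mean of the tracked FH/RL shifts) by k-space
  linear phase, and each echo is reconstructed with (weighted) itSENSE.
* **NRC**: lines are corrected per bin toward the bin centers to form
  the bin images; for the final solve every line is corrected beat-wise
  to the central position and the per-bin fields carry only the
  estimated non-rigid residual.  (Correcting the final solve only to
  bin centers would leave intra-bin translational blur that beat-wise
  correction removes for free.)  The generalized encoding operator per
  bin is mask ∘ FFT ∘ coils ∘ warp; one solve per echo; the output
  lives on the central-bin anatomy.

The warp inside the operator uses trilinear interpolation by default
(`warp_order=3` selects cubic convolution, which preserves peaks better
at sub-voxel displacements but overshoots at sharp edges).  CG keeps
the best-residual iterate; mild residual oscillation ends the iteration
early, and a residual exceeding ten times the best seen aborts with a
diagnostic.  Coil maps are taken as known (simulator truth).

## Dixon separation

Under the exact opposed/in-phase timing, `W = |IP + OP|/2`,
`F = |IP − OP|/2`.  The `smooth_phasor` mode estimates the slowly
varying B0 phase from the squared echo product (squaring removes the
sign ambiguity of fat-dominant voxels) as a magnitude-weighted degree-2
polynomial field, demodulates both echoes, removes the residual
echo-independent (receiver) phase the same way, and then combines.  A
polynomial fit was chosen over iterated Gaussian smoothing of the
phasor because the weighted low-pass leaves a persistent high-frequency
bias where the signal amplitude and the phase both vary; the low-order
fit recovers smooth (shim-like) fields essentially exactly.  Outputs
are magnitude maps; region-growing phase unwrapping and multi-peak fat
models are out of scope.

## Quantification

* Contrast ratio: mean signal over pooled numerator ROIs divided by the
  pooled denominator mean.  Truth-derived ROIs: scar and remote
  myocardium each split into three equal-count chunks, blood measured
  luminally (eroded pool).  ROIs and contours are single voxel-index
  masks shared verbatim between the two reconstructions.
* FWHM mass: threshold = half of the maximum signal within the
  myocardial shell; scar voxels = shell voxels at or above threshold;
  mass = count × voxel volume × 1.05 g/mL (standard myocardial
  density).  Contours follow the plain label boundaries; since scar is
  the brightest tissue, the threshold is scar-anchored, and the blood
  partial volume bleeding into the endocardial ring makes the method
  overestimate mass on blurred images — which is exactly the behaviour
  whose reduction under non-rigid correction the paired experiment
  measures.  An optional endocardial margin supports conservative
  contouring.  The search region is the whole shell (the synthetic
  truth makes a manual scar seed unnecessary).
* Edge sharpness: mean gradient magnitude in a band straddling the
  blood–myocardium interface, normalized by the image's 1–99 percentile
  range.
* RMSE: scale-matched (least-squares global intensity factor) root mean
  squared magnitude difference over a mask; experiments evaluate it
  over the heart region (the moving anatomy the method targets), each
  reconstruction against a motion-free reference rendered at its own
  output breathing position.

## What the synthetic experiments do and do not show

The generator emulates the salient physics the motion-correction
problem depends on: beat-to-beat pseudo-periodic breathing with a
smooth non-rigid component, navigator/data motion consistency,
variable-density golden-step undersampling with a shared dense core,
multi-coil complex acquisition, exact in/opposed-phase fat–water
mixing, and complex Gaussian noise.  It does not emulate cardiac
contraction (one motion state per beat), arrhythmia, Bloch-level signal
evolution, B1/eddy-current effects, intra-beat motion, or realistic
coil-array geometry beyond smooth analytic lobes.  Passing tests
therefore demonstrate the correctness and the qualitative clinical
directions of the pipeline (NRC sharper and lower-error than TC under
non-rigid breathing, equivalence under pure translation), not
quantitative performance on patient data.  Desk-scale problem sizes
(64×64×32, 100 heartbeats, 8 coils) were chosen so a full paired
experiment runs in about a minute; the acquisition-scale trajectory
calibration runs at full 240×240 size.

## Known limitations

* The per-bin field estimator is deliberately conservative: deformation
  that does not cross-validate across split halves is dropped, so NRC
  approaches TC from above rather than risking artifact-driven warps.
  At desk scale the detectable non-rigid signal is at most a voxel or
  two.
* FWHM scar mass on a 2-mm grid with an 8-mm wall is dominated by
  partial-volume effects; the TC-vs-NRC mass difference is a one-to-two
  voxel-shell effect and correspondingly noisy.
* AP motion is uncorrectable by the navigator (coronal projection) and
  only partially recovered by the bin registration.
* The container stores the motion trace and phantom as ground truth;
  per-beat dense fields are reconstructed on demand from the trace
  (they are deterministic) rather than stored.
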