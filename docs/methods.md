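# Methods

## The measurement being modeled

MISL (magnetization-transfer indirect spin labeling) quantifies water
exchange from brain tissue into CSF. A train of off-resonance MT pulses
saturates parenchymal water (CSF, with negligible semi-solid content, is
left alone); the labeled water exchanges into CSF during the train and is
read out with a long-TE acquisition in which only long-T2 fluid retains
signal. The observable is the fractional CSF signal drop between a control
acquisition (far off-resonance, 200 ppm) and a label acquisition (−10 ppm):

    ΔZ = (S_control − S_label) / S_control.

## Signal model

Two closed forms carry the quantification (`misl.signal_model`):

**Tissue buildup.** The tissue MT signal grows mono-exponentially with
saturation time,

    ΔZ_tissue(t) = α · (1 − e^(−R1ρ,tissue · t)),

with asymptote α (the labeling efficiency) and rate R1ρ,tissue, the tissue
rotating-frame longitudinal rate during the train. Fitting this curve to
measurements at several train lengths yields both parameters
(`fit_saturation_curve`; bounded least squares, initialized at
α₀ = max ΔZ and R1ρ₀ = 1/t at half-max, which puts any monotone curve in
the convergence basin). A flat curve leaves R1ρ unidentifiable and is
rejected explicitly.

**Compartmental exchange.** In a CSF compartment receiving tissue water at
rate TCF (mL per 100 mL of CSF per minute; the factor 6000 converts to a
fractional rate per second),

    ΔZ = α · (TCF/6000) · (1/R1,CSF)
           · [1 + e^(−R1ρ·t)·R1,CSF/R1,app − e^(−R1,CSF·t)·R1ρ/R1,app],

with R1,app = R1ρ,tissue − R1,CSF. ΔZ is linear in TCF, so the ΔZ→TCF
inversion is exact. The bracket has a removable singularity at
R1,app = 0; below |R1,app| = 1e-4 s⁻¹ a second-order series around the
degenerate point is used, which agrees with the two-sided numeric limit to
better than 1e-8 and keeps the branch switch continuous.

A note on the buildup equation: some typeset renderings of the
mono-exponential model carry a spurious TCF/6000 factor that contradicts
both the definition of α as the steady-state tissue MT signal and the
reported fit (α = 0.42 with ΔZ_tissue(3.725 s) = 0.42). The implementation
follows the definition.

Defaults (all overridable): α = 0.42, R1ρ,tissue = 1.72 s⁻¹ (the group
values obtained from the buildup fit at 3 T), R1,CSF = 0.23 s⁻¹
(literature value; T1,CSF ≈ 4350 ms). In practice α should be measured per
subject as ΔZ_tissue at the full train length. Negative ΔZ voxels invert
to negative TCF and are preserved and flagged, never clamped — clamping
would bias ROI means upward.

## Bloch simulation of direct saturation

The main confound of MISL is direct saturation (DS) of CSF water by the
labeling pulses themselves. `misl.bloch` propagates a single water pool
(T1 = 4350 ms, T2 = 2000 ms for CSF) through the full train — 50
SincGaussian pulses, 3 μT peak, 50 ms width, 25 ms gaps, −10 ppm at 3 T —
and reports DS = 1 − Mz(end)/M0.

Numerics. The envelope is discretized into 50 μs piecewise-constant steps;
each step is propagated by the exact matrix exponential of the constant
affine Bloch generator (homogeneous 4×4 form), so for a rectangular pulse
the integrator *is* the closed-form solution, and for shaped pulses the
only error is envelope sampling (halving the step changes DS by < 1e-6).
All steps of a pulse are composed into one propagator reused across the
train, making a full-train simulation take ~30 ms. Delays use the
closed-form relaxation/precession map; transverse magnetization is spoiled
at the end of each delay by default (gradient-spoiler assumption — for
this protocol the DS estimate moves by well under 5% when spoiling is
disabled, because the smooth envelope returns magnetization almost
adiabatically to z). The readout is not simulated: it attenuates control
and label identically and cancels in ΔZ.

Pulse shape. Vendor "SincGaussian" envelopes are not uniquely defined, so
the shape is pinned to the one observable the protocol provides, its
continuous-wave-equivalent power. The envelope is a single-main-lobe sinc
(time-bandwidth product 2, zeros at the pulse edges) times a Gaussian
window whose width (σ = 0.465 × duration, frozen in
`SINCGAUSS_SIGMA_HALF`) is calibrated once so that the RMS B1 *during the
pulse* equals 1.90 μT at 3 μT peak. The two power conventions in
circulation differ: RMS over the whole train period (pulse + delay) vs.
RMS over the RF-on interval. Only the second is physically consistent
here — an envelope forced to 1.90 μT train-RMS must carry large edge
amplitude (a smooth window cannot supply enough area) and its simulated DS
at −10 ppm rises to ≳0.7%, incompatible with the protocol's negligible-DS
design; the pulse-interval calibration yields DS = 0.258% at −10 ppm,
matching the protocol's simulated bound (0.26%) and its in-vivo
arachnoid-cyst validation (0.30%). `cw_equivalent_b1` exposes both
conventions (`over="train"` default, `over="pulse"`). The DS bound is not
fragile to this choice of shape constants: varying the time-bandwidth
product and Gaussian width by ±20% keeps DS below 0.5%, an order of
magnitude under the 2–4% exchange signal.

## Voxelwise pipeline

`misl.maps` assumes pre-aligned inputs (grid mismatch is an error) and
computes ΔS = mean(control) − mean(label), ΔZ = ΔS/mean(control), and the
TCF map by elementwise inversion.

- ΔZ is defined only inside the CSF ∪ PVS mask and where mean control
  exceeds 5× a robust background noise estimate (scaled MAD outside the
  brain mask); excluded voxels are NaN with QC flags, never zero.
- CSF mask: Otsu's rule on brain-masked mean-control intensities by
  default (the long-TE histogram is strongly bimodal), or an absolute
  cutoff. An empty mask is a QC error.
- PVS mask: threshold the long-TE T2w volume, label connected components
  (26-neighborhood default), drop components larger than 300 voxels (at
  1 mm³) — ventricles and SAS sheets — and keep the remaining thin tubes.
  Both the size cutoff and connectivity are exposed; neither is a
  published value, and segmentations near the cutoff are
  connectivity-dependent (tested explicitly).
- Atlas ROIs are dilated by a Euclidean ball (radius 1 voxel default) and
  intersected with the CSF mask; contested voxels go to the nearest
  original label, distance ties to the lower label id (deterministic).
- ROI/composite statistics exclude flagged voxels; an ROI with no valid
  voxels is reported missing (n = 0, NaN), not zero. Composite means equal
  the voxel-count-weighted means of their members by construction.

## Synthetic phantom

`misl.phantom` renders compartments with known TCF into a noisy
acquisition so every downstream stage is testable without human data. The
default 72×72×60 grid (1 mm) contains an SAS shell (TCF 160), two lateral
ventricles (120), two choroid-plexus blobs inside them (288), three PVS
capsule-tubes of radius 1.2 voxels in deep tissue (543), and a zero-TCF
cyst mirroring the arachnoid-cyst negative control. Control intensities:
CSF 1000, parenchyma 20 (the ≈2% residual of a TE ≈ 1.1 s readout).
Label volumes are attenuated by the forward model plus a DS floor
(default 0.003, the measured cyst value) on CSF compartments. Noise is
Rician — magnitude of the complex signal with i.i.d. Gaussian channels —
with σ = 20 (CSF SNR 50) and 18 control/label pairs by default, matching
the averaging of the in-vivo protocol. Substreams are derived from the
spec seed per volume, so a spec+seed pair is bit-reproducible.

What the phantom does not emulate: partial-volume mixing at compartment
boundaries, motion, B0/B1 inhomogeneity, spatially correlated noise from
parallel imaging/compressed sensing, and anatomical realism beyond
compartment topology. Passing recovery tests therefore demonstrate the
correctness of the quantification chain, not robustness to those in-vivo
effects.

Under the default study conditions the pipeline recovers every
compartment's TCF exactly (≤1e-6 relative) without noise and within 5%
(including the PVS tubes) at SNR 50 with 18 pairs; recovery runs use a
DS-free acquisition, while the DS floor's ≈0.3% ΔZ bias in the zero-TCF
cyst is exercised by its own test.

## Statistics

`misl.stats` operates on long-format region tables. Age trends are
ordinary least squares of regional TCF on age with a two-sided t-test on
the slope (constant responses are flagged degenerate rather than
propagating NaN). Test–retest reliability is ICC(2,1) — two-way random
effects, absolute agreement, single measure, the standard test–retest
choice — with F-based 95% CIs, computed over (subject, region) pairs
pooled across all ROIs; ICC(3,1) is available via a flag. Bland–Altman
agreement uses session 1 − session 2 differences with limits of agreement
at bias ± 1.96·SD. No multiple-testing correction is applied across
regions; p values are raw. The ICC implementation is backed by pingouin
and verified in tests against the hand ANOVA mean-squares formula.

## Problem sizes and tolerances

Defaults were chosen as the smallest sizes that exercise every code path
at full fidelity: Bloch simulations run the complete 3.725 s train at
50 μs steps (50 000 exact-propagator steps, ~30 ms via per-pulse
propagator reuse); phantom validations use the full 72×72×60 grid with 18
pairs (~2 s per realization). Numerical tolerances: forward/inverse TCF
roundtrip 1e-10, degenerate-limit agreement 1e-8, integrator-vs-oracle
1e-8, Z-spectrum ± symmetry 1e-9, norm conservation 1e-9.

## Known limitations

- Single-pool DS simulation only: two-pool (bound/free) tissue MT
  Z-spectrum modeling is out of scope (tissue pool parameters are not
  part of the quantification).
- R1ρ,tissue, R1,CSF and α are treated as spatially uniform; regional and
  age variation of these parameters propagates directly into TCF.
- The exact vendor SincGaussian envelope is unknown; the calibrated shape
  reproduces the protocol's power and DS observables but is not
  pulse-program-identical.
- No registration/motion correction: inputs must be pre-aligned, and the
  pipeline refuses rather than resamples on grid mismatch.
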