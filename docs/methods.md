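# Methods

## Signal models and parameter fitting

All fitting is voxel-wise and deterministic (no random initialization).
Voxels where a model is undefined (non-positive signal, non-convergence,
out-of-range solution) carry a NaN sentinel plus an authoritative boolean
`valid` grid, and are excluded from every downstream statistic; exclusion
counts are reported.

**ADC.** Two-point linearized mono-exponential,
`ADC = ln(S(b1)/S(b2)) / (b2 − b1)` with b = 50 and 800 s/mm² — the
clinical convention. Because b = 50 retains a perfusion contribution, the
noiseless ADC is ≥ the IVIM *D* wherever *f* > 0 (asserted in tests).

**Segmented IVIM.** The two-compartment diffusion signal is
`S(b) = S0 [ f·e^{−b·D*} + (1−f)·e^{−b·D} ]` with pseudo-diffusion
D\* ≫ D. For b ≥ 200 s/mm² the pseudo-diffusion compartment is negligible,
so ordinary least squares of ln S(b) on b over b ∈ {200, 300, 400, 600,
800} gives slope −D and intercept c, and `f = 1 − e^c / S(0)` referenced to
the measured b = 0 volume, clamped to [0, 1] with the clamp count logged.
Equal-weight OLS on the log-signal is used deliberately: it is the
segmented convention, deterministic, and its residual pseudo-diffusion
error admits a closed-form bound. The high-b log-signal perturbation is
δ(b) = ln(1 + (f/(1−f))·e^{−b(D*−D)}); OLS amplifies its maximum (at
b = 200) into the slope by Σ|b−b̄|/Σ(b−b̄)² and into the intercept by
1/n + b̄·Σ|b−b̄|/Σ(b−b̄)². For the default b-set these leverages are
960/232000 and ≈ 2.10; the tests assert the fitted D and f stay inside the
propagated bound (e.g. for f = 0.10, D = 1.2 × 10⁻³ mm²/s, D* = 10 D the
actual errors are ΔD/D ≈ +1.5 % and Δf ≈ −0.011, about half the bound).

**Hypoxia score.** `HS(v) = combine(D(v), f(v))` pointwise, with no
rescaling or distribution matching of D and f. The combining function is
pluggable; the default is

```
HS = (1 − f) · exp(−D / d0),   d0 = 1.5 × 10⁻³ mm²/s
```

— positive and bounded in (0, 1), monotone decreasing in the supply proxy
*f* and in *D* (low diffusivity ≈ high cellularity ≈ high oxygen
consumption). A positive-valued default matters operationally: %CV has the
mean in its denominator and the pipeline excludes non-positive means, so a
signed score would silently drop out of every repeatability table. The
exact published consumption-and-supply formulation is not reproduced here;
any alternative can be supplied via `combine=`.

**R2\*.** `S(TE) = S0·e^{−TE·R2*}` over 12 echoes (4.92–73.8 ms), solved
per voxel by a projected Gauss–Newton on (S0, R2\*) vectorized across
voxels, initialized from the log-linear fit, bound R2\* ≥ 0, relative
parameter-change tolerance 10⁻⁸ (≤ 60 iterations). In the noiseless case
the initializer is already exact and the solver recovers R2\* to machine
precision.

**B1⁺ correction and VFA T1.** The transmit-field factor is
κ = (actual flip angle)/(nominal 90°), linearly resampled to the VFA grid
when acquired on a coarser one. The SPGR steady state
`S(α) = M0·sin(κα)(1−E1)/(1−E1·cos(κα))`, `E1 = e^{−TR/T1}`, TR = 4.63 ms,
flip angles 2/5/10/15/20/30°, is solved per voxel by the same Gauss–Newton
scheme on (M0, E1), initialized from the DESPOT1 linearization
(S/sin(κα) regressed on S/tan(κα); the slope is E1). E1 outside (0, 1)
marks the voxel invalid. T1 is very sensitive to E1 at short TR
(|dT1/T1| ≈ |dE1/E1|/|ln E1| ≈ 300 at T1 = 1400 ms), which is why the
noiseless closed-loop test demands machine-precision E1; the DESPOT1
linearization is exact on noiseless data, so this is met.

## Texture-feature maps

Preprocessing per source image (T2w and the six parameter maps): resample
to 1 mm isotropic (trilinear; nearest-neighbor for masks), z-score
normalize with scale 100 and clip to [−300, 300], discretize with fixed
bin width 20 anchored at the volume-global masked minimum (labels
contiguous from 1; ≤ 31 levels over the full band). A global anchor keeps
labels comparable across windows; normalization makes features invariant
to global intensity shifts (asserted in tests).

Extraction slides a 5 × 5 mm in-plane (2-D, per-slice) window over every
masked voxel. Windows are cropped at slice edges and intersected with the
analysis mask — no intensities are invented by padding. Four texture
matrices are built per window over the gray levels present:

* **GLCM** — distance 1, the four in-plane directions, symmetric matrices;
  24 features computed per direction and averaged;
* **GLRLM** — maximal equal-label runs per direction (invalid voxels break
  runs); 16 features averaged over directions;
* **GLDM** — 8-neighborhood, zero gray-level tolerance; dependence =
  (number of equal-label valid neighbors) + 1; 14 features;
* **NGTDM** — absolute difference from the mean of existing valid
  8-neighbors; 5 features.

Feature formulas follow the IBSI definitions with gray levels entering as
bin numbers and base-2 logarithms in entropies. Degenerate (single-level)
windows use the common library conventions: correlation-type features
(Correlation, MCC) evaluate to 1, difference-type features to 0, NGTDM
coarseness saturates at 10⁶. Every builder is checked against brute-force
pair/run/dependence/difference enumeration on small windows, and map
values are spot-checked against the standalone single-window evaluation.

## Repeatability statistics

%CV uses the n−1 standard deviation (for two repeats, |x1−x2|/√2) divided
by the mean; voxels or ROIs with non-positive means are excluded and
counted. ROI mode takes the median over a region's valid voxels per scan,
one %CV per subject, and the cohort %wCV is the RMS over subjects. Voxel
mode computes a %CV per voxel (valid in both sessions) and an RMS over the
region per subject — one %wCV per subject — and reports the cohort median
and range of the per-subject %RC. In both modes %RC = 2.77 × %wCV exactly.

Zone dependence (PZ vs nPZ) is tested on all subjects, tissue dependence
(tumor vs benign) on patients only, with two-tailed paired t tests at
α = 0.05 on the per-subject metrics (ROI %CV, or voxel-mode %wCV). Subjects
missing either member of a pair are dropped pairwise with a logged count;
fewer than three complete pairs marks a contrast untestable. A degenerate
pairing (zero variance of differences, nonzero mean) is reported
significant with p at the numerical floor and flagged, since the direction
is unambiguous but the t statistic is not finite. No multiple-testing
correction enters the classification (per-feature α matches the analysis
convention); a Benjamini–Hochberg column is emitted alongside for
transparency. Ranking uses the WG %RC for features whose repeatability
depends on neither factor and the largest %RC over the relevant regions
otherwise (voxel mode: cohort medians first); ties break lexicographically
by identifier.

## The synthetic phantom

The phantom is a scaled-down digital prostate: a 44 × 44 × 10 grid at 1 mm
with an ellipsoidal whole gland (semi-axes 16 × 12 × 4 mm), a posterior
peripheral zone (the posterior half-space, giving PZ ≈ nPZ in volume so
the two zones carry equal sampling error), and an optional 3 mm-radius
tumor sphere in the PZ. Analysis regions are derived exactly as for real
data: the WG eroded by 1 mm in 3-D, nPZ = eroded WG minus PZ, the tumor
mask from Yen's threshold (256-bin masked histogram) of a smooth synthetic
probability bump restricted to the eroded gland, benign = eroded WG minus
tumor.

Zone-wise ground truth (typical 3 T values, configuration defaults rather
than cohort estimates): D = 1.6/1.3/0.9 × 10⁻³ mm²/s, f = 0.08/0.06/0.04,
R2\* = 25/30/35 s⁻¹, T1 = 1600/1400/1200 ms for PZ/nPZ/tumor; D\* = 10 D;
S0 of 500/400/1000 for the diffusion/multi-echo/VFA series. The B1⁺ factor
is a smooth in-plane polynomial (κ ≈ 0.87–1.03), emitted by default on the
reference grid (a coarse-grid option exercises the resampling path).

Acquisitions are forward-simulated through the exact signal models and
corrupted with Rician noise — the magnitude of signal plus complex
Gaussian noise, applied independently per volume. Default per-channel σ:
10 (diffusion), 8 (multi-echo), 2 (VFA), 6 (T2w). The VFA σ is small in
absolute terms because 3-D SPGR signals at short TR are weak (≈ 20–30
units here); the resulting voxel-wise T1 %RC (~20–35 %) is in the range
reported for prostate T1 mapping. Diffusion noise is inflated 2× inside
the PZ by default, emulating rectal susceptibility artifacts; this
reproduces a PZ/nPZ ADC %RC ratio near 2. Session 2 additionally applies a
global parameter drift (fraction 0.01, one Gaussian draw per parameter —
day-to-day biological variation) and a rigid jitter (≤ 1 mm, ≤ 0.5°
in-plane) resampled back to the reference grid with linear interpolation,
standing in for residual test–retest registration error. Everything is
bit-reproducible given the seed.

What the phantom does **not** emulate: susceptibility-induced geometric
distortion, eddy currents, motion between b-values/echoes/flip angles,
spatially correlated noise, partial-volume anatomy, or deformable
inter-session motion. Passing tests therefore demonstrate the correctness
of the estimators and statistics under the stated noise model, not the
magnitude of artifact-driven effects in patients.

## The zone-effect experiment

The power/type-I experiment (`qmrep.pipeline.zone_effect_replicate`)
simulates 16-subject cohorts (10 patients + 6 volunteers), computes each
subject's ROI %CV of ADC in PZ and nPZ, and applies the paired zone test.
Two design choices matter:

1. **Noise-only conditions.** Inter-session jitter and drift are disabled
   in this experiment. Both are zone-neutral by construction, so they can
   only dilute the PZ/nPZ contrast (with defaults on, the measured CV
   ratio collapses from ≈ 4 to ≈ 1.3); the experiment isolates the
   zone-dependent noise mechanism it is designed to detect, while the
   homogeneous-noise arm provides the matched null.
2. **Inflation 3.5×.** A two-repeat %CV estimate is half-normal with
   relative sd ≈ 0.76 regardless of scale, which bounds the paired-t
   effect size at d = (r−1)/√(0.58(r²+1)) for a CV ratio r. Reaching 90 %
   power at n = 16 therefore requires r ≳ 3.2; the experiment uses 3.5.
   The phantom default stays at 2× — the ratio itself, not the test's
   power, is what that default is meant to reproduce.

Measured over 20 seeded replicates: the inflated arm is significant in
20/20, the homogeneous arm non-significant in 19–20/20.

## Problem sizes and numerical choices

The test suite and the acceptance script run on the 44 × 44 × 10 phantom
(≈ 2000 gland voxels). Feature extraction costs ≈ 2 ms per voxel per
source image, so the single-session 413-map inventory takes ≈ 30 s; the
cohort feature-repeatability run restricts extraction to a seeded
400-voxel sub-mask of the gland across a 6-subject cohort to keep the full
413-feature dependency/ranking analysis around a minute. The
constant-phantom %RC check uses 10 625 voxels at SNR 20, where the
analytic expectation %RC = 277·σ/μ holds to within Monte-Carlo error
(standard error of an RMS over N voxels: RMS/√(2N)). Gauss–Newton solves
2 × 2 normal equations in closed form with a 10⁻¹² trace-scaled damping;
convergence is declared at relative parameter change < 10⁻⁸.

## Known limitations

* The hypoxia-score default is an implementation choice, not the published
  coefficient set (which the source text does not print).
* ADC/IVIM fits apply no magnitude-bias (Rician floor) correction; at the
  phantom's SNR the induced bias is < 2 % (asserted), but the estimators
  would be biased at very low SNR.
* N4 bias-field correction and deformable registration are out of scope;
  the phantom has no bias field and emulates residual misalignment with a
  single rigid jitter.
* ROI-mode feature medians in the scaled-down acceptance run are computed
  over the extraction sub-mask, a subsample of the full region.
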