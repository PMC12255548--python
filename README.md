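# qmrep — test–retest repeatability of quantitative prostate MRI

Quantitative MRI (qMRI) parameters — the apparent diffusion coefficient
(ADC), the intravoxel-incoherent-motion (IVIM) diffusion coefficient *D* and
perfusion fraction *f*, a hypoxia score (HS) combining them, the transverse
relaxation rate R2\*, and the longitudinal relaxation time T1 — are
candidate imaging biomarkers for monitoring prostate-cancer treatment
response. Using them longitudinally requires knowing the smallest change
that exceeds measurement noise. The QIBA repeatability coefficient supplies
that threshold: for a quantity measured twice under identical conditions,

```
%CV  = 100 · sd / mean            (per ROI or per voxel, n−1 sd)
%wCV = RMS of %CV                 (over subjects, or over voxels per subject)
%RC  = 2.77 · %wCV                (2.77 = 1.96·√2; the 95% minimum
                                   detectable percentage change)
```

Because image artifacts concentrate near the rectum, repeatability differs
between the peripheral zone (PZ) and the non-peripheral zone (nPZ), and
between tumor and benign tissue — so a single whole-gland threshold can be
wrong for the region you care about. `qmrep` implements the full analysis
needed to establish region-resolved thresholds:

* **Parametric-map fitting** (`qmrep.qmaps`): two-point ADC (b = 50/800
  s/mm²); segmented IVIM (OLS on log-signal, b ≥ 200 s/mm²) for *D* and
  *f*; a pluggable hypoxia-score combine of *D* and *f*; mono-exponential
  R2\* from multi-echo gradient echo; B1⁺-corrected variable-flip-angle
  SPGR T1 (DESPOT1-initialized nonlinear least squares).
* **Voxel-wise texture-feature maps** (`qmrep.texture`): 1 mm isotropic
  resampling, z-score normalization (×100, clipped to ±300), fixed bin
  width 20, and a 5 × 5 mm in-plane sliding window evaluating 59
  IBSI-compliant features per source image (24 GLCM + 16 GLRLM + 14 GLDM +
  5 NGTDM); with the T2-weighted image and six parameter maps that is
  7 × 59 = 413 feature maps per session.
* **Repeatability statistics** (`qmrep.repeatability`): %CV/%wCV/%RC in
  ROI (region-median) and voxel-wise modes; paired t tests for zone
  (PZ vs nPZ, all subjects) and tissue (tumor vs benign, patients only)
  dependence at α = 0.05; dependency classification (both / tissue only /
  zone only / neither); top-50 feature ranking by summary %RC.
* **A synthetic test–retest phantom** (`qmrep.phantom`): an ellipsoidal
  gland with a posterior PZ and an optional tumor sphere, forward-simulated
  through the actual signal models with Rician noise, optional PZ-specific
  diffusion-noise inflation, inter-session parameter drift and rigid
  jitter — so the entire chain is testable without patient data.

## Worked example

```python
import qmrep

# a 16-subject synthetic test-retest cohort (10 patients, 6 volunteers)
spec = qmrep.PhantomSpec(seed=0)
cohort = qmrep.simulate_cohort(spec, n_patients=10, n_volunteers=6, seed=0)

model = qmrep.RepeatabilityStudy.from_cohort(cohort)
results = model.fit()
rec = results.records
print(rec[(rec.quantity == "ADC") & (rec["mode"] == "voxel")]
      [["region", "wcv", "rc", "rc_min", "rc_max"]].round(1).to_string(index=False))
```

prints (voxel-wise ADC; `rc` is the cohort median of per-subject %RC):

```
region  wcv   rc  rc_min  rc_max
    WG 11.3 31.2    28.9    36.0
    PZ 14.4 40.0    35.6    46.6
   nPZ  7.3 20.1    18.0    22.4
 tumor 18.8 52.2    46.7    58.9
benign 10.4 28.9    25.8    31.1
```

The default phantom inflates diffusion noise 2× inside the PZ (emulating
rectal susceptibility artifacts) and places a small tumor sphere, so the
%RC of ADC is roughly twice as large in PZ as in nPZ and clearly larger in
tumor than in benign tissue — the reason zone- and tissue-specific
thresholds are needed. `results.dependency()` runs the paired tests and
classification, `results.rank_features(mode="ROI", k=50)` ranks features,
and `results.summary()` prints a combined table.

A command-line interface covers the file-based workflow:

```bash
qmrep simulate --out study/ --seed 0          # NIfTI study + manifest
qmrep fit --manifest study/manifest.yaml --session session1 --out maps1/
qmrep features --maps maps1/ --t2w study/session1/t2w.nii.gz \
               --mask study/truth/wg.nii.gz --out featuremaps/
qmrep repeat --session1 maps1/ --session2 maps2/ \
             --regions study/truth/ --out results/
```

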