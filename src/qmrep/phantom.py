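"""Synthetic test-retest prostate phantom.

Builds a digital phantom of the prostate gland — an ellipsoidal whole gland
(WG) split into a posterior peripheral zone (PZ) and an anterior
non-peripheral zone (nPZ), optionally carrying a spherical tumor — assigns
zone-wise ground-truth values for the six quantitative parameters, and
forward-simulates the full multi-parametric acquisition twice:

* diffusion series, two-compartment (IVIM) signal
  ``S(b) = S0 [ f exp(-b D*) + (1-f) exp(-b D) ]`` with ``D* = dstar_factor x D``;
* multi-echo gradient echo, ``S(TE) = S0 exp(-TE R2*)``;
* variable-flip-angle SPGR,
  ``S(a) = M0 sin(k a)(1-E1)/(1-E1 cos(k a))``, ``E1 = exp(-TR/T1)``, with a
  smooth transmit-field (B1+) factor ``k``;
* a T2-weighted anatomical volume and the actual-flip-angle B1+ map.

Noise is Rician: the magnitude of the noiseless signal plus complex Gaussian
noise of per-channel standard deviation sigma.  The diffusion-series noise
can be inflated inside the PZ to emulate the susceptibility artifacts near
the rectum that degrade echo-planar diffusion imaging there.  The second
session differs from the first only through an independent noise
realization, an optional global parameter drift (day-to-day biological
variation), and an optional small rigid-body jitter resampled back to the
reference grid (residual test-retest registration error).

Everything is deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .regions import RegionSet, derive_regions
from .volume import AcquisitionSeries, ImageVolume, ParametricMap

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "SyntheticStudy",
    "build_truth",
    "simulate_session",
    "simulate_study",
    "simulate_cohort",
    "predict_rc_direct",
    "rician",
]

#: Acquisition axes emulating a 3 T multi-parametric prostate protocol.
B_VALUES = np.array([0.0, 20.0, 50.0, 100.0, 200.0, 300.0, 400.0, 600.0, 800.0])
ECHO_TIMES = np.linspace(4.92, 73.8, 12)  # ms
FLIP_ANGLES = np.array([2.0, 5.0, 10.0, 15.0, 20.0, 30.0])  # degrees
TR_VFA = 4.63  # ms
NOMINAL_B1_ANGLE = 90.0  # degrees

SERIES_NAMES = ("dwi", "megre", "vfa", "b1", "t2w")


@dataclass
class PhantomSpec:
    """Geometry, ground truth, noise and session-perturbation settings.

    Ground-truth parameter values are configuration defaults chosen to be
    typical of benign peripheral-zone, benign transition-zone and tumor
    prostate tissue at 3 T; they are not cohort estimates.
    """

    shape: tuple[int, int, int] = (44, 44, 10)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm

    # zone geometry (mm, grid-center relative)
    wg_semi_axes: tuple[float, float, float] = (16.0, 12.0, 4.0)
    pz_offset_mm: float = 0.0        # PZ = WG with y >= center_y + offset
    tumor_center_mm: tuple[float, float, float] = (3.0, 5.0, 0.0)
    tumor_radius_mm: float = 3.0

    # ground truth per region {PZ, nPZ, tumor, background}
    d_values: dict = field(default_factory=lambda: {
        "PZ": 1.6e-3, "nPZ": 1.3e-3, "tumor": 0.9e-3, "background": 2.0e-3})
    f_values: dict = field(default_factory=lambda: {
        "PZ": 0.08, "nPZ": 0.06, "tumor": 0.04, "background": 0.0})
    r2s_values: dict = field(default_factory=lambda: {
        "PZ": 25.0, "nPZ": 30.0, "tumor": 35.0, "background": 10.0})
    t1_values: dict = field(default_factory=lambda: {
        "PZ": 1600.0, "nPZ": 1400.0, "tumor": 1200.0, "background": 3000.0})
    t2w_values: dict = field(default_factory=lambda: {
        "PZ": 300.0, "nPZ": 200.0, "tumor": 150.0, "background": 50.0})

    s0_dwi: float = 500.0
    s0_megre: float = 400.0
    m0_vfa: float = 1000.0
    dstar_factor: float = 10.0  # D* = dstar_factor * D (pseudo-diffusion)

    # transmit field k(x,y) = c0 + c1*xn + c2*yn + c3*(xn^2 + yn^2)
    b1_coeffs: tuple[float, float, float, float] = (1.0, 0.03, -0.05, -0.08)
    b1_downsample: int = 1  # emit B1 map every k-th voxel (1 = reference grid)

    # per-series complex-noise sd (signal units)
    sigma: dict = field(default_factory=lambda: {
        "dwi": 10.0, "megre": 8.0, "vfa": 2.0, "t2w": 6.0, "b1": 0.0})
    pz_noise_inflation: float = 2.0  # diffusion-series noise multiplier in PZ

    # inter-session perturbation (session 2 only)
    jitter_mm: float = 1.0
    jitter_deg: float = 0.5
    drift_fraction: float = 0.01

    seed: int = 0

    def validate(self) -> None:
        if any(n <= 0 for n in self.shape) or any(s <= 0 for s in self.spacing):
            raise ValueError("shape and spacing must be positive")
        if any(a <= 0 for a in self.wg_semi_axes):
            raise ValueError("WG semi-axes must be positive")
        if self.tumor_radius_mm < 0:
            raise ValueError("tumor radius must be >= 0")
        for name, vals in (("f", self.f_values),):
            for region, v in vals.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}[{region}] must lie in [0, 1]")
        for d in (self.d_values, self.r2s_values, self.t1_values, self.t2w_values):
            for region, v in d.items():
                if v < 0:
                    raise ValueError(f"ground-truth value {region} must be >= 0")
        if any(s < 0 for s in self.sigma.values()):
            raise ValueError("noise sd must be >= 0")
        if self.pz_noise_inflation < 0:
            raise ValueError("PZ noise inflation must be >= 0")
        if self.tumor_radius_mm > 0 and not self._tumor_inside_wg():
            raise ValueError("tumor sphere must lie fully inside the WG ellipsoid")

    def _tumor_inside_wg(self, n_dirs: int = 400) -> bool:
        rng = np.random.default_rng(12345)  # fixed: geometric check only
        u = rng.normal(size=(n_dirs, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts = np.asarray(self.tumor_center_mm) + self.tumor_radius_mm * u
        norm = np.sum((pts / np.asarray(self.wg_semi_axes)) ** 2, axis=1)
        return bool(np.all(norm <= 1.0))

    def grid_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Center-relative physical coordinates (mm) of every voxel."""
        axes = [
            (np.arange(n) - (n - 1) / 2.0) * s
            for n, s in zip(self.shape, self.spacing)
        ]
        return np.meshgrid(*axes, indexing="ij")


@dataclass
class PhantomTruth:
    """Ground-truth maps, analysis regions, and auxiliary truth fields."""

    maps: dict                      # quantity -> ParametricMap (ADC, D, f, HS, R2*, T1, T2w)
    regions: RegionSet              # analysis regions (WG eroded, Yen tumor)
    tumor_prob: ImageVolume         # synthetic tumor probability map
    kappa: ImageVolume              # true B1+ factor on the reference grid
    wg_raw: np.ndarray              # uneroded geometric WG mask
    pz_raw: np.ndarray              # geometric PZ mask
    tumor_geom: np.ndarray          # geometric tumor sphere mask
    s0: dict                        # series -> equilibrium-signal map (ndarray)

    @property
    def reference(self) -> ImageVolume:
        return self.maps["D"].volume


@dataclass
class SyntheticStudy:
    """Truth plus two complete simulated sessions."""

    truth: PhantomTruth
    sessions: list  # two dicts: {"dwi": AcquisitionSeries, ..., "t2w": ImageVolume}
    spec: PhantomSpec


def _paint(shape, regions_masks, values, background):
    out = np.full(shape, float(background))
    for name, mask in regions_masks.items():
        out[mask] = float(values[name])
    return out


def _adc_from_ivim(d, f, dstar_factor, b1=50.0, b2=800.0):
    """Analytic two-point ADC of the two-compartment diffusion signal."""
    s1 = f * np.exp(-b1 * dstar_factor * d) + (1.0 - f) * np.exp(-b1 * d)
    s2 = f * np.exp(-b2 * dstar_factor * d) + (1.0 - f) * np.exp(-b2 * d)
    return np.log(s1 / s2) / (b2 - b1)


def build_truth(spec: PhantomSpec) -> PhantomTruth:
    """Construct ground-truth parameter maps, region masks and the synthetic
    tumor probability map from a validated :class:`PhantomSpec`."""
    from .qmaps import default_hypoxia_combine  # avoid circular import at module load

    spec.validate()
    x, y, z = spec.grid_mm()
    a, b, c = spec.wg_semi_axes
    wg = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    pz = wg & (y >= spec.pz_offset_mm)
    if spec.tumor_radius_mm > 0:
        tc = spec.tumor_center_mm
        dist2 = (x - tc[0]) ** 2 + (y - tc[1]) ** 2 + (z - tc[2]) ** 2
        tumor_geom = wg & (dist2 <= spec.tumor_radius_mm**2)
        prob_vals = 0.95 * np.exp(-2.0 * dist2 / max(spec.tumor_radius_mm, 1e-9) ** 2)
        prob_vals[~wg] = 0.0
    else:
        tumor_geom = np.zeros(spec.shape, dtype=bool)
        prob_vals = np.zeros(spec.shape)

    paint_masks = {"nPZ": wg & ~pz, "PZ": pz, "tumor": tumor_geom}
    shape = spec.shape
    d_map = _paint(shape, paint_masks, spec.d_values, spec.d_values["background"])
    f_map = _paint(shape, paint_masks, spec.f_values, spec.f_values["background"])
    r2s_map = _paint(shape, paint_masks, spec.r2s_values, spec.r2s_values["background"])
    t1_map = _paint(shape, paint_masks, spec.t1_values, spec.t1_values["background"])
    t2w_map = _paint(shape, paint_masks, spec.t2w_values, spec.t2w_values["background"])
    adc_map = _adc_from_ivim(d_map, f_map, spec.dstar_factor)
    hs_map = default_hypoxia_combine(d_map, f_map)

    xn = x / np.max(np.abs(x)) if np.max(np.abs(x)) > 0 else x
    yn = y / np.max(np.abs(y)) if np.max(np.abs(y)) > 0 else y
    c0, c1, c2, c3 = spec.b1_coeffs
    kappa_vals = c0 + c1 * xn + c2 * yn + c3 * (xn**2 + yn**2)

    ref = ImageVolume(d_map, spec.spacing)
    prob = ref.with_values(prob_vals)
    regions = derive_regions(wg, pz, prob, spacing=spec.spacing)

    def pmap(values, quantity):
        return ParametricMap(ref.with_values(values), quantity)

    maps = {
        "ADC": pmap(adc_map, "ADC"),
        "D": pmap(d_map, "D"),
        "f": pmap(f_map, "f"),
        "HS": pmap(hs_map, "HS"),
        "R2*": pmap(r2s_map, "R2*"),
        "T1": pmap(t1_map, "T1"),
        "T2w": pmap(t2w_map, "T2w"),
    }
    s0 = {
        "dwi": np.full(shape, spec.s0_dwi),
        "megre": np.full(shape, spec.s0_megre),
        "vfa": np.full(shape, spec.m0_vfa),
    }
    return PhantomTruth(
        maps=maps,
        regions=regions,
        tumor_prob=prob,
        kappa=ref.with_values(kappa_vals),
        wg_raw=wg,
        pz_raw=pz,
        tumor_geom=tumor_geom,
        s0=s0,
    )


def rician(signal: np.ndarray, sigma, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of ``signal`` plus complex Gaussian noise (per-channel sd
    ``sigma``; scalar or broadcastable array)."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("noise sd must be >= 0")
    if np.all(sigma == 0):
        return np.asarray(signal, dtype=float).copy()
    n_re = rng.normal(size=np.shape(signal))
    n_im = rng.normal(size=np.shape(signal))
    return np.hypot(signal + sigma * n_re, sigma * n_im)


def _rigid_resample(values, spacing, angle_deg, shift_mm):
    """Apply a rigid in-plane rotation + 3-D translation, resampling back to
    the original grid with linear interpolation (residual-misregistration
    model)."""
    theta = np.deg2rad(angle_deg)
    ct, st = np.cos(theta), np.sin(theta)
    r_phys = np.array([[ct, -st, 0.0], [st, ct, 0.0], [0.0, 0.0, 1.0]])
    s = np.diag(spacing)
    s_inv = np.diag(1.0 / np.asarray(spacing))
    # output voxel -> input voxel: v_in = S^-1 R^-1 (S v_out - center - t) + center'
    m = s_inv @ r_phys.T @ s
    center = (np.asarray(values.shape) - 1) / 2.0
    shift_vox = np.asarray(shift_mm) / np.asarray(spacing)
    offset = center - m @ (center + shift_vox)
    return ndimage.affine_transform(values, m, offset=offset, order=1, mode="nearest")


def _session_rng_streams(spec_seed: int, session_index: int, extra_seed=None):
    entropy = [int(spec_seed), int(session_index)]
    if extra_seed is not None:
        entropy.append(int(extra_seed))
    ss = np.random.SeedSequence(entropy)
    return np.random.default_rng(ss)


def simulate_session(
    truth: PhantomTruth,
    spec: PhantomSpec,
    session_index: int,
    seed=None,
    series: tuple = SERIES_NAMES,
) -> dict:
    """Forward-simulate one acquisition session.

    Session index 0 is the reference; index >= 1 additionally applies the
    spec's global parameter drift and a rigid jitter (resampled back to the
    reference grid) before the noise.  ``series`` selects which acquisitions
    to simulate (all by default); restricting it is cheap and exact.

    Returns a dict with ``AcquisitionSeries`` under ``"dwi"``, ``"megre"``
    and ``"vfa"``, and ``ImageVolume`` under ``"b1"`` and ``"t2w"``.
    """
    rng = _session_rng_streams(spec.seed, session_index, seed)

    d_map = truth.maps["D"].values.copy()
    f_map = truth.maps["f"].values.copy()
    r2s_map = truth.maps["R2*"].values.copy()
    t1_map = truth.maps["T1"].values.copy()
    t2w_map = truth.maps["T2w"].values.copy()

    perturb = session_index >= 1
    if perturb and spec.drift_fraction > 0:
        drift = rng.normal(size=5) * spec.drift_fraction
        d_map = d_map * (1.0 + drift[0])
        f_map = np.clip(f_map * (1.0 + drift[1]), 0.0, 1.0)
        r2s_map = r2s_map * (1.0 + drift[2])
        t1_map = t1_map * (1.0 + drift[3])
        t2w_map = t2w_map * (1.0 + drift[4])
    else:
        rng.normal(size=5)  # keep the stream layout fixed across settings

    if perturb and (spec.jitter_mm > 0 or spec.jitter_deg > 0):
        angle = rng.uniform(-spec.jitter_deg, spec.jitter_deg)
        shift = rng.uniform(-spec.jitter_mm, spec.jitter_mm, size=3)
    else:
        rng.uniform(size=4)
        angle, shift = 0.0, np.zeros(3)

    def maybe_jitter(vol_values):
        if angle == 0.0 and not np.any(shift):
            return vol_values
        return _rigid_resample(vol_values, spec.spacing, angle, shift)

    ref = truth.reference
    out: dict = {}

    if "dwi" in series:
        dstar = spec.dstar_factor * d_map
        sigma_map = spec.sigma["dwi"] * (
            1.0 + (spec.pz_noise_inflation - 1.0) * truth.pz_raw
        )
        vols = []
        for b in B_VALUES:
            signal = truth.s0["dwi"] * (
                f_map * np.exp(-b * dstar) + (1.0 - f_map) * np.exp(-b * d_map)
            )
            noisy = rician(maybe_jitter(signal), sigma_map, rng)
            vols.append(ref.with_values(noisy))
        out["dwi"] = AcquisitionSeries(vols, "b-value", B_VALUES)

    if "megre" in series:
        vols = []
        for te in ECHO_TIMES:
            signal = truth.s0["megre"] * np.exp(-te * 1e-3 * r2s_map)
            noisy = rician(maybe_jitter(signal), spec.sigma["megre"], rng)
            vols.append(ref.with_values(noisy))
        out["megre"] = AcquisitionSeries(vols, "echo-time", ECHO_TIMES)

    if "vfa" in series:
        kappa = truth.kappa.values
        e1 = np.exp(-TR_VFA / t1_map)
        vols = []
        for alpha in FLIP_ANGLES:
            a_eff = np.deg2rad(alpha) * kappa
            signal = (
                truth.s0["vfa"]
                * np.sin(a_eff)
                * (1.0 - e1)
                / (1.0 - e1 * np.cos(a_eff))
            )
            noisy = rician(maybe_jitter(signal), spec.sigma["vfa"], rng)
            vols.append(ref.with_values(noisy))
        out["vfa"] = AcquisitionSeries(vols, "flip-angle", FLIP_ANGLES, TR_VFA)

    if "b1" in series:
        ds = max(int(spec.b1_downsample), 1)
        actual = NOMINAL_B1_ANGLE * truth.kappa.values
        if ds > 1:
            actual = actual[::ds, ::ds, ::ds]
            b1_spacing = tuple(s * ds for s in spec.spacing)
        else:
            b1_spacing = spec.spacing
        noisy = rician(actual, spec.sigma.get("b1", 0.0), rng)
        out["b1"] = ImageVolume(noisy, b1_spacing)

    if "t2w" in series:
        noisy = rician(maybe_jitter(t2w_map), spec.sigma["t2w"], rng)
        out["t2w"] = ref.with_values(noisy)

    return out


def simulate_study(spec: PhantomSpec, seed=None, series: tuple = SERIES_NAMES) -> SyntheticStudy:
    """Build the truth and simulate the two test-retest sessions."""
    truth = build_truth(spec)
    sessions = [
        simulate_session(truth, spec, 0, seed=seed, series=series),
        simulate_session(truth, spec, 1, seed=seed, series=series),
    ]
    return SyntheticStudy(truth=truth, sessions=sessions, spec=spec)


def simulate_cohort(
    spec: PhantomSpec,
    n_patients: int = 10,
    n_volunteers: int = 6,
    seed: int = 0,
    series: tuple = SERIES_NAMES,
):
    """Simulate a test-retest cohort.

    Patients carry the spec's tumor; volunteers are healthy (tumor radius 0).
    Returns a list of ``(SyntheticStudy, is_patient)`` pairs; each subject
    gets an independent, reproducible noise/perturbation stream.
    """
    cohort = []
    for i in range(n_patients + n_volunteers):
        is_patient = i < n_patients
        subj_spec = replace(
            spec,
            tumor_radius_mm=spec.tumor_radius_mm if is_patient else 0.0,
        )
        sub_seed = int(
            np.random.SeedSequence([int(seed), i]).generate_state(1)[0] % (2**31)
        )
        cohort.append((simulate_study(subj_spec, seed=sub_seed, series=series), is_patient))
    return cohort


def predict_rc_direct(sigma: float, mu: float) -> float:
    """Expected %RC of a directly measured quantity under additive noise.

    For a quantity measured twice with i.i.d. additive noise of sd ``sigma``
    about mean ``mu`` (Gaussian regime, SNR >~ 5), the large-sample
    within-subject CV is ``100 sigma/mu`` and the repeatability coefficient
    is ``2.77 x 100 x sigma/mu``.
    """
    if mu <= 0:
        raise ValueError("mean signal must be positive")
    if sigma < 0:
        raise ValueError("noise sd must be >= 0")
    return 2.77 * 100.0 * sigma / mu
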