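"""Voxel-wise fitting of the six quantitative parameter maps.

* ``fit_adc`` — two-point linearized mono-exponential ADC from the b = 50
  and 800 s/mm^2 diffusion volumes (the clinical convention).
* ``fit_ivim_simplified`` — segmented IVIM: ordinary least squares on
  log-signal over the high b-values (b >= 200 s/mm^2), where perfusion-driven
  pseudo-diffusion is negligible; slope gives the tissue diffusion
  coefficient D, and the intercept against the measured b = 0 signal gives
  the perfusion fraction f = 1 - exp(c)/S(0).
* ``compute_hypoxia_score`` — pointwise combination of D (oxygen-consumption
  proxy) and f (oxygen-supply proxy) into a hypoxia score; the combining
  function is pluggable and the default is an implementation choice (see
  :func:`default_hypoxia_combine`), applied with no rescaling of D and f.
* ``fit_r2star`` — mono-exponential fit to the multi-echo gradient-echo
  decay, nonlinear least squares initialized from the log-linear fit.
* ``flip_angle_correction`` / ``fit_t1_vfa`` — B1+ transmit correction
  factor kappa = actual/nominal flip angle, and the variable-flip-angle SPGR
  T1 fit with the flip angles uniformly scaled by kappa, initialized from
  the DESPOT1 linearization.

All fits are deterministic (no random initialization).  Voxels where a fit
is undefined or fails to converge are flagged invalid (NaN sentinel) and
excluded from all downstream statistics.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .volume import AcquisitionSeries, ImageVolume, ParametricMap

__all__ = [
    "fit_adc",
    "fit_ivim_simplified",
    "compute_hypoxia_score",
    "default_hypoxia_combine",
    "fit_r2star",
    "flip_angle_correction",
    "fit_t1_vfa",
    "fit_all",
]

log = logging.getLogger(__name__)

#: Diffusivity scale (mm^2/s) of the default hypoxia-score combine.
HS_D_SCALE = 1.5e-3


def default_hypoxia_combine(d: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Default hypoxia-score combine: ``HS = (1 - f) exp(-D / d0)``.

    Monotone decreasing in both the supply proxy f and the diffusivity D
    (low D ~ high cellularity ~ high oxygen consumption), bounded in (0, 1).
    This exact functional form is an implementation default pending the
    published consumption-and-supply model's coefficients; swap it via the
    ``combine=`` argument of :func:`compute_hypoxia_score`.
    """
    return (1.0 - np.asarray(f)) * np.exp(-np.asarray(d) / HS_D_SCALE)


def _series_volume(series: AcquisitionSeries, axis_value: float) -> np.ndarray:
    idx = np.where(np.isclose(series.axis_values, axis_value))[0]
    if idx.size == 0:
        raise ValueError(
            f"required {series.axis_kind} {axis_value} missing from series "
            f"(available: {series.axis_values.tolist()})"
        )
    return series.volumes[int(idx[0])].values


def fit_adc(dwi: AcquisitionSeries, b_pair=(50.0, 800.0)) -> ParametricMap:
    """Two-point ADC: ``ADC = ln(S(b1)/S(b2)) / (b2 - b1)``.

    Voxels with a non-positive signal at either b-value are invalid.
    """
    b1, b2 = float(b_pair[0]), float(b_pair[1])
    if b1 == b2:
        raise ValueError("the two b-values must differ")
    if b1 > b2:
        b1, b2 = b2, b1
    s1 = _series_volume(dwi, b1)
    s2 = _series_volume(dwi, b2)
    valid = (s1 > 0) & (s2 > 0) & np.isfinite(s1) & np.isfinite(s2)
    adc = np.full(s1.shape, np.nan)
    adc[valid] = np.log(s1[valid] / s2[valid]) / (b2 - b1)
    return ParametricMap(dwi.reference.with_values(adc), "ADC", valid=valid)


def fit_ivim_simplified(
    dwi: AcquisitionSeries,
    b_min: float = 200.0,
    report: dict | None = None,
) -> tuple[ParametricMap, ParametricMap]:
    """Segmented IVIM fit over b >= ``b_min`` (default 200 s/mm^2).

    Ordinary least squares of ln S(b) on b gives slope -D and intercept c;
    the perfusion fraction is ``f = 1 - exp(c)/S(0)``, clamped to [0, 1]
    with the clamp count logged (and recorded in ``report`` if given).
    """
    b = dwi.axis_values
    if not np.any(np.isclose(b, 0.0)):
        raise ValueError("IVIM fit requires a b = 0 volume")
    hi = b >= b_min
    if hi.sum() < 2:
        raise ValueError(f"need >= 2 b-values >= {b_min}, found {int(hi.sum())}")
    s0 = _series_volume(dwi, 0.0)
    stack = dwi.stack()[hi]           # (nb, nx, ny, nz)
    bh = b[hi]
    valid = (s0 > 0) & np.all(stack > 0, axis=0) & np.all(np.isfinite(stack), axis=0)

    logs = np.where(stack > 0, np.log(np.where(stack > 0, stack, 1.0)), 0.0)
    bm = bh.mean()
    lm = logs.mean(axis=0)
    cov = np.tensordot(bh - bm, logs - lm, axes=(0, 0)) / len(bh)
    var_b = np.mean((bh - bm) ** 2)
    slope = cov / var_b
    intercept = lm - slope * bm
    d = -slope
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 1.0 - np.exp(intercept) / s0
    clamped = valid & ((f < 0) | (f > 1))
    n_clamped = int(clamped.sum())
    if n_clamped:
        log.info("IVIM: clamped f to [0, 1] at %d voxels", n_clamped)
    if report is not None:
        report["f_clamped"] = n_clamped
        report["ivim_valid"] = int(valid.sum())
    f = np.clip(f, 0.0, 1.0)
    d_out = np.where(valid, d, np.nan)
    f_out = np.where(valid, f, np.nan)
    ref = dwi.reference
    return (
        ParametricMap(ref.with_values(d_out), "D", valid=valid),
        ParametricMap(ref.with_values(f_out), "f", valid=valid),
    )


def compute_hypoxia_score(
    d_map: ParametricMap, f_map: ParametricMap, combine=None
) -> ParametricMap:
    """Pointwise hypoxia score ``HS(v) = combine(D(v), f(v))``.

    No rescaling or distribution matching of D and f is applied before the
    combination.  Voxels invalid in either input are invalid in HS.
    """
    if combine is None:
        combine = default_hypoxia_combine
    if not d_map.volume.aligned_with(f_map.volume):
        raise ValueError("D and f maps must be aligned")
    valid = d_map.valid & f_map.valid
    hs = np.full(d_map.shape, np.nan)
    hs[valid] = combine(d_map.values[valid], f_map.values[valid])
    return ParametricMap(d_map.volume.with_values(hs), "HS", valid=valid)


def _gauss_newton_2p(y, model_jac, theta0, lower, upper, tol=1e-8, max_iter=60):
    """Projected Gauss-Newton for a 2-parameter separable decay model,
    vectorized over voxels.

    ``y``: (n_pts, n_vox) data; ``model_jac(theta)`` returns (resid, j1, j2)
    each (n_pts, n_vox); ``theta0``: (2, n_vox).  Returns (theta, converged).
    """
    theta = theta0.copy()
    converged = np.zeros(theta.shape[1], dtype=bool)
    active = ~converged
    for _ in range(max_iter):
        r, j1, j2 = model_jac(theta)
        a11 = np.sum(j1 * j1, axis=0)
        a12 = np.sum(j1 * j2, axis=0)
        a22 = np.sum(j2 * j2, axis=0)
        g1 = np.sum(j1 * r, axis=0)
        g2 = np.sum(j2 * r, axis=0)
        damp = 1e-12 * (a11 + a22) + 1e-300
        det = (a11 + damp) * (a22 + damp) - a12 * a12
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        d1 = ((a22 + damp) * g1 - a12 * g2) / det
        d2 = ((a11 + damp) * g2 - a12 * g1) / det
        step = np.vstack([d1, d2])
        step[:, converged] = 0.0
        theta_new = theta - step
        theta_new[0] = np.clip(theta_new[0], lower[0], upper[0])
        theta_new[1] = np.clip(theta_new[1], lower[1], upper[1])
        rel = np.max(
            np.abs(theta_new - theta) / np.maximum(np.abs(theta), 1e-30), axis=0
        )
        theta = theta_new
        newly = active & (rel < tol)
        converged |= newly
        active = ~converged
        if not active.any():
            break
    return theta, converged


def fit_r2star(megre: AcquisitionSeries, mask: np.ndarray | None = None) -> ParametricMap:
    """Mono-exponential R2* fit: ``S(TE) = S0 exp(-TE R2*)``.

    Nonlinear least squares initialized from the log-linear fit, with
    ``R2* >= 0`` enforced; relative-change tolerance 1e-8.  Echo times are in
    ms in the series axis; R2* is returned in 1/s.
    """
    if len(megre) < 3:
        raise ValueError("R2* fit requires >= 3 echoes")
    te = megre.axis_values * 1e-3  # s
    stack = megre.stack()
    shape = stack.shape[1:]
    flat = stack.reshape(len(te), -1)
    sel = np.all(flat > 0, axis=0) & np.all(np.isfinite(flat), axis=0)
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool).ravel()
    y = flat[:, sel]

    # log-linear init: ln S = ln S0 - TE * R2*
    logy = np.log(y)
    tm = te.mean()
    lm = logy.mean(axis=0)
    slope = ((te - tm) @ (logy - lm)) / np.sum((te - tm) ** 2)
    r2s0 = np.clip(-slope, 0.0, None)
    s0_init = np.exp(lm + slope * tm)
    theta0 = np.vstack([s0_init, r2s0])

    te_col = te[:, None]

    def model_jac(theta):
        e = np.exp(-te_col * theta[1])
        pred = theta[0] * e
        return pred - y, e, -theta[0] * te_col * e

    theta, converged = _gauss_newton_2p(
        y, model_jac, theta0, lower=(0.0, 0.0), upper=(np.inf, np.inf)
    )
    vals = np.full(flat.shape[1], np.nan)
    ok = np.zeros(flat.shape[1], dtype=bool)
    ok[sel] = converged
    vals[sel] = np.where(converged, theta[1], np.nan)
    return ParametricMap(
        megre.reference.with_values(vals.reshape(shape)),
        "R2*",
        valid=ok.reshape(shape),
    )


def resample_to_grid(vol: ImageVolume, reference: ImageVolume) -> ImageVolume:
    """Linearly resample ``vol`` onto the grid of ``reference``.

    Grids are assumed axis-aligned with coincident first-voxel centers
    (the convention of all phantom outputs).
    """
    if vol.shape == reference.shape and np.allclose(vol.spacing, reference.spacing):
        return vol.copy()
    coords = np.meshgrid(
        *[
            np.arange(n) * rs / vs
            for n, rs, vs in zip(reference.shape, reference.spacing, vol.spacing)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        vol.values, np.array(coords), order=1, mode="nearest"
    )
    return reference.with_values(out)


def flip_angle_correction(
    b1_actual: ImageVolume,
    nominal: float = 90.0,
    reference: ImageVolume | None = None,
) -> ImageVolume:
    """Transmit-field correction factor ``kappa = actual / nominal``.

    ``b1_actual`` is the actual-flip-angle map from B1+ mapping (degrees).
    Non-positive actual angles are flagged invalid (NaN).  If ``reference``
    is given, kappa is linearly resampled onto its grid.
    """
    if nominal <= 0:
        raise ValueError("nominal flip angle must be positive")
    kappa_vals = np.where(b1_actual.values > 0, b1_actual.values / nominal, np.nan)
    kappa = ImageVolume(kappa_vals, b1_actual.spacing, b1_actual.affine.copy())
    if reference is not None and (
        kappa.shape != reference.shape
        or not np.allclose(kappa.spacing, reference.spacing)
    ):
        kappa = resample_to_grid(kappa, reference)
    return kappa


def fit_t1_vfa(
    vfa: AcquisitionSeries,
    kappa: ImageVolume | None = None,
    mask: np.ndarray | None = None,
) -> ParametricMap:
    """Variable-flip-angle SPGR T1 fit with B1+ correction.

    Per voxel, ``S(a) = M0 sin(ka)(1 - E1)/(1 - E1 cos(ka))`` with
    ``E1 = exp(-TR/T1)`` is solved by nonlinear least squares initialized
    from the DESPOT1 linearization (S/sin(ka) vs S/tan(ka), slope = E1).
    Voxels whose fitted E1 falls outside (0, 1) are invalid.  T1 in ms.
    """
    if len(vfa) < 2:
        raise ValueError("T1 fit requires >= 2 flip angles")
    tr = float(vfa.repetition_time)
    alphas = np.deg2rad(vfa.axis_values)
    stack = vfa.stack()
    shape = stack.shape[1:]
    flat = stack.reshape(len(alphas), -1)
    if kappa is None:
        kap = np.ones(flat.shape[1])
    else:
        kap = flip_angle_correction(
            ImageVolume(kappa.values * 90.0, kappa.spacing, kappa.affine),
            nominal=90.0,
            reference=vfa.reference,
        ).values.ravel()
    sel = (
        np.all(flat > 0, axis=0)
        & np.all(np.isfinite(flat), axis=0)
        & np.isfinite(kap)
        & (kap > 0)
    )
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool).ravel()
    y = flat[:, sel]
    a_eff = alphas[:, None] * kap[None, sel]
    s, c = np.sin(a_eff), np.cos(a_eff)

    # DESPOT1: S/sin = E1 * (S/tan) + M0 (1 - E1)
    ys = y / s
    xs = y * c / s
    xm = xs.mean(axis=0)
    ym = ys.mean(axis=0)
    sxx = np.sum((xs - xm) ** 2, axis=0)
    sxy = np.sum((xs - xm) * (ys - ym), axis=0)
    e1_init = np.where(sxx > 0, sxy / np.maximum(sxx, 1e-300), 0.5)
    e1_init = np.clip(e1_init, 1e-8, 1.0 - 1e-8)
    m0_init = np.maximum((ym - e1_init * xm) / (1.0 - e1_init), 1e-12)
    theta0 = np.vstack([m0_init, e1_init])

    def model_jac(theta):
        den = 1.0 - theta[1] * c
        pred = theta[0] * s * (1.0 - theta[1]) / den
        j_m0 = s * (1.0 - theta[1]) / den
        j_e1 = theta[0] * s * (c - 1.0) / den**2
        return pred - y, j_m0, j_e1

    theta, converged = _gauss_newton_2p(
        y, model_jac, theta0, lower=(0.0, 1e-12), upper=(np.inf, 1.0 - 1e-12)
    )
    e1 = theta[1]
    good = converged & (e1 > 1e-10) & (e1 < 1.0 - 1e-10)
    t1 = np.where(good, -tr / np.log(np.clip(e1, 1e-300, 1 - 1e-16)), np.nan)
    vals = np.full(flat.shape[1], np.nan)
    ok = np.zeros(flat.shape[1], dtype=bool)
    ok[sel] = good
    vals[sel] = t1
    return ParametricMap(
        vfa.reference.with_values(vals.reshape(shape)), "T1", valid=ok.reshape(shape)
    )


def fit_all(session: dict, mask: np.ndarray | None = None, report: dict | None = None) -> dict:
    """Fit all six parametric maps from one simulated/loaded session.

    ``session`` maps series names (``dwi``, ``megre``, ``vfa``, ``b1``,
    ``t2w``) to their data.  Returns ``{quantity: ParametricMap}`` including
    the pass-through T2w volume.
    """
    maps: dict = {}
    maps["ADC"] = fit_adc(session["dwi"])
    d_map, f_map = fit_ivim_simplified(session["dwi"], report=report)
    maps["D"] = d_map
    maps["f"] = f_map
    maps["HS"] = compute_hypoxia_score(d_map, f_map)
    maps["R2*"] = fit_r2star(session["megre"], mask=mask)
    kappa = None
    if session.get("b1") is not None:
        kappa = flip_angle_correction(session["b1"], reference=session["vfa"].reference)
    maps["T1"] = fit_t1_vfa(session["vfa"], kappa=kappa, mask=mask)
    maps["T2w"] = ParametricMap(session["t2w"].copy(), "T2w")
    if report is not None:
        for q, m in maps.items():
            report[f"valid_{q}"] = int(m.valid.sum())
    return maps
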