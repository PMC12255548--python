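"""End-to-end glue: phantom study -> fitted maps (-> feature maps) -> model.

These helpers connect the forward simulation to the repeatability model so
that the whole chain — simulate two sessions, fit the six parametric maps
per session, optionally extract the 413 texture-feature maps, and feed the
paired maps into :class:`~qmrep.repeatability.RepeatabilityStudy` — is a
couple of calls.
"""

from __future__ import annotations

import numpy as np

from . import qmaps
from .phantom import SyntheticStudy
from .repeatability import SubjectData
from .texture import extract_voxel_features, normalize_image

SOURCE_QUANTITIES = ("T2w", "ADC", "D", "f", "HS", "R2*", "T1")

#: PZ diffusion-noise inflation used by the zone-effect power experiment.
#: The paired t on two-repeat %CVs is structurally noisy (a two-repeat %CV
#: estimate is half-normal with relative sd ~0.76, bounding the effect size
#: at d = (r-1)/sqrt(0.58 (r^2+1)) for a PZ/nPZ CV ratio r), so detecting
#: the zone effect reliably in a 16-subject cohort needs r >~ 3.2.
ZONE_EXPERIMENT_INFLATION = 3.5


def zone_effect_replicate(
    inflation: float,
    seed: int,
    n_patients: int = 10,
    n_volunteers: int = 6,
) -> float:
    """One replicate of the ROI-mode ADC zone-dependence experiment.

    Simulates a test-retest cohort with the given PZ diffusion-noise
    inflation under noise-only conditions (no inter-session jitter or
    drift, isolating the zone-dependent noise mechanism the experiment
    tests), computes each subject's ROI %CV of ADC in PZ and nPZ, and
    returns the two-tailed paired-t p value of the zone contrast.
    """
    import pandas as pd

    from .phantom import PhantomSpec, simulate_cohort
    from .qmaps import fit_adc
    from .repeatability import compare_repeatability, percent_cv, roi_measurement

    spec = PhantomSpec(
        pz_noise_inflation=inflation, jitter_mm=0.0, jitter_deg=0.0,
        drift_fraction=0.0, seed=0,
    )
    cohort = simulate_cohort(spec, n_patients, n_volunteers, seed=seed, series=("dwi",))
    pz_cv, npz_cv = {}, {}
    for i, (study, _) in enumerate(cohort):
        regions = study.truth.regions
        adcs = [fit_adc(s["dwi"]) for s in study.sessions]
        pz_cv[i] = percent_cv([roi_measurement(a, regions.pz) for a in adcs])
        npz_cv[i] = percent_cv([roi_measurement(a, regions.npz) for a in adcs])
    result = compare_repeatability(
        "ADC", "zone", "ROI", pd.Series(pz_cv), pd.Series(npz_cv)
    )
    return result.p


def feature_maps_for_session(
    maps: dict,
    wg: np.ndarray,
    feature_mask: np.ndarray | None = None,
    sources=SOURCE_QUANTITIES,
    kernel_mm: float = 5.0,
    bin_width: float = 20.0,
) -> dict:
    """Extract the 59 texture-feature maps from each source image of one
    session's fitted maps; returns ``{key: FeatureMap}`` (7 x 59 entries
    for the full source set).

    Each source is z-score normalized (scale 100, clipped to [-300, 300])
    before discretization; extraction runs over the eroded whole gland
    intersected with the source's valid voxels (and ``feature_mask``, a
    compute-bounding sub-mask, when given).
    """
    out: dict = {}
    for src in sources:
        pmap = maps[src]
        mask = wg & pmap.valid
        if feature_mask is not None:
            mask = mask & feature_mask
        if not mask.any():
            continue
        vol = normalize_image(pmap.volume)
        for fm in extract_voxel_features(
            vol, mask, kernel_mm=kernel_mm, bin_width=bin_width, source_quantity=src
        ):
            out[fm.key] = fm
    return out


def subject_from_study(
    study: SyntheticStudy,
    subject_id: str,
    is_patient: bool,
    include_features: bool = False,
    feature_mask: np.ndarray | None = None,
    feature_sources=SOURCE_QUANTITIES,
) -> SubjectData:
    """Fit both sessions of a phantom study into a :class:`SubjectData`."""
    regions = study.truth.regions
    wg = regions.wg
    maps1 = qmaps.fit_all(study.sessions[0], mask=wg)
    maps2 = qmaps.fit_all(study.sessions[1], mask=wg)
    if include_features:
        maps1 = {**maps1, **feature_maps_for_session(
            maps1, wg, feature_mask, sources=feature_sources)}
        maps2 = {**maps2, **feature_maps_for_session(
            maps2, wg, feature_mask, sources=feature_sources)}
    return SubjectData(
        subject_id=subject_id,
        is_patient=is_patient,
        maps1=maps1,
        maps2=maps2,
        regions=regions,
    )
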