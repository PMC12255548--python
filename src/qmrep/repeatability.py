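"""QIBA test-retest repeatability statistics, dependency testing and ranking.

The repeatability chain, per quantity (a qMRI parameter or a texture
feature), region (WG, PZ, nPZ, tumor, benign) and analysis mode:

* %CV — coefficient of variation of the repeated measurements,
  ``100 x sd / mean`` with the n-1 standard deviation (for two repeats,
  ``sd = |x1 - x2| / sqrt(2)``);
* %wCV — within-subject CV, the root mean square of %CV over subjects
  (ROI mode: one %wCV per cohort) or over voxels (voxel mode: one
  %wCV_voxel per subject);
* %RC — repeatability coefficient, ``2.77 x %wCV`` (2.77 = 1.96 sqrt(2) to
  two decimals), the 95% minimum detectable percentage change between two
  repeated measurements.

Zone (PZ vs nPZ, all subjects) and tissue (tumor vs benign, patients only)
dependence of the repeatability metrics is tested with two-tailed paired t
tests at alpha = 0.05, each quantity is classified as dependent on both /
tissue only / zone only / neither, and features are ranked by their summary
%RC (WG when independent, the largest region %RC otherwise) to give the
top-k most repeatable features.

The statsmodels-style entry point is :class:`RepeatabilityStudy` (the model,
built from a cohort of paired sessions) whose :meth:`~RepeatabilityStudy.fit`
returns :class:`RepeatabilityResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regions import REGION_NAMES, RegionSet

__all__ = [
    "RC_MULTIPLIER",
    "percent_cv",
    "voxel_cv",
    "wcv_roi",
    "wcv_voxel",
    "repeatability_coefficient",
    "roi_measurement",
    "compare_repeatability",
    "classify_dependency",
    "rank_features",
    "DependencyResult",
    "SubjectData",
    "RepeatabilityStudy",
    "RepeatabilityResults",
]

log = logging.getLogger(__name__)

#: %RC multiplier: 1.96 * sqrt(2) rounded to two decimals (QIBA convention).
RC_MULTIPLIER = 2.77

ALPHA = 0.05
QMRI_QUANTITIES = ("ADC", "D", "f", "HS", "R2*", "T1")


def percent_cv(measurements) -> float:
    """Coefficient of variation of repeated measurements, in percent.

    ``100 x sd / mean`` with the sample (n-1) standard deviation.  Scale
    invariant; requires >= 2 measurements and a positive mean.
    """
    x = np.asarray(measurements, dtype=float)
    if x.size < 2:
        raise ValueError("percent_cv requires >= 2 repeated measurements")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("percent_cv is undefined for non-positive mean")
    return float(100.0 * x.std(ddof=1) / mean)


def voxel_cv(values1: np.ndarray, values2: np.ndarray, valid: np.ndarray):
    """Per-voxel %CV of two repeated maps.

    Voxels invalid in either session or with a non-positive mean are
    excluded; returns ``(cv_grid, used_mask, n_excluded_nonpositive)``.
    For two repeats the n-1 sd is ``|x1 - x2| / sqrt(2)``.
    """
    valid = (
        np.asarray(valid, dtype=bool)
        & np.isfinite(values1)
        & np.isfinite(values2)
    )
    mean = 0.5 * (values1 + values2)
    pos = valid & (mean > 0)
    n_excluded = int(valid.sum() - pos.sum())
    cv = np.full(np.shape(values1), np.nan)
    cv[pos] = 100.0 * np.abs(values1[pos] - values2[pos]) / np.sqrt(2.0) / mean[pos]
    return cv, pos, n_excluded


def wcv_roi(per_subject_cv) -> float:
    """Cohort within-subject CV: RMS of the per-subject ROI %CV values."""
    x = np.asarray(per_subject_cv, dtype=float)
    if x.size == 0:
        raise ValueError("wcv_roi requires at least one subject")
    return float(np.sqrt(np.mean(x**2)))


def wcv_voxel(per_voxel_cv: np.ndarray, region: np.ndarray | None = None) -> float:
    """Per-subject within-subject CV: RMS of voxel %CV over the region's
    valid (finite) voxels."""
    cv = np.asarray(per_voxel_cv, dtype=float)
    if region is not None:
        cv = cv[np.asarray(region, dtype=bool)]
    cv = cv[np.isfinite(cv)]
    if cv.size == 0:
        raise ValueError("wcv_voxel requires at least one valid voxel")
    return float(np.sqrt(np.mean(cv**2)))


def repeatability_coefficient(wcv: float) -> float:
    """%RC = 2.77 x %wCV."""
    if wcv < 0:
        raise ValueError("%wCV must be >= 0")
    return RC_MULTIPLIER * wcv


def roi_measurement(pmap, region: np.ndarray):
    """Median of the map's valid voxels within ``region``; None if the
    intersection is empty (logged, excluded upstream)."""
    sel = pmap.valid & np.asarray(region, dtype=bool)
    if not sel.any():
        return None
    return float(np.median(pmap.values[sel]))


@dataclass
class DependencyResult:
    """Outcome of one paired contrast (zone or tissue) for one quantity."""

    quantity: str
    contrast: str           # "zone" or "tissue"
    mode: str               # "ROI" or "voxel"
    t: float = np.nan
    p: float = np.nan
    significant: bool = False
    n_pairs: int = 0
    degenerate: bool = False
    testable: bool = True


def compare_repeatability(
    quantity: str, contrast: str, mode: str, values_a: pd.Series, values_b: pd.Series
) -> DependencyResult:
    """Two-tailed paired t test between per-subject repeatability metrics of
    two regions.

    ``values_a`` / ``values_b`` are indexed by subject; subjects missing
    either member are dropped pairwise (logged).  Fewer than 3 complete
    pairs marks the result untestable.  A degenerate pairing (zero variance
    of differences, nonzero mean difference) is reported significant with p
    at the numerical floor and flagged.
    """
    joined = pd.concat([values_a, values_b], axis=1, keys=["a", "b"]).dropna()
    n_dropped = max(len(values_a), len(values_b)) - len(joined)
    if n_dropped:
        log.info(
            "%s %s (%s): dropped %d subjects with incomplete pairs",
            quantity, contrast, mode, n_dropped,
        )
    n = len(joined)
    res = DependencyResult(quantity=quantity, contrast=contrast, mode=mode, n_pairs=n)
    if n < 3:
        res.testable = False
        return res
    diff = joined["a"].to_numpy() - joined["b"].to_numpy()
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.isclose(diff.mean(), 0.0):
            res.t, res.p = 0.0, 1.0
        else:
            res.t = np.inf * np.sign(diff.mean())
            res.p = float(np.finfo(float).tiny)
            res.significant = True
            res.degenerate = True
        return res
    t, p = stats.ttest_rel(joined["a"], joined["b"])
    res.t, res.p = float(t), float(p)
    res.significant = bool(p < ALPHA)
    return res


def classify_dependency(zone: DependencyResult, tissue: DependencyResult) -> str:
    """Map the two significance flags to a dependency category."""
    if not (zone.testable and tissue.testable):
        return "unclassified"
    if zone.significant and tissue.significant:
        return "both"
    if tissue.significant:
        return "tissue only"
    if zone.significant:
        return "zone only"
    return "neither"


_CATEGORY_REGIONS = {
    "neither": ("WG",),
    "zone only": ("PZ", "nPZ"),
    "tissue only": ("tumor", "benign"),
    "both": ("PZ", "nPZ", "tumor", "benign"),
}


def rank_features(
    records: pd.DataFrame, categories: dict, mode: str, k: int = 50
) -> pd.DataFrame:
    """Rank features by their summary %RC and return the top ``k``.

    The summary %RC of a feature is its WG %RC when its repeatability
    depends on neither tissue type nor zone, and otherwise the largest %RC
    over the regions of its dependency (voxel mode %RCs are the per-cohort
    medians of the per-subject values).  Ascending sort; ties broken
    lexicographically by quantity identifier.  Features with a missing %RC
    in a required region are excluded and logged.
    """
    sub = records[records["mode"] == mode]
    rows = []
    for quantity, grp in sub.groupby("quantity"):
        category = categories.get(quantity, "neither")
        if category == "unclassified":
            log.info("ranking: %s unclassified, excluded", quantity)
            continue
        regions = _CATEGORY_REGIONS[category]
        rc_by_region = grp.set_index("region")["rc"]
        if any(r not in rc_by_region.index or not np.isfinite(rc_by_region[r]) for r in regions):
            log.info("ranking: %s missing %%RC in a required region, excluded", quantity)
            continue
        rows.append(
            {
                "quantity": quantity,
                "category": category,
                "rc_summary": float(rc_by_region[list(regions)].max()),
            }
        )
    ranked = pd.DataFrame(rows, columns=["quantity", "category", "rc_summary"])
    ranked = ranked.sort_values(
        ["rc_summary", "quantity"], kind="mergesort"
    ).reset_index(drop=True)
    parts = ranked["quantity"].str.split("|", expand=True)
    if parts.shape[1] == 3:
        ranked["source"], ranked["feature_class"], ranked["feature_name"] = (
            parts[0], parts[1], parts[2],
        )
    return ranked.head(k)


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


@dataclass
class SubjectData:
    """One subject's paired test-retest maps and analysis regions.

    ``maps1`` / ``maps2`` map quantity identifiers to objects exposing
    ``values`` and ``valid`` (ParametricMap or FeatureMap).
    """

    subject_id: str
    is_patient: bool
    maps1: dict
    maps2: dict
    regions: RegionSet


class RepeatabilityStudy:
    """Test-retest repeatability model over a cohort of paired maps.

    Parameters
    ----------
    subjects : list of SubjectData
        The cohort; patients contribute to the tissue contrast, all
        subjects to the zone contrast.
    quantities : sequence of str, optional
        Quantity identifiers to analyze; defaults to all quantities present
        in every subject's map dictionaries.
    """

    def __init__(self, subjects: list, quantities=None):
        if not subjects:
            raise ValueError("at least one subject is required")
        self.subjects = subjects
        if quantities is None:
            quantities = sorted(
                set.intersection(*(set(s.maps1) & set(s.maps2) for s in subjects))
            )
        self.quantities = list(quantities)

    @classmethod
    def from_cohort(cls, cohort, include_features: bool = False, feature_mask=None,
                    quantities=None):
        """Build the model from phantom studies (``simulate_cohort`` output).

        Fits the six parametric maps per session with
        :func:`qmrep.qmaps.fit_all`; with ``include_features`` additionally
        extracts the 59 texture-feature maps per source image (optionally on
        a sub-mask, ``feature_mask``, to bound compute).
        """
        from .pipeline import subject_from_study  # local import: avoids cycle

        subjects = [
            subject_from_study(
                study, f"subject{i:02d}", is_patient,
                include_features=include_features, feature_mask=feature_mask,
            )
            for i, (study, is_patient) in enumerate(cohort)
        ]
        return cls(subjects, quantities=quantities)

    def fit(self, modes=("ROI", "voxel"), regions=REGION_NAMES) -> "RepeatabilityResults":
        """Compute all repeatability records and dependency inputs."""
        records = []
        per_subject: dict = {}  # (quantity, region, mode) -> {subject: metric}
        for q in self.quantities:
            for region_name in regions:
                roi_cvs: dict = {}
                voxel_wcvs: dict = {}
                n_excl_roi = 0
                n_excl_vox = 0
                for subj in self.subjects:
                    if q not in subj.maps1 or q not in subj.maps2:
                        continue
                    m1, m2 = subj.maps1[q], subj.maps2[q]
                    region = subj.regions[region_name]
                    if not region.any():
                        continue
                    if "ROI" in modes:
                        a = roi_measurement(m1, region)
                        b = roi_measurement(m2, region)
                        if a is not None and b is not None:
                            if a + b > 0:
                                roi_cvs[subj.subject_id] = percent_cv([a, b])
                            else:
                                n_excl_roi += 1
                        else:
                            log.info(
                                "missing ROI measurement: %s %s %s",
                                subj.subject_id, q, region_name,
                            )
                    if "voxel" in modes:
                        cv, used, n_excl = voxel_cv(
                            m1.values, m2.values, m1.valid & m2.valid & region
                        )
                        n_excl_vox += n_excl
                        if used.any():
                            voxel_wcvs[subj.subject_id] = wcv_voxel(cv, used)
                if "ROI" in modes and roi_cvs:
                    wcv = wcv_roi(list(roi_cvs.values()))
                    records.append(
                        {
                            "quantity": q,
                            "region": region_name,
                            "mode": "ROI",
                            "wcv": wcv,
                            "rc": repeatability_coefficient(wcv),
                            "rc_min": np.nan,
                            "rc_max": np.nan,
                            "n_subjects": len(roi_cvs),
                            "n_excluded": n_excl_roi,
                        }
                    )
                    per_subject[(q, region_name, "ROI")] = roi_cvs
                if "voxel" in modes and voxel_wcvs:
                    rcs = {
                        s: repeatability_coefficient(w) for s, w in voxel_wcvs.items()
                    }
                    vals = np.array(list(rcs.values()))
                    records.append(
                        {
                            "quantity": q,
                            "region": region_name,
                            "mode": "voxel",
                            "wcv": float(np.median(list(voxel_wcvs.values()))),
                            "rc": float(np.median(vals)),
                            "rc_min": float(vals.min()),
                            "rc_max": float(vals.max()),
                            "n_subjects": len(rcs),
                            "n_excluded": n_excl_vox,
                        }
                    )
                    per_subject[(q, region_name, "voxel")] = voxel_wcvs
        frame = pd.DataFrame(
            records,
            columns=[
                "quantity", "region", "mode", "wcv", "rc",
                "rc_min", "rc_max", "n_subjects", "n_excluded",
            ],
        )
        return RepeatabilityResults(self, frame, per_subject)


class RepeatabilityResults:
    """Fitted repeatability records with dependency tests and ranking.

    Attributes
    ----------
    records : DataFrame
        One row per quantity x region x mode: %wCV, %RC (voxel mode: the
        cohort median of per-subject %RC, with min/max), subject counts and
        exclusion counts.
    """

    def __init__(self, model: RepeatabilityStudy, records: pd.DataFrame, per_subject: dict):
        self.model = model
        self.records = records
        self._per_subject = per_subject
        self._dependency_cache: pd.DataFrame | None = None

    def _metric_series(self, quantity, region, mode, patients_only=False) -> pd.Series:
        data = self._per_subject.get((quantity, region, mode), {})
        if patients_only:
            patient_ids = {s.subject_id for s in self.model.subjects if s.is_patient}
            data = {k: v for k, v in data.items() if k in patient_ids}
        return pd.Series(data, dtype=float)

    def dependency(self, modes=("ROI", "voxel")) -> pd.DataFrame:
        """Zone and tissue paired t tests plus the dependency category for
        every quantity and mode.

        Adds a Benjamini-Hochberg adjusted p value column per contrast for
        transparency; the classification itself uses the per-quantity
        alpha = 0.05.
        """
        rows = []
        for mode in modes:
            for q in self.model.quantities:
                zone = compare_repeatability(
                    q, "zone", mode,
                    self._metric_series(q, "PZ", mode),
                    self._metric_series(q, "nPZ", mode),
                )
                tissue = compare_repeatability(
                    q, "tissue", mode,
                    self._metric_series(q, "tumor", mode, patients_only=True),
                    self._metric_series(q, "benign", mode, patients_only=True),
                )
                rows.append(
                    {
                        "quantity": q,
                        "mode": mode,
                        "zone_t": zone.t, "zone_p": zone.p,
                        "zone_significant": zone.significant,
                        "zone_testable": zone.testable,
                        "tissue_t": tissue.t, "tissue_p": tissue.p,
                        "tissue_significant": tissue.significant,
                        "tissue_testable": tissue.testable,
                        "degenerate": zone.degenerate or tissue.degenerate,
                        "category": classify_dependency(zone, tissue),
                    }
                )
        frame = pd.DataFrame(rows)
        for contrast in ("zone", "tissue"):
            pcol = f"{contrast}_p"
            adj = np.full(len(frame), np.nan)
            ok = frame[pcol].notna().to_numpy()
            if ok.any():
                adj[ok] = stats.false_discovery_control(frame.loc[ok, pcol])
            frame[f"{contrast}_p_bh"] = adj
        self._dependency_cache = frame
        return frame

    def categories(self, mode: str) -> dict:
        dep = self.dependency(modes=(mode,))
        return dict(zip(dep["quantity"], dep["category"]))

    def rank_features(self, mode: str = "ROI", k: int = 50,
                      quantities=None) -> pd.DataFrame:
        """Top-k most repeatable quantities (ascending summary %RC)."""
        records = self.records
        if quantities is not None:
            records = records[records["quantity"].isin(quantities)]
        return rank_features(records, self.categories(mode), mode, k=k)

    def summary(self) -> str:
        """Human-readable repeatability and dependency summary."""
        lines = ["Test-retest repeatability (%RC = 2.77 x %wCV)", ""]
        qmri = self.records[self.records["quantity"].isin(QMRI_QUANTITIES)]
        shown = qmri if len(qmri) else self.records
        lines.append(
            shown.to_string(
                index=False,
                float_format=lambda v: f"{v:.3g}",
                columns=["quantity", "region", "mode", "wcv", "rc", "n_subjects"],
            )
        )
        try:
            dep = self.dependency()
            dep_q = dep[dep["quantity"].isin(QMRI_QUANTITIES)]
            dep_shown = dep_q if len(dep_q) else dep.head(20)
            lines += [
                "",
                "Dependency of repeatability (paired t, alpha = 0.05):",
                dep_shown.to_string(
                    index=False,
                    float_format=lambda v: f"{v:.3g}",
                    columns=["quantity", "mode", "zone_p", "tissue_p", "category"],
                ),
            ]
        except Exception:  # dependency needs paired regions; summary stays usable
            pass
        return "\n".join(lines)
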