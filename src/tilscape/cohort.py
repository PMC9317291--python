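"""Patient-level aggregation, reproducibility and variability screens.

ROI-level measure values are averaged per patient (unweighted; NA/inf values
are excluded from the mean rather than poisoning it).  Reproducibility across
ROIs of the same patient and variation across patients are both quantified
with a robust coefficient of variation |MAD / median| (unscaled MAD), and a
configurable screen excludes measures that either barely vary across patients
or vary wildly between ROIs of one patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ALL_COLUMNS, MEASURE_NAMES

#: Default screening thresholds (the published screen was qualitative; these
#: defaults reproduce its outcome on data with the same structure).
CV_VARIATION_FLOOR = 1e-6
CV_REPRODUCIBILITY_CEILING = 2.0


def _finite_mean(values: Iterable[float]) -> float:
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    return float(arr.mean()) if arr.size else np.nan


def average_over_rois(
    roi_measures: pd.DataFrame,
    measure_cols: Optional[Sequence[str]] = None,
    group_cols: Sequence[str] = ("patient_id", "cancer_type", "scale"),
) -> pd.DataFrame:
    """Unweighted per-patient mean of each measure over that patient's ROIs.

    NA and infinite ROI values are excluded from the mean; a patient whose
    every ROI is NA stays NA.  ROI size does not weight the mean — a good
    spatial measure should not depend on fragment size.
    """
    cols = list(measure_cols) if measure_cols is not None else [
        c for c in ALL_COLUMNS if c in roi_measures.columns
    ]
    group_cols = [c for c in group_cols if c in roi_measures.columns]
    work = roi_measures.copy()
    work[cols] = work[cols].replace([np.inf, -np.inf], np.nan)
    out = work.groupby(list(group_cols), sort=True)[cols].mean().reset_index()
    return out


def robust_cv(values: Iterable[float]) -> float:
    """|MAD / median| with unscaled MAD = median(|x - median(x)|).

    Requires at least two finite values; a zero median makes the ratio
    undefined and returns NA.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        return np.nan
    med = float(np.median(arr))
    if med == 0.0:
        return np.nan
    mad = float(np.median(np.abs(arr - med)))
    return abs(mad / med)


def cv_across_rois(
    roi_measures: pd.DataFrame,
    measure_cols: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Robust CV over each patient's ROIs: rows (cancer, patient, scale, measure, cv).

    Only patients with at least two ROIs carrying finite values contribute.
    """
    cols = list(measure_cols) if measure_cols is not None else [
        c for c in MEASURE_NAMES if c in roi_measures.columns
    ]
    rows: List[Dict] = []
    keys = [c for c in ("cancer_type", "patient_id", "scale") if c in roi_measures.columns]
    for key, grp in roi_measures.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(keys, key))
        for m in cols:
            rows.append({**rec, "measure": m, "cv": robust_cv(grp[m])})
    return pd.DataFrame(rows)


def cv_across_patients(
    patient_measures: pd.DataFrame,
    measure_cols: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Robust CV of patient-level values within each (cancer, scale)."""
    cols = list(measure_cols) if measure_cols is not None else [
        c for c in MEASURE_NAMES if c in patient_measures.columns
    ]
    keys = [c for c in ("cancer_type", "scale") if c in patient_measures.columns]
    rows: List[Dict] = []
    grouped = patient_measures.groupby(keys) if keys else [((), patient_measures)]
    for key, grp in grouped:
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(keys, key))
        for m in cols:
            rows.append({**rec, "measure": m, "cv": robust_cv(grp[m])})
    return pd.DataFrame(rows)


def cross_scale_correlation(
    patient_measures: pd.DataFrame,
    measure_cols: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Spearman and Pearson correlation between the binary- and
    probability-scale value of each measure, per cancer type.

    Pairs with an NA on either scale are dropped pairwise; fewer than three
    complete pairs, or zero variance, yields NA.
    """
    cols = list(measure_cols) if measure_cols is not None else [
        c for c in MEASURE_NAMES if c in patient_measures.columns
    ]
    idx_cols = [c for c in ("cancer_type", "patient_id") if c in patient_measures.columns]
    wide = patient_measures.pivot_table(
        index=idx_cols, columns="scale", values=cols, aggfunc="mean"
    )
    rows: List[Dict] = []
    cancers = (
        wide.index.get_level_values("cancer_type").unique()
        if "cancer_type" in idx_cols
        else [None]
    )
    for cancer in cancers:
        block = wide.xs(cancer, level="cancer_type") if cancer is not None else wide
        for m in cols:
            try:
                a = block[(m, "binary")].to_numpy(dtype=float)
                b = block[(m, "probability")].to_numpy(dtype=float)
            except KeyError:
                continue
            ok = np.isfinite(a) & np.isfinite(b)
            rec = {"cancer_type": cancer, "measure": m, "n": int(ok.sum())}
            if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
                rec["spearman"] = np.nan
                rec["pearson"] = np.nan
            else:
                rec["spearman"] = float(stats.spearmanr(a[ok], b[ok]).statistic)
                rec["pearson"] = float(stats.pearsonr(a[ok], b[ok]).statistic)
            rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class ScreeningResult:
    included: List[str]
    excluded: Dict[str, str]  # measure -> reason

    def __contains__(self, measure: str) -> bool:
        return measure in self.included


def screen_measures(
    cv_patients: pd.DataFrame,
    cv_rois: Optional[pd.DataFrame] = None,
    variation_floor: float = CV_VARIATION_FLOOR,
    reproducibility_ceiling: float = CV_REPRODUCIBILITY_CEILING,
    measures: Sequence[str] = tuple(MEASURE_NAMES),
) -> ScreeningResult:
    """Exclude measures with no across-patient variation or poor across-ROI
    reproducibility.

    A measure is excluded when its median across-patient CV (over cancers and
    scales) falls below ``variation_floor`` — it cannot separate patients —
    or when its median across-ROI CV exceeds ``reproducibility_ceiling`` —
    ROIs of the same patient disagree wildly.  A measure whose across-patient
    CV is NA everywhere (e.g. zero median in every cancer) is also excluded.
    Pure function of the CV tables and the two thresholds.
    """
    included: List[str] = []
    excluded: Dict[str, str] = {}
    for m in measures:
        pat = cv_patients.loc[cv_patients["measure"] == m, "cv"].to_numpy(dtype=float)
        pat_fin = pat[np.isfinite(pat)]
        if pat.size and pat_fin.size == 0:
            excluded[m] = "across-patient CV undefined everywhere"
            continue
        if pat_fin.size and np.median(pat_fin) < variation_floor:
            excluded[m] = "no variation across patients"
            continue
        if cv_rois is not None and len(cv_rois):
            roi = cv_rois.loc[cv_rois["measure"] == m, "cv"].to_numpy(dtype=float)
            roi_fin = roi[np.isfinite(roi)]
            if roi_fin.size and np.median(roi_fin) > reproducibility_ceiling:
                excluded[m] = "irreproducible across ROIs"
                continue
        included.append(m)
    return ScreeningResult(included=included, excluded=excluded)
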