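"""Penalized-Cox survival evaluation of the spatial measures.

Each measure is evaluated under 16 scenarios: {OS, PFI} endpoints x
{original, adjusted} Cox models x {continuous, discretized} measure scale x
{binary, probability} map scale.  Measures are min-max scaled to [0, 1]
(NA/inf dropped first); the discretized scenarios pick a low/high cutpoint by
the minimum-p-value method over 30 candidate thresholds between the 10th and
90th percentile.  Every Cox fit carries an L2 (ridge) penalty of 0.1 for
stability and includes patient age; the adjusted model adds the TIL fraction
as a further covariate.  Measures are ranked per (cancer, endpoint, model)
block by Harrell's concordance index and ranks averaged across blocks.

The minimum-p selection is the minimum of ~30 dependent tests and is
anti-conservative by construction; the full p-curve is returned so callers
can apply a multiplicity correction if they need honest selection p-values.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .types import MEASURE_NAMES

logger = logging.getLogger(__name__)

PENALIZER = 0.1
N_THRESHOLDS = 30
QUANTILE_LO = 0.10
QUANTILE_HI = 0.90

ENDPOINTS = ("OS", "PFI")
MODELS = ("original", "adjusted")
MEASURE_SCALES = ("continuous", "discretized")
MAP_SCALES = ("binary", "probability")

#: Measures the published screen removed before survival analysis.
DEFAULT_EXCLUDED = ("ripley_f", "ripley_g", "average_clustering", "det_ratio")
#: Measures restricted to probability-scale maps.
PROBABILITY_ONLY = ("banfeld_raftery",)


@dataclass(frozen=True)
class Scenario:
    endpoint: str
    model: str
    measure_scale: str
    map_scale: str

    def __post_init__(self):
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint must be in {ENDPOINTS}")
        if self.model not in MODELS:
            raise ValueError(f"model must be in {MODELS}")
        if self.measure_scale not in MEASURE_SCALES:
            raise ValueError(f"measure_scale must be in {MEASURE_SCALES}")
        if self.map_scale not in MAP_SCALES:
            raise ValueError(f"map_scale must be in {MAP_SCALES}")

    @property
    def name(self) -> str:
        return f"{self.endpoint}|{self.model}|{self.measure_scale}|{self.map_scale}"


def all_scenarios() -> List[Scenario]:
    """The full 2 x 2 x 2 x 2 = 16 scenario grid."""
    return [
        Scenario(e, m, s, g)
        for e, m, s, g in itertools.product(ENDPOINTS, MODELS, MEASURE_SCALES, MAP_SCALES)
    ]


@dataclass
class CoxResult:
    cancer: str
    measure: str
    scenario: Scenario
    hazard_ratio: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_value: float = np.nan
    c_index: float = np.nan
    threshold: float = np.nan  # chosen cutpoint on the 0-1 scale (discretized only)
    n_used: int = 0
    note: str = ""

    def to_row(self) -> Dict:
        return {
            "cancer_type": self.cancer,
            "measure": self.measure,
            "endpoint": self.scenario.endpoint,
            "model": self.scenario.model,
            "measure_scale": self.scenario.measure_scale,
            "map_scale": self.scenario.map_scale,
            "hazard_ratio": self.hazard_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "c_index": self.c_index,
            "threshold": self.threshold,
            "n_used": self.n_used,
            "note": self.note,
        }


def minmax_scale(values: np.ndarray) -> np.ndarray:
    """Scale finite values to [0, 1]; NA/inf entries are dropped first.

    Raises on a constant (degenerate) measure.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("degenerate measure: fewer than 2 finite values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        raise ValueError("degenerate measure: constant values")
    return (arr - lo) / (hi - lo)


def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str,
             penalizer: float = PENALIZER) -> CoxPHFitter:
    cph = CoxPHFitter(penalizer=penalizer)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    return cph


def minp_dichotomize(
    measure: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    age: np.ndarray,
    n_thresholds: int = N_THRESHOLDS,
    penalizer: float = PENALIZER,
    threshold_space: str = "quantile",
) -> Tuple[float, np.ndarray, pd.DataFrame]:
    """Minimum-p-value cutpoint for a min-max-scaled measure.

    Candidate thresholds are ``n_thresholds`` equally spaced quantile levels
    between the 10th and 90th percentile of the scaled measure (set
    ``threshold_space="value"`` for equally spaced raw values between those
    percentiles instead).  For each candidate the measure is binarized
    (>= threshold -> 1), a ridge-penalized Cox model with age is fitted and
    the Wald p of the binary coefficient stored.  Returns the argmin-p
    threshold (ties broken toward the smaller threshold), its labels, and the
    full p-curve.  Thresholds leaving either group without an event are
    skipped; if all are skipped the threshold and labels are NA.
    """
    x = np.asarray(measure, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    age = np.asarray(age, dtype=float)
    if events.sum() < 1:
        raise ValueError("need at least one event")
    lo_q, hi_q = np.quantile(x, [QUANTILE_LO, QUANTILE_HI])
    if threshold_space == "quantile":
        levels = np.linspace(QUANTILE_LO, QUANTILE_HI, n_thresholds)
        cands = np.quantile(x, levels)
    elif threshold_space == "value":
        cands = np.linspace(lo_q, hi_q, n_thresholds)
    else:
        raise ValueError("threshold_space must be 'quantile' or 'value'")

    records: List[Dict] = []
    best_p, best_t, best_labels = np.inf, np.nan, None
    for t in cands:
        labels = (x >= t).astype(float)
        rec = {"threshold": float(t), "p": np.nan, "skipped": True}
        n1 = labels.sum()
        if 0 < n1 < len(labels) and events[labels == 1].sum() >= 1 and events[labels == 0].sum() >= 1:
            df = pd.DataFrame({"group": labels, "age": age, "T": times, "E": events})
            try:
                cph = _fit_cox(df, "T", "E", penalizer=penalizer)
                p = float(cph.summary.loc["group", "p"])
                rec.update(p=p, skipped=False)
                if p < best_p - 1e-15 or (np.isinf(best_p) and np.isfinite(p)):
                    best_p, best_t, best_labels = p, float(t), labels
            except Exception as exc:  # convergence failure on this candidate
                logger.debug("threshold %.4f skipped: %s", t, exc)
        records.append(rec)
    p_curve = pd.DataFrame(records)
    if best_labels is None:
        return np.nan, np.full(len(x), np.nan), p_curve
    return best_t, best_labels, p_curve


def fit_cox(
    scenario: Scenario,
    cancer: str,
    measure: str,
    patients: pd.DataFrame,
    penalizer: float = PENALIZER,
    min_patients: int = 10,
) -> CoxResult:
    """One (cancer, measure, scenario) penalized Cox fit.

    ``patients`` must contain ``age``, the endpoint columns (``OS``,
    ``OS.time`` / ``PFI``, ``PFI.time``), ``pct_tils`` and the measure
    column, already averaged per patient on the scenario's map scale.
    Rows with NA/inf in any used column are dropped; fewer than
    ``min_patients`` usable rows, no events, a degenerate measure or a
    non-convergent fit yield an NA result with a note.
    """
    res = CoxResult(cancer=cancer, measure=measure, scenario=scenario)
    time_col = f"{scenario.endpoint}.time"
    event_col = scenario.endpoint
    cols = [measure, "age", time_col, event_col]
    if scenario.model == "adjusted":
        cols.append("pct_tils")
    missing = [c for c in cols if c not in patients.columns]
    if missing:
        res.note = f"missing columns: {missing}"
        return res
    work = patients[cols].replace([np.inf, -np.inf], np.nan).dropna()
    n = len(work)
    if n < min_patients:
        res.note = f"too few usable patients ({n})"
        return res
    if work[event_col].sum() < 1:
        res.note = "no events"
        return res
    x = work[measure].to_numpy(dtype=float)
    try:
        scaled = minmax_scale(x)
    except ValueError as exc:
        res.note = str(exc)
        return res
    times = work[time_col].to_numpy(dtype=float)
    events = work[event_col].to_numpy(dtype=float)
    age = work["age"].to_numpy(dtype=float)

    if scenario.measure_scale == "discretized":
        thr, labels, _ = minp_dichotomize(scaled, times, events, age, penalizer=penalizer)
        if not np.isfinite(thr):
            res.note = "all thresholds skipped"
            return res
        covariate = labels
        res.threshold = thr
    else:
        covariate = scaled

    df = pd.DataFrame({"measure": covariate, "age": age})
    if scenario.model == "adjusted":
        df["pct_tils"] = work["pct_tils"].to_numpy(dtype=float)
    df["T"] = times
    df["E"] = events
    try:
        cph = _fit_cox(df, "T", "E", penalizer=penalizer)
    except Exception as exc:
        res.note = f"fit failed: {exc}"
        logger.warning("Cox fit failed for %s/%s/%s: %s", cancer, measure, scenario.name, exc)
        return res
    summ = cph.summary.loc["measure"]
    res.hazard_ratio = float(summ["exp(coef)"])
    res.ci_low = float(summ["exp(coef) lower 95%"])
    res.ci_high = float(summ["exp(coef) upper 95%"])
    res.p_value = float(summ["p"])
    res.c_index = float(cph.concordance_index_)
    res.n_used = n
    return res


def run_all_scenarios(
    patients: pd.DataFrame,
    measures: Optional[Sequence[str]] = None,
    scenarios: Optional[Sequence[Scenario]] = None,
    probability_only: Sequence[str] = PROBABILITY_ONLY,
    penalizer: float = PENALIZER,
    min_patients: int = 10,
) -> pd.DataFrame:
    """Full cross of cancers x measures x scenarios.

    ``patients`` is the patient-level table with one row per (patient,
    map scale): columns ``patient_id, cancer_type, scale, age, OS, OS.time,
    PFI, PFI.time, pct_tils`` plus measure columns.  Scenarios whose map
    scale is absent from the table are skipped; measures in
    ``probability_only`` run only on probability-scale maps.  Deterministic
    given the input.
    """
    if measures is None:
        measures = [m for m in MEASURE_NAMES if m not in DEFAULT_EXCLUDED and m in patients.columns]
    if scenarios is None:
        scenarios = all_scenarios()
    available_scales = set(patients["scale"].unique()) if "scale" in patients.columns else {"binary"}
    rows: List[Dict] = []
    cancers = sorted(patients["cancer_type"].unique()) if "cancer_type" in patients.columns else [""]
    for cancer in cancers:
        for scn in scenarios:
            if scn.map_scale not in available_scales:
                continue
            sel = patients
            if "cancer_type" in patients.columns:
                sel = sel[sel["cancer_type"] == cancer]
            if "scale" in sel.columns:
                sel = sel[sel["scale"] == scn.map_scale]
            for m in measures:
                if m in probability_only and scn.map_scale != "probability":
                    continue
                res = fit_cox(scn, cancer, m, sel, penalizer=penalizer, min_patients=min_patients)
                rows.append(res.to_row())
    return pd.DataFrame(rows)


def rank_measures(results: pd.DataFrame) -> pd.DataFrame:
    """Rank measures by Harrell's C within each evaluation block and average.

    Blocks are (cancer, endpoint, model, measure scale, map scale); within a
    block measures are ranked by descending concordance (ties get the average
    rank, all-NA measures are excluded from that block).  The output has one
    row per measure with its mean rank and block count, sorted best first.
    """
    block_cols = ["cancer_type", "endpoint", "model", "measure_scale", "map_scale"]
    block_cols = [c for c in block_cols if c in results.columns]
    work = results.dropna(subset=["c_index"]).copy()
    if work.empty:
        return pd.DataFrame(columns=["measure", "mean_rank", "n_blocks"])
    work["rank"] = work.groupby(block_cols)["c_index"].rank(ascending=False, method="average")
    agg = (
        work.groupby("measure")["rank"]
        .agg(mean_rank="mean", n_blocks="count")
        .reset_index()
        .sort_values(["mean_rank", "measure"], kind="mergesort")
        .reset_index(drop=True)
    )
    return agg


def km_curves(
    times: np.ndarray,
    events: np.ndarray,
    labels: np.ndarray,
    group_names: Tuple[str, str] = ("low", "high"),
) -> Dict[str, object]:
    """Kaplan-Meier product-limit curves for a low/high split plus log-rank p.

    ``labels`` is 0/1; both groups must be non-empty.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    labels = np.asarray(labels)
    out: Dict[str, object] = {}
    masks = [labels == 0, labels == 1]
    if not all(m.any() for m in masks):
        raise ValueError("both groups must be non-empty")
    for name, m in zip(group_names, masks):
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m], label=name)
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        out[name] = sf
    lr = logrank_test(times[masks[0]], times[masks[1]], events[masks[0]], events[masks[1]])
    out["logrank_p"] = float(lr.p_value)
    return out
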