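"""End-to-end orchestration: simulate -> preprocess -> measures -> cohort -> survival.

A single global seed fans out to per-stage seeds by fixed offsets so each
stage is independently reproducible; every stage writes its tables under the
output directory, and ``run_pipeline`` finishes with a JSON manifest holding
versions, the seed and per-stage counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    average_over_rois,
    cross_scale_correlation,
    cv_across_patients,
    cv_across_rois,
    screen_measures,
)
from .io import (
    read_clinical,
    write_clinical,
    write_ground_truth,
    write_map_csv,
    write_map_png,
    write_rois,
    write_table,
)
from .measures import compute_measures
from .preprocess import preprocess_maps
from .survival import rank_measures, run_all_scenarios
from .synthetic import CohortSpec, MapSpec, generate_cohort, generate_til_map_pair
from .types import ROI, TILMap

logger = logging.getLogger(__name__)

# Seed offsets per stage (all derived seeds stay below 2**31).
_SEED_MAPS = 11
_SEED_MEASURES = 23
_SEED_COHORT = 37


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults match the analysis parameters
    (radius 50, k = 6, 8 GLCM levels, ridge penalty 0.1, 30 thresholds)."""

    out_dir: str = "tilscape_run"
    seed: int = 0

    # simulate
    n_patients: int = 24
    cancer_type: str = "synthetic"
    map_height: int = 110
    map_width: int = 110
    n_fragments: int = 1
    fragment_radius: float = 18.0
    density_range: Tuple[float, float] = (0.35, 0.7)
    clustered_fraction: float = 0.5
    n_artifact_lines: int = 1
    speckle_count: int = 2
    scales: Tuple[str, ...] = ("binary", "probability")

    # preprocess
    min_map_pixels: int = 10_000
    min_area_fraction: float = 0.10
    line_frac: float = 0.20
    closing_size: int = 3

    # measures
    knn_k: int = 6
    ripley_radius: float = 50.0
    ap_max_points: int = 1000

    # cohort / screening
    clinical_path: Optional[str] = None
    driver_measure: str = "spatial_autocorrelation"
    beta: float = 1.5
    censor_rate: float = 0.3
    variation_floor: float = 1e-6
    reproducibility_ceiling: float = 2.0

    # survival
    penalizer: float = 0.1
    min_patients: int = 10
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not set(self.scales) <= {"binary", "probability"}:
            raise ValueError("scales must be a subset of {binary, probability}")
        if self.clinical_path is not None and not Path(self.clinical_path).exists():
            raise ValueError(f"clinical file not found: {self.clinical_path}")
        if self.map_height * self.map_width < self.min_map_pixels:
            raise ValueError("configured maps would all be removed by the size filter")


def stage_simulate(cfg: PipelineConfig) -> Tuple[List[TILMap], List[TILMap], List]:
    """Per-patient map pairs (binary + probability) with varying density and
    clustering so measures genuinely differ across the cohort."""
    rng = np.random.default_rng(cfg.seed + _SEED_MAPS)
    bins: List[TILMap] = []
    probs: List[TILMap] = []
    truths: List = []
    for i in range(cfg.n_patients):
        density = float(rng.uniform(*cfg.density_range))
        clustered = rng.random() < cfg.clustered_fraction
        spec = MapSpec(
            height=cfg.map_height,
            width=cfg.map_width,
            n_fragments=cfg.n_fragments,
            fragment_radius=cfg.fragment_radius,
            til_density=density,
            clustering="clustered" if clustered else "csr",
            n_artifact_lines=cfg.n_artifact_lines,
            speckle_count=cfg.speckle_count,
            seed=int(rng.integers(0, 2**31)),
        )
        pid = f"P{i:04d}"
        bmap, pmap, gt = generate_til_map_pair(
            spec, map_id=f"{pid}-map0", patient_id=pid, cancer_type=cfg.cancer_type
        )
        bins.append(bmap)
        probs.append(pmap)
        truths.append(gt)
    return bins, probs, truths


def stage_measures(rois: Sequence[ROI], cfg: PipelineConfig) -> pd.DataFrame:
    rng = np.random.default_rng(cfg.seed + _SEED_MEASURES)
    rows: List[Dict] = []
    for roi in rois:
        vals = compute_measures(
            roi,
            k=cfg.knn_k,
            radius=cfg.ripley_radius,
            ap_max_points=cfg.ap_max_points,
            seed=int(rng.integers(0, 2**31)),
        )
        rows.append(
            {
                "roi_id": roi.roi_id,
                "map_id": roi.parent_map_id,
                "patient_id": roi.patient_id,
                "cancer_type": roi.cancer_type,
                "scale": roi.scale,
                **vals,
            }
        )
    return pd.DataFrame(rows)


def stage_cohort(
    roi_measures: pd.DataFrame, cfg: PipelineConfig
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, object]:
    """Patient averaging, CV tables, screening, and the clinical join."""
    patient_measures = average_over_rois(roi_measures)
    cv_roi = cv_across_rois(roi_measures)
    cv_pat = cv_across_patients(patient_measures)
    screening = screen_measures(
        cv_pat,
        cv_roi,
        variation_floor=cfg.variation_floor,
        reproducibility_ceiling=cfg.reproducibility_ceiling,
    )

    if cfg.clinical_path is not None:
        clinical = read_clinical(cfg.clinical_path)
    else:
        base_scale = "binary" if "binary" in set(patient_measures["scale"]) else "probability"
        base = patient_measures[patient_measures["scale"] == base_scale].set_index("patient_id")
        driver = cfg.driver_measure
        if driver not in base.columns or not np.isfinite(base[driver]).all():
            raise ValueError(f"driver measure {driver!r} unusable for cohort simulation")
        cspec = CohortSpec(
            n_patients=len(base),
            driver_measure=driver,
            beta=cfg.beta,
            censor_rate=cfg.censor_rate,
            seed=(cfg.seed + _SEED_COHORT) % (2**31),
        )
        clinical = generate_cohort(cspec, base.reset_index())

    patients = patient_measures.merge(clinical, on="patient_id", how="inner")
    return patients, cv_pat, cv_roi, screening


def stage_survival(
    patients: pd.DataFrame, included: Sequence[str], cfg: PipelineConfig
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    results = run_all_scenarios(
        patients,
        measures=list(included),
        penalizer=cfg.penalizer,
        min_patients=cfg.min_patients,
    )
    ranking = rank_measures(results)
    return results, ranking


def _sha1(path: Path) -> str:
    h = hashlib.sha1()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> Dict[str, object]:
    """Run every stage, write artifacts under ``cfg.out_dir`` and return the
    in-memory tables.  Any stage failure aborts with a stage-named error."""
    cfg.validate()
    out = Path(cfg.out_dir)
    (out / "maps").mkdir(parents=True, exist_ok=True)
    (out / "rois").mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: Dict[str, object] = {
        "tilscape_version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
    }

    try:
        bins, probs, truths = stage_simulate(cfg)
        for m, gt in zip(bins, truths):
            write_map_png(m, out / "maps" / f"{m.map_id}_binary.png")
            write_ground_truth(gt, out / "maps" / f"{m.map_id}.json")
        for m in probs:
            write_map_csv(m, out / "maps" / f"{m.map_id}_probability.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    maps: List[TILMap] = []
    if "binary" in cfg.scales:
        maps += bins
    if "probability" in cfg.scales:
        maps += probs
    try:
        rois, report = preprocess_maps(
            maps,
            min_pixels=cfg.min_map_pixels,
            min_area_fraction=cfg.min_area_fraction,
            line_frac=cfg.line_frac,
            closing_size=cfg.closing_size,
        )
        write_rois(rois, out / "rois")
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc
    manifest["preprocess"] = report

    try:
        roi_measures = stage_measures(rois, cfg)
        write_table(roi_measures, out / "measures.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'measures' failed: {exc}") from exc
    na_counts = {
        c: int(roi_measures[c].isna().sum()) for c in roi_measures.columns if roi_measures[c].dtype.kind == "f"
    }
    manifest["measures"] = {"rois": len(roi_measures), "na_per_measure": na_counts}

    try:
        patients, cv_pat, cv_roi, screening = stage_cohort(roi_measures, cfg)
        write_table(patients, out / "patients.tsv")
        write_table(cv_pat, out / "cv_patients.tsv")
        write_table(cv_roi, out / "cv_rois.tsv")
        corr = cross_scale_correlation(patients) if len(cfg.scales) == 2 else pd.DataFrame()
        if len(corr):
            write_table(corr, out / "cross_scale_correlation.tsv")
        if cfg.clinical_path is None:
            write_clinical(
                patients.drop_duplicates("patient_id"), out / "clinical.tsv"
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'cohort' failed: {exc}") from exc
    manifest["cohort"] = {
        "patients": int(patients["patient_id"].nunique()),
        "included_measures": screening.included,
        "excluded_measures": screening.excluded,
    }

    try:
        results, ranking = stage_survival(patients, screening.included, cfg)
        write_table(results, out / "cox_results.tsv")
        write_table(ranking, out / "measure_ranking.tsv")
        if cfg.make_plots and len(results):
            from .plots import forest_plot

            ok = results.dropna(subset=["hazard_ratio"])
            if len(ok):
                forest_plot(ok, out / "forest.png")
    except Exception as exc:
        raise RuntimeError(f"stage 'survival' failed: {exc}") from exc
    manifest["survival"] = {
        "rows": len(results),
        "fitted": int(results["hazard_ratio"].notna().sum()) if len(results) else 0,
    }

    manifest["runtime_s"] = round(time.time() - t0, 2)
    manifest["artifact_hashes"] = {
        p.name: _sha1(p) for p in sorted(out.glob("*.tsv"))
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    logger.info("pipeline finished in %.1fs: %s", manifest["runtime_s"], report)
    return {
        "rois": rois,
        "roi_measures": roi_measures,
        "patients": patients,
        "cv_patients": cv_pat,
        "cv_rois": cv_roi,
        "screening": screening,
        "results": results,
        "ranking": ranking,
        "manifest": manifest,
    }
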