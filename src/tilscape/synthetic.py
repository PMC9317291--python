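"""Synthetic TIL maps and survival cohorts with known ground truth.

The generator emulates the qualitative features of real patch-level TIL maps:
several disjoint tissue fragments on one slide, dark scanner-line artifacts
spanning a full row or column, small background speckle left over from
thresholding, and TIL placement that is either completely spatially random
(CSR) or clustered (a Matern-style parent/offspring process) within each
fragment.  Cohorts are drawn from a Weibull proportional-hazards model whose
linear predictor depends on a chosen "driver" spatial measure, so survival
machinery can be tested against known effect sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import BINARY, PROBABILITY, SCALES, TILMap


@dataclass
class MapSpec:
    """Parameters of one synthetic TIL map.

    ``til_density`` is the Bernoulli rate of TIL positivity *within* tissue
    fragments (CSR) or the target mean rate (clustered).  Fragments are discs
    of radius ``fragment_radius``; when ``fragment_centers`` is None they are
    placed equally spaced along the horizontal mid-line.
    """

    height: int = 160
    width: int = 160
    n_fragments: int = 2
    fragment_centers: Optional[Sequence[Tuple[float, float]]] = None
    fragment_radius: float = 24.0
    til_density: float = 0.55
    clustering: str = "csr"  # "csr" | "clustered"
    cluster_parent_rate: float = 8.0  # mean parents per fragment
    cluster_radius: float = 4.0  # offspring disc radius (patches)
    n_artifact_lines: int = 1
    speckle_count: int = 3
    speckle_max_area: int = 4
    scale: str = BINARY
    # TIL probabilities are 0.5 + 0.5 * Beta(a, b); None draws (a, b) per map
    # uniformly from [1, 4], emulating slide-to-slide variation in classifier
    # confidence (staining, focus, model calibration differ between slides).
    prob_alpha: Optional[float] = None
    prob_beta: Optional[float] = None
    seed: int = 0

    def validate(self) -> None:
        if self.height * self.width < 1:
            raise ValueError("map must contain at least one patch")
        if not 0.0 <= self.til_density <= 1.0:
            raise ValueError("til_density must be in [0, 1]")
        if self.clustering not in ("csr", "clustered"):
            raise ValueError("clustering must be 'csr' or 'clustered'")
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}")
        if self.n_fragments < 0:
            raise ValueError("n_fragments must be >= 0")
        if self.fragment_radius <= 0.5:
            raise ValueError("zero-area fragments: fragment_radius too small")
        if self.speckle_max_area < 1:
            raise ValueError("speckle_max_area must be >= 1")


@dataclass
class MapGroundTruth:
    """What was planted in a synthetic map (JSON-serialisable)."""

    fragment_centers: List[Tuple[float, float]]
    fragment_radius: float
    fragment_masks: List[np.ndarray]  # boolean, one per fragment
    artifact_lines: List[Tuple[str, int]]  # ("row"|"col", index)
    speckle_boxes: List[Tuple[int, int, int, int]]  # r0, c0, h, w
    til_count_pre_artifact: int

    def to_json_dict(self) -> Dict:
        return {
            "fragment_centers": [list(map(float, c)) for c in self.fragment_centers],
            "fragment_radius": float(self.fragment_radius),
            "n_fragments": len(self.fragment_masks),
            "fragment_til_areas": [int(m.sum()) for m in self.fragment_masks],
            "artifact_lines": [[a, int(i)] for a, i in self.artifact_lines],
            "speckle_boxes": [list(map(int, b)) for b in self.speckle_boxes],
            "til_count_pre_artifact": int(self.til_count_pre_artifact),
        }


def _default_centers(spec: MapSpec) -> List[Tuple[float, float]]:
    k = spec.n_fragments
    row = spec.height / 2.0
    return [(row, spec.width * (i + 1) / (k + 1)) for i in range(k)]


def _disc_mask(h: int, w: int, center: Tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[:h, :w]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _fill_csr(rng: np.random.Generator, mask: np.ndarray, density: float) -> np.ndarray:
    til = np.zeros(mask.shape, dtype=bool)
    idx = np.flatnonzero(mask)
    hit = rng.random(idx.size) < density
    til.flat[idx[hit]] = True
    return til


def _fill_matern(
    rng: np.random.Generator,
    mask: np.ndarray,
    density: float,
    parent_rate: float,
    radius: float,
) -> np.ndarray:
    """Parent/offspring clustered fill: parents uniform in the fragment,
    offspring uniform in a disc around each parent, clipped to the fragment.
    Because offspring collapse onto grid cells, proposals are drawn in rounds
    until the realised TIL cell count reaches density * fragment area (or the
    parent discs saturate), so clustered and CSR fills are density-matched."""
    til = np.zeros(mask.shape, dtype=bool)
    cells = np.argwhere(mask)
    if cells.size == 0:
        return til
    target = int(round(density * len(cells)))
    if target == 0:
        return til
    n_parents = max(1, rng.poisson(parent_rate))
    parents = cells[rng.integers(0, len(cells), size=n_parents)].astype(float)
    for _round in range(30):
        deficit = target - int(til.sum())
        if deficit <= 0:
            break
        k_per = np.maximum(1, rng.poisson(deficit / n_parents, size=n_parents))
        for p, k in zip(parents, k_per):
            ang = rng.random(k) * 2 * np.pi
            rad = radius * np.sqrt(rng.random(k))
            pts = np.round(
                p + np.column_stack([rad * np.sin(ang), rad * np.cos(ang)])
            ).astype(int)
            ok = (
                (pts[:, 0] >= 0)
                & (pts[:, 0] < mask.shape[0])
                & (pts[:, 1] >= 0)
                & (pts[:, 1] < mask.shape[1])
            )
            pts = pts[ok]
            pts = pts[mask[pts[:, 0], pts[:, 1]]]
            til[pts[:, 0], pts[:, 1]] = True
    return til


def _place_speckles(
    rng: np.random.Generator,
    shape: Tuple[int, int],
    forbidden: np.ndarray,
    count: int,
    max_area: int,
    margin: int = 6,
) -> List[Tuple[int, int, int, int]]:
    """Sample small solid rectangles in the background, at least ``margin``
    patches away from the forbidden (fragment) mask so morphological closing
    cannot attach them to real tissue."""
    from scipy.ndimage import binary_dilation

    h, w = shape
    keepout = binary_dilation(forbidden, iterations=margin) if forbidden.any() else forbidden
    boxes: List[Tuple[int, int, int, int]] = []
    attempts = 0
    while len(boxes) < count and attempts < 200 * max(count, 1):
        attempts += 1
        bh = int(rng.integers(1, 3))
        bw = int(rng.integers(1, 3))
        if bh * bw > max_area:
            continue
        r0 = int(rng.integers(0, max(1, h - bh)))
        c0 = int(rng.integers(0, max(1, w - bw)))
        region = keepout[r0 : r0 + bh, c0 : c0 + bw]
        if region.any():
            continue
        near = any(abs(r0 - b[0]) < 6 and abs(c0 - b[1]) < 6 for b in boxes)
        if near:
            continue
        boxes.append((r0, c0, bh, bw))
    return boxes


def generate_til_map(
    spec: MapSpec,
    map_id: str = "synthetic",
    patient_id: str = "",
    cancer_type: str = "synthetic",
) -> Tuple[TILMap, MapGroundTruth]:
    """Generate one synthetic TIL map plus its ground truth.

    Returns the map on ``spec.scale`` and a :class:`MapGroundTruth` holding
    the planted fragment masks, injected line indices and speckle boxes.
    Fully reproducible from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    centers = list(spec.fragment_centers) if spec.fragment_centers is not None else _default_centers(spec)
    if len(centers) != spec.n_fragments:
        raise ValueError("fragment_centers length must equal n_fragments")

    frag_masks: List[np.ndarray] = []
    til = np.zeros((h, w), dtype=bool)
    tissue = np.zeros((h, w), dtype=bool)
    for center in centers:
        disc = _disc_mask(h, w, center, spec.fragment_radius)
        if not disc.any():
            raise ValueError(f"zero-area fragment at center {center}")
        if spec.clustering == "csr":
            frag_til = _fill_csr(rng, disc, spec.til_density)
        else:
            frag_til = _fill_matern(
                rng, disc, spec.til_density, spec.cluster_parent_rate, spec.cluster_radius
            )
        frag_masks.append(frag_til)
        til |= frag_til
        tissue |= disc

    boxes = _place_speckles(rng, (h, w), tissue, spec.speckle_count, spec.speckle_max_area)
    for r0, c0, bh, bw in boxes:
        til[r0 : r0 + bh, c0 : c0 + bw] = True

    til_count_pre = int(til.sum())

    grid = til.astype(float)
    if spec.scale == PROBABILITY:
        a = spec.prob_alpha if spec.prob_alpha is not None else float(rng.uniform(1.0, 4.0))
        b = spec.prob_beta if spec.prob_beta is not None else float(rng.uniform(1.0, 4.0))
        grid[til] = 0.5 + 0.5 * rng.beta(a, b, size=til_count_pre)

    tmap = TILMap(grid=grid, scale=spec.scale, map_id=map_id, patient_id=patient_id, cancer_type=cancer_type)

    # Line artifacts go through tissue (that is where scanner lines matter and
    # where they would perturb ROI segmentation if left in).
    lines: List[Tuple[str, int]] = []
    half = max(2, int(spec.fragment_radius / 2))
    used_rows: List[int] = []
    used_cols: List[int] = []
    for _ in range(spec.n_artifact_lines):
        for _try in range(100):
            axis = "row" if rng.random() < 0.5 else "col"
            if axis == "row":
                lo = max(1, int(h / 2 - half))
                hi = min(h - 2, int(h / 2 + half))
                idx = int(rng.integers(lo, hi + 1))
                if all(abs(idx - u) >= 3 for u in used_rows):
                    used_rows.append(idx)
                    break
            else:
                c = centers[int(rng.integers(0, len(centers)))][1] if centers else w / 2
                lo = max(1, int(c - half))
                hi = min(w - 2, int(c + half))
                idx = int(rng.integers(lo, hi + 1))
                if all(abs(idx - u) >= 3 for u in used_cols):
                    used_cols.append(idx)
                    break
        else:  # pragma: no cover - pathological spec
            continue
        tmap = inject_line_artifact(tmap, idx, axis)
        lines.append((axis, idx))

    gt = MapGroundTruth(
        fragment_centers=[tuple(c) for c in centers],
        fragment_radius=spec.fragment_radius,
        fragment_masks=frag_masks,
        artifact_lines=lines,
        speckle_boxes=boxes,
        til_count_pre_artifact=til_count_pre,
    )
    return tmap, gt


def generate_til_map_pair(
    spec: MapSpec,
    map_id: str = "synthetic",
    patient_id: str = "",
    cancer_type: str = "synthetic",
) -> Tuple[TILMap, TILMap, MapGroundTruth]:
    """Binary and probability maps of the *same* slide (shared TIL mask).

    The binary map is the thresholded (>= 0.5) version of the probability
    map, mirroring how the two public scales relate to one another.
    """
    from dataclasses import replace as _replace

    pspec = _replace(spec, scale=PROBABILITY)
    prob_map, gt = generate_til_map(pspec, map_id, patient_id, cancer_type)
    bin_grid = (prob_map.grid >= 0.5).astype(float)
    bin_map = TILMap(
        grid=bin_grid, scale=BINARY, map_id=map_id, patient_id=patient_id, cancer_type=cancer_type
    )
    return bin_map, prob_map, gt


def inject_line_artifact(tmap: TILMap, index: int, axis: str) -> TILMap:
    """Return a new map with the full row/column set TIL-positive (value 1).

    Idempotent; the input map is not modified.
    """
    if axis not in ("row", "col"):
        raise ValueError("axis must be 'row' or 'col'")
    h, w = tmap.shape
    n = h if axis == "row" else w
    if not 0 <= index < n:
        raise IndexError(f"{axis} index {index} out of bounds for shape {tmap.shape}")
    out = tmap.copy()
    if axis == "row":
        out.grid[index, :] = 1.0
    else:
        out.grid[:, index] = 1.0
    return out


@dataclass
class CohortSpec:
    """Parameters of a synthetic survival cohort.

    Event times follow a Weibull proportional-hazards model with linear
    predictor ``beta * scaled(driver) + beta_age * (age - mean age)`` where
    ``scaled`` is min-max scaling of the driver measure over the cohort.
    ``threshold_effect`` switches the driver term from linear to a step at
    ``threshold`` on the scaled measure (a true low/high cutpoint effect).
    """

    n_patients: int = 200
    driver_measure: str = "spatial_autocorrelation"
    beta: float = 1.0
    beta_age: float = 0.02  # per year, centred
    weibull_shape: float = 1.2
    weibull_scale: float = 1500.0  # days
    censor_rate: float = 0.3
    age_mean: float = 60.0
    age_sd: float = 10.0
    threshold_effect: bool = False
    threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def _draw_times(
    rng: np.random.Generator, eta: np.ndarray, shape: float, scale: float
) -> np.ndarray:
    u = rng.uniform(size=eta.size)
    # Weibull PH: S(t) = exp(-(t/scale)^shape * exp(eta))
    return scale * (-np.log(u) / np.exp(eta)) ** (1.0 / shape)


def generate_cohort(spec: CohortSpec, measures: pd.DataFrame) -> pd.DataFrame:
    """Simulate a clinical table for the patients in ``measures``.

    Parameters
    ----------
    spec
        Cohort parameters; ``spec.driver_measure`` must be a finite column of
        ``measures``.
    measures
        Per-patient measure table indexed by (or containing) ``patient_id``.

    Returns
    -------
    DataFrame with TCGA pan-cancer clinical column names:
    ``patient_id, age, OS, OS.time, PFI, PFI.time``.
    """
    spec.validate()
    df = measures.reset_index() if measures.index.name == "patient_id" else measures.copy()
    if "patient_id" not in df.columns:
        df = df.copy()
        df["patient_id"] = [f"P{i:04d}" for i in range(len(df))]
    if spec.driver_measure not in df.columns:
        raise ValueError(f"driver measure {spec.driver_measure!r} not in measure table")
    driver = df[spec.driver_measure].to_numpy(dtype=float)
    if not np.isfinite(driver).all():
        raise ValueError("driver measure must be finite for every patient")
    n = len(df)
    if n != spec.n_patients and spec.n_patients != 0:
        # The measure table wins; spec.n_patients is a convenience for callers
        # that generate measures from the spec itself.
        pass

    rng = np.random.default_rng(spec.seed)
    age = rng.normal(spec.age_mean, spec.age_sd, size=n).clip(30, 90)
    scaled = _minmax(driver)
    if spec.threshold_effect:
        term = (scaled >= spec.threshold).astype(float)
    else:
        term = scaled
    eta = spec.beta * term + spec.beta_age * (age - spec.age_mean)

    out = pd.DataFrame({"patient_id": df["patient_id"].to_numpy(), "age": age})
    for endpoint, offset in (("OS", 1), ("PFI", 104729)):
        ep_rng = np.random.default_rng((spec.seed + offset) % (2**31))
        t = _draw_times(ep_rng, eta, spec.weibull_shape, spec.weibull_scale)
        censored = ep_rng.uniform(size=n) < spec.censor_rate
        time = np.where(censored, t * ep_rng.uniform(size=n), t)
        event = (~censored).astype(int)
        if event.sum() == 0:
            warnings.warn(
                f"{endpoint}: all patients censored (censor_rate={spec.censor_rate})",
                RuntimeWarning,
            )
        out[endpoint] = event
        out[f"{endpoint}.time"] = np.maximum(time, 0.5)
    return out
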