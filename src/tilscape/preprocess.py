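"""Three-step preprocessing of raw TIL maps.

1.  Detect and delete dark-line artifacts: a row/column whose TIL-positive
    count exceeds the mean of its adjacent lines' counts by more than 20% of
    the line length (discrete second-difference of the per-line count
    profile; border lines are compared to their single neighbour).
2.  Split the TIL-positive mask into connected regions of interest (ROIs)
    after a 3x3 binary closing, 8-connectivity.
3.  Drop background-speckle components smaller than 10% of the slide's total
    TIL-positive area; crop survivors tight to their bounding box.

Maps smaller than 10,000 patches (a 100x100 map is kept) are excluded before
anything else, since genuine whole-slide images are much larger.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Set, Tuple

import numpy as np
from skimage.measure import label as cc_label
from skimage.morphology import closing as _gray_closing

from .types import ROI, TILMap

Line = Tuple[str, int]  # ("row" | "col", index)

MIN_MAP_PIXELS = 10_000
DEFAULT_MIN_AREA_FRACTION = 0.10
LINE_EXCESS_FRACTION = 0.20


def filter_small_maps(maps: Iterable[TILMap], min_pixels: int = MIN_MAP_PIXELS) -> List[TILMap]:
    """Drop maps with fewer than ``min_pixels`` patches (boundary kept)."""
    return [m for m in maps if m.n_patches >= min_pixels]


def _axis_artifacts(counts: np.ndarray, length: int, frac: float) -> List[int]:
    n = counts.size
    if n == 1:
        return []
    flagged = []
    for i in range(n):
        if i == 0:
            neighbor = counts[1]
        elif i == n - 1:
            neighbor = counts[n - 2]
        else:
            neighbor = 0.5 * (counts[i - 1] + counts[i + 1])
        if counts[i] - neighbor > frac * length:
            flagged.append(i)
    return flagged


def detect_artifact_lines(tmap: TILMap, frac: float = LINE_EXCESS_FRACTION) -> Set[Line]:
    """Rows/columns whose TIL count spikes above their neighbours.

    A line is flagged when its TIL-positive patch count exceeds the mean of
    its two adjacent lines' counts by more than ``frac`` of the line length.
    Clean maps return the empty set.
    """
    mask = tmap.til_mask
    h, w = mask.shape
    rows = mask.sum(axis=1).astype(float)
    cols = mask.sum(axis=0).astype(float)
    out: Set[Line] = set()
    for i in _axis_artifacts(rows, w, frac):
        out.add(("row", i))
    for j in _axis_artifacts(cols, h, frac):
        out.add(("col", j))
    return out


def remove_lines(tmap: TILMap, lines: Iterable[Line]) -> TILMap:
    """Delete flagged rows/columns; the grid shrinks (no zero-fill).

    Deleting rather than zero-filling keeps a fake TIL line from leaving a
    void that would split one tissue region into two ROIs.
    """
    lines = list(lines)
    rows = sorted({i for a, i in lines if a == "row"})
    cols = sorted({j for a, j in lines if a == "col"})
    h, w = tmap.shape
    if len(rows) >= h or len(cols) >= w:
        raise ValueError("degenerate map: line removal would delete every row or column")
    grid = np.delete(tmap.grid, rows, axis=0)
    grid = np.delete(grid, cols, axis=1)
    out = tmap.copy()
    out.grid = grid
    return out


def segment_rois(
    tmap: TILMap,
    min_area_fraction: float = DEFAULT_MIN_AREA_FRACTION,
    closing_size: int = 3,
    connectivity: int = 2,
) -> List[ROI]:
    """Split the TIL-positive mask into cropped ROIs.

    Connected components are labelled on the closed mask (``closing_size`` x
    ``closing_size`` structuring element, 8-connectivity by default) so that
    stippled TIL tissue coheres, but component area and the crop are taken on
    the original TIL-positive patches of each component.  Components whose
    TIL area is below ``min_area_fraction`` of the slide's total TIL area are
    treated as background speckle and dropped.
    """
    mask = tmap.til_mask
    total = int(mask.sum())
    if total == 0:
        return []
    if closing_size > 1:
        closed = _gray_closing(mask, footprint=np.ones((closing_size, closing_size), dtype=bool))
        closed = closed | mask  # closing must never lose real TIL patches
    else:
        closed = mask
    labels = cc_label(closed, connectivity=connectivity)
    rois: List[ROI] = []
    idx = 0
    for lab in range(1, labels.max() + 1):
        comp = (labels == lab) & mask
        area = int(comp.sum())
        if area == 0 or area < min_area_fraction * total:
            continue
        rr, cc = np.nonzero(comp)
        r0, r1 = rr.min(), rr.max() + 1
        c0, c1 = cc.min(), cc.max() + 1
        grid = np.where(comp, tmap.grid, 0.0)[r0:r1, c0:c1]
        rois.append(
            ROI(
                grid=grid,
                offset=(int(r0), int(c0)),
                parent_map_id=tmap.map_id,
                roi_index=idx,
                scale=tmap.scale,
                patient_id=tmap.patient_id,
                cancer_type=tmap.cancer_type,
            )
        )
        idx += 1
    return rois


def preprocess_map(
    tmap: TILMap,
    min_area_fraction: float = DEFAULT_MIN_AREA_FRACTION,
    line_frac: float = LINE_EXCESS_FRACTION,
    closing_size: int = 3,
    connectivity: int = 2,
) -> Tuple[List[ROI], Set[Line]]:
    """Full per-map pipeline: detect/remove lines, then segment ROIs.

    Returns the ROI list and the set of removed lines.  Running the pipeline
    on its own output changes nothing (idempotence).
    """
    lines = detect_artifact_lines(tmap, frac=line_frac)
    cleaned = remove_lines(tmap, lines) if lines else tmap
    rois = segment_rois(
        cleaned,
        min_area_fraction=min_area_fraction,
        closing_size=closing_size,
        connectivity=connectivity,
    )
    return rois, lines


def preprocess_maps(
    maps: Sequence[TILMap],
    min_pixels: int = MIN_MAP_PIXELS,
    **kwargs,
) -> Tuple[List[ROI], dict]:
    """Preprocess a batch of maps; returns all ROIs plus a count report."""
    maps = list(maps)
    kept = filter_small_maps(maps, min_pixels=min_pixels)
    all_rois: List[ROI] = []
    n_lines = 0
    for m in kept:
        rois, lines = preprocess_map(m, **kwargs)
        n_lines += len(lines)
        all_rois.extend(rois)
    report = {
        "maps_in": len(maps),
        "maps_kept": len(kept),
        "maps_size_filtered": len(maps) - len(kept),
        "lines_removed": n_lines,
        "rois_out": len(all_rois),
    }
    return all_rois, report
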