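"""Core containers for patch-level TIL maps and derived objects.

A TIL map is a 2-D grid in which each cell summarises one 50x50-pixel tile of
a whole-slide image.  Two scales exist: ``binary`` (0 = no TILs on the patch,
1 = TILs present) and ``probability`` (0 for non-TIL patches, a value in
[0.5, 1] for TIL patches, the classifier's confidence).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

BINARY = "binary"
PROBABILITY = "probability"
SCALES = (BINARY, PROBABILITY)

#: Names of the 14 spatial heterogeneity measures, in canonical order.
MEASURE_NAMES = [
    "ripley_f",
    "ripley_g",
    "ripley_l",
    "spatial_autocorrelation",
    "degree_centrality",
    "closeness_centrality",
    "average_clustering",
    "ball_hall",
    "banfeld_raftery",
    "c_index",
    "det_ratio",
    "glcm_m1",
    "glcm_m2",
    "spatial_chaos",
]

#: Measures plus the TIL fraction covariate.
ALL_COLUMNS = MEASURE_NAMES + ["pct_tils"]


def _check_grid(grid: np.ndarray, scale: str) -> None:
    if grid.ndim != 2 or grid.size == 0:
        raise ValueError("grid must be a non-empty 2-D array")
    if scale not in SCALES:
        raise ValueError(f"scale must be one of {SCALES}, got {scale!r}")
    vals = np.asarray(grid)
    if scale == BINARY:
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("binary map values must be in {0, 1}")
    else:
        pos = vals[vals > 0]
        if pos.size and (pos.min() < 0.5 or pos.max() > 1.0):
            raise ValueError("probability map values must be 0 or in [0.5, 1]")


@dataclass
class TILMap:
    """One slide's patch grid plus identifiers.

    Parameters
    ----------
    grid
        2-D float array; rows increase downward, 0-based (row, col) indexing.
    scale
        ``"binary"`` or ``"probability"``.
    """

    grid: np.ndarray
    scale: str = BINARY
    map_id: str = ""
    patient_id: str = ""
    cancer_type: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        _check_grid(self.grid, self.scale)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.grid.shape

    @property
    def n_patches(self) -> int:
        return self.grid.size

    @property
    def til_mask(self) -> np.ndarray:
        """Boolean mask of TIL-positive patches (value > 0 on either scale)."""
        return self.grid > 0

    @property
    def til_count(self) -> int:
        return int(self.til_mask.sum())

    def copy(self) -> "TILMap":
        return replace(self, grid=self.grid.copy())


@dataclass
class ROI:
    """A cropped connected TIL-bearing region extracted from a TILMap.

    ``offset`` is the (row, col) of the ROI's top-left corner in the parent
    map.  The crop is tight: the first and last row and column of ``grid``
    each contain at least one TIL-positive patch.
    """

    grid: np.ndarray
    offset: Tuple[int, int]
    parent_map_id: str
    roi_index: int
    scale: str = BINARY
    patient_id: str = ""
    cancer_type: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        _check_grid(self.grid, self.scale)

    @property
    def roi_id(self) -> str:
        return f"{self.parent_map_id}:roi{self.roi_index}"

    @property
    def shape(self) -> Tuple[int, int]:
        return self.grid.shape

    @property
    def til_mask(self) -> np.ndarray:
        return self.grid > 0

    @property
    def til_area(self) -> int:
        return int(self.til_mask.sum())


@dataclass
class PointPattern:
    """Patch centres of an ROI as a marked point pattern.

    Every in-ROI patch becomes a point; ``values`` carries the patch value on
    the map's scale and ``is_til`` flags TIL-positive points.  ``window`` is
    the (height, width) of the ROI grid; coordinates are (row, col) with unit
    spacing between adjacent patch centres.
    """

    coords: np.ndarray  # (n, 2) float
    values: np.ndarray  # (n,) float
    is_til: np.ndarray  # (n,) bool
    window: Tuple[int, int]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.is_til = np.asarray(self.is_til, dtype=bool)
        n = len(self.coords)
        if len(self.values) != n or len(self.is_til) != n:
            raise ValueError("coords, values and is_til must have equal length")

    @property
    def n_points(self) -> int:
        return len(self.coords)

    @property
    def til_coords(self) -> np.ndarray:
        return self.coords[self.is_til]


def point_pattern_from_roi(roi: ROI) -> PointPattern:
    """Unroll an ROI grid into a marked point pattern (one point per patch)."""
    h, w = roi.grid.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    values = roi.grid.ravel().astype(float)
    if roi.scale == PROBABILITY:
        is_til = values >= 0.5
    else:
        is_til = values > 0
    return PointPattern(coords=coords, values=values, is_til=is_til, window=(h, w))
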