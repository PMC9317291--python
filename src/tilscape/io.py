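"""Reading and writing TIL maps, ROIs and result tables.

Maps travel as 8-bit grayscale PNG (0 = background, 128-255 = scaled TIL
probability, 255 = binary TIL) or as plain CSV matrices; synthetic ground
truth rides in a JSON sidecar.  Clinical tables use the TCGA pan-cancer
column names (``patient_id, age, OS, OS.time, PFI, PFI.time``).  Measure
tables are TSV with NA spelled ``NA`` and infinity ``Inf``.

Adapters for the public TIL-map repository layout and the TCGA pan-cancer
clinical file are provided for users who download those resources; nothing
here performs a download.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image

from .synthetic import MapGroundTruth
from .types import BINARY, ROI, TILMap

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# Maps
# ---------------------------------------------------------------------------

def write_map_png(tmap: TILMap, path: PathLike) -> None:
    """Encode a map as 8-bit grayscale: pixel = round(value * 255)."""
    arr = np.round(tmap.grid * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(str(path))


def read_map_png(
    path: PathLike,
    scale: str = BINARY,
    map_id: str = "",
    patient_id: str = "",
    cancer_type: str = "",
) -> TILMap:
    """Decode an 8-bit grayscale map; inverse of :func:`write_map_png`.

    Binary scale: any nonzero pixel is a TIL patch.  Probability scale:
    pixel/255 with sub-threshold noise (< 0.25) squashed to 0 and TIL values
    clipped into [0.5, 1].
    """
    arr = np.asarray(Image.open(str(path)).convert("L"), dtype=float) / 255.0
    if scale == BINARY:
        grid = (arr > 0).astype(float)
    else:
        grid = arr.copy()
        grid[grid < 0.25] = 0.0
        pos = grid > 0
        grid[pos] = np.clip(grid[pos], 0.5, 1.0)
    mid = map_id or Path(path).stem
    return TILMap(grid=grid, scale=scale, map_id=mid, patient_id=patient_id, cancer_type=cancer_type)


def write_map_csv(tmap: TILMap, path: PathLike) -> None:
    np.savetxt(str(path), tmap.grid, fmt="%.6g", delimiter=",")


def read_map_csv(
    path: PathLike,
    scale: str = BINARY,
    map_id: str = "",
    patient_id: str = "",
    cancer_type: str = "",
) -> TILMap:
    grid = np.loadtxt(str(path), delimiter=",", ndmin=2)
    mid = map_id or Path(path).stem
    return TILMap(grid=grid, scale=scale, map_id=mid, patient_id=patient_id, cancer_type=cancer_type)


def write_ground_truth(gt: MapGroundTruth, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(gt.to_json_dict(), fh, indent=1)


def read_ground_truth(path: PathLike) -> Dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# ROIs
# ---------------------------------------------------------------------------

def write_rois(rois: Sequence[ROI], out_dir: PathLike) -> pd.DataFrame:
    """Write each ROI grid as CSV plus a TSV manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: List[Dict] = []
    for roi in rois:
        fname = f"{roi.parent_map_id}_roi{roi.roi_index}.csv".replace(":", "_")
        np.savetxt(out_dir / fname, roi.grid, fmt="%.6g", delimiter=",")
        rows.append(
            {
                "map_id": roi.parent_map_id,
                "roi_index": roi.roi_index,
                "file": fname,
                "offset_row": roi.offset[0],
                "offset_col": roi.offset[1],
                "height": roi.shape[0],
                "width": roi.shape[1],
                "til_area": roi.til_area,
                "scale": roi.scale,
                "patient_id": roi.patient_id,
                "cancer_type": roi.cancer_type,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "rois.tsv", sep="\t", index=False)
    return manifest


def read_rois(out_dir: PathLike) -> List[ROI]:
    out_dir = Path(out_dir)
    manifest = pd.read_csv(out_dir / "rois.tsv", sep="\t")
    rois: List[ROI] = []
    for _, row in manifest.iterrows():
        grid = np.loadtxt(out_dir / row["file"], delimiter=",", ndmin=2)
        rois.append(
            ROI(
                grid=grid,
                offset=(int(row["offset_row"]), int(row["offset_col"])),
                parent_map_id=str(row["map_id"]),
                roi_index=int(row["roi_index"]),
                scale=str(row["scale"]),
                patient_id=str(row["patient_id"]),
                cancer_type=str(row["cancer_type"]),
            )
        )
    return rois


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: PathLike) -> None:
    """TSV with NA spelled ``NA`` and infinities ``Inf``/``-Inf``."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].astype(object)
            out.loc[df[col] == np.inf, col] = "Inf"
            out.loc[df[col] == -np.inf, col] = "-Inf"
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)


def write_clinical(clinical: pd.DataFrame, path: PathLike) -> None:
    cols = ["patient_id", "age", "OS", "OS.time", "PFI", "PFI.time"]
    clinical[cols].to_csv(path, sep="\t", index=False)


def read_clinical(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "age", "OS", "OS.time", "PFI", "PFI.time"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Optional adapters for the public resources
# ---------------------------------------------------------------------------

def load_public_til_map(path: PathLike, scale: str, cancer_type: str = "") -> TILMap:
    """Load one map from the public TIL-map repository layout.

    Files are named by TCGA slide barcode (PNG or CSV); the patient id is the
    first 12 characters of the barcode and the cancer type defaults to the
    parent directory name.
    """
    path = Path(path)
    stem = path.stem
    patient = stem[:12]
    cancer = cancer_type or path.parent.name
    if path.suffix.lower() == ".png":
        return read_map_png(path, scale=scale, map_id=stem, patient_id=patient, cancer_type=cancer)
    return read_map_csv(path, scale=scale, map_id=stem, patient_id=patient, cancer_type=cancer)


def load_tcga_clinical(path: PathLike) -> pd.DataFrame:
    """Adapt the TCGA pan-cancer clinical file to the package schema.

    Accepts either the package's own column names or the pan-cancer resource
    names (``bcr_patient_barcode``, ``age_at_initial_pathologic_diagnosis``).
    """
    df = pd.read_csv(path, sep="\t")
    renames = {
        "bcr_patient_barcode": "patient_id",
        "age_at_initial_pathologic_diagnosis": "age",
    }
    df = df.rename(columns={k: v for k, v in renames.items() if k in df.columns})
    required = {"patient_id", "age", "OS", "OS.time", "PFI", "PFI.time"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical file missing columns: {sorted(missing)}")
    out = df[sorted(required, key=["patient_id", "age", "OS", "OS.time", "PFI", "PFI.time"].index)]
    return out.dropna(subset=["OS.time", "PFI.time"], how="all")
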