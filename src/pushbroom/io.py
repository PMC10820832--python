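"""File formats: frames (PNG/TIFF), ENVI BIL cubes, CSV tables, JSON configs.

An ENVI cube stores a scan as ``lines`` = frames along the motion
direction, ``samples`` = spatial positions along the slit, and ``bands`` =
spectral columns, band-interleaved-by-line (``interleave = bil``) as raw
unsigned bytes (``data type = 1``) next to a plain-text ``.hdr`` header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
import tifffile

from .calibrate import CalibrationFit, PeakEntry, PeakTable
from .classify import LabeledDataset, MLPModel
from .reflectance import FeatureVector, feature_names
from .simulate import SmileModel

__all__ = [
    "read_frame", "write_frame",
    "read_envi_cube", "write_envi_cube",
    "read_peak_table", "write_peak_table",
    "read_calibration", "write_calibration",
    "read_model", "write_model",
    "write_feature_vectors", "read_feature_dataset",
]

COORDINATE_CONVENTION = "columns 0-based, pixel centers at integer coordinates"


# -- single frames ---------------------------------------------------------

def read_frame(path: str | Path) -> np.ndarray:
    """Read one 8-bit grayscale detector frame from TIFF or PNG."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("L"))
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a single-channel 2-D image")
    return arr


def write_frame(path: str | Path, frame: np.ndarray) -> None:
    path = Path(path)
    frame = np.asarray(frame)
    if frame.dtype != np.uint8:
        frame = np.clip(np.round(frame), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, frame)
    else:
        Image.fromarray(frame, mode="L").save(path)


# -- ENVI BIL cubes --------------------------------------------------------

def write_envi_cube(hdr_path: str | Path, cube: np.ndarray) -> None:
    """Write a (frames, rows, cols) uint8 scan as an ENVI BIL cube.

    ``hdr_path`` names the text header; the raw data file drops the
    ``.hdr`` suffix.
    """
    hdr_path = Path(hdr_path)
    cube = np.asarray(cube)
    if cube.ndim != 3:
        raise ValueError("cube must be (frames, rows, cols)")
    if cube.dtype != np.uint8:
        cube = np.clip(np.round(cube), 0, 255).astype(np.uint8)
    frames, rows, cols = cube.shape
    header = "\n".join([
        "ENVI",
        "description = {push-broom scan; lines=frames, samples=slit rows, "
        "bands=spectral columns; " + COORDINATE_CONVENTION + "}",
        f"samples = {rows}",
        f"lines = {frames}",
        f"bands = {cols}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 1",
        "interleave = bil",
        "byte order = 0",
        "",
    ])
    hdr_path.write_text(header)
    # BIL: per line, band-major blocks of samples -> (frames, cols, rows)
    cube.transpose(0, 2, 1).tofile(hdr_path.with_suffix(""))


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            fields[key.strip().lower()] = val.strip().strip("{}").strip()
    return fields


def read_envi_cube(hdr_path: str | Path) -> np.ndarray:
    """Read an 8-bit BIL ENVI cube back as (frames, rows, cols)."""
    hdr_path = Path(hdr_path)
    fields = _parse_envi_header(hdr_path.read_text())
    if fields.get("interleave", "").lower() != "bil":
        raise ValueError("only BIL interleave is supported")
    if fields.get("data type") != "1":
        raise ValueError("only 8-bit (data type 1) cubes are supported")
    rows = int(fields["samples"])
    frames = int(fields["lines"])
    cols = int(fields["bands"])
    raw = np.fromfile(hdr_path.with_suffix(""), dtype=np.uint8)
    if raw.size != frames * rows * cols:
        raise ValueError("ENVI data size does not match the header")
    return raw.reshape(frames, cols, rows).transpose(0, 2, 1)


# -- peak tables -----------------------------------------------------------

def write_peak_table(path: str | Path, table: PeakTable) -> None:
    pd.DataFrame(
        [{"wavelength_nm": e.wavelength_nm, "pixel": e.pixel, "source": e.source}
         for e in table.entries]
    ).to_csv(path, index=False)


def read_peak_table(path: str | Path) -> PeakTable:
    df = pd.read_csv(path)
    entries = [
        PeakEntry(
            None if pd.isna(r["wavelength_nm"]) else float(r["wavelength_nm"]),
            float(r["pixel"]),
            "" if ("source" not in r or pd.isna(r["source"])) else str(r["source"]),
        )
        for _, r in df.iterrows()
    ]
    return PeakTable(entries)


# -- calibration -----------------------------------------------------------

def write_calibration(path: str | Path, fit: CalibrationFit) -> None:
    Path(path).write_text(json.dumps({
        "A_prime": fit.A_prime,
        "B_prime": fit.B_prime,
        "C_disp": fit.C_disp,
        "residual_rms_px": fit.residual_rms_px,
        "smile": {"a1": fit.smile.a1, "a2": fit.smile.a2},
        "lambda_min_nm": fit.lambda_min_nm,
        "lambda_max_nm": fit.lambda_max_nm,
        "coordinate_convention": COORDINATE_CONVENTION,
    }, indent=2))


def read_calibration(path: str | Path) -> CalibrationFit:
    d = json.loads(Path(path).read_text())
    return CalibrationFit(
        A_prime=float(d["A_prime"]),
        B_prime=float(d["B_prime"]),
        C_disp=float(d["C_disp"]),
        residual_rms_px=float(d.get("residual_rms_px", 0.0)),
        smile=SmileModel(**d.get("smile", {})),
        lambda_min_nm=float(d.get("lambda_min_nm", 300.0)),
        lambda_max_nm=float(d.get("lambda_max_nm", 1000.0)),
    )


# -- models ----------------------------------------------------------------

def write_model(path: str | Path, model: MLPModel) -> None:
    Path(path).write_text(model.to_json())


def read_model(path: str | Path) -> MLPModel:
    return MLPModel.from_json(Path(path).read_text())


# -- feature datasets ------------------------------------------------------

def write_feature_vectors(
    path: str | Path,
    vectors: list[FeatureVector],
    labels=None,
    frame_ids=None,
) -> None:
    """Feature vectors as CSV: 50 ``f<lo>_<hi>`` columns plus
    ``row, frame, valid, label``."""
    if not vectors:
        raise ValueError("no feature vectors to write")
    names = feature_names(vectors[0].bin_edges_nm)
    rows = []
    for i, v in enumerate(vectors):
        rec = dict(zip(names, v.features))
        rec["row"] = v.position
        rec["frame"] = 0 if frame_ids is None else frame_ids[i]
        rec["valid"] = v.valid
        rec["label"] = "" if labels is None else labels[i]
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_feature_dataset(path: str | Path, valid_only: bool = True
                         ) -> LabeledDataset:
    """Load a feature CSV into a labelled dataset (string labels mapped
    A -> 0, B -> 1)."""
    df = pd.read_csv(path)
    if valid_only and "valid" in df:
        df = df[df["valid"]]
    feats = [c for c in df.columns if c.startswith("f") and "_" in c[1:]]
    label_map = {"class_A": 0, "class_B": 1, "A": 0, "B": 1,
                 "lettuce": 0, "arugula": 1, "0": 0, "1": 1, 0: 0, 1: 1}
    y = np.array([label_map[v] for v in df["label"]])
    return LabeledDataset(df[feats].to_numpy(float), y, provenance=str(path))
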