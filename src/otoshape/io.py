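"""File formats: sample manifests, contour CSVs, binary masks, matrices, reports.

All tabular files are UTF-8 comma-separated with a header row and '.' decimal
separator; matrices are row-major with the sample id in the first column.
Matrix files written here carry a leading '#' provenance comment (tool version
and configuration hash) that pandas skips on read.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .contour import Contour

__all__ = [
    "read_manifest",
    "write_manifest",
    "read_contour_csv",
    "write_contour_csv",
    "read_mask",
    "write_mask",
    "load_sample",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_report_json",
    "config_hash",
]

MANIFEST_REQUIRED = ("sample_id", "population", "path")


def read_manifest(path, check_paths: bool = True) -> pd.DataFrame:
    """Load and validate a sample manifest.

    Requires columns sample_id, population, path; optional TL_mm, OL_mm,
    side.  Sample ids must be unique, OL_mm positive where present, and every
    referenced file must exist (relative paths resolve against the manifest's
    directory).
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate sample_id values: {sorted(dup.unique().tolist())}")
    if "OL_mm" in df.columns:
        bad = df.loc[df["OL_mm"].notna() & (df["OL_mm"] <= 0), "sample_id"]
        if not bad.empty:
            raise ValueError(f"non-positive OL_mm for samples: {bad.tolist()}")
    df["path"] = [str((path.parent / p)) if not Path(p).is_absolute() else p for p in df["path"]]
    if check_paths:
        gone = [p for p in df["path"] if not Path(p).exists()]
        if gone:
            raise FileNotFoundError(f"manifest references missing files: {gone[:5]}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    pd.DataFrame(df).to_csv(path, index=False)


def _parse_float(token: str, path, lineno: int, column: str) -> float:
    try:
        return float(token)
    except ValueError:
        hint = ""
        if "," in token:
            hint = " (decimal commas are not accepted; use '.' as the decimal separator)"
        raise ValueError(f"{path}, line {lineno}: cannot parse {column}={token!r}{hint}") from None


def read_contour_csv(path, side: str | None = None, units: str = "mm") -> Contour:
    """Read an x,y-per-row contour file (header row required)."""
    path = Path(path)
    xs, ys = [], []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise ValueError(f"{path}: expected a header row with x,y columns")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}, line {lineno}: expected two columns, got {len(row)}")
            xs.append(_parse_float(row[0], path, lineno, "x"))
            ys.append(_parse_float(row[1], path, lineno, "y"))
    if len(xs) < 3:
        raise ValueError(f"{path}: a contour needs at least 3 vertices")
    return Contour(np.column_stack([xs, ys]), side=side, units=units)


def write_contour_csv(contour: Contour, path) -> None:
    pd.DataFrame(contour.vertices, columns=["x", "y"]).to_csv(path, index=False)


def read_mask(path) -> np.ndarray:
    """Read a PNG/TIFF mask; foreground = any pixel above half the maximum."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    if img.max() == 0:
        return np.zeros_like(img, dtype=bool)
    return img > img.max() / 2.0


def write_mask(mask: np.ndarray, path) -> None:
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def load_sample(path, side: str | None = None):
    """Load one sample as a contour (CSV) or a mask (PNG/TIFF)."""
    from .contour import extract_contour

    p = Path(path)
    if p.suffix.lower() == ".csv":
        return read_contour_csv(p, side=side)
    if p.suffix.lower() in (".png", ".tif", ".tiff"):
        c = extract_contour(read_mask(p))
        c.side = side
        return c
    raise ValueError(f"unsupported sample format: {p.suffix!r}")


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_matrix_csv(path, ids, matrix, columns, version: str = "", cfg_hash: str = "") -> None:
    """Matrix with sample id as the first column, behind a provenance comment."""
    M = np.asarray(matrix)
    df = pd.DataFrame(M, columns=list(columns))
    df.insert(0, "sample_id", list(ids))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# otoshape {version} config={cfg_hash}\n")
        df.to_csv(fh, index=False)


def read_matrix_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_report_json(report: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
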