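"""Readers and writers for the pipeline's tabular and JSON artifacts.

Everything tabular is header-rowed UTF-8 CSV; missing values are empty
fields.  Nested artifacts (ground truth, diagnostics, run manifests) are
JSON.  Readers validate schemas up front and report the offending column
or line rather than failing downstream.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ExperimentDesign
from .errors import SchemaError

DESIGN_COLUMNS = [
    "plate", "well", "array", "row", "col",
    "ecm", "ecm_conc", "ligand", "ligand_conc", "is_control",
]
CELL_REQUIRED = DESIGN_COLUMNS[:5] + ["cell_id", "dapi_intensity", "edu_intensity"]
SPOT_REQUIRED = DESIGN_COLUMNS[:5] + ["ecm", "ligand", "cell_count", "edu_prop"]


def _read_csv(path, required: list[str], kind: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{kind} file not found", path=str(path))
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"could not parse {kind} CSV: {exc}", path=str(path))
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{kind} CSV missing column(s) {missing}", path=str(path), line=1
        )
    return frame


def read_design(path) -> ExperimentDesign:
    frame = _read_csv(path, DESIGN_COLUMNS, "design")
    return ExperimentDesign.from_frame(frame)


def write_design(design: ExperimentDesign, path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_cells(path) -> pd.DataFrame:
    frame = _read_csv(path, CELL_REQUIRED, "cell")
    for col in ("dapi_intensity", "edu_intensity"):
        bad = ~(frame[col].to_numpy(float) > 0)
        if bad.any():
            line = int(np.argmax(bad)) + 2  # header + 1-based
            raise SchemaError(
                f"non-positive {col} value", path=str(path), line=line
            )
    return frame


def write_cells(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def read_spots(path) -> pd.DataFrame:
    return _read_csv(path, SPOT_REQUIRED, "spot")


def write_spots(spots: pd.DataFrame, path) -> None:
    spots.to_csv(path, index=False)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict("list")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
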