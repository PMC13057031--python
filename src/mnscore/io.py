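"""Reading and writing fields, label images, cell tables and reports.

Fields travel as plain TIFF with a JSON ImageDescription carrying channel
semantics and the pixel size, so ``read_field(write_field(x))`` round-trips
exactly.  Per-cell tables are CSV with a fixed, documented column schema;
reports are canonical (sorted-key) JSON so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .classify import CellRecord
from .errors import FieldFormatError
from .segment import CellMask
from .simulate import SmearField

#: column schema of the per-cell record CSV (one row per classified cell)
CELL_TABLE_COLUMNS = [
    "field_id", "cell_id", "label", "mn_count", "area_um2",
    "equivalent_diameter_um", "centroid_row", "centroid_col",
    "aspect_ratio", "solidity", "dna_area_ratio", "blue_dominance",
    "morphology",
]

#: column schema of the simulator ground-truth CSV
TRUTH_TABLE_COLUMNS = [
    "field_id", "cell_id", "class", "mn_count", "x_px", "y_px",
    "diameter_um", "aspect_ratio", "morphology", "is_ret",
]


def write_field(field: SmearField, path) -> None:
    """Write a field as float32 TIFF (H, W, C) with JSON metadata."""
    meta = {
        "channels": list(field.channels),
        "pixel_size_um": field.pixel_size_um,
        "provenance": field.provenance,
        "field_id": field.field_id,
    }
    tifffile.imwrite(str(path), field.raster,
                     description=json.dumps(meta, sort_keys=True),
                     photometric="minisblack")


def read_field(path) -> SmearField:
    """Read a TIFF field written by :func:`write_field` (or a bare 2-D/RGB
    TIFF, in which case channel semantics are inferred)."""
    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tf:
            arr = tf.asarray()
            desc = tf.pages[0].description
    except Exception as exc:  # malformed container
        raise FieldFormatError(f"{path}: unreadable TIFF ({exc})") from exc
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise FieldFormatError(f"{path}: expected a 2-D (multi-channel) image, "
                               f"got shape {arr.shape}")
    channels = meta.get("channels")
    if channels is None:
        channels = {1: ["cell_body"], 2: ["cell_body", "dna"],
                    3: ["R", "G", "B"]}.get(arr.shape[2])
        if channels is None:
            raise FieldFormatError(
                f"{path}: cannot infer semantics for {arr.shape[2]} channels")
    if len(channels) != arr.shape[2]:
        raise FieldFormatError(
            f"{path}: metadata lists {len(channels)} channels for a "
            f"{arr.shape[2]}-channel raster")
    return SmearField(
        raster=np.asarray(arr),
        channels=tuple(channels),
        pixel_size_um=float(meta.get("pixel_size_um", 0.25)),
        provenance=meta.get("provenance", "read-from-file"),
        field_id=meta.get("field_id", path.stem),
    )


def write_label_image(masks: list[CellMask], shape, path) -> None:
    """Write masks as an int32 label TIFF (0 = background, ids = cell_id+1)."""
    lab = np.zeros(shape, np.int32)
    for m in masks:
        lab[m.pixels[:, 0], m.pixels[:, 1]] = m.cell_id + 1
    tifffile.imwrite(str(path), lab, photometric="minisblack")


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "field_id": r.field_id,
            "cell_id": r.cell_id,
            "label": r.label.label,
            "mn_count": r.mn_count,
            "area_um2": r.area_um2,
            "equivalent_diameter_um": r.equivalent_diameter_um,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
            "aspect_ratio": r.aspect_ratio,
            "solidity": r.solidity,
            "dna_area_ratio": r.dna_area_ratio,
            "blue_dominance": r.blue_dominance,
            "morphology": r.morphology if r.morphology else "",
        })
    return pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)


def write_cell_table(records: list[CellRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_truth_table(truth_records: pd.DataFrame, path) -> None:
    truth_records[TRUTH_TABLE_COLUMNS].to_csv(path, index=False)


def config_hash(config) -> str:
    """Stable sha256 over the canonical JSON form of a (nested) dataclass."""
    if dataclasses.is_dataclass(config):
        payload = dataclasses.asdict(config)
    else:
        payload = config
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_report(report_dict: dict, path) -> None:
    """Canonical-JSON report writer (sorted keys, fixed separators)."""
    Path(path).write_text(
        json.dumps(report_dict, sort_keys=True, indent=2, allow_nan=True)
        + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def load_yaml_config(path) -> dict:
    """Load a YAML config file; must contain a mapping."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise FieldFormatError(f"{path}: config must be a YAML mapping")
    return data


def dump_yaml_config(data: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
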