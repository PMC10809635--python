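"""CSV/TSV/JSON input-output and run manifests.

Input schemas (headered CSV, UTF-8, "." decimal):

* ``plates.csv``  — founder_number, replicate_id, bust_hr, timepoint_hr,
  count1, count2, count3, volume_ml, contaminated
* ``lawn_qc.csv`` — plate_id, area_cm2, od600
* ``lengths.csv`` — timepoint_hr, worm_id, length_um

Schema violations are collected per row (with row numbers); a whole file is
rejected only when its header is invalid.  Wide simulation outputs go to
TSV.  Every CLI run writes a JSON manifest recording command, config
digest, seed, timestamps and paths.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .assay_analysis import (
    AssayDataset,
    LAWN_COLUMNS,
    LENGTH_COLUMNS,
    PLATE_COLUMNS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "read_assay_csvs",
    "write_assay_csvs",
    "write_reports",
    "RunManifest",
]


class SchemaError(ValueError):
    """A CSV header does not match the expected schema."""


def _check_header(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


def _validate_plates(df: pd.DataFrame) -> list[str]:
    errors = []
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based plus header line
        if not float(row["founder_number"]).is_integer() or row["founder_number"] <= 0:
            errors.append(f"row {rownum}: founder_number must be a positive integer")
        for c in ("count1", "count2", "count3"):
            if row[c] < 0:
                errors.append(f"row {rownum}: {c} is negative")
        if not row["volume_ml"] > 0:
            errors.append(f"row {rownum}: volume_ml must be positive")
        if not pd.isna(row["bust_hr"]) and row["bust_hr"] < 0:
            errors.append(f"row {rownum}: bust_hr is negative")
        if row["timepoint_hr"] < 0:
            errors.append(f"row {rownum}: timepoint_hr is negative")
    return errors


def read_assay_csvs(
    plates_path: Union[str, Path],
    lawn_path: Optional[Union[str, Path]] = None,
    lengths_path: Optional[Union[str, Path]] = None,
    *,
    strict: bool = True,
) -> tuple[AssayDataset, list[str]]:
    """Read the assay tables; returns the dataset and per-row violations.

    With ``strict`` (default) any row-level violation raises; otherwise
    offending rows are dropped and reported in the returned list.  A bad
    header always raises :class:`SchemaError`.
    """
    plates = pd.read_csv(plates_path)
    _check_header(plates, PLATE_COLUMNS, Path(plates_path).name)
    plates["contaminated"] = (
        plates["contaminated"]
        .map(lambda v: str(v).strip().lower() in ("1", "true", "yes"))
        .astype(bool)
    )
    errors = _validate_plates(plates)
    if errors and strict:
        raise ValueError("invalid plate rows:\n  " + "\n  ".join(errors))
    if errors:
        bad = {int(e.split()[1].rstrip(":")) - 2 for e in errors}
        plates = plates.drop(index=[i for i in bad if i in plates.index])

    lawn = pd.DataFrame(columns=LAWN_COLUMNS)
    if lawn_path is not None:
        lawn = pd.read_csv(lawn_path)
        _check_header(lawn, LAWN_COLUMNS, Path(lawn_path).name)
    lengths = pd.DataFrame(columns=LENGTH_COLUMNS)
    if lengths_path is not None:
        lengths = pd.read_csv(lengths_path)
        _check_header(lengths, LENGTH_COLUMNS, Path(lengths_path).name)

    ds = AssayDataset(plates, lawn, lengths)
    n_exc = ds.n_excluded()
    if n_exc:
        logger.info("excluding %d contaminated plate(s) from all statistics", n_exc)
    return ds, errors


def write_assay_csvs(ds: AssayDataset, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write plates/lawn_qc/lengths CSVs; the write→read round trip is lossless."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("plates", ds.plates),
        ("lawn_qc", ds.lawn_qc),
        ("lengths", ds.lengths),
    ):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_reports(results: dict, out_dir: Union[str, Path]) -> list[Path]:
    """Write analysis outputs: DataFrames as TSV, everything else as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    json_payload = {}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            p = out / f"{name}.tsv"
            obj.to_csv(p, sep="\t", index=False)
            written.append(p)
        else:
            json_payload[name] = obj
    if json_payload:
        p = out / "report.json"
        p.write_text(json.dumps(json_payload, indent=2, default=_jsonable) + "\n")
        written.append(p)
    return written


@dataclass
class RunManifest:
    """Provenance record written once per CLI run."""

    command: str
    seed: Optional[int]
    config_digest: str
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def write(self, out_dir: Union[str, Path]) -> Path:
        payload = {
            "command": self.command,
            "seed": self.seed,
            "config_digest": self.config_digest,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "timestamp_utc": datetime.now(timezone.utc).isoformat(),
            "package_version": __version__,
        }
        p = Path(out_dir) / "manifest.json"
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(json.dumps(payload, indent=2) + "\n")
        return p


def config_digest(cfg) -> str:
    """Stable SHA-256 digest of a life-history config."""
    blob = json.dumps(
        {
            "stages": [
                cfg.stages.egg_hr,
                cfg.stages.l1_hr,
                cfg.stages.l2_hr,
                cfg.stages.l3_hr,
                cfg.stages.l4_hr,
                cfg.stages.adult_tracking_hr,
            ],
            "fecundity": [round(float(x), 12) for x in cfg.fecundity.eggs_per_hr],
            "consumption": list(cfg.consumption.as_tuple()),
            "patch": [cfg.patch.patch_units, cfg.patch.horizon_hr, list(cfg.patch.founder_numbers)],
        },
        sort_keys=True,
    ).encode()
    return hashlib.sha256(blob).hexdigest()
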