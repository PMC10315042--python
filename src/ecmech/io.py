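"""CSV readers/writers, run configuration, and the seeded demo pipeline.

All inputs and outputs are plain CSV with required headers.  Output files
begin with comment lines embedding the package version, the seed, and a
hash of the run configuration, so any result can be traced to the exact
run that produced it.  Readers validate rather than coerce: malformed rows
are reported with their line numbers and the file is rejected.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .afm import ForceCurve, ForceMap
from .fibers import FiberField
from .histology import CollagenAssayRecord, IHCRecord, ihc_classify, pct_category_from_raw

__all__ = [
    "DataValidationError",
    "config_hash",
    "provenance_header",
    "write_table",
    "read_angles",
    "write_angles",
    "read_force_curve",
    "write_force_curve",
    "read_force_map",
    "write_force_map",
    "read_ihc",
    "write_ihc",
    "read_collagen",
    "write_collagen",
]


class DataValidationError(ValueError):
    """Raised when an input file fails validation (exit code 2 in the CLI)."""


def config_hash(config) -> str:
    """Short stable hash of a run configuration (dataclass or mapping)."""
    payload = asdict(config) if is_dataclass(config) else dict(config)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(seed=None, config=None) -> str:
    """Comment lines recording version, seed and config hash."""
    parts = [f"# ecmech version={__version__}"]
    if seed is not None:
        parts.append(f"# seed={seed}")
    if config is not None:
        parts.append(f"# config_hash={config_hash(config)}")
    return "\n".join(parts) + "\n"


def write_table(df: pd.DataFrame, path, *, seed=None, config=None) -> None:
    """Write a DataFrame as CSV with a provenance comment header."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write(provenance_header(seed=seed, config=config))
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def _read_csv(path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except Exception as exc:  # malformed CSV structure
        raise DataValidationError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataValidationError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    bad_lines = []
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        bad_lines += [(int(i) + 2, col, df.loc[i, col]) for i in bad]
        if df[col].isna().any():
            bad_lines += [(int(i) + 2, col, "<empty>") for i in df.index[df[col].isna()]]
        df[col] = coerced
    if bad_lines:
        detail = "; ".join(f"line {ln}: {col}={val!r}" for ln, col, val in bad_lines[:10])
        raise DataValidationError(f"{path}: non-numeric value(s): {detail}")
    return df


# ---------------------------------------------------------------- fiber angles

ANGLE_COLUMNS = ["case_id", "group", "field_id", "angle_deg"]


def read_angles(path) -> list[FiberField]:
    """Read a per-fiber angle table into FiberField objects.

    Required columns: case_id, group, field_id, angle_deg.  Angles may be
    any real number; they are reduced mod 180 on load.
    """
    df = _read_csv(path, ANGLE_COLUMNS, numeric=["angle_deg"])
    if df.empty:
        raise DataValidationError(f"{path}: no data rows")
    fields = []
    for (case_id, group, field_id), sub in df.groupby(
        ["case_id", "group", "field_id"], sort=False
    ):
        fields.append(
            FiberField(
                case_id=str(case_id),
                group=str(group),
                field_id=str(field_id),
                angles_deg=sub["angle_deg"].to_numpy(),
            )
        )
    return fields


def write_angles(fields: list[FiberField], path, *, seed=None, config=None) -> None:
    rows = [
        {"case_id": f.case_id, "group": f.group, "field_id": f.field_id, "angle_deg": a}
        for f in fields
        for a in f.angles_deg
    ]
    write_table(pd.DataFrame(rows, columns=ANGLE_COLUMNS), path, seed=seed, config=config)


# ---------------------------------------------------------------- force curves

CURVE_COLUMNS_M = ["piezo_z_m", "deflection_m"]
CURVE_COLUMNS_NM = ["piezo_z_nm", "deflection_nm"]


def read_force_curve(path, *, k: float, R: float, nu: float) -> ForceCurve:
    """Read one raw force curve; SI metres or a _nm header variant."""
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"curve file not found: {path}")
    head = pd.read_csv(path, comment="#", nrows=0)
    if all(c in head.columns for c in CURVE_COLUMNS_M):
        cols, scale = CURVE_COLUMNS_M, 1.0
    elif all(c in head.columns for c in CURVE_COLUMNS_NM):
        cols, scale = CURVE_COLUMNS_NM, 1e-9
    else:
        raise DataValidationError(
            f"{path}: expected columns {CURVE_COLUMNS_M} or {CURVE_COLUMNS_NM}, "
            f"found {list(head.columns)}"
        )
    df = _read_csv(path, cols, numeric=cols)
    try:
        return ForceCurve(
            piezo_z=df[cols[0]].to_numpy() * scale,
            deflection=df[cols[1]].to_numpy() * scale,
            k=k,
            R=R,
            nu=nu,
        )
    except ValueError as exc:
        raise DataValidationError(f"{path}: {exc}") from exc


def write_force_curve(curve: ForceCurve, path, *, unit: str = "m", seed=None, config=None) -> None:
    if unit == "m":
        cols, scale = CURVE_COLUMNS_M, 1.0
    elif unit == "nm":
        cols, scale = CURVE_COLUMNS_NM, 1e9
    else:
        raise ValueError(f"unit must be 'm' or 'nm', got {unit!r}")
    df = pd.DataFrame({cols[0]: curve.piezo_z * scale, cols[1]: curve.deflection * scale})
    write_table(df, path, seed=seed, config=config)


MANIFEST_COLUMNS = ["path", "row", "col"]


def read_force_map(manifest_path, *, k: float, R: float, nu: float) -> ForceMap:
    """Assemble a ForceMap from a manifest CSV (columns path, row, col).

    Curve paths are resolved relative to the manifest's directory.  The
    grid must be complete and free of duplicates; violations are reported
    naming the offending cell.
    """
    manifest_path = Path(manifest_path)
    df = _read_csv(manifest_path, MANIFEST_COLUMNS, numeric=["row", "col"])
    if df.empty:
        raise DataValidationError(f"{manifest_path}: empty manifest")
    rows = df["row"].astype(int)
    cols = df["col"].astype(int)
    if (rows < 0).any() or (cols < 0).any():
        raise DataValidationError(f"{manifest_path}: negative grid indices")
    nrow, ncol = int(rows.max()) + 1, int(cols.max()) + 1
    seen: dict[tuple[int, int], str] = {}
    for _, rec in df.iterrows():
        cell = (int(rec["row"]), int(rec["col"]))
        if cell in seen:
            raise DataValidationError(f"{manifest_path}: duplicate grid cell {cell}")
        seen[cell] = str(rec["path"])
    missing = [(r, c) for r in range(nrow) for c in range(ncol) if (r, c) not in seen]
    if missing:
        raise DataValidationError(f"{manifest_path}: missing grid cell(s) {missing[:5]}")
    grid = [
        [
            read_force_curve(manifest_path.parent / seen[(r, c)], k=k, R=R, nu=nu)
            for c in range(ncol)
        ]
        for r in range(nrow)
    ]
    return ForceMap(curves=grid, label=manifest_path.stem)


def write_force_map(
    fmap: ForceMap, directory, *, unit: str = "m", seed=None, config=None
) -> Path:
    """Write per-curve CSVs plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for r, row in enumerate(fmap.curves):
        for c, curve in enumerate(row):
            name = f"curve_r{r:03d}_c{c:03d}.csv"
            write_force_curve(curve, directory / name, unit=unit, seed=seed, config=config)
            rows.append({"path": name, "row": r, "col": c})
    manifest = directory / "manifest.csv"
    write_table(pd.DataFrame(rows, columns=MANIFEST_COLUMNS), manifest, seed=seed, config=config)
    return manifest


# ------------------------------------------------------------------------- IHC

def read_ihc(path) -> list[IHCRecord]:
    """Read an IHC score table into classified records.

    Required columns: case_id, group, intensity, and either pct_category
    (0-4) or pct_raw (a percentage, binned with the default scheme).
    """
    path = Path(path)
    head = pd.read_csv(path, comment="#", nrows=0) if path.exists() else None
    if head is None:
        raise DataValidationError(f"input file not found: {path}")
    has_cat = "pct_category" in head.columns
    pct_col = "pct_category" if has_cat else "pct_raw"
    df = _read_csv(path, ["case_id", "group", pct_col, "intensity"], numeric=[pct_col, "intensity"])
    records = []
    for i, rec in df.iterrows():
        try:
            cat = (
                int(rec["pct_category"])
                if has_cat
                else pct_category_from_raw(float(rec[pct_col]))
            )
            records.append(
                ihc_classify(
                    cat,
                    int(rec["intensity"]),
                    case_id=str(rec["case_id"]),
                    group=str(rec["group"]),
                )
            )
        except ValueError as exc:
            raise DataValidationError(f"{path}: line {int(i) + 2}: {exc}") from exc
    return records


def write_ihc(records: list[IHCRecord], path, *, seed=None, config=None) -> None:
    df = pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "group": r.group,
                "pct_category": r.pct_category,
                "intensity": r.intensity,
                "score": r.score,
                "class": r.label,
            }
            for r in records
        ]
    )
    write_table(df, path, seed=seed, config=config)


# -------------------------------------------------------------------- collagen

COLLAGEN_COLUMNS = ["sample_id", "group", "total", "soluble"]


def read_collagen(path) -> list[CollagenAssayRecord]:
    """Read a collagen assay table (sample_id, group, total, soluble)."""
    df = _read_csv(path, COLLAGEN_COLUMNS, numeric=["total", "soluble"])
    records = []
    for i, rec in df.iterrows():
        try:
            records.append(
                CollagenAssayRecord(
                    sample_id=str(rec["sample_id"]),
                    group=str(rec["group"]),
                    total=float(rec["total"]),
                    soluble=float(rec["soluble"]),
                )
            )
        except ValueError as exc:
            raise DataValidationError(f"{path}: line {int(i) + 2}: {exc}") from exc
    return records


def write_collagen(records: list[CollagenAssayRecord], path, *, seed=None, config=None) -> None:
    df = pd.DataFrame(
        [
            {"sample_id": r.sample_id, "group": r.group, "total": r.total, "soluble": r.soluble}
            for r in records
        ],
        columns=COLLAGEN_COLUMNS,
    )
    write_table(df, path, seed=seed, config=config)
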