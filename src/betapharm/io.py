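"""Tabular I/O, dataset containers, and run configuration.

CSV schemas (long/tidy, one measurement per row, mandatory header):

* dose-response: ``ligand,receptor,pathway,dose,dose_unit,signal,replicate``
* kinetics: ``trace_id,trace_type,competitor,competitor_conc,conc_unit,
  time,time_unit,signal``

Concentrations are converted to molar and times to seconds on read;
result writers emit JSON (full float precision, lossless round-trip)
plus a human-readable table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from betapharm.errors import (
    SchemaError,
    SpecError,
    ValidationError,
)
from betapharm.kinetics import KineticTrace, RadioligandKinetics
from betapharm.units import to_molar, to_seconds

logger = logging.getLogger("betapharm")

DOSE_RESPONSE_COLUMNS = ("ligand", "receptor", "pathway", "dose", "signal", "replicate")
KINETIC_COLUMNS = ("trace_id", "trace_type", "competitor_conc", "time", "signal")


@dataclass
class DoseResponseDataset:
    """Tidy dose-response measurements.

    ``records`` has columns ligand, receptor, pathway, dose (molar),
    signal (raw assay units) and replicate.  Zero doses are allowed and
    denote vehicle (basal) wells; doses used for curve fitting must be
    strictly positive.
    """

    records: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in DOSE_RESPONSE_COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(f"dose-response table missing column(s): {missing}")
        if (self.records["dose"] < 0).any():
            raise ValidationError("doses must be non-negative (0 = vehicle well)")
        key = ["ligand", "receptor", "pathway", "dose", "replicate"]
        dup = self.records.duplicated(subset=key)
        if dup.any():
            first = self.records[dup].iloc[0]
            raise ValidationError(
                "duplicate measurement key "
                f"{tuple(first[k] for k in key)}"
            )

    def groups(self):
        """Iterate (ligand, receptor, pathway) -> sub-frame for positive doses."""
        pos = self.records[self.records["dose"] > 0]
        return pos.groupby(["ligand", "receptor", "pathway"], sort=True)

    @property
    def n_records(self) -> int:
        return len(self.records)


@dataclass
class KineticDataset:
    """A set of radioligand time-course traces plus the (fixed) labeled-ligand kinetics."""

    traces: list[KineticTrace]
    radioligand_params: RadioligandKinetics | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValidationError("kinetic dataset contains no traces")
        short = [t.trace_id for t in self.traces if t.times.size < 5]
        if short:
            raise ValidationError(
                f"every trace needs >= 5 time points; too short: {short}"
            )

    def association_traces(self) -> list[KineticTrace]:
        return [t for t in self.traces if t.trace_type == "association"]

    def dissociation_traces(self) -> list[KineticTrace]:
        return [t for t in self.traces if t.trace_type == "dissociation"]


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} CSV missing required column(s): {missing}")


def _numeric_column(df: pd.DataFrame, col: str, path: str) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any() or vals.isna().any():
        # +2: 1 for header, 1 for 0-based index
        line = int(df.index[vals.isna()][0]) + 2
        raise ValidationError(
            f"non-numeric value in column {col!r} of {path} at line {line}"
        )
    return vals.to_numpy(dtype=float)


def read_dose_response_csv(
    path: str | Path,
    default_dose_unit: str = "M",
    metadata: dict[str, Any] | None = None,
) -> DoseResponseDataset:
    """Read a long-format dose-response CSV, converting doses to molar.

    A ``dose_unit`` column overrides *default_dose_unit* per row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    _require_columns(df, DOSE_RESPONSE_COLUMNS, "dose-response")
    dose = _numeric_column(df, "dose", str(path))
    signal = _numeric_column(df, "signal", str(path))
    if "dose_unit" in df.columns:
        units = df["dose_unit"].fillna(default_dose_unit)
    else:
        units = pd.Series([default_dose_unit] * len(df))
    dose_m = np.array([to_molar(d, u) for d, u in zip(dose, units)])
    out = pd.DataFrame(
        {
            "ligand": df["ligand"].astype(str),
            "receptor": df["receptor"].astype(str),
            "pathway": df["pathway"].astype(str),
            "dose": dose_m,
            "signal": signal,
            "replicate": df["replicate"].astype(str),
        }
    )
    logger.info("read %d dose-response records from %s", len(out), path)
    return DoseResponseDataset(records=out, metadata=metadata or {"source": str(path)})


def read_kinetic_csv(
    path: str | Path,
    radioligand_params: RadioligandKinetics | None = None,
    default_conc_unit: str = "M",
    default_time_unit: str = "s",
) -> KineticDataset:
    """Read a kinetics time-course CSV into a KineticDataset.

    Rows are grouped by ``trace_id``; times are sorted ascending within
    a trace and converted to seconds, competitor concentrations to molar.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if df.empty:
        raise ValidationError(f"kinetics CSV {path} contains no data rows")
    _require_columns(df, KINETIC_COLUMNS, "kinetics")
    time = _numeric_column(df, "time", str(path))
    signal = _numeric_column(df, "signal", str(path))
    conc = _numeric_column(df, "competitor_conc", str(path))
    cunit = df["conc_unit"].fillna(default_conc_unit) if "conc_unit" in df.columns \
        else pd.Series([default_conc_unit] * len(df))
    tunit = df["time_unit"].fillna(default_time_unit) if "time_unit" in df.columns \
        else pd.Series([default_time_unit] * len(df))
    work = pd.DataFrame(
        {
            "trace_id": df["trace_id"].astype(str),
            "trace_type": df["trace_type"].astype(str).str.strip().str.lower(),
            "competitor": df.get("competitor", pd.Series([""] * len(df))).astype(str),
            "conc": [to_molar(c, u) for c, u in zip(conc, cunit)],
            "time": [to_seconds(t, u) for t, u in zip(time, tunit)],
            "signal": signal,
        }
    )
    bad_types = set(work["trace_type"]) - {"association", "dissociation"}
    if bad_types:
        raise ValidationError(
            f"trace_type must be association|dissociation, got {sorted(bad_types)}"
        )
    traces: list[KineticTrace] = []
    for tid, grp in work.groupby("trace_id", sort=True):
        grp = grp.sort_values("time")
        traces.append(
            KineticTrace(
                trace_id=str(tid),
                trace_type=str(grp["trace_type"].iloc[0]),
                competitor_conc=float(grp["conc"].iloc[0]),
                times=grp["time"].to_numpy(dtype=float),
                signal=grp["signal"].to_numpy(dtype=float),
                competitor=str(grp["competitor"].iloc[0]),
            )
        )
    logger.info("read %d kinetic traces from %s", len(traces), path)
    return KineticDataset(traces=traces, radioligand_params=radioligand_params,
                          metadata={"source": str(path)})


# ---------------------------------------------------------------------------
# result serialization


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return _to_jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _flatten(prefix: str, obj: Any, rows: list[tuple[str, Any]]) -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _flatten(f"{prefix}.{k}" if prefix else str(k), v, rows)
    elif isinstance(obj, list):
        for i, v in enumerate(obj):
            _flatten(f"{prefix}[{i}]", v, rows)
    else:
        rows.append((prefix, obj))


def write_report(results: Any, path: str | Path) -> None:
    """Write *results* as machine-readable JSON plus a human-readable table.

    The JSON at *path* round-trips every numeric field at full double
    precision (python ``repr`` floats).  A ``.txt`` sibling holds a flat
    ``key<TAB>value`` table for eyeballing.
    """
    path = Path(path)
    payload = _to_jsonable(results)
    path.write_text(json.dumps(payload, indent=2) + "\n")
    rows: list[tuple[str, Any]] = []
    _flatten("", payload, rows)
    width = max((len(k) for k, _ in rows), default=0)
    table = "\n".join(f"{k.ljust(width)}\t{v}" for k, v in rows)
    path.with_suffix(path.suffix + ".txt").write_text(table + "\n")
    logger.info("wrote report to %s", path)


def read_report(path: str | Path) -> Any:
    """Read back a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run.

    Units must resolve to the internal standard (molar, seconds); the
    seed is an explicit integer so every stochastic step is reproducible.
    """

    input_path: str | None = None
    stages: list[str] = field(default_factory=list)
    max_iterations: int = 2000
    multi_start: int = 7
    seed: int = 0
    noise_sigma: float = 0.0
    concentration_unit: str = "M"
    time_unit: str = "s"
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # validate units and seed eagerly so misconfiguration fails on load
        to_molar(1.0, self.concentration_unit)
        to_seconds(1.0, self.time_unit)
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise SpecError(f"seed must be an explicit integer, got {self.seed!r}")
        if self.multi_start < 1:
            raise SpecError("multi_start must be >= 1")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a JSON or YAML file (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise SpecError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SpecError(f"unknown config key(s): {sorted(unknown)}; known: {sorted(known)}")
    return RunConfig(**raw)
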