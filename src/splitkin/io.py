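"""Readers and writers for assay tables, sequencing reads and fit reports.

The canonical tabular format is a tidy long CSV: one measurement per row with
a series identifier, a condition (analyte/peptide concentration, stored
internally in molar), an independent variable (``time``: seconds for time
courses and sensorgrams, degrees Celsius for melt curves, nanometres for
emission scans and line profiles) and the measured value. Input dialects
declare their units explicitly and default to nanomolar / seconds, the units
plate-reader assays in this domain are usually reported in.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AssayTable",
    "Dialect",
    "SchemaError",
    "ValidationError",
    "read_assay_table",
    "write_assay_table",
    "read_reads",
    "write_reads",
    "write_report",
    "read_report",
]

ASSAY_KINDS = (
    "fp_timecourse",
    "saturation",
    "sensorgram",
    "emission_scan",
    "melt_curve",
    "line_profile",
)

#: Multiplicative factors to molar / seconds.
_CONC_UNITS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}
_TIME_UNITS = {"s": 1.0, "min": 60.0, "h": 3600.0}


class SchemaError(ValueError):
    """A required column is missing or a declared unit is unknown."""


class ValidationError(ValueError):
    """Table contents violate an assay-table invariant."""


@dataclass
class Dialect:
    """Column naming and units of a delimited assay file."""

    series_col: str = "series"
    condition_col: str = "conc_nM"
    time_col: str = "time_s"
    value_col: str = "FP"
    condition_unit: str = "nM"
    time_unit: str = "s"
    sep: str = ","


@dataclass
class AssayTable:
    """Tidy long-format container for one assay's measurements.

    ``data`` columns: ``series`` (str), ``condition`` (molar), ``time``
    (seconds / °C / nm depending on ``kind``), ``value`` plus any extra
    columns (``phase``, ``replicate`` ...). ``meta`` carries free-form
    context such as reagent concentrations.
    """

    data: pd.DataFrame
    kind: str
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ASSAY_KINDS:
            raise SchemaError(f"unknown assay kind {self.kind!r}; expected one of {ASSAY_KINDS}")
        validate_table(self.data, kind=self.kind)

    def series_ids(self) -> list[str]:
        return list(self.data["series"].unique())

    def series(self, series_id: str) -> pd.DataFrame:
        sub = self.data[self.data["series"] == series_id]
        if sub.empty:
            raise KeyError(f"series {series_id!r} not in table")
        return sub.reset_index(drop=True)


def validate_table(df: pd.DataFrame, kind: str = "fp_timecourse") -> None:
    """Enforce the assay-table invariants on a canonical dataframe."""
    for col in ("series", "condition", "time", "value"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    if (df["condition"] < 0).any():
        bad = df.loc[df["condition"] < 0, "series"].iloc[0]
        raise ValidationError(f"negative condition value in series {bad!r}")
    group_cols = ["series"]
    if "replicate" in df.columns:
        group_cols.append("replicate")
    if "phase" in df.columns:
        group_cols.append("phase")
    for key, sub in df.groupby(group_cols, sort=False):
        t = sub["time"].to_numpy(float)
        if len(t) < 3:
            raise ValidationError(f"series {key!r} has fewer than 3 points")
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"non-monotonic or duplicated time in series {key!r}")


def read_assay_table(path: str | Path, kind: str, dialect: Dialect | None = None) -> AssayTable:
    """Read a tidy delimited file into a validated :class:`AssayTable`.

    Condition and time columns are converted to the internal molar/second
    units according to the dialect.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=dialect.sep)
    for col in (dialect.series_col, dialect.condition_col, dialect.time_col, dialect.value_col):
        if col not in raw.columns:
            raise SchemaError(f"missing column {col!r} in {path.name}")
    try:
        cfac = _CONC_UNITS[dialect.condition_unit]
    except KeyError:
        raise SchemaError(f"unknown concentration unit {dialect.condition_unit!r}") from None
    try:
        tfac = _TIME_UNITS[dialect.time_unit]
    except KeyError:
        raise SchemaError(f"unknown time unit {dialect.time_unit!r}") from None
    df = pd.DataFrame(
        {
            "series": raw[dialect.series_col].astype(str),
            "condition": raw[dialect.condition_col].astype(float) * cfac,
            "time": raw[dialect.time_col].astype(float) * tfac,
            "value": raw[dialect.value_col].astype(float),
        }
    )
    for extra in ("phase", "replicate"):
        if extra in raw.columns:
            df[extra] = raw[extra].to_numpy()
    return AssayTable(data=df, kind=kind)


def write_assay_table(table: AssayTable, path: str | Path, dialect: Dialect | None = None) -> None:
    """Write an :class:`AssayTable` back to a tidy delimited file.

    Inverse of :func:`read_assay_table` under the same dialect.
    """
    dialect = dialect or Dialect()
    out = pd.DataFrame(
        {
            dialect.series_col: table.data["series"],
            dialect.condition_col: table.data["condition"] / _CONC_UNITS[dialect.condition_unit],
            dialect.time_col: table.data["time"] / _TIME_UNITS[dialect.time_unit],
            dialect.value_col: table.data["value"],
        }
    )
    for extra in ("phase", "replicate"):
        if extra in table.data.columns:
            out[extra] = table.data[extra].to_numpy()
    out.to_csv(path, sep=dialect.sep, index=False, float_format="%.12g")


def read_reads(path: str | Path) -> list[tuple[str, str, str | None]]:
    """Read FASTA or FASTQ records, auto-detected from the first character.

    Returns ``(read_id, uppercase sequence, quality-or-None)`` tuples in file
    order.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        fmt = "fasta"
    elif first == "@":
        fmt = "fastq"
    else:
        raise ValueError(f"{path.name}: cannot detect FASTA/FASTQ (first char {first!r})")
    out: list[tuple[str, str, str | None]] = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            qual = None
            if fmt == "fastq":
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append((rec.id, str(rec.seq).upper(), qual))
    except ValueError as exc:  # malformed record
        raise ValueError(f"{path.name}: malformed {fmt} record near record {len(out) + 1}: {exc}") from exc
    return out


def write_reads(reads: list[tuple[str, str, str | None]], path: str | Path) -> None:
    """Write reads as FASTQ when qualities are present, else FASTA."""
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            if qual is None:
                fh.write(f">{rid}\n{seq}\n")
            else:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    return obj


def write_report(results: Any, path: str | Path, format: str = "json") -> None:
    """Serialize a fit object (any dataclass) with full numeric precision."""
    payload = _to_jsonable(results)
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
    elif format == "csv":
        flat = {k: v for k, v in payload.items() if np.isscalar(v) or v is None}
        pd.DataFrame([flat]).to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)
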