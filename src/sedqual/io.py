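"""Delimited-text readers and writers.

All tables are UTF-8 text with a mandatory header row; the delimiter is
comma by default and tab is accepted (auto-detected when not given). Lines
starting with ``#`` are treated as comments. Headers are matched
case-insensitively, and a ``column_map`` may rename nonstandard headers.

The bundled default tables are loadable by name::

    read_guidelines("default-guidelines")
    read_constants("default-constants")

Writers emit floats with ``repr`` precision so that a write/read round trip
reproduces every numeric field exactly.
"""

from __future__ import annotations

import csv
import io as _io
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import (
    ConcentrationRecord,
    ConstantTables,
    FractionRecord,
    GuidelineEntry,
    GuidelineTable,
    SchemaError,
    ValidationError,
)

_FRACTION_COLUMNS = ("site", "metal", "period", "f1", "f2", "f3", "f4", "f5")
_CONCENTRATION_COLUMNS = ("site", "metal", "period", "c")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("sedqual").joinpath("data", name)))


_BUNDLED = {
    "default-guidelines": "default_guidelines.csv",
    "default-constants": "default_constants.csv",
}


def _read_table(
    path,
    delimiter: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a delimited table into a DataFrame with normalised headers."""
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise SchemaError(f"{path}: empty file (no header row)")
    if delimiter is None:
        header = lines[0]
        delimiter = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(_io.StringIO("\n".join(lines)), sep=delimiter, dtype=str)
    rename = {c: c.strip().lower() for c in df.columns}
    if column_map:
        lowered = {str(k).strip().lower(): str(v).strip().lower() for k, v in column_map.items()}
        rename = {c: lowered.get(v, v) for c, v in rename.items()}
    return df.rename(columns=rename)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def _build_records(df, path, factory):
    """Instantiate one record per row, collecting failures with row numbers."""
    records, errors = [], []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(factory(row))
        except (ValidationError, ValueError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError(f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors))
    return records


def read_fraction_table(
    path,
    delimiter: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> list[FractionRecord]:
    """Read a five-fraction speciation table (site, metal, period, F1..F5)."""
    df = _read_table(path, delimiter, column_map)
    _require_columns(df, _FRACTION_COLUMNS, path)

    def factory(row):
        return FractionRecord(
            site=str(row.site),
            metal=str(row.metal),
            period=str(row.period),
            f1=float(row.f1),
            f2=float(row.f2),
            f3=float(row.f3),
            f4=float(row.f4),
            f5=float(row.f5),
        )

    return _build_records(df, path, factory)


def write_fraction_table(records: Iterable[FractionRecord], path, delimiter: str = ",") -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(_FRACTION_COLUMNS)
        for r in records:
            writer.writerow([r.site, r.metal, r.period, *(repr(f) for f in r.fractions)])


def read_concentration_table(
    path,
    delimiter: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> list[ConcentrationRecord]:
    """Read a totals table (site, metal, period, c[, sd])."""
    df = _read_table(path, delimiter, column_map)
    _require_columns(df, _CONCENTRATION_COLUMNS, path)
    has_sd = "sd" in df.columns

    def factory(row):
        sd = getattr(row, "sd", None) if has_sd else None
        sd = None if sd in (None, "") or pd.isna(sd) else float(sd)
        return ConcentrationRecord(
            site=str(row.site), metal=str(row.metal), period=str(row.period),
            c=float(row.c), sd=sd,
        )

    return _build_records(df, path, factory)


def write_concentration_table(
    records: Iterable[ConcentrationRecord], path, delimiter: str = ","
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["site", "metal", "period", "c", "sd"])
        for r in records:
            writer.writerow(
                [r.site, r.metal, r.period, repr(r.c), "" if r.sd is None else repr(r.sd)]
            )


def _resolve(path_or_name) -> Path:
    if isinstance(path_or_name, str) and path_or_name in _BUNDLED:
        return _data_path(_BUNDLED[path_or_name])
    return Path(path_or_name)


def read_guidelines(path_or_name, delimiter: str | None = None) -> GuidelineTable:
    """Read a guideline table (metal, tel, pel[, sel]); duplicates rejected.

    ``"default-guidelines"`` loads the bundled compilation (provenance
    documented in the file header).
    """
    path = _resolve(path_or_name)
    df = _read_table(path, delimiter)
    _require_columns(df, ("metal", "tel", "pel"), path)
    entries: dict[str, GuidelineEntry] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        metal = str(row.metal).strip()
        if metal in entries:
            raise ValidationError(f"{path}: duplicate metal {metal!r} at row {i}")
        sel = getattr(row, "sel", None)
        sel = None if sel in (None, "") or pd.isna(sel) else float(sel)
        try:
            entries[metal] = GuidelineEntry(tel=float(row.tel), pel=float(row.pel), sel=sel)
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i} ({metal}): {exc}") from exc
    return GuidelineTable(entries=entries)


def read_constants(path_or_name, delimiter: str | None = None) -> ConstantTables:
    """Read backgrounds and toxic-response factors (metal, background, tr)."""
    path = _resolve(path_or_name)
    df = _read_table(path, delimiter)
    _require_columns(df, ("metal", "background", "tr"), path)
    background: dict[str, float] = {}
    tr: dict[str, float] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        metal = str(row.metal).strip()
        if metal in background:
            raise ValidationError(f"{path}: duplicate metal {metal!r} at row {i}")
        background[metal] = float(row.background)
        tr[metal] = float(row.tr)
    return ConstantTables(background=background, toxic_response=tr)


def default_guidelines() -> GuidelineTable:
    """The bundled TEL/PEL/SEL compilation for Cd, Cr, Cu, Ni, Pb."""
    return read_guidelines("default-guidelines")


def default_constants() -> ConstantTables:
    """The bundled average-shale backgrounds and Hakanson Tr factors."""
    return read_constants("default-constants")
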