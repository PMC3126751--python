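"""Readers and writers for the tabular isotopologue format.

Tables are CSV or TSV with a ``time`` column and contiguous mass
columns ``m0..mN`` (0-based: m0 is the monoisotopic species), plus an
optional ``replicate`` column.  Leading ``#`` lines carry provenance
metadata as ``key=value`` pairs and are written on every output.
"""

from __future__ import annotations

import csv
import hashlib
import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class TableValidationError(ValueError):
    """Carries every validation offense found in an input table."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass
class IsotopologueTable:
    """A validated isotopologue intensity table plus metadata."""

    data: pd.DataFrame
    metadata: dict[str, str] = field(default_factory=dict)

    @property
    def mass_columns(self) -> list[str]:
        return [c for c in self.data.columns if _is_mass_column(c)]

    @property
    def n_masses(self) -> int:
        return len(self.mass_columns)

    @property
    def times(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    def intensities(self) -> np.ndarray:
        """Row-major intensity matrix, columns ordered m0..mN."""
        cols = sorted(self.mass_columns, key=lambda c: int(c[1:]))
        return self.data[cols].to_numpy(dtype=float)


def _is_mass_column(name: str) -> bool:
    return name.startswith("m") and name[1:].isdigit()


def _detect_dialect(path: Path, forced: str | None) -> str:
    if forced is not None:
        if forced not in ("csv", "tsv"):
            raise ValueError(f"unknown dialect {forced!r}")
        return forced
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".tsv", ".tab"):
        return "tsv"
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                return "tsv" if "\t" in line else "csv"
    return "tsv"


def read_table(path, dialect: str | None = None) -> IsotopologueTable:
    """Read and validate an isotopologue table.

    All offenses (missing m0, gaps in mass columns, non-numeric cells
    with their row and column, negative intensities, negative or
    unparseable times, duplicate time/replicate keys) are collected and
    raised together in a single :class:`TableValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    d = _detect_dialect(path, dialect)
    sep = "," if d == "csv" else "\t"

    metadata: dict[str, str] = {}
    body_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if "=" in stripped:
                    k, _, v = stripped.partition("=")
                    metadata[k.strip()] = v.strip()
            else:
                body_lines.append(line)
    if not body_lines:
        raise TableValidationError(["file has no table body"])
    raw = pd.read_csv(_io.StringIO("".join(body_lines)), sep=sep, dtype=str)
    raw.columns = [str(c).strip() for c in raw.columns]

    errors: list[str] = []
    if "time" not in raw.columns:
        errors.append("missing required column 'time'")
    mass_cols = [c for c in raw.columns if _is_mass_column(c)]
    if "m0" not in mass_cols:
        errors.append("missing required column 'm0'")
    else:
        indices = sorted(int(c[1:]) for c in mass_cols)
        expected = list(range(len(indices)))
        if indices != expected:
            errors.append(f"mass columns are not contiguous from m0: {sorted(mass_cols)}")
    if errors:
        raise TableValidationError(errors)

    numeric_cols = ["time"] + mass_cols
    parsed = {}
    for col in numeric_cols:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        for row in raw.index[bad]:
            errors.append(f"non-numeric value {raw.at[row, col]!r} at row {row}, column {col}")
        if converted.isna().any() and not bad.any():
            for row in raw.index[converted.isna()]:
                errors.append(f"missing value at row {row}, column {col}")
        parsed[col] = converted

    df = raw.copy()
    for col, series in parsed.items():
        df[col] = series
    # value-level checks run even when some cells failed to parse, so one
    # read reports every offense (NaN comparisons are False, hence safe)
    for row in df.index[df["time"] < 0]:
        errors.append(f"negative time at row {row}")
    for col in mass_cols:
        for row in df.index[df[col] < 0]:
            errors.append(f"negative intensity at row {row}, column {col}")
    key_cols = ["time"] + (["replicate"] if "replicate" in df.columns else [])
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        keys = df.loc[dup, key_cols].drop_duplicates().to_dict("records")
        errors.append(f"duplicate timepoint/replicate keys: {keys}")
    if errors:
        raise TableValidationError(errors)

    ordered = ["time"] + (["replicate"] if "replicate" in df.columns else [])
    ordered += sorted(mass_cols, key=lambda c: int(c[1:]))
    extra = [c for c in df.columns if c not in ordered]
    return IsotopologueTable(data=df[ordered + extra], metadata=metadata)


def write_table(
    table: IsotopologueTable | pd.DataFrame,
    path,
    dialect: str = "tsv",
    metadata: dict | None = None,
) -> None:
    """Write a table with provenance header lines.

    Column order is ``time, [replicate], m0..mN`` then extras; floats
    are written at full precision.
    """
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "csv" else "\t"
    if isinstance(table, IsotopologueTable):
        df = table.data
        meta = dict(table.metadata)
    else:
        df = table
        meta = {}
    if metadata:
        meta.update({str(k): str(v) for k, v in metadata.items()})

    mass_cols = sorted((c for c in df.columns if _is_mass_column(c)), key=lambda c: int(c[1:]))
    ordered = [c for c in ("time", "replicate") if c in df.columns] + mass_cols
    ordered += [c for c in df.columns if c not in ordered]

    with open(path, "w", newline="") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df[ordered].to_csv(fh, sep=sep, index=False, float_format="%.17g")


def file_sha256(path) -> str:
    """Hex digest of a file, for provenance headers."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
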