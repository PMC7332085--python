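"""Society data model and tabular / point-geometry input-output.

A society table holds one row per ethnolinguistic population with its
population size ``N``, geographic range ``A`` (km^2), jurisdictional
hierarchy level ``omega`` in 1..5, the nested grouping labels language /
family / continent, and a point location in decimal degrees (WGS84).
Population density ``D = N/A`` is always derived, never stored, so the
identity ``ln D = ln N - ln A`` holds exactly per record.
"""

from __future__ import annotations

import json
import math
import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd

__all__ = [
    "COLUMNS",
    "COLUMN_ALIASES",
    "SocietyRecord",
    "SocietyTable",
    "ValidationReport",
    "read_society_table",
    "write_report",
]

#: Canonical column order of a society table.
COLUMNS: tuple[str, ...] = (
    "society_id",
    "language",
    "family",
    "continent",
    "longitude",
    "latitude",
    "pop_size",
    "range_area_km2",
    "level",
)

#: Accepted header synonyms (lower-cased) -> canonical column name.
COLUMN_ALIASES: dict[str, str] = {
    "n": "pop_size",
    "population": "pop_size",
    "population_size": "pop_size",
    "a": "range_area_km2",
    "area": "range_area_km2",
    "range_area": "range_area_km2",
    "omega": "level",
    "w": "level",
    "lon": "longitude",
    "lng": "longitude",
    "lat": "latitude",
    "id": "society_id",
    "lang": "language",
    "language_family": "family",
}


@dataclass(frozen=True)
class SocietyRecord:
    """One ethnolinguistic population."""

    society_id: str
    language: str
    family: str
    continent: str
    longitude: float
    latitude: float
    pop_size: float
    range_area_km2: float
    level: int

    @property
    def density(self) -> float:
        """Population density D = N / A in km^-2 (derived)."""
        return self.pop_size / self.range_area_km2


@dataclass
class ValidationReport:
    """Bookkeeping of row-level validation: kept + rejected = read."""

    n_rows_read: int = 0
    n_rows_kept: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def check(self) -> None:
        if self.n_rows_kept + len(self.rejected) != self.n_rows_read:
            raise AssertionError("validation conservation violated")


class SocietyTable:
    """Ordered collection of society records backed by a DataFrame.

    Invariants enforced on construction: unique ``society_id``, every
    language maps to one family and every family to one continent (strict
    nesting C(F(L))), positive N and A, level in 1..5.
    """

    def __init__(self, df: pd.DataFrame, provenance: str = "") -> None:
        df = df.loc[:, list(COLUMNS)].reset_index(drop=True)
        df = df.astype(
            {
                "society_id": str,
                "language": str,
                "family": str,
                "continent": str,
                "longitude": float,
                "latitude": float,
                "pop_size": float,
                "range_area_km2": float,
                "level": int,
            }
        )
        _check_invariants(df)
        self.df = df
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SocietyTable):
            return NotImplemented
        return self.df.equals(other.df)

    def records(self) -> list[SocietyRecord]:
        return [
            SocietyRecord(**row._asdict())
            for row in self.df.itertuples(index=False)
        ]

    def metric_values(self, metric: str) -> pd.Series:
        """Values of metric 'N' (pop size), 'A' (range) or 'D' (density)."""
        if metric == "N":
            return self.df["pop_size"]
        if metric == "A":
            return self.df["range_area_km2"]
        if metric == "D":
            return self.df["pop_size"] / self.df["range_area_km2"]
        raise ValueError(f"unknown metric {metric!r}; expected N, A or D")

    @property
    def levels(self) -> list[int]:
        return sorted(self.df["level"].unique())


def _check_invariants(df: pd.DataFrame) -> None:
    if df["society_id"].duplicated().any():
        dup = df.loc[df["society_id"].duplicated(), "society_id"].iloc[0]
        raise ValueError(f"duplicate society_id {dup!r}")
    if (df["pop_size"] <= 0).any() or (df["range_area_km2"] <= 0).any():
        raise ValueError("pop_size and range_area_km2 must be positive")
    if (~df["level"].isin([1, 2, 3, 4, 5])).any():
        raise ValueError("level must be in 1..5")
    for child, parent in (("language", "family"), ("family", "continent")):
        n_parents = df.groupby(child)[parent].nunique()
        bad = n_parents[n_parents > 1]
        if len(bad):
            raise ValueError(
                f"nesting violated: {child} {bad.index[0]!r} maps to "
                f"{bad.iloc[0]} distinct values of {parent}"
            )


def _validate_row(row: Mapping[str, Any]) -> str | None:
    """Return a rejection reason, or None if the row is admissible."""
    for col in COLUMNS:
        if col not in row or row[col] is None or (
            isinstance(row[col], float) and math.isnan(row[col])
        ):
            return f"missing value for {col}"
    if not isinstance(row["pop_size"], numbers.Real) or row["pop_size"] <= 0:
        return "non-positive N"
    if (
        not isinstance(row["range_area_km2"], numbers.Real)
        or row["range_area_km2"] <= 0
    ):
        return "non-positive A"
    try:
        level = int(row["level"])
    except (TypeError, ValueError):
        return "non-integer level"
    if level != float(row["level"]) or level not in (1, 2, 3, 4, 5):
        return "level outside 1..5"
    if not -180 <= float(row["longitude"]) <= 180:
        return "longitude outside [-180, 180]"
    if not -90 <= float(row["latitude"]) <= 90:
        return "latitude outside [-90, 90]"
    return None


def _canonicalize_headers(df: pd.DataFrame) -> pd.DataFrame:
    mapping = {}
    for col in df.columns:
        key = str(col).strip().lower()
        mapping[col] = COLUMN_ALIASES.get(key, key)
    return df.rename(columns=mapping)


def _rows_from_geojson(path: Path) -> list[dict[str, Any]]:
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("type") != "FeatureCollection":
        raise ValueError("GeoJSON input must be a FeatureCollection")
    rows = []
    for feat in obj.get("features", []):
        props = dict(feat.get("properties") or {})
        geom = feat.get("geometry") or {}
        if geom.get("type") == "Point":
            lon, lat = geom["coordinates"][:2]
            props["longitude"], props["latitude"] = lon, lat
        rows.append(props)
    return rows


def read_society_table(
    path: str | Path,
    format: str | None = None,
    column_map: Mapping[str, str] | None = None,
    sheet: int | str = 0,
) -> tuple[SocietyTable, ValidationReport]:
    """Read a society table from CSV/TSV, GeoJSON points, or XLSX.

    Rows failing validation (non-positive N or A, level outside 1..5,
    coordinates out of range, missing fields) are rejected individually and
    listed in the report with a reason; a missing file or a missing required
    column is fatal. ``column_map`` maps source headers to canonical names,
    for files whose layout is not documented (e.g. spreadsheet supplements);
    it is applied before the built-in alias map.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {
            ".csv": "csv",
            ".tsv": "tsv",
            ".geojson": "geojson",
            ".json": "geojson",
            ".xlsx": "xlsx",
        }.get(path.suffix.lower(), "csv")

    if format == "csv":
        raw = pd.read_csv(path)
    elif format == "tsv":
        raw = pd.read_csv(path, sep="\t")
    elif format == "xlsx":
        raw = pd.read_excel(path, sheet_name=sheet)
    elif format == "geojson":
        raw = pd.DataFrame(_rows_from_geojson(path))
    else:
        raise ValueError(f"unknown format {format!r}")

    if column_map:
        raw = raw.rename(columns=dict(column_map))
    raw = _canonicalize_headers(raw)

    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")

    report = ValidationReport(n_rows_read=len(raw))
    kept: list[dict[str, Any]] = []
    for idx, row in enumerate(raw[list(COLUMNS)].to_dict("records")):
        reason = _validate_row(row)
        if reason is None:
            kept.append(row)
        else:
            report.rejected.append((idx, reason))
    report.n_rows_kept = len(kept)
    report.check()

    df = pd.DataFrame(kept, columns=list(COLUMNS))
    table = SocietyTable(df, provenance=str(path))
    return table, report


def _results_to_frame(results: Any) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results.copy()
    if isinstance(results, Mapping):
        return pd.DataFrame([results])
    if isinstance(results, Iterable):
        rows = []
        for item in results:
            if hasattr(item, "to_row"):
                rows.append(item.to_row())
            elif hasattr(item, "__dataclass_fields__"):
                from dataclasses import asdict

                rows.append(asdict(item))
            elif isinstance(item, Mapping):
                rows.append(dict(item))
            else:
                raise TypeError(f"cannot serialize result item {item!r}")
        return pd.DataFrame(rows)
    raise TypeError(f"cannot serialize results of type {type(results)}")


def write_report(results: Any, path: str | Path, format: str = "csv") -> Path:
    """Serialize analysis outputs to CSV or JSON at full precision.

    Numeric values are written with enough digits to round-trip exactly
    (repr precision); display rounding is the caller's concern.
    """
    frame = _results_to_frame(results)
    if frame.empty:
        raise ValueError("refusing to write an empty report")
    path = Path(path)
    if path.parent and not path.parent.exists():
        raise FileNotFoundError(f"output directory {path.parent} does not exist")
    if format == "csv":
        frame.to_csv(path, index=False, float_format="%.17g")
    elif format == "json":
        path.write_text(
            json.dumps(frame.to_dict(orient="records"), indent=2, default=str)
        )
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path
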