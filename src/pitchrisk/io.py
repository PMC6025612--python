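"""File formats and validation for the survey pipeline.

Tabular data (soil, water, questionnaire) travel as UTF-8 comma-separated
CSV with required headers and "." decimals; site geometry as GeoJSON
polygons with a ``zone`` property; interpolated concentration maps as
ESRI ASCII grids (.asc -- human-diffable, so round-trips are testable by
eye); risk reports as JSON.

All readers validate on load and fail loudly with row numbers; rows are
never silently dropped.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping as geom_mapping, shape as geom_shape
from shapely.geometry.base import BaseGeometry

from .idw import NODATA, RasterGrid

__all__ = [
    "SchemaError",
    "SOIL_COLUMNS",
    "WATER_COLUMNS",
    "SURVEY_COLUMNS",
    "read_soil_table", "write_soil_table",
    "read_water_table", "write_water_table",
    "read_survey_table", "write_survey_table",
    "reconcile_duplicates",
    "read_zones", "write_zones",
    "read_raster", "write_raster",
    "CLOTHING_CATEGORIES",
    "map_clothing_to_surface_area",
    "survey_exposure_frame",
]


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


#: Soil-sample table schema: one georeferenced total-As (aqua-regia
#: recoverable) measurement.  Coordinates are planar projected metres,
#: y increasing north; depth interval in cm; tAs in mg/kg.
SOIL_COLUMNS = ["sample_id", "x", "y", "zone", "depth_top", "depth_bottom",
                "tAs", "is_duplicate", "duplicate_of"]
_SOIL_NUMERIC = ["x", "y", "depth_top", "depth_bottom", "tAs"]
ZONE_LABELS = ("IA", "NIA")

#: Irrigation-water table: As in mg/L plus in-situ physicochemistry.
WATER_COLUMNS = ["location", "replicate", "As", "T", "pH", "EC", "TDS",
                 "ORP", "DO", "alkalinity"]

#: Questionnaire table: one row per respondent.
SURVEY_COLUMNS = ["respondent_id", "clothing", "games_per_visit",
                  "visits_per_year", "years_member"]


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing column(s): {', '.join(missing)}")


def _numeric(df: pd.DataFrame, cols: list[str], what: str) -> pd.DataFrame:
    for col in cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{what} table: non-numeric {col!r} at row(s) {list(bad + 2)} "
                "(1-based, counting the header)"
            )
        df[col] = parsed
    return df


def read_soil_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a soil-sample CSV.

    Rejects (with row numbers) rows with non-positive tAs, inverted depth
    intervals, or zone labels outside {IA, NIA}.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "duplicate_of": str})
    _check_columns(df, SOIL_COLUMNS, "soil")
    df = _numeric(df, _SOIL_NUMERIC, "soil")
    df["is_duplicate"] = df["is_duplicate"].astype(bool)

    def _reject(mask: pd.Series, reason: str) -> None:
        if mask.any():
            rows = list(df.index[mask] + 2)
            raise SchemaError(f"soil table: {reason} at row(s) {rows}")

    _reject(~(df["tAs"] > 0), "tAs must be > 0")
    _reject(~(df["depth_top"] < df["depth_bottom"]), "depth_top must be < depth_bottom")
    _reject(~df["zone"].isin(ZONE_LABELS), f"zone must be one of {ZONE_LABELS}")
    return df[SOIL_COLUMNS]


def write_soil_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples[SOIL_COLUMNS].to_csv(path, index=False)


def read_water_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"location": str})
    _check_columns(df, WATER_COLUMNS, "water")
    df = _numeric(df, [c for c in WATER_COLUMNS if c not in ("location",)], "water")
    if (df["As"] < 0).any():
        raise SchemaError("water table: As must be >= 0")
    if ((df["pH"] <= 0) | (df["pH"] >= 14)).any():
        raise SchemaError("water table: pH must lie in (0, 14)")
    return df[WATER_COLUMNS]


def write_water_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples[WATER_COLUMNS].to_csv(path, index=False)


def read_survey_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"respondent_id": str, "clothing": str})
    _check_columns(df, SURVEY_COLUMNS, "survey")
    df = _numeric(df, ["games_per_visit", "visits_per_year", "years_member"], "survey")
    if (df["games_per_visit"] < 1).any():
        raise SchemaError("survey table: games_per_visit must be >= 1")
    if (df["years_member"] <= 0).any():
        raise SchemaError("survey table: years_member must be > 0")
    unknown = set(df["clothing"]) - set(CLOTHING_CATEGORIES)
    if unknown:
        raise SchemaError(f"survey table: unknown clothing category(ies) {sorted(unknown)}")
    return df[SURVEY_COLUMNS]


def write_survey_table(responses: pd.DataFrame, path: str | Path) -> None:
    responses[SURVEY_COLUMNS].to_csv(path, index=False)


def reconcile_duplicates(soil: pd.DataFrame) -> pd.DataFrame:
    """Average QA duplicates into their primary samples.

    Each duplicate row (``is_duplicate`` true, ``duplicate_of`` set) is
    averaged with its primary's tAs and dropped, so the row count decreases
    by exactly the number of duplicates.
    """
    dups = soil[soil["is_duplicate"]]
    out = soil[~soil["is_duplicate"]].copy().set_index("sample_id")
    for _, row in dups.iterrows():
        primary = row["duplicate_of"]
        if primary not in out.index:
            raise SchemaError(
                f"duplicate {row['sample_id']!r} references unknown primary {primary!r}"
            )
        out.loc[primary, "tAs"] = (out.loc[primary, "tAs"] + row["tAs"]) / 2.0
    return out.reset_index()[SOIL_COLUMNS]


# ---------------------------------------------------------------------------
# vector geometry (GeoJSON)

def read_zones(path: str | Path) -> dict[str, BaseGeometry]:
    """Read zone polygons from a GeoJSON FeatureCollection.

    Every feature must carry a ``zone`` property; invalid (e.g.
    self-intersecting) polygons are rejected.  Returns {label: geometry};
    multiple features with one label are unioned.
    """
    with open(path) as fh:
        doc = json.load(fh)
    zones: dict[str, BaseGeometry] = {}
    for i, feature in enumerate(doc.get("features", [])):
        props = feature.get("properties") or {}
        if "zone" not in props:
            raise SchemaError(f"zones file: feature {i} lacks a 'zone' property")
        geom = geom_shape(feature["geometry"])
        if not geom.is_valid:
            raise SchemaError(
                f"zones file: feature {i} (zone {props['zone']!r}) has invalid "
                "geometry (self-intersection?)"
            )
        label = str(props["zone"])
        zones[label] = geom if label not in zones else zones[label].union(geom)
    if not zones:
        raise SchemaError("zones file contains no features")
    return zones


def write_zones(zones: dict[str, BaseGeometry], path: str | Path) -> None:
    features = [
        {"type": "Feature", "properties": {"zone": label},
         "geometry": geom_mapping(geom)}
        for label, geom in zones.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


# ---------------------------------------------------------------------------
# raster (ESRI ASCII grid)

def write_raster(grid: RasterGrid, path: str | Path, precision: int = 6) -> None:
    """Write an ESRI ASCII grid (.asc); NaN cells become the NODATA value."""
    values = np.where(np.isnan(grid.values), NODATA, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner!r}\n")
        fh.write(f"yllcorner {grid.yllcorner!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {NODATA:g}\n")
        for row in values:
            fh.write(" ".join(f"{v:.{precision}g}" for v in row) + "\n")


def read_raster(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid; NODATA cells come back as NaN."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"):
                header[key] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise SchemaError(f"raster file missing header field {key!r}")
    values = np.array(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise SchemaError(
            f"raster data shape {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value", NODATA)
    values[values == nodata] = np.nan
    return RasterGrid(header["xllcorner"], header["yllcorner"],
                      header["cellsize"], values)


# ---------------------------------------------------------------------------
# clothing -> exposed skin surface area

#: Exposed-area increments (cm^2, both limbs) per uncovered body region.
#: Head, neck and hands are always exposed (the base area); short sleeves
#: add the forearms, shorts the thighs/knees, short socks the ankle band.
#: The per-region areas are a fixed convention anchored so that the fully
#: covered ensemble gives 3300 cm^2 and the fully uncovered one 5700 cm^2
#: (the questionnaire-derived range); they approximate adult body-part
#: proportions from USEPA exposure-factor tables.
_BASE_EXPOSED_CM2 = 3300.0
_REGION_INCREMENTS = {
    "short_sleeves": 1200.0,  # forearms
    "shorts": 1000.0,         # thighs and knees
    "short_socks": 200.0,     # ankle band above the boot
}

#: The eight clothing ensembles: sleeves-bottoms-socks.
CLOTHING_CATEGORIES = tuple(
    f"{sleeves}-{bottoms}-{socks}"
    for sleeves in ("long_sleeves", "short_sleeves")
    for bottoms in ("pants", "shorts")
    for socks in ("long_socks", "short_socks")
)


def map_clothing_to_surface_area(category: str) -> float:
    """Exposed skin surface area SA (cm^2) for a clothing ensemble.

    Strictly monotone: every additional uncovered region increases SA.
    Bounds: long_sleeves-pants-long_socks -> 3300; short_sleeves-shorts-
    short_socks -> 5700.
    """
    if category not in CLOTHING_CATEGORIES:
        raise ValueError(
            f"unknown clothing category {category!r}; valid categories: "
            f"{', '.join(CLOTHING_CATEGORIES)}"
        )
    sa = _BASE_EXPOSED_CM2
    for part, extra in _REGION_INCREMENTS.items():
        if part in category:
            sa += extra
    return sa


def survey_exposure_frame(responses: pd.DataFrame) -> pd.DataFrame:
    """Map questionnaire responses to exposure parameters (SA, EV, EF, ED).

    SA from the clothing ensemble, EV = games per visit (events/day),
    EF = visits per year (days/yr), ED = years of membership (yr).
    """
    return pd.DataFrame({
        "SA": responses["clothing"].map(map_clothing_to_surface_area).astype(float),
        "EV": responses["games_per_visit"].astype(float),
        "EF": responses["visits_per_year"].astype(float),
        "ED": responses["years_member"].astype(float),
    })
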