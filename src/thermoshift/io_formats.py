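"""Readers, writers and validation for the pipeline's external artifacts.

Four kinds of input are handled: stem-level census tables (long format, one
row per stem per census), species occurrence tables (GBIF Darwin-Core style
column names), species trait tables, and gridded climatologies of mean annual
temperature (MAT, degC) and mean annual precipitation (MAP, mm).

Climate grids use a plain-text format (header lines followed by one row of
values per grid row) so that fixtures stay human-readable and the package has
no binary raster dependency.  Grid cells are half-open intervals
``[edge, edge + cell_size)`` on both axes with the origin at the lower-left
(south-west) edge, so every in-bounds coordinate falls in exactly one cell.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Recorded species names starting with this prefix denote stems identified
#: only to genus or family.  They never match an affiliation table entry, so
#: downstream community indices exclude them and renormalize.
SPECIES_SENTINEL_PREFIX = "Indet"

CENSUS_REQUIRED_COLUMNS = [
    "plot_id",
    "tag",
    "species",
    "census_index",
    "census_date",
    "diameter_cm",
    "alive",
]
CENSUS_OPTIONAL_COLUMNS = ["height_m", "plot_lon", "plot_lat", "elevation_m"]

MIN_DIAMETER_CM = 10.0  # census protocol: all stems >= 10 cm diameter


def is_species_level(name: str) -> bool:
    """True when a recorded name is a species-level determination."""
    return not str(name).startswith(SPECIES_SENTINEL_PREFIX)


# ---------------------------------------------------------------------------
# Climate grids
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ClimateGrid:
    """A regular lon/lat grid of one climate variable.

    ``values`` has shape (nrows, ncols); row 0 is the southernmost row,
    column 0 the westernmost column.  ``origin_lon``/``origin_lat`` are the
    coordinates of the lower-left *edge* of cell (0, 0).
    """

    variable: str
    origin_lon: float
    origin_lat: float
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/column of the half-open cell containing each point.

        Out-of-bounds points get index -1 in the offending axis.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.cell_size).astype(int)
        row = np.floor((lat - self.origin_lat) / self.cell_size).astype(int)
        nrows, ncols = self.shape
        col = np.where((col >= 0) & (col < ncols), col, -1)
        row = np.where((row >= 0) & (row < nrows), row, -1)
        return row, col

    def extract(self, lon, lat):
        """Value of the unique cell containing each point.

        Out-of-bounds points and nodata cells yield NaN; the caller decides
        whether to drop the record.
        """
        lon_a = np.atleast_1d(np.asarray(lon, dtype=float))
        lat_a = np.atleast_1d(np.asarray(lat, dtype=float))
        row, col = self.cell_index(lon_a, lat_a)
        ok = (row >= 0) & (col >= 0)
        out = np.full(lon_a.shape, np.nan)
        vals = self.values[row[ok], col[ok]]
        vals = np.where(np.isclose(vals, self.nodata), np.nan, vals)
        out[ok] = vals
        if np.isscalar(lon) or (isinstance(lon, float) or isinstance(lon, int)):
            return float(out[0])
        return out


def extract_climate(grid: ClimateGrid, lon, lat):
    """Functional alias for :meth:`ClimateGrid.extract`."""
    return grid.extract(lon, lat)


def write_climate_grid(grid: ClimateGrid, path) -> None:
    nrows, ncols = grid.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# thermoshift climate grid\n")
        fh.write(f"variable: {grid.variable}\n")
        fh.write(f"origin_lon: {grid.origin_lon!r}\n")
        fh.write(f"origin_lat: {grid.origin_lat!r}\n")
        fh.write(f"cell_size: {grid.cell_size!r}\n")
        fh.write(f"ncols: {ncols}\n")
        fh.write(f"nrows: {nrows}\n")
        fh.write(f"nodata: {grid.nodata!r}\n")
        for r in range(nrows):
            fh.write(" ".join(repr(float(v)) for v in grid.values[r]) + "\n")


def read_climate_grid(path) -> ClimateGrid:
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" in line and not rows and line.split(":")[0] in {
                "variable",
                "origin_lon",
                "origin_lat",
                "cell_size",
                "ncols",
                "nrows",
                "nodata",
            }:
                key, _, val = line.partition(":")
                header[key.strip()] = val.strip()
            else:
                rows.append([float(v) for v in line.split()])
    missing = {"variable", "origin_lon", "origin_lat", "cell_size", "ncols", "nrows"} - set(header)
    if missing:
        raise ValueError(f"climate grid header missing fields: {sorted(missing)}")
    values = np.array(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"climate grid body shape {values.shape} does not match header "
            f"({header['nrows']} rows x {header['ncols']} cols)"
        )
    return ClimateGrid(
        variable=header["variable"],
        origin_lon=float(header["origin_lon"]),
        origin_lat=float(header["origin_lat"]),
        cell_size=float(header["cell_size"]),
        values=values,
        nodata=float(header.get("nodata", -9999.0)),
    )


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ValidationReport:
    """Line-numbered record of accepted and rejected input rows."""

    n_input: int
    errors: list[tuple[int, str]] = dataclasses.field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.errors)

    @property
    def n_accepted(self) -> int:
        return self.n_input - self.n_rejected

    def summary(self) -> str:
        return f"{self.n_accepted}/{self.n_input} rows accepted, {self.n_rejected} rejected"


# ---------------------------------------------------------------------------
# Census tables
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CensusSeries:
    """Stem-level repeated inventory for one plot.

    ``stems`` is a long-format frame (one row per stem per census) with the
    columns of :data:`CENSUS_REQUIRED_COLUMNS` plus ``height_m``.
    ``censuses`` are the census dates (decimal years), strictly increasing,
    indexed by census_index.
    """

    plot_id: str
    stems: pd.DataFrame
    censuses: np.ndarray
    elevation: float = float("nan")
    lon: float = float("nan")
    lat: float = float("nan")

    @property
    def n_censuses(self) -> int:
        return len(self.censuses)

    @property
    def interval(self) -> float:
        """Total census interval (last minus first date) in years."""
        return float(self.censuses[-1] - self.censuses[0])

    def census(self, census_index: int, alive_only: bool = True) -> pd.DataFrame:
        sel = self.stems[self.stems["census_index"] == census_index]
        if alive_only:
            sel = sel[sel["alive"]]
        return sel


def _validate_census_frame(df: pd.DataFrame) -> ValidationReport:
    """Row-level invariant checks.  Adds a boolean ``_ok`` column in place."""
    report = ValidationReport(n_input=len(df))
    lineno = df.index.to_numpy() + 2  # header is line 1
    ok = np.ones(len(df), dtype=bool)

    def reject(mask: np.ndarray, reason_fmt) -> None:
        for pos in np.nonzero(mask & ok)[0]:
            report.errors.append((int(lineno[pos]), reason_fmt(df.iloc[pos])))
        ok[mask & ok] = False

    bad_num = df["census_date"].isna() | df["diameter_cm"].isna() | df["census_index"].isna()
    reject(bad_num.to_numpy(), lambda r: "unparseable numeric field")
    small = (df["alive"].fillna(False).astype(bool) & (df["diameter_cm"] < MIN_DIAMETER_CM)).to_numpy()
    small &= ~bad_num.to_numpy()
    reject(small, lambda r: f"alive stem below {MIN_DIAMETER_CM} cm minimum diameter (tag {r['tag']})")

    # census_date must be a consistent, strictly increasing function of
    # census_index within each plot
    for plot_id, grp in df[ok].groupby("plot_id"):
        date_map = grp.groupby("census_index")["census_date"].agg(["min", "max"])
        inconsistent = date_map.index[date_map["min"] != date_map["max"]]
        dates = date_map["min"]
        decreasing = dates.index[
            (dates.diff().fillna(1.0) <= 0) & (np.arange(len(dates)) > 0)
        ]
        bad_idx = set(inconsistent) | set(decreasing)
        if bad_idx:
            mask = (df["plot_id"] == plot_id) & df["census_index"].isin(bad_idx)
            reject(
                mask.to_numpy(),
                lambda r: f"census_date not strictly increasing with census_index (plot {r['plot_id']})",
            )

    # a tag never resurrects: once recorded dead, no later alive record
    work = df[ok]
    work = work.sort_values(["plot_id", "tag", "census_index"])
    for (plot_id, tag), grp in work.groupby(["plot_id", "tag"], sort=False):
        alive = grp["alive"].astype(bool).to_numpy()
        dead_seen = False
        bad_rows = []
        for pos, a in zip(grp.index, alive):
            if a and dead_seen:
                bad_rows.append(pos)
            if not a:
                dead_seen = True
        if bad_rows:
            mask = np.zeros(len(df), dtype=bool)
            mask[df.index.get_indexer(bad_rows)] = True
            reject(mask, lambda r: f"tag {r['tag']} recorded alive after dead (plot {r['plot_id']})")

    df["_ok"] = ok
    return report


def read_census_table(path) -> tuple[dict[str, CensusSeries], ValidationReport]:
    """Read and validate a long-format census CSV.

    Returns one :class:`CensusSeries` per plot built from the accepted rows,
    plus a line-numbered report of rejected rows.  Missing required columns
    are fatal.
    """
    df = pd.read_csv(path)
    missing = [c for c in CENSUS_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"census table {path}: missing required columns {missing}")
    for col in ("census_date", "diameter_cm", "height_m"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "height_m" not in df.columns:
        df["height_m"] = np.nan
    df["census_index"] = pd.to_numeric(df["census_index"], errors="coerce").astype("Int64")
    df["alive"] = df["alive"].map(
        lambda v: bool(v) if isinstance(v, (bool, np.bool_)) else str(v).strip().lower() in {"true", "1", "t", "yes"}
    )
    report = _validate_census_frame(df)
    accepted = df[df["_ok"]].drop(columns="_ok")
    series: dict[str, CensusSeries] = {}
    for plot_id, grp in accepted.groupby("plot_id"):
        grp = grp.reset_index(drop=True)
        dates = grp.groupby("census_index")["census_date"].first().sort_index()
        meta = {}
        for col, attr in (("elevation_m", "elevation"), ("plot_lon", "lon"), ("plot_lat", "lat")):
            meta[attr] = float(grp[col].iloc[0]) if col in grp.columns and grp[col].notna().any() else float("nan")
        keep = [c for c in CENSUS_REQUIRED_COLUMNS + ["height_m"] if c in grp.columns]
        series[str(plot_id)] = CensusSeries(
            plot_id=str(plot_id),
            stems=grp[keep],
            censuses=dates.to_numpy(dtype=float),
            **meta,
        )
    return series, report


def write_census_table(series: Iterable[CensusSeries], path) -> None:
    frames = []
    for s in series:
        frame = s.stems.copy()
        frame["plot_id"] = s.plot_id
        if not math.isnan(s.elevation):
            frame["elevation_m"] = s.elevation
        if not math.isnan(s.lon):
            frame["plot_lon"] = s.lon
        if not math.isnan(s.lat):
            frame["plot_lat"] = s.lat
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Occurrence tables
# ---------------------------------------------------------------------------

_OCC_COLUMN_ALIASES: Mapping[str, str] = {
    "species": "species",
    "decimallongitude": "lon",
    "decimallatitude": "lat",
    "lon": "lon",
    "lat": "lat",
    "year": "year",
    "issue": "issue",
    "flagged": "flagged",
}


def read_occurrences(path) -> tuple[pd.DataFrame, ValidationReport]:
    """Read a GBIF-style occurrence export.

    Accepts either Darwin-Core column names (``decimalLongitude`` /
    ``decimalLatitude`` with an ``issue`` string column) or the package's own
    short names.  Rows with unparseable or out-of-range coordinates are
    rejected and counted; the result has columns
    ``species, lon, lat, year, flagged``.
    """
    raw = pd.read_csv(path)
    cols = {c: _OCC_COLUMN_ALIASES.get(c.strip().lower()) for c in raw.columns}
    raw = raw.rename(columns={c: t for c, t in cols.items() if t})
    for needed in ("species", "lon", "lat"):
        if needed not in raw.columns:
            raise ValueError(f"occurrence table {path}: missing column for '{needed}'")
    report = ValidationReport(n_input=len(raw))
    lon = pd.to_numeric(raw["lon"], errors="coerce")
    lat = pd.to_numeric(raw["lat"], errors="coerce")
    bad = lon.isna() | lat.isna() | (lon < -180) | (lon > 180) | (lat < -90) | (lat > 90)
    for pos in np.nonzero(bad.to_numpy())[0]:
        report.errors.append((int(raw.index[pos]) + 2, "invalid coordinates"))
    if "flagged" in raw.columns:
        flagged = raw["flagged"].map(
            lambda v: bool(v) if isinstance(v, (bool, np.bool_)) else str(v).strip().lower() in {"true", "1"}
        )
    elif "issue" in raw.columns:
        flagged = raw["issue"].fillna("").astype(str).str.strip() != ""
    else:
        flagged = pd.Series(False, index=raw.index)
    year = pd.to_numeric(raw["year"], errors="coerce") if "year" in raw.columns else pd.Series(np.nan, index=raw.index)
    out = pd.DataFrame(
        {
            "species": raw["species"].astype(str),
            "lon": lon,
            "lat": lat,
            "year": year,
            "flagged": flagged.astype(bool),
        }
    )[~bad.to_numpy()].reset_index(drop=True)
    return out, report


def write_occurrences(occ: pd.DataFrame, path, gbif_style: bool = True) -> None:
    out = occ.copy()
    if gbif_style:
        out = out.rename(columns={"lon": "decimalLongitude", "lat": "decimalLatitude"})
        out["issue"] = np.where(out.pop("flagged"), "COORDINATE_ROUNDED", "")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------

TRAIT_COLUMNS = ["taxon", "genus", "family", "wood_density", "max_height", "light_guild"]


def read_traits(path) -> tuple[pd.DataFrame, ValidationReport]:
    """Read a species trait table.

    ``wood_density`` must be positive (g cm^-3); ``light_guild`` is the
    ordinal 0-3 coding (0 no data, 1 pioneer light demander, 2 non-pioneer
    light demander, 3 shade bearer).  Violating rows are rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("taxon", "wood_density") if c not in df.columns]
    if missing:
        raise ValueError(f"trait table {path}: missing required columns {missing}")
    report = ValidationReport(n_input=len(df))
    wd = pd.to_numeric(df["wood_density"], errors="coerce")
    guild = pd.to_numeric(df.get("light_guild", 0), errors="coerce").fillna(0)
    bad = wd.isna() | (wd <= 0) | ~guild.isin([0, 1, 2, 3])
    for pos in np.nonzero(bad.to_numpy())[0]:
        report.errors.append((int(df.index[pos]) + 2, "invalid wood_density or light_guild"))
    out = df[~bad.to_numpy()].reset_index(drop=True)
    out["wood_density"] = wd[~bad.to_numpy()].to_numpy()
    if "genus" not in out.columns:
        out["genus"] = out["taxon"].astype(str).str.split().str[0]
    if "family" not in out.columns:
        out["family"] = ""
    return out, report


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, index=False)
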