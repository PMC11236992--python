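"""Species climate affiliations from occurrence records.

A species' thermal optimum is the arithmetic mean of the mean annual
temperature (MAT) of the grid cells holding its cleaned, cell-deduplicated
occurrence records; the precipitation optimum is defined identically on the
MAP grid.  Niche breadth is the spread (95th minus 5th percentile, linear
interpolation between order statistics) of those same MAT values.

Cleaning order is fixed: provider-flag filter, then the optional year cutoff,
then removal of records over nodata cells (water / out of climatology
domain), then one-record-per-species-per-grid-cell deduplication — dedupe
last so the retained cell representative is always a clean record.

Optimum precision grows with record count; :func:`threshold_error_curve`
quantifies this by subsampling a species' records and measuring the error of
the subsampled optimum against the full-record optimum.  The inclusion
threshold (default 10 records) is a configuration choice informed by that
curve, not an automated change point.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io_formats import ClimateGrid

DEFAULT_THRESHOLD = 10
#: named presets: no threshold / the default / the stricter sensitivity case
THRESHOLD_PRESETS = {"none": 0, "default": 10, "strict": 30}


def clean_occurrences(
    occ: pd.DataFrame,
    grid: ClimateGrid,
    since: int | None = None,
) -> pd.DataFrame:
    """Drop flagged records, optionally old records, and records on nodata cells.

    ``since`` keeps only records with ``year >= since`` (records lacking a
    year are dropped when the cutoff is active, since they cannot be shown to
    be temporally matched with the climatology).
    """
    out = occ[~occ["flagged"].astype(bool)]
    if since is not None:
        out = out[out["year"].notna() & (out["year"] >= since)]
    vals = grid.extract(out["lon"].to_numpy(), out["lat"].to_numpy())
    return out[~np.isnan(vals)].reset_index(drop=True)


def dedupe_by_cell(occ: pd.DataFrame, grid: ClimateGrid) -> pd.DataFrame:
    """Keep at most one record per species per grid cell (first in file).

    Deduplication is per species: co-occurring species in one cell each keep
    a record.
    """
    row, col = grid.cell_index(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    key = pd.DataFrame({"species": occ["species"].to_numpy(), "row": row, "col": col})
    keep = ~key.duplicated()
    return occ[keep.to_numpy()].reset_index(drop=True)


def species_optimum(occ: pd.DataFrame, grid: ClimateGrid) -> tuple[float, int]:
    """Mean extracted climate value over a species' records, plus the count used.

    Returns ``(nan, 0)`` when no record has a usable climate value; such a
    species carries no affiliation and is excluded downstream.
    """
    vals = grid.extract(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan"), 0
    return float(vals.mean()), int(vals.size)


def niche_breadth(occ: pd.DataFrame, grid: ClimateGrid) -> float:
    """95th minus 5th percentile of extracted MAT across a species' records.

    Quantiles use linear interpolation between order statistics
    (``h = (n - 1) p + 1``).  Needs at least two usable records.
    """
    vals = grid.extract(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        return float("nan")
    q5, q95 = np.percentile(vals, [5.0, 95.0])
    return float(q95 - q5)


@dataclasses.dataclass
class ThresholdCurve:
    """Subsampling error of a species' optimum as a function of record count."""

    species: str
    sizes: np.ndarray
    mean_abs_error: np.ndarray
    replicates: int
    seed: int
    n_records: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "n": self.sizes,
                "mean_abs_error": self.mean_abs_error,
                "replicates": self.replicates,
            }
        )


def threshold_error_curve(
    occ: pd.DataFrame,
    grid: ClimateGrid,
    sizes,
    replicates: int = 100,
    seed: int = 0,
) -> ThresholdCurve:
    """Mean |subsampled optimum - full optimum| at each subsample size.

    Subsampling is without replacement from the species' usable (cleaned,
    deduplicated) extracted values; sizes exceeding the available record
    count are skipped with a warning.  Reproducible under a fixed seed.
    """
    import warnings

    vals = grid.extract(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    vals = vals[~np.isnan(vals)]
    full = vals.mean()
    rng = np.random.default_rng(seed)
    kept_sizes, errors = [], []
    for n in sizes:
        if n > vals.size:
            warnings.warn(f"subsample size {n} exceeds record count {vals.size}; skipped")
            continue
        errs = np.empty(replicates)
        for r in range(replicates):
            sub = rng.choice(vals, size=int(n), replace=False)
            errs[r] = abs(sub.mean() - full)
        kept_sizes.append(int(n))
        errors.append(errs.mean())
    species = str(occ["species"].iloc[0]) if len(occ) else ""
    return ThresholdCurve(
        species=species,
        sizes=np.array(kept_sizes),
        mean_abs_error=np.array(errors),
        replicates=replicates,
        seed=seed,
        n_records=int(vals.size),
    )


def build_affiliation_table(
    occ: pd.DataFrame,
    grid_t: ClimateGrid,
    grid_p: ClimateGrid,
    threshold: int | str = DEFAULT_THRESHOLD,
    since: int | None = None,
) -> pd.DataFrame:
    """One affiliation row per species: optima, record count, breadth, inclusion.

    The returned frame is indexed by species with columns ``t_opt`` (degC),
    ``p_opt`` (mm), ``n_records`` (post-cleaning, post-dedupe on the MAT
    grid), ``niche_breadth_t`` (degC) and ``included``
    (``n_records >= threshold``).  ``threshold`` accepts the named presets
    'none' (0), 'default' (10) and 'strict' (30) or any integer.
    """
    if isinstance(threshold, str):
        threshold = THRESHOLD_PRESETS[threshold]
    clean = clean_occurrences(occ, grid_t, since=since)
    clean = dedupe_by_cell(clean, grid_t)
    rows = []
    for species, grp in clean.groupby("species", sort=True):
        t_opt, n = species_optimum(grp, grid_t)
        p_opt, _ = species_optimum(grp, grid_p)
        rows.append(
            {
                "species": species,
                "t_opt": t_opt,
                "p_opt": p_opt,
                "n_records": n,
                "niche_breadth_t": niche_breadth(grp, grid_t),
                "included": n >= threshold,
            }
        )
    table = pd.DataFrame(rows).set_index("species")
    return table


def included_values(affiliations: pd.DataFrame, attribute: str = "t_opt") -> pd.Series:
    """Attribute values of the included species only (the weighting input)."""
    inc = affiliations[affiliations["included"]]
    return inc[attribute].dropna()
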