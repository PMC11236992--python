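"""Synthetic study generator: climate grids, occurrence clouds, censuses.

Everything the pipeline consumes can be generated here with known ground
truth, so every stage is testable without downloads and parameter recovery
is the main validation surface.

The world is deliberately simple.  Mean annual temperature (MAT) follows a
deterministic lapse-rate ramp along the grid's x axis (columns = elevation
axis, warmest at column 0); mean annual precipitation ramps along the y
axis.  A horizontal band of nodata cells (a "lake") exercises the
occurrence-cleaning rules without disturbing the ramp's column means.

Each species ``s`` has a Gaussian thermal niche with mean ``mu_s`` (its true
optimum) and width ``sigma_s``.  Occurrence records are placed in grid cells
whose MAT is drawn from that niche (truncated to the ramp's support), so the
occurrence-based optimum estimator targets ``mu_s`` by construction.

Plot communities start with stem abundances proportional to Gaussian
suitability exp(-(MAT_plot - mu_s)^2 / (2 sigma_s^2)).  Census to census,
each stem dies with annual probability
``logistic(logit(m0) - b_m * (mu_s - MAT_plot))`` (warm-affiliated species
die less when the mortality bias ``b_m`` is positive), survivors grow in
diameter, and Poisson recruits enter at 10-15 cm with species drawn
proportional to suitability times ``exp(b_r * mu_s)``.  The recruitment bias
``b_r`` shifts *which* species recruit, not how many stems do, so stem
density is trend-stationary under the null and thermophilization is isolated
from densification.  Growth is species-independent by default (a
``growth_optimum_corr`` knob exists), so the growth component of basal-area-
weighted index change has a known zero expectation.

Default parameter values mirror the study conditions this generator
emulates: 17 one-hectare plots on a 10-23 degC gradient, three censuses
spanning twelve years, ~560 stems per plot, ~200 species, occurrence counts
with mean ~92 and SD ~89, a 3 degC niche width, and field-typical montane
tropical demographic rates (1.5%/y mortality, 8 recruits/ha/y, 0.20 cm/y
diameter growth).  See docs/methods.md for the rationale of each.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io_formats import (
    CensusSeries,
    ClimateGrid,
    write_census_table,
    write_climate_grid,
    write_occurrences,
    write_traits,
)

SEA_LEVEL_MAT = 26.0  # degC, for the synthetic lapse relation
LAPSE_RATE = 0.0055  # degC per m elevation


@dataclasses.dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    n_plots: int = 17
    n_species: int = 200
    stems_per_plot: int = 560
    area_ha: float = 1.0
    mat_range: tuple[float, float] = (10.0, 23.0)  # plot gradient, degC
    niche_sd: float = 3.0  # sigma_s, degC
    niche_margin: float = 2.0  # species optima extend this far beyond the gradient
    census_dates: tuple[float, ...] = (2010.5, 2016.5, 2022.5)
    annual_mortality: float = 0.015  # m0, per stem per year
    recruitment_rate: float = 8.0  # r0, stems per ha per year
    recruit_bias: float = 0.2  # b_r, log-odds per degC of optimum
    mortality_bias: float = 0.1  # b_m, log-odds per degC of optimum
    growth_mean: float = 0.20  # cm/y diameter increment
    growth_sd: float = 0.15  # cm/y
    growth_optimum_corr: float = 0.0  # growth boost per degC of optimum (cm/y)
    init_diameter_scale: float = 8.0  # cm above the 10 cm floor (exponential)
    large_stem_preset: bool = False  # skew initial mass toward >=70 cm stems
    unidentified_fraction: float = 0.03  # stems recorded under an Indet sentinel
    occ_count_mean: float = 92.0  # occurrence records per species (exponential)
    occ_count_min: int = 3
    occ_fixed_count: int | None = None  # override: same count for every species
    occ_flagged_fraction: float = 0.05
    occ_nodata_fraction: float = 0.03
    occ_year_range: tuple[int, int] = (1950, 2022)
    grid_shape: tuple[int, int] = (60, 80)  # (nrows, ncols)
    cell_size: float = 1.0 / 120.0  # 30 arc-seconds
    grid_origin: tuple[float, float] = (29.0, -4.0)  # lon, lat of SW edge
    ramp_pad: float = 6.0  # degC of ramp beyond the species-optimum span
    map_range: tuple[float, float] = (800.0, 2400.0)  # mm
    n_height_measured: int = 60  # stems with measured height, last census
    climate_trend: float = 0.01  # imposed station warming, degC/y
    climate_noise_sd: float = 0.15  # interannual MAT noise, degC
    species_per_genus: int = 4
    genera_per_family: int = 5

    def __post_init__(self) -> None:
        if self.n_plots < 1 or self.n_species < 1:
            raise ValueError("need at least one plot and one species")
        if self.niche_sd <= 0:
            raise ValueError("niche_sd must be positive")
        if not 0 <= self.annual_mortality <= 1:
            raise ValueError("annual_mortality must be a probability")
        if any(b - a <= 0 for a, b in zip(self.census_dates, self.census_dates[1:])):
            raise ValueError("census_dates must be strictly increasing")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Climate grids
# ---------------------------------------------------------------------------


def mat_ramp(cfg: SimulationConfig) -> np.ndarray:
    """Per-column MAT values: warmest at column 0, cooling with elevation."""
    lo = cfg.mat_range[0] - cfg.niche_margin - cfg.ramp_pad
    hi = cfg.mat_range[1] + cfg.niche_margin + cfg.ramp_pad
    return np.linspace(hi, lo, cfg.grid_shape[1])


def lake_rows(cfg: SimulationConfig) -> np.ndarray:
    """Row indices of the full-width nodata band used for cleaning tests."""
    nrows = cfg.grid_shape[0]
    start = nrows // 3
    return np.arange(start, start + max(2, nrows // 10))


def generate_climate_grid(cfg: SimulationConfig) -> tuple[ClimateGrid, ClimateGrid]:
    """Deterministic (MAT, MAP) grid pair.

    The nodata band spans full rows, so the mean over valid MAT cells equals
    the ramp midpoint exactly.
    """
    nrows, ncols = cfg.grid_shape
    ramp = mat_ramp(cfg)
    mat = np.tile(ramp, (nrows, 1))
    pr = np.linspace(cfg.map_range[0], cfg.map_range[1], nrows)
    pmap = np.tile(pr[:, None], (1, ncols))
    nod = lake_rows(cfg)
    mat[nod, :] = -9999.0
    pmap[nod, :] = -9999.0
    olon, olat = cfg.grid_origin
    kw = dict(origin_lon=olon, origin_lat=olat, cell_size=cfg.cell_size, nodata=-9999.0)
    return (
        ClimateGrid(variable="MAT", values=mat, **kw),
        ClimateGrid(variable="MAP", values=pmap, **kw),
    )


# ---------------------------------------------------------------------------
# Species pool and traits
# ---------------------------------------------------------------------------


def species_pool(cfg: SimulationConfig, seed: int) -> pd.DataFrame:
    """Species names, taxonomy and true thermal optima mu_s.

    Optima are uniform over the plot gradient widened by ``niche_margin`` so
    the pool includes species centred beyond both ends of the gradient.
    """
    rng = np.random.default_rng([seed, 11])
    mu = rng.uniform(
        cfg.mat_range[0] - cfg.niche_margin,
        cfg.mat_range[1] + cfg.niche_margin,
        cfg.n_species,
    )
    names, genera, families = [], [], []
    for i in range(cfg.n_species):
        g = i // cfg.species_per_genus
        f = g // cfg.genera_per_family
        genus = f"Genus{g:03d}"
        names.append(f"{genus} species{i:03d}")
        genera.append(genus)
        families.append(f"Family{f:02d}")
    return pd.DataFrame(
        {"species": names, "genus": genera, "family": families, "mu": mu}
    ).set_index("species")


def generate_traits(cfg: SimulationConfig, seed: int, coverage: float = 0.75) -> pd.DataFrame:
    """Species trait table with deliberate gaps to exercise taxonomic fallback.

    ``coverage`` of species get a species-level row; the rest resolve via
    congeners (genus mean) or family mean downstream.
    """
    pool = species_pool(cfg, seed)
    rng = np.random.default_rng([seed, 12])
    keep = rng.random(len(pool)) < coverage
    sub = pool[keep]
    wd = np.clip(rng.normal(0.60, 0.10, len(sub)), 0.25, 0.95)
    return pd.DataFrame(
        {
            "taxon": sub.index,
            "genus": sub["genus"].to_numpy(),
            "family": sub["family"].to_numpy(),
            "wood_density": wd,
            "max_height": rng.uniform(15.0, 45.0, len(sub)),
            "light_guild": rng.integers(0, 4, len(sub)),
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------


def generate_occurrences(cfg: SimulationConfig, seed: int) -> pd.DataFrame:
    """Occurrence clouds drawn from each species' thermal niche.

    Record MATs are Normal(mu_s, sigma_s) truncated to the ramp support and
    snapped to the nearest grid column; rows are uniform over non-lake rows.
    A configured fraction of records is provider-flagged and a fraction is
    placed on nodata (lake) cells so the cleaning rules have work to do.
    """
    pool = species_pool(cfg, seed)
    grid_t, _ = generate_climate_grid(cfg)
    ramp = mat_ramp(cfg)
    step = ramp[0] - ramp[1]  # ramp is decreasing
    nrows, ncols = cfg.grid_shape
    nod = set(lake_rows(cfg).tolist())
    good_rows = np.array([r for r in range(nrows) if r not in nod])
    rng = np.random.default_rng([seed, 13])
    olon, olat = cfg.grid_origin

    frames = []
    for species, row in pool.iterrows():
        if cfg.occ_fixed_count is not None:
            n = int(cfg.occ_fixed_count)
        else:
            n = int(cfg.occ_count_min + round(rng.exponential(cfg.occ_count_mean - cfg.occ_count_min)))
        t = np.clip(rng.normal(row["mu"], cfg.niche_sd, n), ramp[-1], ramp[0])
        cols = np.clip(np.rint((ramp[0] - t) / step).astype(int), 0, ncols - 1)
        rows_ = rng.choice(good_rows, size=n)
        n_nod = int(round(cfg.occ_nodata_fraction * n))
        if n_nod and nod:
            idx = rng.choice(n, size=n_nod, replace=False)
            rows_[idx] = rng.choice(sorted(nod), size=n_nod)
        lon = olon + (cols + rng.uniform(0.05, 0.95, n)) * cfg.cell_size
        lat = olat + (rows_ + rng.uniform(0.05, 0.95, n)) * cfg.cell_size
        frames.append(
            pd.DataFrame(
                {
                    "species": species,
                    "lon": lon,
                    "lat": lat,
                    "year": rng.integers(cfg.occ_year_range[0], cfg.occ_year_range[1] + 1, n),
                    "flagged": rng.random(n) < cfg.occ_flagged_fraction,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Plot communities and censuses
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GroundTruth:
    """What the simulator knows that the pipeline must recover."""

    mu: pd.Series  # true optimum per species
    niche_sd: float
    recruit_bias: float
    mortality_bias: float
    climate_trend: float
    plot_mat: pd.Series
    realized_rates_stem: pd.Series  # per-plot annual dCTI_Stem from true optima
    deaths: pd.Series
    recruits: pd.Series
    height_models: dict[str, dict]

    @property
    def realized_trend_stem(self) -> float:
        return float(self.realized_rates_stem.mean())

    def to_json(self, path) -> None:
        payload = {
            "niche_sd": self.niche_sd,
            "recruit_bias": self.recruit_bias,
            "mortality_bias": self.mortality_bias,
            "climate_trend": self.climate_trend,
            "realized_trend_stem": self.realized_trend_stem,
            "mu": self.mu.to_dict(),
            "plot_mat": self.plot_mat.to_dict(),
            "realized_rates_stem": self.realized_rates_stem.to_dict(),
            "deaths": self.deaths.to_dict(),
            "recruits": self.recruits.to_dict(),
            "height_models": self.height_models,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def plot_metadata(cfg: SimulationConfig) -> pd.DataFrame:
    """Plot MATs (snapped to grid columns), coordinates, elevations, sites.

    Plots are evenly spaced along the gradient and assigned round-robin to
    three named sites, mimicking a three-mountain-region design.
    """
    ramp = mat_ramp(cfg)
    step = ramp[0] - ramp[1]
    olon, olat = cfg.grid_origin
    nrows, _ = cfg.grid_shape
    nod = set(lake_rows(cfg).tolist())
    home_row = next(r for r in range(nrows) if r not in nod)
    targets = np.linspace(cfg.mat_range[0], cfg.mat_range[1], cfg.n_plots)
    cols = np.clip(np.rint((ramp[0] - targets) / step).astype(int), 0, len(ramp) - 1)
    mats = ramp[cols]
    sites = [f"site{1 + i % 3}" for i in range(cfg.n_plots)]
    return pd.DataFrame(
        {
            "plot_id": [f"P{i:02d}" for i in range(cfg.n_plots)],
            "site": sites,
            "mat": mats,
            "map": np.full(cfg.n_plots, float(np.mean(cfg.map_range))),
            "lon": olon + (cols + 0.5) * cfg.cell_size,
            "lat": olat + (home_row + 0.5) * cfg.cell_size,
            "elevation": (SEA_LEVEL_MAT - mats) / LAPSE_RATE,
        }
    ).set_index("plot_id")


def _sample_heights(rng, plot_idx: int, diam: np.ndarray, n_measured: int):
    """True per-plot height-diameter relation and a measured subsample."""
    if plot_idx % 2 == 0:
        fam = "weibull"
        params = (rng.uniform(35.0, 50.0), rng.uniform(20.0, 40.0), rng.uniform(0.6, 1.0))
        a, b, c = params
        pred = lambda d: a * (1.0 - np.exp(-((d / b) ** c)))
    else:
        fam = "loglog"
        params = (rng.uniform(0.3, 0.7), rng.uniform(0.5, 0.7))
        a, b = params
        pred = lambda d: np.exp(a + b * np.log(d))
    n = diam.size
    k = min(n_measured, n)
    order = np.argsort(diam)
    chosen = order[np.linspace(0, n - 1, k).astype(int)]  # stratified by size
    h = pred(diam[chosen]) * np.exp(rng.normal(0.0, 0.05, k))
    return fam, tuple(float(p) for p in params), chosen, h


def simulate_census_series(
    cfg: SimulationConfig, seed: int
) -> tuple[list[CensusSeries], GroundTruth]:
    """Simulate every plot's stem-level census history.

    Returns the per-plot :class:`CensusSeries` (what a field campaign would
    deposit) and the :class:`GroundTruth` (true optima, realized per-plot
    stem-weighted index rates computed from the simulator's own event log,
    demographic counts, and the true height models).
    """
    pool = species_pool(cfg, seed)
    mu = pool["mu"].to_numpy()
    meta = plot_metadata(cfg)
    rng = np.random.default_rng([seed, 14])
    dates = np.asarray(cfg.census_dates, dtype=float)
    total_interval = dates[-1] - dates[0]
    diam_scale = cfg.init_diameter_scale * (3.0 if cfg.large_stem_preset else 1.0)

    series_list: list[CensusSeries] = []
    realized, death_counts, recruit_counts, height_truth = {}, {}, {}, {}

    for pi, (plot_id, prow) in enumerate(meta.iterrows()):
        matp = float(prow["mat"])
        suit = np.exp(-((matp - mu) ** 2) / (2.0 * cfg.niche_sd**2))
        p_init = suit / suit.sum()
        n0 = cfg.stems_per_plot
        sp = rng.choice(cfg.n_species, size=n0, p=p_init)
        diam = 10.0 + rng.exponential(diam_scale, n0)
        tag_counter = n0
        tags = np.array([f"{plot_id}T{i:05d}" for i in range(n0)])
        unid = rng.random(n0) < cfg.unidentified_fraction
        recorded = np.array(
            [pool.index[s] if not u else f"Indet sp{1 + s % 4}" for s, u in zip(sp, unid)]
        )

        recs: dict[str, list] = {k: [] for k in ("tag", "species", "ci", "date", "diam", "alive")}

        def record(tags_, names_, ci, date, diams_, alive_flag):
            recs["tag"].append(tags_)
            recs["species"].append(names_)
            recs["ci"].append(np.full(len(tags_), ci))
            recs["date"].append(np.full(len(tags_), date))
            recs["diam"].append(diams_)
            recs["alive"].append(np.full(len(tags_), alive_flag))

        record(tags, recorded, 0, dates[0], diam.copy(), True)
        first_sp = sp.copy()
        n_dead = n_rec = 0

        # recruitment species weights (fixed per plot)
        w_rec = suit * np.exp(cfg.recruit_bias * mu)
        w_rec = w_rec / w_rec.sum()
        logit_m0 = logit(cfg.annual_mortality) if cfg.annual_mortality > 0 else -np.inf

        for ci in range(1, len(dates)):
            T = dates[ci] - dates[ci - 1]
            if np.isfinite(logit_m0):
                p_ann = expit(logit_m0 - cfg.mortality_bias * (mu[sp] - matp))
                p_die = 1.0 - (1.0 - p_ann) ** T
                die = rng.random(sp.size) < p_die
            else:
                die = np.zeros(sp.size, dtype=bool)
            # record the newly dead at their last live diameter
            if die.any():
                record(tags[die], recorded[die], ci, dates[ci], diam[die].copy(), False)
            n_dead += int(die.sum())
            # survivors grow
            keep = ~die
            sp, tags, recorded, diam = sp[keep], tags[keep], recorded[keep], diam[keep]
            g_mean = cfg.growth_mean + cfg.growth_optimum_corr * (mu[sp] - matp)
            diam = diam + np.clip(rng.normal(g_mean * T, cfg.growth_sd * np.sqrt(T)), 0.0, None)
            # recruits
            k = rng.poisson(cfg.recruitment_rate * cfg.area_ha * T)
            if k:
                sp_new = rng.choice(cfg.n_species, size=k, p=w_rec)
                d_new = rng.uniform(10.0, 15.0, k)
                t_new = np.array([f"{plot_id}T{tag_counter + j:05d}" for j in range(k)])
                tag_counter += k
                u_new = rng.random(k) < cfg.unidentified_fraction
                r_new = np.array(
                    [pool.index[s] if not u else f"Indet sp{1 + s % 4}" for s, u in zip(sp_new, u_new)]
                )
                sp = np.concatenate([sp, sp_new])
                tags = np.concatenate([tags, t_new])
                recorded = np.concatenate([recorded, r_new])
                diam = np.concatenate([diam, d_new])
                n_rec += k
            record(tags, recorded, ci, dates[ci], diam.copy(), True)

        stems = pd.DataFrame(
            {
                "plot_id": plot_id,
                "tag": np.concatenate(recs["tag"]),
                "species": np.concatenate(recs["species"]),
                "census_index": np.concatenate(recs["ci"]).astype(int),
                "census_date": np.concatenate(recs["date"]),
                "diameter_cm": np.concatenate(recs["diam"]),
                "alive": np.concatenate(recs["alive"]),
                "height_m": np.nan,
            }
        )
        # measured heights on a size-stratified subsample at the last census
        fam, params, chosen, h = _sample_heights(rng, pi, diam, cfg.n_height_measured)
        height_truth[plot_id] = {"family": fam, "params": list(params)}
        last_mask = (stems["census_index"] == len(dates) - 1) & stems["alive"]
        last_idx = stems.index[last_mask]
        stems.loc[last_idx[chosen], "height_m"] = h

        series_list.append(
            CensusSeries(
                plot_id=str(plot_id),
                stems=stems,
                censuses=dates.copy(),
                elevation=float(prow["elevation"]),
                lon=float(prow["lon"]),
                lat=float(prow["lat"]),
            )
        )
        # realized stem-weighted index change from the event log (true optima)
        cti_first = float(mu[first_sp].mean())
        cti_last = float(mu[sp].mean())
        realized[plot_id] = (cti_last - cti_first) / total_interval
        death_counts[plot_id] = n_dead
        recruit_counts[plot_id] = n_rec

    truth = GroundTruth(
        mu=pool["mu"].copy(),
        niche_sd=cfg.niche_sd,
        recruit_bias=cfg.recruit_bias,
        mortality_bias=cfg.mortality_bias,
        climate_trend=cfg.climate_trend,
        plot_mat=meta["mat"].copy(),
        realized_rates_stem=pd.Series(realized, name="realized_rate"),
        deaths=pd.Series(death_counts, name="deaths"),
        recruits=pd.Series(recruit_counts, name="recruits"),
        height_models=height_truth,
    )
    return series_list, truth


def generate_annual_climate(cfg: SimulationConfig, seed: int) -> pd.DataFrame:
    """Annual MAT/MAP series per plot with the imposed warming trend."""
    meta = plot_metadata(cfg)
    rng = np.random.default_rng([seed, 15])
    years = np.arange(2010, 2020)
    rows = []
    for plot_id, prow in meta.iterrows():
        mat = (
            prow["mat"]
            + cfg.climate_trend * (years - years[0])
            + rng.normal(0.0, cfg.climate_noise_sd, years.size)
        )
        pr = prow["map"] + rng.normal(0.0, 40.0, years.size)
        for y, t, p in zip(years, mat, pr):
            rows.append({"plot_id": plot_id, "year": int(y), "mat": t, "map": p})
    return pd.DataFrame(rows)


def simulate_bundle(cfg: SimulationConfig, seed: int, outdir=None) -> dict:
    """Generate every pipeline input (and ground truth) in one call.

    When ``outdir`` is given, writes census.csv, occurrences.csv,
    mat_grid.txt, map_grid.txt, traits.csv, annual_climate.csv and
    ground_truth.json there.
    """
    grid_t, grid_p = generate_climate_grid(cfg)
    occ = generate_occurrences(cfg, seed)
    traits = generate_traits(cfg, seed)
    plots, truth = simulate_census_series(cfg, seed)
    climate = generate_annual_climate(cfg, seed)
    bundle = {
        "config": cfg,
        "grid_t": grid_t,
        "grid_p": grid_p,
        "occurrences": occ,
        "traits": traits,
        "plots": plots,
        "plot_meta": plot_metadata(cfg),
        "annual_climate": climate,
        "truth": truth,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_census_table(plots, outdir / "census.csv")
        write_occurrences(occ, outdir / "occurrences.csv")
        write_climate_grid(grid_t, outdir / "mat_grid.txt")
        write_climate_grid(grid_p, outdir / "map_grid.txt")
        write_traits(traits, outdir / "traits.csv")
        climate.to_csv(outdir / "annual_climate.csv", index=False)
        truth.to_json(outdir / "ground_truth.json")
    return bundle
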