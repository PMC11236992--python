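"""Validation experiments on synthetic data with known ground truth.

These are the package's core self-checks: does the occurrence-based optimum
estimator converge at the expected rate, does the full pipeline recover an
imposed thermophilization trend with unit slope, and is the plot-level
Wilcoxon test calibrated under the null?  They are used by the test suite,
the analysis drivers and the acceptance script alike.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats as st

from .community_index import mean_annual_rate
from .inference import wilcoxon_one_sample
from .synthetic_data import (
    SimulationConfig,
    generate_climate_grid,
    generate_occurrences,
    simulate_census_series,
    species_pool,
)
from .thermal_affiliation import build_affiliation_table, included_values

#: Scaled-down study used by the replicate experiments: fewer, smaller plots
#: and a smaller species pool than the headline configuration, but the same
#: gradient, niche width, census cadence and demographic rates.
SMALL_STUDY = SimulationConfig(
    n_plots=10,
    n_species=40,
    stems_per_plot=80,
    occ_fixed_count=60,
    n_height_measured=20,
)


def _derived_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def optimum_recovery(
    sizes=(5, 10, 30, 100),
    n_species: int = 80,
    niche_sd: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean absolute error of occurrence-based optima versus true optima.

    For each record count ``n`` an independent pool of ``n_species``
    synthetic species is generated with exactly ``n`` clean records each,
    optima estimated through the full clean/dedupe/extract/average path, and
    |t_opt - mu_s| summarized.  Returns a frame with columns
    ``n, mae, se, n_species``.
    """
    seeds = _derived_seeds(seed, len(sizes))
    rows = []
    for n, s in zip(sizes, seeds):
        cfg = SimulationConfig(
            n_plots=2,
            n_species=n_species,
            stems_per_plot=10,
            niche_sd=niche_sd,
            occ_fixed_count=int(n),
            occ_flagged_fraction=0.0,
            occ_nodata_fraction=0.0,
            mat_range=(13.0, 20.0),  # keep optima central in the ramp
            ramp_pad=10.0,
        )
        occ = generate_occurrences(cfg, int(s))
        grid_t, grid_p = generate_climate_grid(cfg)
        table = build_affiliation_table(occ, grid_t, grid_p, threshold=0)
        mu = species_pool(cfg, int(s))["mu"]
        err = (table["t_opt"] - mu).abs().dropna()
        rows.append(
            {
                "n": int(n),
                "mae": float(err.mean()),
                "se": float(err.std(ddof=1) / np.sqrt(err.size)),
                "n_species": int(err.size),
            }
        )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class RecoveryResult:
    slope: float
    intercept: float
    r2: float
    replicates: pd.DataFrame  # realized vs estimated trend per replicate


def thermophilization_recovery(
    biases=(0.0, 0.5, 1.0, 1.5, 2.0),
    reps_per_bias: int = 40,
    seed: int = 0,
    base_cfg: SimulationConfig = SMALL_STUDY,
    threshold: int = 10,
) -> RecoveryResult:
    """Regress pipeline-estimated trends on simulator-realized trends.

    Each replicate imposes one recruitment bias, simulates a study, computes
    the realized cross-plot stem-weighted index trend from the simulator's
    event log (true optima), and estimates the same trend through the full
    pipeline (occurrence records -> cleaned optima -> community index ->
    cross-plot mean annual rate).  An unbiased pipeline gives OLS slope 1.
    """
    grid_t, grid_p = generate_climate_grid(base_cfg)
    n = len(biases) * reps_per_bias
    seeds = _derived_seeds(seed, n)
    rows = []
    i = 0
    for b in biases:
        cfg = base_cfg.replace(recruit_bias=float(b))
        for _ in range(reps_per_bias):
            s = int(seeds[i])
            i += 1
            plots, truth = simulate_census_series(cfg, s)
            occ = generate_occurrences(cfg, s)
            table = build_affiliation_table(occ, grid_t, grid_p, threshold=threshold)
            est = mean_annual_rate(plots, included_values(table, "t_opt"), weighting="stem")
            rows.append(
                {"bias": float(b), "realized": truth.realized_trend_stem, "estimated": est}
            )
    df = pd.DataFrame(rows)
    fit = st.linregress(df["realized"], df["estimated"])
    return RecoveryResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        replicates=df,
    )


def null_calibration(
    reps: int = 500,
    seed: int = 0,
    base_cfg: SimulationConfig = SMALL_STUDY,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the plot-level Wilcoxon test under the demographic null.

    With zero recruitment and mortality bias, per-plot stem-weighted index
    rates are symmetric around zero; the one-sample Wilcoxon at level
    ``alpha`` should reject in ~alpha of replicate studies.  True optima are
    used as the attribute table so the calibration isolates the test from
    optimum-estimation noise.
    """
    cfg = base_cfg.replace(recruit_bias=0.0, mortality_bias=0.0)
    mu = species_pool(cfg, seed)["mu"]
    seeds = _derived_seeds(seed, reps)
    rejections = 0
    used = 0
    for s in seeds:
        plots, _ = simulate_census_series(cfg, int(s))
        rates = [
            mean_annual_rate([p], mu, weighting="stem") for p in plots
        ]
        rates = [r for r in rates if np.isfinite(r)]
        try:
            res = wilcoxon_one_sample(rates)
        except ValueError:
            continue
        used += 1
        if res.p_value <= alpha:
            rejections += 1
    return {
        "rejection_rate": rejections / used if used else float("nan"),
        "replicates": used,
        "alpha": alpha,
    }
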