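"""End-to-end orchestration: simulate-or-read, optima, indices, carbon, report.

A single configuration mapping (usually loaded from YAML) drives the whole
run.  It contains either a ``simulate`` block (keys of
:class:`~thermoshift.synthetic_data.SimulationConfig` plus ``seed``) or an
``inputs`` block with paths to census/occurrence/grid/trait files, plus
optional ``optima`` (threshold, since) and ``report`` (bootstrap reps, seed)
blocks.  All randomness flows from one root seed split per stage.

Every run writes CSV stage outputs, a ``report.json`` with every named
statistic, and a ``manifest.json`` recording the config hash, seeds, input
digests, per-stage row counts and output paths, so a rerun with the same
manifest inputs reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .carbon_dynamics import carbon_fluxes, fit_height_model, resolve_wood_density
from .community_index import (
    index_trajectory,
    jackknife_contributions,
    mean_annual_rate,
    partition_change,
    size_class_summary,
)
from .inference import (
    bootstrap_ci,
    climate_trend,
    cti_vs_mat_regression,
    intercept_only_t_test,
    kruskal_wallis,
    leave_one_out_wilcoxon,
    spearman,
    wilcoxon_one_sample,
)
from .io_formats import (
    read_census_table,
    read_climate_grid,
    read_occurrences,
    read_traits,
)
from .synthetic_data import SimulationConfig, simulate_bundle
from .thermal_affiliation import build_affiliation_table, included_values

log = logging.getLogger("thermoshift")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _stage_inputs(config: dict, outdir: Path, manifest: dict):
    """Simulate a bundle or read user-supplied files."""
    if "simulate" in config:
        sim = dict(config["simulate"])
        seed = int(sim.pop("seed", config.get("seed", 0)))
        cfg = SimulationConfig(**sim)
        bundle = simulate_bundle(cfg, seed, outdir=outdir / "inputs")
        manifest["seeds"]["simulate"] = seed
        plots = bundle["plots"]
        occ = bundle["occurrences"]
        grid_t, grid_p = bundle["grid_t"], bundle["grid_p"]
        traits = bundle["traits"]
        annual = bundle["annual_climate"]
        plot_meta = bundle["plot_meta"]
        manifest["stages"]["inputs"] = {
            "mode": "simulate",
            "n_plots": len(plots),
            "n_census_rows": int(sum(len(p.stems) for p in plots)),
            "n_occurrence_rows": int(len(occ)),
        }
        return plots, occ, grid_t, grid_p, traits, annual, plot_meta
    paths = config["inputs"]
    for key in ("census", "occurrences", "mat_grid", "map_grid"):
        if key not in paths:
            raise ValueError(f"inputs block missing '{key}'")
        p = Path(paths[key])
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
        manifest["input_digests"][key] = _digest(p)
    series_map, census_report = read_census_table(paths["census"])
    occ, occ_report = read_occurrences(paths["occurrences"])
    grid_t = read_climate_grid(paths["mat_grid"])
    grid_p = read_climate_grid(paths["map_grid"])
    traits = None
    if paths.get("traits"):
        traits, _ = read_traits(paths["traits"])
    annual = pd.read_csv(paths["annual_climate"]) if paths.get("annual_climate") else None
    plots = list(series_map.values())
    meta = pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in plots],
            "site": [config.get("sites", {}).get(p.plot_id, "site1") for p in plots],
            "lon": [p.lon for p in plots],
            "lat": [p.lat for p in plots],
            "elevation": [p.elevation for p in plots],
        }
    ).set_index("plot_id")
    meta["mat"] = grid_t.extract(meta["lon"].to_numpy(), meta["lat"].to_numpy())
    meta["map"] = grid_p.extract(meta["lon"].to_numpy(), meta["lat"].to_numpy())
    manifest["stages"]["inputs"] = {
        "mode": "read",
        "census": census_report.summary(),
        "occurrences": occ_report.summary(),
        "n_plots": len(plots),
    }
    return plots, occ, grid_t, grid_p, traits, annual, meta


def run_pipeline(config: dict, outdir) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "package_version": __version__,
        "seeds": {},
        "input_digests": {},
        "stages": {},
        "outputs": [],
    }

    def emit(frame: pd.DataFrame, name: str, index=True) -> None:
        path = outdir / name
        frame.to_csv(path, index=index)
        manifest["outputs"].append(name)
        log.info("wrote %s (%d rows)", name, len(frame))

    plots, occ, grid_t, grid_p, traits, annual, plot_meta = _stage_inputs(config, outdir, manifest)

    # ---- optima ----------------------------------------------------------
    opt_cfg = config.get("optima", {})
    threshold = opt_cfg.get("threshold", 10)
    since = opt_cfg.get("since")
    affiliations = build_affiliation_table(occ, grid_t, grid_p, threshold=threshold, since=since)
    emit(affiliations, "affiliations.csv")
    manifest["stages"]["optima"] = {
        "n_species": int(len(affiliations)),
        "n_included": int(affiliations["included"].sum()),
        "threshold": threshold,
    }
    t_opt = included_values(affiliations, "t_opt")
    p_opt = included_values(affiliations, "p_opt")

    # ---- community indices ----------------------------------------------
    traj_rows, part_rows = [], []
    for p in plots:
        for attr, vals in (("t_opt", t_opt), ("p_opt", p_opt)):
            for weighting in ("stem", "basal_area"):
                tr = index_trajectory(p, vals, weighting=weighting, attribute=attr)
                traj_rows.append(
                    {
                        "plot_id": p.plot_id,
                        "attribute": attr,
                        "weighting": weighting,
                        "annual_rate": tr.annual_rate,
                        "first": tr.values[0],
                        "last": tr.values[-1],
                        "coverage_first": tr.coverage[0],
                        **{f"rate_interval_{i}": r for i, r in enumerate(tr.interval_rates)},
                    }
                )
                pr = partition_change(p, vals, weighting=weighting, attribute=attr)
                ann = pr.annualized()
                part_rows.append(
                    {
                        "plot_id": p.plot_id,
                        "attribute": attr,
                        "weighting": weighting,
                        **{k: ann[k] for k in ("total", "recruitment", "mortality", "growth")},
                    }
                )
    trajectories = pd.DataFrame(traj_rows)
    partitions = pd.DataFrame(part_rows)
    emit(trajectories, "trajectories.csv", index=False)
    emit(partitions, "partition.csv", index=False)
    manifest["stages"]["indices"] = {"n_trajectories": len(trajectories)}

    jack = jackknife_contributions(plots, t_opt, weighting="stem")
    emit(jack, "jackknife.csv")
    size_rows = [size_class_summary(p, t_opt).assign(plot_id=p.plot_id) for p in plots]
    emit(pd.concat(size_rows), "size_classes.csv")

    # ---- carbon ----------------------------------------------------------
    carbon_summary = {}
    if traits is not None:
        all_species = sorted({s for p in plots for s in p.stems["species"].unique()})
        wd = resolve_wood_density(all_species, traits)["wood_density"]
        carbon_rows = []
        for p in plots:
            last = p.census(p.n_censuses - 1)
            measured = last[last["height_m"].notna()]
            hm = fit_height_model(measured["diameter_cm"], measured["height_m"], plot_id=p.plot_id)
            ledger = carbon_fluxes(p, wd, hm, area_ha=config.get("area_ha", 1.0))
            fl = ledger.mean_fluxes(corrected=True)
            flu = ledger.mean_fluxes(corrected=False)
            carbon_rows.append(
                {
                    "plot_id": p.plot_id,
                    "height_model": hm.family,
                    "stock_first": ledger.stocks[0],
                    "stock_last": ledger.stocks[-1],
                    **{k: v for k, v in fl.items()},
                    **{f"uncorrected_{k}": v for k, v in flu.items()},
                }
            )
        carbon = pd.DataFrame(carbon_rows).set_index("plot_id")
        emit(carbon, "carbon.csv")
        carbon_summary = {
            "net": float(carbon["net"].mean()),
            "gain_growth": float(carbon["gain_growth"].mean()),
            "gain_recruitment": float(carbon["gain_recruitment"].mean()),
            "loss_mortality": float(carbon["loss_mortality"].mean()),
        }
        manifest["stages"]["carbon"] = {"n_plots": len(carbon)}

    # ---- statistical report ---------------------------------------------
    rep_cfg = config.get("report", {})
    boot_seed = int(rep_cfg.get("seed", config.get("seed", 0)))
    reps = int(rep_cfg.get("bootstrap_reps", 1000))
    report: dict = {"threshold": threshold, "n_plots": len(plots)}

    def rates(attr, weighting):
        sel = trajectories[
            (trajectories["attribute"] == attr) & (trajectories["weighting"] == weighting)
        ]
        return sel.set_index("plot_id")["annual_rate"].dropna()

    for attr, tag in (("t_opt", "CTI"), ("p_opt", "CPI")):
        for weighting, wtag in (("stem", "stem"), ("basal_area", "ba")):
            r = rates(attr, weighting)
            key = f"{tag}_{wtag}"
            entry = {"mean_rate": float(r.mean()), "n": int(r.size)}
            try:
                w = wilcoxon_one_sample(r)
                entry.update({"wilcoxon_V": w.statistic, "wilcoxon_p": w.p_value})
            except ValueError:
                entry.update({"wilcoxon_V": float("nan"), "wilcoxon_p": float("nan")})
            boot = bootstrap_ci(r, reps=reps, seed=boot_seed)
            entry["bootstrap_CI"] = [boot.ci_low, boot.ci_high]
            tt = intercept_only_t_test(r)
            entry["t_test_CI"] = [tt.ci_low, tt.ci_high]
            report[key] = entry

    r_stem = rates("t_opt", "stem")
    report["mean_dCTI_stem"] = report["CTI_stem"]["mean_rate"]
    report["mean_dCTI_ba"] = report["CTI_ba"]["mean_rate"]
    report["wilcoxon_V"] = report["CTI_stem"]["wilcoxon_V"]
    report["wilcoxon_p"] = report["CTI_stem"]["wilcoxon_p"]
    report["bootstrap_CI"] = report["CTI_stem"]["bootstrap_CI"]
    report["leave_one_out_min_mean"] = float(
        leave_one_out_wilcoxon(r_stem, r_stem.index)["mean"].min()
    )

    # partition means (annualized, per weighting)
    part_means = {}
    for weighting in ("stem", "basal_area"):
        sel = partitions[(partitions["attribute"] == "t_opt") & (partitions["weighting"] == weighting)]
        part_means[weighting] = {
            k: float(sel[k].mean()) for k in ("total", "recruitment", "mortality", "growth")
        }
    report["partition"] = part_means

    # cross-sectional CTI ~ MAT
    first_cti = trajectories[
        (trajectories["attribute"] == "t_opt") & (trajectories["weighting"] == "stem")
    ].set_index("plot_id")["first"]
    mats = plot_meta.loc[first_cti.index, "mat"]
    if mats.nunique() > 1 and len(mats) >= 3:
        reg = cti_vs_mat_regression(first_cti.to_numpy(), mats.to_numpy())
        report["cti_vs_mat"] = {
            "slope": reg.statistic,
            "se": reg.extra["se"],
            "t": reg.extra["t"],
            "r2": reg.extra["r2"],
            "lag": reg.extra["lag"],
        }
        sp_res = spearman(mats.to_numpy(), first_cti.to_numpy())
        report["cti_vs_mat"]["spearman_r"] = sp_res.statistic

    # site comparison of rates
    if "site" in plot_meta.columns and plot_meta["site"].nunique() > 1:
        groups = [
            r_stem.loc[[p for p in grp.index if p in r_stem.index]].to_numpy()
            for _, grp in plot_meta.groupby("site")
        ]
        groups = [g for g in groups if g.size]
        if len(groups) > 1:
            kw_res = kruskal_wallis(groups)
            report["site_kruskal"] = {"H": kw_res.statistic, "p": kw_res.p_value}
            report["site_mean_rates"] = {
                site: float(r_stem.loc[[p for p in grp.index if p in r_stem.index]].mean())
                for site, grp in plot_meta.groupby("site")
            }

    # climate trends at plot locations
    if annual is not None:
        slopes_t, slopes_p = [], []
        for _, grp in annual.groupby("plot_id"):
            slopes_t.append(climate_trend(grp["year"], grp["mat"]).statistic)
            slopes_p.append(climate_trend(grp["year"], grp["map"]).statistic)
        report["climate_trend_mat"] = float(np.mean(slopes_t))
        report["climate_trend_map"] = float(np.mean(slopes_p))

    if carbon_summary:
        report["carbon"] = carbon_summary
        report["carbon_net"] = carbon_summary["net"]

    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=float))
    manifest["outputs"].append("report.json")
    manifest["stages"]["report"] = {"keys": sorted(report.keys())}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    manifest["outputs"].append("manifest.json")
    return manifest
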