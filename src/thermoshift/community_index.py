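"""Community-weighted indices, their change, and its demographic anatomy.

The community temperature index (CTI) of a plot census is the weighted mean
of the thermal optima of its living stems, weighted either equally per stem
(CTI_Stem) or by each stem's basal area (CTI_BA).  The same machinery serves
any species-level attribute: precipitation optimum (CPI), wood density, and
so on.  Stems whose species carries no attribute (excluded species,
genus/family-only determinations) are dropped and the weights renormalized
over the remainder; the covered fraction is reported as ``coverage``.

Change in an index between the first and last census is decomposed into
demographic components using four stem sets: Alive_F (alive at first
census), Alive_L (alive at last), and the survivors valued at first-census
sizes (Survive_F) and at last-census sizes (Survive_L).  Under stem
weighting the survivor index does not depend on size, and

    mortality    = I(Survive)  - I(Alive_F)
    recruitment  = I(Alive_L)  - I(Survive)

Under basal-area weighting the unique three-term chain that telescopes to
the total is used:

    mortality    = I(Survive_F) - I(Alive_F)
    growth       = I(Survive_L) - I(Survive_F)
    recruitment  = I(Alive_L)   - I(Survive_L)

so recruitment + mortality (+ growth) always equals the total change
exactly.  A literal two-term variant (mortality = Survive_L - Alive_F,
recruitment = Alive_L - Survive_F, which does not telescope under basal-area
weighting) is available behind ``literal_two_term=True`` for comparison.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CensusSeries

SIZE_CLASS_EDGES = [10.0, 30.0, 50.0, 70.0]
SIZE_CLASS_LABELS = ["10-30", "30-50", "50-70", ">=70"]


def basal_area(diameter) -> np.ndarray | float:
    """Cross-sectional stem area pi*(D/2)^2 in cm^2, for D in cm."""
    d = np.asarray(diameter, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    out = np.pi * (d / 2.0) ** 2
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass
class CommunityIndex:
    plot_id: str
    census_index: int
    weighting: str
    attribute: str
    value: float
    coverage: float
    n_stems: int


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Weighted mean over entries with a value; returns (mean, coverage)."""
    total = weights.sum()
    mask = ~np.isnan(values)
    if total == 0 or not mask.any():
        return float("nan"), 0.0
    covered = weights[mask].sum()
    return float(np.dot(values[mask], weights[mask]) / covered), float(covered / total)


def _stem_values_weights(
    stems: pd.DataFrame,
    attribute_values: Mapping[str, float] | pd.Series,
    weighting: str,
) -> tuple[np.ndarray, np.ndarray]:
    if not isinstance(attribute_values, pd.Series):
        attribute_values = pd.Series(attribute_values)
    vals = stems["species"].map(attribute_values).to_numpy(dtype=float)
    if weighting == "stem":
        w = np.ones(len(stems))
    elif weighting == "basal_area":
        w = np.pi * (stems["diameter_cm"].to_numpy(dtype=float) / 2.0) ** 2
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return vals, w


def community_index(
    stems: pd.DataFrame,
    attribute_values: Mapping[str, float] | pd.Series,
    weighting: str = "stem",
    attribute: str = "t_opt",
    plot_id: str = "",
    census_index: int = 0,
) -> CommunityIndex:
    """Weighted mean of a species attribute over one census's living stems.

    ``stems`` must already be the living stems of a single census.  Stems
    whose species is missing from ``attribute_values`` are dropped and
    weights renormalized; if no stem is covered the value is NaN with
    coverage 0.
    """
    alive = stems[stems["alive"]] if "alive" in stems.columns else stems
    vals, w = _stem_values_weights(alive, attribute_values, weighting)
    value, coverage = _weighted_mean(vals, w)
    if math.isnan(value):
        warnings.warn(
            f"no stem in plot {plot_id or '?'} census {census_index} carries attribute {attribute!r}"
        )
    return CommunityIndex(
        plot_id=plot_id,
        census_index=census_index,
        weighting=weighting,
        attribute=attribute,
        value=value,
        coverage=coverage,
        n_stems=int(len(alive)),
    )


@dataclasses.dataclass
class IndexTrajectory:
    plot_id: str
    weighting: str
    attribute: str
    dates: np.ndarray
    values: np.ndarray
    coverage: np.ndarray

    @property
    def annual_rate(self) -> float:
        """(last - first) / total interval; NaN if an endpoint is missing."""
        interval = float(self.dates[-1] - self.dates[0])
        if interval <= 0:
            raise ValueError("census interval must be positive")
        return float((self.values[-1] - self.values[0]) / interval)

    @property
    def interval_rates(self) -> np.ndarray:
        """Per-interval annualized changes (census 1->2, 2->3, ...)."""
        return np.diff(self.values) / np.diff(self.dates)


def index_trajectory(
    series: CensusSeries,
    attribute_values: Mapping[str, float] | pd.Series,
    weighting: str = "stem",
    attribute: str = "t_opt",
) -> IndexTrajectory:
    """Per-census index values and the endpoint-based annual rate of change."""
    if series.n_censuses < 2:
        raise ValueError(f"plot {series.plot_id}: need >= 2 censuses for a trajectory")
    values, cover = [], []
    for ci in range(series.n_censuses):
        idx = community_index(
            series.census(ci),
            attribute_values,
            weighting=weighting,
            attribute=attribute,
            plot_id=series.plot_id,
            census_index=ci,
        )
        values.append(idx.value)
        cover.append(idx.coverage)
    return IndexTrajectory(
        plot_id=series.plot_id,
        weighting=weighting,
        attribute=attribute,
        dates=np.asarray(series.censuses, dtype=float),
        values=np.array(values),
        coverage=np.array(cover),
    )


@dataclasses.dataclass
class PartitionResult:
    plot_id: str
    weighting: str
    attribute: str
    total: float
    recruitment: float
    mortality: float
    growth: float
    interval: float
    indices: dict[str, float]

    def annualized(self) -> dict[str, float]:
        return {
            k: getattr(self, k) / self.interval
            for k in ("total", "recruitment", "mortality", "growth")
        }


def _partition_sets(series: CensusSeries) -> dict[str, pd.DataFrame]:
    """The four stem sets of the demographic partition.

    Survivor species identity is taken from the first census when
    determinations conflict; recruits keep their last-census identity.
    """
    first_ci, last_ci = 0, series.n_censuses - 1
    f = series.census(first_ci).set_index("tag")
    l = series.census(last_ci).set_index("tag")
    surv_tags = f.index.intersection(l.index)
    surv_f = f.loc[surv_tags]
    surv_l = l.loc[surv_tags].copy()
    surv_l["species"] = surv_f["species"]  # harmonize identity to first census
    recruits = l.loc[l.index.difference(surv_tags)]
    alive_l = pd.concat([surv_l, recruits])
    return {"alive_f": f, "alive_l": alive_l, "survive_f": surv_f, "survive_l": surv_l}


def partition_change(
    series: CensusSeries,
    attribute_values: Mapping[str, float] | pd.Series,
    weighting: str = "stem",
    attribute: str = "t_opt",
    literal_two_term: bool = False,
) -> PartitionResult:
    """Decompose first-to-last index change into demographic components."""
    if series.n_censuses < 2:
        raise ValueError(f"plot {series.plot_id}: need >= 2 censuses to partition change")
    sets = _partition_sets(series)
    if len(sets["survive_f"]) == 0:
        warnings.warn(f"plot {series.plot_id}: no survivors; survivor index undefined")
    idx = {
        name: community_index(frame, attribute_values, weighting=weighting, attribute=attribute,
                              plot_id=series.plot_id).value
        for name, frame in sets.items()
    }
    total = idx["alive_l"] - idx["alive_f"]
    if literal_two_term:
        mortality = idx["survive_l"] - idx["alive_f"]
        recruitment = idx["alive_l"] - idx["survive_f"]
        growth = 0.0
    elif weighting == "stem":
        # survivor index is size-free; survive_f == survive_l by construction
        mortality = idx["survive_f"] - idx["alive_f"]
        recruitment = idx["alive_l"] - idx["survive_f"]
        growth = 0.0
    else:
        mortality = idx["survive_f"] - idx["alive_f"]
        growth = idx["survive_l"] - idx["survive_f"]
        recruitment = idx["alive_l"] - idx["survive_l"]
    return PartitionResult(
        plot_id=series.plot_id,
        weighting=weighting,
        attribute=attribute,
        total=total,
        recruitment=recruitment,
        mortality=mortality,
        growth=growth,
        interval=series.interval,
        indices=idx,
    )


def _endpoint_rate(
    series: CensusSeries,
    attribute_values: pd.Series,
    weighting: str,
    exclude_species: str | None = None,
) -> float:
    """Annual rate from endpoint censuses, optionally with one species removed."""
    first_ci, last_ci = 0, series.n_censuses - 1
    vals = []
    for ci in (first_ci, last_ci):
        stems = series.census(ci)
        if exclude_species is not None:
            stems = stems[stems["species"] != exclude_species]
        vals.append(community_index(stems, attribute_values, weighting=weighting).value)
    return (vals[1] - vals[0]) / series.interval


def mean_annual_rate(
    plots: Sequence[CensusSeries],
    attribute_values: pd.Series,
    weighting: str = "stem",
    exclude_species: str | None = None,
) -> float:
    """Unweighted cross-plot mean of per-plot endpoint annual rates.

    Plots whose rate is undefined (no covered stems at an endpoint) are
    dropped from the mean.
    """
    rates = [
        _endpoint_rate(p, attribute_values, weighting, exclude_species) for p in plots
    ]
    rates = [r for r in rates if not math.isnan(r)]
    if not rates:
        return float("nan")
    return float(np.mean(rates))


def signed_sqrt(x) -> np.ndarray | float:
    """sqrt of |x| with the original sign reapplied (monotone, sign-preserving)."""
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.sqrt(np.abs(x))
    return float(out) if out.ndim == 0 else out


def jackknife_contributions(
    plots: Sequence[CensusSeries],
    attribute_values: pd.Series,
    weighting: str = "stem",
    species: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-species contribution to the cross-plot mean index trend.

    Each species is removed in turn (its stems dropped entirely), the
    cross-plot mean annual rate recomputed, and the contribution formed as
    ``(rate_jackknife - rate_all) / rate_all``.  Negative contributions mark
    species that increase the trend (the trend weakens without them).
    Species absent from every plot contribute exactly 0.  Raises if the
    baseline trend is zero, where contributions are undefined.
    """
    base = mean_annual_rate(plots, attribute_values, weighting)
    if base == 0 or math.isnan(base):
        raise ValueError("baseline cross-plot trend is zero or undefined; contributions undefined")
    present: set[str] = set()
    for p in plots:
        present |= set(p.stems["species"].unique())
    if species is None:
        species = sorted(set(attribute_values.index) | present)
    rows = []
    for sp in species:
        if sp not in present:
            contrib = 0.0
            jack = base
        else:
            jack = mean_annual_rate(plots, attribute_values, weighting, exclude_species=sp)
            contrib = (jack - base) / base
        rows.append(
            {
                "species": sp,
                "rate_jackknife": jack,
                "contribution": contrib,
                "contribution_sqrt": signed_sqrt(contrib),
            }
        )
    out = pd.DataFrame(rows).set_index("species")
    out.attrs["rate_all"] = base
    return out


def size_class_summary(
    series: CensusSeries,
    attribute_values: pd.Series,
    attribute: str = "t_opt",
) -> pd.DataFrame:
    """Distribution of stem-level optima by diameter class at the first census.

    Classes are half-open on diameter: [10,30), [30,50), [50,70) and >=70 cm.
    Restricted to the first census so each stem enters once.  Empty classes
    are reported with n = 0.
    """
    stems = series.census(0)
    vals = stems["species"].map(attribute_values)
    cls = pd.cut(
        stems["diameter_cm"],
        bins=SIZE_CLASS_EDGES + [np.inf],
        labels=SIZE_CLASS_LABELS,
        right=False,
    )
    rows = []
    for label in SIZE_CLASS_LABELS:
        sel = vals[(cls == label).to_numpy()]
        known = sel.dropna()
        rows.append(
            {
                "size_class": label,
                "n_stems": int((cls == label).sum()),
                "n_with_attribute": int(known.size),
                "mean": float(known.mean()) if known.size else float("nan"),
                "sd": float(known.std(ddof=1)) if known.size > 1 else float("nan"),
            }
        )
    out = pd.DataFrame(rows).set_index("size_class")
    out.attrs["attribute"] = attribute
    out.attrs["plot_id"] = series.plot_id
    return out
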