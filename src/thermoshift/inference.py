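"""Statistical layer: location tests, bootstrap CIs, correlations, trends.

The one-sample Wilcoxon signed-rank test is implemented in-package because
the exact null distribution matters for the small plot counts this kind of
study works with: for n <= 25 (after dropping exact zeros, the standard
signed-rank convention) the null distribution of V — the sum of the ranks of
positive values — is built by generating-function convolution over the
observed (mid)ranks, giving the exact permutation p-value even with ties;
larger samples use the normal approximation with tie correction and a
continuity correction.

Everything else delegates to scipy/statsmodels: Spearman rank correlation
(midrank ties), Kruskal-Wallis with tie correction, OLS slopes for climate
trends, and the cross-sectional CTI-versus-MAT regression.  Confidence
intervals of mean changes use percentile bootstrap (sampling with
replacement), seed-deterministic.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

EXACT_WILCOXON_MAX_N = 25


@dataclasses.dataclass
class TrendTestResult:
    name: str  # statistic name: V, t, H, r_s, slope
    statistic: float
    p_value: float
    n: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    seed: int | None = None
    extra: dict = dataclasses.field(default_factory=dict)


def _signed_rank_exact_sf(ranks2: np.ndarray, w2: int) -> tuple[float, float]:
    """P(W <= w) and P(W >= w) for W = sum of a uniformly random sign subset.

    ``ranks2`` are the (mid)ranks doubled to integers; ``w2`` the doubled
    observed statistic.  Exact convolution of the generating function
    prod_i (1 + x^r_i) over 2^n equally likely sign assignments.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    le = float(counts[: w2 + 1].sum())
    ge = float(counts[w2:].sum())
    return le, ge


def wilcoxon_one_sample(values, mu: float = 0.0) -> TrendTestResult:
    """One-sample Wilcoxon signed-rank test against location ``mu``.

    Returns V (sum of positive ranks, the R convention) and the two-sided
    p-value: exact for n <= 25 non-zero values, normal approximation with
    tie and continuity corrections otherwise.  Exact zeros are dropped
    before ranking; an all-zero sample is undefined.
    """
    v = np.asarray(values, dtype=float) - mu
    v = v[v != 0.0]
    n = v.size
    if n == 0:
        raise ValueError("all values equal the hypothesized location; test undefined")
    ranks = st.rankdata(np.abs(v))
    V = float(ranks[v > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        ranks2 = np.rint(ranks * 2).astype(int)
        w2 = int(round(V * 2))
        le, ge = _signed_rank_exact_sf(ranks2, w2)
        p = min(1.0, 2.0 * min(le, ge))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (V - mean - 0.5 * np.sign(V - mean)) / math.sqrt(var)
        p = float(2.0 * st.norm.sf(abs(z)))
        method = "normal-approx"
    return TrendTestResult(name="V", statistic=V, p_value=p, n=n, extra={"method": method})


def bootstrap_ci(
    values,
    statistic=np.mean,
    reps: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> TrendTestResult:
    """Percentile bootstrap CI of a statistic (default: the mean).

    ``reps`` resamples with replacement; bounds are the (1-level)/2 and
    1-(1-level)/2 percentiles of the resampled statistic.  Deterministic
    under a fixed seed.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("bootstrap needs at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(reps, v.size))
    stats = np.apply_along_axis(statistic, 1, v[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return TrendTestResult(
        name="bootstrap",
        statistic=float(statistic(v)),
        p_value=float("nan"),
        n=int(v.size),
        ci_low=float(lo),
        ci_high=float(hi),
        seed=seed,
        extra={"reps": reps, "level": level},
    )


def spearman(x, y) -> TrendTestResult:
    """Spearman rank correlation (midrank ties) with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("spearman needs >= 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    r, p = st.spearmanr(x, y)
    return TrendTestResult(name="r_s", statistic=float(r), p_value=float(p), n=int(x.size))


def kruskal_wallis(groups) -> TrendTestResult:
    """Kruskal-Wallis H (tie-corrected) with chi-square p on k-1 df.

    All observations identical across groups gives H = 0, p = 1 by
    convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n = pooled.size
    if np.all(pooled == pooled[0]):
        return TrendTestResult(name="H", statistic=0.0, p_value=1.0, n=int(n))
    h, p = st.kruskal(*groups)
    return TrendTestResult(name="H", statistic=float(h), p_value=float(p), n=int(n))


def climate_trend(years, values) -> TrendTestResult:
    """OLS slope of an annual climate series on year (degC/y or mm/y)."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.size < 3:
        raise ValueError("climate trend needs >= 3 annual values")
    res = st.linregress(years, values)
    return TrendTestResult(
        name="slope",
        statistic=float(res.slope),
        p_value=float(res.pvalue),
        n=int(years.size),
        extra={"intercept": float(res.intercept), "stderr": float(res.stderr)},
    )


def cti_vs_mat_regression(cti, mat) -> TrendTestResult:
    """Cross-sectional OLS of plot CTI on plot MAT.

    Reports slope, SE, t, df, R^2, and a ``lag`` flag set when the slope is
    below 1 — community composition tracking less than one-for-one with the
    temperature gradient.
    """
    cti = np.asarray(cti, dtype=float)
    mat = np.asarray(mat, dtype=float)
    if cti.size < 3:
        raise ValueError("regression needs >= 3 plots")
    if np.all(mat == mat[0]):
        raise ValueError("MAT is constant across plots; slope undefined")
    model = sm.OLS(cti, sm.add_constant(mat)).fit()
    slope = float(model.params[1])
    return TrendTestResult(
        name="slope",
        statistic=slope,
        p_value=float(model.pvalues[1]),
        n=int(cti.size),
        extra={
            "se": float(model.bse[1]),
            "t": float(model.tvalues[1]),
            "df": int(model.df_resid),
            "r2": float(model.rsquared),
            "intercept": float(model.params[0]),
            "lag": slope < 1.0,
        },
    )


def intercept_only_t_test(values) -> TrendTestResult:
    """Intercept-only linear model: the one-sample t-test cross-check."""
    v = np.asarray(values, dtype=float)
    model = sm.OLS(v, np.ones((v.size, 1))).fit()
    ci = model.conf_int()[0]
    return TrendTestResult(
        name="t",
        statistic=float(model.tvalues[0]),
        p_value=float(model.pvalues[0]),
        n=int(v.size),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        extra={"mean": float(model.params[0])},
    )


def leave_one_out_wilcoxon(values, labels=None) -> pd.DataFrame:
    """Re-run the one-sample Wilcoxon dropping each observation in turn.

    The robustness loop behind "the effect remains when any individual plot
    is removed".
    """
    v = np.asarray(values, dtype=float)
    labels = list(labels) if labels is not None else list(range(v.size))
    rows = []
    for i, lab in enumerate(labels):
        rest = np.delete(v, i)
        res = wilcoxon_one_sample(rest)
        rows.append(
            {"left_out": lab, "mean": float(rest.mean()), "V": res.statistic, "p": res.p_value}
        )
    return pd.DataFrame(rows).set_index("left_out")
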