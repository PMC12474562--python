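"""Run-timing descriptors, multi-year trends, and modality from daily counts.

Daily counts are long-form tables with columns population, year, doy,
size_class, count. Size classes are always pooled (small and large returns
show the same seasonal pattern, so counts are summed per day), and the
percentile descriptors operate on the cumulative count fraction over
day-of-year: *early* is the day by which 5% of all counted fish have entered
the river, *late* the day by which 95% have.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

log = logging.getLogger(__name__)

COUNT_COLUMNS = ["population", "year", "doy", "size_class", "count"]


class EmptyCountsError(ValueError):
    """Raised when a descriptor is requested for data with zero total count."""


@dataclass
class RunTimingSummary:
    population: str
    early_doy: int
    median_doy: int
    late_doy: int
    se_early: float  # nan when undefined (single year)
    se_late: float
    modality: str
    n_years: int


@dataclass
class TrendFit:
    slopes: pd.Series  # days/year per population
    intercepts: pd.Series
    slope_p: pd.Series
    interaction_F: float
    interaction_p: float
    latitude_correlation: float
    latitude_correlation_p: float


def _validate(counts: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing columns {missing}")
    if (counts["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    return counts


def pool_daily(counts: pd.DataFrame) -> pd.Series:
    """Total count per DOY, summed over years and size classes."""
    _validate(counts)
    return counts.groupby("doy")["count"].sum().sort_index()


def percentile_day(counts: pd.DataFrame, q: float) -> int:
    """Smallest DOY at which the cumulative count fraction reaches q.

    Pooling sums counts per day across all years and both size classes; no
    interpolation (counts are integers per day, descriptors are integer days).
    q = 0 maps to the first day with a positive count.
    """
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    daily = pool_daily(counts)
    daily = daily[daily > 0]
    total = daily.sum()
    if total == 0:
        raise EmptyCountsError("total count is zero")
    cumfrac = daily.cumsum() / total
    return int(cumfrac.index[np.searchsorted(cumfrac.to_numpy(), max(q, 1e-12))])


def run_year_median(counts: pd.DataFrame, population: str, year: int) -> int:
    """Median run date (DOY at which half the year's counted fish have entered)."""
    sub = counts[(counts["population"] == population) & (counts["year"] == year)]
    return percentile_day(sub, 0.5)


def yearly_medians(counts: pd.DataFrame) -> pd.DataFrame:
    """Median DOY per (population, year); zero-count years dropped with a warning."""
    _validate(counts)
    rows = []
    for (pop, year), sub in counts.groupby(["population", "year"]):
        if sub["count"].sum() == 0:
            log.warning("dropping %s year %s: zero total count", pop, year)
            continue
        rows.append((pop, year, percentile_day(sub, 0.5)))
    return pd.DataFrame(rows, columns=["population", "year", "median_doy"])


def classify_modality(counts: pd.DataFrame, bandwidth_days: float = 7.0,
                      prominence_frac: float = 0.2) -> str:
    """'single' vs 'multiple' seasonal peaks in the mean daily count curve.

    The mean count per DOY (averaged over years) is smoothed with a Gaussian
    kernel (default 7-day bandwidth); local maxima with prominence >= 20% of
    the global maximum count as peaks.
    """
    _validate(counts)
    per_day = counts.groupby("doy")["count"].sum()
    n_years = max(counts["year"].nunique(), 1)
    grid = np.arange(per_day.index.min(), per_day.index.max() + 1)
    mean_daily = per_day.reindex(grid, fill_value=0).to_numpy() / n_years
    smooth = gaussian_filter1d(mean_daily.astype(float), sigma=bandwidth_days)
    peaks, _ = find_peaks(smooth, prominence=prominence_frac * smooth.max())
    return "multiple" if len(peaks) >= 2 else "single"


def summarize_population(counts: pd.DataFrame, population: str,
                         n_boot: int = 1000, seed: int = 0) -> RunTimingSummary:
    """Pooled early/median/late descriptors with bootstrap-over-years SEs.

    SEs come from a nonparametric bootstrap resampling whole years with
    replacement (seeded); with a single contributing year they are ``nan``.
    """
    sub = _validate(counts)[counts["population"] == population]
    years = [y for y, s in sub.groupby("year") if s["count"].sum() > 0]
    if not years:
        raise EmptyCountsError(f"no non-zero count years for {population}")
    sub = sub[sub["year"].isin(years)]
    early = percentile_day(sub, 0.05)
    median = percentile_day(sub, 0.5)
    late = percentile_day(sub, 0.95)
    if len(years) > 1 and n_boot > 0:
        rng = np.random.default_rng(seed)
        by_year = {y: s for y, s in sub.groupby("year")}
        boots_e, boots_l = [], []
        for _ in range(n_boot):
            pick = rng.choice(years, size=len(years), replace=True)
            resampled = pd.concat([by_year[y] for y in pick])
            boots_e.append(percentile_day(resampled, 0.05))
            boots_l.append(percentile_day(resampled, 0.95))
        se_early, se_late = float(np.std(boots_e, ddof=1)), float(np.std(boots_l, ddof=1))
    else:
        se_early = se_late = float("nan")
    return RunTimingSummary(
        population=population, early_doy=early, median_doy=median, late_doy=late,
        se_early=se_early, se_late=se_late,
        modality=classify_modality(sub), n_years=len(years),
    )


def summarize_all(counts: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    rows = []
    for pop in pd.unique(counts["population"]):
        s = summarize_population(counts, pop, n_boot=n_boot, seed=seed)
        rows.append(vars(s))
    return pd.DataFrame(rows).set_index("population")


def fit_trends(medians: pd.DataFrame, latitudes: dict[str, float] | pd.Series) -> TrendFit:
    """OLS of median_doy ~ Year * Site with a Type II ANOVA interaction test.

    Per-population slopes and their p-values come from linear contrasts of the
    full interaction model (slope_p = beta_year + beta_{year:pop}); the
    latitude correlation is Pearson's r between slopes and population latitude.
    """
    medians = medians.copy()
    pops = sorted(medians["population"].unique())
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    if (medians.groupby("population")["year"].nunique() < 3).any():
        raise ValueError("need >= 3 years per population")
    medians["year_c"] = medians["year"] - medians["year"].mean()
    model = smf.ols("median_doy ~ year_c * C(population)", data=medians)
    try:
        fit = model.fit()
    except np.linalg.LinAlgError as e:  # pragma: no cover - defensive
        raise ValueError(f"rank-deficient design (year x population): {e}") from e
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("rank-deficient design: year_c:C(population) collinear")
    anova = sm.stats.anova_lm(fit, typ=2)
    inter = anova.loc["year_c:C(population)"]

    names = list(fit.params.index)
    slopes, slope_p, intercepts = {}, {}, {}
    for pop in pops:
        contrast = np.zeros(len(names))
        contrast[names.index("year_c")] = 1.0
        iname = f"year_c:C(population)[T.{pop}]"
        if iname in names:
            contrast[names.index(iname)] = 1.0
        t = fit.t_test(contrast)
        slopes[pop] = float(np.atleast_1d(t.effect)[0])
        slope_p[pop] = float(np.atleast_1d(t.pvalue.ravel())[0])
        mname = f"C(population)[T.{pop}]"
        intercepts[pop] = float(
            fit.params["Intercept"] + (fit.params[mname] if mname in names else 0.0)
        )
    slopes = pd.Series(slopes)
    lat = pd.Series(dict(latitudes)).reindex(slopes.index)
    r, rp = stats.pearsonr(slopes.to_numpy(), lat.to_numpy())
    return TrendFit(
        slopes=slopes,
        intercepts=pd.Series(intercepts),
        slope_p=pd.Series(slope_p),
        interaction_F=float(inter["F"]),
        interaction_p=float(inter["PR(>F)"]),
        latitude_correlation=float(r),
        latitude_correlation_p=float(rp),
    )
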