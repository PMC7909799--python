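"""Climate response screening and climate-vs-defoliation linear models.

The site chronology I_t (double-detrended growth index) is modelled from
monthly weather and a defoliation indicator:

* weather-only model:      I_t = Σ a_i·W_it + C
* weather + outbreak model: I_t = Σ a_i·W_it + b·O_t + C

where W_it are monthly mean temperature and precipitation sums from
January of the previous year to September of the growth year (21 months ×
2 = 42 candidates), and O_t is 1 in the years carrying defoliation
after-effects (default: lags +1 and +2 after each event year).  Candidate
months are screened with a bootstrapped response function (regression of
the chronology on the principal components of the standardised monthly
matrix, coefficients back-transformed; a variable is significant when its
bootstrap 95% interval excludes 0).  Final predictors are chosen by
backward stepwise elimination on AIC; the dummy is never eligible for
elimination.  The added value of the dummy is tested by refitting both
models on linked bootstrap resamples and comparing the paired adjusted R²
values with Friedman's rank test.

Superposed epoch analysis (SEA) averages the chronology at fixed lags
around the event years and assesses each lag against random pseudo-event
draws.

Variable naming follows the dendroclimatology convention: ``Tjan`` is the
previous year's January temperature (lowercase month), ``TJUL`` the growth
year's July temperature (uppercase month); ``P`` prefixes precipitation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .series import IndexSeries

logger = logging.getLogger(__name__)

_MONTHS = ["jan", "feb", "mar", "apr", "may", "jun",
           "jul", "aug", "sep", "oct", "nov", "dec"]


def month_variable_names() -> list[str]:
    """The 42 candidate names, previous-Jan .. current-Sep, T then P."""
    names = []
    for prefix in ("T", "P"):
        names += [prefix + m for m in _MONTHS]            # previous year
        names += [prefix + m.upper() for m in _MONTHS[:9]]  # current year
    return names


def monthly_design(climate: pd.DataFrame, years) -> pd.DataFrame:
    """Monthly predictor matrix for the given growth years.

    Row ``y`` holds the previous year's 12 months and the growth year's
    January–September, for temperature and precipitation.
    """
    piv_t = climate.pivot(index="year", columns="month", values="temperature")
    piv_p = climate.pivot(index="year", columns="month", values="precipitation")
    rows = {}
    for y in years:
        if y - 1 not in piv_t.index or y not in piv_t.index:
            continue
        row = {}
        for prefix, piv in (("T", piv_t), ("P", piv_p)):
            for m in range(1, 13):
                row[prefix + _MONTHS[m - 1]] = piv.loc[y - 1, m]
            for m in range(1, 10):
                row[prefix + _MONTHS[m - 1].upper()] = piv.loc[y, m]
        rows[y] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    return out[month_variable_names()]


@dataclass
class DefoliationDummy:
    """Indicator O_t of defoliation after-effects.

    ``effect_lags`` lists the lags (years after each event) at which
    O_t = 1; the default {+1, +2} matches the two-year growth suppression
    seen in superposed epoch analysis.
    """

    event_years: list[int]
    effect_lags: tuple[int, ...] = (1, 2)

    def indicator(self, years) -> np.ndarray:
        years = np.asarray(years, dtype=int)
        hot = {e + lag for e in self.event_years for lag in self.effect_lags}
        return np.array([1.0 if y in hot else 0.0 for y in years])


@dataclass
class ModelFit:
    """A fitted linear model: predictors, dummy, intercept and scores."""

    predictors: list[tuple[str, float]]
    intercept: float
    r2adj: float
    aic: float
    dummy_coefficient: float | None = None
    dummy_ci: tuple[float, float] | None = None
    n_obs: int = 0
    residual_sd: float = field(default=float("nan"))


# ---------------------------------------------------------------------------
# response-function screening

def _pc_regression_coefs(xz: np.ndarray, yz: np.ndarray, var_keep: float = 0.9,
                         max_frac: float = 1 / 3) -> np.ndarray:
    """Back-transformed PCA-regression coefficients in standardised space."""
    n, p = xz.shape
    u, s, vt = np.linalg.svd(xz, full_matrices=False)
    var = s**2
    if var.sum() == 0:
        return np.zeros(p)
    cum = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(cum, var_keep) + 1)
    k = max(1, min(k, int(np.ceil(n * max_frac)), len(s)))
    nz = s[:k] > 1e-12
    scores = u[:, :k] * s[:k]
    gamma = np.zeros(k)
    gamma[nz] = (u[:, :k][:, nz].T @ yz) / s[:k][nz]
    del scores
    return vt[:k].T @ gamma


def response_screen(
    chronology: IndexSeries,
    climate: pd.DataFrame,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Bootstrapped response-function screening of the 42 monthly variables.

    Returns the significant variable names and a table with the median
    coefficient and the bootstrap percentile interval per variable.
    """
    years = [
        y for y in chronology.years
        if np.isfinite(chronology.value_at(y))
    ]
    design = monthly_design(climate, years)
    years = [y for y in years if y in design.index]
    if len(years) < 30:
        raise ValueError("chronology and climate must overlap >= 30 years")
    design = design.loc[years]
    y = np.array([chronology.value_at(yy) for yy in years])
    keep = design.std(ddof=1) > 0
    if not keep.all():
        dropped = list(design.columns[~keep])
        logger.warning("zero-variance climate variables excluded: %s", dropped)
        design = design.loc[:, keep]
    x = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.corrcoef(x, rowvar=False)) < 2:
        raise ValueError("climate matrix is degenerate")
    rng = np.random.default_rng(seed)
    n = len(years)
    coefs = np.empty((n_boot, x.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        xsd = xb.std(axis=0, ddof=1)
        ysd = yb.std(ddof=1)
        if ysd == 0 or (xsd == 0).any():
            coefs[b] = 0.0
            continue
        xz = (xb - xb.mean(axis=0)) / xsd
        yz = (yb - yb.mean()) / ysd
        coefs[b] = _pc_regression_coefs(xz, yz)
    lo = np.percentile(coefs, 100 * alpha / 2, axis=0)
    hi = np.percentile(coefs, 100 * (1 - alpha / 2), axis=0)
    med = np.median(coefs, axis=0)
    table = pd.DataFrame(
        {"coef": med, "ci_low": lo, "ci_high": hi},
        index=design.columns,
    )
    table["significant"] = (table["ci_low"] > 0) | (table["ci_high"] < 0)
    significant = list(table.index[table["significant"]])
    return significant, table


# ---------------------------------------------------------------------------
# linear models

def _exog(x: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    if cols:
        return sm.add_constant(x[cols])
    return pd.DataFrame({"const": np.ones(len(x))}, index=x.index)


def _backward_aic(y: np.ndarray, x: pd.DataFrame, locked: list[str]) -> sm.regression.linear_model.RegressionResultsWrapper:
    """Backward stepwise elimination by AIC; ``locked`` columns stay."""
    cols = list(x.columns)
    model = sm.OLS(y, _exog(x, cols)).fit()
    while True:
        candidates = [c for c in cols if c not in locked]
        if not candidates:
            break
        best_aic, best_col = model.aic, None
        for c in candidates:
            trial = [col for col in cols if col != c]
            m = sm.OLS(y, _exog(x, trial)).fit()
            if m.aic < best_aic:
                best_aic, best_col = m.aic, c
        if best_col is None:
            break
        cols.remove(best_col)
        model = sm.OLS(y, _exog(x, cols)).fit()
    return model


def _to_modelfit(res, dummy_name: str | None) -> ModelFit:
    params = res.params
    names = [n for n in params.index if n not in ("const", dummy_name)]
    dummy_coef = dummy_ci = None
    if dummy_name is not None and dummy_name in params.index:
        dummy_coef = float(params[dummy_name])
        ci = res.conf_int().loc[dummy_name]
        dummy_ci = (float(ci[0]), float(ci[1]))
    return ModelFit(
        predictors=[(n, float(params[n])) for n in names],
        intercept=float(params.get("const", 0.0)),
        r2adj=float(res.rsquared_adj),
        aic=float(res.aic),
        dummy_coefficient=dummy_coef,
        dummy_ci=dummy_ci,
        n_obs=int(res.nobs),
        residual_sd=float(np.sqrt(res.mse_resid)),
    )


def fit_models(
    chronology: IndexSeries,
    climate: pd.DataFrame,
    selected_vars: list[str],
    dummy: DefoliationDummy,
    stepwise: bool = True,
) -> tuple[ModelFit, ModelFit]:
    """Fit the weather-only and weather+defoliation models.

    Both models undergo independent backward AIC elimination over the
    screened climate variables; the defoliation indicator is locked into
    the second model.
    """
    years = [y for y in chronology.years if np.isfinite(chronology.value_at(y))]
    design = monthly_design(climate, years)
    years = [y for y in years if y in design.index]
    x = design.loc[years, selected_vars].astype(float)
    if len(years) < 5 * max(1, len(selected_vars)):
        raise ValueError("need >= 5 observations per candidate predictor")
    y = np.array([chronology.value_at(yy) for yy in years])
    o = dummy.indicator(years)
    if stepwise:
        res2 = _backward_aic(y, x, locked=[])
        x3 = x.copy()
        x3["O"] = o
        res3 = _backward_aic(y, x3, locked=["O"])
    else:
        res2 = sm.OLS(y, sm.add_constant(x)).fit()
        x3 = x.copy()
        x3["O"] = o
        res3 = sm.OLS(y, sm.add_constant(x3)).fit()
    return _to_modelfit(res2, None), _to_modelfit(res3, "O")


def friedman_test(*samples) -> tuple[float, float]:
    """Friedman rank test over k ≥ 2 linked samples.

    Returns (chi-square statistic, p).  Implemented directly so that the
    two-sample case (two linked bootstrap R² series) is supported; agrees
    with scipy.stats.friedmanchisquare for k ≥ 3.
    """
    k = len(samples)
    if k < 2:
        raise ValueError("need at least two linked samples")
    data = np.column_stack([np.asarray(s, dtype=float) for s in samples])
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least two blocks")
    ranks = np.apply_along_axis(scipy.stats.rankdata, 1, data)
    rj = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)
    # tie correction within blocks
    ties = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts**3 - counts)
    denom = 1.0 - ties / (n * k * (k**2 - 1))
    if denom > 0:
        stat /= denom
    p = float(scipy.stats.chi2.sf(stat, k - 1))
    return float(stat), p


def bootstrap_r2_compare(
    chronology: IndexSeries,
    climate: pd.DataFrame,
    selected_vars: list[str],
    dummy: DefoliationDummy,
    n_boot: int = 100,
    seed: int = 0,
) -> dict:
    """Friedman comparison of linked bootstrap adjusted-R² samples.

    Each bootstrap resample of the years refits both models (coefficients
    only; the predictor sets are fixed).  A resample in which the dummy
    has zero variance reuses the weather-only fit for both models and is
    counted in ``n_degenerate``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2 for the rank test")
    years = [y for y in chronology.years if np.isfinite(chronology.value_at(y))]
    design = monthly_design(climate, years)
    years = [y for y in years if y in design.index]
    x = design.loc[years, selected_vars].to_numpy(dtype=float)
    y = np.array([chronology.value_at(yy) for yy in years])
    o = dummy.indicator(years)
    rng = np.random.default_rng(seed)
    n = len(years)
    r2_weather = np.empty(n_boot)
    r2_dummy = np.empty(n_boot)
    n_degenerate = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb, ob = x[idx], y[idx], o[idx]
        res2 = sm.OLS(yb, sm.add_constant(xb)).fit()
        r2_weather[b] = res2.rsquared_adj
        if ob.std() == 0:
            n_degenerate += 1
            r2_dummy[b] = res2.rsquared_adj
        else:
            res3 = sm.OLS(yb, sm.add_constant(np.column_stack([xb, ob]))).fit()
            r2_dummy[b] = res3.rsquared_adj
    stat, p = friedman_test(r2_weather, r2_dummy)
    return {
        "r2adj_weather": r2_weather,
        "r2adj_dummy": r2_dummy,
        "friedman_stat": stat,
        "friedman_p": p,
        "n_degenerate": n_degenerate,
    }


# ---------------------------------------------------------------------------
# superposed epoch analysis

def sea(
    chronology: IndexSeries,
    event_years,
    lags: range = range(-3, 6),
    n_draws: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Superposed epoch analysis of the chronology around event years.

    The mean departure from the chronology mean is computed at each lag
    across events; significance compares the observed mean against
    ``n_draws`` random pseudo-event sets of the same size (two-sided
    percentile test).
    """
    events = sorted(int(y) for y in event_years)
    if len(events) < 3:
        raise ValueError("SEA requires at least 3 events")
    years = chronology.years
    vals = chronology.values
    finite = np.isfinite(vals)
    base = vals[finite].mean()
    dep = vals - base

    def lag_means(evs):
        out = np.full(len(lags), np.nan)
        for i, lag in enumerate(lags):
            acc = [
                dep[e + lag - chronology.first_year]
                for e in evs
                if chronology.first_year <= e + lag <= chronology.last_year
                and np.isfinite(dep[e + lag - chronology.first_year])
            ]
            if acc:
                out[i] = np.mean(acc)
        return out

    obs = lag_means(events)
    usable = sum(
        1 for e in events
        if chronology.first_year <= e <= chronology.last_year
    )
    if usable < 3:
        raise ValueError("fewer than 3 events fall inside the chronology span")
    rng_gen = np.random.default_rng(seed)
    pool = years[finite]
    null = np.empty((n_draws, len(lags)))
    for d in range(n_draws):
        draw = rng_gen.choice(pool, size=len(events), replace=False)
        null[d] = lag_means(draw)
    p = np.empty(len(lags))
    for i in range(len(lags)):
        col = null[:, i]
        col = col[np.isfinite(col)]
        if not np.isfinite(obs[i]) or col.size == 0:
            p[i] = np.nan
            continue
        lo = (col <= obs[i]).mean()
        hi = (col >= obs[i]).mean()
        p[i] = min(1.0, 2.0 * min(lo, hi))
    return pd.DataFrame(
        {
            "lag": list(lags),
            "mean_departure": obs,
            "p": p,
            "significant": p < alpha,
        }
    )


class ClimateDefoliationModel(BaseEstimator):
    """End-to-end climate/defoliation modelling as an estimator.

    ``fit(chronology, climate, event_years)`` screens the monthly
    variables, fits both linear models and runs the bootstrap comparison.
    Fitted attributes: ``selected_vars_``, ``weather_fit_``, ``dummy_fit_``,
    ``friedman_p_``, ``screen_table_``.
    """

    def __init__(
        self,
        effect_lags: tuple[int, ...] = (1, 2),
        screen_n_boot: int = 1000,
        compare_n_boot: int = 100,
        alpha: float = 0.05,
        seed: int = 0,
        stepwise: bool = True,
    ):
        self.effect_lags = effect_lags
        self.screen_n_boot = screen_n_boot
        self.compare_n_boot = compare_n_boot
        self.alpha = alpha
        self.seed = seed
        self.stepwise = stepwise

    def fit(self, chronology: IndexSeries, climate: pd.DataFrame, event_years):
        selected, table = response_screen(
            chronology, climate,
            n_boot=self.screen_n_boot, alpha=self.alpha, seed=self.seed,
        )
        if not selected:
            logger.warning("no significant climate variable; using the top 2 by |coef|")
            selected = list(table["coef"].abs().sort_values(ascending=False).index[:2])
        dummy = DefoliationDummy(list(event_years), tuple(self.effect_lags))
        fit2, fit3 = fit_models(
            chronology, climate, selected, dummy, stepwise=self.stepwise
        )
        cmp = bootstrap_r2_compare(
            chronology, climate,
            [n for n, _ in fit3.predictors] or selected,
            dummy,
            n_boot=self.compare_n_boot,
            seed=self.seed,
        )
        self.selected_vars_ = selected
        self.screen_table_ = table
        self.weather_fit_ = fit2
        self.dummy_fit_ = fit3
        self.friedman_p_ = cmp["friedman_p"]
        self.compare_ = cmp
        return self
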