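"""Driver-association pipeline for overdispersed municipality case counts.

The analysis chain mirrors standard ecological count-regression practice:

1. standardise continuous covariates (rate ratios are then per 1-SD increase
   and comparable across covariates of wildly different units);
2. univariate screening — a single-covariate count model per driver, retained
   when the 95% CI of its rate ratio excludes 1;
3. collinearity control — variance inflation factors (flag VIF > 5) and
   pairwise Pearson correlation (|r| > 0.8 drops the weaker-screening member
   of the pair);
4. multivariate Poisson and negative-binomial (NB2) fits with Wald intervals;
5. model choice by DIC (computed from a Laplace approximation to the
   posterior under flat priors, with AIC always reported alongside);
6. a high- vs low-incidence group contrast per driver (Welch t-test on a
   median split of the incidence rate).

The dependent variable is the raw case count per municipality; a
log-population exposure offset is available but off by default.
Model fitting itself is delegated to statsmodels (Poisson GLM/IRLS and
maximum-likelihood NB2 with jointly estimated dispersion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats
from statsmodels.discrete.discrete_model import NegativeBinomial as _NB2
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ScreenResult",
    "RegressionFit",
    "CollinearityReport",
    "standardize",
    "inverse_standardize",
    "univariate_screen",
    "vif",
    "pearson_filter",
    "fit_count_model",
    "compare_models",
    "incidence_group_contrast",
    "driver_pipeline",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class ScreenResult:
    driver: str
    rr: float
    ci_low: float
    ci_high: float
    retained: bool
    converged: bool = True
    note: str = ""


@dataclass
class CollinearityReport:
    vif: pd.Series
    correlation: pd.DataFrame
    excluded: list = field(default_factory=list)  # (driver, reason) pairs

    @property
    def flagged(self) -> list:
        return list(self.vif.index[self.vif > 5])


@dataclass
class RegressionFit:
    """A fitted count model with per-1-SD rate ratios and fit criteria."""

    family: str                    # "poisson" | "nb"
    params: pd.Series              # coefficients incl. intercept "const"
    se: pd.Series
    theta: float | None            # NB dispersion (None for Poisson)
    rr: pd.DataFrame               # index drivers; columns RR, ci_low, ci_high
    deviance: float
    llf: float
    aic: float
    converged: bool
    dic: float | None = None
    _endog: np.ndarray = field(default=None, repr=False)
    _exog: np.ndarray = field(default=None, repr=False)
    _offset: np.ndarray = field(default=None, repr=False)
    _cov: np.ndarray = field(default=None, repr=False)


# ---------------------------------------------------------------------- #
# standardisation
# ---------------------------------------------------------------------- #
def standardize(
    drivers: pd.DataFrame, dichotomous: Sequence[str] = ("habitat_tropical",)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale continuous drivers to mean 0, SD 1; dichotomies pass through raw.

    Returns the standardised table and a parameter table (rows ``mean, sd``)
    for the inverse transform.  Zero-variance continuous columns are dropped
    with a warning — they carry no information for the regression.
    """
    out = {}
    params = {}
    for col in drivers.columns:
        v = drivers[col].astype(float)
        if col in dichotomous:
            out[col] = v
            params[col] = (0.0, 1.0)
            continue
        mean, sd = float(v.mean()), float(v.std(ddof=0))
        if sd == 0:
            warnings.warn(f"driver {col!r} has zero variance; excluded", stacklevel=2)
            continue
        out[col] = (v - mean) / sd
        params[col] = (mean, sd)
    return pd.DataFrame(out, index=drivers.index), pd.DataFrame(params, index=["mean", "sd"])


def inverse_standardize(standardized: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col in standardized.columns:
        mean, sd = params[col]
        out[col] = standardized[col] * sd + mean
    return pd.DataFrame(out, index=standardized.index)


# ---------------------------------------------------------------------- #
# model fitting
# ---------------------------------------------------------------------- #
def _nb_deviance(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB2 deviance: 2*[ y log(y/mu) - (y+theta) log((y+theta)/(mu+theta)) ]."""
    y = np.asarray(y, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y + theta) * np.log((y + theta) / (mu + theta))))


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    y = np.asarray(y, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def fit_count_model(
    cases,
    design: pd.DataFrame,
    family: str = "nb",
    offset: np.ndarray | None = None,
) -> RegressionFit:
    """Maximum-likelihood Poisson or negative-binomial (NB2) count regression.

    ``design`` holds the (already standardised) driver columns without an
    intercept; one is added.  Rate ratios are exp(beta) with Wald 95%
    intervals exp(beta +/- 1.96 se).  ``offset`` is an optional log-exposure
    term.  Raises on non-convergence rather than returning silent garbage.
    """
    y = np.asarray(cases, dtype=float)
    if np.any(y < 0):
        raise ValueError("case counts must be non-negative")
    X = sm.add_constant(design.astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")

    if family == "poisson":
        res = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        if not res.converged:
            raise RuntimeError("Poisson IRLS did not converge")
        params = res.params
        se = res.bse
        theta = None
        deviance = float(res.deviance)
        llf, aic = float(res.llf), float(res.aic)
        cov = np.asarray(res.cov_params())[: X.shape[1], : X.shape[1]]
        converged = bool(res.converged)
    elif family == "nb":
        start = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit().params
        model = _NB2(y, X, loglike_method="nb2", offset=offset)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = model.fit(
                start_params=np.append(np.asarray(start), 0.1),
                method="bfgs", maxiter=500, disp=0,
            )
            if not res.mle_retvals.get("converged", False):
                res = model.fit(
                    start_params=np.append(np.asarray(start), 0.1),
                    method="nm", maxiter=5000, disp=0,
                )
        if not res.mle_retvals.get("converged", False):
            raise RuntimeError(f"NB fit did not converge: {res.mle_retvals}")
        alpha = float(np.asarray(res.params)[-1])
        theta = np.inf if alpha <= 0 else 1.0 / alpha
        params = pd.Series(np.asarray(res.params[:-1]), index=X.columns)
        se = pd.Series(np.asarray(res.bse[:-1]), index=X.columns)
        lin = X.to_numpy() @ params.to_numpy()
        if offset is not None:
            lin = lin + offset
        deviance = _nb_deviance(y, np.exp(lin), theta)
        llf, aic = float(res.llf), float(res.aic)
        cov = np.asarray(res.cov_params())[: X.shape[1], : X.shape[1]]
        converged = True
    else:
        raise ValueError(f"unknown family {family!r}")

    drivers = [c for c in X.columns if c != "const"]
    rr = pd.DataFrame(
        {
            "RR": np.exp(params[drivers]),
            "ci_low": np.exp(params[drivers] - Z95 * se[drivers]),
            "ci_high": np.exp(params[drivers] + Z95 * se[drivers]),
        },
        index=drivers,
    )
    return RegressionFit(
        family=family,
        params=params,
        se=se,
        theta=theta,
        rr=rr,
        deviance=deviance,
        llf=llf,
        aic=aic,
        converged=converged,
        _endog=y,
        _exog=X.to_numpy(),
        _offset=offset,
        _cov=cov,
    )


def nb_loglike(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB2 log-likelihood at given mean vector and dispersion."""
    y = np.asarray(y, float)
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


# ---------------------------------------------------------------------- #
# screening and collinearity
# ---------------------------------------------------------------------- #
def univariate_screen(cases, driver, name: str, family: str = "nb") -> ScreenResult:
    """Single-covariate count regression; retained iff the 95% CI excludes 1."""
    design = pd.DataFrame({name: np.asarray(driver, dtype=float)})
    try:
        fit = fit_count_model(cases, design, family=family)
    except (RuntimeError, ValueError, np.linalg.LinAlgError) as exc:
        return ScreenResult(name, np.nan, np.nan, np.nan, False, converged=False, note=str(exc))
    row = fit.rr.loc[name]
    retained = bool(row.ci_low > 1.0 or row.ci_high < 1.0)
    return ScreenResult(name, float(row.RR), float(row.ci_low), float(row.ci_high), retained)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per driver: 1/(1-R^2) of each column on the rest."""
    if design.shape[1] < 2:
        raise ValueError("VIF needs at least two drivers")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("VIF needs more rows than drivers")
    out = {}
    X = design.astype(float)
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=col), has_constant="add")
        r2 = sm.OLS(X[col], others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def pearson_filter(
    drivers: pd.DataFrame,
    threshold: float = 0.8,
    strength: Mapping[str, float] | None = None,
) -> tuple[list[str], list[tuple[str, str]], pd.DataFrame]:
    """Exclude one member of each driver pair with |Pearson r| > threshold.

    The member with the weaker screening association (``strength``, higher =
    stronger; e.g. |log RR| from the univariate screen) is dropped; without
    strengths the tie-break is deterministic name order (the later name is
    dropped).  Constant columns have undefined correlation and are excluded
    with that reason.  Returns (retained, excluded-with-reason, r-matrix).
    """
    cols = list(drivers.columns)
    excluded: list[tuple[str, str]] = []
    for col in cols:
        if drivers[col].astype(float).std(ddof=0) == 0:
            excluded.append((col, "constant column: correlation undefined"))
    active = [c for c in cols if c not in {e[0] for e in excluded}]
    corr = drivers[active].astype(float).corr(method="pearson")
    dropped: set[str] = set()
    for a_i, a in enumerate(active):
        for b in active[a_i + 1 :]:
            if a in dropped or b in dropped:
                continue
            r = corr.loc[a, b]
            if abs(r) > threshold:
                if strength is not None:
                    loser = a if strength.get(a, 0.0) < strength.get(b, 0.0) else b
                    if strength.get(a, 0.0) == strength.get(b, 0.0):
                        loser = max(a, b)
                else:
                    loser = max(a, b)
                dropped.add(loser)
                excluded.append((loser, f"|r|={abs(r):.3f} with {a if loser == b else b}"))
    retained = [c for c in active if c not in dropped]
    return retained, excluded, corr


def collinearity_report(
    drivers: pd.DataFrame, threshold: float = 0.8, strength: Mapping[str, float] | None = None
) -> CollinearityReport:
    retained, excluded, corr = pearson_filter(drivers, threshold, strength)
    vifs = vif(drivers[retained]) if len(retained) >= 2 else pd.Series(dtype=float)
    return CollinearityReport(vif=vifs, correlation=corr, excluded=excluded)


# ---------------------------------------------------------------------- #
# model comparison
# ---------------------------------------------------------------------- #
def compare_models(fits: Sequence[RegressionFit], n_draws: int = 500, seed: int = 0) -> dict:
    """Rank fitted models by DIC from a Laplace-approximate posterior.

    With flat priors the posterior of the coefficients is approximately
    N(beta_hat, Cov(beta_hat)).  The Bayesian deviance D(beta) = -2 log
    p(y|beta) (comparable across families, unlike residual deviance which is
    relative to each family's own saturated model) is averaged by Monte Carlo
    over that approximation, with the NB dispersion held at its MLE:

        p_D  = Dbar - D(beta_hat),        DIC = D(beta_hat) + 2 p_D.

    Lower DIC wins.  Ties (|dDIC| < 1e-6, e.g. the same model twice) are
    reported as ties.  All fits must be on identical data.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    y0 = fits[0]._endog
    for f in fits[1:]:
        if f._endog.shape != y0.shape or not np.array_equal(f._endog, y0):
            raise ValueError("fits are not on identical data")

    dics = {}
    for f in fits:
        rng = np.random.default_rng(seed)  # same draws stream per fit: exact ties tie
        beta_hat = f.params.to_numpy()
        draws = rng.multivariate_normal(beta_hat, f._cov, size=n_draws, method="svd")
        lin = f._exog @ draws.T
        if f._offset is not None:
            lin = lin + f._offset[:, None]
        mu = np.exp(lin)
        y = f._endog[:, None]
        if f.family == "poisson":
            ll_draws = np.sum(y * np.log(mu) - mu - special.gammaln(y + 1), axis=0)
        else:
            th = f.theta
            ll_draws = np.sum(
                special.gammaln(y + th) - special.gammaln(th) - special.gammaln(y + 1)
                + th * np.log(th / (th + mu)) + y * np.log(mu / (th + mu)),
                axis=0,
            )
        dev_draws = -2.0 * ll_draws
        d_hat = -2.0 * f.llf
        dbar = float(np.mean(dev_draws))
        p_d = dbar - d_hat
        f.dic = d_hat + 2.0 * p_d
        dics[f.family] = {"dic": f.dic, "p_d": p_d, "deviance": f.deviance, "aic": f.aic}

    order = sorted(range(len(fits)), key=lambda i: fits[i].dic)
    best, runner = fits[order[0]], fits[order[1]]
    tie = abs(best.dic - runner.dic) < 1e-6
    return {
        "criterion": "DIC",
        "models": dics,
        "ranking": [fits[i].family for i in order],
        "best": None if tie else best.family,
        "tie": tie,
        "aic_ranking": [f.family for f in sorted(fits, key=lambda f: f.aic)],
    }


# ---------------------------------------------------------------------- #
# group contrast
# ---------------------------------------------------------------------- #
def incidence_group_contrast(incidence: pd.Series, drivers: pd.DataFrame) -> pd.DataFrame:
    """Welch t-test per driver between high- and low-incidence municipalities.

    Municipalities are split at the median incidence rate (strictly above =
    high).  Returns per-driver group medians, Welch t and p.  Drivers with a
    degenerate group (n < 2) are skipped with a reason.  Two identical groups
    report t = 0, p = 1.
    """
    inc = incidence.astype(float)
    med = inc.median()
    high = inc > med
    rows = []
    for col in drivers.columns:
        v = drivers[col].astype(float)
        a, b = v[high].to_numpy(), v[~high].to_numpy()
        if len(a) < 2 or len(b) < 2:
            rows.append({"driver": col, "median_high": np.nan, "median_low": np.nan,
                         "t": np.nan, "p": np.nan, "note": "degenerate group (n < 2)"})
            continue
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            t = 0.0 if a.mean() == b.mean() else np.inf
            p = 1.0 if t == 0.0 else 0.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"driver": col, "median_high": float(np.median(a)),
                     "median_low": float(np.median(b)), "t": float(t), "p": float(p),
                     "note": ""})
    return pd.DataFrame(rows).set_index("driver")


# ---------------------------------------------------------------------- #
# full pipeline
# ---------------------------------------------------------------------- #
def driver_pipeline(
    cases,
    drivers: pd.DataFrame,
    dichotomous: Sequence[str] = ("habitat_tropical",),
    corr_threshold: float = 0.8,
    dic_draws: int = 500,
    seed: int = 0,
) -> dict:
    """Screen -> collinearity filter -> Poisson & NB fits -> DIC selection.

    Returns a dict with the standardisation parameters, per-driver screening
    results, the collinearity report, both multivariate fits on the retained
    drivers, and the model-selection report.
    """
    std, std_params = standardize(drivers, dichotomous=dichotomous)
    screens = {c: univariate_screen(cases, std[c], c) for c in std.columns}
    strength = {
        c: abs(np.log(s.rr)) if s.converged and np.isfinite(s.rr) and s.rr > 0 else 0.0
        for c, s in screens.items()
    }
    report = collinearity_report(std, threshold=corr_threshold, strength=strength)
    kept = [c for c in std.columns if c not in {e[0] for e in report.excluded}]
    design = std[kept]
    fits = {
        "poisson": fit_count_model(cases, design, family="poisson"),
        "nb": fit_count_model(cases, design, family="nb"),
    }
    selection = compare_models([fits["poisson"], fits["nb"]], n_draws=dic_draws, seed=seed)
    return {
        "standardization": std_params,
        "screen": screens,
        "collinearity": report,
        "retained": kept,
        "fits": fits,
        "selection": selection,
    }
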