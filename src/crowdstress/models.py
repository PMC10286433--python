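"""Association models: per-site mixed models and geographically weighted regression.

The global analysis regresses the per-second change score on the seven
overcrowding predictors with random intercepts for time slot, participant
and gender — a Gaussian linear mixed model fitted by REML, reported per
site with Wald 95% CIs, significance bands, variance components, ICC and
Nakagawa marginal/conditional R².

The local analysis is a geographically weighted regression: at every
record location, weighted least squares with a fixed Gaussian kernel
``w = exp(−d²/(2b²))`` over planar metres, bandwidth ``b`` either fixed or
chosen by AICc minimisation, with per-location coefficients, leverages and
standardized residuals.  An ordinary-least-squares fit provides the global
comparison (the GWR large-bandwidth limit).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

from .errors import ModelError
from .geo import to_planar
from .proxemics import COUNT_COLUMNS

__all__ = [
    "GlmmSpec",
    "GlmmResult",
    "GwrResult",
    "fit_glmm",
    "fit_glmm_per_site",
    "icc",
    "r2_mixed",
    "significance_stars",
    "fit_gwr",
    "fit_ols",
]

RANDOM_GROUPINGS = ("timeslot", "participant_id", "gender")


def significance_stars(p: float) -> str:
    """Per-coefficient significance band: *** <0.1%, ** <1%, * <5%, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GlmmSpec:
    """What to fit: response column, fixed-effect predictors, random intercepts."""

    response: str = "CS"
    fixed: tuple[str, ...] = COUNT_COLUMNS
    random_intercepts: tuple[str, ...] = RANDOM_GROUPINGS
    per_site: bool = True
    min_records: int = 50


@dataclass
class GlmmResult:
    """Table-shaped summary of one mixed-model fit.

    ``fixed_effects`` maps predictor → {estimate, ci_low, ci_high, p, stars};
    ``tau`` maps grouping → random-intercept variance (τ00); ``sigma2`` is the
    residual variance; ``icc``/``r2_conditional`` are NaN when undefined
    (total random variance ≈ 0, printed as a dash in tables).
    """

    site: str
    n_obs: int
    n_groups: dict
    fixed_effects: dict
    tau: dict
    sigma2: float
    var_fixed: float
    icc: float
    r2_marginal: float
    r2_conditional: float
    converged: bool
    optimizer: str
    dropped_groupings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = {
            "site": self.site,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "fixed_effects": self.fixed_effects,
            "tau": self.tau,
            "sigma2": self.sigma2,
            "var_fixed": self.var_fixed,
            "icc": self.icc,
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "converged": self.converged,
            "optimizer": self.optimizer,
            "dropped_groupings": list(self.dropped_groupings),
        }
        return d

    def to_json(self, path) -> None:
        def clean(x):
            if isinstance(x, float) and math.isnan(x):
                return None
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, list):
                return [clean(v) for v in x]
            return x

        with open(path, "w") as fh:
            json.dump(clean(self.to_dict()), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GlmmResult":
        with open(path) as fh:
            d = json.load(fh)

        def restore(x):
            if x is None:
                return math.nan
            if isinstance(x, dict):
                return {k: restore(v) for k, v in x.items()}
            if isinstance(x, list):
                return [restore(v) for v in x]
            return x

        d = restore(d)
        d["dropped_groupings"] = tuple(d["dropped_groupings"])
        return cls(**d)


def icc(result: GlmmResult) -> float:
    """Intraclass correlation: Στ00 / (Στ00 + σ²); NaN when Στ00 ≈ 0
    (printed as a dash in result tables)."""
    tau_total = sum(result.tau.values())
    if tau_total <= 1e-10:
        return math.nan
    return tau_total / (tau_total + result.sigma2)


def r2_mixed(result: GlmmResult) -> tuple[float, float]:
    """Nakagawa marginal and conditional R² from stored variance pieces.

    Marginal: fixed-effect variance over total; conditional adds the
    random-intercept variance.  Conditional is NaN when the random part
    collapsed to zero (degenerate fit, printed as NA)."""
    tau_total = sum(result.tau.values())
    total = result.var_fixed + tau_total + result.sigma2
    marginal = result.var_fixed / total if total > 0 else math.nan
    if tau_total <= 1e-10:
        return marginal, math.nan
    return marginal, (result.var_fixed + tau_total) / total


def _fit_one(df: pd.DataFrame, spec: GlmmSpec, site: str) -> GlmmResult:
    if len(df) < spec.min_records:
        raise ModelError(
            f"site {site!r}: {len(df)} records < configured floor {spec.min_records}"
        )
    groupings, dropped = [], []
    for g in spec.random_intercepts:
        if df[g].nunique() >= 2:
            groupings.append(g)
        else:
            dropped.append(g)
            warnings.warn(
                f"site {site!r}: random grouping {g!r} has <2 levels and is dropped",
                stacklevel=2,
            )
    y = df[spec.response].to_numpy(dtype=float)
    X = sm.add_constant(df[list(spec.fixed)].to_numpy(dtype=float), has_constant="add")

    if groupings:
        data = df.copy()
        data["_one"] = 1
        # variance components estimated at the zero boundary leave MixedLM's
        # Hessian singular; drop the offending grouping (reported as tau=0.00,
        # matching how degenerate components are printed) and refit
        attempt = list(groupings)
        fit = model = None
        while True:
            vc = {g: f"0 + C({g})" for g in attempt}
            model = sm.MixedLM.from_formula(
                f"{spec.response} ~ " + " + ".join(spec.fixed),
                groups="_one",
                vc_formula=vc,
                data=data,
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = model.fit(reml=True, method="bfgs", maxiter=200)
                    if not fit.converged:
                        fit = model.fit(reml=True, method="powell", maxiter=500)
            except np.linalg.LinAlgError:
                fit = None
            if fit is not None and fit.converged:
                break
            if len(attempt) == 1:
                raise ModelError(
                    f"site {site!r}: mixed model did not converge "
                    f"(optimizer bfgs/powell, {len(df)} records, groupings {groupings})"
                )
            # drop the coarsest grouping (fewest levels) as the likely culprit
            drop = min(attempt, key=lambda g: (df[g].nunique(), -attempt.index(g)))
            attempt.remove(drop)
            dropped.append(drop)
        groupings = attempt
        params = fit.fe_params
        bse = fit.bse_fe
        vcomp = dict(zip(model.exog_vc.names, np.asarray(fit.vcomp, dtype=float)))
        tau = {g: max(0.0, float(vcomp[g])) for g in groupings}
        sigma2 = float(fit.scale)
        names = list(params.index)
        est = params.to_numpy()
        se = bse.to_numpy()
        converged = bool(fit.converged)
        optimizer = "statsmodels MixedLM REML (bfgs)"
    else:
        ols = sm.OLS(y, X).fit()
        names = ["Intercept", *spec.fixed]
        est, se = ols.params, ols.bse
        tau = {}
        sigma2 = float(ols.mse_resid)
        converged = True
        optimizer = "OLS (no random groupings retained)"

    from scipy.stats import norm

    fixed_effects = {}
    for name, b, s in zip(names, est, se):
        key = name if name != "Intercept" else "(Intercept)"
        z = b / s if s > 0 else math.inf
        p = 2 * (1 - norm.cdf(abs(z)))
        fixed_effects[key] = {
            "estimate": float(b),
            "ci_low": float(b - 1.959963984540054 * s),
            "ci_high": float(b + 1.959963984540054 * s),
            "p": float(p),
            "stars": significance_stars(p),
        }

    # variance of the fixed-effect linear predictor (Nakagawa's σ²_f)
    order = {n: i for i, n in enumerate(names)}
    beta_vec = np.array([est[order[n]] if n in order else 0.0 for n in ["Intercept", *spec.fixed]])
    var_fixed = float(np.var(X @ beta_vec))

    for g in dropped:
        tau[g] = 0.0

    result = GlmmResult(
        site=site,
        n_obs=len(df),
        n_groups={g: int(df[g].nunique()) for g in spec.random_intercepts},
        fixed_effects=fixed_effects,
        tau=tau,
        sigma2=sigma2,
        var_fixed=var_fixed,
        icc=math.nan,
        r2_marginal=math.nan,
        r2_conditional=math.nan,
        converged=converged,
        optimizer=optimizer,
        dropped_groupings=tuple(dropped),
    )
    result.icc = icc(result)
    result.r2_marginal, result.r2_conditional = r2_mixed(result)
    return result


def fit_glmm(records: pd.DataFrame, spec: GlmmSpec = GlmmSpec()) -> dict[str, GlmmResult]:
    """Fit the change-score mixed model, by default one fit per site.

    Records labelled ``unassigned`` are excluded from per-site fits, which
    mirrors separating data points into locations by GPS.  Returns
    site → GlmmResult (key ``"all"`` when ``per_site`` is off).
    """
    missing = [c for c in (spec.response, *spec.fixed) if c not in records.columns]
    if missing:
        raise ModelError(f"records are missing required columns: {missing}")
    if not spec.per_site:
        return {"all": _fit_one(records, spec, "all")}
    out: dict[str, GlmmResult] = {}
    for site, grp in records.groupby("site", sort=False):
        if site == "unassigned":
            continue
        out[site] = _fit_one(grp, spec, str(site))
    if not out:
        raise ModelError("no site has any assigned records")
    return out


fit_glmm_per_site = fit_glmm


# ---------------------------------------------------------------------------
# GWR / OLS

def _aicc_ols(n: int, rss: float, k: int) -> float:
    aic = n * math.log(rss / n) + n * math.log(2 * math.pi) + n + 2 * (k + 1)
    denom = n - k - 2
    corr = (2 * (k + 1) * (k + 2)) / denom if denom > 0 else math.inf
    return aic + corr


@dataclass
class GwrResult:
    """Per-location coefficient surfaces from a Gaussian-kernel GWR."""

    bandwidth_m: float
    predictors: tuple[str, ...]
    local: pd.DataFrame  # per record: intercept, coefficients, fitted, leverage, std_resid
    trace_hat: float
    sigma2: float
    aicc: float
    origin: tuple[float, float]

    def to_geojson(self, path, records: pd.DataFrame) -> None:
        feats = []
        for i in range(len(self.local)):
            props = {k: _jsonable(v) for k, v in self.local.iloc[i].items()}
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [
                            float(records["lon"].iloc[i]),
                            float(records["lat"].iloc[i]),
                        ],
                    },
                    "properties": props,
                }
            )
        doc = {
            "type": "FeatureCollection",
            "properties": {
                "bandwidth_m": self.bandwidth_m,
                "aicc": self.aicc,
                "predictors": list(self.predictors),
            },
            "features": feats,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


def _jsonable(v):
    v = float(v)
    return None if math.isnan(v) else v


def gaussian_kernel(d: np.ndarray, bandwidth: float) -> np.ndarray:
    """Spatial weight ``exp(−d²/(2b²))``; weight 1 at distance 0."""
    return np.exp(-(d**2) / (2.0 * bandwidth**2))


def _gwr_solve(
    X: np.ndarray, y: np.ndarray, coords: np.ndarray, bandwidth: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local WLS at every record location.

    Returns (betas, fitted, leverage).  A locally singular design (a
    predictor with no weighted variance in the neighbourhood) yields NaN
    for the affected coefficients instead of raising.
    """
    n, p = X.shape
    betas = np.full((n, p), np.nan)
    fitted = np.full(n, np.nan)
    lev = np.full(n, np.nan)
    for i in range(n):
        d = np.hypot(coords[:, 0] - coords[i, 0], coords[:, 1] - coords[i, 1])
        w = gaussian_kernel(d, bandwidth)
        Xw = X * w[:, None]
        XtWX = Xw.T @ X
        XtWy = Xw.T @ y
        try:
            if np.linalg.cond(XtWX) > 1e10:
                raise np.linalg.LinAlgError("ill-conditioned local design")
            beta = np.linalg.solve(XtWX, XtWy)
            ci = np.linalg.solve(XtWX, X[i])
            ok = np.ones(p, dtype=bool)
        except np.linalg.LinAlgError:
            # flag columns without local weighted variation as undefined
            wmean = Xw.sum(axis=0) / w.sum()
            dev = ((X - wmean) ** 2 * w[:, None]).sum(axis=0)
            ok = dev > 1e-12
            ok[0] = True  # intercept
            XtWX_ok = XtWX[np.ix_(ok, ok)]
            beta = np.full(p, np.nan)
            beta[ok] = np.linalg.pinv(XtWX_ok) @ XtWy[ok]
            ci = np.zeros(p)
            ci[ok] = np.linalg.pinv(XtWX_ok) @ X[i, ok]
        betas[i] = beta
        use = ~np.isnan(beta)
        fitted[i] = X[i, use] @ beta[use]
        lev[i] = float(w[i] * (X[i] @ ci))
    return betas, fitted, lev


def _gwr_aicc(X, y, coords, bandwidth) -> float:
    _, fitted, lev = _gwr_solve(X, y, coords, bandwidth)
    n = y.size
    rss = float(((y - fitted) ** 2).sum())
    tr = float(np.clip(lev, 0, 1).sum())
    if n - 2 - tr <= 0 or rss <= 0:
        return math.inf
    sigma2 = rss / n
    return (
        2 * n * math.log(math.sqrt(sigma2))
        + n * math.log(2 * math.pi)
        + n * (n + tr) / (n - 2 - tr)
    )


def fit_gwr(
    records: pd.DataFrame,
    predictors: tuple[str, ...] | list[str],
    bandwidth: float | str = "auto",
    response: str = "CS",
) -> GwrResult:
    """Geographically weighted regression of the change score.

    Coordinates are projected from lat/lon to local planar metres.  With
    ``bandwidth="auto"`` the Gaussian kernel bandwidth is chosen by AICc
    minimisation (golden-section search over a log-spaced bracket spanning
    roughly 1% to 4× the data extent).
    """
    predictors = tuple(predictors)
    x, y_m, origin = to_planar(records["lat"].to_numpy(), records["lon"].to_numpy())
    coords = np.column_stack([x, y_m])
    X = np.column_stack(
        [np.ones(len(records))] + [records[p].to_numpy(dtype=float) for p in predictors]
    )
    yv = records[response].to_numpy(dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ModelError(f"GWR needs at least p+2={p + 2} records, got {n}")

    if bandwidth == "auto":
        extent = max(
            float(coords[:, 0].max() - coords[:, 0].min()),
            float(coords[:, 1].max() - coords[:, 1].min()),
            1.0,
        )
        res = minimize_scalar(
            lambda lb: _gwr_aicc(X, yv, coords, 10.0**lb),
            bounds=(math.log10(extent * 0.01), math.log10(extent * 4.0)),
            method="bounded",
            options={"xatol": 0.01},
        )
        bandwidth = float(10.0**res.x)
    bandwidth = float(bandwidth)

    betas, fitted, lev = _gwr_solve(X, yv, coords, bandwidth)
    resid = yv - fitted
    tr = float(np.clip(lev, 0, 1).sum())
    rss = float((resid**2).sum())
    dof = max(n - tr, 1.0)
    sigma2 = rss / dof
    denom = np.sqrt(sigma2 * np.clip(1.0 - lev, 1e-12, None))
    std_resid = resid / denom
    aicc = (
        2 * n * math.log(math.sqrt(rss / n))
        + n * math.log(2 * math.pi)
        + n * (n + tr) / (n - 2 - tr)
        if n - 2 - tr > 0
        else math.inf
    )

    local = pd.DataFrame(betas, columns=["intercept", *predictors])
    local["fitted"] = fitted
    local["leverage"] = lev
    local["std_resid"] = std_resid
    return GwrResult(
        bandwidth_m=bandwidth,
        predictors=predictors,
        local=local,
        trace_hat=tr,
        sigma2=sigma2,
        aicc=aicc,
        origin=origin,
    )


def fit_ols(
    records: pd.DataFrame,
    predictors: tuple[str, ...] | list[str],
    response: str = "CS",
) -> dict:
    """Global ordinary-least-squares fit with intercept, plus AICc.

    The comparison partner for GWR; raises on a rank-deficient design,
    naming the collinear columns.
    """
    predictors = tuple(predictors)
    X = np.column_stack(
        [np.ones(len(records))] + [records[p].to_numpy(dtype=float) for p in predictors]
    )
    names = ["intercept", *predictors]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns that do not increase the rank
        bad, cols = [], [X[:, 0]]
        for j in range(1, X.shape[1]):
            trial = np.column_stack(cols + [X[:, j]])
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(names[j])
            else:
                cols.append(X[:, j])
        raise ModelError(f"design is rank deficient; collinear columns: {bad}")
    yv = records[response].to_numpy(dtype=float)
    fit = sm.OLS(yv, X).fit()
    k = X.shape[1]
    n = len(yv)
    rss = float(fit.ssr)
    return {
        "coefficients": dict(zip(names, map(float, fit.params))),
        "bse": dict(zip(names, map(float, fit.bse))),
        "p": dict(zip(names, map(float, fit.pvalues))),
        "r2": float(fit.rsquared),
        "aicc": _aicc_ols(n, rss, k),
        "n": n,
    }
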