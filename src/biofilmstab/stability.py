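"""Stability dimensions of biomass under extreme perturbations.

The response is the log-response ratio (LRR) of plot biomass against the
mean of the control plots at each date.  Over the post-extreme sampling
dates a linear mixed model with control as baseline,

    y = a0 + a0_i + b1*t + b1_i*(t x treat_i) + plot intercept + plot slope + e,

with time centred at the first post-extreme date, yields the four stability
dimensions: sensitivity (treatment main effect a0_i), resilience (treatment
x time deviation b1_i), temporal stability (inverse SD of residuals, pooled
within treatment) and recovery (fixed-effect deviation from control at the
last date).  Uncertainty comes from a parametric bootstrap of the fitted
model.  A before-after control-impact (BACI) model and phase-1 trend
models with planned contrasts complete the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import InsufficientDataError, ValidationError
from .stochasticity import fdr_adjust

__all__ = [
    "log_response_ratio",
    "bca_interval",
    "fit_stability_model",
    "extract_dimensions",
    "parametric_bootstrap",
    "baci_analysis",
    "phase1_trend_contrasts",
    "control_vs_extreme_prephase",
    "artifact_control_test",
    "StabilityModelFit",
]

CONTROL = "control"


# ---------------------------------------------------------------------------
# log-response ratios


def log_response_ratio(
    biomass: pd.DataFrame, baseline: str = CONTROL, subplot_average: bool = True
) -> pd.DataFrame:
    """Per plot x date LRR of biomass against the mean control trajectory.

    Subplots are averaged within plot first; the baseline at each date is
    the mean over control plots.  Control plots themselves are retained
    (their LRRs scatter around zero), so the stability model can estimate
    the control slope and residual variance.
    """
    if (biomass["biomass"] <= 0).any():
        bad = biomass.loc[biomass["biomass"] <= 0].iloc[0]
        raise ValidationError(
            f"non-positive biomass for plot {bad['plot_id']} at date {bad['date']}"
        )
    keys = ["plot_id", "treatment", "date"] + (
        ["phase"] if "phase" in biomass.columns else []
    )
    if subplot_average:
        per_plot = biomass.groupby(keys, as_index=False)["biomass"].mean()
    else:
        per_plot = biomass.copy()
    ctrl = (
        per_plot[per_plot["treatment"] == baseline]
        .groupby("date")["biomass"]
        .mean()
    )
    missing = sorted(set(per_plot["date"]) - set(ctrl.index))
    if missing:
        raise ValidationError(f"no {baseline} biomass at dates: {missing}")
    out = per_plot.copy()
    out["lrr"] = np.log(out["biomass"].to_numpy() / ctrl.reindex(out["date"]).to_numpy())
    return out.drop(columns=["biomass"])


# ---------------------------------------------------------------------------
# BCa bootstrap interval


@dataclass(frozen=True)
class BcaInterval:
    low: float
    high: float
    level: float
    degenerate: bool = False


def bca_interval(
    values,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    statistic=np.mean,
) -> BcaInterval:
    """Bias-corrected and accelerated bootstrap interval of a statistic."""
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise InsufficientDataError("BCa interval needs at least 8 observations")
    if np.ptp(x) == 0:
        return BcaInterval(float(x[0]), float(x[0]), level, degenerate=True)
    rng = np.random.default_rng(seed)
    res = stats.bootstrap(
        (x,),
        statistic,
        n_resamples=n_boot,
        confidence_level=level,
        method="BCa",
        vectorized=False,
        random_state=rng,
    )
    return BcaInterval(
        float(res.confidence_interval.low), float(res.confidence_interval.high), level
    )


# ---------------------------------------------------------------------------
# Eq.-1 style mixed model


@dataclass
class StabilityModelFit:
    """Fitted stability mixed model plus everything a bootstrap refit needs."""

    result: object
    treatments: list[str]
    param_names: list[str]
    exog: np.ndarray = field(repr=False)
    groups: np.ndarray = field(repr=False)
    group_time: dict = field(repr=False)
    vcspec: VCSpec | None = field(repr=False, default=None)
    exog_re: np.ndarray | None = field(repr=False, default=None)
    time_c: np.ndarray = field(repr=False, default=None)
    treatment_of_row: np.ndarray = field(repr=False, default=None)
    t_last_c: float = 0.0
    random_slope: bool = True

    @property
    def fe_params(self) -> pd.Series:
        return pd.Series(self.result.fe_params, index=self.param_names)

    @property
    def resid(self) -> np.ndarray:
        return np.asarray(self.result.resid)

    @property
    def var_intercept(self) -> float:
        return float(np.asarray(self.result.cov_re)[0, 0])

    @property
    def var_slope(self) -> float:
        return float(self.result.vcomp[0]) if self.random_slope else 0.0

    @property
    def sigma2(self) -> float:
        return float(self.result.scale)


def _build_design(
    df: pd.DataFrame, treatments: list[str], time_c: np.ndarray
) -> tuple[np.ndarray, list[str], np.ndarray]:
    cols = [np.ones(len(df)), time_c]
    names = ["intercept", "time"]
    treat = df["treatment"].to_numpy()
    for t in treatments:
        d = (treat == t).astype(float)
        cols.append(d)
        names.append(f"sens[{t}]")
    for t in treatments:
        d = (treat == t).astype(float)
        cols.append(d * time_c)
        names.append(f"resil[{t}]")
    X = np.column_stack(cols)
    return X, names, treat


def _make_vcspec(groups: np.ndarray, time_c: np.ndarray) -> VCSpec:
    labels = sorted(pd.unique(groups))
    mats, colnames = [], []
    for g in labels:
        tg = time_c[groups == g][:, None]
        mats.append(tg)
        colnames.append(["time"])
    return VCSpec(["slope"], [colnames], [mats])


def _fit_mixedlm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    time_c: np.ndarray,
    random_slope: bool = True,
    start_params=None,
    fast: bool = False,
):
    exog_re = np.ones((len(y), 1))
    vcspec = _make_vcspec(groups, time_c) if random_slope else None
    best = None
    last_exc: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                model = MixedLM(y, X, groups, exog_re=exog_re, exog_vc=vcspec)
                res = model.fit(reml=True, method=method, start_params=start_params)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                start_params = None
                continue
            finite = np.isfinite(np.asarray(res.fe_params)).all()
            # boundary fits report converged=False with finite estimates;
            # bootstrap refits accept them rather than cascading optimisers
            if finite and (res.converged or fast):
                return res, vcspec, exog_re
            if best is None:
                best = res
            start_params = None
    if best is not None:
        return best, vcspec, exog_re
    raise last_exc if last_exc is not None else RuntimeError("mixed-model fit failed")


def _fit_plain_mixedlm(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """Random-intercept MixedLM with an optimiser cascade for boundary fits."""
    best = None
    last_exc: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell", "nm"):
            try:
                res = MixedLM(y, X, groups).fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            if res.converged and np.isfinite(np.asarray(res.fe_params)).all():
                return res
            if best is None and np.isfinite(np.asarray(res.fe_params)).all():
                best = res
    if best is not None:
        return best
    raise last_exc if last_exc is not None else RuntimeError("mixed-model fit failed")


class _FastREMLFit:
    """Minimal REML fit of the stability model, for bootstrap refits.

    Profiles the fixed effects and residual variance out of the restricted
    likelihood and optimises only the two variance ratios (plot intercept
    and slope variance over residual variance).  Orders of magnitude faster
    than a general mixed-model fit; exact for this model family.
    """

    __slots__ = ("fe_params", "resid", "sigma2", "var_intercept", "var_slope", "converged")

    def __init__(self, fe_params, resid, sigma2, var_intercept, var_slope, converged):
        self.fe_params = fe_params
        self.resid = resid
        self.sigma2 = sigma2
        self.var_intercept = var_intercept
        self.var_slope = var_slope
        self.converged = converged

    # mirror the statsmodels result surface used downstream
    @property
    def cov_re(self):
        return np.array([[self.var_intercept]])

    @property
    def vcomp(self):
        return np.array([self.var_slope])

    @property
    def scale(self):
        return self.sigma2


def _fast_reml(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    time_c: np.ndarray,
    random_slope: bool = True,
    start_ratios: tuple[float, float] | None = None,
) -> _FastREMLFit:
    from scipy.optimize import minimize

    labels = pd.unique(groups)
    idxs = [np.flatnonzero(groups == g) for g in labels]
    sizes = {len(i) for i in idxs}
    n, p = X.shape
    if len(sizes) == 1:
        k = sizes.pop()
        Xg = np.stack([X[i] for i in idxs])
        yg = np.stack([y[i] for i in idxs])
        tg = np.stack([time_c[i] for i in idxs])
    else:  # unbalanced: pad with zero rows (zero rows contribute nothing)
        k = max(sizes)
        G = len(idxs)
        Xg = np.zeros((G, k, p))
        yg = np.zeros((G, k))
        tg = np.zeros((G, k))
        for gi, i in enumerate(idxs):
            Xg[gi, : len(i)] = X[i]
            yg[gi, : len(i)] = y[i]
            tg[gi, : len(i)] = time_c[i]
    eye = np.eye(k)[None]
    ones = np.ones((k, k))[None]

    def profile(logr):
        r0 = float(np.exp(np.clip(logr[0], -25, 12)))
        r1 = float(np.exp(np.clip(logr[1], -25, 12))) if random_slope else 0.0
        W = eye + r0 * ones + r1 * tg[:, :, None] * tg[:, None, :]
        try:
            L = np.linalg.cholesky(W)
        except np.linalg.LinAlgError:
            return None
        logdet = float(2 * np.sum(np.log(np.einsum("gii->gi", L))))
        rhs = np.concatenate([Xg, yg[:, :, None]], axis=2)
        Z = np.linalg.solve(W, rhs)
        WinvX, Winvy = Z[:, :, :p], Z[:, :, p]
        xtwx = np.einsum("gkp,gkq->pq", Xg, WinvX)
        xtwy = np.einsum("gkp,gk->p", Xg, Winvy)
        try:
            beta = np.linalg.solve(xtwx, xtwy)
        except np.linalg.LinAlgError:
            return None
        resid = yg - Xg @ beta
        rss = float(np.einsum("gk,gk->", resid, np.linalg.solve(W, resid[:, :, None])[:, :, 0]))
        sigma2 = max(rss / (n - p), 1e-30)
        sign, ld_fe = np.linalg.slogdet(xtwx)
        crit = 0.5 * (logdet + (n - p) * np.log(sigma2) + ld_fe)
        return crit, beta, sigma2, resid, r0, r1

    def objective(logr):
        out = profile(logr)
        return np.inf if out is None else out[0]

    # the profiled surface can have ridges (intercept vs slope variance);
    # a coarse log-grid scan picks the basin before local refinement
    starts = [np.array([g0, g1]) for g0 in (-9.0, -4.5, -1.0) for g1 in (-12.0, -7.0, -3.0)]
    if start_ratios is not None:
        starts.append(np.log(np.clip(np.asarray(start_ratios, float), 1e-10, 1e5)))
    x0 = min(starts, key=objective)
    opt = minimize(
        objective, x0, method="Nelder-Mead",
        options={"xatol": 5e-3, "fatol": 1e-5, "maxiter": 300},
    )
    out = profile(opt.x)
    if out is None:
        raise np.linalg.LinAlgError("fast REML fit failed")
    _, beta, sigma2, resid_g, r0, r1 = out
    resid = np.empty(n)
    for gi, i in enumerate(idxs):
        resid[i] = resid_g[gi, : len(i)]
    return _FastREMLFit(
        fe_params=beta,
        resid=resid,
        sigma2=sigma2,
        var_intercept=r0 * sigma2,
        var_slope=r1 * sigma2,
        converged=bool(opt.success),
    )


def fit_stability_model(
    lrr: pd.DataFrame,
    response: str = "lrr",
    baseline: str = CONTROL,
    random_slope: bool = True,
    engine: str = "statsmodels",
) -> StabilityModelFit:
    """REML fit of the stability model over post-extreme dates.

    ``lrr`` needs columns plot_id, treatment, date and the response.  Time
    is centred at the first date present, so treatment main effects are the
    deviations from control immediately after the extremes (sensitivity).
    Random structure: uncorrelated intercept and slope per plot; if the fit
    is singular the model is downgraded to a random intercept (logged).
    ``engine='fast'`` uses the package's profiled REML solver (identical
    estimates, no Wald covariance matrix) — useful in large simulation
    studies.
    """
    df = lrr.copy()
    if baseline not in set(df["treatment"]):
        raise ValidationError(f"baseline treatment {baseline!r} absent")
    dates = np.sort(df["date"].unique())
    if dates.size < 3:
        raise InsufficientDataError("stability model needs at least 3 dates")
    counts = df.groupby("treatment")["plot_id"].nunique()
    if (counts < 2).any():
        raise InsufficientDataError("need at least 2 plots per treatment")
    t0 = dates.min()
    time_c = df["date"].to_numpy(dtype=float) - t0
    treatments = [t for t in sorted(df["treatment"].unique()) if t != baseline]
    X, names, treat_of_row = _build_design(df, treatments, time_c)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("rank-deficient stability design")
    y = df[response].to_numpy(dtype=float)
    groups = df["plot_id"].to_numpy()

    if engine == "fast":
        res = _fast_reml(y, X, groups, time_c, random_slope)
        vcspec, exog_re = None, None
        used_slope = random_slope
    else:
        res, vcspec, exog_re = _fit_mixedlm(y, X, groups, time_c, random_slope)
        used_slope = random_slope
        if random_slope and (not res.converged or not np.isfinite(res.fe_params).all()):
            import logging

            logging.getLogger(__name__).warning(
                "singular random-slope fit; downgrading to random intercept only"
            )
            res, vcspec, exog_re = _fit_mixedlm(y, X, groups, time_c, False)
            used_slope = False

    group_time = {
        g: time_c[groups == g] for g in pd.unique(groups)
    }
    return StabilityModelFit(
        result=res,
        treatments=treatments,
        param_names=names,
        exog=X,
        groups=groups,
        group_time=group_time,
        vcspec=vcspec,
        exog_re=exog_re,
        time_c=time_c,
        treatment_of_row=treat_of_row,
        t_last_c=float(dates.max() - t0),
        random_slope=used_slope,
    )


def _dimensions_from_params(
    fe: np.ndarray,
    names: list[str],
    treatments: list[str],
    t_last_c: float,
    resid: np.ndarray,
    treat_of_row: np.ndarray,
    baseline: str = CONTROL,
) -> pd.DataFrame:
    idx = {n: i for i, n in enumerate(names)}
    rows = []
    all_treats = [baseline] + treatments
    for t in all_treats:
        sens = fe[idx[f"sens[{t}]"]] if t != baseline else 0.0
        resil = fe[idx[f"resil[{t}]"]] if t != baseline else 0.0
        r = resid[treat_of_row == t]
        sd = r.std(ddof=1) if r.size > 1 else np.nan
        ts = 1.0 / sd if sd and sd > 0 else np.nan
        rows.append(
            {
                "treatment": t,
                "sensitivity": sens,
                "resilience": resil,
                "temporal_stability": ts,
                "recovery": sens + resil * t_last_c,
            }
        )
    return pd.DataFrame(rows)


def _simulate_response(fit: StabilityModelFit, rng) -> np.ndarray:
    mu = fit.exog @ np.asarray(fit.result.fe_params)
    y = mu.copy()
    sd_int = np.sqrt(max(fit.var_intercept, 0.0))
    sd_slope = np.sqrt(max(fit.var_slope, 0.0))
    for g in pd.unique(fit.groups):
        mask = fit.groups == g
        b0 = rng.normal(0.0, sd_int)
        b1 = rng.normal(0.0, sd_slope) if fit.random_slope else 0.0
        y[mask] += b0 + b1 * fit.time_c[mask]
    y += rng.normal(0.0, np.sqrt(fit.sigma2), size=len(y))
    return y


def parametric_bootstrap(
    fit: StabilityModelFit, n_boot: int = 1000, seed: int = 0, baseline: str = CONTROL
) -> pd.DataFrame:
    """Bootstrap replicate estimates of the four dimensions per treatment.

    Each replicate simulates new responses from the fitted model (fixed
    effects + fresh random-effect and residual draws), refits, and records
    the dimension estimates.  Returns a long table with one row per
    replicate x treatment.
    """
    rng = np.random.default_rng(seed)
    sigma2 = max(fit.sigma2, 1e-12)
    start_ratios = (
        max(fit.var_intercept, 1e-8) / sigma2,
        max(fit.var_slope, 1e-8) / sigma2,
    )
    reps = []
    for b in range(n_boot):
        ystar = _simulate_response(fit, rng)
        try:
            res = _fast_reml(
                ystar, fit.exog, fit.groups, fit.time_c, fit.random_slope,
                start_ratios=start_ratios,
            )
        except np.linalg.LinAlgError:
            continue
        fe = np.asarray(res.fe_params)
        if not np.isfinite(fe).all():
            continue
        dims = _dimensions_from_params(
            fe,
            fit.param_names,
            fit.treatments,
            fit.t_last_c,
            np.asarray(res.resid),
            fit.treatment_of_row,
            baseline,
        )
        dims["replicate"] = b
        reps.append(dims)
    if not reps:
        raise RuntimeError("all bootstrap refits failed")
    return pd.concat(reps, ignore_index=True)


def extract_dimensions(
    fit: StabilityModelFit,
    n_boot: int = 1000,
    seed: int = 0,
    baseline: str = CONTROL,
    level: float = 0.95,
) -> pd.DataFrame:
    """Point estimates of the four stability dimensions with bootstrap SE/CI.

    One row per treatment x dimension, with percentile CIs over ``n_boot``
    parametric-bootstrap replicates.
    """
    point = _dimensions_from_params(
        np.asarray(fit.result.fe_params),
        fit.param_names,
        fit.treatments,
        fit.t_last_c,
        fit.resid,
        fit.treatment_of_row,
        baseline,
    )
    boot = parametric_bootstrap(fit, n_boot=n_boot, seed=seed, baseline=baseline)
    alpha = (1.0 - level) / 2.0
    rows = []
    for t in point["treatment"]:
        bt = boot[boot["treatment"] == t]
        pt = point[point["treatment"] == t].iloc[0]
        for dim in ("sensitivity", "resilience", "temporal_stability", "recovery"):
            vals = bt[dim].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            est = pt[dim]
            if vals.size:
                lo, hi = np.quantile(vals, [alpha, 1 - alpha])
                if dim == "temporal_stability" and est > 0 and (vals > 0).all():
                    # scale parameter under a homoscedastic refit: recentre
                    # the bootstrap distribution on the treatment's own
                    # estimate (log-scale pivot interval)
                    shift = np.log(est) - np.mean(np.log(vals))
                    lo, hi = np.exp(np.log([lo, hi]) + shift)
            else:
                lo = hi = np.nan
            rows.append(
                {
                    "treatment": t,
                    "dimension": dim,
                    "estimate": est,
                    "se": vals.std(ddof=1) if vals.size > 1 else np.nan,
                    "ci_low": lo,
                    "ci_high": hi,
                    "n_boot": int(vals.size),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BACI


def baci_analysis(
    table: pd.DataFrame, response: str = "lrr", baseline: str = CONTROL
) -> pd.DataFrame:
    """Before-after control-impact interaction per treatment.

    Expects >= 2 dates per period (column ``phase`` in {pre, post}).  Fixed
    effects: treatment, period and their interaction (control x pre as
    reference); random intercept per plot.  The interaction coefficient is
    the BACI effect.
    """
    df = table.copy()
    for period in ("pre", "post"):
        sub = df[df["phase"] == period]
        if sub.empty:
            raise ValidationError(f"missing {period!r} period")
        if sub["date"].nunique() < 2:
            raise InsufficientDataError(f"need >= 2 dates in the {period!r} period")
    treatments = [t for t in sorted(df["treatment"].unique()) if t != baseline]
    if not treatments:
        raise ValidationError("no treatment to contrast against control")
    post = (df["phase"] == "post").astype(float).to_numpy()
    cols = [np.ones(len(df)), post]
    names = ["intercept", "post"]
    treat = df["treatment"].to_numpy()
    for t in treatments:
        cols.append((treat == t).astype(float))
        names.append(f"treat[{t}]")
    for t in treatments:
        cols.append((treat == t).astype(float) * post)
        names.append(f"baci[{t}]")
    X = np.column_stack(cols)
    y = df[response].to_numpy(dtype=float)
    res = _fit_plain_mixedlm(y, X, df["plot_id"].to_numpy())
    fe = np.asarray(res.fe_params)
    se = np.asarray(res.bse_fe)
    rows = []
    for t in treatments:
        i = names.index(f"baci[{t}]")
        z = fe[i] / se[i]
        rows.append(
            {
                "treatment": t,
                "baci_effect": fe[i],
                "se": se[i],
                "z": z,
                "p": float(2 * stats.norm.sf(abs(z))),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phase-1 trend models with planned contrasts


def _pool_fluctuating(treat: pd.Series) -> pd.Series:
    return treat.where(~treat.str.startswith("fluct"), "fluct")


def _wald(est: float, se: float) -> tuple[float, float]:
    if not np.isfinite(se) or se == 0:
        return np.nan, np.nan
    z = est / se
    return z, float(2 * stats.norm.sf(abs(z)))


def phase1_trend_contrasts(
    table: pd.DataFrame,
    response: str = "value",
    center_dates: tuple[float, float] | None = None,
    random_slope: bool = True,
) -> pd.DataFrame:
    """Planned contrasts control-vs-fluctuating and fixed-vs-fluctuating.

    Fits a mixed trend model (treatment x time, fluctuating sequences pooled
    into one level, random intercept + uncorrelated slope per plot) twice:
    centred on the 2nd sampling date (warming-history effects) and on the
    last date (recovery), reporting each planned level contrast and its
    time-interaction with Wald z tests.  p-values of the last-date family
    are BH-adjusted.
    """
    df = table.copy()
    df["treatment"] = _pool_fluctuating(df["treatment"].astype(str))
    df = df[df["treatment"].isin([CONTROL, "fixed", "fluct"])]
    levels = set(df["treatment"])
    if not {"fixed", "fluct", CONTROL} <= levels:
        raise ValidationError("contrasts need control, fixed and fluctuating levels")
    dates = np.sort(df["date"].unique())
    if dates.size < 3:
        raise InsufficientDataError("trend model needs at least 3 dates")
    if center_dates is None:
        center_dates = (float(dates[1]), float(dates[-1]))
    y = df[response].to_numpy(dtype=float)
    groups = df["plot_id"].to_numpy()
    treat = df["treatment"].to_numpy()
    rows = []
    for label, center in zip(("second", "last"), center_dates):
        time_c = df["date"].to_numpy(dtype=float) - center
        d_fix = (treat == "fixed").astype(float)
        d_flu = (treat == "fluct").astype(float)
        X = np.column_stack(
            [np.ones(len(df)), time_c, d_fix, d_flu, d_fix * time_c, d_flu * time_c]
        )
        res, _, _ = _fit_mixedlm(y, X, groups, time_c, random_slope)
        fe = np.asarray(res.fe_params)
        cov = np.asarray(res.cov_params())[: len(fe), : len(fe)]
        # contrast vectors over [1, t, fixed, fluct, fixed:t, fluct:t]
        specs = {
            ("control_vs_fluct", "level"): np.array([0, 0, 0, 1, 0, 0.0]),
            ("control_vs_fluct", "trend"): np.array([0, 0, 0, 0, 0, 1.0]),
            ("fixed_vs_fluct", "level"): np.array([0, 0, 1, -1, 0, 0.0]),
            ("fixed_vs_fluct", "trend"): np.array([0, 0, 0, 0, 1, -1.0]),
        }
        for (name, kind), c in specs.items():
            est = float(c @ fe)
            var = float(c @ cov @ c)
            se = float(np.sqrt(var)) if np.isfinite(var) and var > 0 else np.nan
            z, p = _wald(est, se)
            rows.append(
                {
                    "center": label,
                    "contrast": name,
                    "type": kind,
                    "estimate": est,
                    "se": se,
                    "z": z,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    last = (out["center"] == "last").to_numpy()
    pvals = out.loc[last, "p"].to_numpy()
    finite = np.isfinite(pvals)
    adj = np.full_like(pvals, np.nan)
    if finite.any():
        adj[finite] = fdr_adjust(pvals[finite])
    out.loc[last, "p_fdr"] = adj
    return out


def control_vs_extreme_prephase(
    table: pd.DataFrame, response: str = "value"
) -> pd.DataFrame:
    """Control vs extreme-only comparison before the extremes.

    Treatment, time and their interaction as fixed effects; random intercept
    per plot only (no random slope), as appropriate for the short pre-phase
    series.
    """
    df = table[table["treatment"].isin([CONTROL, "extreme-only"])].copy()
    if df["treatment"].nunique() < 2:
        raise ValidationError("need both control and extreme-only plots")
    time_c = df["date"].to_numpy(dtype=float)
    time_c = time_c - time_c.min()
    d = (df["treatment"] == "extreme-only").astype(float).to_numpy()
    X = np.column_stack([np.ones(len(df)), time_c, d, d * time_c])
    res, _, _ = _fit_mixedlm(
        df[response].to_numpy(dtype=float), X, df["plot_id"].to_numpy(), time_c, False
    )
    fe = np.asarray(res.fe_params)
    se = np.asarray(res.bse_fe)
    rows = []
    for i, term in ((2, "extreme_only"), (3, "extreme_only:time")):
        z, p = _wald(fe[i], se[i])
        rows.append({"term": term, "estimate": fe[i], "se": se[i], "z": z, "p": p})
    return pd.DataFrame(rows)


def artifact_control_test(table: pd.DataFrame, response: str = "value") -> pd.DataFrame:
    """Control vs artifact-control (shaded, unwarmed) with treatment only."""
    df = table[table["treatment"].isin([CONTROL, "artifact-control"])].copy()
    if df["treatment"].nunique() < 2:
        raise ValidationError("need both control and artifact-control plots")
    d = (df["treatment"] == "artifact-control").astype(float).to_numpy()
    X = np.column_stack([np.ones(len(df)), d])
    res = _fit_plain_mixedlm(df[response].to_numpy(dtype=float), X, df["plot_id"].to_numpy())
    fe = np.asarray(res.fe_params)
    se = np.asarray(res.bse_fe)
    z, p = _wald(fe[1], se[1])
    return pd.DataFrame(
        [{"term": "artifact_control", "estimate": fe[1], "se": se[1], "z": z, "p": p}]
    )
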