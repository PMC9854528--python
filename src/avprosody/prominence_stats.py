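"""Positional summary curves and brow-peak magnitude models.

Two questions are answered here.  First, descriptively: how do eyebrow height
and pitch behave, on average, around the brow-raise peak?  (Smoothed positional
curves with pointwise 95% bands, optionally split into low / high raises at a
1.5-SD peak threshold.)  Second, inferentially: do the sinusoid parameters of
the pre- and post-peak pitch contours predict the magnitude of the brow raise?
(Linear mixed models with a per-speaker random intercept, REML estimation,
Satterthwaite degrees of freedom.)

statsmodels' MixedLM performs the REML fit; the Satterthwaite approximation is
implemented here on top of it, using the closed-form restricted likelihood of
the random-intercept model and a finite-difference information matrix, so that
t-tests carry per-coefficient denominator df as in lme4/lmerTest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.interpolate import BSpline

from .errors import (
    BasisError,
    CollinearityError,
    DegenerateGroupingError,
    InsufficientDataError,
    NoOverlapError,
)
from .measurements_io import POSITIONS
from .peak_windows import SegmentWindow

#: Predictors of the combined model: the ones significant in the separate
#: pre (size-19) and post (size-17) models.
COMBINED_PREDICTORS = ("A_pre", "f_pre", "phi_pre", "A_post", "f_post")


@dataclass
class PositionalSummary:
    """Smoothed mean curve of one signal across window positions."""

    positions: np.ndarray
    mean: np.ndarray
    lower: np.ndarray  # pointwise 95% band
    upper: np.ndarray
    k: int
    signal: str
    subset: str = "all"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "mean": self.mean,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


@dataclass
class MixedModelResult:
    """Fixed effects plus variance components of one mixed model."""

    fixed_effects: pd.DataFrame  # index: term; columns: estimate, std_error, df, t, p
    random_intercept_variance: float
    residual_variance: float
    n_obs: int
    n_groups: int
    region: str
    window_sizes: tuple[int, ...]
    loglik: float
    aic_ml: float | None = None

    def to_frame(self) -> pd.DataFrame:
        out = self.fixed_effects.reset_index().rename(columns={"index": "term"})
        return out


def _bspline_basis(x: np.ndarray, k: int, lo: float, hi: float) -> np.ndarray:
    """Full cubic B-spline basis of dimension k on [lo, hi] (spans constants)."""
    degree = 3
    n_interior = k - degree - 1
    if n_interior < 0:
        raise BasisError(f"basis size k={k} too small for cubic splines (need >= 4)")
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()


def positional_summary(
    windows: list[SegmentWindow],
    signal: str = "eyebrow",
    k: int = 30,
    subset_rule=None,
    subset_label: str = "all",
) -> PositionalSummary:
    """Penalized-spline-style smooth of value vs. position, pooled over windows.

    Fits an OLS regression on a cubic B-spline basis of size ``k`` (at k equal
    to the number of positions the smooth interpolates the per-position means)
    and reports the mean curve with pointwise 95% confidence bands.
    """
    if subset_rule is not None:
        windows = [w for w in windows if subset_rule(w)]
    if not windows:
        raise InsufficientDataError("no windows after subsetting")
    mat = np.stack([getattr(w, signal) for w in windows])
    pos = np.tile(POSITIONS, len(windows)).astype(float)
    val = mat.ravel()
    ok = ~np.isnan(val)
    pos, val = pos[ok], val[ok]
    n_distinct = len(np.unique(pos))
    if k > n_distinct:
        raise BasisError(f"basis size k={k} exceeds {n_distinct} distinct positions")
    if k < n_distinct and len(val) <= k + 2:
        raise InsufficientDataError("too few observations for the requested basis")
    X = _bspline_basis(pos, k, float(POSITIONS[0]), float(POSITIONS[-1]))
    fit = sm.OLS(val, X).fit()
    Xg = _bspline_basis(POSITIONS.astype(float), k, float(POSITIONS[0]), float(POSITIONS[-1]))
    pred = fit.get_prediction(Xg)
    mean = np.asarray(pred.predicted_mean)
    # an interpolating basis can round variances to tiny negatives; clip
    se = np.sqrt(np.clip(np.asarray(pred.var_pred_mean), 0.0, None))
    tq = stats.t.ppf(0.975, max(int(fit.df_resid), 1))
    return PositionalSummary(
        positions=POSITIONS.copy(),
        mean=mean,
        lower=mean - tq * se,
        upper=mean + tq * se,
        k=k,
        signal=signal,
        subset=subset_label,
    )


def split_by_peak(
    windows: list[SegmentWindow], threshold: float = 1.5
) -> tuple[list[SegmentWindow], list[SegmentWindow]]:
    """Partition windows into (low, high) raises at a peak-height threshold.

    Boundary values (peak exactly at the threshold) go to the high set.
    """
    low = [w for w in windows if w.peak_height < threshold]
    high = [w for w in windows if w.peak_height >= threshold]
    return low, high


# ---------------------------------------------------------------------------
# Random-intercept LMM: REML restricted likelihood and Satterthwaite df


def _reml_loglik(theta: np.ndarray, y, X, group_idx, group_sizes) -> float:
    """Restricted log-likelihood of y = X b + u_group + e at theta=(sigma2, tau).

    V is block diagonal: sigma2*I + tau*J per group, inverted in closed form
    (Sherman-Morrison), so evaluation is O(n).
    """
    sigma2, tau = theta
    if sigma2 <= 0 or tau < 0:
        return -np.inf
    # accumulate X'V^-1 X, X'V^-1 y, y'V^-1 y, log|V|
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    for g, n_g in enumerate(group_sizes):
        sl = group_idx[g]
        Xg, yg = X[sl], y[sl]
        c = tau / (sigma2 + n_g * tau)
        sx, sy = Xg.sum(axis=0), yg.sum()
        xtvx += (Xg.T @ Xg - c * np.outer(sx, sx)) / sigma2
        xtvy += (Xg.T @ yg - c * sx * sy) / sigma2
        ytvy += (yg @ yg - c * sy * sy) / sigma2
        logdet += (n_g - 1) * np.log(sigma2) + np.log(sigma2 + n_g * tau)
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(xtvx, xtvy)
    quad = ytvy - beta @ xtvy
    return -0.5 * (logdet + logdet_x + quad)


def _beta_cov(theta, X, group_idx, group_sizes) -> np.ndarray:
    """(X' V(theta)^-1 X)^-1."""
    sigma2, tau = theta
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    for g, n_g in enumerate(group_sizes):
        Xg = X[group_idx[g]]
        c = tau / (sigma2 + n_g * tau)
        sx = Xg.sum(axis=0)
        xtvx += (Xg.T @ Xg - c * np.outer(sx, sx)) / sigma2
    return np.linalg.inv(xtvx)


def _satterthwaite_df(theta, y, X, group_idx, group_sizes) -> np.ndarray:
    """Per-coefficient Satterthwaite denominator df.

    df_j = 2 * var_j^2 / (g_j' W g_j), where var_j = [C(theta)]_jj with
    C = (X'V^-1 X)^-1, g_j its gradient in theta (finite differences), and W
    the inverse observed information of the restricted likelihood.
    """
    theta = np.asarray(theta, dtype=float)
    p = X.shape[1]
    h = np.maximum(np.abs(theta), 1e-6) * 1e-5

    def var_vec(th):
        return np.diag(_beta_cov(th, X, group_idx, group_sizes))

    grads = np.zeros((2, p))
    for i in range(2):
        e = np.zeros(2)
        e[i] = h[i]
        if theta[i] - h[i] > 0:
            grads[i] = (var_vec(theta + e) - var_vec(theta - e)) / (2 * h[i])
        else:  # one-sided at the tau >= 0 boundary
            grads[i] = (var_vec(theta + e) - var_vec(theta)) / h[i]

    def nll(th):
        return -_reml_loglik(th, y, X, group_idx, group_sizes)

    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.zeros(2)
            ej = np.zeros(2)
            ei[i], ej[j] = h[i], h[j]
            th_pp = np.maximum(theta + ei + ej, 1e-12)
            th_pm = np.maximum(theta + ei - ej, 1e-12)
            th_mp = np.maximum(theta - ei + ej, 1e-12)
            th_mm = np.maximum(theta - ei - ej, 1e-12)
            H[i, j] = (nll(th_pp) - nll(th_pm) - nll(th_mp) + nll(th_mm)) / (
                4 * h[i] * h[j]
            )
    try:
        W = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        W = np.linalg.pinv(H)
    var = var_vec(theta)
    df = np.empty(p)
    for jdx in range(p):
        g = grads[:, jdx]
        denom = float(g @ W @ g)
        n_total = len(y)
        if denom <= 0 or not np.isfinite(denom):
            df[jdx] = n_total - p  # fall back to residual df
        else:
            df[jdx] = 2.0 * var[jdx] ** 2 / denom
            df[jdx] = min(max(df[jdx], 1.0), float(n_total - p))
    return df


def _fit_mixedlm(y, X, groups, reml: bool):
    """MixedLM fit with optimizer fallbacks (small-sample paths can be fragile)."""
    last_exc: Exception | None = None
    for method in ("powell", "lbfgs", "cg", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return sm.MixedLM(y, X, groups=groups).fit(reml=reml, method=[method])
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
    raise last_exc


def _design(
    fit_table: pd.DataFrame, predictors: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    X = np.column_stack(
        [np.ones(len(fit_table))] + [fit_table[p].to_numpy(dtype=float) for p in predictors]
    )
    names = ["Intercept", *predictors]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(f"rank-deficient design with predictors {predictors}")
    return X, names


def fit_peak_model(
    fit_table: pd.DataFrame,
    response: str = "peak_height",
    predictors: tuple[str, ...] = ("I", "A", "f", "phi"),
    grouping: str = "speaker",
    region: str = "",
    window_sizes: tuple[int, ...] = (),
    random_intercept: bool = True,
    reml: bool = True,
) -> MixedModelResult:
    """Mixed linear model: peak height ~ sinusoid parameters + (1 | speaker).

    ``fit_table`` must hold one row per segment with the response, the
    predictors, and the grouping column; rows with missing values are dropped.
    With ``random_intercept=False`` the model degrades to OLS (identical fixed
    effects when the intercept variance is zero).
    """
    cols = [response, grouping, *predictors]
    missing = [c for c in cols if c not in fit_table.columns]
    if missing:
        raise KeyError(f"fit table lacks columns {missing}")
    data = fit_table.dropna(subset=cols)
    if len(data) < 10:
        raise InsufficientDataError(f"need >= 10 observations, got {len(data)}")
    groups = data[grouping].to_numpy()
    uniq = np.unique(groups)
    if random_intercept and len(uniq) < 2:
        raise DegenerateGroupingError("random intercept requires >= 2 speakers")
    y = data[response].to_numpy(dtype=float)
    X, names = _design(data, predictors)

    if not random_intercept:
        ols = sm.OLS(y, X).fit()
        fe = pd.DataFrame(
            {
                "estimate": ols.params,
                "std_error": ols.bse,
                "df": float(ols.df_resid),
                "t": ols.tvalues,
                "p": ols.pvalues,
            },
            index=names,
        )
        return MixedModelResult(
            fixed_effects=fe,
            random_intercept_variance=0.0,
            residual_variance=float(ols.mse_resid),
            n_obs=len(y),
            n_groups=len(uniq),
            region=region,
            window_sizes=tuple(window_sizes),
            loglik=float(ols.llf),
            aic_ml=float(ols.aic),
        )

    res = _fit_mixedlm(y, X, groups, reml=reml)
    sigma2 = float(res.scale)
    cov_re = np.asarray(res.cov_re)
    tau = float(cov_re[0, 0]) if cov_re.size else 0.0

    order = np.argsort(groups, kind="stable")
    ys, Xs, gs = y[order], X[order], groups[order]
    group_sizes = [int((gs == u).sum()) for u in uniq]
    slices = []
    start = 0
    for n_g in group_sizes:
        slices.append(slice(start, start + n_g))
        start += n_g

    theta = np.array([sigma2, max(tau, 1e-10)])
    cov_beta = _beta_cov(theta, Xs, slices, group_sizes)
    se = np.sqrt(np.diag(cov_beta))
    beta = np.asarray(res.fe_params)
    dfs = _satterthwaite_df(theta, ys, Xs, slices, group_sizes)
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dfs)
    fe = pd.DataFrame(
        {"estimate": beta, "std_error": se, "df": dfs, "t": tvals, "p": pvals},
        index=names,
    )
    # AIC from an ML refit (REML likelihoods are not comparable across fixed effects)
    res_ml = _fit_mixedlm(y, X, groups, reml=False)
    k_par = X.shape[1] + 2
    aic_ml = float(-2 * res_ml.llf + 2 * k_par)
    return MixedModelResult(
        fixed_effects=fe,
        random_intercept_variance=tau,
        residual_variance=sigma2,
        n_obs=len(y),
        n_groups=len(uniq),
        region=region,
        window_sizes=tuple(window_sizes),
        loglik=float(res.llf),
        aic_ml=aic_ml,
    )


def make_model_table(
    fits: pd.DataFrame,
    peaks: pd.DataFrame,
    region: str,
    window_size: int,
) -> pd.DataFrame:
    """Join one region's fits at one window size with per-segment peak heights."""
    sub = fits[
        (fits["region"] == region)
        & (fits["window_size"] == window_size)
        & (~fits["skipped"].astype(bool))
    ]
    merged = sub.merge(
        peaks[["segment_id", "speaker", "peak_height"]],
        on=["segment_id", "speaker"],
        how="inner",
    )
    return merged


def select_best_window(
    models: dict[int, MixedModelResult]
) -> tuple[int, MixedModelResult, pd.DataFrame]:
    """Pick the window size whose model minimizes ML-AIC (ties -> smallest size).

    Returns (size, model, criterion table) so callers can apply alternatives.
    """
    if not models:
        raise InsufficientDataError("no candidate models")
    table = pd.DataFrame(
        {
            "window_size": list(models.keys()),
            "aic_ml": [m.aic_ml for m in models.values()],
            "n_obs": [m.n_obs for m in models.values()],
        }
    ).sort_values(["aic_ml", "window_size"], kind="stable")
    best_size = int(table.iloc[0]["window_size"])
    return best_size, models[best_size], table.reset_index(drop=True)


def combined_model(
    pre_fits: pd.DataFrame,
    post_fits: pd.DataFrame,
    peaks: pd.DataFrame,
    pre_size: int = 19,
    post_size: int = 17,
    grouping: str = "speaker",
    random_intercept: bool = True,
) -> MixedModelResult:
    """Model with predictors from both regions: {A,f,phi}_pre + {A,f}_post.

    Segments must appear in both fit tables (inner join); the predictor set is
    the variables significant in the separate per-region models.
    """
    pre = make_model_table(pre_fits, peaks, "pre", pre_size)
    post = make_model_table(post_fits, peaks, "post", post_size)
    merged = pre.merge(
        post,
        on=["segment_id", "speaker", "peak_height"],
        suffixes=("_pre", "_post"),
        how="inner",
    )
    if len(merged) == 0:
        raise NoOverlapError("no segments present in both pre and post fit tables")
    return fit_peak_model(
        merged,
        predictors=COMBINED_PREDICTORS,
        grouping=grouping,
        region="combined",
        window_sizes=(pre_size, post_size),
        random_intercept=random_intercept,
    )
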