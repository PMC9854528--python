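"""Baseline-shifted sinusoid model of short pitch contours.

The model is

    y(t) = I + A * sin(2*pi*f*t + phi*pi)

with baseline shift I (pitch units), amplitude A >= 0, ordinary frequency f
(cycles per second), and phase phi in [0, 2) expressed in units of pi radians.
Amplitude and frequency quantify the *dynamicity* of a contour — how far and
how fast pitch moves — while phi captures its shape: where in the cycle the
window starts.  Phases are categorized into quadrants: high-rising
(0 <= phi < 0.5), high-falling (0.5 <= phi < 1), low-falling (1 <= phi < 1.5),
low-rising (1.5 <= phi < 2).

Fitting uses variable projection: for fixed f the model is linear in
(I, a, b) with y = I + a*sin(2*pi*f*t) + b*cos(2*pi*f*t), where
A = hypot(a, b) and phi*pi = atan2(b, a).  The nonlinear problem therefore
reduces to a one-dimensional search over f, solved by a dense presolve grid
followed by local refinement of the best candidates — cheap, deterministic,
and immune to the phase local minima that plague 4-parameter starts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import (
    InsufficientDataError,
    PhaseRangeError,
    UndefinedRSquaredError,
    UnidentifiableFrequencyError,
)
from .peak_windows import SegmentWindow, interpolate_missing

FPS = 30.0

#: f starts (cycles/s) retained from the classic multi-start scheme; the dense
#: presolve grid is layered on top of these.
F_STARTS = (0.3, 0.6, 1.0, 1.6, 2.4)
F_BOUNDS = (0.05, 5.0)

PHASE_LABELS = ("high_rising", "high_falling", "low_falling", "low_rising")


@dataclass(frozen=True)
class SineParams:
    """Canonical parameters: A >= 0, f > 0, phi in [0, 2) (units of pi)."""

    I: float
    A: float
    f: float
    phi: float


@dataclass
class SineFit:
    """Result of fitting one region of one window."""

    params: SineParams
    r2: float
    sse: float
    window_size: int
    region: str  # "pre" or "post"
    segment_id: str
    converged: bool
    n_missing_interpolated: int
    skipped: bool = False
    skip_reason: str | None = None


def sine_value(params: SineParams, t) -> np.ndarray | float:
    """Evaluate y = I + A*sin(2*pi*f*t + phi*pi)."""
    t = np.asarray(t, dtype=float)
    y = params.I + params.A * np.sin(2 * np.pi * params.f * t + params.phi * np.pi)
    return float(y) if y.ndim == 0 else y


def normalize_params(I: float, A: float, f: float, phi: float) -> SineParams:
    """Map raw (I, A, f, phi) to the unique equivalent canonical set.

    Uses sin(-x) = sin(x + pi) and sin's 2*pi periodicity; the curve is
    pointwise unchanged.  A negative frequency flips the sign of the time
    argument: sin(-w t + p) = sin(w t + (pi - p) + pi)... handled by negating
    both A-phase jointly via f -> -f, phi -> -phi symmetry of the composed map.
    """
    if f == 0:
        raise UnidentifiableFrequencyError("f = 0: phase and amplitude not unique")
    if f < 0:
        # sin(2*pi*(-|f|)t + phi*pi) = -sin(2*pi*|f|*t - phi*pi)
        f, A, phi = -f, -A, -phi
    if A < 0:
        A = -A
        phi = phi + 1.0
    phi = phi % 2.0
    if phi >= 2.0:  # tiny negative inputs round to exactly 2.0 under fmod
        phi = 0.0
    return SineParams(I=float(I), A=float(A), f=float(f), phi=float(phi))


def phase_category(phi: float) -> str:
    """Quadrant label of a canonical phase (units of pi, in [0, 2))."""
    if not (0.0 <= phi < 2.0):
        raise PhaseRangeError(f"phi {phi} outside [0, 2); normalize first")
    return PHASE_LABELS[int(phi // 0.5)]


def r_squared(predicted: np.ndarray, values: np.ndarray) -> float:
    """1 - SSE/SST with SST about the mean of ``values``."""
    values = np.asarray(values, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    sst = float(np.sum((values - values.mean()) ** 2))
    if sst == 0:
        raise UndefinedRSquaredError("constant data: r-squared undefined")
    sse = float(np.sum((values - predicted) ** 2))
    return 1.0 - sse / sst


def _projected_sse(f: float, t: np.ndarray, y: np.ndarray):
    """Best linear (I, a, b) for fixed f; returns (sse, coef).

    Solves the 3x3 normal equations directly (the design is tiny and well
    scaled for the short windows fitted here); falls back to lstsq if the
    system is numerically singular (e.g. f*t spanning < one sample period).
    """
    w = 2 * np.pi * f * t
    X = np.column_stack([np.ones_like(t), np.sin(w), np.cos(w)])
    xtx = X.T @ X
    xty = X.T @ y
    try:
        coef = np.linalg.solve(xtx, xty)
    except np.linalg.LinAlgError:
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef


def fit_sine(
    times: np.ndarray,
    values: np.ndarray,
    f_bounds: tuple[float, float] = F_BOUNDS,
    n_grid: int = 64,
) -> tuple[SineParams, float, bool]:
    """Least-squares fit of the baseline-shifted sinusoid.

    Returns (canonical params, SSE, converged).  Constant input yields
    A = 0, I = mean, converged = True with an arbitrary (unidentifiable)
    phase/frequency of (f_lo, 0).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) < 5:
        raise InsufficientDataError(f"need >= 5 points to fit, got {len(t)}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.ptp(y) == 0:
        return SineParams(I=float(y.mean()), A=0.0, f=f_bounds[0], phi=0.0), 0.0, True

    lo, hi = f_bounds
    # Amplitude bound: 5x the data range, ruling out the degenerate low-f
    # regime where the sine is locally linear and A diverges.  An essentially
    # exact fit is exempt: a shallow crest sampled over a fraction of a cycle
    # can truly have A > 5*ptp, and an exact interpolant is unambiguous
    # evidence for it.  The unconstrained profile is searched first; only a
    # non-exact, bound-violating optimum triggers a penalized re-search.
    a_max = 5.0 * float(np.ptp(y))
    sst = float(np.sum((y - y.mean()) ** 2))
    exact_tol = 1e-10 * sst

    def sse_only(f: float) -> float:
        return _projected_sse(f, t, y)[0]

    def penalized(f: float) -> float:
        sse, coef = _projected_sse(f, t, y)
        amp = float(np.hypot(coef[1], coef[2]))
        if amp > a_max:  # soft barrier keeps the 1-D profile continuous
            sse += (amp - a_max) ** 2 * len(y)
        return sse

    grid = np.unique(
        np.concatenate([np.geomspace(lo, hi, n_grid), np.asarray(F_STARTS)])
    )
    best_f, best_sse, converged = _search_profile(sse_only, grid)
    _, best_coef = _projected_sse(best_f, t, y)
    amp = float(np.hypot(best_coef[1], best_coef[2]))
    if amp > a_max and best_sse > exact_tol:
        best_f, _, converged = _search_profile(penalized, grid)
        _, best_coef = _projected_sse(best_f, t, y)
        amp = float(np.hypot(best_coef[1], best_coef[2]))
    I0, a, b = best_coef
    if amp > a_max and sse_only(best_f) > exact_tol:
        # boundary solution: project onto the amplitude bound
        scale = a_max / amp
        a, b = a * scale, b * scale
        w = 2 * np.pi * best_f * t
        I0 = float(np.mean(y - a * np.sin(w) - b * np.cos(w)))
    resid = y - (I0 + a * np.sin(2 * np.pi * best_f * t) + b * np.cos(2 * np.pi * best_f * t))
    best_sse = float(resid @ resid)
    A = float(np.hypot(a, b))
    phi = float(np.arctan2(b, a) / np.pi)
    params = normalize_params(I=float(I0), A=A, f=best_f, phi=phi)
    return params, best_sse, bool(converged)


def _search_profile(fun, grid: np.ndarray) -> tuple[float, float, bool]:
    """Minimize a 1-D profile: grid presolve, Brent refinement of local minima."""
    vals = np.array([fun(f) for f in grid])
    interior = np.r_[False, (vals[1:-1] < vals[:-2]) & (vals[1:-1] < vals[2:]), False]
    seeds = set(np.flatnonzero(interior).tolist()) | {int(np.argmin(vals))}
    best_f, best_val, converged = float(grid[0]), np.inf, False
    for i in sorted(seeds):
        f_lo = grid[max(i - 1, 0)]
        f_hi = grid[min(i + 1, len(grid) - 1)]
        if f_hi <= f_lo:  # degenerate bracket at a boundary
            f_ref, success = float(grid[i]), True
        else:
            res = minimize_scalar(
                fun,
                bounds=(f_lo, f_hi),
                method="bounded",
                options={"xatol": 1e-11, "maxiter": 500},
            )
            f_ref, success = float(res.x), bool(res.success)
        val = fun(f_ref)
        if val < best_val:
            best_f, best_val, converged = f_ref, val, success
    return best_f, best_val, converged


def fit_region(
    window: SegmentWindow,
    region: str,
    window_size: int,
    fps: float = FPS,
    min_coverage: float = 0.75,
) -> SineFit:
    """Fit the sinusoid to one side of a window's pitch contour.

    pre  : positions -(window_size-1) ... 0 (peak included)
    post : positions 0 ... +(window_size-1) (peak included, mirrored)

    Time runs in seconds from the first fitted position: t = (pos - pos0)/fps.
    Missing pitch is linearly interpolated over the *whole* 121-position
    window before slicing the region, so voiceless runs at a region edge are
    bridged from their true neighbors instead of being flat-extended; only
    values missing at the window's own boundary fall back to nearest-value
    extension.  The fit proceeds when at least ``min_coverage`` of the
    region's positions were observed; otherwise it is skip-marked, not raised.
    """
    if region == "pre":
        idx = np.arange(-(window_size - 1), 1)
    elif region == "post":
        idx = np.arange(0, window_size)
    else:
        raise ValueError(f"region must be 'pre' or 'post', got {region!r}")
    vals = window.pitch[idx + len(window.pitch) // 2]
    n_missing = int(np.isnan(vals).sum())
    skip_reason = None
    if window_size < 5:
        raise ValueError("window_size must be >= 5")
    if (len(vals) - n_missing) / len(vals) < min_coverage:
        skip_reason = f"coverage {(len(vals) - n_missing)}/{len(vals)} below {min_coverage:.0%}"
    else:
        try:
            filled = interpolate_missing(window.pitch)[idx + len(window.pitch) // 2]
        except InsufficientDataError as exc:
            skip_reason = str(exc)
    if skip_reason is not None:
        return SineFit(
            params=SineParams(np.nan, np.nan, np.nan, np.nan),
            r2=np.nan,
            sse=np.nan,
            window_size=window_size,
            region=region,
            segment_id=window.segment_id,
            converged=False,
            n_missing_interpolated=n_missing,
            skipped=True,
            skip_reason=skip_reason,
        )
    t = (idx - idx[0]) / fps
    params, sse, converged = fit_sine(t, filled)
    try:
        r2 = r_squared(sine_value(params, t), filled)
    except UndefinedRSquaredError:
        r2 = np.nan
    return SineFit(
        params=params,
        r2=r2,
        sse=sse,
        window_size=window_size,
        region=region,
        segment_id=window.segment_id,
        converged=converged,
        n_missing_interpolated=n_missing,
    )


def sweep_window_sizes(
    windows: Iterable[SegmentWindow],
    region: str,
    sizes: Sequence[int] = tuple(range(10, 21)),
    fps: float = FPS,
) -> pd.DataFrame:
    """One fit per (window, size); skip markers preserved.  Deterministic."""
    if not all(5 <= s <= 60 for s in sizes):
        raise ValueError("window sizes must lie within 5..60")
    rows = []
    for w in windows:
        for size in sizes:
            fit = fit_region(w, region, size, fps=fps)
            rows.append(fit_to_row(fit, speaker=w.speaker))
    return pd.DataFrame(
        rows,
        columns=[
            "segment_id",
            "speaker",
            "region",
            "window_size",
            "I",
            "A",
            "f",
            "phi",
            "r2",
            "converged",
            "n_missing_interpolated",
            "skipped",
            "skip_reason",
        ],
    )


def fit_to_row(fit: SineFit, speaker: str = "") -> dict:
    return {
        "segment_id": fit.segment_id,
        "speaker": speaker,
        "region": fit.region,
        "window_size": fit.window_size,
        "I": fit.params.I,
        "A": fit.params.A,
        "f": fit.params.f,
        "phi": fit.params.phi,
        "r2": fit.r2,
        "converged": fit.converged,
        "n_missing_interpolated": fit.n_missing_interpolated,
        "skipped": fit.skipped,
        "skip_reason": fit.skip_reason,
    }


def window_duration_ms(window_size: int, fps: float = FPS) -> float:
    """Duration spanned by a window of n frames at the given frame rate.

    A 19-frame window at 30 fps covers 19/30 s ~ 633 ms (reported as ~630 ms);
    17 frames cover ~567 ms (~570 ms).
    """
    return 1000.0 * window_size / fps
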