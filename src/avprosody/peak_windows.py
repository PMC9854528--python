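"""Segment frame streams, locate eyebrow peaks, and extract analysis windows.

Each subtitle segment contributes one :class:`SegmentWindow`: the 121 positions
-60...+60 of standardized eyebrow height and pitch centered on the frame of
maximal eyebrow height (the "eyebrow peak", position 0).  Positions outside the
segment's frame range are missing (NaN) — windows hold *up to* 60 values on
either side.  The raise-scope test asks, position by position, whether eyebrow
heights are elevated relative to the pooled distribution over all positions,
using rank statistics so the answer is invariant under monotone rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, NoPeakError, OverlapError
from .measurements_io import HALF_WIDTH, POSITIONS, SubtitleSegment


@dataclass
class SegmentWindow:
    """Pitch/eyebrow series at positions -60...+60 around a segment's eyebrow peak."""

    segment_id: str
    speaker: str
    peak_frame: int
    peak_height: float
    eyebrow: np.ndarray  # length 121, NaN where outside the segment
    pitch: np.ndarray  # length 121, NaN where voiceless or outside
    short_segment: bool = False  # segment shorter than the default fit window

    def __post_init__(self) -> None:
        self.eyebrow = np.asarray(self.eyebrow, dtype=float)
        self.pitch = np.asarray(self.pitch, dtype=float)
        if self.eyebrow.shape != (len(POSITIONS),) or self.pitch.shape != (
            len(POSITIONS),
        ):
            raise ValueError("window arrays must have length 121")

    @property
    def positions(self) -> np.ndarray:
        return POSITIONS


@dataclass
class ScopeResult:
    """Per-position elevation test of eyebrow heights around the peak."""

    positions: np.ndarray
    p_values: np.ndarray  # corrected, two-sided
    elevated: np.ndarray  # bool: position median above pooled (rank direction)
    significant_positions: set[int]  # corrected-significant AND elevated
    alpha: float
    correction: str

    def significant_run(self) -> tuple[int, int] | None:
        """Largest contiguous run of significant positions, as (lo, hi) inclusive."""
        if not self.significant_positions:
            return None
        pos = np.array(sorted(self.significant_positions))
        breaks = np.where(np.diff(pos) > 1)[0]
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, len(pos) - 1]
        lengths = ends - starts
        k = int(np.argmax(lengths))
        return int(pos[starts[k]]), int(pos[ends[k]])


def attach_segments(
    records: pd.DataFrame, segments: list[SubtitleSegment], episode: str | None = None
) -> pd.DataFrame:
    """Fill ``segment_id`` for every frame inside a subtitle interval.

    Intervals are half-open [start, end); frames outside any segment keep a
    missing segment_id.  Overlapping segments within an episode are an error.
    """
    segs = sorted(segments, key=lambda s: s.start_frame)
    for a, b in zip(segs, segs[1:]):
        if b.start_frame < a.end_frame:
            raise OverlapError(
                f"segments {a.segment_id} and {b.segment_id} overlap "
                f"([{a.start_frame},{a.end_frame}) vs [{b.start_frame},{b.end_frame}))"
            )
    out = records.copy()
    mask = np.ones(len(out), dtype=bool) if episode is None else (
        out["episode"].to_numpy() == episode
    )
    frames = out["frame"].to_numpy()
    starts = np.array([s.start_frame for s in segs])
    ends = np.array([s.end_frame for s in segs])
    ids = np.array([s.segment_id for s in segs], dtype=object)
    idx = np.searchsorted(starts, frames, side="right") - 1
    valid = mask & (idx >= 0)
    valid[valid] &= frames[valid] < ends[idx[valid]]
    assigned = np.full(len(out), pd.NA, dtype=object)
    assigned[valid] = ids[idx[valid]]
    out.loc[mask, "segment_id"] = assigned[mask]
    return out


def find_eyebrow_peak(segment: pd.DataFrame) -> tuple[int, float]:
    """Frame and height of the segment's maximal eyebrow value (earliest tie wins)."""
    seg = segment.sort_values("frame", kind="stable")
    vals = seg["eyebrow_height"].to_numpy(dtype=float)
    if np.all(np.isnan(vals)):
        raise NoPeakError("segment has no non-missing eyebrow values")
    i = int(np.nanargmax(vals))  # nanargmax returns the first maximal index
    return int(seg["frame"].iloc[i]), float(vals[i])


def extract_window(
    segment: pd.DataFrame,
    peak_frame: int,
    half_width: int = HALF_WIDTH,
    fit_span: int = 19,
) -> SegmentWindow:
    """Copy pitch/eyebrow values to positions -half_width...+half_width.

    Values are taken only from frames inside the segment; everything else is
    NaN.  ``fit_span`` marks windows from segments shorter than the default
    fitting window as ``short_segment`` (they are retained, not dropped).
    """
    seg = segment.sort_values("frame", kind="stable")
    frames = seg["frame"].to_numpy()
    if not (frames[0] <= peak_frame <= frames[-1]):
        raise ValueError(f"peak frame {peak_frame} outside segment range")
    n = 2 * half_width + 1
    eyebrow = np.full(n, np.nan)
    pitch = np.full(n, np.nan)
    rel = frames - peak_frame
    ok = (rel >= -half_width) & (rel <= half_width)
    eyebrow[rel[ok] + half_width] = seg["eyebrow_height"].to_numpy(dtype=float)[ok]
    pitch[rel[ok] + half_width] = seg["pitch"].to_numpy(dtype=float)[ok]
    peak_height = eyebrow[half_width]
    return SegmentWindow(
        segment_id=str(seg["segment_id"].iloc[0]),
        speaker=str(seg["speaker"].iloc[0]),
        peak_frame=int(peak_frame),
        peak_height=float(peak_height),
        eyebrow=eyebrow,
        pitch=pitch,
        short_segment=len(frames) < fit_span,
    )


def build_windows(records: pd.DataFrame, half_width: int = HALF_WIDTH) -> list[SegmentWindow]:
    """Per segment: find the eyebrow peak and extract its window."""
    windows = []
    with_seg = records.dropna(subset=["segment_id"])
    for _, seg in with_seg.groupby("segment_id", sort=True):
        try:
            peak_frame, _ = find_eyebrow_peak(seg)
        except NoPeakError:
            continue
        windows.append(extract_window(seg, peak_frame, half_width=half_width))
    return windows


def interpolate_missing(values: np.ndarray) -> np.ndarray:
    """Fill NaN runs by linear interpolation; extend edges with the nearest value.

    Exact on affine signals; never changes non-missing entries.  A single
    observed value extends to a constant series; an all-missing input is an
    error.
    """
    v = np.asarray(values, dtype=float)
    good = np.flatnonzero(~np.isnan(v))
    if len(good) < 1:
        raise InsufficientDataError("cannot interpolate an all-missing series")
    x = np.arange(len(v))
    out = v.copy()
    out[np.isnan(v)] = np.interp(x[np.isnan(v)], good, v[good])
    return out


def raise_scope(
    windows: list[SegmentWindow],
    alpha: float = 0.05,
    correction: str = "holm",
    signal: str = "eyebrow",
) -> ScopeResult:
    """Which window positions carry significantly elevated eyebrow heights?

    At every position p a two-sided Mann-Whitney U test compares the values at
    p against the pooled values over all positions and windows.  P-values are
    corrected (Holm by default); ``significant_positions`` keeps only the
    corrected-significant positions whose rank direction is *elevated*
    (common-language effect size > 1/2), since the raise scope is about
    heights above, not below, the norm.
    """
    if len(windows) < 2:
        raise InsufficientDataError("raise_scope needs at least 2 windows")
    mat = np.stack([getattr(w, signal) for w in windows])  # (n_windows, 121)
    pooled = mat[~np.isnan(mat)]
    pvals = np.ones(len(POSITIONS))
    elevated = np.zeros(len(POSITIONS), dtype=bool)
    tested = np.zeros(len(POSITIONS), dtype=bool)
    for j in range(len(POSITIONS)):
        col = mat[:, j]
        col = col[~np.isnan(col)]
        if len(col) < 2:
            continue
        u, p = mannwhitneyu(col, pooled, alternative="two-sided")
        pvals[j] = p
        elevated[j] = (u / (len(col) * len(pooled))) > 0.5
        tested[j] = True
    corrected = pvals.copy()
    reject = np.zeros(len(POSITIONS), dtype=bool)
    if tested.any():
        rej, corr, _, _ = multipletests(pvals[tested], alpha=alpha, method=correction)
        corrected[tested] = corr
        reject[tested] = rej
    significant = {int(p) for p, r, e in zip(POSITIONS, reject, elevated) if r and e}
    return ScopeResult(
        positions=POSITIONS.copy(),
        p_values=corrected,
        elevated=elevated,
        significant_positions=significant,
        alpha=alpha,
        correction=correction,
    )


def windows_to_frame(windows: list[SegmentWindow], signal: str) -> pd.DataFrame:
    """(segment x position) DataFrame of one signal, for serialization."""
    data = {w.segment_id: getattr(w, signal) for w in windows}
    df = pd.DataFrame.from_dict(data, orient="index", columns=POSITIONS)
    df.index.name = "segment_id"
    return df


def window_meta(windows: list[SegmentWindow]) -> pd.DataFrame:
    """Per-window metadata table (speaker, peak frame/height, flags)."""
    return pd.DataFrame(
        {
            "segment_id": [w.segment_id for w in windows],
            "speaker": [w.speaker for w in windows],
            "peak_frame": [w.peak_frame for w in windows],
            "peak_height": [w.peak_height for w in windows],
            "short_segment": [w.short_segment for w in windows],
        }
    )
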