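"""Tabular and subtitle I/O for the audiovisual-prosody pipeline.

Frame-level measurements travel as pandas DataFrames with a canonical column
order (one row per video frame at 30 fps); missing pitch — voiceless or
undetected frames — is ``NaN`` in memory and the literal token ``NA`` on disk.
SubRip (.srt) subtitle files define the segmentation of an episode into
analysis units; their timestamps are converted to frame indices by flooring.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    DuplicateRecordError,
    EmptyInputError,
    FormatError,
    InvalidIntervalError,
    PositionRangeError,
    SchemaError,
    SrtParseError,
)

#: Canonical column order of a frame table.
FRAME_COLUMNS = (
    "speaker",
    "episode",
    "segment_id",
    "frame",
    "eyebrow_height",
    "lat_angle",
    "sag_angle",
    "pitch",
)

#: On-disk token for a missing value.
NA_TOKEN = "NA"

#: Analysis windows span positions -60 ... +60 around the eyebrow peak.
HALF_WIDTH = 60
POSITIONS = np.arange(-HALF_WIDTH, HALF_WIDTH + 1)


@dataclass(frozen=True)
class SubtitleSegment:
    """One subtitle unit, as a half-open frame interval [start_frame, end_frame)."""

    segment_id: str
    start_frame: int
    end_frame: int
    text: str = ""

    def __post_init__(self) -> None:
        if self.start_frame >= self.end_frame:
            raise InvalidIntervalError(
                f"segment {self.segment_id}: end_frame {self.end_frame} "
                f"<= start_frame {self.start_frame}"
            )


def read_frame_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a tab-separated frame table into the canonical layout.

    Parameters
    ----------
    path
        TSV file with a header row.
    column_map
        Optional mapping from the file's column names to canonical names,
        for loading foreign files whose headers differ.

    Returns
    -------
    DataFrame with :data:`FRAME_COLUMNS`, sorted by (speaker, episode, frame).
    Unparseable or empty pitch cells become NaN (missing).
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[NA_TOKEN, ""]
    )
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = [c for c in FRAME_COLUMNS if c != "segment_id"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"mandatory column missing: {col!r}")
    if "segment_id" not in df.columns:
        df["segment_id"] = pd.NA
    df = df[list(FRAME_COLUMNS)].copy()
    df["frame"] = df["frame"].astype(int)
    for col in ("eyebrow_height", "lat_angle", "sag_angle", "pitch"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    dup = df.duplicated(subset=["episode", "frame", "speaker"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise DuplicateRecordError(
            f"duplicate record for episode={first['episode']!r} "
            f"frame={first['frame']} speaker={first['speaker']!r}"
        )
    if (df["frame"] < 0).any():
        raise SchemaError("negative frame index")
    return df.sort_values(["speaker", "episode", "frame"], kind="stable").reset_index(
        drop=True
    )


def write_frame_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a frame table as canonical TSV, missing values as ``NA``."""
    if len(records) == 0:
        raise EmptyInputError("refusing to write an empty frame table")
    out = records[list(FRAME_COLUMNS)]
    out.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


_TIME_RE = re.compile(r"^(\d{2,}):(\d{2}):(\d{2})[,.](\d{3})$")
_ARROW_RE = re.compile(r"^(\S+)\s+-->\s+(\S+)\s*$")


def _parse_srt_time(token: str, lineno: int) -> float:
    m = _TIME_RE.match(token)
    if not m:
        raise SrtParseError(f"malformed timestamp {token!r}", line=lineno)
    h, mi, s, ms = (int(g) for g in m.groups())
    return h * 3600 + mi * 60 + s + ms / 1000.0


def parse_srt(
    path: str | Path, fps: float = 30.0, episode: str | None = None
) -> list[SubtitleSegment]:
    """Parse a SubRip file into frame-indexed subtitle segments.

    Timestamps map to frames by ``floor(seconds * fps)``; intervals are
    half-open so adjacent subtitles never share a frame.  Segment ids are
    ``"<episode>-<index zero-padded to 4>"`` where the episode defaults to
    the file's stem (``0145.srt`` -> ``0145``).
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    path = Path(path)
    if episode is None:
        episode = path.stem
    segments: list[SubtitleSegment] = []
    lines = path.read_text(encoding="utf-8-sig").splitlines()
    i = 0
    n = len(lines)
    while i < n:
        while i < n and not lines[i].strip():
            i += 1
        if i >= n:
            break
        index_line = lines[i].strip()
        try:
            idx = int(index_line)
        except ValueError:
            raise SrtParseError(f"expected subtitle index, got {index_line!r}", line=i + 1)
        i += 1
        if i >= n:
            raise SrtParseError("unexpected end of file after subtitle index", line=i)
        m = _ARROW_RE.match(lines[i].strip())
        if not m:
            raise SrtParseError(f"expected timestamp line, got {lines[i]!r}", line=i + 1)
        start_s = _parse_srt_time(m.group(1), i + 1)
        end_s = _parse_srt_time(m.group(2), i + 1)
        i += 1
        text_lines: list[str] = []
        while i < n and lines[i].strip():
            text_lines.append(lines[i])
            i += 1
        start_frame = int(np.floor(start_s * fps))
        end_frame = int(np.floor(end_s * fps))
        if end_frame <= start_frame:
            raise InvalidIntervalError(
                f"subtitle {idx}: end {end_s}s does not follow start {start_s}s "
                f"at {fps} fps"
            )
        segments.append(
            SubtitleSegment(
                segment_id=f"{episode}-{idx:04d}",
                start_frame=start_frame,
                end_frame=end_frame,
                text="\n".join(text_lines),
            )
        )
    return segments


def write_window_table(
    series: pd.DataFrame, path: str | Path, orientation: str = "wide"
) -> None:
    """Serialize position-indexed series (rows = segments, cols = -60...60)."""
    if orientation == "wide":
        out = series.copy()
        out.columns = [str(c) for c in out.columns]
        out.index.name = "segment_id"
        out.to_csv(path, sep="\t", na_rep=NA_TOKEN)
    elif orientation == "long":
        long = series.stack(future_stack=True).rename("value").reset_index()
        long.columns = ["segment_id", "position", "value"]
        long = long.dropna(subset=["value"])
        long.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)
    else:
        raise FormatError(f"unknown orientation {orientation!r}")


def read_window_table(path: str | Path, orientation: str | None = None) -> pd.DataFrame:
    """Read a window table into a (segment x position) DataFrame.

    Wide layout: one row per segment with 121 position columns -60...60.
    Long layout: (segment_id, position, value) rows.  With ``orientation=None``
    the layout is auto-detected from the header.  The result always spans
    exactly positions -60...+60; absent cells are NaN.
    """
    head = pd.read_csv(path, sep="\t", nrows=0)
    cols = list(head.columns)
    if orientation is None:
        if set(cols) >= {"segment_id", "position", "value"}:
            orientation = "long"
        elif "segment_id" in cols and any(re.fullmatch(r"-?\d+", c) for c in cols[1:]):
            orientation = "wide"
        else:
            raise FormatError(f"cannot auto-detect window-table layout from {cols!r}")
    if orientation == "wide":
        df = pd.read_csv(
            path, sep="\t", index_col="segment_id", na_values=[NA_TOKEN, ""]
        )
        df.columns = [int(c) for c in df.columns]
        positions = np.asarray(df.columns)
    elif orientation == "long":
        long = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN, ""])
        positions = long["position"].to_numpy()
        df = long.pivot(index="segment_id", columns="position", values="value")
    else:
        raise FormatError(f"unknown orientation {orientation!r}")
    if len(positions) and (positions.min() < -HALF_WIDTH or positions.max() > HALF_WIDTH):
        raise PositionRangeError(
            f"positions outside [-{HALF_WIDTH}, {HALF_WIDTH}]: "
            f"[{positions.min()}, {positions.max()}]"
        )
    df = df.reindex(columns=POSITIONS)
    df.index = df.index.astype(str)
    return df.astype(float)


def validate_frame_table(path: str | Path) -> dict:
    """Light-weight validation used by ``avprosody io validate``.

    Returns a summary dict (row counts, speakers, missing-pitch fraction).
    Raises the same errors as :func:`read_frame_table` on malformed input.
    """
    df = read_frame_table(path)
    return {
        "rows": int(len(df)),
        "speakers": sorted(df["speaker"].unique().tolist()),
        "episodes": sorted(df["episode"].unique().tolist()),
        "missing_pitch_fraction": float(df["pitch"].isna().mean()),
    }
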