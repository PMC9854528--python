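"""Eyebrow height and head angles from 68-point 3D facial landmarks.

Coordinate convention: x to the subject's image-right, y up, z toward the
camera.  Landmark indices follow the standard 68-point annotation (0-based):
eyebrows 17-26, nose block {27, 31, 33, 35} (bridge top, nose-wing extremes,
tip base), outer eye corners {36, 45} as the normalizing distance.  The
eyebrow-height measure is the distance between the brow centroid and the nose
centroid divided by the outer-eye-corner distance, which makes it invariant
under translation, rotation and uniform scaling of the landmark set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateFaceError, ZeroVarianceError

N_LANDMARKS = 68


@dataclass(frozen=True)
class GeometryConfig:
    """Landmark index sets used by the geometric measures."""

    brow_indices: tuple[int, ...] = tuple(range(17, 27))
    nose_indices: tuple[int, ...] = (27, 31, 33, 35)
    scale_indices: tuple[int, int] = (36, 45)

    def __post_init__(self) -> None:
        all_idx = (*self.brow_indices, *self.nose_indices, *self.scale_indices)
        if any(i < 0 or i >= N_LANDMARKS for i in all_idx):
            raise ValueError("landmark index outside 0..67")
        if set(self.brow_indices) & set(self.nose_indices):
            raise ValueError("brow and nose index sets must be disjoint")


DEFAULT_GEOMETRY = GeometryConfig()


def _as_landmarks(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.shape != (N_LANDMARKS, 3):
        raise ValueError(f"expected (68, 3) landmark array, got {pts.shape}")
    if not np.isfinite(pts).all():
        raise ValueError("landmark coordinates must be finite")
    return pts


def eyebrow_height_ratio(
    points: np.ndarray, config: GeometryConfig = DEFAULT_GEOMETRY
) -> float:
    """Distance(brow centroid, nose centroid) / distance(scale pair)."""
    pts = _as_landmarks(points)
    brow = pts[list(config.brow_indices)].mean(axis=0)
    nose = pts[list(config.nose_indices)].mean(axis=0)
    a, b = config.scale_indices
    scale = float(np.linalg.norm(pts[a] - pts[b]))
    if scale <= 1e-12:
        raise DegenerateFaceError("normalizing landmark distance is zero")
    return float(np.linalg.norm(brow - nose) / scale)


def head_angles(points: np.ndarray) -> tuple[float, float]:
    """Signed (lateral, sagittal) head angles in degrees.

    lateral
        Rotation of the inter-ocular axis (outer eye corner 36 -> 45) about
        the camera's depth axis; positive = head tilted so the subject's
        image-left eye rises (counter-clockwise on screen).
    sagittal
        Elevation of the face's vertical axis (nose-bridge top 27 -> chin 8)
        out of the frontal x-y plane; positive = head pitched up (chin
        swinging toward the camera).  A frontal, symmetric face yields (0, 0).
    """
    pts = _as_landmarks(points)
    eye_axis = pts[45] - pts[36]
    if np.linalg.norm(eye_axis[:2]) <= 1e-12:
        raise DegenerateFaceError("inter-ocular axis has no in-plane extent")
    lateral = np.degrees(np.arctan2(eye_axis[1], eye_axis[0]))
    face_axis = pts[8] - pts[27]  # points downward (-y) on a frontal face
    planar = np.hypot(face_axis[0], face_axis[1])
    if planar <= 1e-12 and abs(face_axis[2]) <= 1e-12:
        raise DegenerateFaceError("face vertical axis is degenerate")
    sagittal = np.degrees(np.arctan2(face_axis[2], planar))
    return float(lateral), float(sagittal)


def standardize_by_speaker(
    df: pd.DataFrame,
    columns: tuple[str, ...] = ("eyebrow_height", "pitch"),
    by: str = "speaker",
) -> pd.DataFrame:
    """Z-score the given columns within each speaker (sample SD, ddof=1).

    Missing values pass through unchanged and are excluded from the moments.
    Raises :class:`ZeroVarianceError` naming the speaker if a group is
    constant in any requested column.
    """
    out = df.copy()
    for col in columns:
        grp = out.groupby(by, sort=False)[col]
        sd = grp.transform("std")
        bad = (sd <= 0) | ((sd.isna()) & out[col].notna())
        if bad.any():
            speaker = out.loc[bad.idxmax(), by]
            raise ZeroVarianceError(
                f"speaker {speaker!r}: column {col!r} has zero variance"
            )
        out[col] = (out[col] - grp.transform("mean")) / sd
    return out


# ---------------------------------------------------------------------------
# Synthetic face template (for tests and the geometry CLI's self-check)

def frontal_template(scale: float = 100.0) -> np.ndarray:
    """A symmetric, frontal 68-point face with zero head angles.

    Not a statistical face model: a geometric stand-in whose brow/nose/eye
    landmarks sit at plausible relative locations, used to exercise the
    geometry operations.  All 68 slots are filled; indices not named by
    :class:`GeometryConfig` lie on a coarse oval.
    """
    pts = np.zeros((N_LANDMARKS, 3))
    # jaw 0-16: oval, symmetric about x=0, equal depth
    theta = np.linspace(np.pi, 2 * np.pi, 17)
    pts[0:17, 0] = 0.6 * scale * np.cos(theta)
    pts[0:17, 1] = -0.7 * scale - 0.2 * scale * np.sin(theta + np.pi)
    # brows 17-26: arc above the eyes
    bx = np.linspace(-0.45, 0.45, 10)
    pts[17:27, 0] = bx * scale
    pts[17:27, 1] = 0.35 * scale + 0.05 * scale * (1 - (bx / 0.45) ** 2)
    # nose bridge 27-30 down the midline, protruding toward the camera
    pts[27] = (0, 0.25 * scale, 0.05 * scale)
    pts[28] = (0, 0.15 * scale, 0.10 * scale)
    pts[29] = (0, 0.05 * scale, 0.15 * scale)
    pts[30] = (0, -0.05 * scale, 0.20 * scale)
    # nose base 31-35
    for i, x in zip(range(31, 36), (-0.12, -0.06, 0.0, 0.06, 0.12)):
        pts[i] = (x * scale, -0.12 * scale, 0.10 * scale)
    # eyes 36-41 (subject right), 42-47 (subject left)
    for k, (cx, sgn) in enumerate(((-0.3, -1), (0.3, 1))):
        base = 36 + 6 * k
        ex = np.array([-0.1, -0.05, 0.05, 0.1, 0.05, -0.05]) * sgn
        ey = np.array([0.0, 0.03, 0.03, 0.0, -0.03, -0.03])
        pts[base : base + 6, 0] = (cx + ex) * scale
        pts[base : base + 6, 1] = (0.18 + ey) * scale
    # mouth 48-67: ring on the midline-symmetric lower face
    phi = np.linspace(0, 2 * np.pi, 20, endpoint=False)
    pts[48:68, 0] = 0.2 * scale * np.cos(phi)
    pts[48:68, 1] = -0.4 * scale + 0.08 * scale * np.sin(phi)
    # chin index 8 must share the bridge-top depth for a frontal face
    pts[8, 2] = pts[27, 2]
    return pts


def rotation_matrix(axis: str, degrees: float) -> np.ndarray:
    """Right-handed rotation about 'x' (left-right), 'y' (vertical) or 'z' (depth)."""
    c, s = np.cos(np.radians(degrees)), np.sin(np.radians(degrees))
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    raise ValueError(f"unknown axis {axis!r}")


def landmarks_to_frame_table(
    landmarks: pd.DataFrame, config: GeometryConfig = DEFAULT_GEOMETRY
) -> pd.DataFrame:
    """Convert a landmark table to per-frame geometric measurements.

    Input columns: speaker, episode, frame, then x0,y0,z0 ... x67,y67,z67.
    Output: canonical frame-table columns with raw (un-standardized) eyebrow
    height and head angles; pitch is NaN (it comes from the audio pipeline).
    """
    coord_cols = [f"{ax}{i}" for i in range(N_LANDMARKS) for ax in ("x", "y", "z")]
    rows = []
    for _, rec in landmarks.iterrows():
        pts = rec[coord_cols].to_numpy(dtype=float).reshape(N_LANDMARKS, 3)
        lat, sag = head_angles(pts)
        rows.append(
            {
                "speaker": rec["speaker"],
                "episode": rec["episode"],
                "segment_id": rec.get("segment_id", pd.NA),
                "frame": int(rec["frame"]),
                "eyebrow_height": eyebrow_height_ratio(pts, config),
                "lat_angle": lat,
                "sag_angle": sag,
                "pitch": np.nan,
            }
        )
    return pd.DataFrame(rows)
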