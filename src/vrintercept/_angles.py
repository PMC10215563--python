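"""Angle/vector helpers shared by the generator and the preprocessing chain.

Coordinate convention (documented in the README): right-handed, y up,
+z pointing from the player toward the front wall.  Yaw is rotation about
the vertical (y) axis, positive to the player's right; pitch is elevation
from the horizontal eye-height plane, positive up.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def angles_to_vec(yaw_deg: np.ndarray, pitch_deg: np.ndarray) -> np.ndarray:
    """(yaw, pitch) in degrees -> unit direction vectors, shape (n, 3)."""
    yaw = np.deg2rad(np.asarray(yaw_deg, dtype=float))
    pitch = np.deg2rad(np.asarray(pitch_deg, dtype=float))
    return np.stack(
        [np.cos(pitch) * np.sin(yaw), np.sin(pitch), np.cos(pitch) * np.cos(yaw)],
        axis=-1,
    )


def vec_to_angles(vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit direction vectors -> (yaw, pitch) in degrees."""
    v = np.asarray(vec, dtype=float)
    yaw = np.degrees(np.arctan2(v[..., 0], v[..., 2]))
    pitch = np.degrees(np.arctan2(v[..., 1], np.hypot(v[..., 0], v[..., 2])))
    return yaw, pitch


def rotate_vectors(quat_wxyz: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Rotate vectors by unit quaternions given in (w, x, y, z) order."""
    q = np.asarray(quat_wxyz, dtype=float)
    rot = Rotation.from_quat(np.roll(q, -1, axis=-1))  # scipy wants (x, y, z, w)
    return rot.apply(np.atleast_2d(vec))


def great_circle_deg(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Great-circle separation between paired unit vectors, in degrees."""
    dot = np.clip(np.sum(v1 * v2, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(dot))
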