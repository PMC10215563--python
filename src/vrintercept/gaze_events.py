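"""Saccade and fixation detection from filtered gaze kinematics.

Saccades: candidate periods where |angular acceleration| exceeds five
times its per-trial median absolute value, accepted only if gaze velocity
exceeds 40 deg/s for at least five consecutive frames while also being at
least 20% above the ball's angular velocity (which screens out smooth
pursuit of a fast ball).  Onsets/offsets are refined to the nearest
acceleration maximum before / minimum after the candidate.  Candidates
touching missing data are discarded.

Fixations: the classic dispersion-threshold (I-DT) sweep — grow a window
while its yaw range plus pitch range stays within 3 deg, and emit it once
it lasts at least 100 ms.  Windows never span missing samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._angles import angles_to_vec, great_circle_deg
from .preprocess import TrialRecording, _runs

MIN_SACCADE_VEL = 40.0       # deg/s
MIN_VEL_FRAMES = 5
BALL_VEL_FACTOR = 1.2
ACC_MAD_MULT = 5.0
EXTREMA_WINDOW_S = 0.050     # onset/offset search bound beyond the candidate
MERGE_GAP_FRAMES = 2         # adjacent candidates closer than this merge
DISPERSION_DEG = 3.0
MIN_FIX_DUR_S = 0.100


@dataclass
class SaccadeEvent:
    onset_frame: int          # half-open [onset, offset)
    offset_frame: int
    peak_velocity: float      # deg/s
    amplitude: float          # deg, great-circle onset->offset


@dataclass
class FixationEvent:
    onset_frame: int          # half-open [onset, offset)
    offset_frame: int
    centroid_yaw: float
    centroid_pitch: float
    dispersion: float         # deg, yaw range + pitch range
    duration: float           # s
    mean_ego_pitch: float     # deg, gaze-head pitch averaged over the event


def detect_saccades(
    rec: TrialRecording,
    min_velocity: float = MIN_SACCADE_VEL,
    min_frames: int = MIN_VEL_FRAMES,
    ball_factor: float = BALL_VEL_FACTOR,
    mad_mult: float = ACC_MAD_MULT,
) -> list[SaccadeEvent]:
    """Detect saccades on the 50 Hz-filtered kinematic chain of ``rec``."""
    vel, acc, ballv = rec.gaze_vel, rec.gaze_acc, rec.ball_ang_vel
    miss = rec.missing | np.isnan(vel)
    n = len(vel)
    finite_acc = np.abs(acc[~np.isnan(acc) & ~miss])
    if finite_acc.size == 0:
        return []
    mad = float(np.median(finite_acc))
    thr = mad_mult * max(mad, 1e-9)
    window = max(1, int(round(EXTREMA_WINDOW_S * rec.fs)))

    cand = (np.abs(np.nan_to_num(acc)) > thr) & ~miss
    runs = _runs(cand)
    # merge candidates separated by fewer than MERGE_GAP_FRAMES frames
    merged: list[list[int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] < MERGE_GAP_FRAMES:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])

    gvec = angles_to_vec(rec.yaw_sac, rec.pitch_sac)
    events: list[SaccadeEvent] = []
    for start, stop in merged:
        # reject candidates preceded/followed by (or containing) missing data
        lo, hi = max(0, start - 1), min(n, stop + 1)
        if miss[lo:hi].any():
            continue
        v = vel[start:stop]
        gate = (v > min_velocity) & (v >= ball_factor * np.nan_to_num(ballv[start:stop]))
        if not _has_run(gate, min_frames):
            continue
        # refine onset/offset from the acceleration extrema: the burst's
        # acceleration maximum precedes the velocity peak and its minimum
        # follows it, both as near-plateaus for fast saccades, so the
        # boundaries are the plateau edges (first/last frame above half the
        # extremum).  The candidate edges themselves are not trusted:
        # zero-phase filtering spreads the threshold crossing outward.
        peak_i = start + int(np.nanargmax(vel[start:stop]))
        w0 = max(1, start - window)
        rise = acc[w0:peak_i + 1]
        up = np.flatnonzero(rise > 0.5 * np.nanmax(rise))
        onset = w0 + int(up[0]) if up.size else start
        w1 = min(n, stop + window)
        fall = acc[peak_i:w1]
        down = np.flatnonzero(fall < 0.5 * np.nanmin(fall))
        offset = peak_i + int(down[-1]) if down.size else stop - 1
        off_excl = min(n - 1, offset + 1)   # velocity index range [onset, off_excl)
        seg = vel[onset:off_excl + 1]
        peak = float(np.nanmax(seg)) if np.isfinite(seg).any() else float("nan")
        amp = float(great_circle_deg(gvec[onset], gvec[min(n - 1, off_excl + 1)]))
        events.append(SaccadeEvent(onset, off_excl + 1, peak, amp))

    # enforce ordering / non-overlap after boundary refinement
    events.sort(key=lambda e: e.onset_frame)
    out: list[SaccadeEvent] = []
    for ev in events:
        if out and ev.onset_frame < out[-1].offset_frame:
            continue
        out.append(ev)
    return out


def _has_run(mask: np.ndarray, length: int) -> bool:
    count = 0
    for m in mask:
        count = count + 1 if m else 0
        if count >= length:
            return True
    return False


def detect_fixations(
    rec_or_yaw,
    pitch: np.ndarray | None = None,
    missing: np.ndarray | None = None,
    fs: float = 90.0,
    ego_pitch: np.ndarray | None = None,
    dispersion_deg: float = DISPERSION_DEG,
    min_duration_s: float = MIN_FIX_DUR_S,
    metric: str = "range",
) -> list[FixationEvent]:
    """Dispersion-threshold (I-DT) fixation detection.

    Accepts either a :class:`TrialRecording` (uses its 15 Hz positional
    chain) or explicit yaw/pitch/missing arrays.  ``metric='range'`` is
    the classic yaw-range + pitch-range dispersion; ``metric='pairwise'``
    uses the maximum pairwise great-circle separation instead.
    """
    if isinstance(rec_or_yaw, TrialRecording):
        rec = rec_or_yaw
        yaw, pitch, missing, fs = rec.yaw_pos, rec.pitch_pos, rec.missing, rec.fs
        ego_pitch = rec.ego_pitch
    else:
        yaw = np.asarray(rec_or_yaw, dtype=float)
        pitch = np.asarray(pitch, dtype=float)
        if missing is None:
            missing = np.isnan(yaw) | np.isnan(pitch)
    if ego_pitch is None:
        ego_pitch = np.full(len(yaw), np.nan)
    miss = np.asarray(missing, dtype=bool) | np.isnan(yaw) | np.isnan(pitch)
    n = len(yaw)
    min_frames = int(np.ceil(min_duration_s * fs))

    if metric == "range":
        def disp(i: int, j: int) -> float:      # window [i, j)
            return (yaw[i:j].max() - yaw[i:j].min()
                    + pitch[i:j].max() - pitch[i:j].min())
    elif metric == "pairwise":
        vec = angles_to_vec(yaw, np.nan_to_num(pitch))

        def disp(i: int, j: int) -> float:
            w = vec[i:j]
            return float(great_circle_deg(w[:, None, :], w[None, :, :]).max())
    else:
        raise ValueError("metric must be 'range' or 'pairwise'")

    events: list[FixationEvent] = []
    i = 0
    while i + min_frames <= n:
        if miss[i:i + min_frames].any() or disp(i, i + min_frames) > dispersion_deg:
            i += 1
            continue
        j = i + min_frames
        while j < n and not miss[j] and disp(i, j + 1) <= dispersion_deg:
            j += 1
        events.append(FixationEvent(
            onset_frame=i, offset_frame=j,
            centroid_yaw=float(yaw[i:j].mean()),
            centroid_pitch=float(pitch[i:j].mean()),
            dispersion=float(disp(i, j)),
            duration=(j - i) / fs,
            mean_ego_pitch=float(np.nanmean(ego_pitch[i:j]))
            if np.isfinite(ego_pitch[i:j]).any() else float("nan"),
        ))
        i = j
    return events
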