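"""Trial segmentation, filtering, angular kinematics, QC and winsorization.

The processing chain mirrors standard motion-capture / eye-tracking
practice: positional channels get a dual-pass (zero-phase) low-pass
Butterworth at 10 Hz; gaze angle channels get a three-frame median filter
followed by a zero-lag second-order Butterworth, with separate cutoffs for
saccade identification (50 Hz, clamped below Nyquist at 90 Hz recordings)
and positional tracking analysis (15 Hz).  Gaze-in-world yaw/pitch come
from composing the recorded head orientation with the head-centred gaze
vector; angular velocity is the great-circle separation of consecutive
gaze vectors divided by the sample interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, medfilt

from ._angles import angles_to_vec, great_circle_deg, rotate_vectors, vec_to_angles
from .config import PhysicsConfig

log = logging.getLogger("vrintercept")

MISSING_GAP_S = 0.100     # gaps longer than this exclude the trial
MISSING_FRAC = 0.20       # so does more missing data than this
CONTACT_DEV_MULT = 5.0    # ballistic-deviation multiple flagging contact
CONTACT_DEV_FLOOR = 1e-3  # m, deviation noise floor


_clamp_warned: set[tuple[float, float]] = set()


class FilterError(ValueError):
    pass


class SegmentationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# filters


def filter_positional(series: np.ndarray, fs: float, cutoff: float = 10.0,
                      order: int = 2) -> np.ndarray:
    """Dual-pass (forward-backward, zero-phase) low-pass Butterworth.

    ``order`` is per pass (2nd order per pass, 4th effective).  Endpoints
    are handled by filtfilt's reflection padding.  Works column-wise on
    2-D input.
    """
    series = np.asarray(series, dtype=float)
    if cutoff >= fs / 2:
        raise FilterError(f"cutoff {cutoff} Hz must be below Nyquist {fs / 2} Hz")
    b, a = butter(order, cutoff / (fs / 2))
    padlen = 3 * (max(len(b), len(a)) - 1)
    if series.shape[0] <= padlen:
        raise FilterError(f"series of {series.shape[0]} frames is shorter than "
                          f"the filter warm-up ({padlen + 1} frames)")
    return filtfilt(b, a, series, axis=0)


def filter_gaze(series: np.ndarray, fs: float, purpose: str = "position") -> np.ndarray:
    """Three-frame median filter, then zero-lag 2nd-order Butterworth.

    ``purpose='saccade'`` uses a 50 Hz cutoff, ``'position'`` 15 Hz.  A
    cutoff at or above Nyquist (50 Hz against 90 Hz data) is clamped to
    0.99x Nyquist with a logged warning.  NaN samples (missing gaze) are
    preserved: each contiguous valid run is filtered independently, and
    runs shorter than the filter warm-up are left at their median-filtered
    values.
    """
    cutoffs = {"saccade": 50.0, "position": 15.0}
    if purpose not in cutoffs:
        raise FilterError(f"purpose must be one of {sorted(cutoffs)}")
    cutoff = cutoffs[purpose]
    nyq = fs / 2
    if cutoff >= nyq:
        clamped = 0.99 * nyq
        if (cutoff, fs) not in _clamp_warned:
            _clamp_warned.add((cutoff, fs))
            log.warning("gaze filter cutoff %.1f Hz >= Nyquist %.1f Hz; "
                        "clamping to %.2f Hz", cutoff, nyq, clamped)
        cutoff = clamped

    x = np.asarray(series, dtype=float).copy()
    valid = ~np.isnan(x)
    out = np.full_like(x, np.nan)
    b, a = butter(2, cutoff / nyq)
    padlen = 3 * (max(len(b), len(a)) - 1)
    for start, stop in _runs(valid):
        seg = x[start:stop]
        if len(seg) >= 3:
            seg = medfilt(seg, kernel_size=3)
            # medfilt zero-pads the ends; keep the raw endpoint samples
            seg[0], seg[-1] = x[start], x[stop - 1]
        out[start:stop] = (filtfilt(b, a, seg) if len(seg) > padlen else seg)
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs in a boolean mask."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return list(zip(idx[::2], idx[1::2]))


# ---------------------------------------------------------------------------
# angles and kinematics


def to_world_angles(gaze_dir: np.ndarray, head_quat_wxyz: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Head-centred gaze vectors -> world yaw/pitch + egocentric pitch (deg).

    Yaw is rotation about the gravity-aligned vertical axis; pitch is
    elevation from the horizontal eye-height plane.  Egocentric pitch is
    the pitch of the gaze vector expressed in the head frame (the
    gaze-head angle).  Zero-norm or NaN gaze vectors yield NaN angles.
    """
    g = np.asarray(gaze_dir, dtype=float)
    norms = np.linalg.norm(g, axis=-1)
    bad = ~np.isfinite(norms) | (norms < 1e-9)
    safe = np.where(bad[:, None], [[0.0, 0.0, 1.0]], g)
    world = rotate_vectors(np.asarray(head_quat_wxyz, dtype=float), safe)
    yaw, pitch = vec_to_angles(world)
    _, ego_pitch = vec_to_angles(safe)
    yaw[bad] = pitch[bad] = ego_pitch[bad] = np.nan
    return yaw, pitch, ego_pitch


def angular_kinematics(yaw: np.ndarray, pitch: np.ndarray, dt: float
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Angular velocity (deg/s) and acceleration (deg/s^2) series.

    Velocity at frame i is the great-circle separation between the gaze
    vectors at frames i and i+1 divided by dt (the last frame is NaN);
    acceleration is its first difference over dt (the first frame is NaN).
    Missing samples propagate into both derivatives.
    """
    vec = angles_to_vec(yaw, pitch)
    n = len(vec)
    vel = np.full(n, np.nan)
    if n > 1:
        vel[:-1] = great_circle_deg(vec[:-1], vec[1:]) / dt
    acc = np.full(n, np.nan)
    if n > 1:
        acc[1:] = np.diff(vel, prepend=np.nan)[1:] / dt
    return vel, acc


# ---------------------------------------------------------------------------
# segmentation


@dataclass
class TrialRecording:
    """One trial after preprocessing: landmarks, filtered series, QC."""

    frame: pd.DataFrame
    fs: float
    release_frame: int
    bounce_frame: int
    contact_frame: int
    ctrl_filt: np.ndarray          # (n, 3), 10 Hz dual-pass
    head_filt: np.ndarray
    yaw_sac: np.ndarray            # world yaw/pitch, 50 Hz chain
    pitch_sac: np.ndarray
    yaw_pos: np.ndarray            # world yaw/pitch, 15 Hz chain
    pitch_pos: np.ndarray
    ego_pitch: np.ndarray          # gaze-head pitch, 15 Hz chain
    gaze_vel: np.ndarray           # deg/s, from the 50 Hz chain
    gaze_acc: np.ndarray           # deg/s^2
    ball_ang_vel: np.ndarray       # deg/s, ball direction from the eye
    missing: np.ndarray            # bool, invalid/missing gaze samples
    excluded: bool = False
    exclusion_reason: str | None = None
    qc_flags: list[str] = field(default_factory=list)


def find_release(ball: np.ndarray, tol: float = 1e-9) -> int:
    moved = np.flatnonzero(np.any(np.abs(ball - ball[0]) > tol, axis=1))
    if moved.size == 0:
        raise SegmentationError("no ball motion: release not detectable")
    return int(moved[0])


def find_bounce(ball_y: np.ndarray, release: int, height_max: float = 0.5) -> int:
    """Frame of floor contact: where vertical velocity flips sign near the floor."""
    vy = np.diff(ball_y)
    for i in range(release + 1, len(ball_y) - 1):
        if vy[i - 1] < 0 <= vy[i] and ball_y[i] < height_max:
            return i
    raise SegmentationError("no bounce found")


def find_contact(ball: np.ndarray, ctrl_z: np.ndarray, bounce: int,
                 gravity: float, dt: float) -> int:
    """First frame of racquet contact, or of the ball passing the racquet.

    Contact shows as the ball deviating from its ballistic prediction by
    more than ``CONTACT_DEV_MULT`` times the running pre-contact RMS
    deviation (with an absolute noise floor); a miss is the first frame
    whose ball depth is behind the racquet depth.
    """
    n = len(ball)
    g = np.array([0.0, gravity, 0.0]) * dt * dt
    # the prediction window must sit fully past the bounce discontinuity
    # (the bounce frame may straddle the exact contact time either side)
    start = bounce + 3
    dev_hist: list[float] = []
    for i in range(start, n):
        pred = 2 * ball[i - 1] - ball[i - 2] + g
        dev = float(np.linalg.norm(ball[i] - pred))
        rms = float(np.sqrt(np.mean(np.square(dev_hist)))) if dev_hist else 0.0
        tol = max(CONTACT_DEV_MULT * rms, CONTACT_DEV_FLOOR)
        if dev > tol:
            return i - 1          # last frame still on the ballistic path
        if ball[i, 2] < ctrl_z[i]:
            return i
        dev_hist.append(dev)
    raise SegmentationError("no contact or pass-by found")


def missing_mask(frame: pd.DataFrame) -> np.ndarray:
    dirs = frame[[f"gaze_dir_{c}" for c in "xyz"]].to_numpy(float)
    return (frame["gaze_valid"].to_numpy() == 0) | np.isnan(dirs).any(axis=1)


def exclude_trial(missing: np.ndarray, fs: float) -> tuple[bool, str | None]:
    """Apply the missing-data exclusion rules to a segmented-window mask."""
    n = len(missing)
    if n == 0:
        return True, "empty segment"
    frac = missing.mean()
    if frac > MISSING_FRAC:
        return True, f"missing fraction {frac:.2f} > {MISSING_FRAC}"
    for start, stop in _runs(missing):
        gap = (stop - start) / fs
        if gap > MISSING_GAP_S:
            return True, f"missing run {gap * 1e3:.0f} ms > {MISSING_GAP_S * 1e3:.0f} ms"
    return False, None


def process_trial(frame: pd.DataFrame, physics: PhysicsConfig | None = None,
                  cutoff: float = 10.0) -> TrialRecording:
    """Run the full per-trial chain: segment, filter, kinematics, QC.

    Exclusion (too much missing gaze) is assessed over the segmented
    release-to-contact window and flags the recording rather than raising;
    segmentation failures are likewise recorded as exclusions.
    """
    physics = physics or PhysicsConfig()
    fs = physics.sample_rate
    dt = 1.0 / fs
    ball = frame[[f"ball_{c}" for c in "xyz"]].to_numpy(float)
    ctrl = frame[[f"ctrl_{c}" for c in "xyz"]].to_numpy(float)
    head = frame[[f"head_{c}" for c in "xyz"]].to_numpy(float)
    quat = frame[[f"head_q{c}" for c in "wxyz"]].to_numpy(float)
    gaze_dir = frame[[f"gaze_dir_{c}" for c in "xyz"]].to_numpy(float)
    miss = missing_mask(frame)

    rec = TrialRecording(
        frame=frame, fs=fs, release_frame=-1, bounce_frame=-1, contact_frame=-1,
        ctrl_filt=ctrl, head_filt=head,
        yaw_sac=np.full(len(frame), np.nan), pitch_sac=np.full(len(frame), np.nan),
        yaw_pos=np.full(len(frame), np.nan), pitch_pos=np.full(len(frame), np.nan),
        ego_pitch=np.full(len(frame), np.nan),
        gaze_vel=np.full(len(frame), np.nan), gaze_acc=np.full(len(frame), np.nan),
        ball_ang_vel=np.full(len(frame), np.nan), missing=miss,
    )
    try:
        rec.release_frame = find_release(ball)
        rec.bounce_frame = find_bounce(ball[:, 1], rec.release_frame)
        # the depth comparison uses the raw controller track: it is a
        # geometric pass-by test, not a kinematic one
        rec.contact_frame = find_contact(ball, ctrl[:, 2],
                                         rec.bounce_frame, physics.gravity, dt)
        rec.ctrl_filt = filter_positional(ctrl, fs, cutoff)
        rec.head_filt = filter_positional(head, fs, cutoff)
    except (SegmentationError, FilterError) as err:
        rec.excluded, rec.exclusion_reason = True, str(err)
        return rec

    yaw_raw, pitch_raw, ego_raw = to_world_angles(gaze_dir, quat)
    miss = miss | np.isnan(yaw_raw)
    rec.missing = miss
    yaw_raw = np.where(miss, np.nan, yaw_raw)
    pitch_raw = np.where(miss, np.nan, pitch_raw)
    ego_raw = np.where(miss, np.nan, ego_raw)

    rec.yaw_sac = filter_gaze(yaw_raw, fs, "saccade")
    rec.pitch_sac = filter_gaze(pitch_raw, fs, "saccade")
    rec.yaw_pos = filter_gaze(yaw_raw, fs, "position")
    rec.pitch_pos = filter_gaze(pitch_raw, fs, "position")
    rec.ego_pitch = filter_gaze(ego_raw, fs, "position")
    rec.gaze_vel, rec.gaze_acc = angular_kinematics(rec.yaw_sac, rec.pitch_sac, dt)

    eye = frame[[f"gaze_origin_{c}" for c in "xyz"]].to_numpy(float)
    byaw, bpitch = vec_to_angles(ball - eye)
    rec.ball_ang_vel, _ = angular_kinematics(byaw, bpitch, dt)

    seg = slice(rec.release_frame, rec.contact_frame + 1)
    rec.excluded, rec.exclusion_reason = exclude_trial(miss[seg], fs)
    if rec.excluded:
        rec.qc_flags.append("gaze-excluded")
    return rec


# ---------------------------------------------------------------------------
# outlier screening


def winsorize(values, groups=None, k: float = 3.0):
    """Replace values beyond mean +/- k*SD with the boundary, per group.

    The mean and (sample) SD are computed once on the original data of
    each group; only values strictly beyond the boundary move.  A
    zero-variance group is returned unchanged.  NaNs are ignored and
    preserved.
    """
    x = np.asarray(values, dtype=float).copy()
    if groups is None:
        codes = np.zeros(len(x), dtype=int)
    else:
        codes = pd.factorize(np.asarray(groups))[0]
    for gid in np.unique(codes):
        sel = codes == gid
        vals = x[sel]
        ok = ~np.isnan(vals)
        if ok.sum() < 2:
            continue
        m, sd = vals[ok].mean(), vals[ok].std(ddof=1)
        if sd == 0:
            continue
        lo, hi = m - k * sd, m + k * sd
        x[sel] = np.clip(vals, lo, hi)
    if isinstance(values, pd.Series):
        return pd.Series(x, index=values.index, name=values.name)
    return x
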