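"""Per-trial dependent measures and the probe-aligned analysis tables.

The four trial-level outcomes are: interception (did the ball enter the
racquet's padded collision box), the bounce fixation's egocentric pitch
angle and duration (from the fixation at or immediately before the
bounce), and peak swing velocity (highest controller speed during the
foreswing).  The assembly step attaches probe self-reports, codes each
trial's run of consecutive preceding fed-back errors (capped at 4) and
carries the most recent anxiety rating forward across trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .config import PhysicsConfig
from .gaze_events import FixationEvent, detect_fixations, detect_saccades
from .preprocess import TrialRecording, process_trial

MAX_PRIOR_ERRORS = 4


@dataclass
class TrialMetrics:
    intercepted: bool | None
    bounce_fix_pitch: float | None    # deg, egocentric
    bounce_fix_duration: float | None  # s
    peak_swing_velocity: float | None  # m/s
    qc: list[str]


# ---------------------------------------------------------------------------
# gaze outcomes


def bounce_fixation(fixations: list[FixationEvent], bounce_frame: int
                    ) -> FixationEvent | None:
    """The fixation spanning the bounce, else the latest one ending before it."""
    covering = [f for f in fixations
                if f.onset_frame <= bounce_frame < f.offset_frame]
    if covering:
        return covering[0]
    before = [f for f in fixations if f.offset_frame <= bounce_frame]
    if before:
        return max(before, key=lambda f: (f.offset_frame, f.onset_frame))
    return None


def bounce_fixation_metrics(fix: FixationEvent, ego_pitch: np.ndarray,
                            fs: float) -> tuple[float, float]:
    """(mean gaze-head pitch in deg, duration in s) over [onset, offset)."""
    seg = ego_pitch[fix.onset_frame:fix.offset_frame]
    pitch = float(np.nanmean(seg)) if np.isfinite(seg).any() else float("nan")
    return pitch, (fix.offset_frame - fix.onset_frame) / fs


# ---------------------------------------------------------------------------
# swing outcome


def peak_swing_velocity(ctrl_filt: np.ndarray, contact_frame: int,
                        fs: float, approach_axis: int = 2) -> float | None:
    """Highest controller speed during the foreswing, in m/s.

    The foreswing is the forward phase of the hand movement before ball
    contact: the contiguous run of frames immediately before contact whose
    velocity component along the approach axis (depth, toward the oncoming
    ball) is positive, starting at the last sign change of that component.
    The backswing's rearward motion supplies that sign change.  Speed is
    the Euclidean norm of the positional differentials times the rate.
    """
    if contact_frame < 2:
        return None
    vel = np.diff(ctrl_filt[:contact_frame + 1], axis=0) * fs   # vel[i]: i -> i+1
    toward = vel[:, approach_axis]
    pos_idx = np.flatnonzero(toward[:contact_frame] > 1e-12)
    if pos_idx.size == 0:
        return None
    end = int(pos_idx[-1])
    onset = end
    while onset > 0 and toward[onset - 1] > 1e-12:
        onset -= 1
    speeds = np.linalg.norm(vel[onset:end + 1], axis=1)
    return float(speeds.max())


# ---------------------------------------------------------------------------
# interception


def interception_outcome(ball: np.ndarray, ctrl_pos: np.ndarray,
                         ctrl_quat_wxyz: np.ndarray,
                         physics: PhysicsConfig | None = None) -> bool:
    """True iff the ball sphere ever intersects the padded racquet box.

    The racquet is an oriented box centred on the controller with the
    visible extent inflated in thickness by the collision pad; the test is
    sphere-vs-oriented-box with an inclusive boundary.
    """
    physics = physics or PhysicsConfig()
    ex, ey, ez = physics.racquet_extent
    half = np.array([ex / 2, ey / 2, (ez + physics.collision_pad) / 2])
    radius = physics.ball_diameter / 2
    rel = ball - ctrl_pos
    rot = Rotation.from_quat(np.roll(np.asarray(ctrl_quat_wxyz, float), -1, axis=-1))
    local = rot.inv().apply(rel)
    closest = np.clip(local, -half, half)
    dist = np.linalg.norm(local - closest, axis=1)
    # inclusive boundary, with float-subtraction slack
    return bool(np.any(dist <= radius + 1e-12))


# ---------------------------------------------------------------------------
# per-trial driver


def compute_trial_metrics(rec: TrialRecording,
                          physics: PhysicsConfig | None = None) -> TrialMetrics:
    """Run detection + all trial measures on one preprocessed recording.

    Gaze metrics are withheld (None) on QC-excluded trials; interception
    and swing metrics are still computed, flagged with the exclusion.
    """
    physics = physics or PhysicsConfig()
    qc = list(rec.qc_flags)
    frame = rec.frame
    ball = frame[[f"ball_{c}" for c in "xyz"]].to_numpy(float)
    quat = frame[[f"ctrl_q{c}" for c in "wxyz"]].to_numpy(float)
    if rec.contact_frame < 0:
        return TrialMetrics(None, None, None, None, qc + ["segmentation-failed"])

    intercepted = interception_outcome(ball, rec.ctrl_filt, quat, physics)
    peak = peak_swing_velocity(rec.ctrl_filt, rec.contact_frame, rec.fs)
    if peak is None:
        qc.append("no-foreswing")

    pitch = duration = None
    if not rec.excluded:
        fixations = detect_fixations(rec)
        fix = bounce_fixation(fixations, rec.bounce_frame)
        if fix is not None:
            pitch, duration = bounce_fixation_metrics(fix, rec.ego_pitch, rec.fs)
        else:
            qc.append("no-bounce-fixation")
    return TrialMetrics(intercepted, pitch, duration, peak, qc)


def session_metrics(trials, physics: PhysicsConfig | None = None) -> pd.DataFrame:
    """Per-trial metrics table for an iterable of simulated/loaded trials.

    ``trials`` yields objects with ``frame`` (trial DataFrame), ``block``,
    ``trial`` and ``feedback_call`` attributes (e.g.
    :class:`~vrintercept.synthdata.SimulatedTrial`).
    """
    physics = physics or PhysicsConfig()
    rows = []
    for tr in trials:
        rec = process_trial(tr.frame, physics)
        m = compute_trial_metrics(rec, physics)
        rows.append({
            "block": tr.block, "trial": tr.trial,
            "feedback_call": tr.feedback_call,
            "intercepted": m.intercepted,
            "bounce_fix_pitch": m.bounce_fix_pitch,
            "bounce_fix_duration": m.bounce_fix_duration,
            "peak_swing_velocity": m.peak_swing_velocity,
            "qc": ";".join(m.qc),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# analysis tables


def prior_error_counts(feedback_calls) -> np.ndarray:
    """Consecutive preceding 'miss' calls per trial, capped at 4.

    The count resets to zero after any 'hit' call; the first trial of a
    block has no preceding calls, hence zero.
    """
    calls = list(feedback_calls)
    out = np.zeros(len(calls), dtype=int)
    run = 0
    for i, call in enumerate(calls):
        out[i] = min(run, MAX_PRIOR_ERRORS)
        run = run + 1 if call == "miss" else 0
    return out


def assemble_analysis_table(manifest_trials: pd.DataFrame,
                            probes: pd.DataFrame,
                            trial_metrics: pd.DataFrame | None = None
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the probe-level and trial-level analysis tables.

    Returns ``(probe_table, trial_table)``.  The probe table has one row
    per probe with self-reports, 0/1 condition indicators and (if metrics
    are supplied) the probe trial's outcome measures.  The trial table has
    one row per trial with ``prior_errors`` (run of consecutive preceding
    fed-back misses, capped at 4) and ``carried_anxiety`` (most recent
    probe's anxiety within the block; NaN before the first probe).
    """
    trials = manifest_trials.sort_values(["participant", "block", "trial"]).copy()
    for col in ("pressure", "feedback"):
        if trials[col].dtype == object:
            trials[col + "_hi"] = (trials[col] == "high").astype(int)
        else:
            trials[col + "_hi"] = trials[col].astype(int)

    parts = []
    for (_, _), grp in trials.groupby(["participant", "block"], sort=False):
        g = grp.copy()
        g["prior_errors"] = prior_error_counts(g["feedback_call"])
        parts.append(g)
    trial_table = pd.concat(parts, ignore_index=True)

    probe_keyed = probes.set_index(["participant", "block", "trial"])
    anx = probe_keyed["anxiety"]

    def carry(group: pd.DataFrame) -> pd.Series:
        key = group.name
        out, current = [], np.nan
        for t in group["trial"]:
            out.append(current)
            if (key[0], key[1], t) in anx.index:
                current = anx.loc[(key[0], key[1], t)]
        return pd.Series(out, index=group.index)

    trial_table["carried_anxiety"] = (
        trial_table.groupby(["participant", "block"], sort=False, group_keys=False)
        .apply(carry, include_groups=False))

    probe_table = probes.copy()
    for col in ("pressure", "feedback"):
        if probe_table[col].dtype == object:
            probe_table[col] = (probe_table[col] == "high").astype(int)

    if trial_metrics is not None:
        tm = trial_metrics.copy()
        if "participant" not in tm.columns:
            tm["participant"] = probe_table["participant"].iloc[0]
        keys = ["participant", "block", "trial"]
        probe_table = probe_table.merge(tm.drop(columns=["feedback_call"],
                                                errors="ignore"),
                                        on=keys, how="left")
        trial_table = trial_table.merge(tm.drop(columns=["feedback_call"],
                                                errors="ignore"),
                                        on=keys, how="left")
    return probe_table, trial_table
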