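"""Synthetic VR interception sessions with known ground truth.

One simulated trial reproduces the structure of a recorded trial: a ball
launched from a 2 m port on the front wall, following a ballistic path,
bouncing once 3.5 m in front of the player with a type-dependent
restitution, and either being intercepted by the racquet or flying past;
a gaze track that pursues the ball, jumps ahead to a predictive fixation
a few degrees above the bounce point, and re-acquires the ball with a
catch-up saccade; and a hand-controller swing with a backswing and a
bell-shaped foreswing peaking at contact.

Every injected quantity (event frames and classes, contact frame,
interception outcome, configured swing peak) is returned alongside the
time series so downstream detectors and metrics can be tested against
construction ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._angles import angles_to_vec, vec_to_angles
from .config import (ConfigError, GazeGenConfig, PhysicsConfig, SelfReportTruth,
                     SessionConfig, SwingGenConfig)
from .trialio import (MANIFEST_COLUMNS, PROBE_COLUMNS, SessionManifest,
                      TRIAL_COLUMNS, trial_filename, write_manifest,
                      write_trial_csv)

EYE_HEIGHT = 1.70          # m, static head model
REST_OFFSET = np.array([0.30, -0.70, 0.20])   # controller rest relative to eye
CONTACT_PLANE_AHEAD = 0.4  # m in front of the player where contact happens
POST_CONTACT_S = 0.25      # s of trial retained after contact
HOLD_AFTER_BOUNCE_S = 0.25  # s the bounce fixation is held past the bounce
BACKSWING_AMPLITUDE = 0.15  # m


# ---------------------------------------------------------------------------
# ball flight


@dataclass
class BallTrajectory:
    """Sampled ballistic path of one ball, with analytic landmarks."""

    t: np.ndarray          # s, one entry per frame
    pos: np.ndarray        # (n, 3) m
    release_frame: int     # first frame displaced from the launch port
    bounce_frame: int      # frame of minimum height (floor contact)
    bounce_time: float     # exact (off-grid) floor-contact time, s
    bounce_point: np.ndarray
    velocity: np.ndarray   # (n, 3) analytic velocity at each sample
    ball_type: str


def _launch_solution(cfg: PhysicsConfig) -> tuple[float, float, float]:
    """Vertical launch speed, flight time to bounce, and horizontal speed.

    The launch is solved backward from the bounce constraints: the ball
    leaves the 2 m port with whatever upward speed makes its floor-contact
    speed equal ``bounce_vertical_speed``, and covers the wall-to-bounce
    depth in exactly that flight time.
    """
    g = cfg.gravity
    vb = cfg.bounce_vertical_speed                       # negative
    v0y_sq = vb * vb + 2 * g * cfg.launch_height
    if v0y_sq <= 0:
        raise ConfigError("bounce_vertical_speed: unreachable from launch_height")
    v0y = math.sqrt(v0y_sq)
    t_flight = (v0y - vb) / (-g)
    depth = cfg.start_behind_wall - cfg.bounce_distance_ahead
    v_horiz = depth / t_flight
    return v0y, t_flight, v_horiz


def generate_ball_trajectory(ball_type: str, cfg: PhysicsConfig) -> BallTrajectory:
    """Sample the full ballistic path of one ball at ``cfg.sample_rate``.

    The pre-bounce segment is identical for both ball types; at the bounce
    the vertical velocity reverses scaled by the type's restitution, with
    horizontal velocity conserved.  The series ends once the ball is
    0.75 m past the player plane.
    """
    e = cfg.elasticity(ball_type)
    v0y, t_flight, v_horiz = _launch_solution(cfg)
    g = cfg.gravity
    dt = 1.0 / cfg.sample_rate
    t0 = cfg.pre_release_s
    t_bounce = t0 + t_flight
    v_post = e * abs(cfg.bounce_vertical_speed)

    z_wall = cfg.start_behind_wall          # player is at z = 0
    z_bounce = cfg.bounce_distance_ahead

    # stop once 0.75 m behind the player plane
    t_end = t_bounce + (z_bounce + 0.75) / v_horiz
    n = int(math.floor(t_end / dt)) + 1
    t = np.arange(n) * dt

    pos = np.zeros((n, 3))
    vel = np.zeros((n, 3))
    pos[:, 1] = cfg.launch_height
    pos[:, 2] = z_wall

    tau = t - t0
    pre = (tau >= 0) & (t < t_bounce)
    pos[pre, 1] = cfg.launch_height + v0y * tau[pre] + 0.5 * g * tau[pre] ** 2
    pos[pre, 2] = z_wall - v_horiz * tau[pre]
    vel[pre, 1] = v0y + g * tau[pre]
    vel[pre, 2] = -v_horiz

    tau2 = t - t_bounce
    post = tau2 >= 0
    pos[post, 1] = v_post * tau2[post] + 0.5 * g * tau2[post] ** 2
    pos[post, 2] = z_bounce - v_horiz * tau2[post]
    vel[post, 1] = v_post + g * tau2[post]
    vel[post, 2] = -v_horiz

    moved = np.nonzero(np.any(pos != pos[0], axis=1))[0]
    release_frame = int(moved[0]) if moved.size else 0
    # floor contact lands between two samples; the truth frame is the one
    # with the lower sampled height (where the detector's velocity sign flips)
    i0 = int(np.searchsorted(t, t_bounce))
    bounce_frame = i0 - 1 if (i0 > 0 and pos[i0 - 1, 1] < pos[i0, 1]) else i0

    return BallTrajectory(
        t=t, pos=pos, release_frame=release_frame, bounce_frame=bounce_frame,
        bounce_time=t_bounce, bounce_point=np.array([0.0, 0.0, z_bounce]),
        velocity=vel, ball_type=ball_type,
    )


# ---------------------------------------------------------------------------
# gaze


@dataclass
class GazeTruthEvent:
    kind: str          # 'fixation' | 'saccade' | 'pursuit'
    onset: int         # frame, half-open interval [onset, offset)
    offset: int
    amplitude_deg: float = 0.0
    target_pitch_deg: float | None = None   # egocentric, fixations only


def _saccade_angles(a0: np.ndarray, a1: np.ndarray, n_frames: int) -> np.ndarray:
    """Triangular-velocity displacement from angle a0 to a1 over n frames."""
    s = np.linspace(0.0, 1.0, n_frames + 1)[1:]
    frac = np.where(s < 0.5, 2 * s * s, 1 - 2 * (1 - s) ** 2)
    return a0 + np.outer(frac, a1 - a0)


def generate_gaze(
    ball: BallTrajectory,
    cfg: GazeGenConfig,
    eye_origin: np.ndarray,
    rng: np.random.Generator,
    sample_rate: float = 90.0,
) -> tuple[np.ndarray, np.ndarray, list[GazeTruthEvent]]:
    """Synthesize a gaze-direction track locked to the ball's flight.

    Returns ``(gaze_dir, valid, events)`` where ``gaze_dir`` is an (n, 3)
    array of unit vectors in the (static, world-aligned) head frame,
    ``valid`` marks non-dropout samples and ``events`` is the injected
    ground-truth event list covering every frame of the trial.
    """
    n = len(ball.t)
    dt = 1.0 / sample_rate
    rel = ball.pos - eye_origin
    ball_yaw, ball_pitch = vec_to_angles(rel)
    ball_ang = np.stack([ball_yaw, ball_pitch], axis=1)

    bp_rel = ball.bounce_point - eye_origin
    fix_yaw, fix_pitch = vec_to_angles(bp_rel)
    fix_target = np.array([fix_yaw, fix_pitch + cfg.bounce_fixation_pitch_offset])

    r = ball.release_frame
    b = ball.bounce_frame
    f0 = max(r + 2, b - int(round(cfg.bounce_fixation_lead * sample_rate)))
    f1 = min(n - 4, b + int(round(HOLD_AFTER_BOUNCE_S * sample_rate)))

    ang = np.empty((n, 2))
    events: list[GazeTruthEvent] = []

    # initial fixation on the launch port
    ang[:r] = ball_ang[0]

    # early pursuit: anchored at the ball's release direction, tracking a
    # configurable fraction of its angular motion
    def pursue(start: int, stop: int, anchor_idx: int, anchor_ang: np.ndarray) -> None:
        delta = ball_ang[start:stop] - ball_ang[anchor_idx]
        ang[start:stop] = anchor_ang + cfg.pursuit_gain * delta

    # provisional pursuit up to the fixation start to know the saccade's
    # launch angle, then carve the saccade out of its tail
    pursue(r, f0, r, ball_ang[r])
    amp1 = float(np.hypot(*(fix_target - ang[f0 - 1])))
    n_sac1 = max(3, int(round(2 * amp1 / cfg.saccade_peak_velocity * sample_rate)))
    s0 = max(r + 2, f0 - n_sac1)
    ang[s0:f0] = _saccade_angles(ang[s0 - 1], fix_target, f0 - s0)

    # bounce fixation
    ang[f0:f1] = fix_target

    # catch-up saccade back onto the ball, then post-bounce pursuit
    amp2 = float(np.hypot(*(ball_ang[f1] - fix_target)))
    n_sac2 = max(3, int(round(2 * amp2 / cfg.saccade_peak_velocity * sample_rate)))
    if cfg.catchup_saccades < 1:
        n_sac2 = 1
    f2 = min(n - 1, f1 + n_sac2)
    ang[f1:f2] = _saccade_angles(fix_target, ball_ang[f2], f2 - f1)
    pursue(f2, n, f2, ball_ang[f2])

    events.append(GazeTruthEvent("fixation", 0, r, target_pitch_deg=float(ball_ang[0, 1])))
    events.append(GazeTruthEvent("pursuit", r, s0))
    events.append(GazeTruthEvent("saccade", s0, f0, amplitude_deg=amp1))
    events.append(GazeTruthEvent("fixation", f0, f1, target_pitch_deg=float(fix_target[1])))
    if cfg.catchup_saccades >= 1:
        events.append(GazeTruthEvent("saccade", f1, f2, amplitude_deg=amp2))
    events.append(GazeTruthEvent("pursuit", f2, n))

    if cfg.fixation_jitter_sd > 0:
        ang += rng.normal(0.0, cfg.fixation_jitter_sd, ang.shape)

    valid = np.ones(n, dtype=bool)
    if cfg.dropout_rate > 0:
        starts = np.nonzero(rng.random(n) < cfg.dropout_rate)[0]
        for s in starts:
            valid[s:s + cfg.dropout_run_length] = False

    gaze_dir = angles_to_vec(ang[:, 0], ang[:, 1])
    return gaze_dir, valid, events


# ---------------------------------------------------------------------------
# swing


@dataclass
class SwingTruth:
    peak_speed: float
    foreswing_onset: int
    contact_frame: int
    aim_point: np.ndarray


def generate_swing(
    cfg: SwingGenConfig,
    t: np.ndarray,
    contact_frame: int,
    aim_point: np.ndarray,
    rest_pos: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, SwingTruth]:
    """Controller positions for one trial.

    The hand rests, draws back ``BACKSWING_AMPLITUDE`` m away from the aim
    point, then sweeps to the aim point along a quarter-sine speed profile
    that reaches ``cfg.peak_speed`` exactly at the contact frame, and
    decelerates symmetrically through the follow-through.
    """
    n = len(t)
    dt = float(t[1] - t[0]) if n > 1 else 1.0 / 90.0
    pos = np.tile(rest_pos, (n, 1)).astype(float)
    if cfg.peak_speed <= 0:
        return pos, SwingTruth(0.0, contact_frame, contact_frame, aim_point.copy())

    u = aim_point - rest_pos
    dist = np.linalg.norm(u)
    u = u / dist if dist > 0 else np.array([0.0, 0.0, 1.0])
    p0 = rest_pos - BACKSWING_AMPLITUDE * u
    length = dist + BACKSWING_AMPLITUDE

    t_fore = math.pi * length / (2 * cfg.peak_speed)
    fore_start = max(1, contact_frame - int(round(t_fore / dt)))
    back_start = max(0, fore_start - int(round(cfg.backswing_s / dt)))

    # backswing: half-cosine ease from rest to p0
    nb = fore_start - back_start
    if nb > 0:
        frac = (1 - np.cos(np.pi * np.arange(1, nb + 1) / nb)) / 2
        pos[back_start:fore_start] = rest_pos + np.outer(frac, p0 - rest_pos)

    # foreswing + follow-through: speed = peak * sin(pi*tau/(2*T)) up to the
    # contact (tau = T), then mirrors down; displacement is its integral
    tau = (np.arange(fore_start, n) - fore_start) * dt
    T = (contact_frame - fore_start) * dt
    if T <= 0:
        T = dt
    s = np.where(
        tau <= T,
        length * (1 - np.cos(np.pi * tau / (2 * T))),
        length + length * np.sin(np.clip(np.pi * (tau - T) / (2 * T), 0, np.pi / 2)),
    )
    pos[fore_start:] = p0 + np.outer(s, u)

    if cfg.noise_sd > 0:
        pos += rng.normal(0.0, cfg.noise_sd, pos.shape)

    truth = SwingTruth(
        peak_speed=float(length * np.pi / (2 * T)) if T > 0 else 0.0,
        foreswing_onset=fore_start, contact_frame=contact_frame,
        aim_point=aim_point.copy(),
    )
    return pos, truth


# ---------------------------------------------------------------------------
# feedback schedule


@dataclass
class BlockSchedule:
    """Bogus-feedback calls, ball types and probe placement for one block."""

    feedback: str                  # 'low' or 'high' (probability of failure)
    n_trials: int
    feedback_calls: list[str]      # 'hit' / 'miss' per trial
    probe_trials: list[int]        # 0-based trial indices, sorted
    ball_types: list[str]          # 'normal' / 'elastic' per trial

    @property
    def hit_rate(self) -> float:
        return self.feedback_calls.count("hit") / self.n_trials


def build_feedback_schedule(
    feedback: str,
    n_trials: int,
    rng: np.random.Generator,
    hit_rate_low: float = 0.58,
    hit_rate_high: float = 0.42,
    p_normal: float = 0.67,
    n_probes: int = 6,
    max_tries: int = 10_000,
) -> BlockSchedule:
    """Seeded feedback/probe schedule satisfying the probe-matching rules.

    The hit-call count is the nearest integer to the block's nominal hit
    rate times ``n_trials``.  Probes are placed one per equal-width window
    across the block, subject to: half follow a 'hit' call and half a
    'miss' call, and the cumulative hit proportion at every probe matches
    the nominal rate to within one trial's worth of rounding.  Orders are
    drawn by rejection sampling.
    """
    if feedback not in ("low", "high"):
        raise ConfigError(f"feedback: unknown level {feedback!r}")
    if n_trials < 2 * n_probes:
        raise ConfigError("n_trials: too few trials for the probe constraints")
    if n_probes % 2:
        raise ConfigError("n_probes: must be even (half after hits, half after misses)")
    rate = hit_rate_low if feedback == "low" else hit_rate_high
    n_hits = int(round(rate * n_trials))
    base = np.array(["hit"] * n_hits + ["miss"] * (n_trials - n_hits))
    windows = np.array_split(np.arange(n_trials), n_probes)
    half = n_probes // 2

    for _ in range(max_tries):
        calls = rng.permutation(base)
        cum = np.cumsum(calls == "hit")
        tcount = np.arange(1, n_trials + 1)
        eligible = np.abs(cum - rate * tcount) <= 1.0
        picks: list[int] = []
        n_hit_probes = 0
        ok = True
        for w in windows:
            cand = w[eligible[w]]
            if cand.size == 0:
                ok = False
                break
            # steer the hit/miss split toward the required half/half
            want_hit = n_hit_probes < half
            typed = cand[(calls[cand] == "hit") == want_hit]
            pool = typed if typed.size else cand
            pick = int(rng.choice(pool))
            picks.append(pick)
            n_hit_probes += calls[pick] == "hit"
        if not ok or n_hit_probes != half:
            continue
        n_normal = int(round(p_normal * n_trials))
        balls = rng.permutation(
            np.array(["normal"] * n_normal + ["elastic"] * (n_trials - n_normal)))
        return BlockSchedule(
            feedback=feedback, n_trials=n_trials,
            feedback_calls=calls.tolist(), probe_trials=sorted(picks),
            ball_types=balls.tolist(),
        )
    raise ConfigError(
        f"could not satisfy probe constraints for n_trials={n_trials} "
        f"within {max_tries} tries")


# ---------------------------------------------------------------------------
# self-reports


def generate_selfreports(
    design: pd.DataFrame,
    truth: SelfReportTruth,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate POF/COF/anxiety probe reports from the linear truth model.

    ``design`` needs one row per probe with columns ``participant``,
    ``pressure`` and ``feedback`` (0/1 indicators).  Each participant gets
    independent random intercepts for the three outcomes; residual noise is
    Gaussian; POF/COF are clipped to [0, 6] and anxiety to [0, 10].
    """
    out = design.copy()
    participants = out["participant"].unique()
    idx = out["participant"].map({p: i for i, p in enumerate(participants)}).to_numpy()
    u_pof = rng.normal(0, truth.sd_intercept_pof, len(participants))[idx]
    u_cof = rng.normal(0, truth.sd_intercept_cof, len(participants))[idx]
    u_anx = rng.normal(0, truth.sd_intercept_anx, len(participants))[idx]
    press = out["pressure"].to_numpy(float)
    feed = out["feedback"].to_numpy(float)
    m = len(out)

    pof = (truth.intercept_pof + truth.beta_pressure_on_pof * press
           + truth.beta_feedback_on_pof * feed
           + truth.beta_interaction_on_pof * press * feed
           + u_pof + rng.normal(0, truth.sd_resid_pof, m))
    pof = np.clip(pof, 0.0, 6.0)
    cof = (truth.intercept_cof + truth.beta_pressure_on_cof * press
           + truth.beta_feedback_on_cof * feed
           + truth.beta_interaction_on_cof * press * feed
           + u_cof + rng.normal(0, truth.sd_resid_cof, m))
    cof = np.clip(cof, 0.0, 6.0)
    anx = (truth.intercept_anx + truth.beta_pof_on_anx * pof
           + truth.beta_cof_on_anx * cof + truth.beta_pofxcof_on_anx * pof * cof
           + u_anx + rng.normal(0, truth.sd_resid_anx, m))
    anx = np.clip(anx, 0.0, 10.0)

    out["pof"], out["cof"], out["anxiety"] = pof, cof, anx
    return out


# ---------------------------------------------------------------------------
# whole trials and sessions


@dataclass
class TrialTruth:
    """Everything the generator knows about one trial."""

    release_frame: int
    bounce_frame: int
    contact_frame: int
    intercepted: bool
    ball_type: str
    gaze_events: list[GazeTruthEvent]
    swing: SwingTruth
    bounce_fixation_pitch: float   # egocentric deg, injected
    eye_origin: np.ndarray


@dataclass
class SimulatedTrial:
    frame: pd.DataFrame     # TRIAL_COLUMNS layout
    truth: TrialTruth
    block: int = 0
    trial: int = 0
    feedback_call: str = "hit"


def simulate_trial(
    config: SessionConfig,
    ball_type: str,
    intercepted: bool,
    rng: np.random.Generator,
) -> SimulatedTrial:
    """Simulate one complete trial's synchronized 90 Hz channels."""
    phys = config.physics
    dt = 1.0 / phys.sample_rate
    ball = generate_ball_trajectory(ball_type, phys)

    player = np.array([-phys.lateral_start_offset, 0.0, 0.0])
    eye = player + np.array([0.0, EYE_HEIGHT, 0.0])
    rest = eye + REST_OFFSET

    # contact where the ball crosses the plane 0.4 m in front of the player
    crossing = np.nonzero(ball.pos[:, 2] <= CONTACT_PLANE_AHEAD)[0]
    contact_frame = int(crossing[0]) if crossing.size else len(ball.t) - 1
    ball_at_contact = ball.pos[contact_frame].copy()

    aim = ball_at_contact.copy()
    if not intercepted:
        aim[0] += config.swing.miss_offset * (1 if rng.random() < 0.5 else -1)

    # truncate the trial shortly after contact
    n = min(len(ball.t), contact_frame + int(round(POST_CONTACT_S / dt)) + 1)
    t = ball.t[:n]
    pos = ball.pos[:n].copy()
    if intercepted:
        # racquet contact: the ball deflects back toward the wall
        v = ball.velocity[contact_frame].copy()
        v[2] = abs(v[2])
        v[1] = abs(v[1]) * 0.5
        tau = t[contact_frame + 1:] - t[contact_frame]
        pos[contact_frame + 1:] = (ball_at_contact
                                   + np.outer(tau, v)
                                   + 0.5 * phys.gravity * np.outer(tau ** 2, [0, 1, 0]))
    ball_cut = BallTrajectory(
        t=t, pos=pos, release_frame=ball.release_frame,
        bounce_frame=ball.bounce_frame, bounce_time=ball.bounce_time,
        bounce_point=ball.bounce_point, velocity=ball.velocity[:n],
        ball_type=ball_type,
    )

    gaze_dir, valid, events = generate_gaze(
        ball_cut, config.gaze, eye, rng, sample_rate=phys.sample_rate)
    ctrl, swing_truth = generate_swing(
        config.swing, t, contact_frame, aim, rest, rng)

    frame = pd.DataFrame({"time_s": t})
    for i, c in enumerate("xyz"):
        frame[f"head_{c}"] = eye[i]
    frame["head_qw"], frame["head_qx"] = 1.0, 0.0
    frame["head_qy"], frame["head_qz"] = 0.0, 0.0
    for i, c in enumerate("xyz"):
        frame[f"ctrl_{c}"] = ctrl[:, i]
    frame["ctrl_qw"], frame["ctrl_qx"] = 1.0, 0.0
    frame["ctrl_qy"], frame["ctrl_qz"] = 0.0, 0.0
    for i, c in enumerate("xyz"):
        frame[f"gaze_origin_{c}"] = eye[i]
    for i, c in enumerate("xyz"):
        frame[f"gaze_dir_{c}"] = gaze_dir[:, i]
    for i, c in enumerate("xyz"):
        frame[f"ball_{c}"] = pos[:, i]
    frame["gaze_valid"] = valid.astype(int)
    frame = frame[TRIAL_COLUMNS]

    # the contact landmark on a miss is the frame where the ball's depth
    # first passes behind the racquet (what segmentation reports)
    truth_contact = contact_frame
    if not intercepted:
        passed = np.nonzero(pos[ball.bounce_frame + 3:, 2] < ctrl[ball.bounce_frame + 3:, 2])[0]
        if passed.size:
            truth_contact = int(passed[0]) + ball.bounce_frame + 3

    bounce_fix = next(e for e in events
                      if e.kind == "fixation" and e.onset > ball.release_frame)
    truth = TrialTruth(
        release_frame=ball.release_frame, bounce_frame=ball.bounce_frame,
        contact_frame=truth_contact, intercepted=intercepted,
        ball_type=ball_type, gaze_events=events, swing=swing_truth,
        bounce_fixation_pitch=float(bounce_fix.target_pitch_deg),
        eye_origin=eye,
    )
    return SimulatedTrial(frame=frame, truth=truth)


CONDITIONS = [("low", "low"), ("low", "high"), ("high", "low"), ("high", "high")]


@dataclass
class SessionBundle:
    """All simulated artefacts for one participant."""

    participant: str
    config: SessionConfig
    trials: list[SimulatedTrial]
    manifest: SessionManifest
    block_conditions: list[tuple[str, str]] = field(default_factory=list)


def simulate_session(
    config: SessionConfig,
    seed: int,
    participant: str = "p01",
    participant_index: int = 0,
    out_dir=None,
) -> SessionBundle:
    """Simulate one participant: 4 blocks (2 pressure x 2 feedback) of trials.

    Block order is a rotation of the 2x2 condition list by
    ``participant_index`` (counterbalancing across participants).  With a
    fixed seed the output — including any files written to ``out_dir`` —
    is bit-for-bit reproducible.
    """
    rng = np.random.default_rng(seed)
    k = participant_index % 4
    order = CONDITIONS[k:] + CONDITIONS[:k]

    trials: list[SimulatedTrial] = []
    man_rows, probe_design = [], []
    for b, (pressure, feedback) in enumerate(order):
        sched = build_feedback_schedule(
            feedback, config.n_trials_per_block, rng,
            hit_rate_low=config.hit_rate_low_feedback,
            hit_rate_high=config.hit_rate_high_feedback,
            p_normal=config.p_normal_ball, n_probes=config.n_probes_per_block)
        for i in range(sched.n_trials):
            hit = bool(rng.random() < config.interception_rate)
            tr = simulate_trial(config, sched.ball_types[i], hit, rng)
            tr.block, tr.trial = b, i
            tr.feedback_call = sched.feedback_calls[i]
            trials.append(tr)
            man_rows.append({
                "participant": participant, "block": b,
                "pressure": pressure, "feedback": feedback,
                "trial": i, "ball_type": sched.ball_types[i],
                "feedback_call": sched.feedback_calls[i],
                "is_probe": int(i in sched.probe_trials),
            })
        for i in sched.probe_trials:
            probe_design.append({
                "participant": participant, "block": b,
                "pressure": int(pressure == "high"),
                "feedback": int(feedback == "high"), "trial": i,
            })

    design = pd.DataFrame(probe_design)
    reports = generate_selfreports(design, config.truth, rng)
    probes = reports.rename(columns={"anxiety": "anxiety"})
    probes["pressure"] = np.where(probes["pressure"] == 1, "high", "low")
    probes["feedback"] = np.where(probes["feedback"] == 1, "high", "low")
    manifest = SessionManifest(
        trials=pd.DataFrame(man_rows)[MANIFEST_COLUMNS],
        probes=probes[PROBE_COLUMNS],
    )
    bundle = SessionBundle(participant=participant, config=config,
                           trials=trials, manifest=manifest,
                           block_conditions=order)
    if out_dir is not None:
        from pathlib import Path
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for tr in trials:
            write_trial_csv(tr.frame, out_dir / trial_filename(participant, tr.block, tr.trial))
        write_manifest(manifest, out_dir)
    return bundle
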