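"""Configuration objects for the simulated interception task.

The defaults encode the task as run in the original VR racquetball
paradigm: a 15 m court, balls launched from a 2 m port on the front wall,
bouncing 3.5 m in front of a start position 9 m behind the wall, with two
coefficients of restitution (a normal tennis-ball-like 0.65 and a lively
0.85), and motion/gaze channels sampled at 90 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


class ConfigError(ValueError):
    """A configuration value violates its documented bounds."""


def _check(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{key}: {msg}")


@dataclass
class PhysicsConfig:
    """Ball-flight and collision geometry.

    Units are metres, seconds and m/s throughout.  ``bounce_vertical_speed``
    is the (downward, hence negative) vertical velocity at floor contact;
    the launch velocity is solved from it and the 2 m launch height, so the
    pre-bounce path is identical for both ball types.
    """

    gravity: float = -9.8                 # m/s^2
    bounce_vertical_speed: float = -9.0   # m/s at floor contact
    elasticity_normal: float = 0.65
    elasticity_elastic: float = 0.85
    ball_diameter: float = 0.057          # m
    bounce_distance_ahead: float = 3.5    # m in front of the start position
    start_behind_wall: float = 9.0        # m
    lateral_start_offset: float = 0.75    # m (player left of midline)
    launch_height: float = 2.0            # m
    court_length: float = 15.0            # m
    racquet_extent: tuple[float, float, float] = (0.6, 0.3, 0.01)
    collision_pad: float = 0.20           # m added to racquet thickness
    sample_rate: float = 90.0             # Hz
    pre_release_s: float = 0.3            # stationary ball before launch

    def __post_init__(self) -> None:
        _check(0 < self.elasticity_normal < 1, "elasticity_normal", "must be in (0, 1)")
        _check(0 < self.elasticity_elastic < 1, "elasticity_elastic", "must be in (0, 1)")
        _check(self.sample_rate > 0, "sample_rate", "must be positive")
        _check(self.gravity < 0, "gravity", "must be negative (downward)")
        _check(self.bounce_vertical_speed < 0, "bounce_vertical_speed",
               "must be negative (downward at contact)")
        _check(self.bounce_distance_ahead < self.start_behind_wall,
               "bounce_distance_ahead", "bounce must be between wall and player")
        _check(self.launch_height > 0, "launch_height", "must be positive")

    def elasticity(self, ball_type: str) -> float:
        if ball_type == "normal":
            return self.elasticity_normal
        if ball_type == "elastic":
            return self.elasticity_elastic
        raise ConfigError(f"ball_type: unknown value {ball_type!r}")


@dataclass
class GazeGenConfig:
    """Shape of the synthetic gaze track.

    The track follows the canonical interception strategy: early pursuit of
    the ball, one predictive saccade to a spot a few degrees above the
    future bounce point, a fixation held there through the bounce, then a
    catch-up saccade back onto the ball and post-bounce pursuit.  The
    magnitudes below are generator choices (the strategy, not the numbers,
    is what real data constrain).
    """

    pursuit_gain: float = 0.95            # fraction of ball angular motion matched
    saccade_peak_velocity: float = 300.0  # deg/s, triangular profile
    bounce_fixation_pitch_offset: float = 4.0  # deg above the bounce point
    bounce_fixation_lead: float = 0.30    # s before bounce that the fixation starts
    fixation_jitter_sd: float = 0.0       # deg, white jitter on gaze angles
    dropout_rate: float = 0.0             # per-frame probability a missing run starts
    dropout_run_length: int = 3           # frames per missing run
    catchup_saccades: int = 1             # catch-up saccades after the bounce

    def __post_init__(self) -> None:
        _check(0 <= self.pursuit_gain <= 1.2, "pursuit_gain", "must be in [0, 1.2]")
        _check(0 <= self.dropout_rate <= 1, "dropout_rate", "must be in [0, 1]")
        _check(self.saccade_peak_velocity > 0, "saccade_peak_velocity", "must be positive")
        _check(self.bounce_fixation_lead >= 0, "bounce_fixation_lead", "must be >= 0")
        _check(self.fixation_jitter_sd >= 0, "fixation_jitter_sd", "must be >= 0")
        _check(self.dropout_run_length >= 1, "dropout_run_length", "must be >= 1")


@dataclass
class SwingGenConfig:
    """Bell-profile hand swing toward the interception point."""

    peak_speed: float = 4.0       # m/s along the approach direction
    backswing_speed: float = 1.5  # m/s peak of the backswing
    foreswing_s: float = 0.40     # s
    backswing_s: float = 0.30     # s
    noise_sd: float = 0.0         # m, positional white noise
    miss_offset: float = 0.8      # m lateral offset applied on intended misses

    def __post_init__(self) -> None:
        _check(self.peak_speed >= 0, "peak_speed", "must be >= 0")
        _check(self.foreswing_s > 0, "foreswing_s", "must be positive")
        _check(self.backswing_s >= 0, "backswing_s", "must be >= 0")


@dataclass
class SelfReportTruth:
    """Generative coefficients for the probe self-reports.

    POF (perceived probability of failure) and COF (cost of failure) are
    0-6 Likert ratings; the anxiety thermometer is 0-10.  Defaults for the
    slopes are the point estimates of the reported condition and appraisal
    models; intercepts and variance components are chosen so that the
    ratings stay well inside their scales (clipping is a rare safety valve,
    keeping the linear-Gaussian generative model faithful).
    """

    intercept_pof: float = 2.8
    intercept_cof: float = 2.6
    intercept_anx: float = 1.6
    beta_feedback_on_pof: float = 0.46
    beta_pressure_on_pof: float = -0.01
    beta_interaction_on_pof: float = 0.06
    beta_pressure_on_cof: float = -0.12
    beta_feedback_on_cof: float = 0.07
    beta_interaction_on_cof: float = 0.43
    beta_pof_on_anx: float = 0.18
    beta_cof_on_anx: float = 0.29
    beta_pofxcof_on_anx: float = 0.02
    sd_intercept_pof: float = 0.8
    sd_intercept_cof: float = 1.0
    sd_intercept_anx: float = 0.7
    sd_resid_pof: float = 0.8
    sd_resid_cof: float = 0.6
    sd_resid_anx: float = 0.6

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name.startswith("sd_"):
                _check(getattr(self, f.name) >= 0, f.name, "SD must be >= 0")


@dataclass
class SessionConfig:
    """Everything needed to simulate one participant session."""

    physics: PhysicsConfig = field(default_factory=PhysicsConfig)
    gaze: GazeGenConfig = field(default_factory=GazeGenConfig)
    swing: SwingGenConfig = field(default_factory=SwingGenConfig)
    truth: SelfReportTruth = field(default_factory=SelfReportTruth)
    n_trials_per_block: int = 72
    n_probes_per_block: int = 6
    hit_rate_low_feedback: float = 0.58
    hit_rate_high_feedback: float = 0.42
    p_normal_ball: float = 0.67
    interception_rate: float = 0.65   # true (not fed back) hit probability
    lowpass_cutoff_hz: float = 10.0   # echoed into preprocessing

    def __post_init__(self) -> None:
        _check(self.n_trials_per_block >= 12, "n_trials_per_block", "must be >= 12")
        _check(0 < self.hit_rate_low_feedback < 1, "hit_rate_low_feedback", "must be in (0, 1)")
        _check(0 < self.hit_rate_high_feedback < 1, "hit_rate_high_feedback", "must be in (0, 1)")
        _check(0 < self.p_normal_ball < 1, "p_normal_ball", "must be in (0, 1)")
        _check(0 <= self.interception_rate <= 1, "interception_rate", "must be in [0, 1]")


_SECTIONS = {
    "physics": PhysicsConfig,
    "gaze": GazeGenConfig,
    "swing": SwingGenConfig,
    "truth": SelfReportTruth,
}


def session_config_from_dict(raw: dict) -> SessionConfig:
    """Build a validated :class:`SessionConfig` from a nested plain dict.

    Unknown keys are rejected by name; every numeric value passes through
    the dataclass invariant checks.
    """
    raw = dict(raw or {})
    kwargs: dict = {}
    for section, cls in _SECTIONS.items():
        sub = raw.pop(section, {})
        if not isinstance(sub, dict):
            raise ConfigError(f"{section}: expected a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(sub) - known
        if unknown:
            raise ConfigError(f"{section}: unknown keys {sorted(unknown)}")
        fixed = {k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()}
        kwargs[section] = cls(**fixed)
    top_known = {f.name for f in fields(SessionConfig)} - set(_SECTIONS)
    unknown = set(raw) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
    kwargs.update(raw)
    return SessionConfig(**kwargs)
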