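"""Reading and writing the session file formats.

A session on disk is a directory of per-trial time-series CSVs (90 Hz
head / hand-controller / gaze / ball channels), one manifest CSV of
trial-level labels (block, condition, ball type, bogus feedback call),
one probe CSV of self-reports, and an optional YAML configuration file.

All formats are plain comma-separated UTF-8 with a header row and a
schema-version comment line stamped on top.  Floats are written with
shortest round-trip precision, so write -> read is value-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import ConfigError, SessionConfig, session_config_from_dict

log = logging.getLogger("vrintercept")

TRIAL_SCHEMA_TAG = "# vrintercept-trial-v1"
TABLE_SCHEMA_TAG = "# vrintercept-table-v1"

TRIAL_COLUMNS = (
    ["time_s"]
    + [f"head_{c}" for c in "xyz"]
    + [f"head_q{c}" for c in "wxyz"]
    + [f"ctrl_{c}" for c in "xyz"]
    + [f"ctrl_q{c}" for c in "wxyz"]
    + [f"gaze_origin_{c}" for c in "xyz"]
    + [f"gaze_dir_{c}" for c in "xyz"]
    + [f"ball_{c}" for c in "xyz"]
    + ["gaze_valid"]
)

MANIFEST_COLUMNS = [
    "participant", "block", "pressure", "feedback",
    "trial", "ball_type", "feedback_call", "is_probe",
]
PROBE_COLUMNS = ["participant", "block", "pressure", "feedback", "trial",
                 "pof", "cof", "anxiety"]


class SchemaError(ValueError):
    """A file does not match the declared schema."""


@dataclass
class SessionManifest:
    """Trial-level labels and probe-level self-reports for one session."""

    trials: pd.DataFrame   # MANIFEST_COLUMNS
    probes: pd.DataFrame   # PROBE_COLUMNS

    def __post_init__(self) -> None:
        t = self.trials
        if t.duplicated(subset=["participant", "block", "trial"]).any():
            raise SchemaError("duplicate trial index within a block")
        key = set(map(tuple, t[["participant", "block", "trial"]].itertuples(index=False)))
        for row in self.probes[["participant", "block", "trial"]].itertuples(index=False):
            if tuple(row) not in key:
                raise SchemaError(f"probe references absent trial {tuple(row)}")


def _write_tagged_csv(df: pd.DataFrame, path: Path, tag: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(tag + "\n")
        # %.17g is the shortest format guaranteed to round-trip float64
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_tagged_csv(path: Path, tag: str) -> pd.DataFrame:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if first != tag:
            raise SchemaError(f"{path}: expected schema tag {tag!r}, found {first!r}")
        return pd.read_csv(fh, float_precision="round_trip")


def write_trial_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write one trial's synchronized time series in fixed column order."""
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"trial frame missing columns: {missing}")
    _write_tagged_csv(frame[TRIAL_COLUMNS], Path(path), TRIAL_SCHEMA_TAG)
    log.debug("wrote trial %s (%d frames)", path, len(frame))


def read_trial_csv(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read one trial time-series CSV.

    ``column_map`` adapts an external layout: a mapping of
    ``external_name -> schema_name`` applied before validation, for use
    with deposited datasets whose column names differ from ours.
    Invalid-gaze rows (``gaze_valid == 0``) have their gaze direction
    masked to NaN so missing data propagates explicitly.
    """
    path = Path(path)
    if column_map:
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
        frame = frame.rename(columns=column_map)
    else:
        frame = _read_tagged_csv(path, TRIAL_SCHEMA_TAG)
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    frame = frame[TRIAL_COLUMNS].astype(
        {c: float for c in TRIAL_COLUMNS if c != "gaze_valid"})
    t = frame["time_s"].to_numpy()
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise SchemaError(f"{path}: time_s is not strictly increasing")
    bad = frame["gaze_valid"].to_numpy() == 0
    if bad.any():
        frame.loc[bad, [f"gaze_dir_{c}" for c in "xyz"]] = np.nan
    dir_cols = frame[[f"gaze_dir_{c}" for c in "xyz"]].to_numpy()
    norms = np.linalg.norm(dir_cols, axis=1)
    ok = ~bad
    if ok.any() and np.any(np.abs(norms[ok] - 1.0) > 1e-3):
        raise SchemaError(f"{path}: gaze direction not unit-norm on valid rows")
    log.debug("read trial %s (%d frames, %d invalid gaze)", path, len(frame), int(bad.sum()))
    return frame


def write_manifest(manifest: SessionManifest, directory: str | Path) -> tuple[Path, Path]:
    """Write ``manifest.csv`` and ``probes.csv`` into *directory*."""
    directory = Path(directory)
    mpath, ppath = directory / "manifest.csv", directory / "probes.csv"
    _write_tagged_csv(manifest.trials[MANIFEST_COLUMNS], mpath, TABLE_SCHEMA_TAG)
    _write_tagged_csv(manifest.probes[PROBE_COLUMNS], ppath, TABLE_SCHEMA_TAG)
    return mpath, ppath


def read_manifest(directory: str | Path) -> SessionManifest:
    """Read the manifest/probe pair; referential integrity is re-checked."""
    directory = Path(directory)
    trials = _read_tagged_csv(directory / "manifest.csv", TABLE_SCHEMA_TAG)
    probes = _read_tagged_csv(directory / "probes.csv", TABLE_SCHEMA_TAG)
    for col in ("pof", "cof", "anxiety"):
        if col in probes.columns:
            probes[col] = probes[col].astype(float)
    for cols, df, name in ((MANIFEST_COLUMNS, trials, "manifest"),
                           (PROBE_COLUMNS, probes, "probes")):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{name}: missing columns {missing}")
    return SessionManifest(trials=trials, probes=probes)


def trial_filename(participant: str | int, block: int, trial: int) -> str:
    return f"{participant}_b{block}_t{trial:03d}.csv"


def load_config(path: str | Path | None = None) -> SessionConfig:
    """Load a YAML session configuration; an empty/absent file means defaults.

    Unknown keys raise :class:`~vrintercept.config.ConfigError`; every
    numeric is validated against its documented bounds (e.g. elasticities
    must lie in (0, 1)).
    """
    if path is None:
        return SessionConfig()
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        return SessionConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return session_config_from_dict(raw)


def dump_config(cfg: SessionConfig, path: str | Path) -> None:
    """Write every configuration value (defaults included) as YAML."""
    from dataclasses import asdict
    out = asdict(cfg)
    for section in ("physics", "gaze", "swing", "truth"):
        for k, v in out[section].items():
            if isinstance(v, tuple):
                out[section][k] = list(v)
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False), encoding="utf-8")
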