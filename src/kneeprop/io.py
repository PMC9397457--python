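"""CSV/JSON file formats and configuration validation.

Pose CSV dialects (UTF-8, comma-separated, header required; auto-detected
from the header, never from the filename):

* ``relative``: session_id, trial_id, frame_pct, r11..r33 (row-major
  shank-relative-to-thigh rotation matrix);
* ``segments``: session_id, trial_id, frame_pct, t11..t33, s11..s33 (thigh
  and shank orientations in the world frame; the relative rotation is
  formed on reading).

Rotations read from file are validated for orthonormality within 1e-6
(with the offending line reported) and then projected onto the nearest
proper rotation, since the fixed 9-significant-digit CSV formatting leaves
round-off beyond the strict internal tolerance.  Trials not sampled on the
0..100% integer grid are resampled by linear interpolation of the rotation
vector.  Numeric output uses 9 significant digits so regression tests can
be bit-exact.  Output files embed provenance (config hash, seed, tool
version) as a leading ``#`` comment (CSV) or a ``provenance`` key (JSON).
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .kinematics import (
    GaitCycleSequence,
    attitude_from_rotation,
    enforce_axis_continuity,
    relative_rotation,
    rotation_from_rotvec,
    validate_rotation,
)
from .synthetic import Session, SessionDataset, Trial
from .uncertainty import SOURCE_GROUPS, PropagatedUncertainty

__all__ = [
    "PoseCsvError",
    "ConfigError",
    "provenance_dict",
    "write_pose_csv",
    "read_pose_csv",
    "write_angles_csv",
    "write_uncertainty_csv",
    "read_uncertainty_csv",
    "write_variability_csv",
    "load_json_config",
    "validate_config",
]

CSV_FLOAT_FORMAT = "%.9g"
CSV_ORTHONORMALITY_TOL = 1e-6

_R_COLS = [f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]
_T_COLS = [f"t{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]
_S_COLS = [f"s{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]
_KEY_COLS = ["session_id", "trial_id", "frame_pct"]
RELATIVE_COLUMNS = _KEY_COLS + _R_COLS
SEGMENTS_COLUMNS = _KEY_COLS + _T_COLS + _S_COLS

_UNCERTAINTY_COLUMNS = (
    ["frame_pct", "u_theta1", "u_theta2", "u_theta3"]
    + [f"src_{src}_u{i}" for src in SOURCE_GROUPS for i in (1, 2, 3)]
)


class PoseCsvError(ValueError):
    """Malformed pose CSV (header, values or rotation validity)."""


class ConfigError(ValueError):
    """Invalid run configuration."""


def provenance_dict(config: dict | None, seed: int | None) -> dict:
    canonical = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "tool": "kneeprop",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
    }


def _write_csv(df: pd.DataFrame, path, provenance: dict | None) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        if provenance is not None:
            fh.write("# provenance " + json.dumps(provenance, sort_keys=True) + "\n")
        df.to_csv(fh, index=False, float_format=CSV_FLOAT_FORMAT)


def write_pose_csv(dataset: SessionDataset, path,
                   provenance: dict | None = None) -> None:
    """Write a dataset in the ``relative`` pose dialect."""
    rows = []
    for sid, tid, cycle in dataset.iter_trials():
        for i in range(cycle.n_frames):
            rows.append([sid, tid, cycle.frame_pct[i],
                         *cycle.rotations[i].reshape(9)])
    df = pd.DataFrame(rows, columns=RELATIVE_COLUMNS)
    _write_csv(df, path, provenance)


def _nearest_rotation(R: np.ndarray) -> np.ndarray:
    U, _, Vt = np.linalg.svd(R)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


def _validate_row_rotation(R: np.ndarray, line_no: int, label: str) -> np.ndarray:
    try:
        validate_rotation(R, tol=CSV_ORTHONORMALITY_TOL)
    except ValueError as exc:
        raise PoseCsvError(f"line {line_no}: invalid {label} rotation: {exc}") from exc
    return _nearest_rotation(R)


def _resample_cycle(pct: np.ndarray, rotations: np.ndarray,
                    stance_fraction: float) -> GaitCycleSequence:
    """Resample an arbitrary frame grid to 0..100% by linear interpolation
    of the rotation vector (continuity-fixed theta*k, radians)."""
    theta = np.empty(len(pct))
    k = np.empty((len(pct), 3))
    degen = np.empty(len(pct), dtype=bool)
    for i, R in enumerate(rotations):
        att = attitude_from_rotation(R)
        theta[i], k[i], degen[i] = att.theta_deg, att.axis, att.degenerate
    theta, k = enforce_axis_continuity(theta, k, degen)
    rotvec = np.radians(theta)[:, None] * k
    grid = np.arange(101.0)
    interp = np.stack([np.interp(grid, pct, rotvec[:, j]) for j in range(3)],
                      axis=1)
    R = np.stack([rotation_from_rotvec(v) for v in interp])
    return GaitCycleSequence(R, stance_fraction=stance_fraction)


def read_pose_csv(path, stance_fraction: float = 0.616) -> SessionDataset:
    """Read either pose dialect into a :class:`SessionDataset`."""
    path = Path(path)
    n_comment = 0
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                n_comment += 1
            else:
                break
    df = pd.read_csv(path, comment="#")
    cols = list(df.columns)
    if cols == RELATIVE_COLUMNS:
        dialect = "relative"
    elif cols == SEGMENTS_COLUMNS:
        dialect = "segments"
    else:
        raise PoseCsvError(
            f"malformed header: expected the relative or segments pose "
            f"dialect, got columns {cols}")
    if df[_KEY_COLS[2]].min() < 0 or df[_KEY_COLS[2]].max() > 100:
        raise PoseCsvError("frame_pct values must lie in [0, 100]")

    sessions: dict[str, Session] = {}
    for (sid, tid), group in df.groupby(["session_id", "trial_id"], sort=False):
        group = group.sort_values("frame_pct")
        if len(group) < 2:
            raise PoseCsvError(f"trial {sid}/{tid} has fewer than 2 frames")
        pct = group["frame_pct"].to_numpy(dtype=float)
        if np.any(np.diff(pct) <= 0):
            raise PoseCsvError(f"trial {sid}/{tid} has duplicate frame_pct values")
        rotations = np.empty((len(group), 3, 3))
        for i, (idx, row) in enumerate(group.iterrows()):
            line_no = n_comment + 2 + idx  # header + 1-based data rows
            if dialect == "relative":
                R = row[_R_COLS].to_numpy(dtype=float).reshape(3, 3)
                rotations[i] = _validate_row_rotation(R, line_no, "relative")
            else:
                T = row[_T_COLS].to_numpy(dtype=float).reshape(3, 3)
                S = row[_S_COLS].to_numpy(dtype=float).reshape(3, 3)
                T = _validate_row_rotation(T, line_no, "thigh")
                S = _validate_row_rotation(S, line_no, "shank")
                rotations[i] = relative_rotation(T, S)
        if len(pct) == 101 and np.array_equal(pct, np.arange(101.0)):
            cycle = GaitCycleSequence(rotations, stance_fraction=stance_fraction)
        else:
            cycle = _resample_cycle(pct, rotations, stance_fraction)
        sessions.setdefault(str(sid), Session(str(sid), [])).trials.append(
            Trial(str(tid), cycle))
    return SessionDataset(sessions=list(sessions.values()))


def write_angles_csv(dataset: SessionDataset, path,
                     provenance: dict | None = None) -> None:
    """Per-frame attitude, Cardan and projected angles for every trial."""
    rows = []
    for sid, tid, cycle in dataset.iter_trials():
        theta, k, _ = cycle.attitudes()
        cardan = cycle.cardan_angles()
        proj = cycle.projected_angles()
        for i in range(cycle.n_frames):
            rows.append([sid, tid, cycle.frame_pct[i], theta[i], *k[i],
                         *cardan[i], *proj[i]])
    df = pd.DataFrame(rows, columns=[
        "session_id", "trial_id", "frame_pct", "theta", "kx", "ky", "kz",
        "cardan1", "cardan2", "cardan3", "proj1", "proj2", "proj3"])
    _write_csv(df, path, provenance)


def write_uncertainty_csv(prop: PropagatedUncertainty, path,
                          provenance: dict | None = None) -> None:
    data = {"frame_pct": prop.frame_pct}
    for i in range(3):
        data[f"u_theta{i + 1}"] = prop.combined[:, i]
    for src in SOURCE_GROUPS:
        for i in range(3):
            data[f"src_{src}_u{i + 1}"] = prop.by_source[src][:, i]
    _write_csv(pd.DataFrame(data, columns=_UNCERTAINTY_COLUMNS), path, provenance)


def read_uncertainty_csv(path) -> PropagatedUncertainty:
    df = pd.read_csv(path, comment="#")
    missing = set(_UNCERTAINTY_COLUMNS) - set(df.columns)
    if missing:
        raise PoseCsvError(f"uncertainty CSV is missing columns {sorted(missing)}")
    combined = df[["u_theta1", "u_theta2", "u_theta3"]].to_numpy(dtype=float)
    by_source = {
        src: df[[f"src_{src}_u{i}" for i in (1, 2, 3)]].to_numpy(dtype=float)
        for src in SOURCE_GROUPS
    }
    return PropagatedUncertainty(
        frame_pct=df["frame_pct"].to_numpy(dtype=float), combined=combined,
        by_source=by_source,
        degenerate=np.zeros(len(df), dtype=bool))


def write_variability_csv(table: pd.DataFrame, path,
                          provenance: dict | None = None) -> None:
    df = table.reset_index(names="quantity")
    _write_csv(df, path, provenance)


def load_json_config(path) -> dict:
    with Path(path).open() as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a JSON object")
    return cfg


def validate_config(cfg: dict, allowed: dict, required: set = frozenset()) -> dict:
    """Check a flat config dict against ``{key: type_or_types}``; unknown
    keys are rejected, missing required keys raise."""
    unknown = set(cfg) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    missing = set(required) - set(cfg)
    if missing:
        raise ConfigError(f"missing required configuration keys: {sorted(missing)}")
    for key, value in cfg.items():
        types = allowed[key]
        if not isinstance(value, types):
            raise ConfigError(
                f"configuration key {key!r} has invalid type {type(value).__name__}")
    return cfg
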