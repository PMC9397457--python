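"""Inter-/intra-session variability of knee rotational quantities.

For every trial of a multi-session dataset the per-frame rotation angle,
rotation-axis orientation, Cardan angles and projected attitude-vector
components are extracted, and their reproducibility is summarized as scalar
root-mean-square deviations (RMSD):

* intra-session: deviations from the per-session frame mean, pooled over
  sessions, trials and frames;
* inter-session: deviations from the grand frame mean over all trials,
  pooled over trials and frames.

Axis orientation uses the angular deviation (acos of the dot product) from
the respective mean direction.  The module also provides the mean cycle
used as the linearization point of the analytic propagation, per-frame
experimental SD corridors, and a coarse qualitative classification of how
an analytic uncertainty corridor compares to an experimental one.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .kinematics import GaitCycleSequence, joint_axes_from_rotation
from .synthetic import SessionDataset

__all__ = [
    "QUANTITY_ROWS",
    "DEFAULT_PHASES",
    "MeanCycle",
    "AgreementLabel",
    "mean_cycle",
    "angular_deviation",
    "rmsd_table",
    "summarize_table",
    "experimental_sd_curves",
    "classify_agreement",
]

#: row order of the variability table
QUANTITY_ROWS = (
    "rotation_angle",
    "axis_orientation",
    "cardan_flexion",
    "projected_e1",
    "cardan_adduction",
    "projected_e2",
    "cardan_rotation",
    "projected_e3",
)

#: default gait-cycle phase segments (% cycle): stance, early/mid swing,
#: terminal swing
DEFAULT_PHASES = ((0.0, 61.6), (61.8, 85.0), (85.0, 100.0))


@dataclasses.dataclass
class MeanCycle:
    """Across-trial mean pose per frame: the linearization point.

    theta is the arithmetic mean of the (continuity-consistent) rotation
    angles; k, e1 and e3 are normalized arithmetic mean directions (e2
    follows from the floating-axis construction when needed).  Frames where
    no trial has an identifiable axis are flagged degenerate.
    """

    frame_pct: np.ndarray     # (101,)
    theta_deg: np.ndarray     # (101,)
    k: np.ndarray             # (101, 3)
    e1: np.ndarray            # (101, 3)
    e3: np.ndarray            # (101, 3)
    degenerate: np.ndarray    # (101,) bool
    stance_fraction: float = 0.616


@dataclasses.dataclass(frozen=True)
class AgreementLabel:
    """Qualitative analytic-vs-experimental verdict for one phase segment."""

    phase: tuple[float, float]
    ratio: float | None
    label: str | None
    indeterminate: bool = False


def _oriented_attitudes(cycle: GaitCycleSequence):
    """Continuity-fixed attitudes, globally oriented so k points along +Z
    (the knee's flexion direction) on average."""
    theta, k, degen = cycle.attitudes()
    valid = ~degen
    if valid.any() and k[valid, 2].sum() < 0:
        k = -k
        theta = -theta
    return theta, k, degen


def _trial_quantities(cycle: GaitCycleSequence) -> dict:
    theta, k, degen = _oriented_attitudes(cycle)
    e3 = np.array([joint_axes_from_rotation(R).e3 for R in cycle.rotations])
    return {
        "theta": theta,
        "k": k,
        "degen": degen,
        "e3": e3,
        "cardan": cycle.cardan_angles(),
        "projected": cycle.projected_angles(),
    }


def _mean_direction(vectors: np.ndarray) -> np.ndarray:
    """Normalized arithmetic mean of unit vectors, rows = samples."""
    v = vectors.mean(axis=0)
    n = np.linalg.norm(v)
    if n < 1e-6:
        raise ValueError("mean direction is undefined (near-antipodal axes)")
    return v / n


def mean_cycle(trials: Sequence[GaitCycleSequence]) -> MeanCycle:
    """Across-trial mean pose per frame.

    Degenerate frames are excluded from axis averaging; a frame where every
    trial is degenerate keeps the fallback axis and is flagged.
    """
    if len(trials) == 0:
        raise ValueError("mean_cycle requires at least one trial")
    qs = [_trial_quantities(c) for c in trials]
    n_frames = trials[0].n_frames
    theta = np.mean([q["theta"] for q in qs], axis=0)
    e1 = np.tile([0.0, 0.0, 1.0], (n_frames, 1))
    e3 = np.empty((n_frames, 3))
    k = np.empty((n_frames, 3))
    degenerate = np.zeros(n_frames, dtype=bool)
    for i in range(n_frames):
        e3[i] = _mean_direction(np.array([q["e3"][i] for q in qs]))
        ks = np.array([q["k"][i] for q in qs if not q["degen"][i]])
        if ks.size == 0:
            k[i] = [0.0, 0.0, 1.0]
            degenerate[i] = True
        else:
            k[i] = _mean_direction(ks)
    return MeanCycle(frame_pct=trials[0].frame_pct.copy(), theta_deg=theta,
                     k=k, e1=e1, e3=e3, degenerate=degenerate,
                     stance_fraction=trials[0].stance_fraction)


def angular_deviation(k_trial: np.ndarray, k_reference: np.ndarray) -> float:
    """Angle (degrees) between two unit vectors, in [0, 180]."""
    a = np.asarray(k_trial, dtype=float)
    b = np.asarray(k_reference, dtype=float)
    for v in (a, b):
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise ValueError("angular_deviation requires unit vectors")
    return float(np.degrees(np.arccos(np.clip(a @ b, -1.0, 1.0))))


def _axis_rmsd(k_stack: np.ndarray, degen_stack: np.ndarray,
               groups: Sequence[np.ndarray]) -> float:
    """RMS angular deviation of axes from the per-group mean direction.

    k_stack: (n_trials, n_frames, 3); groups: index arrays over trials.
    Frames where a trial is degenerate are excluded.
    """
    sq = []
    for idx in groups:
        for i in range(k_stack.shape[1]):
            rows = idx[~degen_stack[idx, i]]
            if rows.size < 2:
                continue
            ref = _mean_direction(k_stack[rows, i])
            d = np.degrees(np.arccos(np.clip(k_stack[rows, i] @ ref, -1.0, 1.0)))
            sq.extend(d**2)
    if not sq:
        return 0.0
    return float(np.sqrt(np.mean(sq)))


def rmsd_table(dataset: SessionDataset) -> pd.DataFrame:
    """Inter- and intra-session RMSD of all rotational quantities (degrees).

    Rows follow :data:`QUANTITY_ROWS`; columns ``inter_session`` and
    ``intra_session``.
    """
    session_sizes = [len(s.trials) for s in dataset.sessions]
    if not any(n >= 2 for n in session_sizes):
        raise ValueError("intra-session RMSD requires >= 2 trials in a session")
    if len(dataset.sessions) < 2:
        raise ValueError("inter-session RMSD requires >= 2 sessions")

    qs, session_of = [], []
    for si, s in enumerate(dataset.sessions):
        for t in s.trials:
            qs.append(_trial_quantities(t.cycle))
            session_of.append(si)
    session_of = np.asarray(session_of)

    scalars = {
        "rotation_angle": np.array([q["theta"] for q in qs]),
        "cardan_flexion": np.array([q["cardan"][:, 0] for q in qs]),
        "projected_e1": np.array([q["projected"][:, 0] for q in qs]),
        "cardan_adduction": np.array([q["cardan"][:, 1] for q in qs]),
        "projected_e2": np.array([q["projected"][:, 1] for q in qs]),
        "cardan_rotation": np.array([q["cardan"][:, 2] for q in qs]),
        "projected_e3": np.array([q["projected"][:, 2] for q in qs]),
    }
    k_stack = np.array([q["k"] for q in qs])
    degen_stack = np.array([q["degen"] for q in qs])

    intra_groups = [np.where(session_of == si)[0]
                    for si in range(len(dataset.sessions))
                    if (session_of == si).sum() >= 2]
    all_trials = [np.arange(len(qs))]

    def scalar_rmsd(values: np.ndarray, groups) -> float:
        sq = []
        for idx in groups:
            dev = values[idx] - values[idx].mean(axis=0, keepdims=True)
            sq.append(dev**2)
        return float(np.sqrt(np.concatenate(sq).mean()))

    rows = {}
    for name in QUANTITY_ROWS:
        if name == "axis_orientation":
            rows[name] = {
                "inter_session": _axis_rmsd(k_stack, degen_stack, all_trials),
                "intra_session": _axis_rmsd(k_stack, degen_stack, intra_groups),
            }
        else:
            rows[name] = {
                "inter_session": scalar_rmsd(scalars[name], all_trials),
                "intra_session": scalar_rmsd(scalars[name], intra_groups),
            }
    return pd.DataFrame.from_dict(rows, orient="index").loc[list(QUANTITY_ROWS)]


def summarize_table(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and population standard deviation (divisor n)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("summarize_table requires at least one value")
    return float(v.mean()), float(v.std(ddof=0))


def experimental_sd_curves(dataset: SessionDataset) -> dict[str, np.ndarray]:
    """Per-frame sample SD across all trials, for Cardan and projected
    angles; each array has shape (101, 3)."""
    cycles = dataset.all_cycles()
    if len(cycles) < 2:
        raise ValueError("experimental SD curves require >= 2 trials")
    cardan = np.array([c.cardan_angles() for c in cycles])
    projected = np.array([c.projected_angles() for c in cycles])
    return {
        "cardan": cardan.std(axis=0, ddof=1),
        "projected": projected.std(axis=0, ddof=1),
    }


def classify_agreement(
    analytic_u: np.ndarray,
    experimental_sd: np.ndarray,
    phases: Sequence[tuple[float, float]] = DEFAULT_PHASES,
    frame_pct: np.ndarray | None = None,
) -> list[AgreementLabel]:
    """Coarse per-phase verdict on how the analytic corridor compares with
    the experimental one.

    Per phase, the ratio r = mean(analytic) / mean(experimental) maps to
    '--' (r < 0.5), '-' (0.5 <= r < 0.8), '0' (0.8 <= r <= 1.25),
    '+' (1.25 < r <= 2) or '++' (r > 2).  A near-zero experimental mean is
    flagged indeterminate.
    """
    analytic_u = np.asarray(analytic_u, dtype=float)
    experimental_sd = np.asarray(experimental_sd, dtype=float)
    if analytic_u.shape != experimental_sd.shape:
        raise ValueError("curves must have matching shapes")
    if frame_pct is None:
        frame_pct = np.arange(analytic_u.shape[0], dtype=float)
    out = []
    for pi, (lo, hi) in enumerate(phases):
        if pi == 0:
            m = (frame_pct >= lo) & (frame_pct <= hi)
        else:
            m = (frame_pct > lo) & (frame_pct <= hi)
        if not m.any():
            raise ValueError(f"phase ({lo}, {hi}) contains no frames")
        exp_mean = experimental_sd[m].mean()
        ana_mean = analytic_u[m].mean()
        if exp_mean < 1e-9:
            out.append(AgreementLabel((lo, hi), None, None, indeterminate=True))
            continue
        r = float(ana_mean / exp_mean)
        if r < 0.5:
            label = "--"
        elif r < 0.8:
            label = "-"
        elif r <= 1.25:
            label = "0"
        elif r <= 2.0:
            label = "+"
        else:
            label = "++"
        out.append(AgreementLabel((lo, hi), r, label))
    return out
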