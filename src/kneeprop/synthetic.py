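"""Synthetic multi-session knee gait data with controllable variability.

The generator emulates a single-subject reproducibility design: several
capture sessions, several trials per session, each trial a time-normalized
101-frame gait cycle of shank-relative-to-thigh rotations.

The template cycle is a smooth two-bump knee flexion profile (a small
stance bump plus a large swing bump, both raised cosines) with small
constant adduction (varus) and internal-rotation offsets, composed through
the ZXY Cardan sequence.  Defaults follow conventional normal-gait
magnitudes: stance ends at 61.6% of the cycle, ~18 deg peak stance flexion,
~60 deg peak swing flexion at 72% of the cycle.

Two kinds of dispersion can be injected:

* intrinsic (trial-level): a smooth low-frequency offset on the rotation
  angle theta (constant + first harmonic, exactly ``sd_theta`` framewise
  standard deviation) and a per-trial tilt of the rotation axis k drawn
  from a cone of half-angle ``cone_k``;
* extrinsic (session-level): one fixed misorientation of the thigh frame
  (tilting the flexion axis e1) and of the shank frame (tilting the
  longitudinal axis e3) per session, shared by all of that session's
  trials, mimicking marker-placement error that is constant within a
  session.
"""
from __future__ import annotations

import dataclasses
from typing import Iterator

import numpy as np

from .kinematics import (
    GaitCycleSequence,
    compose_cardan_zxy,
    rotation_from_attitude,
    rotation_from_rotvec,
)

__all__ = [
    "GeneratorConfig",
    "SessionPerturbation",
    "Trial",
    "Session",
    "SessionDataset",
    "template_knee_cycle",
    "draw_session_perturbation",
    "generate_trial",
    "generate_dataset",
]


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Shape and dispersion parameters of the synthetic gait generator.

    Angles in degrees, locations in % of the gait cycle.  Dispersion
    defaults approximate reported single-subject knee reproducibility
    magnitudes (intra-session rotation-angle RMSD ~ 2 deg, axis-orientation
    RMSD ~ 3 deg, with session-level axis misalignment of similar size).
    """

    stance_fraction: float = 0.616
    peak_stance_flexion_deg: float = 18.0
    peak_swing_flexion_deg: float = 60.0
    swing_peak_pct: float = 72.0
    varus_offset_deg: float = 2.0
    rotation_offset_deg: float = 5.0
    sd_theta_deg: float = 2.0
    cone_k_deg: float = 3.0
    cone_e1_session_deg: float = 3.0
    cone_e3_session_deg: float = 3.0
    n_sessions: int = 5
    n_trials: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must be in (0, 1)")
        if not 0.0 < self.swing_peak_pct < 100.0:
            raise ValueError("swing_peak_pct must be in (0, 100)")
        for name in ("sd_theta_deg", "cone_k_deg",
                     "cone_e1_session_deg", "cone_e3_session_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_sessions < 1 or self.n_trials < 1:
            raise ValueError("n_sessions and n_trials must be at least 1")

    @property
    def has_intrinsic_noise(self) -> bool:
        return self.sd_theta_deg > 0 or self.cone_k_deg > 0

    @property
    def has_extrinsic_noise(self) -> bool:
        return self.cone_e1_session_deg > 0 or self.cone_e3_session_deg > 0


@dataclasses.dataclass(frozen=True)
class SessionPerturbation:
    """Fixed per-session frame misorientations (rotation matrices)."""

    q_thigh: np.ndarray
    q_shank: np.ndarray


@dataclasses.dataclass
class Trial:
    trial_id: str
    cycle: GaitCycleSequence


@dataclasses.dataclass
class Session:
    session_id: str
    trials: list[Trial]


@dataclasses.dataclass
class SessionDataset:
    """sessions x trials of gait cycles plus generation provenance."""

    sessions: list[Session]
    config: GeneratorConfig | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        ids = [(s.session_id, t.trial_id) for s in self.sessions for t in s.trials]
        if len(set(ids)) != len(ids):
            raise ValueError("session/trial identifiers must be unique")

    def iter_trials(self) -> Iterator[tuple[str, str, GaitCycleSequence]]:
        for s in self.sessions:
            for t in s.trials:
                yield s.session_id, t.trial_id, t.cycle

    def all_cycles(self) -> list[GaitCycleSequence]:
        return [t.cycle for s in self.sessions for t in s.trials]

    @property
    def n_trials(self) -> int:
        return sum(len(s.trials) for s in self.sessions)


def _raised_cosine(t: np.ndarray, center: float, half_width: float,
                   amplitude: float) -> np.ndarray:
    x = np.abs(t - center)
    out = np.zeros_like(t)
    m = x < half_width
    out[m] = 0.5 * amplitude * (1.0 + np.cos(np.pi * x[m] / half_width))
    return out


def template_knee_cycle(cfg: GeneratorConfig = GeneratorConfig()) -> GaitCycleSequence:
    """Deterministic noise-free template cycle.

    Flexion is the sum of a stance raised cosine (peak at a quarter of
    stance) and a swing raised cosine (peak ``peak_swing_flexion_deg`` at
    ``swing_peak_pct``, returning to zero at 100%), so the cycle is
    periodic in flexion.  Adduction and rotation are the constant offsets.
    """
    t = np.arange(101.0)
    stance_pct = 100.0 * cfg.stance_fraction
    flexion = (
        _raised_cosine(t, stance_pct / 4.0, stance_pct / 4.0,
                       cfg.peak_stance_flexion_deg)
        + _raised_cosine(t, cfg.swing_peak_pct, 100.0 - cfg.swing_peak_pct,
                         cfg.peak_swing_flexion_deg)
    )
    R = np.stack([
        compose_cardan_zxy(f, cfg.varus_offset_deg, cfg.rotation_offset_deg)
        for f in flexion
    ])
    return GaitCycleSequence(R, stance_fraction=cfg.stance_fraction)


def draw_session_perturbation(cfg: GeneratorConfig,
                              rng: np.random.Generator) -> SessionPerturbation:
    """One fixed axis misorientation per session.

    The thigh frame is tilted so the flexion axis (thigh Z) moves by
    components drawn N(0, tan(cone_e1_session)); the shank frame likewise
    for its longitudinal axis (shank Y) with cone_e3_session.
    """
    s1 = np.tan(np.radians(cfg.cone_e1_session_deg))
    s3 = np.tan(np.radians(cfg.cone_e3_session_deg))
    d1 = rng.normal(0.0, s1, size=2) if s1 > 0 else np.zeros(2)
    d3 = rng.normal(0.0, s3, size=2) if s3 > 0 else np.zeros(2)
    q_thigh = rotation_from_rotvec(np.array([d1[0], d1[1], 0.0]))
    q_shank = rotation_from_rotvec(np.array([d3[0], 0.0, d3[1]]))
    return SessionPerturbation(q_thigh=q_thigh, q_shank=q_shank)


def generate_trial(
    template: GaitCycleSequence,
    cfg: GeneratorConfig,
    session_perturbation: SessionPerturbation | None = None,
    rng: np.random.Generator | int = 0,
) -> GaitCycleSequence:
    """One noisy trial from the template.

    With all dispersions zero (and no session perturbation) the template is
    returned unchanged, bit for bit.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    R = template.rotations
    if cfg.has_intrinsic_noise:
        theta, k, _ = template.attitudes()
        if cfg.sd_theta_deg > 0:
            # constant + first harmonic with exactly sd_theta framewise SD
            z = rng.standard_normal(3)
            ph = 2.0 * np.pi * template.frame_pct / 100.0
            theta = theta + cfg.sd_theta_deg / np.sqrt(2.0) * (
                z[0] + z[1] * np.cos(ph) + z[2] * np.sin(ph))
        if cfg.cone_k_deg > 0:
            d = rng.normal(0.0, np.tan(np.radians(cfg.cone_k_deg)), size=2)
            qk = rotation_from_rotvec(np.array([d[0], d[1], 0.0]))
            k = k @ qk.T
        R = np.stack([rotation_from_attitude(theta[i], k[i])
                      for i in range(template.n_frames)])
    if session_perturbation is not None:
        R = np.einsum("ji,fjk,kl->fil",
                      session_perturbation.q_thigh, R,
                      session_perturbation.q_shank)
    if R is template.rotations:
        return template.copy()
    return GaitCycleSequence(R, stance_fraction=template.stance_fraction)


def generate_dataset(cfg: GeneratorConfig) -> SessionDataset:
    """Full sessions x trials dataset, reproducible from ``cfg.seed``."""
    template = template_knee_cycle(cfg)
    root = np.random.SeedSequence(cfg.seed)
    sessions = []
    for si, sess_seed in enumerate(root.spawn(cfg.n_sessions), start=1):
        children = sess_seed.spawn(cfg.n_trials + 1)
        pert = None
        if cfg.has_extrinsic_noise:
            pert = draw_session_perturbation(
                cfg, np.random.default_rng(children[0]))
        trials = []
        for ti in range(1, cfg.n_trials + 1):
            cycle = generate_trial(template, cfg, pert,
                                   np.random.default_rng(children[ti]))
            trials.append(Trial(trial_id=f"T{ti:02d}", cycle=cycle))
        sessions.append(Session(session_id=f"S{si}", trials=trials))
    return SessionDataset(sessions=sessions, config=cfg, seed=cfg.seed)
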