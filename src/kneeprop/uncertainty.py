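"""First-order propagation of input uncertainty to the three joint angles.

The projected joint angles are ratios ``theta_i = f_i / g`` with

    f_1 = (e2 x e3 . k) * theta,   f_2 = (e3 x e1 . k) * theta,
    f_3 = (e1 x e2 . k) * theta,   g   = e1 x e2 . e3,

where ``e2 = (e3 x e1)/||e3 x e1||``.  Because the axes are unit vectors,
the pose reduces to seven independent parameters

    x = (theta, kx, ky, e1x, e1y, e3x, e3z)

with the main-direction components recovered as ``kz = sqrt(1-kx^2-ky^2)``,
``e1z = sqrt(1-e1x^2-e1y^2)`` and ``e3y = sqrt(1-e3x^2-e3z^2)`` (knee
convention: the rotation and flexion axes point along +Z of the thigh and
the shank long axis along +Y).

For uncorrelated inputs the squared standard uncertainty of each output is
the quotient rule

    u^2(y) = 1/g^4 * sum_i (g df/dx_i - f dg/dx_i)^2 u^2(x_i)

Axis-direction input uncertainty is parameterized as a cone of half-angle
``alpha`` about the nominal direction; each of the two free components of
that axis then carries a standard uncertainty ``tan(alpha)``, independently
and identically, with no covariance between components.

The closed-form partial derivatives are generated symbolically (sympy) once
per process and cached; the test suite validates every partial against
central finite differences of the plain numeric forward model
(:func:`evaluate_projection_terms`).
"""
from __future__ import annotations

import dataclasses
from functools import lru_cache
from typing import Mapping

import numpy as np

from .kinematics import (
    AXIS_DEGENERACY_TOL,
    AttitudeState,
    DegenerateConfigurationError,
    GaitCycleSequence,
    JointAxesFrame,
)

__all__ = [
    "THETA_IDENTIFIABILITY_DEG",
    "PARAMETER_NAMES",
    "SOURCE_GROUPS",
    "MainDirectionSignError",
    "ParameterVector",
    "UncertaintyInputs",
    "SensitivityTerms",
    "PropagationResult",
    "PropagatedUncertainty",
    "independent_parameters",
    "reconstruct_from_parameters",
    "cone_to_component_uncertainty",
    "evaluate_projection_terms",
    "sensitivity_terms",
    "propagate",
    "propagate_sequence",
]

#: below this rotation angle the rotation axis is unidentifiable and the
#: axis-cone contributions are reported as zero (with a degeneracy flag)
THETA_IDENTIFIABILITY_DEG = 1.0

#: order of the seven independent parameters (theta in radians internally)
PARAMETER_NAMES = ("theta", "kx", "ky", "e1x", "e1y", "e3x", "e3z")

#: grouping of the seven parameters into the four uncertainty sources
SOURCE_GROUPS: Mapping[str, tuple[int, ...]] = {
    "theta": (0,),
    "k": (1, 2),
    "e1": (3, 4),
    "e3": (5, 6),
}


class MainDirectionSignError(ValueError):
    """Pose incompatible with the knee sign convention (kz, e1z or e3y <= 0)."""


@dataclasses.dataclass(frozen=True)
class ParameterVector:
    """The seven independent pose parameters (theta in degrees)."""

    theta_deg: float
    kx: float
    ky: float
    e1x: float
    e1y: float
    e3x: float
    e3z: float

    def __post_init__(self) -> None:
        if self.kx**2 + self.ky**2 > 1.0:
            raise ValueError("kx^2 + ky^2 must not exceed 1")
        if self.e1x**2 + self.e1y**2 > 1.0:
            raise ValueError("e1x^2 + e1y^2 must not exceed 1")
        if self.e3x**2 + self.e3z**2 > 1.0:
            raise ValueError("e3x^2 + e3z^2 must not exceed 1")

    def as_array(self) -> np.ndarray:
        """[theta_rad, kx, ky, e1x, e1y, e3x, e3z]"""
        return np.array([
            np.radians(self.theta_deg), self.kx, self.ky,
            self.e1x, self.e1y, self.e3x, self.e3z,
        ])


@dataclasses.dataclass(frozen=True)
class UncertaintyInputs:
    """Standard uncertainty of theta and cone half-angles, all in degrees."""

    u_theta_deg: float = 0.0
    alpha_k_deg: float = 0.0
    alpha_e1_deg: float = 0.0
    alpha_e3_deg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("u_theta_deg", "alpha_k_deg", "alpha_e1_deg", "alpha_e3_deg"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("alpha_k_deg", "alpha_e1_deg", "alpha_e3_deg"):
            if getattr(self, name) >= 90.0:
                raise ValueError(f"{name} must be below 90 degrees")

    def component_sd_vector(self) -> np.ndarray:
        """Per-parameter standard uncertainties in internal units.

        [u(theta) rad, tan(a_k), tan(a_k), tan(a_e1), tan(a_e1),
         tan(a_e3), tan(a_e3)]
        """
        tk = cone_to_component_uncertainty(self.alpha_k_deg)
        t1 = cone_to_component_uncertainty(self.alpha_e1_deg)
        t3 = cone_to_component_uncertainty(self.alpha_e3_deg)
        return np.array([np.radians(self.u_theta_deg), tk, tk, t1, t1, t3, t3])

    @classmethod
    def uniform(cls, level_deg: float) -> "UncertaintyInputs":
        """All four inputs set to the same level (degrees)."""
        return cls(level_deg, level_deg, level_deg, level_deg)


@dataclasses.dataclass(frozen=True)
class SensitivityTerms:
    """Numerators, denominator and their partials at the linearization point.

    ``f`` has shape (3,), ``df`` shape (3, 7), ``dg`` shape (7,); angles in
    radians, axis components dimensionless.  ``g`` is shared by the three
    outputs.
    """

    f: np.ndarray
    g: float
    df: np.ndarray
    dg: np.ndarray


@dataclasses.dataclass(frozen=True)
class PropagationResult:
    """Combined and per-source standard uncertainties for one pose (degrees)."""

    combined: np.ndarray                     # (3,)
    by_source: Mapping[str, np.ndarray]      # each (3,)
    degenerate: bool = False


@dataclasses.dataclass
class PropagatedUncertainty:
    """Framewise combined and per-source uncertainty curves (degrees)."""

    frame_pct: np.ndarray                    # (n,)
    combined: np.ndarray                     # (n, 3)
    by_source: Mapping[str, np.ndarray]      # each (n, 3)
    degenerate: np.ndarray                   # (n,) bool


def independent_parameters(att: AttitudeState, axes: JointAxesFrame) -> ParameterVector:
    """Reduce an (attitude, joint axes) pose to the seven free parameters.

    Requires the knee sign convention kz > 0, e1z > 0, e3y > 0 so that the
    unit-norm reductions are invertible.
    """
    k, e1, e3 = att.axis, axes.e1, axes.e3
    if k[2] <= 0:
        raise MainDirectionSignError("kz <= 0: pose violates the knee convention")
    if e1[2] <= 0:
        raise MainDirectionSignError("e1z <= 0: pose violates the knee convention")
    if e3[1] <= 0:
        raise MainDirectionSignError("e3y <= 0: pose violates the knee convention")
    return ParameterVector(att.theta_deg, k[0], k[1], e1[0], e1[1], e3[0], e3[2])


def reconstruct_from_parameters(
    p: ParameterVector,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Rebuild (k, e1, e3, e2) from the free parameters via the unit-norm
    reductions and the floating-axis construction."""
    k = np.array([p.kx, p.ky, np.sqrt(1.0 - p.kx**2 - p.ky**2)])
    e1 = np.array([p.e1x, p.e1y, np.sqrt(1.0 - p.e1x**2 - p.e1y**2)])
    e3 = np.array([p.e3x, np.sqrt(1.0 - p.e3x**2 - p.e3z**2), p.e3z])
    c = np.cross(e3, e1)
    n = np.linalg.norm(c)
    if n <= AXIS_DEGENERACY_TOL:
        raise DegenerateConfigurationError("e3 parallel to e1 after reconstruction")
    return k, e1, e3, c / n


def cone_to_component_uncertainty(alpha_deg: float) -> float:
    """Standard uncertainty tan(alpha) of each free axis component for a
    cone of half-angle alpha (degrees) about the main direction."""
    if not 0.0 <= alpha_deg < 90.0:
        raise ValueError("cone half-angle must be in [0, 90) degrees")
    return float(np.tan(np.radians(alpha_deg)))


def evaluate_projection_terms(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact numerators f = (f1, f2, f3) and denominator g at parameters x.

    ``x[..., 0:7] = (theta_rad, kx, ky, e1x, e1y, e3x, e3z)``; broadcasts
    over leading axes.  This is the plain numeric forward model used by the
    Monte-Carlo oracle and by the finite-difference validation of the
    symbolic partials.
    """
    x = np.asarray(x, dtype=float)
    th = x[..., 0]
    kx, ky = x[..., 1], x[..., 2]
    e1x, e1y = x[..., 3], x[..., 4]
    e3x, e3z = x[..., 5], x[..., 6]
    k = np.stack([kx, ky, np.sqrt(1.0 - kx**2 - ky**2)], axis=-1)
    e1 = np.stack([e1x, e1y, np.sqrt(1.0 - e1x**2 - e1y**2)], axis=-1)
    e3 = np.stack([e3x, np.sqrt(1.0 - e3x**2 - e3z**2), e3z], axis=-1)
    c31 = np.cross(e3, e1)
    e2 = c31 / np.linalg.norm(c31, axis=-1, keepdims=True)
    g = np.einsum("...i,...i->...", np.cross(e1, e2), e3)
    f1 = np.einsum("...i,...i->...", np.cross(e2, e3), k) * th
    f2 = np.einsum("...i,...i->...", np.cross(e3, e1), k) * th
    f3 = np.einsum("...i,...i->...", np.cross(e1, e2), k) * th
    return np.stack([f1, f2, f3], axis=-1), g


@lru_cache(maxsize=1)
def _symbolic_sensitivities():
    """Build and lambdify f1..f3, g and all their partials (done once)."""
    import sympy as sp

    th, kx, ky, e1x, e1y, e3x, e3z = sp.symbols(
        "th kx ky e1x e1y e3x e3z", real=True)
    k = sp.Matrix([kx, ky, sp.sqrt(1 - kx**2 - ky**2)])
    e1 = sp.Matrix([e1x, e1y, sp.sqrt(1 - e1x**2 - e1y**2)])
    e3 = sp.Matrix([e3x, sp.sqrt(1 - e3x**2 - e3z**2), e3z])
    c31 = e3.cross(e1)
    e2 = c31 / sp.sqrt(c31.dot(c31))
    g = e1.cross(e2).dot(e3)
    fs = [e2.cross(e3).dot(k) * th, e3.cross(e1).dot(k) * th,
          e1.cross(e2).dot(k) * th]
    params = (th, kx, ky, e1x, e1y, e3x, e3z)
    exprs = list(fs) + [g]
    for f in fs:
        exprs.extend(sp.diff(f, x) for x in params)
    exprs.extend(sp.diff(g, x) for x in params)
    return sp.lambdify(params, exprs, modules="numpy")


def sensitivity_terms(p: ParameterVector) -> SensitivityTerms:
    """Evaluate f, g and the 28 closed-form partials at the pose ``p``."""
    reconstruct_from_parameters(p)  # raises on degenerate / invalid poses
    x = p.as_array()
    vals = np.asarray(_symbolic_sensitivities()(*x), dtype=float)
    f = vals[0:3]
    g = float(vals[3])
    df = vals[4:25].reshape(3, 7)
    dg = vals[25:32]
    return SensitivityTerms(f=f, g=g, df=df, dg=dg)


def propagate(p: ParameterVector, u: UncertaintyInputs) -> PropagationResult:
    """Combined and per-source output uncertainties at one pose (degrees).

    Implements the quotient-rule variance combination over the seven
    uncorrelated parameters; the combined value is the root of the sum of
    the squared per-source contributions, so variance additivity holds by
    construction.
    """
    st = sensitivity_terms(p)
    coef = (st.g * st.df - np.outer(st.f, st.dg)) / st.g**2       # (3, 7)
    contrib2 = (coef * u.component_sd_vector()) ** 2              # rad^2
    degenerate = abs(p.theta_deg) < THETA_IDENTIFIABILITY_DEG
    by_source = {}
    for name, idx in SOURCE_GROUPS.items():
        v = np.sqrt(contrib2[:, list(idx)].sum(axis=1))
        if degenerate and name != "theta":
            v = np.zeros(3)
        by_source[name] = np.degrees(v)
    combined = np.sqrt(sum(v**2 for v in by_source.values()))
    return PropagationResult(combined=combined, by_source=by_source,
                             degenerate=degenerate)


def _pose_parameters_from_cycle(cycle) -> tuple[np.ndarray, list, np.ndarray]:
    """Per-frame ParameterVectors from a GaitCycleSequence or a mean-cycle
    record (any object with theta_deg, k, e1, e3, frame_pct attributes)."""
    from .kinematics import joint_axes_from_rotation

    if isinstance(cycle, GaitCycleSequence):
        theta, k, degen = cycle.attitudes()
        e1 = np.tile([0.0, 0.0, 1.0], (cycle.n_frames, 1))
        e3 = np.array([joint_axes_from_rotation(R).e3 for R in cycle.rotations])
        pct = cycle.frame_pct
    else:
        theta, k, e1, e3 = cycle.theta_deg, cycle.k, cycle.e1, cycle.e3
        pct = cycle.frame_pct
    poses = []
    for i in range(len(theta)):
        poses.append(ParameterVector(
            float(theta[i]), float(k[i, 0]), float(k[i, 1]),
            float(e1[i, 0]), float(e1[i, 1]), float(e3[i, 0]), float(e3[i, 2])))
    return np.asarray(pct, dtype=float), poses, np.asarray(theta, dtype=float)


def propagate_sequence(cycle, u: UncertaintyInputs) -> PropagatedUncertainty:
    """Framewise propagation along a (mean) gait cycle.

    ``cycle`` may be a :class:`GaitCycleSequence` or the mean-cycle record
    produced by :func:`kneeprop.variability.mean_cycle`.  Frames with a
    rotation angle below 1 degree are flagged degenerate and carry zero
    axis-cone contributions.
    """
    pct, poses, _ = _pose_parameters_from_cycle(cycle)
    n = len(poses)
    combined = np.empty((n, 3))
    by_source = {name: np.empty((n, 3)) for name in SOURCE_GROUPS}
    degenerate = np.empty(n, dtype=bool)
    for i, p in enumerate(poses):
        res = propagate(p, u)
        combined[i] = res.combined
        degenerate[i] = res.degenerate
        for name in SOURCE_GROUPS:
            by_source[name][i] = res.by_source[name]
    if degenerate.all():
        raise DegenerateConfigurationError("every frame of the cycle is degenerate")
    return PropagatedUncertainty(frame_pct=pct, combined=combined,
                                 by_source=by_source, degenerate=degenerate)
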