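"""Rotation-matrix algebra for knee joint kinematics.

The knee is described by the rotation matrix ``R`` of the shank relative to
the thigh (columns of ``R`` are the shank X, Y, Z axes expressed in the thigh
frame).  Three equivalent descriptions of the same finite rotation are
handled here:

* Cardan angles for a ZXY sequence, ``R = Rz(th1) @ Rx(th2) @ Ry(th3)``,
  with th1 flexion-extension, th2 adduction-abduction and th3
  internal-external rotation;
* the attitude (helical/screw) representation, rotation angle ``theta`` and
  unit rotation axis ``k``, related to ``R`` through the Rodrigues formula
  ``R = cos(theta) I + sin(theta) [k]_x + (1 - cos(theta)) k k^T``;
* the non-orthogonal projection of the attitude vector ``theta * k`` on the
  joint coordinate system (JCS) axes ``e1`` (thigh Z, flexion axis), ``e3``
  (shank Y, longitudinal axis, i.e. the second column of ``R``) and the
  floating axis ``e2 = (e3 x e1) / ||e3 x e1||``:

      theta_1 = (e2 x e3 . k) / (e1 x e2 . e3) * theta
      theta_2 = (e3 x e1 . k) / (e1 x e2 . e3) * theta
      theta_3 = (e1 x e2 . k) / (e1 x e2 . e3) * theta

All public interfaces use degrees; radians are used internally.
"""
from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "ORTHONORMALITY_TOL",
    "AXIS_DEGENERACY_TOL",
    "MIXED_PRODUCT_TOL",
    "FALLBACK_AXIS",
    "InvalidRotationError",
    "GimbalLockError",
    "DegenerateConfigurationError",
    "CardanAngles",
    "ProjectedAngles",
    "AttitudeState",
    "JointAxesFrame",
    "GaitCycleSequence",
    "validate_rotation",
    "compose_cardan_zxy",
    "extract_cardan_zxy",
    "attitude_from_rotation",
    "rotation_from_attitude",
    "rotation_from_rotvec",
    "joint_axes_from_rotation",
    "project_attitude",
    "relative_rotation",
    "enforce_axis_continuity",
]

#: elementwise tolerance for R R^T = I and det(R) = 1
ORTHONORMALITY_TOL = 1e-9
#: ||e3 x e1|| below this means the shank long axis aligns with the flexion axis
AXIS_DEGENERACY_TOL = 1e-6
#: |e1 x e2 . e3| below this means a singular (non-invertible) JCS basis
MIXED_PRODUCT_TOL = 1e-9

# near theta = 0 the rotation axis is unidentifiable; this is the documented
# fallback (the knee's nominal flexion axis, thigh Z)
FALLBACK_AXIS = np.array([0.0, 0.0, 1.0])

_THETA_ZERO_RAD = 1e-6      # below this the axis is reported as degenerate
_THETA_PI_BRANCH = np.pi - 1e-4


class InvalidRotationError(ValueError):
    """Input matrix is not a proper rotation within tolerance."""


class GimbalLockError(ValueError):
    """ZXY extraction is singular (second angle at +/-90 deg)."""


class DegenerateConfigurationError(ValueError):
    """Joint axes are (numerically) parallel or the JCS basis is singular."""


class CardanAngles(NamedTuple):
    """ZXY Cardan angles in degrees: flexion, adduction, rotation."""

    theta1: float
    theta2: float
    theta3: float


class ProjectedAngles(NamedTuple):
    """Non-orthogonal projections of the attitude vector on e1, e2, e3 (deg)."""

    theta1: float
    theta2: float
    theta3: float


@dataclasses.dataclass(frozen=True)
class AttitudeState:
    """Rotation angle (degrees) and unit rotation axis in the thigh frame."""

    theta_deg: float
    axis: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        object.__setattr__(self, "axis", axis)
        if axis.shape != (3,):
            raise ValueError("axis must be a 3-vector")
        if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
            raise ValueError("rotation axis must be unit length")

    @property
    def theta_rad(self) -> float:
        return float(np.radians(self.theta_deg))

    @property
    def attitude_vector_deg(self) -> np.ndarray:
        """theta * k in degrees."""
        return self.theta_deg * self.axis


@dataclasses.dataclass(frozen=True)
class JointAxesFrame:
    """Non-orthogonal joint axes e1, e2, e3 expressed in the thigh frame."""

    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray

    def __post_init__(self) -> None:
        for name in ("e1", "e2", "e3"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be unit length")

    @property
    def mixed_product(self) -> float:
        """e1 x e2 . e3, the common denominator of the projections."""
        return float(np.cross(self.e1, self.e2) @ self.e3)


def validate_rotation(R: np.ndarray, tol: float = ORTHONORMALITY_TOL) -> np.ndarray:
    """Return ``R`` as a float array after checking it is a proper rotation."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise InvalidRotationError(f"expected a 3x3 matrix, got shape {R.shape}")
    if not np.all(np.isfinite(R)):
        raise InvalidRotationError("rotation matrix contains non-finite entries")
    if np.abs(R @ R.T - np.eye(3)).max() > tol:
        raise InvalidRotationError("matrix is not orthonormal within tolerance")
    if abs(np.linalg.det(R) - 1.0) > tol:
        raise InvalidRotationError("matrix determinant is not +1 within tolerance")
    return R


def compose_cardan_zxy(theta1_deg: float, theta2_deg: float = None,
                       theta3_deg: float = None) -> np.ndarray:
    """Rotation matrix of a ZXY Cardan sequence, angles in degrees.

    Accepts either three scalars or a single :class:`CardanAngles`.
    """
    if theta2_deg is None and theta3_deg is None:
        theta1_deg, theta2_deg, theta3_deg = theta1_deg
    a, b, c = np.radians([theta1_deg, theta2_deg, theta3_deg])
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cb, -sb], [0.0, sb, cb]])
    ry = np.array([[cc, 0.0, sc], [0.0, 1.0, 0.0], [-sc, 0.0, cc]])
    return rz @ rx @ ry


def extract_cardan_zxy(R: np.ndarray) -> CardanAngles:
    """ZXY Cardan angles (degrees) from a rotation matrix.

    theta2 = asin(R[2,1]); theta1 = atan2(-R[0,1], R[1,1]);
    theta3 = atan2(-R[2,0], R[2,2]).  Raises :class:`GimbalLockError` when
    |R[2,1]| >= 1 - 1e-9 (second angle at +/-90 deg).
    """
    R = validate_rotation(R)
    s2 = R[2, 1]
    if abs(s2) >= 1.0 - 1e-9:
        raise GimbalLockError("ZXY sequence is singular: |sin(theta2)| ~ 1")
    theta2 = np.arcsin(s2)
    theta1 = np.arctan2(-R[0, 1], R[1, 1])
    theta3 = np.arctan2(-R[2, 0], R[2, 2])
    return CardanAngles(*np.degrees([theta1, theta2, theta3]))


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([
        [0.0, -v[2], v[1]],
        [v[2], 0.0, -v[0]],
        [-v[1], v[0], 0.0],
    ])


def attitude_from_rotation(R: np.ndarray) -> AttitudeState:
    """Rotation angle and unit axis of ``R`` (Rodrigues inverse).

    theta = acos((trace(R) - 1) / 2) in [0, 180] deg.  The axis comes from
    the skew-symmetric part ``(R - R^T) / (2 sin(theta))``; near theta = 180
    deg, where the skew part vanishes and ``R ~ 2 k k^T - I``, the axis is
    recovered as the invariant direction of ``R`` instead.  Near
    theta = 0 the axis is unidentifiable and the fallback axis [0, 0, 1] is
    returned with ``degenerate=True``.
    """
    R = validate_rotation(R)
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = float(np.arccos(cos_theta))
    if theta < _THETA_ZERO_RAD:
        return AttitudeState(np.degrees(theta), FALLBACK_AXIS.copy(), degenerate=True)
    if theta > _THETA_PI_BRANCH:
        # near a half turn R ~ 2 k k^T - I and the skew part is tiny:
        # recover the axis as the rotation-invariant direction (null
        # vector of R - I), resolving the sign from the skew part when it
        # is informative, otherwise by convention
        _, _, Vt = np.linalg.svd(R - np.eye(3))
        k = Vt[2]
        w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        if np.linalg.norm(w) > 1e-12:
            if w @ k < 0:
                k = -k
        elif k[int(np.argmax(np.abs(k)))] < 0:
            k = -k
    else:
        w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        k = w / (2.0 * np.sin(theta))
    k = k / np.linalg.norm(k)
    return AttitudeState(np.degrees(theta), k)


def rotation_from_attitude(theta_deg: float, axis: np.ndarray = None) -> np.ndarray:
    """Rodrigues formula: cos(t) I + sin(t) [k]_x + (1 - cos(t)) k k^T.

    Accepts ``(theta_deg, axis)`` or a single :class:`AttitudeState`.
    A signed angle is accepted (a negative angle about ``k`` equals the
    positive angle about ``-k``).
    """
    if axis is None:
        att = theta_deg
        theta_deg, axis = att.theta_deg, att.axis
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
        raise ValueError("rotation axis must be unit length")
    t = np.radians(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return c * np.eye(3) + s * _skew(axis) + (1.0 - c) * np.outer(axis, axis)


def rotation_from_rotvec(v: np.ndarray) -> np.ndarray:
    """Rotation matrix from a rotation vector (radians)."""
    v = np.asarray(v, dtype=float)
    angle = np.linalg.norm(v)
    if angle < 1e-15:
        return np.eye(3)
    return rotation_from_attitude(np.degrees(angle), v / angle)


def joint_axes_from_rotation(R: np.ndarray) -> JointAxesFrame:
    """JCS axes from ``R``: e1 = thigh Z, e3 = shank Y (second column of R),
    e2 = (e3 x e1) / ||e3 x e1||."""
    R = validate_rotation(R)
    e1 = np.array([0.0, 0.0, 1.0])
    e3 = R[:, 1].copy()
    c = np.cross(e3, e1)
    n = np.linalg.norm(c)
    if n <= AXIS_DEGENERACY_TOL:
        raise DegenerateConfigurationError(
            "shank long axis is parallel to the flexion axis (||e3 x e1|| ~ 0)")
    return JointAxesFrame(e1, c / n, e3)


def project_attitude(att: AttitudeState, axes: JointAxesFrame) -> ProjectedAngles:
    """Non-orthogonal projection of the attitude vector on the JCS axes.

    Satisfies the decomposition identity
    ``theta1 e1 + theta2 e2 + theta3 e3 = theta k``.
    """
    g = axes.mixed_product
    if abs(g) < MIXED_PRODUCT_TOL:
        raise DegenerateConfigurationError("singular JCS basis: e1 x e2 . e3 ~ 0")
    k = att.axis
    t1 = float(np.cross(axes.e2, axes.e3) @ k) / g * att.theta_deg
    t2 = float(np.cross(axes.e3, axes.e1) @ k) / g * att.theta_deg
    t3 = float(np.cross(axes.e1, axes.e2) @ k) / g * att.theta_deg
    return ProjectedAngles(t1, t2, t3)


def relative_rotation(thigh_in_world: np.ndarray, shank_in_world: np.ndarray) -> np.ndarray:
    """Shank-relative-to-thigh rotation from world orientations.

    Both inputs have segment axes as columns in the world frame; the result
    ``T^T S`` has the shank axes as columns in the thigh frame (the table of
    dot products X_Shank.X_Thigh, ...).
    """
    T = validate_rotation(thigh_in_world)
    S = validate_rotation(shank_in_world)
    return T.T @ S


def enforce_axis_continuity(
    theta_deg: np.ndarray, axes: np.ndarray, degenerate: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the (theta, k) vs (-theta, -k) sign ambiguity along a cycle.

    Non-degenerate frames are sign-flipped so consecutive axes satisfy
    ``k(t) . k(t+1) > 0``; the attitude vector theta*k per frame is
    unchanged.  Degenerate frames (theta ~ 0, axis unidentifiable) receive
    the normalized average of the nearest non-degenerate neighbour axes.
    """
    theta = np.array(theta_deg, dtype=float)
    k = np.array(axes, dtype=float)
    degenerate = np.asarray(degenerate, dtype=bool)
    valid = np.where(~degenerate)[0]
    for a, b in zip(valid[:-1], valid[1:]):
        if k[b] @ k[a] < 0:
            k[b] = -k[b]
            theta[b] = -theta[b]
    for i in np.where(degenerate)[0]:
        before = valid[valid < i]
        after = valid[valid > i]
        if before.size and after.size:
            v = k[before[-1]] + k[after[0]]
        elif before.size:
            v = k[before[-1]].copy()
        elif after.size:
            v = k[after[0]].copy()
        else:
            v = FALLBACK_AXIS.copy()
        n = np.linalg.norm(v)
        k[i] = v / n if n > 1e-12 else FALLBACK_AXIS.copy()
    return theta, k


@dataclasses.dataclass
class GaitCycleSequence:
    """One time-normalized gait cycle of relative rotations (101 frames).

    ``rotations`` is a (101, 3, 3) stack of shank-relative-to-thigh rotation
    matrices at 0, 1, ..., 100 % of the gait cycle.
    """

    rotations: np.ndarray
    stance_fraction: float = 0.616
    frame_pct: np.ndarray = None

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, dtype=float)
        if self.frame_pct is None:
            self.frame_pct = np.arange(101.0)
        self.frame_pct = np.asarray(self.frame_pct, dtype=float)
        if self.rotations.shape != (101, 3, 3):
            raise ValueError("a gait cycle requires exactly 101 rotation matrices")
        if self.frame_pct.shape != (101,):
            raise ValueError("frame_pct must have 101 entries")
        if not np.all(np.diff(self.frame_pct) > 0):
            raise ValueError("frame percentages must be strictly increasing")
        if not (self.frame_pct[0] == 0.0 and self.frame_pct[-1] == 100.0):
            raise ValueError("frame percentages must span 0..100")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must be in (0, 1)")
        self._attitude_cache = None

    @property
    def n_frames(self) -> int:
        return self.rotations.shape[0]

    def copy(self) -> "GaitCycleSequence":
        return GaitCycleSequence(self.rotations.copy(), self.stance_fraction,
                                 self.frame_pct.copy())

    def attitudes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-frame (theta_deg, axis, degenerate) with continuity enforced.

        After continuity the whole cycle is oriented to the knee
        convention (axis along +Z of the thigh on average), so the signed
        rotation angle is comparable across trials even when it crosses
        zero within the cycle.
        """
        if self._attitude_cache is None:
            theta = np.empty(self.n_frames)
            k = np.empty((self.n_frames, 3))
            degen = np.empty(self.n_frames, dtype=bool)
            for i, R in enumerate(self.rotations):
                att = attitude_from_rotation(R)
                theta[i], k[i], degen[i] = att.theta_deg, att.axis, att.degenerate
            theta, k = enforce_axis_continuity(theta, k, degen)
            valid = ~degen
            if valid.any() and k[valid, 2].sum() < 0:
                theta, k = -theta, -k
            self._attitude_cache = (theta, k, degen)
        theta, k, degen = self._attitude_cache
        return theta.copy(), k.copy(), degen.copy()

    def cardan_angles(self) -> np.ndarray:
        """Per-frame ZXY Cardan angles, shape (101, 3), degrees."""
        return np.array([extract_cardan_zxy(R) for R in self.rotations])

    def joint_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-frame JCS axes (e1, e2, e3), each shape (101, 3)."""
        e1 = np.empty((self.n_frames, 3))
        e2 = np.empty((self.n_frames, 3))
        e3 = np.empty((self.n_frames, 3))
        for i, R in enumerate(self.rotations):
            ax = joint_axes_from_rotation(R)
            e1[i], e2[i], e3[i] = ax.e1, ax.e2, ax.e3
        return e1, e2, e3

    def projected_angles(self) -> np.ndarray:
        """Per-frame non-orthogonal projections, shape (101, 3), degrees."""
        theta, k, _ = self.attitudes()
        out = np.empty((self.n_frames, 3))
        for i, R in enumerate(self.rotations):
            axes = joint_axes_from_rotation(R)
            g = axes.mixed_product
            if abs(g) < MIXED_PRODUCT_TOL:
                raise DegenerateConfigurationError("singular JCS basis in sequence")
            out[i, 0] = np.cross(axes.e2, axes.e3) @ k[i] / g * theta[i]
            out[i, 1] = np.cross(axes.e3, axes.e1) @ k[i] / g * theta[i]
            out[i, 2] = np.cross(axes.e1, axes.e2) @ k[i] / g * theta[i]
        return out
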