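"""Monte-Carlo verification of the analytical uncertainty propagation.

Draws perturbed parameter sets around a nominal pose (Gaussian on theta and
on the free axis components, standard deviations matching the analytic
input model), pushes every draw through the exact projection equations, and
reports empirical output standard deviations next to the analytic ones.
Gaussian perturbations are used because the first-order variance rule is
agnostic to the distribution shape and Gaussians make the standard
deviation semantics exact.

Draws that leave the parameter domain (a squared-component sum above 1) or
produce a degenerate joint axis configuration are rejected and resampled;
a rejection rate above 50% raises, which surfaces misuse at very large cone
angles.  All randomness is seed-parameterized; no global state.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .kinematics import AXIS_DEGENERACY_TOL, MIXED_PRODUCT_TOL
from .uncertainty import (
    ParameterVector,
    PropagationResult,
    UncertaintyInputs,
    evaluate_projection_terms,
    propagate,
)

__all__ = [
    "RejectionRateError",
    "MonteCarloReport",
    "near_domain_boundary",
    "sample_perturbed_parameters",
    "empirical_output_uncertainty",
]


class RejectionRateError(RuntimeError):
    """More than half of the Monte-Carlo draws fell outside the domain."""


@dataclasses.dataclass(frozen=True)
class MonteCarloReport:
    """Empirical vs analytic output uncertainties for one pose (degrees).

    ``rel_diff`` is (empirical - analytic) / analytic per output; NaN where
    the analytic value is zero.
    """

    n_samples: int
    seed: int
    empirical_sd_deg: np.ndarray   # (3,)
    analytic: PropagationResult
    rel_diff: np.ndarray           # (3,)

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")


def near_domain_boundary(p: ParameterVector, u: UncertaintyInputs,
                         n_sigma: float = 4.0) -> bool:
    """True when input perturbations reach the parameter domain boundary.

    The unit-norm reductions require each main-direction component
    (kz, e1z, e3y) to stay positive; when a nominal component is within
    ``n_sigma`` input standard deviations of zero, both the linearization
    and the Gaussian sampling model break down at that pose.
    """
    sd = u.component_sd_vector()
    mains = (
        (np.sqrt(max(0.0, 1.0 - p.kx**2 - p.ky**2)), sd[1]),
        (np.sqrt(max(0.0, 1.0 - p.e1x**2 - p.e1y**2)), sd[3]),
        (np.sqrt(max(0.0, 1.0 - p.e3x**2 - p.e3z**2)), sd[5]),
    )
    return any(main <= n_sigma * s for main, s in mains)


def _domain_mask(x: np.ndarray) -> np.ndarray:
    """True where a draw keeps every axis parameterization real and the
    joint configuration non-degenerate."""
    kx, ky = x[:, 1], x[:, 2]
    e1x, e1y = x[:, 3], x[:, 4]
    e3x, e3z = x[:, 5], x[:, 6]
    eps = 1e-12
    ok = (kx**2 + ky**2 <= 1.0 - eps)
    ok &= (e1x**2 + e1y**2 <= 1.0 - eps)
    ok &= (e3x**2 + e3z**2 <= 1.0 - eps)
    if not ok.any():
        return ok
    # degenerate configuration check on the rows that are still in-domain
    sub = x[ok]
    e1 = np.stack([sub[:, 3], sub[:, 4],
                   np.sqrt(1.0 - sub[:, 3]**2 - sub[:, 4]**2)], axis=-1)
    e3 = np.stack([sub[:, 5], np.sqrt(1.0 - sub[:, 5]**2 - sub[:, 6]**2),
                   sub[:, 6]], axis=-1)
    c31 = np.cross(e3, e1)
    good = np.linalg.norm(c31, axis=-1) > AXIS_DEGENERACY_TOL
    ok[np.where(ok)[0][~good]] = False
    return ok


def sample_perturbed_parameters(
    p: ParameterVector, u: UncertaintyInputs, n: int, seed: int
) -> np.ndarray:
    """n draws of the seven parameters, shape (n, 7), theta in radians.

    theta ~ N(theta0, u(theta)); each free axis component ~ N(value,
    tan(alpha)) of its cone.  Out-of-domain draws are rejected and
    resampled (hard 50% guard).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    mean = p.as_array()
    sd = u.component_sd_vector()
    draws = mean + sd * rng.standard_normal((n, 7))
    ok = _domain_mask(draws)
    n_drawn, n_rejected = n, int((~ok).sum())
    while not ok.all():
        bad = np.where(~ok)[0]
        draws[bad] = mean + sd * rng.standard_normal((bad.size, 7))
        ok[bad] = _domain_mask(draws[bad])
        n_drawn += bad.size
        n_rejected += int((~ok[bad]).sum())
        if n_drawn > 2 * n and n_rejected > 0.5 * n_drawn:
            raise RejectionRateError(
                f"rejection rate {n_rejected / n_drawn:.0%} exceeds 50%; "
                "input uncertainties are too large for this pose")
    if n_rejected > 0.5 * n_drawn:
        raise RejectionRateError(
            f"rejection rate {n_rejected / n_drawn:.0%} exceeds 50%")
    return draws


def empirical_output_uncertainty(
    p: ParameterVector, u: UncertaintyInputs, n: int = 100_000, seed: int = 0
) -> MonteCarloReport:
    """Empirical output SDs from n exact forward evaluations vs analytic.

    Every draw is reconstructed through the unit-norm reductions and pushed
    through the exact (not linearized) projection equations; the sample
    standard deviation of each output is compared with the analytic
    first-order value.
    """
    draws = sample_perturbed_parameters(p, u, n, seed)
    f, g = evaluate_projection_terms(draws)
    # draws with a near-singular basis are resampled under the same guard
    bad = np.abs(g) < MIXED_PRODUCT_TOL
    tries = 0
    while bad.any():
        tries += 1
        if tries > 50:
            raise RejectionRateError("could not obtain non-singular draws")
        redraw = sample_perturbed_parameters(p, u, int(bad.sum()), seed + 1 + tries)
        draws[bad] = redraw
        f[bad], g[bad] = evaluate_projection_terms(redraw)
        bad = np.abs(g) < MIXED_PRODUCT_TOL
    outputs = np.degrees(f / g[:, None])
    empirical = outputs.std(axis=0, ddof=1)
    analytic = propagate(p, u)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(analytic.combined > 0,
                       (empirical - analytic.combined) / analytic.combined,
                       np.nan)
    return MonteCarloReport(n_samples=n, seed=seed,
                            empirical_sd_deg=empirical,
                            analytic=analytic, rel_diff=rel)
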