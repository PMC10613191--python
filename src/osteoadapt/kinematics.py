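"""Strain, 2D polar-rotation angle, misalignment and principal directions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Relative eigenvalue-gap threshold below which the principal direction of a
#: (near-)isotropic strain is flagged indeterminate.
ISOTROPY_TOL = 1e-2


@dataclass
class OrientationState:
    """Co-located orientation fields: material symmetry angle ``psi``,
    macro-rotation ``theta`` and misalignment ``gamma = theta - psi`` [rad].

    ``psi`` is the stored/evolved state variable; ``gamma`` is recomputed
    from the current equilibrium rotation each step. For all energy purposes
    ``psi`` matters modulo pi.
    """

    psi: np.ndarray
    theta: np.ndarray
    gamma: np.ndarray


def small_strain(grad_u: np.ndarray) -> np.ndarray:
    """Symmetric part of the displacement gradient, E = (grad u + grad u^T)/2."""
    grad_u = np.asarray(grad_u, dtype=float)
    return 0.5 * (grad_u + np.swapaxes(grad_u, -1, -2))


def polar_angle(F: np.ndarray) -> np.ndarray:
    """Rotation angle of the 2D polar decomposition F = R(theta) U.

    theta = atan2(F21 - F12, F11 + F22); exact for symmetric positive U.
    Raises for non-invertible (det F <= 0) deformations.
    """
    F = np.asarray(F, dtype=float)
    det = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    if np.any(det <= 0):
        raise ValueError("degenerate deformation gradient: det F <= 0")
    return np.arctan2(F[..., 1, 0] - F[..., 0, 1], F[..., 0, 0] + F[..., 1, 1])


def wrap_half(angle: np.ndarray) -> np.ndarray:
    """Wrap an angle (difference) to (-pi/2, pi/2]."""
    a = np.asarray(angle, dtype=float)
    w = (a + np.pi / 2) % np.pi - np.pi / 2
    return np.where(w == -np.pi / 2, np.pi / 2, w)


def misalignment(F: np.ndarray, psi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Misalignment gamma between macro rotation and material axes [rad].

    Two evaluations are returned, both wrapped to (-pi/2, pi/2]:

    * exact: ``gamma = polar_angle(F) - psi``;
    * approximate: ``gamma = arctan(G21 / G11)`` with ``G = R(psi)^T F``,
      valid to O(||E||) since the stretch tends to identity at small strain.
    """
    F = np.asarray(F, dtype=float)
    psi = np.asarray(psi, dtype=float)
    exact = wrap_half(polar_angle(F) - psi)
    c, s = np.cos(psi), np.sin(psi)
    g11 = c * F[..., 0, 0] + s * F[..., 1, 0]
    g21 = -s * F[..., 0, 0] + c * F[..., 1, 0]
    approx = wrap_half(np.arctan2(g21, g11))
    return exact, approx


def principal_strain_angle(
    E: np.ndarray, isotropy_tol: float = ISOTROPY_TOL
) -> tuple[np.ndarray, np.ndarray]:
    """Angle of the major principal strain direction, wrapped to [0, pi).

    Returns ``(angle, indeterminate)``; the flag marks points where the two
    eigenvalues coincide within ``isotropy_tol`` relative to the largest
    eigenvalue magnitude (there the direction is arbitrary, not an error).
    """
    E = np.asarray(E, dtype=float)
    if not np.allclose(E, np.swapaxes(E, -1, -2), atol=1e-12 * max(np.abs(E).max() if E.size else 0.0, 1.0)):
        raise ValueError("strain tensor must be symmetric")
    d = E[..., 0, 0] - E[..., 1, 1]
    o = 2.0 * E[..., 0, 1]
    angle = 0.5 * np.arctan2(o, d) % np.pi
    gap = np.sqrt(d**2 + o**2)  # |lambda1 - lambda2|
    lam_scale = 0.5 * np.abs(E[..., 0, 0] + E[..., 1, 1]) + 0.5 * gap  # max |lambda|
    indeterminate = gap <= isotropy_tol * np.maximum(lam_scale, 1e-300)
    return angle, indeterminate
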