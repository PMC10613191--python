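"""Orthotropic first- and second-gradient strain energy and its derivatives.

The first-gradient energy density is a quadratic orthotropic form in the
small-strain invariants

    w1 = 1/2 K J1^2 + mu (J2 - 1/2 J1^2) + (alpha1 J4 + alpha2 J6) J1
         + 2 mu1 J5 + 2 mu2 J7
         + 1/2 beta1 J4^2 + 1/2 beta2 J6^2 + beta3 J4 J6

with J1 = tr E, J2 = tr E^2, J4 = A1.E A1, J5 = A1.E^2 A1, J6 = A2.E A2,
J7 = A2.E^2 A2, and A1 = (cos psi, sin psi), A2 the quarter-turn of A1.

The second-gradient energy penalizes the linearized tangential stretch
gradients s_i and fiber bending measures b_i,

    w2 = 1/2 (Ks1 s1^2 + Ks2 s2^2) + 1/2 (Kb1 b1^2 + Kb2 b2^2),

where, for H = D^2 u the displacement Hessian, s_i = A_i . (H : A_i x A_i)
and b_i = N_i . (H : A_i x A_i) with N1 = A2, N2 = -A1.

All functions are vectorized over arbitrary leading array dimensions; moduli
may themselves be fields broadcastable against those dimensions, which is how
the per-point evolving stiffnesses enter the assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

_EVOLVING = ("mu", "beta1", "beta2")


@dataclass(frozen=True)
class ModuliSet:
    """The 13 material parameters of the orthotropic second-gradient energy.

    First-gradient moduli are in Pa, second-gradient stiffnesses in N (per
    unit thickness the 2D energy density is then Pa). Fields may be numpy
    arrays (per-quadrature-point evolving values).
    """

    K: ArrayLike
    mu: ArrayLike
    alpha1: ArrayLike
    alpha2: ArrayLike
    mu1: ArrayLike
    mu2: ArrayLike
    beta1: ArrayLike
    beta2: ArrayLike
    beta3: ArrayLike
    Ks1: ArrayLike = 0.0
    Ks2: ArrayLike = 0.0
    Kb1: ArrayLike = 0.0
    Kb2: ArrayLike = 0.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.K) <= 0) or np.any(np.asarray(self.mu) <= 0):
            raise ValueError("K and mu must be positive")
        for name in ("Ks1", "Ks2", "Kb1", "Kb2"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_gpa(
        cls,
        moduli_gpa: dict[str, float],
        second_gradient_n: float = 0.0,
        validate: bool = True,
    ) -> "ModuliSet":
        """Build from first-gradient moduli in GPa and a common
        second-gradient stiffness in N, checking admissibility."""
        p = cls(
            **{k: 1e9 * v for k, v in moduli_gpa.items()},
            Ks1=second_gradient_n,
            Ks2=second_gradient_n,
            Kb1=second_gradient_n,
            Kb2=second_gradient_n,
        )
        if validate:
            p.check_positive_definite()
        return p

    def with_fields(self, **updates: ArrayLike) -> "ModuliSet":
        """Copy with some moduli replaced by (array-valued) fields."""
        return replace(self, **updates)

    def as_dict(self) -> dict[str, ArrayLike]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def quadratic_form(self, psi: float = 0.0) -> np.ndarray:
        """Hessian of w1 with respect to (E11, E22, E12) at orientation psi.

        w1 = 1/2 x^T H x for x = (E11, E22, E12).
        """
        basis = [
            np.array([[1.0, 0.0], [0.0, 0.0]]),
            np.array([[0.0, 0.0], [0.0, 1.0]]),
            np.array([[0.0, 1.0], [1.0, 0.0]]),
        ]
        cols = []
        for e in basis:
            s = stress(e, psi, self)
            cols.append(np.stack([s[..., 0, 0], s[..., 1, 1], 2.0 * s[..., 0, 1]], axis=-1))
        return np.stack(cols, axis=-1)

    def diagonal_coefficients(self, psi: float = 0.0) -> np.ndarray:
        """Coefficients of E11^2, E22^2, E12^2 in w1 (Pa); logged by the
        admissibility check at configuration load."""
        return np.diagonal(self.quadratic_form(psi), axis1=-2, axis2=-1) / 2.0

    def check_positive_definite(self) -> np.ndarray:
        """Verify the 3x3 quadratic form of w1 at psi = 0 is positive
        definite; returns its eigenvalues. Raises ``ValueError`` otherwise."""
        h = self.quadratic_form(0.0)
        if h.ndim != 2:
            raise ValueError("positive-definiteness check requires scalar moduli")
        eigs = np.linalg.eigvalsh(h)
        if np.any(eigs <= 0):
            raise ValueError(f"first-gradient quadratic form not positive definite (eigenvalues {eigs})")
        return eigs

    @property
    def evolving(self) -> tuple[str, ...]:
        """Names of the stiffnesses subject to remodeling."""
        return _EVOLVING


@dataclass(frozen=True)
class InvariantSet:
    """Orthotropic strain invariants (dimensionless strain combinations)."""

    J1: ArrayLike
    J2: ArrayLike
    J4: ArrayLike
    J5: ArrayLike
    J6: ArrayLike
    J7: ArrayLike


@dataclass(frozen=True)
class SecondGradientMeasures:
    """Linearized tangential stretch-gradient (s) and bending (b) scalars [1/m]."""

    s1: ArrayLike
    s2: ArrayLike
    b1: ArrayLike
    b2: ArrayLike


def structural_vectors(psi: ArrayLike) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal material symmetry directions A1, A2 for orientation psi.

    A1 = (cos psi, sin psi), A2 = (-sin psi, cos psi). Shapes broadcast:
    scalar psi gives (2,) vectors, an array gives (..., 2).
    """
    psi = np.asarray(psi)
    if not np.iscomplexobj(psi):  # complex kept for complex-step derivatives
        psi = psi.astype(float)
    if not np.all(np.isfinite(psi)):
        raise ValueError("psi must be finite")
    c, s = np.cos(psi), np.sin(psi)
    a1 = np.stack([c, s], axis=-1)
    a2 = np.stack([-s, c], axis=-1)
    return a1, a2


def _check_symmetric(E: np.ndarray) -> np.ndarray:
    E = np.asarray(E)
    if not np.iscomplexobj(E):
        E = E.astype(float)
    if E.shape[-2:] != (2, 2):
        raise ValueError("strain must have trailing shape (2, 2)")
    scale = np.abs(E).max() if E.size else 0.0
    if not np.allclose(E, np.swapaxes(E, -1, -2), atol=1e-12 * max(scale, 1.0)):
        raise ValueError("strain tensor must be symmetric")
    return E


def invariants(E: np.ndarray, psi: ArrayLike) -> InvariantSet:
    """Orthotropic invariants of a symmetric 2x2 strain at orientation psi."""
    E = _check_symmetric(E)
    a1, a2 = structural_vectors(psi)
    j1 = np.trace(E, axis1=-2, axis2=-1)
    j2 = np.einsum("...ij,...ji->...", E, E)
    m1 = np.einsum("...ij,...j->...i", E, a1)
    m2 = np.einsum("...ij,...j->...i", E, a2)
    j4 = np.einsum("...i,...i->...", a1, m1)
    j6 = np.einsum("...i,...i->...", a2, m2)
    # E symmetric: A.E^2 A = |E A|^2
    j5 = np.einsum("...i,...i->...", m1, m1)
    j7 = np.einsum("...i,...i->...", m2, m2)
    return InvariantSet(J1=j1, J2=j2, J4=j4, J5=j5, J6=j6, J7=j7)


def energy_w1(inv: InvariantSet, p: ModuliSet) -> np.ndarray:
    """First-gradient orthotropic energy density [Pa]."""
    return (
        0.5 * p.K * inv.J1**2
        + p.mu * (inv.J2 - 0.5 * inv.J1**2)
        + (p.alpha1 * inv.J4 + p.alpha2 * inv.J6) * inv.J1
        + 2.0 * p.mu1 * inv.J5
        + 2.0 * p.mu2 * inv.J7
        + 0.5 * p.beta1 * inv.J4**2
        + 0.5 * p.beta2 * inv.J6**2
        + p.beta3 * inv.J4 * inv.J6
    )


def energy_w2(sg: SecondGradientMeasures, p: ModuliSet) -> np.ndarray:
    """Second-gradient energy density [Pa] (unit-thickness convention)."""
    return 0.5 * (
        p.Ks1 * sg.s1**2 + p.Ks2 * sg.s2**2 + p.Kb1 * sg.b1**2 + p.Kb2 * sg.b2**2
    )


def _check_hessian(hess_u: np.ndarray) -> np.ndarray:
    hess_u = np.asarray(hess_u)
    if not np.iscomplexobj(hess_u):
        hess_u = hess_u.astype(float)
    if hess_u.shape[-3:] != (2, 2, 2):
        raise ValueError("displacement Hessian must have trailing shape (2, 2, 2)")
    scale = np.abs(hess_u).max() if hess_u.size else 0.0
    if not np.allclose(hess_u, np.swapaxes(hess_u, -1, -2), atol=1e-12 * max(scale, 1.0)):
        raise ValueError("Hessian must be symmetric in its differentiation indices")
    return hess_u


def second_gradient_measures(hess_u: np.ndarray, psi: ArrayLike) -> SecondGradientMeasures:
    """Stretch-gradient and bending scalars from the displacement Hessian.

    ``hess_u[..., k, p, q]`` is u_k,pq. These are the small-strain
    linearizations of the fiber directional stretch gradient A_i . grad
    lambda_i and of the deformed-fiber curvature measure lambda_i^2 eta_i.
    """
    h = _check_hessian(hess_u)
    a1, a2 = structural_vectors(psi)
    n1, n2 = a2, -a1
    proj1 = np.einsum("...kpq,...p,...q->...k", h, a1, a1)
    proj2 = np.einsum("...kpq,...p,...q->...k", h, a2, a2)
    s1 = np.einsum("...k,...k->...", a1, proj1)
    b1 = np.einsum("...k,...k->...", n1, proj1)
    s2 = np.einsum("...k,...k->...", a2, proj2)
    b2 = np.einsum("...k,...k->...", n2, proj2)
    return SecondGradientMeasures(s1=s1, s2=s2, b1=b1, b2=b2)


def stress(E: np.ndarray, psi: ArrayLike, p: ModuliSet) -> np.ndarray:
    """First-gradient stress dw1/dE (symmetric 2x2, Pa). Closed form."""
    E = _check_symmetric(E)
    a1, a2 = structural_vectors(psi)
    inv = invariants(E, psi)
    eye = np.eye(2)
    m1 = np.einsum("...ij,...j->...i", E, a1)
    m2 = np.einsum("...ij,...j->...i", E, a2)
    p1 = np.einsum("...i,...j->...ij", a1, a1)
    p2 = np.einsum("...i,...j->...ij", a2, a2)
    j1 = inv.J1[..., None, None]
    sym1 = np.einsum("...i,...j->...ij", a1, m1)
    sym1 = sym1 + np.swapaxes(sym1, -1, -2)
    sym2 = np.einsum("...i,...j->...ij", a2, m2)
    sym2 = sym2 + np.swapaxes(sym2, -1, -2)

    def _c(x):  # scalar coefficient -> broadcastable over the 2x2 block
        return np.asarray(x)[..., None, None] if np.ndim(x) else x

    return (
        _c(p.K) * j1 * eye
        + 2.0 * _c(p.mu) * (E - 0.5 * j1 * eye)
        + _c(p.alpha1 * inv.J4 + p.alpha2 * inv.J6) * eye
        + j1 * (_c(p.alpha1) * p1 + _c(p.alpha2) * p2)
        + 2.0 * _c(p.mu1) * sym1
        + 2.0 * _c(p.mu2) * sym2
        + _c(p.beta1 * inv.J4 + p.beta3 * inv.J6) * p1
        + _c(p.beta2 * inv.J6 + p.beta3 * inv.J4) * p2
    )


def hyperstress(hess_u: np.ndarray, psi: ArrayLike, p: ModuliSet) -> np.ndarray:
    """Second-gradient stress dw2/dH (third-order, Pa m). Closed form."""
    sg = second_gradient_measures(hess_u, psi)
    a1, a2 = structural_vectors(psi)
    n1, n2 = a2, -a1

    def term(k, s, v, a):
        return (np.asarray(k * s))[..., None, None, None] * np.einsum(
            "...k,...p,...q->...kpq", v, a, a
        )

    return (
        term(p.Ks1, sg.s1, a1, a1)
        + term(p.Ks2, sg.s2, a2, a2)
        + term(p.Kb1, sg.b1, n1, a1)
        + term(p.Kb2, sg.b2, n2, a2)
    )


def _torque_w1(E: np.ndarray, psi: ArrayLike, p: ModuliSet) -> np.ndarray:
    a1, a2 = structural_vectors(psi)
    inv = invariants(E, psi)
    m1 = np.einsum("...ij,...j->...i", E, a1)
    m2 = np.einsum("...ij,...j->...i", E, a2)
    q = np.einsum("...i,...i->...", a1, m2)  # A1 . E A2
    m12 = np.einsum("...i,...i->...", m1, m2)  # A1 . E^2 A2
    return (
        2.0
        * q
        * (
            (p.alpha1 - p.alpha2) * inv.J1
            + p.beta1 * inv.J4
            - p.beta2 * inv.J6
            + p.beta3 * (inv.J6 - inv.J4)
        )
        + 4.0 * (p.mu1 - p.mu2) * m12
    )


def _torque_w2(hess_u: np.ndarray, psi: ArrayLike, p: ModuliSet) -> np.ndarray:
    h = _check_hessian(hess_u)
    a1, a2 = structural_vectors(psi)

    def t(v, a, b):
        return np.einsum("...kpq,...k,...p,...q->...", h, v, a, b)

    s1 = t(a1, a1, a1)
    b1 = t(a2, a1, a1)
    s2 = t(a2, a2, a2)
    b2 = -t(a1, a2, a2)
    u = t(a1, a1, a2)
    v = t(a2, a1, a2)
    ds1 = b1 + 2.0 * u
    db1 = -s1 + 2.0 * v
    ds2 = b2 - 2.0 * v
    db2 = -s2 + 2.0 * u
    return p.Ks1 * s1 * ds1 + p.Ks2 * s2 * ds2 + p.Kb1 * b1 * db1 + p.Kb2 * b2 * db2


def orientation_curvature(E: np.ndarray, psi: ArrayLike, p: ModuliSet) -> np.ndarray:
    """d^2 w1 / dpsi^2 at fixed strain [Pa].

    Used to damp the orientation update (local relaxation rate of the
    gradient flow); positive near energy minima in psi.
    """
    E = _check_symmetric(E)
    a1, a2 = structural_vectors(psi)
    inv = invariants(E, psi)
    m2 = np.einsum("...ij,...j->...i", E, a2)
    q = np.einsum("...i,...i->...", a1, m2)
    bracket = (
        (p.alpha1 - p.alpha2) * inv.J1
        + p.beta1 * inv.J4
        - p.beta2 * inv.J6
        + p.beta3 * (inv.J6 - inv.J4)
    )
    return (
        2.0 * (inv.J6 - inv.J4) * bracket
        + 4.0 * q**2 * (p.beta1 + p.beta2 - 2.0 * p.beta3)
        + 4.0 * (p.mu1 - p.mu2) * (inv.J7 - inv.J5)
    )


def orientation_torque(
    E: np.ndarray,
    psi: ArrayLike,
    p: ModuliSet,
    hess_u: np.ndarray | None = None,
) -> np.ndarray:
    """d(w1 + w2)/dpsi at fixed strain and Hessian [Pa].

    The second-gradient contribution is included whenever ``hess_u`` is
    given; pass ``None`` for the first-gradient torque alone.
    """
    tq = _torque_w1(E, psi, p)
    if hess_u is not None:
        tq = tq + _torque_w2(hess_u, psi, p)
    return tq


def stress_and_torque(
    E: np.ndarray,
    hess_u: np.ndarray | None,
    psi: ArrayLike,
    p: ModuliSet,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stress, hyperstress and orientation torque in one call.

    With ``hess_u=None`` the hyperstress is a zero array and the torque is
    first-gradient only.
    """
    s = stress(E, psi, p)
    if hess_u is None:
        hs = np.zeros(s.shape[:-2] + (2, 2, 2))
        tq = _torque_w1(E, psi, p)
    else:
        hs = hyperstress(hess_u, psi, p)
        tq = orientation_torque(E, psi, p, hess_u)
    return s, hs, tq


def energy_shares(E: np.ndarray, psi: ArrayLike, p: ModuliSet) -> dict[str, np.ndarray]:
    """Energy-density portions attributed to the evolving moduli [Pa].

    These act as the stimulus source terms (proportionality constant 1):
    U_mu = mu (J2 - J1^2/2), U_beta1 = beta1 J4^2 / 2,
    U_beta2 = beta2 J6^2 / 2.
    """
    inv = invariants(E, psi)
    return {
        "mu": p.mu * (inv.J2 - 0.5 * inv.J1**2),
        "beta1": 0.5 * p.beta1 * inv.J4**2,
        "beta2": 0.5 * p.beta2 * inv.J6**2,
    }


def second_gradient_matrix(psi: ArrayLike, p: ModuliSet) -> np.ndarray:
    """6x6 Hessian of w2 with respect to the packed displacement Hessian
    h = (u1,11, u1,22, u1,12, u2,11, u2,22, u2,12); used by the FEM assembly.

    w2 = 1/2 h^T D h with D = sum_m K_m g_m g_m^T, where g_m picks the
    projection defining each second-gradient scalar (the mixed component
    carries the H12 + H21 multiplicity).
    """
    a1, a2 = structural_vectors(psi)
    n1, n2 = a2, -a1

    def g(v, a):
        ax, ay = a[..., 0], a[..., 1]
        vx, vy = v[..., 0], v[..., 1]
        return np.stack(
            [
                vx * ax * ax,
                vx * ay * ay,
                2.0 * vx * ax * ay,
                vy * ax * ax,
                vy * ay * ay,
                2.0 * vy * ax * ay,
            ],
            axis=-1,
        )

    terms = (
        (p.Ks1, g(a1, a1)),
        (p.Ks2, g(a2, a2)),
        (p.Kb1, g(n1, a1)),
        (p.Kb2, g(n2, a2)),
    )
    out = 0.0
    for k, gv in terms:
        out = out + np.asarray(k)[..., None, None] * np.einsum("...i,...j->...ij", gv, gv)
    return out


def stiffness_matrix(psi: ArrayLike, p: ModuliSet) -> np.ndarray:
    """3x3 Hessian of w1 with respect to e = (E11, E22, E12) at each point.

    Columns are (s11, s22, 2 s12) for unit strains; w1 = 1/2 e^T Q e.
    """
    psi = np.asarray(psi, dtype=float)
    base = psi.shape
    basis = [
        np.array([[1.0, 0.0], [0.0, 0.0]]),
        np.array([[0.0, 0.0], [0.0, 1.0]]),
        np.array([[0.0, 1.0], [1.0, 0.0]]),
    ]
    cols = []
    for e in basis:
        eb = np.broadcast_to(e, base + (2, 2))
        s = stress(eb, psi, p)
        cols.append(np.stack([s[..., 0, 0], s[..., 1, 1], 2.0 * s[..., 0, 1]], axis=-1))
    return np.stack(cols, axis=-1)
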