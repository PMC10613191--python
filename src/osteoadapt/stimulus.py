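"""Reaction--diffusion evolution of the mechanobiological stimulus fields.

Each evolving modulus carries a scalar stimulus S obeying

    d dS/dt = div(kappa grad S) + r - R S,

with a no-flux (insulated) boundary, zero initial condition, and source r
equal to the energy-density share of the same modulus (proportionality
constant 1). Time stepping is backward Euler on the same spline mesh (the
C1 basis is a fortiori C0-conforming); the factorized system matrix is
cached per (parameters, dt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from osteoadapt.constitutive import ModuliSet, energy_shares
from osteoadapt.fem import StructuredMesh

EVOLVING_FIELDS = ("mu", "beta1", "beta2")


@dataclass(frozen=True)
class StimulusParams:
    """Damping d [Pa s], diffusivity kappa [N], absorption R [Pa], and the
    homeostatic reference value S0 [Pa].

    Units follow the source data verbatim; the balance is integrated with
    the printed coefficient values (see package notes on unit bookkeeping).
    """

    d: float
    kappa: float
    R: float
    S0: float = 0.0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("damping coefficient d must be positive")
        if self.kappa < 0 or self.R < 0:
            raise ValueError("kappa and R must be non-negative")


class DiffusionStepper:
    """Backward-Euler reaction--diffusion stepper on a spline mesh."""

    def __init__(self, mesh: StructuredMesh):
        self.mesh = mesh
        self._mass = mesh.scalar_matrix("mass")
        self._lap = mesh.scalar_matrix("laplace")
        self._lu_cache: dict[tuple, spla.SuperLU] = {}

    def step(
        self,
        S: np.ndarray,
        source_qp: np.ndarray,
        params: StimulusParams,
        dt: float,
    ) -> np.ndarray:
        """One implicit step; ``S`` are spline coefficients, ``source_qp``
        the source field at quadrature points [Pa]."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        S = np.asarray(S, dtype=float)
        if S.shape != (self.mesh.n_scalar,):
            raise ValueError("stimulus coefficient vector does not match the mesh")
        key = (params.d, params.kappa, params.R, float(dt))
        lu = self._lu_cache.get(key)
        if lu is None:
            A = params.d * self._mass + dt * (
                params.kappa * self._lap + params.R * self._mass
            )
            lu = spla.splu(A.tocsc())
            self._lu_cache[key] = lu
        rhs = params.d * (self._mass @ S) + dt * self.mesh.scalar_load_vector(source_qp)
        return lu.solve(rhs)

    def integral(self, S: np.ndarray) -> float:
        """Domain integral of the stimulus field."""
        return float(np.sum(self._mass @ np.asarray(S)))


@dataclass
class StimulusSet:
    """The three stimulus fields (spline coefficients) with their parameters."""

    params: dict[str, StimulusParams]
    coeffs: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def zeros(cls, mesh: StructuredMesh, params: dict[str, StimulusParams]) -> "StimulusSet":
        return cls(
            params=dict(params),
            coeffs={name: np.zeros(mesh.n_scalar) for name in params},
        )

    def step_all(
        self,
        stepper: DiffusionStepper,
        sources_qp: dict[str, np.ndarray],
        dt: float,
    ) -> None:
        for name, S in self.coeffs.items():
            self.coeffs[name] = stepper.step(S, sources_qp[name], self.params[name], dt)

    def at_qp(self, mesh: StructuredMesh) -> dict[str, np.ndarray]:
        return {name: mesh.scalar_at_qp(S) for name, S in self.coeffs.items()}

    def copy(self) -> "StimulusSet":
        return StimulusSet(
            params=dict(self.params),
            coeffs={k: v.copy() for k, v in self.coeffs.items()},
        )


def source_field(
    E_qp: np.ndarray, psi_qp: np.ndarray, p: ModuliSet
) -> dict[str, np.ndarray]:
    """Stimulus source fields at quadrature points: the energy-density share
    of each evolving modulus evaluated on the current equilibrium strain."""
    return energy_shares(E_qp, psi_qp, p)
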