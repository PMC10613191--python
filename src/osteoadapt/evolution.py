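"""Orientation and stiffness evolution, staggered quasi-static coupling.

Strong-form rate equations extracted from the generalized virtual-work
balance:

* orientation (gradient flow of the stored energy in psi, perturbed by the
  small restoring coefficient tau_gamma):

      gamma_dot = (dw_m/dpsi - tau_gamma * gamma) / c_gamma,
      psi_dot   = -gamma_dot          (at frozen macro-rotation),

* evolving stiffnesses, driven by the deviation of their stimulus from the
  homeostatic reference:

      p_dot = [tau_p (S - S0) - chi * U_p] / c_p,

  with chi = 0 by default (pure stimulus feedback; homeostasis is then the
  exact fixed point S = S0) and a floor clamp preventing loss of
  ellipticity under sustained resorption.

The coupled step is staggered: load -> equilibrium at frozen (psi, p) ->
stimulus diffusion step sourced by the energy shares -> explicit Euler update
of psi and the moduli. An overshoot guard rejects steps with |dpsi| > 0.1 rad
and halves dt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from osteoadapt.constitutive import (
    ModuliSet,
    energy_shares,
    energy_w1,
    energy_w2,
    invariants,
    orientation_curvature,
    orientation_torque,
    second_gradient_measures,
)
from osteoadapt.fem import BoundarySpec, ContactPin, EquilibriumSolver, StructuredMesh
from osteoadapt.kinematics import polar_angle, small_strain, wrap_half
from osteoadapt.stimulus import DiffusionStepper, StimulusParams, StimulusSet

logger = logging.getLogger(__name__)

EVOLVING = ("mu", "beta1", "beta2")


@dataclass(frozen=True)
class RemodelingParams:
    """Evolution coefficients: orientation viscosity/restoring and
    per-modulus viscosities and gains."""

    c_gamma: float
    tau_gamma: float
    c_p: dict[str, float]
    tau_p: dict[str, float]
    chi: int = 0
    floor_frac: float = 0.01
    dpsi_max: float = 0.1
    psi_integrator: str = "exponential"

    def __post_init__(self) -> None:
        if self.psi_integrator not in ("exponential", "explicit"):
            raise ValueError("psi_integrator must be 'exponential' or 'explicit'")
        if self.c_gamma <= 0 or any(v <= 0 for v in self.c_p.values()):
            raise ValueError("viscous coefficients must be positive")
        if self.tau_gamma < 0 or any(v < 0 for v in self.tau_p.values()):
            raise ValueError("gains must be non-negative")
        if self.chi not in (0, 1):
            raise ValueError("chi is a {0,1} flag")


@dataclass
class EvolutionState:
    """Evolving fields at quadrature points plus stimulus coefficients."""

    t: float
    u: np.ndarray
    psi: np.ndarray
    moduli: dict[str, np.ndarray]  # evolving entries: mu, beta1, beta2
    stimuli: StimulusSet
    floors: dict[str, float]

    def copy(self) -> "EvolutionState":
        return EvolutionState(
            t=self.t,
            u=self.u.copy(),
            psi=self.psi.copy(),
            moduli={k: v.copy() for k, v in self.moduli.items()},
            stimuli=self.stimuli.copy(),
            floors=dict(self.floors),
        )


@dataclass
class CoupledProblem:
    """Everything needed to advance the staggered coupling on one mesh."""

    mesh: StructuredMesh
    boundary: BoundarySpec
    pins: list[ContactPin]
    moduli: ModuliSet
    stimulus_params: dict[str, StimulusParams]
    remodeling: RemodelingParams
    load_scale: Callable[[float], float]
    psi0: float = 0.0
    solver: EquilibriumSolver = field(init=False)
    stepper: DiffusionStepper = field(init=False)

    def __post_init__(self) -> None:
        self.solver = EquilibriumSolver(
            self.mesh, self.boundary.fixed_dofs(self.mesh), self.pins
        )
        self.stepper = DiffusionStepper(self.mesh)

    def initial_state(self) -> EvolutionState:
        shape = (self.mesh.n_elems, self.mesh.n_qp)
        moduli = {
            name: np.full(shape, float(getattr(self.moduli, name)))
            for name in EVOLVING
        }
        floors = {
            name: self.remodeling.floor_frac * float(getattr(self.moduli, name))
            for name in EVOLVING
        }
        return EvolutionState(
            t=0.0,
            u=np.zeros(self.mesh.n_dof),
            psi=np.full(shape, self.psi0),
            moduli=moduli,
            stimuli=StimulusSet.zeros(self.mesh, self.stimulus_params),
            floors=floors,
        )

    def field_moduli(self, state: EvolutionState) -> ModuliSet:
        return self.moduli.with_fields(**state.moduli)

    def equilibrium(self, state: EvolutionState, t: float) -> tuple[np.ndarray, dict]:
        """Solve quasi-static equilibrium at frozen (psi, p) and time t."""
        from osteoadapt.constitutive import second_gradient_matrix, stiffness_matrix

        p = self.field_moduli(state)
        Q = stiffness_matrix(state.psi, p)
        D = second_gradient_matrix(state.psi, p)
        K = self.mesh.assemble_stiffness(Q, D)
        f = self.boundary.load_vector(self.mesh, scale=self.load_scale(t))
        return self.solver.solve(K, f, t=t, u0=state.u)


def orientation_rate(
    torque: np.ndarray, gamma: np.ndarray, params: RemodelingParams
) -> np.ndarray:
    """psi_dot [rad/s] from the orientation torque and current misalignment."""
    return (params.tau_gamma * gamma - torque) / params.c_gamma


def orientation_increment(
    rate: np.ndarray,
    curvature: np.ndarray,
    dt: float,
    params: RemodelingParams,
) -> np.ndarray:
    """Orientation update over one step.

    'explicit': plain Euler, dt * rate. 'exponential' (default): Rosenbrock-
    type step dt * rate * phi(lambda dt) with the local relaxation rate
    lambda = (max(d2w/dpsi2, 0) + tau_gamma) / c_gamma and
    phi(x) = (1 - exp(-x))/x. Exact for a locally quadratic energy well and
    unconditionally stable there, while reducing to explicit Euler as
    dt -> 0; needed because the aligned-state relaxation is orders of
    magnitude faster than the remodeling horizon.
    """
    if params.psi_integrator == "explicit":
        return dt * rate
    lam = (np.maximum(curvature, 0.0) + params.tau_gamma) / params.c_gamma
    x = np.asarray(lam * dt, dtype=float)
    phi = np.ones_like(x)
    big = x > 1e-12
    phi[big] = -np.expm1(-x[big]) / x[big]
    return dt * rate * phi


def modulus_rate(
    S: np.ndarray,
    U_share: np.ndarray,
    *,
    tau_p: float,
    c_p: float,
    S0: float,
    chi: int = 0,
) -> np.ndarray:
    """p_dot [Pa/s]; exactly zero at homeostasis S = S0 when chi = 0."""
    return (tau_p * (np.asarray(S) - S0) - chi * np.asarray(U_share)) / c_p


def evolve_step(
    state: EvolutionState, problem: CoupledProblem, dt: float
) -> tuple[EvolutionState, dict]:
    """One staggered step; returns (new_state, diagnostics).

    If the explicit orientation update would exceed ``dpsi_max`` the step is
    rejected (``diagnostics['rejected']`` is True and the input state is
    returned untouched) so the caller can halve dt.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    mesh = problem.mesh
    rp = problem.remodeling
    t_new = state.t + dt

    u, solve_info = problem.equilibrium(state, t_new)
    grad, hess = mesh.displacement_gradients(u)
    E = small_strain(grad)
    F = grad + np.eye(2)
    theta = polar_angle(F)
    gamma = wrap_half(theta - state.psi)

    p = problem.field_moduli(state)
    torque = orientation_torque(E, state.psi, p, hess)
    psi_dot = orientation_rate(torque, gamma, rp)
    curvature = orientation_curvature(E, state.psi, p)
    dpsi = orientation_increment(psi_dot, curvature, dt, rp)
    max_dpsi = float(np.abs(dpsi).max())
    if max_dpsi > rp.dpsi_max:
        logger.info("step rejected at t=%.4g: |dpsi|=%.3g rad; halving dt", t_new, max_dpsi)
        return state, {"rejected": True, "max_dpsi": max_dpsi}

    shares = energy_shares(E, state.psi, p)

    new = state.copy()
    new.t = t_new
    new.u = u
    new.stimuli.step_all(problem.stepper, shares, dt)
    S_qp = new.stimuli.at_qp(mesh)
    new.psi = state.psi + dpsi
    for name in EVOLVING:
        rate = modulus_rate(
            S_qp[name],
            shares[name],
            tau_p=rp.tau_p[name],
            c_p=rp.c_p[name],
            S0=problem.stimulus_params[name].S0,
            chi=rp.chi,
        )
        new.moduli[name] = np.maximum(
            state.moduli[name] + dt * rate, state.floors[name]
        )

    inv = invariants(E, state.psi)
    sg = second_gradient_measures(hess, state.psi)
    w_m = energy_w1(inv, p) + energy_w2(sg, p)
    diag = {
        "rejected": False,
        "max_dpsi": max_dpsi,
        "torque_max": float(np.abs(torque).max()),
        "stored_energy": float(np.sum(mesh.qw * w_m)),
        "solve": solve_info,
    }
    return new, diag


def steady_state_check(
    prev: EvolutionState,
    curr: EvolutionState,
    mesh: StructuredMesh,
    tol: float = 1e-8,
) -> tuple[bool, dict[str, float]]:
    """Relative L2 change per unit time of psi and each evolving modulus.

    True when every rate falls below ``tol`` [1/s]. The caller is expected
    to require several consecutive positives before declaring steady state.
    """
    dt = curr.t - prev.t
    if dt <= 0:
        raise ValueError("snapshots must be time ordered")
    w = mesh.qw
    area = w.sum()
    norms: dict[str, float] = {}

    def rel_rate(a: np.ndarray, b: np.ndarray, scale_floor: float) -> float:
        diff = np.sqrt(np.sum(w * (b - a) ** 2))
        scale = max(np.sqrt(np.sum(w * b**2)), scale_floor * np.sqrt(area))
        return float(diff / (scale * dt))

    norms["psi"] = rel_rate(prev.psi, curr.psi, 1.0)  # 1 rad floor
    for name in EVOLVING:
        norms[name] = rel_rate(prev.moduli[name], curr.moduli[name], 1.0)
    return all(v < tol for v in norms.values()), norms


@dataclass
class Snapshot:
    """Recorded coupling state plus step diagnostics."""

    t: float
    u: np.ndarray
    psi: np.ndarray
    moduli: dict[str, np.ndarray]
    stimuli_qp: dict[str, np.ndarray]
    stored_energy: float


@dataclass
class Trajectory:
    snapshots: list[Snapshot]
    steady_time: float | None
    converged: bool
    n_accepted: int
    n_rejected: int
    metadata: dict

    @property
    def final(self) -> Snapshot:
        return self.snapshots[-1]


def run_coupled(
    problem: CoupledProblem,
    dt: float,
    horizon: float,
    dt_max: float | None = None,
    snapshot_every: float | None = None,
    steady_tol: float = 1e-8,
    steady_consecutive: int = 3,
    stop_at_steady: bool = True,
    max_steps: int = 200_000,
    state: EvolutionState | None = None,
) -> Trajectory:
    """Advance the coupled system from t = 0 to the horizon.

    dt adapts: halved on orientation-overshoot rejection, doubled back (up
    to the initial value) after five consecutive accepted steps. Snapshots
    are recorded every ``snapshot_every`` seconds of simulated time (default
    horizon/20) and steady state is declared after ``steady_consecutive``
    consecutive quiet snapshot intervals.
    """
    if snapshot_every is None:
        snapshot_every = horizon / 20.0
    mesh = problem.mesh
    state = problem.initial_state() if state is None else state
    dt_max = dt if dt_max is None else max(dt_max, dt)
    dt_min = dt * 2.0**-40

    def record(st: EvolutionState) -> Snapshot:
        grad, hess = mesh.displacement_gradients(st.u)
        E = small_strain(grad)
        p = problem.field_moduli(st)
        w_m = energy_w1(invariants(E, st.psi), p) + energy_w2(
            second_gradient_measures(hess, st.psi), p
        )
        return Snapshot(
            t=st.t,
            u=st.u.copy(),
            psi=st.psi.copy(),
            moduli={k: v.copy() for k, v in st.moduli.items()},
            stimuli_qp={k: v.copy() for k, v in st.stimuli.at_qp(mesh).items()},
            stored_energy=float(np.sum(mesh.qw * w_m)),
        )

    snapshots = [record(state)]
    last_snap_state = state.copy()
    next_snap = snapshot_every
    n_acc = n_rej = quiet = 0
    accept_streak = 0
    steady_time: float | None = None
    converged = False

    for _ in range(max_steps):
        if state.t >= horizon - 1e-9 * horizon:
            converged = True
            break
        dt_step = min(dt, horizon - state.t)
        new_state, diag = evolve_step(state, problem, dt_step)
        if diag["rejected"]:
            n_rej += 1
            accept_streak = 0
            dt = dt_step / 2.0
            if dt < dt_min:
                raise RuntimeError("time step collapsed below dt_min; aborting")
            continue
        n_acc += 1
        accept_streak += 1
        if accept_streak >= 5 and dt < dt_max:
            dt = min(2.0 * dt, dt_max)
            accept_streak = 0
        state = new_state
        if state.t >= next_snap - 1e-9 * snapshot_every:
            snapshots.append(record(state))
            next_snap += snapshot_every
            is_quiet, norms = steady_state_check(
                last_snap_state, state, mesh, steady_tol
            )
            last_snap_state = state.copy()
            quiet = quiet + 1 if is_quiet else 0
            if quiet >= steady_consecutive and steady_time is None:
                steady_time = state.t
                logger.info("steady state detected at t=%.4g s", state.t)
                if stop_at_steady:
                    converged = True
                    break
    else:
        logger.warning("run_coupled hit max_steps before the horizon")

    if snapshots[-1].t < state.t:
        snapshots.append(record(state))
    metadata = {
        "dt_final": dt,
        "horizon": horizon,
        "steady_tol": steady_tol,
    }
    return Trajectory(
        snapshots=snapshots,
        steady_time=steady_time,
        converged=converged,
        n_accepted=n_acc,
        n_rejected=n_rej,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# 0-D (spatially uniform) drivers: exact reductions used by tests/acceptance
# ---------------------------------------------------------------------------


def relax_orientation_uniform(
    E: np.ndarray,
    p: ModuliSet,
    params: RemodelingParams,
    psi0: float,
    torque_tol_rel: float = 1e-8,
    t_max: float = 1e12,
    dpsi_cap: float = 0.02,
) -> dict:
    """Integrate the orientation gradient flow under a fixed uniform strain.

    F = I + E (symmetric), so the macro rotation is zero and gamma = -psi.
    Returns the final angle, the flow history and the stored-energy samples
    (non-increasing up to the tiny tau_gamma contribution).
    """
    E = np.asarray(E, dtype=float)
    psi = float(psi0)
    t = 0.0
    history = {"t": [0.0], "psi": [psi], "w1": [], "torque": []}

    def w1_of(angle: float) -> float:
        return float(energy_w1(invariants(E, angle), p))

    w_scale = max(w1_of(psi), 1e-300)
    history["w1"].append(w1_of(psi))
    while t < t_max:
        tq = float(orientation_torque(E, psi, p))
        history["torque"].append(tq)
        gamma = wrap_half(-psi)
        rate = float(orientation_rate(tq, gamma, params))
        if abs(tq) < torque_tol_rel * w_scale and abs(rate) * params.c_gamma < 1e-12 * w_scale:
            break
        if rate == 0.0:
            break
        dt = min(dpsi_cap / abs(rate), t_max - t)
        psi += dt * rate
        t += dt
        history["t"].append(t)
        history["psi"].append(psi)
        history["w1"].append(w1_of(psi))
    else:  # pragma: no cover - defensive
        pass
    history["torque"].append(float(orientation_torque(E, psi, p)))
    return {
        "psi": psi,
        "t": t,
        "history": {k: np.asarray(v) for k, v in history.items()},
    }


def grid_minimizer_w1(E: np.ndarray, p: ModuliSet, n: int = 100_000) -> tuple[float, float]:
    """Brute-force minimizer of w1(psi) on [0, pi): independent oracle for
    the gradient flow."""
    angles = np.linspace(0.0, np.pi, n, endpoint=False)
    w = energy_w1(invariants(np.broadcast_to(E, (n, 2, 2)), angles), p)
    i = int(np.argmin(w))
    return float(angles[i]), float(w[i])
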