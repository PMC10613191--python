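"""C1 B-spline FEM on a structured rectangle for first+second-gradient
elasticity, with edge tractions, coefficient-elimination Dirichlet
conditions and frictionless penalty pin contact.

The discretization uses open-knot tensor-product B-splines of degree >= 2,
which are globally C1 on the rectangle, so the second-gradient bilinear form
(square-integrable displacement Hessians) is conforming. Displacement dofs
are the two components of each control coefficient, interleaved as
``dof = 2 * (i * n_by + j) + comp``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline

EDGES = ("left", "right", "bottom", "top")


class SplineBasis1D:
    """Open uniform B-spline basis of a given degree on [0, length].

    Tabulates values and first/second derivatives of the ``degree + 1``
    non-vanishing basis functions on each knot span at Gauss points.
    """

    def __init__(self, n_el: int, length: float, degree: int = 2, n_gauss: int | None = None):
        if n_el < 1 or length <= 0:
            raise ValueError("need positive element count and length")
        if degree < 1:
            raise ValueError("degree must be >= 1")
        self.n_el = int(n_el)
        self.length = float(length)
        self.degree = int(degree)
        self.n_gauss = int(n_gauss) if n_gauss else degree + 1
        self.n_basis = self.n_el + self.degree
        breaks = np.linspace(0.0, length, n_el + 1)
        self.knots = np.concatenate(
            [np.zeros(degree), breaks, np.full(degree, length)]
        )
        self.h = length / n_el
        xg, wg = leggauss(self.n_gauss)
        # Gauss points/weights mapped to every span: shape (n_el, n_gauss)
        self.qp = breaks[:-1, None] + 0.5 * self.h * (xg[None, :] + 1.0)
        self.qw = np.broadcast_to(0.5 * self.h * wg, self.qp.shape).copy()
        flat = self.qp.ravel()
        tabs = self._tabulate(flat)  # (3, n_basis, n_pts)
        # per-element local slices: local a -> global index el + a
        loc = np.arange(degree + 1)
        gidx = np.arange(self.n_el)[:, None] + loc[None, :]
        tabs = tabs.reshape(3, self.n_basis, self.n_el, self.n_gauss)
        # val/d1/d2 arrays of shape (n_el, degree+1, n_gauss)
        self.val = tabs[0][gidx, np.arange(self.n_el)[:, None]]
        self.d1 = tabs[1][gidx, np.arange(self.n_el)[:, None]]
        self.d2 = tabs[2][gidx, np.arange(self.n_el)[:, None]]
        self.support = gidx  # (n_el, degree+1) global basis indices

    def _tabulate(self, x: np.ndarray) -> np.ndarray:
        out = np.zeros((3, self.n_basis, x.size))
        for i in range(self.n_basis):
            c = np.zeros(self.n_basis)
            c[i] = 1.0
            spl = BSpline(self.knots, c, self.degree, extrapolate=False)
            out[0, i] = np.nan_to_num(spl(x))
            out[1, i] = np.nan_to_num(spl.derivative()(x))
            if self.degree >= 2:
                out[2, i] = np.nan_to_num(spl.derivative(2)(x))
        return out

    def design_matrix(self, x: np.ndarray, deriv: int = 0) -> np.ndarray:
        """Dense (len(x), n_basis) matrix of basis (derivative) values."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.zeros((x.size, self.n_basis))
        for i in range(self.n_basis):
            c = np.zeros(self.n_basis)
            c[i] = 1.0
            spl = BSpline(self.knots, c, self.degree, extrapolate=False)
            if deriv:
                spl = spl.derivative(deriv)
            out[:, i] = np.nan_to_num(spl(np.clip(x, 0.0, self.length)))
        return out


@dataclass(frozen=True)
class EdgeQuadrature:
    """1D Gauss rule on a domain edge with the scalar trace basis."""

    points: np.ndarray  # (nq, 2) physical coordinates
    weights: np.ndarray  # (nq,)
    scalar_idx: np.ndarray  # (nq, degree+1) global scalar basis indices
    values: np.ndarray  # (nq, degree+1) basis values
    normal: np.ndarray  # (2,) outward unit normal
    d_normal: np.ndarray | None = None  # (nq, degree+1, n_other) normal-derivative table


class StructuredMesh:
    """Tensor-product spline discretization of [0,Lx] x [0,Ly].

    Precomputes shape-function value/gradient/Hessian tables at the 2D Gauss
    points of every element, the strain and Hessian operator matrices used by
    the assembly, and edge trace data.
    """

    def __init__(
        self,
        Lx: float,
        Ly: float,
        nx: int,
        ny: int,
        degree: int = 2,
        n_gauss: int | None = None,
    ):
        if Lx <= 0 or Ly <= 0:
            raise ValueError("domain lengths must be positive")
        self.Lx, self.Ly = float(Lx), float(Ly)
        self.nx, self.ny = int(nx), int(ny)
        self.degree = int(degree)
        self.bx = SplineBasis1D(nx, Lx, degree, n_gauss)
        self.by = SplineBasis1D(ny, Ly, degree, n_gauss)
        self.n_scalar = self.bx.n_basis * self.by.n_basis
        self.n_dof = 2 * self.n_scalar
        self.n_elems = self.nx * self.ny
        ngx, ngy = self.bx.n_gauss, self.by.n_gauss
        self.n_qp = ngx * ngy
        p = self.degree
        self.n_loc = (p + 1) * (p + 1)

        ex = np.repeat(np.arange(self.nx), self.ny)
        ey = np.tile(np.arange(self.ny), self.nx)

        def outer(tx, ty):
            # tx: (n_elx, p+1, ngx), ty: (n_ely, p+1, ngy) -> (nel, nloc, nq)
            t = tx[ex][:, :, None, :, None] * ty[ey][:, None, :, None, :]
            return t.reshape(self.n_elems, self.n_loc, self.n_qp)

        self.N = outer(self.bx.val, self.by.val)
        self.Nx = outer(self.bx.d1, self.by.val)
        self.Ny = outer(self.bx.val, self.by.d1)
        self.Nxx = outer(self.bx.d2, self.by.val)
        self.Nyy = outer(self.bx.val, self.by.d2)
        self.Nxy = outer(self.bx.d1, self.by.d1)

        self.qp_x = (self.bx.qp[ex][:, :, None] * np.ones((1, 1, ngy))).reshape(
            self.n_elems, self.n_qp
        )
        self.qp_y = (np.ones((1, ngx, 1)) * self.by.qp[ey][:, None, :]).reshape(
            self.n_elems, self.n_qp
        )
        self.qw = (self.bx.qw[ex][:, :, None] * self.by.qw[ey][:, None, :]).reshape(
            self.n_elems, self.n_qp
        )

        gx = self.bx.support[ex]  # (nel, p+1)
        gy = self.by.support[ey]
        self.scalar_dofs = (
            gx[:, :, None] * self.by.n_basis + gy[:, None, :]
        ).reshape(self.n_elems, self.n_loc)

        self._build_operators()
        self._edge_cache: dict[str, EdgeQuadrature] = {}
        self._scalar_mats: dict[str, sp.csr_matrix] = {}

    # -- operator tables ---------------------------------------------------
    def _build_operators(self) -> None:
        nel, nq, nloc = self.n_elems, self.n_qp, self.n_loc
        ndl = 2 * nloc
        B1 = np.zeros((nel, nq, 3, ndl))
        B2 = np.zeros((nel, nq, 6, ndl))
        Nx = np.transpose(self.Nx, (0, 2, 1))  # (nel, nq, nloc)
        Ny = np.transpose(self.Ny, (0, 2, 1))
        Nxx = np.transpose(self.Nxx, (0, 2, 1))
        Nyy = np.transpose(self.Nyy, (0, 2, 1))
        Nxy = np.transpose(self.Nxy, (0, 2, 1))
        # strain components e = (E11, E22, E12)
        B1[:, :, 0, 0::2] = Nx
        B1[:, :, 1, 1::2] = Ny
        B1[:, :, 2, 0::2] = 0.5 * Ny
        B1[:, :, 2, 1::2] = 0.5 * Nx
        # packed Hessian h = (u1,11 u1,22 u1,12 u2,11 u2,22 u2,12)
        B2[:, :, 0, 0::2] = Nxx
        B2[:, :, 1, 0::2] = Nyy
        B2[:, :, 2, 0::2] = Nxy
        B2[:, :, 3, 1::2] = Nxx
        B2[:, :, 4, 1::2] = Nyy
        B2[:, :, 5, 1::2] = Nxy
        self.B1, self.B2 = B1, B2
        loc_dofs = np.empty((self.n_elems, ndl), dtype=np.int64)
        loc_dofs[:, 0::2] = 2 * self.scalar_dofs
        loc_dofs[:, 1::2] = 2 * self.scalar_dofs + 1
        self.elem_dofs = loc_dofs
        self._rows = np.repeat(loc_dofs[:, :, None], ndl, axis=2)
        self._cols = np.repeat(loc_dofs[:, None, :], ndl, axis=1)

    # -- assembly ----------------------------------------------------------
    def assemble_stiffness(
        self, Q_qp: np.ndarray, D_qp: np.ndarray | None = None
    ) -> sp.csr_matrix:
        """Assemble the symmetric equilibrium matrix from per-quadrature-point
        first-gradient (3x3) and optional second-gradient (6x6) Hessians."""
        if D_qp is not None and self.degree < 2:
            raise ValueError(
                "second-gradient terms require basis degree >= 2 (Hessians unavailable)"
            )
        w = self.qw[:, :, None, None]
        Ke = np.einsum("egai,egab,egbj->eij", self.B1, Q_qp * w, self.B1, optimize=True)
        if D_qp is not None:
            Ke += np.einsum(
                "egai,egab,egbj->eij", self.B2, D_qp * w, self.B2, optimize=True
            )
        K = sp.coo_matrix(
            (Ke.ravel(), (self._rows.ravel(), self._cols.ravel())),
            shape=(self.n_dof, self.n_dof),
        ).tocsr()
        return K

    def scalar_matrix(self, kind: str) -> sp.csr_matrix:
        """Scalar-basis mass ('mass') or Laplacian ('laplace') matrix."""
        if kind not in self._scalar_mats:
            if kind == "mass":
                Me = np.einsum("eag,eg,ebg->eab", self.N, self.qw, self.N)
            elif kind == "laplace":
                Me = np.einsum("eag,eg,ebg->eab", self.Nx, self.qw, self.Nx)
                Me += np.einsum("eag,eg,ebg->eab", self.Ny, self.qw, self.Ny)
            else:
                raise ValueError(kind)
            nloc = self.n_loc
            rows = np.repeat(self.scalar_dofs[:, :, None], nloc, axis=2)
            cols = np.repeat(self.scalar_dofs[:, None, :], nloc, axis=1)
            self._scalar_mats[kind] = sp.coo_matrix(
                (Me.ravel(), (rows.ravel(), cols.ravel())),
                shape=(self.n_scalar, self.n_scalar),
            ).tocsr()
        return self._scalar_mats[kind]

    # -- field evaluation at quadrature points -----------------------------
    def scalar_at_qp(self, coeffs: np.ndarray) -> np.ndarray:
        """Evaluate a scalar spline field at all quadrature points."""
        c = np.asarray(coeffs)[self.scalar_dofs]  # (nel, nloc)
        return np.einsum("ea,eag->eg", c, self.N)

    def scalar_load_vector(self, values_qp: np.ndarray) -> np.ndarray:
        """L2 load vector of a scalar field given at quadrature points."""
        b = np.zeros(self.n_scalar)
        contrib = np.einsum("eag,eg,eg->ea", self.N, self.qw, values_qp)
        np.add.at(b, self.scalar_dofs, contrib)
        return b

    def displacement_gradients(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Gradient (nel, nq, 2, 2) and Hessian (nel, nq, 2, 2, 2) of the
        displacement field at quadrature points; grad[..., i, j] = u_i,j."""
        d = np.asarray(u)[self.elem_dofs]  # (nel, 2*nloc)
        dx = d[:, 0::2]
        dy = d[:, 1::2]
        grad = np.empty((self.n_elems, self.n_qp, 2, 2))
        grad[:, :, 0, 0] = np.einsum("ea,eag->eg", dx, self.Nx)
        grad[:, :, 0, 1] = np.einsum("ea,eag->eg", dx, self.Ny)
        grad[:, :, 1, 0] = np.einsum("ea,eag->eg", dy, self.Nx)
        grad[:, :, 1, 1] = np.einsum("ea,eag->eg", dy, self.Ny)
        hess = np.empty((self.n_elems, self.n_qp, 2, 2, 2))
        for k, dk in ((0, dx), (1, dy)):
            hxx = np.einsum("ea,eag->eg", dk, self.Nxx)
            hyy = np.einsum("ea,eag->eg", dk, self.Nyy)
            hxy = np.einsum("ea,eag->eg", dk, self.Nxy)
            hess[:, :, k, 0, 0] = hxx
            hess[:, :, k, 1, 1] = hyy
            hess[:, :, k, 0, 1] = hxy
            hess[:, :, k, 1, 0] = hxy
        return grad, hess

    # -- point evaluation --------------------------------------------------
    def evaluate_scalar(self, coeffs: np.ndarray, x, y) -> np.ndarray:
        """Evaluate a scalar spline field at arbitrary points."""
        mx = self.bx.design_matrix(x)
        my = self.by.design_matrix(y)
        C = np.asarray(coeffs).reshape(self.bx.n_basis, self.by.n_basis)
        return np.einsum("pi,ij,pj->p", mx, C, my)

    def evaluate_displacement(self, u: np.ndarray, x, y) -> np.ndarray:
        """Evaluate the displacement field at arbitrary points -> (npts, 2)."""
        u = np.asarray(u)
        ux = self.evaluate_scalar(u[0::2], x, y)
        uy = self.evaluate_scalar(u[1::2], x, y)
        return np.stack([ux, uy], axis=-1)

    # -- edges -------------------------------------------------------------
    def edge_scalar_indices(self, edge: str) -> np.ndarray:
        """Scalar basis indices controlling the trace on an edge (open-knot
        interpolation: only the boundary row/column is nonzero on the edge)."""
        nbx, nby = self.bx.n_basis, self.by.n_basis
        if edge == "left":
            return np.arange(nby)
        if edge == "right":
            return (nbx - 1) * nby + np.arange(nby)
        if edge == "bottom":
            return np.arange(nbx) * nby
        if edge == "top":
            return np.arange(nbx) * nby + (nby - 1)
        raise ValueError(f"unknown edge {edge!r}")

    def edge_quadrature(self, edge: str) -> EdgeQuadrature:
        if edge in self._edge_cache:
            return self._edge_cache[edge]
        nbx, nby = self.bx.n_basis, self.by.n_basis
        if edge in ("bottom", "top"):
            b, other = self.bx, self.by
            coord = 0.0 if edge == "bottom" else self.Ly
            normal = np.array([0.0, -1.0]) if edge == "bottom" else np.array([0.0, 1.0])
            fixed_idx = 0 if edge == "bottom" else nby - 1
            d_edge = other.design_matrix(np.array([coord]), deriv=1)[0]
        else:
            b, other = self.by, self.bx
            coord = 0.0 if edge == "left" else self.Lx
            normal = np.array([-1.0, 0.0]) if edge == "left" else np.array([1.0, 0.0])
            fixed_idx = 0 if edge == "left" else nbx - 1
            d_edge = other.design_matrix(np.array([coord]), deriv=1)[0]
        qp = b.qp.ravel()
        qw = b.qw.ravel()
        nq = qp.size
        p1 = b.degree + 1
        support = np.repeat(b.support, b.n_gauss, axis=0)  # (nq, p+1)
        vals = np.concatenate(
            [b.val[e].T for e in range(b.n_el)], axis=0
        )  # (nq, p+1)
        if edge in ("bottom", "top"):
            scalar_idx = support * nby + fixed_idx
            pts = np.stack([qp, np.full(nq, coord)], axis=-1)
        else:
            scalar_idx = fixed_idx * nby + support
            pts = np.stack([np.full(nq, coord), qp], axis=-1)
        eq = EdgeQuadrature(
            points=pts, weights=qw, scalar_idx=scalar_idx, values=vals, normal=normal
        )
        self._edge_cache[edge] = eq
        return eq

    def traction_vector(self, edge: str, density: Sequence[float]) -> np.ndarray:
        """Load vector of a uniform traction line density [N/m] on an edge."""
        eq = self.edge_quadrature(edge)
        f = np.zeros(self.n_dof)
        for comp, val in enumerate(density):
            if val == 0.0:
                continue
            np.add.at(
                f,
                2 * eq.scalar_idx + comp,
                val * eq.weights[:, None] * eq.values,
            )
        return f

    def double_force_vector(self, edge: str, density: Sequence[float]) -> np.ndarray:
        """Load vector of a uniform double-force density (work-conjugate to
        the normal derivative of the virtual displacement) on an edge."""
        eq = self.edge_quadrature(edge)
        nbx, nby = self.bx.n_basis, self.by.n_basis
        # normal derivative couples the first two transverse basis layers
        if edge == "bottom":
            layers, db = (0, 1), self.by.design_matrix(np.array([0.0]), 1)[0]
        elif edge == "top":
            layers, db = (nby - 1, nby - 2), self.by.design_matrix(np.array([self.Ly]), 1)[0]
        elif edge == "left":
            layers, db = (0, 1), self.bx.design_matrix(np.array([0.0]), 1)[0]
        else:
            layers, db = (nbx - 1, nbx - 2), self.bx.design_matrix(np.array([self.Lx]), 1)[0]
        f = np.zeros(self.n_dof)
        sgn = 1.0 if edge in ("top", "right") else -1.0  # n . grad
        for layer in layers:
            dval = db[layer]
            if edge in ("bottom", "top"):
                idx = np.repeat(self.bx.support, self.bx.n_gauss, axis=0) * nby + layer
                vals = np.concatenate([self.bx.val[e].T for e in range(self.nx)], axis=0)
            else:
                idx = layer * nby + np.repeat(self.by.support, self.by.n_gauss, axis=0)
                vals = np.concatenate([self.by.val[e].T for e in range(self.ny)], axis=0)
            for comp, val in enumerate(density):
                if val == 0.0:
                    continue
                np.add.at(
                    f,
                    2 * idx + comp,
                    sgn * val * dval * eq.weights[:, None] * vals,
                )
        return f

    def edge_displacement(self, edge: str, u: np.ndarray) -> np.ndarray:
        """Displacement at the edge quadrature points -> (nq, 2)."""
        eq = self.edge_quadrature(edge)
        u = np.asarray(u)
        out = np.empty((eq.points.shape[0], 2))
        for comp in range(2):
            out[:, comp] = np.einsum(
                "qa,qa->q", eq.values, u[2 * eq.scalar_idx + comp]
            )
        return out

    @property
    def area(self) -> float:
        return float(self.qw.sum())


@dataclass(frozen=True)
class BoundarySpec:
    """Edge conditions: homogeneous Dirichlet components, ramped tractions
    and (static) double forces. Unlisted edges carry the natural (traction-
    and double-force-free) condition."""

    fixed: tuple[tuple[str, tuple[int, ...]], ...] = ()
    tractions: tuple[tuple[str, tuple[float, float]], ...] = ()
    double_forces: tuple[tuple[str, tuple[float, float]], ...] = ()

    def __post_init__(self) -> None:
        seen: dict[tuple[str, int], int] = {}
        for edge, comps in self.fixed:
            if edge not in EDGES:
                raise ValueError(f"unknown edge {edge!r}")
            for c in comps:
                key = (edge, c)
                seen[key] = seen.get(key, 0) + 1
                if seen[key] > 1:
                    raise ValueError(f"duplicate displacement condition on {key}")

    def fixed_dofs(self, mesh: StructuredMesh) -> np.ndarray:
        dofs: list[np.ndarray] = []
        for edge, comps in self.fixed:
            idx = mesh.edge_scalar_indices(edge)
            for c in comps:
                dofs.append(2 * idx + c)
        if not dofs:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(dofs))

    def load_vector(self, mesh: StructuredMesh, scale: float = 1.0) -> np.ndarray:
        f = np.zeros(mesh.n_dof)
        for edge, density in self.tractions:
            f += mesh.traction_vector(edge, tuple(scale * d for d in density))
        for edge, density in self.double_forces:
            f += mesh.double_force_vector(edge, density)
        return f


@dataclass
class ContactPin:
    """Rigid frictionless circular pin enforced with a quadratic penalty.

    ``center`` is the pin center at zero motion; ``motion(t)`` (optional)
    returns the added center displacement. The contact force at an edge
    quadrature point with penetration g > 0 is ``penalty * g`` along the
    radial direction away from the pin center; tangentially free.
    """

    center: np.ndarray
    radius: float
    penalty: float
    edge: str
    motion: Callable[[float], np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0 or self.penalty <= 0:
            raise ValueError("pin radius and penalty stiffness must be positive")

    def center_at(self, t: float) -> np.ndarray:
        if self.motion is None:
            return self.center
        return self.center + np.asarray(self.motion(t), dtype=float)


class EquilibriumSolver:
    """Constrained (and optionally contact-regularized) linear solver.

    Keeps the fixed-dof reduction, applies pins by fixed-point iteration on
    the linearized penalty gaps, reusing the sparse LU of the contact-free
    matrix when no pins are present.
    """

    def __init__(
        self,
        mesh: StructuredMesh,
        fixed_dofs: np.ndarray,
        pins: Sequence[ContactPin] = (),
        contact_tol: float = 1e-9,
        max_contact_iter: int = 60,
    ):
        self.mesh = mesh
        self.pins = list(pins)
        self.contact_tol = contact_tol
        self.max_contact_iter = max_contact_iter
        free = np.ones(mesh.n_dof, dtype=bool)
        free[np.asarray(fixed_dofs, dtype=np.int64)] = False
        self.free = np.flatnonzero(free)
        if self.free.size == 0:
            raise ValueError("all degrees of freedom constrained")

    def _contact_system(
        self, u: np.ndarray, t: float
    ) -> tuple[sp.csr_matrix, np.ndarray, dict]:
        mesh = self.mesh
        rows, cols, vals = [], [], []
        rhs = np.zeros(mesh.n_dof)
        info: dict[str, list] = {"active": [], "penetration": [], "force": []}
        for pin in self.pins:
            eq = mesh.edge_quadrature(pin.edge)
            c = pin.center_at(t)
            ue = mesh.edge_displacement(pin.edge, u)
            x = eq.points + ue
            r = x - c[None, :]
            d = np.linalg.norm(r, axis=1)
            d = np.maximum(d, 1e-12 * pin.radius)
            g = pin.radius - d
            n = r / d[:, None]
            active = g > 0.0
            # keep the closest point in the tangent set so the system stays
            # nonsingular before contact engages (force there is ~ 0)
            stiff = active.copy()
            stiff[np.argmax(g)] = True
            sel = np.flatnonzero(stiff)
            info["active"].append(int(active.sum()))
            info["penetration"].append(float(max(g.max(), 0.0)))
            fmag = pin.penalty * np.where(active, g, 0.0)
            info["force"].append(
                (fmag[:, None] * n * eq.weights[:, None]).sum(axis=0)
            )
            for q in sel:
                w = eq.weights[q] * pin.penalty
                nn = np.outer(n[q], n[q]) * w
                # linearized gap: g(u) = g_q + n . u_q - n . u
                rhs_q = w * (g[q] + n[q] @ ue[q]) * n[q]
                dofs = 2 * eq.scalar_idx[q]
                shape = eq.values[q]
                for a in range(shape.size):
                    for comp in range(2):
                        rhs[dofs[a] + comp] += shape[a] * rhs_q[comp]
                    for b in range(shape.size):
                        w_ab = shape[a] * shape[b]
                        for ci in range(2):
                            for cj in range(2):
                                rows.append(dofs[a] + ci)
                                cols.append(dofs[b] + cj)
                                vals.append(w_ab * nn[ci, cj])
        Kc = sp.coo_matrix(
            (vals, (rows, cols)), shape=(mesh.n_dof, mesh.n_dof)
        ).tocsr()
        return Kc, rhs, info

    def solve(
        self,
        K: sp.csr_matrix,
        f: np.ndarray,
        t: float = 0.0,
        u0: np.ndarray | None = None,
    ) -> tuple[np.ndarray, dict]:
        free = self.free
        if not self.pins:
            Kff = K[free][:, free].tocsc()
            lu = spla.splu(Kff)
            u = np.zeros(self.mesh.n_dof)
            u[free] = lu.solve(f[free])
            if not np.all(np.isfinite(u)):
                raise RuntimeError("singular equilibrium system: insufficient constraints")
            res = np.linalg.norm(Kff @ u[free] - f[free]) / max(
                np.linalg.norm(f[free]), 1e-300
            )
            return u, {"contact_iterations": 0, "relative_residual": float(res)}

        u = np.zeros(self.mesh.n_dof) if u0 is None else np.asarray(u0, float).copy()
        reg = 1e-12 * K.diagonal().max()
        prev_active: tuple[int, ...] | None = None
        info: dict = {}
        for it in range(self.max_contact_iter):
            Kc, rhs_c, cinfo = self._contact_system(u, t)
            A = (K + Kc + reg * sp.identity(self.mesh.n_dof, format="csr"))[free][
                :, free
            ].tocsc()
            lu = spla.splu(A)
            u_new = np.zeros(self.mesh.n_dof)
            u_new[free] = lu.solve((f + rhs_c)[free])
            if not np.all(np.isfinite(u_new)):
                raise RuntimeError("singular equilibrium system during contact iteration")
            scale = max(np.abs(u_new).max(), 1e-300)
            err = np.abs(u_new - u).max() / scale
            active = tuple(cinfo["active"])
            if prev_active is not None and active != prev_active and it > 10:
                u = 0.5 * (u + u_new)  # damp active-set flip-flop
            else:
                u = u_new
            info = {
                "contact_iterations": it + 1,
                "displacement_change": float(err),
                "active_points": cinfo["active"],
                "max_penetration": cinfo["penetration"],
                "contact_forces": cinfo["force"],
            }
            if err < self.contact_tol and active == prev_active:
                return u, info
            prev_active = active
        raise RuntimeError(
            f"contact iteration did not converge in {self.max_contact_iter} steps "
            f"(last change {info.get('displacement_change'):.3e})"
        )


def build_mesh(
    Lx: float,
    Ly: float,
    nx: int,
    ny: int,
    degree: int = 2,
    n_gauss: int | None = None,
    second_gradient: bool = True,
) -> StructuredMesh:
    """Construct the structured spline mesh; rejects degree < 2 when
    second-gradient stiffnesses are in play (Hessians unavailable)."""
    if second_gradient and degree < 2:
        raise ValueError("second-gradient energy requires spline degree >= 2")
    return StructuredMesh(Lx, Ly, nx, ny, degree, n_gauss)
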