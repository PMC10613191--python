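"""Trajectorial diagnostics and field export.

The central diagnostic folds the difference between the material symmetry
angle and the principal-strain (isostatic) angle modulo pi/2 — the two
orthotropy axes may align with either eigendirection (or swap), and all four
assignments represent the same aligned micro-architecture.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from osteoadapt.constitutive import ModuliSet, stress
from osteoadapt.evolution import Snapshot, Trajectory
from osteoadapt.fem import StructuredMesh
from osteoadapt.kinematics import principal_strain_angle

#: Default alignment tolerance [rad] (10 degrees).
ALIGNMENT_TOL = np.deg2rad(10.0)
#: Default relative eigenvalue gap below which strain is treated isotropic.
MASK_TOL = 1e-2


@dataclass(frozen=True)
class AlignmentReport:
    """Folded angle-difference field and area fractions.

    ``delta`` is in [0, pi/4]; fractions are area-weighted and satisfy
    aligned + misaligned + masked = 1. ``aligned_fraction_unmasked``
    restricts the ratio to points with a well-defined principal direction.
    """

    delta: np.ndarray
    masked: np.ndarray
    aligned_fraction: float
    misaligned_fraction: float
    masked_fraction: float
    aligned_fraction_unmasked: float
    tolerance: float


def fold_quarter(angle_difference: np.ndarray) -> np.ndarray:
    """Fold an angle difference modulo pi/2 into [0, pi/4]."""
    delta = np.mod(np.asarray(angle_difference, dtype=float), np.pi / 2.0)
    delta = np.where(delta > np.pi / 4.0, np.pi / 2.0 - delta, delta)
    return delta


def angle_difference_field(
    psi: np.ndarray,
    E: np.ndarray,
    weights: np.ndarray,
    tolerance: float = ALIGNMENT_TOL,
    mask_tol: float = MASK_TOL,
) -> AlignmentReport:
    """Compare material orientation with the principal-strain direction.

    ``psi`` and ``E`` are co-located fields (any common leading shape);
    ``weights`` are the corresponding area weights.
    """
    phi, indeterminate = principal_strain_angle(E, isotropy_tol=mask_tol)
    delta = fold_quarter(np.asarray(psi) - phi)
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    masked_area = float(w[indeterminate].sum())
    ok = (~indeterminate) & (delta <= tolerance)
    aligned_area = float(w[ok].sum())
    unmasked = total - masked_area
    return AlignmentReport(
        delta=delta,
        masked=indeterminate,
        aligned_fraction=aligned_area / total,
        misaligned_fraction=(unmasked - aligned_area) / total,
        masked_fraction=masked_area / total,
        aligned_fraction_unmasked=aligned_area / unmasked if unmasked > 0 else 1.0,
        tolerance=tolerance,
    )


def principal_stress_angle(
    E: np.ndarray, psi: np.ndarray, p: ModuliSet, mask_tol: float = MASK_TOL
) -> tuple[np.ndarray, np.ndarray]:
    """Principal direction of the first-gradient stress (the alternative
    isostatic-line generator; coincides with the strain one when the axes
    are aligned)."""
    s = stress(E, psi, p)
    return principal_strain_angle(s, isotropy_tol=mask_tol)


# ---------------------------------------------------------------------------
# quadrature-point grids and streamlines
# ---------------------------------------------------------------------------


def qp_grid(mesh: StructuredMesh, field_qp: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reshape a (n_elems, n_qp) quadrature field onto the tensor grid of
    Gauss abscissae -> (x1d, y1d, grid[nx*ngx, ny*ngy])."""
    ngx, ngy = mesh.bx.n_gauss, mesh.by.n_gauss
    f = np.asarray(field_qp).reshape(mesh.nx, mesh.ny, ngx, ngy)
    grid = f.transpose(0, 2, 1, 3).reshape(mesh.nx * ngx, mesh.ny * ngy)
    return mesh.bx.qp.ravel(), mesh.by.qp.ravel(), grid


def field_streamlines(
    mesh: StructuredMesh,
    angle_qp: np.ndarray,
    seeds: Sequence[Sequence[float]],
    step: float | None = None,
    max_steps: int = 4000,
) -> list[np.ndarray]:
    """Integrate streamlines of a line field given by its angle (mod pi).

    The field is interpolated through its doubled-angle vector
    (cos 2 psi, sin 2 psi), which is continuous across the pi ambiguity;
    stepping keeps the branch of +-direction closest to the previous step.
    Lines terminate at the domain boundary.
    """
    x1d, y1d, grid = qp_grid(mesh, angle_qp)
    interp = RegularGridInterpolator(
        (x1d, y1d),
        np.stack([np.cos(2.0 * grid), np.sin(2.0 * grid)], axis=-1),
        bounds_error=False,
        fill_value=None,
    )
    if step is None:
        step = min(mesh.Lx / mesh.nx, mesh.Ly / mesh.ny) / 4.0

    def direction(pt: np.ndarray, prev: np.ndarray | None) -> np.ndarray:
        c2, s2 = interp(pt[None, :])[0]
        ang = 0.5 * np.arctan2(s2, c2)
        d = np.array([np.cos(ang), np.sin(ang)])
        if prev is not None and d @ prev < 0:
            d = -d
        return d

    def inside(pt: np.ndarray) -> bool:
        return 0.0 <= pt[0] <= mesh.Lx and 0.0 <= pt[1] <= mesh.Ly

    lines = []
    for seed in seeds:
        seed = np.asarray(seed, dtype=float)
        if not inside(seed):
            raise ValueError(f"seed {seed} outside the domain")
        line = [seed]
        for sign in (1.0, -1.0):
            pt = seed.copy()
            prev = None
            segment = []
            for _ in range(max_steps):
                d = sign * direction(pt, prev if prev is not None else None)
                # midpoint (RK2) step along the line field
                mid = pt + 0.5 * step * d
                if not inside(mid):
                    break
                d2 = direction(mid, d)
                nxt = pt + step * d2
                if not inside(nxt):
                    break
                segment.append(nxt)
                prev = d2
                pt = nxt
            if sign > 0:
                line = line + segment
            else:
                line = segment[::-1] + line
        lines.append(np.asarray(line))
    return lines


def streamline_alignment(
    mesh: StructuredMesh,
    angle_a_qp: np.ndarray,
    angle_b_qp: np.ndarray,
    line: np.ndarray,
) -> float:
    """Mean folded angle difference [rad] between two line fields sampled
    along a polyline."""
    xa, ya, ga = qp_grid(mesh, angle_a_qp)
    _, _, gb = qp_grid(mesh, angle_b_qp)

    def sample(grid, pts):
        f = RegularGridInterpolator(
            (xa, ya),
            np.stack([np.cos(2.0 * grid), np.sin(2.0 * grid)], axis=-1),
            bounds_error=False,
            fill_value=None,
        )
        v = f(pts)
        return 0.5 * np.arctan2(v[:, 1], v[:, 0])

    da = sample(ga, line)
    db = sample(gb, line)
    return float(np.mean(fold_quarter(da - db)))


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def export_fields(mesh: StructuredMesh, snapshot: Snapshot, path) -> Path:
    """Write one snapshot as a legacy-ASCII VTK structured grid sampled at
    the quadrature points (displacement, orientation, moduli, stimuli)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ux = mesh.scalar_at_qp(snapshot.u[0::2])
    uy = mesh.scalar_at_qp(snapshot.u[1::2])
    fields: dict[str, np.ndarray] = {"psi": snapshot.psi}
    fields.update(snapshot.moduli)
    fields.update({f"S_{k}": v for k, v in snapshot.stimuli_qp.items()})

    x1d, y1d, _ = qp_grid(mesh, snapshot.psi)
    nxp, nyp = x1d.size, y1d.size
    npts = nxp * nyp

    def flat(field_qp: np.ndarray) -> np.ndarray:
        # VTK structured grids vary x fastest
        _, _, g = qp_grid(mesh, field_qp)
        return g.T.ravel()

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"osteoadapt snapshot t={snapshot.t:.6e}\n")
        fh.write("ASCII\nDATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {nxp} {nyp} 1\n")
        fh.write(f"POINTS {npts} double\n")
        xs = np.tile(x1d, nyp)
        ys = np.repeat(y1d, nxp)
        for x, y in zip(xs, ys):
            fh.write(f"{x:.9e} {y:.9e} 0.0\n")
        fh.write(f"POINT_DATA {npts}\n")
        fh.write("VECTORS displacement double\n")
        for vx, vy in zip(flat(ux), flat(uy)):
            fh.write(f"{vx:.9e} {vy:.9e} 0.0\n")
        for name, field_qp in fields.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for v in flat(field_qp):
                fh.write(f"{v:.9e}\n")
    return path


def read_vtk_point_data(path) -> dict[str, np.ndarray]:
    """Minimal reader for the files written by :func:`export_fields`
    (round-trip checks)."""
    out: dict[str, np.ndarray] = {}
    lines = Path(path).read_text().splitlines()
    i = 0
    npts = 0
    while i < len(lines):
        tok = lines[i].split()
        if tok[:1] == ["POINTS"]:
            npts = int(tok[1])
            vals = [list(map(float, lines[i + 1 + k].split())) for k in range(npts)]
            out["points"] = np.asarray(vals)[:, :2]
            i += npts + 1
        elif tok[:1] == ["VECTORS"]:
            vals = [list(map(float, lines[i + 1 + k].split())) for k in range(npts)]
            out[tok[1]] = np.asarray(vals)[:, :2]
            i += npts + 1
        elif tok[:1] == ["SCALARS"]:
            vals = [float(lines[i + 2 + k]) for k in range(npts)]
            out[tok[1]] = np.asarray(vals)
            i += npts + 2
        else:
            i += 1
    return out


def summary_csv(
    mesh: StructuredMesh, trajectory: Trajectory, path, tolerance: float = ALIGNMENT_TOL
) -> Path:
    """One row per snapshot: time, stored energy, alignment fractions and
    per-field extrema."""
    from osteoadapt.kinematics import small_strain

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    field_names = ["psi", "mu", "beta1", "beta2"]
    header = (
        ["t", "stored_energy", "aligned_fraction", "masked_fraction"]
        + [f"{n}_min" for n in field_names]
        + [f"{n}_max" for n in field_names]
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for snap in trajectory.snapshots:
            grad, _ = mesh.displacement_gradients(snap.u)
            E = small_strain(grad)
            rep = angle_difference_field(snap.psi, E, mesh.qw, tolerance)
            fields = {"psi": snap.psi, **snap.moduli}
            writer.writerow(
                [snap.t, snap.stored_energy, rep.aligned_fraction, rep.masked_fraction]
                + [float(fields[n].min()) for n in field_names]
                + [float(fields[n].max()) for n in field_names]
            )
    return path
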