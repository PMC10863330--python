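"""Quasi-static voxel FEM solver for tDCS and TMS electric fields.

First-order (trilinear) hexahedral elements on the regular voxel grid with
element-wise constant conductivity.  For tDCS the scalar potential solves
``div(sigma grad phi) = 0`` with Dirichlet values on the electrode
connector nodes and natural (no-flux) conditions elsewhere; the solution
is rescaled so that the current flowing into the head matches the target
stimulation current.  For TMS the source problem
``div(sigma grad phi) = -div(sigma dA/dt)`` is solved with the natural
boundary condition ``n . (grad phi + dA/dt) = 0`` and the total field is
``E = -grad phi - dA/dt``.

Linear systems are solved with Jacobi-preconditioned conjugate gradients
to a relative residual of 1e-6 (direct sparse factorization for small
systems); the electric field is evaluated at element centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .coil import CoilSpec, coil_dA_dt
from .conductor import VoxelConductorModel

__all__ = [
    "FieldSolution",
    "hex_stiffness",
    "assemble_system",
    "solve_tdcs",
    "solve_tms",
    "current_flux",
    "node_current",
]

_CORNERS = np.array([[a, b, c] for a in (0, 1) for b in (0, 1) for c in (0, 1)], dtype=int)


@dataclass
class FieldSolution:
    """Node potentials and element-wise E-vectors for one montage/current."""

    phi: np.ndarray  # flattened node potentials (V)
    e_field: np.ndarray  # (nx, ny, nz, 3) element-centered field (V/m)
    injected_current_A: float
    relative_residual: float
    mode: str  # "tdcs" | "tms"
    provenance: dict = field(default_factory=dict)


def _gauss2() -> tuple[np.ndarray, np.ndarray]:
    g = 1.0 / np.sqrt(3.0)
    pts = np.array([[(1 + sx * g) / 2, (1 + sy * g) / 2, (1 + sz * g) / 2]
                    for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
    w = np.full(8, 1.0 / 8.0)
    return pts, w


def _shape_gradients(u: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Gradients of the 8 trilinear shape functions at unit coords u (3,)."""
    grads = np.empty((8, 3))
    for l, (a, b, c) in enumerate(_CORNERS):
        f = [a * u[0] + (1 - a) * (1 - u[0]),
             b * u[1] + (1 - b) * (1 - u[1]),
             c * u[2] + (1 - c) * (1 - u[2])]
        df = [(2 * a - 1) / h[0], (2 * b - 1) / h[1], (2 * c - 1) / h[2]]
        grads[l] = [df[0] * f[1] * f[2], f[0] * df[1] * f[2], f[0] * f[1] * df[2]]
    return grads


def hex_stiffness(spacing_mm: Sequence[float]) -> np.ndarray:
    """8x8 stiffness template for a rectangular hexahedron (unit sigma).

    Distances in meters so that fields come out in V/m.
    """
    h = np.asarray(spacing_mm, dtype=float) * 1e-3
    vol = float(np.prod(h))
    pts, w = _gauss2()
    K = np.zeros((8, 8))
    for u, wq in zip(pts, w):
        G = _shape_gradients(u, h)
        K += wq * vol * (G @ G.T)
    return K


def _grad_integrals(spacing_mm: Sequence[float]) -> np.ndarray:
    """(8, 3) integrals of shape-function gradients over one element (m^2)."""
    h = np.asarray(spacing_mm, dtype=float) * 1e-3
    vol = float(np.prod(h))
    pts, w = _gauss2()
    G = np.zeros((8, 3))
    for u, wq in zip(pts, w):
        G += wq * vol * _shape_gradients(u, h)
    return G


def _element_nodes(model: VoxelConductorModel, eidx: np.ndarray) -> np.ndarray:
    """Flattened node indices (ne, 8) for element index triples (ne, 3)."""
    ijk = eidx[:, None, :] + _CORNERS[None, :, :]
    return model.node_index(ijk[..., 0], ijk[..., 1], ijk[..., 2])


def assemble_system(model: VoxelConductorModel) -> tuple[sp.csr_matrix, np.ndarray]:
    """Assemble the global stiffness matrix.

    Returns ``(K, active_nodes)`` where K is symmetric positive semidefinite
    over all grid nodes and ``active_nodes`` flags nodes touching at least
    one conducting element.  Air elements contribute nothing.
    """
    sigma = model.sigma_elem
    if not np.any(sigma > 0):
        raise ValueError("model has no conducting elements")
    eidx = np.argwhere(sigma > 0)
    nodes = _element_nodes(model, eidx).astype(np.int32)
    Kt = hex_stiffness(model.spacing_mm)
    nn = int(np.prod(model.node_shape))
    sig = sigma[eidx[:, 0], eidx[:, 1], eidx[:, 2]]
    data = (sig[:, None, None] * Kt[None, :, :]).ravel()
    rows = np.broadcast_to(nodes[:, :, None], (len(eidx), 8, 8)).ravel()
    cols = np.broadcast_to(nodes[:, None, :], (len(eidx), 8, 8)).ravel()
    K = sp.coo_matrix((data, (rows, cols)), shape=(nn, nn)).tocsr()
    active = np.zeros(nn, dtype=bool)
    active[np.unique(nodes)] = True
    return K, active


def _solve_spd(K_ff, b, tol, maxiter=40000, direct_threshold=20000):
    """Solve the SPD reduced system; returns (x, residual_history)."""
    if K_ff.shape[0] <= direct_threshold:
        x = spla.spsolve(K_ff.tocsc(), b)
        return x, []
    d = K_ff.diagonal()
    d[d <= 0] = 1.0
    M = spla.LinearOperator(K_ff.shape, matvec=lambda v: v / d)
    hist: list[float] = []
    bn = np.linalg.norm(b)

    def cb(xk):
        hist.append(float(np.linalg.norm(b - K_ff @ xk) / bn))

    x, info = spla.cg(K_ff, b, rtol=tol * 0.5, atol=0.0, maxiter=maxiter, M=M)
    if info > 0:
        raise RuntimeError(
            f"CG failed to converge within {maxiter} iterations; "
            f"residual history tail: {hist[-5:]}"
        )
    return x, hist


def _element_field(model: VoxelConductorModel, phi: np.ndarray) -> np.ndarray:
    """E = -grad(phi) at element centers; zero in air elements. (V/m)"""
    nshape = model.node_shape
    p = phi.reshape(nshape)
    h = np.asarray(model.spacing_mm) * 1e-3
    # face-mean differences of the trilinear interpolant at the center
    fx0 = (p[:-1, :-1, :-1] + p[:-1, 1:, :-1] + p[:-1, :-1, 1:] + p[:-1, 1:, 1:]) / 4
    fx1 = (p[1:, :-1, :-1] + p[1:, 1:, :-1] + p[1:, :-1, 1:] + p[1:, 1:, 1:]) / 4
    fy0 = (p[:-1, :-1, :-1] + p[1:, :-1, :-1] + p[:-1, :-1, 1:] + p[1:, :-1, 1:]) / 4
    fy1 = (p[:-1, 1:, :-1] + p[1:, 1:, :-1] + p[:-1, 1:, 1:] + p[1:, 1:, 1:]) / 4
    fz0 = (p[:-1, :-1, :-1] + p[1:, :-1, :-1] + p[:-1, 1:, :-1] + p[1:, 1:, :-1]) / 4
    fz1 = (p[:-1, :-1, 1:] + p[1:, :-1, 1:] + p[:-1, 1:, 1:] + p[1:, 1:, 1:]) / 4
    E = np.stack([-(fx1 - fx0) / h[0], -(fy1 - fy0) / h[1], -(fz1 - fz0) / h[2]], axis=-1)
    E[model.sigma_elem == 0] = 0.0
    return E


def node_current(K: sp.csr_matrix, phi: np.ndarray, nodes: np.ndarray) -> float:
    """Discrete current (A) flowing out of the given node set (reaction sum)."""
    r = K @ phi
    return float(np.sum(r[nodes]))


def solve_tdcs(
    model: VoxelConductorModel,
    target_current_A: float,
    tol: float = 1e-6,
    force_iterative: bool = False,
) -> FieldSolution:
    """Solve the tDCS scalar-potential problem and scale to the target current.

    Dirichlet values of +-0.5 (arbitrary units) are imposed on the anode and
    cathode connector nodes, then potential and field are rescaled so the
    current flowing into the head equals ``target_current_A``.  A target of
    0 A means sham: no solve, identically zero field.
    """
    if target_current_A < 0:
        raise ValueError("target current must be >= 0")
    if "anode" not in model.dirichlet_nodes or "cathode" not in model.dirichlet_nodes:
        raise ValueError("model must carry anode and cathode Dirichlet sets")
    if target_current_A == 0.0:
        nn = int(np.prod(model.node_shape))
        return FieldSolution(
            phi=np.zeros(nn),
            e_field=np.zeros(model.shape + (3,)),
            injected_current_A=0.0,
            relative_residual=0.0,
            mode="tdcs",
            provenance={"sham": True, "variant": model.provenance.get("variant")},
        )
    K, active = assemble_system(model)
    nn = K.shape[0]
    anode = np.asarray(model.dirichlet_nodes["anode"])
    cathode = np.asarray(model.dirichlet_nodes["cathode"])
    phi = np.zeros(nn)
    phi[anode] = 0.5
    phi[cathode] = -0.5
    fixed = np.zeros(nn, dtype=bool)
    fixed[anode] = True
    fixed[cathode] = True
    free = active & ~fixed
    fidx = np.nonzero(free)[0]
    K_ff = K[fidx][:, fidx]
    b = -(K[fidx] @ phi)
    x, hist = _solve_spd(K_ff, b, tol, direct_threshold=0 if force_iterative else 20000)
    phi[fidx] = x
    res = float(np.linalg.norm(b - K_ff @ x) / np.linalg.norm(b))
    current = node_current(K, phi, anode)
    if not np.isfinite(current) or abs(current) < 1e-300:
        raise RuntimeError("electrode appears disconnected: no injected current")
    scale = target_current_A / current
    phi *= scale
    E = _element_field(model, phi)
    return FieldSolution(
        phi=phi,
        e_field=E,
        injected_current_A=target_current_A,
        relative_residual=res,
        mode="tdcs",
        provenance={
            "variant": model.provenance.get("variant"),
            "raw_current_A": current,
            "cg_iters": len(hist),
        },
    )


def solve_tms(
    model: VoxelConductorModel,
    coil: CoilSpec,
    tol: float = 1e-6,
) -> FieldSolution:
    """Solve the TMS source problem; total field E = -grad(phi) - dA/dt.

    Pure-Neumann problem; the potential gauge is fixed by a zero-mean
    constraint over the active nodes.
    """
    K, active = assemble_system(model)
    nn = K.shape[0]
    sigma = model.sigma_elem
    eidx = np.argwhere(sigma > 0)
    centers = model.element_centers(eidx)
    a_dot = coil_dA_dt(coil, centers)  # (ne, 3) V/m
    Gint = _grad_integrals(model.spacing_mm)  # (8, 3)
    sig = sigma[eidx[:, 0], eidx[:, 1], eidx[:, 2]]
    contrib = -sig[:, None] * (a_dot @ Gint.T)  # (ne, 8)
    nodes = _element_nodes(model, eidx)
    b = np.zeros(nn)
    np.add.at(b, nodes.ravel(), contrib.ravel())
    fidx = np.nonzero(active)[0]
    K_ff = K[fidx][:, fidx]
    bf = b[fidx]
    bf = bf - bf.mean()  # project out the constant null space
    x, hist = _solve_spd(K_ff, bf, tol)
    x -= x.mean()
    res = float(np.linalg.norm(bf - K_ff @ x) / np.linalg.norm(bf))
    phi = np.zeros(nn)
    phi[fidx] = x
    E = _element_field(model, phi)
    adot_full = np.zeros(model.shape + (3,))
    adot_full[eidx[:, 0], eidx[:, 1], eidx[:, 2]] = a_dot
    E = E - adot_full
    E[sigma == 0] = 0.0
    return FieldSolution(
        phi=phi,
        e_field=E,
        injected_current_A=0.0,
        relative_residual=res,
        mode="tms",
        provenance={"variant": model.provenance.get("variant"), "cg_iters": len(hist)},
    )


def current_flux(
    solution: FieldSolution,
    model: VoxelConductorModel,
    region: np.ndarray,
) -> float:
    """Net current (A) flowing out of a region of elements.

    ``region`` is a boolean element mask.  The flux is summed over region
    boundary faces using a two-point approximation with harmonic-mean face
    conductivity and element-mean potentials.
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != model.shape:
        raise ValueError("region mask shape must match the element grid")
    p = solution.phi.reshape(model.node_shape)
    # element-mean potential
    pm = (
        p[:-1, :-1, :-1] + p[1:, :-1, :-1] + p[:-1, 1:, :-1] + p[:-1, :-1, 1:]
        + p[1:, 1:, :-1] + p[1:, :-1, 1:] + p[:-1, 1:, 1:] + p[1:, 1:, 1:]
    ) / 8.0
    sig = model.sigma_elem
    h = np.asarray(model.spacing_mm) * 1e-3
    areas = [h[1] * h[2], h[0] * h[2], h[0] * h[1]]
    total = 0.0
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        ra, rb = region[tuple(sl_a)], region[tuple(sl_b)]
        sa, sb = sig[tuple(sl_a)], sig[tuple(sl_b)]
        pa, pb = pm[tuple(sl_a)], pm[tuple(sl_b)]
        with np.errstate(divide="ignore", invalid="ignore"):
            sh = np.where((sa > 0) & (sb > 0), 2 * sa * sb / (sa + sb), 0.0)
        j = sh * (pa - pb) / h[ax] * areas[ax]  # current a -> b
        # faces where a in region, b outside: outflow +j ; reverse: -j
        total += float(j[ra & ~rb].sum()) - float(j[rb & ~ra].sum())
    return total
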