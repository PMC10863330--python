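"""Closed-form and semi-analytic reference solutions.

Independent oracles used to validate the numerical pipeline: the
Legendre-series potential of current injection through surface cap
electrodes on a concentric N-shell sphere (the classic volume-conductor
forward problem), and the elliptic-integral vector potential of a
circular current loop.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ellipe, ellipk, eval_legendre

MU0 = 4e-7 * np.pi

__all__ = ["shell_sphere_potential", "loop_A_exact"]


def _cap_legendre_coeffs(half_angle_rad: float, lmax: int) -> np.ndarray:
    """Legendre coefficients a_l of a unit-total-current cap density.

    The surface current density is uniform on the polar cap of the given
    half-angle and integrates to 1 over the unit sphere; returns a_l such
    that j(theta) = sum_l a_l P_l(cos theta).
    """
    x0 = np.cos(half_angle_rad)
    dens = 1.0 / (2 * np.pi * (1 - x0))  # A/m^2 on the unit sphere, unit current
    # a_l = (2l+1)/2 * integral_{x0}^{1} dens * P_l(x) dx, Gauss-Legendre
    xs, ws = np.polynomial.legendre.leggauss(4 * lmax + 64)
    x = (xs + 1) / 2 * (1 - x0) + x0
    w = ws * (1 - x0) / 2
    ls = np.arange(lmax + 1)
    P = np.stack([eval_legendre(l, x) for l in ls], axis=0)
    a = (2 * ls + 1) / 2.0 * (P * (dens * w)[None, :]).sum(axis=1)
    return a


def shell_sphere_potential(
    points_mm: np.ndarray,
    shell_radii_mm: np.ndarray,
    shell_sigma: np.ndarray,
    anode_dir: np.ndarray,
    cathode_dir: np.ndarray,
    current_A: float,
    electrode_half_angle_rad: float,
    lmax: int = 120,
) -> np.ndarray:
    """Potential (V) inside a concentric multi-shell sphere.

    ``shell_radii_mm`` are the outer radii of each layer, innermost first;
    ``shell_sigma`` the matching conductivities (S/m).  Current is injected
    through a uniform spherical-cap electrode around ``anode_dir`` on the
    outer surface and withdrawn around ``cathode_dir``.  The returned
    potential has zero monopole term (mean-free gauge).
    """
    radii = np.asarray(shell_radii_mm, dtype=float) * 1e-3
    sig = np.asarray(shell_sigma, dtype=float)
    R = radii[-1]
    pts = np.atleast_2d(points_mm) * 1e-3
    r = np.linalg.norm(pts, axis=1)
    if np.any(r > R * (1 + 1e-9)):
        raise ValueError("evaluation points must lie inside the sphere")
    a_l = _cap_legendre_coeffs(electrode_half_angle_rad, lmax)
    # per-degree radial profiles: layer j has phi = A r^l + B r^-(l+1)
    nlay = len(radii)
    ls = np.arange(1, lmax + 1)
    coeffs = np.zeros((len(ls), nlay, 2))
    for li, l in enumerate(ls):
        A, B = 1.0, 0.0
        layer_AB = [(A, B)]
        for j in range(nlay - 1):
            rj = radii[j] / R  # scaled radius for conditioning
            M1 = np.array(
                [
                    [rj**l, rj ** -(l + 1)],
                    [sig[j] * l * rj ** (l - 1), -sig[j] * (l + 1) * rj ** -(l + 2)],
                ]
            )
            M2 = np.array(
                [
                    [rj**l, rj ** -(l + 1)],
                    [
                        sig[j + 1] * l * rj ** (l - 1),
                        -sig[j + 1] * (l + 1) * rj ** -(l + 2),
                    ],
                ]
            )
            A, B = np.linalg.solve(M2, M1 @ np.array([A, B]))
            layer_AB.append((A, B))
        # outer Neumann BC (scaled radius 1): sigma dphi/dr = j_l / R... in
        # scaled units phi(r) uses x = r/R, d/dr = (1/R) d/dx
        An, Bn = layer_AB[-1]
        dphi_dx = sig[-1] * (l * An - (l + 1) * Bn)
        # physical current density coefficient: I * a_l / R^2
        target = current_A * a_l[l] / R**2 * R  # multiply by R for d/dx scaling
        scale = target / dphi_dx
        coeffs[li] = np.asarray(layer_AB) * scale

    def eval_for(direction: np.ndarray, sign: float) -> np.ndarray:
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        cosg = np.clip((pts @ d) / np.maximum(r, 1e-300), -1, 1)
        cosg[r == 0] = 0.0
        x = r / R
        layer = np.searchsorted(radii / R, x * (1 - 1e-12))
        layer = np.minimum(layer, nlay - 1)
        out = np.zeros(len(pts))
        P_prev = np.ones_like(cosg)  # P_0
        P_curr = cosg.copy()  # P_1
        for li, l in enumerate(ls):
            radial = (
                coeffs[li, layer, 0] * x**l
                + coeffs[li, layer, 1] * np.where(x > 0, x, 1.0) ** -(l + 1)
            )
            radial[x == 0] = 0.0
            out += sign * radial * P_curr
            P_next = ((2 * l + 1) * cosg * P_curr - l * P_prev) / (l + 1)
            P_prev, P_curr = P_curr, P_next
        return out

    return eval_for(anode_dir, +1.0) + eval_for(cathode_dir, -1.0)


def loop_A_exact(
    radius_m: float,
    current_A: float,
    rho: np.ndarray,
    z: np.ndarray,
) -> np.ndarray:
    """Azimuthal vector potential A_phi (T m) of a circular loop.

    Loop of the given radius in the z=0 plane centered on the axis;
    ``rho``/``z`` are cylindrical coordinates of the field points.
    """
    rho = np.asarray(rho, dtype=float)
    z = np.asarray(z, dtype=float)
    a = radius_m
    m = 4 * a * rho / ((a + rho) ** 2 + z**2)
    m = np.clip(m, 0.0, 1.0 - 1e-15)
    k = np.sqrt(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        A = (
            MU0
            * current_A
            / (4 * np.pi)
            * 4
            * a
            / np.sqrt((a + rho) ** 2 + z**2)
            * ((2 - m) * ellipk(m) - 2 * ellipe(m))
            / m
        )
    A = np.where(rho < 1e-12, 0.0, A)
    return A
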