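"""Figure-eight TMS coil model.

The coil is represented as two coplanar, counter-wound circular loops
("wings") whose centers sit one wing radius on either side of the coil
center along the lateral axis (normal x handle), so that the winding
currents at the junction — and hence the induced field under the coil
center — run along the handle direction.  Each wing is discretized as a sheet
of magnetic dipoles tiling the wing disc (a current loop is equivalent to
a uniformly magnetized sheet spanning it), which converges to the exact
loop vector potential as the dipole count grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoilSpec", "coil_dA_dt", "loop_dA_dt_dipoles", "MU0"]

MU0 = 4e-7 * np.pi  # vacuum permeability (T m / A)


@dataclass
class CoilSpec:
    """Figure-eight coil pose and drive.

    ``handle`` is the direction of the induced field under the coil
    center (the junction current direction); the wing centers lie along
    the lateral axis perpendicular to it.  ``normal`` is the coil plane
    normal pointing away from the head.
    """

    center_mm: tuple[float, float, float]
    handle: tuple[float, float, float]
    normal: tuple[float, float, float]
    wing_diameter_mm: float = 70.0
    dIdt: float = 1.0e6  # A/s
    dipole_count: int = 256

    def __post_init__(self) -> None:
        h = np.asarray(self.handle, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        h = h / np.linalg.norm(h)
        n = n - np.dot(n, h) * h
        nrm = np.linalg.norm(n)
        if nrm < 1e-12:
            raise ValueError("coil normal is parallel to the handle")
        n = n / nrm
        self.handle = tuple(h)
        self.normal = tuple(n)
        if self.dipole_count < 8:
            raise ValueError("dipole_count must be >= 8")


def _sunflower_disc(n: int) -> tuple[np.ndarray, float]:
    """n roughly uniform points on the unit disc plus per-point area."""
    k = np.arange(1, n + 1)
    r = np.sqrt((k - 0.5) / n)
    th = k * np.pi * (3.0 - np.sqrt(5.0))
    pts = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
    return pts, np.pi / n


def loop_dA_dt_dipoles(
    center_m: np.ndarray,
    normal: np.ndarray,
    radius_m: float,
    dIdt: float,
    points_m: np.ndarray,
    n_dipoles: int = 256,
) -> np.ndarray:
    """dA/dt (V/m) of one circular loop via the dipole-sheet discretization."""
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    e1 = np.array([1.0, 0, 0]) if abs(normal[0]) < 0.9 else np.array([0.0, 1, 0])
    e1 = np.cross(normal, e1)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    disc, darea = _sunflower_disc(n_dipoles)
    dip_pos = center_m + radius_m * (disc[:, :1] * e1 + disc[:, 1:] * e2)
    m_dot = dIdt * darea * radius_m**2 * normal  # moment rate per dipole
    out = np.zeros((len(points_m), 3))
    # A = mu0/4pi * (m x r) / |r|^3 summed over dipoles; chunk over dipoles
    for ppos in np.array_split(dip_pos, max(1, len(dip_pos) // 64)):
        r = points_m[:, None, :] - ppos[None, :, :]
        r3 = np.linalg.norm(r, axis=2) ** 3
        cross = np.cross(np.broadcast_to(m_dot, r.shape), r)
        out += (MU0 / (4 * np.pi)) * (cross / r3[..., None]).sum(axis=1)
    return out


def coil_dA_dt(coil: CoilSpec, points_mm: np.ndarray) -> np.ndarray:
    """dA/dt (V/m) of the figure-eight coil at world points (N, 3) in mm."""
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float)) * 1e-3
    center = np.asarray(coil.center_mm, dtype=float) * 1e-3
    h = np.asarray(coil.handle)
    n = np.asarray(coil.normal)
    lateral = np.cross(n, h)
    a = coil.wing_diameter_mm / 2.0 * 1e-3
    out = np.zeros_like(pts)
    for sign in (+1.0, -1.0):
        c = center + sign * a * lateral
        out += loop_dA_dt_dipoles(c, n, a, sign * coil.dIdt, pts, coil.dipole_count)
    return out
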