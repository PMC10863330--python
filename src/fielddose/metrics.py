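"""Dose outcome measures read from field solutions at the cortical site.

Four measures per montage/current, mirroring the study's outcome set:

* ``E_FDI`` — signed normal component of the tDCS field at the target
  site, 2 mm below the pial surface.  Sign convention: positive when the
  field points into the cortex along the inward normal (the
  anodal-facilitatory direction); a flag flips it.
* ``absE_FDI`` — field strength at the site.
* ``E_sphere`` — mean field strength over the precentral-gyrus gray
  matter within a 3 cm diameter ball around the site.
* ``E_TMS`` — mean tDCS field strength over the gray-matter region where
  the TMS-induced field exceeds 70% of its gray-matter maximum.

Fields are interpolated trilinearly from element centers (nearest-element
fallback at mask edges); regional averages are unweighted over element
centers in-mask.  All measures are linear in the stimulation current.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .conductor import VoxelConductorModel
from .phantom import TISSUE_CODES, CorticalSite, RegionMask
from .solver import FieldSolution

__all__ = [
    "FieldMetrics",
    "interpolate_field",
    "normal_component_at_site",
    "magnitude_at_site",
    "sphere_average",
    "tms_hotspot_average",
    "site_sweep",
    "metrics_table",
]


@dataclass
class FieldMetrics:
    """One row of the dose-measure table."""

    participant_id: str
    current_mA: float
    E_FDI: float
    absE_FDI: float
    E_sphere: float
    E_TMS: float
    variant_tag: str = "default"

    def __post_init__(self) -> None:
        if self.absE_FDI + 1e-12 < abs(self.E_FDI):
            raise ValueError("field strength cannot be below |normal component|")


def interpolate_field(
    solution: FieldSolution,
    model: VoxelConductorModel,
    point_mm: Sequence[float],
    trilinear: bool = True,
) -> np.ndarray:
    """E-vector at a world point, trilinear from element centers."""
    p = np.asarray(point_mm, dtype=float)
    spacing = np.asarray(model.spacing_mm)
    origin = np.asarray(model.origin_mm)
    coords = ((p - origin) / spacing - 0.5)[:, None]
    if not trilinear:
        idx = tuple(np.clip(np.round(coords[:, 0]).astype(int), 0, np.asarray(model.shape) - 1))
        return solution.e_field[idx]
    return np.array(
        [
            ndimage.map_coordinates(solution.e_field[..., d], coords, order=1, mode="nearest")[0]
            for d in range(3)
        ]
    )


def _site_element(model: VoxelConductorModel, site: CorticalSite) -> tuple[int, int, int]:
    idx = np.floor(
        (np.asarray(site.world_mm) - np.asarray(model.origin_mm)) / np.asarray(model.spacing_mm)
    ).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(model.shape)):
        raise ValueError("site lies outside the model grid")
    return tuple(idx)


def normal_component_at_site(
    solution: FieldSolution,
    model: VoxelConductorModel,
    site: CorticalSite,
    trilinear: bool = True,
    inward_positive: bool = True,
) -> float:
    """Signed normal component of E at the site (V/m).

    Positive means the field points along the inward cortical normal
    (current entering the cortex under an anode); set
    ``inward_positive=False`` to flip the convention.
    """
    el = _site_element(model, site)
    if model.sigma_elem[el] == 0:
        raise ValueError("site lies in a non-conducting (air) element")
    e = interpolate_field(solution, model, site.world_mm, trilinear)
    v = -float(np.dot(e, site.normal))  # site.normal points outward
    return v if inward_positive else -v


def magnitude_at_site(
    solution: FieldSolution,
    model: VoxelConductorModel,
    site: CorticalSite,
    trilinear: bool = True,
) -> float:
    """Field strength |E| at the site (V/m)."""
    el = _site_element(model, site)
    if model.sigma_elem[el] == 0:
        raise ValueError("site lies in a non-conducting (air) element")
    e = interpolate_field(solution, model, site.world_mm, trilinear)
    return float(np.linalg.norm(e))


def sphere_average(
    solution: FieldSolution,
    model: VoxelConductorModel,
    site: CorticalSite,
    mask: RegionMask,
    diameter_mm: float = 30.0,
) -> float:
    """Mean |E| over mask elements within the ball around the site (V/m)."""
    idx = mask.voxel_indices
    centers = model.element_centers(idx)
    inside = np.linalg.norm(centers - np.asarray(site.world_mm), axis=1) <= diameter_mm / 2.0
    sel = idx[inside]
    if len(sel) == 0:
        raise ValueError("empty intersection of mask and sphere")
    e = solution.e_field[sel[:, 0], sel[:, 1], sel[:, 2]]
    return float(np.linalg.norm(e, axis=1).mean())


def tms_hotspot_average(
    tdcs_solution: FieldSolution,
    tms_solution: FieldSolution,
    model: VoxelConductorModel,
    threshold: float = 0.70,
) -> float:
    """Mean tDCS |E| where the TMS field exceeds ``threshold`` x its GM max."""
    if tdcs_solution.e_field.shape != tms_solution.e_field.shape:
        raise ValueError("solutions live on different grids")
    gm = model.labels_elem == TISSUE_CODES["gray_matter"]
    if not gm.any():
        raise ValueError("model has no gray matter")
    tms_mag = np.linalg.norm(tms_solution.e_field, axis=-1)
    mmax = float(tms_mag[gm].max())
    if mmax <= 0:
        raise ValueError("TMS field is identically zero in gray matter")
    if threshold >= 1.0:
        hot = gm & (tms_mag >= mmax)
    else:
        hot = gm & (tms_mag > threshold * mmax)
    if not hot.any():
        raise ValueError("empty TMS hotspot mask")
    tdcs_mag = np.linalg.norm(tdcs_solution.e_field, axis=-1)
    return float(tdcs_mag[hot].mean())


def site_sweep(
    solution: FieldSolution,
    model: VoxelConductorModel,
    candidate_sites: Sequence[CorticalSite],
) -> pd.DataFrame:
    """EFDI and |E|FDI recomputed for each candidate site."""
    rows = []
    for i, s in enumerate(candidate_sites):
        rows.append(
            {
                "site_index": i,
                "world_x_mm": s.world_mm[0],
                "world_y_mm": s.world_mm[1],
                "world_z_mm": s.world_mm[2],
                "E_FDI": normal_component_at_site(solution, model, s),
                "absE_FDI": magnitude_at_site(solution, model, s),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["site_index", "world_x_mm", "world_y_mm", "world_z_mm", "E_FDI", "absE_FDI"],
    )


def metrics_table(rows: Sequence[FieldMetrics]) -> pd.DataFrame:
    """Assemble FieldMetrics rows into the CSV-ready long table."""
    return pd.DataFrame(
        [
            {
                "participant": m.participant_id,
                "current_mA": m.current_mA,
                "variant": m.variant_tag,
                "E_FDI": m.E_FDI,
                "absE_FDI": m.absE_FDI,
                "E_sphere": m.E_sphere,
                "E_TMS": m.E_TMS,
            }
            for m in rows
        ]
    )
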