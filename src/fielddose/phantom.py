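"""Synthetic multi-tissue head phantoms.

Spherical-shell phantoms stand in for MRI-derived head segmentations: an
ordered list of tissue shells (scalp, skull, CSF, gray matter, ...) is
voxelized onto a regular grid, optionally with a sinusoidally "gyrified"
gray-matter/CSF interface.  The module also defines the cortical target
site (2 mm below the pial surface, with an outward surface normal) where
the field dose measures are read, region masks around it, and NIfTI-1
round-trip I/O with a JSON label legend sidecar.

Coordinate convention: world coordinates in mm on RAS-like axes; voxel
indices are 0-based and voxel ``[i, j, k]`` occupies the half-open box
``[origin + i*s, origin + (i+1)*s)`` so its center is at
``origin + (i + 0.5)*s``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "TISSUE_CODES",
    "TissueLabelVolume",
    "CorticalSite",
    "RegionMask",
    "make_sphere_phantom",
    "sphere_geometry",
    "define_target_site",
    "signed_distance_to_pial",
    "make_region_masks",
    "read_label_volume",
    "write_label_volume",
    "DEFAULT_SHELLS",
    "MNI_FDI_SITE",
    "MNI_FDI_SITE_RESULTS",
]

#: Integer tissue codes shared by the whole pipeline.  0 is air/background.
TISSUE_CODES: dict[str, int] = {
    "air": 0,
    "scalp": 1,
    "fat": 2,
    "muscle": 3,
    "compact_bone": 4,
    "cancellous_bone": 5,
    "dura": 6,
    "csf": 7,
    "blood": 8,
    "gray_matter": 9,
    "white_matter": 10,
    "eye": 11,
    "paste": 12,
    "rubber": 13,
    "connector": 14,
}

#: Nominal MNI coordinate of the average cortical activation site of the
#: FDI muscle (default used throughout; the alternative Results-section
#: coordinate is provided as well and both are accepted by callers).
MNI_FDI_SITE = (-43.0, -11.0, 60.0)
MNI_FDI_SITE_RESULTS = (-41.0, -7.0, 63.0)

#: Default shell stack, outside in.  ``None`` thickness = fill to center.
DEFAULT_SHELLS: tuple[tuple[str, float | None], ...] = (
    ("scalp", 6.0),
    ("compact_bone", 4.0),
    ("csf", 3.0),
    ("gray_matter", 4.0),
    ("white_matter", None),
)


@dataclass
class TissueLabelVolume:
    """Voxel grid of integer tissue labels with spacing and origin."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    label_legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("tissue labels must be integers")
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        used = set(np.unique(self.labels).tolist())
        missing = used - set(self.label_legend)
        if missing:
            raise ValueError(f"labels missing from legend: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def voxel_center(self, idx: np.ndarray) -> np.ndarray:
        """World coordinate (mm) of voxel center(s) for index array (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin_mm) + (idx + 0.5) * np.asarray(self.spacing_mm)

    def containing_voxel(self, world_mm: np.ndarray) -> np.ndarray:
        """0-based voxel index containing the world point(s) (..., 3)."""
        p = np.asarray(world_mm, dtype=float)
        return np.floor((p - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)).astype(int)

    def label_at(self, world_mm) -> int:
        i, j, k = self.containing_voxel(world_mm)
        return int(self.labels[i, j, k])


@dataclass
class CorticalSite:
    """Target coordinate 2 mm below the pial surface with outward normal."""

    world_mm: tuple[float, float, float]
    normal: tuple[float, float, float]
    source_coord_mni: tuple[float, float, float]

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        nrm = float(np.linalg.norm(n))
        if abs(nrm - 1.0) > 1e-9:
            raise ValueError("site normal must be a unit vector")
        self.world_mm = tuple(float(v) for v in self.world_mm)
        self.normal = tuple(float(v) for v in n)


@dataclass
class RegionMask:
    """Named set of voxel indices (N, 3)."""

    name: str
    voxel_indices: np.ndarray

    def __post_init__(self) -> None:
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=int).reshape(-1, 3)
        if len(self.voxel_indices) == 0:
            raise ValueError(f"region mask '{self.name}' is empty")

    def __len__(self) -> int:
        return len(self.voxel_indices)


def _shell_radii(outer_radius_mm: float, shell_spec: Sequence[tuple[str, float | None]]):
    """Outer radius of each shell, outside in. Validates thicknesses."""
    radii = []
    r = float(outer_radius_mm)
    names = []
    total = 0.0
    for i, (name, thick) in enumerate(shell_spec):
        if name not in TISSUE_CODES:
            raise ValueError(f"unknown tissue name '{name}'")
        if thick is None:
            if i != len(shell_spec) - 1:
                raise ValueError("only the innermost shell may have open thickness")
            thick = r
        thick = float(thick)
        if thick <= 0:
            raise ValueError(f"shell '{name}' has non-positive thickness {thick}")
        total += thick
        names.append(name)
        radii.append(r)
        r -= thick
    if total > outer_radius_mm + 1e-9 and shell_spec[-1][1] is not None:
        raise ValueError("shell thicknesses exceed the outer radius")
    return names, np.asarray(radii, dtype=float)


def sphere_geometry(
    outer_radius_mm: float,
    shell_spec: Sequence[tuple[str, float | None]] = DEFAULT_SHELLS,
    gyrification: tuple[float, float] | None = None,
) -> Callable[[np.ndarray], np.ndarray]:
    """Analytic tissue sampler for the spherical phantom.

    Returns a callable mapping world points (N, 3) to integer tissue codes.
    Used both for voxelization and for sub-voxel partial-volume estimation.
    """
    names, radii = _shell_radii(outer_radius_mm, shell_spec)
    codes = np.array([TISSUE_CODES[n] for n in names], dtype=np.int16)
    gm_idx = names.index("gray_matter") if "gray_matter" in names else None

    amp, wavelength = (0.0, 1.0)
    if gyrification is not None:
        amp, wavelength = float(gyrification[0]), float(gyrification[1])
        if gm_idx is None:
            raise ValueError("gyrification requires a gray_matter shell")
        if wavelength <= 0:
            raise ValueError("gyrification wavelength must be positive")

    def sample(points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.linalg.norm(p, axis=1)
        bounds = np.broadcast_to(radii, (len(p), len(radii))).copy()
        if amp != 0.0:
            # modulate the GM outer (pial) radius only
            rr = np.maximum(r, 1e-12)
            theta = np.arccos(np.clip(p[:, 2] / rr, -1, 1))
            phi = np.arctan2(p[:, 1], p[:, 0])
            n_wave = max(1, int(round(2 * np.pi * radii[gm_idx] / wavelength)))
            bounds[:, gm_idx] = radii[gm_idx] + amp * np.cos(n_wave * theta) * np.cos(n_wave * phi)
        out = np.zeros(len(p), dtype=np.int16)  # air
        # assign outside-in: innermost matching shell wins
        for s in range(len(radii)):
            out[r <= bounds[:, s]] = codes[s]
        return out

    return sample


def make_sphere_phantom(
    outer_radius_mm: float,
    shell_spec: Sequence[tuple[str, float | None]] = DEFAULT_SHELLS,
    spacing_mm: float | tuple[float, float, float] = 2.0,
    gyrification: tuple[float, float] | None = None,
    air_margin_voxels: int = 2,
) -> TissueLabelVolume:
    """Voxelize a concentric-shell sphere phantom, centered at the origin.

    ``shell_spec`` lists ``(tissue_name, thickness_mm)`` outside in; the last
    entry may use ``None`` to fill the remaining core.  ``gyrification`` is an
    ``(amplitude_mm, wavelength_mm)`` pair modulating the GM/CSF interface.
    Deterministic given its arguments.
    """
    if np.isscalar(spacing_mm):
        spacing = (float(spacing_mm),) * 3
    else:
        spacing = tuple(float(s) for s in spacing_mm)  # type: ignore[arg-type]
    names, radii = _shell_radii(outer_radius_mm, shell_spec)
    thicknesses = -np.diff(np.append(radii, 0.0))
    for (name, _), th in zip(shell_spec, thicknesses):
        if name != shell_spec[-1][0] and min(spacing) > th:
            raise ValueError(
                f"voxel spacing {min(spacing)} mm exceeds the thickness of shell '{name}' ({th} mm)"
            )
    sampler = sphere_geometry(outer_radius_mm, shell_spec, gyrification)
    shape = tuple(
        int(np.ceil(2 * outer_radius_mm / s)) + 2 * air_margin_voxels for s in spacing
    )
    origin = tuple(-sh * s / 2.0 for sh, s in zip(shape, spacing))
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    centers = np.stack(
        [o + (x + 0.5) * s for o, s, x in zip(origin, spacing, (ii, jj, kk))], axis=-1
    )
    labels = sampler(centers.reshape(-1, 3)).reshape(shape)
    legend = {0: "air"}
    legend.update({TISSUE_CODES[n]: n for n in names})
    return TissueLabelVolume(labels, spacing, origin, legend)


_BRAIN_CODES = (TISSUE_CODES["gray_matter"], TISSUE_CODES["white_matter"])


def signed_distance_to_pial(volume: TissueLabelVolume) -> np.ndarray:
    """Signed distance (mm) to the pial (brain outer) surface; >0 outside."""
    brain = np.isin(volume.labels, _BRAIN_CODES)
    sp = volume.spacing_mm
    d_out = ndimage.distance_transform_edt(~brain, sampling=sp)
    d_in = ndimage.distance_transform_edt(brain, sampling=sp)
    return d_out - d_in


def define_target_site(
    volume: TissueLabelVolume,
    nominal_mni: Sequence[float] = MNI_FDI_SITE,
    anchor: Sequence[float] | None = None,
    depth_mm: float = 2.0,
    smooth_voxels: float = 1.0,
    signed_distance: np.ndarray | None = None,
) -> CorticalSite:
    """Project a nominal MNI coordinate onto the phantom cortex.

    The anchor direction (default: the normalized MNI coordinate, taken from
    the brain centroid) is cast outward from the brain centroid; the point
    where it crosses the pial surface is found on a signed-distance field,
    and the site is placed ``depth_mm`` below the surface along the outward
    normal (the normalized gradient of the signed distance).
    """
    labels = volume.labels
    if not np.isin(labels, TISSUE_CODES["gray_matter"]).any():
        raise ValueError("volume contains no gray matter")
    if signed_distance is not None:
        sd = signed_distance
    else:
        sd = signed_distance_to_pial(volume)
        if smooth_voxels > 0:
            sd = ndimage.gaussian_filter(sd, sigma=smooth_voxels)
    spacing = np.asarray(volume.spacing_mm)
    origin = np.asarray(volume.origin_mm)

    brain_idx = np.argwhere(np.isin(labels, _BRAIN_CODES))
    centroid = volume.voxel_center(brain_idx).mean(axis=0)

    if anchor is None:
        anchor = np.asarray(nominal_mni, dtype=float)
    a = np.asarray(anchor, dtype=float)
    a = a / np.linalg.norm(a)

    def sd_at(points: np.ndarray) -> np.ndarray:
        coords = ((np.atleast_2d(points) - origin) / spacing - 0.5).T
        return ndimage.map_coordinates(sd, coords, order=1, mode="nearest")

    # march outward from the centroid to bracket the pial crossing
    extent = float(np.max(np.asarray(volume.shape) * spacing))
    ts = np.arange(0.0, extent, min(spacing) / 8.0)
    vals = sd_at(centroid + ts[:, None] * a)
    inside = np.nonzero(vals < 0)[0]
    if len(inside) == 0:
        raise ValueError("anchor ray does not start inside the brain")
    i0 = inside[-1]
    if i0 + 1 >= len(ts):
        raise ValueError("anchor ray never leaves the brain")
    # linear interpolation of the zero crossing
    t0, t1, v0, v1 = ts[i0], ts[i0 + 1], vals[i0], vals[i0 + 1]
    t_star = t0 + (0.0 - v0) / (v1 - v0) * (t1 - t0)
    surface_pt = centroid + t_star * a

    def normal_at(point: np.ndarray) -> np.ndarray:
        eps = spacing / 2.0
        g = np.empty(3)
        for d in range(3):
            e = np.zeros(3)
            e[d] = eps[d]
            g[d] = (sd_at(point + e)[0] - sd_at(point - e)[0]) / (2 * eps[d])
        return g / np.linalg.norm(g)

    normal = normal_at(surface_pt)
    site_pt = surface_pt - depth_mm * normal
    # ensure the site lands in a GM voxel: search along the normal line
    if volume.label_at(site_pt) != TISSUE_CODES["gray_matter"]:
        for dd in np.linspace(-min(spacing), min(spacing), 17):
            cand = surface_pt - (depth_mm + dd) * normal
            if volume.label_at(cand) == TISSUE_CODES["gray_matter"]:
                site_pt = cand
                break
        else:
            raise ValueError("could not place site inside gray matter")
    return CorticalSite(tuple(site_pt), tuple(normal), tuple(np.asarray(nominal_mni, float)))


def make_region_masks(
    volume: TissueLabelVolume,
    site: CorticalSite,
    ball_diameter_mm: float = 30.0,
) -> list[RegionMask]:
    """Gray-matter patch around the site (stand-in for the precentral gyrus).

    Returns the ``precentral_gm`` mask: GM voxels whose centers lie within a
    ball of the given diameter centered at the site.
    """
    gm_idx = np.argwhere(volume.labels == TISSUE_CODES["gray_matter"])
    if len(gm_idx) == 0:
        raise ValueError("volume contains no gray matter")
    centers = volume.voxel_center(gm_idx)
    d = np.linalg.norm(centers - np.asarray(site.world_mm), axis=1)
    sel = gm_idx[d <= ball_diameter_mm / 2.0]
    if len(sel) == 0:
        raise ValueError("no gray-matter voxel falls inside the region ball")
    return [RegionMask("precentral_gm", sel)]


def write_label_volume(volume: TissueLabelVolume, path: str | Path) -> None:
    """Write a NIfTI-1 integer image plus a JSON legend sidecar."""
    path = Path(path)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.spacing_mm)
    # NIfTI affine maps voxel indices to voxel-center world coordinates
    affine[:3, 3] = np.asarray(volume.origin_mm) + np.asarray(volume.spacing_mm) / 2.0
    img = nib.Nifti1Image(volume.labels.astype(np.int16), affine)
    nib.save(img, str(path))
    sidecar = _sidecar_path(path)
    with open(sidecar, "w") as fh:
        json.dump({"label_legend": {str(k): v for k, v in volume.label_legend.items()}}, fh)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".legend.json")
    return path.with_name(name + ".legend.json")


def read_label_volume(path: str | Path) -> TissueLabelVolume:
    """Read a label volume written by :func:`write_label_volume`."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError("voxel data are not integer tissue labels")
        data = np.round(data).astype(np.int16)
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValueError("only axis-aligned label volumes are supported")
    spacing = tuple(np.diag(aff[:3, :3]).astype(float))
    origin = tuple(aff[:3, 3] - np.asarray(spacing) / 2.0)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"missing label legend sidecar {sidecar}")
    with open(sidecar) as fh:
        legend = {int(k): v for k, v in json.load(fh)["label_legend"].items()}
    used = set(np.unique(data).tolist())
    unknown = used - set(legend)
    if unknown:
        raise ValueError(f"label code(s) {sorted(unknown)} missing from legend")
    return TissueLabelVolume(data, spacing, origin, legend)
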