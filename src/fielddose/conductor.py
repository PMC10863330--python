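"""Volume-conductor construction: conductivities and electrodes.

Turns a tissue label volume into a per-element conductivity model for the
voxel FEM solver.  Elements on a short list of tissue boundary pairs
(WM-GM, GM-CSF, CSF-dura, dura-compact bone, and the electrode interfaces)
receive a volume-fraction-weighted average conductivity; every other mixed
element takes the conductivity of its dominant tissue (the conventional
staircase approximation).  Volume fractions are estimated by sub-voxel
point sampling against either the analytic phantom geometry or the label
image itself.

Small disc electrodes are modeled as a conductive-rubber cylinder on a
slightly wider electrode-paste layer that conforms to the scalp, with a
needle-shaped connector inside the rubber whose penetrated elements carry
the Dirichlet boundary nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .phantom import TISSUE_CODES, TissueLabelVolume

__all__ = [
    "ConductivityTable",
    "ElectrodeSpec",
    "NeedleSpec",
    "VoxelConductorModel",
    "MIXING_PAIRS",
    "assign_conductivities",
    "place_electrode",
    "perturb_conductivity",
    "mix_conductivity",
    "scalp_point",
]

# tDCS conductivities (S/m)
_TDCS_SIGMA = {
    "air": 0.0,
    "gray_matter": 0.2,
    "white_matter": 0.14,
    "csf": 1.8,
    "blood": 0.7,
    "dura": 0.16,
    "compact_bone": 0.008,
    "cancellous_bone": 0.027,
    "scalp": 0.08,
    "fat": 0.08,
    "muscle": 0.16,
    "eye": 1.5,
    "rubber": 28.3,
    "paste": 0.504,
    "connector": 28.3,  # Dirichlet block inside the rubber
}

# TMS conductivities differ slightly
_TMS_SIGMA = {
    "air": 0.0,
    "gray_matter": 0.215,
    "white_matter": 0.142,
    "csf": 1.79,
    "blood": 0.7,
    "dura": 0.18,
    "compact_bone": 0.009,
    "cancellous_bone": 0.034,
    "scalp": 0.43,
    "fat": 0.15,
    "muscle": 0.18,
    "eye": 1.5,
    "rubber": 28.3,
    "paste": 0.504,
    "connector": 28.3,
}

#: Tissue boundary pairs across which partial-volume mixing is applied.
MIXING_PAIRS: frozenset[frozenset[str]] = frozenset(
    frozenset(p)
    for p in [
        ("white_matter", "gray_matter"),
        ("gray_matter", "csf"),
        ("csf", "dura"),
        ("dura", "compact_bone"),
        ("scalp", "paste"),
        ("paste", "rubber"),
        ("paste", "air"),
        ("rubber", "air"),
    ]
)


@dataclass(frozen=True)
class ConductivityTable:
    """Tissue-name -> conductivity (S/m) map with a variant tag."""

    sigma: dict[str, float]
    variant_tag: str = "default"

    def __post_init__(self) -> None:
        for name, s in self.sigma.items():
            if name != "air" and s <= 0:
                raise ValueError(f"non-positive conductivity for '{name}'")

    @classmethod
    def default(cls) -> "ConductivityTable":
        return cls(dict(_TDCS_SIGMA), "default")

    @classmethod
    def tms(cls) -> "ConductivityTable":
        return cls(dict(_TMS_SIGMA), "tms")

    def lookup_by_code(self) -> np.ndarray:
        """Conductivity indexed by tissue code (dense lookup table)."""
        lut = np.full(max(TISSUE_CODES.values()) + 1, np.nan)
        for name, code in TISSUE_CODES.items():
            if name in self.sigma:
                lut[code] = self.sigma[name]
        return lut


def perturb_conductivity(
    table: ConductivityTable, tissue_group: str, factor: float
) -> ConductivityTable:
    """Scale the CSF or bone conductivities; bone scales both bone types.

    The four sensitivity variants carry the tags ``csf-10``, ``csf+10``,
    ``bone-50`` and ``bone+50``.
    """
    if factor <= 0:
        raise ValueError("conductivity scale factor must be positive")
    groups = {"csf": ("csf",), "bone": ("compact_bone", "cancellous_bone")}
    if tissue_group not in groups:
        raise ValueError(f"unknown tissue group '{tissue_group}'")
    sigma = dict(table.sigma)
    for t in groups[tissue_group]:
        sigma[t] = sigma[t] * factor
    pct = int(round((factor - 1.0) * 100))
    tag = f"{tissue_group}{pct:+d}" if pct != 0 else table.variant_tag
    return ConductivityTable(sigma, tag)


@dataclass(frozen=True)
class NeedleSpec:
    """Needle-shaped connector segment inside the electrode rubber."""

    base_mm: tuple[float, float, float]
    direction: tuple[float, float, float]
    length_mm: float
    radius_mm: float = 0.5


@dataclass
class ElectrodeSpec:
    """Small disc electrode: rubber cylinder on a conforming paste layer."""

    role: str  # "anode" | "cathode"
    center_mm: tuple[float, float, float]
    axis: tuple[float, float, float]
    rubber_radius_mm: float = 10.0
    rubber_thickness_mm: float = 2.0
    paste_thickness_mm: float = 2.0
    paste_radius_extra_mm: float = 1.0
    connector: NeedleSpec | None = None

    def __post_init__(self) -> None:
        if self.role not in ("anode", "cathode"):
            raise ValueError("electrode role must be 'anode' or 'cathode'")
        a = np.asarray(self.axis, dtype=float)
        self.axis = tuple(a / np.linalg.norm(a))
        if self.connector is None:
            # default: single axial needle through the rubber center
            top = np.asarray(self.center_mm) + a / np.linalg.norm(a) * (
                self.paste_thickness_mm + self.rubber_thickness_mm
            )
            self.connector = NeedleSpec(
                base_mm=tuple(top),
                direction=tuple(-np.asarray(self.axis)),
                length_mm=self.rubber_thickness_mm,
                radius_mm=0.5,
            )

    @property
    def paste_radius_mm(self) -> float:
        return self.rubber_radius_mm + self.paste_radius_extra_mm


@dataclass
class VoxelConductorModel:
    """Per-element conductivities plus Dirichlet node sets on a regular grid."""

    sigma_elem: np.ndarray
    labels_elem: np.ndarray  # dominant tissue code per element
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    dirichlet_nodes: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.sigma_elem.shape  # type: ignore[return-value]

    @property
    def node_shape(self) -> tuple[int, int, int]:
        return tuple(n + 1 for n in self.shape)  # type: ignore[return-value]

    def node_index(self, i, j, k):
        """Flattened node index for node grid coordinates."""
        _, ny1, nz1 = self.node_shape
        return (np.asarray(i) * ny1 + np.asarray(j)) * nz1 + np.asarray(k)

    def element_centers(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin_mm) + (idx + 0.5) * np.asarray(self.spacing_mm)


def mix_conductivity(fractions: dict[str, float], table: ConductivityTable) -> float:
    """Conductivity of one element from its tissue volume fractions.

    Two tissues forming a listed boundary pair are volume averaged; any
    other composition falls back to the staircase rule (dominant tissue).
    """
    present = {t: f for t, f in fractions.items() if f > 0}
    for t in present:
        if t not in table.sigma:
            raise ValueError(f"no conductivity for tissue '{t}'")
    if len(present) == 1:
        return table.sigma[next(iter(present))]
    if len(present) == 2 and frozenset(present) in MIXING_PAIRS:
        total = sum(present.values())
        return sum(table.sigma[t] * f / total for t, f in present.items())
    dominant = max(sorted(present), key=lambda t: present[t])
    return table.sigma[dominant]


def _subvoxel_offsets(factor: int) -> np.ndarray:
    """Offsets (factor^3, 3) of sub-sample points inside a unit voxel."""
    u = (np.arange(factor) + 0.5) / factor
    g = np.stack(np.meshgrid(u, u, u, indexing="ij"), axis=-1).reshape(-1, 3)
    return g


def _mixed_sigma_from_counts(
    counts: np.ndarray, codes: np.ndarray, lut: np.ndarray
) -> np.ndarray:
    """Vectorized mixing rule. counts: (n_elem, n_codes) sample counts."""
    n = counts.sum(axis=1, keepdims=True)
    frac = counts / n
    present = counts > 0
    npresent = present.sum(axis=1)
    # staircase default: dominant tissue (ties -> lowest code, via argmax order)
    dom = np.argmax(frac, axis=1)
    sigma = lut[codes[dom]]
    # two-tissue elements on a listed pair: weighted average
    two = np.nonzero(npresent == 2)[0]
    if len(two):
        idx2 = np.argsort(~present[two], axis=1)[:, :2]  # the two present columns
        c_a, c_b = codes[idx2[:, 0]], codes[idx2[:, 1]]
        pair_ok = np.array(
            [
                frozenset((_CODE_NAME[a], _CODE_NAME[b])) in MIXING_PAIRS
                for a, b in zip(c_a, c_b)
            ]
        )
        sel = two[pair_ok]
        if len(sel):
            ia, ib = idx2[pair_ok, 0], idx2[pair_ok, 1]
            fa = frac[sel, ia]
            fb = frac[sel, ib]
            sigma[sel] = fa * lut[codes[ia]] + fb * lut[codes[ib]]
    return sigma


_CODE_NAME = {v: k for k, v in TISSUE_CODES.items()}


def assign_conductivities(
    volume: TissueLabelVolume,
    table: ConductivityTable,
    subvoxel_factor: int = 4,
    geometry: Callable[[np.ndarray], np.ndarray] | None = None,
) -> VoxelConductorModel:
    """Per-element conductivities with partial-volume mixing.

    Each element is sampled at ``subvoxel_factor**3`` interior points.  When
    ``geometry`` (a world-point -> tissue-code callable, e.g. from
    :func:`fielddose.phantom.sphere_geometry`) is given, the samples probe
    the continuous geometry and boundary elements acquire genuine tissue
    fractions; without it the samples probe the label image and elements
    coincide with voxels, reproducing the staircase model.
    """
    if subvoxel_factor < 1:
        raise ValueError("subvoxel_factor must be >= 1")
    lut = table.lookup_by_code()
    used_codes = np.unique(volume.labels)
    for c in used_codes:
        if not np.isfinite(lut[c]):
            raise ValueError(f"missing conductivity for tissue '{_CODE_NAME[int(c)]}'")
    shape = volume.shape
    spacing = np.asarray(volume.spacing_mm)
    origin = np.asarray(volume.origin_mm)

    if geometry is None:
        labels_elem = volume.labels.astype(np.int16)
        sigma = lut[labels_elem]
        return VoxelConductorModel(
            sigma_elem=sigma,
            labels_elem=labels_elem.copy(),
            spacing_mm=volume.spacing_mm,
            origin_mm=volume.origin_mm,
            provenance={"variant": table.variant_tag, "subvoxel_factor": subvoxel_factor},
        )

    offsets = _subvoxel_offsets(subvoxel_factor) * spacing  # (f^3, 3)
    codes = np.arange(max(TISSUE_CODES.values()) + 1)
    sigma = np.empty(shape, dtype=float)
    labels_elem = np.empty(shape, dtype=np.int16)
    # chunk over x-slabs to bound memory
    ny, nz = shape[1], shape[2]
    jj, kk = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
    for i in range(shape[0]):
        base = origin + np.stack(
            [np.full(jj.size, i), jj.ravel(), kk.ravel()], axis=1
        ) * spacing
        pts = (base[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
        smp = geometry(pts).reshape(-1, len(offsets))
        counts = np.stack(
            [(smp == c).sum(axis=1) for c in codes], axis=1
        )
        sigma[i] = _mixed_sigma_from_counts(counts, codes, lut).reshape(ny, nz)
        labels_elem[i] = codes[np.argmax(counts, axis=1)].reshape(ny, nz)
    return VoxelConductorModel(
        sigma_elem=sigma,
        labels_elem=labels_elem,
        spacing_mm=volume.spacing_mm,
        origin_mm=volume.origin_mm,
        provenance={"variant": table.variant_tag, "subvoxel_factor": subvoxel_factor},
    )


def scalp_point(volume: TissueLabelVolume, direction: Sequence[float]) -> np.ndarray:
    """World point on the outer head surface along a ray from the head centroid."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    head = volume.labels != TISSUE_CODES["air"]
    centroid = volume.voxel_center(np.argwhere(head)).mean(axis=0)
    spacing = min(volume.spacing_mm)
    extent = float(np.max(np.asarray(volume.shape) * np.asarray(volume.spacing_mm)))
    ts = np.arange(0.0, extent, spacing / 8.0)
    pts = centroid + ts[:, None] * d
    idx = volume.containing_voxel(pts)
    ok = np.all((idx >= 0) & (idx < np.asarray(volume.shape)), axis=1)
    inside = head[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    last = np.nonzero(inside)[0][-1]
    t_surf = ts[ok][last] + spacing / 16.0
    return centroid + t_surf * d


def place_electrode(
    model: VoxelConductorModel,
    spec: ElectrodeSpec,
    table: ConductivityTable,
    subvoxel_factor: int = 4,
) -> VoxelConductorModel:
    """Insert the rubber/paste/needle electrode into the conductor model.

    The paste cylinder (radius rubber + 1 mm) fills the air gap between the
    scalp and the flat rubber underside up to its nominal thickness; the
    rubber disc sits above the paste; elements penetrated by the needle
    connector become the Dirichlet block.  Partial-volume mixing is applied
    at the electrode boundary pairs.  Returns a new model.
    """
    spacing = np.asarray(model.spacing_mm)
    origin = np.asarray(model.origin_mm)
    shape = np.asarray(model.shape)
    center = np.asarray(spec.center_mm, dtype=float)
    axis = np.asarray(spec.axis, dtype=float)

    # electrode center must sit at the scalp surface, not inside the head
    probe = center + 1.5 * float(max(spacing)) * axis
    pi = np.floor((probe - origin) / spacing).astype(int)
    if np.all((pi >= 0) & (pi < shape)):
        lab = int(model.labels_elem[tuple(pi)])
        if lab not in (TISSUE_CODES["air"], TISSUE_CODES["paste"], TISSUE_CODES["rubber"]):
            raise ValueError("electrode center lies inside the head")

    # needle must stay inside the rubber cylinder
    nd = spec.connector
    assert nd is not None
    n_dir = np.asarray(nd.direction, dtype=float)
    n_dir = n_dir / np.linalg.norm(n_dir)
    for t in np.linspace(0, nd.length_mm, 16):
        p = np.asarray(nd.base_mm) + t * n_dir
        s = float(np.dot(p - center, axis))
        rho = float(np.linalg.norm((p - center) - s * axis))
        if not (
            spec.paste_thickness_mm - 1e-6
            <= s
            <= spec.paste_thickness_mm + spec.rubber_thickness_mm + 1e-6
        ) or rho > spec.rubber_radius_mm + 1e-6:
            raise ValueError("needle connector lies outside the electrode rubber")

    total_h = spec.paste_thickness_mm + spec.rubber_thickness_mm
    r_max = spec.paste_radius_mm
    # bounding box of the electrode in element indices
    corners = []
    for s in (0.0, total_h):
        for u in np.linspace(0, 2 * np.pi, 13):
            e1 = _perp(axis)
            e2 = np.cross(axis, e1)
            corners.append(center + s * axis + r_max * (np.cos(u) * e1 + np.sin(u) * e2))
    corners = np.asarray(corners)
    lo = np.maximum(np.floor((corners.min(0) - origin) / spacing).astype(int) - 1, 0)
    hi = np.minimum(np.ceil((corners.max(0) - origin) / spacing).astype(int) + 1, shape)

    new_sigma = model.sigma_elem.copy()
    new_labels = model.labels_elem.copy()
    lut = table.lookup_by_code()
    offsets = _subvoxel_offsets(subvoxel_factor) * spacing
    codes = np.arange(max(TISSUE_CODES.values()) + 1)

    ii, jj, kk = np.meshgrid(*[np.arange(lo[d], hi[d]) for d in range(3)], indexing="ij")
    eidx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    base = origin + eidx * spacing
    pts = (base[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    rel = pts - center
    s_ax = rel @ axis
    rho = np.linalg.norm(rel - s_ax[:, None] * axis, axis=1)
    existing = np.repeat(model.labels_elem[ii.ravel(), jj.ravel(), kk.ravel()], len(offsets))
    tissue = existing.copy()
    in_paste = (
        (existing == TISSUE_CODES["air"])
        & (s_ax >= -1e-9)
        & (s_ax < spec.paste_thickness_mm)
        & (rho <= spec.paste_radius_mm)
    )
    in_rubber = (
        (existing == TISSUE_CODES["air"])
        & (s_ax >= spec.paste_thickness_mm)
        & (s_ax < total_h)
        & (rho <= spec.rubber_radius_mm)
    )
    tissue[in_paste] = TISSUE_CODES["paste"]
    tissue[in_rubber] = TISSUE_CODES["rubber"]
    tissue = tissue.reshape(-1, len(offsets))
    touched = np.any(
        (tissue == TISSUE_CODES["paste"]) | (tissue == TISSUE_CODES["rubber"]), axis=1
    )
    if touched.any():
        counts = np.stack([(tissue[touched] == c).sum(axis=1) for c in codes], axis=1)
        sig = _mixed_sigma_from_counts(counts, codes, lut)
        dom = codes[np.argmax(counts, axis=1)]
        sel = eidx[touched]
        new_sigma[sel[:, 0], sel[:, 1], sel[:, 2]] = sig
        new_labels[sel[:, 0], sel[:, 1], sel[:, 2]] = dom.astype(np.int16)

    # needle block: elements penetrated by the needle segment
    step = float(min(spacing)) / 8.0
    ts = np.arange(0.0, nd.length_mm + step, step)
    npts = np.asarray(nd.base_mm) + ts[:, None] * n_dir
    block = np.unique(
        np.floor((npts - origin) / spacing).astype(int), axis=0
    )
    block = block[np.all((block >= 0) & (block < shape), axis=1)]
    if len(block) == 0:
        raise ValueError("needle connector does not intersect any element")
    new_sigma[block[:, 0], block[:, 1], block[:, 2]] = table.sigma["connector"]
    new_labels[block[:, 0], block[:, 1], block[:, 2]] = TISSUE_CODES["connector"]

    # Dirichlet nodes = all 8 corner nodes of every block element
    corners8 = np.array(
        [[a, b, c] for a in (0, 1) for b in (0, 1) for c in (0, 1)], dtype=int
    )
    node_ijk = (block[:, None, :] + corners8[None, :, :]).reshape(-1, 3)
    out = VoxelConductorModel(
        sigma_elem=new_sigma,
        labels_elem=new_labels,
        spacing_mm=model.spacing_mm,
        origin_mm=model.origin_mm,
        dirichlet_nodes=dict(model.dirichlet_nodes),
        provenance=dict(model.provenance),
    )
    nodes = np.unique(out.node_index(node_ijk[:, 0], node_ijk[:, 1], node_ijk[:, 2]))
    for role, other in out.dirichlet_nodes.items():
        if role != spec.role and np.intersect1d(nodes, other).size:
            raise ValueError("electrode Dirichlet sets overlap")
    out.dirichlet_nodes[spec.role] = nodes
    electrodes = list(out.provenance.get("electrodes", []))
    electrodes.append(
        {
            "role": spec.role,
            "center_mm": tuple(np.asarray(spec.center_mm, float)),
            "axis": tuple(axis),
            "rubber_radius_mm": spec.rubber_radius_mm,
        }
    )
    out.provenance["electrodes"] = electrodes
    return out


def _perp(v: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to v."""
    a = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, a)
    return p / np.linalg.norm(p)
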