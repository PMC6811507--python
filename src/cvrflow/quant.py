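"""Per-vessel flow and cross-sectional area from centerline planes.

At every measurement node a square plane perpendicular to the local tangent
is sampled at half-voxel pitch by trilinear interpolation of the velocity
field and (as floats) of the binary lumen mask.  Lumen pixels are those with
interpolated mask >= 0.5, restricted to the in-plane connected component
containing the plane center so that neighboring vessels sliced by the same
plane are ignored.  Flux integrates the normal velocity over the lumen
(cm^3/s -> mL/min); CSA is lumen pixel count x pixel area.  Per-vessel values
are unweighted means over all valid sections, matching an along-the-vessel
average.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .angio import VesselTree
from .volume import VelocityVolume

__all__ = [
    "CrossSection",
    "VesselMeasurement",
    "sample_cross_section",
    "measure_vessel",
    "global_flow",
]

log = logging.getLogger(__name__)

REQUIRED_FOR_GLOBAL = ("ICA_L", "ICA_R", "BA")


@dataclass
class CrossSection:
    node: int
    origin: np.ndarray  # world cm
    normal: np.ndarray  # unit vector
    n_pixels: int
    pixel_area: float  # cm^2
    csa: float  # cm^2
    flux: float  # mL/min


@dataclass
class VesselMeasurement:
    label: str
    flow: float  # mL/min, mean over sections
    csa: float  # cm^2, mean over sections
    n_sections: int
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        if not (np.isfinite(self.flow) and np.isfinite(self.csa)):
            raise ValueError("flow and csa must be finite")


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal in-plane vectors for a given unit normal."""
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(normal)))] = 1.0
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    w = np.cross(normal, u)
    return u, w


def sample_cross_section(
    vol: VelocityVolume,
    mask: np.ndarray,
    tree: VesselTree,
    node: int,
    side_factor: float = 4.0,
    pixel_scale: float = 0.5,
    flux_dilation: int = 2,
) -> CrossSection | None:
    """Sample one perpendicular plane; ``None`` when the section is invalid.

    The plane has side ``side_factor x local radius`` and pixel size
    ``pixel_scale x voxel``.  CSA counts the lumen pixels themselves, while
    flux integrates over the lumen dilated by ``flux_dilation`` pixels: the
    acquisition box-averages velocity into voxels, which smears part of the
    near-wall flux just outside the lumen contour, and flux — unlike area —
    is conserved under that smearing, so a slightly larger integration domain
    recovers it.  Sections whose plane leaves the grid or whose lumen is
    empty are skipped (returned as ``None``).
    """
    data = tree.graph.nodes[node]
    normal = np.asarray(data["tangent"], dtype=float)
    nn = np.linalg.norm(normal)
    if nn == 0:
        return None
    normal = normal / nn
    origin = np.asarray(data["world"], dtype=float)
    radius = max(float(data["radius"]), vol.voxel_size)

    pixel = pixel_scale * vol.voxel_size
    half = side_factor * radius / 2.0
    m = int(np.ceil(half / pixel))
    ab = np.arange(-m, m + 1) * pixel
    u, w = _plane_basis(normal)
    A, B = np.meshgrid(ab, ab, indexing="ij")
    pts = origin[None, None, :] + A[..., None] * u + B[..., None] * w
    idx = pts / vol.voxel_size  # fractional voxel indices

    shape = np.array(vol.grid_shape)
    if np.any(idx < 0) or np.any(idx > shape - 1):
        log.warning("section at node %d leaves the grid; skipped", node)
        return None

    coords = idx.reshape(-1, 3).T
    mask_interp = ndimage.map_coordinates(
        mask.astype(float), coords, order=1
    ).reshape(A.shape)
    lumen = mask_interp >= 0.5
    if not np.any(lumen):
        return None
    # keep only the in-plane component containing (or nearest to) the center
    labels, _ = ndimage.label(lumen)
    center = (m, m)
    if lumen[center]:
        lumen = labels == labels[center]
    else:
        cand = np.argwhere(lumen)
        nearest = cand[np.argmin(np.linalg.norm(cand - center, axis=1))]
        lumen = labels == labels[tuple(nearest)]

    flux_domain = (
        ndimage.binary_dilation(lumen, iterations=flux_dilation)
        if flux_dilation > 0
        else lumen
    )
    tavg = vol.tavg_velocity
    vn = np.zeros(A.shape)
    dom_coords = coords[:, flux_domain.ravel()]
    for axis in range(3):
        comp = ndimage.map_coordinates(tavg[axis], dom_coords, order=1)
        vn[flux_domain] += normal[axis] * comp

    pixel_area = pixel * pixel
    flux = float(vn[flux_domain].sum() * pixel_area * 60.0)  # cm^3/s -> mL/min
    n_pix = int(lumen.sum())
    return CrossSection(
        node=node,
        origin=origin,
        normal=normal,
        n_pixels=n_pix,
        pixel_area=pixel_area,
        csa=n_pix * pixel_area,
        flux=flux,
    )


def _other_vessel_tree(
    tree: VesselTree, label: str
) -> tuple[cKDTree | None, float]:
    pts, radii = [], []
    for other, nodes in tree.measurement_nodes.items():
        if other == label:
            continue
        for n in nodes:
            pts.append(tree.graph.nodes[n]["world"])
            radii.append(tree.graph.nodes[n]["radius"])
    if not pts:
        return None, 0.0
    return cKDTree(np.array(pts)), float(max(radii))


def measure_vessel(
    vol: VelocityVolume,
    mask: np.ndarray,
    tree: VesselTree,
    label: str,
    exclude_overlapping: bool = True,
    **section_kw,
) -> VesselMeasurement:
    """Average flux and CSA over a vessel's measurement nodes.

    Sections whose lumen pixels fall inside another labeled vessel (within
    that vessel's local radius of its centerline) are skipped to avoid double
    counting near junctions.  Flux sign follows the node ordering fixed at
    labeling time.
    """
    nodes = tree.measurement_nodes.get(label)
    if not nodes:
        raise ValueError(f"label {label!r} has no measurement nodes")
    other_tree, other_rmax = (
        _other_vessel_tree(tree, label) if exclude_overlapping else (None, 0.0)
    )
    fluxes, csas = [], []
    for node in nodes:
        sec = sample_cross_section(vol, mask, tree, node, **section_kw)
        if sec is None:
            continue
        if other_tree is not None:
            d, _ = other_tree.query(sec.origin)
            if d < 2.0 * other_rmax:
                # cheap conservative proximity test before the exact one
                u, w = _plane_basis(sec.normal)
                half = np.sqrt(sec.csa)  # ~lumen extent
                probes = sec.origin + np.array(
                    [a * u + b * w for a in (-half, 0, half) for b in (-half, 0, half)]
                )
                dd, _ = other_tree.query(probes)
                if np.any(dd < other_rmax):
                    log.info("section at node %d overlaps another vessel", node)
                    continue
        fluxes.append(sec.flux)
        csas.append(sec.csa)
    if not fluxes:
        raise ValueError(f"no valid cross-sections for {label!r}")
    return VesselMeasurement(
        label=label,
        flow=float(np.mean(fluxes)),
        csa=float(np.mean(csas)),
        n_sections=len(fluxes),
    )


def global_flow(measurements: dict[str, VesselMeasurement] | list[VesselMeasurement]) -> float:
    """Global cerebral inflow = ICA_L + ICA_R + BA flow (mL/min)."""
    if not isinstance(measurements, dict):
        measurements = {m.label: m for m in measurements}
    missing = [v for v in REQUIRED_FOR_GLOBAL if v not in measurements]
    if missing:
        raise ValueError(f"global flow requires {', '.join(missing)}")
    return float(sum(measurements[v].flow for v in REQUIRED_FOR_GLOBAL))
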