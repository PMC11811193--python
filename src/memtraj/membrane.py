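"""Leaflet thinning maps, water defects, occupancy grids and depth traces.

All lateral fields are computed on frames that have already been centred
and rotationally fitted (``core.center_and_rotfit``) when a protein is
present, so that protein-anchored features accumulate in fixed bins.

Conventions: thinning is the mean absolute distance of a leaflet's
phosphates to the global membrane centre, on a 0.1 nm xy grid, with bins
kept only when they collect more than ``min_bin_count`` (30) phosphate
observations; the water-defect cylinder has radius 2.5 nm and spans
±1.5 nm around the global membrane centre; occupancy grids use 0.2 nm
voxels and per-frame binary presence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    AnalysisConfig,
    BeadSelection,
    ConfigError,
    FrameSeries,
    MembraneFrameRefs,
    MemtrajError,
    SelectionError,
    minimum_image_vectors,
)

__all__ = [
    "EmptyRegionError",
    "LeafletMap",
    "RadialProfile",
    "DefectTrace",
    "OccupancyGrid",
    "IsoSurface",
    "DepthTrace",
    "leaflet_thinning_map",
    "map_summary",
    "radial_minimum_profile",
    "annulus_around_protein",
    "water_defect_count",
    "occupancy_grid",
    "export_isosurface",
    "write_opendx",
    "write_obj",
    "residue_depth_trace",
]


class EmptyRegionError(MemtrajError):
    """A map summary was requested over a region with no valid bins."""


@dataclass
class LeafletMap:
    """2-D leaflet thinning field with observation counts and validity mask."""

    thickness: np.ndarray    # (nx, ny) mean |z - center| in nm; NaN where invalid
    counts: np.ndarray       # (nx, ny) phosphate observations per bin
    valid: np.ndarray        # counts > min_bin_count
    x_edges: np.ndarray
    y_edges: np.ndarray
    leaflet: str

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            0.5 * (self.x_edges[:-1] + self.x_edges[1:]),
            0.5 * (self.y_edges[:-1] + self.y_edges[1:]),
        )


@dataclass
class RadialProfile:
    """Per-azimuth minimum thickness on a ring around a protein."""

    sector_deg: np.ndarray       # sector centre azimuths, degrees
    sector_min: np.ndarray       # min thickness per sector, NaN if empty
    ring_min: float
    ring_min_azimuth_deg: float
    r_inner: float
    r_outer: float


@dataclass
class DefectTrace:
    """Per-frame water count inside the defect cylinder."""

    counts: np.ndarray
    dt: float
    mean: float
    sem: float          # over frames; replicate-level SEM is taken downstream
    radius: float
    half_height: float


@dataclass
class OccupancyGrid:
    """3-D per-voxel occupancy in percent of frames."""

    occupancy: np.ndarray    # (nx, ny, nz), 0..100
    origin: np.ndarray       # nm
    spacing: np.ndarray      # nm per voxel edge, per axis
    n_frames: int


@dataclass
class IsoSurface:
    mask: np.ndarray         # occupancy >= threshold
    vertices: np.ndarray     # (n, 3) nm; empty when the level is out of range
    faces: np.ndarray        # (m, 3) vertex indices
    threshold: float


@dataclass
class DepthTrace:
    """Per-frame z of a residue relative to the glycerol membrane centre.

    Positive values lie on the cytosolic (top) side of the centre.
    """

    values: np.ndarray
    dt: float
    mean: float
    sd: float


# ---------------------------------------------------------------------------
# Thinning maps
# ---------------------------------------------------------------------------

def _grid_edges(box_xy: np.ndarray, bin_xy: float) -> tuple[np.ndarray, np.ndarray]:
    nx = max(1, int(round(box_xy[0] / bin_xy)))
    ny = max(1, int(round(box_xy[1] / bin_xy)))
    return np.linspace(0.0, box_xy[0], nx + 1), np.linspace(0.0, box_xy[1], ny + 1)


def leaflet_thinning_map(
    frames: FrameSeries,
    phosphates: BeadSelection,
    leaflet: str,
    refs: MembraneFrameRefs,
    cfg: AnalysisConfig | None = None,
) -> LeafletMap:
    """Accumulate the leaflet thinning field over all frames.

    For every phosphate of the requested leaflet, in every frame, the
    absolute distance of its z position to the global membrane centre is
    added to the xy bin it falls in; bins report the mean and are masked
    unless they collected strictly more than ``cfg.min_bin_count``
    observations.  Bins are anchored at the box corner of the first frame.
    """
    cfg = cfg or AnalysisConfig()
    if refs.center_z_global is None:
        raise ConfigError("refs.center_z_global is required; run membrane_centers first")
    rid = phosphates.residue_ids()
    member = np.array([refs.leaflet_of_lipid.get(int(r)) == leaflet for r in rid])
    if not member.any():
        raise SelectionError(f"no phosphates in leaflet {leaflet!r}")
    sel = phosphates.indices[member]

    x_edges, y_edges = _grid_edges(frames.box[0, :2], cfg.bin_xy)
    nx, ny = len(x_edges) - 1, len(y_edges) - 1

    pos = frames.coords[:, sel, :]                      # (F, N, 3)
    box = frames.box[:, None, :]
    xy = np.mod(pos[:, :, :2], box[:, :, :2])           # wrap into the box
    dz = np.abs(pos[:, :, 2] - refs.center_z_global[:, None])

    ix = np.clip((xy[:, :, 0] / (x_edges[-1] / nx)).astype(int), 0, nx - 1)
    iy = np.clip((xy[:, :, 1] / (y_edges[-1] / ny)).astype(int), 0, ny - 1)
    flat = (ix * ny + iy).ravel()
    sums = np.bincount(flat, weights=dz.ravel(), minlength=nx * ny).reshape(nx, ny)
    counts = np.bincount(flat, minlength=nx * ny).reshape(nx, ny)

    with np.errstate(invalid="ignore", divide="ignore"):
        thickness = sums / counts
    valid = counts > cfg.min_bin_count
    thickness[~valid] = np.nan
    return LeafletMap(thickness, counts, valid, x_edges, y_edges, leaflet)


def map_summary(
    lmap: LeafletMap, region: np.ndarray | None = None
) -> tuple[float, float]:
    """Minimum and mean thickness over the valid bins of a (masked) region."""
    mask = lmap.valid if region is None else (lmap.valid & np.asarray(region, bool))
    if not mask.any():
        raise EmptyRegionError("no valid bins in the requested region")
    vals = lmap.thickness[mask]
    return float(vals.min()), float(vals.mean())


def annulus_around_protein(
    frames: FrameSeries,
    protein: BeadSelection,
    width: float = 0.8,
    reference_frame: int = 0,
) -> tuple[np.ndarray, float, float]:
    """Protein xy-centre and a default ring just outside the protein wall.

    The ring runs from the protein's maximal xy bead radius to ``width`` nm
    beyond it, measured at ``reference_frame`` of (fitted) frames.
    """
    protein.validate_against(frames)
    p = frames.coords[reference_frame, protein.indices, :2]
    center = p.mean(axis=0)
    r_max = float(np.max(np.linalg.norm(p - center, axis=1)))
    return center, r_max, r_max + width


def radial_minimum_profile(
    lmap: LeafletMap,
    center_xy: np.ndarray,
    r_inner: float,
    r_outer: float,
    n_sectors: int = 36,
) -> RadialProfile:
    """Minimum thickness per azimuthal sector on a ring around the protein.

    Bins whose centre lies in the annulus ``[r_inner, r_outer]`` around
    ``center_xy`` are grouped into ``n_sectors`` equal azimuthal sectors;
    the lowest leaflet value of each sector and of the whole ring is
    returned.
    """
    if r_inner < 0 or r_outer <= r_inner:
        raise ConfigError("annulus must satisfy 0 <= r_inner < r_outer")
    cx, cy = np.asarray(center_xy, dtype=float)
    xc, yc = lmap.bin_centers()
    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    dx, dy = gx - cx, gy - cy
    r = np.hypot(dx, dy)
    in_ring = (r >= r_inner) & (r <= r_outer) & lmap.valid
    if not in_ring.any():
        raise EmptyRegionError("no valid bins inside the annulus")
    azimuth = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    sector = np.minimum((azimuth / (2 * np.pi) * n_sectors).astype(int), n_sectors - 1)
    sector_min = np.full(n_sectors, np.nan)
    for s in range(n_sectors):
        m = in_ring & (sector == s)
        if m.any():
            sector_min[s] = np.nanmin(lmap.thickness[m])
    ring_vals = lmap.thickness[in_ring]
    ring_min = float(np.nanmin(ring_vals))
    flat_idx = np.nanargmin(np.where(in_ring, lmap.thickness, np.nan))
    min_az = float(np.degrees(azimuth.ravel()[flat_idx]))
    sector_deg = (np.arange(n_sectors) + 0.5) * 360.0 / n_sectors
    return RadialProfile(sector_deg, sector_min, ring_min, min_az, r_inner, r_outer)


# ---------------------------------------------------------------------------
# Water defects
# ---------------------------------------------------------------------------

def water_defect_count(
    frames: FrameSeries,
    waters: BeadSelection,
    refs: MembraneFrameRefs,
    cfg: AnalysisConfig | None = None,
    protein: BeadSelection | None = None,
    anchor_xy: np.ndarray | None = None,
) -> DefectTrace:
    """Count water beads inside the protein-anchored defect cylinder.

    A water is inside when its minimum-image xy distance to the anchor is
    at most ``cfg.cyl_radius`` and its |z - global membrane centre| is at
    most ``cfg.cyl_half_height``.  The anchor is the protein's current xy
    geometric centre, re-evaluated every frame (frames are fitted per
    frame, so the cylinder follows the protein), or a fixed ``anchor_xy``.
    """
    cfg = cfg or AnalysisConfig()
    if refs.center_z_global is None:
        raise ConfigError("refs.center_z_global is required; run membrane_centers first")
    if len(waters) == 0:
        raise SelectionError("water selection is empty")
    waters.validate_against(frames)
    if protein is not None:
        protein.validate_against(frames)
        anchors = frames.coords[:, protein.indices, :2].mean(axis=1)  # (F, 2)
    elif anchor_xy is not None:
        anchors = np.tile(np.asarray(anchor_xy, float), (frames.n_frames, 1))
    else:
        raise ConfigError("water_defect_count needs a protein selection or anchor_xy")

    w = frames.coords[:, waters.indices, :]
    dxy = w[:, :, :2] - anchors[:, None, :]
    dxy = minimum_image_vectors(dxy, frames.box[:, None, :2])
    in_xy = np.sum(dxy * dxy, axis=-1) <= cfg.cyl_radius**2
    in_z = np.abs(w[:, :, 2] - refs.center_z_global[:, None]) <= cfg.cyl_half_height
    counts = np.sum(in_xy & in_z, axis=1)
    mean = float(counts.mean())
    sem = float(counts.std(ddof=1) / np.sqrt(len(counts))) if len(counts) > 1 else 0.0
    return DefectTrace(counts, frames.dt, mean, sem, cfg.cyl_radius, cfg.cyl_half_height)


# ---------------------------------------------------------------------------
# Occupancy grids
# ---------------------------------------------------------------------------

def occupancy_grid(
    frames: FrameSeries,
    beads: BeadSelection,
    cfg: AnalysisConfig | None = None,
) -> OccupancyGrid:
    """Per-voxel presence frequency of the selected beads, 0-100%.

    The box of the first (fitted reference) frame is gridded at
    ``cfg.grid_spacing``; in every frame a voxel scores a hit when at
    least one selected bead lies in it (beads outside the box are wrapped
    by the periodic boundary first).  Occupancy is the hit count as a
    percentage of all frames.
    """
    cfg = cfg or AnalysisConfig()
    if len(beads) == 0:
        raise SelectionError("bead selection is empty")
    beads.validate_against(frames)
    box0 = frames.box[0]
    dims = np.maximum(1, np.round(box0 / cfg.grid_spacing).astype(int))
    spacing = box0 / dims
    hits = np.zeros(dims, dtype=np.int64)
    strides = np.array([dims[1] * dims[2], dims[2], 1])
    for f in range(frames.n_frames):
        pos = np.mod(frames.coords[f, beads.indices, :], frames.box[f])
        idx = np.minimum((pos / spacing).astype(int), dims - 1)
        flat = np.unique(idx @ strides)
        hits.ravel()[flat] += 1
    occ = 100.0 * hits / frames.n_frames
    return OccupancyGrid(occ, np.zeros(3), spacing, frames.n_frames)


def export_isosurface(grid: OccupancyGrid, threshold: float = 0.5) -> IsoSurface:
    """Boolean mask and triangulated surface at an iso-occupancy level.

    The mask marks voxels with occupancy >= threshold and is monotonically
    non-increasing in the threshold.  The triangle mesh (marching cubes,
    vertex coordinates in nm) is empty when the level lies outside the
    grid's value range.
    """
    if not 0 < threshold < 100:
        raise ConfigError(f"isosurface threshold must lie in (0, 100), got {threshold}")
    mask = grid.occupancy >= threshold
    occ = grid.occupancy
    if occ.min() < threshold < occ.max() and all(s >= 2 for s in occ.shape):
        from skimage.measure import marching_cubes

        verts, faces, _, _ = marching_cubes(occ, level=threshold, spacing=tuple(grid.spacing))
        verts = verts + grid.origin
    else:
        verts = np.zeros((0, 3))
        faces = np.zeros((0, 3), dtype=int)
    return IsoSurface(mask, verts, faces, threshold)


def write_opendx(grid: OccupancyGrid, path) -> None:
    """Write the occupancy grid in OpenDX format (loadable in VMD/PyMOL)."""
    from gridData import Grid

    g = Grid(grid.occupancy, origin=grid.origin, delta=grid.spacing)
    g.export(str(path), file_format="dx")


def write_obj(surface: IsoSurface, path) -> None:
    """Write the isosurface triangle mesh as a Wavefront OBJ file."""
    with open(path, "w") as fh:
        for v in surface.vertices:
            fh.write(f"v {v[0]:.4f} {v[1]:.4f} {v[2]:.4f}\n")
        for f in surface.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


# ---------------------------------------------------------------------------
# Buried-residue depth
# ---------------------------------------------------------------------------

def residue_depth_trace(
    frames: FrameSeries,
    residue_beads: BeadSelection,
    refs: MembraneFrameRefs,
) -> DepthTrace:
    """z of a residue's side-chain bead(s) relative to the glycerol centre.

    Uses the centre of geometry when the residue has several side-chain
    beads.  Positive depths lie on the cytosolic (top) side.
    """
    if len(residue_beads) == 0:
        raise SelectionError("residue selection is empty")
    if refs.center_z_glycerol is None:
        raise ConfigError("refs.center_z_glycerol is required; run membrane_centers first")
    residue_beads.validate_against(frames)
    z = frames.coords[:, residue_beads.indices, 2].mean(axis=1)
    values = z - refs.center_z_glycerol
    return DepthTrace(values, frames.dt, float(values.mean()), float(values.std()))
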