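"""Trajectory data model, periodic-boundary geometry and frame fitting.

Everything downstream (contact kinetics, thinning maps, defect counts,
occupancy grids, residence and titration analysis) consumes the containers
defined here.  Internal units are nanometres and nanoseconds throughout;
coordinate files in Ångström (PDB) are converted on read.

Boxes are orthorhombic only: every system this package targets (Martini
bilayer patches with an embedded β-barrel) is built in a rectangular box,
and all minimum-image arithmetic below relies on that.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MemtrajError",
    "FormatError",
    "StructureError",
    "SelectionError",
    "ConfigError",
    "EmptyInputError",
    "DegenerateMembraneError",
    "NonIdentifiableError",
    "LEAFLET_TOP",
    "LEAFLET_BOTTOM",
    "ROLES",
    "FrameSeries",
    "BeadSelection",
    "AnalysisConfig",
    "MembraneFrameRefs",
    "read_frames",
    "write_frames_text",
    "read_role_map",
    "write_role_map",
    "selection_from_roles",
    "minimum_image_vectors",
    "minimum_image_distance",
    "assign_leaflets",
    "membrane_centers",
    "center_and_rotfit",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class MemtrajError(Exception):
    """Base class for all package errors."""


class FormatError(MemtrajError):
    """A file could not be parsed in the declared format."""


class StructureError(MemtrajError):
    """A trajectory violates a structural invariant (e.g. particle count)."""


class SelectionError(MemtrajError):
    """A bead selection is empty, overlapping or otherwise unusable."""


class ConfigError(MemtrajError):
    """An analysis parameter is out of its valid range."""


class EmptyInputError(MemtrajError):
    """An operation that needs at least one element received none."""


class DegenerateMembraneError(MemtrajError):
    """Leaflets cannot be told apart (e.g. all phosphates at one z)."""


class NonIdentifiableError(MemtrajError):
    """A fit has no information about its parameter (e.g. flat titration)."""


# Leaflet tags.  By convention the cytosolic leaflet is "top" (+z) and the
# intermembrane-space leaflet is "bottom" (-z).
LEAFLET_TOP = "top"
LEAFLET_BOTTOM = "bottom"

ROLES = frozenset(
    {"phosphate", "glycerol", "water", "protein", "proton", "titratable_site", "other"}
)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class FrameSeries:
    """Time-ordered particle coordinates with per-frame box lengths.

    Attributes
    ----------
    coords : ndarray, shape (n_frames, n_particles, 3)
        Positions in nm.
    box : ndarray, shape (n_frames, 3)
        Orthorhombic box edge lengths in nm, per frame.
    dt : float
        Time between stored frames in ns.
    origin_format : str
        Tag recording the source format ("gro", "pdb", "xtc", "trr",
        "text", "memory").
    """

    coords: np.ndarray
    box: np.ndarray
    dt: float
    origin_format: str = "memory"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError(
                f"coords must have shape (n_frames, n_particles, 3), got {self.coords.shape}"
            )
        if self.box.ndim == 1:
            self.box = np.tile(self.box, (self.coords.shape[0], 1))
        if self.box.shape != (self.coords.shape[0], 3):
            raise StructureError(
                f"box must have shape (n_frames, 3), got {self.box.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("coordinates contain non-finite values")
        if not np.all(self.box > 0):
            raise StructureError("all box lengths must be positive")
        if self.coords.shape[0] < 1:
            raise StructureError("a FrameSeries needs at least one frame")
        if self.dt <= 0:
            raise StructureError(f"dt must be positive, got {self.dt}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords.shape[1]

    @property
    def total_time(self) -> float:
        """Total simulated time covered by the stored frames (ns)."""
        return self.n_frames * self.dt

    def times(self) -> np.ndarray:
        """Frame times in ns (frame_index * dt; frames are 0-based)."""
        return np.arange(self.n_frames) * self.dt

    def copy(self) -> "FrameSeries":
        return FrameSeries(
            self.coords.copy(), self.box.copy(), self.dt, self.origin_format
        )


@dataclass
class BeadSelection:
    """An index set over particles with residue/bead labels and a role.

    ``labels`` holds one ``(residue_id, residue_name, bead_name)`` tuple per
    index.  The role is one of :data:`ROLES` and applies to every member.
    """

    indices: np.ndarray
    labels: list
    role: str

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.intp)
        if self.indices.ndim != 1:
            raise SelectionError("indices must be one-dimensional")
        if len(np.unique(self.indices)) != len(self.indices):
            raise SelectionError("selection indices must be unique")
        if np.any(self.indices < 0):
            raise SelectionError("selection indices must be non-negative")
        if len(self.labels) != len(self.indices):
            raise SelectionError(
                f"{len(self.labels)} labels for {len(self.indices)} indices"
            )
        if self.role not in ROLES:
            raise SelectionError(f"unknown role {self.role!r}; valid: {sorted(ROLES)}")

    def __len__(self) -> int:
        return len(self.indices)

    def validate_against(self, frames: FrameSeries) -> None:
        if len(self) and self.indices.max() >= frames.n_particles:
            raise SelectionError(
                f"selection index {int(self.indices.max())} out of range for "
                f"{frames.n_particles} particles"
            )

    def residue_ids(self) -> np.ndarray:
        return np.array([lab[0] for lab in self.labels], dtype=int)

    def residue_keys(self) -> list:
        """Human-readable residue keys like 'MET1', one per bead."""
        return [f"{lab[1]}{lab[0]}" for lab in self.labels]

    def subset(self, mask: np.ndarray) -> "BeadSelection":
        mask = np.asarray(mask, dtype=bool)
        return BeadSelection(
            self.indices[mask],
            [lab for lab, m in zip(self.labels, mask) if m],
            self.role,
        )


@dataclass
class AnalysisConfig:
    """All numeric analysis constants in one place.

    Defaults are the values used throughout the analyses this package
    implements: residue contacts at 0.6 nm; contact events with the 0.6/1.0
    nm double cutoff; desorption at 1.4 nm; lateral thinning bins of 0.1 nm
    masked below >30 observations; the water-defect cylinder of radius
    2.5 nm and half-height 1.5 nm; occupancy grids at 0.2 nm (2 Å) with a
    0.5% iso-surface threshold; and titration over pH 3–8 in half steps,
    analysed over the final 10 ns.
    """

    d_contact: float = 0.6          # nm, residue-contact cutoff
    d_event_outer: float = 1.0      # nm, outer event cutoff
    d_desorb: float = 1.4           # nm, desorption threshold
    bin_xy: float = 0.1             # nm, lateral thinning bin
    min_bin_count: int = 30         # bins kept only if count > this
    cyl_radius: float = 2.5         # nm, defect cylinder radius
    cyl_half_height: float = 1.5    # nm, defect cylinder half height
    grid_spacing: float = 0.2       # nm, occupancy voxel edge
    occupancy_threshold: float = 0.5  # %, iso-occupancy surface level
    titration_window: float = 10.0  # ns, analysis window at trace end
    pH_min: float = 3.0
    pH_max: float = 8.0
    pH_step: float = 0.5
    center_mode: str = "uniform"    # global-center weighting: uniform | mass

    def __post_init__(self) -> None:
        lengths = {
            "d_contact": self.d_contact,
            "d_event_outer": self.d_event_outer,
            "d_desorb": self.d_desorb,
            "bin_xy": self.bin_xy,
            "cyl_radius": self.cyl_radius,
            "cyl_half_height": self.cyl_half_height,
            "grid_spacing": self.grid_spacing,
            "titration_window": self.titration_window,
        }
        for name, value in lengths.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if self.d_contact >= self.d_event_outer:
            raise ConfigError(
                f"d_contact ({self.d_contact}) must be below d_event_outer "
                f"({self.d_event_outer})"
            )
        if not 0 < self.occupancy_threshold < 100:
            raise ConfigError(
                f"occupancy_threshold must lie in (0, 100), got {self.occupancy_threshold}"
            )

    def pH_grid(self) -> np.ndarray:
        n = int(round((self.pH_max - self.pH_min) / self.pH_step)) + 1
        return self.pH_min + self.pH_step * np.arange(n)


@dataclass
class MembraneFrameRefs:
    """Per-frame membrane reference quantities and the leaflet partition.

    ``center_z_glycerol`` is the mean of the two leaflet glycerol
    centres-of-geometry (the reference for buried-residue depth);
    ``center_z_global`` is the centre of all lipid beads (the reference for
    thinning maps and water defects).  ``leaflet_of_lipid`` maps each lipid
    residue_id to "top" or "bottom"; labels are assigned once at a
    reference frame and kept fixed (coarse-grained lipids do not flip-flop
    on the timescales analysed here).
    """

    leaflet_of_lipid: dict = field(default_factory=dict)
    center_z_glycerol: np.ndarray | None = None
    center_z_global: np.ndarray | None = None

    def lipids_in(self, leaflet: str) -> set:
        return {rid for rid, tag in self.leaflet_of_lipid.items() if tag == leaflet}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MDA_FORMATS = {"gro", "pdb", "xtc", "trr"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _MDA_FORMATS:
        return suffix
    if suffix in {"txt", "traj"}:
        return "text"
    raise FormatError(f"cannot infer trajectory format from {path.name!r}")


def read_frames(
    path: str | Path,
    format: str | None = None,
    dt_override: float | None = None,
    topology: str | Path | None = None,
) -> FrameSeries:
    """Read a trajectory into a :class:`FrameSeries` (coordinates in nm).

    Parameters
    ----------
    path : path
        Coordinate/trajectory file: GRO, PDB (single- or multi-model),
        XTC/TRR (requires ``topology``), or the plain-text fallback format
        (header ``nframes nparticles dt_ns box_x box_y box_z`` followed by
        one ``x y z`` line per particle per frame).
    format : str, optional
        Explicit format tag; inferred from the suffix when omitted.
    dt_override : float, optional
        Frame spacing in ns; overrides whatever the file declares.  The
        fallback when neither source provides a spacing is 0.5 ns, the
        granularity at which the target simulations store frames.
    topology : path, optional
        Topology file for binary trajectory formats.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = (format or _infer_format(path)).lower()
    if fmt == "text":
        return _read_text_frames(path, dt_override)
    if fmt not in _MDA_FORMATS:
        raise FormatError(f"unsupported format {fmt!r}")
    return _read_mda_frames(path, fmt, dt_override, topology)


def _read_mda_frames(
    path: Path, fmt: str, dt_override: float | None, topology: str | Path | None
) -> FrameSeries:
    import warnings

    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if fmt in {"xtc", "trr"}:
                if topology is None:
                    raise FormatError(f"{fmt} trajectories need a topology file")
                u = mda.Universe(str(topology), str(path))
            else:
                u = mda.Universe(str(path))
            coords = []
            boxes = []
            for ts in u.trajectory:
                if ts.dimensions is None or np.any(ts.dimensions[:3] <= 0):
                    raise FormatError(f"frame {ts.frame} of {path.name} has no box")
                angles = ts.dimensions[3:6]
                if not np.allclose(angles, 90.0, atol=1e-3):
                    raise StructureError(
                        f"frame {ts.frame}: box angles {angles} — only "
                        "orthorhombic boxes are supported"
                    )
                coords.append(ts.positions.copy())
                boxes.append(ts.dimensions[:3].copy())
            # MDAnalysis positions are Å; dt is ps.
            dt_ns = dt_override
            if dt_ns is None:
                file_dt = getattr(u.trajectory, "dt", None)
                dt_ns = file_dt / 1000.0 if file_dt else 0.5
    except MemtrajError:
        raise
    except Exception as exc:  # MDAnalysis raises a zoo of parser errors
        raise FormatError(f"could not parse {path.name} as {fmt}: {exc}") from exc
    arr = np.asarray(coords, dtype=float) / 10.0
    box = np.asarray(boxes, dtype=float) / 10.0
    return FrameSeries(arr, box, float(dt_ns), origin_format=fmt)


def _read_text_frames(path: Path, dt_override: float | None) -> FrameSeries:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 6:
            raise FormatError(
                f"{path.name} line 1: expected 'nframes nparticles dt_ns "
                f"box_x box_y box_z', got {len(header)} fields"
            )
        try:
            n_frames, n_particles = int(header[0]), int(header[1])
            dt = float(header[2])
            box = np.array([float(v) for v in header[3:6]])
        except ValueError as exc:
            raise FormatError(f"{path.name} line 1: {exc}") from exc
        values = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(
                    f"{path.name} line {lineno}: expected 3 coordinates, got {len(parts)}"
                )
            try:
                values.append([float(v) for v in parts])
            except ValueError as exc:
                raise FormatError(f"{path.name} line {lineno}: {exc}") from exc
    arr = np.asarray(values, dtype=float)
    if len(arr) != n_frames * n_particles:
        frame, rem = divmod(len(arr), n_particles)
        raise StructureError(
            f"{path.name}: header promises {n_frames} frames x {n_particles} "
            f"particles = {n_frames * n_particles} rows, found {len(arr)} "
            f"(frame {frame} is incomplete)" if rem else
            f"{path.name}: header promises {n_frames} frames, found {frame}"
        )
    coords = arr.reshape(n_frames, n_particles, 3)
    return FrameSeries(
        coords,
        np.tile(box, (n_frames, 1)),
        dt_override if dt_override is not None else dt,
        origin_format="text",
    )


def write_frames_text(frames: FrameSeries, path: str | Path) -> None:
    """Write the plain-text fallback trajectory format."""
    if not np.allclose(frames.box, frames.box[0], atol=1e-9):
        raise FormatError("the plain-text format stores a single box for all frames")
    path = Path(path)
    with open(path, "w") as fh:
        bx, by, bz = frames.box[0]
        fh.write(
            f"{frames.n_frames} {frames.n_particles} {frames.dt:.6f} "
            f"{bx:.6f} {by:.6f} {bz:.6f}\n"
        )
        flat = frames.coords.reshape(-1, 3)
        np.savetxt(fh, flat, fmt="%.6f")


def read_role_map(path: str | Path) -> pd.DataFrame:
    """Read a role-map CSV (columns: index,residue_id,residue_name,bead_name,role)."""
    df = pd.read_csv(path)
    required = {"index", "residue_id", "residue_name", "bead_name", "role"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"role map {path} lacks columns: {sorted(missing)}")
    bad = set(df["role"]) - ROLES
    if bad:
        raise FormatError(f"role map {path} has unknown roles: {sorted(bad)}")
    return df


def write_role_map(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def selection_from_roles(
    roles: pd.DataFrame,
    role: str,
    residue_ids: Iterable[int] | None = None,
    bead_names: Iterable[str] | None = None,
) -> BeadSelection:
    """Build a :class:`BeadSelection` from a role-map table.

    Optionally restrict to particular residues or bead names (e.g. the
    side-chain bead of one glutamate).
    """
    sub = roles[roles["role"] == role]
    if residue_ids is not None:
        sub = sub[sub["residue_id"].isin(set(residue_ids))]
    if bead_names is not None:
        sub = sub[sub["bead_name"].isin(set(bead_names))]
    if len(sub) == 0:
        raise SelectionError(f"no beads with role {role!r} match the filter")
    labels = list(
        zip(
            sub["residue_id"].astype(int),
            sub["residue_name"].astype(str),
            sub["bead_name"].astype(str),
        )
    )
    return BeadSelection(sub["index"].to_numpy(), labels, role)


# ---------------------------------------------------------------------------
# Periodic-boundary geometry
# ---------------------------------------------------------------------------

def minimum_image_vectors(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    ``delta`` may have any shape ending in 3; ``box`` broadcasts against it.
    """
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def minimum_image_distance(
    a: np.ndarray, b: np.ndarray, box: np.ndarray
) -> float | np.ndarray:
    """Minimum-image distance between points in an orthorhombic box (nm).

    Accepts single points or broadcastable arrays of points; the result is
    never larger than half the box diagonal.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b)) and np.all(np.isfinite(box))):
        raise ValueError("minimum_image_distance requires finite inputs")
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    d = np.linalg.norm(minimum_image_vectors(a - b, box), axis=-1)
    return float(d) if d.ndim == 0 else d


def pairwise_min_distance(
    frames: FrameSeries,
    sel_a: BeadSelection,
    sel_b: BeadSelection,
    chunk: int = 256,
) -> np.ndarray:
    """Per-frame minimum over all bead pairs of minimum-image distances."""
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise SelectionError("both selections must be non-empty")
    sel_a.validate_against(frames)
    sel_b.validate_against(frames)
    out = np.empty(frames.n_frames)
    for lo in range(0, frames.n_frames, chunk):
        hi = min(lo + chunk, frames.n_frames)
        ca = frames.coords[lo:hi][:, sel_a.indices]  # (F, Na, 3)
        cb = frames.coords[lo:hi][:, sel_b.indices]  # (F, Nb, 3)
        delta = ca[:, :, None, :] - cb[:, None, :, :]
        delta = minimum_image_vectors(delta, frames.box[lo:hi, None, None, :])
        d = np.sqrt(np.sum(delta * delta, axis=-1))
        out[lo:hi] = d.min(axis=(1, 2))
    return out


# ---------------------------------------------------------------------------
# Leaflets and membrane centres
# ---------------------------------------------------------------------------

def assign_leaflets(
    frames: FrameSeries,
    phosphates: BeadSelection,
    reference_frame: int = 0,
) -> MembraneFrameRefs:
    """Partition lipids into leaflets by phosphate z at a reference frame.

    A lipid goes to the top (cytosolic) leaflet when its phosphate sits
    above the median phosphate z at ``reference_frame``, else to the bottom
    (IMS) leaflet.  Labels are fixed for the whole trajectory.
    """
    if len(phosphates) < 2:
        raise SelectionError("leaflet assignment needs at least two phosphates")
    phosphates.validate_against(frames)
    if not 0 <= reference_frame < frames.n_frames:
        raise IndexError(
            f"reference frame {reference_frame} out of range [0, {frames.n_frames})"
        )
    z = frames.coords[reference_frame, phosphates.indices, 2]
    if np.ptp(z) < 1e-9:
        raise DegenerateMembraneError(
            "all phosphates share one z position; cannot split leaflets"
        )
    median = np.median(z)
    refs = MembraneFrameRefs()
    for lab, zi in zip(phosphates.labels, z):
        refs.leaflet_of_lipid[int(lab[0])] = LEAFLET_TOP if zi > median else LEAFLET_BOTTOM
    tags = set(refs.leaflet_of_lipid.values())
    if len(tags) != 2:
        raise DegenerateMembraneError("leaflet split produced a single leaflet")
    return refs


def membrane_centers(
    frames: FrameSeries,
    glycerols: BeadSelection,
    all_lipid_beads: BeadSelection,
    leaflets: MembraneFrameRefs,
    center_mode: str = "uniform",
    masses: np.ndarray | None = None,
) -> MembraneFrameRefs:
    """Compute both per-frame membrane-centre definitions.

    ``center_z_glycerol`` — mean of the two leaflet glycerol
    centres-of-geometry (used for buried-residue depth).
    ``center_z_global`` — centre of all lipid beads, uniform bead weights by
    default (used for thinning maps and water defects); pass
    ``center_mode="mass"`` with per-bead ``masses`` to weight by mass.
    """
    if len(glycerols) == 0:
        raise SelectionError("glycerol selection is empty")
    glycerols.validate_against(frames)
    all_lipid_beads.validate_against(frames)
    rid_g = glycerols.residue_ids()
    top = np.array([leaflets.leaflet_of_lipid.get(r) == LEAFLET_TOP for r in rid_g])
    bottom = np.array(
        [leaflets.leaflet_of_lipid.get(r) == LEAFLET_BOTTOM for r in rid_g]
    )
    if not top.any() or not bottom.any():
        raise SelectionError("both leaflets need at least one glycerol bead")
    zg = frames.coords[:, glycerols.indices, 2]
    cog_top = zg[:, top].mean(axis=1)
    cog_bottom = zg[:, bottom].mean(axis=1)
    center_gly = 0.5 * (cog_top + cog_bottom)

    zl = frames.coords[:, all_lipid_beads.indices, 2]
    if center_mode == "uniform":
        center_global = zl.mean(axis=1)
    elif center_mode == "mass":
        if masses is None or len(masses) != len(all_lipid_beads):
            raise ConfigError("center_mode='mass' needs one mass per lipid bead")
        w = np.asarray(masses, dtype=float)
        center_global = (zl * w).sum(axis=1) / w.sum()
    else:
        raise ConfigError(f"unknown center_mode {center_mode!r}")
    return MembraneFrameRefs(
        leaflet_of_lipid=dict(leaflets.leaflet_of_lipid),
        center_z_glycerol=center_gly,
        center_z_global=center_global,
    )


# ---------------------------------------------------------------------------
# Centering and rotational fitting
# ---------------------------------------------------------------------------

def _optimal_z_angle(p_xy: np.ndarray, ref_xy: np.ndarray) -> float:
    """Angle about z that minimises xy-RMSD of centred coords to centred ref.

    Closed form of the 2-D orthogonal Procrustes problem: rotating ``p`` by
    theta maximises ``sum ref . R(theta) p``, giving
    ``theta = atan2(sum(ref_y p_x - ref_x p_y), sum(ref_x p_x + ref_y p_y))``.
    """
    a = float(np.sum(ref_xy[:, 0] * p_xy[:, 0] + ref_xy[:, 1] * p_xy[:, 1]))
    b = float(np.sum(ref_xy[:, 1] * p_xy[:, 0] - ref_xy[:, 0] * p_xy[:, 1]))
    return float(np.arctan2(b, a))


def _rotate_z(coords: np.ndarray, angle: float, pivot_xy: np.ndarray) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    out = coords.copy()
    x = coords[..., 0] - pivot_xy[0]
    y = coords[..., 1] - pivot_xy[1]
    out[..., 0] = c * x - s * y + pivot_xy[0]
    out[..., 1] = s * x + c * y + pivot_xy[1]
    return out


def center_and_rotfit(
    frames: FrameSeries,
    protein: BeadSelection,
    reference_coords: np.ndarray,
) -> tuple[FrameSeries, np.ndarray]:
    """Centre the protein in xy and rotationally fit about the z axis only.

    Each frame is translated so the protein's xy geometric centre sits at
    the box xy-centre, then the whole frame is rotated about z by the angle
    that minimises the xy-RMSD of the protein beads to ``reference_coords``
    (same bead count and order; its own xy centroid is removed before
    fitting, and only x/y enter the fit).  All particles are transformed
    together; z is untouched.  Returns the fitted frames and the per-frame
    rotation angle in radians.
    """
    if len(protein) < 3:
        raise SelectionError("rotational fitting needs at least three protein beads")
    protein.validate_against(frames)
    ref = np.asarray(reference_coords, dtype=float)
    if ref.shape[0] != len(protein):
        raise SelectionError(
            f"reference has {ref.shape[0]} beads, selection has {len(protein)}"
        )
    ref_xy = ref[:, :2] - ref[:, :2].mean(axis=0)
    coords = frames.coords.copy()
    angles = np.empty(frames.n_frames)
    for f in range(frames.n_frames):
        box_center = frames.box[f, :2] / 2.0
        p = coords[f, protein.indices]
        shift = box_center - p[:, :2].mean(axis=0)
        coords[f, :, 0] += shift[0]
        coords[f, :, 1] += shift[1]
        p_xy = coords[f, protein.indices, :2] - box_center
        angle = _optimal_z_angle(p_xy, ref_xy)
        coords[f] = _rotate_z(coords[f], angle, box_center)
        angles[f] = angle
    fitted = FrameSeries(coords, frames.box.copy(), frames.dt, frames.origin_format)
    return fitted, angles


def xy_rmsd(
    frames: FrameSeries, protein: BeadSelection, reference_coords: np.ndarray
) -> np.ndarray:
    """Per-frame xy-RMSD of centred protein beads to the centred reference."""
    ref_xy = np.asarray(reference_coords, dtype=float)[:, :2]
    ref_xy = ref_xy - ref_xy.mean(axis=0)
    out = np.empty(frames.n_frames)
    for f in range(frames.n_frames):
        p_xy = frames.coords[f, protein.indices, :2]
        p_xy = p_xy - p_xy.mean(axis=0)
        out[f] = np.sqrt(np.mean(np.sum((p_xy - ref_xy) ** 2, axis=1)))
    return out
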