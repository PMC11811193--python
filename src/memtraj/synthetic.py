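"""Synthetic coarse-grained trajectory generator with analytic ground truth.

Every analysis stage in this package is exercised against data from this
module: bilayers with a controlled local "funnel" thinning, water beads
with a controlled defect column, a rigid β-barrel stand-in with one buried
anionic side chain, two-state contact traces with prescribed on/off
kinetics, exponential desorption traces, and Bernoulli proton-binding
series following a Henderson–Hasselbalch law.  Generators emit
geometry-level realism only (bead positions and roles, not physics) —
sufficient because every analysis consumes geometry.

Each generator returns a machine-readable ground-truth record, and all
randomness flows from the single spec seed: identical specs yield
identical output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (
    ConfigError,
    FrameSeries,
    LEAFLET_BOTTOM,
    LEAFLET_TOP,
)
from .contacts import ContactEvent, DistanceTrace
from .titration import TitrationSeries, henderson_hasselbalch

__all__ = [
    "BilayerSpec",
    "FunnelSpec",
    "ProteinSpec",
    "WaterSpec",
    "KineticsSpec",
    "DesorptionSpec",
    "TitrationSpec",
    "SyntheticSpec",
    "make_bilayer",
    "make_protein_wall",
    "make_waters",
    "make_contact_trace",
    "make_desorption_trace",
    "make_titration_series",
    "make_membrane_system",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class FunnelSpec:
    """A local thinning funnel: phosphates move toward the membrane centre
    by depth * exp(-r^2 / (2 width^2)) around (x, y)."""

    x: float
    y: float
    depth: float = 1.20     # nm
    width: float = 0.8      # nm (Gaussian sigma)
    leaflet: str = LEAFLET_TOP


@dataclass
class BilayerSpec:
    """Bilayer patch: 386 lipids (193 per leaflet) with phosphate planes at
    ±1.95 nm, matching a pure-POPC coarse-grained patch."""

    lipids_per_leaflet: int = 193
    h: float = 1.95             # nm, leaflet phosphate plane
    z_jitter: float = 0.08      # nm, per-frame Gaussian z noise
    diffusion_step: float = 0.1  # nm, lateral random-walk step per frame
    glycerol_offset: float = 0.45  # nm, glycerol below phosphate, toward centre


@dataclass
class ProteinSpec:
    """Rigid barrel wall spanning the membrane with one buried anionic bead."""

    radius: float = 1.7        # nm
    beads_per_ring: int = 24
    n_rings: int = 9
    glu_depth: float = 0.4     # nm, signed z of the Glu side-chain bead


@dataclass
class WaterSpec:
    """Bulk water excluded from |z - centre| < h, plus a defect column.

    The column (radius/half-height below) receives an expected
    ``bulk_density * enrichment * column volume`` beads per frame; with
    enrichment 0 no water ever enters the membrane slab.
    """

    bulk_density: float = 1.0   # beads / nm^3 in the aqueous slabs
    enrichment: float = 1.0
    column_radius: float = 0.5  # nm
    column_half_height: float = 1.4  # nm, keep below bilayer h


@dataclass
class KineticsSpec:
    """Two-state (bound/unbound) telegraph kinetics for contact traces."""

    k_on: float = 0.02      # per ns
    k_off: float = 0.01     # per ns
    excursion_prob: float = 0.0  # near-cutoff excursions to exercise the double cutoff


@dataclass
class DesorptionSpec:
    """Membrane-bound distance trace with exponential desorption."""

    mean_residence: float = 350.0  # ns
    baseline: float = 0.3          # nm, bound-state distance
    jitter: float = 0.05           # nm
    rise_slope: float = 11.0       # nm/ns after desorption


@dataclass
class TitrationSpec:
    """Bernoulli proton-binding series on a pH grid."""

    pka: float = 4.8
    hill: float = 1.0
    n_replicates: int = 3
    total_frames: int = 2000
    window_frames: int = 1000
    dt: float = 0.01               # ns -> 1000 frames = the last 10 ns
    pH_min: float = 3.0
    pH_max: float = 8.0
    pH_step: float = 0.5


@dataclass
class SyntheticSpec:
    """Top-level spec; sub-specs default to the study conditions."""

    seed: int = 0
    n_frames: int = 200
    dt: float = 0.5                # ns, the saved-frame granularity
    box: tuple = (11.0, 11.0, 10.0)
    bilayer: BilayerSpec = field(default_factory=BilayerSpec)
    funnels: list = field(default_factory=list)
    protein: ProteinSpec = field(default_factory=ProteinSpec)
    waters: WaterSpec = field(default_factory=WaterSpec)
    kinetics: KineticsSpec = field(default_factory=KineticsSpec)
    desorption: DesorptionSpec = field(default_factory=DesorptionSpec)
    titration: TitrationSpec = field(default_factory=TitrationSpec)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible RNG stream per generator."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])


def _roles_frame(rows: list) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["index", "residue_id", "residue_name", "bead_name", "role"]
    )


# ---------------------------------------------------------------------------
# Bilayer
# ---------------------------------------------------------------------------

def make_bilayer(spec: SyntheticSpec) -> tuple[FrameSeries, pd.DataFrame, dict]:
    """Bilayer frames (phosphate + glycerol beads) with analytic truth.

    Lipids start uniformly in xy and perform a periodic lateral random
    walk; phosphate z is the leaflet plane ± Gaussian jitter, displaced
    toward the membrane centre inside funnels by
    ``depth * exp(-r^2 / 2 width^2)`` (evaluated at the lipid's current
    lateral position, so the thinning field is stationary in space).
    Glycerols ride ``glycerol_offset`` below their phosphate.  The bead
    order is lipid-major: PO4 then GL1 for lipid 1, 2, ...

    The ground-truth record stores each lipid's leaflet, the leaflet plane,
    and the analytic map minimum ``h - depth`` per funnel.
    """
    b = spec.bilayer
    for fn in spec.funnels:
        if fn.depth >= b.h:
            raise ConfigError(
                f"funnel depth {fn.depth} must be below the leaflet plane {b.h}"
            )
    rng = spec.rng(1)
    box = np.asarray(spec.box, dtype=float)
    zc = box[2] / 2.0
    n_per = b.lipids_per_leaflet
    n_lip = 2 * n_per
    F = spec.n_frames

    # lateral positions: uniform start, periodic Gaussian random walk
    xy0 = rng.uniform(0, box[:2], size=(n_lip, 2))
    steps = rng.normal(0, b.diffusion_step, size=(F, n_lip, 2))
    steps[0] = 0.0
    xy = np.mod(xy0[None] + np.cumsum(steps, axis=0), box[:2])

    sign = np.concatenate([np.ones(n_per), -np.ones(n_per)])  # top first
    jitter = rng.normal(0, b.z_jitter, size=(F, n_lip))
    z_phos = zc + sign[None] * (b.h + 0.0) + jitter

    for fn in spec.funnels:
        s = 1.0 if fn.leaflet == LEAFLET_TOP else -1.0
        mask = sign == s
        d = xy[:, mask, :] - np.array([fn.x, fn.y])
        d -= box[:2] * np.round(d / box[:2])
        r2 = np.sum(d * d, axis=-1)
        disp = fn.depth * np.exp(-r2 / (2.0 * fn.width**2))
        z_phos[:, mask] -= s * disp  # toward the centre

    z_gly = z_phos - sign[None] * b.glycerol_offset

    coords = np.empty((F, 2 * n_lip, 3))
    coords[:, 0::2, :2] = xy
    coords[:, 1::2, :2] = xy
    coords[:, 0::2, 2] = z_phos
    coords[:, 1::2, 2] = z_gly

    rows = []
    leaflet_of_lipid = {}
    for i in range(n_lip):
        rid = i + 1
        tag = LEAFLET_TOP if sign[i] > 0 else LEAFLET_BOTTOM
        leaflet_of_lipid[rid] = tag
        rows.append((2 * i, rid, "POPC", "PO4", "phosphate"))
        rows.append((2 * i + 1, rid, "POPC", "GL1", "glycerol"))

    frames = FrameSeries(coords, np.tile(box, (F, 1)), spec.dt)
    truth = {
        "leaflet_of_lipid": leaflet_of_lipid,
        "plane": b.h,
        "z_jitter": b.z_jitter,
        "center_z": zc,
        "funnels": [
            {**asdict(fn), "analytic_min": b.h - fn.depth} for fn in spec.funnels
        ],
    }
    return frames, _roles_frame(rows), truth


# ---------------------------------------------------------------------------
# Protein wall
# ---------------------------------------------------------------------------

def make_protein_wall(
    spec: SyntheticSpec, frames: FrameSeries, roles: pd.DataFrame
) -> tuple[FrameSeries, pd.DataFrame, dict]:
    """Append a rigid barrel-wall bead set spanning the membrane.

    Rings of backbone beads sit on a cylinder at the box xy-centre between
    the two leaflet planes; one extra side-chain bead (residue GLU, role
    titratable_site) sits on the wall at signed depth ``glu_depth`` from
    the membrane centre, standing in for the bilayer-facing glutamate.
    """
    p = spec.protein
    box = frames.box[0]
    if p.radius >= min(box[:2]) / 2:
        raise ConfigError("barrel radius must be below half the box")
    zc = box[2] / 2.0
    h = spec.bilayer.h
    theta = 2 * np.pi * np.arange(p.beads_per_ring) / p.beads_per_ring
    ring_z = np.linspace(-h, h, p.n_rings)
    wall = np.array(
        [
            [box[0] / 2 + p.radius * np.cos(t), box[1] / 2 + p.radius * np.sin(t), zc + z]
            for z in ring_z
            for t in theta
        ]
    )
    glu = np.array([[box[0] / 2 + p.radius, box[1] / 2, zc + p.glu_depth]])
    beads = np.vstack([wall, glu])
    n_new = len(beads)
    coords = np.concatenate(
        [frames.coords, np.tile(beads, (frames.n_frames, 1, 1))], axis=1
    )
    base = frames.n_particles
    next_rid = int(roles["residue_id"].max()) + 1 if len(roles) else 1
    rows = [(base + i, next_rid, "BAR", f"BB{i}", "protein") for i in range(len(wall))]
    rows.append((base + len(wall), next_rid + 1, "GLU", "SC1", "titratable_site"))
    roles2 = pd.concat([roles, _roles_frame(rows)], ignore_index=True)
    out = FrameSeries(coords, frames.box.copy(), frames.dt)
    truth = {
        "wall_residue_id": next_rid,
        "glu_residue_id": next_rid + 1,
        "glu_depth": p.glu_depth,
        "radius": p.radius,
        "center_xy": [box[0] / 2, box[1] / 2],
    }
    return out, roles2, truth


# ---------------------------------------------------------------------------
# Waters
# ---------------------------------------------------------------------------

def make_waters(
    spec: SyntheticSpec, frames: FrameSeries, roles: pd.DataFrame
) -> tuple[FrameSeries, pd.DataFrame, dict]:
    """Append water beads: aqueous slabs plus an optional defect column.

    Bulk waters are uniform in the two slabs |z - centre| > h and never
    enter the membrane.  Column waters live on a fixed set of bead slots;
    each slot is independently placed inside the defect column (uniform,
    |z - centre| < column_half_height) with probability lambda/n_slots per
    frame and parked in the bulk otherwise, so the in-column count is
    Binomial with the analytic mean

        lambda = bulk_density * enrichment * pi * r^2 * 2 * half_height.
    """
    w = spec.waters
    box = frames.box[0]
    zc = box[2] / 2.0
    h = spec.bilayer.h
    if w.column_half_height >= h:
        raise ConfigError("defect column must stay inside the membrane slab")
    rng = spec.rng(2)
    F = frames.n_frames

    slab = box[2] / 2.0 - h          # thickness of each aqueous slab
    if slab <= 0:
        raise ConfigError("box too short for aqueous slabs above/below the membrane")
    v_bulk = box[0] * box[1] * 2 * slab
    n_bulk = max(1, int(round(w.bulk_density * v_bulk)))

    v_col = np.pi * w.column_radius**2 * 2 * w.column_half_height
    lam = w.bulk_density * w.enrichment * v_col
    n_slots = int(np.ceil(4 * lam)) + 8 if lam > 0 else 0
    col_xy = box[:2] / 2.0

    def bulk_positions(rng, n):
        pos = np.empty((n, 3))
        pos[:, 0] = rng.uniform(0, box[0], n)
        pos[:, 1] = rng.uniform(0, box[1], n)
        u = rng.uniform(-slab, slab, n)
        pos[:, 2] = np.where(u < 0, zc - h + u, zc + h + u)
        return pos

    n_wat = n_bulk + n_slots
    wat = np.empty((F, n_wat, 3))
    for f in range(F):
        wat[f, :n_bulk] = bulk_positions(rng, n_bulk)
        if n_slots:
            in_col = rng.random(n_slots) < lam / n_slots
            k = int(in_col.sum())
            pos = bulk_positions(rng, n_slots)
            if k:
                r = w.column_radius * np.sqrt(rng.random(k))
                t = rng.uniform(0, 2 * np.pi, k)
                pos[in_col, 0] = col_xy[0] + r * np.cos(t)
                pos[in_col, 1] = col_xy[1] + r * np.sin(t)
                pos[in_col, 2] = zc + rng.uniform(
                    -w.column_half_height, w.column_half_height, k
                )
            wat[f, n_bulk:] = pos

    coords = np.concatenate([frames.coords, wat], axis=1)
    base = frames.n_particles
    next_rid = int(roles["residue_id"].max()) + 1 if len(roles) else 1
    rows = [(base + i, next_rid + i, "W", "W", "water") for i in range(n_wat)]
    roles2 = pd.concat([roles, _roles_frame(rows)], ignore_index=True)
    out = FrameSeries(coords, frames.box.copy(), frames.dt)
    truth = {
        "n_bulk": n_bulk,
        "n_column_slots": n_slots,
        "expected_in_column": lam,
        "column_radius": w.column_radius,
        "column_half_height": w.column_half_height,
        "column_xy": list(col_xy),
    }
    return out, roles2, truth


def make_membrane_system(
    spec: SyntheticSpec,
    with_protein: bool = True,
    with_waters: bool = True,
) -> tuple[FrameSeries, pd.DataFrame, dict]:
    """Bilayer plus optional protein wall and waters, with merged truth."""
    frames, roles, truth = make_bilayer(spec)
    truth = {"bilayer": truth}
    if with_protein:
        frames, roles, t = make_protein_wall(spec, frames, roles)
        truth["protein"] = t
    if with_waters:
        frames, roles, t = make_waters(spec, frames, roles)
        truth["waters"] = t
    return frames, roles, truth


# ---------------------------------------------------------------------------
# Contact kinetics
# ---------------------------------------------------------------------------

def make_contact_trace(
    spec: SyntheticSpec, stream: int = 3
) -> tuple[DistanceTrace, list, dict]:
    """Two-state telegraph distance trace with recorded true events.

    Per-frame switch probabilities are p = 1 - exp(-k dt).  Bound frames
    emit distances Uniform(0.2, 0.55) nm, unbound frames
    Uniform(1.3, 3.0) nm.  With ``excursion_prob`` > 0, interior bound
    frames (never the first of a run) may rise into (0.6, 1.0) nm and
    isolated unbound frames (both neighbours unbound) may dip into
    (0.6, 1.0) nm — exercising the double-cutoff rule without changing
    which events a correct detector finds.
    """
    k = spec.kinetics
    rng = spec.rng(stream)
    F = spec.n_frames
    dt = spec.dt
    p_on = 1.0 - np.exp(-k.k_on * dt)
    p_off = 1.0 - np.exp(-k.k_off * dt)
    pi_bound = p_on / (p_on + p_off)

    u = rng.random(F)
    states = np.empty(F, dtype=bool)
    states[0] = u[0] < pi_bound
    for i in range(1, F):
        states[i] = (not states[i - 1] and u[i] < p_on) or (
            states[i - 1] and u[i] >= p_off
        )

    values = np.where(
        states, rng.uniform(0.2, 0.55, F), rng.uniform(1.3, 3.0, F)
    )
    if k.excursion_prob > 0:
        exc = rng.random(F) < k.excursion_prob
        prev_bound = np.concatenate([[False], states[:-1]])
        next_bound = np.concatenate([states[1:], [False]])
        bound_interior = states & prev_bound  # never the first frame of a run
        unbound_isolated = ~states & ~prev_bound & ~next_bound
        lift = exc & (bound_interior | unbound_isolated)
        values[lift] = rng.uniform(0.6, 1.0, int(lift.sum()))

    trace = DistanceTrace(values, dt, "MET1", "GLU73")
    events = []
    padded = np.concatenate([[False], states, [False]])
    diff = np.diff(padded.astype(np.int8))
    for s, e in zip(np.nonzero(diff == 1)[0], np.nonzero(diff == -1)[0] - 1):
        events.append(ContactEvent(int(s), int(e), dt, s == 0 or e == F - 1))
    truth = {
        "stationary_bound": float(pi_bound),
        "mean_event_duration": dt / p_off,
        "k_on": k.k_on,
        "k_off": k.k_off,
        "bound_frames": int(states.sum()),
    }
    return trace, events, truth


# ---------------------------------------------------------------------------
# Desorption
# ---------------------------------------------------------------------------

def make_desorption_trace(
    spec: SyntheticSpec, stream: int = 4
) -> tuple[DistanceTrace, dict]:
    """Membrane-distance trace with an exponential desorption time.

    The trace jitters around the bound baseline (clipped below 1.3 nm so
    it can never cross early), then rises linearly past the 1.4 nm
    threshold after the drawn desorption time.  The truth records the
    drawn time and the analytic first-exceedance frame.
    """
    d = spec.desorption
    rng = spec.rng(stream)
    F, dt = spec.n_frames, spec.dt
    tau = float(rng.exponential(d.mean_residence))
    t = np.arange(F) * dt
    values = np.clip(d.baseline + rng.normal(0, d.jitter, F), 0.05, 1.3)
    rising = t >= tau
    values[rising] = d.baseline + d.rise_slope * (t[rising] - tau)
    values = np.clip(values, 0.0, 5.0)

    crossing_time = tau + (1.4 - d.baseline) / d.rise_slope
    first_frame = int(np.floor(crossing_time / dt)) + 1
    censored = first_frame > F - 1
    truth = {
        "tau": tau,
        "analytic_first_exceed_frame": None if censored else first_frame,
        "analytic_residence": (F * dt) if censored else first_frame * dt,
        "censored": censored,
        "mean_residence": d.mean_residence,
    }
    return DistanceTrace(values, dt, "HKI-N", "membrane"), truth


# ---------------------------------------------------------------------------
# Titration
# ---------------------------------------------------------------------------

def make_titration_series(
    spec: SyntheticSpec, stream: int = 5
) -> tuple[TitrationSeries, dict]:
    """Bernoulli proton-binding series on the pH grid.

    At each pH the per-frame bound indicator is Bernoulli with
    P(bound) = 1 - f(pH), f the Henderson–Hasselbalch curve at the true
    pKa; three independent replicate sets by default, total_frames frames
    each, of which the final window_frames form the analysis window.
    """
    ts = spec.titration
    rng = spec.rng(stream)
    n_pH = int(round((ts.pH_max - ts.pH_min) / ts.pH_step)) + 1
    grid = ts.pH_min + ts.pH_step * np.arange(n_pH)
    f = henderson_hasselbalch(grid, ts.pka, ts.hill)

    blocks = []
    times = (np.arange(ts.total_frames) + 1) * ts.dt
    for i, pH in enumerate(grid):
        for rep in range(ts.n_replicates):
            bound = (rng.random(ts.total_frames) >= f[i]).astype(int)
            blocks.append(
                pd.DataFrame(
                    {
                        "pH": pH,
                        "replicate": rep,
                        "frame_time_ns": times,
                        "bound_protons": bound,
                    }
                )
            )
    data = pd.concat(blocks, ignore_index=True)
    series = TitrationSeries(data, dt=ts.dt, window=ts.window_frames * ts.dt)
    truth = {
        "pka": ts.pka,
        "hill": ts.hill,
        "pH_grid": list(grid),
        "true_fractions": list(f),
        "n_replicates": ts.n_replicates,
        "window_frames": ts.window_frames,
    }
    return series, truth
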