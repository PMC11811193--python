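"""Residue contact prevalence, double-cutoff event kinetics and lifetimes.

The kinetic primitive here is the double-cutoff contact event: a maximal
run of frames in which an inter-residue minimum distance stays inside an
outer cutoff (1.0 nm) and dips below an inner cutoff (0.6 nm) at least
once.  The outer cutoff suppresses the spurious binding/unbinding frames a
single cutoff would count whenever the distance fluctuates around it, so
long binding events survive intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    BeadSelection,
    ConfigError,
    EmptyInputError,
    FrameSeries,
    SelectionError,
    minimum_image_vectors,
    pairwise_min_distance,
)

__all__ = [
    "DistanceTrace",
    "ContactEvent",
    "LifetimeHistogram",
    "min_distance_trace",
    "residue_contact_fraction",
    "detect_contact_events",
    "lifetime_histogram",
    "weighted_mean_lifetime",
    "replicate_stats",
]


@dataclass
class DistanceTrace:
    """Per-frame minimum distance between two bead groups (nm)."""

    values: np.ndarray
    dt: float
    group_a: str = "A"
    group_b: str = "B"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("a DistanceTrace is one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("distances cannot be negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def total_time(self) -> float:
        return self.n_frames * self.dt


@dataclass
class ContactEvent:
    """One binding interval, frame indices inclusive on both ends."""

    start_frame: int
    end_frame: int
    dt: float
    truncated: bool = False  # event touches the start/end of the trace

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError("event start after end")

    @property
    def duration(self) -> float:
        return (self.end_frame - self.start_frame + 1) * self.dt


@dataclass
class LifetimeHistogram:
    """Log-binned, duration-weighted contact-lifetime distribution.

    ``mass`` holds the summed event duration per bin; ``normalized`` is the
    per-bin mass divided by the total simulated time, so bars report which
    fraction of the whole simulation was spent in events of a given
    lifetime decade.
    """

    edges: np.ndarray        # ns, len n_bins + 1, strictly increasing
    mass: np.ndarray         # ns per bin
    normalized: np.ndarray   # mass / total simulated time
    total_time: float        # ns
    mean_lifetime: float     # ns, duration-weighted
    sem_lifetime: float      # ns, weighted SEM (0 with sem_defined=False for 1 event)
    sem_defined: bool
    n_events: int


def min_distance_trace(
    frames: FrameSeries,
    group_a: BeadSelection,
    group_b: BeadSelection,
    allow_overlap: bool = False,
) -> DistanceTrace:
    """Per-frame minimum-image minimum distance over all bead pairs."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise SelectionError("both groups must be non-empty")
    if not allow_overlap and np.intersect1d(group_a.indices, group_b.indices).size:
        raise SelectionError("groups overlap; a trace of a group against itself is undefined")
    values = pairwise_min_distance(frames, group_a, group_b)
    name_a = group_a.residue_keys()[0] if group_a.labels else "A"
    name_b = group_b.residue_keys()[0] if group_b.labels else "B"
    return DistanceTrace(values, frames.dt, name_a, name_b)


def residue_contact_fraction(
    frames: FrameSeries,
    group_a: BeadSelection,
    group_b: BeadSelection,
    cutoff: float = 0.6,
    chunk: int = 128,
) -> pd.DataFrame:
    """Fraction of frames each residue pair has any bead pair within cutoff.

    Residues are in contact in a frame when any of their beads (backbone or
    side chain alike) are closer than ``cutoff`` under the minimum-image
    convention.  Returns one row per residue pair with columns
    ``residue_a``, ``residue_b``, ``fraction``.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise SelectionError("both groups must be non-empty")
    if np.intersect1d(group_a.indices, group_b.indices).size:
        raise SelectionError("contact groups must be disjoint")
    group_a.validate_against(frames)
    group_b.validate_against(frames)

    keys_a = group_a.residue_keys()
    keys_b = group_b.residue_keys()
    res_a, inv_a = np.unique(keys_a, return_inverse=True)
    res_b, inv_b = np.unique(keys_b, return_inverse=True)
    counts = np.zeros((len(res_a), len(res_b)), dtype=np.int64)

    for lo in range(0, frames.n_frames, chunk):
        hi = min(lo + chunk, frames.n_frames)
        ca = frames.coords[lo:hi][:, group_a.indices]
        cb = frames.coords[lo:hi][:, group_b.indices]
        delta = ca[:, :, None, :] - cb[:, None, :, :]
        delta = minimum_image_vectors(delta, frames.box[lo:hi, None, None, :])
        close = np.sum(delta * delta, axis=-1) < cutoff**2  # (F, Na, Nb)
        for f in range(close.shape[0]):
            ia, ib = np.nonzero(close[f])
            if ia.size:
                pairs = np.unique(np.stack([inv_a[ia], inv_b[ib]], axis=1), axis=0)
                counts[pairs[:, 0], pairs[:, 1]] += 1

    rows = []
    for i, ra in enumerate(res_a):
        for j, rb in enumerate(res_b):
            rows.append((ra, rb, counts[i, j] / frames.n_frames))
    return pd.DataFrame(rows, columns=["residue_a", "residue_b", "fraction"])


def detect_contact_events(
    trace: DistanceTrace, inner: float = 0.6, outer: float = 1.0
) -> list[ContactEvent]:
    """Detect double-cutoff contact events in a distance trace.

    A candidate is a maximal run of consecutive frames with distance below
    ``outer``; it becomes an event iff the distance drops below ``inner``
    at some frame of the run.  Events are disjoint and time-ordered;
    events cut off by the trace boundaries are flagged ``truncated``.
    """
    if inner >= outer:
        raise ConfigError(f"inner cutoff ({inner}) must be below outer ({outer})")
    v = trace.values
    inside = v < outer
    events: list[ContactEvent] = []
    # run boundaries of the `inside` mask
    padded = np.concatenate([[False], inside, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0] - 1
    for s, e in zip(starts, ends):
        if v[s : e + 1].min() < inner:
            truncated = s == 0 or e == len(v) - 1
            events.append(ContactEvent(int(s), int(e), trace.dt, truncated))
    return events


def default_log_edges(dt: float, total_time: float, per_decade: int = 5) -> np.ndarray:
    """Logarithmic bin edges from one frame spacing to the trace length."""
    if total_time <= dt:
        return np.array([dt, dt * 10.0])
    n = int(np.ceil(per_decade * np.log10(total_time / dt)))
    edges = dt * 10.0 ** (np.arange(n + 1) / per_decade)
    edges[-1] = max(edges[-1], total_time * (1 + 1e-12))
    return edges


def lifetime_histogram(
    events: list[ContactEvent],
    total_time: float,
    edges: np.ndarray | None = None,
) -> LifetimeHistogram:
    """Histogram event durations into log bins, weighted by duration.

    Each event contributes its duration (not a unit count) to the bin its
    duration falls in (half-open ``[lo, hi)``), and bin values are
    normalised by the total simulated time.
    """
    durations = np.array([ev.duration for ev in events])
    if durations.size and total_time < durations.sum() - 1e-9:
        raise ValueError(
            f"total_time ({total_time}) is below the summed event time "
            f"({durations.sum()})"
        )
    if edges is None:
        dt = events[0].dt if events else 1.0
        edges = default_log_edges(dt, max(total_time, dt * 10))
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    mass = np.zeros(len(edges) - 1)
    for ev, d in zip(events, durations):
        if d < edges[0] or d >= edges[-1]:
            raise ValueError(
                f"event at frame {ev.start_frame} has duration {d} ns outside "
                f"the bin span [{edges[0]}, {edges[-1]})"
            )
        mass[np.searchsorted(edges, d, side="right") - 1] += d
    if durations.size:
        mean, sem, defined = weighted_mean_lifetime(events)
    else:
        mean, sem, defined = 0.0, 0.0, False
    return LifetimeHistogram(
        edges=edges,
        mass=mass,
        normalized=mass / total_time,
        total_time=total_time,
        mean_lifetime=mean,
        sem_lifetime=sem,
        sem_defined=defined,
        n_events=len(events),
    )


def weighted_mean_lifetime(events: list[ContactEvent]) -> tuple[float, float, bool]:
    """Duration-weighted mean lifetime and its weighted SEM.

    Weighting each event by its own duration d gives mean = sum(d^2)/sum(d):
    the expected lifetime of the event a randomly chosen bound frame
    belongs to.  The weighted SEM uses reliability weights w = d,

        SEM = sqrt( Var_w * sum(w^2) / (sum w)^2 ),

    with Var_w the reliability-weighted sample variance.  For a single
    event the SEM is undefined and reported as 0 with the third return
    value False.
    """
    if not events:
        raise EmptyInputError("weighted_mean_lifetime needs at least one event")
    d = np.array([ev.duration for ev in events], dtype=float)
    w = d
    sw = w.sum()
    mean = float((w * d).sum() / sw)
    if len(d) < 2:
        return mean, 0.0, False
    sw2 = float((w**2).sum())
    denom = sw - sw2 / sw  # reliability-weight correction
    if denom <= 0:
        return mean, 0.0, False
    var_w = float((w * (d - mean) ** 2).sum() / denom)
    sem = float(np.sqrt(var_w * sw2 / sw**2))
    return mean, sem, True


def replicate_stats(values: list[float] | np.ndarray) -> tuple[float, float, bool]:
    """Mean and SEM (sample sd / sqrt(n)) over replicate values.

    With a single replicate the SEM is undefined: reported as 0 with the
    third return value False.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise EmptyInputError("replicate_stats needs at least one value")
    mean = float(v.mean())
    if v.size < 2:
        return mean, 0.0, False
    sem = float(v.std(ddof=1) / np.sqrt(v.size))
    return mean, sem, True
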