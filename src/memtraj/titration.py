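"""Titration-curve analysis: degree of deprotonation and pKa estimation.

Constant-pH coarse-grained simulations record, at every frame, how many
proton particles are bound to a titratable side chain (e.g. the
membrane-buried glutamate of a VDAC channel).  The degree of deprotonation
at a given pH is the fraction of analysis-window frames with no bound
proton; fitting the Henderson–Hasselbalch curve

    f(pH) = 1 / (1 + 10 ** (n * (pKa - pH)))

to the per-pH fractions (Hill coefficient n fixed to 1 by default) yields
the apparent pKa.  Only the final part of each per-pH simulation (the
last 10 ns by default) enters the analysis, discarding equilibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import ConfigError, EmptyInputError, NonIdentifiableError

__all__ = [
    "TitrationSeries",
    "TitrationFit",
    "henderson_hasselbalch",
    "degree_of_deprotonation",
    "fit_pka",
    "midpoint_by_interpolation",
    "reference_shift",
    "GLU_SOLUTION_PKA",
]

# Reference pKa of a free glutamate side chain in aqueous solution.
GLU_SOLUTION_PKA = 4.3


@dataclass
class TitrationSeries:
    """Per-pH, per-replicate bound-proton counts over time.

    ``data`` columns: pH, replicate, frame_time_ns, bound_protons (integer
    count of protons on the titratable site in that frame).
    """

    data: pd.DataFrame
    dt: float                 # ns between frames
    window: float = 10.0      # ns, analysis window anchored at the trace end

    REQUIRED = ("pH", "replicate", "frame_time_ns", "bound_protons")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ConfigError(f"titration table lacks columns: {sorted(missing)}")
        if (self.data["bound_protons"] < 0).any():
            raise ConfigError("bound_protons must be non-negative")
        if self.window <= 0:
            raise ConfigError("analysis window must be positive")


@dataclass
class TitrationFit:
    pka: float
    hill: float
    pka_stderr: float
    fractions: pd.DataFrame   # pH, mean fraction, sem, n_replicates
    residuals: np.ndarray
    extrapolated: bool        # pKa outside the fitted pH span
    midpoint: float           # monotone-interpolation crossing of f = 0.5


def henderson_hasselbalch(pH: np.ndarray, pka: float, n: float = 1.0) -> np.ndarray:
    """Deprotonated fraction of a titratable site at a given pH."""
    return 1.0 / (1.0 + 10.0 ** (n * (pka - np.asarray(pH, dtype=float))))


def degree_of_deprotonation(series: TitrationSeries) -> pd.DataFrame:
    """Per-pH deprotonation fraction, mean ± SEM over replicates.

    For each pH and replicate, only frames within ``series.window`` ns of
    that replicate's last frame are used; the fraction is the share of
    those frames with zero bound protons.  Returns columns ``pH``,
    ``fraction``, ``sem``, ``n_replicates`` (plus per-replicate fractions
    in ``replicate_fractions``).
    """
    rows = []
    for (pH, rep), grp in series.data.groupby(["pH", "replicate"]):
        t_end = grp["frame_time_ns"].max()
        window = grp[grp["frame_time_ns"] > t_end - series.window]
        if len(window) == 0:
            raise ConfigError(f"empty analysis window at pH {pH}, replicate {rep}")
        frac = float((window["bound_protons"] == 0).mean())
        rows.append((pH, rep, frac))
    per_rep = pd.DataFrame(rows, columns=["pH", "replicate", "fraction"])
    out = []
    for pH, grp in per_rep.groupby("pH"):
        v = grp["fraction"].to_numpy()
        sem = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        out.append((pH, float(v.mean()), sem, len(v), list(v)))
    return pd.DataFrame(
        out, columns=["pH", "fraction", "sem", "n_replicates", "replicate_fractions"]
    )


def midpoint_by_interpolation(pH: np.ndarray, fraction: np.ndarray) -> float:
    """pH at which the (monotone-interpolated) deprotonation curve crosses 0.5.

    Works directly on the averaged fractions without assuming a functional
    form; useful as a model-free cross-check of the fitted pKa.
    """
    pH = np.asarray(pH, float)
    f = np.asarray(fraction, float)
    order = np.argsort(pH)
    pH, f = pH[order], f[order]
    f = np.maximum.accumulate(f)  # enforce monotonicity for the crossing search
    if f[0] > 0.5 or f[-1] < 0.5:
        return float("nan")
    return float(np.interp(0.5, f, pH))


def fit_pka(
    fractions: pd.DataFrame,
    fit_hill: bool = False,
) -> TitrationFit:
    """Least-squares Henderson–Hasselbalch fit of per-pH fractions.

    ``fractions`` needs columns ``pH`` and ``fraction`` (the output of
    :func:`degree_of_deprotonation` works directly).  The Hill coefficient
    is fixed at 1 unless ``fit_hill`` is set.  Raises
    :class:`NonIdentifiableError` when the data carry no transition (all
    fractions 0 or all 1).
    """
    pH = fractions["pH"].to_numpy(dtype=float)
    f = fractions["fraction"].to_numpy(dtype=float)
    if len(pH) == 0:
        raise EmptyInputError("no titration points to fit")
    if np.all(f <= 1e-12) or np.all(f >= 1 - 1e-12):
        raise NonIdentifiableError(
            "titration curve is flat (all fractions 0 or 1); pKa not identifiable"
        )
    mid0 = midpoint_by_interpolation(pH, f)
    p0_pka = mid0 if np.isfinite(mid0) else float(np.median(pH))
    if fit_hill:
        popt, pcov = curve_fit(
            lambda x, pka, n: henderson_hasselbalch(x, pka, n),
            pH, f, p0=[p0_pka, 1.0], maxfev=10000,
        )
        pka, hill = float(popt[0]), float(popt[1])
    else:
        popt, pcov = curve_fit(
            lambda x, pka: henderson_hasselbalch(x, pka, 1.0),
            pH, f, p0=[p0_pka], maxfev=10000,
        )
        pka, hill = float(popt[0]), 1.0
    stderr = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else float("nan")
    residuals = f - henderson_hasselbalch(pH, pka, hill)
    cols = ["pH", "fraction"] + [c for c in ("sem", "n_replicates") if c in fractions]
    return TitrationFit(
        pka=pka,
        hill=hill,
        pka_stderr=stderr,
        fractions=fractions[cols].copy(),
        residuals=residuals,
        extrapolated=not (pH.min() <= pka <= pH.max()),
        midpoint=mid0,
    )


def reference_shift(pka: float, reference: float = GLU_SOLUTION_PKA) -> float:
    """Shift of an apparent pKa relative to the free side chain in solution.

    A membrane-buried glutamate with pKa 4.8 is shifted by +0.5 units from
    the solution value of 4.3.
    """
    return pka - reference
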