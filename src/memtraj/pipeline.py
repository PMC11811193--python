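"""Stage orchestration: config parsing, dispatch, aggregation, manifests.

``run_pipeline`` drives the individual analysis stages over one system
(a trajectory plus a bead role map, or a generated synthetic scenario),
writes one CSV per stage plus OpenDX/OBJ grids, and records a manifest
(config snapshot, input hashes, seed, package version, output paths) so a
rerun of the same manifest reproduces byte-identical deterministic
outputs.  CSV outputs use '.' decimals, UTF-8 and six significant digits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    AnalysisConfig,
    BeadSelection,
    ConfigError,
    FrameSeries,
    LEAFLET_BOTTOM,
    LEAFLET_TOP,
    SelectionError,
    assign_leaflets,
    center_and_rotfit,
    membrane_centers,
    read_frames,
    read_role_map,
    selection_from_roles,
    write_frames_text,
    write_role_map,
)
from . import contacts as ct
from . import membrane as mb
from . import residence as rs
from . import titration as ti
from . import synthetic as sy

log = logging.getLogger("memtraj")

__all__ = [
    "load_config",
    "dump_config",
    "selection_by_residue_key",
    "run_pipeline",
    "summarize_condition",
]

STAGES = (
    "thinning",
    "radial",
    "defects",
    "occupancy",
    "depth",
    "contacts",
    "residence",
    "titration",
)

_TOP_KEYS = {"seed", "out_dir", "stages", "input", "analysis", "selections"}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    _validate_config(cfg)
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _validate_config(cfg: dict) -> None:
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    stages = cfg.get("stages", [])
    bad = set(stages) - set(STAGES)
    if bad:
        raise ConfigError(f"unknown stages: {sorted(bad)} (valid: {list(STAGES)})")
    if "analysis" in cfg:
        allowed = {f.name for f in dataclasses.fields(AnalysisConfig)}
        bad = set(cfg["analysis"]) - allowed
        if bad:
            raise ConfigError(f"unknown analysis keys: {sorted(bad)}")


def _analysis_config(cfg: dict) -> AnalysisConfig:
    return AnalysisConfig(**cfg.get("analysis", {}))


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def selection_by_residue_key(roles: pd.DataFrame, key: str) -> BeadSelection:
    """Select all beads of the residue named e.g. 'MET1' or 'GLU73'."""
    keys = roles["residue_name"].astype(str) + roles["residue_id"].astype(str)
    sub = roles[keys == key]
    if len(sub) == 0:
        raise SelectionError(f"no residue matches key {key!r}")
    labels = list(
        zip(sub["residue_id"].astype(int), sub["residue_name"], sub["bead_name"])
    )
    role = sub["role"].mode().iloc[0]
    return BeadSelection(sub["index"].to_numpy(), labels, role)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def _leaflet_map_frame(lmap: mb.LeafletMap) -> pd.DataFrame:
    xc, yc = lmap.bin_centers()
    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    return pd.DataFrame(
        {
            "x": gx.ravel(),
            "y": gy.ravel(),
            "thickness": lmap.thickness.ravel(),
            "count": lmap.counts.ravel(),
            "valid": lmap.valid.ravel().astype(int),
        }
    )


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the configured stages and return the manifest dictionary.

    ``config`` is a dict or a YAML path (see ``load_config``); stages run
    in dependency order regardless of the order listed.  An empty stage
    list produces a manifest only.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    _validate_config(cfg)
    out = Path(out_dir or cfg.get("out_dir", "memtraj_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    acfg = _analysis_config(cfg)
    stages = [s for s in STAGES if s in set(cfg.get("stages", []))]
    inputs = cfg.get("input", {})
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "stages": stages,
        "constants": dataclasses.asdict(acfg),
        "inputs": {},
        "outputs": {},
    }
    log.info("analysis constants in use: %s", manifest["constants"])

    frames = roles = None
    if "synthetic" in inputs:
        syn = inputs["synthetic"]
        spec = sy.SyntheticSpec(seed=seed, n_frames=int(syn.get("n_frames", 200)))
        if syn.get("funnel"):
            fn = syn["funnel"]
            spec.funnels = [sy.FunnelSpec(**fn)]
        frames, roles, truth = sy.make_membrane_system(
            spec,
            with_protein=syn.get("with_protein", True),
            with_waters=syn.get("with_waters", True),
        )
        write_frames_text(frames, out / "synthetic.traj")
        write_role_map(roles, out / "synthetic_roles.csv")
        with open(out / "synthetic_truth.json", "w") as fh:
            json.dump(_jsonable(truth), fh, indent=1)
        manifest["inputs"]["synthetic"] = {"seed": seed, "scenario": "membrane"}
    elif "trajectory" in inputs:
        traj = Path(inputs["trajectory"])
        roles_path = Path(inputs["roles"])
        frames = read_frames(
            traj,
            format=inputs.get("format"),
            dt_override=inputs.get("dt"),
            topology=inputs.get("topology"),
        )
        roles = read_role_map(roles_path)
        manifest["inputs"]["trajectory"] = {
            "path": str(traj), "sha256": _hash_file(traj)
        }
        manifest["inputs"]["roles"] = {
            "path": str(roles_path), "sha256": _hash_file(roles_path)
        }
    elif stages and set(stages) - {"titration"}:
        raise ConfigError("geometry stages need input.trajectory or input.synthetic")

    geometry_stages = {"thinning", "radial", "defects", "occupancy", "depth",
                       "contacts", "residence"}
    if frames is not None and set(stages) & geometry_stages:
        _run_geometry_stages(frames, roles, acfg, stages, cfg, out, manifest)

    if "titration" in stages:
        tpath = inputs.get("titration_csv")
        if tpath is None:
            raise ConfigError("the titration stage needs input.titration_csv")
        data = pd.read_csv(tpath)
        series = ti.TitrationSeries(data, dt=1.0, window=acfg.titration_window)
        fractions = ti.degree_of_deprotonation(series)
        fit = ti.fit_pka(fractions)
        _write_csv(fractions.drop(columns=["replicate_fractions"]), out / "titration_curve.csv")
        report = {
            "pka": fit.pka,
            "hill": fit.hill,
            "pka_stderr": fit.pka_stderr,
            "midpoint": fit.midpoint,
            "extrapolated": fit.extrapolated,
            "shift_vs_solution_glu": ti.reference_shift(fit.pka),
        }
        with open(out / "titration_fit.json", "w") as fh:
            json.dump(report, fh, indent=1)
        manifest["outputs"]["titration"] = [
            str(out / "titration_curve.csv"), str(out / "titration_fit.json")
        ]

    with open(out / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=1)
    return manifest


def _run_geometry_stages(frames, roles, acfg, stages, cfg, out, manifest):
    phos = selection_from_roles(roles, "phosphate")
    lipid_rows = roles[roles["role"].isin(["phosphate", "glycerol"])]
    all_lipid = BeadSelection(
        lipid_rows["index"].to_numpy(),
        list(zip(lipid_rows["residue_id"].astype(int), lipid_rows["residue_name"],
                 lipid_rows["bead_name"])),
        "other",
    )
    gly = selection_from_roles(roles, "glycerol")
    leaflets = assign_leaflets(frames, phos)

    has_protein = (roles["role"] == "protein").any()
    protein = selection_from_roles(roles, "protein") if has_protein else None
    if protein is not None:
        ref = frames.coords[0, protein.indices]
        frames, angles = center_and_rotfit(frames, protein, ref)
        manifest["outputs"]["rotfit_mean_angle_deg"] = float(
            np.degrees(np.mean(np.abs(angles)))
        )
    refs = membrane_centers(frames, gly, all_lipid, leaflets,
                            center_mode=acfg.center_mode)

    if "thinning" in stages or "radial" in stages:
        maps = {}
        for leaflet in (LEAFLET_TOP, LEAFLET_BOTTOM):
            lmap = mb.leaflet_thinning_map(frames, phos, leaflet, refs, acfg)
            maps[leaflet] = lmap
            path = out / f"thinning_{leaflet}.csv"
            _write_csv(_leaflet_map_frame(lmap), path)
            mn, avg = mb.map_summary(lmap)
            manifest["outputs"][f"thinning_{leaflet}"] = {
                "csv": str(path), "min_nm": mn, "mean_nm": avg
            }
        if "radial" in stages and protein is not None:
            center, r_in, r_out = mb.annulus_around_protein(frames, protein)
            prof = mb.radial_minimum_profile(maps[LEAFLET_TOP], center, r_in, r_out)
            df = pd.DataFrame(
                {"azimuth_deg": prof.sector_deg, "min_thickness": prof.sector_min}
            )
            _write_csv(df, out / "radial_profile.csv")
            manifest["outputs"]["radial"] = {
                "csv": str(out / "radial_profile.csv"),
                "ring_min_nm": prof.ring_min,
                "ring_min_azimuth_deg": prof.ring_min_azimuth_deg,
            }

    if "defects" in stages:
        waters = selection_from_roles(roles, "water")
        trace = mb.water_defect_count(frames, waters, refs, acfg, protein=protein,
                                      anchor_xy=None if protein is not None
                                      else frames.box[0, :2] / 2)
        df = pd.DataFrame({"frame": np.arange(len(trace.counts)),
                           "time_ns": np.arange(len(trace.counts)) * frames.dt,
                           "count": trace.counts})
        _write_csv(df, out / "defects.csv")
        manifest["outputs"]["defects"] = {
            "csv": str(out / "defects.csv"), "mean": trace.mean, "sem": trace.sem
        }

    if "occupancy" in stages:
        grid = mb.occupancy_grid(frames, phos, acfg)
        mb.write_opendx(grid, out / "occupancy_po4.dx")
        surf = mb.export_isosurface(grid, acfg.occupancy_threshold)
        mb.write_obj(surf, out / "occupancy_po4.obj")
        manifest["outputs"]["occupancy"] = {
            "dx": str(out / "occupancy_po4.dx"),
            "obj": str(out / "occupancy_po4.obj"),
            "cells_above_threshold": int(surf.mask.sum()),
        }

    if "depth" in stages:
        tit = selection_from_roles(roles, "titratable_site")
        dep = mb.residue_depth_trace(frames, tit, refs)
        df = pd.DataFrame({"time_ns": np.arange(len(dep.values)) * frames.dt,
                           "depth_nm": dep.values})
        _write_csv(df, out / "depth.csv")
        manifest["outputs"]["depth"] = {
            "csv": str(out / "depth.csv"), "mean_nm": dep.mean, "sd_nm": dep.sd
        }

    sel_cfg = cfg.get("selections", {})
    if "contacts" in stages:
        ga = selection_by_residue_key(roles, sel_cfg.get("group_a", "MET1"))
        gb = selection_by_residue_key(roles, sel_cfg.get("group_b", "GLU73"))
        prev = ct.residue_contact_fraction(frames, ga, gb, acfg.d_contact)
        _write_csv(prev, out / "contact_prevalence.csv")
        trace = ct.min_distance_trace(frames, ga, gb)
        events = ct.detect_contact_events(trace, acfg.d_contact, acfg.d_event_outer)
        ev_df = pd.DataFrame(
            [(e.start_frame * frames.dt, (e.end_frame + 1) * frames.dt, e.duration)
             for e in events],
            columns=["start_ns", "end_ns", "duration_ns"],
        )
        _write_csv(ev_df, out / "contact_events.csv")
        hist = ct.lifetime_histogram(events, frames.total_time)
        h_df = pd.DataFrame({"bin_lo_ns": hist.edges[:-1], "bin_hi_ns": hist.edges[1:],
                             "mass_ns": hist.mass, "normalized": hist.normalized})
        _write_csv(h_df, out / "contact_lifetimes.csv")
        manifest["outputs"]["contacts"] = {
            "prevalence_csv": str(out / "contact_prevalence.csv"),
            "events_csv": str(out / "contact_events.csv"),
            "histogram_csv": str(out / "contact_lifetimes.csv"),
            "n_events": len(events),
            "mean_lifetime_ns": hist.mean_lifetime,
        }

    if "residence" in stages:
        pep_key = sel_cfg.get("peptide")
        pep = (selection_by_residue_key(roles, pep_key) if pep_key
               else selection_from_roles(roles, "protein"))
        membrane_sel = BeadSelection(all_lipid.indices, all_lipid.labels, "other")
        trace = rs.peptide_membrane_trace(frames, pep, membrane_sel)
        res = rs.residence_time(trace, acfg.d_desorb)
        df = pd.DataFrame({"time_ns": np.arange(trace.n_frames) * frames.dt,
                           "distance_nm": trace.values})
        _write_csv(df, out / "residence_trace.csv")
        manifest["outputs"]["residence"] = {
            "csv": str(out / "residence_trace.csv"),
            "residence_ns": res.residence,
            "censored": res.censored,
        }


def summarize_condition(
    per_replica: list[pd.DataFrame],
    label: str = "",
    weights: list[float] | None = None,
) -> pd.DataFrame:
    """Aggregate per-replica contact prevalence tables for one condition.

    Returns per residue pair the replicate mean ± SEM, plus the pooled
    (replica-length weighted) aggregate as a secondary column — the two
    differ when replica lengths differ, and both views are reported.
    """
    if not per_replica:
        raise ConfigError("summarize_condition needs at least one replica table")
    cols = {"residue_a", "residue_b", "fraction"}
    for df in per_replica:
        if not cols <= set(df.columns):
            raise ConfigError(f"replica table lacks columns {sorted(cols)}")
    if weights is None:
        weights = [1.0] * len(per_replica)
    if len(weights) != len(per_replica):
        raise ConfigError("one weight per replica table required")
    merged = pd.concat(
        [df.assign(_rep=i, _w=w) for i, (df, w) in enumerate(zip(per_replica, weights))],
        ignore_index=True,
    )
    rows = []
    for (ra, rb), grp in merged.groupby(["residue_a", "residue_b"]):
        v = grp["fraction"].to_numpy(dtype=float)
        w = grp["_w"].to_numpy(dtype=float)
        mean, sem, defined = ct.replicate_stats(v)
        pooled = float((v * w).sum() / w.sum())
        rows.append((label, ra, rb, mean, sem, int(defined), pooled, len(v)))
    return pd.DataFrame(
        rows,
        columns=["condition", "residue_a", "residue_b", "mean", "sem",
                 "sem_defined", "pooled", "n_replicas"],
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
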