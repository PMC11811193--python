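# memtraj

Analysis toolkit for coarse-grained molecular-dynamics trajectories of
membrane proteins, built around the question of how a β-barrel channel
(such as VDAC, the voltage-dependent anion channel of the outer
mitochondrial membrane) reshapes its surrounding bilayer and binds a
peptide ligand (such as the N-terminal amphipathic helix of hexokinase-I).
It is aimed at simulators who have Martini-style CG trajectories in hand
and want the standard battery of membrane/contact analyses without writing
one-off scripts.

## What it computes

- **Residue contact prevalence** — fraction of simulation time two residues
  have any bead pair within 0.6 nm (minimum-image convention).
- **Contact-event kinetics** — a binding event is a maximal run of frames
  with the inter-residue minimum distance inside a 1.0 nm outer cutoff that
  dips below the 0.6 nm inner cutoff at least once. The double cutoff
  suppresses spurious recrossing frames when the distance fluctuates around
  a single cutoff. Event durations d are histogrammed into logarithmic
  bins weighted by duration and normalised by total simulated time; the
  duration-weighted mean lifetime is Σd²/Σd with a weighted SEM
  (reliability weights w = d).
- **Leaflet thinning maps** — mean |z(PO4) − global membrane centre| per
  leaflet on a 0.1 nm lateral grid; bins need more than 30 phosphate
  observations to count. Radial minimum profiles report the lowest leaflet
  value on a ring around the protein, per azimuthal sector.
- **Water defects** — waters inside a cylinder of radius 2.5 nm anchored at
  the protein's xy centre, spanning ±1.5 nm about the membrane centre.
- **Occupancy grids** — per-voxel (0.2 nm) percentage of frames in which a
  selected bead type is present, exported as OpenDX plus an iso-occupancy
  surface (default 0.5%) as an OBJ mesh.
- **Buried-residue depth** — z of a chosen side chain relative to the mean
  of the two leaflet glycerol centres-of-geometry.
- **Membrane residence times** — first frame at which the peptide–membrane
  minimum distance exceeds 1.4 nm; traces that never desorb are censored
  and reported as lower bounds.
- **Titration curves** — degree of deprotonation (fraction of
  analysis-window frames with no bound proton particle) per pH over the
  grid 3–8 in half steps, and a Henderson–Hasselbalch fit
  f(pH) = 1 / (1 + 10^(pKa − pH)) for the apparent pKa, plus its shift
  against a free glutamate in solution (pKa 4.3).

Trajectories are read through MDAnalysis (GRO, multi-model PDB, XTC/TRR)
or a plain-text fallback format; all analyses run in nm/ns on orthorhombic
boxes, with protein-centred frames rotationally fitted about z only.

A synthetic-trajectory module generates every input the analyses expect —
bilayers with an imposed Gaussian thinning funnel, a rigid barrel wall with
one buried anionic bead, defect-column waters, telegraph contact traces,
exponential desorption traces, Bernoulli titration series — each with a
machine-readable analytic ground-truth record, so the entire pipeline is
testable without an MD engine.

## Worked example

```python
import numpy as np
import memtraj as mt

# a funnel-thinned membrane with an embedded barrel and a wet defect column
spec = mt.SyntheticSpec(seed=7, n_frames=2000)
spec.funnels = [mt.FunnelSpec(x=7.2, y=5.5, depth=1.20, width=0.8)]
spec.waters = mt.WaterSpec(bulk_density=1.0, enrichment=4.0)
frames, roles, truth = mt.make_membrane_system(spec)

protein = mt.selection_from_roles(roles, "protein")
frames, _ = mt.center_and_rotfit(frames, protein, frames.coords[0, protein.indices])

phos = mt.selection_from_roles(roles, "phosphate")
gly = mt.selection_from_roles(roles, "glycerol")
lipid = mt.BeadSelection(np.concatenate([phos.indices, gly.indices]),
                         phos.labels + gly.labels, "other")
leaflets = mt.assign_leaflets(frames, phos)
refs = mt.membrane_centers(frames, gly, lipid, leaflets)

lmap = mt.leaflet_thinning_map(frames, phos, mt.LEAFLET_TOP, refs)
mn, avg = mt.map_summary(lmap)
print(f"cytosolic leaflet: min thickness {mn:.2f} nm, mean {avg:.2f} nm")

waters = mt.selection_from_roles(roles, "water")
defects = mt.water_defect_count(frames, waters, refs, protein=protein)
print(f"waters in defect cylinder: {defects.mean:.2f} ± {defects.sem:.2f}")

glu = mt.selection_from_roles(roles, "titratable_site")
depth = mt.residue_depth_trace(frames, glu, refs)
print(f"buried Glu depth: {depth.mean:+.2f} nm from the membrane centre")

series, _ = mt.make_titration_series(spec)   # true pKa 4.8
fit = mt.fit_pka(mt.degree_of_deprotonation(series))
print(f"fitted pKa {fit.pka:.2f}, shift vs solution Glu {mt.reference_shift(fit.pka):+.2f}")
```

Output:

```
cytosolic leaflet: min thickness 0.77 nm, mean 1.93 nm
waters in defect cylinder: 8.76 ± 0.06
buried Glu depth: +0.42 nm from the membrane centre
fitted pKa 4.80, shift vs solution Glu +0.50
```

The leaflet minimum of 0.77 nm recovers the generator's imposed funnel
floor (plane 1.95 nm minus depth 1.20 nm = 0.75 nm) within sampling noise,
while the map mean stays at the unperturbed plane; the defect count
matches the column's analytic expectation; the depth trace returns the
bead's construction height (the small excess comes from the funnel pulling
the cytosolic glycerol centre down); and the titration fit recovers the
true pKa with its +0.5 shift from the solution glutamate value.

## Command line

```sh
memtraj synth membrane --seed 1 --out data/       # trajectory + roles + truth
memtraj thinning  --traj data/membrane.traj --roles data/membrane_roles.csv --out maps/
memtraj contacts  --traj t.traj --roles r.csv --group-a MET1 --group-b GLU73 --out c/
memtraj residence --traj t.traj --roles r.csv --threshold 1.4 --out res/
memtraj titration --csv titr.csv --window 10 --out fit/
memtraj run-all   --config config.yaml
```

Each subcommand is a thin wrapper over the library; `run-all` executes the
configured stages on one system and writes a manifest (config snapshot,
input hashes, seed, version) so deterministic outputs reproduce
byte-identically.

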