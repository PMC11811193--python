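# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic generator does and does not
emulate, and the design decisions taken where more than one reasonable
convention exists.

## Data model and geometry

Trajectories are held as dense arrays of particle positions (nm) with
per-frame orthorhombic box lengths and a fixed frame spacing dt (ns).
Frames are 0-based and times are reported as frame_index × dt. The
default dt of 0.5 ns matches the granularity at which production CG
simulations of these systems typically store coordinates. Triclinic boxes
are rejected: every system this package targets is built rectangular, and
the minimum-image arithmetic (component-wise nearest-image shift) relies
on it. File input goes through MDAnalysis for GRO/PDB/XTC/TRR (Å → nm on
read); a plain-text fallback format (header plus one x-y-z line per
particle per frame) exists so that fixtures and small exchanges need no
binary files.

Bead semantics come from a role map (CSV: index, residue_id,
residue_name, bead_name, role) with roles phosphate, glycerol, water,
protein, proton, titratable_site, other. Selections are validated for
uniqueness and range; distance kernels operate on whole selections under
the minimum-image convention.

**Leaflet assignment.** Lipids are split by the sign of their phosphate z
relative to the median at a reference frame (default frame 0) and the
labels are frozen. CG lipids do not flip-flop on the timescales analysed
here, so tracking per-frame leaflet membership would only add noise. A
bilayer whose phosphates share a single z is rejected as degenerate.
Convention: the cytosolic leaflet is "top" (+z), the intermembrane-space
leaflet "bottom".

**Two membrane centres.** Depth traces use the mean of the two leaflet
glycerol centres-of-geometry; thinning maps and water defects use the
centre of all lipid beads. The two definitions serve different questions
(where a side chain sits between the headgroup belts vs. where the
bilayer midplane lies) and coincide for symmetric bilayers. The global
centre uses uniform bead weights by default, with a mass-weighted option
exposed (`center_mode="mass"`); at CG resolution with near-uniform bead
masses the difference is negligible.

**Centering and rotational fit.** Each frame is translated so the
protein's xy geometric centre sits at the box centre, then the whole
frame is rotated about z by the closed-form 2-D Procrustes angle
θ = atan2(Σ(ref_y·p_x − ref_x·p_y), Σ(ref_x·p_x + ref_y·p_y)) that
minimises the xy-RMSD of the protein beads to a common reference. Beads
get uniform weights. Only x and y enter the fit; z is untouched, so
membrane-normal quantities are unaffected. The closed form is exact, so
the fit can never increase the RMSD, and it agrees with a 0.01°
brute-force scan to better than 0.02° (tested).

## Contact analysis

Residues are in contact in a frame when any bead pair (backbone and side
chain alike) lies within the 0.6 nm cutoff. Prevalence is the fraction of
frames in contact, computed per replica and aggregated as mean ± SEM
(sample sd/√n) across replicas; a pooled, replica-length-weighted
aggregate is also reported because combined-replica figures are common
and the two differ when replica lengths differ.

**Event detection.** A candidate event is a maximal run of frames with
the distance below the 1.0 nm outer cutoff; it is kept iff the distance
drops below the 0.6 nm inner cutoff somewhere in the run. Events are
therefore disjoint, ordered, and separated by at least one frame at or
above the outer cutoff. Events touching either end of the trace are
included with their observed duration and flagged truncated — no
censoring model is applied, which biases the longest lifetimes low when
events outlive the trajectory; downstream users can filter on the flag.

**Lifetime statistics.** Durations are binned into logarithmic bins
(default five per decade from dt up to the trace length; half-open
[lo, hi)), each event contributing its duration rather than a unit count,
and bin values are normalised by total simulated time, so a bar reads as
"fraction of the simulation spent in events of this lifetime scale". The
duration-weighted mean lifetime is Σd²/Σd — the expected lifetime of the
event a randomly chosen bound frame belongs to, which is the quantity a
"how long does a typical bound state last" question asks for when short
events are numerous. Its uncertainty is a weighted SEM with reliability
weights w = d: SEM = sqrt(Var_w · Σw² / (Σw)²), Var_w the
reliability-weighted sample variance. For a single event the SEM is
undefined and reported as 0 with an explicit flag, never silently.

## Membrane geometry

**Thinning maps.** For each phosphate of a leaflet, in every frame,
|z − global centre| is accumulated on a lateral grid of 0.1 nm bins
anchored at the box corner of the first (fitted) frame; bins report the
mean and are masked unless they collected strictly more than 30
observations (30 is masked, 31 is valid). Observations are pooled over
frames within a replica; replicate aggregation happens on the summary
statistics. Map summaries (min, mean) ignore masked bins and can be
restricted to a region mask.

**Radial minima.** The "ring around the protein" is an annulus from the
protein's maximal xy bead radius to 0.8 nm beyond it (both configurable),
split into azimuthal sectors (default 36); each sector reports its lowest
valid bin and the ring reports the global minimum and its azimuth. This
makes "each polar patch has its own local minimum" statements testable:
removing the deeper of two funnels promotes the shallower to the ring
minimum (tested).

**Water defects.** Waters count when their minimum-image xy distance to
the cylinder anchor is ≤ 2.5 nm and |z − global centre| ≤ 1.5 nm (total
height 3 nm, protruding 1.5 nm into each leaflet). The anchor is the
protein's xy geometric centre re-evaluated every frame — consistent with
frames being re-fitted every frame — or an explicit fixed point for
protein-free systems.

**Occupancy grids.** The first-frame box is gridded at 0.2 nm; a voxel
scores when at least one selected bead lies in it that frame (binary
presence, not density), giving 0–100% occupancy over frames. Beads
outside the box are wrapped first. The iso-occupancy surface (default
0.5%) is exported two ways: a boolean mask (occupancy ≥ threshold), whose
volume is non-increasing in the threshold by construction, and a marching
-cubes triangle mesh (vertices in nm) when the level lies inside the
grid's value range. Grids write to OpenDX, meshes to Wavefront OBJ.

**Depth traces.** Per-frame z of the residue's side-chain bead (or
centre-of-geometry of several) minus the glycerol-based centre; positive
is cytosolic. Summarised as mean ± per-frame SD within a replica; across
replicas the SEM of the means is the appropriate uncertainty.

## Residence times

The peptide–membrane minimum distance (against the adsorbed-side leaflet
by default, all membrane beads optionally) is scanned for the first frame
strictly above 1.4 nm; residence is dt × that index, with no smoothing —
the first-passage reading of desorption. Traces that never cross are
censored at the trace end: their total time is a lower bound, reported
separately and never averaged into the mean. Residence is monotonically
non-decreasing in the threshold (tested).

## Titration analysis

The degree of deprotonation at a pH is the fraction of analysis-window
frames with zero bound proton particles at the titratable site; the
window is the final 10 ns of each per-pH simulation (anchored at the
trace end), discarding equilibration. Per-pH fractions are averaged over
replicate titration sets (three by default) with SEM. The apparent pKa
comes from an unweighted least-squares fit of the Henderson–Hasselbalch
curve f(pH) = 1/(1 + 10^(n(pKa − pH))) with the Hill coefficient fixed at
n = 1 (one site, one proton); freeing n is an option for diagnosing
cooperativity artefacts. A model-free monotone-interpolation midpoint
(pH where the averaged curve crosses 0.5) is always reported alongside,
since near-symmetric data make the two agree and a discrepancy flags a
distorted curve. Flat curves (all 0 or all 1) raise a non-identifiability
error rather than returning an extrapolated number; fits whose pKa falls
outside the pH span are flagged extrapolated. The pKa shift is reported
against the free-glutamate solution reference of 4.3 (configurable).

## Synthetic generator

The generator produces geometry, not physics: bead positions and roles
with controlled statistical structure, which is exactly what every
analysis stage consumes. Defaults are the study conditions: 386 lipids
(193 per leaflet) in an 11 × 11 × 10 nm box, phosphate planes at
±1.95 nm (the pure-POPC CG leaflet value), Gaussian z-jitter of 0.08 nm,
a 0.1 nm-per-frame lateral random walk, glycerols 0.45 nm below their
phosphates, 0.5 ns frame spacing.

- *Funnels* displace phosphate z toward the centre by
  depth·exp(−r²/2σ²) evaluated at the lipid's current lateral position,
  so the imposed thinning field is stationary in space and the analytic
  map minimum is plane − depth.
- *The barrel wall* is a rigid cylinder of bead rings spanning the
  membrane with one side-chain bead at a prescribed signed depth — a
  stand-in for a β-barrel with a bilayer-facing glutamate.
- *Waters* occupy the two aqueous slabs (excluded from |z| < plane) plus
  a defect column whose per-frame in-column count is Binomial with
  analytic mean density × enrichment × column volume; particle count per
  frame stays constant (a container invariant), so column occupancy is
  realised by per-frame relocation of a fixed slot set. Enrichment 0
  yields a perfectly dry membrane core.
- *Contact traces* are two-state telegraph processes with per-frame
  switch probabilities p = 1 − exp(−k dt); bound frames emit distances in
  (0.2, 0.55) nm, unbound in (1.3, 3.0) nm, and optional excursions into
  the (0.6, 1.0) nm dead zone exercise the double cutoff without changing
  the true event list (interior bound frames only, never the first of a
  run; isolated unbound frames only). The truth records the exact
  discrete-chain stationary fraction p_on/(p_on + p_off) and mean dwell
  dt/p_off, which approach k_on/(k_on + k_off) and 1/k_off for k·dt ≪ 1.
- *Desorption traces* jitter around 0.3 nm (clipped below 1.3 nm so no
  early crossing is possible), then rise linearly after an exponential
  desorption time, making the first-exceedance frame analytic.
- *Titration series* draw per-frame bound indicators Bernoulli(1 − f(pH))
  at the true pKa over the pH 3–8 half-step grid, 2000 frames per pH of
  which the last 1000 (10 ns at dt = 0.01 ns) form the window.

All randomness flows from the single spec seed through per-generator
streams; identical specs reproduce outputs bit for bit.

What the generator does **not** emulate: lipid packing correlations and
area-per-lipid physics, protein flexibility and tilt, water structure,
electrostatics, and any coupling between stages (the funnel does not
attract waters; contact kinetics are independent of geometry). Passing
tests therefore demonstrate that the analysis code measures imposed
geometric/statistical structure correctly at realistic noise levels — not
that the physics of any real system is reproduced. Real-trajectory
results additionally depend on sampling quality and force-field accuracy,
which are outside this package's scope.

## Problem sizes and tolerances in the validation suite

Thinning-recovery runs use 3000 frames so that 0.1 nm bins collect ~50
observations each, comfortably past the >30 mask while keeping per-bin
standard errors near 0.01 nm; the funnel-minimum check allows ±0.05 nm
(extreme-value bias of a minimum over ~10⁴ noisy bins plus the small
global-centre shift the funnel itself induces, both ≈0.01–0.02 nm).
Residence recovery uses 200 replicas of 3 µs traces (censoring
probability e⁻⁸·⁵) against a 3-Monte-Carlo-SE band; pKa recovery uses 50
experiments per scenario with a 0.05-unit median-bias bound (per-fit
standard error ≈0.01 at 3000 window frames per pH). Exact-match oracles
(event enumeration, point-in-cylinder, first-crossing, 27-image distance)
run on 1000–10000 random cases each. Statistical tests are seeded;
hypothesis profiles are derandomised.

## Known limitations

- Orthorhombic boxes only; no triclinic support.
- No lipid flip-flop tracking; leaflet labels are fixed at a reference
  frame.
- Truncated contact events are flagged, not survival-modelled; lifetime
  means are biased low when events outlive trajectories.
- The occupancy grid is binary presence per voxel, not a density — two
  beads in one voxel count once.
- Titration ingests the constant-pH bookkeeping (bound-proton counts per
  frame); it does not recompute proton binding from coordinates.
- Residence summaries stop at censoring flags; no Kaplan–Meier or
  parametric survival estimates.
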