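# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `scarvt`, in the spirit of a simulator's methods
appendix. Everything quantitative stated here is computed by the test suite
or `scripts/acceptance.py`; nothing is asserted that the code does not
measure.

## Synthetic anatomy

The generator replaces segmented in-vivo imaging with an idealized
two-ventricle phantom: the LV is a truncated prolate ellipsoid (default
epicardial semi-axes 25 × 25 × 45 mm, 9 mm wall, base cut at 45% of the
long semi-axis), and the RV blood pool is a larger overlapping ellipsoid
clipped against the LV epicardium, whose free wall is built by uniform
4 mm morphological dilation of the pool — the same construction used when a
thin RV wall cannot be segmented directly. Voxels are 1 mm isotropic by
default (configurable ≤ 2 mm); world coordinates are
`origin + index × spacing` with z as the slice/long axis.

The anteroseptal scar is transmural and elliptical in (apicobasal,
circumferential) extent, centred by a fractional apicobasal height and a
rotation angle measured from the RV-insertion direction. The conducting
isthmus is carved as a circumferential band of non-scar tissue at the scar
centre height: this orientation — channel running *within* an apicobasal
band — is exactly the configuration in which thick clinical z-slices can
miss the channel entirely, which is the resolution phenomenon the package
studies. A border-zone rim of configurable thickness (default 2 mm,
Euclidean distance transform) surrounds the core, spilling onto the RV
septal side where the scar reaches it.

Synthetic late-enhancement intensities use per-class means (healthy 0.2,
BZ 0.5, scar 1.0 of the maximum) plus i.i.d. Gaussian noise within the
myocardium; segmentation assigns scar at ≥ 60% and BZ at 40–60% of the
within-myocardium maximum. The source description of these thresholds is
internally inconsistent; the standard hyperenhancement convention
(brightest = scar) is implemented, with both fractions and the
normalisation mask exposed as arguments. Down-sampling to 4/10 mm keeps the
window-centre slice (nearest-neighbour, emulating thick-slice acquisition);
per-window majority voting is available as an option.

What the phantom does *not* emulate: MRI physics (partial volume, bias
fields, through-plane blur), papillary muscles and trabeculation, real scar
texture, or inter-subject anatomical variability. Tests passing on the
phantom therefore demonstrate the pipeline's internal consistency and its
resolution/personalisation phenomenology, not segmentation accuracy on
clinical images.

## logOdds scar reconstruction

Each label is reconstructed independently: binary occupancy → in-plane
Gaussian blur (default sd 1 mm = one voxel; small enough to preserve thin
structures) → probabilities clamped to [1e−6, 1−1e−6] → logit → natural
cubic interpolation along z onto the fine grid (linear fallback with a
warning below 4 slices) → sigmoid ≥ 0.5 (ties count as foreground).
Classes are composed with precedence background < blood < wall < BZ < scar.
Isthmus patency is quantified as a widest-path (maximin distance-transform
clearance) search between anchors flanking the channel, restricted to the
scar's own apicobasal span (shrunk 2.5 mm) and angular span (padded 5 mm of
arc) so that detours over the scar's edge do not masquerade as an isthmus;
`min_width` is twice the smallest clearance along the best path (±1 voxel
at 1 mm resolution).

## Meshes, coordinates, fibres

Meshing is voxel-derived: one hexahedron or 5/6 tetrahedra per myocardial
voxel (Kuhn 6-tet split by default — conforming on a grid), element regions
from voxel labels, surfaces from voxel-face adjacency (endocardium = wall
face against a blood pool, epicardium = against background, base = the open
top). Desk tests run at ≥ 1 mm; 325 µm is reserved for the conductivity
tuning strand. This replaces Delaunay-style meshing to avoid an external
meshing dependency; total element volume equals myocardial voxel volume to
machine precision.

Universal ventricular coordinates come from Laplace solves with P1 FEM:
transmural ρ (endocardia 0, epicardium 1; the septum has both faces at 0 so
ρ peaks mid-septum), apicobasal z (apex band 0, base 1), rotational φ as
the geometric angle about the LV centroid axis referenced to the RV
direction. On an annulus ρ matches the log-radial harmonic closed form to
~0.015 median at 1 mm. Fibres follow a rule-based construction: local frame
from ∇ρ (transmural) and ∇z (longitudinal), helix angle linear in ρ from
+60° (endo) to −60° (epi) — standard values, configurable; degenerate
frames (mid-septum, apex) inherit the nearest valid element's fibre.
The FEC layer tags elements whose minimum nodal ρ ≤ 0.05 (healthy →
fec_healthy; BZ and scar → fec_bz, the thin surviving endocardial sheet
over scar); at coarse resolution the effective layer is one element thick,
which is the resolution floor, approaching the nominal 5% depth as the mesh
refines. LV-only models drop RV free-wall elements while keeping the septum
with its RV-facing FEC.

Pacing sites: 17 LV endocardial sites on an AHA-style grid (apex cap plus
apical/mid/basal rings of 4/6/6 at z ≈ 0.28/0.52/0.78) and, when an RV is
present, RV apex and free wall (19 total); each site is the node ball of
radius 2.5 mm around its seed, and seeds falling in scar core are dropped
with a warning. The RV-pacing reference site is the septal RV-facing
endocardial point closest to the apex.

## Membrane model

The 2006 epicardial formulation of the ten Tusscher–Panfilov human
ventricular cell is implemented in full (12 gates, intracellular
Na/K/Ca with CICR), integrated with Rush–Larsen gate updates and forward
Euler elsewhere (single-cell dt 0.02 ms; tissue dt 0.05 ms). The epicardial
variant was chosen because the potassium-scaling anchor is testable against
it: at 1 Hz the model yields APD90 ≈ 305 ms (published ≈ 306 ms), and with
gKs and gKr scaled by 2.3 the paced APD90 at a 500 ms cycle length is
207 ms against the 205 ms anchor. APD is measured as APD90 on the last beat
of a 20-beat train (steady state enforced as consecutive-beat difference
< 1 ms). Border-zone remodelling multiplies INa × 0.38, ICaL × 0.31,
IKr × 0.30, IKs × 0.20 (longer APD, reduced upstroke velocity); a guard
flag prevents accidental double application. QT-based APD fitting adjusts a
single common gKs/gKr multiplier by bisection (APD is monotone in the
multiplier over the range used) to within 5 ms of the ECG-derived target
(QT interval minus QRS duration).

For tissue runs, the voltage-dependent Rush–Larsen coefficients of the 11
V-gated variables are tabulated per time step on a 0.02 mV grid and
linearly interpolated (the Ca-dependent gate and all concentrations stay
analytic); the table path deviates from direct integration by < 1e−4 mV
per beat and runs ~2.5× faster.

## Propagation

**Eikonal.** First-arrival times solve ‖∇T‖_M = 1 with the anisotropic
metric built per element from the fibre direction and per-region speeds
(healthy 0.67/0.3 m/s longitudinal/transverse at baseline, BZ 0.15 m/s
isotropic, FEC 6× longitudinal with healthy transverse, 6× the BZ value
over scar, scar non-conducting; in single-parameter fitting mode the
ratios ×0.45, ×0.225, ×6 tie every region to the healthy longitudinal CV).
The discretization is a dense local neighbourhood graph (all node pairs
within 3.2 element-lengths in 2-D, 2.5 in 3-D) whose edge weights are
sampled line integrals of the anisotropic slowness; a sample deep inside
scar blocks the edge, while samples near the scar *surface* take the
nearest conducting element so wavefronts can hug the boundary as in the
continuum. An iterative label-correcting sweep relaxes to a 1e−3 ms
tolerance. Against an independent Dijkstra oracle on the subdivided edge
graph the activation times around a non-conducting obstacle agree within
2%; a point source in an anisotropic sheet reproduces the elliptical
isochrone semi-axes to < 1%. Because all speeds scale together in fitting
mode, activation times scale exactly as 1/CV, which the CV sweeps exploit
by reusing the cached geometry.

**Reaction-eikonal.** The diffusion-free variant: each node plays a
steady-paced action-potential template shifted by its activation time
(scar at rest, template padded at rest with a warning if short). Detected
upstroke times match the eikonal activation times within the output step.

**Monodomain.** Mass-lumped P1 FEM on lines/triangles/tets with per-element
conductivity tensors σ_t I + (σ_l−σ_t) ff^T (S/m), C_m = 1 µF/cm²,
β = 0.14 µm⁻¹ (diffusivity in mm²/ms = σ/(10 β C_m)); operator splitting
with explicit diffusion at the membrane step (default 0.05 ms, well inside
the diffusion stability limit at the resolutions used). Scar elements are
excluded from assembly and scar-only nodes held at rest; |V| leaving
(−200, 200) mV aborts with a diagnostic rather than returning garbage.
On matched strands, monodomain and reaction-eikonal activation agree within
2 ms over 20 mm, and CV changes < 5% between 325 and 250 µm meshes.

**Conductivity tuning.** Planar CV is the slope of distance versus
activation time over the central half of a 20 mm strand; the tuning loop
iterates σ ← σ (target/measured)² to within 0.005 m/s, which converges in
a few iterations because CV ∝ √σ in the continuum. At 325 µm with the
porcine-modified cell, the 0.67 m/s target tunes to σ_l ≈ 0.211 S/m —
about 7% below the published 0.2262 S/m monodomain value, a residual we
report rather than hide: the printed value depends on surface-to-volume
ratio, capacitance and solver details not stated alongside it, and the
√σ-scaling law itself is verified near the converged-resolution limit
(coarse grids slow slow waves disproportionately, which is precisely why
the tuning is resolution-aware).

## Forward ECG and feature extraction

Extracellular potentials use the infinite-volume-conductor dipole integral
φ_e(x) = Σ_e (−σ_e ∇V_m V_e)·r̂ /(4π σ_b r²) with bath conductivity
σ_b = 1 S/m; since φ_e is linear in nodal V_m, a lead-field matrix is
assembled once per (mesh, electrodes, conductivity) and reused across CV
sweeps. Electrodes are placed parametrically on a bounding ellipsoid
(2.5× the heart's half-extents; limb electrodes further out) — a stand-in
for torso-model registration with documented conventions (right = +x
toward the RV, anterior = +y). A single dipole element matches the analytic
dipole potential to < 1%.

QRS bounds come from the spatial velocity of a quasi-orthogonal VCG
(X = V6, Y = aVF, Z = −(V1+V2)/2; transform selectable), smoothed 5 ms,
thresholded at 10% of the beat maximum, with the offset limited to a
150 ms window — threshold, window and transform are assumptions, flagged
as such, because no numeric values accompany the method's description.
T-wave end uses tangent extrapolation from the steepest post-peak slope to
the pre-QRS baseline (median of the 30 ms before onset), with iterative
exclusion of leads whose QT exceeds the median plus one SD. Paced-beat
averaging discards the first beat and averages beats 2–4. Electrogram
activation is the maximum negative dV/dt; repolarization follows the Wyatt
method within a pacing-dependent window (0.15–0.9 of the cycle length after
activation, assumed bounds), with the negative-T fallback; consecutive
activation-recovery intervals differing by more than 10% exclude the point.

## Personalisation

TACT-fit sweeps the healthy longitudinal CV 0.36–0.96 m/s in 0.01 m/s
steps (eikonal from the RV septal site; all regional CVs tied by the fixed
ratios) and keeps the CV whose total activation time at the base
(apicobasal coordinate ≥ 0.9 — the cut-off is a documented choice) best
matches the measured QRS duration, ties broken toward slower CV and
boundary optima flagged. QRSd-fit refines ±0.2 m/s around it by matching
the QRS duration of the fully simulated 12-lead ECG, clipping the window
at 0.05 m/s and skipping (with a log entry) sweep points whose ECG fails.
On the RV-paced phantom TACT exceeds QRSd at matched CV, so the QRSd-fit
CV is slower than the TACT-fit CV — the direction the study reports — and
closed-loop recovery over five seeded scar phantoms returns the generating
CV within 0.03 m/s. Desk-scale tests use a reduced phantom (0.55-scaled
geometry) and coarser sweep steps (0.02 m/s over a window bracketing the
truth) to keep the suite within minutes; the contracts default to the full
ranges. Conductivities are derived per region by the strand-tuning loop
(BZ slow and isotropic at 0.225× in fitting mode), FEC values following by
the square of the velocity ratio; the literature (VARP) set is healthy
0.2262/0.0642 S/m with BZ longitudinal equal to the healthy transverse
value and BZ transverse 10% of that.

## VT induction

The protocol delivers an S1 drive train (600 ms cycle length) and a single
S2 (250 ms coupling, or fitted APD + 45 ms for QT-personalised models) at
each pacing site as 1 ms transmembrane current pulses over the 2.5 mm node
ball, then observes 2 s unstimulated. Stimulus amplitude is specified as
current per membrane capacitance (default 100 pA/pF ≈ 2× diastolic
threshold); the nodal-lumping conversion from a volume current density is
absorbed into this number. Desk-scale runs shorten the drive train to one
or two S1 beats — the classification target is qualitative inducibility,
and the restitution state after a short train differs little at this cycle
length. Classification analyses the RMS 12-lead envelope after S2: induced
means at least two non-stimulated complexes beyond a 120 ms capture margin,
sustained means complexes persist into the final 500 ms of the window, and
the cycle length is the median inter-peak interval of the last complexes
(on small 2-D phantoms the envelope can double-count deflections within one
re-entrant lap, so phantom cycle lengths are indicative only). The
detailed morphology analysis used clinically is not reproduced; this
peak-train classifier is a documented stand-in with thresholds in one
place.

The canonical 2-D isthmus phantom (60 × 44 mm sheet, 0.5 mm elements) has
two non-conducting lobes separated by a 3 mm channel of surviving tissue —
slow-conducting (σ = 0.027 S/m, ~0.09 m/s) with a near-normal action
potential, as in clinical zig-zag isthmus conduction — and a border-zone
rim with remodelled electrophysiology guarding the proximal mouth
(σ = 0.0642 S/m). With QRSd-fit-like slow healthy tissue (σ = 0.12 S/m,
~0.4 m/s at this resolution) the S2 blocks at the long-refractory proximal
mouth, circulates around the scar, re-enters the recovered distal mouth and
sustains through the full 2 s window; filling the channel with scar (the
thick-slice reconstruction outcome) abolishes induction, and the faster
literature-like conductivity set induces but self-terminates — slower
conductivities never reduce inducibility at matched geometry. A second
simultaneous wavefront source (the role the RV plays in a biventricular
model) collides near the distal mouth and shifts the onset of re-entry by
~100 ms on this phantom without flipping the binary outcome; the
anatomy dependence of the binary outcome is additionally exercised at the
activation level, where removing the RV lengthens the total activation
time at matched CV so an LV-only model fits a faster CV.

The ring (annulus) experiment verifies the wavelength law that underpins
all of this: circulation started with a transient one-way barrier survives
only when the path length exceeds CV × refractory period (50 mm ring dies,
113 mm sustains at ~0.25 m/s and ~250 ms refractoriness).

## Registration and scoring

Mapping-catheter point clouds are registered to the endocardium by ICP
(Kabsch rigid steps, no scaling); the activation-time error is the
nearest-neighbour point-wise absolute difference with both LAT sets zeroed
at their stimulus time (export clocks differ) and matches farther than
5 mm excluded with a reported count. The error is invariant under joint
rigid motion and, in closed-loop sweeps, minimized at the generating CV.
Note that registration is only well-posed on surfaces without rotational
near-symmetries — an idealized cylinder or ellipsoid of revolution admits
rotations that ICP cannot (and should not) recover.

## Known limitations

- Phantom geometry is idealized; no real-image segmentation is attempted.
- The eikonal solver's node-graph discretization carries O(h) boundary
  error near obstacles; the 2% oracle agreement is demonstrated at 1 mm in
  2-D.
- Monodomain at coarse grids underestimates slow CVs (quantified above);
  VT phantoms at 0.5 mm inherit this, which the conductivity choices
  account for.
- The stimulus-strength unit convention absorbs the surface-to-volume
  conversion; absolute capture thresholds are not calibrated against a
  reference simulator.
- Single-cell pacing, not restitution protocols, anchors the APD fitting;
  regional APD gradients are out of scope.
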