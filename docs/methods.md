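# Methods

This note documents the models, conventions, numerical choices, and
limitations behind `cntdiff`.

## Surfaces and lattice bookkeeping

All surfaces are hexagonal carbon lattices with a single free parameter,
the C–C bond length `a_cc = 1.4180 Å`.  This value is chosen so that the
standard production boxes come out exactly: 41 armchair translational
cells give a 100.698 Å tube (`41·√3·a_cc`), and a 40 × 23 rectangular
graphene supercell gives a 98.2419 × 97.8420 Å² sheet
(`40·√3·a_cc × 23·3·a_cc`).

The rectangular graphene cell is `√3·a_cc × 3·a_cc` with 4 atoms; x runs
along the armchair direction and y along the zigzag direction.  Armchair
`(n,n)` tubes roll the zigzag direction around the circumference
(circumference `3·n·a_cc`, axial period `√3·a_cc`, `4n` atoms per cell);
zigzag `(0,m)` tubes roll the armchair direction (circumference
`√3·m·a_cc`, axial period `3·a_cc`).  The rolling map preserves geodesic
distances, so every bonded pair sits at geodesic length `a_cc` exactly.
General chiral `(n,m)` tubes are not implemented.  The tube radius is
`R = √3·a_cc·√(n² + nm + m²)/(2π)`, identical to the circumference/2π of
the rolled lattice.

Zigzag tube lengths are a configuration choice (24 cells ≈ 102.1 Å for
the ~100 Å systems); the axial length is a free parameter of the study
design rather than a lattice constraint.

The groove is two identical armchair tubes with parallel z axes at
center-to-center distance `2R + gap`; the default gap of 3.4 Å is the
van der Waals contact of two carbon walls.  Surface atoms are immobile,
so a built `Structure` carries only species, coordinates, and the box.

## Surface-local coordinates

A tracked point above a surface is described by the axial arc coordinate
`s_par`, the circumferential arc coordinate `s_perp`, and the vertical
distance `d` (plane: `z − z0`; cylinder exterior: `ρ − R`; interior:
`R − ρ`; groove: exterior rule on the nearer wall).  Unwrapping
accumulates minimum-image differences (`np.unwrap` with the box period or
2π); a frame-to-frame step larger than 45% of the period is treated as an
unresolvable sampling gap and raises an error, since a minimum-image step
near half the period cannot be distinguished from its opposite image.

**Circumferential radius convention.**  The angle-to-arc conversion uses
the trajectory-mean radial distance of the tracked point (`rho_ref =
'mean'`) by default: the adsorbate travels on a cylinder of its own
height above the wall, so its displacement per unit angle is `ρ·Δθ`, not
`R·Δθ`.  The wall-radius convention (`'wall'`) and explicit values are
available; for an adsorbate at ~3.4 Å on a 10 Å tube the two differ by
~30%, which is why the choice is surfaced in the API.

For the groove, a trajectory is decomposed against its majority-occupied
wall, with the angular origin on the groove midline (the direction facing
the other tube).  Occupancy maps use a signed circumferential coordinate:
arc distance from the midline, negative on wall A's side, positive on
wall B's, so two-wall trajectories appear as a bimodal split at 0.

## Diffusion estimation

MSDs are time-origin averaged with stride 1 over all origins, computed
with the standard FFT autocorrelation decomposition (O(N log N)); the
estimator is tested for exact (1e-10) agreement with the brute-force
double loop.  The 2D MSD is the sum of the two 1D component MSDs.

The Einstein relation `MSD_1d = 2·D·t` is fitted by least squares on a
4–10 ps lag window (configurable).  The window sits beyond the
short-time ballistic/caging regime but well inside the trajectory; each
replicate is fitted separately and the reported D is the mean with the
replicate standard deviation as its uncertainty (ten replicates in the
standard protocol).  The overall 2D coefficient is the mean of the two 1D
coefficients, with errors propagated in quadrature — equivalent to
applying `MSD_2d = 4·D·t` to the summed MSD.

Finite-size effects of periodic boxes are corrected by a weighted linear
regression of D against 1/L over at least three axial lengths; the
intercept is D∞.  The linear-in-1/L form follows hydrodynamic
self-interaction corrections for periodic systems and is documented as a
model assumption.

The hydration analysis regresses D on `N_water^(−1/3)` by ordinary least
squares.  Under a Stokes–Einstein picture `D ∝ 1/R_H` and the effective
hydrodynamic radius grows with the cube root of the number of solvating
waters, so fewer first-shell waters should mean faster diffusion; the
relation is used as a correlation diagnostic, not a quantitative law.

## Structural descriptors

Moiety centers of mass are mass-weighted with members minimum-imaged
relative to the first member (valid for moieties smaller than half the
box).  The tilt angle φ is the signed angle between the C2→C7 backbone
vector and its projection onto the tangent plane at the surface foot of
the vector midpoint, positive when C7 is farther from the wall;
histograms conventionally show |φ|, the signed value is kept internally.
The axial orientation θ is wrapped into [0°, 90°] because the two axial
directions are equivalent.  Default bin widths are 0.1 Å for lateral
maps, 0.36° for φ, and 3.6° for θ.

Vertical distributions are fitted as k-Gaussian mixtures
(`scipy.optimize.curve_fit`, peaks seeded from local maxima); for
synthetic mixtures with component separation above twice the width the
centers are recovered to well under half a bin.

The hydration count follows the first-shell rule: a water counts when its
oxygen is within 5 Å of any adsorbate atom *and* on the adsorbate's side
of the wall.  Water is represented by oxygen sites throughout.  The 5 Å
cutoff coincides with the density minimum between the first (≈3.3 Å) and
second (≈6.2 Å) water layers; `water_density_profile` weights cylinder
samples by the inverse shell circumference so the reported profile is a
volume density.

## Groove analysis

Frames are labeled by the wall with the smaller minimum atom-to-wall
distance; exact ties keep the previous label.  A wall-to-wall jump is a
label change that persists at least a debounce time (default 1 ps; there
is no unique operational definition of a jump, so both the raw and the
debounced counts are available — the raw count is an upper bound).  The
rate is events per ns with a Poisson `√n/T` error.  Groove entry is the
first frame with both wall distances below a cutoff (default 8 Å, chosen
to cover the full groove-seated density), and retention requires the
condition to hold to the end of the trajectory; groove diffusion analyses
should use only post-entry segments.

## Synthetic ground truth

The generators emulate the statistical structure of adsorbate MD, not its
physics — no forces, no integrator, no water dynamics:

* **Surface Brownian motion** — Euler–Maruyama steps
  `Δs ~ N(0, 2·D·dt)` independently in the ∥ and ⊥ arc coordinates at a
  fixed height (default 3.4 Å, van der Waals contact), mapped to the
  surface.  `dt = 0.1 ps` and 10 × 10 ns replicates mirror the standard
  sampling.
* **Rigid adsorbate** — an idealized planar dopamine-like template
  (6-C ring, two diol oxygens, side-chain C7 with |C2−C7| = 3.8 Å, amine
  N + 2H) placed at each path point with vertical distance d (applied to
  the amine COM along the local normal), tilt φ, and in-plane azimuth θ
  drawn from configurable Gaussian mixtures.  Time correlation uses
  sticky resampling (keep the previous value with probability
  `exp(−dt/τ)`, default τ = 1 ps), which preserves the marginal
  distribution exactly.  On a plane the placement is exact; on cylinders
  the tangent frame varies across the molecule, so angles are recovered
  to within the molecule-size/radius ratio.
* **Layered solvent** — water oxygens drawn per frame from a vertical
  volume-density profile (Gaussian layers at 3.3 and 6.2 Å plus a uniform
  bulk beyond 7.5 Å), uniform laterally, weighted by the cylindrical
  shell area.  Frames are independent; the per-frame count is the rounded
  expectation.  Layer amplitudes (0.064 / 0.041 Å⁻³, bulk 0.025 Å⁻³) are
  calibrated once so the reference adsorbate holds roughly 26–33 waters
  in its 5 Å shell, the physically expected first-shell range.
* **Wall switching** — a homogeneous Poisson process of wall swaps (the
  position mirrors across the groove midplane), with the adsorbate seated
  40° ± 3° off the midline at van der Waals height and diffusing axially.
  The seat angle keeps the nearest-wall assignment unambiguous while
  staying inside the groove cutoff.

What passing tests on these generators shows: the estimator stack
(unwrapping, MSD, fits, labeling, peak fitting, counting) is correct and
unbiased at realistic sampling.  What it does not show: anything about
force-field accuracy, real water structure or dynamics, adsorbate
flexibility, or the actual values of diffusion coefficients in solvated
MD — those require explicit-water simulations and are out of scope.

## I/O and pipeline

LAMMPS text dumps (unscaled `x y z` or scaled `xs ys zs` columns), LAMMPS
data files (atom-style atomic), and multi-frame XYZ are read and written
in plain text; readers accept streams and report parse errors with line
numbers, and writers round-trip losslessly at the written precision
(cross-checked against MDAnalysis in the test suite).  Dump files store
integer steps, so the physical frame spacing is supplied to the reader.
Coordinates are in Å, wrapped to [0, L) along periodic directions;
indices are 0-based internally and 1-based in LAMMPS-facing files.

The YAML-driven pipeline (build → synth → descriptors → diffusion →
groove) logs the seeds of every stage and is reproducible from
(config, seed).  Problem sizes in the bundled tests and the acceptance
script (10 × 10 ns walkers at 0.1 ps; 1.2e5-sample mixtures; 5 × 50 ns
switching runs) were chosen to put statistical errors well inside the
assertion tolerances while keeping a full run in the seconds-to-minutes
range.

## Known limitations

* Only planes, single cylinders, and two-cylinder grooves; no general
  curved surfaces, multiwall tubes, bundles, defects, or edges.
* Chiral `(n,m)` tubes (beyond armchair/zigzag) are not generated.
* The finite-size correction assumes the 1/L form; curvature in 1/L is
  not modeled.
* The adsorbate template is rigid and planar; conformational flexibility
  of the real molecule is represented only through the distributions of
  d, φ, θ.
* The groove decomposition references a single wall; trajectories that
  change walls should be segmented (or analyzed via the occupancy/jump
  tools) before MSD analysis.
* Binary trajectory formats (DCD/XTC) are not supported.
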