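# Methods

This note documents the models, conventions and numerical choices behind
`microves`, what the synthetic phantoms do and do not emulate, and the known
limitations.

## Pipeline model

The input is a confocal z-stack of a microvascular network perfused with a
fluorescent probe, so the bright phase is the vessel *lumen* (not the
endothelium): the analysis therefore measures the perfusable network and
implicitly excludes non-perfused sprouts. The stages are:

1. **Isotropization.** Confocal stacks are anisotropic (e.g. 0.98 μm/px in
   x–y, 5 μm z-step). The z-axis is linearly interpolated to the x–y pixel
   size, giving cubic voxels; linear interpolation is monotone and adds no
   assumptions. The z extent is preserved to within one voxel; x–y planes
   are untouched.
2. **Downsampling (optional).** Pure per-axis decimation — one voxel in
   *n* kept per axis, spacing multiplied by *n* — not block averaging, so
   intensities remain original samples. Factor 2 is a reasonable choice for
   millimetre-scale stitched volumes.
3. **Segmentation.** Morphological Chan–Vese active contours (two-phase
   region energy, no edge term), initialised from an Otsu threshold, default
   100 iterations / smoothing 1. The method is deterministic and invariant
   to affine intensity rescaling. After convergence one zero-smoothing
   update reassigns each voxel to the nearer converged phase mean: the
   curvature-smoothing operator otherwise biases thin tubes inward by a
   fraction of a voxel (≈14% volume at radius 5 voxels), and the finishing
   sweep is the exact two-phase energy minimum for the fitted means.
   Externally produced masks (e.g. from learned segmenters) enter through
   `load_mask`; a largest-connected-component filter (26-connectivity,
   deterministic lexicographic tie-break) isolates the perfused network.
4. **Vertical alignment.** Chip/stage misalignment shows as a planar tilt.
   A least-squares plane z = αx + βy + γ is fitted to the *per-x-y-column
   mean height* of the foreground (robust to vessel thickness), and the
   mask is rigidly rotated about the volume centre so the plane normal
   becomes vertical, with nearest-neighbour resampling to preserve
   binarity. A rigid rotation (rather than a z-shear) preserves lengths
   exactly; voxels rotated out of the box are dropped and counted (< 2%
   for the few-degree tilts this corrects).
5. **Skeletonization.** 3D medial-axis thinning (Lee–Kashyap–Chu, as
   implemented in scikit-image), topology-preserving; the skeleton is a
   subset of the mask.
6. **Graph extraction.** Skeleton voxels are classified by their
   26-neighbour count: 1 → endpoint, 2 → branch interior, ≥3 →
   ramification. Thinning leaves small clumps of ramification voxels at
   bifurcations; adjacent ones are merged into a single junction node at
   their centroid. Maximal interior runs between nodes become branches
   (each interior voxel has exactly two skeleton neighbours, so tracing is
   deterministic); isolated cycles get an anchor node and a self-loop.
   Self-loops and multi-edges are allowed — anastomoses are real.
7. **Branch smoothing.** Each branch is fitted with a cubic smoothing
   spline parameterised by normalised arc length, endpoints pinned by
   heavy fit weights. The residual budget defaults to 0.25 per centerline
   point, calibrated so a straight 45° voxel staircase recovers its true
   length within 0.1% while a two-period sine of amplitude 10 voxels keeps
   its arc length within 0.5%; smoothing 0 interpolates every voxel.
   Optionally, terminal branches shorter than a threshold are pruned
   (only branches terminal *at entry* are candidates, so interior
   junction-to-junction vessels can never be removed) and resulting
   degree-2 junctions are dissolved by concatenating their branches.

## Morphometry conventions

* **Length**: sum of Euclidean distances along the finely resampled spline.
* **Tortuosity**: arc length / endpoint chord, ≥ 1, so a perfectly straight
  vessel scores 1 (closed loops are reported NaN). The convention is chosen
  to match in-vivo indices that start at 1 for straight vessels.
* **Radius**: n_r stations (default 3) at equidistant arc-length fractions
  (2k+1)/(2 n_r) — the extremes sit half a step inward so junction blobs do
  not inflate end radii. At each station the mask is resampled
  (nearest-neighbour) on the plane perpendicular to the spline tangent and
  only the connected region containing the centerline point is kept, so
  neighbouring vessels crossing the plane are not counted. The radius is
  half the equivalent diameter 2·√(A/π); n_r = 1 and length-weighted
  network averages are available, and they genuinely differ on tapered
  vessels.
* **Eccentricity**: least-squares ellipse on the boundary pixels of the same
  sections (moment-based fallback for degenerate fits; stations with < 5
  boundary pixels are skipped). The reported index is the mean axis ratio
  b/a — 1 for a circle, lower for flatter sections, matching the intuition
  that gel-embedded vessels flatten with the major axis horizontal. The
  classical eccentricity √(1−(b/a)²) (circle → 0) is available behind
  `eccentricity_convention="classical"`; the axis-ratio form is the default
  because it is the one on which qualitative statements like "close to 1 =
  circular" hold.
* **Lateral area**: frustum sum π(r_k + r_{k+1})·Δs between consecutive
  stations plus cylindrical half-step end caps; exactly 2πrL for constant
  radius and 2πr̄L for n_r = 1. Stations skipped as empty rescale the chain
  to the full branch length.
* **S/V**: Σ lateral areas over the *extravascular* volume (analysis box
  minus lumen voxels), in mm²/mm³ — the exchange surface available per unit
  of perfused tissue-equivalent volume.
* **Planar comparison mode**: the z-projection is skeletonised in 2D and
  measured with z dropped; radii come from the 2D Euclidean distance
  transform minus half a pixel (the EDT measures to the nearest background
  pixel *centre*). On flattened elliptical vessels the planar radius reads
  the horizontal semi-major axis while the 3D analysis reports √(ab), so
  planar radii are systematically larger, and projected lengths are never
  longer than 3D ones — up to a tip-discretization caveat: planar and
  volumetric thinning retract branch ends by slightly different amounts
  (~1 voxel per tip), so on perfectly flat phantoms the comparison holds
  only to that tolerance.

## Hemodynamics

Each branch is a Poiseuille resistor R_i = 128 μ L_i/(π D_i⁴) with D_i
twice the mean equivalent radius; the cross-section is treated as circular
for flow, which is a minor approximation for steady flow in mildly
elliptical tubes. Nodes on the two opposite sides of the analysis box
(within a configurable margin, default 20 μm; nodes exactly on the margin
are included) receive the two side pressures, mimicking perfusion through
the chip's side channels. Interior nodes satisfy Σ Q = 0 — filtration
through the wall is neglected, so dead-end branches carry exactly zero
flow. The resulting sparse symmetric system in the nodal pressures is
solved directly; branch flows follow from Q = ΔP/R, velocities from
v = Q/(πr²), and wall shear stress from τ = 4μv/r. Components without a
boundary node are anchored at zero pressure and carry no flow (warned).
The formulation is algebraically equivalent to the full set of n_branch
pressure-drop equations plus n_node balances, and the test suite checks it
against an independently coded dense solve of exactly that larger system
(agreement to 1e-10 relative on random networks; interior mass-balance
residuals below 1e-9 of the largest flow). Because the system is linear,
scaling the boundary pressure drop scales every Q, v and τ exactly.

**Viscosity** defaults to μ = 1.0 mPa·s — aqueous culture medium near room
temperature — and is configurable (`--viscosity`, in mPa·s).

**Uncertainty.** The measured radius dominates the error budget: at fixed
Δp and l, v = Δp·r²/(8μl) and τ = Δp·r/(2l), so first-order propagation of
an uncertainty dr gives dv = 2v·dr/r and dτ = τ·dr/r. For the reference
single vessel (r = 15 μm, l = 100 μm, dr = 1.6 μm, Δp set for 500 μm/s)
this evaluates to dv ≈ 107 μm/s and dτ ≈ 14 mPa. The Monte-Carlo route
draws radii from Normal(r̄, dr) truncated positive by redraw (the redraw
count is logged; at r̄/dr ≈ 9 truncation is astronomically rare), and
re-evaluates either the closed forms (single vessel, vectorised over 10⁶
draws in well under a second) or the full network solve per draw, tracking
per-draw medians. Since τ is linear in r, its Monte-Carlo distribution is
Gaussian with mean Δp·r̄/(2l) and SD Δp·σ_r/(2l) (≈133 and 14 mPa for the
reference vessel); v is quadratic in r, hence skewed, while √v is again
Gaussian.

## Phantoms: what they emulate and what they don't

The generator sweeps elliptical cross-sections (major axis horizontal,
the orientation observed for gel-embedded networks) along analytic
centerlines — lines, circular arcs, sinusoids — with a hard in/out lumen
test against the densely sampled curve, so lengths, tortuosities,
semi-axes and lateral areas of the truth are closed-form. Junctions are
simply overlapping tubes; no fillet is modelled. Intensities are two-level
(foreground/background) plus optional Gaussian or Poisson noise;
deterministic for a fixed seed. `make_reference_network` builds a planar
n×n lattice (2·n·(n−1) edges of ~100 μm, the capillary length scale of
these cultures, in a 150 μm-tall box) and solves the common tube radius in
closed form so the analytic S/V hits a target, default 4.5 mm²/mm³; the
vasculogenic style jitters node positions and flattens sections.

Not emulated: optics (PSF, z-attenuation, shot-noise structure),
autofluorescent clutter, probe diffusion gradients, wall signal, and
realistic junction geometry. Passing phantom tests therefore demonstrates
correctness of the geometric and flow computations on tube-like objects
with known truth — not robustness to every imaging artifact of real
confocal data; the segmentation stage in particular sees far cleaner
two-phase statistics in phantoms than in tissue.

## Numerical choices and degenerate inputs

* 26-connectivity throughout (thinning output, component labelling,
  graph tracing); standard for 3D skeletons.
* Axis order (x, y, z) with z the TIFF page axis; coordinates in μm are
  voxel index × spacing, voxel-centre convention, 0-based.
* Equal-size component ties break toward the component containing the
  lexicographically smallest voxel index.
* Uniform-intensity volumes are rejected by segmentation ("no separable
  phases"); empty masks are rejected by skeletonization, component
  filtering and plane fitting; collinear foreground columns make the plane
  fit degenerate and raise.
* Cross-section stations that miss the mask (skeleton/mask mismatch) are
  skipped with a warning; a branch with no valid station raises.
* Zero-chord (closed-loop) branches report NaN tortuosity.
* Test problem sizes: phantoms of 10⁵–10⁷ voxels on 1–2.5 μm grids, tube
  radii 4–30 voxels, networks of ≤ 12 branches for the solver oracle —
  sizes at which every analytic check above resolves comfortably.

## Known limitations

* The active-contour path is the only built-in segmenter; learned
  segmenters are supported through mask import only.
* Flow assumes rigid circular tubes, Newtonian fluid, no filtration, and
  no red-blood-cell rheology (Fåhræus–Lindqvist / plasma skimming); the
  exported node/segment tables feed external coupled 3D–1D solvers that
  model filtration.
* The vertical alignment corrects a single planar tilt; curved-substrate
  dewarping is out of scope.
* Junction-clump merging can displace a node by a voxel or two, and
  corner-like degree-2 junctions between collinear tube pairs dissolve
  into single curved branches — branch counts are therefore not directly
  comparable to a generator's tube count.
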