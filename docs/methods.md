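# Methods

This note documents the models, numerical choices, and limitations of
psrdose: what each component assumes, which knobs matter, and what the
synthetic studies do and do not demonstrate about real measured data.

## Beam model

The beam is described on a plane at `plane_z` (default 26 cm) below the
focal spot (`source_z` = 0), with the isocenter at `sad` = 100 cm; the
coordinate system is right-handed with z along the beam axis, lengths in
cm, energies in MeV. The plane is partitioned into `n_rings` equal-width
annuli up to `r_max` (default 8 cm) and `n_energy_bins` equal-width
energy bins over [0.25, 6] MeV, for three particle classes. Sub-sources
are ordered class-major, then energy, then ring; that ordering is the
column order of the sub-source dose matrix and is stable across runs.

The intensity/direction parameterization is a *toy stand-in* for forms
fitted from vendor phase-space files, chosen to preserve the structure
the algorithms rely on rather than any specific machine:

- per class, intensity factors into (ring area × exponential radial
  fall-off) × (gamma-shaped energy spectrum whose mean softens off axis
  by 30% at `r_max`);
- primary photons are harder (mean 2.0 MeV) and angularly narrow
  (0.01 rad, flat in radius); scattered photons are softer (1.2 MeV) and
  widen linearly with ring radius (0.03 → 0.08 rad); contaminant
  electrons are soft, broad (0.12–0.17 rad), and carry exactly
  `electron_fraction` (default 1%) of the total intensity;
- total intensity is normalized to 1 (particles per history).

**Sampling.** Sub-sources are drawn proportional to intensity among
those whose ring overlaps the jaw shadow on the phase-space plane
expanded by a `margin` (default 0.5 cm at the plane). Every sampled
particle's weight starts at 1 and is multiplied by the acceptance factor
q = (restricted intensity mass)/(total intensity mass), which makes
`(1/n) Σ w·dose` an unbiased per-full-history estimator: sub-sources
outside the restricted set would be blocked by the jaws anyway, and the
restricted ones are over-sampled by exactly 1/q. Positions are
area-uniform in the annulus, energies uniform within the bin (bins are
narrow), and directions are the focal ray through the sampled position
with a transverse Gaussian kick of scale equal to the sub-source angular
width. Sampling is fully reproducible from a seed; identical seeds give
bit-identical particle lists.

## Transport stand-in and the concurrent tally

Full condensed-history particle physics is out of scope. The transport
is deliberately simple but *deterministic per particle*, so that all
statistical noise originates in source sampling and a fixed particle
list always produces a bit-identical dose grid:

- each ray is intersected with the phantom box; along the ray, energy is
  deposited in steps of the smallest voxel dimension with an analytic
  depth kernel. Photons: k_E(d) = N(E)·(e^(−μ(E)d) − e^(−β(E)d)) with
  μ(E) = 0.04 + 0.05·e^(−E/3) cm⁻¹ and β(E) = max(5/(1+E/2), 2μ); the
  normalization N deposits the full particle energy over infinite depth,
  and the build-up term puts dmax near 1.5 cm at ~2 MeV, rising with
  energy. Electrons: a linear ramp over a practical range R = E/2 cm.
- each step's energy is spread over the eight surrounding voxels with
  trilinear (cloud-in-cell) weights. Lateral beam spread — including the
  wider penumbra of the scattered class — is carried entirely by the
  sampled angular widths, not by an extra smoothing kernel; this keeps
  the transport deterministic and fast at the particle budgets the
  commissioning matrix needs.
- rectangular jaws (X at 36 cm, Y at 44 cm from the source, zero
  transmission) collimate the beam between sampling and transport. The
  two different jaw elevations make rectangular fields
  non-interchangeable (6×15 vs 15×6 give distinct output factors).

**Matrix A.** Commissioning uses only the central-axis depth-dose column
and the inline/cross-line profile rows at requested depths. A per-voxel
row-index look-up table maps those voxels to rows (negative = ignored);
during transport every deposition into a mapped voxel is also added to
`A[row, subsource_index]`, scaled by the particle weight. A entries are
accumulated strictly in (particle, step, corner) stream order, which
makes the concurrent pass bit-identical to the sum of per-sub-source
passes on the same stream partitioned by sub-source, independent of
internal chunking — the property that lets one mixed-stream run replace
thousands of per-sub-source simulations.

**Uncertainty.** The particle stream is split into `n_batches` (default
10) contiguous batches; per-voxel/per-entry standard errors come from the
spread of batch means. The average statistical uncertainty of a dose is
the mean per-voxel SEM over voxels above 50% of a reference
(prescription-stand-in) dose, divided by that reference, in percent. The
statistical quality of A is a budget choice, not a contract; the
commissioning studies are constructed so their conclusions do not depend
on it (below).

## Commissioning

Stage 1 fits one non-negative factor per photon sub-source to the
measured-style data on rows labelled after-build-up, inner-beam, or
outer-beam; stage 2 fits one factor per electron energy-bin group to the
build-up rows with the photon dose fixed. Because the two row sets are
disjoint, stage 2 cannot change any stage-1 residual. Penumbra rows
(dose between 20% and 80% of the same-depth central-axis dose, dilated
by one measurement point each side) are excluded from both stages: the
point-wise difference there is dominated by sub-millimetre positioning,
which would mislead a least-squares objective. The build-up/after split
is the per-field dmax of the measured depth curve (parabolic sub-sample
refinement through the three highest samples), with a fixed-depth
override available. Because the toy electron range slightly exceeds
dmax, stage-1 rows retain a ~10⁻⁵-level electron tail that the photon
factors absorb; recovery tests account for this.

Measurements are relative, so a single closed-form scalar
s = argmin_s ‖s·A₁ₚ·1 − b₁‖ pre-scales the target; factors near 1 then
mean "no change", and s is folded back into the returned factors. Rows
are not weighted by measurement or tally uncertainty by default
(inverse-variance weighting sits behind a config flag).

**Solver.** Projected gradient descent on ‖Mx − b‖² with x ≥ 0:
Barzilai–Borwein (BB1) step lengths safeguarded by a halving line search
that keeps the objective non-increasing; x₀ = 1; stop when the relative
objective change falls below 1e−10 or at 20,000 iterations (the best
iterate is returned with a `converged` flag). scipy's active-set NNLS
serves as an independent oracle in the tests, never as the solver.

**What recovery tests show.** Synthetic measurements are manufactured
from the tallied matrix itself, b = A·x_true + ε, with ε i.i.d. Gaussian
scaled as a percentage of each field's dmax dose. This isolates the
commissioning mathematics from the Monte Carlo noise inside A: recovery
of A·x_true is well-posed regardless of how noisy A is, which is why the
default study's A (150k particles per field, ~41×41×100-voxel phantom at
1.25×1.25×0.25 cm, fields 40×40/10×10/2×2 cm², profile depths
dmax/5/10/20 cm) can stay modest. The individual factors are *not*
identifiable — adjacent energy bins produce nearly collinear dose
shapes — and on the excluded penumbra rows the fitted solution is not
pinned; recovery is therefore stated, and tested, as dose agreement on
the commissioning rows the model uses. What these tests do not show:
performance against real measurements, where A's noise, detector volume
effects, and model inadequacy all enter.

## Plan sampling

Fluence maps are rasterized at isocenter scale (0.25 cm pixels, grid =
jaw + 3 cm pad) on a plane at 50 cm from the source (the MLC upper
surface): FM(x,y,k) = MUₖ inside the aperture, MUₖ·T under a closed
leaf inside the jaw (T = 0.015 default), 0 outside the jaw. Leaves
travel along x; leaf pairs partition the jaw y-extent uniformly.

The inverse CPDF table stores, per pixel and probability bin
(default 16·K bins, nearest-bin lookup), the control point k satisfying
CPDF_{k−1} ≤ γ < CPDF_k — i.e. k is drawn with probability
FM(·,k)/ΣFM exactly, up to a quantization of at most half a bin around
each CPDF jump (tested to vanish as the resolution grows). The
FM-weighting baseline draws k uniformly and multiplies the weight by
K·FM(x,y,k), which gives it the same expectation as the biased method at
every (pixel, k) — the matched-estimand construction a fair efficiency
comparison requires; its per-pixel weight variance is never smaller.

Gantry rotation is about the y axis through the isocenter (IEC 61217
sense). The plan-dose loop samples near the arc's jaw, collimates,
assigns control points, rotates, and transports in batches until the
target average uncertainty is met; particles whose plane crossing lands
on a zero-mass FM pixel (outside the jaw shadow) are discarded with
weight 0 and counted separately from the "less useful" particles, which
are those assigned to a control point whose leaf is closed at their
position. A single-control-point open-field "arc" at gantry 0 reproduces
the static-field dose bit-exactly.

## Evaluation metrics

- RMS(%) = 100/D_max^m · sqrt(mean((D_c − D_m)²)) and
  Max(%) = 100/D_max^m · max|D_c − D_m|, with D_max^m the measured
  dmax dose — applied to low-gradient regions.
- DTA: for each measured point, the smallest |x − y| at which the
  linearly interpolated calculated curve attains the measured value;
  points with no crossing within 1 cm are capped and flagged rather than
  silently averaged.
- Output factor: central-axis dose at the field's own (parabolically
  refined) dmax over the reference field's, at matched SSD.
- 3D gamma: global normalization to the reference maximum (the
  literature is split between global and local; global is the choice
  here), 10%-of-max low-dose threshold, search radius 3× the distance
  criterion, evaluated dose interpolated on a 10× refined sub-grid.
  Offsets are visited in ascending spatial distance with early
  termination once no voxel can improve, making the exhaustive search
  tractable; results match a brute-force search on small grids. Gamma is
  asymmetric in (evaluated, reference) by definition and no symmetry is
  assumed; the passing rate is monotone non-increasing as criteria
  tighten.

## Synthetic studies: sizes and seeds

The default study uses 8 rings × 6 energy bins (144 sub-sources), three
commissioning fields, a K = 36 single-arc plan on a 30³ × 0.5 cm phantom
centred at the isocenter, and 150k particles per commissioning field —
sizes chosen so the full suite runs on one CPU at desk scale while every
algorithmic property (multi-field identifiability pressure, sparse VMAT
fluence, build-up resolution) is still exercised. A full-scale preset
(40 × 20 rings/bins, K = 178) exists for slower runs. Every generator is
driven by `numpy.random.SeedSequence` spawning, so a study is a pure
function of its seed.

## Known limitations

- The transport kernel has no scatter tails, no heterogeneity handling,
  and water-only radiological depth; absolute dose units are arbitrary
  (per-history kernel units), so only relative quantities are
  meaningful.
- MLC geometry is not transported; leaf transmission enters only through
  the fluence maps, and tongue-and-groove/rounded-leaf effects do not
  exist.
- The FM-weighting baseline's control-point draw (uniform over K) is one
  of several defensible conventions; MU-proportional drawing would shift
  its variance but not its expectation.
- Electron grouping assumes the electron spectrum shape within an energy
  bin is correct and only its amplitude needs tuning.
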