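# Methods

This note documents the models implemented in `carbonpb`, the choices
made where the design was genuinely open, and what the synthetic data do
and do not validate.

## Physical dose model

The dose at voxel *i* from a plan of scanning spots *j* is

    d_i(x, y, z) = Σ_j w_j Σ_{n=1..3} f_j^n(z_eff) G_j^n(x, y; z),

with `w_j` the spot weight (MU), `f^n` the integral depth dose of the
n-th component (Gy·mm²/MU) evaluated on the water-equivalent depth
`z_eff`, and `G^n` a *normalized* bivariate Gaussian
`(2π σ_x σ_y)⁻¹ exp[−Δx²/2σ_x² − Δy²/2σ_y²]` (plane integral exactly 1,
so the transverse voxel sum of a spot reproduces its IDD — asserted in
the tests at the 2% grid-discretization level).

Component semantics: n=1 is the primary carbon beam, n=2 fragments with
small-angle scattering (mixed with carbon), n=3 large-angle fragments.
The n=1 width combines the in-air optics (phase-space Gaussian with
waist at the isocenter) and in-medium multiple-Coulomb-scattering growth
in quadrature; components 2 and 3 are isotropic with linear depth
growth, and their depth is always taken along the spot's *central* axis.

**Coordinates.** The beam axis is z, isocenter at z = 0, +z toward the
source; voxel membership is by voxel-center containment and grids store
voxel centers.  Effective depth is the line integral of RSP along the
ray, accumulated per z-plane with nearest-voxel sampling.

### Beam splitting

Lateral heterogeneity off the spot axis is handled by splitting
component 1 once, at the plane 700 mm upstream of the isocenter, into
N×N sub-beams (default 3×3 = 9; the delivery-system default).  Each axis
of the phase-space Gaussian (position–angle covariance Σ) is decomposed
as Σ = Σ_sub + (1−f²)·a aᵀ, where a is the position column of Σ; the
rank-one spread is discretized with N-node Gauss–Hermite quadrature.
Consequences:

- sub-beam offsets come with correlated deflection angles
  (slope = S_xθ/S_xx per offset), so sub-beams diverge and sample
  different material columns downstream;
- the weighted mixture preserves the parent's moments through order 5
  for *any* sub-sigma fraction f;
- f is chosen at run time (bisection, cached) as the smallest fraction
  for which the mixture's sup density error stays below 0.5% of the
  parent peak — e.g. f² ≈ 0.72 for N=3, ≈ 0.19 for N=15.  This makes
  the homogeneous-water "split vs. unsplit within 1% of peak" property
  hold by construction while still narrowing sub-beams as N grows.

The literature decomposition re-splits at every heterogeneity; the
single 700 mm split implemented here mirrors the delivery-system
simplification and inherits its known limitation (residual error behind
lateral interfaces that decreases, but does not vanish, as N grows — the
engine reproduces this trend, asserted as a monotone-convergence test).

### Transit dose and control points

Raster scanning does not switch the beam off between spots; the moving
dose of a segment is current × period (period set by the slower scan
axis) and is deposited as equally spaced point deposits (≤ 1 mm apart,
a discretization the source does not prescribe).  Control points are cut
at: (1) stationary spot dose below a threshold (default 0.00018 MU);
(2) a change of range (energy); (3) beam-stop time strictly below 90 µs;
(4) moving-segment dose below the 0.00018 MU spot-position-monitor
threshold; (5) stopping:moving dose ratio away from 1:1 (relative
tolerance 1%).  Rules 1 and 4 are distinguished as stationary vs. moving
dose; the source wording is ambiguous on rule 1.

### MU calibration

1 MU is defined as 1 cGy mean physical dose to a 100 × 100 × 100 mm³
water volume irradiated at 200 mm range, so 200 MU correspond to
200 cGy.  `mu_calibration` builds that reference field (100 × 100 mm²,
100 mm SOBP, 6 mm spot spacing — spacing is our choice), computes it on
the fixed 2 mm grid with the homogeneous-water layered fast path
(mathematically identical to the per-spot sum for parallel unsplit
beams; equality is a unit test), and rescales the IDD tables so the mean
volume dose per MU is exactly 0.01 Gy.

## Synthetic beam library

Real commissioning feeds the model from measured IDDs, in-air profiles
and Monte-Carlo LET tables; none of those are available to a desk-scale
artifact, so the generator produces an analytic emulation:

- **IDD component 1**: rising entrance plateau (1 + 0.4 (z/z_peak)²)
  times an erfc range cutoff, plus a Gaussian peak; peak width
  σ = 0.35 + 0.008·R mm — the *effective* pristine-peak width of a
  3 mm-step machine (range straggling, momentum spread and mini-ridge
  broadening folded together), which is what makes 3 mm layer spacing
  produce ≤ ±2.5% SOBP ripple, as it does clinically.  The peak position
  is solved (Brent) so the distal 90% depth matches the requested range
  to < 0.25 mm.  Component 1 is identically zero beyond the primary
  range (z_peak + 4σ).
- **Components 2/3**: slow build-up to the peak, exponential tails
  beyond it (decay lengths 0.25·R+10 and 0.35·R+15 mm), amplitudes
  scaling with energy as (R/302)^0.8 — the fragmentation tail grows with
  energy, as measured.
- **Fragment ratio R(z)**: logistic rise centered at the peak from a
  small entrance value to exactly 1 beyond the primary range;
  non-decreasing by construction.
- **LET_d tables**: monotone analytic curves per species (carbon rising
  from ~11–45 keV/µm at entrance to 150 keV/µm at the peak; fragments
  2–12 keV/µm).  These stand in for Monte-Carlo LET_d; *absolute* RBE
  numbers from this package are therefore emulations, not reproductions.
- **Optics**: spot 1σ at isocenter 3.0·(302/R)^0.3 mm (x; y 6% larger),
  angular σ 2.5 mrad, waist at the isocenter; in-medium MCS growth
  ∝ weq^1.7 anchored to a Highland-like value at full range.
- **Absolute scale**: entrance IDD amplitude chosen so an uncalibrated
  library already sits near the 1 cGy/MU machine convention, which puts
  optimized spot weights inside the deliverable 0.0006–0.15 MU window.
- The per-energy absolute correction factor is drawn uniformly from
  [0.96, 1.02] (seeded), within the commissioning-typical band, and
  multiplies the IDDs in the engine.

Default machine: 100 nominal selections, ranges 5–302 mm water in 3 mm
steps, field ≤ 200 × 200 mm², dose rate 1–8 MU/s.

What passing tests show: internal consistency (conservation, linearity,
oracle agreement, parameter recovery) and qualitative physics (range
ordering behind heterogeneities, RBE rising toward the distal SOBP).
What they cannot show: agreement with any real machine's measured spot
sizes, absolute doses or patient QA pass rates — those comparisons
require measured beam data and are out of scope.

## Mixed-beam RBE chain

Per voxel: mixed LQ parameters are dose-weighted averages over all
contributions, carbon-isotope dose looked up in the carbon α/β(LET_d)
table and fragment dose in a helium-surrogate table; the carbon/fragment
partition of the physical dose is
`d^C = f¹G¹ + (1−R) f²G²`, `d^frag = R f²G² + f³G³` (sums to the total
exactly).  Survival `S = exp(−α_i d_i − β_i d_i²)`; biological dose is
the positive root of the photon LQ inversion
`d_bio = [−α_X + sqrt(α_X² − 4 β_X ln S)] / (2 β_X)` (β_X→0 limit
−ln S/α_X; the printed form of this inversion in the source material is
typographically garbled, so it is implemented from the defining
equation and verified by round-trip to 1e-10).  Clinical dose is exactly
1.46 × biological dose — the fixed clinical-RBE factor that anchors the
model to neutron-therapy experience.  β is dose-averaged directly, as
printed in the model definition (not √β-averaged); voxels with zero
physical dose are flagged (NaN) rather than zeroed.  Photon defaults are
HSG-like (α_X = 0.313 Gy⁻¹, β_X = 0.0615 Gy⁻²); the synthetic ion tables
keep α above α_X at low LET so entrance RBE > 1, and are user-replaceable
from delimited text files.

## Stoichiometric CT calibration

Theoretical CT number: μ ∝ Σ_i (ρ w_i/A_i)(Z_i + k₁ Z_i^3.62 +
k₂ Z_i^1.86), normalized to water (so water predicts 0 HU for any
coefficients); k₁, k₂ fitted to ≥ 4 inserts by least squares.  RSP via
Bethe–Bloch without energy-dependent corrections at β = 0.481
(131.0 MeV/u), I_water = 75.3 eV; element I-values are a
condensed-phase-adjusted ICRU-style table (Bragg additivity then puts
water within ~3% of 75.3 eV; water itself always uses 75.3 eV, making
RSP(water) ≡ 1).  The HU→RSP table holds one breakpoint per
representative tissue (11 emulated compositions shipped as fixtures —
the published reference set is not redistributed here) plus gold as the
final registered breakpoint at the 12-bit HU cap (3071), giving a
continuous, clamped map whose upper clamp is the gold RSP.  Duplicate
rounded HU are merged by averaging.  The composite range uncertainty is
the path-weighted sum σ_R = w_L σ_L + w_S σ_S + w_B σ_B with
user-supplied per-tissue-class uncertainties.

## Gamma index and profile metrics

Local normalization: the dose criterion scales with the local reference
dose; the threshold is a percentage of the reference maximum.  The
evaluated profile/map is linearly refined (10× in 1-D, 4× per axis in
2-D; refinements nest, so finer search never increases γ) and the search
is capped at 3×DTA — sufficient for any passing point and verified
against exhaustive brute force to 1e-6 on the test geometries.  R90 is
the distal 90% crossing (range context); level widths span the outermost
crossings; penumbrae are per-edge 20–80% spans; a level never crossed is
reported absent (None), not fabricated.

## Numerical choices

- Kernel depth grid 0.5 mm (4× finer than the fixed 2 mm dose grid).
- Lateral Gaussian evaluation truncated at 4.5σ (≤ 1e-4 relative error).
- Table lookups are linear; IDDs are zero beyond their grid, the
  fragment ratio is 1 beyond the primary range, LQM(LET) clamps at its
  grid ends (no extrapolation).
- SOBP optimization: NNLS on the central-axis layer-response matrix,
  flat target sampled at 1 mm; weights uniform per layer, rounded to the
  0.00001 MU resolution afterward.
- Ray tracing samples RSP at quarter-voxel steps (generic rays) or per
  z-plane (engine rays); space outside the grid contributes nothing.

## Known limitations

- Single-plane splitting under-corrects strong lateral heterogeneity
  near the entrance (by design, mirroring the system it emulates).
- Components 2/3 never see off-axis density; dose behind interfaces is
  least accurate where fragments dominate.
- Transit dose and control-point sequencing are first-order
  operationalizations of tersely specified delivery rules.
- No DICOM-RT ion I/O, multi-field plans, robust optimization, or
  microdosimetric-kinetic RBE model.
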