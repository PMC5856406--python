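# Methods

## Geometry model

The aortic-root lumen is a straight, rigid surface of revolution
perturbed by three sinus lobes. All lengths derive from the annulus
radius `r_a` (11 mm for the built-in presets) and five dimensionless
factors (`alpha_s`, `alpha_co`, `alpha_stj`, `beta1`, `beta2`). The
boundary radius is prescribed exactly at three stations: `r_a` at the
annulus (y = 0), the three-lobed profile at the widest sinus
cross-section (y = `beta1*r_a`), and `alpha_stj*r_a` at the sino-tubular
junction (y = `(beta1+beta2)*r_a`), circular and constant above it to
the domain top two annulus diameters past the STJ.

At the widest cross-section the boundary follows the arcs of three
circles of radius `r_sp` centred `r_mc` off-axis on bisectors 120° apart
(front lobe at +Z). The closed forms for `r_mc`/`r_sp` follow from
`r_sp + r_mc = alpha_s*r_a` together with the law-of-cosines constraint
`r_sp^2 = r_co^2 + r_mc^2 - r_co*r_mc`, which corresponds to an included
angle of 60° between the commissure direction and the lobe bisector.
With that angle the lobe arcs pass exactly through the commissure points
at radius `r_co` — the profile closes with no extra blending — so the
formula (rather than any prose description of the angle) is taken as
authoritative; the identities are enforced to 1e-9 relative tolerance in
tests.

Between the three stations the geometry is interpolated as a circular
baseline (cosine taper `r_a -> r_stj` over the sinus height) plus the
lobed profile's radial excess modulated by a C¹ cosine-squared bump
(0 at the annulus, 1 at the widest section, 0 at the STJ). This is a
modelling choice — only the three stations are prescribed — selected for
smoothness, matching the cast silicone phantoms. The sinus-less (NS)
preset uses the cosine taper alone.

Consequences worth knowing:

* Annulus-to-STJ volumes computed by polar/axial quadrature give
  V(L) ≈ 1.30 V(M), matching the "roughly 30% more" design statement.
  V(S) ≈ 0.76 V(M) rather than 0.70: holding `r_a` fixed while scaling
  the remaining dimensions −10% loses relatively less volume near the
  annulus. This asymmetry is a property of the scaling rule itself.
* Cross-section areas use 720 azimuthal samples by default; the profile
  has slope discontinuities only at the commissures, and refinement
  changes areas by <1e-4 relative.

Analysis domains: `Omega1` and `Omega2` are lumen slabs one and two
annulus diameters above the valve tips (half-open intervals, hence
disjoint); `OmegaS` is the front sinus lobe (azimuth within ±60° of +Z,
radius beyond the commissure circle, annulus to STJ). For NS the sinus
wedge is bounded inward by the annulus cylinder instead — the commissure
radius does not exist — and is flagged `degenerate` in reports so it is
never mistaken for a real sinus volume.

The flow coordinate `Y` used for cross-section flow rates has its origin
one annulus diameter above the valve tips (the `Omega1`/`Omega2`
boundary), so `Y = 0` sits mid-domain and slices at `Y = -20 ... 20 mm`
span the AAo measurement volume.

## Synthetic velocity fields

The generator emulates the kinematic structure of measured fields, not
their dynamics: it is a prescribed-form model, not a flow solution.

* **Waveform.** 72 bpm (T = 0.8333 s), systole one third of the cycle,
  peak 20 l/min, valve opening 0.06 s after the pump trigger. A half-sine
  of these parameters would eject only 58.9 ml, inconsistent with the
  measured 68 ml stroke volume, so the default is a trapezoid with
  rise/fall fractions 0.27 of systole (stroke volume 67.6 ml, cardiac
  output 4.87 l/min); the half-sine remains available.
* **Jet.** Axisymmetric axial profile: flat potential core of radius
  `r_jet` (from the projected orifice area), tanh shear layer of
  thickness 1.8 mm that thickens linearly past the STJ on the
  potential-core length scale 2·d_a, and a smooth wall cutoff. The
  profile is integrated into a Stokes stream function and normalized per
  cross-section, so the through-plane flux equals the waveform value
  *exactly* in the radial quadrature and within ~0.1% when sampled on
  ≤1.5 mm grids; radial velocities follow from the axial variation of
  the stream function, keeping the axisymmetric part solenoidal.
* **Retrograde flow.** A negative Gaussian annulus near the wall, ramping
  up from t = 0.12 s to valve closing, with peak speed `rf_amp` times the
  nominal jet speed. Its flux is included in the normalization, so
  conservation is unaffected. An azimuthal factor `1 + rf_asym*cos(theta
  - pi)` weights the RF toward the back sinus portion; it integrates to
  zero net flux. The per-phantom default `rf_amp` is proportional to the
  annular (wall minus jet) area fraction — the physical availability of
  low-momentum fluid — which makes RF grow with root size.
* **Starting vortex.** A Gaussian-core ring in the stream function,
  released at 0.075 s near the STJ plane and advected at 0.45 m/s, which
  places it one annulus diameter past the valve at t = 0.12 s and out of
  the domain within ~0.05 s. Its stream function vanishes on the axis
  and decays at the wall, so it is flux-free to within Gaussian tails
  (<1%).
* **Sinus swirl.** A circumferential component confined to the sinus
  annulus with amplitude 10% of the jet speed (kept under the observed
  15% bound).
* **Fluctuations.** Zero-mean Gaussian noise per component with sd
  `sigma_u`, smoothed by a periodic Gaussian kernel (2 voxels) and
  renormalized by the circulant kernel's L2 norm so the pointwise sd is
  exactly `sigma_u`; windowed by a shear-layer weight that widens and
  strengthens downstream, and scaled by the instantaneous flow fraction
  so diastole is quiescent. The per-phantom default `sigma_u` grows with
  the wall-to-jet gap, encoding that free shear layers are less stable
  than wall-bounded ones. The noise is not divergence-free — neither is
  PIV noise — and the analysis is insensitive to this.
* **Pulse-to-pulse jitter.** Each (phase, replicate) pulse scales its
  amplitude by `1 + 0.02*eta`, eta standard normal.

Every replicate derives its RNG from `(master_seed, phase, replicate)`
via `SeedSequence` spawn keys: ensembles are byte-identical under a
fixed configuration and seed, and fields can be generated lazily in any
order.

What the generator does *not* emulate: Navier–Stokes dynamics (no
momentum balance, no instability growth), leaflet kinematics, tomographic
reconstruction artefacts, or correlated turbulence spectra. Passing tests
therefore demonstrate that the *analysis chain* recovers injected
statistical and kinematic parameters, not that the generator predicts
real valve flow.

## Statistics

Phase averages are arithmetic means over the N replicates at a phase;
`u_rms` pools the three component variances with divisor N (population
convention). The N divisor is deliberate: it makes the decomposition
`mean kinetic energy + fluctuating kinetic energy = ensemble-mean total
kinetic energy` exact, which is enforced as a conservation test.
The one-pass (sum/sum-of-squares) route is numerically safe here because
velocities are O(1) m/s and N ≤ ~200.

Velocity gradients use second-order central differences where both
neighbours are inside the lumen mask, first-order one-sided stencils at
mask boundaries (keeping thin sinus regions populated), and are marked
undefined (NaN) where no valid neighbour exists. γ₃D is the eigenvalue
spread of the symmetrized gradient via `eigvalsh`; γ₂D uses the closed
2×2 form on the central Y–Z slice. Because the 2×2 in-plane block is a
principal submatrix of the 3×3 tensor computed with the same stencils,
Cauchy interlacing guarantees γ₂D ≤ γ₃D voxelwise — tested on random
smooth fields.

Flow rates integrate ⟨U_y⟩ (midpoint rule) over the lumen pixels of the
`Y = 0` section; the RF rate integrates only negative values and is
reported positive, following the operational definition used for the
flow-rate figures rather than the Ω₂-superscripted rendering of the
metric formula (the two disagree in the source; the operational one is
explicit). Windowed metrics use the trapezoid rule on the 13 phase
samples; all three standard windows land exactly on samples. Energies
are reported in millijoule.

Dimensionless numbers implement the printed formulas with unit handling
(l/min, mm, μm → SI). Two printed values do not reproduce from their own
formulas: the Womersley number evaluates to 13.9 (printed ≈15) — the
formula is implemented verbatim and the computed value reported — and
the particle relaxation time is dimensionally consistent only with
`d_p²` (giving the printed ≈21 μs at d_p = 42 μm), which is the form
implemented; the tracer diameter is configurable over the seeded 30–50 μm
range.

## Planimetry

The renderer draws a three-lobed polygon `r(phi) = r0(1 + 0.12 cos 3phi)`
scaled to an exact target area, plus three landmark dots, then applies an
affine camera distortion and additive noise. Rectification estimates the
unique affine from the three detected landmark centroids (ordered by
polar angle for correspondence) and resamples bilinearly; segmentation
takes the largest connected component above an Otsu (or fixed) threshold,
area = pixel count × pitch². The systolic mean A_POA averages frames
whose area exceeds half the pulse maximum — an operational gate; boundary
ramp frames flip membership under noise, so recovery is assessed against
the true areas of the *gated* frames (within 2% end-to-end under random
affine distortions and 5% noise). Landmark detection assumes synthetic
images; real-image strut detection is out of scope.

## Problem sizes and numerical defaults

Default pipeline grids use 1.5 mm spacing (~10⁴ lumen voxels per field);
unit and acceptance tests use 1.0–2.5 mm grids and 13×16 ensembles,
chosen so the statistical properties under test (flux conservation to
1%, 3-standard-error parameter recovery at N = 200, metric ordering
across presets) are resolved with comfortable margin. A 0.66 mm spacing
reproduces the ~400,000-vector resolution of the original measurement
volume and runs through the identical code path. Quadrature defaults:
720 azimuthal × 200 axial samples.

## Known limitations

* The axial lobe-blending profile is one smooth choice among many; only
  the three prescribed stations are constrained by the phantom design.
* The generator's amplitude scalings (`rf_amp`, `sigma_u` vs. root size)
  encode the observed qualitative trends; magnitudes of Ē_TJ, Q̄_RF and
  Ē_MKS are therefore illustrative, not predictive.
* Fluctuations are white in time across replicates; pulse-to-pulse and
  turbulent contributions are not separable, matching the pooled
  definition of `u_rms`.
* Wall compliance (~1% deformation in the experiments), coronary ostia,
  aortic curvature and leaflet motion are not modelled.
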