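# Methods

## Model

The package computes the geometric (scatter-free) beam profile that a finite
X-ray focal spot produces on the treatment plane after passing a stack of
circular apertures. It is a phase-space projection rather than particle
tracking: the spot is discretized into slices, each slice projected as a
point source, and the slice images summed.

Coordinates: heights are measured from the treatment plane upward, the source
sits at `H` (mm), apertures at heights `0 ≤ Ha < H`; all lengths are in
millimetres. A point source at lateral position `r0` through an aperture
(radius `Ra`, centre offset `c`) illuminates

    [ r0 + M(c − Ra − r0),  r0 + M(c + Ra − r0) ],   M = H / (H − Ha).

Internally both edges are signed treatment-plane coordinates; the
positive-magnitude "left edge" convention used in reporting is produced only
at the reporting boundary (`FieldInterval.edge_left_magnitude`). This removes
sign errors in interval intersection and in off-centre configurations, where
the closed-form mapping above (both physical edges shifted by `c` before
projection) generalizes the centred case.

With multiple collimation levels the illuminated interval is the
component-wise intersection (innermost edge per side); an empty intersection
contributes nothing. The profile on a uniform grid is

    Profile(r) = Σ_k S(r0_k) · 1[ r ∈ interval_k ] · Δr0.

Membership at an exact edge is closed on both ends; the choice is immaterial
as `Δr0 → 0` and is fixed for reproducibility.

### Assumptions

* 1D slab treatment: slice weights are the spot intensity along a diameter,
  not radial annuli; the angular dependence of emission is neglected. The 2D
  pixel mode (below) quantifies what this approximation costs.
* No interaction physics: no scatter, no attenuation in air or in the
  collimator material, no depth dose. Profiles are in-air geometric
  transmission.
* Apertures are ideal discs; a conical channel is represented by its entrance
  and exit apertures.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `grid_step` | 0.1 mm | treatment-plane resolution; matches the resolution at which reference profiles are quoted |
| grid range | ±(field/2 + 10 mm) | derived from the tightest aperture's projected field unless set explicitly |
| `slice_step` | 0.001 mm | spot discretization; see numerical notes |
| `truncation` | 4 σ | Gaussian span; omits 6.3e−5 of the spot mass |
| `fwhm` | 1.5 mm | Gaussian focal-spot width of the reference beamline |
| `normalization` | `"peak"` | slice intensity convention; `"total"` (unit integral) for dose-rate comparisons |
| penumbra thresholds | 20% / 80% of peak | relative to the actual profile peak, not a plateau estimate |
| detector window | off | top-hat moving average of the given diameter |

Thresholds are peak-relative because a heavily clipped small field may never
reach the open-field plateau; this matches small-field practice. A
consequence worth knowing: for a single aperture the widely used
plateau-relative closed form `(z_0.8 − z_0.2)·(M−1)σ = 1.6832·(M−1)σ`
overstates the peak-relative penumbra by ~1.3% (the actual peak is 0.9898 of
the plateau for the worked 0.9 mm aperture), so tests validate against the
exact closed-form crossings instead.

## Numerical choices

* **Slice step.** The integrand is an indicator times a smooth weight, so the
  quadrature error is dominated by the boundary bin: ≤ `Δr0 · S(boundary)`
  relative to the spot mass, about 6×10⁻⁴ of peak at the default 0.001 mm for
  a 1.5 mm spot — comfortably below the 10⁻³ oracle-equivalence budget while
  keeping a full profile under 50 ms. Runs that emulate coarser published
  settings (0.01 mm) shift penumbra values by ≲ 0.01 mm.
* **Symmetric grids.** Symmetric ranges are built as `step·arange(−m, m+1)` and
  Gaussian weights are evaluated from signed offsets, so centred systems are
  mirror-symmetric to floating-point rounding (< 1e−9 of peak, typically
  1e−15).
* **Crossing search.** Metrics scan from the grid boundary inward and
  interpolate linearly between the bracketing samples; the outermost crossing
  wins, which disambiguates noisy imported profiles. Missing crossings raise
  `UndefinedMetricError` rather than returning silently wrong numbers.
* **Degenerate cases.** `Ha = 0` gives `M = 1` (the aperture stamps itself);
  the closed-form oracle falls back to the exact top-hat there. Apertures at
  or above the source are rejected at validation time. Grids that would
  exceed 2×10⁶ points (e.g. an aperture microns below the source with an
  auto-derived range) are rejected with a clear error.

## Validation oracles

* **Closed form.** For one centred aperture and a centred Gaussian spot the
  membership condition is linear in `r0`, so the profile is
  `Φ((M·Ra − r)/((M−1)σ)) − Φ((−M·Ra − r)/((M−1)σ))`. The integrator matches
  it to < 10⁻³ of peak at defaults.
* **Monte-Carlo rays.** Source positions are sampled from the spot
  distribution; for each grid point the unique ray to that point is tested
  against every aperture disc. The same sample set serves all grid points, so
  deviations are correlated and smooth in `r`. Agreement within 3 binomial
  standard errors at every grid point is verified at 10⁶ samples for the
  two-aperture 4 mm system with a fixed seed. Same seed ⇒ bitwise identical
  output.

## The 2D pixel mode

`integrate_profile_2d` replaces 1D slices with 2D source pixels (isotropic
Gaussian) and interval membership with a point-in-disc test at every aperture
height. It exists for off-axis/misalignment maps and to bound the slab
approximation: disc membership of a 2D Gaussian and interval membership of
its 1D marginal are genuinely different edge responses, and the central row
of the 2D map differs from the 1D profile by up to ~7% of peak in the
penumbra region (FWHM within ~0.3 mm) for the reference systems. The 1D mode
is the method proper and the one the reference figures of merit are computed
with; the 2D mode is a cross-check and exploration tool.

## Example-system reconstruction

Only some numbers of the two bundled example systems are known from the
reference material: the 457 mm source-plane distance, the 1.5 mm spot FWHM,
the design field sizes (4 and 25 mm) and the 4 mm system's aperture diameters
(entrance 2.3 mm, exit 1.8 mm). Heights are not printed anywhere, so the
fixtures document a reconstruction:

* **Exit aperture** tangent to the point-source cone through the nominal
  field edge: `Ha = H·(1 − d/F)` → 251.35 mm for the 1.8 mm exit of the 4 mm
  system; the same height carries a 5.625 mm radius for the 25 mm field.
* **Entrance aperture** at 407 mm (50 mm below the source), where it trims
  far-off-focus rays. Note the entrance (2.3 mm) is *wider* than the exit yet
  converges relative to the beam divergence — it cannot be tangent to the
  same field cone (tangency would force the larger aperture nearer the
  plane), which is why its height is a documented assumption rather than a
  derived value.
* **25 mm system**: both radii scaled from the 4 mm system by the 25/4 field
  ratio (geometric similarity). This keeps the exit aperture in control of
  the field edge; a much smaller entrance (e.g. ≈1.7 mm) would intrude below
  the 80% level and inflate the 20–80% penumbra by ~0.5 mm, inconsistent with
  the reference penumbra for this system.

All reconstructed values are stated in `Fixture.notes` and overridable in
configuration files.

## Dose-rate convention

Peak ("dose rate") comparisons across spot sizes use sources normalized to
equal **total** intensity. With unit-peak spots, a smaller spot simply
carries less integrated intensity and every peak ratio is dominated by that
bookkeeping (a 1.0 mm spot would appear ~30% *weaker* than a 1.5 mm spot);
with equal totals the ratio isolates what the collimator clips, and the
smaller spot correctly shows a ~4% higher peak. Profiles used for shape
metrics (FWHM, penumbra) are peak-normalized, where the convention is
irrelevant.

## What the tests do and do not show

The synthetic systems exercise the geometry the method is built for —
centred and misaligned Gaussian spots, one- and two-level circular
collimation, field sizes from 4 to 25 mm. Passing tests demonstrate internal
consistency (oracle equivalence, symmetry, convergence, determinism) and
agreement with the reference systems' published figures of merit under the
documented reconstruction. They do not demonstrate agreement with measured
profiles of a physical machine: measured penumbras are broadened by detector
volume averaging (the `detector_convolve` operation emulates, not
reproduces, this), phantom scatter and source angularity, none of which are
in the model.

## Known limitations

* No transmission/leakage through aperture material: profiles fall to exactly
  zero outside the geometric field, so the low-intensity tails of real
  profiles are underestimated.
* Rectangular fields are composed as independent orthogonal planes; leaf-end
  and tongue-and-groove effects of real MLCs are not modelled.
* The Monte-Carlo oracle shares the geometric transport assumptions of the
  main engine; it validates the integration, not the physics.
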