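# penumbra

Fast synthesis of radiotherapy beam profiles through multi-aperture circular
collimators from a finite focal spot, built for iterating on small-field
(SRS-class) collimator designs where Monte-Carlo transport is too slow to sit
inside a design loop.

## Who this is for

Medical physicists and beamline engineers who need, in well under a second,
the treatment-plane profile a candidate collimator produces — and from it the
field size (FWHM), the 20–80% penumbra and the relative peak dose rate — as
functions of focal-spot size, aperture radii/heights and misalignment.

## The method

The focal spot at height `H` above the treatment (isocenter) plane is divided
into thin slices at lateral positions `r0_k`, each narrow enough to act as a
point source with the spot's intensity `S(r0_k)` (1D intensity along a
diameter; angular dependence neglected). A slice shining through a circular
aperture of radius `Ra` at height `Ha` illuminates the interval

    right_k = r0_k + M (c + Ra − r0_k),   left_k = r0_k + M (c − Ra − r0_k),

with magnification `M = H / (H − Ha)` and aperture offset `c`. With several
collimation levels the innermost edge on each side wins (interval
intersection). The profile is the sum over slices,

    Profile(r) = Σ_k S(r0_k) · 1[ r ∈ interval_k ] · Δr0,

evaluated on a 0.1 mm grid. From the profile the package computes the FWHM,
the per-side 20–80% penumbra (thresholds relative to the actual peak, linear
interpolation of the outermost crossings), peak ratios across configurations,
and a top-hat detector convolution that emulates finite-diode volume
averaging. Two independent oracles validate the integrator: a closed-form
CDF-difference profile for one centred aperture and a Gaussian spot, and a
seeded Monte-Carlo ray-transmission sampler.

Scatter, leakage through collimator material, air attenuation and depth dose
are out of scope; the model is purely geometric.

## Worked example

The bundled 4 mm conical collimator (457 mm source–plane distance, entrance /
exit aperture diameters 2.3 / 1.8 mm at reconstructed heights 407 / 251.35 mm,
Gaussian spot of 1.5 mm FWHM):

```python
import penumbra as pn

fx = pn.make_fixture("collimator4")
src, aps, geom = fx.config.build()
profile = pn.integrate_profile(src, aps, geom)
m = pn.compute_metrics(profile)
print(f"FWHM            : {m.fwhm:.3f} mm")
print(f"penumbra (L, R) : {m.penumbra_left:.3f}, {m.penumbra_right:.3f} mm")

res = pn.sweep_source_fwhm(fx.config, [1.5, 1.0])
print(res.table[["source_fwhm", "fwhm", "penumbra_right",
                 "peak_ratio_vs_first"]].to_string(index=False))
```

prints

```
FWHM            : 4.054 mm
penumbra (L, R) : 1.258, 1.258 mm
 source_fwhm     fwhm  penumbra_right  peak_ratio_vs_first
         1.5 4.053910         1.25838             1.000000
         1.0 4.003917         0.87441             1.042047
```

The field size barely moves when the spot shrinks from 1.5 to 1.0 mm FWHM
(4.05 → 4.00 mm), but the penumbra sharpens from 1.26 to 0.87 mm and the
peak dose rate rises by 4.2% — the smaller spot is clipped less by the
entrance aperture. That trade-off between spot size and collimator aperture
is exactly what the tool is for.

The same operations are available from a shell:

```bash
penumbra fixtures --out-dir configs
penumbra profile configs/collimator4.yaml -o p.csv
penumbra metrics p.csv -o m.json
penumbra sweep configs/collimator4.yaml --parameter fwhm --values 1.5,1.0 -o sweep.csv
penumbra oracle configs/collimator4.yaml -o oracle.csv --samples 1000000
```

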