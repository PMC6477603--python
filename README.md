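# spatula

Green's function molecular dynamics (GFMD) for the contact of **thin elastic
sheets** with **randomly rough surfaces**.

Biological adhesive systems — insect and gecko setae ending in spatula-shaped
pads, skin, membranes — press thin elastic layers onto rough counterfaces.
`spatula` models the minimal version of this problem: a sheet of width `w`
and contact modulus `E*`, supported from behind by a uniform fluid pressure
`σ0`, pressed against a rigid self-affine rough surface `h(r)`, with an
optional short-range adhesive traction.  The package answers *when is a
layer thin enough to conform — and to stick?*

## The model

The sheet's response is diagonal in Fourier space, `σ(q) = z(q)/G(q)` with

    G(q) = 2 f(qw) / (q E*),   f(t) = [sinh 2t + 2t]/[cosh 2t − 1 − 2t²].

`f → 1` (thick sheet) recovers the elastic half-space; `f ≈ 6/t³` (thin
sheet) gives plate bending, `1/G = E* q⁴ w³/12`.  Equilibrium against the
rough surface is found by damped Verlet relaxation with a hard-wall
constraint, finished by an operator-splitting polish (see
`docs/methods.md`).  Headline scaling results, with `W = w/λs` the width in
units of the shortest roughness wavelength:

* area–load relation `A/A0 = erf(k σ0/E*)` with `k ≈ 2` in the thick limit
  (surfaces normalized to unit rms slope);
* thin sheets reach the same area at loads smaller by a coefficient
  `c(W) ~ W⁻³`;
* the adhesion parameter `θ = U_el/U_ad` drops as `W³` — thin sheets adhere.

## Worked example

```python
from spatula import (SpectrumSpec, LayerSpec, SolverConfig,
                     generate_heightfield, build_kernel, relax)

spec = SpectrumSpec.from_wavelengths(lambda_r=32.0, lambda_s=4.0, hurst=0.8)
surface = generate_heightfield(spec, n=128, a=1.0, seed=7)   # rms slope 1, max 0

for name, layer in [("half-space", LayerSpec.half_space(estar=1.0)),
                    ("thin sheet W=0.25", LayerSpec(estar=1.0, w=1.0))]:
    kernel = build_kernel(layer, surface.n, surface.spacing)
    res = relax(surface, kernel, SolverConfig(sigma0=0.02, max_steps=30000))
    print(name, res.area_fraction, res.normalized_separation)
```

prints (examples/single_contact.py):

```
half-space          A/A0 = 0.0570   s~ = 0.389
thin sheet W=0.25   A/A0 = 0.2687   s~ = 0.033
```

At the same dimensionless load the thin sheet makes ~5× the contact area of
the half-space and has nearly closed the mean gap (`s~ → 0`): its bending
compliance lets it drape into the roughness valleys.  More narrative
scripts live in `examples/` (surface synthesis and Hurst recovery, an
area–load sweep with the erf fit, the `W⁻³` theory predictor).

A thin CLI wraps the library:

```
spatula generate-surface --n 256 --seed 1 --out surf.txt
spatula solve --surface surf.txt --w 1.0 --sigma0 0.02 --out run
spatula sweep --widths inf,0.25 --outdir out/
spatula width-scan --outdir out/    # c(W) and its power-law fit
spatula theta-scan --outdir out/    # theta(W) at fixed area fractions
spatula theory                      # Persson broadening across W
```

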