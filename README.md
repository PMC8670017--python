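# ctrecon

Parallel-beam CT reconstruction in pure scientific Python: filtered
backprojection (FBP), direct Fourier inversion, and algebraic (Kaczmarz)
reconstruction, together with the machinery a reconstruction study needs —
phantom generation with insertable lung nodules, sinogram noise models,
ramp-family reconstruction filters, overlapping block processing, a
momentum-trained convolutional post-filter, and image-quality /
nodule-detectability evaluation.

The package is aimed at people studying how reconstruction algorithm choice
affects downstream image quality and small-lesion detectability — e.g.
comparing FBP against Fourier-gridding and iterative methods on controlled
synthetic data before touching clinical pipelines. No patient data is
required or shipped: lung-like phantoms with nodules of prescribed diameter
and contrast stand in for real scans.

## The model

An image `f(a, b)` of attenuation coefficients is observed through its
parallel projections (the Radon transform)

    T(s, α) = ∫ f ds   along the ray at angle α with signed offset s,

where `s = a·cos α + b·sin α` and the ray runs along `c = b·cos α − a·sin α`.
Three inversions are implemented:

- **Filtered backprojection.** By the Fourier slice theorem, the 1D spectrum
  of `T(·, α)` is the central slice of `F(i, j)` at angle α. Writing the
  inverse 2D transform in polar coordinates and using the half-turn symmetry
  `T(s, α+π) = T(−s, α)` gives

      g_α = ℱ⁻¹[ |ω| · ℱ T(·, α) ],      f(a, b) = ∫₀^π g_α(a cos α + b sin α) dα.

  `|ω|` is the Ram-Lak ramp; apodizing it with a sinc window (the ramp
  convolved with sin(x)/x in the spatial domain) gives the Shepp-Logan
  filter, trading a little resolution for noise suppression.
- **Direct Fourier reconstruction.** Place each projection's 1D spectrum on
  the corresponding central slice of a Cartesian frequency grid (nearest or
  linear gridding with weight normalization) and invert the 2D transform.
- **Algebraic reconstruction (ART).** Discretize the forward model as a
  sparse system `A x = T` (ray-driven bilinear footprints) and cycle Kaczmarz
  row projections `x ← x + λ (Tᵢ − ⟨aᵢ, x⟩)/‖aᵢ‖² · aᵢ` in seeded random
  order.

A single-layer convolutional post-filter `T(x) = d(H*x + p)` can be trained
on (degraded, truth) pairs by gradient descent with momentum
(`v ← βv − η∇`, `H ← H + v`) to clean up reconstructions. Overlapping block
processing (e.g. 32×32 tiles at overlap step 16) with partition-of-unity
merging supports tiled pipelines and the block-parameter sweeps.

## Worked example

```python
import ctrecon as cr

phantom = cr.make_shepp_logan(128)          # standard ten-ellipse head phantom
phantom.pixels /= 2.0                       # scale to [0, 1]
sino = cr.radon_forward(phantom, cr.default_geometry(128, 360))

for name in ("ram-lak", "shepp-logan", "none"):
    rec = cr.fbp_reconstruct(sino, name)
    q = cr.quality_report(rec, phantom)
    print(name, round(q.masked_rmse, 4), round(q.correlation, 4))
```

prints

```
ram-lak 0.0528 0.9828
shepp-logan 0.0593 0.9797
none 129.8969 0.8111
```

— the ramp filter recovers the phantom to ~5% RMS inside the field of view;
the apodized filter is slightly softer; with no filter the backprojection is
the blurred, unnormalized smear that motivates filtering in the first place.
The `examples/` directory holds one short script per capability (projection
and symmetry checks, filter comparison, the three-algorithm comparison with
nodule CNRs, block sweeps, post-filter training, and the detection
benchmark); each prints the numbers it computes and what they mean.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computations from scratch with the given seed:
the noiseless three-algorithm reconstruction comparison on the head phantom,
post-filter training on noisy FBP/truth pairs, and the 50-phantom seeded
nodule-detection benchmark (Poisson noise, I0 = 10⁴, CNR threshold 3),
logging summary figures to stderr and writing the results JSON to `--out`.
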