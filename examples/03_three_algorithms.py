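"""The three-way comparison: FBP vs direct Fourier vs algebraic (ART).

Projects a lung-like phantom with two nodules, adds Poisson photon noise
(I0 = 1e4 incident photons per ray), reconstructs with all three methods
and reports image quality plus each nodule's contrast-to-noise ratio.
FBP typically gives the cleanest images and the best nodule CNR; simple
nearest-neighbor Fourier gridding shows interpolation artifacts; ART
needs iterations but handles the noise gracefully.
"""

import warnings

import ctrecon as cr

warnings.simplefilter("ignore")

spec = cr.sample_lung_phantom(7, n=128, pixel_size=2.0)
truth = cr.render_phantom(spec)
for nd in spec.nodules:
    print(
        f"nodule: {nd.diameter:.1f} mm ({nd.size_class}), contrast "
        f"{nd.contrast:.3f}/mm at ({nd.center_ab[0]:.0f}, {nd.center_ab[1]:.0f}) mm"
    )

geom = cr.default_geometry(128, 120, pixel_size=2.0)
sino = cr.radon_forward(truth, geom)
noisy = cr.add_sinogram_noise(sino, "poisson", 1e4, seed=8)

recons = {
    "fbp": cr.fbp_reconstruct(noisy, "shepp-logan"),
    "fourier": cr.fourier_reconstruct(noisy, 128, "nearest"),
    "art": cr.art_reconstruct(noisy, 128, sweeps=8, relaxation=0.5, seed_order=9, nonneg=True),
}
print(f"\n{'method':>8s}  {'masked RMSE':>11s}  {'corr':>6s}  nodule CNRs")
for name, rec in recons.items():
    q = cr.quality_report(rec, truth)
    cnrs = [o.contrast_to_noise for o in cr.detect_nodules(rec, spec, algorithm=name)]
    cnr_txt = ", ".join(f"{c:.1f}" for c in cnrs)
    print(f"{name:>8s}  {q.masked_rmse:11.5f}  {q.correlation:6.3f}  {cnr_txt}")
print("\n(a nodule counts as detected when its CNR reaches the Rose criterion of 3)")
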