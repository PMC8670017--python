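"""Filtered backprojection and the role of the reconstruction filter.

Reconstructs a noiseless phantom with the ramp (Ram-Lak) filter, the
sinc-apodized Shepp-Logan filter, and no filter at all.  The unfiltered
backprojection shows the classic 1/r blur; the ramp restores resolution;
the apodized ramp trades a little resolution for noise robustness.
"""

import warnings

import ctrecon as cr

warnings.simplefilter("ignore", cr.TruncationWarning)

phantom = cr.make_shepp_logan(128)
phantom.pixels /= 2.0  # scale to [0, 1]
sino = cr.radon_forward(phantom, cr.default_geometry(128, 360))

print("filter responses at DC / half-Nyquist / Nyquist:")
for name in ("ram-lak", "shepp-logan", "hann"):
    f = cr.ReconFilter(name)
    print(
        f"  {name:>12s}: {cr.filter_response(f, 0.0):.3f} / "
        f"{cr.filter_response(f, 0.5):.3f} / {cr.filter_response(f, 1.0):.3f}"
    )

print("\nreconstruction quality vs ground truth (masked RMSE on [0,1] scale):")
for name in ("ram-lak", "shepp-logan", "none"):
    rec = cr.fbp_reconstruct(sino, name)
    q = cr.quality_report(rec, phantom)
    print(f"  {name:>12s}: masked RMSE {q.masked_rmse:.4f}, correlation {q.correlation:.4f}")
print(
    "  (without a filter the backprojection is blurred and offset; the ramp"
    "\n   family inverts the Radon transform's 1/r point response)"
)
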