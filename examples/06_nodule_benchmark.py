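"""Nodule-detection benchmark across reconstruction algorithms.

Renders seeded lung phantoms, each carrying one sub-6 mm and one 6-30 mm
nodule, pushes Poisson-noisy sinograms through FBP and direct Fourier
reconstruction, and scores every nodule by contrast-to-noise ratio (Rose
threshold 3).  Reported rates are per algorithm and size class with Wilson
95% intervals.  The informative result is the ordering -- FBP at or above
the simple Fourier gridding, small nodules never easier than large ones --
not the absolute percentages, which depend on the synthetic noise level.
"""

import warnings

import ctrecon as cr

warnings.simplefilter("ignore")

algorithms = {
    "fbp": lambda s: cr.fbp_reconstruct(s, "shepp-logan"),
    "fourier": lambda s: cr.fourier_reconstruct(s, s.geometry.n_detectors, "nearest"),
}

table = cr.run_detection_benchmark(
    algorithms, n_phantoms=20, seeds=range(20), noise_model="poisson", noise_level=1e4
)
summary = cr.summarize_detection(table)
print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(
    f"\nper-nodule records: {len(table)} "
    "(phantom x nodule x algorithm; save with table.to_csv(...))"
)
med = table[table["evaluable"]].groupby(["algorithm", "size_class"])["cnr"].median()
print("\nmedian CNR by algorithm and size class:")
print(med.to_string(float_format=lambda v: f"{v:.2f}"))
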