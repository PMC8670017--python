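# Methods

This note records the models implemented, the numerical choices behind
them, what the synthetic data does and does not emulate, and the known
limitations. Everything quantitative stated here is computed by the test
suite or the acceptance script; nothing is quoted from external results.

## Geometry and conventions

Images are square `N×N` attenuation maps with physical pixel size (mm per
pixel). The coordinate origin sits at pixel index `(N//2, N//2)`, with the
`a`-axis rightward along columns and `b`-axis upward. Angles are measured
from the `a`-axis, counter-clockwise; the detector coordinate of a point is
`s = a·cos α + b·sin α` and the along-ray coordinate `c = b·cos α − a·sin α`
(the standard rotation; one printed variant of this identity with a flipped
sign is inconsistent with the rest of the derivation and is not used).
Detector bin `D//2` sits on the rotation axis. Reconstruction methods
require angles in `[0, π)` — the half-turn symmetry `T(s, α+π) = T(−s, α)`
makes the second half circle redundant — while the symmetry checker accepts
`[0, 2π)` acquisitions. Defaults: `D = N`, detector spacing = pixel size,
`P` equally spaced angles over `[0, π)`.

## Forward model

`radon_forward` is ray-driven: each (angle, detector) ray is sampled at
step `min(pixel_size, detector_spacing)/2` with bilinear interpolation
(zero-padded beyond the grid, scipy's `grid-constant` mode) and summed
times the step. Consequences verified by tests: linearity to machine
precision, per-angle mass conservation to <1%, and agreement with the
closed-form chord profile of a disk to <2% of the diameter.

One numerical caveat drove a test-design choice: at the exact tangent ray
of a disk (`|s| = r`) the chord formula has a square-root singularity, and
*any* pixel-grid representation of the disk disagrees with it by
O(√(r·px)) there. Chord-oracle tests therefore use a half-integer radius
so no detector bin sits exactly on the rim; away from the rim the
agreement is ~1%.

The ART system matrix uses the identical sampling rule, scattered as
bilinear footprints into a sparse matrix, so `A @ vec(img)` reproduces
`radon_forward(img)` to machine precision — the two forward models are one
model.

## Reconstruction filters

`filter_response` reports the analytic responses in Nyquist units:
`|ω|` (Ram-Lak), `|ω|·sinc(ω/2)` (Shepp-Logan; equals 2/π at Nyquist),
`|ω|·(1+cos πω)/2` (Hann), each zeroed beyond a configurable cutoff
(default 1.0, i.e. full bandwidth).

The *discrete* filter used by `filter_projections` is built in the spatial
domain: the band-limited ramp kernel `h[0] = 1/(4Δs²)`, `h[k] = 0` for even
`k`, `h[k] = −1/(π²k²Δs²)` for odd `k`, transformed by DFT and multiplied
by the apodization window. Sampling `|ω|` directly in the frequency domain
would underweight low frequencies and bias the DC level of reconstructions;
the spatial construction avoids that, and makes the filter's impulse
response exactly the closed-form kernel (tested to 1e-6). Rows are
zero-padded to the next power of two ≥ 2D before the FFT to suppress
circular wrap-around. The kernel's `1/Δs²` scaling times the step-length
scaling of the projector makes FBP amplitudes grid-independent.

Backprojection interpolates linearly into the detector array
(nearest-neighbor available) and discretizes the angle integral as `π/P`
times the sum. Pixels outside the inscribed circle are retained in the
output; quality metrics report both full and circle-masked RMSE because
the corners are never crossed by a full ray set.

## Direct Fourier reconstruction

Projection spectra are computed with the detector center rolled to index 0
so phases are referenced to `s = 0` (an explicit linear phase handles
off-center detectors). Gridding scatters each polar sample onto the `n×n`
frequency grid by nearest-neighbor or bilinear (inverse-distance) weights
with per-cell weight normalization; unvisited cells (the high-frequency
corners) are zeroed — an implicit low-pass — and a warning fires if more
than half the cells are unvisited. Conjugate symmetry is enforced by
averaging the grid with its reflected conjugate, so the inverse transform
is real to better than 1e-6 relative. Nearest-neighbor gridding is kept
deliberately simple: its artifacts are the textbook reason FBP wins the
three-algorithm comparison, and the benchmark asserts exactly that
ordering rather than any absolute error.

The slice-theorem checker zero-pads the image 4× before the 2D FFT so
bilinear interpolation between spectrum samples is not the dominant error
term; with that, a Gaussian phantom agrees to <2% per angle.

## Algebraic reconstruction

Kaczmarz sweeps visit rows in a fresh seeded permutation each sweep
(sequential order causes directional artifacts; the seed restores
reproducibility). Relaxation λ must lie in (0, 2); zero-norm rows (rays
missing the grid) are skipped and counted. Optional non-negativity clamps
after each sweep, and an optional early stop triggers when the residual
reaches zero or its relative change over a sweep falls below 1e-6. On
consistent systems the distance to the least-squares solution is
non-increasing per sweep (property-tested); the residual itself is also
monotone on the shipped toy systems, but that is not a theorem for
arbitrary systems. SIRT is available behind a flag as a smoother, slower
comparator. Sweep count is a fixed user parameter; equivalence with any
particular clinical iterative product is not claimed — only membership in
the row-action family.

## Block processing

"Overlap step" is read as the stride in pixels between tile origins, so
32×32 blocks at step 16 give 50% overlap and `((side−B)/S + 1)²` tiles
(225 on a 256 image). Images whose side does not fit the lattice are
reflection-padded and the padding stripped on merge. Merging averages
covering tiles under either flat or raised-cosine weights; the raised
cosine is sampled at half-integer offsets so it is strictly positive at
tile edges and the normalized weights are defined everywhere. The average
is accumulated in deviation-from-reference form, which makes an
unmodified split→merge round trip bit-exact rather than merely close.
Wall-clock timings in the sweep harness are reported for orientation only
and are never asserted on — they are hardware facts, not algorithm facts.

## Convolutional post-filter

The post-filter is a single convolution layer with bias and optional ReLU,
trained by momentum SGD on the mean squared residual against ground truth.
One layer is deliberate: the update equations implemented define one
kernel's dynamics, and the single-layer least-squares problem has an
analytic gradient that is verified against finite differences to 1e-5.
The momentum recursion is the standard velocity form
`v ← βv − η·∇`, `H ← H + v`; the alternative reading that multiplies β by
the kernel itself (rather than by accumulated gradients) makes the kernel
grow without bound even at zero gradient — it is preserved behind
`literal_update=True` purely as a demonstration and a test pins its
divergence. The learning rate η absorbs the momentum/step-size product into
one hyperparameter. Reflection padding keeps the output size equal to the
input; the gradient accounts for the padding exactly.

## Synthetic data and what green tests mean

The lung phantom is a body ellipse (attenuation 0.02/mm, roughly soft
tissue at CT energies) with two lung fields at 0.004/mm, on a 128 grid at
2 mm/pixel (256 mm field of view). Each sampled phantom carries one
sub-6 mm and one 6–30 mm nodule at +0.014/mm contrast, positions jittered
inside the lung fields. Sinogram noise is Poisson photon statistics with
I0 = 10⁴ incident photons per ray (counts re-logged to line integrals;
zero counts clamped to one photon with a warning) or additive Gaussian.
These choices are fixed once as realistic desk-scale values and are not
tuned per experiment.

The detection rule is artifact-defined: a nodule is detected when its
contrast-to-noise ratio — disk mean minus equal-area annulus mean, over
the pixel standard deviation of a same-tissue background band — reaches
the Rose-criterion threshold of 3. The same-tissue restriction (derived
from the nodule-free phantom) matters: without it the "noise" estimate is
dominated by anatomy edges and penalizes large nodules spuriously. This
detector is a stand-in for a human reader. Green benchmark tests therefore
establish *orderings* (FBP ≥ nearest-neighbor Fourier in both size
classes; sub-6 mm never easier than 6–30 mm; rates monotone in photon
count and threshold) on this synthetic world — they do not establish
clinical detection percentages, observer performance, or anything about
real anatomical texture, which the phantoms do not model.

## Numerical details worth knowing

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); seeded runs are byte-reproducible and a
  test pins this end to end.
- PSNR uses the truth's peak-to-peak range; it is +inf for an exact match
  and NaN for a constant truth. Pearson r is NaN when either image is
  constant.
- Noise-free CNR on an exact phantom divides by a guarded ε, so noiseless
  detection saturates rather than dividing by zero.
- 16-bit image exports are min-max scaled with the scale recorded in a
  JSON sidecar; round trips are exact to one quantization step. NPY is the
  lossless interchange format. All writes are atomic (temp file + rename).
- DICOM reading (rescale slope/intercept, first frame of multi-frame) is
  implemented behind a lazy pydicom import and raises a clear error when
  pydicom is not installed; writing DICOM is out of scope.

## Limitations

Parallel-beam only (no fan/cone beam, no scatter or beam hardening); 2D
only; the Fourier path uses simple gridding rather than NUFFT-grade
kernels; the iterative method is unregularized Kaczmarz/SIRT; the
post-filter is a single layer by design; phantoms are piecewise-constant
ellipse sets without anatomical texture.
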