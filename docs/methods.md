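# Methods

## Measurement model

A scene is an `M × M` transmittance map `x ∈ [0, 1]^N`, `N = M²` (default
`M = 32`). Illumination patterns are rows of a Sylvester Hadamard matrix
`W ∈ {−1, +1}^{N×N}` built by the block recursion `W_{2n} = [[W_n, W_n],
[W_n, −W_n]]`, which guarantees `W Wᵀ = n I` in exact integer arithmetic.
Because a micromirror can only transmit or block, each row is displayed as
the binary mask `(W + 1)/2` and its complement; the differential reading of
the pair is

    y_k = g · (w_k⁺ · x) − g · (w_k⁻ · x) = g · (W x)_k ,

so subtraction simultaneously realizes the ±1 basis and cancels any
constant dark offset (tested explicitly). On the DMD, each image pixel is a
28 × 28 mirror block; a 32 × 32 pattern occupies the centered 896 × 896
mirror region of the 1140 × 912 frame, giving 28 × 0.0076 mm = 0.2128 mm
per image pixel. The block expansion is exactly invertible by block
averaging, which the tests use as the layout oracle.

Row-to-image reshaping is row-major with a top-left origin throughout;
reconstruction uses the same convention, so the choice is load-bearing but
arbitrary.

The detector chain applies a gain `g` (volts per unit integrated
transmittance, default 0.01 — chosen so the brightest flat-field reading
stays below the 10 V ADC range), additive Gaussian noise (default
0.5 LSB ≈ 76 µV), an optional `sqrt(signal)` term (off by default), and a
16-bit quantizer with round-half-up and clamping to [0, 10 V]
(LSB = 10/2¹⁶ V ≈ 0.153 mV). A noiseless reading that exceeds full scale
raises an error rather than clipping: saturation is an acquisition-design
fault, not data.

## Reconstruction

At full sampling the inverse is the scaled transpose, `x = Wᵀ y / n`; the
noiseless round trip is exact to numerical precision and the suite verifies
it against an independent dense linear solve.

At reduced sampling the first `m` Walsh-ordered rows form the sensing
matrix `Φ` (sequency — the count of sign changes along a row — sorted
ascending; low-sequency rows carry coarse structure, so a leading subset is
the informative one). The estimate minimizes

    ‖Φx − y‖₂² + λ‖Ψx‖₁ + μ·TV(x)

with `Ψ = I` (the dictionary slot is pluggable but only the identity is
shipped) and anisotropic TV (sum of absolute horizontal and vertical first
differences). The solver is a monotone FISTA: a gradient step on the data
term with exact step size `1/N` (distinct Hadamard rows are orthogonal with
squared norm `N`, so the Lipschitz constant needs no estimation), then
soft-thresholding, then the TV proximal step computed by 30 projected
gradient iterations on the dual (step 1/8, the inverse Lipschitz constant
of the 2-D difference operator). The accepted iterate is never allowed a
worse objective than its predecessor, which makes the recorded objective
history non-increasing by construction; termination is a relative objective
change below `tol` (default 1e−6) or `max_iter` (default 500), the latter
flagged as non-convergence in `solver_stats`. Measurements are normalized
by their maximum absolute value inside the solver so the default penalties
λ = 0.01, μ = 0.1 are scale-free; both are exposed in the config.

The proximal step applies the ℓ1 and TV operators sequentially, which is an
approximation to the exact prox of their sum; with the small default λ the
error is negligible and the monotone safeguard absorbs it.

## Time-of-flight diffusion fitting

Transmittance of a picosecond pulse through a slab of thickness `d` (mm) is
modelled with the diffusion approximation and four image sources:

    T(d, t) = (4πDc)^{-1/2} t^{-3/2} e^{−μ_a c t} ·
              [ (d−z₀)e^{−(d−z₀)²/4Dct} − (d+z₀)e^{−(d+z₀)²/4Dct}
              + (3d−z₀)e^{−(3d−z₀)²/4Dct} − (3d+z₀)e^{−(3d+z₀)²/4Dct} ]

with `D = 1/(3μ_s′)` mm, `z₀ = 1/μ_s′` mm, and `c` the in-medium speed of
light (default 0.2219 mm/ps, refractive index ≈ 1.351; configurable). Tiny
negative values from cancellation of the image-source terms are clamped to
zero. The default grid is 1–2000 ps at 1 ps.

A measured waveform is emulated by convolving the model with an instrument
response on the same grid (truncated discrete convolution, renormalized to
preserve the model's time integral), Savitzky–Golay smoothed (quadratic,
11-sample window — small against the hundreds-of-ps pulse width), and
peak-normalized. Fitting minimizes the squared residual between this
forward pipeline and the measured waveform, restricted to the window from
the first 5 %-of-peak crossing on the rise to the last on the tail (linear
interpolation between samples). The 5 % rule is interpreted against *peak*
intensity, not cumulative counts; the level is a parameter. For strongly
scattering media the tail may still exceed 5 % at the end of the 2000 ps
grid; the window is then truncated at the last sample, which does not bias
the noiseless fit.

The optimizer is bounded trust-region least squares over
`(μ_a, μ_s′) ∈ [0, 1] × [0.05, 200]` mm⁻¹, start (0.001, 10). When the
medium is known to be nearly non-absorbing at the laser wavelength
(intralipid at 846 nm), a flag narrows `μ_a` to [0, 0.01] mm⁻¹. The
residual landscape has flat shoulders far from the truth, so a failed or
poor first fit triggers a small multi-start grid over
μ_s′ ∈ {5, 10, 20, 50}; failure is reported via `converged=False`, never as
a silent estimate. Noiseless parameter recovery over
μ_s′ ∈ {5, 10, 12.58, 15, 20} mm⁻¹ at d = 3 mm is exact to machine
precision; with 1 % multiplicative noise the median error is ~0.2 %.

## Detection pipeline

Per sample, the three reconstructed bands (850, 910, 970 nm) are divided by
the reconstructed intralipid flat-field (floored at 1e−6, floored pixels
counted), cancelling global source-intensity scale exactly (tested as an
invariance). Each pixel then contributes a 3-vector of corrected
transmittances; PCA (bands mean-centered, *not* variance-standardized, so
loadings reflect physical contrast magnitude) extracts PC1. The eigenvector
sign is arbitrary, so it is anchored by requiring non-negative correlation
of the score image with mean band brightness: bright chocolate sits high,
an absorbing insect low. The score image is min–max scaled to [−1, 1];
pixels strictly below 0.7 become insect candidates; 8-connected components
(4-connected switchable) smaller than 5 pixels are removed (a 5-pixel
component survives — the cutoff is strict); the sample is contaminated iff
any candidate survives. A constant (degenerate) PC1 image carries no
contrast and is classified clean.

PCA is fitted per sample by default; `fit_cohort_loadings` offers pooled
loadings across a cohort as an option.

Note a structural property of this literal chain: after per-image min–max
scaling, a threshold of 0.7 flags the bottom 85 % of the *range*, so every
non-degenerate clean image flags at least its minimum pixel. Clean samples
are therefore cleared solely by the area filter — their flagged pixels must
be sparse and isolated. This is by design (see phantoms below) and is the
reason the pipeline is sensitive to smooth illumination gradients: a tilted
sample whose gradient survives reference correction flags a large connected
region and produces a false positive, which the suite reproduces.

## Phantom generator

The generator emulates 3 mm tempered-chocolate slabs at 32 × 32 pixels
(0.2128 mm/pixel). Defaults, all config-exposed:

* Chocolate baseline transmittance (850, 910, 970 nm) = (0.10, 0.15, 0.20):
  rising with wavelength, as chocolate absorbs less in the NIR. The
  magnitudes are declared modelling assumptions, not measured values.
* Insect: filled ellipse, 3 mm major axis (≈14 px), 1.3 mm minor (≈6 px),
  random orientation and position, soft 1-px Gaussian edge to avoid
  single-pixel aliasing; extra absorbance (0.15, 0.25, 0.60) — largest at
  970 nm where insect body fluids absorb. Footprint ≈ 67 px, comfortably
  above the 5-px filter.
* Texture: *one-sided* extra attenuation, `T = T₀ · 10^(−ε)` with ε
  half-normal (sd 0.005 absorbance). The defect-free slab is the
  transmittance ceiling — inhomogeneities only remove light — so the
  pixel-value bulk sits at the top of the range with a thin lower tail.
  A symmetric (e.g. lognormal) speckle would center the bulk mid-range and,
  under the literal min–max + 0.7-threshold chain above, flag nearly every
  pixel of every clean sample; the one-sided model is both the physically
  sensible choice for attenuation and the regime in which the published
  pipeline operates.
* Sparse dark inclusions: 3 + Poisson(5) single-pixel specks of
  0.1–0.35 absorbance (micro-bubbles, cocoa solids). They set the scaled
  range on clean samples and are exactly the sub-5-pixel clutter the area
  filter rejects.
* Optional tilt: a linear illumination gradient across columns. The
  flat-field reference can share the tilt (correction cancels it exactly)
  or not (the false-positive mechanism of a sample positioned at an angle).
* Determinism: a master seed expands to per-sample 31-bit seeds via a
  counter-based `SeedSequence` derivation, so any benchmark sample is
  regenerable in isolation.

What the phantoms do **not** model: radiative-transfer-accurate chocolate
optics, the 3-D depth of the 1.5 mm embedding plane (scenes are 2-D
projections), spectral filter transmission curves, or source drift. Passing
the synthetic benchmark therefore demonstrates that the pipeline's logic and
numerics are sound under the stated noise and contrast assumptions, not
that these accuracy figures transfer to arbitrary real chocolate.

## Benchmark

The standard experiment is 100 phantoms, exactly 50 contaminated, labels
shuffled by the master seed, full-sampling acquisition, default noise, and
default detection parameters (threshold 0.7, min area 5, 8-connectivity).
Accuracy is the fraction of correct contaminated/clean calls against the
generator's truth labels; `scripts/acceptance.py` recomputes it end to end
from a single seed (about 2–3 s on one CPU). Compressive-sensing sweeps in
the test suite use 16 × 16 piecewise-constant scenes over 20 seeds to keep
the paired comparisons fast; the qualitative orderings they assert
(error non-increasing in sampling ratio, Walsh-first subsets beating random
natural-order subsets) are resolution-independent.

## Known limitations

* The CS solver's sequential ℓ1/TV proximal step is approximate (see above);
  for μ ≫ λ regimes a dedicated composite prox would be preferable.
* The nominal one-mirror-per-pixel resolution figure (0.0076 mm at
  512 × 512) is geometrically unreachable with the centered 896-mirror
  layout; `spatial_resolution` returns the geometric value
  (0.0133 mm/pixel) and documents the conflict.
* `fit_window` truncates rather than extrapolates when the 5 % tail lies
  beyond the grid; extend `t_max_ps` for very strongly scattering slabs.
* The detection threshold (0.7) and area cutoff (5 px) are fixed constants
  of the published pipeline, not tuned quantities of this package; their
  boundary semantics (strict inequalities) are locked by tests.
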