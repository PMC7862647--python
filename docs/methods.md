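# Methods

This note documents the models implemented in `spadffs`, the numerical
choices behind them, and what the synthetic-data generator does and does not
emulate.

## Detector model and data formats

The detector is a 5×5 SPAD array read out as 25 photon-count traces with a
common bin width (0.5 µs by default). Pixels are indexed row-major, 0 (top
left) to 24; pixel 12 is on the optical axis. One pixel unit corresponds to
a 75 nm lateral shift of the detection volume in sample space
(`pitch_sample`), so the interpixel distances ρ from the centre take the
values {1, √2, 2, √5, 2√2} in pixel units.

Three trace dialects are read and written. The `spadffs-packed-v1` dialect
stores one 128-bit record per bin with width allocated by expected flux —
8 bits for the central pixel, 6 bits for its 8 nearest neighbours, 4 bits
for the 16 outer pixels, 8 zero pad bits — and saturates (rather than
wraps) on overflow, reporting the number of clipped values. The exact bit
layout of the original acquisition hardware is not public; this dialect is
our own and is not claimed compatible with any instrument's files. At the
default bin width the packed stream runs at 16 B / 0.5 µs = 30.5 MiB/s.
The `plain` (little-endian uint16) and `text` (CSV) dialects are lossless.
A `key=value` sidecar carries bin width, excluded pixels and free metadata.

Pixel 1 is treated as a hot pixel (high dark count rate) and excluded from
analysis by default, mirroring common SPAD-array practice; exclusions are
stored with the trace and can be overridden per call.

## Synthetic measurements

`simulate_ffs` generates a measurement from an explicit generative model:

- Point emitters diffuse freely in a periodic box (half-lengths 1.5 × 1.5 ×
  3 µm by default, ≥ 10 × ω₀ laterally to keep boundary artefacts
  negligible), with Gaussian steps of variance 2 D Δt per axis per substep.
- Pixel *i* observes a 3D Gaussian detection volume with lateral 1/e² waist
  `omega0_pixel` (0.141 µm) and axial extent z₀ = S·ω₀ (S = 5), displaced
  laterally by `pitch_sample`·(dxᵢ, dyᵢ). A particle at **r** contributes an
  expected rate ε·effᵢ·exp(−2((x−δdxᵢ)² + (y−δdyᵢ)²)/ω₀²)·exp(−2z²/z₀²)
  with molecular brightness ε = 50 kHz at the volume centre.
- effᵢ = exp(−2(δρᵢ)²/ω_exc²) is a per-pixel collection efficiency that
  models the finite excitation envelope (ω_exc = 0.30 µm default): pixels
  whose detection volume sits away from the excitation axis collect less
  flux. This is what gives the fingerprint map its Gaussian-like shape.
  Because correlations are fluctuation-normalized, a per-pixel scale factor
  cancels exactly, so effᵢ changes no diffusion analysis — only mean rates
  and signal-to-noise.
- Counts per bin and pixel are Poisson; dark counts add 200 Hz per pixel
  (25 kHz at the hot pixel).
- After-pulsing: each detected count spawns, with probability
  `p_afterpulse`, one delayed count in the same pixel, the delay drawn from
  a density ∝ Δ^(−B) truncated to [1 µs, 10 ms], B = 1.103; spawned counts
  are themselves eligible (geometric cascade, mean inflation 1/(1−p)). With
  this choice the dark-trace ACF decays as τ^(−B) with the same exponent,
  making the power-law fit term self-consistent. The sign convention is
  ours: a decaying power law is the physically sensible description of an
  after-pulse tail.

`simulate_dark` keeps only the background and after-pulse terms and is
implemented event-wise (Poisson event times, cascade on the event list),
which is exact for sparse dark counts and much faster than the dense path.

Numerics: the position/emission loop is numba-compiled; Gaussian steps are
pregenerated with the SFC64 bit generator (chosen for speed; the seed fixes
the trace bit-exactly). Particles outside the region where the detection
profile exceeds e⁻¹⁶ of its peak skip the profile evaluation. The substep
should satisfy 2DΔt ≤ (ω₀/10)²; a coarser substep is allowed with a warning
and slightly low-pass filters the shortest lags. Delays are discretized to
bins with a floor and a minimum of one bin, which distorts the first few
lags of the after-pulse power law — hence fits of the exponent start at
four bin widths.

What the generator does **not** emulate: non-Gaussian outer-pixel volumes
(vignetting), pixel cross-talk, triplet kinetics, anomalous diffusion,
hold-off dead time (counts per bin are far below saturation at the default
rates). Passing recovery tests therefore demonstrates correctness of the
analysis chain under the stated model, not robustness to those real-optics
effects; the pair-correlation analysis in particular is expected to degrade
at large ρ on real data where outer volumes deviate from Gaussians.

## Correlation

`G(τ) = ⟨δa(t) δb(t+τ)⟩ / (⟨a⟩⟨b⟩)` on a multiple-tau grid: m = 16 linear
lags per level, traces rebinned ×2 between levels, lags from one bin width
to 0.1 s. Means are level-local (computed over the two overlapping
segments at each level's resolution), so a constant trace gives exactly
G ≡ 0, and the zero lag is excluded. The correlator is validated against a
direct O(N²) normalized correlator at every level.

Long traces are split into 10 s chunks (trailing remainder dropped), each
chunk correlated, curves averaged; the per-lag sample standard deviation
across chunks is reported. A trace shorter than one chunk falls back to a
single whole-trace curve with a warning.

Pair-correlation mode cross-correlates the centre pixel with each usable
pixel and averages curves within each ρ class (4, 4, 4, 8, 4 members for
ρ = 1, √2, 2, √5, 2√2; exclusions reduce the counts). STICS mode correlates
all ordered pixel pairs, groups them by spatial shift (ξ, ψ) = (dxⱼ−dxᵢ,
dyⱼ−dyᵢ) into a 9×9 matrix per lag, and symmetrizes under (ξ,ψ) → (−ξ,−ψ),
which is exact for drift-free stationary signals and halves the noise;
ordered pairs (both directions) enter the average, and a flag disables
exclusions. A pixel whose chunk mean is zero has no normalizable
fluctuation signal; its pairs are treated as missing rather than letting
the undefined normalization poison the shift-class averages.

## Fit models

- Free 3D diffusion:
  `G(τ) = (1/N)(1+τ/τ_D)⁻¹(1+τ/(S²τ_D))^(−1/2) + offset`, with
  τ_D = ω₀²/(4D) and S fixed from calibration (default 5).
- After-pulsing: either crop short lags (7.5 µs single pixel, 15 µs summed
  traces) or add `A·τ^(−B)` with B fixed at 1.103 and A free. A dark-trace
  fit with both A and B free is done by weighted least squares in linear G
  space; fitting log G on positive values only would censor downward noise
  excursions of the tail and bias B low.
- Two-focus model for volumes separated by d·ρ (d = 75 nm):
  `G_x(τ) = G(τ)·exp(−(dρ)²/(ω₀²(1+τ/τ_D)))`, fitted globally over the five
  ρ-class curves with shared (N, τ_D); D = ω₀²/(4τ_D) with ω₀ fixed from
  calibration. Per-class individual fits are reported alongside.
- STICS/iMSD: each 9×9 matrix is fitted with an isotropic 2D Gaussian
  (amplitude, centre, σ² in px², offset); the (0,0) cell is excluded below
  20 µs where after-pulsing inflates it, and lags whose amplitude is not
  significant (A < 3 SE) are dropped. σ² converted to µm² via the 75 nm
  pitch follows `σ²(τ) = 2Dτ + ω₀²/2` for free diffusion; a weighted line
  fit over lags below 800 µs gives D = slope/2 with no volume calibration.

Optimization uses Levenberg–Marquardt on log-transformed N and τ_D
(positivity without bounds), tight tolerances (1e−15) so noiseless
self-consistency holds to ≥ 6 digits, and a small multistart over the τ_D
guess on non-convergence. Fits are **unweighted by default**: with the few
chunks of a desk-scale measurement, per-lag spread estimates are noisy
enough that inverse-variance weighting systematically over-weights lags
whose spread fluctuated low and biases τ_D; an opt-in weighted mode smooths
the spread with a running median across lags before inversion and is
appropriate for long measurements with many chunks.

## Workflows

- **Calibration**: ACFs of the centre pixel, the central 3×3 sum and the
  full 5×5 sum on a reference diffusant of known D;
  ω₀ = √(4·D_ref·τ_D) per configuration (e.g. D = 90 µm²/s with
  τ_D = 94 µs gives 184 nm). The summed-configuration waists are emergent —
  they are measured from the data exactly as on a real instrument, not
  assumed.
- **Spot-variation FCS**: τ_D versus ω₀² across the three configurations;
  for free diffusion the line passes through the origin, so the intercept
  τ(0) classifies the diffusion law (|τ(0)| < z·SE: free; significantly
  positive: microdomains; negative: meshwork; z = 2 default). D follows
  pointwise (ω₀²/4τ_D) and from the slope (1/(4·slope)).
- **Chequerboard FCS**: cross-correlation of the odd- and even-numbered
  pixel sums. After-pulsing is uncorrelated between pixels, so no cropping
  is needed. The two parity volumes are nearly identical and centred, and
  D is converted with the sum5×5 waist, the closest calibrated volume.
- **Pair-correlation FCS**: ρ-class cross-correlations, global two-focus
  fit with ω₀ fixed from the centre-pixel calibration.
- **iMSD**: calibration-free; σ²(τ) line fit as above.

## Problem sizes

The acceptance script (`scripts/acceptance.py`) regenerates everything at
desk scale: 30 s at 2 µs bins for the D = 30.6 µm²/s ACF recovery, 20 s at
5 µs bins (1 µs substeps) for the D = 90 µm²/s iMSD recovery, and a 60 s
dark trace at 1 µs bins (5 kHz background, p = 0.05) for the after-pulse
exponent. These durations are integer multiples of the 10 s chunk length
and resolve the relevant time scales (τ_D ≈ 162 µs and 55 µs, after-pulse
window 1 µs–10 ms) by two orders of magnitude. The test suite uses shorter
variants of the same conditions.

## Known limitations

- The degenerate static-sample limit (D = 0, immobile emitters) has no
  concentration fluctuations; iMSD correctly reports that no significant
  correlation surface exists instead of inventing a slope.
- The per-lag σ² uncertainties used to weight the iMSD line come from the
  Gaussian-fit covariance, which ignores correlations between shift-class
  cells sharing pixels.
- Intercept uncertainties in spot-variation rest on three configurations;
  with one degree of freedom the residual-based error is kept from
  collapsing by flooring it at the propagated τ_D errors.
- The packed dialect saturates silently at the per-field maxima beyond the
  reported clip count; quantitative work at very high count rates should
  use the plain dialect.
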