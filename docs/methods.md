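# Methods

## The counting-detector model

The simulator describes an electron-counting sensor with a small set of
interpretable parameters rather than detailed charge-transport physics:

- **Event localization kernel** (`event_psf`): a discrete probability
  distribution over (super-resolution) pixel offsets.  Each counted electron
  is recorded at its arrival position displaced by one draw from this kernel.
- **Backscatter kernel and fraction**: with probability
  `backscatter_fraction` the displacement is drawn instead from a wider,
  long-tailed kernel.  This two-kernel mixture reproduces the qualitative MTF
  and DQE degradation caused by electrons scattering back out of the
  detection layer, with only two parameters.
- **Counting efficiency** `ε ∈ (0, 1]`: independent thinning of arrivals
  before counting.
- **Internal / output frame rates**: electrons arrive as a Poisson process;
  within each *internal* counting frame at most one count is recorded per
  (super-resolution) pixel.  This per-pixel, per-frame saturation is the
  coincidence-loss mechanism; internal frames are summed into the slower
  output frames delivered to the user.  Defaults are 1500 fps internal and
  75 fps output, the operating regime in which coincidence loss stays near
  1% up to 40 e⁻/pixel/s.
- **Super-resolution factor** `s`: events are localized on a grid `s`×
  finer than the physical pixels (2 for super-resolution counting; the
  default models are defined at `s = 1` so that physical-pixel closed forms
  apply directly).

Correlated-double-sampling readout is modeled only as what it delivers in
counting mode: integer counts with zero added read noise.  There is no analog
signal path.

Two exact consequences of this model serve as oracles for every estimator:

1. **MTF**: a continuous arrival position, a discrete kernel displacement,
   and binning into pixels give
   `MTF(f) = |DTFT of the projected mixture kernel| · |sinc(f/s)|`
   in cycles per physical pixel.  Note the *discrete* kernel transform is the
   correct reference: for kernels barely wider than the sampling grid it
   differs from the continuous Gaussian expression by its aliases, and the
   simulator realizes the discrete version.
2. **NNPS and DQE**: thinned, independently displaced Poisson arrivals remain
   a Poisson point process, so pixel counts are uncorrelated and the noise
   power spectrum is flat at the Poisson level regardless of how broad the
   localization kernel is.  Hence `DQE(f) = ε·MTF(f)²` in the low-dose limit.
   (Coincidence loss perturbs this by O(λ): it removes counts and slightly
   *sub*-Poissonizes the variance.)

The default simulated sensor is 256×256 physical pixels; the full-chip
geometry is a constructor argument, not a different code path.

## Slanted-edge MTF estimation

Standard ESF→LSF→MTF chain:

- **Edge location**: per line across the edge, the crossing is the centroid
  of the finite-difference profile within a ±12-sample window around its
  lightly smoothed peak; a least-squares line through the crossings gives the
  angle (accepted range 0.5°–15°) and offset.  Edge polarity is detected and
  normalized internally.
- **ESF**: every pixel center is projected onto its signed perpendicular
  distance from the fitted line and binned at 1/`bin_factor` pixel
  (default 4, the usual 4× oversampling).  Empty interior bins (≤5%,
  otherwise the angle is too shallow for this oversampling) are filled by
  linear interpolation.  The profile is trimmed to a symmetric window;
  by default the window is capped at ±16 pixels (±12 in the end-to-end
  pipeline) because bins far from the edge contribute only noise to the
  Fourier transform.
- **LSF**: central finite difference of the (optionally smoothed) ESF,
  normalized to unit sum.  Smoothing is off by default; when enabled its
  width is recorded in the output metadata.
- **MTF**: magnitude of the zero-padded FFT of the Hann-windowed LSF,
  normalized to 1 at zero frequency.  Two known transfer functions of the
  discrete pipeline are divided out — the central-difference derivative
  filter `sinc(2fΔ)` and the distance-binning aperture `sinc(fΔ)`,
  `Δ = 1/bin_factor` — and frequencies where this correction falls below 0.2
  are dropped (well past the physical Nyquist at the default oversampling).
  Without this deconvolution the raw estimate is biased low by ~10% at
  Nyquist; with it, a noiseless synthetic edge is recovered to 5×10⁻⁴.
- **Averaging**: repeats, including horizontal and vertical edges, are
  interpolated onto a common grid and averaged; the per-point standard
  deviation across images is reported as the spread.

Edge fixtures in the end-to-end tests use a tall narrow sensor strip
(512×64) with the edge along the long axis: every line contributes to the
ESF while columns that could never enter the analysis window are not
simulated.  Exposures are long (tens of seconds at the standard measurement
dose rate of 7.5 e⁻/pixel/s) so that counting noise, not model error,
limits the MTF.

## Noise power spectrum

Frames are divided into non-overlapping tiles (default 128), each tile
detrended (mean subtraction by default; a best-fit plane as an option — the
two differ by far less than 1% on simulated flats), and the 2D periodograms
|FFT|²/area averaged over all tiles and frames.  Radial averaging uses
shells one Fourier sample wide; the result is divided by the mean counts per
pixel so an ideal Poisson counting detector gives NNPS ≡ 1.  The DC sample
and the first radial shell are excluded from the reported curve because
detrending contaminates them.  For super-resolution stacks the frequency
axis is rescaled to cycles per physical pixel.

The per-shell standard error scales as 1/√(n_frames · n_tiles · shell
samples); the tests verify the scaling empirically across 8/32/128-frame
stacks.

## DQE assembly

`DQE(f) = (counted/incident) · MTF(f)² / NNPS(f)` on the NNPS shell grid up
to the physical Nyquist.  The incident rate is treated as known (in a
physical measurement it comes from an absolute beam-current calibration);
the counted rate is measured from the flat stack.  DQE(0) is a straight-line
extrapolation of the first five reported shells to zero frequency, weighted
by √f because shell sample counts grow linearly with frequency.  The
extrapolation — like the edge method itself — carries a small *positive*
bias (one to a few percent, growing with kernel width, driven by the Hann
window's truncation of LSF tails); results are flagged
`dqe_zero_extrapolated` and the summary prints the caveat.  Values above 1
anywhere are flagged as a calibration error rather than clipped.

End-to-end recovery across a 3×3 grid of localization widths
(σ ∈ {0.2, 0.5, 1.0} px) and efficiencies (ε ∈ {0.6, 0.8, 1.0}) stays within
0.05 absolute of the analytic DQE at all frequencies up to Nyquist at the
simulation sizes above (512×64 edge strips at 60 s, 128 flat frames of
256²); the ideal detector reproduces DQE(Nyquist) = (2/π)² within 0.03.

## Half-map and subset-FSC simulators

Half maps are generated in Fourier space: one shared Gaussian random signal
field and two independent noise fields, all band-limited to the Nyquist
sphere, with per-shell signal amplitude √s(f) against unit noise so the
per-half spectral SNR equals the prescribed profile exactly (infinite SSNR
means zero noise, hence identical halves).  This gives `E[FSC] = s/(s+1)`
per shell, which the tests confirm at s = 0, 1, ∞ over 20 seeds.

Subset-FSC ensembles skip the volumes: for a subset of N particles each
shell's FSC is realized as the sample correlation of `n_shell_samples`
independent complex Fourier coefficient pairs drawn from the shared-signal
model with per-half SNR N·ppSSNR(f).  Both the expectation
N·p/(N·p + 1) and the correlation-sampling noise are therefore correct,
without any choice of box size.

These generators emulate the *spectral* statistics of gold-standard
reconstructions — they contain no structure, no mask-induced correlation
unless one is applied, no CTF, and no alignment error.  Passing tests
demonstrate that the estimators are correct and unbiased under the stated
noise model; they do not certify behavior on maps with non-Gaussian signal
or processing-induced correlations between halves.

## Map metrics

- **FSC**: per-shell normalized cross-correlation of the two volumes'
  Fourier transforms, shells one Fourier voxel wide (integer-rounded
  radius), out to the voxel Nyquist; a mask multiplies both maps before
  transforming.  Shell 0 (DC) is omitted from the curve.
- **Mask correction**: phases of both maps are randomized beyond a chosen
  resolution (replacement phases come from the transform of a white random
  volume, preserving Hermitian symmetry), and the corrected FSC is
  `(FSC_t − FSC_n)/(1 − FSC_n)` beyond that resolution.  This is a declared
  convention for noise substitution; upstream packages may differ in detail.
- **Resolution**: first downward crossing of the threshold (default 0.143,
  configurable), linearly interpolated between bracketing shells; later
  re-crossings from noise are ignored.  A curve that never falls below the
  threshold returns the Nyquist resolution with a `crossed=False` flag; a
  curve never above it is rejected.
- **SSNR**: `FSC/(1 − FSC)` with FSC clamped to 1 − 10⁻⁶ (flagged) and
  negative FSC mapped to 0 (flagged), so the FSC↔SSNR bijection round-trips
  to 10⁻⁹ on [0, 1).
- **ppSSNR**: each subset's SSNR divided by its particle count; averaged
  across subsets *in the linear domain*, with the per-shell standard
  deviation as the error bar, and ln(mean) recorded alongside for plotting.
  The curve is truncated where the smallest subset's FSC first crosses the
  threshold, since shells beyond it are noise-dominated for that subset.
- **Guinier B-factor**: least squares of ln(amplitude) on 1/d² restricted to
  a resolution window (default 7–2.7 Å), B = −4·slope; exact on noiseless
  exponential decays, and requiring at least 4 shells in range.
- **Q-score calibration**: the default linear map-average calibration is
  `Q = 1.1192 − 0.1775·d` (slope in Q per Å); inversion gives
  d = (1.1192 − Q)/0.1775, reproducing the two published anchor pairs
  (0.85 → ~1.51 Å, 0.88 → ~1.35 Å) within 0.02 Å.  A two-point calibration
  built from those anchors is provided for sensitivity checks; coefficients
  are plain configuration.
- **Dose arithmetic**: total dose = rate × time / pixel², per-frame dose and
  frame counts derived from the exposure; the 100 kV dose-weighting helper
  multiplies the cumulative exposure by 1.57, compensating motion-correction
  software that only knows the 300 keV critical-dose curve (the inelastic
  cross-section ratio between the two energies).

## Numerical and design choices

- Frequencies are cycles per physical pixel for detector curves and 1/Å for
  map curves; conversions (including to fractions of physical Nyquist) are
  explicit functions, never implicit.
- One integer seed per stochastic operation, one `numpy` Generator stream
  per call; identical seeds give byte-identical outputs, and derived seeds
  stay below 2³¹.
- The event engine processes internal frames in chunks of ~4×10⁶ expected
  events; coincidence de-duplication is a sort-unique over (frame, pixel)
  keys, so memory stays bounded at any exposure length.
- Flat-field simulation uses periodic boundary wrapping for kernel
  displacements (keeps the process statistically uniform for NPS tiles);
  edge simulation drops events displaced off-sensor.
- Degenerate inputs fail loudly with typed errors (`DataError`,
  `NumericalError`), which the CLI maps to exit codes 3 and 4.
- Writers are deterministic byte-for-byte; curve CSVs print 9 significant
  digits and round-trip at that precision; run manifests contain no
  timestamps so reruns are reproducible.

## Known limitations

- No charge-transport or Monte-Carlo silicon simulation: the kernel mixture
  is phenomenological, and detector comparisons based on it are qualitative.
- The one-count-per-pixel coincidence model ignores charge sharing between
  neighboring pixels during pile-up; the closed-form loss fraction is exact
  only for this mechanism.
- The edge method's DQE(0) is extrapolated and biased slightly high by
  construction; absolute efficiency claims should rely on the counted/
  incident rate calibration instead.
- Map-side metrics assume cubic volumes and isotropic shells; no local
  resolution, no Ewald-sphere or CTF effects, and Q-scores themselves are
  not computed from map + model — only the linear calibration between
  map-average Q and resolution is implemented.
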