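# Methods

## Phase-error model

Single-shot EPI reads k-space with a train of bipolar readout gradients;
odd and even lines therefore accumulate phase errors of opposite sign. The
package models the per-line error in x–ky hybrid space (data
inverse-transformed along the readout axis only) as

    theta(x) = alpha + beta * x,

applied as `exp(+i * (-1)^j * theta(x))` to line `j` in 0-based acquisition
order. `alpha` (radians) captures zero-order effects such as a
gradient-induced B0 shift; `beta` captures the first-order readout-direction
term produced by eddy currents and by group delays between gradient and
sampling. The model assumes a non-oblique plane (no cross-term eddy
currents) and a spatially uniform error; a deliberately de-shimmed field
with spatially varying errors is outside the model and is not simulated.

For a full, noiseless acquisition the corrupted reconstruction has the
closed form

    rho_hat(x, y) = rho(x, y) cos(theta(x)) + i rho(x, y - N/2) sin(theta(x)),

which the package implements separately from the FFT pipeline and uses as an
independent oracle in tests (agreement < 1e-10 max abs difference). The
closed form matches the pipeline exactly when the phase-encode matrix size
is a multiple of 4; for other even sizes the alternating-parity modulation
under centred FFT indexing carries a global sign that displaces the sin term
by half a period. All shipped geometries use N = 32 or 64.

## Conventions

* Arrays are `n_readout x n_pe`; DC sits at the matrix centre and all
  transforms use the shifted FFT convention, so the ghost displacement is a
  circular shift by exactly `N // 2` phase-encode pixels.
* `x` is the **centred readout sample index** (`n - n_readout/2`), so
  `beta` is in radians per sample. This choice is load-bearing: one grid
  step of `beta` then tilts the phase at the FOV edge by ~N/2 grid steps,
  so the ghost-minimization objective is steep in `beta` and shallow in
  `alpha`. That reproduces the experimentally observed behaviour of the
  search (the first-order term is pinned reliably even at object SNR near
  the workflow's ~4.7 reliability floor, while the zero-order term is
  loosely determined), and it makes (-pi/2, pi/2] the natural search range:
  `alpha` is periodic in pi outright, and a pi shift of the per-sample
  slope `beta` aliases to the same magnitude image displaced half a FOV
  along readout. Had `beta` been normalized to the FOV edge instead, a
  grid step of `beta` would ghost *less* than a grid step of `alpha` and
  noise would scatter the estimate by several steps at moderate SNR.
* Polarity: even acquisition indices carry `+theta`. The opposite global
  choice only negates `(alpha, beta)`; canonicalization into
  (-pi/2, pi/2] (adding multiples of pi) resolves it. Only the `alpha`
  shift is a true magnitude invariance; canonicalizing `beta` re-expresses
  an out-of-range slope modulo the readout-shift alias.
* Partial Fourier: the acquired lines form one contiguous block from
  `N/2 - lines_before_center` to the end of k-space; missing early lines
  are zero-filled before transformation (no conjugate/POCS completion).
  In the study geometry (32 lines, 4 before centre) this acquires 20 lines
  = 62.5% of k-space.

## Referenceless searches

**1D search.** Every combination of `(alpha, beta)` on an `n_steps x
n_steps` grid (default 100 points per axis, endpoints included, step
pi/99) is applied as a correction and scored by the mean magnitude over
operator-selected ghost bands — the rows outside the object ROI's
phase-encode extent, full readout width. The evaluation is factorized: the
corrected image is `cos(theta(x)) * A - i sin(theta(x)) * B`, where `A` is
the plain reconstruction and `B` its parity-flipped counterpart (the
aliased component), both computed once; a candidate then costs one
elementwise combination over the band pixels instead of an FFT, and the
10^4-point search runs in ~0.1 s at 32 x 32. The search is literal and
exhaustive; exact ties are broken by smallest `|alpha| + |beta|`, then
`|beta|`, then lexicographically, for deterministic results.

**2D search.** An outer grid over an additional first-order phase-encode
term `beta_y` (radians per line, same grid) with, for each candidate, an
independent per-readout-column grid search of a scalar phase minimizing
that column's band magnitude. Columns without band pixels inherit the
global 1D solution and are flagged. Two caveats are inherent and
documented rather than patched: per-column minimization is biased in
columns that carry little ghost (with multiple small sources this can
leave *more* residual ghosting than the 1D search — supplying per-source
ROIs resolves it), and the even default grid cannot represent
`beta_y = 0`, leaving a quantization residual of roughly 1–2 percentage
points of Eq.-3 ghosting on noiseless data (~0.8 with an odd,
zero-containing grid).

**Workflow.** For a dynamic series the search runs once — by default on
the lactate frame with the highest object SNR; alternatives are the summed
pyruvate or lactate k-space or an explicit frame — and the coefficients are
applied to every frame of both metabolites. If the search frame's object
SNR is below a configurable floor (default 4.7, the observed reliability
threshold) a warning is emitted and the search still runs; coefficients
from such frames tend to be random.

## Reference-based estimators

* **Reference scan** (phase-encode gradients off): adjacent hybrid-space
  line pairs differ in phase by `-2 * (-1)^j * theta(x)`. The phase of the
  pair product is unwrapped cumulatively (Ahn-style: each step is the
  angle of `S_n * conj(S_{n-1})`, immune to 2-pi wraps while true steps
  stay below pi), re-anchored at the strongest sample so that noise
  accumulated across the empty background cannot shift the zero-order
  term, and fitted linearly in `x`, restricted to and weighted by samples
  above 10% (configurable) of the peak projection magnitude. Estimates are
  applied per line; zero-magnitude runs carry the last valid phase forward
  and are flagged, and unwrapping resumes against the last valid sample.
* **Integrated reference echoes**: the same pairwise estimate on >= 2
  non-phase-encoded echoes prepended to the train, averaged into a single
  pair. The imaging train then starts `n_echoes` echo spacings later, so
  its T2* decay — and hence SNR — is penalized by
  `exp(-n_echoes * echo_spacing / T2*)` (0.920 for three echoes at 552 us
  and T2* = 20 ms).
* **Proton reference**: coefficients estimated at gamma(1H) are rescaled by
  `alpha *= gamma_ratio` and `beta *= gamma_ratio / fov_ratio`
  (`gamma_ratio = gamma_target/gamma_reference`,
  `fov_ratio = FOV_ref/FOV_target`); with the proton readout FOV about a
  quarter of the carbon FOV the two factors nearly cancel for `beta`
  (0.2515 / 0.25 ~ 1.006).

On noiseless simulations all three estimator families and the 1D search
agree within one search-grid step.

## Metrics

* **Ghosting level** (percent):
  `(mean r1 + mean r2 - mean r3 - mean r4) / (2 mean r5) * 100` on
  magnitude images, where r5 is the object region, r1/r2 the object mask
  circularly shifted by N/2 along phase-encode (split at the midline into
  its two pieces — where the ghost lands), and r3/r4 the same shift along
  readout (ghost-free background that subtracts the noise floor). Values
  can be negative under noise and are not clamped. The midline split of
  the shifted regions is a documented convention; all five regions can
  also be supplied manually (restricted-FOV / multi-source case).
* **SNR**: mean object magnitude / SD of magnitude over a noise source
  (a region of the same image or a designated noise-only frame, e.g. the
  last pyruvate image of a series). Noise statistics are computed on
  magnitudes, so a noise-only region is Rayleigh (mean/SD ~ 1.91); the
  convenience noise region derived from the readout-shifted object mask
  additionally sees a little phase-encode ringing at object boundary rows,
  which slightly inflates the measured SD at high SNR — fine for the
  relative comparisons it is used for (frame selection), while absolute
  SNR statements should use a noise-only frame.
* **SSIM**: mean local structural similarity, 7x7 Gaussian window
  (sigma 1.5), K1 = 0.01, K2 = 0.03, dynamic range = joint maximum,
  delegated to scikit-image.
* **Phase-encode pixel bandwidth**: `1 / (n_pe * echo_spacing)` Hz — the B0
  offset producing a one-pixel shift (56.6 Hz ~ +-57 Hz at 32 lines /
  552 us; 43.9 Hz at 712 us).

## Synthetic data

The simulator emulates the study conditions end to end: ellipse/disk
phantoms (including a dual two-source phantom and a tumour-like lactate
object inside a body-like pyruvate object), forward transform, optional
per-echo T2* decay in acquisition order, the alternating phase corruption,
zero-filled 62.5% partial-Fourier sampling, and seeded complex Gaussian
noise added to acquired lines only. Reference scans replicate the sequence
with phase encoding off (every line is the object's phase-encode
projection); integrated-echo acquisitions prepend alternating-polarity
projection echoes and advance the imaging train's decay accordingly.

Dynamic series: two metabolites acquired alternately at TR = 2 s each,
10 frames by default, first frame 6 s post injection so the delayed lactate
curve is non-zero in every frame. Signal curves are gamma-variates
(pyruvate: shape 3, scale 4 s, unit peak; lactate: same family delayed 4 s,
scaled 0.3) — fixed, stated defaults; no kinetic model is claimed.
Per-frame seeds are `master seed + flat frame index` in (time, metabolite)
order, so golden files are stable. The default true corruption is
alpha = 0.3 rad, beta = 0.05 rad/sample (~0.8 rad edge phase — a strong,
clearly visible ghost; uncorrected Eq.-3 ghosting ~30%).

Noise levels are set via `noise_sd_for_target_snr`, which converts a
requested object SNR into a k-space noise SD exactly (linearity of the
inverse FFT over the acquired samples; Rayleigh SD for the magnitude noise),
measuring the object mean on the noiseless corrupted reconstruction. The
default pipeline condition is peak-lactate-frame object SNR ~ 30.

What the simulator does **not** model — and hence what passing tests do not
show about real data: spatially varying phase errors (de-shimmed fields,
oblique-plane cross terms), flow and motion, B0 inhomogeneity and
off-resonance distortion, ramp sampling, coil combination, and the spatial
remapping of a proton reference object onto its quarter FOV (the proton
reference is simulated through its phase contract only). Real lactate
distributions are also smoother than rasterized ellipses, which affects the
zero-filling residual discussed below.

## Numerical choices and degenerate inputs

* Correcting with the true coefficients on noiseless **full** k-space
  restores the ideal image to floating point (ghosting < 1e-8%). On
  zero-filled partial k-space the same correction restores the zero-filled
  reconstruction of the clean object exactly, which itself carries an
  Eq.-3 residual (~4.6% for the default disk) because phase-encode ringing
  leaks into the shifted regions 1/2 but not into 3/4. Residual-ghosting
  numbers on partial k-space should therefore be read against that
  baseline, not against zero.
* An object ROI spanning every phase-encode line leaves no ghost band; the
  band constructor raises and asks for manual bands (the search needs
  signal that does not cover the whole FOV).
* All-zero k-space reconstructs to a zero image (not an error); a zero
  object-region mean makes the ghosting level undefined and raises.
* Exact objective ties are resolved by the documented preference order;
  the grids contain no exact zero at the default even step count, so a
  "no corruption" search returns the smallest-magnitude grid point.
* Determinism: identical parameters and seeds produce bit-identical
  k-space, searches and JSON reports.

## Problem sizes

Tests and the acceptance script run entirely on 32 x 32 (occasionally
64 x 64) matrices with 100 x 100 search grids: 25 on-grid recovery
searches, 50 seeds per SNR level (5 / 3 / 2) for the noisy-recovery rates,
100 random images for the oracle bound, 100 seeds for the reference-scan
bias check, and 2 x 10-frame dynamic series for the transfer workflow —
about half a minute end to end on one CPU, chosen to keep the full suite
interactive while leaving every statistical check well-powered.
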