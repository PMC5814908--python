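# epighost

Referenceless Nyquist ghost correction for single-shot 2D EPI of
hyperpolarized ¹³C metabolites.

## The problem

Dynamic imaging of hyperpolarized [1-¹³C]pyruvate and its metabolic product
[1-¹³C]lactate has to race a polarization lifetime of tens of seconds, so
single-shot EPI is the workhorse readout. EPI's bipolar readout train,
however, accumulates opposite phase errors on odd and even k-space lines
(group delays and readout-direction eddy currents), which alias into a
*Nyquist ghost*: a copy of the object displaced by half the field of view in
the phase-encode direction. The standard fix — a reference scan with the
phase-encode gradients off — costs a time point of the precious dynamic
series; integrated reference echoes cost SNR through prolonged T₂* decay;
a proton reference scan measures the error at the wrong gyromagnetic ratio
and FOV.

This package implements a workflow that needs no reference data at all:

1. draw an object ROI (e.g. from a proton image) on a single frame of a
   single metabolite — usually the lactate frame with the highest SNR;
2. treat the bands beyond the object's phase-encode extent as
   ghost-containing background;
3. exhaustively search the phase-error coefficients that minimize the mean
   magnitude in those bands;
4. apply the winning coefficients to every frame of every metabolite.

## The model

In the x–ky hybrid space (data inverse-transformed along readout only), line
*j* carries the phase error

θ(x) = α + β·x,  with sign (−1)ʲ,

where α (rad) is the zero-order term, β (rad per readout sample) the
first-order term, and x the centred readout sample index. For a full,
noiseless acquisition the reconstructed image has the closed form

ρ̂(x, y) = ρ(x, y)·cos θ(x) + i·ρ(x, y − N/2)·sin θ(x),

i.e. the ideal image splits into a real copy in place and an imaginary copy
half a FOV away. The error is periodic in π, so the exhaustive search runs
α, β over (−π/2, π/2] on a 100 × 100 grid. The searched objective — the mean
magnitude over the ghost bands — is steep in β (one grid step of β tilts the
edge phase by ~N/2 steps) and comparatively tolerant in α, which is what
makes a single low-SNR metabolite image sufficient to pin down the
correction.

Alongside the referenceless 1D and 2D searches the package provides the
three classical comparators (¹³C reference scan with Ahn-style phase
unwrapping and per-line linear fits, integrated ¹³C reference echoes,
γ-scaled ¹H reference scan), the evaluation metrics (five-region ghosting
level, SNR, SSIM, phase-encode pixel bandwidth), and a complete synthetic
acquisition simulator (phantoms, 62.5% partial-Fourier zero-filled
sampling, T₂* decay, complex Gaussian noise, dynamic two-metabolite
series), so the entire workflow runs and is tested without scanner data.

## Worked example

```python
import numpy as np
from epighost import pe_pixel_bandwidth
from epighost.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1))
c = report["coefficients"]
print("searched coefficients: alpha=%.3f rad, beta=%.4f rad/sample"
      % (c["alpha_rad"], c["beta_rad_per_sample"]))
print("search frame:", report["search_frame"])
unc = [f["ghosting_uncorrected_percent"] for f in report["frames"]]
cor = [f["ghosting_corrected_percent"] for f in report["frames"]]
print("mean ghosting before correction: %.1f%%" % np.mean(unc))
print("mean ghosting after correction:  %.1f%%" % np.mean(cor))
print("phase-encode pixel bandwidth: %.1f Hz" % pe_pixel_bandwidth(32, 552e-6))
```

prints

```
searched coefficients: alpha=0.301 rad, beta=0.0476 rad/sample
search frame: ['lactate', 3]
mean ghosting before correction: 30.5%
mean ghosting after correction:  1.8%
phase-encode pixel bandwidth: 56.6 Hz
```

The run simulates a 2 × 10-frame pyruvate/lactate series (32 × 32 matrix,
20 of 32 phase-encode lines, true corruption α = 0.3 rad,
β = 0.05 rad/sample, peak-frame object SNR ≈ 30), searches the 100 × 100
grid once on the highest-SNR lactate frame, and applies the coefficients to
all 20 frames: the searched pair lands within one grid step of the truth and
the residual ghosting collapses to the zero-filling baseline. The 56.6 Hz
pixel bandwidth (32 lines at 552 µs echo spacing) is the B₀ offset needed to
shift the image by one phase-encode pixel — the sequence's off-resonance
immunity is roughly ±57 Hz.

The same workflow is scriptable from the shell:

```sh
epighost simulate --frames 10 --noise-sd 0.02 --seed 1 --out series.h5
epighost correct --in series.h5 --roi roi.nii.gz --out coeffs.json
epighost run --outdir results/
```

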