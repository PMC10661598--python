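# Methods

## The imaging model

A single-element ultrasound transducer cannot, by itself, tell where in a 3-D
volume a photoacoustic source sits: every source contributes to the same
one-dimensional voltage trace. The system modelled here solves this with a
passive acoustic relay (a right-angle prism feeding a long cylindrical
fused-silica pipe) placed between the water volume and the detector.
Multipath reverberation inside the pipe scrambles the wavefront so that a
source at voxel *i* produces a characteristic temporal signature *k_i* at the
detector. After a one-time pointwise calibration that records *k_i* for every
voxel of the imaging volume, a single laser shot yields

    y = K x,        K = [k_1 ... k_N],

where *x* holds the per-voxel photoacoustic intensities. The volume is
recovered by solving

    x_hat = argmin_x  1/2 ||y - K x||^2 + lambda * TV(x),     x >= 0,

with isotropic 3-D total variation, using the two-step iterative
shrinkage/thresholding (TwIST) family of solvers.

## Synthetic encoder

No measured transfer function of the physical relay is available, so the
calibration dictionary is synthesized phenomenologically from the properties
the reconstruction actually relies on:

1. **Time-of-flight delay.** Water path from the voxel to the centre of the
   pipe entrance (1500 m/s) plus the fixed pipe transit (0.30 m at 5900 m/s).
   This is what encodes depth: axial structure maps to arrival time.
2. **Band-limited pulse.** A unit-norm Gaussian-envelope cosine at the 1 MHz
   centre frequency whose power spectrum has a −6 dB fractional width of
   0.8466, matching the detection transducer.
3. **Reverberation coda.** A voxel-specific pseudorandom sequence
   (deterministic in `(seed, voxel index)`) with an exponential envelope,
   convolved with the pulse. This is the scrambling that gives each voxel a
   unique temporal code. The default envelope time constant is 100 µs —
   comparable to a few pipe transits — because fused silica is essentially
   lossless over the detection pathlength, so reverberant energy decays
   slowly; a fast-decaying coda would also leave too few effective samples
   for the codes of distinct voxels to be nearly orthogonal, which is the
   property the single-shot inversion rests on.
4. **Critical-angle aperture weight.** Only rays that strike the entrance
   disk within the water→silica critical angle θ_c = arcsin(1500/5900) =
   14.73° couple into the pipe. Each voxel's column is scaled by the
   spherical-cap fraction (1 − cos θ_eff)/2 with
   θ_eff = min(θ_c, atan(r_pipe/d)), a first-order model that uses the
   distance *d* to the entrance centre for off-axis voxels as well.
5. **Lateral mixing.** Columns of laterally neighbouring voxels are mixed
   with a normalized Gaussian kernel of 2.5 mm FWHM — the lateral resolution
   the physical system measured, imposed directly rather than derived from
   the half-wavelength-in-silica bound (2.95 mm), because the measured number
   is the reproducible one. Kernel weights are renormalized at volume edges
   so every voxel's weights sum to 1.
6. **Calibration noise.** Each column receives white Gaussian noise at a
   per-column SNR of 40 dB divided across `n_avg = 2` averaged shots
   (implemented as a single draw with variance σ²/n_avg, which is
   distributionally identical to averaging). The scan protocol (2 averages)
   matches the physical calibration; the 40 dB shot SNR is this package's
   choice since no calibration SNR was reported.

Default sampling is 20 MHz with a 4096-sample record (~205 µs): the signal
band is below 2 MHz, and the record covers the pipe transit (~51 µs), the
largest water delay in the supported geometries, and a 1500-sample (75 µs)
coda. Voxels are treated as point samples at voxel centres, matching the
pointwise calibration with a sub-wavelength point absorber.

What this generator does *not* emulate: waveguide mode structure of the
cylindrical pipe, frequency-dependent attenuation (negligible in fused
silica), obliquity corrections beyond the first-order aperture rule, and any
nonlinearity of the detector. Consequently, passing benchmarks here show that
the inversion machinery recovers volumes correctly *given* an incoherent,
physically structured dictionary; they do not certify performance against a
physically measured calibration.

## Solver

TwIST iterates

    x_{t+1} = (1 − α) x_{t−1} + (α − β) x_t + β Γ(x_t),
    Γ(x) = P_+ [ prox_{λ'/L · TV} ( x + (1/L) K~ᵀ (y − K~ x) ) ],

where K~ is the column-normalized dictionary, L its largest squared singular
value (deterministic power iteration; column normalization alone does not
bound it), P_+ the optional nonnegativity projection (on by default —
photoacoustic initial pressure from absorbers is nonnegative), and the
two-step parameters come from an assumed spectral-ratio parameter ξ
(default 1e-2): ρ = (1−√ξ)/(1+√ξ), α = 2/(1+√(1−ρ²)), β = 2α/(1+√ξ).
A monotone safeguard evaluates the objective at every candidate: if the
two-step update would increase it, the solver falls back to the plain IST
step and restarts the two-step memory, so the reported objective trace is
nonincreasing by construction and correctness does not hinge on ξ. Column
norms are folded back into the returned intensities, which makes the scale
of λ portable across encoder configurations.

The TV proximal step is a Chambolle-type dual projection extended to 3-D
(dual step 1/12, the 3-D stability bound; 10 inner iterations by default).
TV uses forward differences with replicate boundary; the discretization is a
package choice. Initialization is x₀ = 0 and there is no randomness anywhere
in the solver path, so reconstructions are bit-reproducible. Stopping:
relative objective change below 1e-4 or 200 iterations (150 in the
benchmarks, where convergence is comfortably reached).

λ is exposed as a user parameter. The helper `suggest_lambda` scales it as a
fraction of max|K~ᵀy|; the benchmarks choose λ from the coarse sweep
{0.01, 0.03, 0.1} of that scale by Pearson correlation against the known
ground truth — legitimate in a synthetic study where truth is available by
construction, and mirroring how the regularizer would be tuned against a
known test object in practice.

## Benchmarks and problem sizes

All benchmarks generate their data at run time; there are no stored fixtures.

* **Resolution** (`resolution_benchmark`): 15×15×11-voxel grid (7×7×3 mm at
  the 0.5/0.5/0.3 mm calibration increments, 10 mm standoff), noiseless
  trace of a centred point target, FWHM of the reconstructed profile through
  the argmax along X (lateral) and Z (axial), by linear interpolation at the
  half-max crossings; a single-sample peak counts one voxel spacing.
* **Tracking** (`tracking_benchmark`): 27×27×11-voxel grid (13×13×3 mm; wide
  enough that a 5 mm disk on a radius-3 mm spiral stays inside), 10 frames of
  one upward spiral turn, traces at 30 dB SNR, centroid of voxels at or above
  half the image maximum ("object pixels"), signed per-axis mean ± standard
  deviation of estimate − truth over frames.
* **Recovery** (`phantom_recovery_benchmark`): block letter B (6 mm tall,
  1.2 mm stroke) in one depth slice of a 15×15×7-voxel grid, 30 dB SNR,
  fidelity as Pearson correlation with the binary truth.

These sizes keep each benchmark to seconds–minutes on one CPU while leaving
the measurement-to-unknowns ratio (4096 samples vs 2475–8019 voxels)
genuinely compressive. The full-scale 31×31×21 calibration grid is supported
by the same code (`--grid 15x15x6` in the CLI).

## Numerical and design choices

* Grid counts use `floor(extent/inc) + 1` with a 1e-6 relative epsilon before
  the floor, so binary-float ratios like 6/0.3 still include both endpoints.
* Linearization is 0-based, X fastest; the 3-D array view is `(nz, ny, nx)`.
* Nearest-voxel lookup breaks exact midpoint ties toward the lower index.
* The centroid threshold (0.5 × max) defines "object pixels"; it is a
  parameter, since no definition is inherited from the physical analysis.
* Two-point resolvability uses a Rayleigh-like criterion: midpoint intensity
  at most 73.5 % of the smaller peak.
* Calibration drift is modelled per column as sub-sample delay jitter (FFT
  phase ramp), multiplicative gain drift, and additive noise; the
  fidelity-vs-perturbation curve is this package's construct for studying
  how much drift the one-time calibration tolerates.
* Degenerate inputs error loudly: zero-power signals cannot take finite SNR,
  phantoms never silently clip against the grid, and a record too short for
  a voxel's arrival names that voxel.

## Known limitations

* The encoder is phenomenological; absolute SNR levels and coda statistics
  are plausible rather than measured, so fidelity numbers should be read as
  properties of the inversion, not of hardware.
* The aperture model ignores the obliquity of off-axis voxels relative to
  the pipe axis beyond the first-order distance rule.
* TV regularization favours piecewise-constant objects; the benchmarks use
  binary phantoms, which sit in its favourable regime.
* With strong lateral mixing and a laterally small grid (≲ 3 voxels), the
  lateral point-spread profile may not fall below half maximum inside the
  grid; resolution measurements need grids several FWHM wide.
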