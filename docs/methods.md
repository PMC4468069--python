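# Methods

## Scope and units

`meamap` estimates activation times and local conduction velocities from
multichannel extracellular recordings on the standard 60-electrode MEA
grid (8×8 minus the four corners, 200 µm pitch).  One canonical unit
system is used everywhere: positions in µm, time in ms, voltage in µV.
Velocities then come out in µm/ms, which is numerically identical to mm/s,
the unit all speeds are reported in.  Electrode labels follow the
two-digit column-row convention (first digit = column 1–8, second = row);
label CR sits at x = (C−1)·200 µm, y = (R−1)·200 µm with **row 1 at the
bottom** (y increases upward).  The convention is stated on every figure
axis; a wave initiated near electrode 12/21 therefore starts at the
bottom-left corner of the plots.

## Smoothing

Traces are smoothed once, at load time, with a Savitzky–Golay filter:
the least-squares fit of a polynomial of order N (default 3) over a
moving frame of 2M+1 samples (default M = 50, frame 101, i.e. 5.05 ms at
20 kHz).  Interior samples use the standard mid-point convolution weights
(scipy's `savgol_coeffs`, cross-checked in the tests against a direct
least-squares solve).  At the M samples nearest each end the full frame
does not exist; there the order-N polynomial is fitted to the largest
available truncated window and evaluated at the sample.  This choice
preserves the filter's defining property — exact reproduction of
polynomials up to order N — at *every* sample, not just the interior,
which the test suite asserts.

The filter's normalised cutoff frequency is predicted by
f_c = (N+1)/(3.2M − 4.6), giving 4/155.4 ≈ 0.02574 for the defaults.
A published worked example of this formula quotes f_c = 0.0346 and a
"2.04 ms" frame for the same N, M and 20 kHz; neither number is
reproducible from the formula or the sampling rate (4/155.4 = 0.02574,
and 101 samples at 20 kHz span 5.05 ms).  The implementation follows the
formula as written and does not attempt to reproduce those figures.
`cutoff_hz` converts f_c to Hz; because f_c is defined as ω_c/π it is a
fraction of Nyquist, so the default multiplies by f_s/2.  The
`convention="fs"` option multiplies by f_s instead, reproducing the
arithmetic that turns 0.0346 into "≈0.7 kHz" at 20 kHz.

Note that the frame is defined in *samples*: at sampling rates far below
20 kHz the default 101-sample frame spans tens of milliseconds and will
smear millisecond-scale FP downstrokes (shifting detected event times by
~10 ms at 5 kHz).  Analyses at other rates should scale `half_width`
to keep the frame's duration comparable.

## Activation detection

The activation time at an electrode is the time of the steepest negative
gradient (dV/dt_min) of its smoothed trace within the analysis window
[start, start+size).  The numeric gradient uses central differences at
interior samples and one-sided differences at the two ends (`np.gradient`,
the same semantics as MATLAB's `gradient`).  Ties are broken toward the
earliest sample so detection is deterministic.  Resolution is one sample
(1/f_s): no sub-sample interpolation is performed, matching the
"mark a sample" character of the method.  An electrode whose steepest
gradient is non-negative had no downstroke in the window; it is *not*
auto-excluded — the slope is surfaced in the activation map so the user
can silence it, matching the manual silencing workflow.

A consequence of sample-resolution argmin detection worth knowing: under
additive noise the smoothed gradient is locally quadratic (nearly flat)
around its minimum, so the argmin scatters over a few neighbouring
samples even at signal-to-noise ratios of 10–50.  With the default
template and smoothing at 20 kHz, roughly a third to a half of noise
realisations at SNR 10 land within ±1 sample of the analytic
steepest-descent time (the acceptance script measures this percentage);
noise-free recovery is exact.  Sub-sample precision under noise would
require interpolation, which is deliberately out of scope.

Beat counting reuses the same feature: events are samples where the
smoothed-trace gradient drops below −k robust SDs of the gradient series
(default k = 5), thinned greedily steepest-first so that surviving events
are at least one refractory period apart (default 100 ms).  The threshold
is relative, making the detector invariant to gain.  This detector is an
extension built on the dV/dt feature, not a published procedure; beats
per minute = count × 60000 / duration_ms.

## Surface fit and velocity vectors

The activation surface T(x, y) = ax² + by² + cxy + dx + ey + f is fitted
by ordinary least squares to all detected, non-silenced activation times
(≥6 required).  Raw µm² design columns reach ~10⁶ and would make the
normal equations ill-conditioned, so coordinates are centered and scaled
to unit RMS before solving (`numpy.linalg.lstsq`, an orthogonal
decomposition returning the minimum-norm solution); coefficients are
algebraically transformed back to µm/ms units.  A rank-deficient design
(electrodes lying on a degenerate conic — e.g. six points on two grid
lines) produces a warning and the minimum-norm surface rather than an
error.

Velocity at each electrode is V = (T_x, T_y)/(T_x² + T_y²) with
(T_x, T_y) = (2ax + cy + d, 2by + cx + e) evaluated at the
electrode position.  The identities V·∇T = 1 and |V| = 1/|∇T| hold to
machine precision and are asserted in the tests.  Electrodes where
|∇T| < 10⁻¹² ms/µm sit at a stationary point of the surface; they are
reported as *undefined* and excluded from the mean rather than silently
dropped.  The mean local conduction velocity is the arithmetic mean of
the defined speeds.  One global quadratic is fitted per wavefront/window;
local or windowed variants of the gradient method are out of scope.

Residual diagnostics report the residual mean and SD (√(RSS/n)),
per-electrode (predicted, residual) pairs for the standard
predicted-vs-residual plot, and the Shapiro–Wilk W statistic and p-value
as the normality summary (NaN for numerically exact fits, where the
statistic is undefined).

## Robustness experiments

**Dropout.**  For each requested n, electrodes are silenced uniformly at
random without replacement (independently across replicates, all draws
from one seeded generator), the surface refitted, and the resulting mean
CV expressed as a percent of the best estimate — the one using every
available electrode.  On exactly-quadratic activation data any subset of
≥6 electrodes in general position returns the identical surface, so the
curve is flat at 100%; the informative case adds Gaussian jitter to the
activation times (`jitter_activation_times`, SD 0.1 ms by default in the
experiments), whereupon the spread of percent-of-best across replicates
grows with n.

**White noise.**  Noise levels are expressed in multiples of each trace's
robust SD (median absolute deviation × 1.4826) — a scale-free definition
chosen because the magnitude units of "+4"-style noise annotations are
otherwise undefined.  On a real recording the MAD tracks the baseline
noise floor.  Noise-free synthetic traces have an essentially zero
baseline (the MAD measures only the template's numerical tails, ~10⁻⁵ of
the dynamic range), so when the MAD-based estimate falls below 0.1% of
the trace's range the plain SD of the trace is used as the scale instead;
no physical recording reaches that regime (quantization noise alone is
larger), so the fallback only ever affects clean synthetic data.  For
each (level, replicate) the raw recording gets fresh seeded noise, is
re-smoothed, re-detected and re-fitted, and the mean absolute
activation-time change and absolute mean-CV change against the clean
analysis are recorded; per-level summaries report mean ± SEM
(SD/√reps, 5 replicates by default).  Level 0 reruns the identical
computation and therefore yields exactly zero error.

## Synthetic data generator

The generator stands in for cultured-cardiomyocyte recordings.  Its FP
template is g(τ) = −A·(τ/w)·exp((1 − (τ/w)²)/2): a biphasic deflection
(positive lobe, then the dominant negative stroke) whose derivative has a
unique, analytically known minimum at τ = 0, so the ground-truth
activation time is exact by construction.  Defaults A = 500 µV and
w = 1 ms give FP amplitude and downstroke duration in the range typical
of cardiomyocyte monolayer recordings.  Wavefront kinds: *planar*
(arrival t₀ + (x cosθ + y sinθ)/v), *focal* (isotropic point source,
t₀ + |r − origin|/v) and *quadratic* (arrival directly on a chosen
T(x, y), the fit's own model class).  Ground truth carries per-electrode
arrival times and closed-form velocity vectors.  Noise is i.i.d.
Gaussian per electrode, scaled by the clean trace's robust SD and drawn
from the spec's seed.

What the generator does **not** emulate: baseline wander and electrode
drift, 50/60 Hz interference, correlated (colored) noise, waveform
heterogeneity across electrodes, anisotropic or heterogeneous
propagation, wavefront curvature beyond what a quadratic surface or a
circular front produces, and repolarisation waves.  Passing tests
therefore demonstrate correctness of the numerics and the estimation
pipeline under the stated model, not detector performance on arbitrary
biological recordings.

## Figures and movies

Every plot function writes the figure and returns the numbers it rendered
(grid values, contour levels, arrow angles, per-frame metadata), so tests
assert on data rather than pixels.  Heat maps annotate per-electrode
times, render silenced/missing cells as blank grey, and map the earliest
time to the blue end of a jet-like colormap.  Isochrone maps impute
missing cells from the fitted surface before contouring — the same model
the CV analysis already trusts.  3-D signal-progression frames show the
*raw* voltages on the 8×8 grid with a z-axis fixed across frames; frames
are written as numbered PNGs or assembled into an animated GIF at 25 fps
(with the default stride of 20 at 20 kHz, playback is ≈100× slower than
real time).

## Numerical and design choices

- Sampling-rate inference from the ASCII time column tolerates ≤1 ppm
  jitter; anything larger is rejected rather than resampled.
- ASCII dialect: tab/semicolon/comma delimiters and `El NN [µV]` or bare
  `NN` headers are auto-detected; `#` comment lines and µs time columns
  are accepted.  Voltages are written with 6 significant digits by
  default; the time column always gets 10 so the grid survives the
  round trip.
- Degenerate inputs: <6 activation times, an all-silenced mask, a
  stationary fitted surface, windows outside the recording and clipped
  synthetic waveforms all raise informative errors rather than produce
  numbers.
- All experiment randomness flows through `numpy.random.default_rng`
  seeds; identical seeds give bitwise-identical curves and recordings.
- Test problem sizes (recordings of ~20–25 ms at 20 kHz, 100 dropout
  replicates, 5 noise replicates per level) were chosen so the whole
  pipeline including every robustness experiment re-runs in seconds,
  which keeps the experiments practical to re-execute as ordinary tests.

## Known limitations

No spike sorting, FP-duration measurement or arrhythmia classification;
no native binary (.mcd) parsing — recordings must be exported to ASCII;
no anisotropy tensor or curvature analysis; a single global quadratic
surface per event; sample-resolution activation times (see the detection
scatter note above); MP4 export requires an external encoder, so movies
are GIF or PNG frames.
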