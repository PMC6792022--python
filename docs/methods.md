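# Methods

## The measurement model

A phone-class triaxial accelerometer strapped to the upper abdomen of a
supine, otherwise stationary person measures almost exclusively the gravity
vector expressed in the sensor's own coordinate frame. Abdominal
(diaphragmatic) breathing tilts the device periodically about a roughly
body-fixed axis, so the measured vector traces a small arc on the sphere of
radius *g*. The breathing information is therefore carried by the sensor's
orientation, not by translational acceleration, and the direction along which
the measurements disperse most — the first principal component of the sample
cloud — is the natural 1-D axis on which to read breathing displacement.

The extraction pipeline is, in order:

1. **RC low-pass filter.** Each axis is smoothed with a first-order
   (single-pole) IIR filter, the discrete analogue of a resistor–capacitor
   low-pass, with a −3 dB cutoff of 0.5 Hz. Breathing lives well below
   0.5 Hz; wideband sensor noise does not.
2. **Projection.** The filtered 3-vector is projected by scalar product onto
   the *principal dispersion direction* `u` obtained from reference
   recordings (below). Because the filter acts per-axis with identical
   coefficients and projection is linear, filtering and projecting commute;
   the implementation filters first, and a property test asserts the
   equivalence.
3. **Affine scaling.** The scalar projection `p` is mapped by
   `value = 2 (p − ref_min)/(ref_max − ref_min) − 1`, so the *reference
   range* `[ref_min, ref_max]` — what deep abdominal breathing spans —
   covers (−1, 1). Excursions outside are allowed and meaningful.

### The reference model

The model is fitted from trials of a few persons already trained in deep
abdominal breathing (the package simulates 5 persons × 3 × 60 s trials):

* `principal_direction` — first principal component of all samples pooled
  across persons and trials, computed by SVD of the mean-centred cloud.
  A principal component is defined only up to sign; the fitted direction is
  oriented to have a non-negative component along the sensor x-axis (falling
  back to y, then z, on exact zeros) so extraction polarity is reproducible.
  Which polarity corresponds to inhalation is a display convention.
* `reference_vector` — the pooled sample mean, also used by the positioning
  procedure.
* `ref_min` / `ref_max` — each person's minimum / maximum projection onto
  `u` (over that person's pooled trials), averaged across persons. Raw
  extrema are used by default; a percentile option exists for noisy data but
  is off.

### Filter discretization

The filter recursion is `y[n] = y[n−1] + α (x[n] − y[n−1])` with the
analog pole mapped exactly: `α = 1 − exp(−dt/RC)`, `RC = 1/(2π f_c)`. The
first-order Euler coefficient `dt/(RC + dt)` is the more common quick
derivation, but at 50 Hz sampling it realizes its −3 dB point about 2% below
the designed cutoff; the pole-mapped form keeps the measured −3 dB point at
the designed 0.5 Hz (measured 0.5003 Hz by the sweep in
`scripts/acceptance.py`). The two agree to first order in `dt/RC`. Filter
state starts at the first input sample, avoiding a start-up transient from
zero. DC gain is exactly 1.

## Positioning calibration

Repeatable placement is enforced by comparing the live accelerometer vector
against `reference_vector` separately in the sensor xy- and xz-planes: both
vectors are orthogonally projected onto the plane and the unsigned angle
between projections is `arccos` of their normalized scalar product. Each
plane's deviation is classified **green < 5°**, **orange < 15°**, **red**
otherwise — the thresholds are strict inequalities, so exactly 5° is orange
and exactly 15° red. Positioning succeeds when both planes stay green for
5 s continuously; any non-green sample resets the dwell timer to zero
(a deliberate full-reset policy — pausing would reward oscillating in and
out of tolerance), and success latches once reached. The dwell comparison
carries a 1 ns tolerance so that accumulating 250 float steps of 0.02 s
counts as the full 5 s.

If a vector is (near-)normal to a plane its projection carries no
directional information; `plane_angle` raises a degenerate-projection error
when the projection norm falls below 1e-6 of the vector norm. A perfectly
leveled device is exactly this degenerate case for the xy-plane — one reason
the simulator's default resting pose is tilted (below).

## Paced breathing

The instructed target is `sin(2π f t − π/2)` at `f` = 0.1 Hz (6 cycles/min),
started at the trough so the first instruction is an inhale. Phase labels
flip at each half-cycle (rising = inhale); each half-cycle is divided into
four equal counting intervals (1.25 s per count at 0.1 Hz). Inhale and
exhale halves are symmetric — no asymmetric duty cycle is modeled. The
target-vs-actual deviation resamples the target onto the signal's timestamps
and reports the pointwise error and its RMS.

## Spectral metrics

The estimator is a mean-removed, Hann-tapered periodogram, zero-padded when
needed so the frequency grid is no coarser than 0.005 Hz, normalized so the
non-DC bins sum to the signal variance. Band power sums bins over half-open
intervals `[lo, hi)`, so contiguous bands partition the spectrum exactly.

* **Slow-breathing table:** 14 contiguous bands of width 0.01 Hz covering
  0.055–0.195 Hz.
* **Recommended-band power:** 0.09–0.11 Hz, around the instructed 0.1 Hz.
* **Respiratory SNR:** recommended-band power divided by the power of the
  rest of the breathing spectrum — `[0.05 Hz, f_max)` minus the recommended
  band, with DC removed by mean subtraction and everything below 0.05 Hz
  excluded as non-respiratory drift. `f_max` defaults to 0.5 Hz, the
  extraction filter's cutoff, beyond which the pipeline attenuates by
  design.
* **Per-minute series:** both metrics per non-overlapping 60 s segment of a
  300 s block (exactly 5 values).
* **Cohort summary:** the full pipeline per subject-block trace, aggregated
  to group × block means and SDs. Subjects missing a required block are
  excluded entirely (block contrasts are paired) with a warning naming them;
  single-subject groups report SD as NaN.

Resolution caveat: a 60 s segment zero-padded onto the fine grid spreads a
sinusoid's power over the Hann main lobe (~4/T ≈ 0.067 Hz wide), so even a
perfect 0.1 Hz sine keeps only ~2/3 of its power inside the 0.02 Hz-wide
recommended band and per-minute SNR saturates around 2. Whole-block (300 s)
spectra resolve the band properly (>99.9% in-band for a pure tone). The
metrics are therefore comparable only between segments of equal length.

## The synthetic data generator

`simulate_breathing_trace` produces
`R_axis(θ(t))ᵀ · a_rest + ε(t)` with `θ(t) = A sin(φ(t))`: the resting
gravity vector `a_rest` rotated about a body-fixed tilt axis (default: the
sensor y-axis) by a sinusoidal tilt of amplitude `A`, plus i.i.d. Gaussian
noise per axis. All randomness flows from one seed. Defaults:

| parameter | default | why |
|---|---|---|
| sampling rate | 50 Hz | typical phone accelerometer rate; Nyquist far above every band of interest |
| tilt amplitude | 5° | a small but clearly resolvable abdominal tilt |
| gravity | 9.81 m/s² | standard |
| noise SD | 0 (sims use 0.05 m/s²) | phone-class accelerometer noise at short horizons |
| resting pose | 8° about x, 5° about y | a strapped-on phone is never perfectly leveled; also keeps both calibration planes non-degenerate |

Cycle-to-cycle irregularity is modeled by redrawing the instantaneous
frequency once per breathing cycle from `N(f_nominal, jitter_sd)` (truncated
at a tenth of the nominal rate); `breathing_freq` may also be a
piecewise-constant trajectory. Translational (body) acceleration is an
optional additive term, off by default — gravity dominates the measurement
in this posture. Not modeled: gyroscope/magnetometer channels, sensor bias
and drift, posture changes mid-recording, thoracic/abdominal mixtures, and
non-sinusoidal breath shapes. Since every evaluation metric here is
spectral, passing tests demonstrate correct frequency-domain behaviour of
the pipeline, not robustness to real-world waveform or artifact variety.

### Synthetic cohort conditions

The two-arm study emulation (`default_group_specs`) uses, per 300 s block:

* **baseline / post:** per-subject spontaneous rate ~ N(0.20, 0.03) Hz
  (slow-deep but unpaced novice breathing, ~12 cycles/min), cycle jitter SD
  0.02 Hz;
* **training, pacing-only arm:** rate ~ N(0.10, 0.005) Hz, jitter SD
  0.02 Hz — follows the pacer loosely;
* **training, biofeedback arm:** rate exactly 0.10 Hz, jitter SD 0.005 Hz —
  holds the target tightly;
* both arms: tilt amplitude ~ N(5, 1)°, noise SD 0.05 m/s².

These produce the qualitative study shape — training beats baseline in both
arms, and the biofeedback arm attains the higher mean SNR — by construction
of the compliance difference; no claim is made about human effect sizes.

## Numerical choices

* PCA via SVD of the centred pooled cloud; degenerate (all-identical)
  clouds and collapsed reference ranges raise fit errors.
* Timestamps must be uniform within 1% of the median step for filtering;
  parse errors name the offending line.
* Spectra require at least two cycles of the lowest slow-band edge
  (~36 s); shorter segments raise an error naming the minimum.
* `arccos`-based angles lose ~√ε precision near 0° and 180°; tests tolerate
  1e-5 degrees there.
* Problem sizes throughout (300 s blocks at 50 Hz, 60 s pretest trials,
  10 subjects per arm in the cohort demonstration) keep any full run in
  seconds while leaving every band of interest resolved by a wide margin.

## Known limitations

* The reference range is a population average from the simulated trained
  cohort; per-user amplitude differences shift the effective scale of the
  extracted signal (excursions beyond ±1 are expected and harmless).
* Inhale/exhale polarity of the extracted signal is fixed by the sign
  convention, not anatomy.
* The SNR depends on segment length through leakage (see the resolution
  caveat); reported values are comparable only within a fixed segmentation.
* Repeated-measures statistics over cohorts are out of scope; the cohort
  summary table is descriptive (means/SDs).
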