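# Methods

This note documents the models and procedures implemented in `dentspike`,
the parameters that matter, what the synthetic generator does and does not
emulate, and the numerical and design choices made where more than one
reasonable option existed.

## Detection

A dentate spike is detected on a single target channel (normally the hilus,
where DSs are most prominent). The pipeline:

1. *(optional)* Subtract a reference channel — by default a single channel far
   from the dentate gyrus; a list of channels may be given, in which case
   their mean is used. Common-mode transients (movement or line artifacts,
   which appear identically on every electrode) cancel exactly.
2. Band-pass 1–200 Hz with a 4th-order Butterworth filter, applied
   forward-backward (zero phase). Zero-phase filtering minimizes peak
   displacement; the residual displacement caused by removing slow components
   is handled by step 4.
3. Find local maxima above `threshold_multiplier × median(|filtered|)`
   (default multiplier 7). The median is taken over the entire analyzed
   signal, literally the median absolute amplitude, not a MAD about the
   median. Peaks closer than `min_spacing_ms` (default 50 ms) are thinned by
   repeatedly removing the globally smallest peak involved in any violating
   pair — deterministic, and equivalent to "keep the highest peaks subject to
   spacing". Amplitude ties resolve against the later peak.
4. Re-align each peak to the maximum of the *raw* target LFP within a 20-ms
   window centered on the filtered peak, recording the offset in ms. Plateau
   ties take the earliest sample. Peaks that collapse onto the same corrected
   sample are merged; spacing is re-checked after correction and violations
   resolved by the same smallest-peak elimination (correction can move peaks
   closer together; the re-check keeps the event table's spacing invariant
   unconditional).
5. *(optional)* Exclude events whose raw peak amplitude falls outside
   Tukey's fences `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` of the amplitude
   distribution. Quartiles use linear interpolation between order statistics
   (numpy's default, the "type 7" convention). Excluded events remain in the
   event table with `excluded=True` and reason `tukey_high`/`tukey_low`.
   Fewer than four amplitudes pass through unfiltered.

## Delta-state segmentation and DS rate

DSs occur almost exclusively in delta-dominated (sleep-like) states, so rates
are computed over "strong delta" windows only.

- The raw LFP is decomposed by **empirical mode decomposition**, implemented
  here as standard sifting: cubic-spline envelopes through local extrema
  (two extrema mirrored at each boundary), the classic normalized
  squared-difference stopping criterion (tolerance 0.2, at most 50 sifting
  passes per mode), decomposition stopping when the residual has fewer than
  four extrema or after 12 modes. The algorithm is deterministic; sifting
  only subtracts envelope means, so the IMFs plus residual reconstruct the
  input exactly.
- The delta carrier defaults to **IMF-5**, the conventional index for 1-kHz
  rodent LFP. Because the index an oscillation lands on depends on the
  recording's broadband content, an automatic fallback selects the most
  powerful IMF whose spectral centroid lies in 0–5 Hz whenever IMF-5's does
  not; the fallback is logged.
- **Relative delta power** per window = (0–5 Hz power of the delta IMF) /
  (its own full-band power, 0 to Nyquist), estimated with a Welch
  periodogram (4-s segments). Windows are contiguous, non-overlapping,
  left-aligned 60-s bins; a trailing partial bin is kept when it covers at
  least 30 s. A window is **strong delta** iff the ratio strictly exceeds
  0.9; exactly 0.9 is weak.
- **DS rate** = events/min per strong window, averaged over strong windows;
  weak-window rates are reported separately. Zero strong windows yield a NaN
  mean with an `undefined` flag rather than an exception.

## Morphometrics

All shape metrics are computed on the **mean** waveform; single events are
contaminated by overlapping slow activity.

- *Scaled peak amplitude*: the mean waveform over ±200 ms is z-scored over
  that window; the scaled amplitude is the z value at the peak column.
- *Width (second-derivative metric)*: the mean waveform is resampled to
  4 kHz by an interpolating cubic spline (original samples are knots and are
  reproduced exactly), and the width is the distance between the second-
  derivative maxima in [−15, −5] ms and [5, 15] ms around the peak —
  the two upward concavities flanking the peak. Resolution 0.25 ms.
  Exact argmax ties break toward the peak and set a flag.
- *Numerical choice — derivative stencil*: the second derivative is a
  central second difference sliding on the 4-kHz grid with a stencil **as
  wide as the original sampling period** (1 ms for 1-kHz input). A one-step
  (0.25-ms) stencil would reproduce the interpolating spline's own second
  derivative, which is piecewise linear with maxima pinned to the original
  1-ms knots, quantizing the width limits to the coarse grid (bias up to
  ~0.7 ms for Gaussian shapes). With the native-period stencil the measured
  width of a Gaussian of width parameter σ matches the analytic value 2√3·σ
  within 0.3 ms over σ ∈ [3.5, 8] ms.
- *Half-height width*: distance between the two crossings of
  (baseline + peak)/2 nearest the peak, linearly interpolated on the 4-kHz
  grid. The baseline is the mean of the ±200-ms window excluding ±50 ms
  around the peak — a choice this metric is inherently sensitive to, which
  is exactly why the second-derivative width (which sees only peri-peak
  curvature) is the primary metric. A missing crossing flags the result
  with NaN width.
- *CV*: sample (n−1) standard deviation over mean, per group and across
  group means.

## CSD-based classification (reference method)

Per event, the laminar potential profile at the peak instant is converted to
CSD by the discrete 1-D Poisson equation with unit conductivity; electrode
spacing is omitted from the Laplacian's scale since only relative sink
positions matter. Negative CSD = sink, positive = source. The
events × interior-channels matrix is reduced by PCA; clustering uses **PC1
only** (which retains the bimodal type separation; a flag enables PC1+PC2),
with the explained variance of the first two components reported. A
2-component full-covariance Gaussian mixture is fit by EM with k-means
initialization once per seed (20 seeds, best log-likelihood kept; covariance
floor 10⁻⁶ of the mean feature variance). Events take the cluster with the
higher posterior, so every assigned posterior exceeds 0.5.

Type assignment: for each cluster's mean CSD profile, the dominant source is
the most positive value (the hilar/granule-layer return current) and the
dominant sink the most negative value among channels superficial to it. The
cluster whose sink sits more superficial — farther from the hilus, toward
the outer molecular layer — is DS1; the other is DS2. This is expressed
relative to the source so it does not depend on probe numbering. Coinciding
sinks leave the assignment unresolved and escalate to the single-type check.

## Waveform-based classification (single-channel method)

Features are the **raw** waveform amplitudes from −15 to +15 ms around the
peak — 31 samples at 1 kHz (other rates are spline-resampled onto that
grid). No z-scoring and no PCA: standardization discards the amplitude
information that separates the types.

- *Artifact-cluster iteration*: after each 2-component GMM fit (same engine
  and seed policy as above), a cluster holding less than 5 % **of the
  originally detected events** is treated as a bundled artifact group; its
  events are marked rejected and the mixture is refit on the remainder,
  until both clusters hold 5–95 %. Exhausting the events raises a "no
  stable partition" error.
- *Type assignment*: the cluster whose mean waveform has the smaller sum
  over the post-peak window — samples strictly after +10 ms through +50 ms
  inclusive — is DS2 (the stronger post-peak negativity). An exact tie (a
  measure-zero event) falls back to the sharper peak and is flagged.
- *Single-type check*: the dissimilarity index (DI) is the mean absolute
  difference of the two cluster means' second derivatives, each min-max
  scaled to [0, 1] over a 20-ms window centered at the peak (±10 ms
  inclusive on the native grid). DI ≤ 0.06 means the mixture split one
  population; all events are then relabeled by a majority of three votes on
  the merged mean waveform's width measurement — type 1 if width > 19 ms,
  if the start limit precedes −9.5 ms, or if the end limit exceeds +9.5 ms,
  else type 2. A flat second derivative (min = max) scales to all-0.5 and
  is flagged. The check runs after artifact rejection.

Determinism: identical inputs and seed lists give identical labels; on
well-separated data the partition is identical across individual seeds.

## Synthetic laminar LFP

The generator emulates the *statistical structure* the methods assume, not
dentate-gyrus biophysics — no compartmental modeling, no spiking units.

- **Templates**: unit-peak Gaussian main lobe (width parameter σ) plus an
  alpha-squared undershoot `−d·(t/τ)²·exp(2(1−t/τ))` for t > 0, which has
  zero value, slope and curvature at the peak, so the peak location and
  peri-peak concavity are untouched. Defaults: DS1 σ = 6.5 ms, undershoot
  depth 0.08, τ = 25 ms, 1.8 mV at the hilus; DS2 σ = 4.2 ms, depth 0.30,
  τ = 15 ms, 2.2 mV. Measured widths land near 22.5 and 14.75 ms — both
  sides of the 19-ms voting boundary — and the constructor rejects
  parameters whose measured width falls on the wrong side for the requested
  type.
- **Laminar gains**: a dipole-like profile — a positive Gaussian lobe (in
  channel index) centered on the hilus minus a negative lobe centered on the
  sink channel, normalized to 1 at the hilus. The DS1 sink sits 5 channels
  superficial to the hilus with wider lobes (its field crosses more
  channels); DS2's sink sits 3 channels up with narrower lobes. The discrete
  CSD of a clean event is most negative exactly at the configured sink.
- **Brain states**: a 3-Hz, 0.2-mV sinusoid on all channels during
  configured strong-delta epochs, a 6.5-Hz, 0.12-mV oscillation elsewhere.
  The amplitudes were fixed once so that (a) the detection threshold
  7 × median(|filtered|) sits well below the ~2-mV DS peaks, as on real
  hilar LFP, and (b) strong-epoch windows clear the 0.9 relative-power
  boundary decisively (≥ 0.94) while weak windows stay far below (≤ 0.24).
  On these defaults the delta oscillation lands in IMF-5, matching the
  conventional index. Events are placed only inside strong epochs (unless
  configured otherwise) with at least 80 ms spacing, by a seeded greedy draw
  over the millisecond grid; amplitudes get 3 % log-normal jitter.
- **Nuisances**: i.i.d. Gaussian noise per channel-sample (default sd
  0.1 mV), and optional common-mode transients (10-ms Hann pulses, default
  8 mV, identical on every channel).
- A single `numpy` Generator seeded once per call drives all randomness.

What the generator does **not** emulate: 1/f background spectra, theta-gamma
coupling, ripples, spatially varying noise, electrode drift, or overlapping
event waveforms. Passing recovery tests on this data therefore demonstrates
the pipeline's correctness and its behavior under the modeled nuisances —
not performance on real recordings, where background structure is richer.
The validation experiments probe exactly the failure modes the method has on
real data: class imbalance, small event counts (spurious single-cluster
merges become more frequent below a few hundred events — more than 500 are
recommended, and the classifiers warn below that), and additive noise
(accuracy decays monotonically, reaching chance when the noise scale matches
the peak amplitude).

## Evaluation conventions

Accuracy is the fraction of events labeled identically by the method under
test and the reference — ground-truth generation labels on synthetic data,
or the CSD-based labels on real recordings. Confusion matrices are reported
as counts with rows = reference; row-normalized, the diagonal holds the
recalls. Regressions are ordinary least squares; the slope-vs-1 test is a
Wald t-test, `(slope − 1)/SE` with n − 2 degrees of freedom. Subsampling
draws without replacement with a fresh seed per round (`base + round`);
the chance reference at DS2 proportion p is max(p, 1 − p). The waveform-
noise experiment balances the pool (equal type counts) before adding noise,
and reports mean ± sd of accuracy over repeats.

Experiment problem sizes in the shipped tests and acceptance script —
2 000-event pools, 50 subsampling rounds, 3 noise repeats — were chosen as
the package's desk-scale defaults; all experiment functions expose the
counts as parameters.

## Known limitations

- The EMD implementation uses mirrored-extrema boundary handling and the
  classic stopping rule; ensemble variants (EEMD) are out of scope, so heavy
  mode mixing in unusually structured recordings can shift which IMF carries
  delta (the centroid-based fallback mitigates this).
- The CSD classifier requires a single depth-ordered electrode column; probe
  layouts with multiple shanks must be split upstream.
- The DI threshold 0.06 is an empirical constant; with noisy cluster means
  (few events, high noise) the index has a noise floor that can approach the
  threshold from above, so borderline single-type decisions deserve manual
  inspection (the alternative 0.07 threshold is exposed in configuration).
- Half-height width is retained for comparison but is baseline-sensitive by
  construction; the second-derivative width is the metric of record.
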