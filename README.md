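# dentspike

Detection and classification of **dentate spikes (DSs)** in hippocampal
laminar LFP recordings.

Dentate spikes are brief (< 30 ms), large (> 1 mV) positive field transients
in the hilus of the dentate gyrus, driven by synchronous entorhinal cortex
input during immobility and sleep.  They come in two physiologically distinct
types: **DS1** (lateral entorhinal input, current sink in the outer molecular
layer, wider waveform) and **DS2** (medial entorhinal input, sink in the
middle molecular layer; taller, sharper, with a stronger post-peak
negativity).  Typing DSs classically requires a laminar probe spanning the
dentate gyrus so that current-source-density (CSD) profiles can be computed —
this package implements that reference method *and* a waveform-based
classifier that needs only a single recording site.

## What is inside

- **Detection** (`dentspike.detection`) — peaks of the 1–200 Hz band-passed
  hilar LFP above `7 × median(|filtered|)`, at least 50 ms apart, re-aligned
  to the raw-LFP maximum in a 20-ms window; optional artifact mitigation by
  reference-channel subtraction and Tukey-fence outlier exclusion
  (`[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` on peak amplitudes).
- **Brain state** (`dentspike.brain_state`) — empirical mode decomposition of
  the raw LFP; a one-minute window is "strong delta" when the delta IMF's
  0–5 Hz power exceeds 90 % of its own full-band power; DS rate is averaged
  over strong-delta windows.
- **Morphology** (`dentspike.morphology`) — mean-waveform metrics: peak
  amplitude, z-scored (±200 ms) peak amplitude, the second-derivative width
  (time between the upward-concavity maxima flanking the peak, searched in
  [−15, −5] and [5, 15] ms on a 4-kHz spline grid) and half-height width,
  plus coefficient-of-variation summaries.
- **CSD classifier** (`dentspike.csd.CsdClassifier`) — per-event CSD profiles
  via the 1-D Poisson equation `CSD(y_i) = −σ[V(y_{i+1}) − 2V(y_i) +
  V(y_{i−1})]`, PCA to the first component, 2-component Gaussian-mixture
  clustering (best of 20 seeds), types assigned by the position of each
  cluster's dominant sink relative to the hilar source.
- **Waveform classifier** (`dentspike.wfbc.WaveformClassifier`) — GMM
  clustering of raw 31-sample (−15…15 ms) waveforms with iterative rejection
  of sub-5 % artifact clusters; the cluster with the lower post-peak
  (10–50 ms) sum is DS2; a dissimilarity index (mean |Δ| of min-max-scaled
  second derivatives over ±10 ms, threshold 0.06) detects spurious splits of
  a single population, resolved by a 3-criterion width vote (width > 19 ms,
  start < −9.5 ms, end > 9.5 ms).
- **Synthesis** (`dentspike.synthesis`) — seeded laminar-LFP generator with
  ground-truth DS1/DS2 events, dipole laminar gains, delta/“theta” epochs,
  broadband noise and common-mode artifacts.
- **Evaluation** (`dentspike.evaluation`) — confusion metrics, slope-vs-1
  Wald regression, and the validation experiments (class-imbalance
  subsampling, waveform-noise tolerance, detection-noise sweep).

Both classifiers follow scikit-learn conventions (`fit`, `fit_predict`,
fitted attributes with trailing underscores) and compose with sklearn
tooling; `classify_csdbc` / `classify_wfbc` are functional wrappers that
operate on event tables.

## Worked example

```python
import dentspike as ds

# synthesize a 10-min, 16-channel recording with 100 DS1 + 100 DS2
cfg = ds.SynthConfig(duration_s=600, n_ds1=100, n_ds2=100, seed=1)
rec, truth = ds.synthesize_recording(cfg)

# detect on the hilus channel (depth index 12)
events = ds.detect_dentate_spikes(rec, 12)
print((~events.excluded).sum())          # -> 200 events kept

# single-channel waveform classification
wm = ds.extract_waveforms(rec, events[~events.excluded],
                          window=(-100, 100), channel=12)
labeled, report = ds.classify_wfbc(wm, events)
print(report["cluster_fractions"])       # -> [0.5, 0.5]
print(report["merged_single_type"])      # -> False (two genuine types)

# delta-state-aware rate
seg = ds.delta_segmentation(rec.get_channel(12), rec.fs)
rate = ds.ds_rate(labeled, seg, rec.fs)
print(round(rate.mean_rate, 1))          # -> 20.0 events/min in strong delta
```

The cluster fractions are the two GMM clusters' shares of all detected
events; with no artifact clusters below 5 % nothing is rejected.  A
`merged_single_type` of `True` would mean the dissimilarity check found the
two clusters morphologically identical and the width vote assigned one type
to every event.

The same pipeline is scriptable from the shell:

```bash
dentspike simulate --seed 1 --out-prefix demo
dentspike detect --recording demo.bin --sidecar demo.json --channel 12 --out events.csv
dentspike classify --method wfbc --recording demo.bin --sidecar demo.json \
    --events events.csv --channel 12 --out labeled.csv
dentspike evaluate --truth demo_truth.csv --pred labeled.csv --out score.json
```

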