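# Methods

This note documents the models behind the package, the parameters that
matter, the numerical conventions, and what the synthetic data do and do
not establish about real recordings.

## The calcium-imaging endpoint

### Acquisition model

A field of cells loaded with a Ca²⁺-sensitive dye is imaged at one frame
per second for 45 frames; the agonist is added by a pipettor at 10 s, so
frame indices 0–9 are the pre-stimulus baseline and frames 10–44 the
response window. All fluorescence values are in arbitrary camera units.

### Baseline, peak and ΔF

For each cell, `find_baseline_and_peak` computes

* **F₀** — the mean of pre-stimulus frames 1..9. Frame 0 is discarded
  because the first exposure of a recording commonly carries
  shutter/settling artefacts; a `f0="frame:k"` switch reads a single
  designated frame instead, for strict emulation of analyses that use
  one fixed baseline frame.
* **F₁** — a peak fluorescence value, in one of two modes (below).
* **ΔF** — one of three offsets: `sub` (F₁ − F₀), `ratio` (F₁/F₀),
  `relratio` (F₁/F₀ − 1). Ratio offsets require F₀ > 0; negative `sub`
  excursions are preserved.

**Peak modes.** `peak="cell"` takes each cell's own post-stimulus maximum
(earliest frame on ties). `peak="field"` — the pipeline default — first
identifies a single stimulus-locked peak time point for the whole field
(the post-stimulus argmax of the population-average trace) and reads
every cell's F₁ at that frame. The distinction matters statistically: a
per-cell maximum over ~35 frames of independent noise is an extreme-value
statistic whose expectation sits ~2 noise SDs above the baseline, so null
cells acquire a positive ΔF bias and a ~5 % spurious exceedance rate at a
3-SD threshold. Reading all cells at one common peak frame leaves null
ΔF zero-mean with SD ≈ noise_sd·√(1 + 1/9), which is what makes the
mean + 3 SD calibration land near 9 and the null false-positive rate near
the Gaussian 0.13 % tail. Responders are essentially unaffected because
they share the population peak time. Both modes are exposed; all
field-level results in this package use `peak="field"`.

### Threshold calibration and classification

`calibrate_threshold` takes ΔF values of buffer-treated (negative
control) cells and returns mean + k·SD (sample SD, n−1 denominator;
k = 3 by default), together with the empirical fraction of calibration
cells at or above their own threshold. Classification is **inclusive**:
reactive ⇔ ΔF ≥ threshold. The constant 9 — the calibrated value under
the default noise model — is available as a fixed override
(`calmea.quant.DEFAULT_THRESHOLD`) so analyses can be run without a
control field.

### Non-reactive-pool correction

A mixed culture contains cells (glia, immature neurons) that cannot
respond to any agonist; the correction assumes this pool to be 20 % of
each field. Two variants are implemented because both appear in practice
and they answer slightly different questions:

* `exclude` (default): drop the ⌊0.2·n⌋ cells with lowest ΔF and
  recompute the reactive fraction over the remainder;
* `subtract`: compute the mean ΔF of that lowest pool and subtract it
  from every cell before re-classifying at the unchanged threshold.

Neither is asserted to be "the" correct correction; the mode is recorded
in every output.

### Offset-method comparison

`rank_offset_methods` scores each offset formula by Cohen's d (pooled-SD
standardised mean difference) between stimulated and control ΔF
populations. When baselines vary from cell to cell and the response is
additive with roughly constant variance — the regime the generator
simulates — the subtraction offset wins, because dividing by a
heterogeneous F₀ injects baseline variance into the ratio offsets.

### Group statistics

Reactive fractions are compared on 2×2 reactive/non-reactive tables with
the Pearson chi-square statistic (no continuity correction, 1 df)
followed by the exact two-sided Fisher test; significance is flagged from
the Fisher p-value (the more conservative) at α = 0.05. Group means use
Welch's unequal-variance two-sided t test. Both tests are two-sided
throughout. No multiple-testing correction is applied across
concentrations of a dose series; the dose–response report makes one
comparison per condition against an explicit, user-designated reference.

## The MEA event cascade

* **Noise estimate** — per 100-ms window, SD = 1.4826 × MAD, robust to
  spikes riding on the noise. Traces shorter than one window get a single
  global estimate.
* **Spikes** — samples with |v| above 5.5× the local SD are grouped;
  groups closer than the 1-ms refractory window merge; each event is
  timed at its extremum sample. Both polarities trigger. At 12.5 kHz and
  Gaussian noise the false-positive rate of the 5.5σ rule is ≈ 0.
* **Bursts** — maximal runs of ≥ 5 spikes on one electrode with every
  ISI ≤ 100 ms. The assay's "minimum 5 spikes per second" burst wording
  is implemented as minimum 5 spikes per burst: the ≤ 100 ms ISI rule
  already guarantees ≥ 10 Hz within a burst, making a separate rate
  criterion redundant.
* **Network bursts** — spikes pooled over electrodes, same ISI rule,
  ≥ 50 spikes per run (a count criterion; a rate reading of the same
  wording would be weaker for runs shorter than 1 s) and ≥ 60 % of
  *active* electrodes contributing ≥ 1 spike. "Active" defaults to ≥ 5
  spikes/min over the analysed window and is configurable (`"all"`, an
  explicit electrode set, or the rate rule).
* **Metrics** — network-burst frequency (events/min), mean spikes per
  burst (NaN when no bursts — deliberately not an error), and the
  synchronicity coefficient: the mean pairwise zero-lag Pearson
  correlation of 0.1-s binned per-electrode counts over active electrode
  pairs. This is a documented proxy for whatever proprietary coordination
  statistic a vendor dashboard reports; it is 1.0 for identical trains
  and ≈ 0 for independent Poisson trains.
* **Acute response** — fold change of the mean post-addition spike rate
  over the mean baseline rate on aligned 0.1-s binned series; an empty
  post window gives fold 0, a zero baseline gives NaN.

Binning is half-open everywhere: a spike exactly on a bin edge counts in
the bin whose left edge it sits on.

## The synthetic generator

### Calcium fields

Each cell's trace is
`baseline + responder·amplitude·template + noise`, with

| parameter | default | meaning |
|---|---|---|
| `baseline_mean`, `baseline_sd` | 50, 10 a.u. | cell-to-cell resting-level heterogeneity (clipped at 1 to keep ratio offsets defined) |
| `noise_sd` | 3.0 a.u. | additive white per-frame noise; chosen so that the mean + 3 SD noise band of null ΔF lands at the working threshold of ~9 |
| `amp_mean`, `amp_sd`, `amp_min` | 40, 10, 15 a.u. | responder peak amplitude, normal truncated below at `amp_min` so true responders stay separable from noise |
| `p_react` | — | responder probability; i.i.d. Bernoulli per cell |
| `fpr_contamination` | 0 | probability a null cell gets a sustained excursion drawn uniformly on (9, 27), for false-positive round trips |
| `n_frames`, `frame_interval`, `stimulus_frame` | 45, 1 s, 10 | acquisition geometry |

Kinetic templates (unit amplitude, zero before the stimulus):
*transient* rises linearly over 3 frames and decays exponentially with
τ = 15 s — the fast-in/slow-out shape of a direct NMDA-type response;
*plateau* rises over 8 frames and stays at maximum for the rest of the
recording — the sustained shape seen with agonists such as quinolinic,
ibotenic or domoic acid. The rise/decay constants are package choices:
only the qualitative contrast (fast-transient vs. slow-sustained ≥ 45 s)
is anchored in observation, and no kinetic curve fitting is attempted.

Since real recordings publish neither amplitude nor baseline
distributions, all generator magnitudes are *defaults defining the
simulation conditions*, not estimates of any particular dataset.

**Rendering.** `render_field_video` places integer-pixel centroids by
rejection sampling (minimum centre distance 2·radius, bounded retries,
then an error) and draws each cell as a 2-D Gaussian blob (σ = radius/2)
whose intensity is normalised so that the mean pixel value inside the
extraction disk equals the trace value — making the noise-free
render → detect → extract round trip scale-true rather than merely
proportional, so ΔF thresholds keep their meaning after extraction. The
nuclear channel marks centroids with sharp Gaussian dots, standing in
for a nuclear-stain image. Residual inaccuracy comes from blob overlap
between cells at the minimum separation (~1 % cross-talk) and from
detected centroids off by a pixel.

### MEA wells

Sixteen electrodes (configurable) carry independent homogeneous Poisson
background spiking; each scheduled burst event injects `n_spikes`
regularly spaced spikes (intra-burst ISI < 100 ms, small per-electrode
onset jitter) on a random `fraction` of electrodes.
`render_voltage_traces` emits unit-SD Gaussian noise at 12.5 kHz plus a
biphasic waveform (dominant negative peak, ~1.6 ms) of peak amplitude
`spike_amplitude_sigma` noise-SDs at each spike time. A 10σ spike is
recovered by the 5.5σ detector with ≥ 95 % sensitivity and ≤ 0.5 ms
jitter; a 4σ spike is recoverable only at the rate at which noise happens
to push it over threshold (~10 % per spike), i.e. not above chance in any
useful sense.

## What the synthetic data do not show

The generator reproduces the *statistical structure* the pipeline
assumes: i.i.d. responder membership, additive Gaussian white noise,
shared response kinetics, stationary Poisson background firing. Real
recordings violate most of these in degree — temporally correlated noise
and photobleaching, overlapping cells and neuropil contamination, cell-
to-cell kinetic variability, non-stationary network states, electrode
cross-talk. Passing round trips therefore validate the *implementation*
of the quantification rules and their behaviour under the stated noise
model; they are not evidence that the rules are optimal for any given
instrument.

## Numerical conventions and problem sizes

* Ties in peak finding resolve to the earliest frame; ties in pool
  selection resolve by stable sort order.
* Sample SDs use the n−1 denominator everywhere.
* Reproducibility: every generator takes an integer seed and identical
  seeds give bit-identical outputs; the CLI writes all parameters to a
  `run_log.json` and its outputs are byte-identical across reruns.
* Validation suites run the pipeline at 2 000–2 600 cells per field and
  3–5 seeds per scenario, and image round trips at 50 cells/field × 40
  fields — sizes at which binomial counting error is a few tenths of a
  percentage point, comfortably inside the tolerances being checked.

## Known limitations

* The cell detector is a local-maximum finder with fixed-radius disk
  ROIs; it is validated on rendered blobs only and makes no claim to
  segment real micrographs (no demixing, no motion or bleaching
  correction).
* Multi-stimulus protocols, kinetic curve fitting, EC₅₀ estimation and
  excitotoxicity modelling are out of scope.
* The MEA path analyses spike lists or single-well voltage arrays; no
  plate-map or vendor file-format handling beyond CSV.
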