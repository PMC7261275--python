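# Methods

## Problem and model

The package classifies short clips of electrosurgical (diathermy) sound
into instrument–tissue interaction classes and locates tissue
transitions in continuous streams. The model is a classical
transfer-learning pipeline: a deterministic spectro-temporal front-end
renders each analysis window as a fixed-size image, a frozen
convolutional network maps the image to a feature vector, and a single
softmax layer — the only trained component — maps features to classes.

## Front-end

Each clip (mono, 44.1 kHz, samples in [−1, 1]) is segmented by a
rectangular sliding window of Δt ∈ {300, 500, 1000} ms with 75 % overlap;
trailing partial windows are discarded because the image renderer needs
fixed-size input. Per window:

- **STFT**: frames of N_f = 2048 samples, hop 512, symmetric Hann taper
  `w[n] = ½(1 − cos 2πn/(M−1))`; one-sided spectrum.
- **Power in dB**: `10·log₁₀(max(|X|², ε))` with `ε = 10^(db_floor/10)`,
  db_floor = −80 dB, so silence maps exactly to the floor and no value is
  ever −∞. No reference-power division is applied; the global
  normalization below absorbs scale.
- **Mel filterbank**: 256 triangular filters whose corner points are
  evenly spaced on the mel scale `f_mel = 2595·log₁₀(1 + f/700)` (the
  purely logarithmic form; 1000 Hz ↦ 1000 mel within 0.1) between f_min
  and f_max = 11 025 Hz. Triangles are unnormalized with peak 1. Bins
  above f_max get zero weight; Nyquist is 22 050 Hz, so the upper octave
  is deliberately excluded. The low-cut of environmental noise is
  realized as f_min = 2000 Hz in the filterbank, not as a time-domain
  high-pass; the band count stays 256 over the reduced range.
  At 256 bands over the full range the narrowest triangles near 0 Hz
  fall between FFT bin centers; such a filter is snapped to its nearest
  bin so every band remains responsive (all rows strictly positive). The
  band count is rejected only when it exceeds the number of FFT bins
  inside [f_min, f_max].
- **Normalization**: scalar μ and σ (population convention) over every
  cell of the fitted collection, applied as (X − μ)/σ. Stats are fitted
  on the *training split* by default to avoid leakage; `norm_split="all"`
  (CLI `--paper-faithful-norm`) fits on the entire dataset instead.
  A global scalar is used rather than per-band statistics because the
  normalization formula carries no band index.
- **Rendering**: bilinear resize of (n_mels × frames) to a 299-pixel
  square, low frequency at the image bottom, gray values replicated
  across 3 channels. Replication is information-preserving and avoids a
  colormap convention.

## Backbone

Transfer learning only requires a fixed, expressive image-to-vector map,
and convolutional networks extract useful features even with random
weights. The default backbone is therefore a *seeded random-weight* CNN:
three 3×3 valid convolutions with stride 2 (8, 16, 32 channels), ReLU,
followed by adaptive 8×8 average pooling of the 32 feature maps —
8·8·32 = 2048 features. Weights are He-scaled draws from a named
substream of the seed and are never trained, so extraction is exactly
reproducible and requires no downloaded weights. The three identical
image channels are collapsed to one before convolution. Any object
satisfying `extract(image) -> vector` (e.g. a locally available
pretrained deep CNN) can be substituted through the same contract.

## Classifier head and training

A single fully connected layer with softmax output is trained with
mini-batch RMSprop (batch 32, decay 0.9, ε = 1e−8) on cross-entropy
`H(y,p) = −Σ_c y_c ln p_c` (probabilities clamped at 1e−12). Defaults:
learning rate 1e−3, at most 100 epochs, early stopping when validation
loss has not improved for 10 epochs; the best-validation-epoch weights
are returned and the per-epoch losses are logged. These optimizer
hyperparameters are the package's own choices for stable desk-scale
convergence; they are exposed in `TrainConfig`.

Splitting is 80/10/10 train/val/test, stratified by class, at **clip
level**: every window of a clip shares its split, so overlapping windows
can never leak between train and test. (A window-level split switch
exists on the CLI for comparison; it is not recommended.)

## Transition localization

A stream is classified window by window (500 ms / 75 % by default), the
label sequence is smoothed with a width-3 majority filter — the smallest
filter that removes single-window flickers — and the transition estimate
is the midpoint between the last window start of the first stable run
and the first window start of the next run, **plus Δt/2**. The centering
term exists because a window is labeled by its dominant content: its
label flips when the window is about half past the physical transition,
so the raw run boundary lags the truth by ≈ (Δt + hop)/2 (≈ 310 ms at
the default configuration). With centering, the median offset on clean
synthetic transitions is a few tens of milliseconds. A stream whose
smoothed labels never change raises `NoTransitionDetected` rather than
fabricating a time.

## Synthetic data generator

The generator emulates the *statistical contract* of intra-operative
diathermy recordings, not their physics (no accepted acoustic model of
tissue vaporization exists):

- **Class textures**: white noise through 1–2 resonant peaks
  (`scipy.signal.iirpeak`) per class plus Poisson crackle transients
  (exponential envelope, ~5 ms decay). Easy difficulty places tissue
  resonances at 3.0/4.6/6.2/7.8 kHz (bandwidth 400 Hz) — spectral
  centroids separated by well over 500 Hz; hard compresses the centers to
  4.8–6.0 kHz with 900 Hz bandwidths so classes genuinely overlap. Under
  the 9-class scheme the cut/coag variants of a tissue share resonance
  centers but differ in crackle rate (cutting doubles it) and secondary
  peak gain (+6 dB in coagulation).
- **Contamination**: mode-matched alarm sines (2020/3035 Hz cutting,
  1380/2270 Hz coagulation; −30 dBFS each) and 1/f environmental noise
  low-passed at 2 kHz (−38 dBFS). `idle` is the noise floor alone.
- **Clip lengths**: Normal(2000 ms, 300 ms) truncated below at 1200 ms
  (1.2× the longest analysis window), so window counts vary across clips
  but every clip yields at least one window at every configuration.
- Classes are exactly balanced; under the 5-class scheme the operation
  mode alternates within each tissue so alarm tones are balanced rather
  than class-informative. All waveforms are deterministic per seed and
  peak-guarded at 0.99.

What passing tests on this data do **not** show: robustness to room
acoustics, reverberation of an insufflated abdomen, instrument
variability, or real tissue acoustics. They do show that the pipeline
recovers class structure when class-conditional spectral envelopes
exist, that no information leaks through splitting or normalization
(label-shuffled control sits at chance), and that the machinery is
deterministic end to end.

## Numerical choices and degenerate inputs

- All seeds flow from one integer through named CRC32-keyed substreams
  (synth, durations, split, backbone, train), keeping stages
  independently reproducible.
- dB flooring uses ε inside the log, making `power_to_db(0)` exactly the
  floor. `fit_normalization` rejects empty or zero-variance collections.
- Softmax is computed with max-subtraction; ties in argmax break toward
  the lowest class index.
- WAV writing refuses samples above full scale instead of clipping
  silently; 16-bit (default) and 24-bit PCM are supported, scaled by
  2^(bits−1) symmetric with reading.
- Notch filtering (second-order IIR biquads, Q = 30, one per alarm tone)
  is off by default in the pipeline — removing the tones is not expected
  to change class information since tones are mode-balanced — but
  available via `NotchSpec` / `--notch`.

## Problem sizes

Default experiment scale is 20 clips (~2 s each) per class, i.e. 100
clips for the 5-class and 180 for the 9-class scheme, ≈ 1200–2300
analysis windows at the 500 ms configuration; the configuration sweep
trains one head per grid cell on the same dataset. These sizes keep a
full pipeline run in minutes on a single CPU while leaving enough test
windows (>100) for stable accuracy estimates.

## Known limitations

- The random-weight backbone is far weaker than a pretrained deep CNN on
  hard or real data; it suffices for the synthetic separability regimes
  tested here.
- The localization estimator assumes exactly one transition; multiple
  transitions report only the first.
- Mel filters are unnormalized (peak 1), so filter bandwidth weights the
  mel-power spectrum; with global z-normalization this is a harmless
  reparametrization for classification but makes absolute band energies
  non-comparable across bands.
- The generator's alarm tones are stationary pure sines; real alarm
  beeps are intermittent.
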