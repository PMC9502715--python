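# Methods

This note documents the models implemented by `spatialspeech`, the design
choices behind them, and what the synthetic test material can and cannot
show.

## Problem and system layout

A listener wearing a binaural hearing-aid array (three microphones behind
each ear) faces an acoustic scene containing one talker and a non-speech
noise source. The task is to identify the talker's azimuth sector so a
spatial filter can be steered at them. Two processing paths run in
parallel:

1. **DOA path** (high spatial resolution, no speech specificity):
   GCC-PHAT features → per-sector linear classifiers → calibrated
   source-presence probabilities `P(α, t)`, time-averaged into `P_DOA(α)`.
2. **Quality path** (speech-specific, low spatial resolution): an MVDR
   beamformer steered at each of 19 sectors (−90°…+90°, 10° steps), a
   phoneme classifier producing a posteriorgram per steered signal, and a
   single-ended quality measure `ASQM(α)` per sector.

The quality profile is min-max rescaled per utterance to `P_ASQM(α)` and
fused multiplicatively:

    P_s(α) = P_ASQM(α) · P_DOA(α),   α̂ = argmax_α P_s(α).

A hit means α̂ falls in the true source's 10°-wide sector (±5° tolerance);
chance level with 19 sectors is 1/19 ≈ 5.26%.

## DOA estimation

Per 25 ms frame (10 ms hop, Hann window), the phase-transform-whitened
cross-correlation

    ρ_kl(τ, t) = (1/Ω) Σ_ω X_k X_l* / |X_k X_l*| · e^{iωτ}

is evaluated on τ ∈ [−τ_max, +τ_max] for every pair of a 4-channel subset
(front and rear microphone of each ear) and concatenated into φ(t).
τ_max = ⌈aperture/c · f_s⌉ + 2 samples (11 at 16 kHz for the default
array) — the physically plausible delay range plus a small guard. The
spectral floor in the PHAT denominator is 1e−12; an all-zero frame yields a
zero feature vector and a degeneracy flag.

One linear max-margin classifier (one-vs-rest, C = 1) is trained per
sector on synthetic scenes: a speech-like source at that sector in an
anechoic diffuse noise field at −15, 0 and +15 dB SNR, all frames labelled
with the source sector. A single logistic calibration (β₁, β₂) is fitted
to the pooled decision values against binary sector-correctness labels, so

    P(α, t) = 1 / (1 + e^{−(β₁ + β₂ D(α, t))}).

No normalization across α is applied; sectors carry independent presence
probabilities. Argmax ties resolve to the lowest azimuth and are flagged.

## Beamforming

Frequency-domain MVDR with free-field steering vectors
`d_m = exp(−iω(τ_m − τ_ref))` (reference: front-left microphone; measured
impulse responses can be loaded instead) and an isotropic noise covariance

    R(ω) = (1/K) Σ_α d(α,ω) d(α,ω)ᴴ + λ·tr(R)/M·I

averaged over K = 72 directions spanning the full horizontal circle, with
diagonal loading λ = 1e−3 for guaranteed invertibility. The STFT uses a
512-sample square-root-Hann window at 50% overlap (perfect reconstruction
within 1e−6); beamformed signals are resynthesized to waveforms because the
quality path needs its own 25 ms/10 ms framing. For a two-microphone
free-field array this R reproduces the cylindrical-isotropic coherence
J₀(ωd/c) — the closed form for averaging plane waves over a horizontal
circle (the spherical-isotropic limit would be sinc).

## Posteriorgrams

Features are 40 log-mel energies (25 ms Hamming window, 10 ms hop, 512-bin
spectra, HTK mel scale 2595·log₁₀(1+f/700), log floor 1e−10), stacked with
±5 frames of context into 440-dimensional vectors (edges replicated). The
classifier is a small feed-forward softmax network (one hidden layer of
128 units by default) trained by cross-entropy on synthetic phone streams;
per-utterance mean normalization of the log-mel features provides level
invariance. Training is multi-condition: clean streams plus copies mixed
with stationary speech-shaped noise at 10–20 dB SNR, labels kept from the
clean alignment. As is typical for multi-condition acoustic models, frame
accuracy at mild noise (≈15 dB) slightly exceeds the clean condition; the
monotone degradation holds from there down (≈95% at 10 dB to ≈77% at
−5 dB on held-out streams).

A parametric generator produces posteriorgrams of controlled quality
directly from label sequences: one-hot rows are mixed toward uniform by a
degradation weight δ ∈ [0,1] and smoothed over time with a normalized
kernel of width `smear_ms`, emulating the reduced sparseness and temporal
smearing of noisy speech. Classifier and generator emit the same type, so
every quality measure is testable without a trained model. A triphone →
monophone grouping utility sums context-dependent columns into their base
phones (e.g. 2026 → 40 classes) for posteriorgrams imported from hybrid
ASR systems.

## Quality measures

* **M-Measure**: `M(Δt) = 1/(T−Δt) Σ_t D(P(t−Δt), P(t))` with
  probability floor 1e−10 and renormalization before the divergence. D is
  the symmetrised KL divergence by default (the asymmetric form is
  selectable; the printed definition does not resolve the direction). The
  scalar is the uniform mean of M(Δt) over Δt = 50…800 ms in 50 ms steps —
  the saturated part of the divergence curve, above typical phone duration
  and co-articulation spans. Utterances shorter than the largest lag
  restrict the grid and flag it rather than failing.
* **MaP filtering**: per phone, the activation trace is convolved with a
  matched filter — the time-reversed average clean activation trace,
  occurrences centred on run midpoints within a 51-frame (510 ms) support,
  normalized so a perfect clean match peaks at 1.0. Events are local
  maxima strictly above 0.5 separated by at least half the support;
  the scalar is the total event count. Counting thresholded peaks rather
  than above-threshold samples makes one phone occurrence one event.
* **Inverse entropy**: the negated average frame-wise entropy (bits,
  0·log 0 = 0). Negation rather than reciprocal — both are strictly
  decreasing in entropy, so every downstream argmax is identical; the
  reciprocal is available.

All three are invariant to a consistent permutation of class labels. The
printed definition of the entropy measure carries a stray factor of T; the
implementation is the stated average frame-wise entropy.

## Synthetic scenes

The scene generator emulates the reference acoustic setups without any
external corpus:

* **Array**: 6 microphones in two lateral triplets at ±9 cm, 1.5 cm
  front-back spacing, 16 kHz (ASR-standard rate).
* **Target**: a speech-like source — a random stream of 40 phone
  templates (harmonic source through formant resonators, or band-passed
  noise bursts) with silence gaps and 2–8 Hz syllabic amplitude
  modulation — at −30° by default. Utterance length defaults to 3 s,
  long enough for the full 800 ms M-Measure lag grid at a desk-scale
  runtime.
* **Noise**: either a diffuse field (19 independent speech-shaped
  stationary noises from equally spaced azimuths over 360°) or a localized
  weakly-modulated broadband interferer (near-white noise with a motor-hum
  harmonic stack and ~5% amplitude ripple) at +40°. The modulation
  asymmetry between target and interferer is deliberate: the interferer
  dominates the whitened cross-correlation statistics in speech pauses and
  high-frequency bands, which is what defeats a coherence-based localizer.
* **SNR**: set on the reference channel over target-active samples
  (frames within 40 dB of the peak frame energy), accurate to 0.01 dB;
  grid −10…+20 dB in 5 dB steps.
* **Spatialization**: far-field plane-wave fractional delays
  (τ_m = −(p_m·u)/c, implemented as exact phase shifts). A first-order
  low-pass (cutoff shrinking with lateral angle) plus broadband
  attenuation on the contralateral ear approximates head shadow and is on
  by default in scene construction: without it the array is perfectly
  left-right symmetric for the intra-ear microphone pairs and a strong
  localized source casts a mirror-image ghost (+40° → −40°) into the DOA
  map, an artifact measured head-related impulse responses do not have.
  An importer for user-supplied multichannel impulse responses is
  provided.
* **Reverberation**: per-channel convolution with a direct path plus an
  independent exponentially decaying random tail (default T60 = 0.5 s,
  Schroeder-verified, direct-to-reverberant ratio 3 dB) — the qualitative
  anechoic/office contrast, not an image-source room model.

### What the synthetic material does not show

The phone templates are acoustically well separated, stationary within a
segment and free of speaker variability, prosody and co-articulation; the
interferer is only vacuum-cleaner-*like*; head shadow is first-order. The
pipeline therefore demonstrates the mechanics and the qualitative
behaviour of the method — diffuse-noise localization near 100%, the
interferer capturing the DOA estimator, fusion recovering the talker — at
desk scale (50 scenes per condition, 2 s training scenes, 60 s classifier
training). Absolute hit rates on real speech, measured HRIRs and real
noise recordings may differ.

## Numerical choices

* Diagonal loading 1e−3·tr(R)/M; PHAT floor 1e−12; probability floor
  1e−10; log-mel floor 1e−10.
* Argmax ties → lowest azimuth, flagged.
* Constant quality profile → `P_ASQM ≡ 1` (degenerate flag), so fusion
  falls back to the DOA profile: a flat profile carries no directional
  information.
* All generators draw from `numpy` Generators seeded via `SeedSequence`;
  identical seeds give identical waveforms, models and tables.

## Known limitations

Single target only (no source counting or tracking); frontal hemisphere
only (no elevation); static scenes and static head; free-field array
model rather than measured head-related responses; the word-error-rate
validation of the quality measures requires a full ASR decoder and is out
of scope.
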