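# Methods

This note records the modeling choices behind the package: what the
synthetic generator does and does not emulate, the analysis conventions,
numerical details, and the places where the design was genuinely open.

## Experiment generator

Each trial holds two independent word-annotated conversations. Trial
duration is drawn N(44.2, 2.0²) s and the total word count N(138, 6.86²),
split evenly between the conversations (the per-trial word count is read as
the total over both streams; the resulting ~1.6 words/s per stream is a
plausible conversational rate once turn-taking pauses are included). Word
durations are log-normal with median 250 ms (the same median word length
that fixes the acoustic window downstream) and log-SD 0.35; inter-word gaps
are exponential draws rescaled so the requested count packs exactly into
the trial — both distributional forms are conventions, not inferences about
any particular stimulus set. The attended conversation begins first; one
attended talker switch occurs at 50% of the trial, two unattended switches
at 25% and 75%, with two talkers alternating per conversation from a pool
of eight.

1-back repeats duplicate the token of the immediately preceding word.
Repeat onsets follow N(7.0, 1.0²)-s target gaps; each target is snapped to
the nearest eligible word (has a predecessor, not adjacent to another
repeat, at least 2 s past the previous repeat, not overlapping a repeat in
the other stream within a 0.25-s guard). Realized intervals are therefore
censored at trial ends — a drawn gap that overshoots the trial is never
placed — which deflates the realized mean interval by under 1% relative to
the configured 7.0 s. Noise-condition labels (babble/pedestrian at
−9/−12 dB) are balanced 25% each and carry no acoustic content.

## Forward model

Electrode `e` responds to word `w` with amplitude `g_cond · (w_e · x_w)`,
convolved with a Hann-shaped 0–400 ms kernel (unit peak, 100 Hz), plus a
per-electrode share of the word-shaped speech envelope and white Gaussian
noise (SD 1.0 per 100-Hz sample). Readout weights are N(0, 1); with
unit-scale embeddings this puts per-word response amplitudes at SD ≈ 1.
`x_w` is the top-layer synthetic embedding computed with the stream's true
context window: 50 tokens (attended) vs 10 (unattended), window counted
*including* the current token so that an analysis context length `M = K`
saturates the generator exactly. Defaults `g_att = 1.0 > g_unatt = 0.4`
encode the attention gain; `K_att = 50 > K_unatt = 10` the timescale
asymmetry. Simulated envelope-mode signals fluctuate around zero (they are
readout fluctuations, not rectified amplitudes); the nonnegativity contract
applies to envelopes produced by the preprocessing chain.

Raw mode wraps the same signal for validating the preprocessing chain: the
envelope-mode signal is low-passed at 3 Hz — amplitude fluctuations above
the sub-band envelope bandwidth are not recoverable by any 70–150 Hz
envelope extractor, so leaving them in the modulator would make the
round-trip oracle unattainable by construction — offset by +2 SD, clipped
positive, and used to amplitude-modulate band-limited (70–150 Hz) Gaussian
noise, plus 1/f noise (0.4× mean modulator) and a fixed 60-Hz line tone
(2×). The per-electrode modulator is stored as the recovery oracle; the
full chain recovers it with r ≈ 0.85–0.89 per channel.

Behavioural simulation: each attended repeat elicits a press with
probability 0.7 (the published detection range is 67–75%) after a
N(0.9, 0.25²)-s reaction delay; unattended repeats with probability 0.05.
Scoring credits each press to at most one repeat within a 2-s window,
shortest delay first.

## Synthetic contextual embeddings

The bundled model mixes a lexical vector with a decayed average of the
preceding tokens: layer ℓ uses mixing weight αℓ (0, 0.1, …, 0.5 across nine
layers; α₀ = 0 keeps layer 0 context-free) and window Kℓ (1, 2, 4, …, 128,
nondecreasing so deeper layers integrate longer context), with geometric
decay γ = 0.95. The decay matters: with fast decay (e.g. 0.85) tokens
beyond ~14 positions carry <1% of the context mass and a "true context
window of 50" would be vacuous; at 0.95, tokens 15–49 carry ≈44% of the
mass, so the long attended window is genuinely informative. Context length
`M` counts the visible window including the current token (M = 1 means no
preceding context), making M = 1 the natural context-free endpoint of the
context-length curve.

Truncation monotonicity — the distance between truncated-M and full-context
vectors shrinking as M grows — holds for M ≥ 2. The M = 1 endpoint is a
genuine exception of the normalized-average mixing rule: the empty context
term (zero vector) typically lies closer to the full-context average than
any single predecessor's unit-scale vector does.

The untrained control redraws the lexicon and mixing parameters at random
with the layer structure preserved, mirroring a randomly re-initialized
network. The one-word-one-token tokenizer keeps the bundled model simple;
the final-token representation rule is exercised through a splitting test
adapter, and the optional transformer adapter applies the same rule to real
subword tokenizations.

## Encoding models

Neural targets are the 100-Hz high-gamma envelope averaged in seven 200-ms
windows, 50-ms stride, spanning 500 ms post word onset. One multi-output
ridge model per electrode predicts all seven lags with a shared λ (scores
averaged over lags; a lag-concatenated scoring variant is available behind
`RidgeConfig.score_mode`). λ is selected per electrode by nested
leave-one-trial-out on the training trials from 13 log-spaced values in
10⁻²–10⁴, maximizing mean held-out correlation; features are standardized
and responses centered with training-fold statistics only. Held-out trials
with fewer than 3 words are skipped; zero-variance predictions score 0 with
a warning.

The fitter works from per-trial Gram/cross-product statistics with one
eigendecomposition per fold, so nested CV cost is independent of total word
count; designs wider than the training word count are routed through the
mathematically identical dual (kernel) form. Both paths are cross-checked
against each other and against an independent Tikhonov least-squares solve
in the tests.

## Statistics

The electrode is the unit: per-trial scores are averaged within electrode
before pairing. Two-sided Wilcoxon signed-rank tests drop zero differences
and mid-rank ties; W is the positive-rank sum. For n ≤ 25 the p-value is
exact (dynamic programming over doubled mid-ranks — exact under ties);
beyond that a normal approximation with tie and continuity corrections is
used. The Bonferroni family size defaults to 6 and is configurable. Curves
report means with SEM across trial-averaged electrodes (undefined and
flagged for a single electrode).

## Numerical choices

Gaussian sub-band filtering runs in the frequency domain; multiplying the
spectrum by a positive-frequency Gaussian window (FWHM 10 Hz, centres 75,
85, …, 145 Hz) yields the analytic sub-band signal directly, so its modulus
is the Hilbert envelope of the band-passed signal. Resampling is polyphase
rational with reflect padding. The notch FIR (order 1000, ±1 Hz notches,
fir2-style frequency sampling, applied forward-backward) reaches −72 dB
per pass at the line harmonics in steady state; filtfilt edge transients
contaminate roughly the outer 1.5 s of a segment, so attenuation is
specified and tested on the steady-state region and the chain flags edge
samples in its logs. The auditory spectrogram uses 128 constant-Q channels
(Q = 8) log-spaced 180 Hz–7 kHz, a 2-kHz hair-cell low-pass, cube-root
compression, rectified spectral differencing, and 8-ms temporal integration
at 1000-Hz frames — frame rate forced by the 250-sample lag windows. It is
a stage-faithful re-implementation of the classic cochlear model, validated
by stage-wise properties (tone selectivity of the filterbank, the
compression law, silence mapping to zero) rather than bit-level identity
with any particular toolbox.

## Study scales

The headline recovery study runs 25 trials × 100 electrodes × 64-dim
embeddings × 9 layers with the full context-length grid (≈4–5 minutes on
one CPU); the acoustic-control comparison uses 5–6 trials and ~10
electrodes because its 1814-dimensional fused features dominate cost. These
sizes are the package's standard desk-scale conditions; all statistical
read-outs are computed, never assumed.

## What passing tests do and do not show

The generator realizes the *assumed* linear readout exactly: passing
recovery tests demonstrates that the analysis chain is correct and
sensitive enough to detect the built-in attention gains and context
timescales at desk scale. They do not show that real cortical responses
are linear in embedding space, that real attention effects have these
magnitudes, or that the synthetic embedding model's geometry matches a
trained transformer's. Known limitations: no acoustic voice or spatial
(HRTF) modeling — talker switches are label changes; noise conditions are
labels only; no artifact rejection or electrode screening; the synthetic
tokenizer is word-level; subject-level heterogeneity is out of scope (one
simulated subject per study).
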