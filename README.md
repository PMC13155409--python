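# cocktail-ctx

Encoding-model pipeline for studying how intracranial neural activity tracks
the *linguistic context* of attended and unattended speech in a
cocktail-party (dual-conversation) listening paradigm — with a fully
synthetic, ground-truth-parameterized data generator so that every stage is
testable without patient data.

## Who this is for

Researchers building or validating word-level neural encoding models
(ECoG/sEEG high-gamma responses predicted from language-model embeddings)
who need a reproducible sandbox: simulated experiments whose attention and
context structure is known exactly, plus the standard analysis chain used in
the intracranial speech-tracking literature.

## The model

Each experiment has 25 two-conversation trials (mean 44.2 s, ~138 words,
1-back repeat-detection task with ~7-s repeat intervals; one attended talker
switch at 50%, two unattended switches at 25%/75%). Simulated electrode
activity is a linear readout of context-dependent word representations:

    y_e(t) = Σ_w g_cond(w) · (w_eᵀ x_w) · k(t − onset_w)
           + a_e · env(t) + ε_e(t)

where `x_w` is the word's contextual embedding computed over the stream's
*true* context window (50 tokens attended, 10 unattended), `g_att = 1.0 >
g_unatt = 0.4`, `k` is a 0–500 ms response kernel, `env` the speech
envelope, and ε Gaussian noise.

The analysis chain mirrors standard practice:

* **neural_preprocess** — resample → common average reference → 400 Hz →
  zero-phase 1000th-order FIR notch (60/120/180 Hz) → eight 10-Hz Gaussian
  sub-bands spanning 70–150 Hz → mean analytic-signal magnitude → 100-Hz
  high-gamma envelope.
* **acoustic_features** — 128-channel constant-Q auditory spectrogram
  (hair-cell rectification/low-pass, cube-root compression, lateral
  inhibition), frequency-averaged speech envelope, and per-word 7×250-ms
  lagged-envelope control features.
* **embedding_context** — layer-wise word embeddings from any adapter
  (a synthetic contextual model is bundled; an optional Hugging Face
  adapter is provided) under related, length-truncated, and
  unrelated-context (donor-transcript) regimes; layer 0 is context-free.
* **encoding_model** — per-electrode multi-output ridge regression from
  word features to seven 200-ms lagged word responses, with nested
  leave-one-trial-out cross-validation and a λ sweep over 10⁻²–10⁴;
  held-out Pearson correlations are the **brain scores**.
* **stats_compare** — paired two-sided Wilcoxon signed-rank tests across
  trial-averaged electrodes (exact for n ≤ 25, tie-aware), Bonferroni
  α = 0.05/6, median differences, layer and context-length curves.

## Worked example

```python
from cocktail_ctx.pipeline import StudyConfig, run_recovery_study

result = run_recovery_study(StudyConfig(seed=1))
print(result.summary())
```

prints (abridged):

```
attended vs unattended (layer-averaged): n=100, W=5050, p=3.96e-18*, median diff=+0.3654 (alpha=0.00833)
layer 8 vs layer 0 (attended): n=100, W=5050, p=3.96e-18*, median diff=+0.0230 (alpha=0.00833)
related vs unrelated context (attended): n=100, W=5050, p=3.96e-18*, median diff=+0.0347 (alpha=0.00833)
aligned vs untrained adapter (attended): n=100, W=5050, p=3.96e-18*, median diff=+0.5960 (alpha=0.00833)
full vs 15-token context (attended): n=100, W=5032, p=6.8e-18*, median diff=+0.0039 (alpha=0.00833)

context-length curve (unattended):
context_len     mean      sem   n
          1 0.245769 0.002971 100
          5 0.255681 0.003188 100
         10 0.268282 0.003226 100
         15 0.264101 0.003176 100
         50 0.260522 0.003111 100
       full 0.260502 0.003109 100
```

Reading the output: every electrode's brain score is higher for the
attended stream (median gain +0.37); contextual layers beat the
context-free layer 0; replacing true context with a donor transcript costs
−0.035; the attended stream keeps gaining from 15 tokens of context to the
full transcript while the unattended curve peaks at its true 10-token
window and declines beyond it — the generator's attention gains and context
timescales are recovered by the analysis.

A thin CLI wraps the same functionality:

```bash
cocktail-ctx simulate --out run/ --seed 1          # transcript.tsv, recordings.h5, presses.json
cocktail-ctx preprocess --in run/recordings.h5 --out run/hg.h5
cocktail-ctx recover --out run/report/ --seed 1    # scores.csv, report.json/md
```

## Layout

```
src/cocktail_ctx/
  synthetic_data.py      experiment generator, forward model, behaviour
  neural_preprocess.py   raw signal -> 100-Hz high-gamma envelope
  acoustic_features.py   auditory spectrogram, envelopes, lagged windows
  embedding_context.py   adapters, context regimes, synthetic LM
  encoding_model.py      LOTO ridge brain scores
  stats_compare.py       Wilcoxon machinery, curves
  pipeline.py            end-to-end studies
  cli.py                 command-line front end
  transformer_adapter.py optional Hugging Face adapter (llm extra)
```

See `docs/methods.md` for modeling assumptions, parameter choices and known
limitations.
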