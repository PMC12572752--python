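# speechmark

Interpretable speech-and-language markers for dementia detection: speech-timing
and lexico-semantic feature extraction, a decision-tree-guided sparse MLP
classifier/regressor, and a within-/between-language evaluation harness, driven
by a synthetic-cohort generator so the full pipeline is testable offline.

## What it does

- **`speechmark.io_preprocess`** — WAV loading (mono mixdown, 16 kHz
  resampling, peak normalization), CHAT-markup cleaning, and a TSV/JSON dialect
  for time-aligned transcripts (token, onset, offset, POS, syllables, stop-word
  flag) plus a JSON cohort manifest.
- **`speechmark.vad`** — energy-based voice activity detection: log-energy on
  25 ms windows with a 10 ms hop, DC removal, Gaussian smoothing, a two-means
  threshold, and run-length speech/pause segmentation; plus an autocorrelation
  F0 tracker for the voiced rate (voiced segments per second).
- **`speechmark.timing_features`** — whole-recording ratios (pause duration
  ratio, speech segment duration ratio, pause ratio), six summary statistics
  (mean, SD, skewness, kurtosis, min, max) over pause/speech-segment durations,
  and word-level duration/count features per token category (all, stop,
  content, other, their combination, and a per-syllable expansion).
- **`speechmark.lexsem_features`** — word-class ratios over all and over
  content words; semantic granularity as the minimum hypernym-path length to
  the root concept (WordNet-style graph or a bundled toy graph, BFS); semantic
  variability as the variance of cosine distances between embeddings of
  successive (filtered) words, in three token-sequence variants.
- **`speechmark.tree_sparse_mlp`** — the classifier/regressor: a CART ensemble
  (grid: trees ∈ {10,20,40,60,80,100} × depth ∈ {4,6,8,10}) whose per-tree
  split features define the connectivity mask of a one-hidden-layer sparse MLP
  trained with Adam, ridge regularization, class-weighted cross-entropy (or
  squared error), and early stopping with patience 10. Feature importance =
  per-feature hidden-unit connection counts.
- **`speechmark.evaluation`** — stratified speaker-independent 80/20 splits
  with repeated resampling, z-scoring from train parameters only, early fusion,
  ROC/AUC, paired DeLong tests, Spearman/RMSE regression metrics, and the
  within-language and strictly 0-shot between-language protocols.
- **`speechmark.synthetic_data`** — two-group cohorts with severity-driven
  pause structure, group-dependent POS mixtures, hypernym-depth distributions,
  embedding-distance variance, and MMSE linked to latent severity; a
  second-"language" cohort that preserves the timing effect while scrambling
  the lexico-semantic effects; and a bundled ≤200-node hypernym graph +
  clustered embedding table.

## CLI

```bash
# generate a synthetic cohort (WAVs, transcripts, manifest, ground truth)
speechmark simulate --out cohort/ --seed 1 --n-per-group 25 --with-audio

# voice activity detection for one recording
speechmark vad --wav cohort/en_patient_000.wav --out segments.tsv

# extract the full feature table for a cohort
speechmark extract --manifest cohort/manifest.json --out features.csv

# train a tree-guided sparse MLP
speechmark train --features features.csv --labels cohort/manifest.json \
    --modality timing --out model.json

# run the evaluation protocol
speechmark evaluate --mode within --source cohort/manifest.json \
    --source-features features.csv --modality fusion --bootstrap 20
```

Between-language (0-shot) evaluation takes `--target`/`--target-features`; the
target cohort is used exclusively for scoring, never for fitting or
normalization.

## Notes

- Denoising and cepstral normalization are not applied (inputs are assumed
  clean); the pipeline logs a warning to that effect.
- Absent features (empty token category, out-of-vocabulary words, too few
  distances) are emitted as NaN, never as zeros; the evaluation harness imputes
  them with train-set medians before z-scoring.
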