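# fewt

Adaptive empirical-wavelet feature extraction for multi-channel
time-series classification, with fuzzy band refinement, multivariate
filter feature selection, and an evaluation harness. Everything runs on
synthetic signals; no external data is required.

The processing chain:

1. **ewt** — a data-driven spectrum segmentation places bandpass supports
   between the strongest spectral peaks; Meyer-style cosine/sine
   transitions make the filter bank a tight frame (exact reconstruction).
2. **fcm** — fuzzy c-means clustering (optionally point-weighted).
3. **features** — the wavelet supports are re-partitioned into
   non-overlapping frequency bands by power-weighted fuzzy clustering of
   the spectrum bins; each band is summarized by eight parameters (RMS,
   LZ76 complexity, Shannon entropy, spectral centroid, spectral peak,
   variance, skewness, kurtosis). Six channels x three bands x eight
   parameters = 144 features per half-second window.
4. **selection** — Bhattacharyya/Chernoff distance, scatter-matrix trace
   ratio, and linear-regression (R²) criteria with greedy forward search.
5. **pipeline** — trial windowing, stratified cross-validated RBF-SVC
   accuracy with in-fold grid search, percentage-gain ranking of method
   combinations, Friedman rank test.
6. **synthio** — AM-FM test signals, two-class EEG-like trial generation
   with planted band-power effects, plain-text trial/feature I/O.

## CLI

```bash
# 6-channel, 250 Hz, 10 s two-class trials; 4x band power on channel 2
fewt simulate --trials 10 --effect 2:8-12:4 --seed 1 --out trials/

# decompose a single-channel signal
fewt decompose signal.txt --supports 3 --out components.tsv

# half-second windows -> 144-column feature table
fewt encode --input trials/ --out features.tsv

# rank features and score the ranking
fewt select features.tsv --criterion lr --k 25 --out selection.json
fewt classify features.tsv --selection selection.json --out accuracy.json

# compare method combinations (gains + Friedman test)
fewt rank accuracy_table.tsv --out ranking.json
```

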