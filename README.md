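# dpcawin

Windowed dynamic-PCA feature extraction and nearest-neighbour classification
for long one-dimensional biomedical signals, with EEG seizure
detection / epilepsy diagnosis as the motivating application.

## The problem and the method

Long EEG recordings must be screened for events (seizures, interictal
activity) that differ from background both in *spectral structure* and in
*signal power*. Dynamic PCA — singular spectrum analysis (SSA) in the
time-series literature — treats time-lagged copies of a signal as a
multivariate observation and applies PCA, but the classical trajectory matrix
of all overlapping lags is hugely redundant: its rows are unit shifts of one
another, so they are strongly cross-correlated and the matrix has `N − l + 1`
rows for an `N`-sample signal.

This package instead partitions each signal `y(n)`, `n = 1..N`, into
**non-overlapping** windows of length `l`: window `w` holds samples
`(w−1)l + 1 .. wl`, giving an `m × l` matrix with `m = ⌊N/l⌋` disjoint rows
(a 4096-sample signal at `l = 512` becomes just an 8 × 512 matrix). Training
windows from all `g` classes are stacked, row-shuffled, and PCA is fitted by
eigendecomposition of the `l × l` covariance of the mean-centred rows,
yielding loadings `V = (V₁, …, V_l)` and eigenvalues `λ₁ ≥ … ≥ λ_l`. Any
window `Y(w)` projects to scores `ŷ_v(w) = ⟨Y(w) − μ, V_v⟩`.

Two per-window feature vectors are built from the scores:

- **FFPC** (first few principal components): `(ŷ₁, ŷ₂, ŷ₃)` — captures the
  within-window correlation/spectral structure;
- **PCPEM** (PCs plus energy measure): `(ŷ₁, ŷ₂, E(w))` with the PC-space
  energy `E(w) = Σ_{v=1}^{t} ŷ_v(w)²`, truncated at `t = ⌊l/2⌋` by default —
  adds a power feature, decisive when event windows carry much higher energy
  than background.

Windows are classified by a 1-nearest-neighbour rule (Euclidean distance,
deterministic smallest-index tie-break) and accuracy is estimated by
stratified 10-fold cross-validation, reported as mean ± standard deviation
over folds. Inside each fold the PCA basis is refitted on the training-fold
windows only, so held-out windows never leak into the basis they are
projected onto.

A fully deterministic synthetic generator (AR(2) resonances + spike
transients + white noise) provides labelled multi-class datasets with
controlled spectral peaks and power ratios, so the entire pipeline is
testable without downloading any EEG database.

## Worked example

```python
import dpcawin as d

# five-class short-segment preset: A/B normal-like, C/D interictal-like,
# E a high-power 4 Hz ictal-like rhythm; 20 signals/class, 4096 samples
signals = d.generate_dataset(d.bonn_like(seed=1))

# seizure detection: ictal vs everything else
grouped = d.apply_label_map(
    signals, {"A": "rest", "B": "rest", "C": "rest", "D": "rest",
              "E": "ictal"})

for scheme in (d.PCPEM, d.FFPC):
    rep = d.evaluate_pipeline(grouped, window_length=512, scheme=scheme,
                              k=10, seed=1)
    print(f"{scheme}: {rep.mean_accuracy:.3f} +/- {rep.sd_accuracy:.3f}")
```

prints

```
PCPEM: 1.000 +/- 0.000
FFPC: 0.994 +/- 0.009
```

i.e. over 10 folds of the 800 windows, PCPEM labels every held-out window
correctly — the ictal class's ~25× power excess makes its energy coordinate
decisive — while FFPC, using spectral structure alone, misses a fraction of
a percent. On the `freiburg_like` preset, whose two classes have *matched*
power but distinct spectral peaks, the situation reverses: FFPC reaches
≈ 0.97 while a 1-D energy-only classifier stays at chance (≈ 0.5).

The same pipeline runs from the shell:

```sh
dpcawin simulate --preset bonn_like --seed 1 --out data/
dpcawin features --data-dir data/ --scheme PCPEM -l 512 --out features.csv
dpcawin cv --data-dir data/ --seed 1 --out results/
dpcawin report --results-dir results/
```

`features.csv` (`source_id, window_index, f1..f3, label`) is suitable for
3-D scatter plotting; `cv` writes one JSON report per scheme × window length
plus a summary table. Readers for real data are included: one-sample-per-line
ASCII segment files (`read_bonn_ascii`, 173.61 Hz default) and delimited
multichannel tables (`read_multichannel_csv`, one signal per column).

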