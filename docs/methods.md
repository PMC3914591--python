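# Methods

## Model and procedure

The pipeline classifies windows of long, uniformly sampled 1-D signals.

1. **Embedding.** Each signal of length `N` is partitioned into
   `m = ⌊N/l⌋` disjoint windows of length `l` (trailing `N mod l` samples
   are discarded with a logged warning). The alternative overlapping
   (Hankel/trajectory) embedding with `N − l + 1` unit-shift rows is provided
   for comparison studies only; its rows are strongly cross-correlated,
   which works against the PCA step's assumption of (approximately)
   independent observations. Window and sample indices are documented
   1-based.
2. **Training matrix.** Non-overlapping embeddings of all labelled signals
   are stacked and row-shuffled with a seed, so consecutive windows of one
   signal are not adjacent. Labels and `(source_id, window_index)` origins
   travel with the rows.
3. **PCA.** The `l × l` sample covariance of the mean-centred training rows
   is eigendecomposed (`numpy.linalg.eigh`; the `l × l` route is cheap for
   `l ≤ ~1280` and mirrors the covariance formulation rather than an SVD of
   the data matrix). The stored model is the training column mean, the
   orthonormal loadings in decreasing-eigenvalue order, and the eigenvalues
   clipped at zero. Every projected window is centred with the *training*
   mean; there is no per-window centring and no correlation-matrix
   (variance-scaled) option — all lagged variables share units.
4. **Features.** FFPC keeps the first `n_components` scores (default 3).
   PCPEM concatenates the first `n_pcs` scores (default 2) with the PC-space
   energy `E(w) = Σ_{v≤t} ŷ_v(w)²`, truncation `t = ⌊l/2⌋` by default; both
   schemes therefore default to 3-D feature vectors, the dimension that a
   visual monitoring display can show directly.
5. **Classification.** 1-NN with Euclidean distance; ties go to the smallest
   training-set index (the `argmin` convention), making predictions
   deterministic.
6. **Evaluation.** Stratified k-fold CV (default k = 10) over *windows*,
   shuffled with a seed. Within each fold, PCA is refitted on the
   training-fold windows only and features of both splits are derived from
   that basis — the leakage-free reading of "train on training signals,
   project test signals". Accuracy is the pooled fraction of correctly
   labelled held-out windows; the report carries per-fold accuracies,
   mean ± sd (sample sd, ddof = 1), per-label confusion totals, a full
   config echo, and a secondary per-segment majority-vote accuracy (one
   vote per source signal; not the primary metric, since the method's unit
   of classification is the window).

## Assumptions

Windows of one class are treated as draws from a common finite-dimensional
distribution: the method assumes within-window (local) stationarity, and the
non-overlapping embedding assumes `l` exceeds the first significant
autocorrelation lag so that rows are weakly dependent. Nothing in the math
uses the sampling rate; it is carried as metadata for axis labelling and
preset realism.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `window_length` (l) | 512 | samples | best-performing value on short segments among {64, 128, 256, 512}; grids for long records use {512, 768, 1024, 1280} |
| `n_components` (FFPC) | 3 | — | 3-D feature vector; more dimensions did not help in the motivating study |
| `n_pcs` (PCPEM) | 2 | — | 2 scores + 1 energy = 3-D |
| `truncation` (energy) | ⌊l/2⌋ | PCs | half of `l` is sufficient for a discriminative energy |
| `k` | 10 | folds | standard CV protocol |
| `standardize` | PCPEM on, FFPC off | — | energy is in squared-amplitude units and would otherwise dominate Euclidean distances; z-scoring is fitted on training folds only and recorded in the report |

## Feature standardization (open design point)

PCPEM mixes amplitude-unit scores with a squared-amplitude energy. With raw
units, 1-NN distance is effectively energy-only whenever powers differ by
orders of magnitude. The package's choice: optional per-dimension z-scoring,
default **on** for PCPEM and **off** for FFPC, always echoed in the CV
report so either convention is reproducible.

## Synthetic generator

Each class is `amplitude_scale ×` an AR(2) resonance (pole radius
`r = exp(−π·bandwidth/fs)`, pole angle `2π·f₀/fs`) driven by unit-variance
white noise, plus Poisson-placed raised-cosine spike transients of fixed
50 ms width (amplitude and rate per class), plus additive white noise. AR(2)
is the simplest stationary process with a tunable spectral peak, honouring
the within-window stationarity assumption, and its variance has a closed
form (`ar2_variance`), so class power ratios are designed analytically
rather than measured post hoc. A 2048-sample burn-in is discarded so the
returned stretch is stationary. Per-signal seeds are spawned as
`SeedSequence([master_seed, class_index, replicate_index])` — collision-free
and fully determined by the master seed.

Presets (YAML files shipped with the package):

- **bonn_like** — five classes of 4096-sample segments at 173.61 Hz, 20
  signals/class: two low-power normal-like rhythms (10 and 9 Hz), an
  interictal-like class whose gain is chosen so its power matches the
  normals (separation must come from its spikes/spectrum, not energy), a
  higher-power spiking interictal-like class, and a 4 Hz ictal-like rhythm
  with 5× gain (≈ 25× window power vs baseline).
- **freiburg_like** — two classes of 16384-sample records at 256 Hz, 8
  signals/class, with AR parts normalised to identical RMS (`target_rms`)
  but distinct narrow spectral peaks (12 Hz vs 4 Hz, 0.5 Hz bandwidth):
  energy alone is uninformative, spectral structure is decisive. These
  frequencies and bandwidth were fixed at design time as the cleanest
  embodiment of the matched-power / distinct-spectrum contrast.

What the generator does **not** emulate: 1/f background spectra,
physiological and movement artifacts, nonstationary drift within a class,
inter-subject variability, or real ictal morphology. Passing tests
demonstrate that the pipeline recovers separability the generator encodes —
spectral contrast and power contrast — not that it attains any particular
accuracy on real EEG.

## Numerical choices

- Eigenvector signs are fixed by flipping each loading so its
  largest-magnitude entry (earliest index on ties) is positive; eigensolver
  sign ambiguity would otherwise break bitwise reproducibility. Energies and
  norms are invariant to this convention.
- Near-degenerate eigenvalues: ordering is by value; individual eigenvectors
  are then unstable, but the spanned subspace, reconstructions and energies
  remain well defined (tests compare eigenvectors only where the eigengap
  exceeds 1e-6).
- Eigenvalues are clipped at 0 (round-off can produce ~−1e-16).
- Zero-variance feature dimensions get unit scale during standardization.
- All randomness flows through explicit integer seeds; identical
  config + seed yields byte-identical feature CSVs and CV reports (floats
  are written with shortest round-trip `repr`).

## Problem sizes

The shipped presets are sized so the full test suite and the acceptance
script each run in seconds on one CPU: 100 four-thousand-sample segments
(800 windows at l = 512) for the five-class problem and 16 records
(512 windows) for the two-class problem. These are scaled-down analogues of
the motivating study's datasets (which use 100 segments per class and
hour-long records); the *contrasts* the presets encode, not the dataset
sizes, are what the experiments probe.

## Known limitations

- Single-channel method: multichannel records are split into per-channel
  signals before embedding; no spatial fusion is attempted.
- No resampling, filtering or artifact rejection — signals are consumed as
  recorded.
- 1-NN only (no k > 1, no LDA or learned classifiers) and accuracy only (no
  ROC/AUC): the pipeline's point is the feature extraction, and a
  parameter-free classifier keeps the features' contribution visible.
- Variable-length windows within one matrix are unsupported.
- The overlapping embedding is exposed for study but not wired into the
  evaluation pipeline.
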