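# Methods

## Problem setting

`pocclass` classifies samples from high-dimensional expression data —
microarray gene expression, protein arrays, or any samples × features real
matrix — into K ≥ 2 known subclasses (e.g. tumour subtypes). The regime it
targets is the classic "large N, small M" one: thousands to tens of
thousands of features, tens to a couple of hundred samples, with only a
small subset of features carrying subclass information.

## The classifier

An expression profile is treated like a 1-D digital signal (or, reshaped,
a small image). For two real vectors `fa`, `fb` of length T with DFTs
`Fa`, `Fb`, the cross-phase spectrum keeps only the phase of the
cross-power spectrum:

    R(n) = Fa(n) · conj(Fb(n)) / |Fa(n) · conj(Fb(n))|

and the phase-only correlation (POC) function is the real part of its
inverse DFT, with the 1/T factor on the inverse transform:

    r(m) = (1/T) Σ_n R(n) e^{+2πi n m / T}

Its maximum — the correlation peak — is the similarity score. Because R is
exactly the all-ones spectrum when `fb` is a circular shift of `fa` (at any
positive amplitude), the peak is exactly 1 in that case and decays toward 0
as the signals decorrelate. Discarding amplitude is what makes the score
invariant to global positive rescaling of either profile, so no data
scaling or normalization step exists anywhere in the pipeline.

Classification is nearest-centroid with POC-peak similarity:

1. **Feature selection.** Rank all features by the tie-corrected
   Kruskal–Wallis H statistic across the K subclasses (chi-squared p-value
   with K−1 df) and keep the top m.
2. **Templates.** For each subclass, average its training profiles
   feature-wise into a "virtual sample template" μ_k (the subclass
   centroid).
3. **Matching.** Compute the POC peak between the test profile and every
   template; `peak(k) = max r_k`.
4. **Decision.** Assign the label `argmax_k peak(k)`.

The 2-D variant reshapes the length-p² profile row-major to a p×p matrix
and replaces the 1-D transforms with 2-D ones; empirically the two modes
give nearly identical accuracies (the test suite checks agreement within
0.05 on synthetic benchmarks).

Two k-NN baselines are included: `classify_poc_knn` (k = 5 neighbours by
highest POC peak, majority vote) and `classify_corr_knn` (k = 5 by
correlation distance, d = 1 − Pearson r, which ranges over [0, 2]).

## Evaluation protocol

- **Balanced division.** A split draws exactly Q samples per subclass
  (without replacement) for training; everything else is test. A Q that
  empties the test set is rejected. Example: 83 samples, 4 subclasses,
  Q = 5 → 20 train / 63 test.
- **Repeated accuracy.** The split–select–template–classify pass is
  repeated (default 200 times) with fresh splits; the mean held-out
  accuracy is reported. Feature selection runs on the training split only
  by default (`selection_scope="train_only"`); `"full"` ranks once on the
  whole dataset for reproducing pipelines that select before splitting,
  at a known risk of selection bias.
- **Permutation assessment.** For each of r randomized splits the trained
  model's fixed predictions are scored against l uniform permutations of
  the test-label multiset (training labels untouched), giving an r×l null
  accuracy matrix. The observed reference `a_mean` comes from 200 separate
  unpermuted randomizations. The p-value is +1-smoothed:
  p = (#{Acc_ij ≥ a_mean} + 1) / (r·l + 1), bounded in
  [1/(r·l+1), 1]. Full scale is r = 1000, l = 50 with Q = 8 and m = 182;
  r = 100, l = 10 is the desk-scale reduction. On balanced data the null
  grand mean `b_mean` sits near 1/K; imbalance pulls it toward
  Σ_c (n_c / n)².

## Tunable parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `m` (n_features) | features kept after ranking | 182 (grid 15²…30²) | standard operating point; square values (169, 196, 225, …) required for 2-D mode |
| `Q` (q_per_class) | training samples per subclass | 8 for permutation runs | keeps training balanced on imbalanced data |
| `k` | KNN neighbours | 5 | conventional for expression KNN baselines |
| `eps` | relative spectral floor | 1e-12 | bins with \|cross spectrum\| ≤ eps·max contribute 0 to R instead of 0/0 |
| `n_repeats` | random splits averaged | 200 | standard repeated-randomization protocol |
| `r`, `l` | permutation splits × label shuffles | 1000 × 50 | full-scale null; 100 × 10 desk scale |

## Synthetic data generator

`simulate.generate` emulates the benchmark structure: per-class sample
counts (imbalance allowed), N noisy features at a common baseline
(default 7.0, a typical log-intensity scale), and `n_informative` features
split into K disjoint blocks; class k's block is shifted by
`effect_size × noise_sd` (defaults 2.0 and 1.0) — the analogue of
subtype-specific differentially expressed genes. Noise is Gaussian on a
linear scale by default (POC is amplitude-free, so no log transform is
applied); Student-t (df 3) noise is available to exercise the rank test's
robustness. `PRESETS` mirrors the shapes of seven published benchmarks
(72×12582/3 through 190×16063/14 subclasses); `srbct_like_config` is the
square-width variant (83 samples, 2304 = 48² features, 4 subclasses sized
29/11/18/25) used throughout the tests.

What the generator does *not* emulate: probe-level artifacts, batch
effects, correlated features, heavy class overlap with non-shift
differences. A green synthetic test therefore establishes that the
arithmetic and the pipeline logic are right and that signal of the stated
kind is recovered — not that any particular real-data accuracy is
reproduced. Reported reference behavior on the real SRBCT benchmark (a
known test profile matching its four subtype templates with peaks
0.7213 / 0.2153 / 0.2154 / 0.1889) requires the external dataset and is
documented here rather than asserted in CI.

## Numerical choices

- **Indexing.** Standard 0..T−1 DFT indexing. A symmetric −Q..Q convention
  (T = 2Q+1) merely relabels the correlation entries; the peak value used
  for classification is identical, only the peak location shifts. Even
  lengths are permitted (nothing in the transform algebra requires odd T).
- **Realness.** The real part (not modulus) of the inverse transform is
  taken; for real inputs R is conjugate-symmetric and r is real in exact
  arithmetic. An imaginary residue above 1e-9 (relative) raises instead of
  being silently discarded.
- **Signed peak.** POC values can be negative; the signed maximum is used
  (no clamping to [0, 1] even though well-matched profiles peak near +1).
- **Degenerate spectra.** An all-zero input yields an all-zero phase
  spectrum flagged `degenerate`, not an error; zero-magnitude bins
  contribute 0 to R.
- **Ties.** Template peaks equal within 1e-12 go to the lowest subclass
  index; KNN vote ties fall back to the single nearest neighbour; ranking
  ties (equal p) break by descending H, then ascending feature index.
- **Kruskal–Wallis.** Computed vectorized over all features (mid-ranks per
  column, tie-corrected H, chi-squared approximation regardless of group
  sizes — no exact small-sample enumeration; a documented limitation for
  very small groups). A feature constant across all samples gets H = 0,
  p = 1 and ranks last among equals.
- **Seeds.** Every stochastic operation derives its per-repeat generator
  from `SeedSequence(master_seed, spawn_key=(stream, repeat))`, so any
  single repeat is reproducible in isolation and the repeated-accuracy
  vector is bitwise stable.
- **I/O.** Values are written at 17 significant digits and read back with
  round-trip float parsing, so save→load is bitwise exact. Missing values
  are a hard error: the correlation pipeline has no missing-data mechanism.

## Design choices made where the design was open

- Feature selection defaults to training-split-only (avoids selection
  bias); the alternative whole-dataset scope is exposed as an explicit
  flag rather than guessed as intent.
- The KNN-on-POC variant ranks neighbours directly by maximal peak value
  (the natural reading; no distance transform is interposed).
- Templates are built on the selected features only — selection precedes
  template construction in the pipeline order.
- Row-major reshaping for the 2-D mode; any fixed order is valid, one is
  declared so results are reproducible.

## Known limitations

- POC assumes profiles are comparable as whole signals; it has no
  mechanism for missing values, and heavy noise in templates suppresses
  the peak (accuracy degrades gracefully, but no warning is emitted).
- The chi-squared p-value is approximate for very small subclasses.
- The permutation p-value can never be smaller than 1/(r·l+1); reports of
  "p = 0" from analogous analyses reflect display rounding, and this
  implementation always reports the exact smoothed value.
- `b_mean ≈ 1/K` is a balanced-data diagnostic only; with imbalanced
  classes or single-sample test subclasses it legitimately deviates.
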