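# Methods

## The model

n-SBC (n-Similarity Binary Classifier) is an instance-based, associative
classifier for tabular data. Training stores every preprocessed, Gray-encoded
training row verbatim in a memory matrix `M` with its class label — there is
no optimisation and no learned parameters beyond the stored patterns and the
encoding layout. To classify a query encoded as a `u`-bit string `b`, the
model computes a similarity to every stored pattern

    z_mu = u − H(b, b_mu),

where `H` is the Hamming distance, then aggregates per class the sum of the
`n` largest `z` among that class's patterns, and predicts the class with the
maximal sum. The one-hot indicator marks every maximal class; when the
maximum is tied the scalar prediction takes the lowest class index (a
deterministic, order-independent tie-break — the multi-hot indicator is
exposed so callers can detect ties and, if they wish, abstain).

Two properties motivate the design:

- **Imbalance robustness.** Because each class contributes only its `n` best
  matches, adding further majority-class rows beyond the top-`n` cannot grow
  that class's evidence. Decisions are driven by local match quality, not
  class prevalence. This is tested directly (duplicating majority patterns
  leaves scores unchanged).
- **Explainability.** Every bit belongs to a feature segment, so each
  selected pattern's similarity decomposes exactly into per-feature
  matched-bit counts (`sum over segments = z`). The explanation report lists
  the selected patterns, their agreement vectors against the query, and the
  per-feature counts.

With `n = 1` and a unique best match the rule reduces to 1-nearest-neighbour
in Hamming space. The hyperparameter `n` is meaningful from 1 up to the
smallest class size `K_min`; if a class holds fewer than `n` patterns the
model clamps `n` to the class size and logs a warning rather than failing,
so one global `n` works across CV folds. The shipped presets are `n = 3`
("3-SBC") and `n = 5` ("5-SBC").

## Preprocessing and encoding

All statistics are fitted on training rows only and reapplied to queries:

- **Column typing.** A column whose non-missing cells all parse as decimal
  numbers is numeric; a column with no numeric cell is categorical; a mixed
  column is an error (silent coercion would corrupt the encoding).
- **Imputation.** Missing numerics get the training mean; missing
  categoricals the training mode (ties to the lexicographically smallest
  token). Recognised missing markers: empty cell, `NA`, `?`, `nan`
  (case-insensitive; configurable).
- **Integerization (numeric).** Subtract the training minimum of the imputed
  column, truncate toward −∞ at two decimal places, multiply by 100. The
  pipeline keeps cells as decimal strings and computes in `decimal.Decimal`,
  so 1.24 always maps to 124 — binary floats would occasionally yield 123.
  Truncation (not rounding) is used because it is the behaviour consistent
  with the encoder's reference conversions. Query values below the training
  minimum clip to 0; above the training maximum they clip to the training
  maximum, which keeps every query representable in the fitted bit widths.
- **Categorical codes.** Categories map to 0..c−1 in sorted token order
  (deterministic across runs); an unseen token at query time falls back to
  the imputation value's code. Codes are used directly as the nonnegative
  integers to encode — the two-decimal truncate-and-scale step exists to
  make continuous values integral and would only inflate the bit width of
  values that are already integers.
- **Gray encoding.** Each feature gets a fixed width
  `w_i = max(1, bit_length(train_max_i))`; the value's Gray code
  `v XOR (v >> 1)` is left-padded to `w_i` bits (MSB first) and the
  per-feature codes are concatenated. Gray code is used because consecutive
  integers differ in exactly one bit, so small numeric perturbations stay
  small in Hamming space; a plain-binary switch (`encoding="binary"`) is
  provided as an ablation of exactly this property.

No normalisation, feature selection or resampling is performed — the method
is evaluated on the tables as given.

## Evaluation protocol

Stratified k-fold cross-validation (default `k = 10`, seed 1): indices are
shuffled within each class by a seeded generator and dealt round-robin to
folds, so per-class fold counts differ by at most one. Each fold refits the
preprocessor, the bit widths and the memory on its training split alone;
the suite verifies this by poisoning a test fold with an extreme outlier and
checking the fitted widths do not move.

The headline metric is balanced accuracy: the unweighted mean of per-class
sensitivities `T_i / N_i`, identical to (sensitivity + specificity)/2 on two
classes. A class absent from a test fold (possible under extreme imbalance)
is excluded from that fold's mean with a warning. The imbalance ratio is
reported as majority count / minority count (≥ 1). Reports round to 3
decimal places.

## Classifier comparison

`rank_stats` consumes a datasets × algorithms matrix of balanced accuracies.
Per dataset, algorithms are ranked descending (rank 1 best, ties averaged);
the Friedman chi-square statistic is the classic sum-of-ranks form

    chi2_F = 12N / (k(k+1)) * sum_j (Rbar_j − (k+1)/2)^2,   df = k − 1,

without tie correction (conservative; with average ranks it is exactly 0 on
identical columns). The tie-corrected variant in scipy serves as the
independent cross-check on tie-free inputs in the tests. The Holm step-down
post-hoc compares every algorithm to the control (lowest mean rank) with
`z = (R_0 − R_i)/SE`, `SE = sqrt(k(k+1)/(6N))`, two-sided normal p-values,
and thresholds `alpha/(m − i + 1)` down the p-sorted table; rejection stops
at the first non-significant comparison. A published 20 × 9
balanced-accuracy benchmark matrix ships as example input
(`nsbc.load_benchmark_matrix()`).

## Synthetic data generator

`SynthSpec`/`generate` emulate the data regime the classifier targets —
small clinical screening tables: tens to low thousands of rows, 2–6 classes,
imbalance ratios from 1 to ~31, mixed numeric/categorical features, a few
percent missing cells. Mechanics:

- Class counts follow the requested proportions (or an imbalance ratio, with
  weights interpolating linearly from IR down to 1 across classes) by
  largest-remainder allocation, so the realised IR matches the request up to
  rounding; a class that would receive zero rows is an error.
- Numeric features are Gaussians whose class centers sit `class_sep` noise
  standard deviations apart (default sep 1.0, spread 1.0 — overlapping
  classes, so default tables are *not* trivially separable). Categorical
  features favour one class-specific level with probability
  `level_affinity` (default 0.7) out of `n_levels` (default 3).
- Missing cells are injected uniformly at `missing_rate` (default 0 —
  missingness is opted into per experiment).
- Defaults (300 rows, 4 numeric + 2 categorical features, 2 classes,
  IR 3) describe a typical mid-sized screening table from this regime.

What the generator does **not** emulate: correlated features, non-Gaussian
marginals, informative missingness, label noise, and feature counts in the
dozens. A perfect cross-validated score on a widely separated synthetic
table therefore shows the pipeline is wired correctly (encoding preserves
cluster structure, no leakage), not that the classifier will match these
numbers on real clinical tables.

Randomness: one user-facing seed fans out into named streams (`cv-shuffle`,
`datagen`) via SHA-256, so adding a stochastic component never perturbs the
draws of existing ones, and every artifact is bit-identical under a fixed
seed.

## Numerical and degenerate-case choices

- Exact decimal arithmetic end-to-end in integerization; model files store
  shifts and imputation values as decimal strings, bit patterns as 0/1 text,
  so a saved model round-trips bit-exactly across platforms.
- Top-n selection breaks ties among equal `z` toward the lower pattern
  index (stable sort); the aggregated score is unaffected, the explanation
  is deterministic.
- All-zero columns still get width 1, so a pattern always has ≥ 1 bit per
  feature and segments are never empty.
- `k` larger than the smallest class count warns (folds may miss a class)
  instead of failing; fold metrics then average over represented classes.
- The six-bit teaching fixture injects its published bit strings directly as
  the memory: its raw two-feature values do not reproduce those strings
  under the documented preprocessing (no consistent shift/width does), so
  the encoder is validated against the reference conversion tables instead,
  and the fixture validates everything downstream of encoding.

## Known limitations

- Classification is an exact linear scan over stored patterns,
  O(|L|·u) per query; no sublinear Hamming index is provided.
- Gray code preserves adjacency but is not distance-monotone globally:
  values far apart can share bit patterns in low-order positions. Highly
  non-monotonic feature–class relationships, strongly overlapping classes,
  or many irrelevant features (inflating `u` with noise bits) degrade the
  similarity signal.
- The two-decimal truncation quantises numeric features to a 0.01 grid of
  the training range; features meaningful at finer resolution lose that
  information.
- The Friedman test without tie correction is conservative on matrices with
  many tied scores (e.g. several algorithms at 1.0 on the same dataset).
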