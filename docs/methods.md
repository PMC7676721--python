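# Methods

## The transform

The tunable-Q wavelet transform decomposes a real signal of length *N*
into *J* highpass subbands plus one lowpass residual by iterating a
two-channel filter bank on the lowpass branch. The scaling factors derive
from the quality factor and redundancy as `β = 2/(Q+1)`, `α = 1 − β/r`;
perfect reconstruction requires `0 < α < 1`, `0 < β ≤ 1`, `α + β > 1`,
which bounds the constructor domain to `Q ≥ 1`, `r > 1`. The admissible
depth is `J_max = ⌊log(βN/8)/log(1/α)⌋`; for the default geometry
(N = 768, Q = 1, r = 3) this is 11.

The filter bank is implemented in the DFT domain rather than by
time-domain filtering: the frequency responses are piecewise constants
joined by the Daubechies-type power-complementary transition function
`θ(ω) = ½(1 + cos ω)√(2 − cos ω)`, which satisfies
`θ(ω)² + θ(π−ω)² = 1`. Each stage copies the passband bins of the current
unitary spectrum into a shorter lowpass spectrum (length `2·round(αN/2)`)
and a highpass subband spectrum (length `2·round(βN/2)`), weighting the
shared transition band by `θ` and its complement. Because every input bin
lands in exactly one subband at full weight or is split with squared
weights summing to one, the transform is a tight frame: subband energies
sum to the input energy and reconstruction is exact to rounding error
(observed ≈1e−15, asserted <1e−8 across Q∈1..6, J∈1..8).

Numerical conventions: unitary DFT normalization (so Parseval holds
without extra factors); subband lengths rounded to the nearest even
integer, making decompositions bit-reproducible; odd-length inputs are
zero padded by one sample and trimmed after reconstruction
(`original_length` is recorded); complex input is rejected (EEG is real,
and the band supports are stated for symmetric |ω|). Equivalent per-level
responses use the input-referred frequency axis: each lowpass stage
compresses the axis by α, so the level-*j* response is
`G1(ω/α^{j−1})·∏ G0(ω/α^m)` with support
`[(1−β)α^{j−1}π, α^{j−1}π]`. The default depth is `min(8, J_max)`,
matching the analyzed range J = 1..8.

## Features

Eleven statistics per subband: mean, variance (N−1 denominator),
skewness, non-excess kurtosis (Gaussian → 3; constant input returns 0
and 3 with a guard), energy `Σx²`, power `Σx²/N`, and five entropies.

* **Shannon / Tsallis** use probabilities from an equal-width 16-bin
  histogram over [min, max] (the notion of "probability of unique
  appearances" is degenerate for continuous coefficients, so a binned
  estimate is the defensible reading; bin count configurable). Tsallis
  uses the standard non-extensive form `(1 − Σpᶦ^q)/(q − 1)` with q = 2;
  a variant summing `p^{q−1}` is available behind a flag
  (`tsallis_verbatim`) because that normalization also circulates. Both
  are affine-invariant by construction and the q→1 limit recovers
  Shannon.
* **ApEn / SampEn** use embedding dimension m = 2 and Chebyshev tolerance
  0.2·SD — the literature-standard Pincus/Richman–Moorman setting; both
  are configurable. ApEn includes self-matches,
  `ApEn = Φ(m) − Φ(m+1)`; SampEn excludes them, `−ln(A/B)` over the
  N−m templates. Both orders share one O(N²) distance-matrix pass
  (pointwise |xᵢ−xⱼ| plus shifted maxima), verified against independent
  double-loop counts to 1e−12. An undefined SampEn (zero matches) is
  reported as +inf by the scalar function and replaced by the finite cap
  `ln((N−m)(N−m−1))` during table assembly so tables stay finite.
* **Fuzzy entropy** applies the binary (De Luca–Termini) entropy to
  memberships obtained by min-max normalizing the subband to [0, 1]
  (clipped at 1e−12), scaled by K = 2 — the simplest membership rule
  consistent with the binary-entropy form; it is linear in K.

Features are computed per channel and averaged across the 14 channels per
subband (per-channel columns available via `channel_mode="stack"`);
averaging is the default because the synthetic classes share their gain
profile across channels, and it keeps the table at (J+1)×11 columns.

## Selection

Every (subband, feature) column gets a one-way ANOVA F and p across the
six classes (zero within-group variance with unequal means maps to the
F = +inf, p = 0 sentinel). A feature name is scored by its minimum p over
subbands — one best (feature, subband) pair per feature — and the top six
names are selected. Ties break by larger F, then name, so the ranking is
deterministic. "Probabilistic values" are read as the ANOVA p-values (the
only named test); box plots are exploratory only and play no part in
selection. No multiple-testing correction is applied, matching the
original selection procedure.

## Classifiers

* **PNN**: class score = mean Gaussian kernel `exp(−‖x−xᵢ‖²/2σ²)` over
  the class's training points (equal class priors so unbalanced folds do
  not bias scores), accumulated in the log domain so the σ → 0 limit
  degrades gracefully to 1-NN instead of underflowing; ties go to the
  lowest class index.
* **ELM**: hidden weights/biases uniform[−1, 1] from a seed (MLP kernel;
  sigmoid/tanh/hardlim/gaussian activations, hardlim = step at 0) or
  Gaussian bumps at seeded training-row centers (RBF kernel); output
  weights solve a ridge-regularized least-squares problem onto one-hot
  targets (λ = 1e−6, never fatal even when overparameterized). Pure
  function of (data, hyperparameters, seed).
* **KNN**: four metrics; Minkowski order defaults to p = 3 so it is
  distinct from the separately listed Euclidean; distance ties resolve by
  training index (stable sort), vote ties by lowest class index.
* **DT/RF**: standard Gini CART and bagged forests with √D feature
  subsampling; they are not methodologically novel here and delegate to
  scikit-learn behind the same fit/predict contract.

## Evaluation

Stratified 5-fold cross-validation (stratification keeps all six classes
in every fold; folds are deterministic given the seed). Per configuration
the pooled confusion matrix yields per-class accuracy (recall), mean
accuracy (= total correct / total, identical to the fold-weighted mean),
across-fold accuracy SD, and unweighted macro one-vs-rest sensitivity and
specificity — the macro definition is our choice, since a single
sensitivity/specificity for a 6-class problem is otherwise ill-defined.
Features are z-scored with training-fold statistics before
classification: the σ (≤0.9) and RBF-width (≤0.1) grids presuppose
unit-scale inputs, and raw subband energies are orders of magnitude
larger. Grid search records every cell and keeps, per classifier, the
best mean accuracy (ties to the earlier grid entry, i.e. smaller
hyperparameter and lower subband). The published grids are available via
`published_grids()`; the KNN neighbour counts (1, 3, 5, 7, 9) are our own
choice, as the source grid specifies only the metrics.

**Selection inside CV.** The reported order of operations — select
features on the full table, then cross-validate — leaks label information
into selection, which matters most at the null: with identical class
distributions the leaky order inflates "chance" accuracy to ≈23%.
`run_pipeline` reproduces the select-then-CV order by default and offers
`honest_selection=True`, which refits the ANOVA ranking inside every
training fold; the pipeline acceptance checks run fold-honest in both
arms, because a chance control is only meaningful without leakage. The
residual excess over 16.7% (observed ≈19–21%) is the max-over-grid bias
of reporting the best of 90 correlated σ cells.

## Synthetic data

Each epoch sums band-limited unit-variance Gaussian carriers in alpha
(8–13 Hz), beta (13–30 Hz) and gamma (30–49 Hz) — realized by weighting
rFFT bins, for exact band control and bit-reproducibility — scaled by a
per-class gain vector shared across channels, plus an independent 1/f
pink-noise background (exponent 1.0, amplitude 1.0) per channel. The six
default profiles span a 4× gain ratio; a `separability` scalar
interpolates all profiles toward their mean (0 ⇒ identically distributed
classes ⇒ chance-level classification), and the PD cohort shrinks
inter-class differences by 0.5, emulating reduced emotional
expressivity. Defaults: 40 epochs per class, 14 channels, 128 Hz, 6 s —
epoch counts per subject were never published, so 40/class was chosen
once as a realistic per-cohort size for a six-condition affective EEG
protocol and is the scale at which the pipeline checks run.

What the generator does *not* emulate: artifacts (blinks, EMG),
nonstationarity within epochs, volume-conduction channel correlations,
and any actual neurophysiology of emotion. Passing pipeline tests
therefore demonstrate that the implementation recovers planted
band-power structure and reports chance when none exists — not that the
method would reach any particular accuracy on clinical recordings.

## Known limitations

* No band-limiting pre-filter is applied before the transform; whether
  the original recordings were band-limited first is unstated, and this
  is a possible discrepancy for narrow-band analyses.
* The SampEn cap and the fuzzy-entropy clipping floor are pragmatic
  finite surrogates; distributions of these features near degeneracy are
  implementation-defined.
* ELM with the published hidden-layer sizes (1000–2500) on small
  synthetic cohorts operates far into the interpolation regime; results
  there test the contract, not generalization.
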