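# Methods

This note documents the models, defaults and numerical choices behind
`moplsda`, and what the synthetic-data tests do and do not establish.

## Problem setting

Input is a genes × samples matrix of raw microarray intensities (thousands
of genes, a few dozen samples) with one of three class labels per sample.
The goal is a small gene panel — 50 by default — whose expression pattern
separates the classes, selected so each gene can be attributed to a
specific two-class contrast, with a known direction (up or down in that
contrast's positive class).

## Preprocessing

The classical intensity-data pipeline, in fixed order:

1. **Clip** intensities into `[100, 16000]`.  Values below 100 are
   scanner background; above 16000, saturation.
2. **Variation filter**: keep gene `g` only if, across samples of the
   clipped matrix, `max/min > 5` **and** `max − min > 500` (the strict
   complement of the discard rule `max/min ≤ 5 or max − min ≤ 500`).
   With a train/test split, the filter is learned on training data and the
   resulting gene list applied to the test set, to avoid leakage.
3. **log10 transform.**
4. **Mean-center** each gene.  Centering only — no unit-variance or Pareto
   scaling — because after the log transform gene ranges are already
   comparable, and variance scaling inflates noise genes.  Test data can be
   centered on training-derived means (`reference_means`) when projected
   into a trained model, or on its own means for standalone analysis.

The `ExpressionMatrix` container enforces this order as a state machine
(`raw → clipped → filtered → log10 → centered`); out-of-order calls raise
instead of silently producing nonsense.

## OPLS-DA core

One predictive latent variable plus `n_ortho` Y-orthogonal components,
NIPALS-style (see README for the update equations).  Choices that matter:

- **Sign convention.**  `w` is oriented so the class coded 1 has positive
  mean predictive score.  This makes S-plot signs deterministic: positive
  correlation ⇒ gene elevated in the positive class.
- **Degeneracy.**  `‖Xᵀy‖ < 1e−10·‖X‖·‖y‖` raises a degenerate-model
  error (no class information in X).  Vanishing orthogonal weights or
  scores during deflation raise a rank error rather than emitting noise
  components.
- **R²X** is `(‖t pᵀ‖² + Σ‖t_o p_oᵀ‖²)/‖X‖²` (squared Frobenius norms of
  the reconstructed blocks over the centered training matrix); the
  decomposition `explained + residual = total` is exact because each score
  is orthogonal to its residual by construction.

### Cross-validation and Q²

`Q²Y = 1 − PRESS/SS`.  Each fold refits from scratch with the fold's own
training means (no leakage through centering); PRESS accumulates squared
held-out prediction errors; SS is the total response sum of squares about
the full-data mean.  Default scheme is 7-fold venetian blinds (sample *i*
→ fold *i* mod 7), the chemometrics-software convention — deterministic,
so Q² is reproducible without a seed; contiguous and seeded-random schemes
are available.  Folds whose training part lacks two classes (≥ 2 samples
each) raise a composition error with a suggestion to reduce the fold
count.

**Orthogonal-component count.**  `n_ortho="auto"` starts at 0 and accepts
another component while Q² improves by more than `gain_threshold` (0.01).
This is a stand-in for the proprietary auto-fit rules of commercial
chemometrics software; on the real leukemia data those rules chose 2
orthogonal components for the AML-vs-ALL model, and the gain rule need not
agree exactly.  Fixed counts can always be passed.

**CV-ANOVA.**  `F = ((SS − PRESS)/d1)/(PRESS/d2)` with `d1 = 1 + n_ortho`
(one degree of freedom per extracted component) and `d2 = n − d1 − 1`;
`p` from the upper F tail, with negative F mapped to `p = 1`.  Commercial
implementations use different (undocumented) degrees-of-freedom
bookkeeping, so printed p-values from such software are reproduced only
approximately.

## S-plot selection

`cov(t, X)_g = tᵀX_g/(N−1)`, `corr_g = cov_g/(s_t·s_X,g)`, both with N−1
denominators for internal consistency.  Genes with `s_X < 1e−12` get
`corr = 0` and a flag.  Ranking is by `|corr|` descending; genes whose
`|corr|` lies within `corr_tie_window` (default 0.01, on the correlation
scale) of the current group's leader are reordered among themselves by
`|cov|` descending — correlation is the reliability axis and dominates,
contribution breaks practical ties — with the gene identifier as the final
deterministic tie-break.  The full ranking is a total order, so a top-k1
panel is always a prefix of the top-k2 panel (k1 < k2).

An optional `balanced` mode takes k/2 most-positive and k/2 most-negative
correlations for users who want symmetric up/down panels; plain top-k is
the default and up/down splits are emergent.

## Multi-model arrangements

- **Hierarchical** (one class is an outgroup, the other two are subtypes
  of a super-class): model 1 = outgroup vs merged subtypes on all samples
  (top 40 genes by default); model 2 = subtype vs subtype fit **only** on
  super-class samples, re-centered on that subset (top 10).  This
  preserves the subtype structure in the panel.
- **Parallel** one-versus-rest: one model per class (that class coded 1),
  top 17 genes each.

Panels merge with duplicates removed, keeping the occurrence with higher
`|corr|` and logging the duplicate with both source models.  If
deduplication leaves a hierarchical panel short of `k_total`, it is topped
up from model 1's continued ranking.  The Welch t-test baseline runs the
same contrasts on uncentered log10 data, ranking by ascending p-value; it
uses the unequal-variance form with a `1e−12` guard on the standard error
so constant genes yield finite statistics.

## Evaluation

PCA is computed by SVD of the centered sample × gene matrix; component
signs are fixed by making each component's largest-magnitude loading
positive.  Clustering uses Euclidean or Pearson (`1 − r` between sample
profiles over the panel genes) distance with Ward, average or complete
linkage.  The dendrogram is cut into k = number-of-classes flat clusters
and the cluster → class assignment minimizing misclassification is found
exactly (Hungarian algorithm; identical to brute-force enumeration of
injective mappings for the ≤ 5-class regime this package targets).  This
replaces by-eye dendrogram reading with a reproducible scalar.  With more
clusters than classes each cluster takes its majority class.

## Synthetic data

The generator emulates a late-90s leukemia-style training set: three
classes of 19/8/11 samples, 2000 genes, per-gene baselines
`~N(2.8, 0.5)` in log10 units, within-gene noise sd 0.2, planted markers
shifted by ±0.6 log10 in the affected class (25 up + 25 down per
contrast), 10% near-constant genes (noise/20) for the variation filter to
remove, and raw intensities `10^log` so effects are exactly linear where
the models operate.  Marker sets of distinct contrasts are disjoint.

What it does **not** model: probe-level artifacts, inter-laboratory batch
effects, correlated gene modules, heavy-tailed noise.  A green recovery
test therefore establishes that the pipeline retrieves additive log-scale
class effects of the stated size under independent Gaussian noise — not
performance on real arrays.

Two measured properties of this stated world are worth knowing:

- The variation filter removes substantially more than the planted 10%
  near-constant genes (~35% of all genes at seed 0), because the
  `max − min > 500` predicate also discards ordinary genes whose baseline
  falls below ≈ `10^2.35`.  That is faithful to how the filter behaves on
  dim probes.
- The same mechanism removes ~10% of planted markers before selection ever
  sees them.  Recovery tests therefore score the selector against markers
  *surviving preprocessing* (where it recovers ≥ 99% at the default effect
  size); end-to-end recovery against all planted markers is bounded near
  0.85–0.89 by filter loss, independent of the selector.

## Known limitations

- Two-class contrasts only per model (no multi-column Y / PLS2); more than
  three classes are supported in parallel mode only and are lightly tested.
- Q² values depend on the fold scheme; second-decimal agreement with other
  software should not be expected.
- The auto rule for orthogonal components is a heuristic; inspect Q² as a
  function of `n_ortho` for borderline models.
- No probe annotation, normalization (RMA/quantile), or missing-value
  handling — inputs are assumed complete positive intensity matrices.
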