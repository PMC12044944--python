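# Methods

## Problem and model

`chemstack` classifies small molecules as active or inactive against a
protein target from SMILES alone, in the common regime where the curated
bioactivity extract is imbalanced (roughly five actives per inactive for
the glucocorticoid-receptor-antagonist setting this package was built
around) and the deployment set is structurally novel. The model is a
two-level stacked ensemble built on disjoint balanced under-sampling:

1. **Balanced training subsets (BTS).** The majority class is shuffled
   once and partitioned into K disjoint, near-equal slices
   (K = round(n_maj/n_min), so a 790/159 training set gives K = 5 slices
   of 158); each slice plus the full minority class is one balanced
   subset. Every majority compound is used exactly once, so no
   information is discarded overall, unlike plain random under-sampling.
2. **Base-classifier matrix.** One classifier per (algorithm, descriptor
   family, subset) triple. The default roster is six algorithms (KNN,
   MLP, PLS-DA, random forest, RBF-SVM, gradient-boosted trees) × five
   SMILES fingerprint families × K subsets — 150 base models in the
   default configuration.
3. **Probabilistic feature vector (PFV).** Each compound is re-described
   by the vector of base-model probability scores, ordered
   algorithm-major, then descriptor, then subset; width is always
   A·D·K (150 by default). For a training compound inside a base
   model's own subset the score is that model's out-of-fold
   cross-validation prediction; outside the subset (and for all new
   compounds) it is the fitted model's prediction. Scoring
   out-of-subset training compounds with the fitted model rather than a
   second CV pass is a design choice: it places the out-of-fold
   protection exactly where leakage is possible, at far lower cost.
4. **Two-step feature selection.** PFV columns are ranked by random
   forest mean decrease of Gini impurity (MDGI), averaged over 5 forest
   seeds to damp seed sensitivity; nested top-m subsets
   (m = 10, 20, …, width; 15 candidates at width 150) are each evaluated
   by stratified CV of an RBF-SVM meta-classifier, and the m with the
   highest pooled CV MCC wins, smallest m on ties (cheaper model at
   equal skill).
5. **Meta-classifier.** An RBF-SVM with Platt-scaled probabilities,
   fitted on the winning columns; predicted label = probability ≥ 0.5
   (threshold configurable).

## Descriptor families

Widths are a hard contract (checked on every call): AP2DC 780 (hashed
atom-pair bits), CDKExt 1024 (path-based bits with ring features),
FP4C 307 (SMARTS functional-group match counts; RDKit's fragment
counters occupy the leading columns of the fixed-width block), MACCS 166
(RDKit's 167-bit vector with the permanently unset bit 0 dropped),
Pubchem 881 (pattern-fingerprint bits folded to width). All are
computed with RDKit after standardization (largest organic fragment,
canonical tautomer, canonical SMILES; idempotent). Bit-level parity
with any external fingerprint program is explicitly out of scope: the
contract is dimension, determinism for a pinned RDKit version, and
value kind (binary vs count). Model artifacts record the registry and
refuse to load under a mismatched one.

## Curation rules

Only measurements whose relation is exactly `=` are kept (censored `<`,
`>`, `/` rows are audited drops); IC50 values are converted as
pIC50 = −log10(value·10⁻⁹). Duplicate structures (same canonical key)
are merged by **median** pIC50 — robust to a discordant assay, where the
mean is not. Labels: active at pIC50 ≥ 6 (1 µM), inactive below 5
(10 µM), the band between is "intermediate" and excluded; these cutoffs
follow the common convention for IC50-based QSAR labeling and are
configurable everywhere. Splits are stratified 75/25 by default.

## Evaluation

SN, SP, ACC, MCC and BACC = (SN+SP)/2 from the confusion matrix, plus
rank-based (Mann–Whitney, midrank-tied) AUC. MCC with a vanishing
denominator is reported as 0 and flagged — the standard convention.
Cross-validation metrics are computed on pooled out-of-fold predictions
(one number per model), with the per-fold breakdown retained; pooled
confusions equal summed per-fold confusions by construction. BACC and
MCC are the headline measures because ACC is inflated by the majority
class.

## Chemical-space audit

Per-class physicochemical profiles (MW, AlogP, HBA, HBD, TPSA, nRotB)
are compared by the two-sided Mann–Whitney U test (exact null when the
smaller group has ≤ 8 members and no ties, tie-corrected normal
approximation otherwise). Lipinski and Veber flags use strict
inequalities (MW < 500, AlogP < 5, HBD < 5, HBA < 10; nRotB < 10,
TPSA < 140 Å²), so a molecule at exactly 500 Da fails. Split novelty is
quantified by (a) the fraction of distinct test-set Bemis–Murcko
scaffolds absent from training (ring-free molecules share one sentinel
key) and (b) the full train×test ECFP4 Tanimoto matrix (mean similarity
and fraction of pairs below 0.5). The Tanimoto audit covers train×test
pairs, not within-set pairs.

## Synthetic data generator

Real extracts cannot be shipped or downloaded at test time, so the
generator emulates what the pipeline assumes about them:

- **Imbalance**: defaults 500 actives / 100 inactives (the ≈5:1 training
  ratio of the motivating dataset; absolute size scaled to desk runtime).
- **Substructure-driven activity**: molecules are assembled from a
  fragment grammar (30 drug-like ring scaffolds × 40 decorations);
  actives carry a planted "pharmacophore" marker (thiol, nitrile, or
  aliphatic primary amine) with probability 0.9, inactives at a 0.05
  background rate. Markers are verified to survive tautomer
  standardization.
- **Label noise**: the final label flips with probability 0.05, with the
  pIC50 resampled to match the flipped label (a discordant assay
  read-out, not a clerical swap).
- **Scaffold novelty**: random scaffold choice from the pool gives
  random splits a test-scaffold-novelty fraction around one half,
  comparable to a curated-extract split.

What it does **not** emulate: activity cliffs, assay-specific systematic
error, correlated analog series, ADMET realism, or the true feature
geometry of any particular target's chemistry. Passing tests therefore
demonstrate that the machinery is correct and that the stack extracts
planted signal under imbalance and noise — not that any particular
real-target accuracy will be reached.

A feature-space twin (`generate_feature_dataset` /
`generate_block_dataset`) plants `n_informative` Bernoulli columns whose
firing probability is shifted by `effect_delta` between classes
(base rate 0.2), for pipeline tests that need exact knowledge of which
features matter.

## Numerical choices

- Probability scores are rounded to 12 decimals at the PFV and
  meta-output boundaries; this is far below score resolution and removes
  sub-ulp BLAS ordering jitter, making identical compounds in one batch
  score identically and repeated runs byte-identical.
- Stratified folds everywhere; fold counts are capped at the smaller
  class size, and base/meta fold seeds are derived independently so base
  and selection folds are not shared.
- Hyperparameter tuning (`tune_base_classifier`) uses declared default
  grids (KNN k ∈ {3,5,7,9}; MLP hidden ∈ {16,32,64}; PLS components
  2–8; RF 500 trees, max_features ∈ {√p, p/4}; SVM C ∈ {0.1,1,10},
  γ ∈ {scale, 0.01}; XGB depth ∈ {3,6}, η ∈ {0.1,0.3}, 300 rounds)
  scored by 10-fold CV MCC. The bundled benchmark runs use the fixed
  per-algorithm defaults instead of grid search: the benchmarks measure
  pipeline properties, not tuning gains.
- PLS-DA probabilities are the clipped-to-[0,1] regression predictions
  of a 0/1 response; component count is capped by rank.
- Ties in screening keep input order (stable sort), so rankings are
  reproducible.
- Degenerate inputs: empty minority class, all-constant PFV, single-class
  AUC, zero-width grids and overlapping subset slices all raise typed
  errors rather than returning silently wrong numbers.

## Benchmark problem sizes

The bundled benchmarks (`chemstack.benchmarks`, reported by
`scripts/acceptance.py`) run at desk scale, chosen so the whole suite
completes in minutes on one core: structural constants at the reference
790/159 scale; metric identities on 1000 random confusion tables;
sampling invariants over 200 random size/seed triples; MDGI recovery on
600/120 samples × 150 features with 10 planted columns (10 seeds);
stacked-vs-base comparison with 3 algorithms × 2 feature blocks × 5
subsets on 300/60 training and 150/30 test samples (10 seeds); and the
full SMILES pipeline on a 300/60 synthetic set split 75/25. The
stacked-vs-base margin and the end-to-end numbers are qualitative
mirrors of the full-scale behavior, not reproductions of any particular
dataset's figures.

## Known limitations

- Probability calibration is whatever the SVM's Platt scaling provides;
  no isotonic or beta recalibration, no applicability-domain estimate.
- The disjoint partition cannot produce slices exactly equal to the
  minority size when the majority count is not a multiple of K (790 → 5
  slices of 158, not 159).
- With rounded auto-K and very small classes, slice size can deviate
  from the minority size by more than 1/K in relative terms; the
  floor/ceil slice contract is what is guaranteed.
- MLP base models on small binary blocks can be weak or unstable; the
  stack tolerates weak members by construction, but single-algorithm
  use of `make_estimator("MLP")` on tiny subsets is not recommended.
- Fingerprints are deterministic only for a pinned RDKit version; model
  bundles embed the version stamp for that reason.
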