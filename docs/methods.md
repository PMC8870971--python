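# Methods

## Problem setting

Given an `n × m` real matrix whose rows are samples, columns are attributes,
and where every sample has a class label, impute each missing cell using
patterns local to that cell: attribute-value combinations that co-occur in a
subset of samples sharing the query's class. The working hypothesis is that
a missing value resembles its *local* feature-space neighbourhood — the
attribute subset that actually co-varies with the target attribute in the
query's class — more than it resembles global trends, especially when the
data mixes several classes and several sub-profiles per class.

## Pipeline

1. **Normalization.** Each attribute column is z-scored over its observed
   entries, using the population standard deviation (ddof = 0; a symmetric
   three-point column then maps to ±1.2247). Columns with zero variance map
   to all zeros. Statistics are computed once from the observed data of the
   run and are not re-estimated after imputation, so results are
   deterministic and independent of imputation order.
2. **Discretization.** Each normalized column is cut into `k` equal-width
   bins over its observed range `[norm_min, norm_max]`:
   `level(x) = min(k, ⌊(x − norm_min)/interval⌋ + 1)` with
   `interval = (norm_max − norm_min)/k`. Bins are left-closed/right-open,
   top bin right-closed, so every observed value gets exactly one level in
   `1..k`. A zero-width range yields level 1 everywhere and interval 0.
3. **Itemization.** Class labels take items `1..C` in order of first
   appearance; the cell (attribute `j`, level `v`) takes item
   `C + j·k + v`. Items are therefore *per column*: every item is traceable
   to the attribute it came from, which the estimation step requires.
   Each row becomes a transaction holding one class item plus one item per
   observed cell.
4. **Item masking.** For a query cell (sample `s`, attribute `a`): in every
   other sample, any item (class item included) that differs from the
   query's item in that column is deleted; column `a` is left intact so
   each sample can vote for its own level there. Columns where the query
   itself is missing mask everything. The query row is excluded from the
   masked database; rows emptied by masking are dropped from mining but
   still counted in `|D|`, keeping support comparable across queries.
   Masking is monotone (each masked transaction is a subset of its
   original) and guarantees every surviving itemset is compatible with the
   query; in particular a candidate can contain at most one item of any
   column.
5. **Mining.** Frequent closed itemsets (`|T(P)| ≥ θ`, no strict superset
   with equal occurrences) are enumerated depth-first by prefix-preserving
   closure extension: a closed itemset is extended with an item beyond its
   core index, the closure of the new occurrence set is taken, and the
   branch is kept only when the closure preserves the prefix below the
   extension item — each closed itemset is generated exactly once and
   non-closed itemsets are never materialized. Occurrence sets and
   transactions are integer bitmasks, so closures are word-wise ANDs. A
   powerset-enumeration oracle (`brute_force_closed`, universes ≤ 16 items)
   provides the independent correctness check in the test suite.
6. **Scoring and selection.** Candidates must contain the query's class
   item and one target-attribute item `Y`; with `X` the remaining items,
   support, confidence and lift are computed from occurrence-set sizes in
   the masked database (`|D|` = rows excluding the query). One index is
   chosen per run (default confidence); ties break by support (desc), then
   itemset size (asc), then lexicographic item order, making the winner
   unique and deterministic.
7. **Estimation.** The winner's target item decodes to a level `v` and the
   estimate, in normalized space, is `norm_min + v·interval` — the right
   edge of bin `v`, implemented literally. This carries a systematic
   `+interval/2` offset relative to the bin center; the
   `bin_point="midpoint"` option (`norm_min + (v − ½)·interval`) removes
   it, but `edge` remains the default for fidelity, and the offset is the
   exact bound the recovery test asserts. Estimates are back-transformed
   (`v·sd + mean`) when filling the completed matrix; evaluation stays in
   normalized space.
8. **Fallback.** When no scorable candidate exists (θ too large for the
   class, heavy masking), the class-conditional column mean of observed
   normalized values is used (column mean if the class has none observed,
   0 if the column is empty) and the cell is flagged, so evaluations can
   report fallback rates separately rather than hiding them.
9. **Attribute reduction (ICIimpute).** Per attribute query, the other
   columns are ranked by cosine similarity to the query column, computed on
   the normalized matrix over pairwise-complete rows (undefined
   similarities — fewer than two shared rows, zero norms — rank last);
   the top `⌈α%·(m−1)⌉` columns are retained (`α = 100 − reduction rate`,
   ceiling so α > 0 never retains zero columns; ties by ascending index).
   The reduced matrix (query column + retained columns + class) is
   re-itemized and the attribute's missing cells are imputed as in
   CIimpute. Retained columns keep their original order, so a reduction
   rate of 0 reproduces CIimpute bit for bit.

Multiple missing cells in one sample are imputed independently against the
original observed data — no chained refill, hence no order dependence.

## Evaluation protocol

`inject_mcar` deletes exactly `round(rate%·n·m)` observed data cells
uniformly at random (the class column is never deleted), deterministically
per seed. Truth values are recorded in raw units and in the z-score space
of the *holed* matrix — the statistics the imputer actually sees — and RMSE
(`√(Σ(xᵢ − xᵢ′)²/n)`) is computed in that space over the injected cells
only. Fallback-imputed cells are included in the RMSE and also reported as
a separate rate. `run_experiment` crosses evaluation indices × reduction
rates × missing rates, with `replicates` fresh draws per condition
(replicate seeds derived from a base seed by fixed offsets; generation and
injection use separated seed streams), and reports mean/sd RMSE, fallback
rate, mean mined-itemset count per query, and wall time per condition. The
default grid is reduction rates 0–50% and missing rates 10–50% with 20
replicates; a reduction rate of 0 is labeled CIimpute. The KNN baseline
(distance-weighted mean of the K nearest rows under Euclidean distance on
jointly observed attributes, via scikit-learn's `KNNImputer`) exists for
comparison and harness smoke tests only.

## Synthetic data

The generator emulates small multiclass measurement panels (tens to a few
hundred samples, ~20–50 attributes, 2–7 classes) without reproducing any
particular dataset's feature distributions. Its components, each tied to a
structural feature of real panels:

- **Equicorrelated background**: cell = `√ρ·gᵢ + √(1−ρ)·εᵢⱼ` with a
  per-sample latent factor `gᵢ` (default ρ = 0.3), standard-normal
  marginals. Real panels are globally inter-correlated; a row factor is the
  simplest such structure, and it is what makes specific high-confidence
  rules informative even off the planted patterns.
- **Planted sub-patterns**: each class holds `n_patterns` (default 3)
  distinct level signatures on a block of attributes, carried by disjoint
  sub-groups of its samples (`carrier_fraction`, default 0.8 of the class,
  split evenly). A class is thus a mixture of local patterns, not one
  global profile — the regime local-feature imputation is designed for; a
  single pattern per class would make the class-wide modal level optimal
  by construction and trivialize the comparison between indices.
- **Correlated signatures**: a pattern's levels are a pattern-wide base
  level ± 1 jitter per attribute, so block columns co-vary across
  sub-groups (severity-gradient structure). This is what gives cosine
  similarity a signal to find the relevant columns; with mutually
  independent signatures, attribute reduction would be a random column
  drop.
- **Block coverage**: by default the blocks cover half the panel
  (`block_size = 10` of 20 attributes), so roughly half the columns are
  irrelevant to any given query — the regime where a 50% reduction rate
  can discard mostly noise.
- **Noise**: planted cells are perturbed by `N(0, noise_sd²)` (default
  0.3) on the background's unit scale.

Planted cells are placed at the *centers* of the bins the equal-width
discretization will form. Because z-scoring is affine, bin boundaries
depend only on a column's observed raw range; the grid is computed from the
cells that remain background, and centers lie strictly inside that range,
so at `noise_sd = 0` every planted cell discretizes back to exactly its
planted level. Consequently a fully planted column is rejected (the grid
needs ≥ 2 background cells), and the exact-recovery study uses
whole-class carriers on disjoint per-class blocks
(`shared_attributes=False, n_patterns=1, carrier_fraction=1`): every
candidate's occurrences then lie inside the query's class, all of whose
members share the planted target level, so 100% exact recovery is a
provable property, and the only remaining error is the deliberate
right-edge offset — RMSE equals half an interval.

What passing these tests does *not* show: the generator has Gaussian
margins, a single global correlation factor, axis-aligned patterns and
MCAR holes only. Real data with skewed margins, MAR/MNAR missingness, or
patterns that are not unions of attribute-level equalities may behave
differently; the directional comparisons (confidence vs. support,
reduction vs. none) are statements about this generative regime.

## Numerical and design choices

- Population (ddof = 0) SD; zero-variance columns → z = 0, interval 0,
  level 1.
- `|D|` excludes the query row; since `|D|` is constant within a query,
  ranking by support equals ranking by frequency, and the choice only
  rescales support/lift, not the confidence ranking.
- Winner tie-break chain (index, support, size, lexicographic) makes every
  run reproducible bit for bit; sample order affects provenance labels
  only, not imputed values.
- Imputation and RMSE live in normalized space (the estimator's native
  space); the raw-unit inverse transform fills the output matrix.
- Experiment sizes used by the shipped studies (60×20 matrices, 20
  replicates, 240 fuzzed miner databases) were chosen as the smallest
  scales at which the compared conditions separate cleanly by several
  standard errors.
- θ defaults to 3 and `k` to 7; smaller θ mines more (and more redundant)
  itemsets at higher cost, larger θ increases fallbacks in small classes.
  `k` trades resolution (larger bins → coarser estimates) against itemset
  support (finer bins → sparser matches).

## Limitations

- Closed-itemset mining is combinatorial; per-query masking and attribute
  reduction keep desk-scale problems fast, but cost grows quickly with
  attribute count and with weak masking (many near-duplicate rows).
  Wall-clock comparisons against other imputers are out of scope.
- MCAR only. MAR/MNAR would require using the distribution of the other
  attributes in the winning itemset, not just the target item.
- The right-edge estimator is biased by `+interval/2`; use
  `bin_point="midpoint"` when unbiasedness matters more than fidelity to
  the reference formulation.
- Single-pass imputation: no EM-style iteration, no uncertainty estimates.
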