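# cimpute

Closed-itemset-based missing value imputation for multiclass matrix data.

Many imputation methods (KNN, least-squares, random-forest) estimate a
missing cell from trends over the *entire* feature space, and most assume a
single-class dataset. `cimpute` implements two methods that instead exploit
**local** feature space in labeled data — subsets of attribute values that
co-occur within a subset of samples of one class:

- **CIimpute** — estimates each missing value from frequent *closed
  itemsets* mined per query, restricted to patterns containing the query's
  class label and the target attribute;
- **ICIimpute** — CIimpute plus an *attribute reduction* step that keeps
  only the columns most similar (cosine similarity) to the one holding the
  missing value, shrinking the combinatorial search space and discarding
  noise attributes.

## Model

Rows are samples, columns are attributes, and every sample carries a class
label `CL`. Attribute columns are z-scored, evenly discretized into `k`
levels (default `k = 7`) and itemized: classes get items `1..C`, the cell
(attribute `j`, level `v`) gets item `C + j·k + v`, so each row becomes a
transaction.

For a missing cell, **item masking** deletes, in every other sample, the
items that differ column-wise from the query row (the target column is kept
intact), and frequent closed itemsets — itemsets `P` with occurrence sets
`T(P)` of size ≥ θ such that no strict superset has the same occurrences —
are enumerated by depth-first prefix-preserving closure extension (the LCM
strategy). Candidates containing both the class item and a target-attribute
item are scored as rules X → Y (Y the target item, X the rest):

```
support(X→Y)    = |T(X∪Y)| / |D|
confidence(X→Y) = |T(X∪Y)| / |T(X)|
lift(X→Y)       = confidence(X→Y) / (|T(Y)| / |D|)
```

The winning itemset's target item gives a discretized level `v`, and the
estimate in normalized space is

```
e(M) = norm_min(aM) + v · interval(aM)
```

with `interval = (norm_max − norm_min)/k` for the target column. Defaults:
`θ = 3`, `k = 7`, index = confidence. ICIimpute keeps, per attribute query,
the top α% most similar other columns; the reduction rate is `(100 − α)%`
and a rate of 0 reproduces CIimpute exactly.

The package also ships the full evaluation protocol (MCAR missingness
injection, RMSE in normalized units, replicated condition grids), a
distance-weighted KNN baseline, and a synthetic generator that plants
class-specific sub-patterns in correlated Gaussian background — so the whole
pipeline is testable without external datasets.

## Worked example

```python
from cimpute import (planted_spec, generate, inject_mcar, iciimpute,
                     rmse, zscore_normalize)

spec = planted_spec(noise_sd=0.3)          # 2 classes x 30 samples, 20 attributes
matrix, truth = generate(spec)
holed, cells = inject_mcar(matrix, rate=10, seed=1)

result = iciimpute(holed, theta=3, k=7, index="confidence", reduction_rate=50)

stats = zscore_normalize(holed).col_stats
est = [(result.completed.values[c.row, c.col] - stats[c.col].raw_mean)
       / stats[c.col].raw_sd for c in cells]
print("RMSE:", round(rmse([c.normalized for c in cells], est), 3))

prov = result.provenance[(cells[0].row, cells[0].col)]
print(prov.level, prov.confidence, prov.n_itemsets)
```

This prints `RMSE: 1.098` — the root mean square error, in z-score units,
over the 120 injected cells (10% of a 60×20 matrix) — and for the first
injected cell the estimated discretization level `7`, the winning rule's
confidence `0.8`, and the `170` closed itemsets mined for that query.
Provenance records, per imputed cell, the winning itemset, its three index
scores, the estimated level, and whether the class-conditional-mean fallback
was used.

The same pipeline from a shell:

```
cimpute simulate --seed 1 --out data.csv --truth truth.tsv
cimpute impute --input data.csv --theta 3 --levels 7 --index confidence \
               --reduction-rate 50 --output completed.csv
cimpute evaluate --replicates 20 --seed 1 --output report.tsv
```

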