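"""Candidate scoring, value estimation, and the CIimpute / ICIimpute drivers.

Each candidate closed itemset is read as an association rule X -> Y, where Y
is the item of the attribute holding the missing value and X the remaining
items (always including the class item).  With |D| the size of the masked
database, the three evaluation indices are

    support(X -> Y)    = |T(X u Y)| / |D|
    confidence(X -> Y) = |T(X u Y)| / |T(X)|
    lift(X -> Y)       = confidence(X -> Y) / (|T(Y)| / |D|)

The winning itemset's target item determines a discretized level v, and the
estimate in normalized space is

    e(M) = norm_min + v * interval

with ``interval = (norm_max - norm_min) / k`` of the target column
(``bin_point="midpoint"`` uses ``v - 0.5`` instead of ``v``).  Estimates are
back-transformed to raw units when filling the completed matrix.

CIimpute runs this per missing cell on the full itemized matrix.  ICIimpute
first reduces, per attribute query, the attribute set to the columns most
similar to the query column, re-itemizes the reduced matrix, and then imputes
that attribute's missing cells the same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .errors import ParameterError, UsageError
from .matrix_io import LabeledMatrix
from .mining import (
    ClosedItemset,
    TransactionDB,
    candidate_itemsets,
    mask_items,
    mine_closed_itemsets,
)
from .preprocess import (
    DEFAULT_LEVELS,
    ItemMatrix,
    NormalizedMatrix,
    discretize,
    itemize,
    reduce_attributes,
    zscore_normalize,
)

logger = logging.getLogger(__name__)

DEFAULT_THETA = 3
INDICES = ("support", "confidence", "lift")
IndexName = Literal["support", "confidence", "lift"]
BinPoint = Literal["edge", "midpoint"]


@dataclass(frozen=True)
class ScoredItemset:
    """A candidate closed itemset with its association-rule indices."""

    itemset: ClosedItemset
    y_item: int
    support: float
    confidence: float
    lift: float

    @property
    def x_items(self) -> tuple[int, ...]:
        return tuple(it for it in self.itemset.items if it != self.y_item)

    def score(self, index: str) -> float:
        return getattr(self, index)


@dataclass(frozen=True)
class CellProvenance:
    """How one missing cell was filled."""

    index: str
    itemset: tuple[int, ...] | None
    score: float | None          # None on the fallback path
    support: float | None
    confidence: float | None
    lift: float | None
    level: int | None
    value_normalized: float
    value_raw: float
    fallback: bool
    n_itemsets: int     # closed itemsets mined for this query
    n_candidates: int   # of which passed the class/target filter


@dataclass
class ImputationResult:
    """Completed matrix (raw units) plus per-cell provenance and parameters."""

    completed: LabeledMatrix
    provenance: dict[tuple[int, int], CellProvenance]
    params: dict

    @property
    def fallback_cells(self) -> list[tuple[int, int]]:
        return [cell for cell, p in self.provenance.items() if p.fallback]


def score_itemset(
    c: ClosedItemset,
    target_attr: int,
    db: TransactionDB,
    column_of_item,
) -> ScoredItemset | None:
    """Compute support/confidence/lift for a candidate closed itemset.

    Frequencies are occurrence-set sizes in the masked database; |D| is
    ``db.db_size``.  Returns None (with a warning) when |T(X)| or |T(Y)| is
    zero, which leaves the indices undefined.
    """
    y_items = [it for it in c.items if column_of_item(it) == target_attr]
    if len(y_items) != 1:
        raise UsageError(
            f"candidate itemset must contain exactly one target-attribute "
            f"item, found {len(y_items)}"
        )
    y = y_items[0]
    x = [it for it in c.items if it != y]
    n_xy = c.frequency
    n_x = len(db.occurrences_of(x))
    n_y = len(db.occurrence.get(y, frozenset()))
    if n_x == 0 or n_y == 0 or db.db_size == 0:
        logger.warning("undefined score for itemset %s; discarded", c.items)
        return None
    support = n_xy / db.db_size
    confidence = n_xy / n_x
    lift = confidence / (n_y / db.db_size)
    return ScoredItemset(c, y, support, confidence, lift)


def select_best(cands: list[ScoredItemset], index: IndexName) -> ScoredItemset:
    """Candidate maximizing the chosen index, deterministically.

    Tie-break chain: chosen index desc, support desc, fewer items first,
    lexicographically smallest item tuple.
    """
    if index not in INDICES:
        raise ParameterError(f"index must be one of {INDICES}, got {index!r}")
    if not cands:
        raise UsageError("select_best requires a nonempty candidate list")
    return min(
        cands,
        key=lambda s: (-s.score(index), -s.support, len(s.itemset.items), s.itemset.items),
    )


def estimate_value(level: int, col_stats, bin_point: BinPoint = "edge") -> float:
    """Numeric estimate (normalized space) for a discretized level.

    ``edge`` places the estimate at the right edge of the level's bin,
    ``norm_min + level * interval``; ``midpoint`` uses the bin center.
    """
    point = level - 0.5 if bin_point == "midpoint" else level
    return col_stats.norm_min + point * col_stats.interval


def _class_fallback(
    nm: NormalizedMatrix, sample: int, target_attr: int
) -> float:
    """Class-conditional column mean in normalized space (column mean, then
    0, when the class or column has no observed value)."""
    col = nm.values[:, target_attr]
    same = nm.class_labels == nm.class_labels[sample]
    pool = col[same & ~np.isnan(col)]
    if pool.size == 0:
        pool = col[~np.isnan(col)]
    return float(pool.mean()) if pool.size else 0.0


def impute_cell(
    im: ItemMatrix,
    nm: NormalizedMatrix,
    sample: int,
    target_attr: int,
    *,
    theta: int = DEFAULT_THETA,
    index: IndexName = "confidence",
    bin_point: BinPoint = "edge",
) -> tuple[float, CellProvenance]:
    """Impute one missing cell: mask, mine, filter, score, select, estimate.

    Returns the estimate in normalized space together with its provenance.
    When no scorable candidate exists the class-conditional column mean is
    used and flagged as a fallback.
    """
    k = im.table.k
    cs = nm.col_stats[target_attr]
    interval = (cs.norm_max - cs.norm_min) / k
    db = mask_items(im, sample, target_attr)
    mined = mine_closed_itemsets(db, theta)
    cl_item = im.table.class_item(nm.class_labels[sample])
    cands = candidate_itemsets(mined, cl_item, target_attr, im.column_of_item)
    scored = [
        s
        for c in cands
        if (s := score_itemset(c, target_attr, db, im.column_of_item)) is not None
    ]
    if not scored:
        logger.warning(
            "no candidate itemset for sample %d attribute %d; using fallback",
            sample, target_attr,
        )
        value = _class_fallback(nm, sample, target_attr)
        prov = CellProvenance(
            index, None, None, None, None, None,
            None, value, cs.to_raw(value), True, len(mined), len(cands),
        )
        return value, prov
    best = select_best(scored, index)
    level = im.table.cell_of_item(best.y_item)[1]
    value = estimate_value(level, replace(cs, interval=interval), bin_point)
    prov = CellProvenance(
        index, best.itemset.items, best.score(index), best.support,
        best.confidence, best.lift, level, value, cs.to_raw(value), False,
        len(mined), len(cands),
    )
    return value, prov


def ciimpute(
    matrix: LabeledMatrix,
    *,
    theta: int = DEFAULT_THETA,
    k: int = DEFAULT_LEVELS,
    index: IndexName = "confidence",
    bin_point: BinPoint = "edge",
) -> ImputationResult:
    """Impute every missing cell using class-specific closed itemsets.

    The matrix is preprocessed once (normalize, discretize into ``k`` levels,
    itemize); each missing cell is then imputed independently against the
    original observed data, so the result does not depend on imputation
    order.
    """
    nm = zscore_normalize(matrix)
    dm = discretize(nm, k)
    im = itemize(dm)
    completed = matrix.copy()
    provenance: dict[tuple[int, int], CellProvenance] = {}
    for i, j in zip(*np.where(matrix.missing_mask)):
        _, prov = impute_cell(
            im, nm, int(i), int(j), theta=theta, index=index, bin_point=bin_point
        )
        completed.values[i, j] = prov.value_raw
        provenance[(int(i), int(j))] = prov
    return ImputationResult(
        completed,
        provenance,
        {"method": "CIimpute", "theta": theta, "k": k, "index": index,
         "reduction_rate": 0, "bin_point": bin_point},
    )


def iciimpute(
    matrix: LabeledMatrix,
    *,
    theta: int = DEFAULT_THETA,
    k: int = DEFAULT_LEVELS,
    index: IndexName = "confidence",
    reduction_rate: float = 50.0,
    bin_point: BinPoint = "edge",
) -> ImputationResult:
    """CIimpute with per-attribute-query attribute reduction.

    For each attribute holding at least one missing value, the attribute set
    is reduced to the query column plus the columns most similar to it (top
    ``100 - reduction_rate`` percent by cosine similarity), the reduced
    matrix is re-itemized, and the attribute's missing cells are imputed on
    that reduced transaction database.  ``reduction_rate=0`` keeps every
    attribute and reproduces CIimpute exactly.
    """
    if not 0 <= reduction_rate < 100:
        raise ParameterError(
            f"reduction_rate must be in [0, 100), got {reduction_rate}"
        )
    nm = zscore_normalize(matrix)
    completed = matrix.copy()
    provenance: dict[tuple[int, int], CellProvenance] = {}
    missing = matrix.missing_mask
    for j in range(matrix.n_attributes):
        rows = np.where(missing[:, j])[0]
        if rows.size == 0:
            continue
        cols = reduce_attributes(nm, j, reduction_rate)
        sub_nm = nm.select_attributes(cols)
        sub_im = itemize(discretize(sub_nm, k))
        j_sub = cols.index(j)
        for i in rows:
            _, prov = impute_cell(
                sub_im, sub_nm, int(i), j_sub,
                theta=theta, index=index, bin_point=bin_point,
            )
            completed.values[i, j] = prov.value_raw
            provenance[(int(i), int(j))] = prov
    return ImputationResult(
        completed,
        provenance,
        {"method": "ICIimpute" if reduction_rate else "CIimpute",
         "theta": theta, "k": k, "index": index,
         "reduction_rate": reduction_rate, "bin_point": bin_point},
    )
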