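"""Preprocessing: z-score normalization, equal-width discretization,
itemization, and similarity-based attribute reduction.

The pipeline turns a labeled real-valued matrix into a transaction database:

1. every attribute column is z-scored over its observed entries
   (population standard deviation, missing cells ignored);
2. each normalized column is cut into ``k`` equal-width levels over its
   observed range, so each observed cell gets a level in ``1..k``;
3. levels are mapped to integer *items*: the ``C`` class labels take items
   ``1..C`` in order of first appearance, and the cell (attribute ``j``,
   level ``v``) takes item ``C + j*k + v`` (0-based ``j``), so every item is
   traceable to a single column.

Attribute reduction ranks the other attribute columns by cosine similarity
to the query column (the one holding a missing value) and keeps the top
alpha percent of them; the reduction rate is ``100 - alpha`` percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .matrix_io import LabeledMatrix

DEFAULT_LEVELS = 7  # discretization levels k


@dataclass(frozen=True)
class ColumnStats:
    """Per-column statistics needed to discretize and to invert estimates."""

    raw_mean: float
    raw_sd: float
    norm_min: float
    norm_max: float
    interval: float = 0.0  # (norm_max - norm_min) / k, filled by discretize()

    def to_raw(self, normalized_value: float) -> float:
        return normalized_value * self.raw_sd + self.raw_mean


@dataclass
class NormalizedMatrix:
    """Z-scored matrix plus the per-column statistics of the raw data."""

    values: np.ndarray
    col_stats: list[ColumnStats]
    class_labels: np.ndarray
    attribute_names: list[str]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    def select_attributes(self, cols: list[int]) -> "NormalizedMatrix":
        """Column-subset view used by attribute reduction (copies data)."""
        return NormalizedMatrix(
            self.values[:, cols].copy(),
            [self.col_stats[j] for j in cols],
            self.class_labels,
            [self.attribute_names[j] for j in cols],
        )


@dataclass
class DiscretizedMatrix:
    """Integer level matrix; 0 marks a missing cell, observed cells are 1..k."""

    levels: np.ndarray
    k: int
    col_stats: list[ColumnStats]  # with interval filled in
    class_labels: np.ndarray
    attribute_names: list[str]

    @property
    def n_samples(self) -> int:
        return self.levels.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.levels.shape[1]


class ItemizationTable:
    """Bijection between (class labels, attribute levels) and item ids.

    Classes get items ``1..C`` in order of first appearance; the cell
    (attribute ``j``, level ``v``) gets item ``C + j*k + v``.
    """

    def __init__(self, classes: list, n_attributes: int, k: int) -> None:
        self.classes = list(classes)
        self.n_classes = len(self.classes)
        self.n_attributes = n_attributes
        self.k = k
        self._class_to_item = {c: i + 1 for i, c in enumerate(self.classes)}

    def class_item(self, label) -> int:
        return self._class_to_item[label]

    def class_of_item(self, item: int):
        if not 1 <= item <= self.n_classes:
            raise KeyError(f"item {item} is not a class item")
        return self.classes[item - 1]

    def cell_item(self, attribute: int, level: int) -> int:
        if not 1 <= level <= self.k:
            raise KeyError(f"level {level} outside 1..{self.k}")
        if not 0 <= attribute < self.n_attributes:
            raise KeyError(f"attribute {attribute} out of range")
        return self.n_classes + attribute * self.k + level

    def cell_of_item(self, item: int) -> tuple[int, int]:
        """Inverse of :meth:`cell_item`: item -> (attribute, level)."""
        offset = item - self.n_classes - 1
        if offset < 0 or offset >= self.n_attributes * self.k:
            raise KeyError(f"item {item} is not an attribute item")
        return offset // self.k, offset % self.k + 1

    def column_of_item(self, item: int) -> int | None:
        """Attribute index of an item, or None for a class item."""
        if item <= self.n_classes:
            return None
        return (item - self.n_classes - 1) // self.k

    @property
    def max_item(self) -> int:
        return self.n_classes + self.n_attributes * self.k


@dataclass
class ItemMatrix:
    """Itemized matrix: one transaction (set of items) per sample.

    Each transaction holds exactly one class item plus one item per observed
    attribute cell; missing cells contribute no item.
    """

    transactions: list[frozenset[int]]
    table: ItemizationTable
    class_labels: np.ndarray = field(repr=False)

    @property
    def n_samples(self) -> int:
        return len(self.transactions)

    def column_of_item(self, item: int) -> int | None:
        return self.table.column_of_item(item)


def zscore_normalize(matrix: LabeledMatrix) -> NormalizedMatrix:
    """Z-score each attribute column over its observed entries.

    Uses the population standard deviation (ddof=0).  A column with zero
    variance (or a single observed value) is mapped to all zeros; columns
    with no observed value stay all-missing with degenerate stats.
    """
    values = matrix.values
    out = np.full_like(values, np.nan, dtype=float)
    stats: list[ColumnStats] = []
    for j in range(values.shape[1]):
        col = values[:, j]
        obs = ~np.isnan(col)
        if not obs.any():
            stats.append(ColumnStats(0.0, 1.0, 0.0, 0.0))
            continue
        mean = float(np.mean(col[obs]))
        sd = float(np.std(col[obs]))  # ddof=0
        if sd == 0.0:
            out[obs, j] = 0.0
            stats.append(ColumnStats(mean, 1.0, 0.0, 0.0))
            continue
        z = (col[obs] - mean) / sd
        out[obs, j] = z
        stats.append(ColumnStats(mean, sd, float(z.min()), float(z.max())))
    return NormalizedMatrix(out, stats, matrix.class_labels, list(matrix.attribute_names))


def discretize(nm: NormalizedMatrix, k: int = DEFAULT_LEVELS) -> DiscretizedMatrix:
    """Cut each normalized column into ``k`` equal-width levels.

    Bins are left-closed/right-open on the observed range with the top bin
    right-closed: ``level(x) = min(k, floor((x - norm_min)/interval) + 1)``.
    A zero-width range (constant column) maps every observed cell to level 1.
    """
    if k < 2:
        raise ParameterError(f"number of levels k must be >= 2, got {k}")
    n, m = nm.values.shape
    levels = np.zeros((n, m), dtype=np.int64)
    stats: list[ColumnStats] = []
    for j in range(m):
        cs = nm.col_stats[j]
        interval = (cs.norm_max - cs.norm_min) / k
        stats.append(replace(cs, interval=interval))
        col = nm.values[:, j]
        obs = ~np.isnan(col)
        if not obs.any():
            continue
        if interval == 0.0:
            levels[obs, j] = 1
            continue
        lv = np.floor((col[obs] - cs.norm_min) / interval).astype(np.int64) + 1
        levels[obs, j] = np.minimum(lv, k)
    return DiscretizedMatrix(levels, k, stats, nm.class_labels, list(nm.attribute_names))


def itemize(dm: DiscretizedMatrix) -> ItemMatrix:
    """Map the discretized matrix to per-sample item sets (transactions)."""
    seen: dict = {}
    for label in dm.class_labels:
        seen.setdefault(label, None)
    table = ItemizationTable(list(seen), dm.n_attributes, dm.k)
    transactions = []
    for i in range(dm.n_samples):
        items = {table.class_item(dm.class_labels[i])}
        for j in range(dm.n_attributes):
            v = int(dm.levels[i, j])
            if v:
                items.add(table.cell_item(j, v))
        transactions.append(frozenset(items))
    return ItemMatrix(transactions, table, dm.class_labels)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity over pairwise-complete positions.

    Returns NaN (treated as lowest rank by callers) when fewer than two
    positions are observed in both vectors or either restricted vector has
    zero norm.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ParameterError("vectors must have the same length")
    both = ~np.isnan(u) & ~np.isnan(v)
    if both.sum() < 2:
        return math.nan
    uu, vv = u[both], v[both]
    nu, nv = float(np.linalg.norm(uu)), float(np.linalg.norm(vv))
    if nu == 0.0 or nv == 0.0:
        return math.nan
    return float(np.clip(np.dot(uu, vv) / (nu * nv), -1.0, 1.0))


def reduce_attributes(
    nm: NormalizedMatrix, query_attr: int, reduction_rate: float
) -> list[int]:
    """Select the query attribute plus the most similar other attributes.

    Keeps the top ``alpha% = (100 - reduction_rate)%`` of the non-query
    attribute columns ranked by cosine similarity to the query column
    (ceiling count, so alpha > 0 always keeps at least one).  Ties and
    undefined similarities rank by ascending attribute index, undefined last.
    Returns sorted attribute indices, always containing ``query_attr``.
    """
    if not 0 <= reduction_rate < 100:
        raise ParameterError(
            f"reduction_rate must be in [0, 100), got {reduction_rate}"
        )
    if not 0 <= query_attr < nm.n_attributes:
        raise ParameterError(f"query attribute {query_attr} out of range")
    others = [j for j in range(nm.n_attributes) if j != query_attr]
    if not others:
        return [query_attr]
    alpha = 100.0 - reduction_rate
    n_keep = min(len(others), math.ceil(alpha / 100.0 * len(others)))
    q = nm.values[:, query_attr]
    sims = []
    for j in others:
        s = cosine_similarity(q, nm.values[:, j])
        sims.append((-(s if not math.isnan(s) else -math.inf), j))
    sims.sort()
    kept = [j for _, j in sims[:n_keep]]
    return sorted([query_attr] + kept)
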