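"""Item masking and frequent closed itemset mining.

A closed itemset is an itemset P such that no strict superset has the same
occurrence set T(P); it is the unique maximal representative of its occurrence
set.  P is frequent when |T(P)| >= theta (the minimum support constant).

``mine_closed_itemsets`` enumerates all frequent closed itemsets with a
depth-first prefix-preserving closure extension (the LCM strategy): each
closed itemset is generated exactly once from its parent by extending with an
item beyond the parent's core index and accepting the closure only when the
prefix below the extension item is preserved.  Occurrence sets and
transactions are held as integer bitmasks, so closures are word-wise ANDs.

``brute_force_closed`` is an independent oracle over the powerset, used to
validate the miner on small databases.

Item masking prepares the per-query database: in every other sample, items
that differ column-wise from the sample query are deleted (the target
attribute column is left intact), so every mined itemset is guaranteed
compatible with the query.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Sequence

from .errors import ParameterError, UsageError
from .preprocess import ItemMatrix

BRUTE_FORCE_MAX_ITEMS = 16


@dataclass(frozen=True)
class ClosedItemset:
    """An itemset with its occurrence set (transaction ids) and frequency."""

    items: tuple[int, ...]
    occurrences: frozenset[int]

    @property
    def frequency(self) -> int:
        return len(self.occurrences)

    def key(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        return self.items, tuple(sorted(self.occurrences))


class TransactionDB:
    """A transaction database: item sets indexed by transaction id.

    ``db_size`` is the |D| used by the evaluation indices; it may exceed the
    number of stored transactions when transactions emptied by masking are
    dropped from the store but still counted.
    """

    def __init__(
        self,
        transactions: Sequence[Iterable[int]],
        ids: Sequence[int] | None = None,
        db_size: int | None = None,
    ) -> None:
        self.transactions = [frozenset(t) for t in transactions]
        self.ids = list(ids) if ids is not None else list(range(len(self.transactions)))
        if len(self.ids) != len(self.transactions):
            raise ParameterError("ids and transactions must have equal length")
        self.db_size = db_size if db_size is not None else len(self.transactions)
        universe: set[int] = set()
        for t in self.transactions:
            universe.update(t)
        self.universe: tuple[int, ...] = tuple(sorted(universe))
        occ: dict[int, set[int]] = {it: set() for it in self.universe}
        for tid, t in zip(self.ids, self.transactions):
            for it in t:
                occ[it].add(tid)
        self.occurrence: dict[int, frozenset[int]] = {
            it: frozenset(s) for it, s in occ.items()
        }

    def __len__(self) -> int:
        return len(self.transactions)

    def occurrences_of(self, items: Iterable[int]) -> frozenset[int]:
        """T(P): transactions containing every item of P (all ids if P empty)."""
        occ: frozenset[int] | None = None
        for it in items:
            cur = self.occurrence.get(it, frozenset())
            occ = cur if occ is None else occ & cur
            if not occ:
                return frozenset()
        return frozenset(self.ids) if occ is None else occ


def mask_items(im: ItemMatrix, query_sample: int, target_attr: int) -> TransactionDB:
    """Build the per-query masked database.

    For every column except the target attribute (class column included), an
    item of another sample is kept only when it equals the query's item in
    that column; columns where the query itself is missing therefore mask
    everything.  The target attribute column is left unmasked so each
    surviving sample can vote for its own level there.  The query transaction
    is excluded; transactions emptied by masking are dropped but still
    counted in ``db_size``.
    """
    query = im.transactions[query_sample]
    if any(im.column_of_item(it) == target_attr for it in query):
        raise UsageError(
            f"sample {query_sample} has an observed value at attribute "
            f"{target_attr}; masking requires a missing target cell"
        )
    kept_t: list[frozenset[int]] = []
    kept_ids: list[int] = []
    n_other = 0
    for tid, t in enumerate(im.transactions):
        if tid == query_sample:
            continue
        n_other += 1
        masked = frozenset(
            it for it in t if im.column_of_item(it) == target_attr or it in query
        )
        if masked:
            kept_t.append(masked)
            kept_ids.append(tid)
    return TransactionDB(kept_t, kept_ids, db_size=n_other)


def mine_closed_itemsets(db: TransactionDB, theta: int) -> list[ClosedItemset]:
    """Enumerate every frequent closed itemset of ``db``.

    Depth-first prefix-preserving closure extension; each closed itemset is
    visited exactly once.  The empty itemset is never reported.  Output is
    sorted by item tuple for determinism.
    """
    if theta < 1:
        raise ParameterError(f"theta must be >= 1, got {theta}")
    n_trans = len(db.transactions)
    if n_trans == 0 or n_trans < 0:
        return []
    items = db.universe
    n_items = len(items)
    pos_of = {it: p for p, it in enumerate(items)}
    # transaction -> bitmask over item positions; item -> bitmask over transactions
    trans_bits = [
        sum(1 << pos_of[it] for it in t) for t in db.transactions
    ]
    occ_bits = [0] * n_items
    for ti, tb in enumerate(trans_bits):
        b = tb
        while b:
            low = b & -b
            occ_bits[low.bit_length() - 1] |= 1 << ti
            b ^= low
    full = (1 << n_trans) - 1

    def closure(occ: int) -> int:
        out = (1 << n_items) - 1
        b = occ
        while b:
            low = b & -b
            out &= trans_bits[low.bit_length() - 1]
            b ^= low
        return out

    results: list[tuple[int, int]] = []

    def recurse(itemset_bits: int, occ: int, core_pos: int) -> None:
        if itemset_bits:
            results.append((itemset_bits, occ))
        for pos in range(core_pos + 1, n_items):
            if itemset_bits >> pos & 1:
                continue
            new_occ = occ & occ_bits[pos]
            if new_occ.bit_count() < theta:
                continue
            new_items = closure(new_occ)
            below = (1 << pos) - 1
            if new_items & below == itemset_bits & below:  # prefix preserved
                recurse(new_items, new_occ, pos)

    if full.bit_count() >= theta:
        recurse(closure(full), full, -1)

    out = []
    for itemset_bits, occ in results:
        its = tuple(items[p] for p in range(n_items) if itemset_bits >> p & 1)
        tids = frozenset(
            db.ids[t] for t in range(n_trans) if occ >> t & 1
        )
        out.append(ClosedItemset(its, tids))
    out.sort(key=lambda c: c.items)
    return out


def brute_force_closed(db: TransactionDB, theta: int) -> list[ClosedItemset]:
    """Powerset oracle for ``mine_closed_itemsets`` (small universes only).

    Enumerates every item subset, groups subsets by occurrence set, and keeps
    the unique maximal itemset of each group with frequency >= theta.
    """
    if theta < 1:
        raise ParameterError(f"theta must be >= 1, got {theta}")
    if len(db.universe) > BRUTE_FORCE_MAX_ITEMS:
        raise ParameterError(
            f"brute-force oracle refuses universes larger than "
            f"{BRUTE_FORCE_MAX_ITEMS} items ({len(db.universe)} given)"
        )
    best: dict[frozenset[int], tuple[int, ...]] = {}
    universe = db.universe
    for r in range(1, len(universe) + 1):
        for subset in combinations(universe, r):
            occ = db.occurrences_of(subset)
            if len(occ) < theta:
                continue
            cur = best.get(occ)
            if cur is None or len(subset) > len(cur):
                best[occ] = subset
    out = [ClosedItemset(items, occ) for occ, items in best.items()]
    out.sort(key=lambda c: c.items)
    return out


def candidate_itemsets(
    itemsets: Iterable[ClosedItemset],
    cl_item: int,
    target_attr: int,
    column_of_item: Callable[[int], int | None],
) -> list[ClosedItemset]:
    """Keep itemsets containing the class item and a target-attribute item.

    The class item restricts candidates to patterns occurring in the query's
    class; the target-attribute item is the one that carries the level used
    to estimate the missing value.
    """
    out = []
    for c in itemsets:
        if cl_item not in c.items:
            continue
        if any(column_of_item(it) == target_attr for it in c.items):
            out.append(c)
    return out
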