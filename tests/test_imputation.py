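import numpy as np
import pytest

import cimpute

from cimpute import (
    ClosedItemset,
    LabeledMatrix,
    TransactionDB,
    ciimpute,
    discretize,
    estimate_value,
    iciimpute,
    impute_cell,
    itemize,
    mask_items,
    mine_closed_itemsets,
    planted_spec,
    generate,
    score_itemset,
    select_best,
    zscore_normalize,
)
from cimpute.errors import ParameterError, UsageError
from cimpute.imputation import ScoredItemset
from cimpute.preprocess import ColumnStats


class TestScoreItemset:
    def make_db(self):
        # |D|=10; X={1}, Y=21: |T(XuY)|=4, |T(X)|=5, |T(Y)|=4
        transactions = (
            [{1, 21, 30}] * 4 + [{1, 30}] + [{2, 30}] * 5
        )
        return TransactionDB(transactions)

    def test_direct_substitution(self):
        db = self.make_db()
        c = ClosedItemset((1, 21, 30), db.occurrences_of((1, 21, 30)))
        col_of = lambda it: 0 if it == 21 else (None if it < 20 else 1)
        s = score_itemset(c, 0, db, col_of)
        assert s.support == pytest.approx(0.4)
        assert s.confidence == pytest.approx(0.8)
        assert s.lift == pytest.approx(2.0)
        assert s.y_item == 21 and set(s.x_items) == {1, 30}

    def test_itemset_occurring_everywhere_has_all_ones(self):
        db = TransactionDB([{1, 21}] * 6)
        c = ClosedItemset((1, 21), db.occurrences_of((1, 21)))
        s = score_itemset(c, 0, db, lambda it: 0 if it == 21 else None)
        assert (s.support, s.confidence, s.lift) == (1.0, 1.0, 1.0)

    def test_scores_match_raw_occurrence_recount(self):
        """Independent recount from raw transactions on a random DB."""
        rng = np.random.default_rng(7)
        target_items = {31, 32, 33}
        col_of = lambda it: 1 if it in target_items else None
        transactions = []
        for _ in range(25):
            t = set(int(x) for x in rng.choice(range(1, 9), 3, replace=False))
            if rng.random() < 0.7:
                t.add(int(rng.choice(sorted(target_items))))
            transactions.append(t)
        db = TransactionDB(transactions)
        for c in mine_closed_itemsets(db, 2):
            ys = [it for it in c.items if it in target_items]
            if len(ys) != 1:
                continue
            s = score_itemset(c, 1, db, col_of)
            x = set(c.items) - set(ys)
            n_xy = sum(1 for t in transactions if set(c.items) <= t)
            n_x = sum(1 for t in transactions if x <= t)
            n_y = sum(1 for t in transactions if ys[0] in t)
            assert s.support == pytest.approx(n_xy / 25)
            assert s.confidence == pytest.approx(n_xy / n_x)
            assert s.lift == pytest.approx((n_xy / n_x) / (n_y / 25))
            assert s.support <= s.confidence
            assert s.lift == pytest.approx(s.confidence * 25 / n_y)

    def test_multiple_target_items_rejected(self):
        db = TransactionDB([{1, 21, 22}])
        c = ClosedItemset((1, 21, 22), frozenset({0}))
        with pytest.raises(UsageError):
            score_itemset(c, 0, db, lambda it: 0 if it > 20 else None)


def scored(items, y, sup, conf, lift):
    return ScoredItemset(ClosedItemset(tuple(items), frozenset()), y, sup, conf, lift)


class TestSelectBest:
    def test_single_and_max_by_index(self):
        a = scored([1, 21], 21, 0.2, 0.9, 1.1)
        b = scored([1, 22], 22, 0.5, 0.5, 2.0)
        assert select_best([a], "confidence") is a
        assert select_best([a, b], "confidence") is a
        assert select_best([a, b], "support") is b
        assert select_best([a, b], "lift") is b

    def test_tie_break_chain(self):
        lo_sup = scored([1, 21], 21, 0.2, 1.0, 1.0)
        hi_sup = scored([1, 22], 22, 0.4, 1.0, 1.0)
        assert select_best([lo_sup, hi_sup], "confidence") is hi_sup
        small = scored([1, 21], 21, 0.4, 1.0, 1.0)
        big = scored([1, 5, 22], 22, 0.4, 1.0, 1.0)
        assert select_best([small, big], "confidence") is small
        lex_lo = scored([1, 21], 21, 0.4, 1.0, 1.0)
        lex_hi = scored([1, 22], 22, 0.4, 1.0, 1.0)
        assert select_best([lex_lo, lex_hi], "confidence") is lex_lo

    def test_empty_or_bad_index(self):
        with pytest.raises(UsageError):
            select_best([], "confidence")
        with pytest.raises(ParameterError):
            select_best([scored([1], 1, 1, 1, 1)], "precision")


class TestEstimateValue:
    def test_right_edge_formula(self):
        cs = ColumnStats(0, 1, -2.0, 1.5, 0.5)
        assert estimate_value(3, cs) == pytest.approx(-0.5)

    def test_degenerate_interval_returns_norm_min(self):
        cs = ColumnStats(0, 1, 0.0, 0.0, 0.0)
        assert estimate_value(4, cs) == 0.0

    def test_top_level_hits_norm_max(self):
        cs = ColumnStats(0, 1, -2.1, 1.4, 0.5)
        assert estimate_value(7, cs) == pytest.approx(1.4)

    def test_midpoint_option(self):
        cs = ColumnStats(0, 1, -2.0, 1.5, 0.5)
        assert estimate_value(3, cs, bin_point="midpoint") == pytest.approx(-0.75)


class TestImputeCell:
    def make_fixture(self):
        """Query's class has 3 identical samples observing the target cell."""
        vals = np.array(
            [
                [1.0, 10.0],
                [1.0, 10.0],
                [1.0, 10.0],
                [1.0, np.nan],
                [4.0, 40.0],
                [4.0, 40.0],
                [4.0, 40.0],
            ]
        )
        labels = np.array(["a"] * 4 + ["b"] * 3, dtype=object)
        m = LabeledMatrix(vals, labels)
        nm = zscore_normalize(m)
        return itemize(discretize(nm, 7)), nm, m

    def test_recovers_level_of_identical_classmates(self):
        im, nm, m = self.make_fixture()
        value, prov = impute_cell(im, nm, 3, 1, theta=3)
        assert not prov.fallback
        dm = discretize(nm, 7)
        assert prov.level == dm.levels[0, 1]  # classmates' observed level
        assert prov.confidence == 1.0
        # brute-force oracle confirms the winning candidate is closed
        db = mask_items(im, 3, 1)
        from cimpute import brute_force_closed

        assert prov.itemset in {c.items for c in brute_force_closed(db, 3)}

    def test_theta_above_class_size_falls_back(self):
        im, nm, m = self.make_fixture()
        value, prov = impute_cell(im, nm, 3, 1, theta=4)
        assert prov.fallback
        # class-conditional mean of the three observed classmates
        col = nm.values[:3, 1]
        assert value == pytest.approx(col.mean())

    def test_observed_cell_rejected(self):
        im, nm, m = self.make_fixture()
        with pytest.raises(UsageError):
            impute_cell(im, nm, 0, 1)


class TestCIimpute:
    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(0)
        m = LabeledMatrix(rng.normal(size=(8, 3)), rng.integers(0, 2, 8))
        res = ciimpute(m)
        assert res.provenance == {}
        assert np.array_equal(res.completed.values, m.values)

    def test_noiseless_planted_levels_recovered_exactly(self):
        spec = planted_spec(
            shared_attributes=False, n_patterns=1, carrier_fraction=1.0,
            noise_sd=0.0, seed=11,
        )
        matrix, truth = generate(spec)
        rng = np.random.default_rng(1)
        cells = sorted(truth)
        holes = [cells[i] for i in rng.choice(len(cells), 60, replace=False)]
        holed = matrix.copy()
        for i, j in holes:
            holed.values[i, j] = np.nan
        res = ciimpute(holed, theta=3)
        for cell in holes:
            prov = res.provenance[cell]
            assert not prov.fallback
            assert prov.level == truth[cell]

    def test_sample_permutation_leaves_values_invariant(self):
        spec = planted_spec(samples_per_class=10, n_attributes=8, block_size=4,
                            n_patterns=2, carrier_fraction=0.5, seed=3)
        matrix, _ = generate(spec)
        holed, _ = cimpute.inject_mcar(matrix, 10, seed=5)
        perm = np.random.default_rng(2).permutation(holed.n_samples)
        permuted = LabeledMatrix(
            holed.values[perm], holed.class_labels[perm], holed.attribute_names
        )
        res, res_p = ciimpute(holed), ciimpute(permuted)
        inv = np.argsort(perm)
        assert np.allclose(
            res.completed.values, res_p.completed.values[inv], equal_nan=True
        )

    def test_imputed_values_stay_inside_column_range(self):
        spec = planted_spec(seed=4)
        matrix, _ = generate(spec)
        holed, _ = cimpute.inject_mcar(matrix, 15, seed=6)
        res = ciimpute(holed)
        stats = discretize(zscore_normalize(holed), 7).col_stats
        for (i, j), prov in res.provenance.items():
            if not prov.fallback:
                cs = stats[j]
                assert cs.norm_min < prov.value_normalized <= cs.norm_max + 1e-12
            assert prov.fallback or prov.support <= prov.confidence


class TestICIimpute:
    def test_reduction_zero_identical_to_ciimpute(self):
        spec = planted_spec(samples_per_class=12, n_attributes=10, block_size=5,
                            n_patterns=2, carrier_fraction=0.5, seed=9)
        matrix, _ = generate(spec)
        holed, _ = cimpute.inject_mcar(matrix, 10, seed=9)
        a = ciimpute(holed)
        b = iciimpute(holed, reduction_rate=0)
        assert np.array_equal(a.completed.values, b.completed.values)
        assert a.provenance == b.provenance

    def test_reduction_mines_strictly_fewer_itemsets(self):
        spec = planted_spec(seed=13)
        matrix, _ = generate(spec)
        holed, _ = cimpute.inject_mcar(matrix, 10, seed=13)
        full = ciimpute(holed)
        red = iciimpute(holed, reduction_rate=50)
        n_full = np.mean([p.n_itemsets for p in full.provenance.values()])
        n_red = np.mean([p.n_itemsets for p in red.provenance.values()])
        assert n_red < n_full

    def test_attribute_without_missing_is_not_a_query(self):
        vals = np.array([[1.0, np.nan], [2.0, 3.0], [1.5, 2.5], [1.7, 2.2]])
        m = LabeledMatrix(vals, np.zeros(4))
        res = iciimpute(m, reduction_rate=50, theta=2)
        assert set(res.provenance) == {(0, 1)}

    def test_invalid_rate(self):
        m = LabeledMatrix(np.ones((2, 2)), np.zeros(2))
        with pytest.raises(ParameterError):
            iciimpute(m, reduction_rate=100)
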