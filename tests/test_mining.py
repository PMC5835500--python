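"""Support/confidence semantics, Apriori maximality, grid sweep, dedupe."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycoctx.mining import (
    AssociationRule,
    AssociationRuleMiner,
    MiningConfig,
    ZeroMatchError,
    confidence,
    dedupe_rules,
    frequent_maximal_itemsets,
    support,
    sweep_support_grid,
)

# ---------------------------------------------------------------- oracle --


def oracle_matches(window: str, itemset) -> bool:
    flank = len(window) // 2
    return all(window[flank + p] == s for s, p in itemset)


def oracle_support(itemset, windows) -> float:
    return 100.0 * sum(oracle_matches(w, itemset) for w in windows) / len(windows)


def oracle_mine(items, windows, threshold, maximal_only=True):
    """Exhaustive enumeration of every itemset over small universes."""
    frequent = {}
    for k in range(1, len(items) + 1):
        for comb in combinations(sorted(set(items)), k):
            sup = oracle_support(comb, windows)
            if sup >= threshold - 1e-9:
                frequent[frozenset(comb)] = sup
    if not maximal_only:
        return frequent
    return {
        s: v
        for s, v in frequent.items()
        if not any(s < t for t in frequent)
    }


# toy data from the worked example: 4 windows, flank 2
# (L,2) holds in 4/4, (O,1) in 2/4, the pair in 2/4
TOY_WINDOWS = ["AANOL", "AANOL", "AANPL", "AANPL"]
TOY_ITEMS = [("L", 2), ("O", 1)]


class TestSupport:
    def test_universal_item_is_100(self):
        assert support([("L", 2)], TOY_WINDOWS) == 100.0

    def test_direct_count(self):
        assert support([("O", 1)], ["AANOL", "AANOL", "AANOL", "AANPL"]) == 75.0

    def test_empty_windows_error(self):
        with pytest.raises(ValueError):
            support([("L", 2)], [])

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.data())
    def test_downward_closure(self, data):
        windows = data.draw(
            st.lists(st.text(alphabet="abc", min_size=5, max_size=5), min_size=1, max_size=20)
        )
        items = [(s, p) for s in "abc" for p in (-2, -1, 1, 2)]
        sub = data.draw(st.sets(st.sampled_from(items), min_size=1, max_size=2))
        extra = data.draw(st.sets(st.sampled_from(items), min_size=0, max_size=2))
        assert support(sub, windows) >= support(sub | extra, windows) - 1e-12


class TestConfidence:
    def test_four_pos_one_neg_is_80(self):
        pos, neg = ["AANOL"] * 4, ["AANOL", "AANPC"]
        assert confidence([("O", 1)], pos, neg) == 80.0

    def test_only_in_positives_is_100(self):
        assert confidence([("L", 2)], ["AANOL"] * 3, ["AANPC"] * 3) == 100.0

    def test_balanced_symmetry_is_50(self):
        assert confidence([("L", 2)], ["AANOL"] * 5, ["AANOL"] * 5) == 50.0

    def test_zero_matches_is_explicit_error(self):
        with pytest.raises(ZeroMatchError):
            confidence([("Z", 2)], ["AANOL"], ["AANPC"])


class TestFrequentMaximal:
    def test_pair_shadows_singletons_at_50(self):
        found = frequent_maximal_itemsets(TOY_ITEMS, TOY_WINDOWS, 50)
        assert found == {frozenset(TOY_ITEMS): 50.0}

    def test_singleton_survives_at_75(self):
        found = frequent_maximal_itemsets(TOY_ITEMS, TOY_WINDOWS, 75)
        assert found == {frozenset([("L", 2)]): 100.0}

    def test_threshold_100_with_universal_item(self):
        found = frequent_maximal_itemsets(TOY_ITEMS, TOY_WINDOWS, 100)
        assert found == {frozenset([("L", 2)]): 100.0}

    def test_all_frequent_mode_keeps_subsets(self):
        found = frequent_maximal_itemsets(
            TOY_ITEMS, TOY_WINDOWS, 50, maximal_only=False
        )
        assert set(found) == {
            frozenset([("L", 2)]),
            frozenset([("O", 1)]),
            frozenset(TOY_ITEMS),
        }

    def test_pad_and_unclassified_never_items(self):
        found = frequent_maximal_itemsets(
            [("-", 1), ("X", 2), ("L", 2)], ["AANXL", "AANXL"], 5
        )
        assert set(found) == {frozenset([("L", 2)])}


class TestSweepAndDedupe:
    def test_toy_grid_emissions(self):
        config = MiningConfig(support_grid=(50, 75), class_label="N+")
        result = sweep_support_grid(config, TOY_ITEMS, TOY_WINDOWS, ["AANPC"] * 4)
        assert result.n_unique == 2
        by_items = {r.itemset: r for r in result.rules}
        assert by_items[frozenset(TOY_ITEMS)].thresholds == (50,)
        assert by_items[frozenset([("L", 2)])].thresholds == (75,)

    def test_threshold_cascade_shape(self):
        """A triple frequent only at low support; its pair persists higher;
        the singleton alone at the top — mirroring the observed cascade of
        3-mers at 5%, 2-mers at intermediate, singletons at high support."""
        # 20 windows, flank 2: (L,2) in 19, (O,1)&(L,2) in 8, +(P,-1) in 2
        windows = (
            ["APNOL"] * 2 + ["AANOL"] * 6 + ["AANCL"] * 11 + ["AANCC"]
        )
        items = [("L", 2), ("O", 1), ("P", -1)]
        config = MiningConfig(support_grid=(10, 25, 50, 90))
        result = sweep_support_grid(config, items, windows, ["AANAA"] * 20)
        by_items = {r.itemset: r for r in result.rules}
        assert by_items[frozenset(items)].thresholds == (10,)
        assert by_items[frozenset([("O", 1), ("L", 2)])].thresholds == (25,)
        assert by_items[frozenset([("L", 2)])].thresholds == (50, 90)

    def test_empty_eligible_items_give_empty_rules(self):
        config = MiningConfig(support_grid=(5,))
        result = sweep_support_grid(config, [], TOY_WINDOWS, ["AANPC"])
        assert result.rules == [] and result.n_emitted == 0

    def test_dedupe_merges_thresholds_and_is_idempotent(self):
        r1 = AssociationRule((("L", 2),), "N+", 95.0, 76.0, (5,))
        r2 = AssociationRule((("L", 2),), "N+", 95.0, 76.0, (10,))
        r3 = AssociationRule((("O", 1),), "N+", 30.0, 60.0, (5,))
        once = dedupe_rules([r1, r2, r3])
        assert len(once) == 2
        merged = next(r for r in once if r.itemset == frozenset([("L", 2)]))
        assert merged.thresholds == (5, 10)
        assert dedupe_rules(once) == once

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            MiningConfig(support_grid=(0, 50))
        with pytest.raises(ValueError):
            MiningConfig(support_grid=(5, 101))


class TestOracleEquivalence:
    def test_matches_exhaustive_enumeration_on_random_instances(self):
        """Miner output (itemsets, supports, maximality) equals brute force
        on random small instances; spot-checks confidences too."""
        rng = np.random.default_rng(7)
        symbols = list("abcdef")
        for trial in range(40):
            flank = int(rng.integers(1, 4))
            width = 2 * flank + 1
            n = int(rng.integers(4, 51))
            windows = [
                "".join(rng.choice(symbols, width)) for _ in range(n)
            ]
            neg = ["".join(rng.choice(symbols, width)) for _ in range(n)]
            universe = [
                (s, p)
                for s in symbols[: int(rng.integers(2, 7))]
                for p in range(-flank, flank + 1)
                if p != 0
            ]
            k = min(len(universe), int(rng.integers(2, 9)))
            idx = rng.choice(len(universe), size=k, replace=False)
            items = [universe[i] for i in idx]
            threshold = float(rng.choice([5, 10, 25, 50, 75]))
            mined = frequent_maximal_itemsets(items, windows, threshold)
            expected = oracle_mine(items, windows, threshold)
            assert mined == expected, f"trial {trial}"
            for itemset in mined:
                try:
                    conf = confidence(itemset, windows, neg)
                except ZeroMatchError:
                    continue
                m_pos = sum(oracle_matches(w, itemset) for w in windows)
                m_neg = sum(oracle_matches(w, itemset) for w in neg)
                assert conf == pytest.approx(100 * m_pos / (m_pos + m_neg))

    def test_maximality_invariant_within_threshold(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            windows = ["".join(rng.choice(list("ab"), 5)) for _ in range(30)]
            items = [(s, p) for s in "ab" for p in (-2, -1, 1, 2)]
            found = frequent_maximal_itemsets(items, windows, 20)
            sets = list(found)
            assert not any(a < b for a in sets for b in sets)


class TestMinerEstimator:
    def test_fit_exposes_rules_and_counts(self):
        X = TOY_WINDOWS + ["AANPC"] * 4
        y = ["pos"] * 4 + ["neg"] * 4
        miner = AssociationRuleMiner(
            support_grid=(50, 75),
            consequent="pos",
            eligible_items=TOY_ITEMS,
        ).fit(X, y)
        assert miner.n_unique_ == 2
        assert miner.n_emitted_ == 2
        assert {r.notation() for r in miner.rules_} == {"<O,1><L,2>", "<L,2>"}

    def test_predict_flags_windows_matching_any_rule(self):
        X = TOY_WINDOWS + ["AANPC"] * 4
        y = ["pos"] * 4 + ["neg"] * 4
        miner = AssociationRuleMiner(
            support_grid=(50,), consequent="pos", eligible_items=TOY_ITEMS
        ).fit(X, y)
        flags = miner.predict(["AANOL", "AANPC", "CCNOL"])
        assert flags.tolist() == [True, False, True]

    def test_preference_gating_by_default(self):
        rng = np.random.default_rng(3)
        pos = []
        for _ in range(200):
            chars = rng.choice(list("GAVC"), 5)
            chars[2] = "N"
            if rng.random() < 0.9:
                chars[4] = "C"  # enrich C at +2
            pos.append("".join(chars))
        neg = ["".join(rng.choice(list("GAVC"), 5)) for _ in range(200)]
        neg = [w[:2] + "N" + w[3:] for w in neg]
        miner = AssociationRuleMiner(consequent="p").fit(
            pos + neg, ["p"] * 200 + ["n"] * 200
        )
        assert ("C", 2) in miner.eligible_items_
        assert any(r.itemset == frozenset([("C", 2)]) for r in miner.rules_)

    def test_rule_notation_sorted_by_position(self):
        rule = AssociationRule((("L", 2), ("O", 1)), "N+", 30.0, 80.0, (5,))
        assert rule.notation() == "<O,1><L,2>"
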