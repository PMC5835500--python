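"""Association-pattern mining over preferred (symbol, position) items.

A pattern is a set of items ``<S,p>`` — "symbol S at signed offset p from
the target Asn".  Definitions used throughout:

support
    ``100 * (#consequent-class windows containing every item) /
    (#consequent-class windows)``.

confidence
    Among all windows of the balanced two-class set containing the pattern,
    the percentage belonging to the consequent class — ``P(class | pattern)``.

At each threshold of a support grid (default 5..95 step 5) the miner emits
the frequent itemsets, by default filtered to *maximal* ones (no frequent
proper superset at that threshold).  This reproduces the characteristic
cascade in which large patterns surface at low support levels and their
sub-patterns take over as the threshold rises.  Patterns repeated across
thresholds are deduplicated with their threshold sets unioned; both the
total emission count and the unique count are reported.

The levelwise search is a classic Apriori: item universes here are small
(only significantly preferred pairs are eligible) so candidate generation
with subset pruning over boolean match columns is exact and fast.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dataset import PAD_SYMBOL
from .encoding import UNCLASSIFIED_SYMBOL
from .preference import Item, PreferenceSelector, as_symbol_strings, _char_matrix

#: symbols that can never be items: pads and the unclassified class
NON_ITEM_SYMBOLS = frozenset({PAD_SYMBOL, UNCLASSIFIED_SYMBOL})

_EPS = 1e-9  # guards float support-threshold comparisons


class ZeroMatchError(ValueError):
    """Confidence is undefined: no window in either class matches."""


def _item_key(item: Item) -> tuple[int, str]:
    return (item[1], item[0])


def item_match_columns(
    windows: Sequence[str], items: Sequence[Item]
) -> dict[Item, np.ndarray]:
    """Boolean match vector per item over the given windows."""
    mat = _char_matrix(list(windows))
    flank = mat.shape[1] // 2
    cols: dict[Item, np.ndarray] = {}
    for symbol, position in items:
        if abs(position) > flank:
            cols[(symbol, position)] = np.zeros(len(windows), dtype=bool)
        else:
            cols[(symbol, position)] = mat[:, flank + position] == symbol
    return cols


def pattern_mask(windows: Sequence[str], items: Iterable[Item]) -> np.ndarray:
    """True where a window contains every item at its offset."""
    items = list(items)
    if not items:
        raise ValueError("pattern must contain at least one item")
    cols = item_match_columns(windows, items)
    mask = np.ones(len(windows), dtype=bool)
    for it in items:
        mask &= cols[it]
    return mask


def support(items: Iterable[Item], class_windows: Iterable) -> float:
    """Percentage of consequent-class windows containing the pattern."""
    strings = as_symbol_strings(class_windows)
    if not strings:
        raise ValueError("support is undefined over zero windows")
    return 100.0 * pattern_mask(strings, items).sum() / len(strings)


def confidence(
    items: Iterable[Item], consequent_windows: Iterable, other_windows: Iterable
) -> float:
    """P(consequent class | pattern) * 100 on the balanced two-class set."""
    items = list(items)
    pos = as_symbol_strings(consequent_windows)
    neg = as_symbol_strings(other_windows)
    m_pos = int(pattern_mask(pos, items).sum()) if pos else 0
    m_neg = int(pattern_mask(neg, items).sum()) if neg else 0
    if m_pos + m_neg == 0:
        raise ZeroMatchError(f"pattern {sorted(items, key=_item_key)} matches no window")
    return 100.0 * m_pos / (m_pos + m_neg)


def frequent_maximal_itemsets(
    eligible_items: Sequence[Item],
    class_windows: Iterable,
    min_support_pct: float,
    maximal_only: bool = True,
) -> dict[frozenset, float]:
    """All itemsets with support >= threshold, optionally maximal ones only.

    Returns ``{itemset: support_pct}``.  With ``maximal_only`` an itemset is
    kept iff none of its frequent proper supersets exists; by downward
    closure it suffices to check the next level up.
    """
    strings = as_symbol_strings(class_windows)
    if not strings:
        raise ValueError("cannot mine zero windows")
    n = len(strings)
    min_count = min_support_pct * n / 100.0 - _EPS

    universe = sorted(set(eligible_items), key=_item_key)
    universe = [it for it in universe if it[0] not in NON_ITEM_SYMBOLS]
    cols = item_match_columns(strings, universe)

    # level 1
    level: dict[frozenset, np.ndarray] = {}
    for it in universe:
        if cols[it].sum() >= min_count:
            level[frozenset([it])] = cols[it]
    frequent: dict[frozenset, float] = {}
    maximal: dict[frozenset, float] = {}

    while level:
        next_level: dict[frozenset, np.ndarray] = {}
        for itemset, mask in level.items():
            for it in universe:
                if it in itemset or _item_key(it) <= max(_item_key(i) for i in itemset):
                    continue
                cand = itemset | {it}
                if cand in next_level:
                    continue
                # subset pruning, then exact count
                if any(cand - {i} not in level for i in cand):
                    continue
                cand_mask = mask & cols[it]
                if cand_mask.sum() >= min_count:
                    next_level[cand] = cand_mask
        for itemset, mask in level.items():
            sup = 100.0 * int(mask.sum()) / n
            frequent[itemset] = sup
            if not any(itemset < sup_set for sup_set in next_level):
                maximal[itemset] = sup
        level = next_level

    return maximal if maximal_only else frequent


@dataclass(frozen=True)
class AssociationRule:
    """A mined pattern with its support, confidence and emission thresholds."""

    items: tuple[Item, ...]
    consequent: str
    support_pct: float
    confidence_pct: float
    thresholds: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "items", tuple(sorted(self.items, key=_item_key))
        )
        object.__setattr__(self, "thresholds", tuple(sorted(self.thresholds)))

    @property
    def itemset(self) -> frozenset:
        return frozenset(self.items)

    def notation(self) -> str:
        """Angle-bracket rendering, e.g. ``<O,1><L,2>``."""
        return "".join(f"<{s},{p}>" for s, p in self.items)

    def to_dict(self) -> dict:
        return {
            "items": [[s, p] for s, p in self.items],
            "consequent": self.consequent,
            "support_pct": round(self.support_pct, 4),
            "confidence_pct": round(self.confidence_pct, 4),
            "thresholds": list(self.thresholds),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AssociationRule":
        return cls(
            items=tuple((s, int(p)) for s, p in d["items"]),
            consequent=d["consequent"],
            support_pct=float(d["support_pct"]),
            confidence_pct=float(d["confidence_pct"]),
            thresholds=tuple(d.get("thresholds", ())),
        )


@dataclass
class MiningConfig:
    """Support grid and emission options for one class's mining run."""

    support_grid: tuple[float, ...] = tuple(range(5, 100, 5))
    maximal_only: bool = True
    class_label: str = "N+"

    def __post_init__(self) -> None:
        grid = tuple(sorted(self.support_grid))
        if not grid or any(not 0 < g <= 100 for g in grid):
            raise ValueError("support grid values must lie in (0, 100]")
        self.support_grid = grid


@dataclass
class MiningResult:
    rules: list[AssociationRule]
    n_emitted: int  # emissions summed over the grid, repetitions included
    n_unique: int

    @property
    def support_range(self) -> tuple[float, float] | None:
        """Lowest and highest grid thresholds at which anything was emitted."""
        levels = sorted({t for r in self.rules for t in r.thresholds})
        return (levels[0], levels[-1]) if levels else None


def sweep_support_grid(
    config: MiningConfig,
    eligible_items: Sequence[Item],
    pos_windows: Iterable,
    neg_windows: Iterable,
) -> MiningResult:
    """Mine at every grid threshold, annotate confidences, deduplicate."""
    pos = as_symbol_strings(pos_windows)
    neg = as_symbol_strings(neg_windows)
    emitted: list[AssociationRule] = []
    for threshold in config.support_grid:
        found = frequent_maximal_itemsets(
            eligible_items, pos, threshold, maximal_only=config.maximal_only
        )
        for itemset, sup in found.items():
            emitted.append(
                AssociationRule(
                    items=tuple(itemset),
                    consequent=config.class_label,
                    support_pct=sup,
                    confidence_pct=confidence(itemset, pos, neg),
                    thresholds=(threshold,),
                )
            )
    rules = dedupe_rules(emitted)
    return MiningResult(rules=rules, n_emitted=len(emitted), n_unique=len(rules))


def dedupe_rules(rules: Iterable[AssociationRule]) -> list[AssociationRule]:
    """Merge rules with identical itemsets, unioning their thresholds.

    Idempotent; output is ordered by support descending, then by the
    itemset's angle-bracket notation, for deterministic files.
    """
    merged: dict[tuple, AssociationRule] = {}
    for rule in rules:
        key = (rule.items, rule.consequent)
        prev = merged.get(key)
        if prev is None:
            merged[key] = rule
        else:
            merged[key] = AssociationRule(
                items=rule.items,
                consequent=rule.consequent,
                support_pct=prev.support_pct,
                confidence_pct=prev.confidence_pct,
                thresholds=tuple(set(prev.thresholds) | set(rule.thresholds)),
            )
    return sorted(
        merged.values(), key=lambda r: (-r.support_pct, r.notation())
    )


def write_rules_json(rules: Sequence[AssociationRule], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([r.to_dict() for r in rules], indent=2) + "\n"
    )


def read_rules_json(path: str | Path) -> list[AssociationRule]:
    return [AssociationRule.from_dict(d) for d in json.loads(Path(path).read_text())]


def rules_to_table(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    """Publication-style table: pattern, confidence %, support levels."""
    return pd.DataFrame(
        {
            "pattern": [r.notation() for r in rules],
            "confidence_pct": [round(r.confidence_pct, 2) for r in rules],
            "support_levels": [
                ", ".join(f"{t:g}" for t in r.thresholds) for r in rules
            ],
            "support_pct": [round(r.support_pct, 2) for r in rules],
        }
    )


class AssociationRuleMiner(BaseEstimator):
    """Preference-gated maximal pattern miner with a scikit-learn surface.

    ``fit(X, y)`` takes window strings ``X`` and class labels ``y``; windows
    whose label equals ``consequent`` form the class being characterized,
    the rest are the contrast class (pass a balanced set for confidences
    that read as P(class | pattern) under a 50% prior).  Unless
    ``eligible_items`` is given, items are restricted to the significantly
    preferred (symbol, position) pairs of the consequent class at ``alpha``.

    Fitted attributes: ``rules_``, ``n_emitted_``, ``n_unique_``,
    ``eligible_items_``, ``preference_`` (None when items were supplied).
    """

    def __init__(
        self,
        support_grid: tuple[float, ...] = tuple(range(5, 100, 5)),
        maximal_only: bool = True,
        consequent: object = "positive",
        class_label: str = "N+",
        alpha: float = 0.05,
        correction: str = "none",
        eligible_items: Sequence[Item] | None = None,
    ):
        self.support_grid = support_grid
        self.maximal_only = maximal_only
        self.consequent = consequent
        self.class_label = class_label
        self.alpha = alpha
        self.correction = correction
        self.eligible_items = eligible_items

    def fit(self, X: Sequence, y: Sequence) -> "AssociationRuleMiner":
        strings = as_symbol_strings(X)
        y = np.asarray(list(y), dtype=object)
        if len(strings) != len(y):
            raise ValueError("X and y length mismatch")
        pos = [w for w, lab in zip(strings, y) if lab == self.consequent]
        neg = [w for w, lab in zip(strings, y) if lab != self.consequent]
        if not pos:
            raise ValueError(f"no windows labelled {self.consequent!r}")

        if self.eligible_items is not None:
            items = list(self.eligible_items)
            self.preference_ = None
        else:
            selector = PreferenceSelector(
                alpha=self.alpha,
                correction=self.correction,
                class_label=self.class_label,
            ).fit(pos)
            self.preference_ = selector.preference_
            items = selector.items_
        self.eligible_items_ = [
            it for it in items if it[0] not in NON_ITEM_SYMBOLS
        ]

        config = MiningConfig(
            support_grid=tuple(self.support_grid),
            maximal_only=self.maximal_only,
            class_label=self.class_label,
        )
        result = sweep_support_grid(config, self.eligible_items_, pos, neg)
        self.result_ = result
        self.rules_ = result.rules
        self.n_emitted_ = result.n_emitted
        self.n_unique_ = result.n_unique
        return self

    def predict(self, X: Sequence) -> np.ndarray:
        """True where a window contains at least one mined pattern."""
        strings = as_symbol_strings(X)
        mask = np.zeros(len(strings), dtype=bool)
        for rule in self.rules_:
            mask |= pattern_mask(strings, rule.items)
        return mask
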