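"""Position-specific preference estimation.

For one class of windows (N+ or N-), each (symbol, signed offset) pair is
tested for enrichment over the class's own pooled composition with a
one-sided exact binomial test.  Significantly enriched pairs are the
*preferred items* that the association-rule miner is allowed to use.

Pads (``-``) and the centre position 0 (always Asn by construction) are
excluded from both observed and background counts.  The background is the
pooled symbol frequency of the same windows over all non-centre, non-pad
positions — self-contained, with no external proteome composition needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .dataset import PAD_SYMBOL, PeptideWindow
from .encoding import EncodedWindow

Item = tuple[str, int]


def as_symbol_strings(windows: Iterable) -> list[str]:
    """Normalize PeptideWindow / EncodedWindow / str inputs to strings."""
    out = []
    for w in windows:
        if isinstance(w, (PeptideWindow, EncodedWindow)):
            out.append(w.symbols)
        else:
            out.append(str(w))
    return out


def _char_matrix(windows: Sequence[str]) -> np.ndarray:
    """(n_windows, width) array of single characters."""
    widths = {len(w) for w in windows}
    if len(widths) != 1:
        raise ValueError(f"windows have inconsistent lengths {sorted(widths)}")
    (width,) = widths
    if width % 2 != 1:
        raise ValueError(f"window width {width} is not odd (2*flank+1)")
    flat = np.frombuffer("".join(windows).encode("ascii"), dtype="S1")
    return flat.reshape(len(windows), width).astype("U1")


@dataclass
class PositionFrequencyMatrix:
    """Per-position symbol counts and fractions over non-pad occupancy.

    ``counts``/``freq`` are DataFrames indexed by symbol with signed-offset
    columns; each ``freq`` column sums to 1 wherever at least one non-pad
    symbol was observed.  Suitable as direct input to logo-plotting tools
    (transpose to position x symbol).
    """

    counts: pd.DataFrame
    freq: pd.DataFrame
    n_windows: int

    @property
    def positions(self) -> list[int]:
        return list(self.counts.columns)

    def to_logo_matrix(self) -> pd.DataFrame:
        """Position x symbol frequency matrix (logo-tool convention)."""
        return self.freq.T


def position_frequency_matrix(windows: Iterable) -> PositionFrequencyMatrix:
    strings = as_symbol_strings(windows)
    if not strings:
        raise ValueError("cannot build a frequency matrix from zero windows")
    mat = _char_matrix(strings)
    flank = mat.shape[1] // 2
    offsets = np.arange(-flank, flank + 1)
    symbols = sorted(set(mat.ravel()) - {PAD_SYMBOL})
    counts = pd.DataFrame(
        {p: [(mat[:, flank + p] == s).sum() for s in symbols] for p in offsets},
        index=symbols,
        dtype=int,
    )
    occupancy = counts.sum(axis=0)
    freq = counts / occupancy.replace(0, np.nan)
    return PositionFrequencyMatrix(
        counts=counts, freq=freq.fillna(0.0), n_windows=len(strings)
    )


def background_composition(windows: Iterable) -> pd.Series:
    """Pooled symbol fractions over all positions except 0 and pads."""
    strings = as_symbol_strings(windows)
    if not strings:
        raise ValueError("cannot compute a background from zero windows")
    mat = _char_matrix(strings)
    flank = mat.shape[1] // 2
    flanks = np.delete(mat, flank, axis=1).ravel()
    flanks = flanks[flanks != PAD_SYMBOL]
    symbols, counts = np.unique(flanks, return_counts=True)
    comp = pd.Series(counts / counts.sum(), index=symbols, dtype=float)
    return comp.sort_index()


@dataclass
class PreferenceTable:
    """Enrichment test results for every (symbol, position) pair.

    ``table`` columns: symbol, position, count, observed_freq,
    background_freq, p_value, preferred.  A pair is preferred iff it is
    enriched (observed > background) and significant at ``alpha`` after the
    selected correction.  Position 0 never appears.
    """

    table: pd.DataFrame
    alpha: float
    correction: str
    class_label: str
    n_windows: int

    @property
    def items(self) -> list[Item]:
        sel = self.table[self.table["preferred"]]
        return [
            (row.symbol, int(row.position))
            for row in sel.itertuples(index=False)
        ]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def preferred_items(
    windows: Iterable,
    alpha: float = 0.05,
    correction: str = "none",
    class_label: str = "N+",
) -> PreferenceTable:
    """One-sided exact binomial enrichment of each (symbol, position) pair.

    For symbol *s* at offset *p* observed *k* times among *n* windows, the
    p-value is ``P(X >= k)`` for ``X ~ Binomial(n, background[s])``.  With
    ``correction='BH'`` p-values are Benjamini-Hochberg adjusted before the
    alpha cut; the default applies no correction, which is deliberately
    permissive.
    """
    if correction not in {"none", "BH"}:
        raise ValueError(f"unknown correction {correction!r}")
    strings = as_symbol_strings(windows)
    if not strings:
        raise ValueError("cannot estimate preferences from zero windows")
    if len(strings) < 10:
        warnings.warn(
            f"only {len(strings)} windows: the enrichment test is underpowered",
            stacklevel=2,
        )
    mat = _char_matrix(strings)
    flank = mat.shape[1] // 2
    background = background_composition(strings)

    rows = []
    for p in range(-flank, flank + 1):
        if p == 0:
            continue
        col = mat[:, flank + p]
        nonpad = int((col != PAD_SYMBOL).sum())
        if nonpad == 0:
            continue
        for s in background.index:
            k = int((col == s).sum())
            bg = float(background[s])
            pval = float(stats.binom.sf(k - 1, nonpad, bg)) if k > 0 else 1.0
            rows.append((s, p, k, k / nonpad, bg, pval))
    table = pd.DataFrame(
        rows,
        columns=[
            "symbol",
            "position",
            "count",
            "observed_freq",
            "background_freq",
            "p_value",
        ],
    )
    if correction == "BH":
        table["p_adjusted"] = multipletests(
            table["p_value"].to_numpy(), method="fdr_bh"
        )[1]
        crit = table["p_adjusted"]
    else:
        crit = table["p_value"]
    table["preferred"] = (table["observed_freq"] > table["background_freq"]) & (
        crit < alpha
    )
    table = table.sort_values(["position", "symbol"]).reset_index(drop=True)
    return PreferenceTable(
        table=table,
        alpha=alpha,
        correction=correction,
        class_label=class_label,
        n_windows=len(strings),
    )


class PreferenceSelector(BaseEstimator):
    """Estimator wrapper around :func:`preferred_items`.

    ``fit(X)`` takes one class's windows and exposes ``table_`` (the full
    test table), ``items_`` (the preferred (symbol, position) pairs),
    ``pfm_`` and ``background_``.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        correction: str = "none",
        class_label: str = "N+",
    ):
        self.alpha = alpha
        self.correction = correction
        self.class_label = class_label

    def fit(self, X: Iterable, y=None) -> "PreferenceSelector":
        pref = preferred_items(
            X,
            alpha=self.alpha,
            correction=self.correction,
            class_label=self.class_label,
        )
        self.preference_ = pref
        self.table_ = pref.table
        self.items_ = pref.items
        self.pfm_ = position_frequency_matrix(X)
        self.background_ = background_composition(X)
        self.n_windows_ = pref.n_windows
        return self
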