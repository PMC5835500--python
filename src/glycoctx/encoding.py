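"""Charge/polarity encoding of residue windows.

Residues are collapsed into five side-chain classes before pattern mining:

====== ============================== =================
symbol chemical nature                members
====== ============================== =================
P      positively charged R-groups    K, R, H
N      negatively charged R-groups    D, E
L      polar, uncharged R-groups      S, T, C, M, N, Q
O      non-polar, aliphatic R-groups  G, A, V, L, I
A      aromatic R-groups              F, Y, W
====== ============================== =================

Proline belongs to none of the five classes and maps to the reserved
unclassified symbol ``X``, which can never be a mined item; a custom scheme
may reassign it.  Note the deliberate namespace split: group symbol ``N``
(acidic) is unrelated to residue letter ``N`` (Asn, a member of group L) —
raw and encoded strings are never mixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import PAD_SYMBOL, STANDARD_RESIDUES, PeptideWindow

#: the default five-group classification
DEFAULT_GROUPS: dict[str, str] = {
    "P": "KRH",
    "N": "DE",
    "L": "STCMNQ",
    "O": "GAVLI",
    "A": "FYW",
}

UNCLASSIFIED_SYMBOL = "X"

#: full encoded alphabet as it can appear in an encoded window
ENCODED_ALPHABET = ("P", "N", "L", "O", "A", UNCLASSIFIED_SYMBOL, PAD_SYMBOL)


@dataclass(frozen=True)
class ClassificationScheme:
    """Residue letter -> group symbol mapping built from disjoint groups."""

    groups: Mapping[str, str]
    unclassified_symbol: str = UNCLASSIFIED_SYMBOL
    mapping: Mapping[str, str] = field(init=False)

    def __post_init__(self) -> None:
        mapping: dict[str, str] = {}
        for symbol, members in self.groups.items():
            for residue in members:
                if residue in mapping:
                    raise ValueError(
                        f"residue {residue!r} assigned to both "
                        f"{mapping[residue]!r} and {symbol!r}"
                    )
                mapping[residue] = symbol
        for residue in STANDARD_RESIDUES:
            mapping.setdefault(residue, self.unclassified_symbol)
        object.__setattr__(self, "mapping", mapping)

    def lookup(self, residue: str) -> str:
        try:
            return self.mapping[residue]
        except KeyError:
            raise KeyError(f"{residue!r} is not a standard residue") from None

    def encode(self, symbols: str) -> str:
        """Positionwise substitution; pad symbols pass through unchanged."""
        out = []
        for ch in symbols:
            if ch == PAD_SYMBOL:
                out.append(PAD_SYMBOL)
            elif ch in self.mapping:
                out.append(self.mapping[ch])
            else:
                raise ValueError(f"cannot encode symbol {ch!r}")
        return "".join(out)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dict(self.groups), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ClassificationScheme":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(groups=json.loads(text))


def build_default_scheme() -> ClassificationScheme:
    """The five-group charge/polarity scheme (Pro unclassified -> 'X')."""
    return ClassificationScheme(groups=dict(DEFAULT_GROUPS))


@dataclass(frozen=True)
class EncodedWindow:
    """A window over the group alphabet, paired with its raw source."""

    symbols: str
    source: PeptideWindow

    @property
    def flank(self) -> int:
        return self.source.flank

    def at(self, offset: int) -> str:
        return self.symbols[self.flank + offset]


def encode_window(
    window: PeptideWindow, scheme: ClassificationScheme | None = None
) -> EncodedWindow:
    scheme = scheme or build_default_scheme()
    return EncodedWindow(symbols=scheme.encode(window.symbols), source=window)


class GroupEncoder(TransformerMixin, BaseEstimator):
    """Stateless transformer mapping raw window strings to group strings.

    Accepts a sequence of equal-length window strings (or
    :class:`PeptideWindow` objects) and returns the encoded strings.  Follows
    the scikit-learn transformer protocol so it can sit in a ``Pipeline``
    ahead of the rule miner.

    Parameters
    ----------
    scheme : ClassificationScheme, optional
        Defaults to the five-group charge/polarity scheme.
    """

    def __init__(self, scheme: ClassificationScheme | None = None):
        self.scheme = scheme

    def fit(self, X: Sequence, y=None) -> "GroupEncoder":
        self.scheme_ = self.scheme or build_default_scheme()
        return self

    def transform(self, X: Iterable) -> list[str]:
        if not hasattr(self, "scheme_"):
            self.fit(X)
        scheme = self.scheme_
        out = []
        for w in X:
            symbols = w.symbols if isinstance(w, PeptideWindow) else str(w)
            out.append(scheme.encode(symbols))
        return out
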