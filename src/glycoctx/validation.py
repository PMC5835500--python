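"""Rule validation: conformity percentages, sequon classes, motif tables.

Mined association patterns are validated against independent peptide sets —
externally produced predictor output (e.g. a NetNGlyc-style site list) or
literature-curated sequon tables.  *Conformity* of a peptide set with a rule
set is the percentage of peptides containing at least one rule, rounded
half-up to an integer.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dataset import PAD_SYMBOL, STANDARD_RESIDUES, PeptideWindow, SiteRecord
from .encoding import ClassificationScheme, build_default_scheme
from .mining import AssociationRule, Item, pattern_mask
from .preference import as_symbol_strings

_ENCODED_SYMBOLS = frozenset("PNLOAX-")
_GROUP_SYMBOLS = frozenset("PNLOA")


class AlphabetMismatchError(ValueError):
    """A rule over one alphabet was applied to windows of the other."""


def _check_alphabet(window: str, items: Sequence[Item]) -> None:
    window_raw = bool(set(window) - _ENCODED_SYMBOLS)
    for symbol, _ in items:
        if window_raw and symbol not in STANDARD_RESIDUES:
            raise AlphabetMismatchError(
                f"item symbol {symbol!r} is not a residue but the window looks raw"
            )
        if not window_raw and symbol not in _GROUP_SYMBOLS and symbol in "BJUZ":
            raise AlphabetMismatchError(f"invalid item symbol {symbol!r}")


def rule_matches(window, rule: AssociationRule | Iterable[Item]) -> bool:
    """True iff every item's symbol sits at its offset in the window.

    Pad symbols (``-``) and the unclassified class (``X``) match no item.
    """
    items = list(rule.items if isinstance(rule, AssociationRule) else rule)
    (symbols,) = as_symbol_strings([window])
    _check_alphabet(symbols, items)
    flank = len(symbols) // 2
    for symbol, position in items:
        if abs(position) > flank:
            return False
        if symbols[flank + position] != symbol or symbol in (PAD_SYMBOL, "X"):
            return False
    return True


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def conformity_percentage(n_matched: int, n_total: int) -> int:
    """Integer conformity percentage, rounded half-up."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round_half_up(100.0 * n_matched / n_total)


@dataclass
class ConformityReport:
    """Matched/total counts for one peptide set against a rule set."""

    dataset_name: str
    n_total: int
    n_matched: int
    percentage: int
    per_rule_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dataset_name": self.dataset_name,
            "n_total": self.n_total,
            "n_matched": self.n_matched,
            "percentage": self.percentage,
            "per_rule_counts": self.per_rule_counts,
        }


def conformity_report(
    windows: Iterable,
    rules: Sequence[AssociationRule],
    name: str = "dataset",
) -> ConformityReport:
    """Count windows containing at least one rule."""
    strings = as_symbol_strings(windows)
    if not strings:
        raise ValueError("conformity over an empty window set is undefined")
    per_rule: dict[str, int] = {}
    matched = [False] * len(strings)
    for rule in rules:
        if strings:
            _check_alphabet(strings[0], list(rule.items))
        mask = pattern_mask(strings, rule.items)
        per_rule[rule.notation()] = int(mask.sum())
        matched = [m or bool(v) for m, v in zip(matched, mask)]
    n_matched = sum(matched)
    return ConformityReport(
        dataset_name=name,
        n_total=len(strings),
        n_matched=n_matched,
        percentage=conformity_percentage(n_matched, len(strings)),
        per_rule_counts=per_rule,
    )


@dataclass(frozen=True)
class SequonClass:
    """Canonical sequon class of one Asn context.

    The class is determined solely by the residue at +2 (S -> NXS,
    T -> NXT, C -> NXC, anything else non-canonical); ``x_is_proline``
    flags Pro at +1, which disfavours glycosylation.
    """

    window: str
    sequon_class: str
    x_is_proline: bool


def classify_sequon(window) -> SequonClass:
    """Classify a window (or an N-anchored sequon string) by its +2 residue."""
    (symbols,) = as_symbol_strings([window])
    if len(symbols) % 2 == 1 and symbols[len(symbols) // 2] == "N":
        center = len(symbols) // 2
    elif symbols.startswith("N"):
        center = 0
    else:
        raise ValueError(f"cannot locate the target Asn in {symbols!r}")
    if len(symbols) - center < 3:
        raise ValueError("need at least two downstream symbols")
    plus1, plus2 = symbols[center + 1], symbols[center + 2]
    cls = {"S": "NXS", "T": "NXT", "C": "NXC"}.get(plus2, "non-canonical")
    return SequonClass(window=symbols, sequon_class=cls, x_is_proline=plus1 == "P")


@dataclass(frozen=True)
class MotifTableEntry:
    """A literature-curated glycosylation sequon, e.g. EGFR N528 (NVSR)."""

    protein: str
    site: str  # e.g. "N558"
    sequon: str

    def __post_init__(self) -> None:
        if not self.sequon.startswith("N"):
            raise ValueError(f"sequon {self.sequon!r} must start with 'N'")

    @property
    def position(self) -> int:
        return int(re.sub(r"\D", "", self.site))


#: UniProt-reported canonical extracellular N-glycosylation sequons of human
#: EGFR (P00533); curated from the literature.
EGFR_MOTIFS: tuple[MotifTableEntry, ...] = tuple(
    MotifTableEntry("EGFR", site, seq)
    for site, seq in [
        ("N56", "NNCE"), ("N73", "NYDL"), ("N128", "NKTG"), ("N175", "NMSM"),
        ("N196", "NGSC"), ("N352", "NATN"), ("N361", "NCTS"), ("N413", "NRTD"),
        ("N444", "NITS"), ("N528", "NVSR"), ("N568", "NITC"), ("N603", "NNTL"),
    ]
)

#: UniProt-reported canonical extracellular N-glycosylation sequons of human
#: E-cadherin (P12830).
ECAD_MOTIFS: tuple[MotifTableEntry, ...] = tuple(
    MotifTableEntry("E-cadherin", site, seq)
    for site, seq in [
        ("N558", "NSTY"), ("N570", "NGSP"), ("N622", "NTSP"), ("N637", "NWTI"),
    ]
)


def motif_window(sequon: str, flank: int = 10) -> str:
    """Embed an N-anchored sequon at offsets 0..len-1 of an all-pad window."""
    if not sequon.startswith("N"):
        raise ValueError(f"sequon {sequon!r} must start with 'N'")
    if len(sequon) > flank + 1:
        raise ValueError("sequon longer than the downstream flank")
    return PAD_SYMBOL * flank + sequon + PAD_SYMBOL * (flank + 1 - len(sequon))


@dataclass
class MotifValidationResult:
    table: pd.DataFrame  # protein, site, sequon, encoded, matched
    fraction_matched: float
    skipped_rules: list[str]  # rules needing offsets outside the sequon span


def validate_motif_table(
    entries: Sequence[MotifTableEntry],
    rules: Sequence[AssociationRule],
    scheme: ClassificationScheme | None = None,
    flank: int = 10,
) -> MotifValidationResult:
    """Match each sequon, Table-2 encoded, against rules within its span.

    A 4-mer sequon only carries offsets 0..+3, so rules referencing any
    offset outside that span cannot be evaluated; they are skipped and
    reported in ``skipped_rules``.
    """
    scheme = scheme or build_default_scheme()
    if not entries:
        raise ValueError("empty motif table")
    span = max(len(e.sequon) for e in entries) - 1
    usable, skipped = [], []
    for rule in rules:
        if all(0 < p <= span for _, p in rule.items):
            usable.append(rule)
        else:
            skipped.append(rule.notation())

    rows = []
    for entry in entries:
        encoded = scheme.encode(motif_window(entry.sequon, flank=flank))
        matched = any(rule_matches(encoded, r) for r in usable)
        rows.append((entry.protein, entry.site, entry.sequon,
                     scheme.encode(entry.sequon), matched))
    table = pd.DataFrame(
        rows, columns=["protein", "site", "sequon", "encoded", "matched"]
    )
    return MotifValidationResult(
        table=table,
        fraction_matched=float(table["matched"].mean()),
        skipped_rules=skipped,
    )


def load_motif_table(path: str | Path) -> list[MotifTableEntry]:
    """Read a TSV with columns ``protein  site  sequon``."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    need = {"protein", "site", "sequon"}
    if not need <= set(frame.columns):
        raise ValueError(f"motif table needs columns {sorted(need)}")
    return [
        MotifTableEntry(r.protein, r.site, r.sequon)
        for r in frame.itertuples(index=False)
    ]


def read_prediction_tsv(path: str | Path) -> tuple[list[SiteRecord], list[SiteRecord]]:
    """Read predictor output as TSV: ``protein_id  position  predicted``.

    Returns (predicted, non_predicted) site records; ``predicted`` accepts
    true/false, 1/0, yes/no (case-insensitive).
    """
    frame = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    need = {"protein_id", "position", "predicted"}
    if not need <= set(frame.columns):
        raise ValueError(f"prediction table needs columns {sorted(need)}")
    truthy = {"true", "1", "yes", "+", "y"}
    pred, nonpred = [], []
    for r in frame.itertuples(index=False):
        site = SiteRecord(
            protein_id=str(r.protein_id),
            position=int(r.position),
            residue="N",
            label="positive" if str(r.predicted).strip().lower() in truthy else "negative",
        )
        (pred if site.label == "positive" else nonpred).append(site)
    return pred, nonpred


_NETNGLYC_LINE = re.compile(
    r"^(?P<name>\S+)\s+(?P<pos>\d+)\s+(?P<seq>[A-Z]{4})\s+"
    r"(?P<potential>[01]\.\d+)\s+\((?P<agreement>\d+/\d+)\)\s*(?P<result>\+*)"
)


def parse_netnglyc_report(text: str) -> pd.DataFrame:
    """Convenience parser for the predictor's plain-text site table.

    Extracts lines of the form ``NAME  POS  SEQN  potential  (agreement)  +``
    into a frame with a boolean ``predicted`` column (any ``+`` marks).
    """
    rows = []
    for line in text.splitlines():
        m = _NETNGLYC_LINE.match(line.strip())
        if m:
            rows.append(
                (
                    m["name"],
                    int(m["pos"]),
                    m["seq"],
                    float(m["potential"]),
                    m["agreement"],
                    bool(m["result"]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "position", "sequon", "potential", "agreement", "predicted"],
    )
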