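"""Dataset assembly: sequences, site annotations, cleaning, and context windows.

The analysis operates on asparagine (Asn, N) sites in protein primary
sequences.  A site is *positive* (N+) when annotated as N-glycosylated and
*negative* (N-) when the Asn carries no annotation.  Every downstream stage
consumes fixed-width context windows: ``2*flank + 1`` residues with the
target Asn at signed offset 0 and ``flank`` residues on each side, padded
with ``-`` where the window runs past a terminus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
PAD_SYMBOL = "-"

POSITIVE = "positive"
NEGATIVE = "negative"

#: header expected in the site-annotation table (residue column optional)
SITE_COLUMNS = ("protein_id", "position", "label")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein accession and its primary sequence (one-letter codes)."""

    id: str
    sequence: str


@dataclass(frozen=True, order=True)
class SiteRecord:
    """One asparagine occurrence: 1-based position plus its N+/N- label."""

    protein_id: str
    position: int  # 1-based, UniProt convention
    residue: str = "N"
    label: str = POSITIVE


@dataclass(frozen=True)
class PeptideWindow:
    """Context window of ``2*flank + 1`` symbols, target Asn at index ``flank``.

    ``symbols[flank + p]`` is the residue at signed offset ``p``; offsets
    beyond the protein termini hold the pad symbol ``-``.
    """

    site: SiteRecord
    symbols: str
    flank: int = 10
    pad_symbol: str = PAD_SYMBOL

    def __post_init__(self) -> None:
        if len(self.symbols) != 2 * self.flank + 1:
            raise ValueError(
                f"window length {len(self.symbols)} != 2*{self.flank}+1"
            )

    def at(self, offset: int) -> str:
        """Symbol at signed offset relative to the target Asn."""
        if abs(offset) > self.flank:
            raise IndexError(f"offset {offset} outside +-{self.flank}")
        return self.symbols[self.flank + offset]


@dataclass
class CleaningReport:
    """Per-category removal counts from :func:`clean_dataset`."""

    n_input: int = 0
    n_position_mismatch: int = 0
    n_nonstandard_char: int = 0
    n_length_error: int = 0
    n_duplicates_removed: int = 0
    n_retained: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def check(self) -> None:
        removed = (
            self.n_position_mismatch
            + self.n_nonstandard_char
            + self.n_length_error
            + self.n_duplicates_removed
        )
        if self.n_retained != self.n_input - removed:
            raise AssertionError("cleaning report counts are inconsistent")


class SiteTableSchemaError(ValueError):
    """The site-annotation TSV is missing a required column."""


def parse_inputs(
    fasta_path: str | Path, sites_path: str | Path
) -> tuple[dict[str, ProteinRecord], list[SiteRecord]]:
    """Read a FASTA file and a site-annotation TSV.

    The TSV must carry columns ``protein_id``, ``position`` (1-based) and
    ``label`` (``positive``/``negative``); a ``residue`` column is accepted
    and ignored in favour of the sequence itself.  Sites referencing an
    accession absent from the FASTA are dropped with a warning.
    """
    proteins: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        proteins[rec.id] = ProteinRecord(id=rec.id, sequence=seq)
    if not proteins:
        raise ValueError(f"no FASTA records parsed from {fasta_path}")

    table = pd.read_csv(sites_path, sep="\t", dtype={"protein_id": str})
    missing = [c for c in SITE_COLUMNS if c not in table.columns]
    if missing:
        raise SiteTableSchemaError(
            f"site table {sites_path} lacks column(s) {missing}; "
            f"expected at least {list(SITE_COLUMNS)}"
        )

    sites: list[SiteRecord] = []
    n_dropped = 0
    for row in table.itertuples(index=False):
        pid = str(row.protein_id)
        if pid not in proteins:
            n_dropped += 1
            continue
        pos = int(row.position)
        seq = proteins[pid].sequence
        residue = seq[pos - 1] if 1 <= pos <= len(seq) else "?"
        sites.append(
            SiteRecord(
                protein_id=pid,
                position=pos,
                residue=residue,
                label=str(row.label),
            )
        )
    if n_dropped:
        logger.warning(
            "%d site(s) referenced unknown protein ids and were dropped", n_dropped
        )
    return proteins, sites


def clean_dataset(
    proteins: Mapping[str, ProteinRecord], sites: Iterable[SiteRecord]
) -> tuple[dict[str, ProteinRecord], list[SiteRecord], CleaningReport]:
    """Remove inconsistent annotations and duplicated entries.

    Checks mirror a data-inconsistency/duplication pass: the annotated
    position must hold an Asn, positions must lie within the sequence,
    sequences must consist of the 20 standard residues, and exact
    (protein, position) duplicates collapse to one record.  A protein with
    non-standard characters is excluded entirely (its composition would
    pollute the background statistics) and its sites are counted under
    ``n_nonstandard_char``.  Conflicting labels at one position resolve to
    positive: an annotated modification wins over an assumed negative.
    """
    sites = list(sites)
    report = CleaningReport(n_input=len(sites))

    clean_proteins = {
        pid: rec
        for pid, rec in proteins.items()
        if set(rec.sequence) <= STANDARD_RESIDUES
    }
    n_excluded = len(proteins) - len(clean_proteins)
    if n_excluded:
        logger.warning(
            "%d protein(s) contain non-standard characters and were excluded",
            n_excluded,
        )

    by_key: dict[tuple[str, int], SiteRecord] = {}
    for site in sites:
        rec = proteins.get(site.protein_id)
        if rec is None or site.protein_id not in clean_proteins:
            report.n_nonstandard_char += 1
            continue
        if not 1 <= site.position <= len(rec.sequence):
            report.n_length_error += 1
            continue
        if rec.sequence[site.position - 1] != "N":
            report.n_position_mismatch += 1
            continue
        key = (site.protein_id, site.position)
        prev = by_key.get(key)
        if prev is None:
            by_key[key] = site
        else:
            report.n_duplicates_removed += 1
            if prev.label != site.label:
                logger.warning(
                    "conflicting labels at %s:%d; keeping positive", *key
                )
                winner = site if site.label == POSITIVE else prev
                by_key[key] = winner

    retained = sorted(by_key.values())
    report.n_retained = len(retained)
    report.check()
    return clean_proteins, retained, report


def enumerate_negative_sites(
    proteins: Mapping[str, ProteinRecord], positive_sites: Iterable[SiteRecord]
) -> list[SiteRecord]:
    """Every Asn occurrence not annotated positive, labelled negative."""
    positive_keys = {(s.protein_id, s.position) for s in positive_sites}
    negatives: list[SiteRecord] = []
    for pid in sorted(proteins):
        seq = proteins[pid].sequence
        start = 0
        while True:
            idx = seq.find("N", start)
            if idx == -1:
                break
            pos = idx + 1
            if (pid, pos) not in positive_keys:
                negatives.append(
                    SiteRecord(protein_id=pid, position=pos, residue="N", label=NEGATIVE)
                )
            start = idx + 1
    return negatives


def balance_dataset(
    positives: Sequence[SiteRecord],
    negatives: Sequence[SiteRecord],
    ratio: str | int | tuple[int, int] = "1:1",
    seed: int = 42,
) -> list[SiteRecord]:
    """Uniform random subsample of negatives, ``ratio`` times the positives.

    The subsample is drawn without replacement by a stated shuffle-then-take
    contract: negatives are sorted by (protein_id, position), permuted with
    ``numpy.random.default_rng(seed)``, and the first ``k`` taken — identical
    seeds give identical subsamples on any platform.
    """
    mult = _ratio_multiplier(ratio)
    k = mult * len(positives)
    if len(negatives) < k:
        raise ValueError(
            f"need {k} negatives for ratio 1:{mult} with {len(positives)} "
            f"positives, only {len(negatives)} available"
        )
    ordered = sorted(negatives)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ordered))
    return [ordered[i] for i in order[:k]]


def _ratio_multiplier(ratio: str | int | tuple[int, int]) -> int:
    if isinstance(ratio, str):
        left, _, right = ratio.partition(":")
        if left.strip() != "1" or right.strip() not in {"1", "2"}:
            raise ValueError(f"unsupported ratio {ratio!r}; use '1:1' or '1:2'")
        return int(right)
    if isinstance(ratio, tuple):
        if ratio[0] != 1:
            raise ValueError(f"unsupported ratio {ratio!r}")
        return int(ratio[1])
    return int(ratio)


def extract_window(
    protein: ProteinRecord, site: SiteRecord, flank: int = 10
) -> PeptideWindow:
    """Cut the ``2*flank+1`` context around ``site``, padding past termini."""
    seq = protein.sequence
    pos0 = site.position - 1
    if not 0 <= pos0 < len(seq):
        raise ValueError(f"position {site.position} outside {protein.id}")
    if seq[pos0] != "N":
        raise ValueError(
            f"site {protein.id}:{site.position} is {seq[pos0]!r}, not 'N'"
        )
    lo, hi = pos0 - flank, pos0 + flank + 1
    core = seq[max(lo, 0) : min(hi, len(seq))]
    left_pad = PAD_SYMBOL * max(-lo, 0)
    right_pad = PAD_SYMBOL * max(hi - len(seq), 0)
    return PeptideWindow(site=site, symbols=left_pad + core + right_pad, flank=flank)


def extract_windows(
    proteins: Mapping[str, ProteinRecord],
    sites: Iterable[SiteRecord],
    flank: int = 10,
) -> list[PeptideWindow]:
    return [extract_window(proteins[s.protein_id], s, flank=flank) for s in sites]


def write_fasta(proteins: Mapping[str, ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in proteins:
            fh.write(f">{pid}\n")
            seq = proteins[pid].sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_site_table(sites: Iterable[SiteRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(s.protein_id, s.position, s.residue, s.label) for s in sites],
        columns=["protein_id", "position", "residue", "label"],
    )
    frame.to_csv(path, sep="\t", index=False)
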