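import numpy as np
import pytest

from glycoctx.dataset import PeptideWindow, SiteRecord
from glycoctx.encoding import build_default_scheme
from glycoctx.validation import ECAD_MOTIFS

CARRIER_LENGTH = 660


@pytest.fixture(scope="session")
def scheme():
    return build_default_scheme()


def _ecad_carrier_sequence() -> str:
    """The four E-cadherin sequons embedded at their native positions in an
    alanine carrier, so site positions match the literature labels."""
    seq = ["A"] * CARRIER_LENGTH
    for entry in ECAD_MOTIFS:
        pos0 = entry.position - 1
        seq[pos0 : pos0 + len(entry.sequon)] = list(entry.sequon)
    return "".join(seq)


@pytest.fixture(scope="session")
def ecad_carrier() -> str:
    return _ecad_carrier_sequence()


@pytest.fixture()
def ecad_inputs(tmp_path, ecad_carrier):
    """FASTA + site TSV for the E-cadherin carrier fixture."""
    fasta = tmp_path / "ecad.fasta"
    fasta.write_text(">ECAD\n" + "\n".join(
        ecad_carrier[i : i + 60] for i in range(0, len(ecad_carrier), 60)
    ) + "\n")
    sites = tmp_path / "sites.tsv"
    lines = ["protein_id\tposition\tresidue\tlabel"]
    for entry in ECAD_MOTIFS:
        lines.append(f"ECAD\t{entry.position}\tN\tpositive")
    sites.write_text("\n".join(lines) + "\n")
    return fasta, sites


def make_window(symbols: str, protein_id: str = "P", position: int = 1) -> PeptideWindow:
    """Wrap a bare odd-length string as a PeptideWindow."""
    flank = len(symbols) // 2
    site = SiteRecord(protein_id=protein_id, position=position)
    return PeptideWindow(site=site, symbols=symbols, flank=flank)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
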