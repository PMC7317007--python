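import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module


def format_genbank(residues: str, feature_block: str = "", name: str = "SYNREC",
                   topology: str = "circular") -> str:
    """Render a minimal single-record GenBank flat file."""
    lines = [
        f"LOCUS       {name:<16} {len(residues):>11} bp    DNA     "
        f"{topology} PLN 01-JAN-2020",
        f"DEFINITION  synthetic test record {name}.",
        f"ACCESSION   {name}",
        f"VERSION     {name}.1",
        "FEATURES             Location/Qualifiers",
        f"     source          1..{len(residues)}",
    ]
    if feature_block:
        lines.append(feature_block.rstrip("\n"))
    lines.append("ORIGIN")
    low = residues.lower()
    for i in range(0, len(low), 60):
        chunk = low[i : i + 60]
        groups = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {groups}")
    lines.append("//")
    return "\n".join(lines) + "\n"


@pytest.fixture
def write_genbank(tmp_path):
    def _write(residues, feature_block="", name="SYNREC", topology="circular"):
        path = tmp_path / f"{name}.gb"
        path.write_text(format_genbank(residues, feature_block, name, topology))
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_residues(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
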