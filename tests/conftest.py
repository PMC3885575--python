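import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from sdrforest.dataset import build_superfamily_dataset
from sdrforest.io import blosum62
from sdrforest.pipeline import train_superfamily
from sdrforest.synthetic import SyntheticConfig, generate_superfamily


@pytest.fixture(scope="session")
def b62():
    return blosum62()


@pytest.fixture(scope="session")
def synthetic_family():
    """The default study conditions: 3 enzymes x 20 sequences of length 150."""
    return generate_superfamily(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def trained(synthetic_family):
    """Dataset + per-enzyme predictors trained once for the whole session."""
    dataset = build_superfamily_dataset(synthetic_family.records, seed=1)
    models = train_superfamily(dataset, synthetic_family.annotations, seed=1)
    return synthetic_family, dataset, models


def _pdb_atom(serial, name, res, chain, resseq, x, y, z, element, het=False):
    rec = "HETATM" if het else "ATOM  "
    return (
        f"{rec}{serial:>5} {name:<4}{res:>4} {chain}{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2}"
    )


@pytest.fixture()
def contact_pdb(tmp_path):
    """Synthetic three-residue peptide + ligand with hand-computed distances.

    SER 1: OG is 3.0 A from ligand O1 (polar pair) and CB 3.5 A from ligand
    C1 (carbon pair) -> satisfies the AND rule.  ALA 2: only a carbon-carbon
    contact (CB 3.0 A from C2).  GLY 3: ~85 A from everything.
    """
    lines = []
    s = 1
    for name, x, y, z, el in [
        ("N", 0, 0, 0, "N"), ("CA", 1.5, 0, 0, "C"), ("C", 2.2, 1.2, 0, "C"),
        ("O", 3.4, 1.2, 0, "O"), ("CB", 1.5, -1.5, 0, "C"), ("OG", 2.5, -2.5, 0, "O"),
    ]:
        lines.append(_pdb_atom(s, name, "SER", "A", 1, x, y, z, el)); s += 1
    for name, x, y, z, el in [
        ("N", 0, 8, 0, "N"), ("CA", 1.5, 8, 0, "C"), ("C", 2.2, 9.2, 0, "C"),
        ("O", 3.4, 9.2, 0, "O"), ("CB", 1.5, 6.5, 0, "C"),
    ]:
        lines.append(_pdb_atom(s, name, "ALA", "A", 2, x, y, z, el)); s += 1
    for name, x, y, z, el in [
        ("N", 50, 50, 50, "N"), ("CA", 51.5, 50, 50, "C"),
        ("C", 52.2, 51.2, 50, "C"), ("O", 53.4, 51.2, 50, "O"),
    ]:
        lines.append(_pdb_atom(s, name, "GLY", "A", 3, x, y, z, el)); s += 1
    for name, x, y, z, el in [
        ("O1", 2.5, -5.5, 0, "O"), ("C1", 1.5, -5.0, 0, "C"), ("C2", 1.5, 3.5, 0, "C"),
    ]:
        lines.append(_pdb_atom(s, name, "LIG", "A", 9, x, y, z, el, het=True)); s += 1
    lines.append("END")
    path = tmp_path / "complex.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
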