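import numpy as np
import pytest

from qtybarrel.sequence_io import ProteinRecord, Topology, TopologySegment

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_record(rng: np.random.Generator, length: int | None = None,
                  rec_id: str = "p1") -> ProteinRecord:
    length = length or int(rng.integers(20, 200))
    seq = "".join(rng.choice(list(AA20), size=length))
    return ProteinRecord(id=rec_id, description="random", sequence=seq,
                         source="synthetic")


def random_topology(rng: np.random.Generator, protein_id: str,
                    length: int) -> Topology:
    """Sorted, non-overlapping tm_strand segments over [1, length]."""
    segments = []
    pos = 1
    while pos <= length - 4:
        gap = int(rng.integers(0, 8))
        start = pos + gap
        if start > length:
            break
        end = min(length, start + int(rng.integers(4, 14)))
        segments.append(TopologySegment(kind="tm_strand", start=start, end=end))
        pos = end + 2
    return Topology(protein_id=protein_id, segments=tuple(segments))


@pytest.fixture
def rng():
    return np.random.default_rng(20230822)


@pytest.fixture
def toy_records():
    return [
        ProteinRecord(id="p1", description="first", sequence="LIVFASNKDE"),
        ProteinRecord(id="p2", description="", sequence="MKTAYIAKQR"),
    ]


# Minimal hand-written PDB fixture: two beta-strands (SHEET) and a short
# chain with an altloc pair on residue 4 and one HETATM to be ignored.
MINI_PDB = """\
HEADER    SYNTHETIC TEST FIXTURE
SHEET    1   A 2 ALA A   3  GLY A   5  0
SHEET    2   A 2 SER A   8  VAL A  10 -1
ATOM      1  N   ALA A   3      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   3       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA ALEU A   4       2.000   1.000   0.000  0.50  0.00           C
ATOM      4  CA BLEU A   4       9.000   9.000   9.000  0.50  0.00           C
ATOM      5  CA  GLY A   5       3.000   0.000   1.000  1.00  0.00           C
ATOM      6  CA  LYS A   6       4.000  -1.000   0.500  1.00  0.00           C
ATOM      7  CA  ASP A   7       5.000   0.500  -0.500  1.00  0.00           C
ATOM      8  CA  SER A   8       6.000   1.500   0.250  1.00  0.00           C
ATOM      9  CA  THR A   9       7.000   0.250   1.250  1.00  0.00           C
ATOM     10  CA  VAL A  10       8.000  -0.750   0.750  1.00  0.00           C
HETATM   11  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O
TER
END
"""

HELIX_ONLY_PDB = """\
HEADER    SYNTHETIC TEST FIXTURE
HELIX    1   1 ALA A    3  GLY A    5  1
ATOM      1  CA  ALA A   3       1.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  LEU A   4       2.000   1.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   5       3.000   0.000   1.000  1.00  0.00           C
END
"""


@pytest.fixture
def mini_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_PDB)
    return path


@pytest.fixture
def helix_only_pdb(tmp_path):
    path = tmp_path / "helix.pdb"
    path.write_text(HELIX_ONLY_PDB)
    return path


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Proper rotation via QR of a Gaussian matrix (sign-fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
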