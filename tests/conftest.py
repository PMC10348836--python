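import numpy as np
import pytest

from mqa.structio import Chain, Residue, Structure
from mqa import synthetic as syn


TWO_CHAIN_PDB = """\
HEADER    SYNTHETIC COMPLEX                       01-JAN-20   SYN1
REMARK   2 RESOLUTION.    1.80 ANGSTROMS.
SEQRES   1 A    3  ALA CYS ASP
SEQRES   1 B    3  GLU PHE LYS
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 90.00           C
ATOM      2  CB  ALA A   1       1.500   0.000   0.000  1.00 90.00           C
ATOM      3  CA  CYS A   2       3.800   0.000   0.000  1.00 85.00           C
ATOM      4  CB  CYS A   2       5.300   0.000   0.000  1.00 85.00           C
ATOM      5  CA  ASP A   3       7.600   0.000   0.000  1.00 80.00           C
ATOM      6  CB  ASP A   3       9.100   0.000   0.000  1.00 80.00           C
ATOM      7  CA  GLU B   1       0.000   6.000   0.000  1.00 75.00           C
ATOM      8  CB  GLU B   1       1.500   6.000   0.000  1.00 75.00           C
ATOM      9  CA  PHE B   2       3.800   6.000   0.000  1.00 70.00           C
ATOM     10  CB  PHE B   2       5.300   6.000   0.000  1.00 70.00           C
ATOM     11  CA  LYS B   3       7.600   6.000   0.000  1.00 65.00           C
ATOM     12  CB  LYS B   3       9.100   6.000   0.000  1.00 65.00           C
TER
END
"""


@pytest.fixture
def two_chain_pdb(tmp_path):
    path = tmp_path / "two_chain.pdb"
    path.write_text(TWO_CHAIN_PDB)
    return path


def point_chain(chain_id: str, xs, y=0.0, names=None) -> Chain:
    """Chain of single-CB residues at given x coordinates (test geometry)."""
    residues = []
    for i, x in enumerate(xs):
        name = names[i] if names else "ALA"
        xyz = np.array([float(x), float(y), 0.0])
        residues.append(
            Residue(
                name=name,
                residue_index=i + 1,
                atoms={"CB": xyz} if name != "GLY" else {"CA": xyz},
                bfactors={"CB": 50.0} if name != "GLY" else {"CA": 50.0},
            )
        )
    seq = "".join(r.one_letter for r in residues)
    return Chain(chain_id=chain_id, seqres=seq, residues=residues)


@pytest.fixture
def contact_fixture():
    """Two chains with known pairwise CB distances (cutoff-8 truth: 3 pairs)."""
    a = point_chain("A", [0.0, 4.0, 8.0])
    b = point_chain("B", [6.0, 20.0, 40.0])
    return Structure(id="fix", chains=[a, b])


def truncate_chain(chain: Chain, keep_slice) -> Chain:
    """Chain with only a subset of residues resolved (SEQRES unchanged)."""
    return Chain(
        chain_id=chain.chain_id,
        seqres=chain.seqres,
        residues=chain.residues[keep_slice],
    )


@pytest.fixture
def dimer_case():
    return syn.generate_case(seed=101, n_chains=2)
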