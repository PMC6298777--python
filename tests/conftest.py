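"""Shared fixtures: small structures and toy systems built in memory."""

from __future__ import annotations

import numpy as np
import pytest

from tunnelfold.structure_io import MolecularStructure
from tunnelfold.synthetic_data import ToyDomainSpec, make_toy_domain


@pytest.fixture(scope="session")
def hairpin():
    """Default 12-residue toy hairpin: (native structure, topology)."""
    return make_toy_domain(ToyDomainSpec("hairpin", 12), seed=1)


@pytest.fixture(scope="session")
def three_helix():
    """Default 28-residue toy helix bundle: (native structure, topology)."""
    return make_toy_domain(ToyDomainSpec("three-helix", 28), seed=1)


@pytest.fixture()
def tiny_pdb(tmp_path):
    """Hand-written 3-atom PDB file."""
    text = (
        "ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C\n"
        "ATOM      3  C   ALA A   1      12.503   7.292  -4.870  1.00  0.00           C\n"
        "END\n"
    )
    path = tmp_path / "tiny.pdb"
    path.write_text(text)
    expected = np.array([[11.104, 6.134, -6.504],
                         [11.639, 6.071, -5.147],
                         [12.503, 7.292, -4.870]])
    return path, expected


def make_peptide(n_res: int = 10, chain: str = "A",
                 first_res: int = 1) -> MolecularStructure:
    """Synthetic poly-ALA with N, CA, C per residue along a line."""
    rows = []
    for i in range(n_res):
        z = 3.8 * i
        rows.append((chain, first_res + i, "ALA", "N", "N", (0.0, -0.8, z - 1.2)))
        rows.append((chain, first_res + i, "ALA", "CA", "C", (0.3 * (i % 2), 0.0, z)))
        rows.append((chain, first_res + i, "ALA", "C", "C", (0.0, 0.9, z + 1.1)))
    return MolecularStructure(
        chain_id=np.array([r[0] for r in rows]),
        res_id=np.array([r[1] for r in rows]),
        res_name=np.array([r[2] for r in rows]),
        atom_name=np.array([r[3] for r in rows]),
        element=np.array([r[4] for r in rows]),
        coord=np.array([r[5] for r in rows]),
    )


def make_nucleotide(chain: str = "R", res: int = 1,
                    with_p: bool = True) -> MolecularStructure:
    rows = []
    if with_p:
        rows.append((chain, res, "A", "P", "P", (0.0, 0.0, 0.0)))
    rows.append((chain, res, "A", "C4'", "C", (2.0, 1.0, 0.5)))
    rows.append((chain, res, "A", "N3", "N", (4.5, 2.0, 1.0)))
    rows.append((chain, res, "A", "N1", "N", (5.5, 3.0, 1.5)))
    return MolecularStructure(
        chain_id=np.array([r[0] for r in rows]),
        res_id=np.array([r[1] for r in rows]),
        res_name=np.array([r[2] for r in rows]),
        atom_name=np.array([r[3] for r in rows]),
        element=np.array([r[4] for r in rows]),
        coord=np.array([r[5] for r in rows]),
    )


def concat_structures(*structures: MolecularStructure) -> MolecularStructure:
    return MolecularStructure(
        chain_id=np.concatenate([s.chain_id for s in structures]),
        res_id=np.concatenate([s.res_id for s in structures]),
        res_name=np.concatenate([s.res_name for s in structures]),
        atom_name=np.concatenate([s.atom_name for s in structures]),
        element=np.concatenate([s.element for s in structures]),
        coord=np.concatenate([s.coord for s in structures]),
    )
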