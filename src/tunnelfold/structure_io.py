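"""Structure input/output and coarse-graining.

Reads PDB/mmCIF files into a light columnar container, coarse-grains proteins
to one bead per residue at the C-alpha position and RNA to three beads per
nucleotide (phosphate P, sugar C4', base N3), and applies the loop deletions
that model uL23/uL24 delta-loop ribosome variants by removing coordinates.

Residue numbering follows the source file's author numbering; deletion ranges
are 1-based and inclusive, e.g. ``LoopDeletion("L", 65, 74)`` removes residues
65..74 of chain L. Altloc conflicts resolve to the highest-occupancy conformer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MolecularStructure",
    "BeadModel",
    "LoopDeletion",
    "StructureFormatError",
    "LOOP_PRESETS",
    "read_structure",
    "write_structure",
    "coarse_grain",
    "apply_loop_deletion",
    "truncate_scaffold",
    "write_bead_model_tsv",
    "read_bead_model_tsv",
    "write_bead_model_pdb",
]

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
NUCLEOTIDES = {"A", "C", "G", "U", "DA", "DC", "DG", "DT", "I"}

#: default excluded-volume radii per bead kind (angstrom); the underlying
#: experiments do not constrain these, so they are plain defaults
DEFAULT_BEAD_RADII = {"CA": 2.0, "P": 2.5, "C4p": 2.5, "N3": 2.5}

#: published loop-deletion ranges for the two ribosome variants. The strain
#: constructions and the volume calculations use slightly different ranges;
#: both are available as presets.
LOOP_PRESETS = {
    "uL23_strain": ("uL23", 65, 74),
    "uL23_volume": ("uL23", 65, 75),
    "uL24_strain": ("uL24", 43, 57),
    "uL24_volume": ("uL24", 42, 57),
}


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed in the named format."""


@dataclass
class MolecularStructure:
    """Columnar all-atom structure: parallel arrays, one entry per atom."""

    chain_id: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coord: np.ndarray
    model_id: int = 1

    def __post_init__(self) -> None:
        self.chain_id = np.asarray(self.chain_id, dtype="U4")
        self.res_id = np.asarray(self.res_id, dtype=np.int64)
        self.res_name = np.asarray(self.res_name, dtype="U5")
        self.atom_name = np.asarray(self.atom_name, dtype="U6")
        self.element = np.asarray(self.element, dtype="U2")
        self.coord = np.asarray(self.coord, dtype=np.float64).reshape(-1, 3)
        n = len(self.coord)
        for arr in (self.chain_id, self.res_id, self.res_name,
                    self.atom_name, self.element):
            if len(arr) != n:
                raise ValueError("column lengths disagree")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.coord)

    def subset(self, mask: np.ndarray) -> "MolecularStructure":
        return MolecularStructure(
            self.chain_id[mask], self.res_id[mask], self.res_name[mask],
            self.atom_name[mask], self.element[mask], self.coord[mask],
            self.model_id,
        )

    def chains(self) -> list[str]:
        return list(dict.fromkeys(self.chain_id.tolist()))

    def atom_coord(self, chain: str, res: int, atom: str) -> np.ndarray:
        """Coordinate of one named atom; raises KeyError if absent."""
        m = (self.chain_id == chain) & (self.res_id == res) & (self.atom_name == atom)
        idx = np.flatnonzero(m)
        if len(idx) == 0:
            raise KeyError(f"atom {atom} of {chain}:{res} not found")
        return self.coord[idx[0]].copy()


@dataclass
class BeadModel:
    """Coarse-grained particle set with provenance to source residues."""

    kind: np.ndarray       # CA | P | C4p | N3
    chain_id: np.ndarray
    res_id: np.ndarray
    coord: np.ndarray
    radius: np.ndarray

    def __post_init__(self) -> None:
        self.kind = np.asarray(self.kind, dtype="U3")
        self.chain_id = np.asarray(self.chain_id, dtype="U4")
        self.res_id = np.asarray(self.res_id, dtype=np.int64)
        self.coord = np.asarray(self.coord, dtype=np.float64).reshape(-1, 3)
        self.radius = np.asarray(self.radius, dtype=np.float64)
        if np.any(self.radius <= 0):
            raise ValueError("bead radii must be positive")

    @property
    def n_beads(self) -> int:
        return len(self.coord)

    def subset(self, mask: np.ndarray) -> "BeadModel":
        return BeadModel(self.kind[mask], self.chain_id[mask],
                         self.res_id[mask], self.coord[mask], self.radius[mask])


@dataclass(frozen=True)
class LoopDeletion:
    """Inclusive residue range to remove from one chain."""

    chain_id: str
    first: int
    last: int

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ValueError("deletion range reversed (first > last)")


def _guess_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suf = path.suffix.lower()
    if suf in (".cif", ".mmcif", ".pdbx"):
        return "mmcif"
    return "pdb"


def read_structure(path: str | Path, fmt: str | None = None,
                   model: int = 1) -> MolecularStructure:
    """Read a PDB or mmCIF file.

    Altlocs resolve to the highest-occupancy conformer; all ATOM/HETATM
    records with coordinates are kept. ``fmt`` is inferred from the file
    extension when omitted.
    """
    import biotite.structure.io.pdb as bio_pdb
    import biotite.structure.io.pdbx as bio_pdbx

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _guess_format(path, fmt)
    try:
        if fmt == "pdb":
            f = bio_pdb.PDBFile.read(str(path))
            atoms = f.get_structure(model=model, altloc="occupancy")
        elif fmt == "mmcif":
            f = bio_pdbx.CIFFile.read(str(path))
            atoms = bio_pdbx.get_structure(f, model=model, altloc="occupancy")
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except ValueError:
        raise
    except Exception as exc:  # biotite raises assorted parse errors
        raise StructureFormatError(
            f"cannot parse {path} as {fmt}: {exc}") from exc
    if atoms.array_length() == 0:
        raise StructureFormatError(f"{path}: no atoms in model {model}")
    return MolecularStructure(
        chain_id=atoms.chain_id,
        res_id=atoms.res_id,
        res_name=atoms.res_name,
        atom_name=atoms.atom_name,
        element=atoms.element,
        coord=atoms.coord,
        model_id=model,
    )


def write_structure(structure: MolecularStructure, path: str | Path,
                    fmt: str | None = None) -> None:
    """Write a structure as PDB or mmCIF (format inferred from extension)."""
    import biotite.structure as bio_struct
    import biotite.structure.io.pdb as bio_pdb
    import biotite.structure.io.pdbx as bio_pdbx

    path = Path(path)
    fmt = _guess_format(path, fmt)
    n = structure.n_atoms
    atoms = bio_struct.AtomArray(n)
    atoms.chain_id = structure.chain_id
    atoms.res_id = structure.res_id
    atoms.res_name = structure.res_name
    atoms.atom_name = structure.atom_name
    atoms.element = structure.element
    atoms.coord = structure.coord
    if fmt == "pdb":
        f = bio_pdb.PDBFile()
        f.set_structure(atoms)
        f.write(str(path))
    elif fmt == "mmcif":
        f = bio_pdbx.CIFFile()
        bio_pdbx.set_structure(f, atoms)
        f.write(str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _residue_class(res_name: str, atom_names: set[str]) -> str:
    if res_name in AMINO_ACIDS or "CA" in atom_names and res_name not in NUCLEOTIDES:
        return "protein"
    if res_name in NUCLEOTIDES or {"C4'", "P", "N3"} & atom_names:
        return "rna"
    return "other"


def coarse_grain(structure: MolecularStructure, scheme: str = "auto",
                 radii: dict[str, float] | None = None) -> BeadModel:
    """Coarse-grain to the one-bead-per-amino-acid / three-bead-per-nucleotide
    representation.

    Protein residues yield one ``CA`` bead at the C-alpha position; RNA
    residues up to three beads at the P, C4' and N3 atom positions. Bead
    positions coincide exactly with the source atoms. Residues missing an
    anchor atom contribute the beads that exist (a warning is emitted for a
    protein residue without C-alpha or an RNA residue missing any anchor).
    """
    if scheme not in ("auto", "protein-CA", "rna-3bead"):
        raise ValueError(f"unknown scheme {scheme!r}")
    radii = {**DEFAULT_BEAD_RADII, **(radii or {})}
    kinds, chains, resids, coords, rads = [], [], [], [], []
    # group by (chain, res_id) preserving file order
    keys = list(zip(structure.chain_id.tolist(), structure.res_id.tolist()))
    order: dict[tuple[str, int], list[int]] = {}
    for i, key in enumerate(keys):
        order.setdefault(key, []).append(i)
    rna_anchor_atoms = {"P": "P", "C4'": "C4p", "N3": "N3"}
    for (chain, res), idxs in order.items():
        res_name = structure.res_name[idxs[0]]
        atom_names = {structure.atom_name[i] for i in idxs}
        cls = _residue_class(res_name, atom_names)
        if cls == "protein" and scheme in ("auto", "protein-CA"):
            hit = [i for i in idxs if structure.atom_name[i] == "CA"]
            if not hit:
                warnings.warn(
                    f"protein residue {chain}:{res} ({res_name}) lacks CA; skipped")
                continue
            kinds.append("CA")
            chains.append(chain)
            resids.append(res)
            coords.append(structure.coord[hit[0]])
            rads.append(radii["CA"])
        elif cls == "rna" and scheme in ("auto", "rna-3bead"):
            found = 0
            for atom, kind in rna_anchor_atoms.items():
                hit = [i for i in idxs if structure.atom_name[i] == atom]
                if hit:
                    kinds.append(kind)
                    chains.append(chain)
                    resids.append(res)
                    coords.append(structure.coord[hit[0]])
                    rads.append(radii[kind])
                    found += 1
            if found < 3:
                warnings.warn(
                    f"RNA residue {chain}:{res} has only {found}/3 anchor atoms")
        elif cls == "other":
            continue
    if not kinds:
        raise ValueError("no residues classifiable under the requested scheme")
    return BeadModel(np.array(kinds), np.array(chains), np.array(resids),
                     np.array(coords), np.array(rads))


def apply_loop_deletion(model, deletions):
    """Remove every particle whose (chain, residue) lies in a deletion range.

    Works identically on :class:`MolecularStructure` and :class:`BeadModel`.
    A range that overlaps no residue of its chain raises ``ValueError`` (the
    likeliest cause is a numbering mistake).
    """
    deletions = list(deletions)
    if not deletions:
        return model
    keep = np.ones(len(model.coord), dtype=bool)
    for d in deletions:
        if not isinstance(d, LoopDeletion):
            d = LoopDeletion(*d)
        if d.chain_id not in set(model.chain_id.tolist()):
            raise ValueError(f"deletion chain {d.chain_id!r} not in structure")
        hit = ((model.chain_id == d.chain_id)
               & (model.res_id >= d.first) & (model.res_id <= d.last))
        if not hit.any():
            raise ValueError(
                f"deletion {d.chain_id}:{d.first}-{d.last} overlaps no residue"
                " (check numbering)")
        keep &= ~hit
    return model.subset(keep)


def _dist_to_segment(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def truncate_scaffold(model: BeadModel, axis: tuple, radius: float) -> BeadModel:
    """Keep only beads within ``radius`` of the axis line segment.

    Used to cut a full large-subunit bead model down to the tunnel-lining
    shell actually needed for nascent-chain simulations.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    a = np.asarray(axis[0], dtype=float)
    b = np.asarray(axis[1], dtype=float)
    d = _dist_to_segment(model.coord, a, b)
    mask = d <= radius
    if not mask.any():
        warnings.warn("truncate_scaffold: no beads within radius; empty scaffold")
    return model.subset(mask)


def write_bead_model_tsv(model: BeadModel, path: str | Path) -> None:
    df = pd.DataFrame({
        "chain": model.chain_id, "residue": model.res_id, "kind": model.kind,
        "x": model.coord[:, 0], "y": model.coord[:, 1], "z": model.coord[:, 2],
        "radius": model.radius,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_bead_model_tsv(path: str | Path) -> BeadModel:
    df = pd.read_csv(path, sep="\t")
    return BeadModel(df["kind"].to_numpy(dtype="U3"),
                     df["chain"].to_numpy(dtype="U4"),
                     df["residue"].to_numpy(),
                     df[["x", "y", "z"]].to_numpy(dtype=float),
                     df["radius"].to_numpy(dtype=float))


def write_conformations_pdb(conformations, path: str | Path,
                            chain: str = "A") -> None:
    """Write a sequence of bead conformations as a multi-model PDB (one
    pseudo-atom per bead), e.g. trajectory snapshots for visualization."""
    with open(path, "w") as fh:
        for m, coords in enumerate(conformations, start=1):
            coords = np.asarray(coords, dtype=float).reshape(-1, 3)
            fh.write(f"MODEL     {m:4d}\n")
            for k, (x, y, z) in enumerate(coords, start=1):
                fh.write(f"ATOM  {k % 100000:5d}  CA  GLY {chain}"
                         f"{k % 10000:4d}    "
                         f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_bead_model_pdb(model: BeadModel, path: str | Path) -> None:
    """Write beads as pseudo-atoms (bead kind in the atom-name field)."""
    import biotite.structure as bio_struct
    import biotite.structure.io.pdb as bio_pdb

    n = model.n_beads
    atoms = bio_struct.AtomArray(n)
    atoms.chain_id = np.array([c[:4] for c in model.chain_id], dtype="U4")
    atoms.res_id = model.res_id
    atoms.res_name = np.where(model.kind == "CA", "GLY", "RNA")
    atoms.atom_name = model.kind
    atoms.element = np.where(model.kind == "P", "P", "C")
    atoms.coord = model.coord
    f = bio_pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))
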