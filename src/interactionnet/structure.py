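"""Heavy-atom complex representation and structure file readers.

A protein-ligand complex is held as a flat, ligand-first list of heavy atoms
plus an intramolecular bond list.  Ligand-first ordering makes the
ligand/protein block layout of the adjacency matrices positional: rows
``0..n_ligand-1`` are ligand atoms, the rest protein atoms.

Hydrogens are removed on loading; waters, monoatomic ions and alternate
location B records are dropped.  Ligand connectivity comes from the SDF/MOL2
connection table; protein connectivity from RDKit's PDB reader (amino-acid
templates with a distance fallback for nonstandard residues).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform


class LoadError(Exception):
    """A structure file could not be parsed."""


class EmptyStructureError(Exception):
    """A parsed molecule contained no heavy atoms."""


class IndexFormatError(Exception):
    """An affinity index line could not be parsed."""


#: residue names treated as solvent and dropped on loading
WATER_RESIDUES = {"HOH", "WAT", "DOD", "H2O", "SOL"}

#: elements dropped when they appear as unbonded monoatomic HETATM records
ION_ELEMENTS = {
    "Na", "K", "Li", "Rb", "Cs", "Mg", "Ca", "Sr", "Ba", "Zn", "Mn", "Fe",
    "Co", "Ni", "Cu", "Cd", "Hg", "Cl", "Br", "I", "F",
}


@dataclass
class Atom:
    """One heavy atom of a complex.

    ``role`` is ``"ligand"`` or ``"protein"``; residue fields are only
    meaningful for protein atoms.  The chemistry annotations (aromaticity,
    formal charge, hybridization, ring membership) are captured at load time
    from the source file's perception and feed the feature matrix.
    """

    index: int
    element: str
    coords: np.ndarray
    role: str
    residue_name: str = ""
    residue_number: int = 0
    aromatic: bool = False
    formal_charge: int = 0
    hybridization: str = "SP3"
    in_ring: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.index}: coords must be a finite 3-vector")
        if self.element == "H":
            raise ValueError("hydrogens are not allowed in a prepared structure")
        if self.role not in ("ligand", "protein"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class ComplexStructure:
    """A prepared protein-ligand complex (heavy atoms, ligand-first).

    ``bonds`` are unordered atom-index pairs; no bond may span the
    ligand/protein boundary (complexes are assumed noncovalent).
    ``label`` is the binding affinity as pKd = -log10 Kd, or None.
    """

    complex_id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int]]
    label: float | None = None

    def __post_init__(self) -> None:
        indices = [a.index for a in self.atoms]
        if indices != list(range(len(self.atoms))):
            raise ValueError("atom indices must be 0-based and contiguous")
        roles = [a.role for a in self.atoms]
        if self.n_ligand < 1 or self.n_protein < 1:
            raise EmptyStructureError(
                f"{self.complex_id}: need >=1 ligand and >=1 protein atom"
            )
        if roles != ["ligand"] * self.n_ligand + ["protein"] * self.n_protein:
            raise ValueError("atoms must be ordered ligand-first")
        norm = []
        for i, j in self.bonds:
            if i == j or not (0 <= i < len(self.atoms)) or not (0 <= j < len(self.atoms)):
                raise ValueError(f"invalid bond ({i},{j})")
            if (roles[i] == "ligand") != (roles[j] == "ligand"):
                raise ValueError(f"bond ({i},{j}) spans ligand and protein")
            norm.append((min(i, j), max(i, j)))
        if len(set(norm)) != len(norm):
            raise ValueError("duplicate bonds")
        self.bonds = norm

    @property
    def n_ligand(self) -> int:
        return sum(1 for a in self.atoms if a.role == "ligand")

    @property
    def n_protein(self) -> int:
        return len(self.atoms) - self.n_ligand

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in atom order."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "complex_id": self.complex_id,
            "label": self.label,
            "bonds": [list(b) for b in self.bonds],
            "atoms": [],
        }
        for a in self.atoms:
            ad = asdict(a)
            ad["coords"] = [float(x) for x in a.coords]
            d["atoms"].append(ad)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ComplexStructure":
        atoms = [Atom(**ad) for ad in d["atoms"]]
        bonds = [tuple(b) for b in d["bonds"]]
        return cls(d["complex_id"], atoms, bonds, d.get("label"))

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load_json(cls, path: str | Path) -> "ComplexStructure":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SanityVerdict:
    """Result of the geometric sanity filter."""

    passed: bool
    reasons: list[tuple[int, int, float]] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def sanity_check(c: ComplexStructure, min_distance: float = 1.0) -> SanityVerdict:
    """Flag chemically abnormal geometry.

    Fails iff any pair of distinct atoms lies strictly below ``min_distance``
    (default 1 A) or two atoms coincide (an atomic collision; distance 0 is
    below any positive threshold, so collisions are a subset).  Reasons list
    the offending pairs as (i, j, distance).
    """
    if len(c.atoms) < 2:
        raise ValueError("sanity_check needs >= 2 atoms")
    d = squareform(pdist(c.coords))
    iu = np.triu_indices(len(c.atoms), k=1)
    bad = d[iu] < min_distance
    reasons = [
        (int(i), int(j), float(d[i, j]))
        for i, j in zip(iu[0][bad], iu[1][bad])
    ]
    return SanityVerdict(passed=not reasons, reasons=reasons)


# ---- RDKit-backed file loading ------------------------------------------


def _mol_atoms(mol, role: str, start_index: int) -> list[Atom]:
    atoms = []
    conf = mol.GetConformer()
    for i, a in enumerate(mol.GetAtoms()):
        if a.GetAtomicNum() == 1:
            raise ValueError("hydrogen survived preparation")
        ri = a.GetPDBResidueInfo()
        pos = conf.GetAtomPosition(i)
        atoms.append(
            Atom(
                index=start_index + i,
                element=a.GetSymbol(),
                coords=np.array([pos.x, pos.y, pos.z]),
                role=role,
                residue_name=(ri.GetResidueName().strip() if ri else ""),
                residue_number=(ri.GetResidueNumber() if ri else 0),
                aromatic=a.GetIsAromatic(),
                formal_charge=a.GetFormalCharge(),
                hybridization=str(a.GetHybridization()),
                in_ring=a.IsInRing(),
            )
        )
    return atoms


def _strip_to_heavy(mol, drop_solvent: bool):
    """Return an editable copy with H, waters, ions and altLoc B removed."""
    from rdkit import Chem

    rw = Chem.RWMol(mol)
    doomed = []
    for a in rw.GetAtoms():
        if a.GetAtomicNum() == 1:
            doomed.append(a.GetIdx())
            continue
        if not drop_solvent:
            continue
        ri = a.GetPDBResidueInfo()
        if ri is None:
            continue
        if ri.GetResidueName().strip().upper() in WATER_RESIDUES:
            doomed.append(a.GetIdx())
        elif ri.GetAltLoc().strip() not in ("", "A"):
            doomed.append(a.GetIdx())
        elif (
            ri.GetIsHeteroAtom()
            and a.GetDegree() == 0
            and a.GetSymbol() in ION_ELEMENTS
        ):
            doomed.append(a.GetIdx())
    for idx in sorted(set(doomed), reverse=True):
        rw.RemoveAtom(idx)
    return rw.GetMol()


def _load_ligand_mol(ligand_file: str | Path):
    from rdkit import Chem

    path = Path(ligand_file)
    if not path.exists():
        raise LoadError(f"ligand file not found: {path}")
    suffix = path.suffix.lower()
    mol = None
    if suffix == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        mol = next(iter(supplier), None)
    elif suffix == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=False)
    else:
        raise LoadError(f"unsupported ligand format {suffix!r}: {path}")
    if mol is None:
        raise LoadError(f"failed to parse ligand file: {path}")
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        # fall back to partial sanitization: keep connection table as given
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
            ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES,
            catchErrors=True,
        )
    return _strip_to_heavy(mol, drop_solvent=False)


def _load_protein_mol(protein_file: str | Path):
    from rdkit import Chem

    path = Path(protein_file)
    if not path.exists():
        raise LoadError(f"protein file not found: {path}")
    mol = Chem.MolFromPDBFile(str(path), removeHs=True, sanitize=False)
    if mol is None:
        raise LoadError(f"failed to parse protein file: {path}")
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_ALL, catchErrors=True)
    return _strip_to_heavy(mol, drop_solvent=True)


def load_complex(
    protein_file: str | Path,
    ligand_file: str | Path,
    complex_id: str,
    label: float | None = None,
) -> ComplexStructure:
    """Read a PDB protein plus an SDF/MOL2 ligand into one heavy-atom complex.

    Hydrogens, waters, unbonded monoatomic ions and altLoc-B records are
    removed.  Ligand atoms come first; bonds are taken from the ligand
    connection table and from the PDB reader's residue templates (distance
    fallback for nonstandard residues).  No ligand-protein bonds are created.
    """
    lig = _load_ligand_mol(ligand_file)
    prot = _load_protein_mol(protein_file)
    if lig.GetNumAtoms() == 0:
        raise EmptyStructureError(f"{complex_id}: ligand has no heavy atoms")
    if prot.GetNumAtoms() == 0:
        raise EmptyStructureError(f"{complex_id}: protein has no heavy atoms")

    atoms = _mol_atoms(lig, "ligand", 0)
    n_lig = len(atoms)
    atoms += _mol_atoms(prot, "protein", n_lig)

    bonds: list[tuple[int, int]] = []
    for b in lig.GetBonds():
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
    for b in prot.GetBonds():
        bonds.append((n_lig + b.GetBeginAtomIdx(), n_lig + b.GetEndAtomIdx()))

    return ComplexStructure(complex_id, atoms, bonds, label)


def read_affinity_index(index_file: str | Path) -> dict[str, float]:
    """Parse a PDBbind-style index file into {complex_id: pKd}.

    Expected dialect: whitespace-delimited records with the complex code in
    column 1 and -log(Kd/Ki) in column 4; lines starting with ``#`` are
    comments.  IDs are lower-cased.
    """
    out: dict[str, float] = {}
    for lineno, line in enumerate(Path(index_file).read_text().splitlines(), 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) < 4:
            raise IndexFormatError(
                f"{index_file}: line {lineno}: expected >= 4 columns"
            )
        try:
            value = float(fields[3])
        except ValueError as exc:
            raise IndexFormatError(
                f"{index_file}: line {lineno}: affinity column "
                f"{fields[3]!r} is not numeric"
            ) from exc
        out[fields[0].lower()] = value
    return out


def write_pdb(
    c: ComplexStructure,
    path: str | Path,
    bfactors: np.ndarray | None = None,
) -> None:
    """Write the complex as a PDB file, optionally with per-atom B-factors.

    Ligand atoms become HETATM records (residue LIG); protein atoms keep
    their residue names/numbers.  ``bfactors`` (length N) lands in the
    B-factor column, e.g. LRP contributions for heat-map rendering.
    """
    if bfactors is not None and len(bfactors) != len(c.atoms):
        raise ValueError("bfactors length must equal atom count")
    lines = []
    for a in c.atoms:
        record = "HETATM" if a.role == "ligand" else "ATOM  "
        resname = "LIG" if a.role == "ligand" else (a.residue_name or "UNK")[:3]
        resnum = 0 if a.role == "ligand" else a.residue_number
        b = 0.0 if bfactors is None else float(bfactors[a.index])
        name = f"{a.element}{a.index % 100}"[:4]
        x, y, z = a.coords
        lines.append(
            f"{record}{a.index + 1:>5} {name:<4} {resname:<3} A{resnum:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}          "
            f"{a.element:>2}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def min_ligand_distances(c: ComplexStructure) -> np.ndarray:
    """For each protein atom, its minimum distance to any ligand atom."""
    xyz = c.coords
    return cdist(xyz[c.n_ligand:], xyz[: c.n_ligand]).min(axis=1)
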