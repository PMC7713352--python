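"""Seeded toy protein-ligand complexes with planted interactions.

The generator builds a linear "ligand" chain (carbons with oxygens at every
fourth position) and a "protein" made of short bonded chains (3-5 atoms):

* planted hydrogen bonds -- a protein N/O placed 2.8-3.2 A from a ligand
  oxygen, the rest of its residue chain pointing away from the ligand;
* planted hydrophobic contacts -- a protein carbon (no polar neighbors)
  placed 3.75-3.9 A from an apolar ligand carbon;
* shell residues -- chains at >= the shell radius (default 5.5-8 A) from
  every ligand atom, carrying no interactions.

Geometry is constructed so that, under the default interaction rules,
detected interactions equal planted interactions exactly, every pairwise
distance is >= 1.2 A (the sanity filter passes), and non-bonded atoms are
far enough apart (>= 2.3 A) that distance-based bond perception on the
exported PDB recovers exactly the intended bonds.

Labels follow ``pKd = alpha * n_contacts + beta + Normal(0, noise_sd)`` with
defaults alpha = 0.5, beta = 4.0, noise_sd = 0.3, spanning a realistic
4-9 pKd range.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .interactions import (
    Contact,
    InteractionProfile,
    InteractionRules,
    profile_interactions,
)
from .structure import Atom, ComplexStructure

LIGAND_SPACING = 1.5
CHAIN_SPACING = 1.5
MIN_NONBONDED = 2.3
MIN_SHELL_LIGAND_DIST = 4.5   # hard floor from the generator contract


class GenerationError(Exception):
    """The requested toy complex is geometrically infeasible."""


@dataclass(frozen=True)
class ToySpec:
    """Parameters of one toy complex."""

    seed: int = 0
    n_ligand_atoms: int = 12
    n_protein_atoms: int = 40
    n_planted_hbonds: int = 2
    n_planted_hydrophobic: int = 1
    shell_radius: tuple[float, float] = (5.5, 8.0)
    noise_sd: float = 0.3
    alpha: float = 0.5
    beta: float = 4.0

    def __post_init__(self) -> None:
        if self.n_ligand_atoms < 2:
            raise GenerationError("ligand needs >= 2 atoms")
        if self.shell_radius[0] < MIN_SHELL_LIGAND_DIST:
            raise GenerationError(
                f"shell radius must start >= {MIN_SHELL_LIGAND_DIST} A"
            )
        if self.n_planted_hbonds < 0 or self.n_planted_hydrophobic < 0:
            raise GenerationError("planted counts must be nonnegative")
        if self.n_planted_hbonds > len(self.hbond_sites()):
            raise GenerationError("too many hydrogen bonds for this ligand size")
        if self.n_planted_hydrophobic > len(self.hydrophobic_sites()):
            raise GenerationError("too many hydrophobic contacts for this ligand")
        needed = 3 * (self.n_planted_hbonds + self.n_planted_hydrophobic)
        if self.n_protein_atoms < max(needed, 1):
            raise GenerationError(
                f"need >= {max(needed, 1)} protein atoms for the planted contacts"
            )

    def hbond_sites(self) -> list[int]:
        """Candidate ligand oxygen positions (every fourth chain index)."""
        return list(range(0, self.n_ligand_atoms, 4))

    def hydrophobic_sites(self) -> list[int]:
        """Apolar ligand carbons whose chain neighbors are all polar carbons."""
        return [i for i in range(2, self.n_ligand_atoms - 1, 4)]

    @property
    def n_contacts(self) -> int:
        return self.n_planted_hbonds + self.n_planted_hydrophobic


def _jittered_direction(rng: np.random.Generator, sign: float) -> np.ndarray:
    u = np.array([rng.uniform(-0.2, 0.2), sign, rng.uniform(-0.2, 0.2)])
    return u / np.linalg.norm(u)


def make_toy_complex(
    spec: ToySpec, label: float | None = None
) -> tuple[ComplexStructure, InteractionProfile]:
    """Generate one toy complex and its planted interaction profile.

    Deterministic for a fixed spec.  If ``label`` is None the noiseless
    label ``alpha * n_contacts + beta`` is attached.
    """
    rng = np.random.default_rng(spec.seed)
    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []

    # --- ligand: bonded chain along x; an oxygen sits at each *engaged*
    # hydrogen-bond site, so ligand composition reflects the planted
    # chemistry (as a real binder's does) rather than being constant
    oxygens = set(spec.hbond_sites()[: spec.n_planted_hbonds])
    for i in range(spec.n_ligand_atoms):
        atoms.append(
            Atom(
                index=i,
                element="O" if i in oxygens else "C",
                coords=np.array([i * LIGAND_SPACING, 0.0, 0.0]),
                role="ligand",
            )
        )
        if i:
            bonds.append((i - 1, i))
    lig_xyz = np.array([a.coords for a in atoms])
    lig_elem = [a.element for a in atoms]
    lig_polar = np.array([e in ("N", "O") for e in lig_elem])
    neighbor_elems = [set() for _ in range(spec.n_ligand_atoms)]
    for i, j in bonds:
        neighbor_elems[i].add(lig_elem[j])
        neighbor_elems[j].add(lig_elem[i])
    lig_apolar = np.array(
        [
            e == "C" and not (neighbor_elems[i] & {"N", "O"})
            for i, e in enumerate(lig_elem)
        ]
    )

    placed: list[np.ndarray] = []          # protein coordinates placed so far
    protein: list[tuple[str, np.ndarray, str, int]] = []  # element, xyz, resname, resnum
    protein_bonds: list[tuple[int, int]] = []            # protein-local indices
    planted_hb: list[tuple[int, int]] = []               # (ligand idx, protein-local idx)
    planted_ph: list[tuple[int, int]] = []
    resnum = 0

    def add_residue(
        elements: list[str], positions: list[np.ndarray], resname: str
    ) -> int:
        nonlocal resnum
        resnum += 1
        start = len(protein)
        for k, (e, xyz) in enumerate(zip(elements, positions)):
            protein.append((e, xyz, resname, resnum))
            placed.append(xyz)
            if k:
                protein_bonds.append((start + k - 1, start + k))
        return start

    def clash(xyz: np.ndarray, min_protein: float = MIN_NONBONDED) -> bool:
        if placed and min(np.linalg.norm(xyz - q) for q in placed) < min_protein:
            return True
        return False

    # --- planted hydrogen-bond residues (N/O anchor + 2 C tail) --------
    for k in range(spec.n_planted_hbonds):
        site = spec.hbond_sites()[k]
        # the first planted bond sits in the lower half of the window so a
        # 3 A crop always retains at least one protein atom
        d = rng.uniform(2.8, 3.0) if k == 0 else rng.uniform(2.8, 3.2)
        for _ in range(200):
            u = _jittered_direction(rng, +1.0)
            anchor = lig_xyz[site] + d * u
            tail = [anchor + CHAIN_SPACING * (t + 1) * u for t in range(2)]
            if any(clash(x) for x in [anchor] + tail):
                continue
            # the anchor must bond only to its own site: stay outside the
            # donor-acceptor window of every other polar ligand atom
            others = lig_polar.copy()
            others[site] = False
            if others.any() and (
                np.linalg.norm(lig_xyz[others] - anchor, axis=1).min() <= 3.55
            ):
                continue
            break
        else:
            raise GenerationError("could not place a hydrogen-bond residue")
        start = add_residue(["N", "C", "C"], [anchor] + tail, "HBR")
        planted_hb.append((site, start))

    # --- planted hydrophobic residues (3 apolar carbons) ----------------
    for k in range(spec.n_planted_hydrophobic):
        site = spec.hydrophobic_sites()[k]
        d = rng.uniform(3.75, 3.9)
        for _ in range(200):
            # jitter only perpendicular to the chain axis: the distance to
            # the neighboring apolar carbons is then sqrt(1.5^2 + d^2),
            # which clears the 4.0 A contact threshold for any d >= 3.75
            u = np.array([0.0, -1.0, rng.uniform(-0.25, 0.25)])
            u /= np.linalg.norm(u)
            anchor = lig_xyz[site] + d * u
            tail = [anchor + CHAIN_SPACING * (t + 1) * u for t in range(2)]
            if any(clash(x) for x in [anchor] + tail):
                continue
            # contact only the intended site: keep every other apolar
            # ligand carbon beyond the contact threshold
            others = lig_apolar.copy()
            others[site] = False
            if others.any() and (
                np.linalg.norm(lig_xyz[others] - anchor, axis=1).min() <= 4.01
            ):
                continue
            break
        else:
            raise GenerationError("could not place a hydrophobic residue")
        start = add_residue(["C", "C", "C"], [anchor] + tail, "HPR")
        planted_ph.append((site, start))

    # --- inert shell residues -------------------------------------------
    budget = spec.n_protein_atoms - len(protein)
    while budget > 0:
        length = int(min(budget, rng.integers(3, 6)))
        if budget - length in (1, 2):
            length = budget          # avoid a leftover chain shorter than 3
        for _ in range(500):
            base_atom = lig_xyz[rng.integers(spec.n_ligand_atoms)]
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = rng.uniform(*spec.shell_radius)
            base = base_atom + r * u
            # grow away from the nearest ligand atom
            nearest = lig_xyz[np.argmin(np.linalg.norm(lig_xyz - base, axis=1))]
            w = base - nearest
            w /= np.linalg.norm(w)
            chain = [base + CHAIN_SPACING * t * w for t in range(length)]
            if all(
                np.linalg.norm(lig_xyz - x, axis=1).min() >= spec.shell_radius[0]
                and not clash(x)
                for x in chain
            ):
                break
        else:
            raise GenerationError("could not place a shell residue")
        elements = [str(rng.choice(["C", "C", "C", "N", "O"])) for _ in chain]
        add_residue(elements, chain, "SHL")
        budget -= length

    # --- assemble --------------------------------------------------------
    n_lig = spec.n_ligand_atoms
    for local, (e, xyz, resname, num) in enumerate(protein):
        atoms.append(
            Atom(
                index=n_lig + local,
                element=e,
                coords=xyz,
                role="protein",
                residue_name=resname,
                residue_number=num,
            )
        )
    bonds += [(n_lig + i, n_lig + j) for i, j in protein_bonds]

    if label is None:
        label = spec.alpha * spec.n_contacts + spec.beta
    structure = ComplexStructure(
        f"toy{spec.seed:06d}", atoms, bonds, label=label
    )

    def tag(local: int) -> str:
        _, _, resname, num = protein[local]
        return f"{resname}{num}"

    def dist(li: int, local: int) -> float:
        return float(np.linalg.norm(lig_xyz[li] - protein[local][1]))

    profile = InteractionProfile(
        complex_id=structure.complex_id,
        hbonds=[
            Contact(li, n_lig + lo, tag(lo), dist(li, lo)) for li, lo in planted_hb
        ],
        hydrophobic=[
            Contact(li, n_lig + lo, tag(lo), dist(li, lo)) for li, lo in planted_ph
        ],
    )
    _verify(structure, profile)
    return structure, profile


def _verify(structure: ComplexStructure, planted: InteractionProfile) -> None:
    """Planted geometry must be exactly what the default rules detect."""
    detected = profile_interactions(structure, InteractionRules())
    det_hb = {(c.ligand_atom, c.protein_atom) for c in detected.hbonds}
    det_ph = {(c.ligand_atom, c.protein_atom) for c in detected.hydrophobic}
    want_hb = {(c.ligand_atom, c.protein_atom) for c in planted.hbonds}
    want_ph = {(c.ligand_atom, c.protein_atom) for c in planted.hydrophobic}
    if det_hb != want_hb or det_ph != want_ph:
        raise GenerationError(
            f"{structure.complex_id}: detected interactions differ from planted "
            f"(hbonds {det_hb} vs {want_hb}; hydrophobic {det_ph} vs {want_ph})"
        )


def make_synthetic_dataset(
    n: int,
    base_spec: ToySpec | None = None,
    seed: int = 0,
    max_hbonds: int = 3,
    max_hydrophobic: int = 2,
    ligand_size_range: tuple[int, int] | None = (9, 15),
) -> list[tuple[ComplexStructure, InteractionProfile]]:
    """A labeled dataset of toy complexes with varying planted counts.

    Labels follow the generator's rule ``alpha * n_contacts + beta + noise``
    exactly.  Each complex draws its own seed from the dataset seed.
    Ligand size varies across complexes (default 9-15 atoms, as real
    ligands vary); pass ``ligand_size_range=None`` to keep the base spec's
    size everywhere.
    """
    if n < 1:
        raise GenerationError("dataset size must be >= 1")
    base_spec = base_spec or ToySpec()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 977]))
    out = []
    for k in range(n):
        if ligand_size_range is not None:
            n_lig = int(rng.integers(ligand_size_range[0], ligand_size_range[1] + 1))
        else:
            n_lig = base_spec.n_ligand_atoms
        probe = replace(base_spec, n_ligand_atoms=n_lig,
                        n_planted_hbonds=0, n_planted_hydrophobic=0)
        hb_cap = min(max_hbonds, len(probe.hbond_sites()))
        ph_cap = min(max_hydrophobic, len(probe.hydrophobic_sites()))
        spec = replace(
            base_spec,
            seed=int(rng.integers(2**31 - 1)),
            n_ligand_atoms=n_lig,
            n_planted_hbonds=int(rng.integers(1, hb_cap + 1)),
            n_planted_hydrophobic=int(rng.integers(0, ph_cap + 1)),
        )
        noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        label = spec.alpha * spec.n_contacts + spec.beta + noise
        structure, profile = make_toy_complex(spec, label=float(label))
        structure.complex_id = f"syn{seed:04d}_{k:04d}"
        profile.complex_id = structure.complex_id
        out.append((structure, profile))
    return out


def dataset_manifest(dataset) -> "pd.DataFrame":
    """Manifest of ids, labels and true planted counts."""
    import pandas as pd

    rows = [
        {
            "complex_id": s.complex_id,
            "label": s.label,
            "n_hbonds": len(p.hbonds),
            "n_hydrophobic": len(p.hydrophobic),
            "n_contacts": p.n_contacts,
        }
        for s, p in dataset
    ]
    return pd.DataFrame(rows)


# ---- file export (exercises the real format readers) --------------------


def write_ligand_sdf(structure: ComplexStructure, path: str | Path) -> None:
    """Export the ligand atoms/bonds as an SDF V2000 file."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    rw = Chem.RWMol()
    for a in structure.atoms[: structure.n_ligand]:
        rw.AddAtom(Chem.Atom(a.element))
    for i, j in structure.bonds:
        if i < structure.n_ligand and j < structure.n_ligand:
            rw.AddBond(i, j, Chem.BondType.SINGLE)
    conf = Chem.Conformer(structure.n_ligand)
    for a in structure.atoms[: structure.n_ligand]:
        conf.SetAtomPosition(a.index, Point3D(*map(float, a.coords)))
    mol = rw.GetMol()
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol)
    mol.SetProp("_Name", structure.complex_id)
    writer = Chem.SDWriter(str(path))
    writer.write(mol)
    writer.close()


def write_protein_pdb(structure: ComplexStructure, path: str | Path) -> None:
    """Export the protein atoms as a PDB file (bonds left to perception)."""
    lines = []
    serial = 0
    element_counts: dict[str, int] = {}
    for a in structure.atoms[structure.n_ligand :]:
        serial += 1
        element_counts[a.element] = element_counts.get(a.element, 0) + 1
        name = f"{a.element}{element_counts[a.element] % 100}"
        x, y, z = a.coords
        lines.append(
            f"ATOM  {serial:>5} {name:<4} {a.residue_name:<3} "
            f"A{a.residue_number:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_dataset(
    dataset, out_dir: str | Path
) -> "pd.DataFrame":
    """Write PDB/SDF pairs plus a manifest CSV; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s, _ in dataset:
        write_ligand_sdf(s, out / f"{s.complex_id}_ligand.sdf")
        write_protein_pdb(s, out / f"{s.complex_id}_protein.pdb")
    manifest = dataset_manifest(dataset)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
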