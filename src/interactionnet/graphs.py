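"""Pocket cropping, atom featurization and the two adjacency matrices.

A complex is represented by one feature matrix X (N x F) and two fixed,
binary, symmetric adjacency matrices over the same ligand-first node order:

* ``A_C``  -- covalent bonds, a disjoint union of the ligand and protein
  molecular graphs; the cross-molecule blocks are identically zero.
* ``A_NC`` -- candidate noncovalent interactions: every ligand-protein pair
  is connected, no within-molecule edges.

In block form (ligand rows/columns first)::

    A_C  = [[A_LL, 0   ],        A_NC = [[0, 1],
            [0,    A_PP]]                [1, 0]]

Both matrices are data, never trained.  Before graph building the protein is
cropped to the ligand neighborhood: a protein atom is kept iff its minimum
distance to any ligand atom does not exceed the range cutoff (3-6 A
typically; 5 A default).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure import Atom, ComplexStructure, min_ligand_distances


class EmptyPocketError(Exception):
    """Cropping removed every protein atom."""


DEFAULT_ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")
HYBRIDIZATIONS = ("SP", "SP2", "SP3")


@dataclass(frozen=True)
class FeatureConfig:
    """Which per-atom feature blocks to stack into X.

    Feature dimensionality F is the sum of the enabled block widths:
    element one-hot (len(vocabulary)+1 incl. "other"), degree one-hot (0-5,
    capped), aromaticity bit, ring bit, formal charge scalar, hybridization
    one-hot (SP/SP2/SP3/other), ligand/protein role bit.
    """

    element_vocabulary: tuple[str, ...] = DEFAULT_ELEMENTS
    use_degree: bool = True
    use_aromaticity: bool = True
    use_ring: bool = True
    use_formal_charge: bool = True
    use_hybridization: bool = True
    use_role: bool = True

    @property
    def n_features(self) -> int:
        f = len(self.element_vocabulary) + 1
        if self.use_degree:
            f += 6
        if self.use_aromaticity:
            f += 1
        if self.use_ring:
            f += 1
        if self.use_formal_charge:
            f += 1
        if self.use_hybridization:
            f += len(HYBRIDIZATIONS) + 1
        if self.use_role:
            f += 1
        return f

    def to_dict(self) -> dict:
        return {
            "element_vocabulary": list(self.element_vocabulary),
            "use_degree": self.use_degree,
            "use_aromaticity": self.use_aromaticity,
            "use_ring": self.use_ring,
            "use_formal_charge": self.use_formal_charge,
            "use_hybridization": self.use_hybridization,
            "use_role": self.use_role,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        d = dict(d)
        d["element_vocabulary"] = tuple(d["element_vocabulary"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ComplexGraph:
    """Featurized complex: X plus the fixed covalent/noncovalent adjacencies."""

    complex_id: str
    X: np.ndarray
    A_C: np.ndarray
    A_NC: np.ndarray
    n_ligand: int
    n_protein: int
    label: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return self.n_ligand + self.n_protein


def crop_protein(c: ComplexStructure, cutoff: float) -> ComplexStructure:
    """Restrict the protein to the ligand neighborhood.

    Keeps every ligand atom and each protein atom whose minimum distance to
    any ligand atom is <= ``cutoff`` (inclusive: an atom is excluded only if
    the distance *exceeds* the cutoff).  Bonds are restricted to surviving
    atoms; ligand-first ordering and relative atom order are preserved.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    dmin = min_ligand_distances(c)
    keep_protein = dmin <= cutoff
    if not keep_protein.any():
        raise EmptyPocketError(
            f"{c.complex_id}: no protein atom within {cutoff} A of the ligand"
        )
    keep = np.concatenate([np.ones(c.n_ligand, bool), keep_protein])
    old_to_new = -np.ones(len(c.atoms), dtype=int)
    old_to_new[keep] = np.arange(int(keep.sum()))
    atoms = []
    for a in c.atoms:
        if keep[a.index]:
            atoms.append(
                Atom(
                    index=int(old_to_new[a.index]),
                    element=a.element,
                    coords=a.coords.copy(),
                    role=a.role,
                    residue_name=a.residue_name,
                    residue_number=a.residue_number,
                    aromatic=a.aromatic,
                    formal_charge=a.formal_charge,
                    hybridization=a.hybridization,
                    in_ring=a.in_ring,
                )
            )
    bonds = [
        (int(old_to_new[i]), int(old_to_new[j]))
        for i, j in c.bonds
        if keep[i] and keep[j]
    ]
    return ComplexStructure(c.complex_id, atoms, bonds, c.label)


def featurize_atoms(c: ComplexStructure, fc: FeatureConfig | None = None) -> np.ndarray:
    """Encode each atom as a fixed-width feature row (N x F).

    Deterministic for a fixed config; elements outside the vocabulary map to
    the trailing "other" slot, degrees are capped at 5, unknown
    hybridizations map to "other".
    """
    fc = fc or FeatureConfig()
    n = len(c.atoms)
    degree = np.zeros(n, dtype=int)
    for i, j in c.bonds:
        degree[i] += 1
        degree[j] += 1
    rows = np.zeros((n, fc.n_features))
    elem_index = {e: k for k, e in enumerate(fc.element_vocabulary)}
    hyb_index = {h: k for k, h in enumerate(HYBRIDIZATIONS)}
    for a in c.atoms:
        row = rows[a.index]
        off = 0
        width = len(fc.element_vocabulary) + 1
        row[off + elem_index.get(a.element, width - 1)] = 1.0
        off += width
        if fc.use_degree:
            row[off + min(int(degree[a.index]), 5)] = 1.0
            off += 6
        if fc.use_aromaticity:
            row[off] = float(a.aromatic)
            off += 1
        if fc.use_ring:
            row[off] = float(a.in_ring)
            off += 1
        if fc.use_formal_charge:
            row[off] = float(a.formal_charge)
            off += 1
        if fc.use_hybridization:
            row[off + hyb_index.get(a.hybridization, len(HYBRIDIZATIONS))] = 1.0
            off += len(HYBRIDIZATIONS) + 1
        if fc.use_role:
            row[off] = 1.0 if a.role == "ligand" else 0.0
            off += 1
    return rows


def build_covalent_adjacency(c: ComplexStructure) -> np.ndarray:
    """Binary bond adjacency; zero diagonal, zero cross-molecule blocks."""
    n = len(c.atoms)
    a = np.zeros((n, n))
    n_lig = c.n_ligand
    for i, j in c.bonds:
        if (i < n_lig) != (j < n_lig):
            raise ValueError(f"bond ({i},{j}) spans ligand and protein")
        a[i, j] = a[j, i] = 1.0
    return a


def build_noncovalent_adjacency(n_ligand: int, n_protein: int) -> np.ndarray:
    """All-ones ligand<->protein blocks, zero within-molecule blocks."""
    if n_ligand < 1 or n_protein < 1:
        raise ValueError("need >= 1 atom on each side")
    n = n_ligand + n_protein
    a = np.zeros((n, n))
    a[:n_ligand, n_ligand:] = 1.0
    a[n_ligand:, :n_ligand] = 1.0
    return a


def assemble_graph(
    c: ComplexStructure,
    fc: FeatureConfig | None = None,
    cutoff: float = 5.0,
) -> ComplexGraph:
    """Crop, featurize and build both adjacencies for one complex."""
    fc = fc or FeatureConfig()
    cropped = crop_protein(c, cutoff)
    return ComplexGraph(
        complex_id=c.complex_id,
        X=featurize_atoms(cropped, fc),
        A_C=build_covalent_adjacency(cropped),
        A_NC=build_noncovalent_adjacency(cropped.n_ligand, cropped.n_protein),
        n_ligand=cropped.n_ligand,
        n_protein=cropped.n_protein,
        label=c.label,
        meta={"cutoff": cutoff, "feature_config": fc.config_hash()},
    )


def save_graph(g: ComplexGraph, path: str | Path) -> None:
    """Persist a graph as an .npz tensor bundle with a JSON sidecar header."""
    np.savez(
        path,
        X=g.X,
        A_C=g.A_C,
        A_NC=g.A_NC,
        n_ligand=np.array(g.n_ligand),
        n_protein=np.array(g.n_protein),
        label=np.array(np.nan if g.label is None else g.label),
        meta=np.array(json.dumps({"complex_id": g.complex_id, **g.meta})),
    )


def load_graph(path: str | Path) -> ComplexGraph:
    with np.load(path) as z:
        meta = json.loads(str(z["meta"]))
        label = float(z["label"])
        return ComplexGraph(
            complex_id=meta.pop("complex_id"),
            X=z["X"],
            A_C=z["A_C"],
            A_NC=z["A_NC"],
            n_ligand=int(z["n_ligand"]),
            n_protein=int(z["n_protein"]),
            label=None if np.isnan(label) else label,
            meta=meta,
        )
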