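"""Knowledge-based interaction detection and comparison with LRP output.

Hydrogen bonds are detected on heavy atoms only: a ligand N/O paired with a
protein N/O whose distance falls inside a donor-acceptor window (default
2.5-3.5 A).  Without explicit hydrogens, donor/acceptor roles cannot be
assigned reliably, so any N/O (optionally S) on either side qualifies; an
inferred-hydrogen angle criterion is deliberately not applied.

Hydrophobic contacts are apolar-carbon pairs across the interface (carbon
with no bonded N/O neighbor, default <= 4.0 A), de-duplicated to one
contact per (ligand atom, protein residue) so counts match residue-level
reporting.

The comparison report relates a detected interaction profile to per-atom
LRP contributions: sign agreement on hydrogen-bond ligand atoms and a
permutation test for rank enrichment of interacting atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .lrp import AtomContribution
from .structure import ComplexStructure


@dataclass(frozen=True)
class InteractionRules:
    """Geometric and typing thresholds for interaction detection."""

    hbond_max_distance: float = 3.5
    hbond_min_distance: float = 2.5
    hbond_elements: tuple[str, ...] = ("N", "O")
    include_sulfur: bool = False
    hydrophobic_max_distance: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.hbond_min_distance < self.hbond_max_distance):
            raise ValueError("need 0 < hbond_min < hbond_max")
        if self.hydrophobic_max_distance <= 0:
            raise ValueError("hydrophobic_max_distance must be positive")

    @property
    def polar_elements(self) -> tuple[str, ...]:
        return self.hbond_elements + (("S",) if self.include_sulfur else ())


@dataclass(frozen=True)
class Contact:
    """One detected interaction (atom indices refer to the complex)."""

    ligand_atom: int
    protein_atom: int
    residue: str
    distance: float


@dataclass
class InteractionProfile:
    """Detected hydrogen bonds and hydrophobic contacts for one complex."""

    complex_id: str
    hbonds: list[Contact] = field(default_factory=list)
    hydrophobic: list[Contact] = field(default_factory=list)

    @property
    def n_contacts(self) -> int:
        return len(self.hbonds) + len(self.hydrophobic)

    def participating_atoms(self) -> set[int]:
        atoms: set[int] = set()
        for c in self.hbonds + self.hydrophobic:
            atoms.add(c.ligand_atom)
            atoms.add(c.protein_atom)
        return atoms

    def to_dict(self) -> dict:
        def rows(contacts):
            return [
                {
                    "ligand_atom": c.ligand_atom,
                    "protein_atom": c.protein_atom,
                    "residue": c.residue,
                    "distance": round(c.distance, 3),
                }
                for c in contacts
            ]

        return {
            "complex_id": self.complex_id,
            "hbonds": rows(self.hbonds),
            "hydrophobic": rows(self.hydrophobic),
        }


def _residue_tag(atom) -> str:
    return f"{atom.residue_name}{atom.residue_number}"


def _bonded_elements(c: ComplexStructure) -> list[set[str]]:
    neighbors: list[set[str]] = [set() for _ in c.atoms]
    for i, j in c.bonds:
        neighbors[i].add(c.atoms[j].element)
        neighbors[j].add(c.atoms[i].element)
    return neighbors


def _cross_distances(c: ComplexStructure) -> np.ndarray:
    xyz = c.coords
    return cdist(xyz[: c.n_ligand], xyz[c.n_ligand:])


def find_hydrogen_bonds(
    c: ComplexStructure, r: InteractionRules | None = None
) -> list[Contact]:
    """All ligand-protein N/O pairs inside the donor-acceptor window."""
    r = r or InteractionRules()
    polar = set(r.polar_elements)
    d = _cross_distances(c)
    out = []
    for li in range(c.n_ligand):
        if c.atoms[li].element not in polar:
            continue
        for pj in range(c.n_protein):
            atom = c.atoms[c.n_ligand + pj]
            if atom.element not in polar:
                continue
            dist = float(d[li, pj])
            if r.hbond_min_distance <= dist <= r.hbond_max_distance:
                out.append(Contact(li, c.n_ligand + pj, _residue_tag(atom), dist))
    return out


def find_hydrophobic_contacts(
    c: ComplexStructure, r: InteractionRules | None = None
) -> list[Contact]:
    """Apolar-carbon pairs across the interface, one per (atom, residue)."""
    r = r or InteractionRules()
    neighbors = _bonded_elements(c)
    polar = {"N", "O"}

    def apolar(idx: int) -> bool:
        return c.atoms[idx].element == "C" and not (neighbors[idx] & polar)

    d = _cross_distances(c)
    best: dict[tuple[int, str], Contact] = {}
    for li in range(c.n_ligand):
        if not apolar(li):
            continue
        for pj in range(c.n_protein):
            gi = c.n_ligand + pj
            if not apolar(gi):
                continue
            dist = float(d[li, pj])
            if dist > r.hydrophobic_max_distance:
                continue
            key = (li, _residue_tag(c.atoms[gi]))
            if key not in best or dist < best[key].distance:
                best[key] = Contact(li, gi, key[1], dist)
    return sorted(best.values(), key=lambda k: (k.ligand_atom, k.residue))


def profile_interactions(
    c: ComplexStructure, r: InteractionRules | None = None
) -> InteractionProfile:
    """Full knowledge-based interaction profile for one complex."""
    r = r or InteractionRules()
    return InteractionProfile(
        complex_id=c.complex_id,
        hbonds=find_hydrogen_bonds(c, r),
        hydrophobic=find_hydrophobic_contacts(c, r),
    )


def rank_enrichment_pvalue(
    values: np.ndarray,
    member_idx: np.ndarray,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """One-sided permutation test: do member atoms out-rank the rest?

    Returns (observed mean rank of members, p-value).  Ranks are ascending
    (highest contribution gets the highest rank); the null draws random
    member sets of the same size.
    """
    values = np.asarray(values, dtype=float)
    member_idx = np.asarray(member_idx, dtype=int)
    if member_idx.size == 0 or member_idx.size >= values.size:
        raise ValueError("member set must be a proper nonempty subset")
    ranks = rankdata(values)
    observed = float(ranks[member_idx].mean())
    rng = np.random.default_rng(seed)
    k = member_idx.size
    # each row is an independent permutation; its first k entries are a
    # uniform random k-subset
    perms = rng.permuted(
        np.tile(ranks, (n_permutations, 1)), axis=1
    )
    draws = perms[:, :k].mean(axis=1)
    p = float((1 + np.sum(draws >= observed)) / (1 + n_permutations))
    return observed, p


def compare_contributions(
    profile: InteractionProfile,
    contrib: AtomContribution,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Relate LRP per-atom contributions to the detected interactions.

    The report lists, per ligand atom, interaction membership and the
    contribution's sign and rank, plus two summaries: the fraction of
    hydrogen-bond ligand atoms with positive contribution, and a permutation
    p-value for rank enrichment of all interacting atoms.
    """
    if profile.complex_id != contrib.complex_id:
        raise ValueError("profile and contributions are from different complexes")
    values = contrib.values
    n = len(values)
    members = sorted(profile.participating_atoms())
    if members and (min(members) < 0 or max(members) >= n):
        raise ValueError("interaction atom indices exceed the contribution length")

    ranks = rankdata(values)
    hbond_lig = sorted({c.ligand_atom for c in profile.hbonds})
    hydro_lig = sorted({c.ligand_atom for c in profile.hydrophobic})
    per_ligand_atom = [
        {
            "atom_index": i,
            "in_hbond": i in hbond_lig,
            "in_hydrophobic": i in hydro_lig,
            "contribution": float(values[i]),
            "sign": int(np.sign(values[i])),
            "rank": float(ranks[i]),
        }
        for i in range(contrib.n_ligand)
    ]
    frac_positive = (
        float(np.mean([values[i] > 0 for i in hbond_lig])) if hbond_lig else None
    )
    if members and len(members) < n:
        observed, p = rank_enrichment_pvalue(
            values, np.array(members), n_permutations, seed
        )
    else:
        observed, p = None, None
    return {
        "complex_id": profile.complex_id,
        "n_hbonds": len(profile.hbonds),
        "n_hydrophobic": len(profile.hydrophobic),
        "ligand_atoms": per_ligand_atom,
        "hbond_positive_fraction": frac_positive,
        "interacting_mean_rank": observed,
        "null_mean_rank": (n + 1) / 2,
        "enrichment_pvalue": p,
    }
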