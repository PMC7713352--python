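"""Knowledge-based interaction detection and the LRP comparison report."""

import numpy as np
import pytest

from interactionnet.interactions import (
    InteractionRules,
    compare_contributions,
    find_hydrogen_bonds,
    find_hydrophobic_contacts,
    profile_interactions,
    rank_enrichment_pvalue,
)
from interactionnet.lrp import AtomContribution
from interactionnet.structure import Atom, ComplexStructure
from interactionnet.synthetic import ToySpec, make_toy_complex


def two_sided(lig, prot, lig_elems, prot_elems, lig_bonds=(), prot_bonds=()):
    atoms = [
        Atom(index=i, element=e, coords=np.asarray(c, float), role="ligand")
        for i, (e, c) in enumerate(zip(lig_elems, lig))
    ]
    off = len(atoms)
    atoms += [
        Atom(index=off + i, element=e, coords=np.asarray(c, float),
             role="protein", residue_name="UNK", residue_number=1 + i // 3)
        for i, (e, c) in enumerate(zip(prot_elems, prot))
    ]
    bonds = list(lig_bonds) + [(off + i, off + j) for i, j in prot_bonds]
    return ComplexStructure("pair", atoms, bonds)


class TestHydrogenBonds:
    def test_planted_oxygen_nitrogen_pair_found(self):
        c = two_sided([[0, 0, 0]], [[0, 2.9, 0]], ["O"], ["N"])
        bonds = find_hydrogen_bonds(c)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9)

    def test_pair_beyond_window_not_found(self):
        c = two_sided([[0, 0, 0]], [[0, 4.5, 0]], ["O"], ["N"])
        assert find_hydrogen_bonds(c) == []

    def test_pair_below_minimum_not_found(self):
        c = two_sided([[0, 0, 0]], [[0, 2.0, 0]], ["O"], ["N"])
        assert find_hydrogen_bonds(c) == []

    def test_carbon_pairs_never_bond(self):
        c = two_sided([[0, 0, 0]], [[0, 2.9, 0]], ["C"], ["N"])
        assert find_hydrogen_bonds(c) == []


class TestHydrophobicContacts:
    def test_apolar_pair_within_range(self):
        c = two_sided([[0, 0, 0]], [[0, 3.8, 0]], ["C"], ["C"])
        contacts = find_hydrophobic_contacts(c)
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(3.8)

    def test_polar_carbon_excluded(self):
        # ligand carbon bonded to an oxygen is polar
        c = two_sided(
            [[0, 0, 0], [1.4, 0, 0]], [[0, 3.8, 0]],
            ["C", "O"], ["C"], lig_bonds=[(0, 1)],
        )
        assert find_hydrophobic_contacts(c) == []

    def test_deduplicated_per_ligand_atom_and_residue(self):
        # two protein carbons of one residue near one ligand carbon
        c = two_sided(
            [[0, 0, 0]], [[0, 3.6, 0], [1.5, 3.6, 0]],
            ["C"], ["C", "C"], prot_bonds=[(0, 1)],
        )
        contacts = find_hydrophobic_contacts(c)
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(3.6)


class TestDetectionProperties:
    @pytest.mark.parametrize("seed", range(4))
    def test_rigid_motion_invariance(self, seed):
        structure, _ = make_toy_complex(ToySpec(seed=seed))
        profile = profile_interactions(structure)

        rng = np.random.default_rng(seed)
        # random rotation (QR of a Gaussian matrix) plus translation
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.uniform(-20, 20, size=3)
        moved = ComplexStructure(
            structure.complex_id,
            [
                Atom(index=a.index, element=a.element,
                     coords=Q @ a.coords + t, role=a.role,
                     residue_name=a.residue_name,
                     residue_number=a.residue_number)
                for a in structure.atoms
            ],
            structure.bonds,
            structure.label,
        )
        profile2 = profile_interactions(moved)
        assert [(c.ligand_atom, c.protein_atom) for c in profile.hbonds] \
            == [(c.ligand_atom, c.protein_atom) for c in profile2.hbonds]
        assert [(c.ligand_atom, c.protein_atom) for c in profile.hydrophobic] \
            == [(c.ligand_atom, c.protein_atom) for c in profile2.hydrophobic]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_scan(self, seed):
        structure, _ = make_toy_complex(ToySpec(seed=100 + seed))
        rules = InteractionRules()
        profile = profile_interactions(structure, rules)
        xyz = structure.coords
        polar = {"N", "O"}
        neighbors = [set() for _ in structure.atoms]
        for i, j in structure.bonds:
            neighbors[i].add(structure.atoms[j].element)
            neighbors[j].add(structure.atoms[i].element)
        n_lig = structure.n_ligand
        brute_hb, brute_ph = set(), set()
        for i in range(n_lig):
            for j in range(n_lig, len(structure.atoms)):
                d = np.linalg.norm(xyz[i] - xyz[j])
                ei = structure.atoms[i].element
                ej = structure.atoms[j].element
                if ei in polar and ej in polar and 2.5 <= d <= 3.5:
                    brute_hb.add((i, j))
                if (ei == "C" and ej == "C"
                        and not (neighbors[i] & polar)
                        and not (neighbors[j] & polar) and d <= 4.0):
                    brute_ph.add((i, j))
        assert {(c.ligand_atom, c.protein_atom) for c in profile.hbonds} \
            == brute_hb
        # profile deduplicates hydrophobic contacts per (atom, residue)
        assert {(c.ligand_atom, c.protein_atom) for c in profile.hydrophobic} \
            <= brute_ph
        got_keys = {
            (c.ligand_atom,
             structure.atoms[c.protein_atom].residue_name
             + str(structure.atoms[c.protein_atom].residue_number))
            for c in profile.hydrophobic
        }
        brute_keys = {
            (i, structure.atoms[j].residue_name
             + str(structure.atoms[j].residue_number))
            for i, j in brute_ph
        }
        assert got_keys == brute_keys

    def test_distances_respect_rule_bounds(self):
        structure, _ = make_toy_complex(ToySpec(seed=17))
        rules = InteractionRules()
        profile = profile_interactions(structure, rules)
        xyz = structure.coords
        for c in profile.hbonds:
            d = np.linalg.norm(xyz[c.ligand_atom] - xyz[c.protein_atom])
            assert rules.hbond_min_distance <= d <= rules.hbond_max_distance
            assert d == pytest.approx(c.distance)
        for c in profile.hydrophobic:
            d = np.linalg.norm(xyz[c.ligand_atom] - xyz[c.protein_atom])
            assert d <= rules.hydrophobic_max_distance


class TestCompareContributions:
    @pytest.fixture
    def planted(self):
        structure, profile = make_toy_complex(ToySpec(seed=23))
        return structure, profile

    def contribution(self, structure, values):
        return AtomContribution(
            complex_id=structure.complex_id, variant="C-NC",
            values=np.asarray(values, float),
            n_ligand=structure.n_ligand, y_hat=float(np.sum(values)),
        )

    def test_positive_exactly_on_hbond_atoms_gives_fraction_one(self, planted):
        structure, profile = planted
        values = np.full(len(structure.atoms), -0.1)
        for c in profile.hbonds:
            values[c.ligand_atom] = 1.0
        report = compare_contributions(
            profile, self.contribution(structure, values), n_permutations=100
        )
        assert report["hbond_positive_fraction"] == 1.0

    def test_flat_contributions_are_not_enriched(self, planted):
        structure, profile = planted
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1e-6, size=len(structure.atoms))
        report = compare_contributions(
            profile, self.contribution(structure, values),
            n_permutations=2000, seed=1,
        )
        assert report["enrichment_pvalue"] > 0.05

    def test_mismatched_complex_rejected(self, planted):
        structure, profile = planted
        bad = AtomContribution(
            complex_id="other", variant="C", values=np.zeros(3),
            n_ligand=1, y_hat=0.0,
        )
        with pytest.raises(ValueError):
            compare_contributions(profile, bad)

    def test_permutation_pvalue_matches_independent_oracle(self):
        """Vectorized permutation test vs a plain-loop implementation."""
        rng = np.random.default_rng(11)
        values = rng.normal(size=15)
        members = np.array([1, 4, 7])
        obs, p = rank_enrichment_pvalue(values, members,
                                        n_permutations=10_000, seed=3)
        from scipy.stats import rankdata

        ranks = rankdata(values)
        assert obs == pytest.approx(ranks[members].mean())
        oracle_rng = np.random.default_rng(99)
        n_perm = 10_000
        hits = 0
        for _ in range(n_perm):
            draw = oracle_rng.choice(15, size=3, replace=False)
            if ranks[draw].mean() >= obs:
                hits += 1
        oracle_p = (1 + hits) / (1 + n_perm)
        assert p == pytest.approx(oracle_p, abs=0.02)
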