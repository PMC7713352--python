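"""Cropping, featurization and the covalent/noncovalent adjacencies."""

import numpy as np
import pytest

from interactionnet.graphs import (
    EmptyPocketError,
    FeatureConfig,
    assemble_graph,
    build_covalent_adjacency,
    build_noncovalent_adjacency,
    crop_protein,
    featurize_atoms,
)
from interactionnet.structure import Atom, ComplexStructure
from interactionnet.synthetic import ToySpec, make_toy_complex


def chain_complex(lig_coords, prot_coords, lig_elems=None, prot_elems=None):
    lig_elems = lig_elems or ["C"] * len(lig_coords)
    prot_elems = prot_elems or ["C"] * len(prot_coords)
    atoms = [
        Atom(index=i, element=e, coords=np.asarray(c, float), role="ligand")
        for i, (e, c) in enumerate(zip(lig_elems, lig_coords))
    ]
    off = len(atoms)
    atoms += [
        Atom(index=off + i, element=e, coords=np.asarray(c, float),
             role="protein", residue_name="UNK", residue_number=i + 1)
        for i, (e, c) in enumerate(zip(prot_elems, prot_coords))
    ]
    return ComplexStructure("chain", atoms, bonds=[])


class TestCropProtein:
    def test_keeps_within_and_drops_beyond_cutoff(self):
        c = chain_complex(
            [[0, 0, 0]], [[3.0, 0, 0], [4.9, 0, 0], [5.1, 0, 0]]
        )
        cropped = crop_protein(c, 5.0)
        assert cropped.n_ligand == 1
        assert cropped.n_protein == 2          # 5.1 A atom excluded
        kept = {tuple(a.coords) for a in cropped.atoms if a.role == "protein"}
        assert kept == {(3.0, 0.0, 0.0), (4.9, 0.0, 0.0)}

    def test_boundary_is_inclusive(self):
        c = chain_complex([[0, 0, 0]], [[5.0, 0, 0]])
        assert crop_protein(c, 5.0).n_protein == 1

    def test_empty_pocket_raises(self):
        c = chain_complex([[0, 0, 0]], [[9.0, 0, 0]])
        with pytest.raises(EmptyPocketError):
            crop_protein(c, 5.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_min_distance_scan(self, seed):
        rng = np.random.default_rng(seed)
        lig = rng.uniform(0, 4, size=(5, 3))
        prot = rng.uniform(-4, 10, size=(80, 3))
        c = chain_complex(lig.tolist(), prot.tolist())
        for cutoff in (3.0, 4.0, 5.0, 6.0):
            expected = {
                i for i in range(80)
                if min(np.linalg.norm(prot[i] - l) for l in lig) <= cutoff
            }
            try:
                cropped = crop_protein(c, cutoff)
                kept = {
                    tuple(np.round(a.coords, 6))
                    for a in cropped.atoms if a.role == "protein"
                }
            except EmptyPocketError:
                kept = set()
            assert kept == {tuple(np.round(prot[i], 6)) for i in expected}

    @pytest.mark.parametrize("seed", range(4))
    def test_retained_set_monotone_in_cutoff(self, seed):
        structure, _ = make_toy_complex(ToySpec(seed=seed))
        prev: set = set()
        for cutoff in (3.0, 4.0, 5.0, 6.0):
            kept = {
                tuple(a.coords)
                for a in crop_protein(structure, cutoff).atoms
                if a.role == "protein"
            }
            assert prev <= kept
            prev = kept


class TestFeaturize:
    def test_single_carbon_one_hot(self):
        c = chain_complex([[0, 0, 0]], [[3, 0, 0]])
        fc = FeatureConfig()
        X = featurize_atoms(c, fc)
        elem_block = X[0, : len(fc.element_vocabulary) + 1]
        assert elem_block.sum() == 1.0
        assert elem_block[fc.element_vocabulary.index("C")] == 1.0

    def test_identical_environments_identical_rows(self):
        c = chain_complex([[0, 0, 0], [1.5, 0, 0]], [[4, 0, 0]])
        X = featurize_atoms(c)
        np.testing.assert_array_equal(X[0], X[1])

    @pytest.mark.parametrize(
        "kwargs",
        [
            {},
            {"use_degree": False},
            {"use_hybridization": False, "use_role": False},
            {"element_vocabulary": ("C", "N", "O")},
            {"use_degree": False, "use_aromaticity": False, "use_ring": False,
             "use_formal_charge": False, "use_hybridization": False},
        ],
    )
    def test_width_equals_sum_of_enabled_blocks(self, kwargs):
        fc = FeatureConfig(**kwargs)
        c = chain_complex([[0, 0, 0]], [[3, 0, 0]], ["P"], ["N"])
        X = featurize_atoms(c, fc)
        assert X.shape == (2, fc.n_features)

    def test_out_of_vocabulary_maps_to_other(self):
        fc = FeatureConfig(element_vocabulary=("C", "N"))
        c = chain_complex([[0, 0, 0]], [[3, 0, 0]], ["Se"], ["C"])
        X = featurize_atoms(c, fc)
        assert X[0, 2] == 1.0          # trailing "other" slot


class TestAdjacencies:
    def test_two_plus_two_block_layout(self):
        atoms = [
            Atom(index=0, element="C", coords=np.zeros(3), role="ligand"),
            Atom(index=1, element="C", coords=np.array([1.5, 0, 0]),
                 role="ligand"),
            Atom(index=2, element="C", coords=np.array([0, 3, 0]),
                 role="protein"),
            Atom(index=3, element="C", coords=np.array([1.5, 3, 0]),
                 role="protein"),
        ]
        c = ComplexStructure("x", atoms, bonds=[(0, 1), (2, 3)])
        A = build_covalent_adjacency(c)
        assert A.sum() == 4.0
        assert A[0, 1] == A[1, 0] == A[2, 3] == A[3, 2] == 1.0
        assert np.all(A[:2, 2:] == 0) and np.all(A[2:, :2] == 0)

    def test_no_bonds_gives_zero_matrix(self):
        c = chain_complex([[0, 0, 0]], [[3, 0, 0]])
        assert build_covalent_adjacency(c).sum() == 0.0

    def test_covalent_symmetric_zero_diagonal(self):
        structure, _ = make_toy_complex(ToySpec(seed=3))
        A = build_covalent_adjacency(structure)
        np.testing.assert_array_equal(A, A.T)
        assert np.all(np.diag(A) == 0)

    def test_noncovalent_smallest_case(self):
        np.testing.assert_array_equal(
            build_noncovalent_adjacency(1, 1), [[0, 1], [1, 0]]
        )

    def test_noncovalent_row_sums(self):
        A = build_noncovalent_adjacency(2, 3)
        assert list(A.sum(axis=1)) == [3, 3, 2, 2, 2]

    def test_block_complementarity(self):
        structure, _ = make_toy_complex(ToySpec(seed=1))
        n_lig = structure.n_ligand
        A_C = build_covalent_adjacency(structure)
        A_NC = build_noncovalent_adjacency(n_lig, structure.n_protein)
        both = A_C + A_NC
        # cross-molecule blocks come only from A_NC and are full
        assert np.all(both[:n_lig, n_lig:] == 1)
        # within-molecule entries come only from A_C
        np.testing.assert_array_equal(both[:n_lig, :n_lig], A_C[:n_lig, :n_lig])


class TestAssembleGraph:
    def test_invariants_hold(self):
        structure, _ = make_toy_complex(ToySpec(seed=9))
        g = assemble_graph(structure, cutoff=5.0)
        n_lig = g.n_ligand
        np.testing.assert_array_equal(g.A_C, g.A_C.T)
        np.testing.assert_array_equal(g.A_NC, g.A_NC.T)
        assert np.all(np.diag(g.A_C) == 0)
        assert np.all(g.A_C[:n_lig, n_lig:] == 0)
        assert np.all(g.A_NC[:n_lig, n_lig:] == 1)
        assert np.all(g.A_NC[:n_lig, :n_lig] == 0)
        assert np.all(g.A_NC[n_lig:, n_lig:] == 0)
        assert g.X.shape == (g.n_atoms, FeatureConfig().n_features)

    def test_deterministic(self):
        structure, _ = make_toy_complex(ToySpec(seed=2))
        g1 = assemble_graph(structure, cutoff=5.0)
        g2 = assemble_graph(structure, cutoff=5.0)
        np.testing.assert_array_equal(g1.X, g2.X)
        np.testing.assert_array_equal(g1.A_C, g2.A_C)
        np.testing.assert_array_equal(g1.A_NC, g2.A_NC)

    def test_atom_count_monotone_over_cutoffs(self):
        from interactionnet.synthetic import make_synthetic_dataset

        dataset = make_synthetic_dataset(10, seed=4)
        means = []
        for cutoff in (3.0, 4.0, 5.0, 6.0):
            graphs = [assemble_graph(s, cutoff=cutoff) for s, _ in dataset]
            means.append(np.mean([g.n_atoms for g in graphs]))
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_commutes_with_protein_relabeling(self):
        """Permuting protein atoms permutes X and adjacencies identically."""
        structure, _ = make_toy_complex(ToySpec(seed=6))
        g = assemble_graph(structure, cutoff=6.0)
        n_lig, n = g.n_ligand, g.n_atoms
        rng = np.random.default_rng(0)
        perm = np.concatenate(
            [np.arange(n_lig), n_lig + rng.permutation(n - n_lig)]
        )
        # permute the input structure's protein atoms consistently
        atoms2, bonds2 = [], []
        inverse = np.argsort(perm)
        cropped = __import__(
            "interactionnet.graphs", fromlist=["crop_protein"]
        ).crop_protein(structure, 6.0)
        for new_idx in perm:
            a = cropped.atoms[new_idx]
            atoms2.append(
                Atom(index=len(atoms2), element=a.element,
                     coords=a.coords.copy(), role=a.role,
                     residue_name=a.residue_name,
                     residue_number=a.residue_number)
            )
        bonds2 = [(int(inverse[i]), int(inverse[j])) for i, j in cropped.bonds]
        relabeled = ComplexStructure("perm", atoms2, bonds2, cropped.label)
        g2 = assemble_graph(relabeled, cutoff=6.0)
        np.testing.assert_array_equal(g2.X, g.X[perm])
        np.testing.assert_array_equal(g2.A_C, g.A_C[np.ix_(perm, perm)])
        np.testing.assert_array_equal(g2.A_NC, g.A_NC[np.ix_(perm, perm)])
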