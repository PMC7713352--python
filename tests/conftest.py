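"""Shared fixtures: tiny structure files and random-graph helpers."""

from __future__ import annotations

import numpy as np
import pytest

from interactionnet.graphs import ComplexGraph
from interactionnet.network import ModelParams, VariantSpec

GLY_ALA_PDB = """\
ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  GLY A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   GLY A   1      10.729   6.768  -4.123  1.00  0.00           C
ATOM      4  O   GLY A   1       9.580   7.091  -4.424  1.00  0.00           O
ATOM      5  N   ALA A   2      11.255   7.011  -2.915  1.00  0.00           N
ATOM      6  CA  ALA A   2      10.475   7.658  -1.854  1.00  0.00           C
ATOM      7  C   ALA A   2      11.128   7.546  -0.471  1.00  0.00           C
ATOM      8  O   ALA A   2      12.295   7.168  -0.339  1.00  0.00           O
ATOM      9  CB  ALA A   2      10.267   9.127  -2.199  1.00  0.00           C
ATOM     10  HA  ALA A   2      10.000   5.000  -2.000  1.00  0.00           H
HETATM   11  O   HOH A 101       2.000   2.000   2.000  1.00  0.00           O
END
"""

MALFORMED_PDB = """\
ATOM      1  N   GLY A   1      xx.xxx   6.134  -6.504  1.00  0.00           N
END
"""

# butan-1-ol with explicit hydrogens: 5 heavy atoms, 4 heavy-atom bonds
BUTANOL_SDF = """\
butanol
  synthetic fixture

 15 14  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5200    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0800    1.4100    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.6000    1.4100    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    4.1300    2.7500    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -0.4000   -0.5000    0.9000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.4000   -0.5000   -0.9000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.4000    1.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.9000   -0.5500    0.8700 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.9000   -0.5500   -0.8700 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.7200    1.9500    0.8800 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.7200    1.9500   -0.8800 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.9700    0.8700    0.8800 H   0  0  0  0  0  0  0  0  0  0  0  0
    3.9700    0.8700   -0.8800 H   0  0  0  0  0  0  0  0  0  0  0  0
    5.0900    2.7100    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  0
  4  5  1  0
  1  6  1  0
  1  7  1  0
  1  8  1  0
  2  9  1  0
  2 10  1  0
  3 11  1  0
  3 12  1  0
  4 13  1  0
  4 14  1  0
  5 15  1  0
M  END
$$$$
"""

AFFINITY_INDEX = """\
# PDBbind-style toy index
# code  resolution  year  -logKd/Ki  Kd/Ki  reference  ligand
1abc  1.80  2005  5.32  Kd=4.8uM  // (ref) (LIG)
2DEF  2.10  2010  7.10  Ki=79nM   // (ref) (LIG)
3ghi  1.55  2018  4.00  Kd=100uM  // (ref) (LIG)
"""


@pytest.fixture
def gly_ala_pdb(tmp_path):
    path = tmp_path / "glyala.pdb"
    path.write_text(GLY_ALA_PDB)
    return path


@pytest.fixture
def malformed_pdb(tmp_path):
    path = tmp_path / "bad.pdb"
    path.write_text(MALFORMED_PDB)
    return path


@pytest.fixture
def butanol_sdf(tmp_path):
    path = tmp_path / "butanol.sdf"
    path.write_text(BUTANOL_SDF)
    return path


@pytest.fixture
def index_file(tmp_path):
    path = tmp_path / "index.txt"
    path.write_text(AFFINITY_INDEX)
    return path


def random_graph(
    rng: np.random.Generator,
    n_ligand: int | None = None,
    n_protein: int | None = None,
    n_features: int = 6,
) -> ComplexGraph:
    """A random small graph obeying the adjacency block invariants."""
    n_ligand = n_ligand or int(rng.integers(1, 5))
    n_protein = n_protein or int(rng.integers(1, 6))
    n = n_ligand + n_protein
    X = rng.uniform(0, 1, size=(n, n_features))
    A_C = np.zeros((n, n))
    for block in ((0, n_ligand), (n_ligand, n)):
        lo, hi = block
        for i in range(lo, hi):
            for j in range(i + 1, hi):
                if rng.random() < 0.5:
                    A_C[i, j] = A_C[j, i] = 1.0
    A_NC = np.zeros((n, n))
    A_NC[:n_ligand, n_ligand:] = 1.0
    A_NC[n_ligand:, :n_ligand] = 1.0
    return ComplexGraph(
        complex_id="rnd", X=X, A_C=A_C, A_NC=A_NC,
        n_ligand=n_ligand, n_protein=n_protein,
        label=float(rng.uniform(3, 9)),
    )


def random_params(
    rng: np.random.Generator, n_features: int, v: VariantSpec,
    zero_bias: bool = False, scale: float = 0.5,
) -> ModelParams:
    """Dense random parameters (nonzero biases unless asked otherwise)."""
    h = v.hidden_dim

    def w(a, b):
        return rng.normal(0, scale, size=(a, b))

    def b(a):
        return np.zeros(a) if zero_bias else rng.normal(0, scale, size=a)

    return ModelParams(
        W_ne1=w(n_features, h), b_ne1=b(h),
        W_ne2=w(h, h), b_ne2=b(h),
        W_c=[w(h, h) for _ in range(v.n_cov_layers)],
        W_nc=[w(h, h) for _ in range(v.n_nc_layers)],
        W_fc1=w(h, h), b_fc1=b(h),
        W_fc2=w(h, 1), b_fc2=b(1),
    )
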