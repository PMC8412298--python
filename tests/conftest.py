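"""Shared fixtures: synthetic proteins and physics-informed toy potentials."""

import numpy as np
import pytest

from cgdyn import constants as C
from cgdyn.fixtures import ToyPotentialSpec, ToyTerm, make_mini_protein, make_toy_potential
from cgdyn.potential import (
    CLOSE_OFFSET,
    SAME_OFFSET,
    angle_table,
    atom_type,
    torsion_table,
)


@pytest.fixture(scope="session")
def mini_proteins():
    """Five deterministic mini-proteins of mixed secondary structure."""
    spec = [(8, "HHHHHHHH", 11), (7, "CHHHHHC", 12), (9, "CEEECEEEC", 13),
            (6, "CCHHCC", 14), (10, "HHHHCCHHHH", 15)]
    return [make_mini_protein(n, ss, rng_seed=s) for n, ss, s in spec]


@pytest.fixture(scope="session")
def random_potential():
    """A potential with small random energies in every table (seeded)."""
    rng = np.random.default_rng(100)
    from cgdyn.potential import init_potential_set
    pot = init_potential_set()
    pot.dist[:] = rng.normal(scale=0.3, size=pot.dist.shape)
    pot.angle[:] = rng.normal(scale=0.3, size=pot.angle.shape)
    pot.torsion[:] = rng.normal(scale=0.3, size=pot.torsion.shape)
    return pot


def _bonded_terms():
    """Gaussian wells holding local covalent geometry near ideal values."""
    terms = []
    ideal_same = {0: 1.46, 1: 2.46, 3: 2.45}   # (N,CA), (N,C), (CA,C)
    for aa in range(20):
        for slot, d0 in ideal_same.items():
            terms.append(ToyTerm("dist_same", SAME_OFFSET + aa * 6 + slot,
                                 "well", d0, k=3.0, sigma=0.2))
        d_sc = min(C.CA_SC_DISTANCE[C.AMINO_ACIDS[aa]], 5.0)
        terms.append(ToyTerm("dist_same", SAME_OFFSET + aa * 6 + 4,
                             "well", d_sc, k=3.0, sigma=0.3))
    for aa1 in range(20):
        for aa2 in range(20):
            t1, t2 = atom_type(aa1, 2), atom_type(aa2, 0)   # C(i) - N(i+1)
            terms.append(ToyTerm("dist_close", CLOSE_OFFSET + t1 * 80 + t2,
                                 "well", 1.33, k=3.0, sigma=0.15))
    for aa in range(20):
        terms.append(ToyTerm("angle", angle_table(0, aa), "well", 111.0,
                             k=2.0, sigma=8.0))
        terms.append(ToyTerm("angle", angle_table(1, aa), "well", 116.0,
                             k=2.0, sigma=8.0))
        terms.append(ToyTerm("angle", angle_table(2, aa), "well", 122.0,
                             k=2.0, sigma=8.0))
    return terms


@pytest.fixture(scope="session")
def helix_toy_potential():
    """Bonded wells plus broad helical torsion wells for ss-state H."""
    terms = _bonded_terms()
    for aa in range(20):
        terms.append(ToyTerm("torsion", torsion_table(0, aa, 0), "well",
                             -60.0, k=8.0, sigma=60.0))
        terms.append(ToyTerm("torsion", torsion_table(1, aa, 0), "well",
                             -45.0, k=8.0, sigma=60.0))
        terms.append(ToyTerm("torsion", torsion_table(2, aa, 0), "well",
                             180.0, k=4.0, sigma=20.0))
    return make_toy_potential(ToyPotentialSpec(terms))


@pytest.fixture(scope="session")
def bonded_toy_potential():
    """Only the covalent-geometry wells (no torsion preferences)."""
    return make_toy_potential(ToyPotentialSpec(_bonded_terms()))
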