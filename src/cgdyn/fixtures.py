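"""Deterministic synthetic fixtures: mini-proteins, toy potentials and toy
systems with planted minima.

These generate everything the pipeline needs (native-like structures,
potentials with known ground truth, two-bead bond systems) from seeds, so
training, folding, threading and design can all be exercised end to end
with no external structure data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .potential import (
    ANGLE_SPEC,
    CLOSE_SPEC,
    GENERAL_SPEC,
    SAME_RESIDUE_SPEC,
    TORSION_SPEC,
    BinSpec,
    InteractionList,
    PAIR_GENERAL,
    PotentialSet,
    atom_type,
    general_table,
    init_potential_set,
)
from .structure_io import CGProtein, PeptideGeometry, build_peptide

__all__ = [
    "ToyTerm", "ToyPotentialSpec", "make_mini_protein", "make_toy_potential",
    "two_bead_system", "recover_pair_minimum",
]

_SPEC_BY_COMPONENT = {
    "dist_general": GENERAL_SPEC,
    "dist_same": SAME_RESIDUE_SPEC,
    "dist_close": CLOSE_SPEC,
    "angle": ANGLE_SPEC,
    "torsion": TORSION_SPEC,
}

# idealised backbone torsions per secondary-structure state
_SS_TORSIONS = {"H": (-60.0, -45.0), "E": (-120.0, 140.0), "C": (-80.0, 150.0)}


@dataclass(frozen=True)
class ToyTerm:
    """One filled table: ``component`` ("dist_general", "dist_same",
    "dist_close", "angle", "torsion"), the table row, a functional ``form``
    ("harmonic" or "well") and its parameters.

    harmonic: E(x) = k * (x - x0)^2.  well: a Gaussian dip of depth k and
    width sigma at x0, E(x) = -k * exp(-(x - x0)^2 / (2 sigma^2)).
    """

    component: str
    table: int
    form: str
    x0: float
    k: float = 1.0
    sigma: float = 0.5


@dataclass
class ToyPotentialSpec:
    terms: list = field(default_factory=list)


def _sample_form(term: ToyTerm, spec: BinSpec) -> np.ndarray:
    x = spec.centres
    if term.form == "harmonic":
        vals = term.k * (x - term.x0) ** 2
    elif term.form == "well":
        if spec.periodic_pad:
            span = spec.hi - spec.lo
            dx = (x - term.x0 + span / 2) % span - span / 2
        else:
            dx = x - term.x0
        vals = -term.k * np.exp(-dx ** 2 / (2 * term.sigma ** 2))
    else:
        raise ValueError(f"unknown functional form {term.form!r}")
    return vals


def make_toy_potential(spec: ToyPotentialSpec) -> PotentialSet:
    """A potential whose named tables are analytic forms sampled at bin
    centres; all other tables stay zero.  Terms on disjoint tables add
    independently; repeated selectors accumulate."""
    pot = init_potential_set()
    for term in spec.terms:
        if term.component not in _SPEC_BY_COMPONENT:
            raise ValueError(f"unknown component selector {term.component!r}")
        bspec = _SPEC_BY_COMPONENT[term.component]
        vals = _sample_form(term, bspec)
        if term.component == "angle":
            pot.angle[term.table] += vals
        elif term.component == "torsion":
            # pad values continue the periodic sampling past each edge
            pot.torsion[term.table, 1:-1] += vals
            pot.torsion[term.table, 0] += vals[-1]
            pot.torsion[term.table, -1] += vals[0]
        else:
            pot.dist[term.table] += vals
    return pot


def make_mini_protein(n_residues: int, ss_pattern: str | None = None,
                      rng_seed: int = 0) -> CGProtein:
    """A native-like synthetic mini-protein built from idealised torsions.

    Residues take idealised backbone torsions for their secondary-structure
    state (helix -60/-45, strand -120/140, coil -80/150) with small seeded
    jitter (sd 4 degrees) so fixtures are not perfectly degenerate.  The
    sequence is drawn from the background amino-acid distribution.
    Deterministic per (inputs, seed).
    """
    if not 3 <= n_residues <= 30:
        raise ValueError("n_residues must be in [3, 30]")
    ss = ss_pattern if ss_pattern is not None else "C" * n_residues
    if len(ss) != n_residues:
        raise ValueError("ss_pattern length mismatch")
    if set(ss) - set(C.SS_STATES):
        raise ValueError(f"invalid ss states in {ss!r}")
    rng = np.random.default_rng(rng_seed)
    seq = "".join(rng.choice(list(C.AMINO_ACIDS), size=n_residues,
                             p=C.background_vector()))
    phi = np.empty(n_residues)
    psi = np.empty(n_residues)
    for i, s in enumerate(ss):
        p0, p1 = _SS_TORSIONS[s]
        phi[i] = p0 + rng.normal(0.0, 4.0)
        psi[i] = p1 + rng.normal(0.0, 4.0)
    # omega jittered too: real peptide bonds deviate slightly from planar,
    # and exactly 180 sits on the periodic bin seam
    omega = 180.0 + rng.normal(0.0, 2.0, size=n_residues)
    geom = PeptideGeometry(phi, psi, omega)
    return build_peptide(seq, geom).with_ss(ss)


def recover_pair_minimum(d_star: float = 2.0, rng_seed: int = 0,
                         n_iterations: int = 200, n_steps: int = 60,
                         dt: float = 0.02, lr: float = 0.05,
                         start_spread: float = 0.4,
                         velocity_sd: float = 0.05) -> tuple[float, np.ndarray]:
    """Learn a planted bond minimum from simulations alone.

    A two-bead system has a single distance table (all zeros to start).
    Each iteration perturbs the start distance around ``d_star``, runs an
    NVE rollout, and backpropagates the log(1 + RMSD-to-native) loss into
    the table.  Returns the bin-centre distance of the learned table's
    minimum (over occupiable bins) and the learned table row — recovery of
    ``d_star`` to within one bin demonstrates that gradients through the
    integrator carry usable physical signal.
    """
    # imported here: fixtures is otherwise independent of the training stack
    from .autodiff import Tensor
    from .dynamics import run_nve
    from .training import Adam, kabsch_rmsd, loss

    rng = np.random.default_rng(rng_seed)
    inter = two_bead_system()
    table = int(inter.pair_table[0])
    pot = PotentialSet()
    native = np.array([[0.0, 0.0, 0.0], [d_star, 0.0, 0.0]])
    opt = Adam([pot.dist.shape], lr=lr)
    for _ in range(n_iterations):
        d0 = rng.uniform(d_star - start_spread, d_star + start_spread)
        x0 = np.array([[0.0, 0.0, 0.0], [d0, 0.0, 0.0]])
        v0 = rng.normal(0.0, velocity_sd, size=(2, 3))
        leaf = Tensor(pot.dist, requires_grad=True)
        xf, _ = run_nve(x0, v0, inter, leaf, pot.angle, pot.torsion,
                        n_steps=n_steps, dt=dt)
        loss(kabsch_rmsd(xf, native)).backward()
        opt.step([pot.dist], [leaf.grad])
    row = pot.dist[table]
    k = 1 + int(np.argmin(row[1:-1]))   # edge bins are never occupied
    return float(GENERAL_SPEC.centres[k]), row


def two_bead_system(table: int | None = None, masses: tuple = (10.0, 10.0)):
    """A bare two-particle system with a single general-table pair term.

    Returns an :class:`InteractionList` whose only interaction is the
    distance potential in table ``table`` (default: the general table of
    two alanine SC beads).  Used for planted-minimum recovery experiments.
    """
    if table is None:
        t = atom_type(C.AA_INDEX["A"], 3)
        table = int(general_table(t, t))
    return InteractionList(
        n_beads=2,
        pair_i=np.array([0], dtype=np.intp),
        pair_j=np.array([1], dtype=np.intp),
        pair_table=np.array([table], dtype=np.intp),
        pair_group=np.array([PAIR_GENERAL], dtype=np.intp),
        angle_atoms=np.zeros((0, 3), dtype=np.intp),
        angle_table=np.zeros(0, dtype=np.intp),
        torsion_atoms=np.zeros((0, 4), dtype=np.intp),
        torsion_table=np.zeros(0, dtype=np.intp),
        masses=np.asarray(masses, float),
    )
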