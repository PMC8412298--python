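"""Downstream protocols: RMSF, helicity, threading, design, scoring, folding."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cgdyn import constants as C
from cgdyn.applications import (
    DesignConfig,
    acceptance_probability,
    ca_sc_minimum_distance,
    design_fixed_backbone,
    fold,
    helix_fraction,
    rmsf,
    score_decoys,
    thread_sequence,
)
from cgdyn.dynamics import SimulationConfig, Trajectory, simulate
from cgdyn.fixtures import (
    ToyPotentialSpec,
    ToyTerm,
    make_mini_protein,
    make_toy_potential,
)
from cgdyn.potential import (
    SAME_OFFSET,
    SAME_RESIDUE_SPEC,
    init_potential_set,
)
from cgdyn.structure_io import PeptideGeometry, build_peptide, build_start_conformation


def _static_trajectory(prot, n_snapshots=5):
    return Trajectory(protein=prot,
                      snapshots=[prot.flat_coords.copy()
                                 for _ in range(n_snapshots)])


class TestRMSF:
    def test_static_trajectory_zero(self, mini_proteins):
        values = rmsf(_static_trajectory(mini_proteins[0]))
        assert np.abs(values).max() < 1e-12

    def test_single_oscillating_residue_closed_form(self):
        """One CA oscillates +-delta along x in an otherwise rigid frame."""
        prot = make_mini_protein(12, "C" * 12, rng_seed=2)
        base = prot.flat_coords
        delta = 0.25
        # displacement sequence with zero mean
        seq = delta * np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        snaps = []
        for s in seq:
            x = base.copy()
            x[4 * 6 + 1, 0] += s          # CA of residue 6
            snaps.append(x)
        traj = Trajectory(protein=prot, snapshots=snaps)
        out = rmsf(traj)
        # rigid-frame anchors dominate the superposition; the moving residue
        # shows (almost exactly) the RMS of its displacement sequence
        # centring transfers 1/n of the motion to the frame, so the moving
        # residue fluctuates by (1 - 1/n) * RMS of its displacement sequence
        expected = np.sqrt((seq ** 2).mean()) * (1.0 - 1.0 / 12.0)
        assert out[6] == pytest.approx(expected, rel=0.05)
        assert out[6] > 8 * np.delete(out, 6).max()

    def test_burn_in_consuming_everything_rejected(self, mini_proteins):
        traj = _static_trajectory(mini_proteins[0], 4)
        with pytest.raises(ValueError):
            rmsf(traj, burn_in_snapshots=4)


class TestHelixFraction:
    def test_ideal_helix_is_fully_helical(self):
        prot = build_peptide("AAAAA", PeptideGeometry.uniform(5, -60.0, -45.0))
        assert helix_fraction(prot) == 1.0

    def test_extended_chain_non_helical(self):
        # phi on the -120 box boundary with extended psi: never helical
        prot = build_peptide("AAAAA", PeptideGeometry.uniform(5, -120.0, 140.0))
        assert helix_fraction(prot) == 0.0

    def test_counting_over_non_terminal_residues(self):
        phi = np.full(5, -150.0)
        psi = np.full(5, 120.0)
        phi[2], psi[2] = -60.0, -45.0              # only residue 3 helical
        prot = build_peptide("AAAAA", PeptideGeometry(phi, psi,
                                                      np.full(5, 180.0)))
        assert helix_fraction(prot) == pytest.approx(1.0 / 3.0)

    def test_rigid_motion_invariance(self):
        prot = build_peptide("ADKL", PeptideGeometry.uniform(4, -65.0, -40.0))
        f0 = helix_fraction(prot)
        R = Rotation.from_euler("xyz", [33.0, -71.0, 12.0], degrees=True)
        moved = prot.with_coords(R.apply(prot.flat_coords) + 7.0)
        assert helix_fraction(moved) == f0

    def test_too_short_rejected(self):
        prot = build_peptide("AA", PeptideGeometry.uniform(2, -60.0, -45.0))
        with pytest.raises(ValueError):
            helix_fraction(prot)


def _distinct_native(sequence, seed):
    """A jittered-coil native whose residues are all distinct amino acids."""
    rng = np.random.default_rng(seed)
    n = len(sequence)
    geom = PeptideGeometry(-80.0 + rng.normal(0, 6, n),
                           150.0 + rng.normal(0, 6, n),
                           180.0 + rng.normal(0, 2, n))
    return build_peptide(sequence, geom)


def _native_rewarding_potential(native):
    """A potential under which the native sequence scores lowest.

    Two ingredients: (i) wells in the same-residue CA-SC tables of the
    native amino acids at their native CA-SC distances, so threading the
    native amino acid reproduces the native sidechain position; (ii) wells
    on the sequence-neighbour SC-SC close-pair tables of the native
    amino-acid pairs at their native distances, which discriminate by
    position (any substitution reroutes the pair to a flat table).
    Assumes all native residues are distinct amino acids.
    """
    from cgdyn.potential import CLOSE_OFFSET, atom_type

    assert len(set(native.sequence)) == native.n_residues
    terms = []
    for i, aa in enumerate(native.sequence):
        d = float(np.linalg.norm(native.coords[i, 3] - native.coords[i, 1]))
        d = float(np.clip(d, SAME_RESIDUE_SPEC.lo + 0.1,
                          SAME_RESIDUE_SPEC.hi - 0.1))
        table = SAME_OFFSET + C.AA_INDEX[aa] * 6 + 4
        terms.append(ToyTerm("dist_same", table, "well", d, k=5.0, sigma=0.3))
    for i in range(native.n_residues - 1):
        d = float(np.linalg.norm(native.coords[i + 1, 3] - native.coords[i, 3]))
        t1 = atom_type(C.AA_INDEX[native.sequence[i]], 3)
        t2 = atom_type(C.AA_INDEX[native.sequence[i + 1]], 3)
        terms.append(ToyTerm("dist_close", CLOSE_OFFSET + t1 * 80 + t2,
                             "well", d, k=5.0, sigma=0.3))
    return make_toy_potential(ToyPotentialSpec(terms))


class TestThreading:
    def test_native_sequence_zero_potential_zero_energy(self, mini_proteins):
        prot = mini_proteins[1]
        e = thread_sequence(prot, prot.sequence, init_potential_set())
        assert e == 0.0

    def test_deterministic(self, mini_proteins, bonded_toy_potential):
        prot = mini_proteins[2]
        seq = "A" * prot.n_residues
        e1 = thread_sequence(prot, seq, bonded_toy_potential)
        e2 = thread_sequence(prot, seq, bonded_toy_potential)
        assert e1 == e2

    def test_length_mismatch_rejected(self, mini_proteins):
        with pytest.raises(ValueError):
            thread_sequence(mini_proteins[0], "AAA", init_potential_set())

    def test_learned_minimum_distance_lookup(self):
        pot = init_potential_set()
        table = SAME_OFFSET + C.AA_INDEX["W"] * 6 + 4
        pot.dist[table] = (SAME_RESIDUE_SPEC.centres - 3.9) ** 2
        assert abs(ca_sc_minimum_distance(pot, "W") - 3.9) <= \
            SAME_RESIDUE_SPEC.width

    def test_native_beats_every_single_mutant(self):
        """Exhaustive scan: with native-rewarding wells, all 57 single
        mutants of a 3-residue toy score higher than the native."""
        native = _distinct_native("KVW", seed=6)
        pot = _native_rewarding_potential(native)
        e_native = thread_sequence(native, native.sequence, pot,
                                   minimise_steps=0)
        worse = 0
        for pos in range(3):
            for aa in C.AMINO_ACIDS:
                if aa == native.sequence[pos]:
                    continue
                mutant = list(native.sequence)
                mutant[pos] = aa
                e = thread_sequence(native, "".join(mutant), pot,
                                    minimise_steps=0)
                assert e > e_native
                worse += 1
        assert worse == 57


class TestDesignRule:
    def test_acceptance_probability_endpoints(self):
        cfg = DesignConfig()
        assert acceptance_probability(5.0, 0, cfg) == 0.25
        assert acceptance_probability(5.0, 500, cfg) == 0.125
        assert acceptance_probability(5.0, 1500, cfg) == 0.0
        assert acceptance_probability(-0.001, 1999, cfg) == 1.0
        assert acceptance_probability(10.0, 0, cfg) == 0.0
        assert acceptance_probability(25.0, 0, cfg) == 0.0

    def test_monte_carlo_frequencies_match_rule(self):
        """1e5 synthetic (dE, trial) draws reproduce the piecewise curve
        within binomial error."""
        cfg = DesignConfig()
        rng = np.random.default_rng(17)
        n = 100_000
        de = rng.uniform(-5.0, 15.0, size=n)
        t = rng.integers(0, 2000, size=n)
        p = np.array([acceptance_probability(d, int(tt), cfg)
                      for d, tt in zip(de, t)])
        accepted = (p == 1.0) | (rng.random(n) < p)

        down = de < 0
        assert accepted[down].all()
        over = de >= cfg.accept_ceiling
        assert not accepted[over].any()
        late = (de >= 0) & (de < cfg.accept_ceiling) & (t >= cfg.anneal_trials)
        assert not accepted[late].any()

        window = (de >= 0) & (de < cfg.accept_ceiling) & (t < cfg.anneal_trials)
        for lo, hi in [(0, 250), (250, 500), (500, 750), (750, 1000)]:
            m = window & (t >= lo) & (t < hi)
            expected = p[m].sum()
            sigma = np.sqrt((p[m] * (1 - p[m])).sum())
            assert abs(accepted[m].sum() - expected) <= 4 * max(sigma, 1.0)

    def test_design_recovers_native_under_planted_potential(self):
        native = _distinct_native("KVWE", seed=8)
        pot = _native_rewarding_potential(native)
        cfg = DesignConfig(n_trials=400, anneal_trials=200, minimise_steps=0,
                           rng_seed=3)
        designed, frac, energies = design_fixed_backbone(native, pot, cfg)
        assert frac >= 0.75
        assert energies[-1] <= energies[0]

    def test_design_is_seeded(self, mini_proteins):
        pot = init_potential_set()
        cfg = DesignConfig(n_trials=50, minimise_steps=0, rng_seed=5)
        a = design_fixed_backbone(mini_proteins[3], pot, cfg)
        b = design_fixed_backbone(mini_proteins[3], pot, cfg)
        assert a[0] == b[0] and a[1] == b[1]


class TestScoreDecoys:
    def test_identical_decoy_identical_energy(self, mini_proteins,
                                              bonded_toy_potential):
        prot = mini_proteins[0]
        copy = prot.with_coords(prot.coords.copy())
        energies, rank, gap = score_decoys([prot, copy],
                                           bonded_toy_potential)
        assert energies[0] == energies[1]

    def test_zero_potential_rank_flagged_undefined(self, mini_proteins):
        prot = mini_proteins[0]
        decoys = [prot.with_coords(prot.coords + k * 0.1) for k in range(3)]
        energies, rank, gap = score_decoys([prot] + decoys,
                                           init_potential_set())
        assert rank is None and not energies.any()

    def test_sequence_mismatch_rejected(self, mini_proteins):
        with pytest.raises(ValueError):
            score_decoys([mini_proteins[0], mini_proteins[1]],
                         init_potential_set())

    def test_planted_native_minimum_ranks_first(self):
        native = make_mini_protein(6, "CCCCCC", rng_seed=9)
        pot = _native_rewarding_potential(native)
        rng = np.random.default_rng(10)
        decoys = [native.with_coords(
            native.coords + rng.normal(scale=0.3, size=native.coords.shape))
            for _ in range(20)]
        energies, rank, gap = score_decoys([native] + decoys, pot)
        assert rank == 1
        assert gap < 0


class TestFold:
    def test_trace_starts_at_zero_against_start_reference(self):
        pot = init_potential_set()
        cfg = SimulationConfig(dt=0.004, n_steps=200, thermostat="andersen",
                               temperature=0.01, rng_seed=1,
                               snapshot_interval=100)
        traj, trace, min_rmsd = fold("AAAA", "HHHH", pot, cfg)
        assert trace[0] == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_identical_traces(self, bonded_toy_potential):
        cfg = SimulationConfig(dt=0.004, n_steps=300, thermostat="andersen",
                               temperature=0.015, rng_seed=2,
                               snapshot_interval=100)
        _, t1, _ = fold("ADKL", "HHHH", bonded_toy_potential, cfg)
        _, t2, _ = fold("ADKL", "HHHH", bonded_toy_potential, cfg)
        np.testing.assert_array_equal(t1, t2)

    def test_helix_forms_under_helical_toy_potential(self, helix_toy_potential):
        """Extended start, helix-favouring torsion wells: the chain winds
        into a helix over the run (scaled-down folding experiment)."""
        seq = "AEAAAKEA"
        start = build_start_conformation(seq, "C" * 8)   # extended
        assert helix_fraction(start) == 0.0
        cfg = SimulationConfig(dt=0.004, n_steps=25000, thermostat="andersen",
                               temperature=0.015, coupling=25.0, rng_seed=4,
                               snapshot_interval=1000)
        prot = start.with_ss("H" * 8)     # predicted-helical torsion tables
        traj = simulate(prot, helix_toy_potential, cfg)
        final = helix_fraction(traj.snapshots[-1].reshape(-1, 4, 3))
        assert final >= 0.5
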