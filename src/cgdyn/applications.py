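"""Downstream protocols built on the learned potential.

* flexibility: per-residue Cα RMSF over a thermostatted trajectory;
* helix content: fraction of non-terminal residues inside the α-helical
  φ/ψ box (φ in (-120, -30), ψ in (-60, 30), boundaries exclusive);
* threading: score a candidate sequence on a fixed native backbone;
* fixed-backbone design: annealed Monte-Carlo mutation search;
* decoy scoring: rank alternative conformations by total energy;
* folding: NVT simulation from a secondary-structure start with an RMSD
  trace against a reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .dynamics import SimulationConfig, Trajectory, compute_forces, simulate
from .geometry import kabsch_rotation, kabsch_rmsd_np
from .potential import (
    SAME_OFFSET,
    SAME_RESIDUE_SPEC,
    PotentialSet,
    resolve_interactions,
    total_energy,
)
from .structure_io import CGProtein, backbone_dihedrals, build_start_conformation

__all__ = [
    "DesignConfig", "rmsf", "helix_fraction", "ca_sc_minimum_distance",
    "thread_sequence", "design_fixed_backbone", "acceptance_probability",
    "score_decoys", "fold",
]

# same-residue bead-pair slot of (CA, SC) in the distance table layout
_CA_SC_SLOT = 4


# ---------------------------------------------------------------------------
# flexibility / helicity analysis
# ---------------------------------------------------------------------------

def rmsf(trajectory: Trajectory, burn_in_snapshots: int = 0) -> np.ndarray:
    """Per-residue Cα root-mean-square fluctuation (A).

    Snapshots after the burn-in are superposed (Kabsch, on Cα) onto their
    mean structure — computed with one alignment bootstrap pass — and the
    RMSF of each Cα about its mean position is returned.
    """
    ca = trajectory.ca_coords()
    if burn_in_snapshots >= len(ca):
        raise ValueError(
            f"burn-in of {burn_in_snapshots} snapshots leaves nothing of "
            f"{len(ca)}")
    ca = ca[burn_in_snapshots:]
    if len(ca) < 2:
        raise ValueError("need at least 2 post-burn-in snapshots")

    def superpose_all(frames, ref):
        out = np.empty_like(frames)
        ref_c = ref - ref.mean(axis=0)
        for k, f in enumerate(frames):
            fc = f - f.mean(axis=0)
            out[k] = fc @ kabsch_rotation(fc, ref_c)
        return out

    aligned = superpose_all(ca, ca[0])
    mean = aligned.mean(axis=0)
    aligned = superpose_all(ca, mean)
    mean = aligned.mean(axis=0)
    disp = aligned - mean
    return np.sqrt((disp ** 2).sum(axis=2).mean(axis=0))


def helix_fraction(conformation: CGProtein | np.ndarray,
                   sequence_length: int | None = None) -> float:
    """Fraction of non-terminal residues with α-helical backbone torsions.

    A residue counts as helical when φ lies strictly between -120 and -30
    degrees and ψ strictly between -60 and 30 degrees.  Values on the
    boundary are non-helical.
    """
    if isinstance(conformation, CGProtein):
        prot = conformation
    else:
        coords = np.asarray(conformation, float).reshape(-1, 4, 3)
        r = coords.shape[0]
        prot = CGProtein("A" * r, "C" * r, coords)
    r = prot.n_residues
    if r < 3:
        raise ValueError("need at least 3 residues")
    geom = backbone_dihedrals(prot)
    helical = 0
    for i in range(1, r - 1):
        if -120.0 < geom.phi[i] < -30.0 and -60.0 < geom.psi[i] < 30.0:
            helical += 1
    return helical / (r - 2)


def helix_fraction_trace(trajectory: Trajectory, window: int = 5) -> np.ndarray:
    """Helix fraction per snapshot, smoothed over ``window`` snapshots on
    either side (for plotting folding traces)."""
    raw = np.array([
        helix_fraction(snap.reshape(-1, 4, 3))
        for snap in trajectory.snapshots])
    if window <= 0:
        return raw
    out = np.empty_like(raw)
    for k in range(len(raw)):
        lo = max(0, k - window)
        hi = min(len(raw), k + window + 1)
        out[k] = raw[lo:hi].mean()
    return out


# ---------------------------------------------------------------------------
# threading and design
# ---------------------------------------------------------------------------

def ca_sc_minimum_distance(potential: PotentialSet, aa: str) -> float:
    """Distance (A) of the lowest-energy occupiable bin of the same-residue
    CA-SC table for amino acid ``aa`` (ties -> smallest distance)."""
    row = potential.dist[SAME_OFFSET + C.AA_INDEX[aa] * 6 + _CA_SC_SLOT]
    centres = SAME_RESIDUE_SPEC.centres
    # edge bins are never occupied; restrict the argmin accordingly
    k = 1 + int(np.argmin(row[1:-1]))
    return float(centres[k])


def _thread_coords(native: CGProtein, sequence: str,
                   potential: PotentialSet) -> np.ndarray:
    """Backbone copied from the native; each SC bead placed at the learned
    CA-SC minimum distance for the new residue, along the native CA->SC
    direction."""
    coords = native.coords.copy()
    for i, aa in enumerate(sequence):
        ca = native.coords[i, 1]
        vec = native.coords[i, 3] - ca
        nrm = np.linalg.norm(vec)
        if nrm < 1e-9:
            raise ValueError(f"degenerate native CA-SC vector at residue {i}")
        coords[i, 3] = ca + ca_sc_minimum_distance(potential, aa) * vec / nrm
    return coords


def _minimise(coords: np.ndarray, inter, potential: PotentialSet,
              n_steps: int, step_scale: float = 0.01,
              max_disp: float = 0.1) -> np.ndarray:
    """Deterministic steepest-descent on the binned energy surface.

    Each step moves along the forces with a fixed scale, with per-bead
    displacement capped for stability; velocity-free, so two runs from the
    same start coincide exactly.
    """
    x = np.array(coords, float).reshape(-1, 3)
    for _ in range(n_steps):
        f = compute_forces(x, inter, potential.dist, potential.angle,
                           potential.torsion)
        step = step_scale * f
        mag = np.linalg.norm(step, axis=1, keepdims=True)
        np.clip(mag / max_disp, 1.0, None, out=mag)
        x = x + step / mag
    return x


def thread_sequence(native: CGProtein, sequence: str,
                    potential: PotentialSet, minimise_steps: int = 100) -> float:
    """Energy of ``sequence`` threaded onto the native backbone.

    Sidechain centroids are re-placed at the learned per-amino-acid CA-SC
    minimum along the native CA->SC vector, a brief deterministic energy
    minimisation is run, and the final total energy is returned.
    """
    if len(sequence) != native.n_residues:
        raise ValueError(
            f"sequence length {len(sequence)} != {native.n_residues} residues")
    threaded = CGProtein(sequence, native.ss,
                         _thread_coords(native, sequence, potential))
    inter = resolve_interactions(threaded)
    x = _minimise(threaded.flat_coords, inter, potential, minimise_steps)
    return total_energy(x, potential, inter)


@dataclass
class DesignConfig:
    """Fixed-backbone design schedule.

    Uphill moves (0 <= dE < accept_ceiling) are accepted with probability
    p0 * (1 - t / anneal_trials), linearly annealed to zero; dE < 0 is
    always accepted and dE >= accept_ceiling always rejected.
    """

    n_trials: int = 2000
    accept_ceiling: float = 10.0
    p0: float = 0.25
    anneal_trials: int = 1000
    background: np.ndarray = field(default_factory=C.background_vector)
    minimise_steps: int = 100
    rng_seed: int = 0

    def __post_init__(self):
        self.background = np.asarray(self.background, float)
        if not (0.0 <= self.p0 <= 1.0):
            raise ValueError("p0 must be a probability")
        if abs(self.background.sum() - 1.0) > 1e-8:
            raise ValueError("background frequencies must sum to 1")


def acceptance_probability(delta_e: float, trial: int, cfg: DesignConfig) -> float:
    """The design acceptance rule as an explicit probability."""
    if delta_e < 0:
        return 1.0
    if delta_e >= cfg.accept_ceiling:
        return 0.0
    return cfg.p0 * max(0.0, 1.0 - trial / cfg.anneal_trials)


def design_fixed_backbone(native: CGProtein, potential: PotentialSet,
                          cfg: DesignConfig | None = None
                          ) -> tuple[str, float, list[float]]:
    """Annealed Monte-Carlo sequence design on a fixed native backbone.

    Starts from a random sequence drawn from the background amino-acid
    distribution; each trial mutates one uniformly chosen position to a
    background-drawn amino acid, re-threads and re-scores.  Returns the
    final sequence, its fraction of native residues, and the energy trace.
    """
    cfg = cfg or DesignConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    aas = np.array(list(C.AMINO_ACIDS))
    seq = list(rng.choice(aas, size=native.n_residues, p=cfg.background))
    energy = thread_sequence(native, "".join(seq), potential,
                             cfg.minimise_steps)
    energies = [energy]
    for trial in range(cfg.n_trials):
        pos = int(rng.integers(native.n_residues))
        new_aa = str(rng.choice(aas, p=cfg.background))
        if new_aa == seq[pos]:
            energies.append(energy)
            continue
        candidate = seq.copy()
        candidate[pos] = new_aa
        cand_energy = thread_sequence(native, "".join(candidate), potential,
                                      cfg.minimise_steps)
        p_acc = acceptance_probability(cand_energy - energy, trial, cfg)
        if p_acc == 1.0 or rng.random() < p_acc:
            seq, energy = candidate, cand_energy
        energies.append(energy)
    designed = "".join(seq)
    native_fraction = float(np.mean(
        [a == b for a, b in zip(designed, native.sequence)]))
    return designed, native_fraction, energies


# ---------------------------------------------------------------------------
# decoy scoring and folding
# ---------------------------------------------------------------------------

def score_decoys(structures: list[CGProtein], potential: PotentialSet,
                 native_index: int = 0):
    """Total energy of each structure plus the native's rank and energy gap.

    All structures must share one sequence.  Returns
    ``(energies, native_rank, energy_gap)`` where rank 1 means the native
    scores lowest and the gap is native energy minus the best non-native
    energy (negative favours the native).  With indistinguishable all-equal
    energies the rank is flagged as ``None``.
    """
    seqs = {s.sequence for s in structures}
    if len(seqs) > 1:
        raise ValueError("decoys must share the native sequence")
    energies = np.array([total_energy(s, potential) for s in structures])
    others = np.delete(energies, native_index)
    if np.allclose(energies, energies[0]):
        return energies, None, 0.0
    rank = 1 + int((others < energies[native_index]).sum())
    gap = float(energies[native_index] - others.min())
    return energies, rank, gap


def fold(sequence: str, ss: str, potential: PotentialSet,
         config: SimulationConfig, reference: CGProtein | None = None,
         start_mode: str = "predicted_ss", burn_in_snapshots: int = 0):
    """Folding run from a secondary-structure (or random-coil) start.

    Runs a thermostatted simulation and reports the Cα RMSD of every
    snapshot against ``reference`` (default: the start itself).  Returns
    ``(trajectory, rmsd_trace, min_rmsd)`` with the minimum taken over
    post-burn-in snapshots.
    """
    start = build_start_conformation(sequence, ss, mode=start_mode,
                                     rng_seed=config.rng_seed)
    traj = simulate(start, potential, config)
    ref = reference if reference is not None else start
    ref_ca = ref.coords[:, 1]
    trace = np.array([kabsch_rmsd_np(ca, ref_ca) for ca in traj.ca_coords()])
    min_rmsd = float(trace[burn_in_snapshots:].min())
    return traj, trace, min_rmsd
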