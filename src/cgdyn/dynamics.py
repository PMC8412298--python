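"""Forces from binned potentials and molecular-dynamics integration.

Force rule, per interaction term: find the occupied bin b of the term's
current value (distance / bond angle / torsion), read the neighbouring
table energies and form the finite-difference force magnitude

    F = (E(b-1) - E(b+1)) / 2

(for torsions the two pad values provide the neighbours across the +-180
seam).  F then multiplies the analytic gradient of the geometric value
with respect to each participating bead, so every term's forces sum to
zero and exert zero net torque — the value is invariant under rigid-body
motion.  A positive F pushes the value uphill, i.e. energy decreasing with
distance repels the pair.

Bin selection is treated as a constant of the backward pass: gradients
flow through the gathered energy values and through the geometry, not
through the discretisation.  The same force code runs on plain ndarrays
(fast production path) or on recorded Tensors (training path).

Integration is velocity Verlet; training runs are NVE, production runs add
an Andersen thermostat (each bead's velocity is redrawn from
Normal(0, temperature) with probability dt/coupling per step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import asarray, cross, norm, scatter_add, sqrt, tsum
from .geometry import bond_angle, dihedral, distance
from .potential import (
    InteractionList,
    PotentialSet,
    occupied_bins,
    resolve_interactions,
    total_energy,
)
from .structure_io import CGProtein

__all__ = [
    "SimulationState", "SimulationConfig", "Trajectory", "DivergenceError",
    "measure", "force_magnitude", "compute_forces", "compute_accelerations",
    "velocity_verlet_step", "andersen_step", "simulate", "run_nve",
]

_EPS = 1e-18


class DivergenceError(RuntimeError):
    """Simulation blow-up; indicates the time step is too large."""


@dataclass
class SimulationState:
    """Coordinates, velocities and accelerations at one instant."""

    coords: np.ndarray
    velocities: np.ndarray
    accelerations: np.ndarray
    step: int = 0


@dataclass
class SimulationConfig:
    dt: float = 0.004
    n_steps: int = 1000
    thermostat: str = "none"          # "none" (NVE) or "andersen" (NVT)
    temperature: float = 0.015
    coupling: float = 25.0
    rng_seed: int = 0
    snapshot_interval: int = 100
    divergence_bound: float = 1.0e4

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.thermostat not in ("none", "andersen"):
            raise ValueError(f"unknown thermostat {self.thermostat!r}")


@dataclass
class Trajectory:
    """Periodic coordinate snapshots plus energies of one simulation."""

    protein: CGProtein
    snapshots: list = field(default_factory=list)      # (n_beads, 3) arrays
    potential_energies: list = field(default_factory=list)
    kinetic_energies: list = field(default_factory=list)
    snapshot_interval: int = 1
    dt: float = 0.004

    @property
    def n_snapshots(self) -> int:
        return len(self.snapshots)

    def ca_coords(self) -> np.ndarray:
        """(n_snapshots, R, 3) alpha-carbon coordinates."""
        r = self.protein.n_residues
        return np.stack([s.reshape(r, 4, 3)[:, 1] for s in self.snapshots])


# ---------------------------------------------------------------------------
# geometry measurement (spec'd scalar operation)
# ---------------------------------------------------------------------------

def measure(coords, term):
    """Value of a geometric property: ``("distance", i, j)``,
    ``("angle", i, j, k)`` or ``("dihedral", i, j, k, l)``.

    Distances in Angstrom; angles in [0, 180] degrees; dihedrals in
    (-180, 180] degrees (IUPAC sign), with colinear degeneracies returning
    (0.0, True) when ``return_flag`` applies.
    """
    x = np.asarray(coords, float).reshape(-1, 3)
    kind, *idx = term
    if kind == "distance":
        return distance(x[idx[0]], x[idx[1]])
    if kind == "angle":
        return bond_angle(x[idx[0]], x[idx[1]], x[idx[2]])
    if kind == "dihedral":
        return dihedral(x[idx[0]], x[idx[1]], x[idx[2]], x[idx[3]])
    raise ValueError(f"unknown term kind {kind!r}")


def force_magnitude(table: np.ndarray, bin_index: int) -> float:
    """F = (E(b-1) - E(b+1)) / 2 for one table row and occupied bin.

    For a 142-value padded torsion row pass the *storage* index of the
    occupied real bin (bin + 1); the pads then act as periodic neighbours.
    """
    return 0.5 * float(table[bin_index - 1] - table[bin_index + 1])


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

def _col(x):
    """Reshape a (P,) vector to (P,1) for broadcasting (Tensor-safe)."""
    return x.reshape(-1, 1)


def compute_forces(coords, inter: InteractionList, dist_tables, angle_tables,
                   torsion_tables):
    """Per-bead force vectors; backend follows the argument types.

    ``coords`` is (n_beads, 3); the three table blocks may be ndarrays or
    autodiff Tensors (in which case the result records the graph).
    """
    xv = asarray(coords).reshape(-1, 3)
    pair_bins, angle_bins, torsion_bins = occupied_bins(xv, inter)
    n = inter.n_beads
    x = coords

    # pairwise distances -----------------------------------------------------
    dvec = x[inter.pair_j] - x[inter.pair_i]
    d = norm(dvec, axis=1)
    e_lo = dist_tables[inter.pair_table, pair_bins - 1]
    e_hi = dist_tables[inter.pair_table, pair_bins + 1]
    f_pair = 0.5 * (e_lo - e_hi)
    f_j = _col(f_pair / d) * dvec          # F * unit(i->j)
    forces = scatter_add(f_j, inter.pair_j, n) + scatter_add(-1.0 * f_j,
                                                             inter.pair_i, n)

    # bond angles ------------------------------------------------------------
    if len(inter.angle_table):
        a = x[inter.angle_atoms[:, 0]]
        b = x[inter.angle_atoms[:, 1]]
        c = x[inter.angle_atoms[:, 2]]
        r_ba = a - b
        r_bc = c - b
        nv = cross(r_ba, r_bc)
        nn = _col(sqrt(tsum(nv * nv, axis=1) + _EPS))
        la2 = _col(tsum(r_ba * r_ba, axis=1))
        lc2 = _col(tsum(r_bc * r_bc, axis=1))
        g_a = cross(r_ba, nv) / (la2 * nn)      # d(theta)/d(a), radians
        g_c = cross(nv, r_bc) / (lc2 * nn)
        e_lo = angle_tables[inter.angle_table, angle_bins - 1]
        e_hi = angle_tables[inter.angle_table, angle_bins + 1]
        f_ang = _col(0.5 * (e_lo - e_hi))
        f_a = f_ang * g_a
        f_c = f_ang * g_c
        forces = forces + scatter_add(f_a, inter.angle_atoms[:, 0], n) \
            + scatter_add(f_c, inter.angle_atoms[:, 2], n) \
            + scatter_add(-1.0 * (f_a + f_c), inter.angle_atoms[:, 1], n)

    # torsions ---------------------------------------------------------------
    if len(inter.torsion_table):
        p = x[inter.torsion_atoms[:, 0]]
        q = x[inter.torsion_atoms[:, 1]]
        s = x[inter.torsion_atoms[:, 2]]
        t = x[inter.torsion_atoms[:, 3]]
        b1 = q - p
        b2 = s - q
        b3 = t - s
        n1 = cross(b1, b2)
        n2 = cross(b2, b3)
        n1sq = _col(tsum(n1 * n1, axis=1) + _EPS)
        n2sq = _col(tsum(n2 * n2, axis=1) + _EPS)
        b2sq = tsum(b2 * b2, axis=1)
        lb2 = _col(sqrt(b2sq))
        g_p = -1.0 * (lb2 / n1sq) * n1          # d(phi)/d(p)
        g_t = (lb2 / n2sq) * n2                 # d(phi)/d(t)
        r1 = _col(tsum(b1 * b2, axis=1) / b2sq)
        r2 = _col(tsum(b3 * b2, axis=1) / b2sq)
        g_q = -1.0 * (g_p + r1 * g_p) + r2 * g_t
        g_s = r1 * g_p - (g_t + r2 * g_t)
        # storage column of real bin k is k+1; pads are columns 0 and 141
        e_lo = torsion_tables[inter.torsion_table, torsion_bins]
        e_hi = torsion_tables[inter.torsion_table, torsion_bins + 2]
        f_tor = _col(0.5 * (e_lo - e_hi))
        forces = forces + scatter_add(f_tor * g_p, inter.torsion_atoms[:, 0], n) \
            + scatter_add(f_tor * g_q, inter.torsion_atoms[:, 1], n) \
            + scatter_add(f_tor * g_s, inter.torsion_atoms[:, 2], n) \
            + scatter_add(f_tor * g_t, inter.torsion_atoms[:, 3], n)

    fv = asarray(forces)
    if not np.all(np.isfinite(fv)):
        raise DivergenceError("non-finite force encountered")
    return forces


def compute_accelerations(coords, inter: InteractionList, dist_tables,
                          angle_tables, torsion_tables):
    f = compute_forces(coords, inter, dist_tables, angle_tables, torsion_tables)
    return f / inter.masses[:, None]


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def velocity_verlet_step(x, v, a, dt, accel_fn):
    """One velocity Verlet cycle; returns (x', v', a') at t + dt."""
    x1 = x + v * dt + (0.5 * dt * dt) * a
    a1 = accel_fn(x1)
    v1 = v + (0.5 * dt) * (a + a1)
    return x1, v1, a1


def andersen_step(v, dt, coupling, temperature, rng):
    """Andersen collisions: with probability dt/coupling per bead, redraw
    all three velocity components iid from Normal(0, temperature)."""
    vv = np.array(asarray(v), copy=True)
    hit = rng.random(vv.shape[0]) < dt / coupling
    n_hit = int(hit.sum())
    if n_hit:
        vv[hit] = rng.normal(0.0, temperature, size=(n_hit, 3))
    return vv


def run_nve(coords0, velocities0, inter: InteractionList, dist_tables,
            angle_tables, torsion_tables, n_steps: int, dt: float,
            divergence_bound: float = 1.0e4):
    """NVE velocity Verlet rollout; differentiable when tables are Tensors.

    Returns the final coordinates (Tensor if the tables were Tensors, so a
    loss on them backpropagates into every table entry used en route).
    """
    def accel(x):
        return compute_accelerations(x, inter, dist_tables, angle_tables,
                                     torsion_tables)

    x, v = coords0, velocities0
    a = accel(x)
    for _ in range(n_steps):
        x, v, a = velocity_verlet_step(x, v, a, dt, accel)
        if np.abs(asarray(x)).max() > divergence_bound:
            raise DivergenceError(
                "coordinates diverged; reduce the time step")
    return x, v


def simulate(protein: CGProtein, potential: PotentialSet,
             config: SimulationConfig, start_coords: np.ndarray | None = None,
             start_velocities: np.ndarray | None = None,
             inter: InteractionList | None = None) -> Trajectory:
    """Run a full (production-style) simulation and record a trajectory.

    Snapshots (with total energies) are recorded at step 0 and every
    ``snapshot_interval`` steps.  With ``thermostat="andersen"`` the run
    samples the NVT ensemble; velocities are otherwise untouched (NVE).
    Deterministic for a fixed seed and configuration.
    """
    if inter is None:
        inter = resolve_interactions(protein)
    x = np.array(protein.flat_coords if start_coords is None
                 else np.asarray(start_coords, float).reshape(-1, 3), copy=True)
    v = np.zeros_like(x) if start_velocities is None \
        else np.array(start_velocities, float).reshape(x.shape)
    rng = np.random.default_rng(config.rng_seed)
    masses = inter.masses

    traj = Trajectory(protein=protein, snapshot_interval=config.snapshot_interval,
                      dt=config.dt)

    def record(x, v):
        traj.snapshots.append(x.copy())
        traj.potential_energies.append(total_energy(x, potential, inter))
        traj.kinetic_energies.append(float(0.5 * (masses * (v * v).sum(axis=1)).sum()))

    def accel(xx):
        return compute_accelerations(xx, inter, potential.dist, potential.angle,
                                     potential.torsion)

    a = accel(x)
    record(x, v)
    for step in range(1, config.n_steps + 1):
        x, v, a = velocity_verlet_step(x, v, a, config.dt, accel)
        if config.thermostat == "andersen":
            v = andersen_step(v, config.dt, config.coupling,
                              config.temperature, rng)
        if np.abs(x).max() > config.divergence_bound:
            raise DivergenceError(
                f"coordinates diverged at step {step}; reduce the time step")
        if step % config.snapshot_interval == 0:
            record(x, v)
    return traj
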