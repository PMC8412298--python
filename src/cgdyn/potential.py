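"""The learnable binned force field.

Every interaction energy in the model is a table of discrete values over
140 evenly spaced bins of a distance or angle range.  Three component
families exist:

* pairwise distance potentials — one table per unordered pair of the 80
  atom types (20 amino acids x 4 beads) for residue separation > 4
  ("general", 1-15 A), one per ordered type pair for each separation 1-4
  ("close", 0.7-14.7 A), and one per same-residue bead pair per amino acid
  (0.7-5.6 A).  Covalent bonds are represented implicitly by the
  same-residue and separation-1 tables.
* bond angle potentials — 5 angles per residue x 20 amino acids
  (60-180 degrees).
* torsion angle potentials — 5 torsions per residue x 20 amino acids x 3
  secondary-structure states (-180 to 180 degrees), stored with one extra
  learnable pad value at each end so the finite-difference force is
  periodic across the seam.

That totals 29,360 tables and 4,111,000 learnable scalars, all initialised
to zero before training.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from . import constants as C
from .structure_io import CGProtein

__all__ = [
    "BinSpec", "PotentialSet", "InteractionList",
    "GENERAL_SPEC", "CLOSE_SPEC", "SAME_RESIDUE_SPEC", "ANGLE_SPEC",
    "TORSION_SPEC", "init_potential_set", "lookup_bin", "lookup_bins",
    "resolve_interactions", "interaction_values", "total_energy",
    "save_potential", "load_potential",
]

N_BINS = 140
FORMAT_VERSION = "cgdyn-potential-1"

# distance-table row layout within the single (28960, 140) block
N_GENERAL = 80 * 81 // 2          # 3,240
N_SAME = 6 * C.N_AA               # 120
N_CLOSE = 80 * 80                 # 6,400 per separation
SAME_OFFSET = N_GENERAL
CLOSE_OFFSET = N_GENERAL + N_SAME
N_DIST_TABLES = CLOSE_OFFSET + 4 * N_CLOSE  # 28,960

PAIR_GENERAL, PAIR_SAME, PAIR_CLOSE = 0, 1, 2

_SAME_PAIR_SLOT = {(0, 1): 0, (0, 2): 1, (0, 3): 2, (1, 2): 3, (1, 3): 4, (2, 3): 5}


@dataclass(frozen=True)
class BinSpec:
    """Evenly spaced binning of a distance (A) or angle (degrees) range."""

    lo: float
    hi: float
    n_bins: int = N_BINS
    periodic_pad: bool = False

    def __post_init__(self):
        if self.hi <= self.lo:
            raise ValueError("hi must exceed lo")

    @property
    def width(self) -> float:
        return (self.hi - self.lo) / self.n_bins

    @property
    def n_values(self) -> int:
        """Stored values per table (pad bins included for periodic tables)."""
        return self.n_bins + 2 if self.periodic_pad else self.n_bins

    @property
    def centres(self) -> np.ndarray:
        return self.lo + (np.arange(self.n_bins) + 0.5) * self.width


GENERAL_SPEC = BinSpec(1.0, 15.0)
CLOSE_SPEC = BinSpec(0.7, 14.7)
SAME_RESIDUE_SPEC = BinSpec(0.7, 5.6)
ANGLE_SPEC = BinSpec(60.0, 180.0)
TORSION_SPEC = BinSpec(-180.0, 180.0, periodic_pad=True)

PAIR_SPECS = (GENERAL_SPEC, SAME_RESIDUE_SPEC, CLOSE_SPEC)  # by PAIR_* group id


# ---------------------------------------------------------------------------
# table index helpers
# ---------------------------------------------------------------------------

def atom_type(aa_index, bead_index):
    """Atom type in [0, 80): amino-acid index x 4 + bead slot (N,CA,C,SC)."""
    return aa_index * 4 + bead_index


def general_table(t1, t2):
    """Row of the unordered general distance table for types t1, t2."""
    a = np.minimum(t1, t2)
    b = np.maximum(t1, t2)
    return a * (2 * 80 - a + 1) // 2 + (b - a)


def same_residue_table(aa_index, bead1, bead2):
    slot = _SAME_PAIR_SLOT[(min(bead1, bead2), max(bead1, bead2))]
    return SAME_OFFSET + aa_index * 6 + slot


def close_table(sep, t_earlier, t_later):
    """Row for an ordered close pair at residue separation 1-4."""
    return CLOSE_OFFSET + (sep - 1) * N_CLOSE + t_earlier * 80 + t_later


def angle_table(slot, aa_index):
    return slot * C.N_AA + aa_index


def torsion_table(slot, aa_index, ss_index):
    return (slot * C.N_AA + aa_index) * 3 + ss_index


# ---------------------------------------------------------------------------
# PotentialSet
# ---------------------------------------------------------------------------

class PotentialSet:
    """All learnable energy tables.

    Arrays: ``dist`` (28960, 140), ``angle`` (100, 140), ``torsion``
    (300, 142).  Torsion column 0 and 141 are the periodic pad values; real
    bin k lives in column k+1.  Energies are unitless.
    """

    def __init__(self, dist=None, angle=None, torsion=None):
        self.dist = np.zeros((N_DIST_TABLES, N_BINS)) if dist is None \
            else np.asarray(dist, float)
        self.angle = np.zeros((5 * C.N_AA, N_BINS)) if angle is None \
            else np.asarray(angle, float)
        self.torsion = np.zeros((5 * C.N_AA * 3, N_BINS + 2)) if torsion is None \
            else np.asarray(torsion, float)
        if self.dist.shape != (N_DIST_TABLES, N_BINS):
            raise ValueError(f"dist table block has shape {self.dist.shape}")
        if self.angle.shape != (5 * C.N_AA, N_BINS):
            raise ValueError(f"angle table block has shape {self.angle.shape}")
        if self.torsion.shape != (5 * C.N_AA * 3, N_BINS + 2):
            raise ValueError(f"torsion table block has shape {self.torsion.shape}")

    @property
    def n_tables(self) -> int:
        return self.dist.shape[0] + self.angle.shape[0] + self.torsion.shape[0]

    @property
    def n_parameters(self) -> int:
        return self.dist.size + self.angle.size + self.torsion.size

    def copy(self) -> "PotentialSet":
        return PotentialSet(self.dist.copy(), self.angle.copy(), self.torsion.copy())

    def __eq__(self, other):
        return (isinstance(other, PotentialSet)
                and np.array_equal(self.dist, other.dist)
                and np.array_equal(self.angle, other.angle)
                and np.array_equal(self.torsion, other.torsion))


def init_potential_set() -> PotentialSet:
    """A fresh, zero-initialised potential (the state before training)."""
    return PotentialSet()


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def lookup_bin(value: float, spec: BinSpec) -> int:
    """Bin index of the closest bin centre, excluding the edge bins.

    Non-periodic tables clamp to [1, n_bins-2]: values beyond the range are
    treated as being in the penultimate (or second) bin.  Periodic torsion
    tables wrap the value and return an index over the 140 real bins.
    """
    if not np.isfinite(value):
        raise ValueError(f"cannot bin non-finite value {value!r}")
    return int(lookup_bins(np.asarray([value], float), spec)[0])


def lookup_bins(values: np.ndarray, spec: BinSpec) -> np.ndarray:
    """Vectorised :func:`lookup_bin`."""
    values = np.asarray(values, float)
    if not np.all(np.isfinite(values)):
        raise ValueError("cannot bin non-finite values")
    if spec.periodic_pad:
        v = np.mod(values - spec.lo, spec.hi - spec.lo) + spec.lo
        k = np.rint((v - spec.lo) / spec.width - 0.5).astype(np.intp)
        return np.clip(k, 0, spec.n_bins - 1)
    k = np.rint((values - spec.lo) / spec.width - 0.5).astype(np.intp)
    return np.clip(k, 1, spec.n_bins - 2)


# ---------------------------------------------------------------------------
# interaction resolution
# ---------------------------------------------------------------------------

@dataclass
class InteractionList:
    """Resolved (table, atom indices) terms for one protein.

    Pair terms partition all bead pairs: separation 0 -> same-residue
    tables, 1-4 -> close tables (earlier residue's atom first), > 4 ->
    general tables.  Angle/torsion terms referencing a nonexistent
    neighbour residue are omitted.
    """

    n_beads: int
    pair_i: np.ndarray
    pair_j: np.ndarray
    pair_table: np.ndarray
    pair_group: np.ndarray      # PAIR_GENERAL / PAIR_SAME / PAIR_CLOSE
    angle_atoms: np.ndarray     # (A, 3)
    angle_table: np.ndarray
    torsion_atoms: np.ndarray   # (T, 4)
    torsion_table: np.ndarray
    masses: np.ndarray          # (n_beads,)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_i)


def resolve_interactions(protein: CGProtein) -> InteractionList:
    """Deterministically map every energy term of a protein to its table."""
    r = protein.n_residues
    aa_idx = np.array([C.AA_INDEX[a] for a in protein.sequence], dtype=np.intp)
    ss_idx = np.array([C.SS_INDEX[s] for s in protein.ss], dtype=np.intp)
    n_beads = 4 * r

    i, j = np.triu_indices(n_beads, k=1)
    res_i, bead_i = i // 4, i % 4
    res_j, bead_j = j // 4, j % 4
    type_i = atom_type(aa_idx[res_i], bead_i)
    type_j = atom_type(aa_idx[res_j], bead_j)
    sep = res_j - res_i

    table = np.empty(len(i), dtype=np.intp)
    group = np.empty(len(i), dtype=np.intp)

    m_same = sep == 0
    slot = np.array([[_SAME_PAIR_SLOT.get((min(a, b), max(a, b)), -1)
                      for b in range(4)] for a in range(4)], dtype=np.intp)
    table[m_same] = SAME_OFFSET + aa_idx[res_i[m_same]] * 6 \
        + slot[bead_i[m_same], bead_j[m_same]]
    group[m_same] = PAIR_SAME

    m_close = (sep >= 1) & (sep <= 4)
    table[m_close] = CLOSE_OFFSET + (sep[m_close] - 1) * N_CLOSE \
        + type_i[m_close] * 80 + type_j[m_close]
    group[m_close] = PAIR_CLOSE

    m_gen = sep > 4
    table[m_gen] = general_table(type_i[m_gen], type_j[m_gen])
    group[m_gen] = PAIR_GENERAL

    angle_atoms, angle_tab = [], []
    torsion_atoms, torsion_tab = [], []
    for ri in range(r):
        N, CA, Cc, SC = 4 * ri, 4 * ri + 1, 4 * ri + 2, 4 * ri + 3
        aa = aa_idx[ri]
        ss = ss_idx[ri]
        angle_atoms.append((N, CA, Cc)); angle_tab.append(angle_table(0, aa))
        if ri < r - 1:
            angle_atoms.append((CA, Cc, Cc + 2)); angle_tab.append(angle_table(1, aa))
        if ri > 0:
            angle_atoms.append((N - 2, N, CA)); angle_tab.append(angle_table(2, aa))
        angle_atoms.append((N, CA, SC)); angle_tab.append(angle_table(3, aa))
        angle_atoms.append((Cc, CA, SC)); angle_tab.append(angle_table(4, aa))

        if ri > 0:
            torsion_atoms.append((N - 2, N, CA, Cc))
            torsion_tab.append(torsion_table(0, aa, ss))         # phi
            torsion_atoms.append((N - 3, N - 2, N, CA))
            torsion_tab.append(torsion_table(2, aa, ss))         # omega
            torsion_atoms.append((N - 2, N, CA, SC))
            torsion_tab.append(torsion_table(3, aa, ss))
        if ri < r - 1:
            torsion_atoms.append((N, CA, Cc, Cc + 2))
            torsion_tab.append(torsion_table(1, aa, ss))         # psi
            torsion_atoms.append((SC, CA, Cc, Cc + 2))
            torsion_tab.append(torsion_table(4, aa, ss))

    return InteractionList(
        n_beads=n_beads,
        pair_i=i, pair_j=j, pair_table=table, pair_group=group,
        angle_atoms=np.asarray(angle_atoms, dtype=np.intp).reshape(-1, 3),
        angle_table=np.asarray(angle_tab, dtype=np.intp),
        torsion_atoms=np.asarray(torsion_atoms, dtype=np.intp).reshape(-1, 4),
        torsion_table=np.asarray(torsion_tab, dtype=np.intp),
        masses=protein.flat_masses.copy(),
    )


# ---------------------------------------------------------------------------
# values, bins and energies
# ---------------------------------------------------------------------------

def interaction_values(coords: np.ndarray, inter: InteractionList):
    """Current (distances, angles, torsions) of every term, plain NumPy.

    Distances in Angstrom, angles/torsions in degrees.
    """
    x = np.asarray(coords, float).reshape(-1, 3)
    d = np.linalg.norm(x[inter.pair_j] - x[inter.pair_i], axis=1)

    a, b, c = (x[inter.angle_atoms[:, k]] for k in range(3))
    u, v = a - b, c - b
    cosang = (u * v).sum(axis=1) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    p, q, s, t = (x[inter.torsion_atoms[:, k]] for k in range(4))
    b1, b2, b3 = q - p, s - q, t - s
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    m = np.cross(b2n, n1)
    tor = np.degrees(np.arctan2((m * n2).sum(axis=1), (n1 * n2).sum(axis=1)))
    degen = (np.linalg.norm(n1, axis=1) < 1e-10) | (np.linalg.norm(n2, axis=1) < 1e-10)
    tor = np.where(degen, 0.0, tor)
    return d, ang, tor


def occupied_bins(coords: np.ndarray, inter: InteractionList):
    """Occupied bin per term: (pair_bins, angle_bins, torsion_bins)."""
    d, ang, tor = interaction_values(coords, inter)
    pair_bins = np.empty(len(d), dtype=np.intp)
    for gid, spec in enumerate(PAIR_SPECS):
        mask = inter.pair_group == gid
        if mask.any():
            pair_bins[mask] = lookup_bins(d[mask], spec)
    return pair_bins, lookup_bins(ang, ANGLE_SPEC), lookup_bins(tor, TORSION_SPEC)


def total_energy(protein_or_coords, potential: PotentialSet,
                 inter: InteractionList | None = None) -> float:
    """Total potential energy: sum of the occupied-bin energy of each term."""
    if isinstance(protein_or_coords, CGProtein):
        coords = protein_or_coords.flat_coords
        if inter is None:
            inter = resolve_interactions(protein_or_coords)
    else:
        coords = np.asarray(protein_or_coords, float).reshape(-1, 3)
        if inter is None:
            raise ValueError("an InteractionList is required with raw coordinates")
    pair_bins, angle_bins, torsion_bins = occupied_bins(coords, inter)
    e = potential.dist[inter.pair_table, pair_bins].sum()
    e += potential.angle[inter.angle_table, angle_bins].sum()
    e += potential.torsion[inter.torsion_table, torsion_bins + 1].sum()
    return float(e)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def save_potential(potential: PotentialSet, path) -> None:
    """Write all tables to a versioned HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = FORMAT_VERSION
        for name in ("dist", "angle", "torsion"):
            f.create_dataset(name, data=getattr(potential, name),
                             compression="gzip", compression_opts=4)
        f.attrs["specs"] = np.array([
            [s.lo, s.hi, s.n_bins, int(s.periodic_pad)]
            for s in (GENERAL_SPEC, SAME_RESIDUE_SPEC, CLOSE_SPEC,
                      ANGLE_SPEC, TORSION_SPEC)])


def load_potential(path) -> PotentialSet:
    """Lossless inverse of :func:`save_potential`; rejects foreign files."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format")
        if version != FORMAT_VERSION:
            raise ValueError(
                f"unsupported potential file version {version!r} "
                f"(expected {FORMAT_VERSION!r})")
        missing = {"dist", "angle", "torsion"} - set(f.keys())
        if missing:
            raise ValueError(f"potential file is missing tables: {sorted(missing)}")
        return PotentialSet(f["dist"][...], f["angle"][...], f["torsion"][...])
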