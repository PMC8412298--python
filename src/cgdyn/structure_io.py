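"""Coarse-grained protein representation and I/O.

A protein is represented by four beads per residue — backbone N, CA, C and
the sidechain heavy-atom centroid SC — with unitless model masses.  This
module reads real structures (PDB) into that representation, reads
secondary-structure predictions (PSIPRED ss2), builds synthetic peptides
from internal coordinates so the whole pipeline runs without downloads, and
writes CG structures/trajectories back out as multi-model PDB.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.PDB import PDBParser

from . import constants as C
from .geometry import dihedral, place_atom, pseudo_cbeta_direction, wrap_angle

__all__ = [
    "CGProtein", "PeptideGeometry", "PDBParseError", "SS2ParseError",
    "read_pdb_to_cg", "read_ss2", "build_peptide", "build_start_conformation",
    "write_cg_pdb", "backbone_dihedrals",
]

_ONE_TO_THREE = {v: k for k, v in C.THREE_TO_ONE.items() if k != "MSE"}
_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


class PDBParseError(ValueError):
    """Structured error raised when a PDB chain cannot be coarse-grained."""


class SS2ParseError(ValueError):
    """Raised on malformed PSIPRED ss2 input."""


@dataclass
class CGProtein:
    """Sequence, secondary structure and 4-bead coordinates of one chain.

    ``coords`` has shape (R, 4, 3) with bead order (N, CA, C, SC) and
    coordinates in Angstrom; ``masses`` has shape (R, 4).
    """

    sequence: str
    ss: str
    coords: np.ndarray
    masses: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        r = len(self.sequence)
        if len(self.ss) != r:
            raise ValueError(
                f"sequence length {r} != secondary structure length {len(self.ss)}")
        if self.coords.shape != (r, 4, 3):
            raise ValueError(f"coords shape {self.coords.shape} != {(r, 4, 3)}")
        bad = set(self.sequence) - set(C.AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-standard amino acids: {sorted(bad)}")
        bad_ss = set(self.ss) - set(C.SS_STATES)
        if bad_ss:
            raise ValueError(f"invalid secondary structure states: {sorted(bad_ss)}")
        if self.masses is None:
            self.masses = np.stack([C.residue_masses(aa) for aa in self.sequence])
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (r, 4):
                raise ValueError(f"masses shape {self.masses.shape} != {(r, 4)}")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def flat_coords(self) -> np.ndarray:
        """(4R, 3) bead coordinates, residue-major."""
        return self.coords.reshape(-1, 3)

    @property
    def flat_masses(self) -> np.ndarray:
        return self.masses.reshape(-1)

    def with_coords(self, coords: np.ndarray) -> "CGProtein":
        return replace(self, coords=np.asarray(coords, float).reshape(self.coords.shape))

    def with_ss(self, ss: str) -> "CGProtein":
        return replace(self, ss=ss)


@dataclass
class PeptideGeometry:
    """Per-residue backbone internal coordinates (degrees) for the builder.

    Bond lengths and angles are the ideal values from :mod:`cgdyn.constants`;
    only the torsions vary per residue.  All angles are wrapped to
    (-180, 180].
    """

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray

    def __post_init__(self):
        self.phi = np.atleast_1d(np.asarray(wrap_angle(self.phi), dtype=float))
        self.psi = np.atleast_1d(np.asarray(wrap_angle(self.psi), dtype=float))
        self.omega = np.atleast_1d(np.asarray(wrap_angle(self.omega), dtype=float))
        if not (len(self.phi) == len(self.psi) == len(self.omega)):
            raise ValueError("phi/psi/omega must have equal lengths")

    @classmethod
    def uniform(cls, n: int, phi: float, psi: float, omega: float = 180.0):
        return cls(np.full(n, phi), np.full(n, psi), np.full(n, omega))

    def __len__(self):
        return len(self.phi)


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def read_pdb_to_cg(pdb_text: str, chain_id: str = "A") -> CGProtein:
    """Coarse-grain one chain of a PDB file.

    The SC bead is the unweighted centroid of the residue's heavy sidechain
    atoms; glycine (which has none) gets a pseudo C-beta placed 1.53 A from
    CA along the ideal tetrahedral direction.  Secondary structure is
    initialised to all-coil; attach a prediction with
    :meth:`CGProtein.with_ss`.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("cg", io.StringIO(pdb_text))
    model = next(structure.get_models())
    if chain_id not in [c.id for c in model]:
        raise PDBParseError(f"chain {chain_id!r} not found")
    chain = model[chain_id]

    seq_chars: list[str] = []
    coords: list[np.ndarray] = []
    prev_resseq: int | None = None
    for res in chain:
        hetflag, resseq, icode = res.id
        resname = res.get_resname().strip()
        if hetflag.strip() and resname not in C.THREE_TO_ONE:
            continue  # waters, ligands
        if resname not in C.THREE_TO_ONE:
            raise PDBParseError(f"non-standard residue {resname} at {resseq}")
        if icode.strip():
            raise PDBParseError(f"insertion code at residue {resseq}{icode}")
        if prev_resseq is not None and resseq != prev_resseq + 1:
            raise PDBParseError(
                f"internal missing residues between {prev_resseq} and {resseq}")
        prev_resseq = resseq
        aa = C.THREE_TO_ONE[resname]

        atom_pos: dict[str, np.ndarray] = {}
        side_atoms: list[np.ndarray] = []
        for atom in res.get_unpacked_list():
            if atom.element == "H" or atom.get_name().startswith("H"):
                continue
            # first altloc wins for disordered atoms
            atom_pos.setdefault(atom.get_name(), np.asarray(atom.get_coord(), float))
        for name, pos in atom_pos.items():
            if name not in _BACKBONE_ATOMS:
                side_atoms.append(pos)

        for bb in ("N", "CA", "C"):
            if bb not in atom_pos:
                raise PDBParseError(f"missing backbone atom {bb} at residue {resseq}")
        n, ca, c = atom_pos["N"], atom_pos["CA"], atom_pos["C"]
        if side_atoms:
            sc = np.mean(side_atoms, axis=0)
        else:
            if aa != "G":
                raise PDBParseError(f"missing sidechain atoms at residue {resseq}")
            sc = ca + 1.53 * pseudo_cbeta_direction(n, ca, c, C.ANGLE_SC_TETRAHEDRAL)
        seq_chars.append(aa)
        coords.append(np.stack([n, ca, c, sc]))

    if not coords:
        raise PDBParseError(f"chain {chain_id!r} has no standard residues")
    seq = "".join(seq_chars)
    return CGProtein(seq, "C" * len(seq), np.stack(coords))


# ---------------------------------------------------------------------------
# PSIPRED ss2 reading
# ---------------------------------------------------------------------------

def read_ss2(ss2_text: str, sequence: str | None = None) -> str:
    """Parse PSIPRED ``.ss2`` output into a 3-state string over {H,E,C}.

    The state per residue is the argmax over the (coil, helix, strand)
    probability columns.  If ``sequence`` is given, a length mismatch is an
    error.
    """
    states: list[str] = []
    for lineno, raw in enumerate(ss2_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise SS2ParseError(f"malformed ss2 row at line {lineno}: {raw!r}")
        try:
            int(parts[0])
            probs = [float(p) for p in parts[3:6]]
        except ValueError as exc:
            raise SS2ParseError(f"malformed ss2 row at line {lineno}: {raw!r}") from exc
        states.append("CHE"[int(np.argmax(probs))])
    if not states:
        raise SS2ParseError("ss2 input contains no data rows")
    ss = "".join(states)
    if sequence is not None and len(ss) != len(sequence):
        raise SS2ParseError(
            f"ss2 has {len(ss)} rows but sequence has {len(sequence)} residues")
    return ss


# ---------------------------------------------------------------------------
# Synthetic peptide building
# ---------------------------------------------------------------------------

def _sc_distance(aa: str, ca_sc_distance: dict[str, float] | None) -> float:
    table = ca_sc_distance or C.CA_SC_DISTANCE
    return table[aa]


def build_peptide(sequence: str, geometry: PeptideGeometry,
                  ca_sc_distance: dict[str, float] | None = None) -> CGProtein:
    """Build a CG peptide from ideal bond geometry and supplied torsions.

    Backbone beads are chained NeRF-style from the ideal bond lengths and
    angles; the SC bead sits along the tetrahedral pseudo C-beta direction
    at a per-amino-acid CA-SC distance (idealised defaults, overridable
    e.g. with minima of a learned potential).  phi[0], psi[-1] and omega[0]
    are unused.  Recomputing the torsions from the output reproduces the
    inputs to well under 0.1 degrees.
    """
    if not sequence:
        raise ValueError("empty sequence")
    n_res = len(sequence)
    if len(geometry) != n_res:
        raise ValueError(f"geometry length {len(geometry)} != sequence length {n_res}")

    coords = np.zeros((n_res, 4, 3))
    # first residue in the xy-plane
    coords[0, 0] = (0.0, 0.0, 0.0)
    coords[0, 1] = (C.BOND_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - C.ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + C.BOND_CA_C * np.array(
        [np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[i - 1, 0], coords[i - 1, 1], coords[i - 1, 2]
        n_i = place_atom(n_prev, ca_prev, c_prev, C.BOND_C_N,
                         C.ANGLE_CA_C_N, geometry.psi[i - 1])
        ca_i = place_atom(ca_prev, c_prev, n_i, C.BOND_N_CA,
                          C.ANGLE_C_N_CA, geometry.omega[i])
        c_i = place_atom(c_prev, n_i, ca_i, C.BOND_CA_C,
                         C.ANGLE_N_CA_C, geometry.phi[i])
        coords[i, 0], coords[i, 1], coords[i, 2] = n_i, ca_i, c_i
    for i, aa in enumerate(sequence):
        direction = pseudo_cbeta_direction(
            coords[i, 0], coords[i, 1], coords[i, 2], C.ANGLE_SC_TETRAHEDRAL)
        coords[i, 3] = coords[i, 1] + _sc_distance(aa, ca_sc_distance) * direction
    return CGProtein(sequence, "C" * n_res, coords)


def backbone_dihedrals(protein: CGProtein) -> PeptideGeometry:
    """Recompute (phi, psi, omega) in degrees from CG coordinates.

    Undefined terminal torsions (phi[0], psi[-1], omega[0]) are reported as
    0.
    """
    r = protein.n_residues
    phi = np.zeros(r)
    psi = np.zeros(r)
    omega = np.zeros(r)
    x = protein.coords
    for i in range(r):
        if i > 0:
            phi[i] = dihedral(x[i - 1, 2], x[i, 0], x[i, 1], x[i, 2])
            omega[i] = dihedral(x[i - 1, 1], x[i - 1, 2], x[i, 0], x[i, 1])
        if i < r - 1:
            psi[i] = dihedral(x[i, 0], x[i, 1], x[i, 2], x[i + 1, 0])
    return PeptideGeometry(phi, psi, omega)


def build_start_conformation(sequence: str, ss: str, mode: str = "predicted_ss",
                             rng_seed: int = 0,
                             ca_sc_distance: dict[str, float] | None = None
                             ) -> CGProtein:
    """Starting conformations for folding runs.

    ``predicted_ss``: helical torsions (phi -60, psi -60) for residues
    predicted H, extended torsions (phi -120, psi 140) for E/C.
    ``random_coil``: per-residue phi uniform in [-180, -30] and psi uniform
    in [-180, 180] from the seeded generator.  omega = 180 throughout.
    """
    if len(sequence) != len(ss):
        raise ValueError("sequence and secondary structure lengths differ")
    n = len(sequence)
    if mode == "predicted_ss":
        phi = np.where([s == "H" for s in ss], -60.0, -120.0)
        psi = np.where([s == "H" for s in ss], -60.0, 140.0)
    elif mode == "random_coil":
        rng = np.random.default_rng(rng_seed)
        phi = rng.uniform(-180.0, -30.0, size=n)
        psi = rng.uniform(-180.0, 180.0, size=n)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    geom = PeptideGeometry(phi, psi, np.full(n, 180.0))
    prot = build_peptide(sequence, geom, ca_sc_distance=ca_sc_distance)
    return prot.with_ss(ss)


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _format_model(coords: np.ndarray, sequence: str, serial_start: int = 1) -> list[str]:
    lines = []
    serial = serial_start
    elements = {"N": "N", "CA": "C", "C": "C", "SC": "C"}
    for i, aa in enumerate(sequence):
        resname = _ONE_TO_THREE[aa]
        for b, bead in enumerate(C.BEAD_NAMES):
            x, y, z = coords[i, b]
            name = f" {bead:<3}" if len(bead) < 4 else bead
            lines.append(
                f"ATOM  {serial:5d} {name} {resname} A{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{elements[bead]:>2}")
            serial += 1
    return lines


def write_cg_pdb(obj) -> str:
    """Serialise a CGProtein or a Trajectory to CG-dialect PDB text.

    One ATOM record per bead (atom names N, CA, C, SC); trajectories get one
    MODEL/ENDMDL block per snapshot.  Coordinates round-trip through
    :func:`read_pdb_to_cg` at PDB 3-decimal precision.
    """
    if hasattr(obj, "snapshots"):  # Trajectory
        protein = obj.protein
        blocks = []
        for m, snap in enumerate(obj.snapshots, start=1):
            blocks.append(f"MODEL     {m:4d}")
            blocks.extend(_format_model(np.asarray(snap).reshape(-1, 4, 3),
                                        protein.sequence))
            blocks.append("ENDMDL")
        blocks.append("END")
        return "\n".join(blocks) + "\n"
    protein = obj
    lines = _format_model(protein.coords, protein.sequence)
    lines.append("END")
    return "\n".join(lines) + "\n"
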