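# Methods

## Coarse-grained representation

Each residue contributes four beads: backbone N, Cα, C and the unweighted
centroid of the heavy sidechain atoms (SC). Masses are unitless model
masses that fold bonded hydrogens (and the carbonyl oxygen) into the heavy
atom: N = 15, Cα = 13, C = 28; the sidechain mass is the summed mass of the
all-atom sidechain including its hydrogens (e.g. alanine CH₃ = 15). Glycine
has no heavy sidechain atoms but the model requires four beads, so it
carries a pseudo-Cβ bead of artificial mass 10, placed 1.53 Å from Cα along
the ideal tetrahedral direction computed from N, Cα and C. Because the
system is coarse-grained, energies, times and temperatures carry no
standard units; all scales are internally consistent.

## Potential architecture

All interactions are binned tables of 140 energy values over a fixed range;
energy lookups use the bin nearest the current value, excluding the first
and last bins (values beyond the range occupy the penultimate/second bin,
so edge entries influence only forces near the edges). Components:

* **Pairwise distances.** 80 atom types (20 amino acids × 4 beads).
  Separation > 4 residues: one table per unordered type pair (3,240; range
  1–15 Å). Separations 1–4: one table per ordered type pair per separation
  (4 × 6,400; 0.7–14.7 Å), the earlier residue's atom first. Same residue:
  one table per bead pair per amino acid (120; 0.7–5.6 Å). Covalent bonds
  are implicit in the same-residue and separation-1 tables.
* **Bond angles.** Five per residue i — (N,Cα,C), (Cα,C,N₊₁), (C₋₁,N,Cα),
  (N,Cα,SC), (C,Cα,SC) — per amino acid (100 tables; 60–180°). Terms
  needing a nonexistent neighbour are omitted at the termini.
* **Torsions.** Five per residue i — φ=(C₋₁,N,Cα,C), ψ=(N,Cα,C,N₊₁),
  ω=(Cα₋₁,C₋₁,N,Cα), and the two sidechain torsions (C₋₁,N,Cα,SC) and
  (SC,Cα,C,N₊₁) — per amino acid per 3-state secondary structure (300
  tables; −180–180°). Each table stores two extra *pad* values, independent
  learnable parameters that serve as the out-of-range neighbours of the
  first and last real bins so the finite-difference force is periodic
  across the ±180° seam. ω is assigned to the later residue of its peptide
  bond, so a residue's own ω table can encode, e.g., a cis preference.

The exact atom membership of the five angles/torsions is this package's
design choice (the count "3 backbone + 2 sidechain" admits several
realisations); the chosen sets are the minimal ones that fully constrain
the SC bead's position and orientation relative to the backbone.

Totals: 29,360 tables; 28,960·140 + 100·140 + 300·142 = 4,111,000
parameters. All are zero before training.

## Forces and integration

Per interaction term at each step: (1) compute the current value (distance,
angle, or signed dihedral, IUPAC convention); (2) find its bin b; (3) form
the finite-difference force magnitude F = ½(E(b−1) − E(b+1)); (4) apply
F times the *analytic gradient* of the value with respect to each
participating bead. Because distances, angles and dihedrals are invariant
under rigid motion, step (4) makes each term's forces sum to zero with zero
net torque identically (machine precision), which the test suite asserts at
1e-9. Angle/dihedral gradients carry the standard 1/r factors; the
degree-vs-radian scale is a constant per component absorbed into the
learned energy units. Degenerate geometry (colinear atoms) is regularised
with a tiny epsilon in the normal-vector norms, and dihedral *values* fall
back to 0° with a flag.

Integration is velocity Verlet. Training runs are NVE with Δt = 0.02 (no
thermostat: stochastic collisions would inject noise into the gradients).
Production runs use Δt = 0.004 and an Andersen thermostat: after each
velocity update, every bead independently has its velocity redrawn from
Normal(0, temperature) per component with probability Δt/coupling (defaults
0.015 and 25). Redrawing per component iid is this package's reading of
"new velocities from a normal distribution"; it reproduces the expected
collision rate exactly. Any coordinate exceeding 1e4 Å raises a divergence
error suggesting a smaller time step, converting silent blow-ups into
diagnostics.

With a binned potential the tracked total energy (staircase potential +
kinetic) oscillates within the half-bin quantisation of the occupied
tables rather than being pointwise constant; NVE conservation is therefore
tested as (a) trajectory agreement with a 10× finer time step and (b) a
bounded, drift-free energy band, plus exact time reversibility.

## Differentiation

The map from table entries to final coordinates is differentiated in
reverse mode by a small vectorised tape engine (`cgdyn.autodiff`) providing
exactly the operations the force loop, integrator and loss need
(arithmetic, reductions, gather/scatter-add, cross products, norms, matrix
product). Bin selection and clamping are treated as constants of the
backward pass — gradients flow through the gathered energy values and the
geometric direction vectors, not through the discretisation. This matches
the vectorised finite-difference design of the force rule and keeps memory
linear in step count (the graph for a 300-step, 10-residue rollout is a few
tens of thousands of small array nodes).

The loss is log(1 + R_f); R_f is the minimal all-bead RMSD after proper
Kabsch superposition (reflections excluded by the SVD sign rule). The
optimal rotation is computed from detached coordinates and treated as a
constant of the backward pass; since it minimises the superposition error,
the envelope theorem makes the resulting coordinate gradient exact. An
end-to-end check against central finite differences (perturbation 1e-3) on
a 3-residue, 20-step rollout agrees to ~1e-7 relative error.

## Training procedure

Each epoch simulates every training protein once, in seeded-shuffled order,
from its native coordinates with starting velocities Normal(0, 0.1). The
simulation length follows a curriculum: min(250·(1+⌊(e−1)/5⌋), 2000) steps
at epoch e — short early simulations teach local chemistry (bonding, steric
exclusion) before longer rollouts refine tertiary stability. Gradients are
summed over `accumulate` proteins per Adam update (batch size 1 per
rollout); at `reset_epoch` the optimiser state is discarded and re-created
with a lower learning rate (defaults: lr 1e-4, reset at epoch 38 to 5e-5,
45 epochs, accumulate 100 — the reference full-scale schedule). Adam's
β₁/β₂/ε are the standard published defaults. Diverging simulations are
skipped and counted, never fatal. Each simulation draws fresh velocities;
no gradient clipping is applied. All randomness (velocities, shuffling)
derives from one master seed.

### Desk-scale training conditions

The full-scale recipe (2,004 chains, 45 epochs, weeks of GPU time) is not
reproducible on one CPU, so the package's training experiment uses 5
synthetic mini-proteins (6–10 residues, mixed helix/strand/coil), 300-step
simulations in every epoch, 20 epochs, accumulate 1 and lr 0.01, seeded.
The learning rate follows from an order-of-magnitude estimate: with Adam,
cumulative parameter movement is roughly lr × number of updates; carving
wells of depth ~1 energy unit in 100 updates needs lr ≈ 1e-2, whereas the
full-scale run has ~40,000 updates at 1e-4. Under these conditions the
epoch-1 mean R_f (≈ 0.9 Å, pure ballistic drift of the flat potential)
falls by roughly 40–55 % by epoch 20 depending on seed. The curriculum
schedule itself is exercised against the quoted full-scale rule in a unit
test; at desk scale the schedule is flat (start = cap = 300) so the
epoch-1 versus epoch-20 comparison measures learning at constant
simulation length rather than confounding it with rollout duration.

A separate two-bead experiment recovers a planted harmonic bond minimum
(d\* = 2.0 Å) from zero-initialised tables through the same loss; the
learned table's minimum lands within one bin of d\*.

## Analysis protocols

* **RMSF**: post-burn-in Cα snapshots are superposed (Kabsch) onto their
  mean structure (one bootstrap pass from the first frame), and each Cα's
  RMS deviation from its mean position is reported. Superposition onto the
  mean is standard practice; the choice is documented because other frames
  of reference change terminal-residue values slightly.
* **Helix fraction**: fraction of non-terminal residues with φ strictly
  inside (−120°, −30°) and ψ strictly inside (−60°, 30°); boundary values
  count as non-helical ("between" read as exclusive). Optional smoothing
  over ±5 snapshots for trajectory traces.
* **Threading**: backbone kept native; each SC bead re-placed along the
  native Cα→SC direction at the distance of the lowest-energy occupiable
  bin of the new amino acid's Cα–SC table (ties → smallest distance, which
  on a flat table gives the shortest occupiable distance); then 100 steps
  of deterministic steepest descent (fixed step scale 0.01, per-bead
  displacement capped at 0.1 Å — the cap makes the velocity-free minimiser
  robust on staircase forces) and the final total energy is the sequence's
  score. All beads move during minimisation; a frozen-backbone variant is a
  flag away.
* **Fixed-backbone design**: start from a random sequence drawn from
  background PDB amino-acid frequencies (constants table, leucine 9.6 %,
  tryptophan 1.2 %; overridable); each of 2,000 trials mutates one uniform
  position to a background-drawn amino acid and re-threads from the native
  template (fresh threading per trial, not from the previous accepted
  state). ΔE < 0 always accepted; ΔE ≥ 10 always rejected; otherwise
  accepted with probability 0.25·max(0, 1 − t/1000). Reported: final
  sequence, native fraction, energy trace.
* **Decoy scoring**: total energy per structure; native rank (1 = best)
  and the native-minus-best-decoy energy gap; an all-equal-energy set
  (e.g. a zero potential) yields an explicitly undefined rank.
* **Folding**: start built from predicted secondary structure (φ/ψ
  −60°/−60° for H, −120°/140° for E/C; ω 180°) or random coil (φ uniform
  in [−180°, −30°], ψ uniform in [−180°, 180°]); NVT simulation; per-
  snapshot Cα RMSD to a reference and the post-burn-in minimum.

## Synthetic data

`cgdyn.fixtures` generates everything the tests need. Mini-proteins are
built by NeRF chaining from ideal bond geometry (N–Cα 1.46 Å, Cα–C 1.52 Å,
C–N 1.33 Å; angles 111°/116°/122° — standard library values, chosen because
the builder's constants are otherwise unconstrained) with idealised
per-state torsions (helix −60°/−45°, strand −120°/140°, coil −80°/150°)
plus small seeded jitter (4° on φ/ψ, 2° on ω — exact 180° ω would sit on
the periodic bin seam, a measure-zero knife edge real structures avoid).
Sequences are drawn from the background PDB composition. Sidechain beads
sit at idealised per-amino-acid Cα–centroid distances along the tetrahedral
pseudo-Cβ direction.

What the fixtures do *not* emulate: real rotamer multi-modality, sequence-
dependent backbone geometry, long-range packing statistics, or chain
lengths beyond 30 residues. Passing the scaled-down training test therefore
shows that the gradient/optimisation machinery extracts real structural
signal at desk scale — not that the resulting toy potential folds real
proteins; that claim requires the full-scale data and compute. Toy
potentials with planted minima (Gaussian wells/harmonics sampled at bin
centres) provide ground truth for threading, design and decoy tests.

## Numerical choices and limitations

* Bin boundary ties round half-to-even; values exactly on a boundary are
  equidistant between centres and either bin is acceptable.
* ε = 1e-18 regularises cross-product norms in angle/torsion forces.
* The thermostat acts after the Verlet velocity update each step.
* Serialisation is versioned HDF5 (`cgdyn-potential-1`), one dataset per
  component block; foreign or truncated files are rejected explicitly.
* Single chains only; no insertion codes; first altloc wins; MSE→MET is
  the only modified-residue mapping shipped.
* Training memory grows linearly with rollout length (reverse-mode taping),
  which is what caps desk-scale experiments at hundreds of steps; the
  gradient-free production path is constant-memory and runs millions of
  steps.
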