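"""Learning the force field by backpropagation through simulation.

Each training example is an NVE simulation started from a native structure
with small random velocities (Normal(0, 0.1) per component).  The loss is
log(1 + R_f), where R_f is the Kabsch-minimised all-bead RMSD between the
final conformation and the native one.  Gradients of the loss with respect
to every table entry are obtained by reverse-mode differentiation through
the whole rollout, accumulated over a batch of proteins, and applied with
Adam.  Tables start at zero: the initial potential is flat, proteins drift
ballistically, and training gradually carves energy wells that hold the
natives in place.

A step-count curriculum lengthens the simulations as training progresses
(250 steps in epoch 1, +250 every 5 epochs, capped at 2,000), and the
optimiser is re-created with a lower learning rate late in training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, asarray
from .dynamics import DivergenceError, run_nve
from .geometry import kabsch_rotation
from .potential import PotentialSet, resolve_interactions, save_potential
from .structure_io import CGProtein

__all__ = [
    "TrainingConfig", "TrainingLog", "EpochRecord", "Adam",
    "kabsch_rmsd", "loss", "steps_for_epoch", "train", "validate",
]


# ---------------------------------------------------------------------------
# loss components
# ---------------------------------------------------------------------------

def kabsch_rmsd(X, Y):
    """Minimal RMSD over proper rigid superposition of X onto Y.

    Differentiable in X when X is an autodiff Tensor: the optimal rotation
    is computed from the detached coordinates, which is exact for the
    gradient because the rotation is a minimiser (envelope theorem).
    Reflections are excluded via the SVD sign rule, which also handles
    degenerate (coplanar/colinear) point sets.
    """
    Xv = asarray(X).reshape(-1, 3)
    Yv = asarray(Y).reshape(-1, 3)
    if Xv.shape != Yv.shape:
        raise ValueError(f"coordinate shape mismatch: {Xv.shape} vs {Yv.shape}")
    if Xv.shape[0] < 2:
        raise ValueError("need at least 2 points")
    R = kabsch_rotation(Xv, Yv)
    Yc = Yv - Yv.mean(axis=0)
    if isinstance(X, Tensor):
        Xt = X.reshape(-1, 3)
        Xc = Xt - ad.mean(Xt, axis=0)
        diff = ad.matmul(Xc, R) - Yc
        return ad.sqrt(ad.tsum(diff * diff) / Xv.shape[0])
    Xc = Xv - Xv.mean(axis=0)
    diff = Xc @ R - Yc
    return float(np.sqrt((diff * diff).sum() / Xv.shape[0]))


def loss(r_f):
    """Training loss log(1 + R_f); monotone, zero at zero."""
    if float(asarray(r_f)) < 0:
        raise ValueError("R_f must be non-negative")
    return ad.log1p(r_f)


# ---------------------------------------------------------------------------
# configuration and bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    epochs: int = 45
    accumulate: int = 100           # proteins per optimiser update
    base_lr: float = 1e-4
    reset_epoch: int = 38           # re-create Adam with reset_lr here
    reset_lr: float = 5e-5
    steps_start: int = 250
    steps_increment: int = 250
    steps_every: int = 5            # epochs between step increases
    steps_cap: int = 2000
    start_velocity_sd: float = 0.1
    dt: float = 0.02
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("epochs", "accumulate", "base_lr", "reset_lr",
                     "steps_start", "steps_cap", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def steps_for_epoch(epoch: int, config: TrainingConfig | None = None) -> int:
    """Simulation length for a 1-based epoch under the curriculum."""
    c = config or TrainingConfig()
    return min(c.steps_start + c.steps_increment * ((epoch - 1) // c.steps_every),
               c.steps_cap)


@dataclass
class EpochRecord:
    epoch: int
    n_steps: int
    mean_train_rf: float
    mean_val_rf: float | None
    n_skipped: int


@dataclass
class TrainingLog:
    records: list = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["epoch\tsteps\tmean_train_rf\tmean_val_rf\tskipped"]
        for r in self.records:
            val = "" if r.mean_val_rf is None else f"{r.mean_val_rf:.6f}"
            lines.append(f"{r.epoch}\t{r.n_steps}\t{r.mean_train_rf:.6f}"
                         f"\t{val}\t{r.n_skipped}")
        return "\n".join(lines) + "\n"


class Adam:
    """Adam with per-parameter adaptive rates (standard defaults)."""

    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training / validation loops
# ---------------------------------------------------------------------------

def _simulation_rf(protein, inter, tables, n_steps, dt, v0):
    """One native-start NVE rollout; returns the (possibly Tensor) R_f."""
    x0 = protein.flat_coords
    xf, _ = run_nve(x0, v0, inter, *tables, n_steps=n_steps, dt=dt)
    return kabsch_rmsd(xf, x0)


def train(dataset: list[CGProtein], config: TrainingConfig,
          potential: PotentialSet | None = None,
          val_dataset: list[CGProtein] | None = None,
          checkpoint_dir: str | Path | None = None
          ) -> tuple[PotentialSet, TrainingLog]:
    """Learn all potential parameters on a set of native structures.

    Per protein: a seeded NVE simulation of the epoch's curriculum length
    from the native coordinates, loss log(1 + R_f), gradients accumulated
    over ``config.accumulate`` proteins per Adam update.  Diverging
    simulations are skipped (and counted), not fatal.  All randomness
    (velocity draws, epoch shuffling) derives from ``config.rng_seed``.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    pot = potential.copy() if potential is not None else PotentialSet()
    inters = [resolve_interactions(p) for p in dataset]

    leaves = (Tensor(pot.dist, requires_grad=True),
              Tensor(pot.angle, requires_grad=True),
              Tensor(pot.torsion, requires_grad=True))
    params = [leaf.data for leaf in leaves]
    opt = Adam([p.shape for p in params], lr=config.base_lr)
    rng = np.random.default_rng(config.rng_seed)
    log = TrainingLog()
    n_accum = 0

    def zero_grads():
        for leaf in leaves:
            leaf.grad = None

    def flush():
        nonlocal n_accum
        if n_accum == 0:
            return
        grads = [leaf.grad if leaf.grad is not None else np.zeros_like(leaf.data)
                 for leaf in leaves]
        opt.step(params, grads)
        zero_grads()
        n_accum = 0

    for epoch in range(1, config.epochs + 1):
        if epoch == config.reset_epoch:
            flush()
            opt = Adam([p.shape for p in params], lr=config.reset_lr)
        n_steps = steps_for_epoch(epoch, config)
        order = rng.permutation(len(dataset))
        rfs: list[float] = []
        skipped = 0
        for idx in order:
            prot, inter = dataset[idx], inters[idx]
            v0 = rng.normal(0.0, config.start_velocity_sd,
                            size=(inter.n_beads, 3))
            try:
                rf = _simulation_rf(prot, inter, leaves, n_steps, config.dt, v0)
            except DivergenceError:
                skipped += 1
                continue
            loss(rf).backward()
            rfs.append(float(asarray(rf)))
            n_accum += 1
            if n_accum >= config.accumulate:
                flush()
        val_rf = None
        if val_dataset is not None:
            val_rf = validate(val_dataset, pot, config, epoch=epoch)
        log.records.append(EpochRecord(
            epoch=epoch, n_steps=n_steps,
            mean_train_rf=float(np.mean(rfs)) if rfs else float("nan"),
            mean_val_rf=val_rf, n_skipped=skipped))
        if checkpoint_dir is not None:
            path = Path(checkpoint_dir)
            path.mkdir(parents=True, exist_ok=True)
            save_potential(pot, path / f"epoch_{epoch:03d}.h5")
    flush()
    return pot, log


def validate(dataset: list[CGProtein], potential: PotentialSet,
             config: TrainingConfig, epoch: int | None = None) -> float:
    """Mean R_f over a dataset under the training protocol, no gradients.

    Deterministic for a fixed configuration: velocity draws come from a
    generator seeded by (rng_seed, epoch).
    """
    if not dataset:
        raise ValueError("empty validation dataset")
    n_steps = steps_for_epoch(epoch if epoch is not None else config.epochs,
                              config)
    rng = np.random.default_rng([config.rng_seed, 0 if epoch is None else epoch])
    tables = (potential.dist, potential.angle, potential.torsion)
    rfs = []
    for prot in dataset:
        inter = resolve_interactions(prot)
        v0 = rng.normal(0.0, config.start_velocity_sd, size=(inter.n_beads, 3))
        try:
            rf = _simulation_rf(prot, inter, tables, n_steps, config.dt, v0)
        except DivergenceError:
            continue
        rfs.append(float(rf))
    return float(np.mean(rfs)) if rfs else float("nan")
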