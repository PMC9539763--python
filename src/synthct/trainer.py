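"""Multi-planar adversarial training loop.

Each iteration draws one axial, one sagittal and one coronal slice pair from
a training case, never reusing a slice index within an epoch for a given
case and orientation; an epoch caps at slices_per_volume × n_cases
iterations. Batches whose planes carry no anatomy (pure background) are
disregarded but still consume their slice indices. The discriminator is fed
generated planes through a history buffer to damp oscillation. Learning
rates decay multiplicatively by 1% per epoch from 2e-4 (generator) and 5e-5
(discriminator); optimization is Adam with momentum parameters (0.5, 0.999)
for 100 epochs at full scale.

The whole loop is a pure function of (cases, config): two runs with the same
seed produce bit-identical loss histories and weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .losses import (
    LossWeights, GeneratorSpec, DiscriminatorSpec,
    build_generator, build_discriminator,
    l1_loss, mi_loss_grad, generator_adversarial_loss, discriminator_loss,
)
from .nn import Adam
from .phantom import PairedCase
from .volume import ORIENTATION_AXES

__all__ = [
    "TrainConfig", "HistoryBuffer", "EpochPlan",
    "sample_multiplanar_batch", "is_empty_plane", "lr_at_epoch", "buffer_draw",
    "train", "evaluate_generator_l1",
]

_BACKGROUND = -1.0  # normalized background for both MR and CT planes


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    lr_g: float = 2e-4
    lr_d: float = 5e-5
    momentum_params: tuple[float, float] = (0.5, 0.999)
    decay_per_epoch: float = 0.01
    buffer_size: int = 50
    swap_probability: float = 0.5
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    discriminator: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)
    mi_bins: int = 64

    def __post_init__(self):
        if self.lr_g <= 0 or self.lr_d <= 0:
            raise ValueError("learning rates must be > 0")
        if not 0 <= self.decay_per_epoch < 1:
            raise ValueError("decay_per_epoch must lie in [0, 1)")


@dataclass
class HistoryBuffer:
    """Pool of previously generated planes used for discriminator updates."""

    capacity: int = 50
    swap_probability: float = 0.5
    pool: list = field(default_factory=list)


def buffer_draw(b: HistoryBuffer, fresh, rng: np.random.Generator):
    """Below capacity: store ``fresh`` and return it. At capacity: with
    ``swap_probability`` return a random stored item (replacing it with
    ``fresh``), otherwise return ``fresh``."""
    if b.capacity <= 0:
        return fresh
    if len(b.pool) < b.capacity:
        b.pool.append(fresh)
        return fresh
    if rng.random() < b.swap_probability:
        idx = int(rng.integers(len(b.pool)))
        out = b.pool[idx]
        b.pool[idx] = fresh
        return out
    return fresh


class EpochPlan:
    """Per-case, per-orientation bookkeeping of unused slice indices.

    ``max_iterations`` is slices_per_volume × n_cases where slices_per_volume
    is the smallest grid side (so every orientation can supply a fresh slice
    at every visit; equal to the side for cubic volumes).
    """

    def __init__(self, cases: list[PairedCase]):
        self.slices_per_volume = min(min(c.ct.shape) for c in cases)
        self.max_iterations = self.slices_per_volume * len(cases)
        self.unused: list[dict[str, list[int]]] = [
            {name: list(range(c.ct.shape[ax])) for name, ax in ORIENTATION_AXES.items()}
            for c in cases
        ]

    def remaining(self, case_idx: int) -> int:
        return min(len(v) for v in self.unused[case_idx].values())


def is_empty_plane(p: np.ndarray, modality: str = "CT") -> bool:
    """True iff every voxel is the normalized background value (-1)."""
    return bool(np.all(np.asarray(p) == _BACKGROUND))


def lr_at_epoch(initial: float, epoch: int, decay: float = 0.01) -> float:
    """Multiplicative schedule: initial × (1 − decay)^epoch, never negative."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return initial * (1.0 - decay) ** epoch


def _take_plane(values: np.ndarray, axis: int, idx: int) -> np.ndarray:
    return np.take(values, idx, axis=axis)


def sample_multiplanar_batch(case: PairedCase, plan_entry: dict[str, list[int]],
                             rng: np.random.Generator):
    """Draw one (mr, ct) plane pair per orientation, uniformly from that
    orientation's unused slice indices, marking them used. Returns a list of
    (orientation, mr_plane, ct_plane) or ``None`` (skip-marker) if any drawn
    plane is pure background."""
    if any(len(v) == 0 for v in plan_entry.values()):
        raise ValueError("epoch plan exhausted for this case")
    batch = []
    empty = False
    for name, axis in sorted(ORIENTATION_AXES.items()):
        pool = plan_entry[name]
        idx = pool.pop(int(rng.integers(len(pool))))
        mr_p = _take_plane(case.mr.values, axis, idx)
        ct_p = _take_plane(case.ct.values, axis, idx)
        if is_empty_plane(mr_p, "MR") or is_empty_plane(ct_p, "CT"):
            empty = True
        batch.append((name, mr_p, ct_p))
    return None if empty else batch


def _check_normalized(case: PairedCase):
    for v, name in ((case.mr, "MR"), (case.ct, "CT")):
        lo, hi = float(np.min(v.values)), float(np.max(v.values))
        if lo < -1.0 - 1e-6 or hi > 1.0 + 1e-6:
            raise ValueError(
                f"{name} values in [{lo:.3g}, {hi:.3g}] — cases must be preprocessed to [-1, 1]"
            )


def train(cases: list[PairedCase], config: TrainConfig = TrainConfig(), log=None):
    """Train the translation generator on preprocessed cases.

    Returns ``(generator, history)`` where ``history`` maps per-epoch lists:
    learning rates, mean generator L1/adversarial/MI losses, mean
    discriminator loss, executed and skipped iteration counts.
    """
    if not cases:
        raise ValueError("need at least one training case")
    for c in cases:
        _check_normalized(c)

    rng = np.random.default_rng(config.seed)
    g_seed, d_seed = int(rng.integers(2 ** 31)), int(rng.integers(2 ** 31))
    G = build_generator(config.generator, seed=g_seed)
    D = build_discriminator(config.discriminator, seed=d_seed)
    opt_g = Adam(G.params, config.lr_g, config.momentum_params)
    opt_d = Adam(D.params, config.lr_d, config.momentum_params)
    buf = HistoryBuffer(config.buffer_size, config.swap_probability)
    w = config.weights

    history = {k: [] for k in ("epoch", "lr_g", "lr_d", "g_l1", "g_adv", "g_mi",
                               "d_loss", "iterations", "skipped")}

    for epoch in range(config.epochs):
        opt_g.lr = lr_at_epoch(config.lr_g, epoch, config.decay_per_epoch)
        opt_d.lr = lr_at_epoch(config.lr_d, epoch, config.decay_per_epoch)
        plan = EpochPlan(cases)
        sums = {"g_l1": 0.0, "g_adv": 0.0, "g_mi": 0.0, "d_loss": 0.0}
        executed = skipped = 0

        for _round in range(plan.slices_per_volume):
            for case_idx in rng.permutation(len(cases)):
                case = cases[case_idx]
                batch = sample_multiplanar_batch(case, plan.unused[case_idx], rng)
                if batch is None:
                    skipped += 1
                    continue
                n_planes = len(batch)

                # --- generator step (one Adam step per batch, mean gradients) ---
                opt_g.zero_grad()
                fakes = []
                for _, mr_p, ct_p in batch:
                    fake = G.forward(mr_p)
                    fakes.append(fake[0].copy())
                    scores = D.forward(mr_p, fake[0])
                    sums["g_adv"] += generator_adversarial_loss(scores) / n_planes
                    d_in_grads = D.backward(2.0 * (scores - 1.0) / scores.size)
                    g_ct = d_in_grads[1]
                    diff = fake[0] - ct_p
                    sums["g_l1"] += float(np.abs(diff).mean()) / n_planes
                    dl1 = np.sign(diff) / diff.size
                    mi_val, dmi = mi_loss_grad(ct_p, fake[0], config.mi_bins)
                    sums["g_mi"] += mi_val / n_planes
                    dfake = (g_ct + w.lambda1 * dl1 + w.lambda2 * dmi) / n_planes
                    G.backward(dfake[None].astype(np.float32))
                opt_g.step()

                # --- discriminator step via the history buffer ---
                opt_d.zero_grad()
                for (name, mr_p, ct_p), fake_p in zip(batch, fakes):
                    mr_d, fake_d = buffer_draw(buf, (mr_p, fake_p), rng)
                    s_real = D.forward(mr_p, ct_p)
                    loss_r = float(((s_real - 1.0) ** 2).mean())
                    D.backward(2.0 * (s_real - 1.0) / s_real.size / n_planes)
                    s_fake = D.forward(mr_d, fake_d)
                    loss_f = float((s_fake ** 2).mean())
                    D.backward(2.0 * s_fake / s_fake.size / n_planes)
                    sums["d_loss"] += (loss_r + loss_f) / n_planes
                opt_d.step()
                executed += 1

        denom = max(executed, 1)
        history["epoch"].append(epoch)
        history["lr_g"].append(opt_g.lr)
        history["lr_d"].append(opt_d.lr)
        for k in ("g_l1", "g_adv", "g_mi", "d_loss"):
            history[k].append(sums[k] / denom)
        history["iterations"].append(executed)
        history["skipped"].append(skipped)
        if log is not None:
            log(f"epoch {epoch:3d}  lr_g {opt_g.lr:.3e}  lr_d {opt_d.lr:.3e}  "
                f"G_L1 {history['g_l1'][-1]:.4f}  G_adv {history['g_adv'][-1]:.4f}  "
                f"G_MI {history['g_mi'][-1]:.4f}  D {history['d_loss'][-1]:.4f}  "
                f"iters {executed} skipped {skipped}")
    return G, history


def evaluate_generator_l1(G, case: PairedCase) -> float:
    """Mean normalized-intensity L1 between generated and real CT planes,
    averaged over every slice of all three orientations (skipping pure
    background planes). An untrained generator gives the pre-training
    baseline this number is compared against."""
    _check_normalized(case)
    total, count = 0.0, 0
    for name, axis in sorted(ORIENTATION_AXES.items()):
        for idx in range(case.ct.shape[axis]):
            mr_p = _take_plane(case.mr.values, axis, idx)
            ct_p = _take_plane(case.ct.values, axis, idx)
            if is_empty_plane(mr_p, "MR"):
                continue
            fake = G.forward(mr_p)[0]
            total += float(np.abs(fake - ct_p).mean())
            count += 1
    if count == 0:
        raise ValueError("case contains only background planes")
    return total / count
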