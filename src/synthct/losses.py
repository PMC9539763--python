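"""Composite conditional-GAN objective for MR-to-CT translation.

The generator objective is

    L_T = L_cGAN + lambda1 * L_L1 + lambda2 * L_MI

with defaults lambda1 = 100, lambda2 = 5. L_cGAN is a least-squares
adversarial loss over a patch score map (real -> 1, fake -> 0; the generator
targets 1), L_L1 the voxel mean absolute error, and L_MI = 1 - nMI where nMI
is mutual information normalized to [0, 1] via I(a,b)/sqrt(H(a) H(b)). The
mutual-information term rewards statistical dependence between the real and
generated CT intensity distributions and is robust to residual MR/CT
misalignment, which a pure L1 loss penalizes.

The reference nMI uses a hard 64-bin joint histogram on [-1, 1]^2;
:func:`mi_loss_grad` provides the soft (linearly binned) variant whose
analytic gradient drives training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import UNetGenerator, PatchDiscriminator

__all__ = [
    "LossWeights", "GeneratorSpec", "DiscriminatorSpec",
    "l1_loss", "normalized_mutual_information", "mi_loss", "mi_loss_grad",
    "discriminator_loss", "generator_adversarial_loss", "total_generator_loss",
    "build_generator", "build_discriminator",
]

_EPS = 1e-12


@dataclass(frozen=True)
class LossWeights:
    lambda1: float = 100.0  # weight on the L1 reconstruction term
    lambda2: float = 5.0    # weight on the mutual-information term

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass(frozen=True)
class GeneratorSpec:
    """U-Net generator hyperparameters. Desk-scale default: depth 3, base 16
    channels for 64² planes; scale up (depth 6+, base 64) for 256² inputs."""

    depth: int = 3
    base_channels: int = 16


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Patch discriminator conditioned on the MR plane. ``patch_grid`` is the
    score-map side at the full 256² input scale (16 -> four stride-2 levels);
    the same network applied to a 64² plane yields a 4×4 map."""

    patch_grid: int = 16
    base_channels: int = 16

    @property
    def n_levels(self) -> int:
        n = int(round(np.log2(256 / self.patch_grid)))
        if 2 ** n * self.patch_grid != 256:
            raise ValueError("patch_grid must be 256 / a power of two")
        return n


def l1_loss(y: np.ndarray, g: np.ndarray) -> float:
    """Mean absolute voxel difference between real and generated planes."""
    y, g = np.asarray(y, dtype=np.float64), np.asarray(g, dtype=np.float64)
    if y.shape != g.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {g.shape}")
    return float(np.abs(y - g).mean())


def _hard_histogram(a, b, bins):
    h, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins, range=[[-1, 1], [-1, 1]])
    return h / h.sum()


def _entropy(p):
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def normalized_mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 64) -> float:
    """nMI = I(a,b)/sqrt(H(a)·H(b)) over a bins×bins joint histogram on [-1,1]².

    Equals 1 for identical images, ~0 for independent ones, and always lies
    in [0, 1]. If either marginal entropy is zero (constant image) the value
    is 1 when the arrays are equal and 0 otherwise.
    """
    a, b = np.asarray(a), np.asarray(b)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    p = _hard_histogram(a, b, bins)
    pa, pb = p.sum(axis=1), p.sum(axis=0)
    ha, hb = _entropy(pa), _entropy(pb)
    if ha == 0.0 or hb == 0.0:
        return 1.0 if np.array_equal(a, b) else 0.0
    mi = _entropy(pa) + _entropy(pb) - _entropy(p.ravel())
    return float(np.clip(mi / np.sqrt(ha * hb), 0.0, 1.0))


def mi_loss(y, g, bins: int = 64) -> float:
    """L_MI = 1 - nMI(y, g); accepts a single plane pair or a batch (mean)."""
    y, g = np.asarray(y), np.asarray(g)
    if y.ndim == g.ndim == 3:
        return float(np.mean([1.0 - normalized_mutual_information(yi, gi, bins)
                              for yi, gi in zip(y, g)]))
    return 1.0 - normalized_mutual_information(y, g, bins)


def _soft_weights(x, bins):
    """Linear (hat-kernel) bin weights for values in [-1, 1]: each sample
    splits mass between its two nearest bin centers."""
    width = 2.0 / bins
    t = (np.clip(x, -1.0, 1.0) + 1.0) / width - 0.5
    j0 = np.clip(np.floor(t), 0, bins - 1).astype(np.intp)
    frac = np.clip(t - j0, 0.0, 1.0)
    j1 = np.minimum(j0 + 1, bins - 1)
    interior = (t > 0) & (t < bins - 1) & (j1 > j0)
    return j0, j1, frac, interior, width


def mi_loss_grad(y: np.ndarray, g: np.ndarray, bins: int = 64):
    """Soft-binned L_MI and its analytic gradient with respect to ``g``.

    ``y`` is hard-binned (it is the fixed target); ``g`` is linearly
    soft-binned so the joint histogram — and hence nMI — is piecewise
    differentiable in the generated intensities. Returns (loss, grad) with
    grad of ``g``'s shape. The hard-histogram :func:`mi_loss` is the
    reference value; this soft variant converges to it as bins grow.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    gf = np.asarray(g, dtype=np.float64).ravel()
    n = y.size
    width = 2.0 / bins
    yi = np.clip(((y + 1.0) / width).astype(np.intp), 0, bins - 1)
    j0, j1, frac, interior, _ = _soft_weights(gf, bins)

    p = np.zeros((bins, bins))
    np.add.at(p, (yi, j0), (1.0 - frac) / n)
    np.add.at(p, (yi, j1), frac / n)
    pa, pb = p.sum(axis=1), p.sum(axis=0)
    ha, hb = _entropy(pa), _entropy(pb)
    if ha == 0.0 or hb == 0.0:
        return (0.0 if np.array_equal(y, gf) else 1.0), np.zeros_like(np.asarray(g, dtype=np.float64))
    mi = ha + hb - _entropy(p.ravel())
    denom = np.sqrt(ha * hb)
    nmi = mi / denom

    logp = np.log(np.maximum(p, _EPS))
    logq = np.log(np.maximum(pb, _EPS))
    # d nMI / d p_ij holding the (constant) row marginal fixed:
    #   dMI/dp_ij = log(p_ij / q_j),  dHb/dp_ij = -(log q_j + 1)
    dmi_dp = logp - logq[None, :]
    dhb_dp = -(logq + 1.0)[None, :]
    dnmi_dp = dmi_dp / denom - mi * ha * dhb_dp / (2.0 * denom ** 3)

    dval = (dnmi_dp[yi, j1] - dnmi_dp[yi, j0]) / (n * width)
    dval[~interior] = 0.0
    grad = (-dval).reshape(np.asarray(g).shape)  # loss = 1 - nMI
    return float(1.0 - nmi), grad


def discriminator_loss(real_scores: np.ndarray, fake_scores: np.ndarray) -> float:
    """Least-squares discriminator loss: mean (real-1)² + mean fake²."""
    r, f = np.asarray(real_scores, dtype=np.float64), np.asarray(fake_scores, dtype=np.float64)
    return float(((r - 1.0) ** 2).mean() + (f ** 2).mean())


def generator_adversarial_loss(fake_scores: np.ndarray) -> float:
    """Least-squares generator loss: mean (fake-1)² — the generator targets 1."""
    f = np.asarray(fake_scores, dtype=np.float64)
    return float(((f - 1.0) ** 2).mean())


def total_generator_loss(adv: float, l1: float, mi: float, w: LossWeights = LossWeights()) -> float:
    """L_T = L_cGAN + lambda1·L_L1 + lambda2·L_MI."""
    return float(adv + w.lambda1 * l1 + w.lambda2 * mi)


def build_generator(spec: GeneratorSpec = GeneratorSpec(), seed: int = 0) -> UNetGenerator:
    """Fresh U-Net generator with seeded weights; callable plane -> plane in [-1,1]."""
    return UNetGenerator(depth=spec.depth, base_channels=spec.base_channels, seed=seed)


def build_discriminator(spec: DiscriminatorSpec = DiscriminatorSpec(), seed: int = 0) -> PatchDiscriminator:
    """Fresh conditional patch discriminator; (mr, ct) planes -> 2D score map."""
    return PatchDiscriminator(n_levels=spec.n_levels, base_channels=spec.base_channels, seed=seed)
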