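"""Objective terms for unpaired denoising with a prior-image anchor.

All L1 / least-squares terms are pixel MEANS (not sums), so the weights
``lambda_cyc`` and ``alpha_prior`` are scale-free across patch sizes.  The
full generator objective is

    L_G = E[(D_N(G_N(x)) - 1)^2] + E[(D_L(F_L(y)) - 1)^2]
          + lambda * (||F_L(G_N(x)) - x||_1 + ||G_N(F_L(y)) - y||_1)
          + alpha * ||G_N(x) - I_prior||_1

where the prior image I_prior is the BM3D-denoised low-dose slice; the
prior term applies to the forward generator G_N only.  Discriminators
minimize E[(D(real) - 1)^2] + E[D(fake)^2] (least-squares GAN, no 1/2
factor).  No identity loss is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import PriorImage


@dataclass
class LossWeights:
    """Balance weights: cycle-consistency ``lambda_cyc`` and prior-image
    MAE ``alpha_prior`` (both default 10)."""

    lambda_cyc: float = 10.0
    alpha_prior: float = 10.0

    def __post_init__(self) -> None:
        if self.lambda_cyc < 0 or self.alpha_prior < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LossReport:
    """Per-step loss components (all finite; total_G is their weighted sum)."""

    g_adv_N: float = 0.0
    g_adv_L: float = 0.0
    d_loss_N: float = 0.0
    d_loss_L: float = 0.0
    cycle: float = 0.0
    prior: float = 0.0
    total_G: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in
                ("g_adv_N", "g_adv_L", "d_loss_N", "d_loss_L",
                 "cycle", "prior", "total_G")}

    def is_finite(self) -> bool:
        return all(np.isfinite(v) for v in self.as_dict().values())


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if np.shape(a) != np.shape(b):
        raise ValueError(f"shape mismatch: {np.shape(a)} vs {np.shape(b)}")


def mae(a: np.ndarray, b: np.ndarray) -> float:
    _check_shapes(a, b)
    return float(np.mean(np.abs(np.asarray(a, float) - np.asarray(b, float))))


def cycle_loss(x: np.ndarray, recon_x: np.ndarray,
               y: np.ndarray, recon_y: np.ndarray) -> float:
    """Cycle-consistency loss: mean|F(G(x)) - x| + mean|G(F(y)) - y|."""
    return mae(recon_x, x) + mae(recon_y, y)


def lsgan_g_loss(d_scores_on_fake: np.ndarray) -> float:
    """Least-squares generator loss: mean over the score map of (D(fake)-1)^2."""
    s = np.asarray(d_scores_on_fake, float)
    return float(np.mean((s - 1.0) ** 2))


def lsgan_d_loss(d_scores_on_real: np.ndarray,
                 d_scores_on_fake: np.ndarray) -> float:
    """Least-squares discriminator loss: mean(D(real)-1)^2 + mean(D(fake))^2."""
    r = np.asarray(d_scores_on_real, float)
    f = np.asarray(d_scores_on_fake, float)
    return float(np.mean((r - 1.0) ** 2) + np.mean(f ** 2))


def prior_loss(generated: np.ndarray, prior: PriorImage,
               generated_id: int | None = None) -> float:
    """Mean absolute error between the forward generator's output and the
    prior image.  When ``generated_id`` is given it must equal the prior's
    ``source_id`` (guards index alignment between slices and priors)."""
    if generated_id is not None and generated_id != prior.source_id:
        raise ValueError(f"prior for slice {prior.source_id} applied to "
                         f"slice {generated_id}")
    return mae(generated, prior.pixels)


def total_generator_loss(parts: LossReport, weights: LossWeights) -> float:
    """g_adv_N + g_adv_L + lambda*cycle + alpha*prior (prior reported
    separately even though it belongs to the forward adversarial term)."""
    vals = (parts.g_adv_N, parts.g_adv_L, parts.cycle, parts.prior)
    if not all(np.isfinite(v) for v in vals):
        raise ValueError("loss components must be finite")
    return float(parts.g_adv_N + parts.g_adv_L
                 + weights.lambda_cyc * parts.cycle
                 + weights.alpha_prior * parts.prior)


# -- gradients of the scalar losses w.r.t. their array arguments, used by the
#    trainer's manual backprop ------------------------------------------------

def d_lsgan_g(scores: np.ndarray) -> np.ndarray:
    return 2.0 * (scores - 1.0) / scores.size


def d_lsgan_d_real(scores: np.ndarray) -> np.ndarray:
    return 2.0 * (scores - 1.0) / scores.size


def d_lsgan_d_fake(scores: np.ndarray) -> np.ndarray:
    return 2.0 * scores / scores.size


def d_mae(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """d mean|a-b| / da (sign convention: subgradient 0 at ties)."""
    return np.sign(a - b) / a.size
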