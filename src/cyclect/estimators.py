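"""scikit-learn-style estimators: the public fit/transform surface.

``CycleGANDenoiser.fit(X, y)`` trains the unpaired translation networks on
two slice collections (X low dose, y normal dose — index correspondence is
neither required nor used); ``transform(X)`` applies the trained forward
generator.  ``BM3DDenoiser`` is the stateless classical baseline behind the
same interface and is also what produces the prior images internally.

Both compose with sklearn pipelines and ``get_params``/``set_params``
model-selection machinery.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .bm3d import BM3DProfile
from .dataprep import build_unpaired_dataset
from .datatypes import CT_RANGE, CTSlice
from .losses import LossWeights
from .prior import build_prior_set, estimate_noise_sigma
from .training import TrainConfig, denoise, select_best_checkpoint, train


def _to_slices(X, dose: float = 1.0) -> list[CTSlice]:
    if len(X) and isinstance(X[0], CTSlice):
        return list(X)
    arr = np.asarray(X, np.float64)
    if arr.ndim != 3:
        raise ValueError("expected (n_slices, H, W) array or list of CTSlice")
    return [CTSlice(pixels=a, dose_fraction=dose, id=i) for i, a in enumerate(arr)]


class BM3DDenoiser(TransformerMixin, BaseEstimator):
    """Slice-wise BM3D with per-slice noise estimation.

    Parameters
    ----------
    sigma : float or None
        Noise standard deviation on the image scale; None estimates it per
        slice from the finest-scale wavelet detail.
    block_size, step, search_radius, max_matches, ht_threshold :
        Grouping/shrinkage parameters, see :class:`~cyclect.bm3d.BM3DProfile`.
    """

    def __init__(self, sigma: float | None = None, block_size: int = 8,
                 step: int = 4, search_radius: int = 19, max_matches: int = 16,
                 ht_threshold: float = 2.7):
        self.sigma = sigma
        self.block_size = block_size
        self.step = step
        self.search_radius = search_radius
        self.max_matches = max_matches
        self.ht_threshold = ht_threshold

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X[0]).size if len(X) else 0
        return self

    def _profile(self) -> BM3DProfile:
        return BM3DProfile(self.block_size, self.step, self.search_radius,
                           self.max_matches, self.ht_threshold)

    def transform(self, X) -> np.ndarray:
        from .bm3d import bm3d
        prof = self._profile()
        out = []
        for s in _to_slices(X):
            sig = self.sigma if self.sigma is not None else estimate_noise_sigma(s)
            out.append(bm3d(s.pixels, sig, prof))
        return np.stack(out)


class CycleGANDenoiser(TransformerMixin, BaseEstimator):
    """Unpaired low-dose CT denoiser: cycle-consistent least-squares GAN with
    a BM3D prior-image anchor on the forward generator.

    Defaults mirror the published training protocol (width-64 generators
    with 6 residual blocks, lambda = alpha = 10, Adam batch 1, lr 2e-4
    constant for 10k epochs then linearly decayed to zero at 20k).  For
    desk-scale experiments pass smaller ``width``/``total_epochs``.

    Parameters
    ----------
    width : base filter count of generators/discriminators.
    n_res_blocks : residual blocks in the generator's convertor.
    lambda_cyc, alpha_prior : cycle and prior loss weights.
    prior_method : "bm3d" | "gaussian" | "nlm" | None (None disables the
        prior term, recovering the plain cycle-consistent baseline).
    total_epochs, decay_start_epoch, max_steps : training budget.
    checkpoint_every : record a checkpoint every k epochs; when nonzero the
        fitted generator is the checkpoint with the best unpaired-legal
        validation score (prior MAE, or cycle error without a prior) rather
        than the endpoint.
    random_state : master seed for weights, sampling and noise.

    Attributes
    ----------
    generator_state_ : trained forward-generator weights (portable).
    series_ : full checkpoint series.
    loss_log_ : per-step loss component records.
    """

    def __init__(self, width: int = 64, n_res_blocks: int = 6,
                 lambda_cyc: float = 10.0, alpha_prior: float = 10.0,
                 prior_method: str | None = "bm3d",
                 lr0: float = 2e-4, total_epochs: int = 20000,
                 decay_start_epoch: int | None = None,
                 max_steps: int | None = None, batch_size: int = 1,
                 adam_beta1: float = 0.5, adam_beta2: float = 0.999,
                 ct_range: tuple[float, float] = CT_RANGE,
                 checkpoint_every: int = 0, random_state: int = 0):
        self.width = width
        self.n_res_blocks = n_res_blocks
        self.lambda_cyc = lambda_cyc
        self.alpha_prior = alpha_prior
        self.prior_method = prior_method
        self.lr0 = lr0
        self.total_epochs = total_epochs
        self.decay_start_epoch = decay_start_epoch
        self.max_steps = max_steps
        self.batch_size = batch_size
        self.adam_beta1 = adam_beta1
        self.adam_beta2 = adam_beta2
        self.ct_range = ct_range
        self.checkpoint_every = checkpoint_every
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        decay = (self.decay_start_epoch if self.decay_start_epoch is not None
                 else max(1, self.total_epochs // 2))
        use_prior = self.prior_method is not None and self.alpha_prior > 0
        return TrainConfig(
            lr0=self.lr0, total_epochs=self.total_epochs,
            decay_start_epoch=decay, batch_size=self.batch_size,
            weights=LossWeights(self.lambda_cyc, self.alpha_prior),
            seed=self.random_state, adam_beta1=self.adam_beta1,
            adam_beta2=self.adam_beta2, width=self.width,
            n_res_blocks=self.n_res_blocks, use_prior=use_prior,
            ct_range=self.ct_range, checkpoint_every=self.checkpoint_every,
            max_steps=self.max_steps)

    def fit(self, X, y, priors=None):
        """Train on unpaired collections X (low dose) and y (normal dose).

        ``priors`` may supply precomputed prior images (index-aligned with
        X); otherwise they are computed with ``prior_method``.
        """
        low = _to_slices(X, dose=0.05)
        normal = _to_slices(y, dose=1.0)
        dataset = build_unpaired_dataset(low, normal,
                                         break_pairing_seed=self.random_state)
        cfg = self._config()
        prior_set = None
        if cfg.use_prior:
            prior_set = (list(priors) if priors is not None
                         else build_prior_set(dataset, method=self.prior_method))
        self.loss_log_ = []
        self.series_ = train(dataset, prior_set, cfg, log=self.loss_log_)
        # with intermediate checkpoints available, pick the one with the best
        # unpaired-legal validation score instead of trusting the endpoint
        if cfg.checkpoint_every:
            self.generator_state_ = select_best_checkpoint(
                self.series_, dataset, prior_set)
        else:
            self.generator_state_ = self.series_.generator_state("G_N")
        self.n_features_in_ = low[0].pixels.size
        return self

    def transform(self, X, mode: str = "full", patch_size: int = 128) -> np.ndarray:
        """Denoise slices with the trained forward generator."""
        check_is_fitted(self, "generator_state_")
        outs = [denoise(s, self.generator_state_, mode=mode,
                        patch_size=patch_size, ct_range=self.ct_range).pixels
                for s in _to_slices(X)]
        return np.stack(outs)
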