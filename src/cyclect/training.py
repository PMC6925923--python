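"""Alternating adversarial optimization for the unpaired denoiser.

Each step touches all four networks exactly once: first the two generators
are updated jointly on the least-squares adversarial terms, the
cycle-consistency term and (forward generator only) the prior-image MAE;
then the two discriminators are updated on real/fake score maps with the
fakes detached.  Adam (batch size 1 by default) with a piecewise learning
rate: constant for ``decay_start_epoch`` epochs, then linearly decayed to
zero at ``total_epochs``.

Images are mapped from the configured CT range to [-1, 1] before entering
the networks and mapped back afterwards.  All randomness flows from
``TrainConfig.seed``; single-threaded runs are bit-reproducible and
resumable from checkpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import losses as L
from . import models, nn
from .dataprep import extract_patches, reassemble_patches
from .datatypes import CT_RANGE, CTSlice, PriorImage, UnpairedDataset


class TrainingDiverged(RuntimeError):
    """Raised when a loss goes non-finite; carries a diagnostic snapshot."""

    def __init__(self, msg: str, snapshot: dict):
        super().__init__(msg)
        self.snapshot = snapshot


@dataclass
class TrainConfig:
    lr0: float = 2e-4
    total_epochs: int = 20000
    decay_start_epoch: int = 10000
    batch_size: int = 1
    weights: L.LossWeights = field(default_factory=L.LossWeights)
    seed: int = 0
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    channels: int = 1
    width: int = 64
    n_res_blocks: int = 6
    use_prior: bool = True
    ct_range: tuple[float, float] = CT_RANGE
    checkpoint_every: int = 0        # 0: record only init + final
    max_steps: int | None = None     # alternative budget unit (total steps)

    def __post_init__(self) -> None:
        if not (0 < self.decay_start_epoch <= self.total_epochs):
            if self.total_epochs != 0:   # 0-epoch runs are legal no-ops
                raise ValueError("need 0 < decay_start_epoch <= total_epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Constant at lr0, then linear decay to 0 at ``total_epochs``."""
    if epoch < 0 or epoch > cfg.total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.total_epochs}]")
    if epoch < cfg.decay_start_epoch:
        return cfg.lr0
    span = cfg.total_epochs - cfg.decay_start_epoch
    if span == 0:
        return 0.0 if epoch == cfg.total_epochs else cfg.lr0
    return cfg.lr0 * (cfg.total_epochs - epoch) / span


@dataclass
class WeightState:
    """Portable generator weights plus the architecture needed to rebuild it."""

    in_channels: int
    out_channels: int
    width: int
    n_res_blocks: int
    weights: dict[str, np.ndarray]

    def realize(self) -> nn.Network:
        spec = models.build_generator(self.in_channels, self.out_channels,
                                      self.width, self.n_res_blocks)
        net = models.realize_generator(spec)
        net.set_weights(self.weights)
        return net


@dataclass
class Checkpoint:
    epoch: int
    net_weights: dict[str, dict[str, np.ndarray]]   # G_N, F_L, D_N, D_L
    optim_state: dict
    rng_state: dict
    report: L.LossReport


@dataclass
class CheckpointSeries:
    cfg: TrainConfig
    checkpoints: list[Checkpoint] = field(default_factory=list)

    def last(self) -> Checkpoint:
        return self.checkpoints[-1]

    def generator_state(self, which: str = "G_N", index: int = -1) -> WeightState:
        ck = self.checkpoints[index]
        return WeightState(self.cfg.channels, self.cfg.channels, self.cfg.width,
                           self.cfg.n_res_blocks, ck.net_weights[which])


class GANState:
    """The four networks, their optimizers and the training RNG."""

    NAMES = ("G_N", "F_L", "D_N", "D_L")

    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        c, w = cfg.channels, cfg.width
        gspec = models.build_generator(c, c, w, cfg.n_res_blocks)
        dspec = models.build_discriminator(c, w)
        self.G_N = models.realize_generator(gspec)
        self.F_L = models.realize_generator(gspec)
        self.D_N = models.realize_discriminator(dspec)
        self.D_L = models.realize_discriminator(dspec)
        seeds = np.random.SeedSequence(cfg.seed).generate_state(5)
        for net, s in zip(self.nets, seeds[:4]):
            net.init_weights(int(s % (2 ** 31)))
        self.rng = np.random.default_rng(int(seeds[4] % (2 ** 31)))
        ad = dict(lr=cfg.lr0, beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
        self.opt_G = nn.Adam(self.G_N.params + self.F_L.params, **ad)
        self.opt_D = nn.Adam(self.D_N.params + self.D_L.params, **ad)
        self.step_count = 0

    @property
    def nets(self):
        return (self.G_N, self.F_L, self.D_N, self.D_L)

    def set_lr(self, lr: float) -> None:
        self.opt_G.lr = lr
        self.opt_D.lr = lr

    def snapshot(self, epoch: int, report: L.LossReport) -> Checkpoint:
        return Checkpoint(
            epoch=epoch,
            net_weights={n: net.get_weights() for n, net in zip(self.NAMES, self.nets)},
            optim_state={"G": self.opt_G.state(), "D": self.opt_D.state(),
                         "step_count": self.step_count},
            rng_state=self.rng.bit_generator.state,
            report=report)

    def restore(self, ck: Checkpoint) -> None:
        for name, net in zip(self.NAMES, self.nets):
            net.set_weights(ck.net_weights[name])
        self.opt_G.load_state(ck.optim_state["G"])
        self.opt_D.load_state(ck.optim_state["D"])
        self.step_count = ck.optim_state["step_count"]
        self.rng.bit_generator.state = ck.rng_state


def _normalize(x: np.ndarray, ct_range) -> np.ndarray:
    lo, hi = ct_range
    c, h = (lo + hi) / 2.0, (hi - lo) / 2.0
    return (np.asarray(x, np.float64) - c) / h


def _denormalize(x: np.ndarray, ct_range) -> np.ndarray:
    lo, hi = ct_range
    c, h = (lo + hi) / 2.0, (hi - lo) / 2.0
    return x * h + c


def _as_batch(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, np.float64)
    if x.ndim == 2:
        x = x[None]
    return x[:, None]        # (N, 1, H, W)


def training_step(batch_x: np.ndarray, batch_y: np.ndarray,
                  prior_for_x: np.ndarray | None,
                  state: GANState) -> L.LossReport:
    """One alternating update on raw-scale image batches.

    ``prior_for_x`` must be present iff ``cfg.use_prior``; all inputs are
    (H, W) or (N, H, W) arrays on the configured CT scale.
    """
    cfg = state.cfg
    if cfg.use_prior and prior_for_x is None:
        raise ValueError("use_prior is set but no prior batch was given")
    w = cfg.weights
    x = _as_batch(_normalize(batch_x, cfg.ct_range))
    y = _as_batch(_normalize(batch_y, cfg.ct_range))
    prior = (_as_batch(_normalize(prior_for_x, cfg.ct_range))
             if prior_for_x is not None else None)

    G, F, DN, DL = state.G_N, state.F_L, state.D_N, state.D_L

    # ---- generator update (discriminator grads discarded afterwards) ----
    for net in state.nets:
        net.zero_grad()
    fake_y, tG1 = G.forward(x)
    rec_x, tF1 = F.forward(fake_y)
    fake_x, tF2 = F.forward(y)
    rec_y, tG2 = G.forward(fake_x)
    sN, tDN = DN.forward(fake_y)
    sL, tDL = DL.forward(fake_x)

    rep = L.LossReport(
        g_adv_N=L.lsgan_g_loss(sN),
        g_adv_L=L.lsgan_g_loss(sL),
        cycle=float(np.mean(np.abs(rec_x - x)) + np.mean(np.abs(rec_y - y))),
        prior=float(np.mean(np.abs(fake_y - prior))) if prior is not None else 0.0)
    rep.total_G = L.total_generator_loss(rep, w)

    # gradients into fake_y: adversarial + forward cycle + prior MAE
    d_fake_y = DN.backward(tDN, L.d_lsgan_g(sN))
    d_fake_y = d_fake_y + F.backward(tF1, w.lambda_cyc * L.d_mae(rec_x, x))
    if prior is not None:
        d_fake_y = d_fake_y + w.alpha_prior * L.d_mae(fake_y, prior)
    G.backward(tG1, d_fake_y)
    # gradients into fake_x: adversarial + backward cycle
    d_fake_x = DL.backward(tDL, L.d_lsgan_g(sL))
    d_fake_x = d_fake_x + G.backward(tG2, w.lambda_cyc * L.d_mae(rec_y, y))
    F.backward(tF2, d_fake_x)
    state.opt_G.step()

    # ---- discriminator update (fakes detached: recomputed scores only) ----
    for net in (DN, DL):
        net.zero_grad()
    sr_N, tDNr = DN.forward(y)
    sf_N, tDNf = DN.forward(fake_y)
    sr_L, tDLr = DL.forward(x)
    sf_L, tDLf = DL.forward(fake_x)
    rep.d_loss_N = L.lsgan_d_loss(sr_N, sf_N)
    rep.d_loss_L = L.lsgan_d_loss(sr_L, sf_L)
    DN.backward(tDNr, L.d_lsgan_d_real(sr_N))
    DN.backward(tDNf, L.d_lsgan_d_fake(sf_N))
    DL.backward(tDLr, L.d_lsgan_d_real(sr_L))
    DL.backward(tDLf, L.d_lsgan_d_fake(sf_L))
    state.opt_D.step()

    state.step_count += 1
    if not rep.is_finite():
        raise TrainingDiverged("non-finite loss encountered",
                               snapshot={"report": rep.as_dict(),
                                         "step": state.step_count})
    return rep


def epoch_pairings(rng: np.random.Generator, n_x: int, n_y: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Unpaired sampling for one epoch: a shuffle of the source indices and
    an independently drawn target index for each step."""
    x_idx = rng.permutation(n_x)
    y_idx = (rng.permutation(n_y) if n_y == n_x
             else rng.integers(0, n_y, size=n_x))
    return x_idx, y_idx


def train(dataset: UnpairedDataset, priors: Sequence[PriorImage] | None,
          cfg: TrainConfig, resume_from: Checkpoint | None = None,
          log: list | None = None) -> CheckpointSeries:
    """Run the optimization; returns the checkpoint series (init included)."""
    if cfg.use_prior:
        if priors is None or len(priors) != len(dataset.source_X):
            raise ValueError("priors must be index-aligned with source_X")
        for ct, p in zip(dataset.source_X, priors):
            if ct.id != p.source_id:
                raise ValueError(f"prior {p.source_id} misaligned with slice {ct.id}")
    state = GANState(cfg)
    series = CheckpointSeries(cfg=cfg)
    start_epoch = 0
    if resume_from is not None:
        state.restore(resume_from)
        start_epoch = resume_from.epoch
    else:
        series.checkpoints.append(state.snapshot(0, L.LossReport()))

    xs = [s.pixels for s in dataset.source_X]
    ys = [s.pixels for s in dataset.target_Y]
    pr = [p.pixels for p in priors] if cfg.use_prior else None
    n_x, n_y = len(xs), len(ys)
    done = False
    for epoch in range(start_epoch, cfg.total_epochs):
        state.set_lr(lr_at_epoch(epoch, cfg))
        x_idx, y_idx = epoch_pairings(state.rng, n_x, n_y)
        rep = L.LossReport()
        for b0 in range(0, n_x, cfg.batch_size):
            xi = x_idx[b0:b0 + cfg.batch_size]
            yi = y_idx[b0:b0 + cfg.batch_size]
            bx = np.stack([xs[i] for i in xi])
            by = np.stack([ys[i] for i in yi])
            bp = np.stack([pr[i] for i in xi]) if pr is not None else None
            rep = training_step(bx, by, bp, state)
            if log is not None:
                log.append({"step": state.step_count, **rep.as_dict()})
            if cfg.max_steps is not None and state.step_count >= cfg.max_steps:
                done = True
                break
        at_checkpoint = (cfg.checkpoint_every and
                         (epoch + 1) % cfg.checkpoint_every == 0)
        if at_checkpoint or done or epoch + 1 == cfg.total_epochs:
            series.checkpoints.append(state.snapshot(epoch + 1, rep))
        if done:
            break
    return series


def select_best_checkpoint(series: CheckpointSeries, dataset: UnpairedDataset,
                           priors: Sequence[PriorImage] | None,
                           subset_stride: int = 6) -> WeightState:
    """Pick the forward-generator checkpoint with the best validation score.

    Adversarial training at small scale has a noisy endpoint, so the final
    weights are not necessarily the best ones.  The score uses only
    information that is legal under the unpaired contract — no normal-dose
    reference is touched: the mean absolute deviation of the generator
    output from the prior image on a fixed subset of source slices (the
    quantity the prior term explicitly controls), or, when training ran
    without a prior, the forward cycle reconstruction error.
    """
    cands = series.checkpoints[1:] if len(series.checkpoints) > 1 else series.checkpoints
    idx = range(0, len(dataset.source_X), subset_stride)
    best, best_score = None, np.inf
    for ck in cands:
        gen = WeightState(series.cfg.channels, series.cfg.channels,
                          series.cfg.width, series.cfg.n_res_blocks,
                          ck.net_weights["G_N"])
        if priors is not None:
            score = float(np.mean(
                [np.mean(np.abs(denoise(dataset.source_X[i], gen,
                                        ct_range=series.cfg.ct_range).pixels
                                - priors[i].pixels)) for i in idx]))
        else:
            back = WeightState(series.cfg.channels, series.cfg.channels,
                               series.cfg.width, series.cfg.n_res_blocks,
                               ck.net_weights["F_L"])
            score = 0.0
            for i in idx:
                fwd = denoise(dataset.source_X[i], gen, ct_range=series.cfg.ct_range)
                rec = denoise(fwd, back, ct_range=series.cfg.ct_range)
                score += float(np.mean(np.abs(rec.pixels
                                              - dataset.source_X[i].pixels)))
        if score < best_score:
            best, best_score = gen, score
    return best


def denoise(ct: CTSlice, generator: WeightState, mode: str = "full",
            patch_size: int = 128, ct_range=CT_RANGE) -> CTSlice:
    """Apply the trained forward generator to one slice.

    ``full`` runs the whole slice through the network (side must be
    divisible by 4); ``patched`` tiles the slice, denoises each tile and
    reassembles.  Inference is deterministic for fixed weights.
    """
    net = generator.realize()

    def run(img: np.ndarray) -> np.ndarray:
        z = _as_batch(_normalize(img, ct_range))
        out = net(z)[0, 0]
        return _denormalize(out, ct_range)

    if mode == "full":
        if ct.side % 4 != 0:
            raise ValueError("slice side must be divisible by 4 in full mode")
        pixels = run(ct.pixels)
    elif mode == "patched":
        patches = extract_patches(ct, patch_size)
        if patch_size % 4 != 0:
            raise ValueError("patch size must be divisible by 4")
        for p in patches:
            p.pixels = run(p.pixels)
        pixels = reassemble_patches(patches, ct.side).pixels
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CTSlice(pixels=pixels, dose_fraction=ct.dose_fraction,
                   provenance=ct.provenance, id=ct.id)
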