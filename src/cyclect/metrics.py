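"""Image-quality metrics (PSNR, SSIM, NMAD), test-set aggregation, the
alpha-sweep protocol and display-window export.

PSNR = 10 log10( MAX^2 / MSE ) with MAX the declared dynamic range of the
reference scale — PSNR is meaningless without one, so every report logs the
range used.  NMAD = sum|f - f0| / sum|f| with f the *denoised* image in the
denominator (an intentional asymmetry; a ``normalize_by_reference`` flag
offers the more common convention).  SSIM uses a Gaussian 11x11 window
(sigma 1.5) with K1=0.01, K2=0.03.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.metrics import structural_similarity

from .datatypes import CT_RANGE, CTSlice

DEFAULT_MAX_VAL = CT_RANGE[1] - CT_RANGE[0]


def _pix(a) -> np.ndarray:
    return a.pixels if isinstance(a, CTSlice) else np.asarray(a, np.float64)


def psnr(f, f0, max_val: float = DEFAULT_MAX_VAL) -> float:
    """Peak signal-to-noise ratio in dB; identical images give +inf."""
    f, f0 = _pix(f), _pix(f0)
    if f.shape != f0.shape:
        raise ValueError("shape mismatch")
    if max_val <= 0:
        raise ValueError("max_val must be positive")
    mse = float(np.mean((f - f0) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(max_val ** 2 / mse)


def nmad(f, f0, normalize_by_reference: bool = False) -> float:
    """Normalized mean absolute distance: sum|f - f0| / sum|f|."""
    f, f0 = _pix(f), _pix(f0)
    if f.shape != f0.shape:
        raise ValueError("shape mismatch")
    denom = float(np.sum(np.abs(f0 if normalize_by_reference else f)))
    if denom == 0.0:
        raise ZeroDivisionError("NMAD undefined: normalizing image is all zero")
    return float(np.sum(np.abs(f - f0)) / denom)


@dataclass
class SSIMParams:
    window: int = 11
    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    data_range: float = DEFAULT_MAX_VAL


def ssim(f, f0, params: SSIMParams | None = None) -> float:
    """Mean local structural similarity with a Gaussian window (<= 1,
    and 1 exactly iff the images are identical)."""
    p = params or SSIMParams()
    f, f0 = _pix(f), _pix(f0)
    if f.shape != f0.shape:
        raise ValueError("shape mismatch")
    if p.window > min(f.shape):
        raise ValueError("SSIM window larger than image")
    return float(structural_similarity(
        f, f0, win_size=p.window, gaussian_weights=True, sigma=p.sigma,
        K1=p.k1, K2=p.k2, data_range=p.data_range,
        use_sample_covariance=False))


@dataclass
class MethodMetrics:
    name: str
    psnr_values: list[float]
    ssim_values: list[float]
    nmad_values: list[float]

    def _ms(self, vals: list[float]) -> tuple[float, float]:
        finite = [v for v in vals if math.isfinite(v)]
        if len(finite) < len(vals):
            warnings.warn(f"{self.name}: {len(vals) - len(finite)} infinite "
                          "PSNR value(s) excluded from the mean")
        a = np.asarray(finite if finite else [math.inf])
        return float(a.mean()), float(a.std())

    def summary(self) -> dict[str, tuple[float, float]]:
        return {"PSNR": self._ms(self.psnr_values),
                "SSIM": self._ms(self.ssim_values),
                "NMAD": self._ms(self.nmad_values)}


@dataclass
class MetricReport:
    methods: list[MethodMetrics]
    max_val: float

    def to_text(self) -> str:
        lines = [f"(dynamic range MAX = {self.max_val:g})",
                 f"{'method':<16}{'PSNR':>20}{'SSIM':>20}{'NMAD':>20}"]
        for m in self.methods:
            s = m.summary()
            cells = [f"{s[k][0]:.4f} ± {s[k][1]:.4f}" for k in ("PSNR", "SSIM", "NMAD")]
            lines.append(f"{m.name:<16}{cells[0]:>20}{cells[1]:>20}{cells[2]:>20}")
        return "\n".join(lines)


def evaluate(method_outputs: dict[str, Sequence], reference: Sequence,
             max_val: float = DEFAULT_MAX_VAL,
             ssim_params: SSIMParams | None = None) -> MetricReport:
    """Per-slice PSNR/SSIM/NMAD against the reference collection, aggregated
    as mean +- std per method.  Collections must be index-aligned."""
    sp = ssim_params or SSIMParams(data_range=max_val)
    ref = [_pix(r) for r in reference]
    methods = []
    for name, outs in method_outputs.items():
        outs = [_pix(o) for o in outs]
        if len(outs) != len(ref):
            raise ValueError(f"method {name!r} not aligned with reference")
        methods.append(MethodMetrics(
            name,
            [psnr(o, r, max_val) for o, r in zip(outs, ref)],
            [ssim(o, r, sp) for o, r in zip(outs, ref)],
            [nmad(o, r) for o, r in zip(outs, ref)]))
    return MetricReport(methods=methods, max_val=max_val)


def apply_display_window(ct, lo: float, hi: float) -> np.ndarray:
    """Clip to [lo, hi], map affinely to [0, 255], round half-to-even; returns
    an 8-bit image for visual inspection (e.g. the bone window [800, 1300])."""
    if lo >= hi:
        raise ValueError("display window requires lo < hi")
    pix = _pix(ct)
    scaled = (np.clip(pix, lo, hi) - lo) / (hi - lo) * 255.0
    return np.rint(scaled).astype(np.uint8)   # rint rounds half to even


def alpha_sweep(dataset, priors, alpha_grid: Sequence[float], cfg,
                eval_inputs: Sequence[CTSlice], eval_reference: Sequence[CTSlice],
                n_eval: int = 10, seed: int = 0,
                max_val: float = DEFAULT_MAX_VAL) -> list[dict]:
    """Train one network per alpha (all other settings identical) and
    evaluate each on a seeded random sample of ``n_eval`` held-out slices.
    Returns the (alpha, mean SSIM, mean NMAD) curve."""
    from dataclasses import replace
    from .training import denoise, train

    if len(alpha_grid) == 0:
        raise ValueError("alpha_grid must be non-empty")
    rng = np.random.default_rng(seed)
    n_eval = min(n_eval, len(eval_inputs))
    pick = rng.choice(len(eval_inputs), size=n_eval, replace=False)
    curve = []
    for alpha in alpha_grid:
        acfg = replace(cfg, weights=replace(cfg.weights, alpha_prior=float(alpha)),
                       use_prior=alpha > 0)
        series = train(dataset, priors if acfg.use_prior else None, acfg)
        gen = series.generator_state("G_N")
        outs = [denoise(eval_inputs[i], gen, mode="full", ct_range=cfg.ct_range)
                for i in pick]
        refs = [eval_reference[i] for i in pick]
        sp = SSIMParams(data_range=max_val)
        curve.append({
            "alpha": float(alpha),
            "mean_ssim": float(np.mean([ssim(o, r, sp) for o, r in zip(outs, refs)])),
            "mean_nmad": float(np.mean([nmad(o, r) for o, r in zip(outs, refs)])),
        })
    return curve
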