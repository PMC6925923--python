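"""Prior-image production: denoise each low-dose slice independently.

The prior image anchors the forward generator during unpaired training: the
generator's output is pulled (by a weighted MAE) toward a classically
denoised version of its *own input*, so no information from the normal-dose
target collection leaks in and the unpaired property is preserved.  BM3D is
the default denoiser; Gaussian and non-local-means alternatives are
available behind the same interface for fast runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pywt
from scipy.ndimage import gaussian_filter, median_filter
from skimage.restoration import denoise_nl_means

from .bm3d import BM3DProfile, bm3d
from .datatypes import CTSlice, PriorImage, UnpairedDataset


def estimate_noise_sigma(ct: CTSlice | np.ndarray) -> float:
    """Robust noise estimate from the finest-scale diagonal wavelet detail:
    ``median(|d|) / 0.6745`` (Donoho's MAD estimator).  Shift-invariant;
    returns 0 for a constant image."""
    pix = ct.pixels if isinstance(ct, CTSlice) else np.asarray(ct, float)
    _, (_, _, diag) = pywt.dwt2(pix, "db2")
    sigma = float(np.median(np.abs(diag)) / 0.6745)
    # constant (or numerically constant) images carry no noise signal
    if sigma <= 1e-9 * max(1.0, float(np.abs(pix).max())):
        return 0.0
    return sigma


def bm3d_denoise(ct: CTSlice, sigma: float | None = None,
                 profile: BM3DProfile | None = None) -> PriorImage:
    """BM3D-denoise one slice into a prior image.

    ``sigma=None`` estimates the noise level from the slice itself.
    """
    if sigma is None:
        sigma = estimate_noise_sigma(ct)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = bm3d(ct.pixels, sigma, profile)
    return PriorImage(pixels=out, source_id=ct.id, sigma_used=float(sigma),
                      method_tag="bm3d")


def _denoise_one(ct: CTSlice, method: str, sigma: float | None,
                 profile: BM3DProfile | None) -> PriorImage:
    if method == "bm3d":
        return bm3d_denoise(ct, sigma, profile)
    s = estimate_noise_sigma(ct) if sigma is None else float(sigma)
    if method == "gaussian":
        out = gaussian_filter(ct.pixels, sigma=1.5)
    elif method == "median":
        # classical choice against sparse streak noise in sparse-view FBP
        # reconstructions, where a white-noise sigma estimate biases low
        out = median_filter(ct.pixels, size=3)
    elif method == "nlm":
        out = denoise_nl_means(ct.pixels, h=0.8 * s if s > 0 else 1.0,
                               sigma=s, fast_mode=True, patch_size=5,
                               patch_distance=6)
    else:
        raise ValueError(f"unknown prior method {method!r}")
    return PriorImage(pixels=out, source_id=ct.id, sigma_used=s, method_tag=method)


def build_prior_set(dataset: UnpairedDataset, profile: BM3DProfile | None = None,
                    method: str = "bm3d", sigma: float | None = None,
                    cache_dir: str | Path | None = None) -> list[PriorImage]:
    """One prior per source slice, index-aligned with ``dataset.source_X``.

    Reads only the source (low-dose) collection — ``target_Y`` is never
    touched.  With ``cache_dir``, priors are persisted per slice and reused
    byte-identically on a second invocation.
    """
    priors: list[PriorImage] = []
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    for ct in dataset.source_X:
        key = None
        if cache is not None:
            digest = hashlib.sha256(ct.pixels.tobytes()).hexdigest()[:16]
            key = cache / f"prior_{ct.id}_{method}_{digest}.npz"
            if key.exists():
                with np.load(key) as z:
                    priors.append(PriorImage(pixels=z["pixels"],
                                             source_id=int(z["source_id"]),
                                             sigma_used=float(z["sigma_used"]),
                                             method_tag=method))
                continue
        p = _denoise_one(ct, method, sigma, profile)
        if key is not None:
            np.savez(key, pixels=p.pixels, source_id=p.source_id,
                     sigma_used=p.sigma_used)
        priors.append(p)
    if cache is not None:
        manifest = {str(p.source_id): {"sigma_used": p.sigma_used,
                                       "method": p.method_tag}
                    for p in priors}
        (cache / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return priors
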