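"""Two-stage BM3D (block-matching and 3-D collaborative filtering) in NumPy.

Stage 1 groups similar 8x8 blocks (L2 patch distance within a search
window), applies a separable 3-D transform (orthonormal 2-D DCT per block,
orthonormal 1-D Haar across the stack), hard-thresholds at ``k * sigma``,
inverts and aggregates overlapping block estimates with per-group weights
inversely proportional to the retained-coefficient count.  Stage 2 re-runs
block matching on the stage-1 estimate and applies empirical Wiener
shrinkage, using the stage-1 group energies as the signal-power estimate.

The global DC coefficient of each group is never shrunk, so flat images
pass through unchanged; at ``sigma == 0`` the filter is the exact identity.
Output is clipped to the input's own intensity range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import dctn, idctn


@dataclass
class BM3DProfile:
    """Grouping/shrinkage parameters (defaults follow the standard profile)."""

    block_size: int = 8
    step: int = 4                # reference-block grid step
    search_radius: int = 19      # 39x39 search window
    max_matches: int = 16        # blocks per group (kept a power of two)
    ht_threshold: float = 2.7    # hard threshold, in units of sigma


def _haar_matrix(n: int) -> np.ndarray:
    """Orthonormal Haar transform matrix for n a power of two."""
    h = np.array([[1.0]])
    while h.shape[0] < n:
        m = h.shape[0]
        top = np.kron(h, [1.0, 1.0])
        bot = np.kron(np.eye(m), [1.0, -1.0])
        h = np.vstack([top, bot]) / np.sqrt(2.0)
    return h


def _ref_positions(extent: int, block: int, step: int) -> np.ndarray:
    pos = list(range(0, extent - block + 1, step))
    if pos[-1] != extent - block:
        pos.append(extent - block)
    return np.asarray(pos)


def _match(blocks: np.ndarray, ri: int, ci: int, prof: BM3DProfile
           ) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of the blocks most similar to the reference at (ri, ci)."""
    nr, nc = blocks.shape[:2]
    r0, r1 = max(0, ri - prof.search_radius), min(nr, ri + prof.search_radius + 1)
    c0, c1 = max(0, ci - prof.search_radius), min(nc, ci + prof.search_radius + 1)
    cand = blocks[r0:r1, c0:c1]
    ref = blocks[ri, ci]
    d = ((cand - ref) ** 2).sum(axis=(2, 3)).ravel()
    # the reference always joins its own group (guarantees full coverage even
    # under exact distance ties, e.g. constant images)
    d[(ri - r0) * (c1 - c0) + (ci - c0)] = -1.0
    n = min(prof.max_matches, d.size)
    n = 2 ** int(np.log2(n))                       # power-of-two stack for Haar
    idx = np.argpartition(d, n - 1)[:n]
    idx = idx[np.argsort(d[idx], kind="stable")]
    rows, cols = np.unravel_index(idx, cand.shape[:2])
    return rows + r0, cols + c0


def _aggregate(num: np.ndarray, den: np.ndarray, rows: np.ndarray,
               cols: np.ndarray, est: np.ndarray, weight: float, b: int) -> None:
    for k in range(est.shape[0]):
        r, c = rows[k], cols[k]
        num[r:r + b, c:c + b] += weight * est[k]
        den[r:r + b, c:c + b] += weight


def bm3d(image: np.ndarray, sigma: float, profile: BM3DProfile | None = None
         ) -> np.ndarray:
    """Denoise a 2-D image contaminated by (approximately) white noise of
    standard deviation ``sigma`` on the image's own intensity scale."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    x = np.asarray(image, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("bm3d expects a 2-D image")
    prof = profile or BM3DProfile()
    if sigma == 0:
        return x.copy()
    lo, hi = float(x.min()), float(x.max())
    basic = _stage(x, x, sigma, prof, wiener=False)
    final = _stage(x, basic, sigma, prof, wiener=True)
    return np.clip(final, lo, hi)


def _stage(noisy: np.ndarray, pilot: np.ndarray, sigma: float,
           prof: BM3DProfile, wiener: bool) -> np.ndarray:
    """One collaborative-filtering pass.

    ``pilot`` drives the block matching (and, for the Wiener stage, the
    signal-energy estimate); ``noisy`` supplies the coefficients actually
    filtered.
    """
    b = prof.block_size
    h, w = noisy.shape
    if h < b or w < b:
        raise ValueError(f"image smaller than the {b}x{b} block size")
    blocks_noisy = sliding_window_view(noisy, (b, b))
    blocks_pilot = sliding_window_view(pilot, (b, b))
    haar_cache: dict[int, np.ndarray] = {}
    num = np.zeros_like(noisy)
    den = np.zeros_like(noisy)
    thr = prof.ht_threshold * sigma
    for ri in _ref_positions(h, b, prof.step):
        for ci in _ref_positions(w, b, prof.step):
            rows, cols = _match(blocks_pilot, ri, ci, prof)
            n = rows.size
            if n not in haar_cache:
                haar_cache[n] = _haar_matrix(n)
            hm = haar_cache[n]
            grp_n = dctn(blocks_noisy[rows, cols], axes=(1, 2), norm="ortho")
            coef_n = np.tensordot(hm, grp_n, axes=(1, 0))
            if wiener:
                grp_p = dctn(blocks_pilot[rows, cols], axes=(1, 2), norm="ortho")
                coef_p = np.tensordot(hm, grp_p, axes=(1, 0))
                shrink = coef_p ** 2 / (coef_p ** 2 + sigma ** 2)
                shrink[0, 0, 0] = 1.0          # keep the group DC
                coef = coef_n * shrink
                weight = 1.0 / max(float((shrink ** 2).sum()), 1e-12)
            else:
                keep = np.abs(coef_n) >= thr
                keep[0, 0, 0] = True           # keep the group DC
                coef = coef_n * keep
                weight = 1.0 / max(int(keep.sum()), 1)
            est = idctn(np.tensordot(hm.T, coef, axes=(1, 0)),
                        axes=(1, 2), norm="ortho")
            _aggregate(num, den, rows, cols, est, weight, b)
    return num / den
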