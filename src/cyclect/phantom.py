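"""Synthetic low-dose CT simulator.

Generates body-like attenuation phantoms, forward-projects them with a
parallel-beam Radon transform, injects sinogram-domain Poisson dose noise and
reconstructs with filtered back-projection (FBP).  The geometry (parallel
beam, 180 degree range) is deliberately simple: Radon/FBP then have clean,
testable reference behavior.

Intensity convention: reconstructed slices are mapped to a CT-number-like
scale via ``mu_to_ct`` (water attenuation -> 1000, air -> 0, dense bone
~ 2000), so display windows such as [800, 1300] apply to synthetic data.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import iradon, radon

from .datatypes import CT_RANGE, CTSlice, PhantomImage, SinogramSet

#: attenuation of water on the simulator's arbitrary linear scale
MU_WATER = 0.2

_FILTERS = {"ramp": "ramp", "shepp-logan": "shepp-logan"}


def mu_to_ct(mu: np.ndarray) -> np.ndarray:
    """Map linear attenuation to the CT-number-like scale (water -> 1000)."""
    ct = 1000.0 * mu / MU_WATER
    return np.clip(ct, CT_RANGE[0], CT_RANGE[1])


def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float,
                  theta: float = 0.0) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    y, x = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * x + st * y
    v = -st * x + ct * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def generate_phantom(seed: int, size: int = 512, n_soft_ellipses: int = 5,
                     n_bone_features: int = 2) -> PhantomImage:
    """Generate a body-like phantom: a large soft-tissue ellipse, random
    interior ellipses, and high-attenuation bone features.

    At least one bone feature contains a narrow gap (1-3 pixels wide) of
    soft-tissue attenuation: a probe for hallucinated bridging, the failure
    mode unpaired GAN denoisers are most criticized for.  Generation is a
    pure function of ``(seed, parameters)``.
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    if n_soft_ellipses < 0 or n_bone_features < 0:
        raise ValueError("feature counts must be >= 0")
    rng = np.random.default_rng(seed)
    mu = np.zeros((size, size), dtype=np.float64)
    mask = np.zeros((size, size), dtype=np.uint8)

    c = (size - 1) / 2.0
    # body ellipse, kept inside the inscribed circle so radon(circle=True) is exact
    body_ry = 0.42 * size * (0.95 + 0.1 * rng.random())
    body_rx = 0.34 * size * (0.95 + 0.1 * rng.random())
    body = _ellipse_mask(size, c, c, body_ry, body_rx, theta=0.0)
    mu[body] = MU_WATER * (0.98 + 0.04 * rng.random())
    mask[body] = PhantomImage.SOFT

    for _ in range(n_soft_ellipses):
        ry = size * rng.uniform(0.03, 0.10)
        rx = size * rng.uniform(0.03, 0.10)
        cy = c + rng.uniform(-0.25, 0.25) * size
        cx = c + rng.uniform(-0.20, 0.20) * size
        ell = _ellipse_mask(size, cy, cx, ry, rx, theta=rng.uniform(0, np.pi))
        ell &= body
        # contrast +-10% around water
        mu[ell] = MU_WATER * rng.uniform(0.90, 1.10)

    bone_mu = MU_WATER * rng.uniform(1.9, 2.1)
    for k in range(n_bone_features):
        ry = size * rng.uniform(0.025, 0.06)
        rx = size * rng.uniform(0.012, 0.03)
        cy = c + rng.uniform(-0.22, 0.22) * size
        cx = c + rng.uniform(-0.18, 0.18) * size
        ell = _ellipse_mask(size, cy, cx, ry, rx, theta=rng.uniform(0, np.pi))
        ell &= body
        mu[ell] = bone_mu
        mask[ell] = PhantomImage.BONE
        if k == 0 and ell.any():
            # carve a narrow gap (1-3 px) through the first bone feature
            width = int(rng.integers(1, 4))
            rows = np.where(ell.any(axis=1))[0]
            row0 = rows[len(rows) // 2]
            gap = np.zeros_like(ell)
            gap[row0:row0 + width, :] = True
            gap &= ell
            mu[gap] = MU_WATER
            mask[gap] = PhantomImage.GAP

    return PhantomImage(pixels=mu, size=size, seed=seed, structure_mask=mask)


#: total attenuation (mu * length, unitless) of a water path across the full
#: image width -- keeps photon transmission realistic at every grid size
WATER_PATH_ATTENUATION = 5.0


def forward_project(phantom: PhantomImage, n_angles: int = 720,
                    n_detectors: int | None = None,
                    incident_counts: float = 1.0e5,
                    water_path_attenuation: float = WATER_PATH_ATTENUATION
                    ) -> SinogramSet:
    """Parallel-beam Radon transform of a phantom.

    Pixel sums are converted to physical line integrals so that a water path
    spanning the image accumulates ``water_path_attenuation`` (default 5, a
    body-scale value): the photon statistics are then independent of the
    grid size.  ``n_detectors`` defaults to the phantom side (skimage's
    convention for ``circle=True``); other values resample the detector axis
    linearly.  Line integrals of a non-negative image are clamped at 0 to
    remove interpolation-induced negative dust.
    """
    if n_angles < 2:
        raise ValueError("need at least 2 projection angles")
    angles = np.linspace(0.0, 180.0, n_angles, endpoint=False)
    sino = radon(phantom.pixels, theta=angles, circle=True).T  # (angles, bins)
    if n_detectors is not None and n_detectors != sino.shape[1]:
        src = np.linspace(0, 1, sino.shape[1])
        dst = np.linspace(0, 1, n_detectors)
        sino = np.stack([np.interp(dst, src, row) for row in sino])
    scale = water_path_attenuation / (MU_WATER * phantom.size)
    sino = np.maximum(sino * scale, 0.0)
    return SinogramSet(projections=sino, angles=angles,
                       incident_counts=incident_counts, dose_fraction=1.0,
                       attenuation_scale=scale)


def apply_dose_noise(sinogram: SinogramSet, dose_fraction: float,
                     seed: int) -> SinogramSet:
    """Inject Poisson photon-counting noise for a reduced tube current.

    Transmitted counts are drawn as
    ``N ~ Poisson(dose_fraction * I0 * exp(-p))`` and the noisy line integral
    is ``-ln(max(N, 1) / (dose_fraction * I0))``; counts are clamped at 1
    before the log (standard pre-log conditioning).
    """
    if not (0 < dose_fraction <= 1):
        raise ValueError("dose_fraction must be in (0, 1]")
    if sinogram.incident_counts <= 0:
        raise ValueError("incident_counts must be positive")
    rng = np.random.default_rng(seed)
    lam = dose_fraction * sinogram.incident_counts * np.exp(-sinogram.projections)
    counts = rng.poisson(lam).astype(np.float64)
    noisy = -np.log(np.maximum(counts, 1.0) / (dose_fraction * sinogram.incident_counts))
    noisy = np.maximum(noisy, 0.0)
    return SinogramSet(projections=noisy, angles=sinogram.angles.copy(),
                       incident_counts=sinogram.incident_counts,
                       dose_fraction=dose_fraction,
                       attenuation_scale=sinogram.attenuation_scale)


def fbp_reconstruct(sinogram: SinogramSet, filter_name: str = "ramp",
                    out_size: int | None = None, slice_id: int = 0,
                    ct_scale: bool = True) -> CTSlice:
    """Filtered back-projection of a sinogram.

    With ``ct_scale`` the attenuation reconstruction is mapped to the
    CT-number-like scale; otherwise raw attenuation values are kept
    (useful for linearity checks).
    """
    if filter_name not in _FILTERS:
        raise ValueError(f"unknown filter {filter_name!r}; choose from {sorted(_FILTERS)}")
    recon = iradon(sinogram.projections.T / sinogram.attenuation_scale,
                   theta=sinogram.angles, filter_name=_FILTERS[filter_name],
                   circle=True, output_size=out_size)
    pixels = mu_to_ct(recon) if ct_scale else recon
    return CTSlice(pixels=pixels, dose_fraction=sinogram.dose_fraction,
                   provenance="simulated", id=slice_id)


def simulate_slices(n_slices: int, size: int = 512, dose_fraction: float = 0.05,
                    seed: int = 0, n_angles: int = 720,
                    incident_counts: float = 1.0e5,
                    filter_name: str = "ramp",
                    return_reference: bool = False,
                    n_soft_ellipses: int = 5, n_bone_features: int = 2):
    """Generate a collection of reconstructed slices at one dose level.

    Each slice gets its own phantom (seeded from ``seed``) so the collection
    has anatomical variability.  With ``return_reference`` the matching
    noiseless (ideal) reconstructions are returned too, for evaluation.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    ss = np.random.SeedSequence([seed, 0x51CE])
    child_seeds = ss.generate_state(2 * n_slices)
    slices: list[CTSlice] = []
    refs: list[CTSlice] = []
    for i in range(n_slices):
        ph = generate_phantom(int(child_seeds[2 * i] % (2 ** 31)), size=size,
                              n_soft_ellipses=n_soft_ellipses,
                              n_bone_features=n_bone_features)
        sino = forward_project(ph, n_angles=n_angles, incident_counts=incident_counts)
        noisy = apply_dose_noise(sino, dose_fraction, int(child_seeds[2 * i + 1] % (2 ** 31)))
        slices.append(fbp_reconstruct(noisy, filter_name, slice_id=i))
        if return_reference:
            refs.append(fbp_reconstruct(sino, filter_name, slice_id=i))
    if return_reference:
        return slices, refs
    return slices
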