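"""Domain containers shared across the simulator, denoisers and trainer.

All containers are thin dataclasses around NumPy arrays.  Images live on a
CT-number-like scale (default dynamic range [0, 2000], water ~ 1000) so that
display windows such as [800, 1300] are meaningful on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Canonical dynamic range of the internal CT-number-like intensity scale.
CT_RANGE: tuple[float, float] = (0.0, 2000.0)

#: Dose fractions emulating tube-current ratios 300/150/75/30/15 mAs.
DOSE_FRACTIONS: tuple[float, ...] = (1.0, 0.5, 0.25, 0.10, 0.05)


@dataclass
class PhantomImage:
    """A synthetic attenuation map with a region label mask.

    ``pixels`` holds linear attenuation coefficients (unitless, >= 0).
    ``structure_mask`` labels each pixel 0 = background, 1 = soft tissue,
    2 = bone, 3 = gap (narrow low-attenuation break inside bone).
    """

    pixels: np.ndarray
    size: int
    seed: int
    structure_mask: np.ndarray

    # mask label values
    BACKGROUND, SOFT, BONE, GAP = 0, 1, 2, 3

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != (self.size, self.size):
            raise ValueError("pixels must be size x size")
        if self.structure_mask.shape != self.pixels.shape:
            raise ValueError("structure_mask must match pixels shape")
        if not np.all(self.pixels >= 0):
            raise ValueError("attenuation values must be non-negative")


@dataclass
class SinogramSet:
    """Parallel-beam projection data: line integrals per (angle, detector bin)."""

    projections: np.ndarray          # (n_angles, n_detectors)
    angles: np.ndarray               # degrees, strictly increasing in [0, 180)
    incident_counts: float           # photons per detector bin at 100% dose (I0)
    dose_fraction: float = 1.0
    #: pixel-sum -> physical line-integral conversion used at projection time;
    #: FBP divides by it to recover attenuation on the phantom's own scale
    attenuation_scale: float = 1.0

    def __post_init__(self) -> None:
        self.projections = np.asarray(self.projections, dtype=np.float64)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.angles.ndim != 1 or self.angles.size < 2:
            raise ValueError("need at least 2 projection angles")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.angles[0] < 0 or self.angles[-1] >= 180:
            raise ValueError("angles must lie in [0, 180)")
        if not (0 < self.dose_fraction <= 1):
            raise ValueError("dose_fraction must be in (0, 1]")
        if self.projections.shape[0] != self.angles.size:
            raise ValueError("projections rows must match number of angles")
        if not np.all(np.isfinite(self.projections)) or np.any(self.projections < 0):
            raise ValueError("projections must be finite and non-negative")


@dataclass
class CTSlice:
    """A reconstructed 2-D CT image on the canonical intensity scale."""

    pixels: np.ndarray
    dose_fraction: float = 1.0
    provenance: str = "simulated"     # "simulated" | "loaded"
    id: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("CTSlice pixels must be square")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("CTSlice pixels must be finite")
        if self.provenance not in ("simulated", "loaded"):
            raise ValueError("provenance must be 'simulated' or 'loaded'")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


@dataclass
class UnpairedDataset:
    """Two index-independent slice collections: source X (low dose) and target Y.

    ``permutation`` records the seeded shuffle applied to ``target_Y`` relative
    to its original order, for audit; ``pairing_broken`` asserts that no
    index-wise correspondence between X and Y should be assumed.
    """

    source_X: list[CTSlice]
    target_Y: list[CTSlice]
    pairing_broken: bool = False
    permutation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.source_X) == 0 or len(self.target_Y) == 0:
            raise ValueError("both collections must be non-empty")


@dataclass
class PriorImage:
    """A denoised companion of one low-dose slice, used to anchor the generator.

    Computed from the source (low-dose) collection only; ``source_id`` must
    refer to a slice of ``UnpairedDataset.source_X``, never of ``target_Y``.
    """

    pixels: np.ndarray
    source_id: int
    sigma_used: float
    method_tag: str = "bm3d"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("PriorImage pixels must be 2-D")


@dataclass
class Patch:
    """A tile of a slice plus its (row, col) origin in the parent image."""

    pixels: np.ndarray
    origin: tuple[int, int]
    parent_id: int = 0


def stack_pixels(slices: Sequence[CTSlice]) -> np.ndarray:
    """Return an (n, H, W) array view of a slice collection."""
    return np.stack([s.pixels for s in slices], axis=0)
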