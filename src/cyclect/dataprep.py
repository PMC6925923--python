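"""Dataset preparation: slice partitioning, patch tiling, pairing removal."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import CTSlice, Patch, UnpairedDataset

logger = logging.getLogger(__name__)


@dataclass
class PartitionScheme:
    """How to split an ordered slice stack into train / test / skipped.

    Two modes:

    * ``mode="take_skip"`` — the literal scheme: walk the stack taking ``take``
      consecutive slices into the training set, then skipping ``skip`` slices,
      repeating.  The test set is empty in this mode.
    * ``mode="counts"`` — a count-targeted deterministic scheme: pick exactly
      ``n_train`` evenly spaced slices for training, then ``n_test`` evenly
      spaced slices from the remainder; everything else is skipped.
    """

    mode: str = "take_skip"
    take: int = 1
    skip: int = 10
    n_train: int = 360
    n_test: int = 180


def _evenly_spaced(n_avail: int, n_pick: int) -> np.ndarray:
    """Indices of n_pick evenly spaced items out of n_avail (deterministic)."""
    if n_pick > n_avail:
        raise ValueError(f"cannot pick {n_pick} from {n_avail} slices")
    return np.unique(np.round(np.linspace(0, n_avail - 1, n_pick)).astype(int))


def partition_slices(slice_ids: Sequence[int], scheme: PartitionScheme
                     ) -> tuple[list[int], list[int], list[int]]:
    """Deterministically split slice ids into (train, test, skipped)."""
    ids = list(slice_ids)
    if not ids:
        raise ValueError("slice_ids must be non-empty")
    if scheme.mode == "take_skip":
        train, skipped = [], []
        i = 0
        while i < len(ids):
            train.extend(ids[i:i + scheme.take])
            skipped.extend(ids[i + scheme.take:i + scheme.take + scheme.skip])
            i += scheme.take + scheme.skip
        return train, [], skipped
    if scheme.mode == "counts":
        train_pos = _evenly_spaced(len(ids), scheme.n_train)
        remaining = np.setdiff1d(np.arange(len(ids)), train_pos)
        test_pos = remaining[_evenly_spaced(len(remaining), scheme.n_test)]
        used = set(train_pos) | set(test_pos)
        skipped = [ids[i] for i in range(len(ids)) if i not in used]
        return ([ids[i] for i in train_pos], [ids[i] for i in test_pos], skipped)
    raise ValueError(f"unknown partition mode {scheme.mode!r}")


def extract_patches(ct: CTSlice, patch_size: int = 128) -> list[Patch]:
    """Tile a slice into non-overlapping patches in row-major order.

    A 512x512 slice at patch size 128 yields 16 patches; each patch records
    its (row, col) origin so tiling is invertible.
    """
    side = ct.side
    if patch_size < 1 or side % patch_size != 0:
        raise ValueError(f"slice side {side} not divisible by patch size {patch_size}")
    patches = []
    for r in range(0, side, patch_size):
        for c in range(0, side, patch_size):
            patches.append(Patch(pixels=ct.pixels[r:r + patch_size, c:c + patch_size].copy(),
                                 origin=(r, c), parent_id=ct.id))
    return patches


def reassemble_patches(patches: Sequence[Patch], side: int) -> CTSlice:
    """Inverse of :func:`extract_patches`; order-invariant via patch origins."""
    if not patches:
        raise ValueError("no patches given")
    ps = patches[0].pixels.shape[0]
    out = np.full((side, side), np.nan)
    seen = set()
    for p in patches:
        r, c = p.origin
        if (r, c) in seen:
            raise ValueError(f"duplicate patch origin {(r, c)}")
        if r % ps or c % ps or r + ps > side or c + ps > side:
            raise ValueError(f"patch origin {(r, c)} inconsistent with tiling")
        seen.add((r, c))
        out[r:r + ps, c:c + ps] = p.pixels
    if np.isnan(out).any():
        raise ValueError("patches do not cover the full slice")
    return CTSlice(pixels=out, id=patches[0].parent_id)


def build_unpaired_dataset(low_slices: Sequence[CTSlice],
                           normal_slices: Sequence[CTSlice],
                           break_pairing_seed: int = 0) -> UnpairedDataset:
    """Assemble an unpaired dataset, shuffling the target collection.

    The seeded permutation applied to the normal-dose collection is recorded
    for audit.  The two collections may differ in size.  For collections of
    size > 1 the permutation is guaranteed non-identity (re-drawn if needed);
    a single-slice target cannot be de-paired, which is logged as a warning.
    """
    low, normal = list(low_slices), list(normal_slices)
    if not low or not normal:
        raise ValueError("both collections must be non-empty")
    rng = np.random.default_rng(break_pairing_seed)
    n = len(normal)
    perm = rng.permutation(n)
    while n > 1 and np.array_equal(perm, np.arange(n)):
        perm = rng.permutation(n)
    if n == 1:
        msg = "target collection has a single slice; pairing cannot be broken"
        warnings.warn(msg)
        logger.warning(msg)
    return UnpairedDataset(source_X=low, target_Y=[normal[i] for i in perm],
                           pairing_broken=True, permutation=perm)
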