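"""Air-cavity delineation in the sinus region.

The procedure works from the tissue-probability maps alone:

1. an *initial air mask* -- air-classified voxels restricted to the
   interior of the head envelope (so exterior air is excluded, while the
   throat and other pockets remain);
2. a *slice profile* -- per-axial-slice counts of initial-mask voxels;
3. a *seed slice* -- the largest local maximum of the profile preceding
   the largest single inter-slice drop (the sinus cavities end abruptly
   toward the top of the head);
4. *seeds* -- one per 2-D connected component in the seed slice, at the
   component's centre of mass snapped to the nearest in-component voxel;
5. *region growing* -- 3-D connected components of the initial mask that
   contain a seed; everything not reachable (throat, stray pockets) is
   excluded.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .mumap import ClassThresholds
from .volume_io import TissueProbabilitySet, VolumeGrid, require_same_grid

#: 26-neighbourhood for 3-D growth; fine sinus channels at 2 mm resolution
#: are frequently diagonal-connected.
STRUCT_3D = np.ones((3, 3, 3), dtype=bool)
#: 8-neighbourhood for 2-D slice components.
STRUCT_2D = np.ones((3, 3), dtype=bool)


@dataclass
class SliceProfile:
    """Per-axial-slice voxel counts of the initial air mask."""

    sums: np.ndarray

    def __post_init__(self) -> None:
        self.sums = np.asarray(self.sums, dtype=np.int64)
        if self.sums.ndim != 1:
            raise ValueError("slice profile must be 1-D")
        if (self.sums < 0).any():
            raise ValueError("slice profile counts must be nonnegative")


def head_envelope(
    probmaps: TissueProbabilitySet,
    thresholds: ClassThresholds = ClassThresholds(),
    closing_iterations: int = 2,
) -> VolumeGrid:
    """Filled morphological hull of all non-air tissue.

    Union of the thresholded soft, bone and brain masks, binary-closed and
    hole-filled, so that interior air (sinuses, throat) lies inside the
    envelope while exterior air does not.
    """
    tissue = (
        (probmaps.soft.data >= thresholds.soft)
        | (probmaps.bone.data >= thresholds.bone)
        | (probmaps.brain_probability().data >= thresholds.brain)
    )
    closed = ndimage.binary_closing(
        tissue, structure=STRUCT_3D, iterations=closing_iterations
    )
    filled = ndimage.binary_fill_holes(closed)
    return probmaps.grid.like(filled.astype(np.uint8))


def initial_air_mask(
    probmaps: TissueProbabilitySet,
    thresholds: ClassThresholds = ClassThresholds(),
) -> VolumeGrid:
    """Air-classified voxels inside the head envelope.

    Includes every interior air pocket (sinus cavities, throat); exterior
    air is excluded by the envelope.
    """
    air = probmaps.air.data >= thresholds.air
    envelope = head_envelope(probmaps, thresholds).data > 0
    return probmaps.grid.like((air & envelope).astype(np.uint8))


def slice_profile(mask: VolumeGrid) -> SliceProfile:
    """Sum the binary mask over each axial (z) slice."""
    data = np.asarray(mask.data)
    return SliceProfile(data.reshape(-1, data.shape[2]).sum(axis=0))


def select_seed_slice(profile: SliceProfile) -> int:
    """Largest local maximum preceding the largest inter-slice drop.

    The largest drop is ``argmax_i sums[i] - sums[i+1]`` scanning in
    ascending slice order (toward the head top); ties go to the smallest
    ``i``.  Among local maxima (non-increasing neighbours, boundaries
    included) at indices ``<= i``, the one with the largest profile value
    is chosen; ties go to the index closest to the drop.
    """
    s = profile.sums
    if not s.any():
        raise ValueError("slice profile is all zero")
    if len(s) == 1:
        return 0
    drops = s[:-1] - s[1:]
    i_drop = int(np.argmax(drops))
    # local maxima up to and including the drop slice
    candidates: List[int] = []
    for i in range(i_drop + 1):
        left_ok = i == 0 or s[i - 1] <= s[i]
        right_ok = i == len(s) - 1 or s[i + 1] <= s[i]
        if left_ok and right_ok:
            candidates.append(i)
    if not candidates:  # profile strictly increasing up to the drop
        candidates = [i_drop]
    best = max(candidates, key=lambda i: (s[i], i))
    return int(best)


def select_seeds(mask: VolumeGrid, slice_idx: int) -> List[Tuple[int, int, int]]:
    """One seed per 2-D connected component of the chosen axial slice.

    Each seed is the component's centre of mass snapped to the nearest
    in-component voxel (Euclidean distance in voxels; ties resolve to the
    lexicographically smallest coordinate).
    """
    data = np.asarray(mask.data) > 0
    plane = data[:, :, slice_idx]
    if not plane.any():
        raise ValueError(f"slice {slice_idx} contains no mask voxels")
    comp, n = ndimage.label(plane, structure=STRUCT_2D)
    seeds: List[Tuple[int, int, int]] = []
    for k in range(1, n + 1):
        pts = np.argwhere(comp == k)
        centroid = pts.mean(axis=0)
        d2 = ((pts - centroid) ** 2).sum(axis=1)
        order = np.lexsort((pts[:, 1], pts[:, 0], d2))
        x, y = pts[order[0]]
        seeds.append((int(x), int(y), int(slice_idx)))
    return seeds


def grow_air_cavities(
    mask: VolumeGrid, seeds: Sequence[Tuple[int, int, int]]
) -> VolumeGrid:
    """Union of the 3-D connected components of ``mask`` containing a seed.

    26-connectivity.  A seed lying outside the mask raises ``ValueError``.
    """
    data = np.asarray(mask.data) > 0
    comp, _ = ndimage.label(data, structure=STRUCT_3D)
    keep = set()
    for seed in seeds:
        label = comp[tuple(int(c) for c in seed)]
        if label == 0:
            raise ValueError(f"seed {tuple(seed)} lies outside the mask")
        keep.add(int(label))
    out = np.isin(comp, sorted(keep)) & data
    return mask.like(out.astype(np.uint8))


def delineate_air_cavities(
    probmaps: TissueProbabilitySet,
    thresholds: ClassThresholds = ClassThresholds(),
) -> VolumeGrid:
    """Full pipeline: initial mask -> profile -> seed slice -> seeds -> growth."""
    mask = initial_air_mask(probmaps, thresholds)
    profile = slice_profile(mask)
    idx = select_seed_slice(profile)
    seeds = select_seeds(mask, idx)
    return grow_air_cavities(mask, seeds)
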