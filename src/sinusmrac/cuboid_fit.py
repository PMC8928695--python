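"""Sinus cuboid fitting.

An axis-aligned cuboid is fitted around the delineated air cavities by
maximizing a goodness score that trades the bone-probability mass captured
inside the box against the box's size,

    CG = sum_{i in C} p_i / (c / 4)^2,

where ``c = 4 (a + b + h)`` is the total edge length of the box in voxel
units, so the denominator is ``(a + b + h)^2``.  Box sums are evaluated in
constant time from a 3-D summed-volume (inclusion-exclusion prefix) table,
which makes the exhaustive search over sub-cuboids tractable.  No tilted
boxes are considered.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .volume_io import VolumeGrid


@dataclass(frozen=True)
class CuboidRegion:
    """Inclusive integer voxel bounds of an axis-aligned box."""

    lo: Tuple[int, int, int]
    hi: Tuple[int, int, int]

    def __post_init__(self) -> None:
        lo = tuple(int(v) for v in self.lo)
        hi = tuple(int(v) for v in self.hi)
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        if any(l > h for l, h in zip(lo, hi)):
            raise ValueError(f"cuboid lo {lo} exceeds hi {hi}")
        if any(l < 0 for l in lo):
            raise ValueError(f"cuboid lo {lo} out of bounds")

    @property
    def dims(self) -> Tuple[int, int, int]:
        return tuple(h - l + 1 for l, h in zip(self.lo, self.hi))

    @property
    def volume(self) -> int:
        d = self.dims
        return d[0] * d[1] * d[2]

    def slices(self) -> Tuple[slice, slice, slice]:
        return tuple(slice(l, h + 1) for l, h in zip(self.lo, self.hi))

    def to_mask(self, shape: Tuple[int, int, int]) -> np.ndarray:
        if any(h >= n for h, n in zip(self.hi, shape)):
            raise ValueError(f"cuboid {self} exceeds volume shape {shape}")
        mask = np.zeros(shape, dtype=bool)
        mask[self.slices()] = True
        return mask

    def contains(self, other: "CuboidRegion") -> bool:
        return all(
            sl <= ol and oh <= sh
            for sl, ol, oh, sh in zip(self.lo, other.lo, other.hi, self.hi)
        )

    @staticmethod
    def from_mask(mask: np.ndarray) -> "CuboidRegion":
        """Bounding box of the nonzero voxels of ``mask``."""
        if not mask.any():
            raise ValueError("empty mask has no bounding box")
        idx = np.nonzero(mask)
        return CuboidRegion(
            tuple(int(a.min()) for a in idx), tuple(int(a.max()) for a in idx)
        )


class SummedVolume:
    """3-D prefix-sum table giving O(1) box sums over a probability volume."""

    def __init__(self, table: np.ndarray):
        self.table = table

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(n - 1 for n in self.table.shape)

    def box_sum(self, lo: Sequence[int], hi: Sequence[int]) -> float:
        """Sum of the volume over the inclusive box ``[lo, hi]``."""
        t = self.table
        x0, y0, z0 = lo
        x1, y1, z1 = (h + 1 for h in hi)
        return float(
            t[x1, y1, z1]
            - t[x0, y1, z1]
            - t[x1, y0, z1]
            - t[x1, y1, z0]
            + t[x0, y0, z1]
            + t[x0, y1, z0]
            + t[x1, y0, z0]
            - t[x0, y0, z0]
        )


def build_summed_volume(p: VolumeGrid) -> SummedVolume:
    """Build the inclusion-exclusion prefix table for ``p``.

    Raises ``ValueError`` if the volume contains NaN.
    """
    data = np.asarray(p.data if isinstance(p, VolumeGrid) else p, dtype=np.float64)
    if np.isnan(data).any():
        raise ValueError("probability volume contains NaN")
    table = np.zeros(tuple(n + 1 for n in data.shape), dtype=np.float64)
    table[1:, 1:, 1:] = data.cumsum(axis=0).cumsum(axis=1).cumsum(axis=2)
    return SummedVolume(table)


def cuboid_goodness(p_sum: float, dims: Sequence[int]) -> float:
    """Goodness of a box: captured probability mass over ``(a+b+h)^2``."""
    dims = tuple(int(d) for d in dims)
    if any(d < 1 for d in dims):
        raise ValueError(f"cuboid dims must be >= 1, got {dims}")
    half_perimeter = sum(dims)
    return float(p_sum) / float(half_perimeter) ** 2


def initial_search_region(
    head_mask: VolumeGrid,
    air_cavities: VolumeGrid,
    axial_margin: int = 5,
) -> CuboidRegion:
    """Initial search box: anterior half of the head around the air cavities.

    Anterior-posterior is the y axis with smaller indices anterior.  The
    region spans the full lateral (x) extent of the head bounding box, the
    anterior half of its y extent, and the axial (z) extent of the air
    cavities padded by ``axial_margin`` slices, clipped to the head box.
    """
    head = np.asarray(head_mask.data) > 0
    air = np.asarray(air_cavities.data) > 0
    if not head.any():
        raise ValueError("empty head mask")
    if not air.any():
        raise ValueError("empty air-cavity mask")
    hbox = CuboidRegion.from_mask(head)
    abox = CuboidRegion.from_mask(air)
    y_mid = (hbox.lo[1] + hbox.hi[1]) // 2
    z_lo = max(hbox.lo[2], abox.lo[2] - axial_margin)
    z_hi = min(hbox.hi[2], abox.hi[2] + axial_margin)
    return CuboidRegion(
        (hbox.lo[0], hbox.lo[1], z_lo), (hbox.hi[0], y_mid, z_hi)
    )


@dataclass(frozen=True)
class CuboidFitResult:
    region: CuboidRegion
    goodness: float


def _axis_positions(n: int, stride: int) -> np.ndarray:
    pos = set(range(0, n, stride))
    pos.add(n - 1)
    return np.asarray(sorted(pos), dtype=int)


def _axis_pairs(positions: np.ndarray, min_dim: int) -> Tuple[np.ndarray, np.ndarray]:
    lo, hi = np.meshgrid(positions, positions, indexing="ij")
    keep = hi - lo + 1 >= min_dim
    return lo[keep], hi[keep]


def _better(
    cand: Tuple[float, int, Tuple[int, ...], Tuple[int, ...]],
    best: Tuple[float, int, Tuple[int, ...], Tuple[int, ...]],
) -> bool:
    """Tie rules: larger goodness, then smaller volume, then lexicographically
    smallest lo, then smallest hi."""
    if cand[0] != best[0]:
        return cand[0] > best[0]
    if cand[1] != best[1]:
        return cand[1] < best[1]
    if cand[2] != best[2]:
        return cand[2] < best[2]
    return cand[3] < best[3]


def _scan_candidates(
    sv: SummedVolume,
    x_pairs: Iterable[Tuple[int, int]],
    y_lo: np.ndarray,
    y_hi: np.ndarray,
    z_lo: np.ndarray,
    z_hi: np.ndarray,
    best,
):
    """Scan (x-pair) x (y-pairs) x (z-pairs) candidates, vectorized over y,z."""
    t = sv.table
    dy = (y_hi - y_lo + 1).astype(float)[:, None]
    dz = (z_hi - z_lo + 1).astype(float)[None, :]
    for x0, x1 in x_pairs:
        dx = float(x1 - x0 + 1)
        slab = t[x1 + 1] - t[x0]  # 2-D prefix over (y, z)
        sums = (
            slab[np.ix_(y_hi + 1, z_hi + 1)]
            - slab[np.ix_(y_lo, z_hi + 1)]
            - slab[np.ix_(y_hi + 1, z_lo)]
            + slab[np.ix_(y_lo, z_lo)]
        )
        goodness = sums / (dx + dy + dz) ** 2
        m = goodness.max()
        if m < best[0]:
            continue
        for iy, iz in zip(*np.nonzero(goodness == m)):
            vol = int(dx * dy[iy, 0] * dz[0, iz])
            cand = (
                float(m),
                vol,
                (int(x0), int(y_lo[iy]), int(z_lo[iz])),
                (int(x1), int(y_hi[iy]), int(z_hi[iz])),
            )
            if _better(cand, best):
                best = cand
    return best


def search_best_cuboid(
    bone_prob: VolumeGrid,
    region: CuboidRegion,
    stride: int = 2,
    min_dim: int = 3,
) -> CuboidFitResult:
    """Argmax of the cuboid goodness over sub-cuboids of ``region``.

    Corner coordinates are first restricted to a lattice with the given
    ``stride`` (the last index on each axis is always included), then the
    optimum is refined by a local stride-1 search over ``+/- stride`` around
    each bound.  With ``stride=1`` this is the exhaustive argmax.  Ties are
    broken toward smaller volume, then lexicographically smallest ``lo``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    data = np.asarray(bone_prob.data, dtype=float)
    if any(h >= n for h, n in zip(region.hi, data.shape)):
        raise ValueError("search region exceeds volume bounds")
    sub = data[region.slices()]
    n = sub.shape
    if any(d < min_dim for d in n):
        raise ValueError(
            f"search region {n} smaller than minimum cuboid {min_dim}^3"
        )
    sv = build_summed_volume(VolumeGrid(sub, (1.0, 1.0, 1.0)))

    xs = _axis_positions(n[0], stride)
    ys = _axis_positions(n[1], stride)
    zs = _axis_positions(n[2], stride)
    x_lo, x_hi = _axis_pairs(xs, min_dim)
    y_lo, y_hi = _axis_pairs(ys, min_dim)
    z_lo, z_hi = _axis_pairs(zs, min_dim)

    best = (-np.inf, 0, (0, 0, 0), (0, 0, 0))
    best = _scan_candidates(sv, zip(x_lo, x_hi), y_lo, y_hi, z_lo, z_hi, best)

    if stride > 1:
        # local stride-1 refinement around the lattice optimum
        lo0, hi0 = best[2], best[3]
        axes_lo, axes_hi = [], []
        for ax in range(3):
            axes_lo.append(
                np.arange(max(0, lo0[ax] - stride), min(n[ax] - 1, lo0[ax] + stride) + 1)
            )
            axes_hi.append(
                np.arange(max(0, hi0[ax] - stride), min(n[ax] - 1, hi0[ax] + stride) + 1)
            )
        xl, xh = np.meshgrid(axes_lo[0], axes_hi[0], indexing="ij")
        keep = xh - xl + 1 >= min_dim
        xl, xh = xl[keep], xh[keep]
        yl, yh = np.meshgrid(axes_lo[1], axes_hi[1], indexing="ij")
        keep = yh - yl + 1 >= min_dim
        yl, yh = yl[keep], yh[keep]
        zl, zh = np.meshgrid(axes_lo[2], axes_hi[2], indexing="ij")
        keep = zh - zl + 1 >= min_dim
        zl, zh = zl[keep], zh[keep]
        best = _scan_candidates(sv, zip(xl, xh), yl, yh, zl, zh, best)

    lo = tuple(l + r for l, r in zip(best[2], region.lo))
    hi = tuple(h + r for h, r in zip(best[3], region.lo))
    return CuboidFitResult(CuboidRegion(lo, hi), best[0])
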