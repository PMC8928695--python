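"""Template-based sinus delineation.

A cuboid mask is defined once in a canonical (MNI-like) template space and
pulled back to each subject's anatomy through that subject's inverse
deformation field.  The field is a per-voxel world-space displacement in
millimetres defined on the *subject* grid: a subject voxel at world
position ``w`` samples the template at ``w + u(w)``.  Binary masks are
looked up with nearest-neighbour interpolation so the warped region stays
crisp; it need not remain a strict cuboid.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Tuple

import numpy as np

from .cuboid_fit import CuboidRegion
from .volume_io import VolumeGrid, require_same_grid


@dataclass(frozen=True)
class TemplateCuboid:
    """A cuboid mask in canonical template space."""

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    bounds: CuboidRegion
    affine: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(
            self, "spacing", tuple(float(s) for s in self.spacing)
        )
        aff = self.affine
        if aff is None:
            aff = np.diag(list(self.spacing) + [1.0])
        object.__setattr__(self, "affine", np.asarray(aff, dtype=float))
        if any(h >= n for h, n in zip(self.bounds.hi, self.shape)):
            raise ValueError(
                f"template bounds {self.bounds} exceed canonical grid {self.shape}"
            )

    def rasterize(self) -> VolumeGrid:
        """Binary mask of the cuboid on the canonical grid."""
        mask = self.bounds.to_mask(self.shape)
        return VolumeGrid(mask.astype(np.uint8), self.spacing, self.affine.copy())

    # -- JSON asset ---------------------------------------------------
    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "shape": list(self.shape),
                    "spacing": list(self.spacing),
                    "affine": self.affine.tolist(),
                    "lo": list(self.bounds.lo),
                    "hi": list(self.bounds.hi),
                },
                indent=2,
            )
        )

    @staticmethod
    def from_json(path) -> "TemplateCuboid":
        d = json.loads(Path(path).read_text())
        return TemplateCuboid(
            tuple(d["shape"]),
            tuple(d["spacing"]),
            CuboidRegion(tuple(d["lo"]), tuple(d["hi"])),
            np.asarray(d["affine"], dtype=float),
        )


def warp_mask(
    template: TemplateCuboid,
    inv_field: VolumeGrid,
    target_grid: VolumeGrid,
) -> VolumeGrid:
    """Pull the template cuboid back to subject space through ``inv_field``.

    For every target voxel, its world coordinate plus the field's
    displacement (mm) is mapped into template voxel indices and the
    template mask is sampled by nearest neighbour; out-of-grid lookups are
    background.  The field must live on the target grid.
    """
    if not inv_field.is_vector:
        raise ValueError("inv_field must be a 3-component displacement field")
    require_same_grid(inv_field, target_grid)

    world = target_grid.world_coordinates() + inv_field.data
    inv_aff = np.linalg.inv(template.affine)
    tpl_idx = world @ inv_aff[:3, :3].T + inv_aff[:3, 3]
    tpl_idx = np.rint(tpl_idx).astype(int)

    inside = np.ones(target_grid.shape, dtype=bool)
    for ax, n in enumerate(template.shape):
        inside &= (tpl_idx[..., ax] >= 0) & (tpl_idx[..., ax] < n)

    tpl_mask = template.bounds.to_mask(template.shape)
    out = np.zeros(target_grid.shape, dtype=np.uint8)
    ii = tpl_idx[inside]
    out[inside] = tpl_mask[ii[:, 0], ii[:, 1], ii[:, 2]]
    return target_grid.like(out)


def template_from_boxes(
    boxes: Sequence[CuboidRegion],
    shape: Tuple[int, int, int],
    spacing: Tuple[float, float, float],
) -> TemplateCuboid:
    """Canonical cuboid from the per-subject boxes' rounded mean bounds.

    For phantom cohorts this derives the template asset from the
    cohort-mean sinus compartment.
    """
    if len(boxes) == 0:
        raise ValueError("need at least one box")
    lo = np.rint(np.mean([b.lo for b in boxes], axis=0)).astype(int)
    hi = np.rint(np.mean([b.hi for b in boxes], axis=0)).astype(int)
    lo = np.clip(lo, 0, np.asarray(shape) - 1)
    hi = np.clip(hi, 0, np.asarray(shape) - 1)
    return TemplateCuboid(shape, spacing, CuboidRegion(tuple(lo), tuple(hi)))
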