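"""Attenuation-map construction.

Builds four-class MR-based attenuation maps (air / soft tissue / brain /
bone) from tissue-probability maps, the CT-based reference map through the
bilinear HU-to-mu transform, and the two sinus-region treatments: a fixed
bulk coefficient, or voxelwise conversion of bone-labelled sinus voxels
through a fitted MRI-to-CT model.

All coefficients are linear attenuation coefficients at 511 keV in cm^-1.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .volume_io import (
    TissueProbabilitySet,
    VolumeGrid,
    require_same_grid,
)


class TissueLabel(enum.IntEnum):
    """Provenance codes carried alongside every mu-map voxel."""

    AIR = 0
    SOFT = 1
    BRAIN = 2
    BONE = 3
    BULK_SINUS = 4
    CONVERTED_SINUS = 5
    CT_DERIVED = 6


@dataclass(frozen=True)
class ClassThresholds:
    """Probability thresholds used to binarize the tissue maps."""

    air: float = 0.25
    soft: float = 0.50
    bone: float = 0.25
    brain: float = 0.50

    def __post_init__(self) -> None:
        for name in ("air", "soft", "bone", "brain"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"threshold '{name}' must be in (0, 1), got {v}")


@dataclass(frozen=True)
class MuCoefficients:
    """Class attenuation coefficients (cm^-1) at 511 keV.

    The brain coefficient defaults to 0.0985 cm^-1, i.e. slightly above
    water, as appropriate for brain tissue at 511 keV.
    """

    air: float = 0.0
    soft: float = 0.096
    brain: float = 0.0985
    bone: float = 0.151
    bulk_sinus: float = 0.100

    def __post_init__(self) -> None:
        for name in ("air", "soft", "brain", "bone", "bulk_sinus"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.2:
                raise ValueError(f"coefficient '{name}' out of [0, 0.2]: {v}")

    def lookup_table(self) -> dict:
        return {
            int(TissueLabel.AIR): self.air,
            int(TissueLabel.SOFT): self.soft,
            int(TissueLabel.BRAIN): self.brain,
            int(TissueLabel.BONE): self.bone,
            int(TissueLabel.BULK_SINUS): self.bulk_sinus,
        }


@dataclass(frozen=True)
class BilinearParams:
    """Two-segment HU -> mu scaling for a 120 kVp CT acquisition.

    Below ``break_hu`` the map is the water line ``soft_slope * (HU+1000)``
    so that -1000 HU -> 0 and 0 HU -> 0.096 cm^-1; above the break the
    slope is chosen so that 157 HU corresponds to 0.105 cm^-1, the boundary
    value between bone and non-bone tissue used throughout the evaluation.
    The transform is continuous at the break and clamped at -1000 HU.
    """

    break_hu: float = 0.0
    soft_slope: float = 0.096 / 1000.0
    upper_slope: float = (0.105 - 0.096) / 157.0

    def mu_at_break(self) -> float:
        return self.soft_slope * (self.break_hu + 1000.0)


#: Upstream unified-segmentation settings recorded as provenance metadata
#: only; the segmentation itself is an input to this package.
SEGMENTATION_PROVENANCE = {
    "engine": "SPM12 Segment",
    "bias_regularization": 0.0001,
    "gaussians_per_class": (2, 2, 2, 3, 4, 2),
    "mrf_strength": 0,
    "cleanup": "none",
    "warping_regularization": (0, 0.001, 0.5, 0.05, 0.2),
    "smoothness_mm": 0,
}


@dataclass
class MuMap:
    """Attenuation-coefficient volume plus per-voxel provenance labels."""

    mu: VolumeGrid
    labels: VolumeGrid

    def __post_init__(self) -> None:
        require_same_grid(self.mu, self.labels)

    def copy(self) -> "MuMap":
        return MuMap(self.mu.copy(), self.labels.copy())


# ---------------------------------------------------------------------------
# Classification and lookup
# ---------------------------------------------------------------------------

def classify_tissues(
    probmaps: TissueProbabilitySet, thresholds: ClassThresholds = ClassThresholds()
) -> VolumeGrid:
    """Threshold the probability maps into one of air/soft/brain/bone.

    Grey matter, white matter and CSF collapse into a single brain class
    (their probabilities are summed before thresholding).  Binary class
    masks are combined with precedence brain > bone > soft > air so that
    brain voxels are protected from skull leakage; any voxel passing no
    threshold falls back to air.
    """
    brain = probmaps.brain_probability().data >= thresholds.brain
    bone = probmaps.bone.data >= thresholds.bone
    soft = probmaps.soft.data >= thresholds.soft

    labels = np.full(probmaps.grid.shape, int(TissueLabel.AIR), dtype=np.int16)
    labels[soft] = int(TissueLabel.SOFT)
    labels[bone] = int(TissueLabel.BONE)
    labels[brain] = int(TissueLabel.BRAIN)
    return probmaps.grid.like(labels)


def assign_mu(labels: VolumeGrid, coeffs: MuCoefficients = MuCoefficients()) -> MuMap:
    """Map a label volume to attenuation coefficients by table lookup."""
    table = coeffs.lookup_table()
    lab = np.asarray(labels.data).astype(np.int16)
    known = np.isin(lab, list(table))
    if not known.all():
        bad = np.unique(lab[~known])
        raise ValueError(f"unknown label code(s): {bad.tolist()}")
    lut = np.zeros(int(max(table)) + 1, dtype=float)
    for code, mu in table.items():
        lut[code] = mu
    return MuMap(labels.like(lut[lab]), labels.like(lab))


def apply_bulk_sinus(
    m: MuMap, sinus_mask: VolumeGrid, coeffs: MuCoefficients = MuCoefficients()
) -> MuMap:
    """Assign the fixed bulk coefficient (0.100 cm^-1) inside the sinus mask."""
    require_same_grid(m.mu, sinus_mask)
    out = m.copy()
    sel = sinus_mask.data > 0
    out.mu.data[sel] = coeffs.bulk_sinus
    out.labels.data[sel] = int(TissueLabel.BULK_SINUS)
    return out


def apply_converted_sinus(
    m: MuMap,
    region,
    mri: VolumeGrid,
    model,
    coeffs: MuCoefficients = MuCoefficients(),
) -> MuMap:
    """Convert bone-labelled voxels inside the sinus region to an air/soft mix.

    ``region`` may be a :class:`~sinusmrac.cuboid_fit.CuboidRegion` or a
    binary mask volume (e.g. a warped template).  Each bone voxel's MRI
    intensity is mapped to a predicted HU in [-1000, 0] through ``model``,
    then to ``mu = mu_soft * (HU + 1000) / 1000`` clamped to
    ``[0, mu_soft]`` -- a linear mix of air and soft tissue.
    """
    require_same_grid(m.mu, mri)
    if hasattr(region, "to_mask"):
        region_sel = region.to_mask(m.mu.shape)
    else:
        require_same_grid(m.mu, region)
        region_sel = region.data > 0
    out = m.copy()
    sel = region_sel & (m.labels.data == int(TissueLabel.BONE))
    hu = model.predict_hu(np.asarray(mri.data)[sel])
    mu = np.clip(coeffs.soft * (hu + 1000.0) / 1000.0, 0.0, coeffs.soft)
    out.mu.data[sel] = mu
    out.labels.data[sel] = int(TissueLabel.CONVERTED_SINUS)
    return out


# ---------------------------------------------------------------------------
# CT reference map
# ---------------------------------------------------------------------------

def hu_to_mu_bilinear(
    hu: Union[float, np.ndarray, VolumeGrid],
    params: BilinearParams = BilinearParams(),
):
    """Bilinear HU -> mu (cm^-1) conversion; continuous, monotone, clamped
    at -1000 HU."""
    is_grid = isinstance(hu, VolumeGrid)
    values = np.asarray(hu.data if is_grid else hu, dtype=float)
    values = np.maximum(values, -1000.0)
    low = params.soft_slope * (values + 1000.0)
    high = params.mu_at_break() + params.upper_slope * (values - params.break_hu)
    mu = np.where(values <= params.break_hu, low, high)
    if is_grid:
        return hu.like(mu)
    if np.isscalar(hu) or np.ndim(hu) == 0:
        return float(mu)
    return mu


def ct_reference_mumap(
    ct: VolumeGrid,
    mrac_soft_mask: VolumeGrid,
    params: BilinearParams = BilinearParams(),
    coeffs: MuCoefficients = MuCoefficients(),
) -> MuMap:
    """CT-based reference mu-map with soft-tissue complementation.

    Voxels the CT did not cover are flagged by NaN; where the MR-based map
    marks soft tissue they are filled with the soft coefficient, elsewhere
    with air.  Covered voxels go through the bilinear transform.
    """
    require_same_grid(ct, mrac_soft_mask)
    data = np.asarray(ct.data, dtype=float)
    missing = np.isnan(data)
    mu = hu_to_mu_bilinear(np.where(missing, -1000.0, data), params)
    labels = np.full(ct.shape, int(TissueLabel.CT_DERIVED), dtype=np.int16)
    fill_soft = missing & (mrac_soft_mask.data > 0)
    fill_air = missing & ~fill_soft
    mu[fill_soft] = coeffs.soft
    mu[fill_air] = coeffs.air
    labels[fill_soft] = int(TissueLabel.SOFT)
    labels[fill_air] = int(TissueLabel.AIR)
    return MuMap(ct.like(mu), ct.like(labels))
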