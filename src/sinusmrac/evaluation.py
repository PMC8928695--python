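"""Quantitative comparison of MR-based and CT-based attenuation maps.

Implements the evaluation battery: DICE overlap of bone masks over the
sinus sub-volume (axial slices 50-70, 1-based, 4.2 cm at 2 mm) and the
whole volume; repeated Pearson-correlation sampling of paired attenuation
values; sinus-VOI mean attenuation coefficients; per-VOI relative
differences of PET-like volumes restricted to high-probability grey
matter; and voxelwise mean bias atlases.

Undefined statistics (zero variance, zero reference) are carried as NaN
sentinels, serialized as null in reports, and never silently dropped.
"""
from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mumap import BilinearParams, MuMap, hu_to_mu_bilinear
from .volume_io import VolumeGrid, require_same_grid

DEFAULT_HU_THRESHOLD = 157.0
DEFAULT_SLICE_RANGE = (50, 70)  # 1-based inclusive
DEFAULT_GM_THRESHOLD = 0.8


def dice(a: VolumeGrid, b: VolumeGrid, empty_value: float = 1.0) -> float:
    """DICE = 2|A n B| / (|A| + |B|); two empty masks agree perfectly."""
    require_same_grid(a, b)
    am = np.asarray(a.data) > 0
    bm = np.asarray(b.data) > 0
    denom = am.sum() + bm.sum()
    if denom == 0:
        return float(empty_value)
    return float(2.0 * np.logical_and(am, bm).sum() / denom)


def bone_masks_for_dice(
    ct: VolumeGrid,
    mrac: MuMap,
    hu_threshold: float = DEFAULT_HU_THRESHOLD,
    bilinear: BilinearParams = BilinearParams(),
) -> Tuple[VolumeGrid, VolumeGrid]:
    """Bone masks for overlap analysis: CT HU > 157 and the matching mu cut.

    The MRAC mask thresholds at the attenuation coefficient corresponding
    to the HU threshold (0.105 cm^-1 at 157 HU), which with discrete class
    values selects exactly the bone class.  Both comparisons are strict.
    """
    require_same_grid(ct, mrac.mu)
    mu_threshold = hu_to_mu_bilinear(hu_threshold, bilinear)
    ct_mask = np.asarray(ct.data) > hu_threshold
    mrac_mask = np.asarray(mrac.mu.data) > mu_threshold
    return ct.like(ct_mask.astype(np.uint8)), ct.like(mrac_mask.astype(np.uint8))


def sinus_subvolume(
    v: VolumeGrid, slice_range: Tuple[int, int] = DEFAULT_SLICE_RANGE
) -> VolumeGrid:
    """Axial crop to a 1-based inclusive slice range (default 50-70)."""
    lo, hi = slice_range
    nz = v.shape[2]
    if not (1 <= lo <= hi <= nz):
        raise ValueError(f"slice range {slice_range} invalid for {nz} axial slices")
    data = np.asarray(v.data)[:, :, lo - 1 : hi]
    return VolumeGrid(data, v.spacing, v.affine.copy())


def sample_correlations(
    ct_mu: VolumeGrid,
    mrac_mu: VolumeGrid,
    include_mask: VolumeGrid,
    n_vox: int = 200,
    n_reps: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Repeatedly sampled Pearson correlations of paired attenuation values.

    Each of ``n_reps`` repetitions draws ``n_vox`` voxel locations without
    replacement from ``include_mask`` and correlates the paired values.  A
    draw with zero variance on either side yields NaN.
    """
    require_same_grid(ct_mu, mrac_mu, include_mask)
    coords = np.argwhere(np.asarray(include_mask.data) > 0)
    if len(coords) < n_vox:
        raise ValueError(
            f"include mask has {len(coords)} voxels, need >= {n_vox}"
        )
    rng = np.random.default_rng(seed)
    a = np.asarray(ct_mu.data)
    b = np.asarray(mrac_mu.data)
    out = np.empty(n_reps, dtype=float)
    for rep in range(n_reps):
        idx = coords[rng.choice(len(coords), size=n_vox, replace=False)]
        x = a[idx[:, 0], idx[:, 1], idx[:, 2]]
        y = b[idx[:, 0], idx[:, 1], idx[:, 2]]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[rep] = np.nan
        else:
            out[rep] = np.corrcoef(x, y)[0, 1]
    return out


def voi_mean_mu(mu, voi: VolumeGrid) -> float:
    """Arithmetic mean attenuation coefficient over a nonempty VOI."""
    grid = mu.mu if isinstance(mu, MuMap) else mu
    require_same_grid(grid, voi)
    sel = np.asarray(voi.data) > 0
    if not sel.any():
        raise ValueError("empty VOI")
    return float(np.asarray(grid.data)[sel].mean())


def voi_rel_diff(
    pet_mrac: VolumeGrid,
    pet_ctac: VolumeGrid,
    labels: VolumeGrid,
    gm_prob: VolumeGrid,
    gm_threshold: float = DEFAULT_GM_THRESHOLD,
) -> pd.DataFrame:
    """Per-VOI relative difference of mean activity, MRAC vs CTAC.

    For each nonzero label, voxels with grey-matter probability >=
    ``gm_threshold`` contribute; the row value is
    ``(mean(PET_MRAC) - mean(PET_CTAC)) / mean(PET_CTAC)``.  Labels whose
    masked region is empty are absent; a zero CTAC mean yields NaN.
    """
    require_same_grid(pet_mrac, pet_ctac, labels, gm_prob)
    lab = np.asarray(labels.data).astype(int)
    if (lab < 0).any():
        raise ValueError("labels must be nonnegative")
    gm = np.asarray(gm_prob.data) >= gm_threshold
    rows = []
    for voi in np.unique(lab[lab > 0]):
        sel = (lab == voi) & gm
        if not sel.any():
            continue
        m_mrac = float(np.asarray(pet_mrac.data)[sel].mean())
        m_ctac = float(np.asarray(pet_ctac.data)[sel].mean())
        rel = np.nan if m_ctac == 0 else (m_mrac - m_ctac) / m_ctac
        rows.append({"voi": int(voi), "n_voxels": int(sel.sum()), "rel_diff": rel})
    return pd.DataFrame(rows, columns=["voi", "n_voxels", "rel_diff"])


def bias_atlas(
    pairs: Sequence[Tuple[VolumeGrid, VolumeGrid]],
    brain_mask: VolumeGrid,
) -> VolumeGrid:
    """Voxelwise mean relative difference across subjects, inside the brain.

    Each pair is (PET_MRAC, PET_CTAC) in a common space.  Voxels where a
    reference value is zero, and voxels outside the brain mask, carry NaN.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one (MRAC, CTAC) pair")
    for mrac, ctac in pairs:
        require_same_grid(mrac, ctac, brain_mask)
    mask = np.asarray(brain_mask.data) > 0
    stack = []
    for mrac, ctac in pairs:
        ref = np.asarray(ctac.data, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = (np.asarray(mrac.data, dtype=float) - ref) / ref
        rel[ref == 0] = np.nan
        stack.append(rel)
    mean = np.mean(stack, axis=0)
    mean[~mask] = np.nan
    return brain_mask.like(mean)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def dice_report(
    rows: List[dict], reference_method: str = "bulk"
) -> pd.DataFrame:
    """Assemble per-subject DICE rows into a table with percentage
    differences to the reference method and cohort medians.

    ``rows`` entries carry keys ``subject``, ``method``, ``scope``
    ("sinus" or "whole") and ``dice``.
    """
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    wide = df.pivot_table(index=["subject", "scope"], columns="method", values="dice")
    for method in wide.columns:
        if method == reference_method:
            continue
        wide[f"pct_diff_{method}_vs_{reference_method}"] = (
            100.0 * (wide[method] - wide[reference_method]) / wide[reference_method]
        )
    return wide.reset_index()
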