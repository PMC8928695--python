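"""Three-segment MRI-to-CT conversion model for the sinus region.

The model maps an MRI intensity ``m`` to a CT value in Hounsfield units:

* ``m <= m_low``  -> -1000 HU (air plateau),
* ``m_low < m < m_high`` -> linear ramp from -1000 to 0 HU (tissue mix),
* ``m >= m_high`` ->  0 HU (soft-tissue plateau).

The two breakpoints are estimated from paired (MRI, HU) samples of
bone-segment voxels inside the sinus region by minimizing the sum of
squared *orthogonal* distances from each (axis-normalized) data point to
the three-segment polyline, searched exhaustively over a breakpoint
lattice.  Per subject the fit is bootstrapped: 100 random draws of 100
voxels, each fitted independently, and the breakpoints averaged.  Cohort
models average the per-subject bootstrap models with equal weight, and a
leave-one-out variant excludes one subject for out-of-sample validation.

Bone-to-HU conversion is deliberately absent: the model's output spans
exactly [-1000, 0] HU, so converted voxels are air, soft tissue, or a mix.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

HU_AIR = -1000.0
HU_SOFT = 0.0
#: HU axis normalization: the curve's vertical span.
HU_SCALE = 1000.0


class IllPosedFitWarning(UserWarning):
    """The sample cannot constrain both breakpoints (e.g. plateau-only data)."""


@dataclass
class ConversionModel:
    """Fitted breakpoints of the three-segment MRI -> HU curve.

    ``m_low`` is the MRI intensity mapped to -1000 HU, ``m_high`` the one
    mapped to 0 HU.  ``fit_meta`` records provenance: repeats, voxels per
    repeat, seed, scales, per-repeat estimates, excluded subjects.
    """

    m_low: float
    m_high: float
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.m_low < self.m_high:
            raise ValueError(
                f"require m_low < m_high, got ({self.m_low}, {self.m_high})"
            )

    def predict_hu(self, mri: Union[float, np.ndarray]):
        """Evaluate the piecewise-linear curve; output lies in [-1000, 0]."""
        values = np.asarray(mri, dtype=float)
        hu = np.interp(values, [self.m_low, self.m_high], [HU_AIR, HU_SOFT])
        if np.ndim(mri) == 0:
            return float(hu)
        return hu

    def to_dict(self) -> dict:
        return {"m_low": self.m_low, "m_high": self.m_high, "fit_meta": self.fit_meta}

    @staticmethod
    def from_dict(d: dict) -> "ConversionModel":
        return ConversionModel(
            float(d["m_low"]), float(d["m_high"]), dict(d.get("fit_meta", {}))
        )


def predict_hu(model: ConversionModel, mri):
    """Functional alias for :meth:`ConversionModel.predict_hu`."""
    return model.predict_hu(mri)


# ---------------------------------------------------------------------------
# Orthogonal point-to-polyline distance
# ---------------------------------------------------------------------------

def _squared_distances(
    xm: np.ndarray,
    ym: np.ndarray,
    low: np.ndarray,
    high: np.ndarray,
    y_air: float = -1.0,
) -> np.ndarray:
    """Squared distance of normalized points to each candidate polyline.

    ``xm, ym``: points, shape (n,); ``low, high``: normalized breakpoints,
    shape (k,).  Returns (k, n).  The polyline is the left plateau ray
    ``y = y_air`` for ``x <= low`` (``y_air`` is -1000 HU in normalized
    units), the diagonal from (low, y_air) to (high, 0), and the right
    plateau ray ``y = 0`` for ``x >= high``.
    """
    x = xm[None, :]
    y = ym[None, :]
    l = low[:, None]
    h = high[:, None]

    # left ray y = y_air, x in (-inf, l]
    d_left = np.where(x <= l, (y - y_air) ** 2, (x - l) ** 2 + (y - y_air) ** 2)
    # right ray y = 0, x in [h, inf)
    d_right = np.where(x >= h, y**2, (x - h) ** 2 + y**2)
    # diagonal segment (l, y_air) -> (h, 0)
    ex = h - l
    ey = -y_air
    t = ((x - l) * ex + (y - y_air) * ey) / (ex**2 + ey**2)
    t = np.clip(t, 0.0, 1.0)
    d_diag = (x - (l + t * ex)) ** 2 + (y - (y_air + t * ey)) ** 2
    return np.minimum(np.minimum(d_left, d_right), d_diag)


def point_curve_distance(
    point: Tuple[float, float],
    candidate: Tuple[float, float],
    scales: Tuple[float, float],
) -> float:
    """Distance from an (MRI, HU) point to a candidate three-segment curve.

    Both axes are divided by their scale before the Euclidean distance is
    taken, so the two axes contribute comparably.
    """
    s_mri, s_hu = scales
    if s_mri <= 0 or s_hu <= 0:
        raise ValueError("scales must be positive")
    m_low, m_high = candidate
    xm = np.asarray([point[0] / s_mri])
    ym = np.asarray([point[1] / s_hu])
    d2 = _squared_distances(
        xm,
        ym,
        np.asarray([m_low / s_mri]),
        np.asarray([m_high / s_mri]),
        y_air=HU_AIR / s_hu,
    )
    return float(np.sqrt(d2[0, 0]))


def default_scales(mri: np.ndarray) -> Tuple[float, float]:
    """Axis normalization: MRI by its 99th-percentile, HU by 1000."""
    s_mri = float(np.percentile(np.asarray(mri, dtype=float), 99))
    if s_mri <= 0:
        s_mri = max(float(np.max(np.abs(mri))), 1.0)
    return s_mri, HU_SCALE


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _loss_on_lattice(
    xm: np.ndarray,
    ym: np.ndarray,
    low_cands: np.ndarray,
    high_cands: np.ndarray,
    y_air: float = -1.0,
) -> Tuple[float, float, float]:
    """Argmin of the squared-distance sum over the (low, high) lattice.

    Ties break toward the smallest ``high - low``, then the smallest
    ``low``.  Inputs are in normalized units; returns normalized
    ``(low, high, loss)``.
    """
    ll, hh = np.meshgrid(low_cands, high_cands, indexing="ij")
    valid = ll < hh
    l_flat = ll[valid]
    h_flat = hh[valid]
    loss = _squared_distances(xm, ym, l_flat, h_flat, y_air=y_air).sum(axis=1)
    order = np.lexsort((l_flat, h_flat - l_flat, loss))
    i = order[0]
    return float(l_flat[i]), float(h_flat[i]), float(loss[i])


def fit_once(
    sample: Sequence[Tuple[float, float]],
    n_grid: int = 64,
    scales: Optional[Tuple[float, float]] = None,
    refine_factor: int = 8,
    bounds: Optional[Tuple[float, float]] = None,
) -> Tuple[float, float]:
    """Fit (m_low, m_high) to one sample of (MRI, HU) pairs.

    Exhaustive search over an ``n_grid x n_grid`` breakpoint lattice
    spanning the sample's MRI range (or explicit ``bounds``, so that
    bootstrap repeats share one candidate grid), followed by one
    ``refine_factor``-times finer local search around the optimum.
    Requires at least 10 pairs.
    """
    arr = np.asarray(sample, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("sample must be pairs of (mri, hu)")
    if len(arr) < 10:
        raise ValueError(f"need >= 10 pairs, got {len(arr)}")
    mri, hu = arr[:, 0], arr[:, 1]
    if scales is None:
        scales = default_scales(mri)
    s_mri, s_hu = scales

    near_air = np.abs(hu - HU_AIR) < 0.05 * HU_SCALE
    near_soft = np.abs(hu - HU_SOFT) < 0.05 * HU_SCALE
    if near_air.all() or near_soft.all():
        warnings.warn(
            "sample lies on a single plateau; breakpoints are ill-posed and "
            "resolve by the lattice tie rule",
            IllPosedFitWarning,
            stacklevel=2,
        )

    xm = mri / s_mri
    ym = hu / s_hu
    if bounds is None:
        lo_bound, hi_bound = float(xm.min()), float(xm.max())
    else:
        lo_bound, hi_bound = bounds[0] / s_mri, bounds[1] / s_mri
    if hi_bound <= lo_bound:
        hi_bound = lo_bound + 1e-6
    y_air = HU_AIR / s_hu
    coarse = np.linspace(lo_bound, hi_bound, n_grid)
    l0, h0, _ = _loss_on_lattice(xm, ym, coarse, coarse, y_air=y_air)

    step = (hi_bound - lo_bound) / (n_grid - 1)
    fine_step = step / refine_factor
    fine_l = l0 + fine_step * np.arange(-refine_factor, refine_factor + 1)
    fine_h = h0 + fine_step * np.arange(-refine_factor, refine_factor + 1)
    l1, h1, _ = _loss_on_lattice(xm, ym, fine_l, fine_h, y_air=y_air)
    return float(l1 * s_mri), float(h1 * s_mri)


def fit_bootstrap(
    voxels: Sequence[Tuple[float, float]],
    n_vox: int = 100,
    n_reps: int = 100,
    seed: int = 0,
    replace: bool = False,
    scales: Optional[Tuple[float, float]] = None,
) -> ConversionModel:
    """Bootstrap fit for one subject: ``n_reps`` draws of ``n_vox`` voxels.

    Each repeat draws voxels without replacement (a flag enables
    with-replacement draws) and is fitted independently; the final model is
    the arithmetic mean of the per-repeat breakpoints.
    """
    arr = np.asarray(voxels, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("voxels must be pairs of (mri, hu)")
    if len(arr) < n_vox:
        raise ValueError(f"need >= {n_vox} voxels, got {len(arr)}")
    if scales is None:
        scales = default_scales(arr[:, 0])
    bounds = (float(arr[:, 0].min()), float(arr[:, 0].max()))
    rng = np.random.default_rng(seed)
    estimates = np.empty((n_reps, 2), dtype=float)
    for rep in range(n_reps):
        idx = rng.choice(len(arr), size=n_vox, replace=replace)
        estimates[rep] = fit_once(arr[idx], scales=scales, bounds=bounds)
    m_low, m_high = estimates.mean(axis=0)
    return ConversionModel(
        float(m_low),
        float(m_high),
        fit_meta={
            "n_vox": int(n_vox),
            "n_reps": int(n_reps),
            "seed": int(seed),
            "replace": bool(replace),
            "scales": [float(scales[0]), float(scales[1])],
            "per_repeat": estimates.tolist(),
        },
    )


def derive_subject_seed(seed: int, subject_index: int) -> int:
    """Deterministic, collision-free per-subject seed below 2^31."""
    return int((1009 * int(seed) + 9176 * int(subject_index) + 17) % 2_147_483_647)


def fit_cohort(
    subjects: Sequence[Sequence[Tuple[float, float]]],
    seed: int = 0,
    n_vox: int = 100,
    n_reps: int = 100,
    subject_models: Optional[Sequence[Optional[ConversionModel]]] = None,
    subject_indices: Optional[Sequence[int]] = None,
) -> ConversionModel:
    """Equal-weight average of per-subject bootstrap models.

    ``subject_indices`` pins each sample to its original cohort index so
    the derived per-subject seed (and hence the per-subject model) does not
    depend on which other subjects are present; ``subject_models`` may
    supply precomputed bootstrap models for reuse.
    """
    if len(subjects) == 0:
        raise ValueError("empty cohort")
    if subject_indices is None:
        subject_indices = list(range(len(subjects)))
    models: List[ConversionModel] = []
    for pos, sample in enumerate(subjects):
        model = None
        if subject_models is not None:
            model = subject_models[pos]
        if model is None:
            model = fit_bootstrap(
                sample,
                n_vox=n_vox,
                n_reps=n_reps,
                seed=derive_subject_seed(seed, subject_indices[pos]),
            )
        models.append(model)
    m_low = float(np.mean([m.m_low for m in models]))
    m_high = float(np.mean([m.m_high for m in models]))
    return ConversionModel(
        m_low,
        m_high,
        fit_meta={
            "n_subjects": len(models),
            "subject_indices": [int(i) for i in subject_indices],
            "seed": int(seed),
            "per_subject": [[m.m_low, m.m_high] for m in models],
        },
    )


def leave_one_out(
    subjects: Sequence[Sequence[Tuple[float, float]]],
    held_out: int,
    seed: int = 0,
    n_vox: int = 100,
    n_reps: int = 100,
    subject_models: Optional[Sequence[Optional[ConversionModel]]] = None,
) -> ConversionModel:
    """Cohort model fitted with one subject excluded.

    The result is independent of the held-out subject's data; its exclusion
    is recorded in ``fit_meta``.
    """
    n = len(subjects)
    if n < 2:
        raise ValueError("leave-one-out needs a cohort of >= 2 subjects")
    if not 0 <= held_out < n:
        raise IndexError(f"held_out index {held_out} out of range for {n} subjects")
    keep = [i for i in range(n) if i != held_out]
    model = fit_cohort(
        [subjects[i] for i in keep],
        seed=seed,
        n_vox=n_vox,
        n_reps=n_reps,
        subject_models=None if subject_models is None else [subject_models[i] for i in keep],
        subject_indices=keep,
    )
    model.fit_meta["held_out"] = int(held_out)
    return model


def extract_pairs(
    mri, ct, bone_label_mask: np.ndarray, region_mask: np.ndarray
) -> np.ndarray:
    """Paired (MRI, HU) samples from bone-labelled voxels inside a region."""
    mri_data = np.asarray(mri.data if hasattr(mri, "data") else mri, dtype=float)
    ct_data = np.asarray(ct.data if hasattr(ct, "data") else ct, dtype=float)
    sel = np.asarray(bone_label_mask, dtype=bool) & np.asarray(region_mask, dtype=bool)
    return np.column_stack([mri_data[sel], ct_data[sel]])
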