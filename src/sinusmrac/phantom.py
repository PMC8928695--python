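"""Seeded synthetic head phantoms.

Each subject is an ellipsoidal head -- background air, scalp shell, skull
shell, brain interior (white/grey/CSF bands) -- with an anterior sinus
compartment and a disconnected lower airway.  The compartment holds two
overlapping superellipsoidal air cavities, a one-voxel fine-bone wall
around them, and soft tissue elsewhere.  Paired MRI and CT volumes are
generated so that inside the compartment the CT value follows a known
three-segment piecewise-linear function of the latent MRI intensity plus
noise: air cavities sit on the -1000 HU plateau, compartment soft tissue
on the 0 HU plateau, and wall ("mixture") voxels span the whole MRI range,
reproducing the scatter geometry the conversion model is fitted to
(concentrations at -1000 and 0 HU with a diagonal in between).

The synthetic segmenter emulates unified-segmentation behaviour: large air
cavities are labelled air, but wall voxels are misclassified as bone with
probability ``segmenter_confusion``, and a small fraction of skull voxels
leaks into soft tissue.  Smooth sinusoidal deformation fields (with an
analytically consistent approximate inverse) relate each subject to a
canonical template space in which the cohort-mean sinus compartment
defines the template cuboid.

Identical spec + seed always produces bit-identical subjects.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .cuboid_fit import CuboidRegion
from .template_warp import TemplateCuboid
from .volume_io import (
    TissueProbabilitySet,
    VolumeGrid,
    read_displacement_field,
    read_volume,
    write_mask,
    write_volume,
)

# true-class codes of the generator (not the segmenter's view)
BG, SCALP, SKULL, WHITE, GREY, CSF, SINUS_AIR, SINUS_WALL, SINUS_SOFT, AIRWAY = range(10)

#: reference geometry, in voxels of a 96^3 grid (scaled to other shapes)
_REF = {
    "head_center": (0.500, 0.542, 0.500),   # fraction of grid dims
    "head_radii": (40.0, 46.0, 42.0),
    "scalp_rho": 1.00,                       # normalized-radius shell bounds
    "skull_rho": 0.94,
    "facial_bone_rho": 0.92,
    "brain_rho": 0.87,
    "csf_rho": 0.80,
    "grey_rho": 0.55,
    "lobe_centers_x": (44.0, 52.0),
    "lobe_center_y": 35.0,
    "lobe_center_z": 59.0,
    "lobe_semi": (7.0, 8.0, 7.0),
    "lobe_exponent": 4,
    "box_pad": 2,
    "airway_center_y": 38.5,
    "airway_radius": 3.0,
    "airway_z": (0.10, 0.45),                # fraction of nz
}

# latent MRI intensity model (arbitrary units)
_MRI_MEANS = {BG: 15.0, SCALP: 820.0, SKULL: 260.0, WHITE: 760.0, GREY: 700.0, CSF: 640.0}
_MRI_CLASS_SD = {BG: 8.0, SCALP: 25.0, SKULL: 25.0, WHITE: 20.0, GREY: 20.0, CSF: 20.0}
_CT_MEANS = {BG: -1000.0, SCALP: 0.0, SKULL: 1000.0, WHITE: 25.0, GREY: 35.0, CSF: 10.0,
             AIRWAY: -1000.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for the synthetic cohort."""

    shape: Tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = 2.0
    seed: int = 0
    #: MRI intensities mapped to -1000 HU and 0 HU by the generating law
    sinus_true_breakpoints: Tuple[float, float] = (120.0, 880.0)
    mri_noise_sd: float = 10.0
    hu_noise_sd: float = 25.0
    sinus_air_fraction: float = 0.55
    sinus_soft_fraction: float = 0.30
    sinus_bone_fraction: float = 0.15
    #: probability that a sinus wall (mixture) voxel is labelled bone
    segmenter_confusion: float = 0.9
    #: probability that a skull voxel leaks into the soft-tissue map
    skull_misclass: float = 0.03
    deformation_amplitude_mm: float = 3.0

    def __post_init__(self) -> None:
        fr = (self.sinus_air_fraction, self.sinus_soft_fraction, self.sinus_bone_fraction)
        if any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"sinus fractions must be nonnegative and sum to 1, got {fr}")
        m_low, m_high = self.sinus_true_breakpoints
        if not m_low < m_high:
            raise ValueError("sinus_true_breakpoints must satisfy m_low < m_high")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")

    @property
    def spacing(self) -> Tuple[float, float, float]:
        return (self.spacing_mm,) * 3

    def generating_law(self, mri: np.ndarray) -> np.ndarray:
        """The true three-segment MRI -> HU law of this cohort."""
        m_low, m_high = self.sinus_true_breakpoints
        return np.interp(np.asarray(mri, dtype=float), [m_low, m_high], [-1000.0, 0.0])

    @property
    def mri_margin(self) -> float:
        m_low, m_high = self.sinus_true_breakpoints
        return 0.1 * (m_high - m_low)


@dataclass
class PhantomSubject:
    """One synthetic subject with full ground truth."""

    mri: VolumeGrid
    ct: VolumeGrid
    probmaps: TissueProbabilitySet
    truth_masks: Dict[str, VolumeGrid]
    sinus_voi: VolumeGrid
    fwd_deformation: VolumeGrid
    inv_deformation: VolumeGrid
    params: dict = field(default_factory=dict)

    @property
    def sinus_box(self) -> CuboidRegion:
        return CuboidRegion(tuple(self.params["box_lo"]), tuple(self.params["box_hi"]))


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _superellipsoid(
    X: np.ndarray, Y: np.ndarray, Z: np.ndarray,
    center: Tuple[float, float, float],
    semi: Tuple[float, float, float],
    p: int,
) -> np.ndarray:
    return (
        np.abs((X - center[0]) / semi[0]) ** p
        + np.abs((Y - center[1]) / semi[1]) ** p
        + np.abs((Z - center[2]) / semi[2]) ** p
    ) <= 1.0


def _sinus_geometry(
    spec: PhantomSpec,
    center_jitter: np.ndarray,
    size_jitter: float,
) -> Tuple[np.ndarray, np.ndarray, CuboidRegion, float]:
    """Cavity mask, wall mask and compartment box on the full grid.

    The common scale of the cavity semi-axes is solved by bisection so the
    cavity occupies ``spec.sinus_air_fraction`` of the compartment box
    (bounding box of the cavity padded by 2 voxels).
    """
    nx, ny, nz = spec.shape
    sx, sy, sz = nx / 96.0, ny / 96.0, nz / 96.0
    pad = _REF["box_pad"]
    centers = [
        np.array([cx * sx, _REF["lobe_center_y"] * sy, _REF["lobe_center_z"] * sz])
        + center_jitter
        for cx in _REF["lobe_centers_x"]
    ]
    semi0 = np.array(_REF["lobe_semi"]) * np.array([sx, sy, sz]) * size_jitter
    p = _REF["lobe_exponent"]

    # crop window generous enough for the largest scale probed
    s_max = 2.2
    lo = np.floor(np.min(centers, axis=0) - semi0 * s_max - pad - 1).astype(int)
    hi = np.ceil(np.max(centers, axis=0) + semi0 * s_max + pad + 1).astype(int)
    lo = np.clip(lo, 0, np.array(spec.shape) - 1)
    hi = np.clip(hi, 0, np.array(spec.shape) - 1)
    win = tuple(slice(l, h + 1) for l, h in zip(lo, hi))
    Xw, Yw, Zw = np.meshgrid(
        *[np.arange(l, h + 1, dtype=float) for l, h in zip(lo, hi)], indexing="ij"
    )

    def cavity_at(scale: float) -> np.ndarray:
        semi = np.maximum(semi0 * scale, 0.75)
        cav = np.zeros(Xw.shape, dtype=bool)
        for c in centers:
            cav |= _superellipsoid(Xw, Yw, Zw, c, semi, p)
        return cav

    def fraction(cav: np.ndarray) -> float:
        if not cav.any():
            return 0.0
        idx = np.nonzero(cav)
        dims = [int(a.max() - a.min() + 1) + 2 * pad for a in idx]
        return cav.sum() / float(np.prod(dims))

    s_lo, s_hi = 0.6, s_max
    for _ in range(30):
        s_mid = 0.5 * (s_lo + s_hi)
        if fraction(cavity_at(s_mid)) < spec.sinus_air_fraction:
            s_lo = s_mid
        else:
            s_hi = s_mid
    scale = 0.5 * (s_lo + s_hi)
    cav_win = cavity_at(scale)

    cavity = np.zeros(spec.shape, dtype=bool)
    cavity[win] = cav_win
    idx = np.nonzero(cavity)
    box = CuboidRegion(
        tuple(max(0, int(a.min()) - pad) for a in idx),
        tuple(min(n - 1, int(a.max()) + pad) for a, n in zip(idx, spec.shape)),
    )
    box_mask = box.to_mask(spec.shape)
    wall = ndimage.binary_dilation(cavity, structure=np.ones((3, 3, 3))) & box_mask & ~cavity
    achieved = cavity.sum() / float(box.volume)
    return cavity, wall, box, float(achieved)


@lru_cache(maxsize=32)
def canonical_sinus_box(spec: PhantomSpec) -> CuboidRegion:
    """Compartment box of the jitter-free canonical anatomy (cached)."""
    _, _, box, _ = _sinus_geometry(spec, np.zeros(3), 1.0)
    return box


def canonical_template(spec: PhantomSpec) -> TemplateCuboid:
    """Template cuboid asset for this cohort's canonical space."""
    return TemplateCuboid(spec.shape, spec.spacing, canonical_sinus_box(spec))


# ---------------------------------------------------------------------------
# subject generation
# ---------------------------------------------------------------------------

def generate_subject(spec: PhantomSpec, subject_seed: int) -> PhantomSubject:
    """Generate one subject; identical spec + seed gives identical volumes."""
    if any(n < 16 for n in spec.shape):
        raise ValueError(f"degenerate shape {spec.shape}: every dim must be >= 16")
    rng = np.random.default_rng(int(subject_seed))
    nx, ny, nz = spec.shape
    shape = spec.shape
    m_low, m_high = spec.sinus_true_breakpoints
    margin = spec.mri_margin

    X, Y, Z = np.indices(shape, dtype=float)

    # --- anatomy ---------------------------------------------------------
    scales = np.array([nx, ny, nz]) / 96.0
    head_center = np.array(_REF["head_center"]) * np.array(shape)
    head_radii = (np.array(_REF["head_radii"]) + rng.uniform(-1.0, 2.0, 3)) * scales
    rho = np.sqrt(
        ((X - head_center[0]) / head_radii[0]) ** 2
        + ((Y - head_center[1]) / head_radii[1]) ** 2
        + ((Z - head_center[2]) / head_radii[2]) ** 2
    )

    labels = np.full(shape, BG, dtype=np.int8)
    labels[rho <= _REF["scalp_rho"]] = SCALP
    labels[rho <= _REF["skull_rho"]] = SKULL
    labels[rho <= _REF["brain_rho"]] = CSF
    labels[rho <= _REF["csf_rho"]] = GREY
    labels[rho <= _REF["grey_rho"]] = WHITE

    # facial sector: anterior to the sinuses the calvarial shell gives way
    # to thin facial bone embedded in soft tissue
    face = (
        (Y < head_center[1] - 0.25 * head_radii[1])
        & (np.abs(Z - head_center[2]) < 0.45 * head_radii[2])
    )
    labels[face & (labels == SKULL) & (rho <= _REF["facial_bone_rho"])] = SCALP

    center_jitter = rng.integers(-1, 2, 3).astype(float) * scales
    size_jitter = float(rng.uniform(0.95, 1.05))
    cavity, wall, box, air_frac = _sinus_geometry(spec, center_jitter, size_jitter)
    box_mask = box.to_mask(shape)

    airway = (
        ((X - 0.5 * nx) ** 2 + (Y - _REF["airway_center_y"] * scales[1]) ** 2
         <= (_REF["airway_radius"] * scales[0]) ** 2)
        & (Z >= _REF["airway_z"][0] * nz)
        & (Z <= _REF["airway_z"][1] * nz)
        & (rho <= _REF["brain_rho"])
        & ~box_mask
    )
    labels[airway] = AIRWAY
    labels[box_mask] = SINUS_SOFT
    labels[wall] = SINUS_WALL
    labels[cavity] = SINUS_AIR

    # --- latent MRI ------------------------------------------------------
    mri = np.zeros(shape, dtype=float)
    for cls, mean in _MRI_MEANS.items():
        sel = labels == cls
        mri[sel] = rng.normal(mean, _MRI_CLASS_SD[cls], int(sel.sum()))
    for cls, (lo, hi) in {
        SINUS_AIR: (max(0.0, m_low - margin), m_low),
        AIRWAY: (max(0.0, m_low - margin), m_low),
        SINUS_SOFT: (m_high, m_high + margin),
        SINUS_WALL: (max(0.0, m_low - margin), m_high + margin),
    }.items():
        sel = labels == cls
        mri[sel] = rng.uniform(lo, hi, int(sel.sum()))

    # --- CT from the generating law -------------------------------------
    ct = np.zeros(shape, dtype=float)
    for cls, mean in _CT_MEANS.items():
        ct[labels == cls] = mean
    sinus_sel = np.isin(labels, (SINUS_AIR, SINUS_WALL, SINUS_SOFT))
    ct[sinus_sel] = spec.generating_law(mri[sinus_sel])
    head = rho <= _REF["scalp_rho"]
    if spec.hu_noise_sd > 0:
        ct[head] = ct[head] + rng.normal(0.0, spec.hu_noise_sd, int(head.sum()))
    ct = np.clip(ct, -1000.0, 3000.0)

    # --- observed MRI ----------------------------------------------------
    mri_obs = mri.copy()
    if spec.mri_noise_sd > 0:
        mri_obs = mri_obs + rng.normal(0.0, spec.mri_noise_sd, shape)
    mri_obs = np.clip(mri_obs, 0.0, None)

    # --- synthetic segmenter output (probability maps) -------------------
    prob = {name: np.zeros(shape, dtype=float)
            for name in ("grey", "white", "csf", "soft", "bone", "air")}
    prob["air"][np.isin(labels, (BG, SINUS_AIR, AIRWAY))] = 1.0
    prob["soft"][labels == SCALP] = 1.0
    prob["grey"][labels == GREY] = 1.0
    prob["white"][labels == WHITE] = 1.0
    prob["csf"][labels == CSF] = 1.0

    skull_sel = labels == SKULL
    leak = skull_sel & (rng.random(shape) < spec.skull_misclass)
    prob["bone"][skull_sel & ~leak] = 1.0
    prob["soft"][leak] = 1.0

    # the segmenter has no sinus class: the mixture (wall + compartment soft
    # tissue) is mostly labelled bone, while large air cavities stay air
    mixture_sel = np.isin(labels, (SINUS_WALL, SINUS_SOFT))
    confused = mixture_sel & (rng.random(shape) < spec.segmenter_confusion)
    prob["bone"][confused] = 1.0
    plain = mixture_sel & ~confused
    prob["air"][plain & (ct < -500.0)] = 1.0
    prob["soft"][plain & (ct >= -500.0)] = 1.0

    # --- deformation fields ----------------------------------------------
    # affine part (translation + per-axis scale about the sinus centre, as a
    # real template registration would capture) plus a smooth sinusoidal
    # wiggle; the affine has an exact inverse so fwd o inv ~ identity
    canon_box = canonical_sinus_box(spec)
    spacing = np.array(spec.spacing)
    c_subj = (np.array(box.lo) + np.array(box.hi)) / 2.0 * spacing
    c_canon = (np.array(canon_box.lo) + np.array(canon_box.hi)) / 2.0 * spacing
    scale_axes = (
        (np.array(canon_box.dims, dtype=float)) / np.array(box.dims, dtype=float)
    )
    offset_mm = c_subj - c_canon
    amp = 0.3 * spec.deformation_amplitude_mm
    phases = rng.uniform(0.0, 2.0 * np.pi, 3)
    coords = (X / nx, Y / ny, Z / nz)
    wiggle = np.stack(
        [amp * np.sin(2.0 * np.pi * coords[k] + phases[k]) for k in range(3)], axis=-1
    )
    world = np.stack([X * spacing[0], Y * spacing[1], Z * spacing[2]], axis=-1)
    # subject -> template lookup (pull-back field on the subject grid)
    u_inv = (c_canon + scale_axes * (world - c_subj)) - world + wiggle
    # template -> subject
    u_fwd = (c_subj + (world - c_canon) / scale_axes) - world - wiggle

    grid = VolumeGrid(np.zeros(shape), spec.spacing)

    def vol(a, dtype=None):
        return grid.like(a if dtype is None else a.astype(dtype))

    probmaps = TissueProbabilitySet(**{k: vol(v) for k, v in prob.items()})
    truth = {
        "scalp": vol((labels == SCALP).astype(np.uint8)),
        "skull": vol(skull_sel.astype(np.uint8)),
        "brain": vol(np.isin(labels, (WHITE, GREY, CSF)).astype(np.uint8)),
        "air_cavity": vol(cavity.astype(np.uint8)),
        "sinus_wall": vol((labels == SINUS_WALL).astype(np.uint8)),
        "sinus_soft": vol((labels == SINUS_SOFT).astype(np.uint8)),
        "airway": vol(airway.astype(np.uint8)),
        "head": vol(head.astype(np.uint8)),
        "sinus_box": vol(box_mask.astype(np.uint8)),
    }
    params = {
        "subject_seed": int(subject_seed),
        "m_low": float(m_low),
        "m_high": float(m_high),
        "box_lo": list(box.lo),
        "box_hi": list(box.hi),
        "canonical_box_lo": list(canon_box.lo),
        "canonical_box_hi": list(canon_box.hi),
        "air_fraction_achieved": air_frac,
        "offset_mm": offset_mm.tolist(),
    }
    return PhantomSubject(
        mri=vol(mri_obs),
        ct=vol(ct),
        probmaps=probmaps,
        truth_masks=truth,
        sinus_voi=truth["sinus_box"].copy(),
        fwd_deformation=vol(u_fwd),
        inv_deformation=vol(u_inv),
        params=params,
    )


def generate_cohort(spec: PhantomSpec, n: int) -> List[PhantomSubject]:
    """n >= 2 subjects sharing the conversion law, differing in anatomy/noise."""
    if n < 2:
        raise ValueError("cohort needs n >= 2 (leave-one-out undefined otherwise)")
    return [generate_subject(spec, spec.seed * 10007 + i) for i in range(n)]


# ---------------------------------------------------------------------------
# on-disk cohort layout
# ---------------------------------------------------------------------------

_PROB_FILES = {name: f"prob_{name}.nii.gz" for name in TissueProbabilitySet.CLASS_NAMES}


def save_subject(subject: PhantomSubject, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(subject.mri, out / "t1.nii.gz")
    write_volume(subject.ct, out / "ct.nii.gz")
    for name, fname in _PROB_FILES.items():
        write_volume(getattr(subject.probmaps, name), out / fname)
    for name, mask in subject.truth_masks.items():
        write_mask(mask, out / f"truth_{name}.nii.gz")
    write_mask(subject.sinus_voi, out / "sinus_voi.nii.gz")
    write_volume(subject.fwd_deformation, out / "field_fwd.nii.gz")
    write_volume(subject.inv_deformation, out / "field_inv.nii.gz")
    (out / "manifest.json").write_text(json.dumps(subject.params, indent=2))


def load_subject(subject_dir) -> PhantomSubject:
    d = Path(subject_dir)
    params = json.loads((d / "manifest.json").read_text())
    probmaps = TissueProbabilitySet(
        **{name: read_volume(d / fname) for name, fname in _PROB_FILES.items()}
    )
    truth = {}
    for f in sorted(d.glob("truth_*.nii.gz")):
        truth[f.name[len("truth_"):-len(".nii.gz")]] = read_volume(f)
    return PhantomSubject(
        mri=read_volume(d / "t1.nii.gz"),
        ct=read_volume(d / "ct.nii.gz"),
        probmaps=probmaps,
        truth_masks=truth,
        sinus_voi=read_volume(d / "sinus_voi.nii.gz"),
        fwd_deformation=read_displacement_field(d / "field_fwd.nii.gz"),
        inv_deformation=read_displacement_field(d / "field_inv.nii.gz"),
        params=params,
    )
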