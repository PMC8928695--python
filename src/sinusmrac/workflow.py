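"""End-to-end orchestration: phantom cohort -> mu-maps -> evaluation.

`run_pipeline` drives one delineation method (bulk, cuboid or template)
over a cohort: per subject it builds the four-class MR-based mu-map,
derives the sinus region (fitted cuboid or warped template), fits the
MRI-to-CT conversion model with per-subject bootstraps, applies the
leave-one-out model of each subject for out-of-sample conversion, and
evaluates everything against the CT-based reference map.  All randomness
derives from the seed recorded in :class:`RunConfig`; reruns with the same
config produce identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import air_cavity, conversion, evaluation
from .cuboid_fit import CuboidRegion, initial_search_region, search_best_cuboid
from .mumap import (
    BilinearParams,
    ClassThresholds,
    MuCoefficients,
    TissueLabel,
    apply_bulk_sinus,
    apply_converted_sinus,
    assign_mu,
    classify_tissues,
    ct_reference_mumap,
)
from .phantom import PhantomSubject, load_subject
from .template_warp import TemplateCuboid, template_from_boxes, warp_mask
from .volume_io import VolumeGrid, write_volume

METHODS = ("bulk", "cuboid", "template")


def _package_version() -> str:
    try:
        return _pkg_version("sinusmrac")
    except PackageNotFoundError:
        return "unknown"


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run; YAML round-trippable."""

    thresholds: ClassThresholds = field(default_factory=ClassThresholds)
    coefficients: MuCoefficients = field(default_factory=MuCoefficients)
    bilinear: BilinearParams = field(default_factory=BilinearParams)
    slice_range: tuple = evaluation.DEFAULT_SLICE_RANGE
    hu_threshold: float = evaluation.DEFAULT_HU_THRESHOLD
    gm_threshold: float = evaluation.DEFAULT_GM_THRESHOLD
    cuboid_stride: int = 2
    cuboid_min_dim: int = 3
    axial_margin: int = 5
    fit_n_vox: int = 100
    fit_n_reps: int = 100
    corr_n_vox: int = 200
    corr_n_reps: int = 100
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["slice_range"] = list(self.slice_range)
        return d

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        for key, cls in (
            ("thresholds", ClassThresholds),
            ("coefficients", MuCoefficients),
            ("bilinear", BilinearParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = cls(**d[key])
        if "slice_range" in d:
            d["slice_range"] = tuple(d["slice_range"])
        return RunConfig(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# per-subject building blocks
# ---------------------------------------------------------------------------

def delineate_region(
    subject: PhantomSubject,
    method: str,
    config: RunConfig,
    template: Optional[TemplateCuboid] = None,
) -> Dict[str, object]:
    """Sinus region for one subject under one method.

    Returns ``{"mask": VolumeGrid, ...}`` plus method-specific artifacts
    (fitted cuboid + goodness, or the warped template mask).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method '{method}'")
    if method == "cuboid":
        cavities = air_cavity.delineate_air_cavities(subject.probmaps, config.thresholds)
        envelope = air_cavity.head_envelope(subject.probmaps, config.thresholds)
        search = initial_search_region(envelope, cavities, config.axial_margin)
        fit = search_best_cuboid(
            subject.probmaps.bone,
            search,
            stride=config.cuboid_stride,
            min_dim=config.cuboid_min_dim,
        )
        mask = subject.probmaps.grid.like(
            fit.region.to_mask(subject.probmaps.grid.shape).astype(np.uint8)
        )
        return {
            "mask": mask,
            "cuboid": fit.region,
            "goodness": fit.goodness,
            "air_cavities": cavities,
        }
    # bulk and template both delineate via the warped canonical cuboid; the
    # bulk method then assigns one fixed coefficient instead of converting
    if template is None:
        raise ValueError(f"method '{method}' requires a template cuboid")
    if subject.inv_deformation is None:
        raise ValueError("subject lacks an inverse deformation field")
    mask = warp_mask(template, subject.inv_deformation, subject.mri)
    return {"mask": mask}


def subject_conversion_pairs(
    subject: PhantomSubject, region_mask: VolumeGrid, config: RunConfig
) -> np.ndarray:
    """(MRI, HU) pairs of bone-labelled voxels inside the sinus region."""
    labels = classify_tissues(subject.probmaps, config.thresholds)
    bone = np.asarray(labels.data) == int(TissueLabel.BONE)
    return conversion.extract_pairs(
        subject.mri, subject.ct, bone, np.asarray(region_mask.data) > 0
    )


def build_method_mumap(
    subject: PhantomSubject,
    method: str,
    region_mask: VolumeGrid,
    config: RunConfig,
    model: Optional[conversion.ConversionModel] = None,
):
    """Four-class mu-map with the chosen sinus treatment applied."""
    labels = classify_tissues(subject.probmaps, config.thresholds)
    base = assign_mu(labels, config.coefficients)
    if method == "bulk":
        return apply_bulk_sinus(base, region_mask, config.coefficients)
    if model is None:
        raise ValueError(f"method '{method}' needs a fitted conversion model")
    return apply_converted_sinus(
        base, region_mask, subject.mri, model, config.coefficients
    )


# ---------------------------------------------------------------------------
# cohort run
# ---------------------------------------------------------------------------

def _as_subjects(
    subjects: Sequence[Union[PhantomSubject, str, Path]]
) -> List[PhantomSubject]:
    out = []
    for s in subjects:
        out.append(s if isinstance(s, PhantomSubject) else load_subject(s))
    return out


def run_pipeline(
    subjects: Sequence[Union[PhantomSubject, str, Path]],
    method: str,
    config: RunConfig = None,
    out_dir=None,
    template: Optional[TemplateCuboid] = None,
) -> dict:
    """Run one delineation method over a cohort and evaluate it.

    ``subjects`` are in-memory phantoms or subject directories.  Returns a
    report dict with per-subject metrics, conversion models, per-subject
    errors, and an exit status (0 = all subjects processed, 1 = partial,
    2 = none).  If ``out_dir`` is given, mu-maps, region artifacts, models,
    TSV reports and the resolved config are written there.
    """
    if config is None:
        config = RunConfig()
    if method not in METHODS:
        raise ValueError(f"unknown method '{method}'")
    cohort = _as_subjects(subjects)
    n = len(cohort)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    if template is None and method in ("bulk", "template"):
        boxes = [s.sinus_box for s in cohort]
        template = template_from_boxes(
            boxes, cohort[0].mri.shape, cohort[0].mri.spacing
        )

    errors: Dict[int, str] = {}
    regions: Dict[int, dict] = {}
    for i, subject in enumerate(cohort):
        try:
            regions[i] = delineate_region(subject, method, config, template)
        except Exception as exc:  # recorded, run continues for the others
            errors[i] = f"delineation failed: {exc}"

    ok = [i for i in range(n) if i not in errors]

    # conversion models: per-subject bootstraps, cohort mean, leave-one-out
    models: Dict[str, object] = {}
    subject_models: Dict[int, conversion.ConversionModel] = {}
    loo_models: Dict[int, conversion.ConversionModel] = {}
    if method in ("cuboid", "template"):
        pairs: Dict[int, np.ndarray] = {}
        for i in list(ok):
            p = subject_conversion_pairs(cohort[i], regions[i]["mask"], config)
            if len(p) < config.fit_n_vox:
                errors[i] = (
                    f"only {len(p)} bone voxels in region, need {config.fit_n_vox}"
                )
                ok.remove(i)
            else:
                pairs[i] = p
        for i in ok:
            subject_models[i] = conversion.fit_bootstrap(
                pairs[i],
                n_vox=config.fit_n_vox,
                n_reps=config.fit_n_reps,
                seed=conversion.derive_subject_seed(config.seed, i),
            )
        if len(ok) >= 1:
            models["cohort"] = conversion.fit_cohort(
                [pairs[i] for i in ok],
                seed=config.seed,
                subject_models=[subject_models[i] for i in ok],
                subject_indices=ok,
            )
        for i in ok:
            others = [j for j in ok if j != i]
            if others:
                loo = conversion.fit_cohort(
                    [pairs[j] for j in others],
                    seed=config.seed,
                    subject_models=[subject_models[j] for j in others],
                    subject_indices=others,
                )
                loo.fit_meta["held_out"] = i
                loo_models[i] = loo

    # mu-maps + evaluation
    rows_dice: List[dict] = []
    rows_voi: List[dict] = []
    rows_corr: List[dict] = []
    for i in ok:
        subject = cohort[i]
        model = loo_models.get(i) or models.get("cohort")
        mumap = build_method_mumap(
            subject, method, regions[i]["mask"], config, model
        )
        soft_mask = subject.mri.like(
            (np.asarray(mumap.labels.data) == int(TissueLabel.SOFT)).astype(np.uint8)
        )
        ctac = ct_reference_mumap(
            subject.ct, soft_mask, config.bilinear, config.coefficients
        )
        ct_mask, mrac_mask = evaluation.bone_masks_for_dice(
            subject.ct, mumap, config.hu_threshold, config.bilinear
        )
        rows_dice.append(
            {
                "subject": i,
                "method": method,
                "scope": "sinus",
                "dice": evaluation.dice(
                    evaluation.sinus_subvolume(ct_mask, config.slice_range),
                    evaluation.sinus_subvolume(mrac_mask, config.slice_range),
                ),
            }
        )
        rows_dice.append(
            {
                "subject": i,
                "method": method,
                "scope": "whole",
                "dice": evaluation.dice(ct_mask, mrac_mask),
            }
        )
        voi = subject.sinus_voi
        rows_voi.append(
            {
                "subject": i,
                "method": method,
                "mu_ctac": evaluation.voi_mean_mu(ctac, voi),
                "mu_mrac": evaluation.voi_mean_mu(mumap, voi),
            }
        )
        rs = evaluation.sample_correlations(
            ctac.mu,
            mumap.mu,
            voi,
            n_vox=min(config.corr_n_vox, int(np.asarray(voi.data).sum())),
            n_reps=config.corr_n_reps,
            seed=conversion.derive_subject_seed(config.seed, 10_000 + i),
        )
        rows_corr.append(
            {
                "subject": i,
                "method": method,
                "median_r": float(np.nanmedian(rs)) if not np.isnan(rs).all() else np.nan,
                "n_undefined": int(np.isnan(rs).sum()),
            }
        )
        if out is not None:
            sdir = out / f"subject_{i:02d}"
            sdir.mkdir(exist_ok=True)
            write_volume(mumap.mu, sdir / f"mumap_{method}.nii.gz")
            write_volume(mumap.labels, sdir / f"labels_{method}.nii.gz", dtype=np.int16)
            if "cuboid" in regions[i]:
                (sdir / "cuboid.json").write_text(
                    json.dumps(
                        {
                            "lo": list(regions[i]["cuboid"].lo),
                            "hi": list(regions[i]["cuboid"].hi),
                            "goodness": regions[i]["goodness"],
                            "stride": config.cuboid_stride,
                        },
                        indent=2,
                        sort_keys=True,
                    )
                )
            if i in loo_models:
                (sdir / "conversion_loo.json").write_text(
                    json.dumps(loo_models[i].to_dict(), indent=2, sort_keys=True)
                )

    dice_df = pd.DataFrame(rows_dice)
    voi_df = pd.DataFrame(rows_voi)
    corr_df = pd.DataFrame(rows_corr)
    summary = {
        "method": method,
        "n_subjects": n,
        "n_processed": len(ok),
        "errors": {str(k): v for k, v in sorted(errors.items())},
        "median_dice_sinus": _median(dice_df, "scope", "sinus", "dice"),
        "median_dice_whole": _median(dice_df, "scope", "whole", "dice"),
        "median_mu_ctac": _nanmedian(voi_df, "mu_ctac"),
        "median_mu_mrac": _nanmedian(voi_df, "mu_mrac"),
        "config_hash": config.content_hash(),
        "package_version": _package_version(),
        "status": 0 if not errors else (1 if ok else 2),
    }
    if "cohort" in models:
        summary["cohort_model"] = {
            "m_low": models["cohort"].m_low,
            "m_high": models["cohort"].m_high,
        }

    if out is not None:
        dice_df.to_csv(out / f"dice_{method}.tsv", sep="\t", index=False)
        voi_df.to_csv(out / f"voi_mu_{method}.tsv", sep="\t", index=False)
        corr_df.to_csv(out / f"correlation_{method}.tsv", sep="\t", index=False)
        (out / f"summary_{method}.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=float)
        )

    return {
        "summary": summary,
        "dice": dice_df,
        "voi": voi_df,
        "correlation": corr_df,
        "models": models,
        "loo_models": loo_models,
        "subject_models": subject_models,
        "regions": regions,
        "status": summary["status"],
    }


def _median(df: pd.DataFrame, col: str, value, target: str):
    if df.empty:
        return None
    sel = df[df[col] == value][target]
    return None if sel.empty else float(sel.median())


def _nanmedian(df: pd.DataFrame, col: str):
    if df.empty or col not in df:
        return None
    return float(np.nanmedian(df[col].to_numpy(dtype=float)))
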