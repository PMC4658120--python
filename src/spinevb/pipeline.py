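"""End-to-end training helpers and the phantom leave-one-out study.

These functions wire the stage modules together the way the method is
meant to be run: train per-VB coarse and fine regressors plus the chain
prior, train per-VB spatial priors and voxel classifiers, then localize
and segment held-out volumes and score them with the metric suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from spinevb.evaluation import (
    detection_rate,
    dice,
    localization_error,
    midsagittal_metrics,
    mld_sd,
    surface_distances,
)
from spinevb.features import FeatureConfig, build_integral_volumes
from spinevb.localization import (
    AggregationConfig,
    ForestConfig,
    LocalizerModel,
    cast_votes,  # noqa: F401  (re-exported for callers)
    learn_chain_prior,
    localize,
    sample_localization_patches,
    train_center_regressor,
)
from spinevb.phantom import PhantomConfig, generate_cohort
from spinevb.segmentation import (
    ROIConfig,
    SegmenterModel,
    learn_spatial_prior,
    sample_segmentation_patches,
    segment_vb,
    train_voxel_classifier,
)
from spinevb.volume_io import CenterAnnotation, LabelVolume, Volume3D, compute_center

__all__ = [
    "PipelineConfig",
    "MODALITY_PATCH_SIZES",
    "train_localizer",
    "train_segmenter",
    "segment_all",
    "run_phantom_loo",
]

# Patch sizes per modality: (coarse, fine, segmentation), in voxels of the
# grid each stage runs on.  Sagittal MR slices are parallel to the YZ
# plane, axial CT slices to the XY plane, hence the differing aspect.
MODALITY_PATCH_SIZES = {
    "mr": {"coarse": (16, 20, 20), "fine": (8, 40, 40), "seg": (8, 8, 8)},
    "ct": {"coarse": (20, 20, 12), "fine": (80, 80, 32), "seg": (8, 8, 8)},
}


@dataclass
class PipelineConfig:
    """Sizes and settings of the full train/test pipeline.

    Defaults are the production values: N = 15000 training and N' = 10000
    test patches per VB for localization, M = 12000 segmentation training
    patches per VB, forests of 20 trees.
    """

    modality: str = "mr"
    n_train: int = 15000
    n_test: int = 10000
    m_seg: int = 12000
    forest: ForestConfig = field(default_factory=ForestConfig)
    seg_forest: ForestConfig = field(default_factory=ForestConfig)
    agg: AggregationConfig = field(default_factory=AggregationConfig)
    roi: ROIConfig = field(default_factory=ROIConfig)
    k_candidates: int = 50
    downsample_factor: int = 4
    fine_halfwidth_mm: float = 30.0
    train_region_halfwidth_mm: float = 30.0
    patch_sizes: dict | None = None  # per-stage override of the modality table

    def feature_cfg(self, stage: str) -> FeatureConfig:
        table = self.patch_sizes or MODALITY_PATCH_SIZES[self.modality.lower()]
        return FeatureConfig(
            patch_size=table[stage], modality=self.modality.lower()
        )


def _gt_annotation(labels: LabelVolume) -> CenterAnnotation:
    n = int(labels.data.max())
    centers = np.stack([compute_center(labels, i) for i in range(1, n + 1)])
    names = labels.vb_names or [f"VB{i}" for i in range(1, n + 1)]
    return CenterAnnotation(centers=centers, vb_names=names)


def _region_around(vol: Volume3D, center_mm, halfwidth_mm: float):
    idx = vol.to_index(center_mm)
    half = halfwidth_mm / vol.spacing
    lo = np.maximum(np.floor(idx - half).astype(int), 0)
    hi = np.minimum(np.ceil(idx + half).astype(int) + 1, np.asarray(vol.shape))
    return lo, hi


def train_localizer(
    volumes: list[Volume3D],
    annotations: list[CenterAnnotation],
    cfg: PipelineConfig,
    seed: int = 0,
) -> LocalizerModel:
    """Train per-VB coarse + fine regression forests and the chain prior.

    Coarse training samples patches over the entire in-plane-downsampled
    volume; fine training restricts sampling to a box around the
    ground-truth center at full resolution.
    """
    from spinevb.volume_io import downsample_inplane

    rng = np.random.default_rng(seed)
    m = len(annotations[0])
    coarse_cfg = cfg.feature_cfg("coarse")
    fine_cfg = cfg.feature_cfg("fine")
    coarse_forests = []
    fine_forests = []

    coarse_vols = [downsample_inplane(v, cfg.downsample_factor) for v in volumes]
    ivs_coarse = [build_integral_volumes(v) for v in coarse_vols]
    ivs_fine = [build_integral_volumes(v) for v in volumes]

    for i in range(m):
        coarse_samples = []
        fine_samples = []
        for vol, cvol, ann, ivc, ivf in zip(
            volumes, coarse_vols, annotations, ivs_coarse, ivs_fine
        ):
            gt = ann.centers[i]
            coarse_samples.append(
                sample_localization_patches(
                    cvol, gt, cfg.n_train, region=None, cfg=coarse_cfg,
                    seed=int(rng.integers(0, 2**31 - 1)), iv=ivc,
                )
            )
            region = _region_around(vol, gt, cfg.train_region_halfwidth_mm)
            fine_samples.append(
                sample_localization_patches(
                    vol, gt, cfg.n_train, region=region, cfg=fine_cfg,
                    seed=int(rng.integers(0, 2**31 - 1)), iv=ivf,
                )
            )
        fc = ForestConfig(**{**cfg.forest.__dict__,
                             "seed": int(rng.integers(0, 2**31 - 1))})
        coarse_forests.append(train_center_regressor(coarse_samples, fc))
        fc = ForestConfig(**{**cfg.forest.__dict__,
                             "seed": int(rng.integers(0, 2**31 - 1))})
        fine_forests.append(train_center_regressor(fine_samples, fc))

    prior = learn_chain_prior(annotations)
    return LocalizerModel(
        coarse_forests=coarse_forests,
        fine_forests=fine_forests,
        prior=prior,
        coarse_cfg=coarse_cfg,
        fine_cfg=fine_cfg,
        agg=cfg.agg,
        vb_names=list(annotations[0].vb_names),
        n_test=cfg.n_test,
        k_candidates=cfg.k_candidates,
        downsample_factor=cfg.downsample_factor,
        fine_halfwidth_mm=cfg.fine_halfwidth_mm,
    )


def train_segmenter(
    volumes: list[Volume3D],
    masks: list[LabelVolume],
    annotations: list[CenterAnnotation],
    cfg: PipelineConfig,
    seed: int = 0,
) -> SegmenterModel:
    """Train per-VB spatial priors and classification forests."""
    rng = np.random.default_rng(seed)
    m = len(annotations[0])
    seg_cfg = cfg.feature_cfg("seg")
    ivs = [build_integral_volumes(v) for v in volumes]
    priors = []
    forests = []
    for i in range(m):
        vb = i + 1
        prior = learn_spatial_prior(masks, annotations, vb, cfg.roi)
        samples = []
        from spinevb.segmentation import ROI

        for vol, mask, ann, iv in zip(volumes, masks, annotations, ivs):
            roi = ROI(center=ann.centers[i], half_extent=prior.half_extent)
            samples.append(
                sample_segmentation_patches(
                    vol, mask, vb, roi, cfg.m_seg // len(volumes) or 1,
                    cfg=seg_cfg, seed=int(rng.integers(0, 2**31 - 1)), iv=iv,
                )
            )
        fc = ForestConfig(**{**cfg.seg_forest.__dict__,
                             "seed": int(rng.integers(0, 2**31 - 1))})
        forests.append(train_voxel_classifier(samples, fc))
        priors.append(prior)
    return SegmenterModel(
        priors=priors, forests=forests, feature_cfg=seg_cfg,
        roi_cfg=cfg.roi, vb_names=list(annotations[0].vb_names),
    )


def segment_all(
    vol: Volume3D, centers: CenterAnnotation, model: SegmenterModel
) -> LabelVolume:
    """Segment every VB around its detected center; labels 1..m."""
    iv = build_integral_volumes(vol)
    out = np.zeros(vol.shape, dtype=np.int32)
    for i in range(model.n_vbs):
        mask = segment_vb(
            vol, centers.centers[i], model.priors[i], model.forests[i],
            feature_cfg=model.feature_cfg, roi_cfg=model.roi_cfg, iv=iv,
        )
        out[mask] = i + 1
    return LabelVolume(out, vol.spacing, vol.slice_axis, vol.origin,
                       vb_names=list(model.vb_names))


def phantom_study_config() -> PipelineConfig:
    """Reduced-size pipeline settings for the phantom leave-one-out study.

    Forests of 10 trees with N = N' = 2000 localization patches and
    M = 3000 segmentation patches keep the six-fold study desk-scale.
    The refinement box half-width is set to half the phantom inter-body
    spacing (12 mm) so the "reduced small local region" of the fine step
    contains exactly one body — the repetitive pattern makes any larger
    box ambiguous again.  Patch sizes are scaled to the phantom geometry:
    the clinical-MR coarse patch would span most of the phantom's coarse
    grid, leaving no discrimination along the chain, so the coarse patch
    is sized to cover about two bodies instead.
    """
    return PipelineConfig(
        n_train=2000,
        n_test=2000,
        m_seg=3000,
        forest=ForestConfig(n_trees=10),
        seg_forest=ForestConfig(n_trees=10),
        fine_halfwidth_mm=12.0,
        train_region_halfwidth_mm=12.0,
    )


def run_phantom_loo(
    n_subjects: int = 6,
    seed: int = 7,
    phantom_cfg: PhantomConfig | None = None,
    pipeline_cfg: PipelineConfig | None = None,
) -> dict:
    """Leave-one-out localization + segmentation study on phantoms.

    Each subject is tested once with models trained on the remaining
    subjects.  Returns per-center localization errors (mm), summary MLD /
    SD / detection rates, per-VB 3D Dice / AAD / HSD and mid-sagittal
    Dice.
    """
    if phantom_cfg is None:
        phantom_cfg = PhantomConfig()
    if pipeline_cfg is None:
        pipeline_cfg = phantom_study_config()
    cohort = generate_cohort(phantom_cfg, n_subjects, seed)
    rng = np.random.default_rng(seed + 1)

    errors = []
    dice3d = []
    aad3d = []
    hsd3d = []
    dice2d = []
    per_fold = []
    for test_idx in range(n_subjects):
        train = [t for s, t in enumerate(cohort) if s != test_idx]
        vol_t, ann_t, mask_t = cohort[test_idx]
        vols = [t[0] for t in train]
        anns = [t[1] for t in train]
        masks = [t[2] for t in train]

        loc_model = train_localizer(
            vols, anns, pipeline_cfg, seed=int(rng.integers(0, 2**31 - 1))
        )
        seg_model = train_segmenter(
            vols, masks, anns, pipeline_cfg,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        detected = localize(
            vol_t, loc_model, seed=int(rng.integers(0, 2**31 - 1))
        )
        fold_errors = [
            localization_error(detected.centers[i], ann_t.centers[i])
            for i in range(len(ann_t))
        ]
        errors.extend(fold_errors)

        seg = segment_all(vol_t, detected, seg_model)
        fold_dice = []
        for i in range(len(ann_t)):
            auto = seg.data == i + 1
            gt = mask_t.data == i + 1
            d3 = dice(auto, gt)
            fold_dice.append(d3)
            dice3d.append(d3)
            if np.any(auto) and np.any(gt):
                aad, hsd = surface_distances(auto, gt, vol_t.spacing)
                aad3d.append(aad)
                hsd3d.append(hsd)
                mid = midsagittal_metrics(
                    auto, gt, vol_t.spacing, ann_t.centers[i],
                    sagittal_axis=vol_t.slice_axis,
                )
                dice2d.append(mid["dice_pct"])
        per_fold.append(
            {"mean_error_mm": float(np.mean(fold_errors)),
             "mean_dice_pct": float(np.mean(fold_dice))}
        )

    mld, sd = mld_sd(errors)
    return {
        "errors_mm": [float(e) for e in errors],
        "mld_mm": mld,
        "sd_mm": sd,
        "median_mm": float(np.median(errors)),
        "detection_rate_2mm_pct": detection_rate(errors, 2.0),
        "detection_rate_4mm_pct": detection_rate(errors, 4.0),
        "detection_rate_6mm_pct": detection_rate(errors, 6.0),
        "mean_dice_3d_pct": float(np.mean(dice3d)),
        "mean_aad_3d_mm": float(np.mean(aad3d)) if aad3d else float("nan"),
        "mean_hsd_3d_mm": float(np.mean(hsd3d)) if hsd3d else float("nan"),
        "mean_dice_midsagittal_pct": (
            float(np.mean(dice2d)) if dice2d else float("nan")
        ),
        "per_fold": per_fold,
        "n_centers": len(errors),
    }
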