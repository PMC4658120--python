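"""Per-VB segmentation inside an ROI: spatial prior + appearance fusion.

Around each detected center, a region of interest (ROI) is carved out and
every voxel receives a posterior foreground probability

    L(v) = alpha * P_s(v) + beta * L_a(v)

where ``P_s`` is a Parzen-window spatial prior (the Gaussian-smoothed
average of center-aligned training masks) and ``L_a`` is a
classification-forest appearance likelihood (the per-tree mean foreground
probability of the voxel's patch feature).  The prior doubles as a
pre-filter: appearance is only evaluated where ``P_s > 0.1``, and voxels
failing the pre-filter are hard-assigned background.  The binary mask is
``L >= 0.5`` restricted to its largest connected component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from spinevb.errors import (
    GridMismatchError,
    MissingDataError,
    ParameterError,
    SamplingError,
    TrainingError,
)
from spinevb.features import FeatureConfig, build_integral_volumes, patch_features
from spinevb.localization import ForestConfig
from spinevb.volume_io import CenterAnnotation, LabelVolume, Volume3D

__all__ = [
    "ROI",
    "ROIConfig",
    "SpatialPrior",
    "SegmentationSampleSet",
    "ClassificationForest",
    "PosteriorMap",
    "SegmenterModel",
    "learn_spatial_prior",
    "prior_on_roi",
    "sample_segmentation_patches",
    "train_voxel_classifier",
    "appearance_likelihood",
    "fuse_posterior",
    "binarize_posterior",
    "segment_vb",
]


@dataclass
class ROIConfig:
    """Segmentation-stage settings.

    The ROI half-extent is learned from the center-aligned training masks
    (their per-axis reach, dilated by ``dilate_frac``); ``bandwidth_vox``
    is the Parzen kernel width in ROI-grid voxels.  ``alpha``/``beta``
    weight prior and appearance in the fusion; ``prefilter`` is the P_s
    gate below which voxels are background by construction.
    """

    dilate_frac: float = 0.25
    bandwidth_vox: float = 2.0
    prefilter: float = 0.1
    alpha: float = 0.4
    beta: float = 0.6
    threshold: float = 0.5
    connectivity: int = 26
    patch_size: tuple[int, int, int] = (8, 8, 8)

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ParameterError("fusion weights must be non-negative")
        if self.connectivity not in (6, 26):
            raise ParameterError("connectivity must be 6 or 26")


@dataclass
class ROI:
    """A box around a detected center: center and half-extent in mm."""

    center: np.ndarray
    half_extent: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.half_extent = np.asarray(self.half_extent, dtype=float)
        if np.any(self.half_extent <= 0):
            raise ParameterError("ROI half-extent must be positive")

    def box(self, vol: Volume3D) -> tuple[np.ndarray, np.ndarray]:
        """Half-open voxel box on ``vol``'s grid, clipped to its bounds."""
        idx = vol.to_index(self.center)
        half = self.half_extent / vol.spacing
        lo = np.maximum(np.floor(idx - half).astype(int), 0)
        hi = np.minimum(np.ceil(idx + half).astype(int) + 1,
                        np.asarray(vol.shape))
        if np.any(hi <= lo):
            raise ParameterError("ROI box lies outside the volume")
        return lo, hi


@dataclass
class SpatialPrior:
    """Parzen-window foreground probability on a center-aligned ROI grid.

    ``data[i]`` is P_s at offset ``(i - center_index) * spacing`` mm from
    the VB center.
    """

    data: np.ndarray
    spacing: np.ndarray
    bandwidth: float
    half_extent: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.half_extent = np.asarray(self.half_extent, dtype=float)

    @property
    def center_index(self) -> np.ndarray:
        return (np.asarray(self.data.shape) - 1) // 2


@dataclass
class SegmentationSampleSet:
    """Balanced foreground/background patch features for one VB."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ParameterError("row counts disagree")
        present = np.unique(self.labels)
        if not (0 in present and 1 in present):
            raise ParameterError("both classes must be present")


class ClassificationForest:
    """Forest of Gini-split trees whose leaves store foreground fractions."""

    def __init__(self, estimator: RandomForestClassifier):
        self._estimator = estimator

    @property
    def n_trees(self) -> int:
        return len(self._estimator.estimators_)

    def predict_proba_per_tree(self, features: np.ndarray) -> np.ndarray:
        """Foreground probability from every tree: shape (T_s, n)."""
        features = np.asarray(features, dtype=np.float32)
        fg = int(np.flatnonzero(self._estimator.classes_ == 1)[0])
        return np.stack(
            [t.predict_proba(features)[:, fg] for t in self._estimator.estimators_]
        )

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Mean foreground probability over the T_s trees."""
        return self.predict_proba_per_tree(features).mean(axis=0)


@dataclass
class PosteriorMap:
    """Fused per-voxel foreground probability L(v) on an ROI box."""

    data: np.ndarray
    alpha: float = 0.4
    beta: float = 0.6
    prefilter: float = 0.1
    threshold: float = 0.5
    connectivity: int = 26
    box_lo: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=int))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.box_lo = np.asarray(self.box_lo, dtype=int)


# ---------------------------------------------------------------------------
# spatial prior


def _aligned_indicator(
    mask: LabelVolume, vb_index: int, center_mm, grid_shape, spacing
) -> np.ndarray:
    """Training mask resampled (nearest) into the center-aligned ROI frame."""
    center_idx = (np.asarray(grid_shape) - 1) // 2
    offsets = [
        (np.arange(n) - c) * s for n, c, s in zip(grid_shape, center_idx, spacing)
    ]
    og = np.meshgrid(*offsets, indexing="ij")
    coords = np.stack(
        [
            (np.asarray(center_mm)[a] + og[a].ravel() - mask.origin[a])
            / mask.spacing[a]
            for a in range(3)
        ]
    )
    indicator = (mask.data == vb_index).astype(float)
    return ndimage.map_coordinates(
        indicator, coords, order=0, mode="constant", cval=0.0
    ).reshape(grid_shape)


def learn_spatial_prior(
    masks: list[LabelVolume],
    centers: list[CenterAnnotation],
    vb_index: int,
    roi_cfg: ROIConfig | None = None,
) -> SpatialPrior:
    """Average the center-aligned training masks and smooth them.

    The ROI half-extent is the per-axis reach of the aligned masks
    dilated by ``roi_cfg.dilate_frac``; the prior is the Gaussian-smoothed
    (bandwidth in ROI voxels) mean of the aligned binary indicators,
    clamped to [0, 1].
    """
    if roi_cfg is None:
        roi_cfg = ROIConfig()
    usable = [
        (m, c) for m, c in zip(masks, centers) if np.any(m.data == vb_index)
    ]
    if not usable:
        raise MissingDataError(f"no training mask contains label {vb_index}")
    spacing = usable[0][0].spacing
    # per-axis reach of mask voxels from the center, over all trainers
    reach = np.zeros(3)
    for mask, ann in usable:
        idx = np.argwhere(mask.data == vb_index)
        pos = mask.physical(idx)
        center = np.asarray(ann.centers[vb_index - 1], dtype=float)
        reach = np.maximum(reach, np.abs(pos - center).max(axis=0))
    half_extent = reach * (1.0 + roi_cfg.dilate_frac) + spacing
    grid_shape = tuple(2 * np.ceil(half_extent / spacing).astype(int) + 1)

    acc = np.zeros(grid_shape)
    for mask, ann in usable:
        acc += _aligned_indicator(
            mask, vb_index, ann.centers[vb_index - 1], grid_shape, spacing
        )
    prior = acc / len(usable)
    if roi_cfg.bandwidth_vox > 0:
        prior = ndimage.gaussian_filter(prior, sigma=roi_cfg.bandwidth_vox)
    return SpatialPrior(
        data=np.clip(prior, 0.0, 1.0),
        spacing=spacing,
        bandwidth=roi_cfg.bandwidth_vox,
        half_extent=half_extent,
    )


def prior_on_roi(prior: SpatialPrior, vol: Volume3D, roi: ROI) -> np.ndarray:
    """Sample the aligned prior onto the ROI box of a target volume."""
    lo, hi = roi.box(vol)
    idx_grids = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)],
                            indexing="ij")
    coords = np.stack(
        [
            (vol.origin[a] + idx_grids[a].ravel() * vol.spacing[a]
             - roi.center[a]) / prior.spacing[a] + prior.center_index[a]
            for a in range(3)
        ]
    )
    return ndimage.map_coordinates(
        prior.data, coords, order=1, mode="constant", cval=0.0
    ).reshape(tuple(hi - lo))


# ---------------------------------------------------------------------------
# appearance likelihood


def sample_segmentation_patches(
    vol: Volume3D,
    mask: LabelVolume,
    vb_index: int,
    roi: ROI,
    m: int,
    cfg: FeatureConfig | None = None,
    seed: int = 0,
    iv=None,
) -> SegmentationSampleSet:
    """Sample ``m`` patches in the ROI, balanced 50/50 between classes.

    The label of a sample is the mask value at its patch center (1 when it
    carries ``vb_index``); features use the segmentation patch size.
    """
    if cfg is None:
        cfg = FeatureConfig(patch_size=(8, 8, 8), modality="mr")
    rng = np.random.default_rng(seed)
    lo, hi = roi.box(vol)
    size = np.asarray(cfg.patch_size, dtype=int)
    v_lo = np.maximum(lo, size // 2)
    v_hi = np.minimum(hi, np.asarray(vol.shape) - size + size // 2 + 1)
    if np.any(v_hi <= v_lo):
        raise SamplingError("ROI leaves no room for segmentation patches")
    sub = mask.data[v_lo[0]:v_hi[0], v_lo[1]:v_hi[1], v_lo[2]:v_hi[2]]
    fg = np.argwhere(sub == vb_index) + v_lo
    bg = np.argwhere(sub != vb_index) + v_lo
    if len(fg) == 0 or len(bg) == 0:
        raise SamplingError("ROI must contain both foreground and background")
    n_fg = m // 2
    n_bg = m - n_fg
    pick_fg = fg[rng.integers(0, len(fg), size=n_fg)]
    pick_bg = bg[rng.integers(0, len(bg), size=n_bg)]
    centers = np.concatenate([pick_fg, pick_bg])
    labels = np.concatenate([np.ones(n_fg, dtype=int), np.zeros(n_bg, dtype=int)])
    if iv is None:
        iv = build_integral_volumes(vol)
    feats = patch_features(iv, centers, cfg)
    return SegmentationSampleSet(features=feats, labels=labels)


def train_voxel_classifier(
    samples: list[SegmentationSampleSet] | SegmentationSampleSet,
    forest_cfg: ForestConfig | None = None,
) -> ClassificationForest:
    """Train the foreground/background classification forest."""
    if forest_cfg is None:
        forest_cfg = ForestConfig()
    if isinstance(samples, SegmentationSampleSet):
        samples = [samples]
    if not samples:
        raise TrainingError("empty training set")
    X = np.concatenate([s.features for s in samples]).astype(np.float32)
    y = np.concatenate([s.labels for s in samples])
    if len(np.unique(y)) < 2:
        raise TrainingError("both classes required to train the classifier")
    depth = forest_cfg.max_depth if forest_cfg.max_depth else None
    min_split = 2 if forest_cfg.max_depth else len(X) + 1
    est = RandomForestClassifier(
        n_estimators=forest_cfg.n_trees,
        criterion="gini",
        max_depth=depth,
        min_samples_split=min_split,
        min_samples_leaf=forest_cfg.min_leaf,
        max_features=forest_cfg.max_features,
        bootstrap=forest_cfg.bootstrap,
        random_state=forest_cfg.seed,
        n_jobs=1,
    )
    est.fit(X, y)
    return ClassificationForest(est)


def appearance_likelihood(
    forest: ClassificationForest,
    vol: Volume3D,
    roi: ROI,
    ps_map: np.ndarray,
    cfg: FeatureConfig | None = None,
    prefilter: float = 0.1,
    iv=None,
) -> np.ndarray:
    """Per-tree mean foreground probability where the prior passes the gate.

    ``L_a(v) = (1/T_s) sum_t p_t(l_v = 1 | f_v)`` for voxels with
    ``P_s(v) > prefilter``; all other voxels get ``L_a = 0`` and their
    features are never computed.  Patch centers near the volume border are
    shifted inward so the patch fits.
    """
    if cfg is None:
        cfg = FeatureConfig(patch_size=(8, 8, 8), modality="mr")
    lo, hi = roi.box(vol)
    if ps_map.shape != tuple(hi - lo):
        raise GridMismatchError(
            f"prior map shape {ps_map.shape} != ROI box shape {tuple(hi - lo)}"
        )
    out = np.zeros_like(ps_map)
    sel = np.argwhere(ps_map > prefilter)
    if len(sel) == 0:
        return out
    centers = sel + lo
    size = np.asarray(cfg.patch_size, dtype=int)
    centers = np.clip(
        centers, size // 2, np.asarray(vol.shape) - size + size // 2
    )
    if iv is None:
        iv = build_integral_volumes(vol)
    feats = patch_features(iv, centers, cfg)
    out[tuple(sel.T)] = forest.predict_proba(feats)
    return out


# ---------------------------------------------------------------------------
# fusion and binarization


def fuse_posterior(
    ps_map: np.ndarray,
    la_map: np.ndarray,
    alpha: float = 0.4,
    beta: float = 0.6,
    prefilter: float = 0.1,
    threshold: float = 0.5,
    connectivity: int = 26,
    box_lo=None,
) -> PosteriorMap:
    """Elementwise fusion ``L = alpha * P_s + beta * L_a``.

    Voxels failing the pre-filter (``P_s <= prefilter``) are hard-assigned
    L = 0: the prior acts as a gate, not merely a compute-saver.
    """
    ps_map = np.asarray(ps_map, dtype=float)
    la_map = np.asarray(la_map, dtype=float)
    if ps_map.shape != la_map.shape:
        raise GridMismatchError(
            f"prior shape {ps_map.shape} != likelihood shape {la_map.shape}"
        )
    if alpha < 0 or beta < 0:
        raise ParameterError("fusion weights must be non-negative")
    fused = alpha * ps_map + beta * la_map
    fused = np.where(ps_map > prefilter, fused, 0.0)
    return PosteriorMap(
        data=fused, alpha=alpha, beta=beta, prefilter=prefilter,
        threshold=threshold, connectivity=connectivity,
        box_lo=np.zeros(3, dtype=int) if box_lo is None else box_lo,
    )


def binarize_posterior(post_map: PosteriorMap) -> np.ndarray:
    """Threshold at ``L >= 0.5`` and keep the largest connected component.

    Connectivity is 26-neighborhood by default (6 available); an empty
    mask is a valid result.
    """
    binary = post_map.data >= post_map.threshold
    if not np.any(binary):
        return binary
    structure = ndimage.generate_binary_structure(
        3, 3 if post_map.connectivity == 26 else 1
    )
    labeled, n = ndimage.label(binary, structure=structure)
    if n <= 1:
        return binary
    sizes = ndimage.sum_labels(binary, labeled, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return labeled == keep


# ---------------------------------------------------------------------------
# end-to-end per-VB segmentation


@dataclass
class SegmenterModel:
    """Trained per-VB spatial priors and classification forests."""

    priors: list[SpatialPrior]
    forests: list[ClassificationForest]
    feature_cfg: FeatureConfig
    roi_cfg: ROIConfig = field(default_factory=ROIConfig)
    vb_names: list[str] = field(default_factory=list)

    @property
    def n_vbs(self) -> int:
        return len(self.priors)


def segment_vb(
    vol: Volume3D,
    center,
    prior: SpatialPrior,
    forest: ClassificationForest,
    feature_cfg: FeatureConfig | None = None,
    roi_cfg: ROIConfig | None = None,
    iv=None,
) -> np.ndarray:
    """Segment one VB around ``center``; returns a full-grid boolean mask."""
    if roi_cfg is None:
        roi_cfg = ROIConfig()
    if feature_cfg is None:
        feature_cfg = FeatureConfig(patch_size=roi_cfg.patch_size, modality="mr")
    roi = ROI(center=center, half_extent=prior.half_extent)
    lo, hi = roi.box(vol)
    ps = prior_on_roi(prior, vol, roi)
    la = appearance_likelihood(
        forest, vol, roi, ps, cfg=feature_cfg,
        prefilter=roi_cfg.prefilter, iv=iv,
    )
    post = fuse_posterior(
        ps, la, alpha=roi_cfg.alpha, beta=roi_cfg.beta,
        prefilter=roi_cfg.prefilter, threshold=roi_cfg.threshold,
        connectivity=roi_cfg.connectivity, box_lo=lo,
    )
    roi_mask = binarize_posterior(post)
    full = np.zeros(vol.shape, dtype=bool)
    full[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = roi_mask
    return full
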