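"""Vertebral-body center localization by regression-forest voting.

Per VB, a random-forest regressor maps the block feature of a randomly
sampled 3D patch to the displacement from the patch center to the VB
center.  At test time every tree of the forest casts one vote per sampled
patch; the votes are aggregated into a *response volume* — a per-voxel
vote density under an isotropic Gaussian kernel — either exactly
(the double-loop oracle) or with an improved fast Gauss transform (IFGT).
Because neighboring vertebrae look alike, per-VB response maxima are
ambiguous; the ordered centers are therefore decoded jointly as a Markov
chain whose transition densities are Gaussians over inter-center offsets
learned from training annotations, maximized by dynamic programming.
Detection runs coarse-to-fine: whole-image voting on an in-plane
downsampled volume, HMM decoding, then refinement at full resolution in a
small box around each coarse estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist
from scipy.special import gammaln
from scipy.stats import multivariate_normal
from sklearn.ensemble import RandomForestRegressor

from spinevb.errors import (
    DecodingError,
    InsufficientDataError,
    ParameterError,
    SamplingError,
    TrainingError,
)
from spinevb.features import FeatureConfig, build_integral_volumes, patch_features
from spinevb.volume_io import CenterAnnotation, Volume3D, downsample_inplane

__all__ = [
    "LocalizationSampleSet",
    "ForestConfig",
    "RegressionForest",
    "VoteSet",
    "GridSpec",
    "ResponseVolume",
    "AggregationConfig",
    "ChainPrior",
    "LocalizerModel",
    "sample_localization_patches",
    "train_center_regressor",
    "cast_votes",
    "aggregate_votes_exact",
    "aggregate_votes_ifgt",
    "learn_chain_prior",
    "decode_center_chain",
    "localize",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class LocalizationSampleSet:
    """Training patches for one VB: features, displacements and centers.

    ``displacements[i] = gt_center - physical(patch_centers[i])`` in mm.
    """

    features: np.ndarray
    displacements: np.ndarray
    patch_centers: np.ndarray

    def __post_init__(self) -> None:
        if not (
            len(self.features) == len(self.displacements) == len(self.patch_centers)
        ):
            raise ParameterError("sample set row counts disagree")
        if not np.all(np.isfinite(self.displacements)):
            raise ParameterError("displacements must be finite")


@dataclass
class ForestConfig:
    """Regression/classification forest hyperparameters.

    ``max_depth=0`` denotes a root-only tree (the forest then predicts the
    training-set mean).  ``max_features='sqrt'`` draws a random feature
    subset of size sqrt(d_f) at every split.
    """

    n_trees: int = 20
    max_depth: int = 12
    min_leaf: int = 5
    max_features: str | int | float = "sqrt"
    bootstrap: bool = True
    seed: int = 0


class RegressionForest:
    """Forest of axis-aligned regression trees predicting 3D displacements.

    Each leaf stores the mean displacement of its training samples (used
    for voting) and the per-axis variance of those displacements
    (diagnostic; the production kernel uses a constant width instead).
    Backed by :class:`sklearn.ensemble.RandomForestRegressor`.
    """

    def __init__(self, estimator: RandomForestRegressor,
                 leaf_variances: list[dict[int, np.ndarray]]):
        self._estimator = estimator
        self.leaf_variances = leaf_variances

    @property
    def n_trees(self) -> int:
        return len(self._estimator.estimators_)

    def predict_per_tree(self, features: np.ndarray) -> np.ndarray:
        """Displacement predicted by every tree: shape (T, n, 3)."""
        features = np.asarray(features, dtype=np.float32)
        return np.stack(
            [t.predict(features).reshape(len(features), 3)
             for t in self._estimator.estimators_]
        )

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Forest-mean displacement, shape (n, 3)."""
        return self.predict_per_tree(features).mean(axis=0)


@dataclass
class VoteSet:
    """Predicted center positions (mm) with per-vote weights."""

    votes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.votes = np.asarray(self.votes, dtype=float).reshape(-1, 3)
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if len(self.weights) != len(self.votes):
            raise ParameterError("one weight per vote required")
        if np.any(self.weights <= 0):
            raise ParameterError("vote weights must be positive")

    def __len__(self) -> int:
        return len(self.votes)


@dataclass
class GridSpec:
    """Geometry of a response grid: shape, spacing (mm) and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if any(s < 1 for s in self.shape):
            raise ParameterError("grid shape components must be >= 1")

    @classmethod
    def like(cls, vol: Volume3D) -> "GridSpec":
        return cls(vol.shape, vol.spacing.copy(), vol.origin.copy())


@dataclass
class ResponseVolume:
    """Per-voxel aggregated vote density G on a grid."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical(self, index) -> np.ndarray:
        return self.origin + np.asarray(index, dtype=float) * self.spacing


@dataclass
class AggregationConfig:
    """Gaussian-transform settings.

    ``h`` is the kernel width in voxel units of the aggregation grid;
    votes of weight 1 and a constant isotropic kernel stand in for
    per-vote covariances, which are not estimable from single tree
    predictions.  ``ifgt_epsilon`` bounds the
    relative error of the fast path against the exact transform at all
    grid voxels whose exact response exceeds 1e-6 of the maximum.
    ``ifgt_order``/``ifgt_clusters`` override the automatic choices; an
    explicit order forces the Taylor-expansion path with no far-field
    cutoff (diagnostic mode).
    """

    h: float = 1.5
    ifgt_epsilon: float = 1e-2
    ifgt_order: int | None = None
    ifgt_clusters: int | None = None

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ParameterError("kernel width h must be positive")
        if not 0 < self.ifgt_epsilon < 1:
            raise ParameterError("ifgt_epsilon must lie in (0, 1)")


@dataclass
class ChainPrior:
    """Gaussian model of the offset between each adjacent VB-center pair.

    ``means[i]`` and ``covs[i]`` describe ``c_{i+1} - c_i`` in mm; a
    variance floor on the diagonal keeps the densities non-singular on
    small training sets.
    """

    means: np.ndarray
    covs: np.ndarray
    variance_floor: float = 1.0

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float).reshape(-1, 3)
        self.covs = np.asarray(self.covs, dtype=float).reshape(-1, 3, 3)
        if len(self.means) != len(self.covs):
            raise ParameterError("one covariance per mean offset required")

    @property
    def n_pairs(self) -> int:
        return len(self.means)

    def transition_logpdf(self, pair: int, offsets: np.ndarray) -> np.ndarray:
        """Log density of candidate offsets (mm) for adjacent pair ``pair``."""
        return multivariate_normal.logpdf(
            np.asarray(offsets, dtype=float), mean=self.means[pair],
            cov=self.covs[pair],
        )


# ---------------------------------------------------------------------------
# patch sampling and forest training


def _valid_center_bounds(shape, patch_size) -> tuple[np.ndarray, np.ndarray]:
    """Half-open per-axis bounds of patch centers whose patch fits."""
    shape = np.asarray(shape, dtype=int)
    size = np.asarray(patch_size, dtype=int)
    lo = size // 2
    hi = shape - size + size // 2 + 1
    return lo, hi


def _sample_patch_centers(
    shape, patch_size, n: int, region, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = _valid_center_bounds(shape, patch_size)
    if region is not None:
        r_lo, r_hi = (np.asarray(b, dtype=int) for b in region)
        lo = np.maximum(lo, r_lo)
        hi = np.minimum(hi, r_hi)
    if np.any(hi <= lo):
        raise SamplingError(
            f"no valid patch centers: patch {tuple(patch_size)} in volume "
            f"{tuple(shape)} with region {region}"
        )
    return np.stack(
        [rng.integers(lo[a], hi[a], size=n) for a in range(3)], axis=1
    )


def sample_localization_patches(
    vol: Volume3D,
    gt_center,
    n: int,
    region=None,
    cfg: FeatureConfig | None = None,
    seed: int = 0,
    iv=None,
) -> LocalizationSampleSet:
    """Sample ``n`` training patches and their displacements to ``gt_center``.

    Patch centers are drawn uniformly at random within ``region`` (a
    half-open voxel box ``(lo, hi)``; ``None`` means the whole volume),
    clamped to positions where the patch fits.  A precomputed integral
    volume may be passed to amortize feature extraction across VBs.
    """
    if cfg is None:
        raise ParameterError("a FeatureConfig is required")
    rng = np.random.default_rng(seed)
    centers = _sample_patch_centers(vol.shape, cfg.patch_size, n, region, rng)
    if iv is None:
        iv = build_integral_volumes(vol)
    feats = patch_features(iv, centers, cfg)
    displacements = np.asarray(gt_center, dtype=float)[None, :] - vol.physical(centers)
    return LocalizationSampleSet(feats, displacements, centers)


def train_center_regressor(
    samples: list[LocalizationSampleSet] | LocalizationSampleSet,
    forest_cfg: ForestConfig | None = None,
) -> RegressionForest:
    """Grow a displacement-regression forest on pooled training samples.

    Trees are grown on bootstrap resamples with variance-reduction splits
    over random feature subsets; training is deterministic given
    ``forest_cfg.seed``.
    """
    if forest_cfg is None:
        forest_cfg = ForestConfig()
    if isinstance(samples, LocalizationSampleSet):
        samples = [samples]
    if not samples or sum(len(s.features) for s in samples) == 0:
        raise TrainingError("empty training set")
    X = np.concatenate([s.features for s in samples]).astype(np.float32)
    y = np.concatenate([s.displacements for s in samples])
    if len(X) < forest_cfg.min_leaf:
        raise TrainingError(
            f"{len(X)} samples < min_leaf={forest_cfg.min_leaf}"
        )
    # max_depth=0 -> root-only trees (see ForestConfig)
    depth = forest_cfg.max_depth if forest_cfg.max_depth else None
    min_split = 2 if forest_cfg.max_depth else len(X) + 1
    est = RandomForestRegressor(
        n_estimators=forest_cfg.n_trees,
        max_depth=depth,
        min_samples_split=min_split,
        min_samples_leaf=forest_cfg.min_leaf,
        max_features=forest_cfg.max_features,
        bootstrap=forest_cfg.bootstrap,
        random_state=forest_cfg.seed,
        n_jobs=1,
    )
    est.fit(X, y)
    leaf_variances = []
    for tree in est.estimators_:
        leaves = tree.apply(X)
        stats: dict[int, np.ndarray] = {}
        for leaf in np.unique(leaves):
            stats[int(leaf)] = y[leaves == leaf].var(axis=0)
        leaf_variances.append(stats)
    return RegressionForest(est, leaf_variances)


def cast_votes(
    forest: RegressionForest,
    vol: Volume3D,
    n_test: int,
    region=None,
    cfg: FeatureConfig | None = None,
    seed: int = 0,
    iv=None,
    weight: float = 1.0,
) -> VoteSet:
    """Sample ``n_test`` patches and collect one vote per patch per tree.

    Each vote is ``physical(patch_center) + leaf-mean displacement``; the
    vote count is ``n_test * T``.
    """
    if cfg is None:
        raise ParameterError("a FeatureConfig is required")
    rng = np.random.default_rng(seed)
    centers = _sample_patch_centers(vol.shape, cfg.patch_size, n_test, region, rng)
    if iv is None:
        iv = build_integral_volumes(vol)
    feats = patch_features(iv, centers, cfg)
    per_tree = forest.predict_per_tree(feats)  # (T, n, 3)
    positions = vol.physical(centers)  # (n, 3)
    votes = (per_tree + positions[None, :, :]).reshape(-1, 3)
    return VoteSet(votes=votes, weights=np.full(len(votes), float(weight)))


# ---------------------------------------------------------------------------
# vote aggregation


def _grid_axes(grid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return tuple(np.arange(n, dtype=float) for n in grid.shape)


def _exact_transform(u: np.ndarray, w: np.ndarray, shape, h: float) -> np.ndarray:
    """Direct Gaussian transform on the integer grid lattice.

    The isotropic kernel factorizes over axes, so per-vote exponential
    tables are combined with an einsum instead of a 3D distance array.
    """
    gx, gy, gz = (np.arange(n, dtype=float) for n in shape)
    out = np.zeros(shape)
    h2 = h**2
    chunk = 128
    for s in range(0, len(u), chunk):
        uc = u[s : s + chunk]
        wc = w[s : s + chunk]
        ex = np.exp(-((gx[:, None] - uc[None, :, 0]) ** 2) / h2)
        ey = np.exp(-((gy[:, None] - uc[None, :, 1]) ** 2) / h2)
        ez = np.exp(-((gz[:, None] - uc[None, :, 2]) ** 2) / h2)
        out += np.einsum("ic,jc,kc,c->ijk", ex, ey, ez, wc, optimize=True)
    return out


def aggregate_votes_exact(
    votes: VoteSet, grid, agg: AggregationConfig | None = None
) -> ResponseVolume:
    """Exact Gaussian transform: ``G(y) = sum_j W_j exp(-|y - y_j|^2 / h^2)``.

    Distances are measured in voxel units of the aggregation grid.  This
    direct summation over all grid voxels and votes is the oracle the
    IFGT path is held to.
    """
    if agg is None:
        agg = AggregationConfig()
    u = (votes.votes - grid.origin[None, :]) / grid.spacing[None, :]
    out = _exact_transform(u, votes.weights, grid.shape, agg.h)
    return ResponseVolume(out, grid.spacing.copy(), grid.origin.copy())


def _farthest_point_clusters(
    pts: np.ndarray, max_clusters: int, target_radius: float | None
):
    """Gonzalez farthest-point clustering.

    Grows centers until the covering radius drops below ``target_radius``
    or ``max_clusters`` is reached (always exactly ``max_clusters`` when
    ``target_radius`` is None).  Returns (center_coords, assignment).
    """
    n = len(pts)
    max_clusters = min(max_clusters, n)
    center_ids = [0]
    diff = pts - pts[0]
    d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    assign = np.zeros(n, dtype=int)
    while len(center_ids) < max_clusters and (
        target_radius is None or d.max() > target_radius
    ):
        i = int(np.argmax(d))
        center_ids.append(i)
        diff = pts - pts[i]
        nd = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        closer = nd < d
        d = np.where(closer, nd, d)
        assign[closer] = len(center_ids) - 1
    return pts[center_ids], assign


def _multi_indices(order: int) -> np.ndarray:
    """All 3D multi-indices of total degree <= order."""
    out = [
        (a, b, c)
        for total in range(order + 1)
        for a in range(total + 1)
        for b in range(total - a + 1)
        for c in (total - a - b,)
    ]
    return np.asarray(out, dtype=int)


def _n_terms(order: int) -> int:
    return (order + 1) * (order + 2) * (order + 3) // 6


def _truncation_order(u_max: float, rel_target: float, p_cap: int = 70) -> int | None:
    """Smallest order whose Taylor tail bound meets ``rel_target``.

    The tail of ``exp(u)`` truncated after total degree ``p`` is bounded by
    ``u^{p+1}/(p+1)! * 1/(1 - u/(p+2))`` for ``p + 2 > u``.
    """
    if u_max <= 0:
        return 0
    log_target = math.log(rel_target)
    for p in range(p_cap + 1):
        if p + 2 <= u_max:
            continue
        log_tail = (
            (p + 1) * math.log(u_max)
            - gammaln(p + 2)
            - math.log1p(-u_max / (p + 2))
        )
        if log_tail <= log_target:
            return p
    return None


def _monomials(scaled: np.ndarray, alphas: np.ndarray, order: int) -> np.ndarray:
    """(n, n_terms) monomial matrix of scaled coordinates."""
    powers = [
        np.power(scaled[:, a : a + 1], np.arange(order + 1)[None, :])
        for a in range(3)
    ]
    return (
        powers[0][:, alphas[:, 0]]
        * powers[1][:, alphas[:, 1]]
        * powers[2][:, alphas[:, 2]]
    )


def aggregate_votes_ifgt(
    votes: VoteSet, grid, agg: AggregationConfig | None = None
) -> ResponseVolume:
    """Improved fast Gauss transform approximation of the exact response.

    Votes are grouped by farthest-point clustering; each cluster's
    contribution is either expanded in a truncated multivariate Taylor
    series about its center or, when the cluster holds fewer sources than
    the expansion has terms, summed directly (exactly) — the standard
    auto-selection of IFGT implementations.  Clusters whose worst-case
    contribution at a target falls below the relative-error budget
    (``ifgt_epsilon`` of 1e-6 times the response maximum) are skipped
    there, which is what reduces the cost from O(M * N) to about O(M + N).
    """
    if agg is None:
        agg = AggregationConfig()
    u = (votes.votes - grid.origin[None, :]) / grid.spacing[None, :]
    w = votes.weights
    h = agg.h
    out = np.zeros(grid.shape)
    if len(u) == 0:
        return ResponseVolume(out, grid.spacing.copy(), grid.origin.copy())

    forced_order = agg.ifgt_order
    shape_arr = np.asarray(grid.shape)

    if forced_order is None:
        # cull votes whose whole possible contribution to the grid is below
        # the error budget (crude weight-based floor keeps this conservative)
        margin = h * math.sqrt(
            max(math.log(2.0 * w.sum() / (agg.ifgt_epsilon * 1e-6 * w.max())), 1.0)
        )
        d_out = np.linalg.norm(
            np.maximum(np.maximum(-u, u - (shape_arr - 1)[None, :]), 0.0), axis=1
        )
        keep = d_out <= margin
        u, w = u[keep], w[keep]
        if len(u) == 0:
            return ResponseVolume(out, grid.spacing.copy(), grid.origin.copy())

    n = len(u)
    if agg.ifgt_clusters is not None:
        centers, assign = _farthest_point_clusters(u, agg.ifgt_clusters, None)
    else:
        centers, assign = _farthest_point_clusters(u, min(n, 256), h)
        radii = np.zeros(len(centers))
        diff = u - centers[assign]
        d_own = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        np.maximum.at(radii, assign, d_own)
        if radii.max() > 2.0 * h:
            # sources too spread for clustering to pay off: the direct
            # separable transform is cheaper and exact (figtree-style
            # auto-selection)
            out = _exact_transform(u, w, grid.shape, h)
            return ResponseVolume(out, grid.spacing.copy(), grid.origin.copy())
    n_clusters = len(centers)

    # conservative lower bound on the response maximum, for the error floor
    d2_cc = cdist(centers, u, metric="sqeuclidean")
    g_at_centers = np.exp(-d2_cc / h**2) @ w
    g_max_lb = max(float(g_at_centers.max()), float(w.max()))
    budget = agg.ifgt_epsilon * 1e-6 * g_max_lb  # absolute error allowance

    shape = np.asarray(grid.shape)
    axes = _grid_axes(grid)

    for c in range(n_clusters):
        members = assign == c
        uc = u[members]
        wc = w[members]
        q_c = float(wc.sum())
        diff = uc - centers[c]
        dists = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        r_c = float(dists.max()) if len(dists) else 0.0

        if forced_order is None:
            share = budget / (2.0 * n_clusters)
            if q_c <= share:
                continue
            d_cut = r_c + h * math.sqrt(math.log(q_c / share))
            lo = np.maximum(np.ceil(centers[c] - d_cut).astype(int), 0)
            hi = np.minimum(np.floor(centers[c] + d_cut).astype(int), shape - 1)
            if np.any(hi < lo):
                continue
        else:
            lo = np.zeros(3, dtype=int)
            hi = shape - 1
            d_cut = float(np.linalg.norm(np.maximum(np.abs(centers[c] - lo),
                                                    np.abs(hi - centers[c]))))

        sub_axes = [axes[a][lo[a] : hi[a] + 1] for a in range(3)]
        tg = np.meshgrid(*sub_axes, indexing="ij")
        targets = np.stack([g.ravel() for g in tg], axis=1)
        dt = targets - centers[c][None, :]
        dist_t = np.linalg.norm(dt, axis=1)
        if forced_order is None:
            in_range = dist_t <= d_cut
            if not np.any(in_range):
                continue
            targets, dt, dist_t = targets[in_range], dt[in_range], dist_t[in_range]
        else:
            in_range = np.ones(len(targets), dtype=bool)

        order = forced_order
        if order is None:
            u_max = 2.0 * (d_cut / h) * (r_c / h)
            share_rel = budget / (2.0 * n_clusters * q_c)
            order = _truncation_order(u_max, share_rel)
            use_direct = order is None or len(uc) <= _n_terms(order)
        else:
            use_direct = False

        if use_direct:
            vals = np.zeros(len(targets))
            chunk = max(1, int(4e6) // max(len(uc), 1))
            for s in range(0, len(targets), chunk):
                d2 = cdist(targets[s : s + chunk], uc, metric="sqeuclidean")
                vals[s : s + chunk] = np.exp(-d2 / h**2) @ wc
        else:
            alphas = _multi_indices(order)
            ds = (uc - centers[c][None, :]) / h
            prefac = wc * np.exp(-(ds**2).sum(axis=1))
            mon_s = _monomials(ds, alphas, order)
            two_pow = 2.0 ** alphas.sum(axis=1)
            inv_fact = np.exp(-(gammaln(alphas + 1).sum(axis=1)))
            coeff = two_pow * inv_fact * (prefac[:, None] * mon_s).sum(axis=0)
            dts = dt / h
            e_t = np.exp(-(dts**2).sum(axis=1))
            vals = np.zeros(len(targets))
            chunk = max(1, int(8e6) // max(len(alphas), 1))
            for s in range(0, len(targets), chunk):
                mon_t = _monomials(dts[s : s + chunk], alphas, order)
                vals[s : s + chunk] = e_t[s : s + chunk] * (mon_t @ coeff)

        block = out[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
        flat = block.ravel()
        idx = np.flatnonzero(in_range)
        flat[idx] += vals
        block[...] = flat.reshape(block.shape)

    return ResponseVolume(out, grid.spacing.copy(), grid.origin.copy())


# ---------------------------------------------------------------------------
# chain prior and decoding


def learn_chain_prior(
    annotations: list[CenterAnnotation], variance_floor: float = 1.0
) -> ChainPrior:
    """Gaussian inter-center offset model from >= 2 training annotations.

    For each adjacent pair, the mean and (unbiased) sample covariance of
    ``c_{i+1} - c_i`` across subjects; diagonal entries are floored at
    ``variance_floor`` mm^2 and the result nudged to positive definite if
    flooring left it singular.
    """
    if len(annotations) < 2:
        raise InsufficientDataError("need >= 2 annotations to learn the chain prior")
    m = len(annotations[0])
    if any(len(a) != m for a in annotations):
        raise ParameterError("annotations disagree on the number of VBs")
    if m < 2:
        return ChainPrior(np.zeros((0, 3)), np.zeros((0, 3, 3)), variance_floor)
    offsets = np.stack([np.diff(a.centers, axis=0) for a in annotations])  # (S, m-1, 3)
    means = offsets.mean(axis=0)
    covs = np.empty((m - 1, 3, 3))
    for i in range(m - 1):
        cov = np.cov(offsets[:, i, :].T, ddof=1)
        cov = np.atleast_2d(cov)
        diag_boost = np.maximum(variance_floor - np.diag(cov), 0.0)
        cov = cov + np.diag(diag_boost)
        # guarantee strict positive definiteness after flooring: the
        # sample covariance of few subjects is rank-deficient, so clamp
        # eigenvalues at a small fraction of the floor
        eigval, eigvec = np.linalg.eigh(cov)
        eigval = np.maximum(eigval, 1e-3 * variance_floor)
        covs[i] = (eigvec * eigval) @ eigvec.T
    return ChainPrior(means, covs, variance_floor)


def _response_candidates(resp: ResponseVolume, k: int):
    """Top-k local maxima (3^3 neighborhood) of a response volume.

    Flat plateaus count as maxima; ties are broken toward the lower flat
    index so candidate order is deterministic.
    """
    data = resp.data
    local_max = ndimage.maximum_filter(data, size=3, mode="constant", cval=-np.inf)
    peaks = np.flatnonzero((data == local_max).ravel())
    if peaks.size == 0:
        raise DecodingError("response volume has no local maxima")
    values = data.ravel()[peaks]
    order = np.lexsort((peaks, -values))[:k]
    chosen = peaks[order]
    coords = np.stack(np.unravel_index(chosen, data.shape), axis=1)
    return coords, data.ravel()[chosen]


def decode_center_chain(
    responses: list[ResponseVolume],
    prior: ChainPrior,
    k_candidates: int = 50,
    vb_names: list[str] | None = None,
) -> CenterAnnotation:
    """Viterbi decoding of the VB-center chain.

    Per VB the top-``k_candidates`` response local maxima form the state
    set; observation scores are the response values normalized to unit sum
    over the candidates, transitions are the chain prior's Gaussian offset
    densities, and the maximum-joint-probability chain is found by dynamic
    programming in the log domain.
    """
    m = len(responses)
    if m == 0:
        raise DecodingError("no response volumes given")
    if prior.n_pairs != m - 1:
        raise ParameterError(
            f"prior has {prior.n_pairs} pair models for {m} response volumes"
        )
    if k_candidates < 1:
        raise DecodingError("k_candidates must be >= 1")

    positions = []  # per VB: (k_i, 3) physical coords
    log_obs = []
    for resp in responses:
        coords, values = _response_candidates(resp, k_candidates)
        pos = resp.origin[None, :] + coords * resp.spacing[None, :]
        total = values.sum()
        probs = values / total if total > 0 else np.full(len(values), 1.0 / len(values))
        with np.errstate(divide="ignore"):
            lo = np.log(probs)
        positions.append(pos)
        log_obs.append(np.maximum(lo, -1e12))

    score = log_obs[0]
    back: list[np.ndarray] = []
    for i in range(1, m):
        deltas = positions[i][None, :, :] - positions[i - 1][:, None, :]
        k_prev, k_cur = deltas.shape[:2]
        trans = prior.transition_logpdf(
            i - 1, deltas.reshape(-1, 3)
        ).reshape(k_prev, k_cur)
        cand = score[:, None] + trans
        best_prev = np.argmax(cand, axis=0)
        back.append(best_prev)
        score = cand[best_prev, np.arange(k_cur)] + log_obs[i]

    chain = [int(np.argmax(score))]
    for bp in reversed(back):
        chain.append(int(bp[chain[-1]]))
    chain.reverse()

    centers = np.stack([positions[i][chain[i]] for i in range(m)])
    if vb_names is None:
        vb_names = [f"VB{i}" for i in range(1, m + 1)]
    return CenterAnnotation(centers=centers, vb_names=vb_names)


# ---------------------------------------------------------------------------
# end-to-end localization


@dataclass
class LocalizerModel:
    """Trained per-VB coarse and fine regressors plus the chain prior."""

    coarse_forests: list[RegressionForest]
    fine_forests: list[RegressionForest]
    prior: ChainPrior
    coarse_cfg: FeatureConfig
    fine_cfg: FeatureConfig
    agg: AggregationConfig = field(default_factory=AggregationConfig)
    vb_names: list[str] = field(default_factory=list)
    n_test: int = 10000
    k_candidates: int = 50
    downsample_factor: int = 4
    fine_halfwidth_mm: float = 30.0

    @property
    def n_vbs(self) -> int:
        return len(self.coarse_forests)


def _mm_box(vol: Volume3D, center_mm, halfwidth_mm: float):
    """Half-open voxel box of a +-halfwidth_mm cube around a point."""
    idx = vol.to_index(center_mm)
    half = halfwidth_mm / vol.spacing
    lo = np.maximum(np.floor(idx - half).astype(int), 0)
    hi = np.minimum(np.ceil(idx + half).astype(int) + 1, np.asarray(vol.shape))
    return lo, hi


def localize(
    vol: Volume3D,
    model: LocalizerModel,
    seed: int = 0,
    return_coarse: bool = False,
):
    """Detect all VB centers with the two-step coarse-to-fine strategy.

    Coarse step: voting over the whole in-plane-downsampled volume,
    followed by HMM chain decoding.  Fine step: voting at the original
    resolution restricted to a small box around each coarse estimate; the
    final center is the argmax of the fine response.
    """
    rng = np.random.default_rng(seed)
    coarse_vol = downsample_inplane(vol, model.downsample_factor)
    iv_coarse = build_integral_volumes(coarse_vol)
    responses = []
    for i in range(model.n_vbs):
        vs = cast_votes(
            model.coarse_forests[i], coarse_vol, model.n_test,
            region=None, cfg=model.coarse_cfg,
            seed=int(rng.integers(0, 2**31 - 1)), iv=iv_coarse,
        )
        responses.append(
            aggregate_votes_ifgt(vs, GridSpec.like(coarse_vol), model.agg)
        )
    names = model.vb_names or None
    coarse_ann = decode_center_chain(
        responses, model.prior, model.k_candidates, vb_names=names
    )

    iv_fine = build_integral_volumes(vol)
    fine_centers = np.empty((model.n_vbs, 3))
    size = np.asarray(model.fine_cfg.patch_size, dtype=int)
    v_lo, v_hi = _valid_center_bounds(vol.shape, size)
    for i in range(model.n_vbs):
        lo, hi = _mm_box(vol, coarse_ann.centers[i], model.fine_halfwidth_mm)
        # keep the refinement box inside the band where fine patches fit
        lo = np.clip(lo, v_lo, np.maximum(v_hi - 1, v_lo))
        hi = np.clip(hi, lo + 1, v_hi)
        vs = cast_votes(
            model.fine_forests[i], vol, model.n_test, region=(lo, hi),
            cfg=model.fine_cfg, seed=int(rng.integers(0, 2**31 - 1)),
            iv=iv_fine,
        )
        sub = GridSpec(
            tuple(hi - lo), vol.spacing.copy(), vol.physical(lo)
        )
        resp = aggregate_votes_ifgt(vs, sub, model.agg)
        peak = np.unravel_index(int(np.argmax(resp.data)), resp.data.shape)
        fine_centers[i] = resp.physical(peak)

    fine_ann = CenterAnnotation(
        centers=fine_centers, vb_names=list(coarse_ann.vb_names)
    )
    if return_coarse:
        return fine_ann, coarse_ann
    return fine_ann


def save_model(model, path) -> None:
    """Serialize a trained model with a format-version tag."""
    joblib.dump({"format_version": 1, "model": model}, path)


def load_model(path):
    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ParameterError(f"unsupported model file version in {path}")
    return payload["model"]
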