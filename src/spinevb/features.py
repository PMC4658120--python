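"""Integral-image machinery and the block mean/variance visual feature.

A sampled 3D patch is evenly divided into ``k x k x k`` blocks; the block
mean intensities (and, for CT, additionally the block variances) form the
feature vector.  Normalizing the vector to unit L1 norm makes it depend
only on relative intensity differences between blocks, so the feature is
insensitive to global or slowly-varying intensity shifts — the reason no
inter-scan intensity standardization or bias-field correction is needed.

Block statistics come from summed-area tables (integral volumes) of the
intensity and the squared intensity: any axis-aligned box sum is an
8-corner lookup, so the cost of one feature is ``k^3`` box queries
regardless of the patch size in voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from spinevb.errors import BoundsError, ParameterError
from spinevb.volume_io import Volume3D

__all__ = [
    "IntegralVolumes",
    "FeatureConfig",
    "build_integral_volumes",
    "block_stats",
    "patch_feature",
    "patch_features",
    "block_edges",
]


@dataclass
class IntegralVolumes:
    """Cumulative-sum arrays of intensity (I) and squared intensity (S).

    Both arrays carry a zero-valued leading plane along every axis so the
    8-corner box-sum formula needs no boundary special-casing: the sum of
    the inclusive voxel box ``[lo, hi]`` is an alternating-sign sum over
    the corners of ``I[lo .. hi+1]``.
    """

    I: np.ndarray
    S: np.ndarray
    shape: tuple[int, int, int]
    spacing: np.ndarray

    def box_sums(self, lo, hi) -> tuple[float, float]:
        """Sum of intensity and of squared intensity over the inclusive box.

        ``lo`` and ``hi`` are 3-vectors of voxel indices with
        ``lo <= hi`` componentwise.
        """
        lo = np.asarray(lo, dtype=int)
        hi = np.asarray(hi, dtype=int)
        if np.any(lo < 0) or np.any(hi >= np.asarray(self.shape)) or np.any(lo > hi):
            raise BoundsError(f"box [{lo}, {hi}] outside volume of shape {self.shape}")
        s_i = 0.0
        s_s = 0.0
        # 8-corner inclusion-exclusion on the zero-padded cumulative sums
        for cx, sx in ((hi[0] + 1, 1), (lo[0], -1)):
            for cy, sy in ((hi[1] + 1, 1), (lo[1], -1)):
                for cz, sz in ((hi[2] + 1, 1), (lo[2], -1)):
                    sign = sx * sy * sz
                    s_i += sign * self.I[cx, cy, cz]
                    s_s += sign * self.S[cx, cy, cz]
        return float(s_i), float(s_s)


@dataclass
class FeatureConfig:
    """Geometry of the block feature.

    ``k`` blocks per axis (default 4) over a patch of ``patch_size``
    voxels; the feature dimension is ``k**3`` for MR and ``2 * k**3`` for
    CT (means plus variances).
    """

    patch_size: tuple[int, int, int]
    modality: str = "mr"
    k: int = 4

    def __post_init__(self) -> None:
        self.patch_size = tuple(int(p) for p in self.patch_size)
        self.modality = self.modality.lower()
        if self.modality not in ("mr", "ct"):
            raise ParameterError(f"modality must be 'mr' or 'ct', got {self.modality!r}")
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if any(p < self.k for p in self.patch_size):
            raise ParameterError(
                f"each patch dimension must be >= k={self.k}, got {self.patch_size}"
            )

    @property
    def d_f(self) -> int:
        """Feature dimension: k^3 block means, doubled for CT variances."""
        base = self.k**3
        return 2 * base if self.modality == "ct" else base


def build_integral_volumes(vol: Volume3D | np.ndarray) -> IntegralVolumes:
    """Build summed-area tables of intensity and squared intensity."""
    if isinstance(vol, Volume3D):
        data, spacing = vol.data, vol.spacing
    else:
        data, spacing = np.asarray(vol), np.ones(3)
    data = data.astype(np.float64)
    shape = data.shape
    I = np.zeros(tuple(s + 1 for s in shape))
    S = np.zeros_like(I)
    I[1:, 1:, 1:] = data.cumsum(0).cumsum(1).cumsum(2)
    S[1:, 1:, 1:] = (data**2).cumsum(0).cumsum(1).cumsum(2)
    return IntegralVolumes(I=I, S=S, shape=shape, spacing=np.asarray(spacing))


def block_stats(iv: IntegralVolumes, lo, hi) -> tuple[float, float]:
    """Mean and variance of the intensities in the inclusive box [lo, hi].

    ``mean = box_sum(I) / N_v``, ``E[X^2] = box_sum(S) / N_v``,
    ``variance = E[X^2] - mean^2`` clamped at zero against floating-point
    cancellation.
    """
    lo = np.asarray(lo, dtype=int)
    hi = np.asarray(hi, dtype=int)
    s_i, s_s = iv.box_sums(lo, hi)
    n_v = int(np.prod(hi - lo + 1))
    mean = s_i / n_v
    var = max(s_s / n_v - mean * mean, 0.0)
    return mean, var


def block_edges(length: int, k: int) -> np.ndarray:
    """Split ``length`` voxels into ``k`` contiguous blocks.

    Returns the ``k + 1`` boundary offsets.  When ``length % k != 0`` the
    remainder goes to the last blocks, so edge lengths differ by at most
    one voxel and the partition is deterministic.
    """
    base, rem = divmod(length, k)
    sizes = np.full(k, base, dtype=int)
    if rem:
        sizes[-rem:] += 1
    return np.concatenate(([0], np.cumsum(sizes)))


def _patch_lo(center: np.ndarray, patch_size: np.ndarray) -> np.ndarray:
    """Low corner of a patch of ``patch_size`` centered on ``center``.

    The patch covers voxels ``[c - P//2, c - P//2 + P)`` per axis.
    """
    return np.asarray(center, dtype=int) - np.asarray(patch_size, dtype=int) // 2


def _normalize_halves(means: np.ndarray, variances: np.ndarray | None):
    """L1-normalize the mean sub-vector; variances normalized separately.

    An all-zero patch yields the uniform mean vector (and zero variances)
    instead of a division by zero, keeping features finite.
    """
    k3 = means.shape[-1]
    m_norm = np.abs(means).sum(axis=-1, keepdims=True)
    uniform = np.full_like(means, 1.0 / k3)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(m_norm > 0, means / m_norm, uniform)
    if variances is None:
        return m
    v_norm = np.abs(variances).sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(v_norm > 0, variances / v_norm, np.zeros_like(variances))
    return np.concatenate([m, v], axis=-1)


def patch_feature(iv: IntegralVolumes, center, cfg: FeatureConfig) -> np.ndarray:
    """Block mean (+ CT variance) feature of one patch centered at ``center``.

    Blocks are enumerated x-fastest, then y, then z.  Exactly ``k^3`` box
    queries are issued, independent of the patch size.
    """
    center = np.asarray(center, dtype=int)
    size = np.asarray(cfg.patch_size, dtype=int)
    lo = _patch_lo(center, size)
    if np.any(lo < 0) or np.any(lo + size > np.asarray(iv.shape)):
        raise BoundsError(
            f"patch of size {tuple(size)} at center {tuple(center)} exceeds "
            f"volume of shape {iv.shape}"
        )
    k = cfg.k
    edges = [lo[a] + block_edges(size[a], k) for a in range(3)]
    means = np.empty(k**3)
    variances = np.empty(k**3)
    for bz in range(k):
        for by in range(k):
            for bx in range(k):
                b_lo = (edges[0][bx], edges[1][by], edges[2][bz])
                b_hi = (edges[0][bx + 1] - 1, edges[1][by + 1] - 1,
                        edges[2][bz + 1] - 1)
                m, v = block_stats(iv, b_lo, b_hi)
                i = bx + k * by + k * k * bz
                means[i] = m
                variances[i] = v
    return _normalize_halves(means, variances if cfg.modality == "ct" else None)


def patch_features(iv: IntegralVolumes, centers, cfg: FeatureConfig) -> np.ndarray:
    """Vectorized :func:`patch_feature` for an ``(n, 3)`` array of centers.

    Returns an ``(n, d_f)`` matrix.  The batch path gathers all 8 corner
    planes with one fancy-indexing pass per corner and is the production
    route for the tens of thousands of patches a forest consumes.
    """
    centers = np.asarray(centers, dtype=int).reshape(-1, 3)
    size = np.asarray(cfg.patch_size, dtype=int)
    lo = centers - size // 2
    if np.any(lo < 0) or np.any(lo + size > np.asarray(iv.shape)):
        raise BoundsError("one or more patches exceed the volume bounds")
    k = cfg.k
    rel = [block_edges(size[a], k) for a in range(3)]
    n = len(centers)

    def corner_index(axis: int, which: np.ndarray) -> np.ndarray:
        # (n, k) table of padded-cumsum indices along one axis
        return lo[:, axis : axis + 1] + which[None, :]

    lo_x, hi_x = corner_index(0, rel[0][:-1]), corner_index(0, rel[0][1:])
    lo_y, hi_y = corner_index(1, rel[1][:-1]), corner_index(1, rel[1][1:])
    lo_z, hi_z = corner_index(2, rel[2][:-1]), corner_index(2, rel[2][1:])

    def gather(arr: np.ndarray) -> np.ndarray:
        out = np.zeros((n, k, k, k))
        for cx, sx in ((hi_x, 1), (lo_x, -1)):
            for cy, sy in ((hi_y, 1), (lo_y, -1)):
                for cz, sz in ((hi_z, 1), (lo_z, -1)):
                    out += (sx * sy * sz) * arr[
                        cx[:, :, None, None], cy[:, None, :, None],
                        cz[:, None, None, :],
                    ]
        return out

    sums_i = gather(iv.I)
    n_v = (
        np.diff(rel[0])[:, None, None]
        * np.diff(rel[1])[None, :, None]
        * np.diff(rel[2])[None, None, :]
    )
    means = sums_i / n_v
    # x-fastest flattening: axes currently (n, x, y, z)
    means_flat = means.transpose(0, 3, 2, 1).reshape(n, k**3)
    if cfg.modality == "ct":
        sums_s = gather(iv.S)
        var = np.maximum(sums_s / n_v - means**2, 0.0)
        var_flat = var.transpose(0, 3, 2, 1).reshape(n, k**3)
        return _normalize_halves(means_flat, var_flat)
    return _normalize_halves(means_flat, None)
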