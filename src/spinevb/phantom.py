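"""Synthetic spine phantoms: a chain of bright ellipsoidal bodies.

The phantom emulates the one property of spinal images that drives the
design of the localization stage — a repetitive chain of similar-looking
bright bodies on a darker background — with full knowledge of the
ground-truth centers and masks.  Every other module is trainable and
testable on phantoms without downloading clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from spinevb.errors import ParameterError
from spinevb.volume_io import CenterAnnotation, LabelVolume, Volume3D

__all__ = ["PhantomConfig", "generate_spine_phantom", "generate_cohort"]


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic spine volume.

    Defaults mirror a reduced sagittal-MR convention: grid 40 x 128 x 128
    at (2, 1.25, 1.25) mm with the slice axis along x, five bodies chained
    along y, 24 mm apart, with per-body jitter of both offsets and radii.
    """

    n_vbs: int = 5
    body_radii: tuple[float, float, float] = (10.0, 8.5, 11.0)  # mm
    radius_jitter_frac: float = 0.08
    inter_body_offset: tuple[float, float, float] = (0.0, 24.0, 0.0)  # mm
    offset_jitter_mm: tuple[float, float, float] = (1.5, 2.0, 1.5)
    fg_intensity: float = 1.0
    bg_intensity: float = 0.2
    noise_sd: float = 0.08
    shape: tuple[int, int, int] = (40, 128, 128)
    spacing: tuple[float, float, float] = (2.0, 1.25, 1.25)  # mm
    slice_axis: int = 0
    modality: str = "mr"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vbs < 1:
            raise ParameterError("n_vbs must be >= 1")
        if any(r <= 0 for r in self.body_radii):
            raise ParameterError("body radii must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise SD must be >= 0")


def generate_spine_phantom(
    cfg: PhantomConfig,
) -> tuple[Volume3D, CenterAnnotation, LabelVolume]:
    """Generate one phantom volume with its centers and label mask.

    Bodies are ellipsoids placed along a chain of jittered inter-body
    offsets; the image is foreground/background intensity plus additive
    Gaussian noise.  The MR flavor adds texture: per-body intensity varies
    a few percent and the foreground carries extra speckle noise; the CT
    flavor keeps a flat foreground plateau.  (Low-frequency bias fields
    are deliberately not simulated.)  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = np.asarray(cfg.shape, dtype=int)
    spacing = np.asarray(cfg.spacing, dtype=float)
    extent = shape * spacing
    mean_offset = np.asarray(cfg.inter_body_offset, dtype=float)
    chain_span = mean_offset * (cfg.n_vbs - 1)

    start = extent / 2.0 - chain_span / 2.0
    radii_nominal = np.asarray(cfg.body_radii, dtype=float)
    margin = radii_nominal + 3.0 * np.asarray(cfg.offset_jitter_mm)
    if np.any(start - margin < 0) or np.any(start + chain_span + margin > extent):
        raise ParameterError(
            f"chain of {cfg.n_vbs} bodies does not fit the "
            f"{tuple(np.round(extent, 1))} mm grid"
        )

    centers = np.empty((cfg.n_vbs, 3))
    centers[0] = start + rng.normal(0.0, cfg.offset_jitter_mm)
    for i in range(1, cfg.n_vbs):
        centers[i] = centers[i - 1] + mean_offset + rng.normal(0.0, cfg.offset_jitter_mm)
    radii = radii_nominal * (
        1.0 + cfg.radius_jitter_frac * rng.standard_normal((cfg.n_vbs, 3))
    )
    radii = np.maximum(radii, 2.0 * spacing)

    grid = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    labels = np.zeros(tuple(shape), dtype=np.int32)
    for i in range(cfg.n_vbs):
        q = sum(((g - c) / r) ** 2 for g, c, r in zip(grid, centers[i], radii[i]))
        labels[q <= 1.0] = i + 1

    fg_levels = np.full(cfg.n_vbs, cfg.fg_intensity)
    if cfg.modality.lower() == "mr":
        # MR-like texture: bodies differ a few percent in brightness and
        # the foreground carries extra speckle on top of the global noise
        fg_levels = fg_levels * (1.0 + 0.04 * rng.standard_normal(cfg.n_vbs))
    image = np.full(tuple(shape), cfg.bg_intensity, dtype=float)
    for i in range(cfg.n_vbs):
        image[labels == i + 1] = fg_levels[i]
    if cfg.modality.lower() == "mr" and cfg.noise_sd > 0:
        speckle = rng.normal(0.0, 0.5 * cfg.noise_sd, size=image.shape)
        image = np.where(labels > 0, image + speckle, image)
    if cfg.noise_sd > 0:
        image = image + rng.normal(0.0, cfg.noise_sd, size=image.shape)

    vb_names = [f"VB{i}" for i in range(1, cfg.n_vbs + 1)]
    vol = Volume3D(image, spacing, cfg.slice_axis)
    mask = LabelVolume(labels, spacing, cfg.slice_axis, np.zeros(3), vb_names=vb_names)
    ann = CenterAnnotation(centers=centers, vb_names=vb_names)
    return vol, ann, mask


def generate_cohort(
    cfg: PhantomConfig, n_subjects: int, seed: int
) -> list[tuple[Volume3D, CenterAnnotation, LabelVolume]]:
    """Generate ``n_subjects`` phantoms with subject-level variation.

    Each subject receives its own seed (derived from ``seed``) plus a
    small subject-level perturbation of the mean inter-body offset and of
    the body radii, so chain-prior and spatial-prior learners see
    realistic between-subject variation on top of the within-subject
    jitter.
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n_subjects):
        subj_seed = int(rng.integers(0, 2**31 - 1))
        offset_shift = rng.normal(0.0, 0.5, 3) * np.asarray(cfg.offset_jitter_mm)
        radius_scale = 1.0 + 0.5 * cfg.radius_jitter_frac * rng.standard_normal()
        sub_cfg = replace(
            cfg,
            seed=subj_seed,
            inter_body_offset=tuple(
                np.asarray(cfg.inter_body_offset) + offset_shift
            ),
            body_radii=tuple(np.asarray(cfg.body_radii) * radius_scale),
        )
        cohort.append(generate_spine_phantom(sub_cfg))
    return cohort
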