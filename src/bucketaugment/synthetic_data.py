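"""Synthetic 3D phantoms with controllable domain shift.

The generator emulates, at toy scale, the cross-dataset variability of
abdominal CT: a large liver-like ellipsoid (class 1) and a pair of small
kidney-like ellipsoids (class 2) on a darker background, with per-domain
appearance knobs — additive intensity offset, gamma-style contrast,
Gaussian noise level and voxel spacing. Labels are produced by the same
geometric process in every domain, so shifting the appearance knobs is a
pure covariate shift: image statistics move, the labeling rule does not.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .transforms3d import VolumePatch

#: noise-free base intensities per class (background, large organ, small organs)
BASE_INTENSITIES = (0.2, 0.6, 0.85)


@dataclass(frozen=True)
class OrganGeometry:
    """Centers and semi-axes (in voxels) of every generated ellipsoid."""

    centers: tuple[tuple[float, float, float], ...]
    semiaxes: tuple[tuple[float, float, float], ...]
    classes: tuple[int, ...]


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (32, 32, 32)
    n_large_organs: int = 1
    n_small_organs: int = 1  # kidney-like pairs
    intensity_offset: float = 0.0
    contrast_gamma: float = 1.0
    noise_sigma: float = 0.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ValueError(f"shape must be 3 ints >= 8, got {self.shape}")
        if self.n_large_organs < 0 or self.n_small_organs < 0:
            raise ValueError("organ counts must be non-negative")
        if self.contrast_gamma <= 0:
            raise ValueError("contrast_gamma must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for v in (self.intensity_offset, self.contrast_gamma, self.noise_sigma):
            if not np.isfinite(v):
                raise ValueError("phantom parameters must be finite")


@dataclass(frozen=True)
class DomainShift:
    """Additive deltas applied to a source PhantomConfig to define the
    target domain (appearance and spacing only, never anatomy)."""

    intensity_offset: float = 0.0
    contrast_gamma: float = 0.0
    noise_sigma: float = 0.0
    spacing_scale: float = 1.0

    def apply(self, config: PhantomConfig) -> PhantomConfig:
        return replace(
            config,
            intensity_offset=config.intensity_offset + self.intensity_offset,
            contrast_gamma=config.contrast_gamma + self.contrast_gamma,
            noise_sigma=config.noise_sigma + self.noise_sigma,
            spacing=tuple(s * self.spacing_scale for s in config.spacing),
        )


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                        indexing="ij")
    d = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return d <= 1.0


def _draw_geometry(config: PhantomConfig,
                   rng: np.random.Generator) -> OrganGeometry:
    shape = np.asarray(config.shape, dtype=np.float64)
    centers, semiaxes, classes = [], [], []

    for _ in range(config.n_large_organs):
        # liver-like: semi-axes around a quarter of each dimension
        ax = shape * rng.uniform(0.22, 0.30, size=3)
        lo, hi = ax + 1, shape - ax - 1
        if np.any(lo > hi):
            raise ValueError(f"large organ does not fit in shape {config.shape}")
        c = rng.uniform(lo, hi)
        centers.append(tuple(c))
        semiaxes.append(tuple(ax))
        classes.append(1)

    for _ in range(config.n_small_organs):
        # kidney-like pair: two small ellipsoids mirrored across the mid-plane
        ax = shape * rng.uniform(0.08, 0.12, size=3)
        # mirrored across the axis-0 mid-plane, so constrain axis 0 to one half
        lo = ax + 1
        hi = np.array([shape[0] / 2 - ax[0] - 1,
                       shape[1] - ax[1] - 1,
                       shape[2] - ax[2] - 1])
        if np.any(lo > hi):
            raise ValueError(f"small organ pair does not fit in shape {config.shape}")
        c = rng.uniform(lo, hi)
        for side in (c, np.array([shape[0] - c[0], c[1], c[2]])):
            centers.append(tuple(side))
            semiaxes.append(tuple(ax))
            classes.append(2)

    return OrganGeometry(tuple(centers), tuple(semiaxes), tuple(classes))


def make_phantom(config: PhantomConfig, return_geometry: bool = False):
    """Generate one phantom volume/label pair.

    The noise-free base image is piecewise constant (one intensity per
    class); the image is then shifted by ``intensity_offset``, passed
    through a gamma curve, corrupted with additive Gaussian noise, and
    clipped to [0, 1]. The label grid is noise-free. Deterministic under
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    geometry = _draw_geometry(config, rng)

    label = np.zeros(config.shape, dtype=np.int16)
    for center, ax, cls in zip(geometry.centers, geometry.semiaxes,
                               geometry.classes):
        # later (small) organs overwrite earlier ones where they overlap
        label[_ellipsoid_mask(config.shape, center, ax)] = cls

    image = np.take(np.asarray(BASE_INTENSITIES), label)
    image = np.clip(image + config.intensity_offset, 0.0, 1.0)
    image = np.power(image, config.contrast_gamma)
    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, size=config.shape)
    image = np.clip(image, 0.0, 1.0)

    patch = VolumePatch(image, label, config.spacing)
    if return_geometry:
        return patch, geometry
    return patch


def make_domain_pair(
    source_config: PhantomConfig,
    target_shift: DomainShift,
    n_source: int,
    n_target: int,
    seed: int,
) -> tuple[list[VolumePatch], list[VolumePatch]]:
    """Draw a source cohort and an appearance-shifted target cohort.

    Each volume gets its own geometry jitter via a per-volume seed; the
    label-generation process is identical across domains (covariate shift
    only).
    """
    if n_source < 1 or n_target < 1:
        raise ValueError("cohort sizes must be positive")
    rng = np.random.default_rng(seed)
    target_config = target_shift.apply(source_config)
    source = [
        make_phantom(replace(source_config, seed=int(rng.integers(2**31))))
        for _ in range(n_source)
    ]
    target = [
        make_phantom(replace(target_config, seed=int(rng.integers(2**31))))
        for _ in range(n_target)
    ]
    return source, target
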