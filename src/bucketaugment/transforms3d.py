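"""Ten 3D volumetric augmentation operations with discretized magnitudes.

Each operation has a predefined uniform magnitude range divided into 15
evenly spaced bins. Spatial operations (translation, rotation, zooming,
elastic deformation) warp image and label with the same geometric map —
linear interpolation for the image, nearest-neighbor for the label, so
that no new label ids can appear. Intensity-only operations modify the
image and leave the label untouched. Every operation is applied with
probability 1 and clips its output image to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

N_BINS = 15

#: magnitude ranges (min, max) per transform; identity has no magnitude
TRANSFORM_RANGES: dict[str, tuple[float, float]] = {
    "identity": (0.0, 0.0),
    "translation": (0.0, 10.0),
    "elastic_deformation": (50.0, 150.0),
    "zooming": (1.0, 2.0),
    "rotation": (0.0, 0.52),
    "intensity": (0.1, 1.0),
    "contrast": (1.0, 5.0),
    "sharpening": (10.0, 30.0),
    "smoothing": (0.1, 2.0),
    "gaussian_noise": (0.1, 0.3),
}

SPATIAL_TRANSFORMS = frozenset(
    {"translation", "rotation", "zooming", "elastic_deformation"}
)
TRANSFORM_NAMES: tuple[str, ...] = tuple(TRANSFORM_RANGES)

# elastic deformation: the magnitude is the amplitude of a random
# displacement field; the field is smoothed with a fixed Gaussian and the
# amplitude rescaled to voxels by ELASTIC_SCALE. Both knobs are module
# constants so they can be overridden for experimentation.
ELASTIC_FIELD_SIGMA = 8.0
ELASTIC_SCALE = 0.02
SHARPEN_BLUR_SIGMA = 1.0


@dataclass
class VolumePatch:
    """A 3D image in [0, 1] with an aligned integer label grid.

    Parameters
    ----------
    image : ndarray
        3D float array, values in [0, 1] (normalized intensity).
    label : ndarray
        3D integer array of class ids, same shape as ``image``.
    spacing : tuple of float
        Voxel size per axis in millimetres.
    """

    image: np.ndarray
    label: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        self.label = np.asarray(self.label)
        if not np.issubdtype(self.label.dtype, np.integer):
            raise TypeError("label grid must have an integer dtype")
        if self.image.ndim != 3:
            raise ValueError(f"image must be 3D, got {self.image.ndim}D")
        if self.image.shape != self.label.shape:
            raise ValueError(
                f"image shape {self.image.shape} != label shape {self.label.shape}"
            )
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        self.spacing = spacing

    def copy(self) -> "VolumePatch":
        return VolumePatch(self.image.copy(), self.label.copy(), self.spacing)


@dataclass(frozen=True)
class TransformSpec:
    """One augmentation operation: a name, a magnitude bin, and the
    resolved magnitude.

    ``params`` optionally pins per-application random draws (e.g. the
    translation axis and sign) so a saved policy replays exactly; when a
    key is absent the draw comes from the rng stream at application time.
    """

    name: str
    bin_index: int
    magnitude: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in TRANSFORM_RANGES:
            raise ValueError(
                f"unknown transform {self.name!r}; expected one of {TRANSFORM_NAMES}"
            )
        if not 0 <= self.bin_index < N_BINS:
            raise ValueError(f"bin_index must be in [0, {N_BINS - 1}], got {self.bin_index}")
        lo, hi = TRANSFORM_RANGES[self.name]
        if not lo <= self.magnitude <= hi:
            raise ValueError(
                f"magnitude {self.magnitude} outside [{lo}, {hi}] for {self.name!r}"
            )

    @property
    def kind(self) -> str:
        return "spatial" if self.name in SPATIAL_TRANSFORMS else "intensity_only"


def magnitude_bins(name: str) -> np.ndarray:
    """Return the 15 evenly spaced magnitudes for a transform.

    The first bin equals the range minimum, the last the maximum
    (step = (max - min) / 14). The identity has no magnitude and returns
    fifteen zeros.
    """
    if name not in TRANSFORM_RANGES:
        raise ValueError(
            f"unknown transform {name!r}; expected one of {TRANSFORM_NAMES}"
        )
    lo, hi = TRANSFORM_RANGES[name]
    return np.linspace(lo, hi, N_BINS)


def spec_from_bin(name: str, bin_index: int, params: dict | None = None) -> TransformSpec:
    """Build a TransformSpec with the magnitude resolved from its bin."""
    mag = float(magnitude_bins(name)[bin_index])
    return TransformSpec(name=name, bin_index=int(bin_index), magnitude=mag,
                         params=dict(params or {}))


# ---------------------------------------------------------------------------
# geometric primitives — image warped with linear interpolation, label with
# nearest neighbor, out-of-field filled with 0 / background


def _warp_pair(patch: VolumePatch, warp_image, warp_label) -> VolumePatch:
    image = np.clip(warp_image(patch.image), 0.0, 1.0)
    label = warp_label(patch.label)
    return VolumePatch(image, label.astype(patch.label.dtype), patch.spacing)


def translate(patch: VolumePatch, offset: np.ndarray) -> VolumePatch:
    return _warp_pair(
        patch,
        lambda im: ndimage.shift(im, offset, order=1, mode="constant", cval=0.0),
        lambda lb: ndimage.shift(lb, offset, order=0, mode="constant", cval=0),
    )


def rotate(patch: VolumePatch, angle_rad: float, axes: tuple[int, int]) -> VolumePatch:
    deg = float(np.degrees(angle_rad))
    return _warp_pair(
        patch,
        lambda im: ndimage.rotate(im, deg, axes=axes, reshape=False, order=1,
                                  mode="constant", cval=0.0),
        lambda lb: ndimage.rotate(lb, deg, axes=axes, reshape=False, order=0,
                                  mode="constant", cval=0),
    )


def _center_crop(arr: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    slices = []
    for big, small in zip(arr.shape, shape):
        start = (big - small) // 2
        slices.append(slice(start, start + small))
    return arr[tuple(slices)]


def zoom(patch: VolumePatch, factor: float) -> VolumePatch:
    """Isotropic magnification about the center, cropped back to shape."""
    shape = patch.image.shape

    def _zoom(arr, order):
        out = ndimage.zoom(arr, factor, order=order, mode="constant",
                           cval=0, grid_mode=False)
        # guard against rounding producing an output smaller than the input
        pad = [(0, max(0, s - o)) for s, o in zip(shape, out.shape)]
        if any(p[1] for p in pad):
            out = np.pad(out, pad, mode="constant")
        return _center_crop(out, shape)

    return _warp_pair(patch, lambda im: _zoom(im, 1), lambda lb: _zoom(lb, 0))


def elastic_deform(
    patch: VolumePatch,
    alpha: float,
    rng: np.random.Generator,
    field_sigma: float = ELASTIC_FIELD_SIGMA,
    scale: float = ELASTIC_SCALE,
) -> VolumePatch:
    """Warp by a smooth random displacement field of amplitude ``alpha``.

    Per axis the field is i.i.d. uniform noise in [-1, 1], smoothed by a
    Gaussian of ``field_sigma`` voxels and scaled to ``alpha * scale``
    voxels peak amplitude. ``alpha = 0`` is the identity.
    """
    shape = patch.image.shape
    coords = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                         indexing="ij")
    warped = []
    for c in coords:
        noise = rng.uniform(-1.0, 1.0, size=shape)
        disp = ndimage.gaussian_filter(noise, sigma=field_sigma) * alpha * scale
        warped.append(c + disp)
    warped = np.asarray(warped)
    return _warp_pair(
        patch,
        lambda im: ndimage.map_coordinates(im, warped, order=1,
                                           mode="constant", cval=0.0),
        lambda lb: ndimage.map_coordinates(lb, warped, order=0,
                                           mode="constant", cval=0),
    )


# ---------------------------------------------------------------------------
# intensity-only primitives — label left bit-identical


def _intensity_result(patch: VolumePatch, image: np.ndarray) -> VolumePatch:
    return VolumePatch(np.clip(image, 0.0, 1.0), patch.label.copy(), patch.spacing)


def scale_intensity(patch: VolumePatch, factor: float) -> VolumePatch:
    return _intensity_result(patch, patch.image * factor)


def adjust_contrast(patch: VolumePatch, gamma: float) -> VolumePatch:
    return _intensity_result(patch, np.power(patch.image, gamma))


def sharpen(patch: VolumePatch, magnitude: float,
            blur_sigma: float = SHARPEN_BLUR_SIGMA) -> VolumePatch:
    blurred = ndimage.gaussian_filter(patch.image, sigma=blur_sigma)
    amount = magnitude / 10.0
    return _intensity_result(patch, patch.image + amount * (patch.image - blurred))


def smooth(patch: VolumePatch, sigma: float) -> VolumePatch:
    return _intensity_result(patch, ndimage.gaussian_filter(patch.image, sigma=sigma))


def add_gaussian_noise(patch: VolumePatch, sigma: float,
                       rng: np.random.Generator) -> VolumePatch:
    noise = rng.normal(0.0, sigma, size=patch.image.shape)
    return _intensity_result(patch, patch.image + noise)


# ---------------------------------------------------------------------------


def apply_transform(patch: VolumePatch, spec: TransformSpec,
                    rng: np.random.Generator) -> VolumePatch:
    """Apply one augmentation to a patch, returning a new patch.

    The input is never mutated. Neutral magnitudes (identity, zoom 1,
    rotation 0, translation 0) reproduce the input bit-exactly.
    Per-application randomness (translation axis/sign, rotation plane,
    noise draws, displacement fields) comes from ``rng`` unless pinned in
    ``spec.params``.
    """
    lo, hi = TRANSFORM_RANGES[spec.name]
    if not lo <= spec.magnitude <= hi:
        raise ValueError(
            f"magnitude {spec.magnitude} outside [{lo}, {hi}] for {spec.name!r}"
        )
    m = spec.magnitude

    if spec.name == "identity":
        return patch.copy()
    if spec.name == "translation":
        axis = spec.params.get("axis")
        sign = spec.params.get("sign")
        if axis is None:
            axis = int(rng.integers(3))
        if sign is None:
            sign = int(rng.choice([-1, 1]))
        if m == 0.0:
            return patch.copy()
        offset = np.zeros(3)
        offset[axis] = sign * m
        return translate(patch, offset)
    if spec.name == "rotation":
        axes = spec.params.get("axes")
        if axes is None:
            axes = tuple(rng.choice(3, size=2, replace=False).tolist())
        if m == 0.0:
            return patch.copy()
        return rotate(patch, m, tuple(axes))
    if spec.name == "zooming":
        if m == 1.0:
            return patch.copy()
        return zoom(patch, m)
    if spec.name == "elastic_deformation":
        return elastic_deform(patch, m, rng)
    if spec.name == "intensity":
        return scale_intensity(patch, m)
    if spec.name == "contrast":
        return adjust_contrast(patch, m)
    if spec.name == "sharpening":
        return sharpen(patch, m)
    if spec.name == "smoothing":
        return smooth(patch, m)
    if spec.name == "gaussian_noise":
        return add_gaussian_noise(patch, m, rng)
    raise ValueError(f"unknown transform {spec.name!r}")  # pragma: no cover
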