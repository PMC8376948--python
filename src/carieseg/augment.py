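"""Training-time augmentation: joint image+mask passes and mask-only passes.

Two distinct passes are used during training.  The joint pass applies one
sampled geometric transform (flips, rotation, anisotropic width scaling,
isotropic zoom, elastic deformation) identically to a radiograph and all of
its masks, plus an intensity jitter on the image alone; it regularizes the
networks against acquisition variability.  The mask-only pass (random
dilation + elastic warp of the binary caries mask) emulates the boundary
inconsistency of human annotators without touching the image.

Masks are resampled with nearest-neighbor interpolation so labels never
blend; images use bilinear interpolation.  Augmentation belongs to training
folds only — validation and test data pass through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import dilation, disk

from .types import CariesMask, Radiograph, StructureMask, ValidationError, MAX_INTENSITY

__all__ = ["AugmentParams", "augment_pair", "augment_mask"]


@dataclass(frozen=True)
class AugmentParams:
    """Sampling ranges for one augmentation draw.

    All ranges are symmetric around identity; set a range to zero (and
    probabilities to zero) to disable that component.  Elastic displacement
    is built from a coarse normal field of std ``elastic_sigma`` pixels on an
    ``elastic_grid``-spaced lattice, smoothed and bilinearly upsampled.
    The default displacement is mild (about 4 px at a 572-px frame) and
    should be scaled with the working resolution.
    """

    intensity_jitter: float = 0.08      # multiplicative gain in [1-j, 1+j]
    flip_horizontal_prob: float = 0.5
    flip_vertical_prob: float = 0.0
    rotation_deg: float = 6.0           # angle drawn from [-r, +r]
    elastic_grid: int = 24              # coarse lattice spacing, px
    elastic_sigma: float = 0.7          # coarse displacement std, px
    width_scale: float = 0.06           # horizontal-only scale in [1-s, 1+s]
    zoom: float = 0.06                  # isotropic scale in [1-z, 1+z]
    dilation_radius: tuple[int, int] = (0, 2)  # mask-only kernel radius range
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("intensity_jitter", "rotation_deg", "elastic_sigma",
                     "width_scale", "zoom"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for name in ("flip_horizontal_prob", "flip_vertical_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        lo, hi = self.dilation_radius
        if lo < 0 or hi < lo:
            raise ValidationError("dilation_radius must be 0 <= low <= high")
        if self.elastic_grid < 2:
            raise ValidationError("elastic_grid must be at least 2")


def _elastic_field(shape: tuple[int, int], grid: int, sigma: float,
                   rng: np.random.Generator) -> np.ndarray:
    """(2, H, W) displacement field from a smoothed coarse lattice."""
    h, w = shape
    gh, gw = h // grid + 3, w // grid + 3
    coarse = rng.normal(0.0, sigma, size=(2, gh, gw))
    coarse = ndi.gaussian_filter(coarse, sigma=(0, 1, 1))
    zoom = (1, h / gh, w / gw)
    return ndi.zoom(coarse, zoom, order=1)[:, :h, :w]


def _sample_geometry(shape, params: AugmentParams, rng: np.random.Generator):
    """Sample one transform; returns None for an exact identity draw."""
    flip_h = rng.random() < params.flip_horizontal_prob
    flip_v = rng.random() < params.flip_vertical_prob
    angle = np.deg2rad(rng.uniform(-params.rotation_deg, params.rotation_deg))
    wscale = 1.0 + rng.uniform(-params.width_scale, params.width_scale)
    zoom = 1.0 + rng.uniform(-params.zoom, params.zoom)
    elastic = None
    if params.elastic_sigma > 0:
        elastic = _elastic_field(shape, params.elastic_grid, params.elastic_sigma, rng)
    if (not flip_h and not flip_v and angle == 0.0 and wscale == 1.0
            and zoom == 1.0 and elastic is None):
        return None
    return flip_h, flip_v, angle, wscale, zoom, elastic


def _coordinate_map(shape, geom) -> np.ndarray:
    """Input coordinates (2, H, W) realizing the sampled output->input map."""
    h, w = shape
    flip_h, flip_v, angle, wscale, zoom, elastic = geom
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    y = yy - cy
    x = xx - cx
    if flip_h:
        x = -x
    if flip_v:
        y = -y
    # inverse of (zoom * width-scale * rotation): rotate back, unscale
    ca, sa = np.cos(-angle), np.sin(-angle)
    xr = ca * x - sa * y
    yr = sa * x + ca * y
    xr /= zoom * wscale
    yr /= zoom
    coords = np.stack([yr + cy, xr + cx])
    if elastic is not None:
        coords = coords + elastic
    return coords


def augment_pair(image: Radiograph,
                 masks: tuple[StructureMask, CariesMask],
                 params: AugmentParams, seed: int | None = None,
                 ) -> tuple[Radiograph, tuple[StructureMask, CariesMask]]:
    """Apply one jointly-sampled augmentation to an image and its masks.

    The same geometric transform (same sampled parameters) warps the image
    and both masks; the intensity jitter touches the image only.  Output
    intensities are clipped back into the 12-bit range.  Deterministic in
    ``(inputs, params, seed)``; ``seed`` defaults to ``params.rng_seed``.
    """
    params.validate()
    struct, caries = masks
    if struct.shape != image.shape or caries.shape != image.shape:
        raise ValidationError("image and mask shapes differ")
    rng = np.random.default_rng(params.rng_seed if seed is None else seed)

    gain = 1.0 + rng.uniform(-params.intensity_jitter, params.intensity_jitter)
    geom = _sample_geometry(image.shape, params, rng)

    img = image.pixels.astype(np.float64)
    if geom is None:
        out_img = img
        out_struct = struct.labels.copy()
        out_caries = caries.mask.copy()
    else:
        coords = _coordinate_map(image.shape, geom)
        out_img = ndi.map_coordinates(img, coords, order=1, mode="constant", cval=0.0)
        out_struct = ndi.map_coordinates(struct.labels, coords, order=0,
                                         mode="constant", cval=0)
        out_caries = ndi.map_coordinates(caries.mask, coords, order=0,
                                         mode="constant", cval=0)
    out_img = np.clip(np.rint(out_img * gain), 0, MAX_INTENSITY).astype(image.pixels.dtype)
    return (Radiograph(pixels=out_img, id=image.id),
            (StructureMask(labels=out_struct), CariesMask(mask=out_caries)))


def augment_mask(mask: CariesMask, params: AugmentParams,
                 seed: int | None = None) -> CariesMask:
    """Mask-only augmentation: random kernel dilation, then elastic warp.

    Output is binary.  With zero elastic displacement the result is a
    superset of the input (pure morphological dilation); with a zero-radius
    kernel and no elastic term the mask passes through unchanged.
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed if seed is None else seed)
    lo, hi = params.dilation_radius
    radius = int(rng.integers(lo, hi + 1))
    m = mask.mask.astype(bool)
    if radius > 0:
        m = dilation(m, disk(radius)).astype(bool)
    if params.elastic_sigma > 0 and m.any():
        field = _elastic_field(m.shape, params.elastic_grid, params.elastic_sigma, rng)
        h, w = m.shape
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        coords = np.stack([yy, xx]) + field
        m = ndi.map_coordinates(m.astype(np.uint8), coords, order=0,
                                mode="constant", cval=0).astype(bool)
    return CariesMask(mask=m.astype(np.uint8))
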