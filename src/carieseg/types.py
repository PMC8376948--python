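"""Core domain types shared across the pipeline.

Conventions used by every module:

* pixel coordinates are 0-based ``(row, col)``, origin top-left, row-major;
* radiograph intensities are 12-bit integers in ``[0, 4095]`` (the raw sensor
  range of intraoral detectors), stored in a 16-bit container;
* structure labels use the fixed integer table in :class:`StructureLabel`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

MAX_INTENSITY = 4095  # 12-bit sensor range
MIN_IMAGE_SIDE = 32


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(ValueError):
    """A file on disk is corrupt or inconsistent with its companions."""


class StructureLabel(enum.IntEnum):
    """Per-pixel anatomical structure classes.

    The integer values are the on-disk mask encoding and the class indices of
    the structure segmenter (which adds no extra classes: background is 0).
    """

    BACKGROUND = 0
    ENAMEL = 1
    DENTIN = 2
    PULP = 3
    METAL_RESTORATION = 4
    TOOTH_COLORED_RESTORATION = 5
    GUTTA_PERCHA = 6


N_STRUCTURE_CLASSES = len(StructureLabel)  # 7, incl. background


class SeverityLabel(str, enum.Enum):
    """Radiographic lesion-depth grade.

    Graded by how far the radiolucency penetrates the dentin: ``initial``
    reaches at most the dentinoenamel junction or the outer third of the
    dentin, ``moderate`` the middle third, ``extensive`` the inner third.
    """

    INITIAL = "initial"
    MODERATE = "moderate"
    EXTENSIVE = "extensive"


@dataclass
class Radiograph:
    """A 2-D grayscale radiograph with 12-bit intensities.

    Parameters
    ----------
    pixels
        Integer array of shape ``(height, width)``, values in ``[0, 4095]``.
    id
        Opaque identifier, unique within a dataset.
    """

    pixels: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError("radiograph pixels must be a 2-D array")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValidationError("radiograph pixels must be integer-typed")
        h, w = self.pixels.shape
        if h < MIN_IMAGE_SIDE or w < MIN_IMAGE_SIDE:
            raise ValidationError(
                f"radiograph must be at least {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}, got {h}x{w}"
            )
        lo, hi = int(self.pixels.min()), int(self.pixels.max())
        if lo < 0 or hi > MAX_INTENSITY:
            raise ValidationError(
                f"intensities outside [0, {MAX_INTENSITY}]: range [{lo}, {hi}]"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class StructureMask:
    """Per-pixel anatomical labels paired with a radiograph."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("structure labels must be a 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("structure labels must be integer-typed")
        bad = (self.labels < 0) | (self.labels >= N_STRUCTURE_CLASSES)
        if bad.any():
            raise ValidationError("structure labels outside the class table")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def support(self, *labels: StructureLabel) -> np.ndarray:
        """Boolean mask of pixels carrying any of ``labels``."""
        out = np.zeros(self.labels.shape, dtype=bool)
        for lab in labels:
            out |= self.labels == int(lab)
        return out


@dataclass
class CariesMask:
    """Binary caries mask paired with a radiograph (1 = caries pixel)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 2:
            raise ValidationError("caries mask must be a 2-D array")
        if self.mask.dtype == bool:
            self.mask = self.mask.astype(np.uint8)
        if not np.issubdtype(self.mask.dtype, np.integer):
            raise ValidationError("caries mask must be integer or boolean")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValidationError("caries mask must be binary (0/1)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def is_empty(self) -> bool:
        return not bool(self.mask.any())


@dataclass
class LesionRecord:
    """One simulated caries lesion and its ground-truth severity.

    ``penetration`` is the fraction of the local dentin thickness reached by
    the lesion front: 0 means the radiolucency is confined to the enamel /
    dentinoenamel junction.
    """

    lesion_id: str
    pixel_set: frozenset[tuple[int, int]]
    penetration: float
    severity: SeverityLabel

    def __post_init__(self) -> None:
        if not self.pixel_set:
            raise ValidationError("lesion pixel_set must be non-empty")
        if not 0.0 <= self.penetration <= 1.0:
            raise ValidationError("penetration must lie in [0, 1]")

    @property
    def area(self) -> int:
        return len(self.pixel_set)

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        rows, cols = zip(*self.pixel_set)
        out[list(rows), list(cols)] = True
        return out


@dataclass
class PhantomSample:
    """One phantom radiograph with its ground truth."""

    radiograph: Radiograph
    structures: StructureMask
    caries: CariesMask
    lesions: list[LesionRecord] = field(default_factory=list)


def pixel_set_of(mask: np.ndarray) -> frozenset[tuple[int, int]]:
    """Frozen set of (row, col) for the nonzero pixels of ``mask``."""
    rows, cols = np.nonzero(mask)
    return frozenset(zip(rows.tolist(), cols.tolist()))
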