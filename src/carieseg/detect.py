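"""From probability maps to final caries detections.

The inference pipeline is: threshold the caries probability map (strictly
greater than the operating threshold, 0.55 by default), extract connected
components ("blobs"), and eliminate every blob that shares no pixel with the
enamel-or-dentin support of the structure segmentation — caries cannot live
outside mineralized tooth tissue, so such blobs are false detections by
construction.  Probability maps are compared at the radiograph's native
resolution so detections, masks and structures share one pixel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .segnet import TrainedModel, predict
from .types import Radiograph, StructureLabel, StructureMask, ValidationError

__all__ = [
    "Blob",
    "DetectionResult",
    "DEFAULT_THRESHOLD",
    "binarize",
    "extract_blobs",
    "structure_labelmap",
    "refine",
    "detect_caries",
    "render_overlay",
]

DEFAULT_THRESHOLD = 0.55
ELIMINATION_REASON = "no-enamel-dentin-overlap"


@dataclass
class Blob:
    """One connected component of predicted caries pixels."""

    pixel_set: frozenset[tuple[int, int]]
    score: float  # mean caries probability over the blob

    def __post_init__(self) -> None:
        if not self.pixel_set:
            raise ValidationError("blob must contain at least one pixel")
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError("blob score must lie in [0, 1]")

    @property
    def area(self) -> int:
        return len(self.pixel_set)

    @property
    def top_left(self) -> tuple[int, int]:
        return min(self.pixel_set)

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        rows, cols = zip(*self.pixel_set)
        out[list(rows), list(cols)] = True
        return out


@dataclass
class DetectionResult:
    """Final detections for one radiograph."""

    radiograph_id: str
    threshold: float
    surviving: list[Blob] = field(default_factory=list)
    eliminated: list[tuple[Blob, str]] = field(default_factory=list)

    @property
    def pixel_union(self) -> frozenset[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for b in self.surviving:
            out |= b.pixel_set
        return frozenset(out)


def binarize(caries_prob: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Strict thresholding: a pixel is caries iff probability > threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must lie in (0, 1)")
    return (np.asarray(caries_prob) > threshold).astype(np.uint8)


def extract_blobs(binary: np.ndarray, caries_prob: np.ndarray,
                  connectivity: int = 8) -> list[Blob]:
    """Maximal connected components of a binary grid, with mean-probability
    scores, ordered by top-left pixel then area.

    ``connectivity`` is 8 (default: diagonal neighbors connect) or 4.
    """
    if connectivity not in (4, 8):
        raise ValidationError("connectivity must be 4 or 8")
    binary = np.asarray(binary)
    prob = np.asarray(caries_prob)
    if binary.shape != prob.shape:
        raise ValidationError("binary grid and probability map shapes differ")
    lab = measure.label(binary > 0, connectivity=1 if connectivity == 4 else 2)
    blobs = []
    for k in range(1, lab.max() + 1):
        rows, cols = np.nonzero(lab == k)
        pix = frozenset(zip(rows.tolist(), cols.tolist()))
        score = float(np.clip(prob[rows, cols].mean(), 0.0, 1.0))
        blobs.append(Blob(pixel_set=pix, score=score))
    blobs.sort(key=lambda b: (b.top_left, b.area))
    return blobs


def structure_labelmap(struct_prob: np.ndarray) -> StructureMask:
    """Per-pixel argmax over a structure probability map.

    Ties resolve to the lowest class index (numpy argmax), so a fully
    uninformative pixel falls to background.
    """
    prob = np.asarray(struct_prob)
    if prob.ndim != 3:
        raise ValidationError("structure probability map must be (C, H, W)")
    return StructureMask(labels=prob.argmax(axis=0).astype(np.uint8))


def refine(blobs: list[Blob], structure: StructureMask,
           ) -> tuple[list[Blob], list[tuple[Blob, str]]]:
    """Keep blobs touching enamel or dentin; eliminate the rest.

    Survival needs at least one shared pixel — no minimum overlap fraction.
    Idempotent: refining the survivors again changes nothing.
    """
    support = structure.support(StructureLabel.ENAMEL, StructureLabel.DENTIN)
    h, w = support.shape
    surviving: list[Blob] = []
    eliminated: list[tuple[Blob, str]] = []
    for b in blobs:
        for r, c in b.pixel_set:
            if not (0 <= r < h and 0 <= c < w):
                raise ValidationError("blob pixel outside the structure mask grid")
        if any(support[r, c] for r, c in b.pixel_set):
            surviving.append(b)
        else:
            eliminated.append((b, ELIMINATION_REASON))
    return surviving, eliminated


def detect_caries(radiograph: Radiograph, ucs: TrainedModel, uss: TrainedModel,
                  threshold: float = DEFAULT_THRESHOLD,
                  connectivity: int = 8) -> DetectionResult:
    """Full two-network inference for one radiograph.

    Runs the caries and structure segmenters, thresholds the caries channel,
    extracts blobs and refines them against the predicted structure map.
    """
    caries_prob = predict(ucs, radiograph)[1]
    struct_prob = predict(uss, radiograph)
    binary = binarize(caries_prob, threshold)
    blobs = extract_blobs(binary, caries_prob, connectivity=connectivity)
    structure = structure_labelmap(struct_prob)
    surviving, eliminated = refine(blobs, structure)
    return DetectionResult(radiograph_id=radiograph.id, threshold=threshold,
                           surviving=surviving, eliminated=eliminated)


def render_overlay(radiograph: Radiograph, result: DetectionResult,
                   ) -> tuple[np.ndarray, list[dict]]:
    """RGB overlay marking surviving blobs, plus a per-blob numeric summary.

    The radiograph is scaled to 8-bit gray; surviving blob pixels are tinted
    red.  The summary lists, per blob, its area in pixels and mean caries
    probability — the numeric "degree of caries" shown to a reader.
    """
    gray = (radiograph.pixels.astype(np.float64) / 4095.0 * 255.0).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    summary = []
    for i, b in enumerate(result.surviving):
        rows, cols = zip(*b.pixel_set)
        rgb[list(rows), list(cols), 0] = 255
        rgb[list(rows), list(cols), 1] //= 2
        rgb[list(rows), list(cols), 2] //= 2
        summary.append({"blob": i, "area_px": b.area, "mean_prob": round(b.score, 4)})
    return rgb, summary
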