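"""Operating-threshold selection by exhaustive sweep on validation data.

Candidate thresholds 0.01, 0.02, ..., 0.99 are each pushed through the full
detection chain (binarize, blob extraction, structure refinement) on every
validation image, scored against the ground-truth lesions with the
component-level F1 at theta = 0.1, pooled over images.  The selected
threshold maximizes the agreement score; ties resolve to the lowest
candidate, preferring sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .detect import binarize, extract_blobs, refine
from .evaluate import (DEFAULT_THETA, MatchResult, component_metrics,
                       match_components, pool_cross_validation)
from .types import CariesMask, StructureMask, ValidationError, pixel_set_of

__all__ = ["ThresholdCurve", "THRESHOLD_GRID", "sweep_threshold"]

THRESHOLD_GRID = np.round(np.arange(1, 100) * 0.01, 2)


@dataclass
class ThresholdCurve:
    """The 99-point sweep and its selection."""

    entries: list[tuple[float, float]] = field(default_factory=list)
    selected: float = 0.0

    def scores(self) -> dict[float, float]:
        return dict(self.entries)


def _truth_lesion_sets(truth: CariesMask, connectivity: int) -> list[frozenset]:
    lab = measure.label(truth.mask > 0, connectivity=1 if connectivity == 4 else 2)
    return [pixel_set_of(lab == k) for k in range(1, lab.max() + 1)]


def sweep_threshold(predictions: list[np.ndarray], truths: list[CariesMask],
                    structures: list[StructureMask], theta: float = DEFAULT_THETA,
                    connectivity: int = 8) -> ThresholdCurve:
    """Sweep the 99-candidate grid and select the F1-maximizing threshold.

    ``predictions`` are caries probability maps (one channel, native
    resolution), aligned index-by-index with the ground-truth caries masks
    and the structure masks used for refinement.
    """
    if not predictions:
        raise ValidationError("need at least one validation image")
    if not (len(predictions) == len(truths) == len(structures)):
        raise ValidationError("predictions, truths and structures must align")
    for p, t, s in zip(predictions, truths, structures):
        if np.asarray(p).shape != t.shape or t.shape != s.shape:
            raise ValidationError("per-image shapes must agree")

    truth_sets = [_truth_lesion_sets(t, connectivity) for t in truths]
    entries: list[tuple[float, float]] = []
    best_score, best_thr = -1.0, None
    for thr in THRESHOLD_GRID:
        fold_results: list[MatchResult] = []
        for prob, lesions, struct in zip(predictions, truth_sets, structures):
            binary = binarize(np.asarray(prob), float(thr))
            blobs = extract_blobs(binary, np.asarray(prob), connectivity=connectivity)
            surviving, _ = refine(blobs, struct)
            fold_results.append(match_components(surviving, lesions, theta=theta))
        pooled = MatchResult(theta=theta,
                             tp=sum(r.tp for r in fold_results),
                             fp=sum(r.fp for r in fold_results),
                             fn=sum(r.fn for r in fold_results))
        if pooled.tp == 0 and pooled.fp == 0 and pooled.fn == 0:
            score = 0.0  # nothing predicted, nothing true: neutral agreement
        else:
            rep = component_metrics(pooled)
            score = rep.f1 if rep.f1 is not None else 0.0
        entries.append((float(thr), float(score)))
        if score > best_score:  # strict: ties keep the lowest threshold
            best_score, best_thr = score, float(thr)
    return ThresholdCurve(entries=entries, selected=best_thr)
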