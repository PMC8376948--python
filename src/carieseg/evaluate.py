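"""Component-level detection scoring, severity stratification, fold pooling
and the reader before/after comparison.

Detection quality is scored at the connected-component level: a predicted
blob is a hit when it covers at least a fraction ``theta`` (default 0.1) of
a ground-truth lesion.  True positives are lesions with at least one
qualifying blob, false positives blobs qualifying for no lesion, false
negatives lesions no blob qualifies for.  Matching is many-to-many — one
blob may validate several lesions and vice versa; no assignment step is
performed.

Cross-validation results are pooled by summing the TP/FP/FN counts across
folds and computing the metrics once on the pooled counts, never by
averaging per-fold percentages.

The reader study compares each reader's lesion-level performance against a
consensus truth before and after revising with the model's output, using an
any-overlap rule (a lesion counts as detected if any tagged region shares at
least one pixel with it, regardless of the overlap ratio).  F1 differences
are assessed by a seeded bootstrap over radiographs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import LesionRecord, SeverityLabel, ValidationError

__all__ = [
    "MatchResult",
    "MetricsReport",
    "ReaderAnnotation",
    "match_components",
    "component_metrics",
    "f1_score",
    "severity_sensitivity",
    "pool_cross_validation",
    "reader_change_analysis",
    "simulate_reader",
    "NoDetectionsNoTruth",
]

DEFAULT_THETA = 0.1


class NoDetectionsNoTruth(ValidationError):
    """All counts zero: there is nothing to score."""


@dataclass
class MatchResult:
    """TP/FP/FN bookkeeping for one scored set at a fixed theta."""

    theta: float
    tp: int
    fp: int
    fn: int
    pairings: list[tuple[int, int, float]] = field(default_factory=list)
    # (blob index, lesion index, overlap fraction) for every overlapping pair


@dataclass
class MetricsReport:
    """Percent-scale precision / recall / F1 with optional extras.

    Undefined components (zero denominator) are ``None``, never silently 0.
    ``f1_defined`` is False when both precision and recall are zero.
    """

    precision: float | None
    recall: float | None
    f1: float | None
    f1_defined: bool = True
    per_severity_sensitivity: dict[str, float | None] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def _overlap_fraction(blob_pixels: frozenset, lesion_pixels: frozenset,
                      denominator: str) -> float:
    inter = len(blob_pixels & lesion_pixels)
    if inter == 0:
        return 0.0
    if denominator == "truth":
        return inter / len(lesion_pixels)
    if denominator == "iou":
        return inter / len(blob_pixels | lesion_pixels)
    raise ValidationError("denominator must be 'truth' or 'iou'")


def match_components(predicted, truth, theta: float = DEFAULT_THETA,
                     denominator: str = "truth") -> MatchResult:
    """Score predicted blobs against ground-truth lesions at overlap ratio theta.

    ``predicted`` and ``truth`` are sequences of objects exposing
    ``pixel_set`` (blobs / lesion records) or raw pixel-sets.  The overlap
    fraction defaults to the share of the *lesion* covered by the blob
    (``denominator='truth'``); intersection-over-union is available via
    ``denominator='iou'``.
    """
    if not 0.0 < theta <= 1.0:
        raise ValidationError("theta must lie in (0, 1]")
    pred_sets = [frozenset(getattr(p, "pixel_set", p)) for p in predicted]
    truth_sets = [frozenset(getattr(t, "pixel_set", t)) for t in truth]
    pairings = []
    lesion_hit = [False] * len(truth_sets)
    blob_hit = [False] * len(pred_sets)
    for bi, bp in enumerate(pred_sets):
        for li, lp in enumerate(truth_sets):
            frac = _overlap_fraction(bp, lp, denominator)
            if frac > 0.0:
                pairings.append((bi, li, frac))
            if frac >= theta:
                lesion_hit[li] = True
                blob_hit[bi] = True
    tp = sum(lesion_hit)
    fn = len(truth_sets) - tp
    fp = sum(not h for h in blob_hit)
    return MatchResult(theta=theta, tp=tp, fp=fp, fn=fn, pairings=pairings)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of percent-scale precision and recall.

    Both zero is a degenerate case reported as 0 (callers that need the
    distinction carry an ``f1_defined`` flag alongside).
    """
    if not (0.0 <= precision <= 100.0 and 0.0 <= recall <= 100.0):
        raise ValidationError("precision and recall must lie in [0, 100]")
    if precision == 0.0 and recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def component_metrics(m: MatchResult) -> MetricsReport:
    """Percent precision / recall / F1 from raw counts.

    Raises :class:`NoDetectionsNoTruth` when TP, FP and FN are all zero.
    A metric whose denominator is zero is reported as ``None`` (absent).
    """
    if m.tp == 0 and m.fp == 0 and m.fn == 0:
        raise NoDetectionsNoTruth("no detections and no truth: metrics undefined")
    precision = 100.0 * m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else None
    recall = 100.0 * m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else None
    if precision is None or recall is None:
        return MetricsReport(precision=precision, recall=recall, f1=None,
                             f1_defined=False)
    defined = not (precision == 0.0 and recall == 0.0)
    return MetricsReport(precision=precision, recall=recall,
                         f1=f1_score(precision, recall), f1_defined=defined)


def pool_cross_validation(results: list[MatchResult]) -> MetricsReport:
    """Sum TP/FP/FN across folds, then compute the metrics once.

    Pooling raw counts weights every lesion equally; it is not the mean of
    the per-fold percentages.  All folds must share one theta.
    """
    if not results:
        raise ValidationError("need at least one fold result")
    thetas = {r.theta for r in results}
    if len(thetas) != 1:
        raise ValidationError(f"mixed theta across folds: {sorted(thetas)}")
    pooled = MatchResult(theta=results[0].theta,
                         tp=sum(r.tp for r in results),
                         fp=sum(r.fp for r in results),
                         fn=sum(r.fn for r in results))
    return component_metrics(pooled)


# ---------------------------------------------------------------------------
# lesion-level (any-overlap) scoring and severity stratification
# ---------------------------------------------------------------------------


def _any_overlap_counts(tagged: list[frozenset], lesions: list[LesionRecord]):
    """Lesion-level hits under the any-overlap rule (no theta).

    Returns (per-lesion detected flags, per-tagged-region hit flags).
    """
    det = []
    for les in lesions:
        det.append(any(les.pixel_set & t for t in tagged))
    tag_hit = [any(t & les.pixel_set for les in lesions) for t in tagged]
    return det, tag_hit


def severity_sensitivity(detections: dict[str, list[frozenset]],
                         truth: dict[str, list[LesionRecord]],
                         ) -> dict[str, float | None]:
    """Per-severity and overall sensitivity (%) under the any-overlap rule.

    ``detections`` maps radiograph id to a list of detected pixel-sets,
    ``truth`` to its lesion records.  A lesion counts as detected as soon as
    any detected region shares one pixel with it.  Severity classes with no
    lesions report ``None``.
    """
    hit = {s: 0 for s in SeverityLabel}
    tot = {s: 0 for s in SeverityLabel}
    for rid, lesions in truth.items():
        tagged = [frozenset(t) for t in detections.get(rid, [])]
        det, _ = _any_overlap_counts(tagged, lesions)
        for les, d in zip(lesions, det):
            tot[les.severity] += 1
            hit[les.severity] += bool(d)
    out: dict[str, float | None] = {}
    n_hit = sum(hit.values())
    n_tot = sum(tot.values())
    out["overall"] = 100.0 * n_hit / n_tot if n_tot else None
    for s in SeverityLabel:
        out[s.value] = 100.0 * hit[s] / tot[s] if tot[s] else None
    return out


# ---------------------------------------------------------------------------
# reader study
# ---------------------------------------------------------------------------


@dataclass
class ReaderAnnotation:
    """One reader's lesion tags for one phase of the study.

    ``regions`` maps radiograph id to the list of tagged pixel-sets.
    ``phase`` is ``"before"`` (unaided) or ``"after"`` (revised with the
    model's detections on screen).
    """

    reader_id: str
    phase: str
    regions: dict[str, list[frozenset]]

    def __post_init__(self) -> None:
        if self.phase not in ("before", "after"):
            raise ValidationError("phase must be 'before' or 'after'")


def _reader_counts(ann: ReaderAnnotation, consensus: dict[str, list[LesionRecord]]):
    """Per-radiograph (n_lesions, n_detected, n_tagged, n_tag_hits)."""
    rows = {}
    for rid, lesions in consensus.items():
        tagged = [frozenset(t) for t in ann.regions.get(rid, [])]
        det, tag_hit = _any_overlap_counts(tagged, lesions)
        rows[rid] = (len(lesions), sum(det), len(tagged), sum(tag_hit))
    return rows


def _metrics_from_rows(rows, rids) -> tuple[float | None, float | None, float]:
    n_les = sum(rows[r][0] for r in rids)
    n_det = sum(rows[r][1] for r in rids)
    n_tag = sum(rows[r][2] for r in rids)
    n_hit = sum(rows[r][3] for r in rids)
    sens = 100.0 * n_det / n_les if n_les else None
    ppv = 100.0 * n_hit / n_tag if n_tag else None
    f1 = f1_score(sens or 0.0, ppv or 0.0) if (sens is not None and ppv is not None) else 0.0
    return sens, ppv, f1


def reader_change_analysis(readers: list[tuple[ReaderAnnotation, ReaderAnnotation]],
                           consensus: dict[str, list[LesionRecord]],
                           model: dict[str, list[frozenset]] | None = None,
                           n_resamples: int = 1000, seed: int = 0) -> dict:
    """Before/after comparison of readers against consensus truth.

    For every reader and phase: lesion-level sensitivity, PPV (fraction of
    tagged regions hitting a consensus lesion), F1, per-severity
    sensitivities and the number of tagged regions.  The before-vs-after F1
    difference is assessed by bootstrap over radiographs (the cluster unit:
    lesions within an image are dependent), reporting a percentile CI of the
    difference and a two-sided bootstrap p-value.  When ``model`` detections
    are given, a model row is computed identically.
    """
    if n_resamples < 1:
        raise ValidationError("n_resamples must be positive")
    rng = np.random.default_rng(seed)
    rids = sorted(consensus)
    report: dict = {"readers": {}, "n_resamples": n_resamples}
    for before, after in readers:
        if before.reader_id != after.reader_id:
            raise ValidationError("before/after annotations belong to different readers")
        if set(before.regions) != set(after.regions):
            raise ValidationError("before/after phases reference different radiographs")
        rows_b = _reader_counts(before, consensus)
        rows_a = _reader_counts(after, consensus)
        entry = {}
        for phase, ann, rows in (("before", before, rows_b), ("after", after, rows_a)):
            sens, ppv, f1 = _metrics_from_rows(rows, rids)
            entry[phase] = {
                "sensitivity": sens, "ppv": ppv, "f1": f1,
                "n_tagged": sum(len(v) for v in ann.regions.values()),
                "per_severity_sensitivity": severity_sensitivity(ann.regions, consensus),
            }
        diffs = np.empty(n_resamples)
        for i in range(n_resamples):
            sample = [rids[j] for j in rng.integers(0, len(rids), size=len(rids))]
            _, _, f1b = _metrics_from_rows(rows_b, sample)
            _, _, f1a = _metrics_from_rows(rows_a, sample)
            diffs[i] = f1a - f1b
        lo, hi = np.percentile(diffs, [2.5, 97.5])
        p = 2.0 * min((diffs <= 0).mean(), (diffs >= 0).mean())
        entry["f1_change"] = {
            "delta": entry["after"]["f1"] - entry["before"]["f1"],
            "ci95": (float(lo), float(hi)),
            "p_boot": float(min(1.0, p)),
        }
        report["readers"][before.reader_id] = entry
    if model is not None:
        rows_m = _reader_counts(
            ReaderAnnotation(reader_id="model", phase="before", regions=model), consensus)
        sens, ppv, f1 = _metrics_from_rows(rows_m, rids)
        report["model"] = {
            "sensitivity": sens, "ppv": ppv, "f1": f1,
            "n_tagged": sum(len(v) for v in model.values()),
            "per_severity_sensitivity": severity_sensitivity(model, consensus),
        }
    return report


def simulate_reader(consensus: dict[str, list[LesionRecord]], miss_rate: float,
                    reader_id: str, phase: str, seed: int = 0,
                    jitter: int = 1) -> ReaderAnnotation:
    """A synthetic reader: tags each consensus lesion except a missed fraction.

    Each kept lesion is tagged as its own pixel-set, optionally eroded/offset
    by up to ``jitter`` pixels to mimic imprecise outlining (overlap with the
    lesion is always preserved, matching the any-overlap scoring rule).
    Deterministic in ``seed``.
    """
    if not 0.0 <= miss_rate < 1.0:
        raise ValidationError("miss_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    regions: dict[str, list[frozenset]] = {}
    for rid in sorted(consensus):
        tags = []
        for les in consensus[rid]:
            if rng.random() < miss_rate:
                continue
            pix = les.pixel_set
            if jitter and len(pix) > 4:
                dr, dc = rng.integers(-jitter, jitter + 1, size=2)
                shifted = frozenset((r + int(dr), c + int(dc)) for r, c in pix)
                if shifted & pix:
                    pix = shifted
            tags.append(pix)
        regions[rid] = tags
    return ReaderAnnotation(reader_id=reader_id, phase=phase, regions=regions)
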