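"""Synthetic bitewing phantom generation, dataset assembly and fold planning.

The phantoms stand in for clinical bitewing radiographs: a row of posterior
crowns rendered as layered superellipses (enamel shell, dentin body, pulp
core) on a 12-bit canvas, with optional restorations and radiolucent caries
lesions placed on proximal surfaces.  Intensity ordering follows radiographic
density — enamel brightest, then dentin, pulp, soft-tissue background — and
lesions darken the tissue they invade, which is the only contrast cue the
segmentation networks are given.

Every lesion carries a ground-truth penetration depth expressed as the
fraction of the local dentin thickness reached by the lesion front, which
maps to the three clinical severity grades (initial / moderate / extensive)
by thirds of the dentin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .types import (
    CariesMask,
    LesionRecord,
    PhantomSample,
    Radiograph,
    SeverityLabel,
    StructureLabel,
    StructureMask,
    ValidationError,
    MAX_INTENSITY,
)

__all__ = [
    "PhantomSpec",
    "DatasetBundle",
    "FoldPlan",
    "classify_severity",
    "generate_phantom",
    "build_dataset",
    "plan_folds",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom renderer.

    All randomness is drawn from a generator seeded per call, so the same
    ``(spec, seed)`` always renders the same image.

    Parameters
    ----------
    image_size
        ``(height, width)`` of the canvas; both at least 32.
    n_teeth
        Crowns rendered in one horizontal row.
    lesion_count
        Inclusive ``(low, high)`` range for the number of lesions per image.
    severity_mix
        Sampling probabilities for (initial, moderate, extensive) lesions.
    restoration_prob
        Per-tooth probability of carrying a restoration (metal or
        tooth-colored, equally likely); restored teeth may also get a
        gutta-percha root filling.
    noise_sigma
        Std of additive Gaussian read-out noise on the 12-bit scale.
    blur_sigma
        Gaussian PSF radius in pixels.
    jitter
        Relative geometric jitter on tooth size and position.
    lesion_contrast
        Multiplicative darkening at the lesion core (0 = black).
    """

    image_size: tuple[int, int] = (256, 320)
    n_teeth: int = 4
    lesion_count: tuple[int, int] = (1, 3)
    severity_mix: tuple[float, float, float] = (0.45, 0.35, 0.20)
    restoration_prob: float = 0.25
    noise_sigma: float = 60.0
    blur_sigma: float = 0.7
    jitter: float = 0.06
    lesion_contrast: float = 0.55
    rng_seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValidationError("image_size must be at least 32x32")
        if self.n_teeth < 1:
            raise ValidationError("n_teeth must be positive")
        lo, hi = self.lesion_count
        if lo < 0 or hi < lo:
            raise ValidationError("lesion_count must be 0 <= low <= high")
        if not 0.0 <= self.restoration_prob <= 1.0:
            raise ValidationError("restoration_prob must lie in [0, 1]")
        if any(p < 0 for p in self.severity_mix) or sum(self.severity_mix) <= 0:
            raise ValidationError("severity_mix must be non-negative, not all zero")
        if self.noise_sigma < 0 or self.blur_sigma < 0 or self.jitter < 0:
            raise ValidationError("noise/blur/jitter must be non-negative")
        if not 0.0 < self.lesion_contrast < 1.0:
            raise ValidationError("lesion_contrast must lie in (0, 1)")


# mean tissue intensities on the 12-bit scale (enamel > dentin > pulp > bg)
_INTENSITY = {
    StructureLabel.BACKGROUND: 550.0,
    StructureLabel.ENAMEL: 3350.0,
    StructureLabel.DENTIN: 2400.0,
    StructureLabel.PULP: 1250.0,
    StructureLabel.METAL_RESTORATION: 4000.0,
    StructureLabel.TOOTH_COLORED_RESTORATION: 2850.0,
    StructureLabel.GUTTA_PERCHA: 3800.0,
}

_SEVERITY_ORDER = (SeverityLabel.INITIAL, SeverityLabel.MODERATE, SeverityLabel.EXTENSIVE)
# sampling windows for the penetration fraction, kept clear of the class
# boundaries so pixel-level re-measurement stays inside the intended grade
_PENETRATION_WINDOW = {
    SeverityLabel.INITIAL: (0.00, 0.28),
    SeverityLabel.MODERATE: (0.38, 0.62),
    SeverityLabel.EXTENSIVE: (0.72, 0.97),
}


def classify_severity(penetration: float) -> SeverityLabel:
    """Map a dentin-penetration fraction to a severity grade.

    ``initial`` up to the outer third of the dentin (boundary included),
    ``moderate`` up to the middle third, ``extensive`` beyond.
    """
    if not 0.0 <= penetration <= 1.0:
        raise ValidationError(f"penetration must lie in [0, 1], got {penetration}")
    if penetration <= 1.0 / 3.0:
        return SeverityLabel.INITIAL
    if penetration <= 2.0 / 3.0:
        return SeverityLabel.MODERATE
    return SeverityLabel.EXTENSIVE


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _superellipse_rho(h: int, w: int, cy: float, cx: float, a: float, b: float,
                      p: float = 2.5) -> np.ndarray:
    """Normalized radial coordinate of a superellipse (<=1 inside)."""
    yy, xx = np.mgrid[0:h, 0:w]
    return (np.abs((xx - cx) / a) ** p + np.abs((yy - cy) / b) ** p) ** (1.0 / p)


def generate_phantom(spec: PhantomSpec, seed: int | None = None,
                     ) -> tuple[Radiograph, StructureMask, CariesMask, list[LesionRecord]]:
    """Render one phantom radiograph with paired ground truth.

    Deterministic in ``(spec, seed)``; ``seed`` defaults to ``spec.rng_seed``.
    Returns the radiograph, the structure label mask, the binary caries mask
    and one :class:`LesionRecord` per lesion.  Every caries pixel lies inside
    the enamel-or-dentin support of the structure mask, which is what makes
    structure-overlap refinement meaningful downstream.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    h, w = spec.image_size
    labels = np.zeros((h, w), dtype=np.uint8)
    tooth_of = np.full((h, w), -1, dtype=np.int16)

    pitch = w / spec.n_teeth
    cy0 = h * 0.5
    half_w = pitch * 0.44
    half_h = h * 0.36
    jit = spec.jitter
    geoms = []
    for i in range(spec.n_teeth):
        cx = pitch * (i + 0.5) + rng.uniform(-jit, jit) * pitch
        cy = cy0 + rng.uniform(-jit, jit) * h * 0.5
        a = half_w * (1 + rng.uniform(-jit, jit))
        b = half_h * (1 + rng.uniform(-jit, jit))
        rho = _superellipse_rho(h, w, cy, cx, a, b)
        enamel_t = 0.16 * (1 + rng.uniform(-0.2, 0.2))
        pulp_r = 0.34 * (1 + rng.uniform(-0.15, 0.15))
        inside = rho <= 1.0
        labels[inside & (rho > 1.0 - enamel_t)] = StructureLabel.ENAMEL
        labels[inside & (rho <= 1.0 - enamel_t) & (rho > pulp_r)] = StructureLabel.DENTIN
        labels[rho <= pulp_r] = StructureLabel.PULP
        tooth_of[inside] = i
        geoms.append((cy, cx, a, b, enamel_t, pulp_r))

    # restorations: an occlusal cap replacing enamel/dentin near the crown top,
    # optionally a gutta-percha strip through the pulp of the same tooth
    for i, (cy, cx, a, b, enamel_t, pulp_r) in enumerate(geoms):
        if rng.random() >= spec.restoration_prob:
            continue
        kind = (StructureLabel.METAL_RESTORATION if rng.random() < 0.5
                else StructureLabel.TOOTH_COLORED_RESTORATION)
        ry = cy - b * 0.75
        rr = _superellipse_rho(h, w, ry, cx, a * 0.45, b * 0.30, 2.0)
        cap = (rr <= 1.0) & (tooth_of == i) & (
            (labels == StructureLabel.ENAMEL) | (labels == StructureLabel.DENTIN))
        labels[cap] = kind
        if rng.random() < 0.5:
            gp = (np.abs(np.arange(w)[None, :] - cx) <= max(1.0, a * 0.08)) & (
                labels == StructureLabel.PULP) & (tooth_of == i)
            labels[gp] = StructureLabel.GUTTA_PERCHA

    # lesions on proximal (left/right) surfaces; one per (tooth, side)
    n_lesions = int(rng.integers(spec.lesion_count[0], spec.lesion_count[1] + 1))
    sides = [(i, s) for i in range(spec.n_teeth) for s in (-1, +1)]
    rng.shuffle(sides)
    mix = np.asarray(spec.severity_mix, dtype=float)
    mix = mix / mix.sum()
    caries = np.zeros((h, w), dtype=np.uint8)
    lesions: list[LesionRecord] = []
    for tooth_i, side in sides:
        if len(lesions) >= n_lesions:
            break
        rec = _place_lesion(labels, tooth_of, geoms[tooth_i], tooth_i, side,
                            rng, mix, len(lesions))
        if rec is None:
            continue
        for r, c in rec.pixel_set:
            caries[r, c] = 1
        lesions.append(rec)

    # render intensities from labels, darken lesions, add PSF blur + noise
    img = np.zeros((h, w), dtype=np.float64)
    for lab, mean in _INTENSITY.items():
        img[labels == lab] = mean * (1 + rng.uniform(-0.02, 0.02))
    for rec in lesions:
        depth_factor = spec.lesion_contrast * (1 + rng.uniform(-0.1, 0.1))
        rows, cols = zip(*rec.pixel_set)
        img[list(rows), list(cols)] *= np.clip(depth_factor, 0.05, 0.95)
    if spec.blur_sigma > 0:
        img = ndi.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    pixels = np.clip(np.rint(img), 0, MAX_INTENSITY).astype(np.uint16)

    return (Radiograph(pixels=pixels, id=""), StructureMask(labels=labels),
            CariesMask(mask=caries), lesions)


def _place_lesion(labels, tooth_of, geom, tooth_i, side, rng, mix, idx):
    """Carve one radiolucent lesion on a proximal surface; None if degenerate."""
    h, w = labels.shape
    cy, cx, a, b, enamel_t, pulp_r = geom
    # surface point at a random height around the proximal contact area
    yfrac = rng.uniform(-0.35, 0.35)
    y = int(round(cy + yfrac * b))
    if not 0 <= y < h:
        return None
    row = labels[y]
    on_tooth = tooth_of[y] == tooth_i
    cols = np.nonzero(on_tooth)[0]
    if cols.size == 0:
        return None
    x_surf = cols.max() if side > 0 else cols.min()

    # measure enamel and dentin thickness along the inward horizontal ray
    step = -side
    xs = x_surf + step * np.arange(0, int(2 * a))
    xs = xs[(xs >= 0) & (xs < w)]
    ray = labels[y, xs]
    # contiguous near-side segments only: enamel shell, then dentin until the
    # pulp (or the end of tissue) — the far side of the crown does not count
    enamel_px = 0
    dentin_px = 0
    i = 0
    while i < ray.size and ray[i] == StructureLabel.ENAMEL:
        enamel_px += 1
        i += 1
    while i < ray.size and ray[i] == StructureLabel.DENTIN:
        dentin_px += 1
        i += 1
    if enamel_px == 0 or dentin_px < 3:
        return None

    severity = rng.choice(3, p=mix)
    lo, hi = _PENETRATION_WINDOW[_SEVERITY_ORDER[severity]]
    target_pen = rng.uniform(lo, hi)
    depth = enamel_px + target_pen * dentin_px
    radius = max(2.0, depth)

    yy, xx = np.mgrid[0:h, 0:w]
    disc = (yy - y) ** 2 + (xx - x_surf) ** 2 <= radius ** 2
    tissue = ((labels == StructureLabel.ENAMEL) | (labels == StructureLabel.DENTIN))
    region = disc & tissue & (tooth_of == tooth_i)
    if not region.any():
        return None
    # keep the connected component at the entry point
    comp = measure.label(region, connectivity=2)
    seed_x = xs[0]
    lab_at = comp[y, seed_x] if comp[y, seed_x] > 0 else comp[region].min()
    region = comp == lab_at
    if region.sum() < 3:
        return None

    # re-measure the achieved penetration on the pixel grid
    ray_in_lesion = region[y, xs]
    reach = int(np.count_nonzero(ray_in_lesion))
    pen = float(np.clip((reach - enamel_px) / dentin_px, 0.0, 1.0))
    rows, cols2 = np.nonzero(region)
    pixel_set = frozenset(zip(rows.tolist(), cols2.tolist()))
    return LesionRecord(lesion_id=f"L{idx}", pixel_set=pixel_set,
                        penetration=pen, severity=classify_severity(pen))


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class DatasetBundle:
    """The four named phantom subsets used by the training curriculum.

    ``d_a`` carries structure and caries truth, ``d_b`` caries truth alone,
    ``d_c`` is caries-free, and ``d_d`` is the held-out evaluation set.
    """

    d_a: list[PhantomSample] = field(default_factory=list)
    d_b: list[PhantomSample] = field(default_factory=list)
    d_c: list[PhantomSample] = field(default_factory=list)
    d_d: list[PhantomSample] = field(default_factory=list)

    def subsets(self) -> dict[str, list[PhantomSample]]:
        return {"d_a": self.d_a, "d_b": self.d_b, "d_c": self.d_c, "d_d": self.d_d}

    def validate(self) -> None:
        ids: set[str] = set()
        for name, subset in self.subsets().items():
            for s in subset:
                if s.radiograph.id in ids:
                    raise ValidationError(f"duplicate sample id {s.radiograph.id!r}")
                ids.add(s.radiograph.id)
                if name == "d_c" and not s.caries.is_empty():
                    raise ValidationError("d_c must be caries-free")


# dataset sizes mirroring the clinical archive the curriculum was designed
# around: 149 structure+caries, 105 caries-only, 50 caries-free, 50 held out
DEFAULT_SIZES = (149, 105, 50, 50)


def build_dataset(spec: PhantomSpec, sizes: tuple[int, int, int, int] = DEFAULT_SIZES,
                  seed: int = 0) -> DatasetBundle:
    """Generate the four subsets with unique ids, deterministically in seed."""
    spec.validate()
    if any(n < 0 for n in sizes):
        raise ValidationError("subset sizes must be non-negative")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(sum(sizes))]
    it = iter(child_seeds)
    bundle = DatasetBundle()
    names = ("A", "B", "C", "D")
    free_spec = replace(spec, lesion_count=(0, 0))
    for name, n, target in zip(names, sizes, (bundle.d_a, bundle.d_b, bundle.d_c, bundle.d_d)):
        sub_spec = free_spec if name == "C" else spec
        for j in range(n):
            rad, struct, car, les = generate_phantom(sub_spec, next(it) % (2 ** 31))
            rad.id = f"{name}-{j:04d}"
            target.append(PhantomSample(rad, struct, car, les))
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# cross-validation folds
# ---------------------------------------------------------------------------

N_FOLDS = 6
_TRAIN, _VAL, _TEST = "train", "validation", "test"


@dataclass
class FoldPlan:
    """Six-fold rotation plan with 4:1:1 train/validation/test roles.

    ``folds[k]`` lists the sample ids in fold ``k``; ``rounds[r]`` maps each
    role to the fold indices serving it in round ``r``.  Across the six
    rounds every fold is the test fold exactly once.
    """

    folds: list[list[str]]
    rounds: list[dict[str, list[int]]]

    def role_ids(self, round_idx: int, role: str) -> list[str]:
        out: list[str] = []
        for k in self.rounds[round_idx][role]:
            out.extend(self.folds[k])
        return out

    def validate(self) -> None:
        if len(self.folds) != N_FOLDS or len(self.rounds) != N_FOLDS:
            raise ValidationError("fold plan must have exactly six folds and rounds")
        all_ids = [i for f in self.folds for i in f]
        if len(all_ids) != len(set(all_ids)):
            raise ValidationError("folds must be disjoint")
        sizes = sorted(len(f) for f in self.folds)
        if sizes[-1] - sizes[0] > 1:
            raise ValidationError("fold sizes must differ by at most one")
        tested = []
        for rd in self.rounds:
            if (len(rd[_TRAIN]), len(rd[_VAL]), len(rd[_TEST])) != (4, 1, 1):
                raise ValidationError("each round must assign folds 4:1:1")
            if sorted(rd[_TRAIN] + rd[_VAL] + rd[_TEST]) != list(range(N_FOLDS)):
                raise ValidationError("each round must use every fold exactly once")
            tested.extend(rd[_TEST])
        if sorted(tested) != list(range(N_FOLDS)):
            raise ValidationError("every fold must serve as test exactly once")


def plan_folds(ids: list[str], seed: int = 0) -> FoldPlan:
    """Partition ids into six balanced folds and build the 4:1:1 rotation.

    Ids are shuffled with the seeded generator and dealt round-robin, so with
    ``len(ids)`` not divisible by six the leading folds (in shuffle order)
    take the remainder.  Round ``r`` tests fold ``r``, validates on fold
    ``(r+1) mod 6`` and trains on the other four.
    """
    if len(set(ids)) != len(ids):
        raise ValidationError("ids must be unique")
    if len(ids) < N_FOLDS:
        raise ValidationError(f"need at least {N_FOLDS} ids, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    folds: list[list[str]] = [[] for _ in range(N_FOLDS)]
    for i, sample_id in enumerate(order):
        folds[i % N_FOLDS].append(sample_id)
    rounds = []
    for r in range(N_FOLDS):
        test, val = r, (r + 1) % N_FOLDS
        train = [k for k in range(N_FOLDS) if k not in (test, val)]
        rounds.append({_TRAIN: train, _VAL: [val], _TEST: [test]})
    plan = FoldPlan(folds=folds, rounds=rounds)
    plan.validate()
    return plan
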