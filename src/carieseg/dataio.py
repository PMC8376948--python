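"""On-disk dataset layout and readers/writers.

Layout written by :func:`write_dataset` under one directory::

    manifest.json            subset membership and sample ids
    images/<id>.png          16-bit grayscale PNG holding 12-bit counts unscaled
    structures/<id>.png      8-bit PNG with the structure label table
                             (0=background, 1=enamel, 2=dentin, 3=pulp,
                              4=metal, 5=tooth-colored, 6=gutta-percha)
    caries/<id>.png          8-bit binary PNG (0/1)
    lesions/<id>.json        lesion records with run-length encoded pixels

Round-trips are lossless: 12-bit intensities fit the 16-bit container
unchanged and masks are stored label-for-label.  A read-only grayscale DICOM
path maps clinical files onto :class:`~carieseg.types.Radiograph`.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .phantom import DatasetBundle, FoldPlan
from .types import (CariesMask, FormatError, LesionRecord, PhantomSample,
                    Radiograph, SeverityLabel, StructureMask, MAX_INTENSITY)

__all__ = [
    "write_dataset", "read_dataset", "read_dicom",
    "write_fold_plan", "read_fold_plan",
    "encode_runs", "decode_runs",
]


def encode_runs(pixel_set: frozenset[tuple[int, int]]) -> list[list[int]]:
    """Row-wise run-length encoding: sorted [row, col_start, length] triples."""
    runs = []
    by_row: dict[int, list[int]] = {}
    for r, c in pixel_set:
        by_row.setdefault(r, []).append(c)
    for r in sorted(by_row):
        cols = sorted(by_row[r])
        start = prev = cols[0]
        for c in cols[1:]:
            if c == prev + 1:
                prev = c
                continue
            runs.append([r, start, prev - start + 1])
            start = prev = c
        runs.append([r, start, prev - start + 1])
    return runs


def decode_runs(runs: list[list[int]]) -> frozenset[tuple[int, int]]:
    out = set()
    for r, start, length in runs:
        out.update((r, start + i) for i in range(length))
    return frozenset(out)


def _lesion_to_json(les: LesionRecord) -> dict:
    return {"lesion_id": les.lesion_id, "penetration": les.penetration,
            "severity": les.severity.value, "runs": encode_runs(les.pixel_set)}


def _lesion_from_json(d: dict) -> LesionRecord:
    return LesionRecord(lesion_id=d["lesion_id"],
                        pixel_set=decode_runs(d["runs"]),
                        penetration=float(d["penetration"]),
                        severity=SeverityLabel(d["severity"]))


def write_dataset(bundle: DatasetBundle, directory: str | Path) -> None:
    """Write a bundle to ``directory`` (created if needed)."""
    root = Path(directory)
    for sub in ("images", "structures", "caries", "lesions"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, samples in bundle.subsets().items():
        manifest[name] = [s.radiograph.id for s in samples]
        for s in samples:
            rid = s.radiograph.id
            iio.imwrite(root / "images" / f"{rid}.png",
                        s.radiograph.pixels.astype(np.uint16))
            iio.imwrite(root / "structures" / f"{rid}.png",
                        s.structures.labels.astype(np.uint8))
            iio.imwrite(root / "caries" / f"{rid}.png",
                        s.caries.mask.astype(np.uint8))
            (root / "lesions" / f"{rid}.json").write_text(json.dumps(
                [_lesion_to_json(l) for l in s.lesions]))
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_dataset(directory: str | Path) -> DatasetBundle:
    """Read a bundle back; raises :class:`FormatError` naming bad files."""
    root = Path(directory)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"missing manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    bundle = DatasetBundle()
    targets = bundle.subsets()
    for name, ids in manifest.items():
        if name not in targets:
            raise FormatError(f"unknown subset {name!r} in {manifest_path}")
        for rid in ids:
            img_path = root / "images" / f"{rid}.png"
            try:
                pixels = np.asarray(iio.imread(img_path))
            except FileNotFoundError as e:
                raise FormatError(f"missing image file: {img_path}") from e
            struct_path = root / "structures" / f"{rid}.png"
            caries_path = root / "caries" / f"{rid}.png"
            labels = np.asarray(iio.imread(struct_path))
            caries = np.asarray(iio.imread(caries_path))
            if labels.shape != pixels.shape:
                raise FormatError(
                    f"structure mask shape {labels.shape} != image shape "
                    f"{pixels.shape}: {struct_path}")
            if caries.shape != pixels.shape:
                raise FormatError(
                    f"caries mask shape {caries.shape} != image shape "
                    f"{pixels.shape}: {caries_path}")
            lesions = [_lesion_from_json(d) for d in
                       json.loads((root / "lesions" / f"{rid}.json").read_text())]
            try:
                sample = PhantomSample(
                    radiograph=Radiograph(pixels=pixels.astype(np.uint16), id=rid),
                    structures=StructureMask(labels=labels.astype(np.uint8)),
                    caries=CariesMask(mask=caries.astype(np.uint8)),
                    lesions=lesions)
            except ValueError as e:
                raise FormatError(f"invalid sample {rid!r}: {e}") from e
            targets[name].append(sample)
    bundle.validate()
    return bundle


def read_dicom(path: str | Path) -> Radiograph:
    """Read a grayscale DICOM file as a 12-bit radiograph.

    Intensities beyond 4095 (e.g. 16-bit exports) are rescaled into the
    12-bit range; multi-sample (color) files are rejected.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise FormatError(f"not a grayscale DICOM: {path}")
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim != 2:
        raise FormatError(f"expected a single 2-D frame: {path}")
    hi = arr.max()
    if hi > MAX_INTENSITY:
        arr = arr / hi * MAX_INTENSITY
    pixels = np.clip(np.rint(arr), 0, MAX_INTENSITY).astype(np.uint16)
    return Radiograph(pixels=pixels, id=Path(path).stem)


def write_fold_plan(plan: FoldPlan, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"folds": plan.folds, "rounds": plan.rounds}))


def read_fold_plan(path: str | Path) -> FoldPlan:
    d = json.loads(Path(path).read_text())
    plan = FoldPlan(folds=d["folds"], rounds=d["rounds"])
    plan.validate()
    return plan
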