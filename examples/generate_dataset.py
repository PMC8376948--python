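"""Generate a small phantom dataset, write it to disk and read it back.

Renders bitewing-like phantoms with ground-truth structure masks, binary
caries masks and per-lesion severity labels, assembles the four study
subsets, and demonstrates the lossless on-disk round trip plus fold
planning for six-round cross-validation.
"""

import tempfile
from pathlib import Path

from carieseg import PhantomSpec, build_dataset, plan_folds
from carieseg.dataio import read_dataset, write_dataset

spec = PhantomSpec(image_size=(128, 160), n_teeth=3, lesion_count=(1, 3))
bundle = build_dataset(spec, sizes=(8, 4, 4, 4), seed=7)

for name, samples in bundle.subsets().items():
    n_lesions = sum(len(s.lesions) for s in samples)
    sev = [l.severity.value for s in samples for l in s.lesions]
    print(f"{name}: {len(samples)} images, {n_lesions} lesions {sev}")
# d_a/d_b carry lesions; d_c is caries-free by construction; d_d is held out

with tempfile.TemporaryDirectory() as d:
    write_dataset(bundle, d)
    back = read_dataset(d)
    n_files = len(list(Path(d).rglob("*")))
    print(f"\nround trip through {n_files} files: "
          f"{len(back.d_a)}+{len(back.d_b)}+{len(back.d_c)}+{len(back.d_d)} samples restored")

ids = [s.radiograph.id for s in bundle.d_a + bundle.d_b]
plan = plan_folds(ids, seed=1)
print(f"\nfold sizes: {[len(f) for f in plan.folds]}")
print(f"round 1 roles: test folds {plan.rounds[0]['test']}, "
      f"validation {plan.rounds[0]['validation']}, train {plan.rounds[0]['train']}")
# each of the six folds serves as the test fold in exactly one round
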