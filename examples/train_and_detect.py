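"""Train the caries and structure segmenters at desk scale, then run the
fused detection pipeline on held-out phantoms.

Uses the desk-scale profile (96x96 inputs, base width 8): 48 training and
12 validation phantoms, 30 epochs for the caries net and 20 for the
structure net.  Takes a few minutes on one core.
"""

from dataclasses import replace

from carieseg import (PhantomSpec, build_model, detect_caries, generate_phantom,
                      match_components, pool_cross_validation, render_overlay, train)
from carieseg.segnet import desk_scale_configs

spec = PhantomSpec(image_size=(96, 96), n_teeth=2, lesion_count=(1, 2))
train_set = [generate_phantom(spec, s) for s in range(48)]
val_set = [generate_phantom(spec, 1000 + s) for s in range(12)]

mcfg, tcfg = desk_scale_configs(n_classes=2, seed=0)
ucs = train(build_model(mcfg), [(r, c.mask) for r, _, c, _ in train_set],
            [(r, c.mask) for r, _, c, _ in val_set], tcfg, mcfg)
print(f"U-CS: best epoch {ucs.optimal_epoch}, "
      f"best val pixel error {min(e['val_error'] for e in ucs.log):.4f}")

mcfg2, tcfg2 = desk_scale_configs(n_classes=7, seed=1)
tcfg2 = replace(tcfg2, fp_penalty=0.0, max_epochs=20)
uss = train(build_model(mcfg2), [(r, st.labels) for r, st, _, _ in train_set],
            [(r, st.labels) for r, st, _, _ in val_set], tcfg2, mcfg2)
print(f"U-SS: best epoch {uss.optimal_epoch}, "
      f"best val pixel error {min(e['val_error'] for e in uss.log):.4f}")

print()
results = []
for i, seed in enumerate(range(2000, 2016)):
    rad, _, _, lesions = generate_phantom(spec, seed)
    result = detect_caries(rad, ucs, uss, threshold=0.55)
    results.append(match_components(result.surviving, lesions, theta=0.1))
    if i < 4:  # show the first few in detail
        _, summary = render_overlay(rad, result)
        rows = ", ".join(f"{r['area_px']} px @ p={r['mean_prob']}"
                         for r in summary) or "none"
        print(f"phantom {seed}: {len(lesions)} true lesions, "
              f"{len(result.surviving)} surviving blobs ({rows}), "
              f"{len(result.eliminated)} eliminated (no enamel/dentin overlap)")

rep = pool_cross_validation(results)
print(f"\npooled over 16 held-out phantoms at theta=0.1: "
      f"precision {rep.precision:.1f}%  recall {rep.recall:.1f}%  F1 {rep.f1:.1f}%")
# precision: share of surviving blobs covering >=10% of some true lesion;
# recall: share of lesions hit by such a blob; F1: their harmonic mean
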