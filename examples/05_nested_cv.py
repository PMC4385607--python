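"""Classify a small synthetic two-class cohort with nested cross-validation.

Generates 12 subjects per class whose textures differ in correlation length
(smooth vs rough white matter), extracts the 48 texture features, and runs
the nested-CV protocol: SMOTE inside each outer training fold, best-first
forward wrapper selection scored by inner-CV macro F-measure, a 10-tree
random forest, and mean(SD) metrics over the outer folds.

Runs in a couple of minutes on one CPU; larger cohorts sharpen the estimates.
"""

import wmtex as w

subs, _ = w.generate_cohort(
    w.signal_spec(n=12, ratio=4.0, seed=5, volume_shape=(32, 32, 8))
)
table = w.extract_cohort(
    ((s.subject_id, s.label, s.volume, s.wm_mask) for s in subs), variant="riu2"
)

report = w.run_nested_cv(table, w.NestedCVConfig(seed=5))
print(report.to_text())
print("\nselected features per outer fold (first three folds):")
for sel in report.selected[:3]:
    print("  ", ", ".join(sel) or "(all features; selection degenerate)")
print("\nT is the total accuracy over outer folds, P_*/R_* per-class precision")
print("and recall, each as mean (sample SD) over the 10 outer folds; with a")
print("4x correlation-length contrast the classes separate almost perfectly.")
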