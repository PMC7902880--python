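"""Run the OCT A-line pipeline on one phantom: unfold along the lumen
border, classify tissue per column, group plaque regions, measure the
fibrous cap and flag thin-cap (TCFA) vulnerable plaque.
"""

import numpy as np

from cardiossae import octplaque, pipelines, synthgen

# train a small A-line classifier on a separate phantom set
stack = pipelines.train_aline_classifier(n_train_phantoms=6, seed=0)

# one phantom: a fibrous arc, a calcified arc, a thin-cap lipid arc, guidewire
spec = synthgen.OCTPhantomSpec(
    arcs=[(20, 80, "F", 90.0), (110, 170, "F-C", 70.0), (200, 270, "F-L", 45.0)],
    guidewire=(300, 330),
)
image, gt_labels, gt_vuln = synthgen.gen_oct_phantom(spec, seed=1)

report = octplaque.analyze_image(image, stack, gold_vulnerable_mask=gt_vuln)

print("plaque regions (half-open column spans):")
for r in report.regions:
    cap = f", min cap {r.min_cap_thickness_um:.0f} um" if r.min_cap_thickness_um else ""
    flag = "  << VULNERABLE (thin cap)" if r.vulnerable else ""
    print(f"  [{r.start_col:3d}, {r.end_col:3d}) {r.tissue_class:<4}{cap}{flag}")

acc = float(np.mean(report.labels == gt_labels))
print(f"\nper-column A-line label accuracy vs ground truth: {acc:.3f}")
m = report.metrics
print(
    f"vulnerable columns vs ground truth: dice {m.dice:.3f}, "
    f"jaccard {m.jaccard:.3f}, hausdorff {m.hausdorff_px:.1f} px"
)
# The F-L arc with a 45 um cap falls under the 65 um thin-cap threshold and
# is the only region flagged vulnerable.
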