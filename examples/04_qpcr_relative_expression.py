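"""Relative qPCR quantification by the 2^-ΔΔCt method.

Builds a triplicate Ct table for one target gene (reference GAPDH) in keloid
and normal fibroblast samples, computes relative expression against the
normal-group calibrator, and tests the group difference on the ΔCt scale.
"""

import pandas as pd

from keloidcerna import delta_delta_ct, group_comparison

rows = []
cts = {
    ("K1", "keloid"): (19.8, 20.0, 19.9),   # ~1.1 cycles below calibrator ΔCt
    ("K2", "keloid"): (20.1, 20.0, 20.2),
    ("K3", "keloid"): (19.9, 20.1, 20.0),
    ("N1", "normal"): (21.0, 21.2, 21.1),
    ("N2", "normal"): (21.1, 20.9, 21.0),
    ("N3", "normal"): (21.2, 21.0, 21.1),
}
for (sample, group), targets in cts.items():
    for rep, ct in enumerate(targets, start=1):
        rows.append({"sample_id": sample, "group": group, "target_gene": "DLEU2",
                     "reference_gene": "GAPDH", "ct_target": ct,
                     "ct_reference": 15.0 + 0.05 * (rep - 2), "replicate": rep})
table = pd.DataFrame(rows)

rel = delta_delta_ct(table, calibrator_group="normal")
print(rel.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

stats = group_comparison(table, "keloid", "normal")
row = stats.iloc[0]
print(f"\nkeloid vs normal ΔCt difference for DLEU2: "
      f"log2 ratio {row['log2_ratio']:.2f}, t = {row['tstat']:.2f}, "
      f"p = {row['pvalue']:.2g} ({'significant' if row['significant'] else 'ns'})")
print("Relative expression ~2 means the target sits about one PCR cycle")
print("earlier than the calibrator after GAPDH normalisation.")
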