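"""From per-cavity counts to SCC per mL, health status and herd orders.

The chip images a slab of 5802 × 4050 × 40 μm ≈ 0.94 μL per photograph,
which converts a mean per-image count into cells per millilitre.
"""

import numpy as np

from milkscc import (
    ChipGeometry,
    SCCResult,
    load_reference_counts,
    plan_herd,
    scc_per_ml,
)

geom = ChipGeometry()
print(f"field-of-view volume: {geom.volume_um3:.6g} um^3 = {geom.volume_ul:.2f} uL")

results = [
    SCCResult(g.group_id, float(np.mean(g.counts)),
              scc_per_ml(float(np.mean(g.counts)), geom), geom.volume_ul)
    for g in load_reference_counts()
]
plan = plan_herd(results)

for r in sorted(plan.results, key=lambda r: r.scc_per_ml)[-3:]:
    print(f"cow {r.cow_id}: {r.scc_per_ml:.3g} cells/mL -> {r.category} ({r.action})")
print("milking order  :", ", ".join(plan.milking_order))
print("treatment order:", ", ".join(plan.treatment_order))
# Healthy/suspect cows are milked cleanest-first; infected cows are
# treated sickest-first, so the worst case gets attention immediately.
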