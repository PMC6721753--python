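"""ldEV-to-leukocyte relative frequency with and without EpCAM enrichment.

Neither leukocytes nor ldEVs carry EpCAM, so immunomagnetic enrichment
retains only a tiny carryover of each; if ldEVs are retained at half the
leukocyte rate, the leukocytes-per-ldEV ratio doubles (1:3 -> 1:6).
"""

import dataclasses

import evcounter as ev

wb = ev.whole_blood_sample(seed=2)
wb = dataclasses.replace(wb, populations=tuple(
    p for p in wb.populations if p.class_name in ("leukocyte", "ldEV")))
totals = {"leukocyte": 0, "ldEV": 0}
for w in range(30):
    for p in ev.sample_well(wb, w):
        totals[p.class_name] += 1
print(f"whole blood: {totals}, leukocytes per ldEV = "
      f"{ev.relative_frequency(totals):.2f}")

enriched = ev.epcam_sample(seed=3, retention={"leukocyte": 1e-3, "ldEV": 0.5e-3})
etotals = {"leukocyte": 0, "ldEV": 0}
for w in range(3):
    for p in ev.sample_well(enriched, w):
        etotals[p.class_name] += 1
print(f"EpCAM-enriched (7.5 mL cartridges): {etotals}, leukocytes per ldEV = "
      f"{ev.relative_frequency(etotals):.2f}")
# The enriched ratio is ~2x the whole-blood ratio purely from the halved
# ldEV retention; absolute counts drop ~1000-fold.
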