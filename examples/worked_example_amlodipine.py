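"""Worked example: sizing an uncharacterized amlodipine-ritonavir interaction.

A patient on ritonavir (a near-complete CYP3A blocker) needs amlodipine.
No clinical study of that combination is at hand, but the amlodipine label
reports that diltiazem — whose inhibitory strength is known from a probe
(midazolam) study — raises amlodipine exposure by 60%. That one number pins
amlodipine's CYP3A pathway fraction, which then predicts the ritonavir
interaction.
"""

import ddiquant as dq

fixtures = dq.load_fixtures()
w = fixtures.worked_examples

# Step 1: diltiazem's inhibitor ratio, derived elsewhere from a probe study.
diltiazem_inr = w["diltiazem_inr_single_calculation"]  # 0.802

# Step 2: the label-reported +60% interaction pins amlodipine's DPI_3A.
dpi = dq.derive_dpi(w["amlodipine_auc_ratio_with_diltiazem"], diltiazem_inr)
print(f"amlodipine DPI_3A = {dpi.value:.3f}  (from AUC ratio 1.60 with diltiazem)")

# Step 3: predict the ritonavir interaction from the derived fraction.
ratio = dq.predict_inhibition_ratio(dpi.value, w["ritonavir_inr"])
cls = dq.classify_ddi(ratio)
print(f"predicted amlodipine AUC ratio with ritonavir = {ratio:.2f} ({cls.label.value} DDI)")
print(
    f"-> a ~{100 * (ratio - 1):.0f}% increase in amlodipine exposure is expected, "
    "suggesting a dose reduction of about one half"
)
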