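"""FDA magnitude classes and fold-band verification of predictions.

Predictions for tyrosine kinase inhibitors co-dosed with ritonavir are
graded into the regulatory bands, and a small predicted-vs-observed set is
scored with the symmetric 1.25/1.5/2-fold criterion.
"""

import ddiquant as dq

table = dq.fixture_parameter_table()

print("tyrosine kinase inhibitors + ritonavir (complete CYP3A blocker):")
for tki in ("ibrutinib", "dasatinib", "gefitinib", "sunitinib", "sorafenib"):
    result = dq.predict_from_table(table, tki, "ritonavir")
    print(f"  {tki:<10} predicted AUC ratio {result.ratio:6.2f}  -> {result.ddi_class.label.value}")

# Verification: how close do predictions land to observed clinical ratios?
pairs = [
    dq.VerificationPair("amlodipine", "diltiazem", "competitive_inhibition",
                        predicted=1.60, observed=1.60),
    dq.VerificationPair("saquinavir", "cimetidine", "competitive_inhibition",
                        predicted=2.21, observed=2.48),
    dq.VerificationPair("maraviroc", "ritonavir", "mechanism_based_inhibition",
                        predicted=5.80, observed=4.55),
]
summary = dq.verification_report(pairs)
print(
    f"\n{len(pairs)} predictions: {summary.pct_within_1_25:.0f}% within 1.25-fold, "
    f"{summary.pct_within_1_5:.0f}% within 1.5-fold, {summary.pct_within_2:.0f}% within 2-fold"
)
for p in summary.pairs:
    band = "outlier" if p.band == float("inf") else f"{p.band}-fold"
    print(f"  {p.victim} + {p.perpetrator}: predicted/observed {p.ratio:.2f} ({band})")
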