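# ddiquant

Quantitative prediction of CYP-mediated drug–drug interaction (DDI)
magnitudes from existing clinical pharmacokinetic data.

Most clinically relevant drug combinations — antiretroviral regimens with
comedications are the motivating case — will never get a dedicated DDI
study. `ddiquant` implements a static mechanistic model that squeezes the
studies that *do* exist for what they are worth: each victim drug is
summarized by the fraction of its disposition carried by one enzyme
(CYP3A by default), each perpetrator by its maximal ability to block or
amplify that pathway, and any victim–perpetrator combination of
characterized drugs can then be predicted, classified, and checked.

The package is a library first (`import ddiquant`), with short narrative
scripts under `examples/` and a thin `ddiquant` command-line interface for
batch use.

## The model

For a victim drug with pathway-contribution fraction `DPI` ∈ [0, 1] on
enzyme *x*, and a perpetrator with inhibitor ratio `InR` ∈ [0, 1] or
inducer ratio `IcR` ∈ [0, 1]:

```
inhibition:   AUC*/AUC = 1 / (1 − DPI·InR)
induction:    AUC*/AUC = 1 / ( DPI/(1 − IcR) + (1 − DPI) )
```

where `AUC*/AUC` is the victim's exposure ratio with vs. without the
perpetrator. Both equations invert in closed form, so an observed clinical
AUC ratio plus one known parameter yields the other:

```
DPI = (1 − 1/R) / InR        InR = (1 − 1/R) / DPI
IcR = (q − 1) / (q − 1 + DPI)          with q = 1/R
```

Calibration is anchored on a probe substrate with a well-established
pathway fraction (midazolam, `DPI_3A = 0.940`): probe studies fix the
perpetrators' `InR`/`IcR`, and those perpetrators' studies on other victims
fix the victims' `DPI`. Replicate studies of the same pair are pooled as a
subject-weighted geometric mean. When two combined drugs both inhibit the
enzyme, the stronger inhibitor ratio governs the prediction.

On top of the point calculations the package provides:

* **Monte Carlo uncertainty** (default 10,000 draws): observed ratios are
  sampled log-normally from each study's CV or CI, propagated through the
  inverse and forward equations, and summarized as geometric means with
  empirical 95% CIs (parameters clamped to [0, 1], predictions capped at
  100-fold).
* **FDA-style magnitude classes**: none (0.8–1.25), weak, moderate, strong
  (≥5-fold for inhibition, ≤0.2-fold for induction).
* **Fold-band verification**: the share of predictions within 1.25-, 1.5-
  and 2-fold of observed clinical ratios, with an optional
  predicted-vs-observed scatter plot.
* **Bundled reference values**: the published CYP3A calibration for 14
  victims, 14 perpetrators and 9 tyrosine kinase inhibitors, ready for
  prediction out of the box.
* **A synthetic-study generator** that emits noisy clinical-style records
  from known ground truth, for end-to-end parameter-recovery testing.

## Worked example

A patient stabilized on ritonavir needs amlodipine; the combination has no
dedicated DDI study. The amlodipine label reports that diltiazem (a CYP3A
inhibitor of known strength, `InR = 0.802` from a midazolam probe study)
raises amlodipine exposure by 60%:

```python
import ddiquant as dq

dpi = dq.derive_dpi(1.60, 0.802)              # amlodipine's CYP3A fraction
ratio = dq.predict_inhibition_ratio(dpi.value, 1.0)   # ritonavir: InR = 1.0
print(dpi.value, ratio, dq.classify_ddi(ratio).label.value)
```

Running `python examples/worked_example_amlodipine.py` prints:

```
amlodipine DPI_3A = 0.468  (from AUC ratio 1.60 with diltiazem)
predicted amlodipine AUC ratio with ritonavir = 1.88 (weak DDI)
-> a ~88% increase in amlodipine exposure is expected, suggesting a dose reduction of about one half
```

That is: 46.8% of amlodipine's disposition runs through CYP3A, so a
complete CYP3A block roughly doubles exposure — a weak-to-borderline
interaction manageable by halving the dose, rather than a contraindication.

The same machinery from the shell:

```
$ ddiquant predict --victim amlodipine --perpetrator ritonavir
amlodipine + ritonavir: AUC ratio 1.88 (inhibition, class weak)
$ ddiquant derive --studies studies.csv --out params.json --seed 1
$ ddiquant verify --pairs pairs.csv --out report.json --plot scatter.png
```

The other scripts in `examples/` walk through anchored calibration on a
synthetic network, Monte Carlo propagation, and classification plus
fold-band verification.

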