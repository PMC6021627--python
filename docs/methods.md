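# Methods

## Model and assumptions

`ddiquant` implements a static (steady-state) mechanistic model of
enzyme-mediated drug–drug interactions. Two numbers summarize each drug
with respect to one enzyme pathway (CYP3A throughout by default, but the
machinery is enzyme-agnostic):

* **DPI** — the fraction of the victim drug's total disposition mediated by
  the pathway. DPI = 1 means the enzyme is the sole route; DPI = 0 means it
  plays no role.
* **InR / IcR** — the perpetrator's inhibitor or inducer ratio, the
  fraction of the pathway's capacity it can remove (InR) or the degree to
  which it amplifies it (IcR). Both live in [0, 1].

The forward equations are

```
inhibition:  AUC*/AUC = 1 / (1 − DPI·InR)                      (≥ 1)
induction:   AUC*/AUC = 1 / ( DPI/(1 − IcR) + (1 − DPI) )      (in (0, 1])
```

Assumptions worth stating plainly: the interaction acts through a single
named pathway; perpetrator effects are at steady state (no dose- or
time-course resolution); competitive and mechanism-based inhibition are not
distinguished mathematically — the mechanism label is metadata for
reporting only; and everything that co-determines a clinical AUC ratio
(gut vs. liver contributions, transporters, minor pathways) is absorbed
into the two effective parameters. That absorption is also the model's
strength: parameters derived from clinical data inherit the combined
in-vivo effect rather than an in-vitro extrapolation.

Because both equations are monotone and invert in closed form, a single
observed AUC ratio plus one known parameter determines the other parameter.
Derived values are clamped to [0, 1] and the clamping is flagged
(`Derived.truncated`) and counted — a perpetrator at its potency ceiling
(e.g. a booster that fully blocks the pathway) routinely computes to
marginally above 1 from rounded inputs, and the clamp to exactly 1.0 is the
intended behavior, not an error.

## Anchored calibration

Calibration starts from a probe substrate with a well-established pathway
fraction; the default anchor is midazolam with `DPI_3A = 0.940` (both are
configurable — the probe's fraction is an external input to the method, not
something it can derive). Two fixed passes follow, so no cyclic dependency
can arise:

1. every perpetrator with a study against the probe gets its InR (or IcR,
   for induction studies) from the pooled observed ratio;
2. every other victim with a study against a pass-1 perpetrator gets a DPI
   estimate per perpetrator, and these are combined into one value.

**Pooling.** Replicate studies of the same victim–perpetrator pair are
combined as a subject-count-weighted geometric mean of their AUC ratios
(ratios are strictly positive, and all study summaries are geometric means,
so the log scale is the natural one). Mixed mechanisms within one pair are
rejected.

**Cross-perpetrator combination.** Pass-2 estimates of one victim's DPI
from different perpetrators are combined as a subject-weighted *arithmetic*
mean of the raw, unclamped estimates, clamped to [0, 1] once at the end.
A geometric mean was considered and rejected: a weak perpetrator whose
pooled ratio lands at or below 1 (easily produced by sampling noise when
the true interaction is small) yields a raw estimate ≤ 0, which a geometric
mean turns into a hard zero for the victim regardless of all other
evidence. The arithmetic mean treats such a study as what it is — weak,
possibly negative-signed evidence — and remains unbiased to first order.

Victims with no study against any calibrated perpetrator are omitted with a
logged warning. Every table entry records the references of the studies
that produced it.

**Stronger-inhibitor rule.** When the victim itself inhibits the enzyme and
the perpetrator is an inhibitor, the prediction uses the larger of the two
inhibitor ratios: a weak co-inhibitor cannot add to an inhibition the
victim already exerts on its own metabolism. `predict_from_table` applies
the rule automatically whenever the victim has a known inhibitor entry.
Ties take either value (they are interchangeable). Inducer perpetrators are
not combined with intrinsic inhibition; that interplay is out of scope.

## Monte Carlo uncertainty

Clinical variability is propagated by parametric resampling
(`MCConfig.n_draws`, default 10,000):

* **Sampling distribution.** Observed ratios are drawn log-normally,
  centered (as a geometric mean) on the reported ratio. The log-scale SD
  comes from the study's CV (`σ = sqrt(ln(1 + CV²))`), from a reported 95%
  CI (`σ = (ln U − ln L) / (2·1.96)`), or from a fallback CV (default 0.30,
  logged whenever used). Log-normality is a declared modeling choice:
  ratios are positive and reported as geometric means with skewed CIs.
* **Propagation.** Draws pass element-wise through the same inverse and
  forward equations as the point calculation. Parameter draws are clamped
  to [0, 1] with counts kept (`n_truncated`). DPI and potency draws are
  sampled independently unless they share provenance within one
  calibration; correlated multivariate sampling is out of scope.
* **Capping.** Predicted inhibition ratios are capped at `ratio_cap`
  (default 100) and induction ratios floored at `1/ratio_cap`, with counts
  kept (`n_capped`). The floor is the symmetric counterpart of the cap and
  is also what keeps the geometric-mean summary finite when an IcR draw
  clamps at exactly 1 (which would otherwise predict a ratio of 0).
* **Summaries.** Geometric mean plus the empirical 2.5th/97.5th
  percentiles. Percentile CIs are used deliberately — no distributional
  form is assumed for the pushed-forward draws.
* **Reproducibility.** One integer seed drives everything; each study gets
  its own substream keyed by a CRC-32 hash of (victim, perpetrator,
  reference), so results are independent of processing order and
  bit-identical under a fixed seed.

## Classification and verification

The regulatory magnitude bands are centralized in `classify.py`:
no interaction for ratios in (0.8, 1.25); for inhibition weak [1.25, 2.0),
moderate [2.0, 5.0), strong [5.0, ∞); for induction weak (0.5, 0.8],
moderate (0.2, 0.5], strong (0, 0.2]. The written bands touch at their
edges and no convention for boundary-exact ratios is established in the
source material, so one is declared here: intervals are half-open away from
1 (a ratio of exactly 2.0 is moderate, exactly 0.5 is moderate).
Classification is a total function of the positive ratio.

Perpetrator strength is graded by predicting the effect on a sensitive
probe victim (DPI 0.940) and classifying that ratio — so "strong inhibitor"
means "at least a 5-fold effect on a near-pure-pathway substrate".

Verification uses the symmetric fold criterion: a prediction is within
*f*-fold of an observation when predicted/observed ∈ [1/f, f], for
f = 1.25, 1.5, 2. Published verification summaries sometimes print
asymmetric empirical ranges (the extremes of a particular dataset); those
are reported extremes, not criteria, and the symmetric bands are used here.

## Bundled reference values and their checks

`fixtures.py` embeds the published CYP3A calibration: single-calculation
DPI values for 14 victims, InR/IcR for 14 perpetrators (with their Monte
Carlo geometric means and CIs), DPI values for 9 tyrosine kinase
inhibitors, the printed single-calculation prediction grids, and the
amlodipine/diltiazem/ritonavir worked example. A SHA-256 checksum test pins
these constants against drift. Diltiazem carries two provenance-tagged
potency values (0.780 in the tabulated calibration, 0.802 in the worked
example); the worked example is only reproduced by the latter, and both are
kept.

Two reproduction regimes apply in the test suite. Twelve grid cells
reproduce exactly at printed 2-decimal precision from the printed inputs
and are asserted as equalities after rounding. The remaining cells were
evidently computed upstream from unrounded internal parameters; they are
asserted within the larger of 1% relative error, half an ULP of the printed
output, and first-order propagation of the ±5·10⁻⁴ rounding of the printed
3-decimal inputs. The propagation term matters only near DPI·InR → 1, where
the predicted ratio's sensitivity to the third decimal of its inputs
exceeds 1% (the simvastatin–ritonavir cell is the extreme case).

The published Monte Carlo columns depend on per-study variance sources that
are not recoverable from the main tables; they are used only as *soft*
plausibility checks (the computed geometric means must land within 2-fold
of the published ones, and are printed for inspection), never as exact
oracles.

## Synthetic data generator

`generate_synthetic_studies` emits clinical-style study records from known
ground truth: the true AUC ratio follows the forward model and each
replicate observes it through log-normal noise at the pair's CV. What it
emulates: multiplicative study-level noise on geometric-mean ratios,
replicate studies of the same pair, subject counts for weighting, and
mixed inhibitor/inducer networks. What it does not emulate: between-study
heterogeneity beyond a shared CV, correlated errors (e.g. a shared control
arm), pathway-selectivity violations, and reporting biases. Passing
recovery tests therefore show that the calibration machinery inverts its
own forward model correctly under realistic noise — not that real clinical
networks satisfy the single-pathway assumption.

The standard recovery configuration (`default_synthetic_network`) is a
dense network of 20 victims (true DPIs spread over [0.20, 0.97]) and 10
perpetrators (8 inhibitors with InR over [0.75, 1.0], inducers at IcR 0.75
and 0.92), with 12 replicate studies of 16 subjects per pair at CV 0.15.
The replicate count was set from a first-order error budget so that the
worst per-victim calibration SD (≈ 0.013, for low-DPI victims facing the
weakest inhibitor) sits about 4σ inside the ±0.05 recovery band; this
exercises the pooling rule on every pair and keeps the whole recovery run
under a second.

## Numerical conventions and degenerate inputs

* An observed ratio of exactly 1 yields a derived parameter of exactly 0 —
  a valid "no interaction" observation, not an error.
* An inhibition-study ratio below 1 (or induction above 1) is rejected by
  default; `strict=False` clamps to 0 with a warning instead. Calibration
  uses the lenient mode internally, since pooled noisy ratios can
  legitimately cross 1 for weak interactions.
* `DPI·InR = 1` raises an explicit unbounded-ratio signal; pair-level
  prediction catches it and reports the cap with `capped=True`.
* `IcR = 1` returns the limiting induction ratio (0 for DPI > 0, 1 for
  DPI = 0) with a warning.
* Inverse round-trips hold to 1e-12 over the parameter grid away from the
  singular boundary (DPI·InR ≤ 0.999); closer to it, float cancellation
  dominates any model statement.
* Drug names are canonicalized to lower case; no synonym resolution.

## Limitations

Single-pathway attribution means the model cannot separate CYP3A from
co-affected enzymes or transporters, nor intestinal from hepatic
contributions — parameters are effective, perpetrator-class-conditional
quantities. Pairs only: multi-way interactions beyond the
stronger-inhibitor rule are not modeled. No genetics, age, organ
impairment, or dose-exposure nonlinearity. Classification is magnitude
only; it is not a dosing recommendation engine. Parameters derived from a
single perpetrator inherit that perpetrator's selectivity profile — for
narrow-therapeutic-index victims, deriving DPI from several perpetrators
and comparing is the recommended guard.
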