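"""FDA-style DDI magnitude classification and fold-band verification.

Classification follows the regulatory AUC-ratio bands: no interaction for
ratios between 0.8 and 1.25; for inhibition, weak [1.25, 2), moderate
[2, 5), strong [5, inf); for induction, weak (0.5, 0.8], moderate
(0.2, 0.5], strong (0, 0.2]. The written bands touch at their edges, so a
boundary convention is needed: intervals are half-open away from 1 (a ratio
of exactly 2.0 is moderate; exactly 0.5 is moderate). All thresholds live in
the constants below.

Verification compares predicted against observed ratios with the symmetric
1.25-, 1.5-, and 2-fold criterion: a prediction is "within f-fold" when
predicted/observed lies in [1/f, f].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence, Union

from .types import DomainError, EffectDirection, Mechanism, PerpetratorDirection
from . import equations

__all__ = [
    "DdiClassLabel",
    "DdiClass",
    "classify_ddi",
    "fold_agreement",
    "VerificationPair",
    "VerificationSummary",
    "verification_report",
    "classify_perpetrator_strength",
    "plot_verification",
    "NO_DDI_BAND",
    "INHIBITION_EDGES",
    "INDUCTION_EDGES",
    "FOLD_BANDS",
]

# Central thresholds table (AUC-ratio scale).
NO_DDI_BAND = (0.8, 1.25)  # exclusive band mapping to "none" in either direction
INHIBITION_EDGES = (1.25, 2.0, 5.0)  # weak / moderate / strong lower edges
INDUCTION_EDGES = (0.8, 0.5, 0.2)  # weak / moderate / strong upper edges
FOLD_BANDS = (1.25, 1.5, 2.0)


class DdiClassLabel(str, Enum):
    NONE = "none"
    WEAK = "weak"
    MODERATE = "moderate"
    STRONG = "strong"


@dataclass(frozen=True)
class DdiClass:
    """Magnitude class of a DDI, with the direction of the exposure change."""

    label: DdiClassLabel
    direction: EffectDirection


def classify_ddi(
    ratio: float, direction: Optional[EffectDirection] = None
) -> DdiClass:
    """Classify a (predicted or observed) AUC ratio into an FDA magnitude band.

    The label is a total function of the ratio: every positive ratio maps to
    exactly one class. ``direction`` fixes the direction recorded on the
    result; when omitted it is inferred from the ratio (>1 inhibition,
    <=1 induction).
    """
    ratio = float(ratio)
    if not math.isfinite(ratio) or ratio <= 0:
        raise DomainError(f"AUC ratio must be > 0, got {ratio!r}")
    if direction is None:
        direction = (
            EffectDirection.INHIBITION if ratio > 1 else EffectDirection.INDUCTION
        )
    elif not isinstance(direction, EffectDirection):
        direction = EffectDirection(direction)

    lo, hi = NO_DDI_BAND
    if lo < ratio < hi:
        label = DdiClassLabel.NONE
    elif ratio >= hi:
        weak, moderate, strong = INHIBITION_EDGES
        if ratio >= strong:
            label = DdiClassLabel.STRONG
        elif ratio >= moderate:
            label = DdiClassLabel.MODERATE
        else:
            label = DdiClassLabel.WEAK
    else:  # ratio <= 0.8
        weak, moderate, strong = INDUCTION_EDGES
        if ratio <= strong:
            label = DdiClassLabel.STRONG
        elif ratio <= moderate:
            label = DdiClassLabel.MODERATE
        else:
            label = DdiClassLabel.WEAK
    return DdiClass(label=label, direction=direction)


def fold_agreement(predicted: float, observed: float) -> float:
    """Smallest fold band containing predicted/observed.

    Returns 1.25, 1.5 or 2.0 — or ``math.inf`` for an outlier beyond 2-fold.
    Symmetric: ``fold_agreement(p, o) == fold_agreement(o, p)``.
    """
    predicted, observed = float(predicted), float(observed)
    if predicted <= 0 or observed <= 0:
        raise DomainError("predicted and observed ratios must be > 0")
    fold = max(predicted / observed, observed / predicted)
    for band in FOLD_BANDS:
        if fold <= band:
            return band
    return math.inf


@dataclass
class VerificationPair:
    """One predicted-vs-observed comparison."""

    victim: str
    perpetrator: str
    mechanism: Mechanism
    predicted: float
    observed: float

    def __post_init__(self) -> None:
        if not isinstance(self.mechanism, Mechanism):
            self.mechanism = Mechanism(str(self.mechanism).strip().lower())
        self.predicted = float(self.predicted)
        self.observed = float(self.observed)
        if self.predicted <= 0 or self.observed <= 0:
            raise DomainError("predicted and observed ratios must be > 0")

    @property
    def ratio(self) -> float:
        return self.predicted / self.observed

    @property
    def band(self) -> float:
        return fold_agreement(self.predicted, self.observed)


@dataclass
class VerificationSummary:
    """Per-pair fold bands plus cumulative percentages within each band."""

    pairs: list[VerificationPair]
    pct_within_1_25: float
    pct_within_1_5: float
    pct_within_2: float

    def to_dict(self) -> dict:
        return {
            "n_pairs": len(self.pairs),
            "pct_within_1_25": round(self.pct_within_1_25, 4),
            "pct_within_1_5": round(self.pct_within_1_5, 4),
            "pct_within_2": round(self.pct_within_2, 4),
            "pairs": [
                {
                    "victim": p.victim,
                    "perpetrator": p.perpetrator,
                    "mechanism": p.mechanism.value,
                    "predicted": round(p.predicted, 6),
                    "observed": round(p.observed, 6),
                    "predicted_over_observed": round(p.ratio, 6),
                    "fold_band": "outlier" if math.isinf(p.band) else p.band,
                }
                for p in self.pairs
            ],
        }


def verification_report(pairs: Sequence[VerificationPair]) -> VerificationSummary:
    """Cumulative fold-band agreement over a set of predicted/observed pairs."""
    pairs = list(pairs)
    if not pairs:
        raise DomainError("verification requires at least one predicted/observed pair")
    n = len(pairs)
    bands = [p.band for p in pairs]
    pct = lambda f: 100.0 * sum(1 for b in bands if b <= f) / n  # noqa: E731
    return VerificationSummary(
        pairs=pairs,
        pct_within_1_25=pct(1.25),
        pct_within_1_5=pct(1.5),
        pct_within_2=pct(2.0),
    )


#: Default pathway fraction of the probe substrate (midazolam) used when
#: grading a perpetrator's strength by its predicted effect on the probe.
PROBE_DPI = 0.940


def classify_perpetrator_strength(potency, probe_dpi: float = PROBE_DPI) -> DdiClassLabel:
    """Grade a perpetrator by its predicted effect on a sensitive probe substrate.

    The perpetrator's potency is applied to a probe victim (default: the
    midazolam pathway fraction of 0.940) and the resulting ratio mapped
    through :func:`classify_ddi`. A perpetrator with no measurable probe
    effect grades as ``none``.
    """
    from .types import PerpetratorPotency  # local import, avoids cycle at module load

    if isinstance(potency, PerpetratorPotency):
        direction, value = potency.direction, potency.value
    else:
        direction, value = potency
        direction = PerpetratorDirection(direction)
    if direction is PerpetratorDirection.INHIBITOR:
        try:
            ratio = equations.predict_inhibition_ratio(probe_dpi, value)
        except Exception:
            return DdiClassLabel.STRONG  # complete blockade of a pure-pathway probe
        return classify_ddi(ratio, EffectDirection.INHIBITION).label
    ratio = equations.predict_induction_ratio(probe_dpi, value)
    return classify_ddi(ratio, EffectDirection.INDUCTION).label


_MECH_MARKERS = {
    Mechanism.COMPETITIVE_INHIBITION: "s",
    Mechanism.MECHANISM_BASED_INHIBITION: "o",
    Mechanism.INDUCTION: "^",
}


def plot_verification(summary: VerificationSummary, path) -> None:
    """Predicted-vs-observed scatter with identity line and fold margins.

    Open markers by mechanism (squares: competitive inhibition, circles:
    mechanism-based inhibition, triangles: induction); dotted, dashed and
    solid gray lines mark the 1.25-, 1.5- and 2-fold margins.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for mech, marker in _MECH_MARKERS.items():
        xs = [p.observed for p in summary.pairs if p.mechanism is mech]
        ys = [p.predicted for p in summary.pairs if p.mechanism is mech]
        if xs:
            ax.scatter(
                xs, ys, marker=marker, facecolors="none", edgecolors="k",
                label=mech.value.replace("_", " "),
            )
    values = [v for p in summary.pairs for v in (p.observed, p.predicted)]
    lo, hi = 0.5 * min(values), 2.0 * max(values)
    grid = [lo, hi]
    ax.plot(grid, grid, "k-", lw=1)
    for f, style in zip(FOLD_BANDS, (":", "--", "-")):
        color = "gray" if style == "-" else "k"
        ax.plot(grid, [g * f for g in grid], style, color=color, lw=0.8)
        ax.plot(grid, [g / f for g in grid], style, color=color, lw=0.8)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("observed AUC ratio")
    ax.set_ylabel("predicted AUC ratio")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
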