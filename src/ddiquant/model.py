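"""Pooling, pair prediction, and the anchored calibration workflow.

Calibration turns a table of clinical DDI studies into a parameter table in
two fixed passes, starting from a probe substrate with a known pathway
fraction (midazolam, DPI 0.940, by default):

1. every perpetrator studied against the probe gets an InR (inhibition
   studies) or IcR (induction studies) from the pooled observed ratio;
2. every other victim studied against a pass-1 perpetrator gets a DPI from
   each such study, and the per-perpetrator estimates are combined into one
   value per victim.

Same-pair replicate studies are pooled as a subject-weighted geometric mean
of their observed ratios. Per-victim combination across different
perpetrators uses a subject-weighted arithmetic mean of the raw (unclamped)
estimates, clamped to [0, 1] at the end: a weak perpetrator whose pooled
ratio lands at or below 1 contributes a raw estimate of zero or less, which
would annihilate a geometric mean but is simply down-weighted evidence here.

When a Monte Carlo configuration is supplied, the same two passes run
element-wise over log-normal draws of every observed ratio, propagating
clinical variability into parameter draws and 95% CIs.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import defaultdict
from typing import Iterable, Optional, Sequence

import numpy as np

from . import equations, uncertainty
from .equations import effective_inhibitor_ratio
from .types import (
    DomainError,
    EffectDirection,
    InteractionStudy,
    Mechanism,
    ParameterTable,
    PathwayContribution,
    PerpetratorDirection,
    PerpetratorPotency,
    PredictionResult,
    UnboundedRatioError,
    ValidationError,
)

__all__ = [
    "pool_auc_ratio",
    "calibrate_network",
    "predict_pair",
    "predict_from_table",
    "DEFAULT_ANCHOR",
    "DEFAULT_ANCHOR_DPI",
]

log = logging.getLogger(__name__)

#: Probe substrate anchoring the calibration and its pathway fraction.
DEFAULT_ANCHOR = "midazolam"
DEFAULT_ANCHOR_DPI = 0.940


def pool_auc_ratio(studies: Sequence[InteractionStudy]) -> float:
    """Subject-weighted geometric mean of replicate studies of one drug pair.

    All studies must share victim, perpetrator and mechanism. AUC ratios are
    reported as geometric means, so replicate studies are combined on the log
    scale with the subject counts as weights.
    """
    studies = list(studies)
    if not studies:
        raise DomainError("cannot pool an empty study list")
    first = studies[0]
    for s in studies[1:]:
        if s.pair != first.pair:
            raise ValidationError(
                f"cannot pool studies of different pairs: {first.pair} vs {s.pair}"
            )
        if s.mechanism is not first.mechanism:
            raise ValidationError(
                f"cannot pool mixed mechanisms for {first.pair}: "
                f"{first.mechanism.value} vs {s.mechanism.value}"
            )
    weights = np.array([s.n_subjects for s in studies], dtype=float)
    logs = np.log([s.auc_ratio_observed for s in studies])
    return float(np.exp(np.average(logs, weights=weights)))


def _group_pairs(
    studies: Iterable[InteractionStudy],
) -> dict[tuple[str, str], list[InteractionStudy]]:
    groups: dict[tuple[str, str], list[InteractionStudy]] = defaultdict(list)
    for s in studies:
        groups[s.pair].append(s)
    for pair, grp in groups.items():
        mechs = {g.mechanism for g in grp}
        if len(mechs) > 1:
            raise ValidationError(
                f"pair {pair} has studies with mixed mechanisms: "
                f"{sorted(m.value for m in mechs)}"
            )
    return dict(groups)


def _pooled_ratio_draws(
    group: Sequence[InteractionStudy], mc: uncertainty.MCConfig
) -> np.ndarray:
    """Element-wise subject-weighted geometric mean of per-study ratio draws."""
    draws = np.stack([uncertainty.sample_observed_ratio(s, mc) for s in group])
    weights = np.array([s.n_subjects for s in group], dtype=float)
    return np.exp(np.average(np.log(draws), axis=0, weights=weights))


def calibrate_network(
    studies: Sequence[InteractionStudy],
    anchor_drug: str = DEFAULT_ANCHOR,
    anchor_dpi: float = DEFAULT_ANCHOR_DPI,
    *,
    enzyme: str = "CYP3A",
    mc: Optional[uncertainty.MCConfig] = None,
) -> ParameterTable:
    """Derive a full parameter table from clinical studies, anchored on a probe.

    Parameters
    ----------
    studies:
        Clinical DDI observations. Studies with the anchor as victim drive
        pass 1 (perpetrator potencies); all other studies involving a pass-1
        perpetrator drive pass 2 (victim pathway fractions).
    anchor_drug, anchor_dpi:
        The probe substrate and its known pathway fraction (default
        midazolam, 0.940).
    enzyme:
        Pathway label stamped on every entry (default ``"CYP3A"``).
    mc:
        Optional Monte Carlo configuration; when given, every entry also
        carries parameter draws and an empirical 95% CI.

    Returns
    -------
    ParameterTable
        With the anchor's DPI, one potency entry per usable perpetrator, and
        one DPI entry per usable victim; per-entry provenance records the
        contributing study references. Victims with no usable perpetrator
        study are omitted with a logged warning.
    """
    anchor_drug = str(anchor_drug).strip().lower()
    if not 0.0 < anchor_dpi <= 1.0:
        raise DomainError(f"anchor_dpi must lie in (0, 1], got {anchor_dpi!r}")
    groups = _group_pairs(studies)
    table = ParameterTable(default_enzyme=enzyme)
    table.add(
        PathwayContribution(drug=anchor_drug, value=anchor_dpi, enzyme=enzyme),
        references=["anchor"],
    )

    # Pass 1: perpetrator potencies from studies on the anchor.
    anchor_groups = {p: g for (v, p), g in groups.items() if v == anchor_drug}
    if not anchor_groups:
        log.warning(
            "no studies with anchor %r as victim: returning an anchor-only table",
            anchor_drug,
        )
    for perp in sorted(anchor_groups):
        group = anchor_groups[perp]
        pooled = pool_auc_ratio(group)
        refs = [s.reference for s in group]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if group[0].mechanism is Mechanism.INDUCTION:
                derived = equations.derive_icr(pooled, anchor_dpi, strict=False)
                direction = PerpetratorDirection.INDUCER
                kind = "icr"
            else:
                derived = equations.derive_inr(pooled, anchor_dpi, strict=False)
                direction = PerpetratorDirection.INHIBITOR
                kind = "inr"
        if derived.truncated:
            log.info("derived %s for %s truncated to %.3f", kind.upper(), perp, derived.value)
        samples = ci95 = None
        n_trunc = 0
        if mc is not None:
            ratio_draws = _pooled_ratio_draws(group, mc)
            samples, n_trunc = uncertainty.derive_parameter_samples(
                ratio_draws, anchor_dpi, kind
            )
            ci = np.percentile(samples, [2.5, 97.5])
            ci95 = (float(ci[0]), float(ci[1]))
        table.add(
            PerpetratorPotency(
                drug=perp,
                direction=direction,
                value=derived.value,
                enzyme=enzyme,
                samples=samples,
                ci95=ci95,
                truncated=derived.truncated,
                n_truncated=n_trunc,
            ),
            references=refs,
        )

    # Pass 2: victim pathway fractions from studies against pass-1 perpetrators.
    victims = sorted({v for (v, _p) in groups if v != anchor_drug})
    for victim in victims:
        raw_estimates: list[float] = []
        weights: list[float] = []
        refs = []
        draw_rows: list[np.ndarray] = []
        n_trunc_draws = 0
        for (v, perp), group in sorted(groups.items()):
            if v != victim or not table.has_potency(perp, enzyme):
                continue
            pot = table.potency(perp, enzyme)
            pooled = pool_auc_ratio(group)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                if pot.direction is PerpetratorDirection.INDUCER:
                    if pot.value == 0.0:
                        continue
                    q = 1.0 / pooled
                    raw = (q - 1.0) * (1.0 - pot.value) / pot.value
                    kind = "dpi_from_induction"
                else:
                    if pot.value == 0.0:
                        continue
                    raw = (1.0 - 1.0 / pooled) / pot.value
                    kind = "dpi"
            raw_estimates.append(raw)
            weights.append(sum(s.n_subjects for s in group))
            refs.extend(s.reference for s in group)
            if mc is not None:
                ratio_draws = _pooled_ratio_draws(group, mc)
                counterpart = pot.samples if pot.samples is not None else pot.value
                row, nt = uncertainty.derive_parameter_samples(ratio_draws, counterpart, kind)
                draw_rows.append(row)
                n_trunc_draws += nt
        if not raw_estimates:
            log.warning(
                "victim %r has no study against a calibrated perpetrator; omitted", victim
            )
            continue
        combined = float(np.average(raw_estimates, weights=weights))
        value = min(max(combined, 0.0), 1.0)
        truncated = value != combined
        samples = ci95 = None
        if mc is not None:
            stacked = np.average(np.stack(draw_rows), axis=0, weights=np.asarray(weights))
            samples = np.clip(stacked, 0.0, 1.0)
            ci = np.percentile(samples, [2.5, 97.5])
            ci95 = (float(ci[0]), float(ci[1]))
        table.add(
            PathwayContribution(
                drug=victim,
                value=value,
                enzyme=enzyme,
                samples=samples,
                ci95=ci95,
                truncated=truncated,
                n_truncated=n_trunc_draws,
            ),
            references=refs,
        )
    return table


def predict_pair(
    victim: PathwayContribution,
    perpetrator: PerpetratorPotency,
    victim_intrinsic: Optional[PerpetratorPotency] = None,
    *,
    config: Optional[uncertainty.MCConfig] = None,
) -> PredictionResult:
    """Predict the AUC ratio for one victim-perpetrator pair.

    The perpetrator's direction selects the inhibition or induction equation.
    When the victim itself inhibits the enzyme (``victim_intrinsic`` is an
    inhibitor potency) and the perpetrator is an inhibitor, the stronger of
    the two inhibitor ratios governs the interaction. A point prediction that
    would be unbounded is capped at ``config.ratio_cap``; Monte Carlo
    summaries are attached whenever either side carries parameter draws.
    """
    from .classify import classify_ddi  # deferred: classify imports equations

    config = config or uncertainty.MCConfig()
    if victim.enzyme != perpetrator.enzyme:
        raise ValidationError(
            f"enzyme mismatch: victim {victim.enzyme!r} vs perpetrator {perpetrator.enzyme!r}"
        )
    intrinsic_value = 0.0
    intrinsic_samples = None
    if (
        victim_intrinsic is not None
        and victim_intrinsic.direction is PerpetratorDirection.INHIBITOR
        and perpetrator.direction is PerpetratorDirection.INHIBITOR
    ):
        if victim_intrinsic.enzyme != victim.enzyme:
            raise ValidationError("enzyme mismatch between victim DPI and intrinsic potency")
        intrinsic_value = victim_intrinsic.value
        intrinsic_samples = victim_intrinsic.samples

    capped = False
    if perpetrator.direction is PerpetratorDirection.INHIBITOR:
        direction = EffectDirection.INHIBITION
        potency_used = effective_inhibitor_ratio(perpetrator.value, intrinsic_value)
        try:
            ratio = equations.predict_inhibition_ratio(victim.value, potency_used)
        except UnboundedRatioError:
            ratio = float(config.ratio_cap)
            capped = True
        if ratio > config.ratio_cap:
            ratio = float(config.ratio_cap)
            capped = True
    else:
        direction = EffectDirection.INDUCTION
        potency_used = perpetrator.value
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ratio = equations.predict_induction_ratio(victim.value, potency_used)
        if ratio < 1.0 / config.ratio_cap:
            ratio = 1.0 / config.ratio_cap
            capped = True

    mc_summary = None
    if victim.samples is not None or perpetrator.samples is not None:
        dpi_draws = victim.samples if victim.samples is not None else victim.value
        pot_draws = (
            perpetrator.samples if perpetrator.samples is not None else perpetrator.value
        )
        if perpetrator.direction is PerpetratorDirection.INHIBITOR and (
            intrinsic_value > 0 or intrinsic_samples is not None
        ):
            other = intrinsic_samples if intrinsic_samples is not None else intrinsic_value
            pot_draws = np.maximum(np.atleast_1d(pot_draws), np.atleast_1d(other))
        mc_summary = uncertainty.predict_distribution(
            dpi_draws, pot_draws, perpetrator.direction, config
        )

    return PredictionResult(
        victim=victim.drug,
        perpetrator=perpetrator.drug,
        ratio=ratio,
        direction=direction,
        ddi_class=classify_ddi(ratio, direction),
        enzyme=victim.enzyme,
        capped=capped,
        mc=mc_summary,
        potency_used=potency_used,
    )


def predict_from_table(
    table: ParameterTable,
    victim: str,
    perpetrator: str,
    *,
    enzyme: Optional[str] = None,
    config: Optional[uncertainty.MCConfig] = None,
) -> PredictionResult:
    """Predict a pair from a calibrated parameter table.

    Looks up the victim's DPI and the perpetrator's potency, and — when the
    victim is itself a known inhibitor of the enzyme — applies the
    stronger-inhibitor rule automatically.
    """
    enzyme = enzyme or table.default_enzyme
    dpi = table.dpi(victim, enzyme)
    potency = table.potency(perpetrator, enzyme)
    intrinsic = None
    if table.has_potency(victim, enzyme):
        candidate = table.potency(victim, enzyme)
        if candidate.direction is PerpetratorDirection.INHIBITOR:
            intrinsic = candidate
    return predict_pair(dpi, potency, intrinsic, config=config)
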