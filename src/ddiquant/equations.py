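"""Closed-form equations of the static DDI model.

The model describes the change in a victim drug's exposure (AUC*/AUC) caused
by a perpetrator acting on a single metabolic pathway (here usually CYP3A):

* inhibition:  ``AUC*/AUC = 1 / (1 - DPI * InR)``
* induction:   ``AUC*/AUC = 1 / (DPI / (1 - IcR) + (1 - DPI))``

where DPI in [0, 1] is the fraction of the victim's disposition mediated by
the pathway, and InR/IcR in [0, 1] is the perpetrator's maximal inhibitory or
inductive potency on that pathway. Each forward equation has a closed-form
inverse used to derive a parameter from an observed clinical AUC ratio:

* ``DPI = (1 - 1/R) / InR``             (inhibition study, known InR)
* ``InR = (1 - 1/R) / DPI``             (inhibition study, known DPI)
* ``IcR = (q - 1) / (q - 1 + DPI)``     (induction study, known DPI; q = 1/R)
* ``DPI = (q - 1)(1 - IcR) / IcR``      (induction study, known IcR; q = 1/R)

Derived parameters falling outside [0, 1] — sampling noise or a perpetrator at
its potency ceiling can push them past the bound — are clamped, and the
clamping is reported through the ``truncated`` flag of :class:`Derived`.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np

from .types import DomainError, UnboundedRatioError, _check_fraction

__all__ = [
    "Derived",
    "predict_inhibition_ratio",
    "predict_induction_ratio",
    "derive_dpi",
    "derive_inr",
    "derive_icr",
    "derive_dpi_from_induction",
    "effective_inhibitor_ratio",
]


class Derived(NamedTuple):
    """A derived model parameter with its truncation flag."""

    value: float
    truncated: bool


def predict_inhibition_ratio(dpi: float, inr: float) -> float:
    """Predicted AUC*/AUC when an inhibitor blocks a fraction ``inr`` of a
    pathway carrying a fraction ``dpi`` of the victim's disposition.

    Returns ``1 / (1 - dpi * inr)``, always >= 1.

    Raises
    ------
    DomainError
        If either argument lies outside [0, 1].
    UnboundedRatioError
        If ``dpi * inr`` reaches 1 (complete shutdown of the sole disposition
        pathway); callers that tolerate this cap the ratio instead.
    """
    dpi = _check_fraction(dpi, "dpi")
    inr = _check_fraction(inr, "inr")
    denom = 1.0 - dpi * inr
    if denom <= 0.0:
        raise UnboundedRatioError(
            f"dpi*inr = {dpi * inr:g} >= 1: predicted inhibition ratio is unbounded"
        )
    return 1.0 / denom


def predict_induction_ratio(dpi: float, icr: float) -> float:
    """Predicted AUC*/AUC when an inducer amplifies the pathway's capacity.

    Returns ``1 / (dpi / (1 - icr) + (1 - dpi))``, always in (0, 1].

    At ``icr == 1`` (complete induction) the expression degenerates; the limit
    is returned with a warning: 0 for any ``dpi > 0``, 1 for ``dpi == 0``.
    """
    dpi = _check_fraction(dpi, "dpi")
    icr = _check_fraction(icr, "icr")
    if icr == 1.0:
        warnings.warn(
            "icr = 1 (complete induction): returning the limiting ratio",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0 if dpi == 0.0 else 0.0
    return 1.0 / (dpi / (1.0 - icr) + (1.0 - dpi))


def _clamp_fraction(raw: float) -> Derived:
    if raw < 0.0:
        return Derived(0.0, True)
    if raw > 1.0:
        return Derived(1.0, True)
    return Derived(float(raw), False)


def _check_inhibition_ratio(auc_ratio: float, strict: bool) -> float:
    auc_ratio = float(auc_ratio)
    if not np.isfinite(auc_ratio) or auc_ratio <= 0:
        raise DomainError(f"auc_ratio must be > 0, got {auc_ratio!r}")
    if auc_ratio < 1.0:
        msg = (
            f"observed AUC ratio {auc_ratio:g} < 1 for an inhibition study; "
            "the derived parameter would be negative (clamped to 0)"
        )
        if strict:
            raise DomainError(msg + "; pass strict=False to clamp instead")
        warnings.warn(msg, RuntimeWarning, stacklevel=3)
    return auc_ratio


def _check_induction_ratio(auc_ratio: float, strict: bool) -> float:
    auc_ratio = float(auc_ratio)
    if not np.isfinite(auc_ratio) or auc_ratio <= 0:
        raise DomainError(f"auc_ratio must be > 0, got {auc_ratio!r}")
    if auc_ratio > 1.0:
        msg = (
            f"observed AUC ratio {auc_ratio:g} > 1 for an induction study; "
            "the derived parameter would be negative (clamped to 0)"
        )
        if strict:
            raise DomainError(msg + "; pass strict=False to clamp instead")
        warnings.warn(msg, RuntimeWarning, stacklevel=3)
    return auc_ratio


def derive_dpi(auc_ratio_observed: float, inr: float, *, strict: bool = True) -> Derived:
    """Derive a victim's pathway fraction from an observed inhibition study.

    ``DPI = (1 - 1/R) / InR`` with R the observed AUC ratio. The result is
    clamped to [0, 1]; :attr:`Derived.truncated` records whether clamping
    occurred. An observed ratio below 1 is rejected (``strict=True``, default)
    or clamped with a warning (``strict=False``).
    """
    auc_ratio_observed = _check_inhibition_ratio(auc_ratio_observed, strict)
    inr = _check_fraction(inr, "inr")
    if inr == 0.0:
        raise DomainError("inr = 0: DPI is undefined for a non-inhibitor perpetrator")
    return _clamp_fraction((1.0 - 1.0 / auc_ratio_observed) / inr)


def derive_inr(auc_ratio_observed: float, dpi: float, *, strict: bool = True) -> Derived:
    """Derive a perpetrator's inhibitor ratio from a study on a probe victim.

    ``InR = (1 - 1/R) / DPI``; clamped to [0, 1] with a truncation flag (a
    perpetrator at its ceiling — e.g. a fully CYP3A-blocking booster — can
    compute marginally above 1 from rounded inputs).
    """
    auc_ratio_observed = _check_inhibition_ratio(auc_ratio_observed, strict)
    dpi = _check_fraction(dpi, "dpi")
    if dpi == 0.0:
        raise DomainError("dpi = 0: InR is undefined for a victim not using the pathway")
    return _clamp_fraction((1.0 - 1.0 / auc_ratio_observed) / dpi)


def derive_icr(auc_ratio_observed: float, dpi: float, *, strict: bool = True) -> Derived:
    """Derive a perpetrator's inducer ratio from a study on a probe victim.

    Algebraic inverse of the induction equation: with ``q = 1/R``,
    ``IcR = (q - 1) / (q - 1 + DPI)``. Clamped to [0, 1] with a flag.
    """
    auc_ratio_observed = _check_induction_ratio(auc_ratio_observed, strict)
    dpi = _check_fraction(dpi, "dpi")
    if dpi == 0.0:
        raise DomainError("dpi = 0: IcR is undefined for a victim not using the pathway")
    q = 1.0 / auc_ratio_observed
    return _clamp_fraction((q - 1.0) / (q - 1.0 + dpi))


def derive_dpi_from_induction(
    auc_ratio_observed: float, icr: float, *, strict: bool = True
) -> Derived:
    """Derive a victim's pathway fraction from an observed induction study.

    Inverse of the induction equation for known inducer potency: with
    ``q = 1/R``, ``DPI = (q - 1)(1 - IcR) / IcR``. Clamped to [0, 1].
    """
    auc_ratio_observed = _check_induction_ratio(auc_ratio_observed, strict)
    icr = _check_fraction(icr, "icr")
    if icr == 0.0:
        raise DomainError("icr = 0: DPI is undefined for a non-inducer perpetrator")
    q = 1.0 / auc_ratio_observed
    return _clamp_fraction((q - 1.0) * (1.0 - icr) / icr)


def effective_inhibitor_ratio(inr_perpetrator: float, inr_victim_intrinsic: float) -> float:
    """Effective InR when both drugs of a pair inhibit the pathway.

    When the victim is itself an inhibitor of the enzyme (e.g. a boosted
    protease inhibitor), the weaker perpetrator cannot add to an inhibition
    the victim already exerts; the stronger of the two inhibitor ratios
    governs the interaction. Pass 0 for a victim with no inhibitory potency.
    """
    a = _check_fraction(inr_perpetrator, "inr_perpetrator")
    b = _check_fraction(inr_victim_intrinsic, "inr_victim_intrinsic")
    return max(a, b)
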