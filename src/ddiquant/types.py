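"""Domain types for clinical drug-drug interaction (DDI) records and model parameters.

The central objects are:

* :class:`InteractionStudy` — one clinical DDI observation: a victim drug whose
  exposure (AUC) changes, the perpetrator causing the change, the mechanism, and
  the observed geometric-mean AUC ratio with its dispersion.
* :class:`PathwayContribution` — a victim drug's fraction of disposition mediated
  by a named enzyme pathway (DPI), a number in [0, 1].
* :class:`PerpetratorPotency` — a perpetrator's inhibitor ratio (InR) or inducer
  ratio (IcR) for a named enzyme, a number in [0, 1] with a direction.
* :class:`ParameterTable` — a keyed collection of the above with per-entry
  provenance, the unit of serialization for calibrated networks.
* :class:`PredictionResult` — a predicted AUC ratio with its FDA magnitude class
  and, when Monte Carlo draws were available, an uncertainty summary.

Drug identifiers are canonicalized to lower-case stripped strings throughout;
no synonym resolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Mechanism",
    "PerpetratorDirection",
    "EffectDirection",
    "Role",
    "InteractionStudy",
    "PathwayContribution",
    "PerpetratorPotency",
    "ParameterTable",
    "PredictionResult",
    "DomainError",
    "ValidationError",
    "UnboundedRatioError",
]


class DomainError(ValueError):
    """An input is outside the mathematical domain of the model equations."""


class ValidationError(ValueError):
    """A record or table failed structural validation."""


class UnboundedRatioError(ArithmeticError):
    """DPI x InR reached 1: the predicted inhibition ratio is unbounded.

    Callers that tolerate this (Monte Carlo prediction, ``predict_pair``)
    catch the signal and apply the configured ratio cap.
    """


class Mechanism(str, Enum):
    """Mechanism of a clinical DDI study.

    Competitive and mechanism-based inhibition share the same steady-state
    ratio equation in this model; the distinction is carried as metadata for
    reporting and plot symbols only.
    """

    COMPETITIVE_INHIBITION = "competitive_inhibition"
    MECHANISM_BASED_INHIBITION = "mechanism_based_inhibition"
    INDUCTION = "induction"

    @property
    def is_inhibition(self) -> bool:
        return self is not Mechanism.INDUCTION


class PerpetratorDirection(str, Enum):
    """Whether a perpetrator blocks (inhibitor) or amplifies (inducer) the pathway."""

    INHIBITOR = "inhibitor"
    INDUCER = "inducer"


class EffectDirection(str, Enum):
    """Direction of an exposure change: ratio above 1 (inhibition) or below (induction)."""

    INHIBITION = "inhibition"
    INDUCTION = "induction"


class Role(str, Enum):
    """Role of a parameter-table entry."""

    VICTIM_DPI = "victim_dpi"
    INHIBITOR_INR = "inhibitor_inr"
    INDUCER_ICR = "inducer_icr"


def _canon(name: str) -> str:
    return str(name).strip().lower()


def _check_fraction(value: float, name: str) -> float:
    value = float(value)
    if not np.isfinite(value) or not 0.0 <= value <= 1.0:
        raise DomainError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass
class InteractionStudy:
    """One clinical DDI observation.

    Parameters
    ----------
    victim, perpetrator:
        Drug identifiers (canonicalized to lower case).
    mechanism:
        ``competitive_inhibition``, ``mechanism_based_inhibition`` or ``induction``.
    auc_ratio_observed:
        Geometric-mean AUC*/AUC of the victim with vs. without the perpetrator
        (> 0; above 1 for inhibition, below 1 for induction).
    cv:
        Optional coefficient of variation (as a fraction, e.g. 0.3) of the
        observed ratio.
    ci:
        Optional 95% confidence-interval pair ``(lower, upper)`` on the ratio.
    n_subjects:
        Number of subjects in the study (weighting for multi-study pooling).
    reference:
        Free-text citation label.
    """

    victim: str
    perpetrator: str
    mechanism: Mechanism
    auc_ratio_observed: float
    cv: Optional[float] = None
    ci: Optional[tuple[float, float]] = None
    n_subjects: int = 1
    reference: str = ""

    def __post_init__(self) -> None:
        self.victim = _canon(self.victim)
        self.perpetrator = _canon(self.perpetrator)
        if not isinstance(self.mechanism, Mechanism):
            try:
                self.mechanism = Mechanism(_canon(self.mechanism))
            except ValueError:
                raise ValidationError(
                    f"unknown mechanism {self.mechanism!r}; expected one of "
                    f"{[m.value for m in Mechanism]}"
                ) from None
        self.auc_ratio_observed = float(self.auc_ratio_observed)
        if not np.isfinite(self.auc_ratio_observed) or self.auc_ratio_observed <= 0:
            raise ValidationError(
                f"auc_ratio_observed must be > 0, got {self.auc_ratio_observed!r}"
            )
        if self.cv is not None:
            self.cv = float(self.cv)
            if not self.cv > 0:
                raise ValidationError(f"cv must be > 0, got {self.cv!r}")
        if self.ci is not None:
            lo, hi = (float(self.ci[0]), float(self.ci[1]))
            if not (0 < lo < hi):
                raise ValidationError(f"ci must satisfy 0 < lower < upper, got {self.ci!r}")
            self.ci = (lo, hi)
        self.n_subjects = int(self.n_subjects)
        if self.n_subjects < 1:
            raise ValidationError(f"n_subjects must be >= 1, got {self.n_subjects!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.victim, self.perpetrator)


def _check_samples(samples, name: str):
    if samples is None:
        return None
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError(f"{name}.samples must be a nonempty 1-d vector")
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValidationError(f"{name}.samples must all lie in [0, 1]")
    return arr


def _check_ci(ci, name: str):
    if ci is None:
        return None
    lo, hi = float(ci[0]), float(ci[1])
    if lo > hi:
        raise ValidationError(f"{name}.ci95 must be ordered (lower <= upper), got {ci!r}")
    return (lo, hi)


@dataclass
class PathwayContribution:
    """Fraction of a victim drug's disposition mediated by one enzyme (DPI)."""

    drug: str
    value: float
    enzyme: str = "CYP3A"
    samples: Optional[np.ndarray] = None
    ci95: Optional[tuple[float, float]] = None
    truncated: bool = False
    n_truncated: int = 0

    def __post_init__(self) -> None:
        self.drug = _canon(self.drug)
        self.value = _check_fraction(self.value, f"DPI({self.drug})")
        self.samples = _check_samples(self.samples, f"DPI({self.drug})")
        self.ci95 = _check_ci(self.ci95, f"DPI({self.drug})")


@dataclass
class PerpetratorPotency:
    """A perpetrator's inhibitor ratio (InR) or inducer ratio (IcR) for one enzyme."""

    drug: str
    direction: PerpetratorDirection
    value: float
    enzyme: str = "CYP3A"
    samples: Optional[np.ndarray] = None
    ci95: Optional[tuple[float, float]] = None
    truncated: bool = False
    n_truncated: int = 0

    def __post_init__(self) -> None:
        self.drug = _canon(self.drug)
        if not isinstance(self.direction, PerpetratorDirection):
            self.direction = PerpetratorDirection(_canon(self.direction))
        label = "InR" if self.direction is PerpetratorDirection.INHIBITOR else "IcR"
        self.value = _check_fraction(self.value, f"{label}({self.drug})")
        self.samples = _check_samples(self.samples, f"{label}({self.drug})")
        self.ci95 = _check_ci(self.ci95, f"{label}({self.drug})")

    @property
    def role(self) -> Role:
        if self.direction is PerpetratorDirection.INHIBITOR:
            return Role.INHIBITOR_INR
        return Role.INDUCER_ICR


class ParameterTable:
    """Keyed collection of calibrated DPI and InR/IcR entries with provenance.

    Entries are keyed by ``(drug, enzyme, role)``; at most one entry per key.
    """

    def __init__(self, default_enzyme: str = "CYP3A") -> None:
        self.default_enzyme = default_enzyme
        self._entries: dict[tuple[str, str, Role], object] = {}
        self.provenance: dict[tuple[str, str, Role], list[str]] = {}

    def add(self, entry, references: Sequence[str] = ()) -> None:
        """Add a :class:`PathwayContribution` or :class:`PerpetratorPotency`."""
        if isinstance(entry, PathwayContribution):
            role = Role.VICTIM_DPI
        elif isinstance(entry, PerpetratorPotency):
            role = entry.role
        else:  # pragma: no cover - programming error
            raise TypeError(f"unsupported entry type {type(entry)!r}")
        key = (entry.drug, entry.enzyme, role)
        if key in self._entries:
            raise ValidationError(f"duplicate parameter-table entry for {key}")
        self._entries[key] = entry
        self.provenance[key] = list(references)

    # -- lookups ----------------------------------------------------------

    def dpi(self, drug: str, enzyme: Optional[str] = None) -> PathwayContribution:
        enzyme = enzyme or self.default_enzyme
        key = (_canon(drug), enzyme, Role.VICTIM_DPI)
        try:
            return self._entries[key]  # type: ignore[return-value]
        except KeyError:
            known = sorted(self.victims(enzyme))
            raise KeyError(
                f"no DPI entry for drug {drug!r} / enzyme {enzyme!r}; known victims: {known}"
            ) from None

    def potency(self, drug: str, enzyme: Optional[str] = None) -> PerpetratorPotency:
        enzyme = enzyme or self.default_enzyme
        drug = _canon(drug)
        for role in (Role.INHIBITOR_INR, Role.INDUCER_ICR):
            entry = self._entries.get((drug, enzyme, role))
            if entry is not None:
                return entry  # type: ignore[return-value]
        known = sorted(self.perpetrators(enzyme))
        raise KeyError(
            f"no InR/IcR entry for drug {drug!r} / enzyme {enzyme!r}; known perpetrators: {known}"
        )

    def has_dpi(self, drug: str, enzyme: Optional[str] = None) -> bool:
        enzyme = enzyme or self.default_enzyme
        return (_canon(drug), enzyme, Role.VICTIM_DPI) in self._entries

    def has_potency(self, drug: str, enzyme: Optional[str] = None) -> bool:
        enzyme = enzyme or self.default_enzyme
        drug = _canon(drug)
        return any(
            (drug, enzyme, role) in self._entries
            for role in (Role.INHIBITOR_INR, Role.INDUCER_ICR)
        )

    def victims(self, enzyme: Optional[str] = None) -> list[str]:
        enzyme = enzyme or self.default_enzyme
        return [d for (d, e, r) in self._entries if e == enzyme and r is Role.VICTIM_DPI]

    def perpetrators(self, enzyme: Optional[str] = None) -> list[str]:
        enzyme = enzyme or self.default_enzyme
        return [
            d
            for (d, e, r) in self._entries
            if e == enzyme and r in (Role.INHIBITOR_INR, Role.INDUCER_ICR)
        ]

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[tuple[tuple[str, str, Role], object]]:
        return iter(sorted(self._entries.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value)))

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParameterTable):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    # -- serialization ----------------------------------------------------

    def to_dict(self, include_samples: bool = False) -> dict:
        """JSON-ready representation; MC draw vectors are omitted by default."""
        entries = []
        for (drug, enzyme, role), entry in self:
            rec: dict = {
                "drug": drug,
                "enzyme": enzyme,
                "role": role.value,
                "value": round(float(entry.value), 12),
                "ci95": list(entry.ci95) if entry.ci95 is not None else None,
                "truncated": bool(entry.truncated),
                "n_truncated": int(entry.n_truncated),
                "references": self.provenance.get((drug, enzyme, role), []),
            }
            if role is not Role.VICTIM_DPI:
                rec["direction"] = entry.direction.value
            if include_samples and entry.samples is not None:
                rec["samples"] = [float(x) for x in entry.samples]
            entries.append(rec)
        return {"default_enzyme": self.default_enzyme, "entries": entries}

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ParameterTable":
        table = cls(default_enzyme=payload.get("default_enzyme", "CYP3A"))
        for rec in payload["entries"]:
            role = Role(rec["role"])
            common = dict(
                drug=rec["drug"],
                value=rec["value"],
                enzyme=rec.get("enzyme", table.default_enzyme),
                samples=rec.get("samples"),
                ci95=tuple(rec["ci95"]) if rec.get("ci95") else None,
                truncated=rec.get("truncated", False),
                n_truncated=rec.get("n_truncated", 0),
            )
            if role is Role.VICTIM_DPI:
                entry: object = PathwayContribution(**common)
            else:
                direction = (
                    PerpetratorDirection.INHIBITOR
                    if role is Role.INHIBITOR_INR
                    else PerpetratorDirection.INDUCER
                )
                entry = PerpetratorPotency(direction=direction, **common)
            table.add(entry, rec.get("references", []))
        return table


@dataclass
class PredictionResult:
    """A predicted AUC ratio for one victim-perpetrator pair.

    ``ratio`` is the single (point) calculation; ``mc`` carries the Monte Carlo
    geometric mean and 95% CI when parameter draws were available. ``capped``
    flags a point prediction that hit the configured ratio cap.
    """

    victim: str
    perpetrator: str
    ratio: float
    direction: EffectDirection
    ddi_class: "object"  # classify.DdiClass; kept loose to avoid an import cycle
    enzyme: str = "CYP3A"
    capped: bool = False
    mc: Optional[object] = None  # uncertainty.McSummary
    potency_used: Optional[float] = None

    def to_dict(self) -> dict:
        out = {
            "victim": self.victim,
            "perpetrator": self.perpetrator,
            "enzyme": self.enzyme,
            "auc_ratio": round(float(self.ratio), 6),
            "direction": self.direction.value,
            "ddi_class": getattr(self.ddi_class, "label", self.ddi_class).value
            if self.ddi_class is not None
            else None,
            "capped": self.capped,
            "potency_used": self.potency_used,
        }
        if self.mc is not None:
            out["mc"] = self.mc.to_dict()
        return out
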