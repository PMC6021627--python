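"""Readers/writers for study and parameter tables, and a synthetic-study generator.

Study tables are flat CSV or JSON with columns/keys ``victim``,
``perpetrator``, ``mechanism``, ``auc_ratio``, optional ``cv`` or
``ci_lower``/``ci_upper``, ``n_subjects`` and ``reference``. Parameter
tables serialize to JSON keyed by (drug, enzyme, role), with point values,
CIs, truncation flags and provenance; raw Monte Carlo draw vectors are
dropped on write (summaries are kept).

The synthetic generator emits study records from known ground-truth
parameters with log-normal noise, enabling end-to-end parameter-recovery
tests without any external data.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import equations
from .types import (
    DomainError,
    InteractionStudy,
    Mechanism,
    ParameterTable,
    PerpetratorDirection,
    ValidationError,
)

__all__ = [
    "read_study_table",
    "write_study_table",
    "write_parameter_table",
    "read_parameter_table",
    "PairDesign",
    "SyntheticSpec",
    "generate_synthetic_studies",
    "default_synthetic_network",
]

_STUDY_COLUMNS = [
    "victim",
    "perpetrator",
    "mechanism",
    "auc_ratio",
    "cv",
    "ci_lower",
    "ci_upper",
    "n_subjects",
    "reference",
]
_REQUIRED_COLUMNS = {"victim", "perpetrator", "mechanism", "auc_ratio", "n_subjects"}


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise ValidationError(f"cannot infer table format from {path.name!r}; pass fmt=")


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or value == ""


def _row_to_study(row: dict, label: str, errors: list[str]) -> Optional[InteractionStudy]:
    missing = [c for c in _REQUIRED_COLUMNS if _is_missing(row.get(c))]
    if missing:
        errors.append(f"{label}: missing required column(s) {sorted(missing)}")
        return None
    ci = None
    lo, hi = row.get("ci_lower"), row.get("ci_upper")
    if not _is_missing(lo) or not _is_missing(hi):
        if _is_missing(lo) or _is_missing(hi):
            errors.append(f"{label}: ci_lower and ci_upper must be given together")
            return None
        ci = (lo, hi)
    cv = None if _is_missing(row.get("cv")) else row.get("cv")
    try:
        return InteractionStudy(
            victim=row["victim"],
            perpetrator=row["perpetrator"],
            mechanism=row["mechanism"],
            auc_ratio_observed=row["auc_ratio"],
            cv=cv,
            ci=ci,
            n_subjects=row["n_subjects"],
            reference="" if _is_missing(row.get("reference")) else str(row["reference"]),
        )
    except (ValidationError, ValueError, TypeError) as exc:
        errors.append(f"{label}: {exc}")
        return None


def read_study_table(path: Union[str, Path], fmt: Optional[str] = None) -> list[InteractionStudy]:
    """Read and validate a study table from CSV or JSON.

    Malformed rows are reported together, each naming its row number.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        frame = pd.read_csv(path)
        rows = frame.to_dict(orient="records")
    elif fmt == "json":
        payload = json.loads(path.read_text())
        if not isinstance(payload, list):
            raise ValidationError(f"{path.name}: JSON study table must be a list of records")
        rows = payload
    else:
        raise ValidationError(f"unsupported study-table format {fmt!r}")
    studies: list[InteractionStudy] = []
    errors: list[str] = []
    for i, row in enumerate(rows):
        study = _row_to_study(dict(row), f"{path.name} row {i + 1}", errors)
        if study is not None:
            studies.append(study)
    if errors:
        raise ValidationError("invalid study table:\n  " + "\n  ".join(errors))
    return studies


def write_study_table(
    studies: Sequence[InteractionStudy], path: Union[str, Path], fmt: Optional[str] = None
) -> None:
    """Write studies as CSV or JSON, round-trippable through :func:`read_study_table`."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    records = [
        {
            "victim": s.victim,
            "perpetrator": s.perpetrator,
            "mechanism": s.mechanism.value,
            "auc_ratio": s.auc_ratio_observed,
            "cv": s.cv,
            "ci_lower": s.ci[0] if s.ci else None,
            "ci_upper": s.ci[1] if s.ci else None,
            "n_subjects": s.n_subjects,
            "reference": s.reference,
        }
        for s in studies
    ]
    if fmt == "csv":
        pd.DataFrame(records, columns=_STUDY_COLUMNS).to_csv(path, index=False)
    else:
        path.write_text(json.dumps(records, indent=1, sort_keys=True) + "\n")


def _package_meta(config=None) -> dict:
    from . import __version__

    meta = {"package": "ddiquant", "version": __version__}
    if config is not None:
        meta["config"] = config.to_dict()
    return meta


def write_parameter_table(
    table: ParameterTable,
    path: Union[str, Path],
    *,
    include_samples: bool = False,
    config=None,
) -> None:
    """Serialize a parameter table to JSON (sorted keys, diff-stable).

    Raw MC draw vectors are omitted unless ``include_samples`` is set;
    summaries (CIs, truncation counts) are always kept. The file embeds the
    package version and, when given, the Monte Carlo configuration used.
    """
    payload = {"meta": _package_meta(config), **table.to_dict(include_samples=include_samples)}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_parameter_table(path: Union[str, Path]) -> ParameterTable:
    """Read a parameter table written by :func:`write_parameter_table`."""
    payload = json.loads(Path(path).read_text())
    return ParameterTable.from_dict(payload)


# ---------------------------------------------------------------------------
# Synthetic clinical-study generation


@dataclass(frozen=True)
class PairDesign:
    """Design of the replicate studies for one victim-perpetrator pair."""

    n_subjects: int = 16
    cv: float = 0.15
    n_studies: int = 1

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_studies < 1:
            raise ValidationError("n_subjects and n_studies must be >= 1")
        if self.cv < 0:
            raise ValidationError("cv must be >= 0")


@dataclass
class SyntheticSpec:
    """Ground truth and design for a synthetic interaction network.

    ``true_dpis`` maps each victim to its pathway fraction; ``true_potencies``
    maps each perpetrator to ``(direction, value)``; ``study_design`` maps
    each (victim, perpetrator) pair to its :class:`PairDesign`. Generation is
    deterministic under ``seed``.
    """

    true_dpis: dict[str, float]
    true_potencies: dict[str, tuple[PerpetratorDirection, float]]
    study_design: dict[tuple[str, str], PairDesign]
    seed: int = 0

    def __post_init__(self) -> None:
        for drug, dpi in self.true_dpis.items():
            if not 0.0 <= dpi <= 1.0:
                raise ValidationError(f"true DPI of {drug!r} must lie in [0, 1]")
        normalized = {}
        for drug, (direction, value) in self.true_potencies.items():
            direction = PerpetratorDirection(direction)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"true potency of {drug!r} must lie in [0, 1]")
            normalized[drug] = (direction, float(value))
        self.true_potencies = normalized


def _pair_rng(seed: int, victim: str, perp: str) -> np.random.Generator:
    key = zlib.crc32(f"{victim}|{perp}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def generate_synthetic_studies(spec: SyntheticSpec) -> list[InteractionStudy]:
    """Emit noisy study records from ground-truth parameters.

    For each designed pair the true AUC ratio follows the forward model; each
    replicate observes it through log-normal noise at the pair's CV. A zero
    CV reproduces the true ratio exactly. Pairs referencing an undefined drug
    raise :class:`DomainError`.
    """
    studies: list[InteractionStudy] = []
    for (victim, perp) in sorted(spec.study_design):
        design = spec.study_design[(victim, perp)]
        if victim not in spec.true_dpis:
            raise DomainError(f"pair ({victim!r}, {perp!r}) references an undefined victim")
        if perp not in spec.true_potencies:
            raise DomainError(f"pair ({victim!r}, {perp!r}) references an undefined perpetrator")
        dpi = spec.true_dpis[victim]
        direction, value = spec.true_potencies[perp]
        if direction is PerpetratorDirection.INHIBITOR:
            true_ratio = equations.predict_inhibition_ratio(dpi, value)
            mechanism = Mechanism.COMPETITIVE_INHIBITION
        else:
            true_ratio = equations.predict_induction_ratio(dpi, value)
            mechanism = Mechanism.INDUCTION
        sigma = math.sqrt(math.log1p(design.cv**2)) if design.cv > 0 else 0.0
        rng = _pair_rng(spec.seed, victim, perp)
        noise = sigma * rng.standard_normal(design.n_studies)
        for k in range(design.n_studies):
            studies.append(
                InteractionStudy(
                    victim=victim,
                    perpetrator=perp,
                    mechanism=mechanism,
                    auc_ratio_observed=true_ratio * math.exp(noise[k]),
                    cv=design.cv if design.cv > 0 else None,
                    n_subjects=design.n_subjects,
                    reference=f"synthetic/{victim}-{perp}/{k + 1}",
                )
            )
    return studies


def default_synthetic_network(
    n_victims: int = 20,
    n_perpetrators: int = 10,
    *,
    cv: float = 0.15,
    n_subjects: int = 16,
    studies_per_pair: int = 12,
    anchor: str = "midazolam",
    anchor_dpi: float = 0.940,
    seed: int = 0,
) -> SyntheticSpec:
    """A dense recovery-test network mirroring the anchored calibration setting.

    Victim pathway fractions are spread over [0.20, 0.97]; perpetrators are
    mostly inhibitors (InR spread over [0.75, 1.0]) plus two moderate/strong
    inducers (IcR 0.75 and 0.92) when room allows. Every victim — and the
    anchor probe — is studied against every perpetrator, with
    ``studies_per_pair`` replicates per pair at the given CV, exercising the
    same-pair pooling rule.
    """
    if n_victims < 1 or n_perpetrators < 1:
        raise ValidationError("need at least one victim and one perpetrator")
    true_dpis = {anchor: anchor_dpi}
    for i, dpi in enumerate(np.linspace(0.20, 0.97, n_victims)):
        true_dpis[f"victim{i + 1:02d}"] = float(dpi)
    n_inducers = min(2, max(0, n_perpetrators - 1))
    n_inhibitors = n_perpetrators - n_inducers
    true_potencies: dict[str, tuple[PerpetratorDirection, float]] = {}
    for i, inr in enumerate(np.linspace(0.75, 1.0, n_inhibitors)):
        true_potencies[f"inhibitor{i + 1:02d}"] = (PerpetratorDirection.INHIBITOR, float(inr))
    for i, icr in enumerate((0.75, 0.92)[:n_inducers]):
        true_potencies[f"inducer{i + 1:02d}"] = (PerpetratorDirection.INDUCER, icr)
    design = PairDesign(n_subjects=n_subjects, cv=cv, n_studies=studies_per_pair)
    study_design = {
        (victim, perp): design for victim in true_dpis for perp in true_potencies
    }
    return SyntheticSpec(
        true_dpis=true_dpis,
        true_potencies=true_potencies,
        study_design=study_design,
        seed=seed,
    )
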