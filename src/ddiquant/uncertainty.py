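"""Monte Carlo propagation of clinical variability through the DDI model.

Observed AUC ratios are strictly positive and summarized throughout as
geometric means, so sampling is log-normal: draws are centered (as a
geometric mean) on the reported ratio with a log-scale standard deviation
taken from the study's CV (``sigma = sqrt(ln(1 + CV^2))``), from a reported
95% CI (``sigma = (ln upper - ln lower) / (2 * 1.96)``), or from a
configurable fallback CV when a study reports no dispersion.

Parameter draws derived through the inverse equations are clamped to [0, 1]
(counted in ``n_truncated``); predicted inhibition ratios are capped at
``ratio_cap`` and predicted induction ratios floored at ``1 / ratio_cap``
(counted in ``n_capped``) so that geometric-mean summaries remain finite.
Summaries report the geometric mean and the empirical 2.5/97.5 percentiles.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .types import DomainError, InteractionStudy, PerpetratorDirection, ValidationError

__all__ = [
    "MCConfig",
    "McSummary",
    "study_rng",
    "sample_observed_ratio",
    "derive_parameter_samples",
    "predict_distribution",
    "summarize",
]

log = logging.getLogger(__name__)

_Z95 = 1.96  # normal quantile used when converting a reported 95% CI to sigma


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo settings.

    Parameters
    ----------
    n_draws:
        Draws per quantity (default 10,000).
    seed:
        Integer seed for the top-level generator; per-study substreams are
        derived from it by hashing the study identity, so results do not
        depend on processing order.
    ratio_cap:
        Upper cap for predicted inhibition ratios (and ``1/ratio_cap`` floor
        for induction ratios). Near-complete blockade of a near-exclusive
        pathway makes the predicted ratio arbitrarily large; the cap keeps
        summaries finite. Default 100.
    default_cv:
        Fallback CV (fraction) for studies reporting no dispersion; its use
        is logged. Default 0.30.
    """

    n_draws: int = 10_000
    seed: int = 0
    ratio_cap: float = 100.0
    default_cv: float = 0.30

    def __post_init__(self) -> None:
        if int(self.n_draws) < 1:
            raise ValidationError(f"n_draws must be >= 1, got {self.n_draws!r}")
        if not self.ratio_cap > 1:
            raise ValidationError(f"ratio_cap must be > 1, got {self.ratio_cap!r}")
        if not self.default_cv > 0:
            raise ValidationError(f"default_cv must be > 0, got {self.default_cv!r}")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "MCConfig":
        """Load settings from a flat YAML or JSON key-value file."""
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise ValidationError(f"config file {path} must hold a key-value mapping")
        known = {"n_draws", "seed", "ratio_cap", "default_cv"}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config keys in {path}: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return {
            "n_draws": self.n_draws,
            "seed": self.seed,
            "ratio_cap": self.ratio_cap,
            "default_cv": self.default_cv,
        }


@dataclass
class McSummary:
    """Geometric mean and empirical 95% CI of a Monte Carlo sample."""

    geometric_mean: float
    ci95: tuple[float, float]
    n_capped: int = 0
    n_truncated: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        tol = 1e-9 * max(abs(lo), abs(hi), 1.0)  # fp slack for degenerate samples
        if not (lo - tol <= self.geometric_mean <= hi + tol):
            raise ValidationError(
                f"inconsistent summary: geometric mean {self.geometric_mean:g} "
                f"outside CI [{lo:g}, {hi:g}]"
            )

    def to_dict(self) -> dict:
        return {
            "geometric_mean": round(float(self.geometric_mean), 6),
            "ci95": [round(float(self.ci95[0]), 6), round(float(self.ci95[1]), 6)],
            "n_capped": int(self.n_capped),
            "n_truncated": int(self.n_truncated),
        }


def study_rng(config: MCConfig, study: InteractionStudy) -> np.random.Generator:
    """Deterministic per-study substream keyed on (victim, perpetrator, reference)."""
    key = f"{study.victim}|{study.perpetrator}|{study.reference}".encode()
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), zlib.crc32(key)]))


def _sigma_for(study: InteractionStudy, config: MCConfig) -> float:
    if study.ci is not None:
        lo, hi = study.ci
        return (math.log(hi) - math.log(lo)) / (2.0 * _Z95)
    if study.cv is not None:
        return math.sqrt(math.log1p(study.cv**2))
    log.info(
        "study %s x %s (%s) reports no dispersion; using default CV %.2f",
        study.victim,
        study.perpetrator,
        study.reference or "unreferenced",
        config.default_cv,
    )
    return math.sqrt(math.log1p(config.default_cv**2))


def sample_observed_ratio(
    study: InteractionStudy,
    config: MCConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Log-normal draws of a study's AUC ratio, geometric-mean-centered on the
    reported value. All draws are strictly positive."""
    if rng is None:
        rng = study_rng(config, study)
    sigma = _sigma_for(study, config)
    return study.auc_ratio_observed * np.exp(sigma * rng.standard_normal(int(config.n_draws)))


def derive_parameter_samples(
    ratio_draws: np.ndarray,
    counterpart,
    which: str,
) -> tuple[np.ndarray, int]:
    """Element-wise inverse-equation derivation of parameter draws.

    Parameters
    ----------
    ratio_draws:
        Draws of the observed AUC ratio.
    counterpart:
        The already-known parameter: InR draws/value for ``which="dpi"``, DPI
        draws/value for ``which="inr"``/``"icr"``, IcR draws/value for
        ``which="dpi_from_induction"``. A scalar is broadcast; a vector must
        match ``ratio_draws`` in length.
    which:
        One of ``"dpi"``, ``"inr"``, ``"icr"``, ``"dpi_from_induction"``.

    Returns
    -------
    (draws, n_truncated):
        Parameter draws clamped to [0, 1] and the count of clamped draws.
    """
    r = np.asarray(ratio_draws, dtype=float)
    c = np.asarray(counterpart, dtype=float)
    if c.ndim > 0 and c.shape != r.shape:
        raise ValidationError(
            f"counterpart length {c.shape} does not match ratio draws {r.shape}"
        )
    if np.any(r <= 0):
        raise DomainError("ratio draws must be strictly positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        if which in ("dpi", "inr"):
            raw = (1.0 - 1.0 / r) / c
        elif which == "icr":
            q = 1.0 / r
            raw = (q - 1.0) / (q - 1.0 + c)
        elif which == "dpi_from_induction":
            q = 1.0 / r
            raw = (q - 1.0) * (1.0 - c) / c
        else:
            raise ValueError(f"unknown parameter kind {which!r}")
    clipped = np.clip(raw, 0.0, 1.0)
    n_truncated = int(np.count_nonzero(raw != clipped))
    return clipped, n_truncated


def predict_distribution(
    dpi_draws,
    potency_draws,
    direction: PerpetratorDirection,
    config: MCConfig,
) -> McSummary:
    """Element-wise forward prediction over parameter draws, with capping.

    Inhibition draws whose ``dpi*inr`` would push the ratio past ``ratio_cap``
    are set to the cap; induction draws are floored at ``1/ratio_cap`` (an IcR
    draw clamped at 1 would otherwise predict a ratio of exactly 0, which has
    no geometric mean). Scalars broadcast against vectors.
    """
    d = np.atleast_1d(np.asarray(dpi_draws, dtype=float))
    p = np.atleast_1d(np.asarray(potency_draws, dtype=float))
    if d.size == 0 or p.size == 0:
        raise DomainError("empty draw vector")
    d, p = np.broadcast_arrays(d, p)
    if np.any((d < 0) | (d > 1)) or np.any((p < 0) | (p > 1)):
        raise DomainError("parameter draws must lie in [0, 1]")
    cap = float(config.ratio_cap)
    if not isinstance(direction, PerpetratorDirection):
        direction = PerpetratorDirection(direction)
    if direction is PerpetratorDirection.INHIBITOR:
        product = d * p
        capped = product >= 1.0 - 1.0 / cap
        ratio = np.where(capped, cap, 1.0 / (1.0 - np.minimum(product, 1.0 - 1.0 / cap)))
    else:
        with np.errstate(divide="ignore"):
            denom = np.where(p < 1.0, d / (1.0 - p) + (1.0 - d), np.inf)
            raw = np.where(np.isinf(denom), np.where(d > 0, 0.0, 1.0), 1.0 / denom)
        capped = raw < 1.0 / cap
        ratio = np.maximum(raw, 1.0 / cap)
    n_capped = int(np.count_nonzero(capped))
    return summarize(ratio, n_capped=n_capped)


def summarize(draws, *, n_capped: int = 0, n_truncated: int = 0) -> McSummary:
    """Geometric mean and empirical [2.5th, 97.5th]-percentile CI of positive draws."""
    arr = np.asarray(draws, dtype=float)
    if arr.size == 0:
        raise DomainError("cannot summarize an empty draw vector")
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise DomainError("draws must be strictly positive and finite")
    gm = float(np.exp(np.mean(np.log(arr))))
    lo, hi = np.percentile(arr, [2.5, 97.5])
    return McSummary(
        geometric_mean=gm,
        ci95=(float(lo), float(hi)),
        n_capped=n_capped,
        n_truncated=n_truncated,
    )
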