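"""Reference parameter values bundled with the package.

The constants below encode the published calibration of the CYP3A interaction
network for antiretroviral drugs and common comedications: per-victim pathway
fractions (DPI_3A), per-perpetrator inhibitor/inducer ratios (InR_3A/IcR_3A),
the corresponding Monte Carlo summaries, the printed single-calculation
prediction grids used as regression oracles, the amlodipine/diltiazem/
ritonavir worked example, and pathway fractions for nine tyrosine kinase
inhibitors. Every entry carries a short internal provenance label.

These values are pinned by a checksum test and must not drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .types import (
    ParameterTable,
    PathwayContribution,
    PerpetratorDirection,
    PerpetratorPotency,
)

__all__ = [
    "VictimFixture",
    "PerpetratorFixture",
    "FixtureSet",
    "load_fixtures",
    "fixture_parameter_table",
]

_V = "victims-table/single-calculation"
_P = "perpetrators-table/single-calculation"
_W = "discussion/worked-example"
_T = "results/tki-predictions"

# drug -> (single-calculation DPI, MC geometric mean, MC 95% CI)
_VICTIMS: dict[str, tuple[float, float, tuple[float, float]]] = {
    "simvastatin": (0.978, 0.979, (0.916, 1.0)),
    "triazolam": (0.959, 0.966, (0.898, 1.0)),
    "midazolam": (0.940, 0.940, (0.909, 0.971)),
    "quetiapine": (0.896, 0.845, (0.645, 1.0)),
    "tacrolimus": (0.875, 0.831, (0.531, 1.0)),
    "maraviroc": (0.828, 0.792, (0.559, 0.998)),
    "saquinavir": (0.638, 0.580, (0.258, 0.849)),
    "darunavir": (0.602, 0.543, (0.215, 0.817)),
    "macitentan": (0.585, 0.524, (0.200, 0.810)),
    "amlodipine": (0.468, 0.464, (0.117, 1.0)),
    "etravirine": (0.340, 0.336, (0.077, 0.701)),
    "rilpivirine": (0.324, 0.334, (0.079, 0.656)),
    "zolpidem": (0.268, 0.303, (0.065, 0.661)),
    "ritonavir": (0.156, 0.231, (0.038, 0.552)),
}

# drug -> (direction, single-calculation InR/IcR, MC geometric mean, MC 95% CI)
_PERPETRATORS: dict[str, tuple[str, float, float, tuple[float, float]]] = {
    "ritonavir": ("inhibitor", 1.0, 0.963, (0.873, 1.0)),
    "ketoconazole": ("inhibitor", 0.981, 0.943, (0.823, 1.0)),
    "cobicistat": ("inhibitor", 0.967, 0.936, (0.810, 1.0)),
    "voriconazole": ("inhibitor", 0.951, 0.916, (0.768, 1.0)),
    "itraconazole": ("inhibitor", 0.920, 0.877, (0.691, 0.986)),
    "clarithromycin": ("inhibitor", 0.912, 0.870, (0.680, 0.982)),
    "saquinavir": ("inhibitor", 0.858, 0.803, (0.557, 0.946)),
    "posaconazole": ("inhibitor", 0.852, 0.797, (0.551, 0.944)),
    "diltiazem": ("inhibitor", 0.780, 0.715, (0.427, 0.898)),
    "fluconazole": ("inhibitor", 0.768, 0.700, (0.403, 0.893)),
    "cimetidine": ("inhibitor", 0.213, 0.256, (0.049, 0.570)),
    "efavirenz": ("inducer", 0.566, 0.539, (0.282, 0.850)),
    "etravirine": ("inducer", 0.662, 0.644, (0.433, 0.882)),
    "rifampin": ("inducer", 0.946, 0.906, (0.846, 0.967)),
}

# Printed single-calculation prediction grids (regression oracles).
# victims table: drug -> (with ritonavir [inhibitor], with etravirine [inducer])
_VICTIM_TABLE_PREDICTIONS: dict[str, tuple[float, float]] = {
    "simvastatin": (45.97, 0.34),
    "triazolam": (24.39, 0.35),
    "midazolam": (16.67, 0.35),
    "quetiapine": (9.66, 0.36),
    "tacrolimus": (8.03, 0.37),
    "maraviroc": (5.80, 0.38),
    "saquinavir": (2.76, 0.44),
    "darunavir": (2.51, 0.46),
    "macitentan": (2.41, 0.47),
    "amlodipine": (1.88, 0.52),
    "etravirine": (1.52, 0.60),
    "rilpivirine": (1.48, 0.61),
    "zolpidem": (1.37, 0.66),
    "ritonavir": (1.19, 0.77),
}

# perpetrators table: drug -> (with maraviroc victim, with rilpivirine victim)
_PERPETRATOR_TABLE_PREDICTIONS: dict[str, tuple[float, float]] = {
    "ritonavir": (5.80, 1.48),
    "ketoconazole": (5.32, 1.47),
    "cobicistat": (5.00, 1.46),
    "voriconazole": (4.69, 1.45),
    "itraconazole": (4.19, 1.43),
    "clarithromycin": (4.08, 1.42),
    "saquinavir": (3.45, 1.39),
    "posaconazole": (3.39, 1.38),
    "diltiazem": (2.82, 1.34),
    "fluconazole": (2.74, 1.33),
    "cimetidine": (1.21, 1.07),
    "efavirenz": (0.48, 0.70),
    "etravirine": (0.38, 0.61),
    "rifampin": (0.06, 0.15),
}

# Monte Carlo prediction examples kept for soft plausibility checks:
# (victim, perpetrator) -> (MC geometric mean, MC 95% CI)
_MC_PREDICTION_EXAMPLES: dict[tuple[str, str], tuple[float, tuple[float, float]]] = {
    ("maraviroc", "ritonavir"): (5.85, (1.98, 7.63)),
    ("rilpivirine", "ritonavir"): (1.73, (1.08, 2.06)),
}

# Worked example: a patient on ritonavir needing amlodipine. The product
# label reports diltiazem raising amlodipine exposure by 60%; the
# single-calculation diltiazem InR used there (0.802) differs from the
# perpetrators-table value (0.780) — both are kept, provenance-tagged.
_WORKED_EXAMPLES: dict[str, float] = {
    "diltiazem_inr_single_calculation": 0.802,
    "diltiazem_inr_table": 0.780,
    "amlodipine_auc_ratio_with_diltiazem": 1.60,
    "amlodipine_dpi": 0.468,
    "ritonavir_inr": 1.0,
    "amlodipine_ritonavir_predicted_ratio": 1.88,
    "saquinavir_cimetidine_observed_ratio": 2.48,
    "saquinavir_cimetidine_predicted_ratio": 2.23,
    "cimetidine_inr": 0.213,
    "saquinavir_inr": 0.858,
    "saquinavir_dpi": 0.638,
}

# Tyrosine kinase inhibitors: drug -> (DPI geometric mean, 95% CI)
_TKI_DPIS: dict[str, tuple[float, tuple[float, float]]] = {
    "ibrutinib": (0.971, (0.916, 1.0)),
    "dasatinib": (0.779, (0.524, 1.0)),
    "lapatinib": (0.696, (0.403, 0.936)),
    "nilotinib": (0.646, (0.333, 0.895)),
    "gefitinib": (0.534, (0.197, 0.884)),
    "pazopanib": (0.383, (0.106, 0.700)),
    "sunitinib": (0.336, (0.079, 0.661)),
    "imatinib": (0.301, (0.064, 0.627)),
    "sorafenib": (0.054, (0.006, 0.391)),
}


@dataclass(frozen=True)
class VictimFixture:
    drug: str
    dpi: float
    mc_mean: float
    ci95: tuple[float, float]
    provenance: str = _V


@dataclass(frozen=True)
class PerpetratorFixture:
    drug: str
    direction: PerpetratorDirection
    value: float
    mc_mean: float
    ci95: tuple[float, float]
    provenance: str = _P


@dataclass(frozen=True)
class FixtureSet:
    """Bundled reference values; see module docstring."""

    victims: dict[str, VictimFixture]
    perpetrators: dict[str, PerpetratorFixture]
    victim_table_predictions: dict[str, tuple[float, float]]
    perpetrator_table_predictions: dict[str, tuple[float, float]]
    mc_prediction_examples: dict[tuple[str, str], tuple[float, tuple[float, float]]]
    worked_examples: dict[str, float]
    tki_dpis: dict[str, tuple[float, tuple[float, float]]]
    provenance: dict[str, str] = field(
        default_factory=lambda: {
            "victims": _V,
            "perpetrators": _P,
            "worked_examples": _W,
            "tki_dpis": _T,
        }
    )

    def to_plain_dict(self) -> dict:
        """Canonical plain representation (for checksums and export)."""
        return {
            "victims": {d: [v[0], v[1], list(v[2])] for d, v in _VICTIMS.items()},
            "perpetrators": {
                d: [p[0], p[1], p[2], list(p[3])] for d, p in _PERPETRATORS.items()
            },
            "victim_table_predictions": {
                d: list(v) for d, v in _VICTIM_TABLE_PREDICTIONS.items()
            },
            "perpetrator_table_predictions": {
                d: list(v) for d, v in _PERPETRATOR_TABLE_PREDICTIONS.items()
            },
            "mc_prediction_examples": {
                f"{v}|{p}": [m, list(ci)]
                for (v, p), (m, ci) in _MC_PREDICTION_EXAMPLES.items()
            },
            "worked_examples": dict(_WORKED_EXAMPLES),
            "tki_dpis": {d: [v[0], list(v[1])] for d, v in _TKI_DPIS.items()},
        }


def load_fixtures() -> FixtureSet:
    """Return the bundled reference values."""
    victims = {
        d: VictimFixture(drug=d, dpi=v[0], mc_mean=v[1], ci95=v[2])
        for d, v in _VICTIMS.items()
    }
    perpetrators = {
        d: PerpetratorFixture(
            drug=d,
            direction=PerpetratorDirection(p[0]),
            value=p[1],
            mc_mean=p[2],
            ci95=p[3],
        )
        for d, p in _PERPETRATORS.items()
    }
    return FixtureSet(
        victims=victims,
        perpetrators=perpetrators,
        victim_table_predictions=dict(_VICTIM_TABLE_PREDICTIONS),
        perpetrator_table_predictions=dict(_PERPETRATOR_TABLE_PREDICTIONS),
        mc_prediction_examples=dict(_MC_PREDICTION_EXAMPLES),
        worked_examples=dict(_WORKED_EXAMPLES),
        tki_dpis=dict(_TKI_DPIS),
    )


def fixture_parameter_table(*, include_tkis: bool = True, enzyme: str = "CYP3A") -> ParameterTable:
    """Bundled single-calculation values as a ready-to-use parameter table.

    Victim DPIs, perpetrator InR/IcR values and (optionally) the tyrosine
    kinase inhibitor DPIs, each carrying its MC 95% CI and provenance label.
    The diltiazem entry uses the perpetrators-table value (0.780); the
    worked-example value (0.802) is available via
    ``load_fixtures().worked_examples``.
    """
    table = ParameterTable(default_enzyme=enzyme)
    for drug, (dpi, _mc, ci) in _VICTIMS.items():
        table.add(
            PathwayContribution(drug=drug, value=dpi, enzyme=enzyme, ci95=ci),
            references=[_V],
        )
    for drug, (direction, value, _mc, ci) in _PERPETRATORS.items():
        table.add(
            PerpetratorPotency(
                drug=drug,
                direction=PerpetratorDirection(direction),
                value=value,
                enzyme=enzyme,
                ci95=ci,
            ),
            references=[_P],
        )
    if include_tkis:
        for drug, (dpi, ci) in _TKI_DPIS.items():
            table.add(
                PathwayContribution(drug=drug, value=dpi, enzyme=enzyme, ci95=ci),
                references=[_T],
            )
    return table
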