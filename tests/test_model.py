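"""Pooling, pair prediction, and anchored network calibration."""

import math

import numpy as np
import pytest

import ddiquant as dq
from ddiquant.types import DomainError, ValidationError


def _study(victim, perp, ratio, n=10, mechanism="competitive_inhibition", ref=""):
    return dq.InteractionStudy(
        victim=victim, perpetrator=perp, mechanism=mechanism,
        auc_ratio_observed=ratio, n_subjects=n, reference=ref,
    )


class TestPooling:
    def test_single_study_is_identity(self):
        assert dq.pool_auc_ratio([_study("a", "b", 2.0)]) == pytest.approx(2.0)

    def test_equal_ratios_pool_to_same_value(self):
        studies = [_study("a", "b", 2.0, n=10), _study("a", "b", 2.0, n=20)]
        assert dq.pool_auc_ratio(studies) == pytest.approx(2.0)

    def test_subject_weighted_geometric_mean(self):
        studies = [_study("a", "b", 2.0, n=10), _study("a", "b", 8.0, n=30)]
        expected = math.exp((10 * math.log(2) + 30 * math.log(8)) / 40)
        assert dq.pool_auc_ratio(studies) == pytest.approx(expected)
        assert dq.pool_auc_ratio(studies) == pytest.approx(5.657, abs=5e-4)

    def test_empty_list_rejected(self):
        with pytest.raises(DomainError):
            dq.pool_auc_ratio([])

    def test_mixed_mechanisms_rejected(self):
        studies = [
            _study("a", "b", 2.0),
            _study("a", "b", 2.1, mechanism="mechanism_based_inhibition"),
        ]
        with pytest.raises(ValidationError):
            dq.pool_auc_ratio(studies)

    def test_mixed_pairs_rejected(self):
        with pytest.raises(ValidationError):
            dq.pool_auc_ratio([_study("a", "b", 2.0), _study("a", "c", 2.0)])


class TestPredictPair:
    def test_point_prediction_and_class(self, param_table):
        result = dq.predict_from_table(param_table, "amlodipine", "ritonavir")
        assert result.ratio == pytest.approx(1.88, abs=0.005)
        assert result.ddi_class.label is dq.DdiClassLabel.WEAK

    def test_zero_dpi_victim_is_no_ddi(self):
        victim = dq.PathwayContribution(drug="x", value=0.0)
        perp = dq.PerpetratorPotency(drug="y", direction="inhibitor", value=0.9)
        result = dq.predict_pair(victim, perp)
        assert result.ratio == 1.0
        assert result.ddi_class.label is dq.DdiClassLabel.NONE

    def test_stronger_inhibitor_rule_applied_from_table(self, param_table):
        # the victim's own inhibitory potency exceeds the weak perpetrator's
        result = dq.predict_from_table(param_table, "saquinavir", "cimetidine")
        assert result.potency_used == pytest.approx(0.858)
        assert result.ratio == pytest.approx(1.0 / (1.0 - 0.638 * 0.858), rel=1e-12)

    def test_intrinsic_ignored_for_inducer_perpetrator(self, param_table):
        # victim ritonavir (a strong inhibitor itself) with the inducer etravirine
        result = dq.predict_from_table(param_table, "ritonavir", "etravirine")
        assert result.ratio == pytest.approx(0.77, abs=0.005)

    def test_enzyme_mismatch_rejected(self):
        victim = dq.PathwayContribution(drug="x", value=0.5, enzyme="CYP3A")
        perp = dq.PerpetratorPotency(drug="y", direction="inhibitor", value=0.5, enzyme="CYP2D6")
        with pytest.raises(ValidationError):
            dq.predict_pair(victim, perp)

    def test_unbounded_point_prediction_is_capped(self):
        victim = dq.PathwayContribution(drug="x", value=1.0)
        perp = dq.PerpetratorPotency(drug="y", direction="inhibitor", value=1.0)
        result = dq.predict_pair(victim, perp, config=dq.MCConfig(ratio_cap=100))
        assert result.ratio == 100.0
        assert result.capped

    def test_mc_summary_attached_when_samples_present(self):
        rng = np.random.default_rng(0)
        victim = dq.PathwayContribution(drug="x", value=0.8, samples=rng.uniform(0.7, 0.9, 500))
        perp = dq.PerpetratorPotency(drug="y", direction="inhibitor", value=0.9)
        result = dq.predict_pair(victim, perp, config=dq.MCConfig(n_draws=500))
        assert result.mc is not None
        assert result.mc.ci95[0] <= result.mc.geometric_mean <= result.mc.ci95[1]


class TestCalibration:
    def test_single_step_derives_ceiling_inhibitor(self):
        studies = [_study("midazolam", "ritonavir", 16.67, n=12)]
        table = dq.calibrate_network(studies, "midazolam", 0.940)
        pot = table.potency("ritonavir")
        assert pot.value == 1.0
        assert pot.truncated  # 1.0006 from printed inputs clamps at the ceiling
        assert table.dpi("midazolam").value == 0.940

    def test_no_anchor_studies_yields_anchor_only_table(self):
        table = dq.calibrate_network([], "midazolam", 0.940)
        assert len(table) == 1
        assert table.dpi("midazolam").value == 0.940

    def test_second_pass_derives_victim_dpi(self, probe_studies):
        table = dq.calibrate_network(probe_studies, "midazolam", 0.940)
        # amlodipine studied against the pass-1 inhibitor ritonavir (InR -> 1.0)
        assert table.dpi("amlodipine").value == pytest.approx(1 - 1 / 1.88, abs=1e-9)
        assert table.potency("etravirine").direction is dq.PerpetratorDirection.INDUCER
        assert table.potency("etravirine").value == pytest.approx(0.662, abs=0.0005)

    def test_victim_without_usable_perpetrator_omitted(self, probe_studies, caplog):
        orphan = _study("orphanvictim", "unknownperp", 2.0)
        with caplog.at_level("WARNING"):
            table = dq.calibrate_network(probe_studies + [orphan], "midazolam", 0.940)
        assert not table.has_dpi("orphanvictim")
        assert any("orphanvictim" in r.message for r in caplog.records)

    def test_provenance_recorded(self, probe_studies):
        table = dq.calibrate_network(probe_studies, "midazolam", 0.940)
        key = ("ritonavir", "CYP3A", dq.Role.INHIBITOR_INR)
        assert table.provenance[key] == ["probe-study-1"]

    def test_mc_calibration_attaches_samples_and_ci(self, probe_studies):
        config = dq.MCConfig(n_draws=2000, seed=7)
        table = dq.calibrate_network(probe_studies, "midazolam", 0.940, mc=config)
        dpi = table.dpi("amlodipine")
        assert dpi.samples is not None and dpi.samples.size == 2000
        assert dpi.ci95[0] <= dpi.ci95[1]
        assert np.all((dpi.samples >= 0) & (dpi.samples <= 1))

    def test_small_network_recovery(self):
        spec = dq.default_synthetic_network(
            5, 4, cv=0.05, studies_per_pair=4, seed=3
        )
        studies = dq.generate_synthetic_studies(spec)
        table = dq.calibrate_network(studies, "midazolam", 0.940)
        for drug, true_dpi in spec.true_dpis.items():
            assert table.dpi(drug).value == pytest.approx(true_dpi, abs=0.05)

    def test_bad_anchor_dpi_rejected(self):
        with pytest.raises(DomainError):
            dq.calibrate_network([], "midazolam", 0.0)


class TestParameterTable:
    def test_duplicate_entry_rejected(self):
        table = dq.ParameterTable()
        table.add(dq.PathwayContribution(drug="a", value=0.5))
        with pytest.raises(ValidationError):
            table.add(dq.PathwayContribution(drug="a", value=0.6))

    def test_unknown_drug_lookup_lists_known(self, param_table):
        with pytest.raises(KeyError, match="known victims"):
            param_table.dpi("nosuchdrug")

    def test_roles_keep_victim_and_perpetrator_entries_distinct(self, param_table):
        # ritonavir appears as both a victim (DPI) and an inhibitor (InR)
        assert param_table.dpi("ritonavir").value == pytest.approx(0.156)
        assert param_table.potency("ritonavir").value == pytest.approx(1.0)
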