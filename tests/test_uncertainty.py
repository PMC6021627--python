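"""Monte Carlo sampling, parameter derivation, prediction and summaries."""

import math

import numpy as np
import pytest

import ddiquant as dq
from ddiquant.types import DomainError, ValidationError
from ddiquant.uncertainty import study_rng


def _study(ratio=2.0, cv=0.3, ci=None, ref="s1"):
    return dq.InteractionStudy(
        victim="v", perpetrator="p", mechanism="competitive_inhibition",
        auc_ratio_observed=ratio, cv=cv, ci=ci, n_subjects=10, reference=ref,
    )


class TestSampling:
    def test_zero_variance_limit_reproduces_observed_ratio(self):
        study = _study(ratio=2.0, cv=1e-12)
        draws = dq.sample_observed_ratio(study, dq.MCConfig(n_draws=100, seed=1))
        assert np.allclose(draws, 2.0, atol=1e-9)

    def test_same_seed_gives_identical_draws(self):
        config = dq.MCConfig(n_draws=1000, seed=42)
        a = dq.sample_observed_ratio(_study(), config)
        b = dq.sample_observed_ratio(_study(), config)
        assert np.array_equal(a, b)

    def test_substreams_are_order_independent(self):
        config = dq.MCConfig(n_draws=100, seed=5)
        s1, s2 = _study(ref="a"), _study(ref="b")
        a_then_b = dq.sample_observed_ratio(s1, config)
        b_first = dq.sample_observed_ratio(s2, config)
        assert np.array_equal(a_then_b, dq.sample_observed_ratio(s1, config))
        assert not np.array_equal(a_then_b, b_first)

    def test_geometric_mean_centering_law_of_large_numbers(self):
        study = _study(ratio=2.0, cv=0.30)
        draws = dq.sample_observed_ratio(study, dq.MCConfig(n_draws=100_000, seed=0))
        gm = math.exp(np.mean(np.log(draws)))
        assert gm == pytest.approx(2.0, rel=0.01)
        assert np.all(draws > 0)

    def test_ci_dispersion_source(self):
        # a reported 95% CI maps to sigma = (ln hi - ln lo) / (2 * 1.96)
        study = _study(cv=None, ci=(1.0, 4.0))
        draws = dq.sample_observed_ratio(study, dq.MCConfig(n_draws=200_000, seed=3))
        expected_sigma = (math.log(4.0) - math.log(1.0)) / (2 * 1.96)
        assert np.std(np.log(draws)) == pytest.approx(expected_sigma, rel=0.02)

    def test_default_cv_fallback_used_when_no_dispersion(self, caplog):
        study = _study(cv=None)
        config = dq.MCConfig(n_draws=50_000, seed=2, default_cv=0.5)
        with caplog.at_level("INFO", logger="ddiquant.uncertainty"):
            draws = dq.sample_observed_ratio(study, config)
        assert np.std(np.log(draws)) == pytest.approx(
            math.sqrt(math.log1p(0.25)), rel=0.03
        )
        assert any("default CV" in r.message for r in caplog.records)


class TestDeriveParameterSamples:
    def test_degenerate_draws_reduce_to_single_calculation(self):
        draws = np.full(100, 16.67)
        params, n_trunc = dq.derive_parameter_samples(draws, 1.0, "dpi")
        assert np.allclose(params, 0.940, atol=5e-4)
        assert n_trunc == 0

    def test_draws_straddling_bound_are_clamped_and_counted(self):
        draws = np.array([1.5, 30.0, 50.0])  # high ratios push InR past 1 at dpi 0.5
        params, n_trunc = dq.derive_parameter_samples(draws, 0.5, "inr")
        assert n_trunc == 2
        assert np.all((params >= 0) & (params <= 1))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            dq.derive_parameter_samples(np.ones(5), np.ones(4), "dpi")

    def test_parameter_recovery_from_synthetic_ratios(self):
        # ratios generated from DPI 0.8, InR 0.9 with CV 0.2: the geometric
        # mean of the recovered DPI draws lands near the truth
        true_ratio = dq.predict_inhibition_ratio(0.8, 0.9)
        study = _study(ratio=true_ratio, cv=0.2)
        draws = dq.sample_observed_ratio(study, dq.MCConfig(n_draws=10_000, seed=11))
        params, _ = dq.derive_parameter_samples(draws, 0.9, "dpi")
        gm = math.exp(np.mean(np.log(np.maximum(params, 1e-12))))
        assert gm == pytest.approx(0.8, rel=0.05)

    @pytest.mark.parametrize("which", ["dpi", "inr", "icr", "dpi_from_induction"])
    def test_elementwise_round_trip(self, which):
        rng = np.random.default_rng(4)
        counterpart = rng.uniform(0.3, 0.9, 200)
        target = rng.uniform(0.1, 0.9, 200)
        if which in ("dpi", "inr"):
            ratios = 1.0 / (1.0 - target * counterpart)
        elif which == "icr":
            ratios = 1.0 / (counterpart / (1.0 - target) + (1.0 - counterpart))
        else:
            ratios = 1.0 / (target / (1.0 - counterpart) + (1.0 - target))
        params, n_trunc = dq.derive_parameter_samples(ratios, counterpart, which)
        assert np.allclose(params, target, atol=1e-10)
        assert n_trunc == 0


class TestPredictDistribution:
    def test_degenerate_draws_equal_point_prediction(self):
        summary = dq.predict_distribution(
            np.full(10, 0.828), np.full(10, 0.963), "inhibitor", dq.MCConfig()
        )
        expected = 1.0 / (1.0 - 0.828 * 0.963)
        assert summary.geometric_mean == pytest.approx(expected, rel=1e-12)
        assert summary.ci95 == pytest.approx((expected, expected))

    def test_cap_contract(self):
        dpi = np.array([0.999, 0.5])
        inr = np.array([0.9999, 0.5])
        summary = dq.predict_distribution(dpi, inr, "inhibitor", dq.MCConfig(ratio_cap=100))
        assert summary.n_capped == 1
        assert summary.ci95[1] <= 100.0

    def test_induction_floor_counted_as_capped(self):
        summary = dq.predict_distribution(
            np.array([0.9, 0.5]), np.array([1.0, 0.5]), "inducer", dq.MCConfig(ratio_cap=100)
        )
        assert summary.n_capped == 1
        assert summary.ci95[0] >= 1.0 / 100.0

    def test_scalar_broadcast(self):
        summary = dq.predict_distribution(0.8, np.full(50, 0.9), "inhibitor", dq.MCConfig())
        assert summary.geometric_mean == pytest.approx(1.0 / (1.0 - 0.72), rel=1e-9)

    def test_empty_vectors_rejected(self):
        with pytest.raises(DomainError):
            dq.predict_distribution(np.array([]), np.array([]), "inhibitor", dq.MCConfig())


class TestSummarize:
    def test_constant_vector(self):
        summary = dq.summarize(np.full(100, 3.5))
        assert summary.geometric_mean == pytest.approx(3.5)
        assert summary.ci95 == pytest.approx((3.5, 3.5))

    def test_two_point_geometric_mean(self):
        assert dq.summarize([1.0, 4.0]).geometric_mean == pytest.approx(2.0)

    def test_lognormal_closed_form(self):
        # draws ~ LogNormal(mu, sigma): geometric mean = e^mu and the 95% CI
        # approaches [e^(mu-1.96 sigma), e^(mu+1.96 sigma)]
        mu, sigma = 0.7, 0.4
        rng = np.random.default_rng(8)
        draws = np.exp(mu + sigma * rng.standard_normal(10_000))
        summary = dq.summarize(draws)
        assert summary.geometric_mean == pytest.approx(math.exp(mu), rel=0.02)
        assert summary.ci95[0] == pytest.approx(math.exp(mu - 1.96 * sigma), rel=0.05)
        assert summary.ci95[1] == pytest.approx(math.exp(mu + 1.96 * sigma), rel=0.05)

    def test_nonpositive_draw_rejected(self):
        with pytest.raises(DomainError):
            dq.summarize([1.0, 0.0, 2.0])


class TestInvariants:
    def test_ci_width_nondecreasing_in_cv(self):
        widths = []
        for cv in (0.05, 0.1, 0.2, 0.3, 0.5):
            study = _study(cv=cv)  # same identity -> same substream draws
            draws = dq.sample_observed_ratio(study, dq.MCConfig(n_draws=5000, seed=9))
            summary = dq.summarize(draws)
            widths.append(summary.ci95[1] - summary.ci95[0])
        assert widths == sorted(widths)

    def test_reproducibility_of_full_summary(self):
        config = dq.MCConfig(n_draws=2000, seed=123)
        run = lambda: dq.predict_distribution(  # noqa: E731
            dq.derive_parameter_samples(
                dq.sample_observed_ratio(_study(), config), 0.9, "dpi"
            )[0],
            0.95,
            "inhibitor",
            config,
        )
        assert run() == run()


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs", [{"n_draws": 0}, {"ratio_cap": 1.0}, {"default_cv": 0.0}]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            dq.MCConfig(**kwargs)

    @pytest.mark.parametrize(
        "text",
        [
            "n_draws: 500\nseed: 3\nratio_cap: 50\ndefault_cv: 0.2\n",
            '{"n_draws": 500, "seed": 3, "ratio_cap": 50, "default_cv": 0.2}',
        ],
        ids=["yaml", "json"],
    )
    def test_config_file_dialects(self, tmp_path, text):
        path = tmp_path / "mc.cfg"
        path.write_text(text)
        config = dq.MCConfig.from_file(path)
        assert config == dq.MCConfig(n_draws=500, seed=3, ratio_cap=50, default_cv=0.2)

    def test_unknown_config_key_rejected(self, tmp_path):
        path = tmp_path / "mc.yaml"
        path.write_text("n_draws: 10\nbogus: 1\n")
        with pytest.raises(ValidationError):
            dq.MCConfig.from_file(path)
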