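import numpy as np
import pytest

from dictatime import (
    ContaminationModel,
    GeneratorConfig,
    MixtureParams,
    classify_records,
    fit_em,
    fit_stochastic_search,
    generate_durations,
    ks_normality_of_retained,
)
from dictatime.io import DurationSample
from dictatime.mixture import ClassifiedSample

from conftest import UNIFORM_MIX

# lighter search settings for unit tests; the full 1000/100 configuration is
# exercised in test_acceptance.py
FAST_SEARCH = dict(n_iterations=400, vector_size=50)


class TestContaminationModel:
    def test_uniform_pdf_integrates_to_one(self):
        c = ContaminationModel(upper=240.0)
        xs = np.linspace(0.001, 240.0, 100_000)
        assert np.trapezoid(c.pdf(xs), xs) == pytest.approx(1.0, abs=1e-3)

    def test_support(self):
        c = ContaminationModel(upper=10.0)
        assert c.pdf([0.0])[0] == 0.0
        assert c.pdf([10.0])[0] == pytest.approx(0.1)
        assert c.pdf([10.5])[0] == 0.0

    def test_invalid_support(self):
        with pytest.raises(ValueError):
            ContaminationModel(upper=0.0)


class TestParamsValidation:
    def test_bad_sigma(self):
        with pytest.raises(ValueError):
            MixtureParams(16.0, 0.0, 0.9)

    @pytest.mark.parametrize("lam", [0.0, 1.2, -0.5])
    def test_bad_lam(self, lam):
        with pytest.raises(ValueError):
            MixtureParams(16.0, 5.0, lam)


class TestFitEm:
    def test_pure_normal_limit(self):
        cfg = GeneratorConfig(n=2000, seed=17, weights=(0.0, 1.0, 0.0, 0.0))
        x = generate_durations(cfg).durations
        params, trace = fit_em(x)
        assert params.lam >= 0.97
        assert params.mu == pytest.approx(16.0, abs=0.3)

    def test_recovers_generating_parameters(self, mix_sample_5000):
        # oracle: the generator's ground-truth parameters
        params, trace = fit_em(mix_sample_5000)
        assert params.mu == pytest.approx(16.0, abs=0.5)
        assert params.sigma == pytest.approx(5.0, abs=0.5)
        assert params.lam == pytest.approx(0.9, abs=0.05)
        assert trace.converged

    def test_loglik_monotone(self, mix_sample_5000):
        _, trace = fit_em(mix_sample_5000)
        diffs = np.diff(trace.objective)
        assert np.all(diffs >= -1e-7)

    def test_degenerate_sample(self):
        with pytest.raises(ValueError, match="degenerate sample"):
            fit_em(np.full(40, 3.0))

    def test_too_small_sample(self):
        with pytest.raises(ValueError, match="too small"):
            fit_em(np.arange(1.0, 11.0))

    def test_accepts_duration_sample(self, mix_sample_500):
        sample = DurationSample("head", mix_sample_500)
        params, _ = fit_em(sample)
        assert 10 < params.mu < 20

    def test_scale_equivariance(self, mix_sample_500):
        p1, _ = fit_em(mix_sample_500)
        p2, _ = fit_em(mix_sample_500 * 3.0)
        assert p2.mu == pytest.approx(3.0 * p1.mu, rel=1e-6)
        assert p2.sigma == pytest.approx(3.0 * p1.sigma, rel=1e-6)
        assert p2.lam == pytest.approx(p1.lam, abs=1e-9)


class TestStochasticSearch:
    def test_agrees_with_em(self, mix_sample_500):
        pe, _ = fit_em(mix_sample_500)
        ps, _ = fit_stochastic_search(mix_sample_500, seed=1)
        assert ps.mu == pytest.approx(pe.mu, abs=0.5)
        assert ps.sigma == pytest.approx(pe.sigma, abs=0.5)
        assert ps.lam == pytest.approx(pe.lam, abs=0.05)

    def test_seed_stability(self, mix_sample_500):
        a, _ = fit_stochastic_search(mix_sample_500, seed=10, **FAST_SEARCH)
        b, _ = fit_stochastic_search(mix_sample_500, seed=77, **FAST_SEARCH)
        assert a.mu == pytest.approx(b.mu, abs=0.5)
        assert a.sigma == pytest.approx(b.sigma, abs=0.5)
        assert a.lam == pytest.approx(b.lam, abs=0.05)

    def test_reproducible_for_fixed_seed(self, mix_sample_500):
        a, ta = fit_stochastic_search(mix_sample_500, seed=4, **FAST_SEARCH)
        b, tb = fit_stochastic_search(mix_sample_500, seed=4, **FAST_SEARCH)
        assert a == b
        np.testing.assert_array_equal(ta.objective, tb.objective)

    def test_single_iteration_not_converged(self, mix_sample_500):
        with pytest.warns(RuntimeWarning, match="did not settle"):
            params, trace = fit_stochastic_search(
                mix_sample_500, n_iterations=1, vector_size=50, seed=0
            )
        assert not trace.converged
        assert trace.iterations_run == 1

    def test_widths_non_increasing(self, mix_sample_500):
        _, trace = fit_stochastic_search(mix_sample_500, seed=2, **FAST_SEARCH)
        for w in (trace.width_mu, trace.width_sigma, trace.width_lam):
            assert np.all(np.diff(w) <= 0)

    def test_objective_non_decreasing(self, mix_sample_500):
        _, trace = fit_stochastic_search(mix_sample_500, seed=2, **FAST_SEARCH)
        assert np.all(np.diff(trace.objective) >= 0)

    def test_ks_objective_close_to_loglik_fit(self, mix_sample_500):
        pl, _ = fit_stochastic_search(mix_sample_500, seed=3, **FAST_SEARCH)
        pk, _ = fit_stochastic_search(
            mix_sample_500, seed=3, objective="ks", **FAST_SEARCH
        )
        assert pk.mu == pytest.approx(pl.mu, abs=1.0)
        assert pk.sigma == pytest.approx(pl.sigma, abs=1.0)

    def test_invalid_arguments(self, mix_sample_500):
        with pytest.raises(ValueError):
            fit_stochastic_search(mix_sample_500, n_iterations=0)
        with pytest.raises(ValueError):
            fit_stochastic_search(mix_sample_500, vector_size=1)
        with pytest.raises(ValueError):
            fit_stochastic_search(mix_sample_500, objective="nope")

    def test_scale_equivariance_same_seed(self, mix_sample_500):
        p1, _ = fit_stochastic_search(mix_sample_500, seed=9, **FAST_SEARCH)
        p2, _ = fit_stochastic_search(mix_sample_500 * 3.0, seed=9, **FAST_SEARCH)
        assert p2.mu == pytest.approx(3.0 * p1.mu, rel=1e-9)
        assert p2.sigma == pytest.approx(3.0 * p1.sigma, rel=1e-9)
        assert p2.lam == pytest.approx(p1.lam, abs=1e-12)


class TestClassify:
    def test_modal_point_is_norm(self):
        params = MixtureParams(16.0, 5.0, 0.9)
        cont = ContaminationModel(upper=240.0)
        c = classify_records(np.array([16.0]), params, cont)
        assert c.posterior_norm[0] > 0.5
        assert c.labels[0] == "norm"

    def test_extreme_tail_is_outlier(self):
        params = MixtureParams(16.0, 5.0, 0.9)
        cont = ContaminationModel(upper=240.0)
        c = classify_records(np.array([16.0 + 50.0]), params, cont)
        assert c.labels[0] == "outlier"

    def test_lam_one_all_norm(self, mix_sample_500):
        params = MixtureParams(16.0, 5.0, 1.0)
        c = classify_records(mix_sample_500, params)
        assert c.n_norm == c.n_total

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -1.0])
    def test_threshold_guard(self, threshold, mix_sample_500):
        with pytest.raises(ValueError):
            classify_records(mix_sample_500, MixtureParams(16, 5, 0.9), threshold=threshold)

    def test_classification_consistency(self):
        cfg = GeneratorConfig(n=10_000, seed=11, **UNIFORM_MIX)
        x = generate_durations(cfg).durations
        params, _ = fit_em(x)
        c = classify_records(x, params)
        assert c.n_norm / c.n_total == pytest.approx(0.9, abs=0.03)

    def test_ground_truth_label_accuracy(self):
        # well-separated contamination by construction (long_shift = 300)
        cfg = GeneratorConfig(n=5000, seed=23, weights=(0.05, 0.85, 0.07, 0.03))
        ds = generate_durations(cfg)
        params, _ = fit_em(ds.durations)
        c = classify_records(ds.durations, params)
        truth_norm = ds.labels == "normal"
        pred_norm = c.labels == "norm"
        accuracy = np.mean(truth_norm == pred_norm)
        assert accuracy >= 0.90


class TestKsRetained:
    def test_well_specified_fit(self, mix_sample_5000):
        params, _ = fit_em(mix_sample_5000)
        c = classify_records(mix_sample_5000, params)
        res = ks_normality_of_retained(c, params)
        assert res.p_value > 0.05

    def test_gross_misfit_detected(self):
        # n = 2000: the deterministic KS distance between Uniform(0,1) and
        # Normal(0.5, 0.29) is ~0.04, too small for p < 1e-3 at n = 500
        rng = np.random.default_rng(31)
        u = rng.uniform(0.0, 1.0, 2000)
        c = ClassifiedSample(
            durations=u,
            posterior_norm=np.ones(2000),
            labels=np.full(2000, "norm"),
            threshold=0.5,
        )
        res = ks_normality_of_retained(c, MixtureParams(0.5, 0.29, 0.9))
        assert res.p_value < 1e-3

    def test_small_subset_rejected(self):
        c = ClassifiedSample(
            durations=np.arange(1.0, 6.0),
            posterior_norm=np.ones(5),
            labels=np.full(5, "norm"),
            threshold=0.5,
        )
        with pytest.raises(ValueError, match="too small"):
            ks_normality_of_retained(c, MixtureParams(3.0, 1.0, 0.9))
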