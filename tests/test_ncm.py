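import numpy as np
import pytest
from scipy import integrate, stats

from rumencm import (CountMatrix, NCMInput, classify_partitions,
                     expected_frequency, fit_ncm, prepare_ncm_input,
                     wilson_band)
from rumencm.ncm import partition_counts


class TestPrepareInput:
    def test_worked_arithmetic_example(self, tiny_counts):
        inp = prepare_ncm_input(tiny_counts)
        np.testing.assert_allclose(inp.p, [0.5, 0.5])
        np.testing.assert_allclose(inp.F, [1.0, 0.5])
        assert inp.N == 5.0 and inp.d == 0.2
        assert inp.dropped == []

    def test_single_sgb_normalizes_to_one(self):
        cm = CountMatrix(["only"], ["S1", "S2"], np.array([[4, 9]]))
        inp = prepare_ncm_input(cm)
        np.testing.assert_allclose(inp.p, [1.0])

    def test_all_zero_row_dropped_and_recorded(self):
        cm = CountMatrix(["a", "b"], ["S1", "S2"],
                         np.array([[3, 4], [0, 0]]))
        inp = prepare_ncm_input(cm)
        assert inp.sgb_ids == ["a"] and inp.dropped == ["b"]

    def test_all_zero_slice_rejected(self):
        cm = CountMatrix(["a"], ["S1", "S2"], np.zeros((1, 2), dtype=int))
        with pytest.raises(ValueError):
            prepare_ncm_input(cm)


class TestExpectedFrequency:
    def test_uniform_beta_closed_form(self):
        # Nm=2, p=0.5 gives Beta(1,1): survival at d is 1-d
        assert expected_frequency(np.array([0.5]), 2.0, 0.01)[0] == pytest.approx(0.99)

    def test_detection_limit_to_zero_gives_one(self):
        # convergence in d is slow when alpha = Nm*p is tiny (mass piles at
        # zero), so the limit is probed at a vanishing detection threshold
        f = expected_frequency(np.array([0.3, 0.001]), 50.0, 1e-280)
        np.testing.assert_allclose(f, 1.0, atol=1e-9)

    def test_matches_quadrature_of_beta_density(self):
        # independent oracle: numerical integration of the Beta pdf
        p, nm, d = 0.001, 200.0, 1e-4
        mass, _ = integrate.quad(
            lambda x: stats.beta.pdf(x, nm * p, nm * (1 - p)), 0, d)
        ours = expected_frequency(np.array([p]), nm, d)[0]
        assert ours == pytest.approx(1.0 - mass, abs=1e-8)

    def test_monotone_in_p_and_d(self):
        # p range chosen so predictions stay strictly inside (0, 1) and the
        # monotone increase is visible above float resolution
        p = np.linspace(0.0005, 0.02, 40)
        f = expected_frequency(p, 100.0, 1e-3)
        assert np.all(np.diff(f) > 0)
        d_grid = np.logspace(-6, -1, 20)
        vals = [expected_frequency(np.array([0.01]), 100.0, d)[0] for d in d_grid]
        assert np.all(np.diff(vals) < 0)

    @pytest.mark.parametrize("bad_p", [0.0, 1.0])
    def test_degenerate_abundance_rejected(self, bad_p):
        with pytest.raises(ValueError):
            expected_frequency(np.array([bad_p]), 10.0, 1e-3)


class TestWilsonBand:
    def test_frozen_worked_values(self):
        lo, hi = wilson_band(np.array([0.5]), 10)
        assert (round(lo[0], 4), round(hi[0], 4)) == (0.2366, 0.7634)
        lo0, hi0 = wilson_band(np.array([0.0]), 10)
        assert lo0[0] == 0.0 and round(hi0[0], 4) == 0.2775

    def test_symmetry_about_half(self):
        f = np.array([0.0, 0.1, 0.25, 0.4])
        lo, hi = wilson_band(f, 10)
        lo_m, hi_m = wilson_band(1.0 - f, 10)
        np.testing.assert_allclose(lo, 1.0 - hi_m, atol=1e-12)
        np.testing.assert_allclose(hi, 1.0 - lo_m, atol=1e-12)

    def test_matches_statsmodels_wilson(self):
        statsmodels = pytest.importorskip("statsmodels.stats.proportion")
        f = np.array([0.05, 0.2, 0.5, 0.77, 0.95])
        for n in (5, 10, 40):
            lo, hi = wilson_band(f, n)
            ref_lo, ref_hi = statsmodels.proportion_confint(
                f * n, n, alpha=0.05, method="wilson")
            np.testing.assert_allclose(lo, ref_lo, atol=1e-12)
            np.testing.assert_allclose(hi, ref_hi, atol=1e-12)

    def test_edge_bounds_exact(self):
        # exact arithmetic gives upper=1 at F_hat=1 and lower=0 at F_hat=0;
        # float rounding must not produce a bound just inside the edge
        lo, hi = wilson_band(np.array([0.0, 1.0]), 10)
        assert hi[1] == 1.0 and lo[0] == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            wilson_band(np.array([0.5]), 1)


class TestFit:
    def test_noise_free_self_consistency(self):
        rng = np.random.default_rng(5)
        raw = rng.lognormal(0, 2, 400)
        p = raw / raw.sum()
        d = 1e-5
        F = expected_frequency(p, 5000.0, d)
        inp = NCMInput([f"g{i}" for i in range(400)], p, np.clip(F, 1e-12, 1),
                       n_samples=10, N=1 / d, d=d)
        fit = fit_ncm(inp)
        assert fit.Nm == pytest.approx(5000.0, rel=1e-3)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_r_squared_nan_with_warning_when_f_constant(self):
        p = np.linspace(0.01, 0.05, 12)
        inp = NCMInput([f"g{i}" for i in range(12)], p, np.full(12, 1.0),
                       n_samples=10, N=1e4, d=1e-4)
        with pytest.warns(UserWarning, match="identical"):
            fit = fit_ncm(inp)
        assert np.isnan(fit.r_squared)

    def test_too_few_sgbs_rejected(self):
        inp = NCMInput(["a", "b"], np.array([0.4, 0.3]),
                       np.array([0.5, 1.0]), 10, 100.0, 0.01)
        with pytest.raises(ValueError, match="minimum"):
            fit_ncm(inp)

    def test_recovers_truth_on_simulated_slice(self, neutral_slice):
        cm, truth = neutral_slice
        fit = fit_ncm(prepare_ncm_input(cm))
        assert fit.converged
        # generator-vs-model detection smoothing biases Nm upward; a factor-2
        # envelope distinguishes working recovery from a broken fit
        assert truth.Nm_true / 2 < fit.Nm < truth.Nm_true * 2
        assert fit.r_squared > 0.5


class TestPartitions:
    def _inp_fit(self, F, lower, upper):
        inp = NCMInput(["g"], np.array([0.1]), np.array([F]), 10, 100.0, 0.01)
        from rumencm.ncm import NCMFit
        fit = NCMFit(Nm=50.0, r_squared=0.9, F_hat=np.array([0.5]),
                     band_lower=np.array([lower]), band_upper=np.array([upper]),
                     converged=True, n_iterations=1, sse=0.0)
        return inp, fit

    @pytest.mark.parametrize("F,expected", [
        (0.9, "above"), (0.8, "neutral"), (0.1, "below"), (0.2, "neutral")])
    def test_strict_inequalities_with_boundary_ties_neutral(self, F, expected):
        inp, fit = self._inp_fit(F, 0.2, 0.8)
        assert classify_partitions(inp, fit)["label"][0] == expected

    def test_labels_exhaustive_and_dropped_excluded(self, neutral_slice):
        cm, _ = neutral_slice
        inp = prepare_ncm_input(cm)
        fit = fit_ncm(inp)
        parts = classify_partitions(inp, fit)
        counts = partition_counts(parts)
        assert sum(counts.values()) == len(parts) == len(inp.sgb_ids)
        assert not set(inp.dropped) & set(parts["sgb_id"])
        props = np.array(list(counts.values())) / len(parts)
        assert props.sum() == pytest.approx(1.0)

    def test_non_converged_fit_rejected(self):
        inp, fit = self._inp_fit(0.5, 0.2, 0.8)
        fit.converged = False
        with pytest.raises(ValueError):
            classify_partitions(inp, fit)
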