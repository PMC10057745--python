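import math

import numpy as np
import pytest

from sizespectra.spectrum_stats import (
    NORMALIZATION_OFFSET,
    EmptySpectrumError,
    aicc,
    filter_bins,
    fit_mixture,
    fit_power_law,
    to_abundance,
    to_normalized,
)


class TestFilterBins:
    def test_rule_application(self):
        x = np.array([0.0, 1.0])
        dens = np.array([1e-6, 1e-4])
        xs, ys = filter_bins(x, dens, cutoff=1e-5)
        assert xs.tolist() == [1.0]
        assert ys[0] == pytest.approx(-4.0)

    def test_boundary_value_retained(self):
        xs, ys = filter_bins(np.array([0.0]), np.array([1e-5]), cutoff=1e-5)
        assert xs.size == 1

    def test_identity_when_all_above(self):
        x = np.linspace(0, 1, 5)
        xs, _ = filter_bins(x, np.ones(5), cutoff=1e-5)
        assert np.array_equal(xs, x)

    def test_all_removed_raises(self):
        with pytest.raises(EmptySpectrumError):
            filter_bins(np.array([0.0]), np.array([1e-9]), cutoff=1e-5)

    def test_bin_width_converts_to_per_bin_biomass(self):
        x = np.array([0.0, 1.0])
        dens = np.array([4e-4, 3.9e-4])  # bin biomass 1e-5 and 0.975e-5
        xs, ys = filter_bins(x, dens, cutoff=1e-5, bin_width=1 / 40)
        assert xs.tolist() == [0.0]
        assert ys[0] == pytest.approx(-5.0)


class TestPowerLaw:
    def test_exact_line(self):
        x = np.linspace(-3, 3, 20)
        fit = fit_power_law(x, 0.1 * x + 3.0)
        assert fit.slope == pytest.approx(0.1)
        assert fit.intercept == pytest.approx(3.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_flat_points(self):
        x = np.linspace(0, 5, 10)
        fit = fit_power_law(x, np.full(10, 2.0))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_power_law(np.array([0.0, 1.0]), np.array([0.0, 1.0]))


class TestTransforms:
    def test_normalization_offset_value(self):
        # log10(10^0.5 - 10^-0.5) = 0.454243...
        assert NORMALIZATION_OFFSET == pytest.approx(0.454, abs=5e-4)

    def test_normalized_example(self):
        out = to_normalized(np.array([0.0]), np.array([0.0]))
        assert out[0] == pytest.approx(-0.454, abs=5e-4)

    def test_abundance_example(self):
        out = to_abundance(np.array([-15.0]), np.array([1.0]))
        assert out[0] == pytest.approx(16.0)

    def test_alpha_equals_beta_minus_one_exactly(self, rng):
        x = np.sort(rng.uniform(-10, 10, 60))
        y = 0.08 * x + rng.normal(0, 0.4, 60)
        beta = fit_power_law(x, y).slope
        alpha = fit_power_law(x, to_abundance(x, y)).slope
        assert alpha == pytest.approx(beta - 1.0, abs=1e-12)

    def test_normalized_minus_abundance_constant(self, rng):
        x = rng.uniform(-5, 5, 30)
        y = rng.normal(size=30)
        diff = to_normalized(x, y) - to_abundance(x, y)
        assert np.allclose(diff, -NORMALIZATION_OFFSET)


class TestAicc:
    def test_closed_form_example(self):
        assert aicc(100.0, 100, 3) == pytest.approx(6.25)

    def test_penalty_monotonic_in_k(self):
        assert aicc(10.0, 50, 7) > aicc(10.0, 50, 4)

    def test_undefined_when_too_few_points(self):
        with pytest.raises(ValueError):
            aicc(1.0, 5, 4)


class TestMixture:
    def test_single_component_recovery(self):
        x = np.linspace(-18, 0, 400)
        y_shifted = 5.0 * np.exp(-(((x + 10.0) / 2.0) ** 2))
        y = y_shifted - 6.0  # fit_mixture adds the +6 shift back
        fit = fit_mixture(x, y, 1, cutoff=1e-5, n_starts=8, seed=1)
        assert fit.amplitudes[0] == pytest.approx(5.0, rel=0.01)
        assert fit.centers[0] == pytest.approx(-10.0, abs=0.02)
        assert fit.widths[0] == pytest.approx(2.0, rel=0.01)
        assert fit.r2 > 0.999

    def test_two_separated_components(self):
        x = np.linspace(-18, 10, 600)
        y = (
            4.0 * np.exp(-(((x + 12.0) / 1.5) ** 2))
            + 6.0 * np.exp(-(((x - 5.0) / 2.5) ** 2))
            - 6.0
        )
        fit = fit_mixture(x, y, 2, cutoff=1e-5, n_starts=10, seed=2)
        centers = np.sort(fit.centers)
        assert centers[0] == pytest.approx(-12.0, abs=0.1)
        assert centers[1] == pytest.approx(5.0, abs=0.1)

    def test_warm_start_never_increases_rss(self, rng):
        x = np.linspace(-10, 10, 300)
        y = (
            3.0 * np.exp(-(((x + 4.0) / 2.0) ** 2))
            + 2.0 * np.exp(-(((x - 4.0) / 1.0) ** 2))
            - 6.0
            + rng.normal(0, 0.05, x.size)
        )
        f1 = fit_mixture(x, y, 1, n_starts=6, seed=3)
        f2 = fit_mixture(x, y, 2, n_starts=0, warm_start=f1, seed=3)
        assert f2.rss <= f1.rss + 1e-9

    def test_aicc_prefers_two_components_on_bimodal_data(self, rng):
        """On clearly bimodal curves the 2-component AICc wins in >= 95%
        of noisy replicates."""
        x = np.linspace(-12, 12, 240)
        base = (
            4.0 * np.exp(-(((x + 6.0) / 1.5) ** 2))
            + 3.0 * np.exp(-(((x - 6.0) / 2.0) ** 2))
        )
        wins = 0
        n_rep = 20
        for r in range(n_rep):
            y = base + rng.normal(0, 0.1, x.size) - 6.0
            f1 = fit_mixture(x, y, 1, n_starts=4, seed=10 + r)
            f2 = fit_mixture(x, y, 2, n_starts=4, warm_start=f1, seed=10 + r)
            if f2.aicc < f1.aicc:
                wins += 1
        assert wins >= 0.95 * n_rep

    def test_r2_reported_on_shifted_fit(self):
        x = np.linspace(-5, 5, 100)
        y = 2.0 * np.exp(-(x**2)) - 6.0
        fit = fit_mixture(x, y, 1, n_starts=4, seed=4)
        pred = fit.predict(x)
        assert np.allclose(pred, y, atol=1e-3)

    def test_component_count_validated(self):
        x = np.linspace(0, 1, 30)
        with pytest.raises(ValueError):
            fit_mixture(x, np.zeros(30), 5)
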