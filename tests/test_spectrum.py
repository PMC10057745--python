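import numpy as np
import pytest

from sizespectra.gev import TruncatedGEV
from sizespectra.spectrum import (
    SpectrumGrid,
    envelope,
    find_modes,
    group_density,
    realm_spectra,
    replicate_spectrum,
)


@pytest.fixture(scope="module")
def grid():
    return SpectrumGrid()


@pytest.fixture(scope="module")
def dist():
    return TruncatedGEV(mu=-2.0, sigma=1.5, xi=0.2, lower=-6.0, upper=3.0)


class TestGrid:
    def test_base_grid_shape(self, grid):
        assert grid.n_bins == 1160
        x = grid.x
        assert x[0] == pytest.approx(-18 + 0.5 / 40)
        assert np.allclose(np.diff(x), 1 / 40)
        assert x[-1] < 11

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            SpectrumGrid(lo=2, hi=1)


class TestGroupDensity:
    def test_zero_biomass(self, dist, grid):
        assert np.all(group_density(dist, 0.0, grid) == 0.0)

    def test_biomass_conserved(self, dist, grid):
        dens = group_density(dist, 10.0, grid)
        assert dens.sum() * grid.spacing == pytest.approx(10.0, rel=5e-3)

    def test_conservation_even_for_spike(self, grid):
        spike = TruncatedGEV(mu=-2.0, sigma=1e-3, xi=0.0, lower=-4.0, upper=0.0)
        dens = group_density(spike, 3.0, grid)
        assert dens.sum() * grid.spacing == pytest.approx(3.0, rel=5e-3)

    def test_linearity(self, dist, grid):
        one = group_density(dist, 1.0, grid)
        two = group_density(dist, 2.0, grid)
        assert np.allclose(one + one, two)

    def test_resolution_convergence(self, dist):
        coarse = SpectrumGrid(resolution=40)
        fine = SpectrumGrid(resolution=80)
        a = group_density(dist, 1.0, coarse).sum() * coarse.spacing
        b = group_density(dist, 1.0, fine).sum() * fine.spacing
        assert abs(a - b) < 1e-3


class TestCumulative:
    def test_total_equals_catalog_sum(self, small_ensemble, grid):
        sp = replicate_spectrum(
            small_ensemble, 0, ("terrestrial", "marine", "subterranean"), grid
        )
        total = sp.sum() * grid.spacing
        drawn = small_ensemble.biomass[0].sum()
        # marine archaea extend slightly below the grid; tolerance 0.5%
        assert total == pytest.approx(drawn, rel=5e-3)

    def test_realm_additivity(self, small_ensemble, grid):
        sets = {
            "all": ("terrestrial", "marine", "subterranean"),
            "t": ("terrestrial",),
            "m": ("marine",),
            "s": ("subterranean",),
        }
        sp = realm_spectra(small_ensemble, sets, grid)
        assert np.allclose(sp["t"] + sp["m"] + sp["s"], sp["all"], atol=1e-9)

    def test_filter_excludes_other_realms(self, small_ensemble, grid):
        terr = realm_spectra(small_ensemble, {"t": ("terrestrial",)}, grid)["t"]
        # subterranean groups live below -11 log g; terrestrial curve must
        # not contain their peak mass
        only_sub = replicate_spectrum(small_ensemble, 0, ("subterranean",), grid)
        overlap = np.minimum(terr[0], only_sub)
        assert overlap.sum() * grid.spacing < only_sub.sum() * grid.spacing

    def test_empty_filter_rejected(self, small_ensemble, grid):
        with pytest.raises(ValueError):
            replicate_spectrum(small_ensemble, 0, (), grid)


class TestEnvelope:
    def test_identical_replicates_coincide(self, grid):
        curve = np.exp(-0.5 * (grid.x + 3) ** 2)
        stack = np.tile(curve, (10, 1))
        env = envelope(stack, grid)
        assert np.allclose(env.lower, env.median)
        assert np.allclose(env.median, env.upper)

    def test_percentile_convention(self, grid):
        stack = np.tile(
            np.arange(1, 101, dtype=float)[:, None], (1, grid.n_bins)
        )
        env = envelope(stack, grid)
        assert np.allclose(env.median, 50.5)  # linear interpolation

    def test_ordering_invariant(self, small_ensemble, grid):
        sp = realm_spectra(
            small_ensemble, {"all": ("terrestrial", "marine", "subterranean")}, grid
        )["all"]
        env = envelope(sp, grid)
        assert np.all(env.lower <= env.median + 1e-12)
        assert np.all(env.median <= env.upper + 1e-12)

    def test_lognormal_perturbation_width(self, grid, rng):
        """1000 lognormally jittered copies of one curve produce an
        envelope whose width matches the generating fold uncertainty."""
        curve = np.full(grid.n_bins, 2.0)
        lam = 4.0
        sd = np.log10(lam) / 1.96
        factors = 10 ** (rng.normal(0, sd, size=1000))
        env = envelope(curve[None, :] * factors[:, None], grid)
        assert np.median(env.upper / env.median) == pytest.approx(lam, rel=0.1)
        assert np.median(env.median / env.lower) == pytest.approx(lam, rel=0.1)

    def test_needs_two_replicates(self, grid):
        with pytest.raises(ValueError):
            envelope(np.ones((1, grid.n_bins)), grid)


class TestFindModes:
    def test_unimodal_curve(self, grid):
        curve = np.exp(-0.5 * ((grid.x + 4.0) / 1.5) ** 2)
        modes = find_modes(curve, grid)
        assert len(modes) == 1
        assert modes[0][0] == pytest.approx(-4.0, abs=grid.spacing)

    def test_flat_curve_has_no_strict_maximum(self, grid):
        assert find_modes(np.ones(grid.n_bins), grid) == []

    def test_sorted_by_density(self, grid):
        curve = np.exp(-0.5 * ((grid.x + 10.0) / 1.0) ** 2) + 3 * np.exp(
            -0.5 * ((grid.x - 5.0) / 1.0) ** 2
        )
        modes = find_modes(curve, grid)
        assert modes[0][0] == pytest.approx(5.0, abs=grid.spacing)
        assert modes[0][1] > modes[1][1]
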