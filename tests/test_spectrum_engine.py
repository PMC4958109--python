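"""Spectrum generation: kV spline, ripple, defaults, normalization, comparison."""

import numpy as np
import pytest

from beamkit import (ConfigurationError, EnergyGrid, OutOfRangeError,
                     ScaleFactorTable, SpectralTable, Spectrum, air_kerma,
                     apply_ripple, beers_filter, compare_spectra,
                     compute_scale_factors, generate_spectrum,
                     interpolate_fluence)
from beamkit.errors import DataValidationError
from beamkit.filtration import FilterLayer
from beamkit import fixtures


@pytest.fixture(scope="module")
def table():
    return fixtures.default_spectral_table()


def cubic_table(grid_bins=10):
    """Table whose per-bin fluence is an exact cubic polynomial of kV."""
    grid = EnergyGrid(n_bins=grid_bins)
    nodes = np.array([40.0, 60.0, 80.0, 100.0, 120.0])
    rng = np.random.default_rng(7)
    coeffs = rng.uniform(0.1, 1.0, size=(grid_bins, 4))  # positive cubic

    def poly(kv):
        kvs = (kv - 40.0) / 80.0  # scaled to keep values well-conditioned
        return coeffs[:, 0] + coeffs[:, 1] * kvs + coeffs[:, 2] * kvs**2 \
            + coeffs[:, 3] * kvs**3

    fluence = np.vstack([poly(kv) for kv in nodes]) * 1e4
    return SpectralTable(model_name="cubic", kv_nodes=nodes, fluence=fluence,
                         grid=grid), lambda kv: poly(kv) * 1e4


class TestInterpolation:
    def test_node_query_returns_exact_row(self, table):
        for i, kv in enumerate(table.kv_nodes):
            assert np.array_equal(interpolate_fluence(table, kv),
                                  table.fluence[i])

    def test_reproduces_generating_cubic_between_nodes(self):
        tab, poly = cubic_table()
        for kv in (47.3, 72.0, 111.9):
            got = interpolate_fluence(tab, kv)
            assert np.allclose(got, poly(kv), rtol=1e-9)

    @pytest.mark.parametrize("kv", [19.9, 151.0, 500.0])
    def test_no_silent_extrapolation(self, table, kv):
        with pytest.raises(OutOfRangeError):
            interpolate_fluence(table, kv)

    def test_interpolated_fluence_nonnegative(self, table):
        for kv in np.linspace(20, 150, 27):
            assert np.all(interpolate_fluence(table, kv) >= 0)


class TestRipple:
    def test_zero_ripple_is_plain_interpolation(self, table):
        assert np.array_equal(apply_ripple(table, 85.0, 0.0),
                              interpolate_fluence(table, 85.0))

    def test_two_sample_ripple_is_mean_of_endpoints(self, table):
        got = apply_ripple(table, 100.0, 10.0, n_samples=2)
        expected = 0.5 * (interpolate_fluence(table, 90.0)
                          + interpolate_fluence(table, 100.0))
        assert np.allclose(got, expected, rtol=1e-12)

    def test_ripple_reduces_total_fluence(self, table):
        # fixture total fluence is increasing in kV, so averaging over
        # lower potentials can only lose photons
        for r in (5.0, 20.0):
            assert apply_ripple(table, 120.0, r).sum() <= \
                interpolate_fluence(table, 120.0).sum()

    def test_ripple_trough_below_table_is_an_error(self, table):
        with pytest.raises(OutOfRangeError):
            apply_ripple(table, 21.0, 50.0)

    def test_invalid_ripple_rejected(self, table):
        with pytest.raises(DataValidationError):
            apply_ripple(table, 100.0, 100.0)


class TestGenerate:
    def test_default_call_applies_inherent_al_and_normalizes(self):
        spec = generate_spectrum(70)
        assert spec.filtration_log == [("Al", 1.6)]
        assert spec.normalized
        assert spec.kv == 70
        explicit = generate_spectrum(70, 1.6, 0.0, normalize=True)
        assert np.array_equal(spec.fluence, explicit.fluence)

    def test_unnormalized_node_query_is_table_row(self, table):
        spec = generate_spectrum(80, 0.0, 0.0, normalize=False)
        assert np.array_equal(spec.fluence,
                              table.fluence[list(table.kv_nodes).index(80.0)])
        assert spec.filtration_log == []

    def test_duane_hunt_limit(self):
        spec = generate_spectrum(60, 0.0, 0.0, normalize=False)
        assert np.all(spec.fluence[spec.grid.lower_edges >= 60] == 0)

    def test_generation_linear_in_table(self, table):
        doubled = SpectralTable(model_name="x2", kv_nodes=table.kv_nodes,
                                fluence=2 * table.fluence, grid=table.grid)
        a = generate_spectrum(95, 1.0, 0.0, table=table, normalize=False)
        b = generate_spectrum(95, 1.0, 0.0, table=doubled, normalize=False)
        assert np.allclose(b.fluence, 2 * a.fluence, rtol=1e-12)

    def test_normalize_without_scale_table_is_an_error(self, table):
        with pytest.raises(ConfigurationError):
            generate_spectrum(80, table=table, normalize=True)


class TestScaleFactors:
    def test_self_normalization_is_unity(self, table):
        sf = compute_scale_factors(table, table, [60.0, 100.0], a_added_al_mm=0.0)
        assert np.allclose(sf.factor, 1.0, rtol=1e-12)

    def test_binwise_doubled_model_gives_half(self, table):
        doubled = SpectralTable(model_name="x2", kv_nodes=table.kv_nodes,
                                fluence=2 * table.fluence, grid=table.grid)
        sf = compute_scale_factors(doubled, table, [60.0, 100.0, 140.0],
                                   a_added_al_mm=0.0)
        assert np.allclose(sf.factor, 0.5, rtol=1e-12)

    def test_normalized_kerma_matches_reference(self, table):
        # the normalization contract: s(kv) * kerma(A filtered) == kerma(B)
        legacy = fixtures.legacy_reference_table()
        kv_list = [60.0, 90.0, 120.0]
        sf = compute_scale_factors(table, legacy, kv_list, a_added_al_mm=1.6)
        for kv in kv_list:
            spec = generate_spectrum(kv, 1.6, 0.0, table=table,
                                     normalize=True, scale_factors=sf)
            ref = Spectrum(interpolate_fluence(legacy, kv), grid=legacy.grid)
            assert air_kerma(spec) == pytest.approx(air_kerma(ref), rel=1e-9)

    def test_factor_interpolates_linearly_between_stored_kv(self):
        sf = ScaleFactorTable(kv=[60.0, 80.0], factor=[1.0, 2.0])
        assert sf(70.0) == pytest.approx(1.5)
        with pytest.raises(OutOfRangeError):
            sf(59.0)

    def test_nonpositive_factors_rejected(self):
        with pytest.raises(DataValidationError):
            ScaleFactorTable(kv=[60.0, 80.0], factor=[1.0, 0.0])


class TestCompare:
    def test_identical_models(self, table):
        result = compare_spectra(table, table, [60.0, 100.0], bin_range=(10, 150))
        assert result.median_percent_diff == 0.0
        assert all(r2 == pytest.approx(1.0) for r2 in result.r_squared.values())

    def test_uniform_scaling_gives_flat_percent_difference(self, table):
        scaled = SpectralTable(model_name="s", kv_nodes=table.kv_nodes,
                               fluence=1.05 * table.fluence, grid=table.grid)
        result = compare_spectra(scaled, table, [80.0], bin_range=(10, 70))
        assert np.allclose(result.percent_diff, 5.0, rtol=1e-12)
        assert result.median_percent_diff == pytest.approx(5.0)
        assert result.r_squared[80.0] == pytest.approx(1.0)

    def test_denominator_convention_sign(self, table):
        # percent difference is 100*(a-b)/b: swapping roles changes the
        # magnitude through the denominator, not just the sign
        scaled = SpectralTable(model_name="s", kv_nodes=table.kv_nodes,
                               fluence=1.05 * table.fluence, grid=table.grid)
        forward = compare_spectra(scaled, table, [80.0], bin_range=(10, 70))
        backward = compare_spectra(table, scaled, [80.0], bin_range=(10, 70))
        assert forward.median_percent_diff == pytest.approx(5.0)
        assert backward.median_percent_diff == pytest.approx(-100 * 0.05 / 1.05)

    def test_zero_reference_bins_are_excluded_and_counted(self, table):
        result = compare_spectra(table, table, [60.0], bin_range=(1, 150))
        # bins at/above 60 keV are zero in the reference at 60 kV
        assert result.n_zero_excluded == 91
        assert np.isfinite(result.percent_diff).all()

    def test_spectra_reproducible_from_filtration_log(self):
        spec = generate_spectrum(90)
        rebuilt = generate_spectrum(90, 0.0, 0.0, normalize=False)
        for material, thickness in spec.filtration_log:
            rebuilt = beers_filter(rebuilt, [FilterLayer(material, thickness)])
        rebuilt = rebuilt.scaled(fixtures.default_scale_factors()(90))
        assert np.allclose(rebuilt.fluence, spec.fluence, rtol=1e-12)
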