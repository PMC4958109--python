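"""Energy grid, elemental/compound attenuation, and the compound registry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beamkit import (COMPOUND_REGISTRY, DEFAULT_GRID, EnergyGrid,
                     MaterialNotFoundError, mu_rho_compound, mu_rho_element)
from beamkit.errors import DataValidationError
from beamkit.materials import (CompoundSpec, MaterialLibrary, _ElementTable,
                               SYNTHETIC_A_PER_Z3, SYNTHETIC_B, K_EDGE_KEV,
                               K_EDGE_JUMP, default_library,
                               synthetic_mu_over_rho)


class TestEnergyGrid:
    def test_bin_convention(self):
        g = EnergyGrid(n_bins=150)
        assert g.bin_center(1) == 1.5
        assert g.bin_center(150) == 150.5
        assert np.array_equal(g.centers, g.lower_edges + 0.5)
        assert np.all(np.diff(g.centers) > 0)

    def test_bin_of_contains_energy(self):
        g = EnergyGrid()
        assert g.bin_of(57.98) == 57
        assert g.bin_of(59.32) == 59

    @pytest.mark.parametrize("n", [0, -3])
    def test_rejects_degenerate_grid(self, n):
        with pytest.raises(ValueError):
            EnergyGrid(n_bins=n)


class TestElements:
    def test_symbol_and_z_give_identical_curves(self):
        by_symbol = mu_rho_element("Al")
        by_z = mu_rho_element(13)
        assert np.array_equal(by_symbol.mu_over_rho, by_z.mu_over_rho)
        assert by_symbol.density == by_z.density

    def test_analytic_form_at_bin_center(self):
        # light element (no K-edge in range): a/E^3 + b exactly at 10.5 keV
        curve = mu_rho_element(6)  # carbon
        a = SYNTHETIC_A_PER_Z3 * 6**3
        expected = a * 10.5**-3 + SYNTHETIC_B
        assert curve.mu_over_rho[9] == pytest.approx(expected, rel=1e-12)

    def test_mu_linear_unit_conversion(self):
        curve = mu_rho_element("Al")
        assert np.allclose(curve.mu_linear,
                           curve.mu_over_rho * curve.density / 10.0)

    @pytest.mark.parametrize("bad", [999, "Xx", -1])
    def test_unknown_material_names_identifier(self, bad):
        with pytest.raises(MaterialNotFoundError) as err:
            mu_rho_element(bad)
        assert str(bad) in str(err.value)

    def test_k_edge_discontinuity_for_tungsten(self):
        curve = mu_rho_element(74)
        ek = K_EDGE_KEV[74]  # 69.525 keV, between bin centers 69.5 and 70.5
        below = curve.mu_over_rho[68]  # center 69.5
        above = curve.mu_over_rho[69]  # center 70.5
        photo_below = SYNTHETIC_A_PER_Z3 * 74**3 / 69.5**3 / K_EDGE_JUMP
        assert below == pytest.approx(photo_below + SYNTHETIC_B, rel=1e-12)
        assert above > 3 * below
        assert 69.5 < ek < 70.5

    def test_interpolation_exact_at_source_energies(self):
        # querying exactly at tabulated energies reproduces the table
        lib = default_library()
        curve = lib.element_curve("Cu", DEFAULT_GRID)
        assert np.allclose(curve.mu_over_rho,
                           synthetic_mu_over_rho(29, DEFAULT_GRID.centers),
                           rtol=1e-12)

    def test_loglog_interpolation_between_source_points(self):
        # pure power law tabulated at two points interpolates exactly
        table = _ElementTable(Z=1, symbol="Pw", density=1.0,
                              energies=np.array([10.0, 40.0]),
                              mu_over_rho=np.array([1000.0, 1000.0 * 4.0**-3]))
        lib = MaterialLibrary(elements={1: table})
        small = EnergyGrid(n_bins=30)
        curve = lib.element_curve("Pw", small)
        inside = (small.centers >= 10) & (small.centers <= 40)
        expected = 1000.0 * (small.centers[inside] / 10.0) ** -3
        assert np.allclose(curve.mu_over_rho[inside], expected, rtol=1e-12)


class TestCompounds:
    def test_registry_corrected_densities(self):
        assert mu_rho_compound("Gd2O2S").density == 7.44
        assert mu_rho_compound("GaAs").density == 5.31

    def test_registry_fractions_sum_to_one(self):
        for spec in COMPOUND_REGISTRY:
            assert sum(w for _, w in spec.composition) == pytest.approx(1.0, abs=1e-9)

    def test_registry_indices_and_names_unique(self):
        indices = [c.index for c in COMPOUND_REGISTRY]
        names = [c.name.lower() for c in COMPOUND_REGISTRY]
        assert len(set(indices)) == len(indices)
        assert len(set(names)) == len(names)

    def test_lookup_by_index_matches_name(self):
        by_name = mu_rho_compound("Water")
        by_index = mu_rho_compound(1)
        assert np.array_equal(by_name.mu_over_rho, by_index.mu_over_rho)

    def test_single_element_compound_degenerates_to_element(self):
        spec = CompoundSpec(name="pure-al", index=20,
                            composition=[(13, 1.0)], density=2.699)
        compound = mu_rho_compound(spec)
        element = mu_rho_element(13)
        assert np.allclose(compound.mu_over_rho, element.mu_over_rho, rtol=1e-15)
        assert compound.density == element.density

    def test_mixture_rule_against_hand_weighted_sum(self):
        spec = CompoundSpec(name="mix", index=19,
                            composition=[(13, 0.3), (29, 0.7)], density=5.0)
        compound = mu_rho_compound(spec)
        al = mu_rho_element(13).mu_over_rho
        cu = mu_rho_element(29).mu_over_rho
        for b in (0, 9, 49, 99, 149):  # 5 sampled bins
            assert compound.mu_over_rho[b] == pytest.approx(
                0.3 * al[b] + 0.7 * cu[b], rel=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(w=st.floats(min_value=0.01, max_value=0.99),
           scale=st.floats(min_value=0.1, max_value=10.0))
    def test_mixture_linear_under_renormalization(self, w, scale):
        # scaling all fractions then renormalizing leaves the curve unchanged
        base = CompoundSpec(name="m", index=18,
                            composition=[(13, w), (29, 1 - w)], density=3.0)
        total = scale * w + scale * (1 - w)
        renorm = CompoundSpec(name="m", index=18,
                              composition=[(13, scale * w / total),
                                           (29, scale * (1 - w) / total)],
                              density=3.0)
        assert np.allclose(mu_rho_compound(base).mu_over_rho,
                           mu_rho_compound(renorm).mu_over_rho, rtol=1e-12)

    def test_bad_fractions_rejected(self):
        with pytest.raises(DataValidationError):
            CompoundSpec(name="bad", index=17,
                         composition=[(13, 0.5), (29, 0.4)], density=1.0)

    def test_unknown_compound_identifiers(self):
        with pytest.raises(MaterialNotFoundError):
            mu_rho_compound("unobtainium")
        with pytest.raises(MaterialNotFoundError):
            mu_rho_compound(19)  # empty registry slot
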