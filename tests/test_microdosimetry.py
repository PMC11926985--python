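"""Microdosimetric estimators against closed forms and brute force."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytodose.errors import DomainError
from cytodose.microdosimetry import (
    FluencePair,
    PulseHeightSpectrum,
    combine_spectra,
    dose_distribution,
    hit_distribution,
    icrp60_quality_factor,
    lineal_energy_means,
    mean_quality_factor,
    specific_energy_from_lineal,
)
from tests.conftest import make_spectrum


class TestCombine:
    def test_zero_gamma_fluence_returns_neutron_spectrum(self):
        edges = np.geomspace(0.1, 100, 11)
        n = PulseHeightSpectrum(edges, np.arange(10.0), "neutron")
        g = PulseHeightSpectrum(edges, np.ones(10), "gamma")
        combined = combine_spectra(n, g, FluencePair(0.177, 0.0))
        assert np.array_equal(combined.counts, n.counts)

    def test_equal_fluences_give_arithmetic_mean(self):
        edges = np.geomspace(1, 100, 5)
        n = PulseHeightSpectrum(edges, [4.0, 0.0, 2.0, 6.0], "neutron")
        g = PulseHeightSpectrum(edges, [0.0, 2.0, 2.0, 0.0], "gamma")
        combined = combine_spectra(n, g, FluencePair(0.5, 0.5))
        assert np.allclose(combined.counts, [2.0, 1.0, 2.0, 3.0])

    def test_hand_computed_weighting_with_study_fluences(self):
        edges = np.geomspace(1, 100, 3)
        n = PulseHeightSpectrum(edges, [10.0, 20.0], "neutron")
        g = PulseHeightSpectrum(edges, [40.0, 4.0], "gamma")
        phi = FluencePair(0.177, 0.00265)
        combined = combine_spectra(n, g, phi)
        w_n = 0.177 / (0.177 + 0.00265)
        w_g = 0.00265 / (0.177 + 0.00265)
        assert combined.counts[0] == pytest.approx(w_n * 10 + w_g * 40)
        assert combined.counts[1] == pytest.approx(w_n * 20 + w_g * 4)

    def test_conserves_weighted_totals_exactly(self):
        edges = np.geomspace(0.1, 100, 31)
        rng = np.random.default_rng(3)
        n = PulseHeightSpectrum(edges, rng.random(30), "neutron")
        g = PulseHeightSpectrum(edges, rng.random(30), "gamma")
        phi = FluencePair(0.178, 0.0022)
        combined = combine_spectra(n, g, phi)
        w_n = phi.phi_n / (phi.phi_n + phi.phi_gamma)
        w_g = phi.phi_gamma / (phi.phi_n + phi.phi_gamma)
        assert combined.counts.sum() == pytest.approx(
            w_n * n.counts.sum() + w_g * g.counts.sum(), rel=1e-14)

    def test_mismatched_binning_rejected(self):
        n = PulseHeightSpectrum(np.geomspace(0.1, 100, 11), np.ones(10), "neutron")
        g = PulseHeightSpectrum(np.geomspace(0.1, 90, 11), np.ones(10), "gamma")
        with pytest.raises(DomainError):
            combine_spectra(n, g, FluencePair(1.0, 1.0))


class TestLinealMeans:
    def test_degenerate_single_bin(self):
        spec = make_spectrum([10.0], [100.0])
        y_f, y_d = lineal_energy_means(spec)
        assert y_f == pytest.approx(10.0)
        assert y_d == pytest.approx(10.0)

    def test_two_equal_bins_closed_form(self):
        spec = make_spectrum([1.0, 100.0], [1.0, 1.0])
        y_f, y_d = lineal_energy_means(spec)
        assert y_f == pytest.approx(50.5)
        # (1*1^2 + 1*100^2) / (1*1 + 1*100)
        assert y_d == pytest.approx(10001 / 101)

    @given(counts=st.lists(st.floats(0.0, 100.0), min_size=6, max_size=6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_dose_mean_at_least_frequency_mean(self, counts):
        if sum(counts) == 0:
            return
        spec = PulseHeightSpectrum(np.geomspace(0.1, 100, 7), counts)
        y_f, y_d = lineal_energy_means(spec)
        assert y_d >= y_f - 1e-12

    def test_empty_spectrum_rejected(self):
        spec = PulseHeightSpectrum(np.geomspace(0.1, 100, 7), np.zeros(6))
        with pytest.raises(DomainError):
            lineal_energy_means(spec)


class TestDoseDistribution:
    def test_single_bin_carries_all_dose(self):
        spec = make_spectrum([10.0], [5.0])
        vals = dose_distribution(spec)
        dlog = np.diff(np.log10(spec.bin_edges))
        assert float(vals @ dlog) == pytest.approx(1.0)

    def test_normalisation_sums_to_one(self, toy_spectrum):
        vals = dose_distribution(toy_spectrum)
        dlog = np.diff(np.log10(toy_spectrum.bin_edges))
        assert float(vals @ dlog) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_counts_grow_proportionally_to_y(self):
        # equal counts on log-uniform bins: dose fraction per bin ~ y_i
        edges = np.geomspace(1.0, 64.0, 7)
        spec = PulseHeightSpectrum(edges, np.ones(6))
        vals = dose_distribution(spec)
        ratio = vals / spec.midpoints
        assert np.allclose(ratio, ratio[0])

    def test_neutron_dominated_spectrum_puts_dose_high(self):
        """When neutron counts dominate the >10 keV/um bins the majority
        of the dose sits above 10 keV/um."""
        edges = np.geomspace(0.1, 100, 31)
        counts = np.where(np.sqrt(edges[:-1] * edges[1:]) > 10, 5.0, 1.0)
        spec = PulseHeightSpectrum(edges, counts)
        vals = dose_distribution(spec)
        dlog = np.diff(np.log10(edges))
        high = spec.midpoints > 10
        assert float(vals[high] @ dlog[high]) > 0.5


class TestQualityFactor:
    def test_low_let_plateau(self):
        spec = make_spectrum([0.5, 2.0, 8.0], [1.0, 2.0, 1.0])
        assert mean_quality_factor(spec) == pytest.approx(1.0)

    def test_single_bin_at_q_twenty(self):
        y20 = (20 + 2.2) / 0.32  # Q(y) = 0.32 y - 2.2 = 20
        spec = make_spectrum([y20], [3.0])
        assert mean_quality_factor(spec) == pytest.approx(20.0, rel=1e-9)

    def test_matches_brute_force_weighted_sum(self, toy_spectrum):
        y = toy_spectrum.midpoints
        c = toy_spectrum.counts
        expected = sum(
            icrp60_quality_factor(yi) * ci * yi for yi, ci in zip(y, c)
        ) / sum(ci * yi for yi, ci in zip(y, c))
        assert mean_quality_factor(toy_spectrum) == pytest.approx(expected, rel=1e-12)

    def test_relation_is_pluggable(self, toy_spectrum):
        assert mean_quality_factor(toy_spectrum, lambda y: np.ones_like(y)) == (
            pytest.approx(1.0))

    def test_piecewise_branches(self):
        assert icrp60_quality_factor(5.0) == 1.0
        assert icrp60_quality_factor(50.0) == pytest.approx(0.32 * 50 - 2.2)
        assert icrp60_quality_factor(400.0) == pytest.approx(300 / 20.0)


class TestSpecificEnergy:
    @pytest.mark.parametrize("y_f,expected", [
        (2.35, 479.40), (2.53, 516.12), (6.44, 1313.76), (6.74, 1374.96),
    ])
    def test_published_unit_sphere_values(self, y_f, expected):
        assert specific_energy_from_lineal(y_f, 1.0, 1.0) == pytest.approx(
            expected, abs=1.0)

    def test_inverse_square_diameter_scaling(self):
        z1 = specific_energy_from_lineal(2.35, 1.0, 1.0)
        z2 = specific_energy_from_lineal(2.35, 2.0, 1.0)
        assert z1 / z2 == pytest.approx(4.0, rel=1e-12)

    def test_inverse_density_scaling(self):
        z1 = specific_energy_from_lineal(2.35, 1.0, 1.0)
        z2 = specific_energy_from_lineal(2.35, 1.0, 2.0)
        assert z1 / z2 == pytest.approx(2.0, rel=1e-12)


class TestHitModel:
    def test_highest_super_mirror_dose_point(self):
        h = hit_distribution(408.0, 479.40)
        assert h.N == pytest.approx(0.851, abs=1e-3)
        assert h.p[0] == pytest.approx(0.427, abs=1e-3)
        assert h.p[1] == pytest.approx(0.363, abs=1e-3)
        assert h.p_multi == pytest.approx(0.210, abs=1e-3)

    def test_low_dose_pg_point(self):
        h = hit_distribution(82.1, 516.12)
        assert h.N == pytest.approx(0.159, abs=1e-3)
        assert h.p[1] == pytest.approx(0.136, abs=1e-3)

    def test_zero_dose(self):
        h = hit_distribution(0.0, 479.40)
        assert h.p[0] == 1.0
        assert np.all(h.p[1:] == 0.0)
        assert h.p_multi == 0.0

    @pytest.mark.parametrize("n_mean", [0.01, 0.5, 3.0])
    def test_probabilities_sum_to_one_with_tail(self, n_mean):
        h = hit_distribution(n_mean * 479.4, 479.4, nu_max=60)
        assert float(h.p.sum()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_zf_rejected(self):
        with pytest.raises(DomainError):
            hit_distribution(100.0, 0.0)
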