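import numpy as np
import pytest

from lvcspec import (DiabaticState, InterStateCoupling, LVCError,
                     LVCHamiltonian, ModeBasis, Spectrum, default_energy_grid,
                     fcvg_correlation, fcvg_spectrum, hwhm_to_gamma,
                     make_displaced_monomer, nonadiabatic_spectrum, peak_hwhm,
                     recover_progression_parameters,
                     spectrum_from_correlations, stick_spectrum_fcvg,
                     weighted_average_spectrum)
from lvcspec.constants import HBAR_EVFS
from lvcspec.lineshape import huang_rhys


class TestCorrelation:
    def test_initial_value_is_one(self, monomer):
        phi = fcvg_correlation(monomer.states[0], monomer.modes,
                               np.array([0.0]))
        assert phi[0] == pytest.approx(1.0, abs=1e-14)

    def test_magnitude_at_ten_fs(self, monomer):
        # |phi(10 fs)| = exp(S (cos(w t / hbar) - 1)) for S=0.5, w=0.15
        phi = fcvg_correlation(monomer.states[0], monomer.modes,
                               np.array([10.0]))
        s, w = 0.5, 0.15
        expect = np.exp(s * (np.cos(w * 10.0 / HBAR_EVFS) - 1.0))
        assert abs(phi[0]) == pytest.approx(expect, rel=1e-12)
        assert abs(phi[0]) == pytest.approx(0.4381, abs=2e-4)

    def test_magnitude_never_exceeds_one(self, monomer):
        t = np.linspace(0, 200, 1000)
        phi = fcvg_correlation(monomer.states[0], monomer.modes, t)
        assert np.all(np.abs(phi) <= 1.0 + 1e-12)

    def test_huang_rhys_round_trip(self, monomer):
        assert huang_rhys(monomer.states[0], monomer.modes)[0] == \
            pytest.approx(0.5, rel=1e-12)


class TestSticks:
    def test_poisson_ratio_exact(self, monomer):
        prog = stick_spectrum_fcvg(monomer.states[0], monomer.modes)
        # I(0-1)/I(0-0) = S = 0.5 exactly
        assert prog.intensities[1] / prog.intensities[0] == 0.5

    def test_positions_are_e00_plus_quanta(self, monomer):
        prog = stick_spectrum_fcvg(monomer.states[0], monomer.modes,
                                   max_quanta=4)
        e00 = 2.0 - 0.5 * 0.15
        assert prog.e00 == pytest.approx(e00, abs=1e-14)
        assert np.allclose(prog.positions,
                           e00 + 0.15 * np.arange(5), atol=1e-12)

    def test_progression_sums_to_one(self, monomer):
        prog = stick_spectrum_fcvg(monomer.states[0], monomer.modes,
                                   max_quanta=40)
        assert prog.intensities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_multimode_product_poisson(self):
        H = make_displaced_monomer(frequencies=(0.15, 0.1),
                                   huang_rhys=(0.3, 0.2))
        prog = stick_spectrum_fcvg(H.states[0], H.modes, max_quanta=2)
        k00 = np.argmax(prog.intensities)
        assert prog.positions[k00] == pytest.approx(prog.e00, abs=1e-12)
        assert prog.intensities[k00] == pytest.approx(np.exp(-0.5),
                                                      rel=1e-12)

    def test_broadened_peak_width(self, monomer):
        prog = stick_spectrum_fcvg(monomer.states[0], monomer.modes)
        omega = np.linspace(1.5, 2.8, 8000)
        y = prog.broadened(omega, hwhm=0.02)
        assert peak_hwhm(omega, y) == pytest.approx(0.02, rel=1e-2)


class TestSpectrumAssembly:
    def test_fcvg_spectrum_peak_near_vertical_energy(self, monomer):
        spec = fcvg_spectrum(monomer, hwhm=0.04)
        assert abs(spec.max_position - 1.925) < 0.01  # 0-0 line dominates

    def test_matches_broadened_sticks(self, monomer):
        omega = np.linspace(1.4, 3.0, 3000)
        spec = fcvg_spectrum(monomer, t_max=300, dt=0.1, hwhm=0.03,
                             omega=omega)
        prog = stick_spectrum_fcvg(monomer.states[0], monomer.modes,
                                   max_quanta=25)
        y = prog.broadened(omega, hwhm=0.03)
        a = spec.normalized("max").total
        b = y / y.max()
        assert np.max(np.abs(a - b)) < 1e-3

    def test_rejects_coupled_model(self):
        H = LVCHamiltonian(
            ModeBasis(np.array([0.15])),
            (DiabaticState("a", "LE", 2.0, np.zeros(1),
                           np.array([1.0, 0, 0])),
             DiabaticState("b", "LE", 2.1, np.zeros(1),
                           np.array([1.0, 0, 0]))),
            (InterStateCoupling((0, 1), 0.05),))
        with pytest.raises(LVCError):
            fcvg_spectrum(H)

    def test_nyquist_guard(self, monomer):
        t = np.arange(0, 100, 2.0)  # limit ~1.03 eV
        phi = fcvg_correlation(monomer.states[0], monomer.modes, t)
        with pytest.raises(LVCError, match="Nyquist"):
            spectrum_from_correlations(
                {(0, 0): phi}, monomer.dipoles, t,
                hwhm_to_gamma(0.04), np.linspace(0, 3, 100))

    def test_single_cross_ordering_doubled(self):
        t = np.arange(0, 50, 0.1)
        phi = np.exp(-1j * 2.0 * t / HBAR_EVFS) * np.exp(-0.001 * t)
        dip = np.array([[1.0, 0, 0], [1.0, 0, 0]])
        omega = np.linspace(1, 3, 500)
        g = hwhm_to_gamma(0.04)
        s1 = spectrum_from_correlations({(0, 1): phi}, dip, t, g, omega)
        s2 = spectrum_from_correlations({(0, 1): phi, (1, 0): phi},
                                        dip, t, g, omega)
        assert np.allclose(s1.total, s2.total, atol=1e-12)

    def test_normalization_modes(self, monomer):
        spec = fcvg_spectrum(monomer)
        assert spec.normalized("max").total.max() == pytest.approx(1.0)
        area = spec.normalized("area")
        assert np.trapezoid(area.total, area.omega) == pytest.approx(1.0)
        with pytest.raises(LVCError):
            spec.normalized("bogus")

    def test_csv_output(self, monomer, tmp_path):
        import pandas as pd

        spec = fcvg_spectrum(monomer)
        p = tmp_path / "spec.csv"
        spec.to_csv(p, metadata_path=tmp_path / "spec.json")
        df = pd.read_csv(p)
        assert "energy_eV" in df.columns and "total" in df.columns
        assert len(df) == spec.omega.size
        assert (tmp_path / "spec.json").exists()

    def test_default_grid_covers_manifold(self, monomer):
        omega = default_energy_grid(monomer)
        assert omega[0] < 2.0 < omega[-1]


class TestNonadiabaticSpectrum:
    def test_components_keyed_lower_triangle(self):
        H = LVCHamiltonian(
            ModeBasis(np.array([0.15])),
            (DiabaticState("a", "LE", 2.0, np.array([0.05]),
                           np.array([1.0, 0, 0])),
             DiabaticState("b", "LE", 2.1, np.array([0.05]),
                           np.array([1.0, 0, 0]))),
            (InterStateCoupling((0, 1), 0.03),))
        spec = nonadiabatic_spectrum(H, n_max=8, t_max=50)
        assert set(spec.components) == {(0, 0), (0, 1), (1, 1)}
        assert np.allclose(spec.total,
                           sum(spec.components.values()), atol=1e-12)

    def test_dark_states_skipped(self):
        H = LVCHamiltonian(
            ModeBasis(np.array([0.15])),
            (DiabaticState("a", "LE", 2.0, np.zeros(1),
                           np.array([1.0, 0, 0])),
             DiabaticState("ct", "CT", 2.3, np.zeros(1), np.zeros(3))),
            (InterStateCoupling((0, 1), 0.02),))
        spec = nonadiabatic_spectrum(H, n_max=6, t_max=50)
        for (i, j) in spec.components:
            assert not (i == 1 and j == 1)


class TestWeightedAverage:
    def test_manual_combination(self, monomer):
        s1 = fcvg_spectrum(monomer)
        H2 = make_displaced_monomer(vertical_energy=2.2)
        s2 = fcvg_spectrum(H2, omega=s1.omega)
        avg = weighted_average_spectrum([s1, s2], [0.6, 0.4])
        assert np.allclose(avg.total, 0.6 * s1.total + 0.4 * s2.total,
                           atol=1e-14)

    def test_weights_must_sum_to_one(self, monomer):
        s = fcvg_spectrum(monomer)
        with pytest.raises(LVCError):
            weighted_average_spectrum([s, s], [0.5, 0.4])


class TestRecovery:
    def test_peak_hwhm_of_gaussian(self):
        omega = np.linspace(-1, 1, 5001)
        sigma = 0.05 / np.sqrt(2 * np.log(2))
        y = np.exp(-(omega**2) / (2 * sigma**2))
        assert peak_hwhm(omega, y) == pytest.approx(0.05, rel=1e-3)

    def test_progression_parameters_recovered(self, monomer):
        omega = np.linspace(1.5, 3.0, 3001)
        spec = fcvg_spectrum(monomer, t_max=200, hwhm=0.02, omega=omega)
        w_est, s_est = recover_progression_parameters(omega, spec.total)
        assert abs(w_est - 0.15) <= omega[1] - omega[0]
        assert abs(s_est - 0.5) / 0.5 < 0.05
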