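"""Peak extraction, surface-area inversion, and electron-transfer kinetics."""

import math

import numpy as np
import pytest

from ampersense import CellSpec, Kinetics, RedoxSpecies, ScanProgram, VoltammogramTrace, simulate_cv
from ampersense.constants import randles_sevcik_coefficient
from ampersense.errors import CalibrationError, NearReversible, NoPeakFound, SuperNernstianRange
from ampersense.voltammetry import (
    CvPeaks,
    esa_randles_sevcik,
    extract_peaks,
    het_fit,
    het_from_peaks,
    psi_extended,
    psi_from_delta_ep,
    psi_oracle,
)

CELL = CellSpec()
SPECIES = RedoxSpecies()


def _gaussian_cv(apex_a=0.25, apex_c=0.15, amp=100e-6, width=0.03, n=600):
    e_fwd = np.linspace(0.0, 0.5, n)
    e_rev = np.linspace(0.5, 0.0, n)[1:]
    i_fwd = amp * np.exp(-((e_fwd - apex_a) ** 2) / (2 * width**2))
    i_rev = -amp * np.exp(-((e_rev - apex_c) ** 2) / (2 * width**2))
    return VoltammogramTrace(
        potential=np.concatenate([e_fwd, e_rev]),
        current=np.concatenate([i_fwd, i_rev]),
        scan_rate=0.1,
    )


class TestExtractPeaks:
    def test_constructed_gaussian_pair(self):
        peaks = extract_peaks(_gaussian_cv())
        assert peaks.ep_anodic == pytest.approx(0.25, abs=0.002)
        assert peaks.ip_anodic == pytest.approx(100e-6, rel=0.01)
        assert peaks.ep_cathodic == pytest.approx(0.15, abs=0.002)
        assert peaks.delta_ep == pytest.approx(0.10, abs=0.003)

    def test_monotonic_ramp_has_no_peak(self):
        e = np.concatenate([np.linspace(0, 0.5, 300), np.linspace(0.5, 0, 300)[1:]])
        trace = VoltammogramTrace(potential=e, current=5e-6 * e, scan_rate=0.1)
        with pytest.raises(NoPeakFound):
            extract_peaks(trace)

    def test_reversible_simulator_separation(self, reversible_trace):
        peaks = extract_peaks(reversible_trace)
        assert 0.056 <= peaks.delta_ep <= 0.061

    def test_branch_symmetry_for_equal_diffusivities(self, reversible_trace):
        # D_O = D_R: anodic and cathodic peaks mirror each other
        peaks = extract_peaks(reversible_trace)
        assert abs(peaks.ip_cathodic) == pytest.approx(peaks.ip_anodic, rel=0.05)
        assert peaks.ep_anodic == pytest.approx(-peaks.ep_cathodic, abs=0.004)

    def test_determinism(self, reversible_trace):
        p1 = extract_peaks(reversible_trace)
        p2 = extract_peaks(reversible_trace)
        assert p1 == p2


class TestEsaRandlesSevcik:
    @staticmethod
    def _exact_peaks(slope=3.56e-4, rates=(0.025, 0.05, 0.1, 0.2)):
        return [
            (v, CvPeaks(0.1, slope * math.sqrt(v), -0.1, -slope * math.sqrt(v), 0.2, "exact"))
            for v in rates
        ]

    def test_exact_points_recover_geometric_area(self):
        """ip = 3.56e-4 sqrt(v) with n=1, D=7.6e-6, C=4 mM inverts to 0.12 cm^2."""
        res = esa_randles_sevcik(self._exact_peaks(), CELL, SPECIES)
        assert res.esa == pytest.approx(0.12, rel=0.005)
        assert res.r_squared > 0.9999
        assert res.branch_used == "anodic"

    def test_current_scaling_scales_area_linearly(self):
        res1 = esa_randles_sevcik(self._exact_peaks(), CELL, SPECIES)
        res2 = esa_randles_sevcik(self._exact_peaks(slope=2 * 3.56e-4), CELL, SPECIES)
        assert res2.esa == pytest.approx(2 * res1.esa, rel=1e-9)

    def test_two_rates_rejected(self):
        with pytest.raises(CalibrationError):
            esa_randles_sevcik(self._exact_peaks(rates=(0.05, 0.1)), CELL, SPECIES)

    def test_cathodic_branch_flag(self):
        res = esa_randles_sevcik(self._exact_peaks(), CELL, SPECIES, branch="cathodic")
        assert res.branch_used == "cathodic"
        assert res.esa == pytest.approx(0.12, rel=0.005)

    def test_unit_consistent_rescaling_invariance(self):
        """Scaling currents and concentration together leaves the area unchanged."""
        res1 = esa_randles_sevcik(self._exact_peaks(), CELL, SPECIES)
        scaled_species = RedoxSpecies(c_bulk=SPECIES.c_bulk * 10)
        res2 = esa_randles_sevcik(self._exact_peaks(slope=10 * 3.56e-4), CELL, scaled_species)
        assert res2.esa == pytest.approx(res1.esa, rel=1e-9)

    def test_recovers_area_from_reversible_simulations(self, cell, species):
        peaks = [
            (v, extract_peaks(simulate_cv(cell, species, Kinetics(k0=1.0), ScanProgram(v=v))))
            for v in (0.025, 0.05, 0.1)
        ]
        res = esa_randles_sevcik(peaks, cell, species)
        assert res.esa == pytest.approx(cell.area_geom, rel=0.02)


class TestWorkingCurve:
    def test_lavagnini_fit_at_100_mV(self):
        assert psi_from_delta_ep(0.100) == pytest.approx(0.5983, abs=0.001)

    def test_lavagnini_near_nicholson_table_point(self):
        # Nicholson tabulates psi = 0.25 at n*dEp = 141 mV
        assert psi_from_delta_ep(0.141) == pytest.approx(0.25, rel=0.10)

    def test_strictly_decreasing(self):
        xs = np.linspace(0.060, 0.212, 40)
        psis = [psi_from_delta_ep(x) for x in xs]
        assert all(b < a for a, b in zip(psis, psis[1:]))

    def test_near_reversible_raises(self):
        with pytest.raises(NearReversible):
            psi_from_delta_ep(0.050)

    def test_beyond_table_directs_to_extension(self):
        with pytest.raises(SuperNernstianRange, match="psi_extended"):
            psi_from_delta_ep(0.250)

    def test_n_scales_separation(self):
        # for n=2 a 60 mV separation is already super-Nernstian territory
        assert psi_from_delta_ep(0.055, n=2) == psi_from_delta_ep(0.110, n=1)


class TestPsiExtended:
    def test_frozen_arithmetic_value(self):
        """k0 = 2.18 sqrt(D alpha n F v/RT) exp(-alpha^2 nF/RT dEp) at 300 mV.

        Hand-evaluated: k0 = 4.525e-4 cm/s, psi = 4.694e-2.
        """
        psi = psi_extended(0.300, n=1, alpha=0.5, species=SPECIES, v=0.1)
        assert psi == pytest.approx(4.694e-2, rel=1e-3)

    def test_monotone_decreasing_in_separation(self):
        psis = [
            psi_extended(d, 1, 0.5, SPECIES, 0.1) for d in (0.25, 0.30, 0.35, 0.40)
        ]
        assert all(b < a for a, b in zip(psis, psis[1:]))

    def test_domain_guard(self):
        with pytest.raises(ValueError):
            psi_extended(0.100, 1, 0.5, SPECIES, 0.1)


class TestHetFit:
    def test_exact_proportional_points_recover_slope(self):
        fa = CELL.f_volt
        psi_map = {
            v: 0.003 / math.sqrt(math.pi * fa * v * SPECIES.d_ox) for v in (0.025, 0.05, 0.1)
        }
        res = het_fit(psi_map, SPECIES)
        assert res.k0 == pytest.approx(0.0030, rel=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_gamma_exponent(self):
        fa = CELL.f_volt
        psi_map = {v: 0.003 / math.sqrt(math.pi * fa * v * 7.6e-6) for v in (0.05, 0.1)}
        asym = RedoxSpecies(d_ox=7.6e-6, d_red=7.6e-6 / 4.0)  # gamma = 4
        res = het_fit(psi_map, asym, alpha=0.5)
        assert res.k0 == pytest.approx(0.0030 / 2.0, rel=1e-12)  # gamma^alpha = 2

    def test_hand_arithmetic_psi_half(self):
        """psi = 0.5 at 0.1 V/s (a = 3.89 1/s) corresponds to k0 = 4.82e-3 cm/s."""
        k0 = 4.820e-3
        fa = CELL.f_volt
        psi_map = {v: k0 / math.sqrt(math.pi * fa * v * SPECIES.d_ox) for v in (0.05, 0.1)}
        assert psi_map[0.1] == pytest.approx(0.5, abs=0.001)
        res = het_fit(psi_map, SPECIES)
        assert res.k0 == pytest.approx(4.82e-3, rel=1e-3)

    def test_single_rate_rejected(self):
        with pytest.raises(CalibrationError):
            het_fit({0.1: 0.5}, SPECIES)


class TestElectrokineticRecovery:
    def test_het_recovers_k0_within_20_percent(self, quasi_peak_sets, cell, species):
        for k0, peaks in quasi_peak_sets.items():
            res = het_from_peaks(peaks, cell, species)
            assert abs(res.k0 - k0) / k0 < 0.20, f"k0={k0}: got {res.k0:.3e}"


class TestPsiOracle:
    def test_round_trip_recovers_known_k0(self, cell, species):
        k0 = 3e-3
        program = ScanProgram(v=0.1)
        trace = simulate_cv(cell, species, Kinetics(k0=k0), program)
        target = extract_peaks(trace).delta_ep
        res = psi_oracle(target, cell, species, 0.5, program)
        assert res.k0 == pytest.approx(k0, rel=0.05)

    def test_reversible_plateau_reported(self, cell, species):
        with pytest.raises(NearReversible):
            psi_oracle(0.057, cell, species, 0.5, ScanProgram(v=0.1))

    def test_oracle_validates_closed_form_at_100mV(self, cell, species):
        res = psi_oracle(0.100, cell, species, 0.5, ScanProgram(v=0.1))
        assert res.psi == pytest.approx(0.5983, rel=0.15)
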