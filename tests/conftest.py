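import numpy as np
import pytest
from hypothesis import settings

from ampersense import (
    AmpTruth,
    CellSpec,
    InjectionSchedule,
    Kinetics,
    RedoxSpecies,
    ScanProgram,
    simulate_amperometry,
    simulate_cv,
)
from ampersense.voltammetry import extract_peaks

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

#: k0 grid (cm/s) and scan rates (V/s) of the quasi-reversible study set
K0_GRID = (1e-3, 3e-3, 1e-2)
RATE_GRID = (0.025, 0.05, 0.1)


@pytest.fixture(scope="session")
def cell():
    return CellSpec()


@pytest.fixture(scope="session")
def species():
    return RedoxSpecies()


@pytest.fixture(scope="session")
def reversible_trace(cell, species):
    """Noise-free CV of a fast couple (k0 = 1 cm/s) at 100 mV/s."""
    return simulate_cv(cell, species, Kinetics(k0=1.0), ScanProgram(v=0.1))


@pytest.fixture(scope="session")
def quasi_peak_sets(cell, species):
    """Peaks of the quasi-reversible CV sets: {k0: [(v, CvPeaks), ...]}."""
    sets = {}
    for k0 in K0_GRID:
        sets[k0] = [
            (v, extract_peaks(simulate_cv(cell, species, Kinetics(k0=k0), ScanProgram(v=v))))
            for v in RATE_GRID
        ]
    return sets


@pytest.fixture(scope="session")
def calibration_run():
    """Factory for staircase calibration traces with known ground truth."""

    def make(
        n_steps=12,
        delta_mM=0.1,
        interval=60.0,
        start=120.0,
        noise_sigma=None,
        seed=0,
        sample_rate=10.0,
        **truth_kw,
    ):
        if noise_sigma is not None:
            truth_kw["noise_sigma"] = noise_sigma
        truth = AmpTruth(**truth_kw)
        schedule = InjectionSchedule.uniform(start, interval, n_steps, delta_mM * 1e-3)
        duration = start + n_steps * interval + interval
        trace = simulate_amperometry(truth, schedule, duration, sample_rate, seed=seed)
        return trace, truth

    return make
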