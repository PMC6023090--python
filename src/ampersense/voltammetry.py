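"""Cyclic-voltammogram analysis: peaks, surface area, electron-transfer kinetics.

Three classical results are implemented on top of simple peak extraction:

* Randles-Sevcik: the reversible peak current grows as the square root of
  the scan rate; the slope of |i_p| vs sqrt(v) yields the electroactive
  surface area (ESA).  Following a common lab usage this i_p-vs-sqrt(v)
  plot is called a "Cottrell plot" here, although the classical Cottrell
  plot is i vs t^-1/2 in chronoamperometry.
* Nicholson's working curve links the anodic/cathodic peak separation
  dEp to the dimensionless kinetic parameter psi and hence to the
  standard heterogeneous rate constant k0.  The tabulated curve is
  represented by Lavagnini's rational fit, valid for n*dEp up to 212 mV.
* Beyond the tabulated range the irreversible-regime relation (also due
  to the Lavagnini treatment) provides k0 directly from dEp.

``psi_oracle`` inverts the finite-difference simulator by bisection and
serves as the independent check of both closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .constants import FARADAY, GAS_CONSTANT, T_STANDARD, randles_sevcik_coefficient
from .errors import CalibrationError, NearReversible, NoPeakFound, SuperNernstianRange
from .synthetic_data import CellSpec, GridConfig, Kinetics, RedoxSpecies, ScanProgram, simulate_cv
from .traces import VoltammogramTrace

__all__ = [
    "CvPeaks",
    "EsaResult",
    "HetResult",
    "OracleResult",
    "extract_peaks",
    "esa_randles_sevcik",
    "psi_from_delta_ep",
    "psi_extended",
    "psi_auto",
    "psi_oracle",
    "het_fit",
    "het_from_peaks",
]

#: upper bound (in mV, for n*dEp) of Nicholson's tabulated working curve
WORKING_CURVE_MAX_MV = 212.0
#: Nernstian floor below which dEp carries no kinetic information
WORKING_CURVE_MIN_MV = 59.0


@dataclass(frozen=True)
class CvPeaks:
    """Baseline-corrected peak pair of one voltammogram.

    ``ip_anodic`` is positive, ``ip_cathodic`` negative (anodic-positive
    sign convention); a branch that could not be extracted is NaN.
    """

    ep_anodic: float
    ip_anodic: float
    ep_cathodic: float
    ip_cathodic: float
    delta_ep: float
    baseline_model: str

    def ip(self, branch: str) -> float:
        return self.ip_anodic if branch == "anodic" else self.ip_cathodic


@dataclass(frozen=True)
class EsaResult:
    """Electroactive surface area from the i_p vs sqrt(v) slope."""

    slope_ip_vs_sqrtv: float  # A / (V/s)^0.5
    esa: float  # cm^2
    r_squared: float
    n_points: int
    branch_used: str


@dataclass(frozen=True)
class HetResult:
    """Standard heterogeneous rate constant from the psi vs (pi a D)^-0.5 regression."""

    psi_by_rate: Mapping[float, float]
    k0: float  # cm/s
    r_squared: float
    regime_by_rate: Mapping[float, str]


@dataclass(frozen=True)
class OracleResult:
    """Simulator-inversion estimate of the kinetics behind a peak separation."""

    psi: float
    k0: float
    delta_ep: float
    n_iterations: int


def _branch_peak(
    potential: np.ndarray,
    current: np.ndarray,
    sign: float,
    baseline_window: float,
) -> tuple[float, float, bool]:
    """Locate the extremum of sign*current after linear-baseline subtraction.

    The baseline is fitted on the leading ``baseline_window`` fraction of
    the branch (the pre-peak region).  Returns (ep, ip_corrected, found);
    found is False when no interior extremum exceeds 3x the baseline
    residual SD.  Ties break to the earliest sample in sweep order.
    """
    n = len(potential)
    nb = max(4, int(round(baseline_window * n)))
    coeffs = np.polyfit(potential[:nb], current[:nb], 1)
    corrected = current - np.polyval(coeffs, potential)
    resid_sd = float(np.std(current[:nb] - np.polyval(coeffs, potential[:nb])))
    y = sign * corrected
    idx = int(np.argmax(y))
    interior = 0 < idx < n - 1
    significant = y[idx] > 3.0 * resid_sd and y[idx] > 0
    if not (interior and significant):
        return math.nan, math.nan, False
    # sub-sample apex: local quadratic fit around the discrete extremum
    half = max(2, n // 100)
    lo, hi = max(0, idx - half), min(n, idx + half + 1)
    ew, yw = potential[lo:hi], y[lo:hi]
    a2, a1, a0 = np.polyfit(ew, yw, 2)
    if a2 < 0:
        e_peak = -a1 / (2.0 * a2)
        if min(ew) <= e_peak <= max(ew):
            return float(e_peak), float(sign * (a0 + a1 * e_peak + a2 * e_peak**2)), True
    return float(potential[idx]), float(corrected[idx]), True


def extract_peaks(
    trace: VoltammogramTrace,
    baseline_window: float = 0.2,
    require: str = "both",
) -> CvPeaks:
    """Extract the anodic and cathodic peaks of one CV cycle.

    The sweep is split at the switching potential; on each branch a
    linear baseline fitted to the leading ``baseline_window`` fraction is
    subtracted and the extremum located.  A peak must be an interior
    extremum exceeding 3x the baseline residual SD, mirroring the
    practical situation where a peak is "not discernable".

    ``require`` controls which branches must be present ("both",
    "anodic", "cathodic", or "any"); missing allowed branches come back
    as NaN.  Raises :class:`NoPeakFound` when the requirement fails.
    """
    if require not in ("both", "anodic", "cathodic", "any"):
        raise ValueError(f"unknown require mode {require!r}")
    trace1 = trace.select_cycle(1) if trace.cycle is not None else trace
    e, i = trace1.potential, trace1.current
    if len(e) < 16:
        raise NoPeakFound("trace too short to contain a full sweep")
    # switching index: extremum of the potential program
    up_first = e[min(len(e) // 4, 8)] > e[0]
    sw = int(np.argmax(e)) if up_first else int(np.argmin(e))
    if sw < 8 or sw > len(e) - 8:
        raise NoPeakFound("trace does not span a forward and a reverse sweep")
    fwd = slice(0, sw + 1)
    rev = slice(sw, len(e))
    if up_first:
        ep_a, ip_a, ok_a = _branch_peak(e[fwd], i[fwd], +1.0, baseline_window)
        ep_c, ip_c, ok_c = _branch_peak(e[rev], i[rev], -1.0, baseline_window)
    else:
        ep_c, ip_c, ok_c = _branch_peak(e[fwd], i[fwd], -1.0, baseline_window)
        ep_a, ip_a, ok_a = _branch_peak(e[rev], i[rev], +1.0, baseline_window)

    missing = [name for name, ok in (("anodic", ok_a), ("cathodic", ok_c)) if not ok]
    if require == "both" and missing:
        raise NoPeakFound(f"no {' or '.join(missing)} peak above 3x baseline residual SD")
    if require in ("anodic", "cathodic") and require in missing:
        raise NoPeakFound(f"no {require} peak above 3x baseline residual SD")
    if require == "any" and len(missing) == 2:
        raise NoPeakFound("no peak above 3x baseline residual SD on either branch")

    delta = ep_a - ep_c if ok_a and ok_c else math.nan
    return CvPeaks(
        ep_anodic=ep_a,
        ip_anodic=ip_a,
        ep_cathodic=ep_c,
        ip_cathodic=ip_c,
        delta_ep=delta,
        baseline_model=f"linear fit on leading {baseline_window:.0%} of each branch",
    )


def esa_randles_sevcik(
    peaks_by_rate: list[tuple[float, CvPeaks]],
    cell: CellSpec,
    species: RedoxSpecies,
    branch: str = "anodic",
) -> EsaResult:
    """Electroactive surface area from peak currents at several scan rates.

    Least-squares line of |i_p| versus sqrt(v); the intercept absorbs any
    capacitive offset and only the slope enters the inversion
    A = slope / (coeff * n^1.5 * D^0.5 * C).  The diffusion coefficient
    of the form consumed on the chosen branch is used (reduced form for
    the anodic branch).  Requires >= 3 distinct scan rates.
    """
    if branch not in ("anodic", "cathodic"):
        raise ValueError(f"branch must be 'anodic' or 'cathodic', got {branch!r}")
    rates = [v for v, _ in peaks_by_rate]
    if len(set(rates)) < 3:
        raise CalibrationError(f"need >= 3 distinct scan rates, got {sorted(set(rates))}")
    pairs = [(v, p.ip(branch)) for v, p in peaks_by_rate if math.isfinite(p.ip(branch))]
    if len({v for v, _ in pairs}) < 3:
        raise CalibrationError(f"fewer than 3 rates carry a usable {branch} peak")
    x = np.sqrt([v for v, _ in pairs])
    y = np.abs([ip for _, ip in pairs])
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise CalibrationError(f"non-positive i_p vs sqrt(v) slope: {slope:.3e}")
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    d = species.d_red if branch == "anodic" else species.d_ox
    coeff = randles_sevcik_coefficient(cell.temperature)
    esa = slope / (coeff * cell.n**1.5 * math.sqrt(d) * species.c_bulk)
    return EsaResult(
        slope_ip_vs_sqrtv=float(slope),
        esa=float(esa),
        r_squared=r2,
        n_points=len(pairs),
        branch_used=branch,
    )


def psi_from_delta_ep(delta_ep: float, n: int = 1) -> float:
    """Working-curve value psi for a peak separation, via Lavagnini's rational fit.

    psi = (-0.6288 + 0.0021 X) / (1 - 0.017 X) with X = n*dEp in mV,
    strictly decreasing over the validity window 59 mV < X <= 212 mV.
    Below the window the couple is effectively Nernstian and k0 cannot be
    resolved from dEp; above it the caller is directed to
    :func:`psi_extended`.
    """
    x = n * delta_ep * 1000.0
    if x <= WORKING_CURVE_MIN_MV:
        raise NearReversible(
            f"n*dEp = {x:.1f} mV is at or below the Nernstian separation (~59 mV); "
            "k0 is not resolvable from dEp"
        )
    if x > WORKING_CURVE_MAX_MV:
        raise SuperNernstianRange(
            f"n*dEp = {x:.1f} mV exceeds the tabulated working curve "
            f"({WORKING_CURVE_MAX_MV:.0f} mV); use psi_extended"
        )
    return (-0.6288 + 0.0021 * x) / (1.0 - 0.017 * x)


def psi_extended(
    delta_ep: float,
    n: int,
    alpha: float,
    species: RedoxSpecies,
    v: float,
    temperature: float = T_STANDARD,
) -> float:
    """psi-equivalent for peak separations beyond the tabulated working curve.

    In the irreversible regime the rate constant follows directly from
    the separation:

        k0 = 2.18 * sqrt(D_O alpha n F v / (R T)) * exp(-(alpha^2 n F/(R T)) * dEp)

    which is then mapped onto psi through psi = gamma^alpha k0
    (pi a D_O)^-0.5 with a = nFv/RT, so that the same regression treats
    both regimes.
    """
    x = n * delta_ep * 1000.0
    if x <= WORKING_CURVE_MAX_MV:
        raise ValueError(
            f"psi_extended applies beyond the working curve (n*dEp > "
            f"{WORKING_CURVE_MAX_MV:.0f} mV); got {x:.1f} mV - use psi_from_delta_ep"
        )
    if v <= 0:
        raise ValueError(f"scan rate must be positive, got {v}")
    fa = n * FARADAY / (GAS_CONSTANT * temperature)
    k0 = 2.18 * math.sqrt(species.d_ox * alpha * fa * v) * math.exp(
        -(alpha**2) * fa * delta_ep
    )
    a = fa * v
    return species.gamma**alpha * k0 / math.sqrt(math.pi * a * species.d_ox)


def psi_auto(
    delta_ep: float,
    n: int,
    alpha: float,
    species: RedoxSpecies,
    v: float,
    temperature: float = T_STANDARD,
) -> tuple[float, str]:
    """psi with automatic regime choice; returns (psi, regime label)."""
    x = n * delta_ep * 1000.0
    if x <= WORKING_CURVE_MAX_MV:
        return psi_from_delta_ep(delta_ep, n), "nicholson_lavagnini"
    return psi_extended(delta_ep, n, alpha, species, v, temperature), "extended_irreversible"


def psi_oracle(
    delta_ep_target: float,
    cell: CellSpec,
    species: RedoxSpecies,
    kinetics_alpha: float,
    program: ScanProgram,
    grid: GridConfig | None = None,
    tol: float = 1e-3,
    k0_bracket: tuple[float, float] = (1e-6, 10.0),
    max_iter: int = 60,
) -> OracleResult:
    """Brute-force working curve: invert the CV simulator for a target dEp.

    dEp is monotone decreasing in k0 in the quasi-reversible regime, so a
    bisection over log k0 converges to the rate constant whose simulated
    separation matches ``delta_ep_target`` within ``tol`` (default 1 mV).
    Returns psi computed from the recovered k0 via psi = gamma^alpha k0
    (pi a D_O)^-0.5.  Raises :class:`NearReversible` when the target sits
    at or below the reversible plateau of the simulator, and
    :class:`CalibrationError` when the bracket cannot reach it.
    """
    grid = grid or GridConfig()

    def sim_dep(k0: float) -> float:
        trace = simulate_cv(
            cell, species, Kinetics(k0=k0, alpha=kinetics_alpha), program, grid=grid
        )
        return extract_peaks(trace).delta_ep

    lo, hi = k0_bracket
    dep_hi = sim_dep(hi)  # reversible plateau
    if delta_ep_target <= dep_hi + tol:
        raise NearReversible(
            f"target dEp {delta_ep_target*1e3:.1f} mV is at the reversible plateau "
            f"({dep_hi*1e3:.1f} mV); k0 not resolvable"
        )
    dep_lo = sim_dep(lo)
    if delta_ep_target > dep_lo:
        raise CalibrationError(
            f"target dEp {delta_ep_target*1e3:.1f} mV unreachable within the k0 bracket "
            f"(max simulated {dep_lo*1e3:.1f} mV)"
        )
    llo, lhi = math.log10(lo), math.log10(hi)
    k0_mid, dep_mid = hi, dep_hi
    iterations = 0
    for iterations in range(1, max_iter + 1):
        lmid = 0.5 * (llo + lhi)
        k0_mid = 10.0**lmid
        dep_mid = sim_dep(k0_mid)
        if abs(dep_mid - delta_ep_target) < tol:
            break
        if dep_mid > delta_ep_target:  # too slow -> raise k0
            llo = lmid
        else:
            lhi = lmid
    a = cell.f_volt * program.v
    psi = species.gamma**kinetics_alpha * k0_mid / math.sqrt(math.pi * a * species.d_ox)
    return OracleResult(psi=psi, k0=k0_mid, delta_ep=dep_mid, n_iterations=iterations)


def het_fit(
    psi_by_rate: Mapping[float, float],
    species: RedoxSpecies,
    alpha: float = 0.5,
    n: int = 1,
    temperature: float = T_STANDARD,
    regime_by_rate: Mapping[float, str] | None = None,
) -> HetResult:
    """Rate constant from the linearity of psi in (pi a D_O)^-0.5.

    With a = nFv/RT, psi = gamma^alpha k0 (pi a D_O)^-0.5 is exactly
    proportional to (pi a D_O)^-0.5 across scan rates, so the regression
    is taken through the origin (an intercept has no physical source here
    and amplifies working-curve error at the slow-kinetics end); the
    slope divided by gamma^alpha is k0.  The quoted R^2 is uncentered.
    Requires psi at two or more scan rates.
    """
    if len(psi_by_rate) < 2:
        raise CalibrationError(f"need >= 2 scan rates, got {len(psi_by_rate)}")
    rates = sorted(psi_by_rate)
    fa = n * FARADAY / (GAS_CONSTANT * temperature)
    x = np.array([1.0 / math.sqrt(math.pi * fa * v * species.d_ox) for v in rates])
    y = np.array([psi_by_rate[v] for v in rates])
    slope = float(np.dot(x, y) / np.dot(x, x))
    if slope <= 0:
        raise CalibrationError(f"non-positive HET-plot slope: {slope:.3e}")
    yhat = slope * x
    ss_tot = float(np.sum(y**2))
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    k0 = float(slope) / species.gamma**alpha
    return HetResult(
        psi_by_rate=dict(psi_by_rate),
        k0=k0,
        r_squared=r2,
        regime_by_rate=dict(regime_by_rate or {v: "nicholson_lavagnini" for v in rates}),
    )


def het_from_peaks(
    peaks_by_rate: list[tuple[float, CvPeaks]],
    cell: CellSpec,
    species: RedoxSpecies,
    alpha: float = 0.5,
) -> HetResult:
    """Convenience pipeline: peak separations at several rates -> k0.

    Rates whose separation falls below the Nernstian floor are skipped;
    separations beyond the tabulated working curve use the
    irreversible-regime extension.
    """
    psi_map: dict[float, float] = {}
    regimes: dict[float, str] = {}
    for v, peaks in peaks_by_rate:
        if not math.isfinite(peaks.delta_ep):
            continue
        try:
            psi, regime = psi_auto(
                peaks.delta_ep, cell.n, alpha, species, v, cell.temperature
            )
        except NearReversible:
            continue
        psi_map[v] = psi
        regimes[v] = regime
    if len(psi_map) < 2:
        raise CalibrationError("fewer than 2 scan rates yield a kinetic psi value")
    return het_fit(
        psi_map, species, alpha=alpha, n=cell.n, temperature=cell.temperature,
        regime_by_rate=regimes,
    )
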