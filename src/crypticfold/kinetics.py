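"""Three-state irreversible thermal-unfolding kinetics.

The model is the sequential irreversible scheme

    N --k1--> I --k2--> D

with temperature-dependent first-order rate constants

    k_i(T) = exp[(Ea_i / R) * (1/Tstar_i - 1/T)]     [min^-1]

where ``Tstar_i`` is the temperature at which step *i* proceeds at
1 min^-1 and ``Ea_i`` is its activation energy.  Under a constant
heating rate v (K/min) the state fractions obey

    dxN/dT = -k1 xN / v
    dxI/dT = (k1 xN - k2 xI) / v
    xD     = 1 - xN - xI

and at constant temperature the system has a closed-form solution.
The observables derived from the fractions are the DSC excess heat
capacity, per-state linear-baseline spectroscopic signals, Eyring
activation free energies, and standard curve-level descriptors
(peak/midpoint melting temperatures, BCM, aggregation maximum,
reversibility ratio).

Temperatures are Kelvin throughout; energies kJ/mol; rates min^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

R_GAS = 8.314  # J mol^-1 K^-1
PLANCK_H = 6.62607015e-34  # J s
BOLTZMANN_KB = 1.380649e-23  # J / K

TECHNIQUES = ("DSC", "DSF_BCM", "CD", "SLS", "ISOTHERMAL")

try:
    from ._integrate import propagate_fixed_step

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally available
    from ._integrate import propagate_fixed_step_py as propagate_fixed_step

    _HAVE_NUMBA = False


class KineticsError(ValueError):
    """Domain or consistency error in the kinetic model layer."""


@dataclass
class KineticParams:
    """Rate-law and enthalpy parameters of the N -> I -> D model.

    Parameters
    ----------
    Ea1, Ea2
        Activation energies of the two unfolding steps, kJ/mol.
    Tstar1, Tstar2
        Temperatures (K) at which the respective rate constant equals
        1 min^-1.
    dHcal1, dHcal2
        Calorimetric enthalpies released by each step, kJ/mol.  One of
        the two may be constrained to exactly zero during fitting.
    """

    Ea1: float
    Tstar1: float
    Ea2: float
    Tstar2: float
    dHcal1: float = 0.0
    dHcal2: float = 0.0

    def __post_init__(self) -> None:
        if self.Ea1 < 0 or self.Ea2 < 0:
            raise KineticsError("activation energies must be non-negative")
        for ts in (self.Tstar1, self.Tstar2):
            if not (273.0 <= ts <= 400.0):
                raise KineticsError(f"Tstar {ts} K outside the 273-400 K range")
        if self.dHcal1 < 0 or self.dHcal2 < 0:
            raise KineticsError("calorimetric enthalpies must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {
            "Ea1": self.Ea1, "Tstar1": self.Tstar1,
            "Ea2": self.Ea2, "Tstar2": self.Tstar2,
            "dHcal1": self.dHcal1, "dHcal2": self.dHcal2,
        }


@dataclass
class StateFractions:
    """Fractions of native, intermediate and denatured states on a grid.

    ``grid`` is temperature (K) for thermal scans or time (min) for
    isothermal holds; which one is recorded in ``kind``.
    """

    grid: np.ndarray
    xN: np.ndarray
    xI: np.ndarray
    xD: np.ndarray
    kind: str = "scan"  # "scan" | "isothermal"
    scan_rate: float | None = None  # K/min, scans only
    hold_temperature: float | None = None  # K, isothermal only

    def conservation_defect(self) -> float:
        return float(np.max(np.abs(self.xN + self.xI + self.xD - 1.0)))


@dataclass
class ExperimentCurve:
    """One technique's measured (x, y) series.

    ``x`` is temperature in K for thermal scans and time in min for
    isothermal traces.  ``baseline_params`` optionally carries per-state
    linear coefficients {state: (a, b)} for spectroscopic techniques.
    """

    technique: str
    x: np.ndarray
    y: np.ndarray
    scan_rate: float | None = None
    hold_temperature: float | None = None
    baseline_params: dict[str, tuple[float, float]] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.technique not in TECHNIQUES:
            raise KineticsError(f"unknown technique {self.technique!r}")
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise KineticsError("x and y must be 1-D arrays of equal length")
        if np.any(np.diff(self.x) <= 0):
            raise KineticsError("x must be strictly increasing")
        if self.technique == "ISOTHERMAL":
            if self.hold_temperature is None:
                raise KineticsError("isothermal curve requires hold_temperature")
        elif self.scan_rate is None:
            raise KineticsError(f"{self.technique} curve requires scan_rate")


@dataclass
class BarrierReport:
    """Eyring activation free energies of both steps on a temperature grid."""

    temperatures: np.ndarray
    dG1: np.ndarray
    dG2: np.ndarray


def rate_constant(params: KineticParams, step: int, T) -> np.ndarray | float:
    """Rate constant of unfolding step 1 or 2 at temperature T (K), min^-1."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise KineticsError("temperature must be positive")
    if step == 1:
        ea, tstar = params.Ea1, params.Tstar1
    elif step == 2:
        ea, tstar = params.Ea2, params.Tstar2
    else:
        raise KineticsError("step must be 1 or 2")
    k = np.exp((ea * 1000.0 / R_GAS) * (1.0 / tstar - 1.0 / T))
    return float(k) if k.ndim == 0 else k


def propagate_scan(
    params: KineticParams,
    T0: float,
    T1: float,
    v: float,
    n_grid: int = 400,
    method: str = "exp",
    substep: float = 0.005,
    grid: np.ndarray | None = None,
) -> StateFractions:
    """Integrate the state fractions along a thermal scan.

    Parameters
    ----------
    T0, T1
        Scan limits in K (T1 > T0); the initial condition is fully
        native, (xN, xI, xD) = (1, 0, 0).
    v
        Heating rate, K/min.
    method
        ``"exp"`` (default): fixed-substep exponential-trapezoidal
        stepper, unconditionally stable and positivity-preserving even
        where the rate constants become stiff beyond the transition;
        ``"ivp"``: adaptive LSODA (rtol 1e-8 / atol 1e-10), used for
        cross-validation.
    substep
        Maximum integration substep (K) for the ``"exp"`` stepper.
    grid
        Optional explicit output grid; overrides T0/T1/n_grid.
    """
    if grid is None:
        if not (T1 > T0):
            raise KineticsError("T1 must exceed T0")
        grid = np.linspace(T0, T1, n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise KineticsError("grid must be strictly increasing")
    if v <= 0:
        raise KineticsError("scan rate must be positive")

    if method == "exp":
        nsub = int(np.ceil(np.max(np.diff(grid)) / substep))
        xN, xI = propagate_fixed_step(
            grid, params.Ea1, params.Tstar1, params.Ea2, params.Tstar2, v, nsub
        )
    elif method == "ivp":
        def rhs(T, y):
            k1 = rate_constant(params, 1, T)
            k2 = rate_constant(params, 2, T)
            return [-k1 * y[0] / v, (k1 * y[0] - k2 * y[1]) / v]

        sol = solve_ivp(
            rhs, (grid[0], grid[-1]), [1.0, 0.0], t_eval=grid,
            method="LSODA", rtol=1e-8, atol=1e-10,
        )
        if not sol.success:
            raise KineticsError(f"scan integration failed: {sol.message}")
        xN, xI = sol.y[0], sol.y[1]
    else:
        raise KineticsError(f"unknown integration method {method!r}")

    # tolerate round-off only; anything larger is an integrator defect
    xN = np.clip(xN, 0.0, 1.0)
    xI = np.clip(xI, 0.0, 1.0)
    xD = 1.0 - xN - xI
    xD[np.abs(xD) < 1e-12] = np.abs(xD[np.abs(xD) < 1e-12])
    return StateFractions(grid=grid, xN=xN, xI=xI, xD=np.clip(xD, 0.0, 1.0),
                          kind="scan", scan_rate=v)


def propagate_isothermal(
    params: KineticParams, T: float, times: np.ndarray, k2_zero: bool = False
) -> StateFractions:
    """Closed-form state fractions at constant temperature.

    xN = exp(-k1 t); xI = k1/(k2-k1) (exp(-k1 t) - exp(-k2 t)) for
    k1 != k2 and k1 t exp(-k1 t) in the degenerate k1 = k2 limit.
    ``k2_zero`` forces the single-step (Tstar2 -> infinity) limit.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0) or np.any(np.diff(times) < 0):
        raise KineticsError("times must be non-negative and ascending")
    k1 = rate_constant(params, 1, T)
    k2 = 0.0 if k2_zero else rate_constant(params, 2, T)
    xN = np.exp(-k1 * times)
    if abs(k1 - k2) < 1e-8:
        xI = k1 * times * np.exp(-k1 * times)
    else:
        xI = k1 / (k2 - k1) * (np.exp(-k1 * times) - np.exp(-k2 * times))
    xI = np.clip(xI, 0.0, 1.0)
    xD = np.clip(1.0 - xN - xI, 0.0, 1.0)
    return StateFractions(grid=times, xN=xN, xI=xI, xD=xD,
                          kind="isothermal", hold_temperature=float(T))


def dsc_signal(params: KineticParams, fractions: StateFractions, v: float) -> np.ndarray:
    """Excess heat capacity of a scan, kJ mol^-1 K^-1.

    Cp_exc(T) = [dHcal1 k1(T) xN(T) + dHcal2 k2(T) xI(T)] / v.  The data
    contract is baseline-subtracted DSC, so no heat-capacity increment
    term appears.
    """
    if fractions.kind != "scan":
        raise KineticsError("dsc_signal requires scan fractions")
    if fractions.scan_rate is not None and not np.isclose(fractions.scan_rate, v):
        raise KineticsError(
            f"fractions computed at {fractions.scan_rate} K/min, requested {v}"
        )
    k1 = rate_constant(params, 1, fractions.grid)
    k2 = rate_constant(params, 2, fractions.grid)
    return (params.dHcal1 * k1 * fractions.xN + params.dHcal2 * k2 * fractions.xI) / v


def spectro_signal(
    fractions: StateFractions,
    baselines: dict[str, tuple[float, float]],
    Tref: float = 298.15,
) -> np.ndarray:
    """Population-weighted per-state linear baselines.

    y(x) = sum_s (a_s + b_s (x - Tref)) x_s(x), s in {N, I, D}.  For
    isothermal traces the grid is time and Tref should be left at its
    default with b_s = 0 (constant per-state signals).
    """
    missing = {"N", "I", "D"} - set(baselines)
    if missing:
        raise KineticsError(f"missing baselines for states {sorted(missing)}")
    dx = fractions.grid - Tref if fractions.kind == "scan" else np.zeros_like(fractions.grid)
    y = np.zeros_like(fractions.grid, dtype=float)
    for s, x_s in (("N", fractions.xN), ("I", fractions.xI), ("D", fractions.xD)):
        a, b = baselines[s]
        y += (a + b * dx) * x_s
    return y


def barrier_at(
    params: KineticParams,
    temperatures=(313.15, 333.15, 353.15),
) -> BarrierReport:
    """Gibbs activation energies (kJ/mol) via Eyring inversion.

    dG_i(T) = -R T ln[k_i(T) h / (kB T)] with k_i converted to s^-1.
    Default grid: 40, 60 and 80 degC.
    """
    T = np.asarray(temperatures, dtype=float)
    if np.any(T <= 0):
        raise KineticsError("temperatures must be positive")
    out = []
    for step in (1, 2):
        k_s = np.asarray(rate_constant(params, step, T)) / 60.0
        dg = -R_GAS * T * np.log(k_s * PLANCK_H / (BOLTZMANN_KB * T)) / 1000.0
        out.append(dg)
    return BarrierReport(temperatures=T, dG1=out[0], dG2=out[1])


def rate_from_barrier(dG: float, T: float) -> float:
    """Invert an Eyring barrier (kJ/mol) back to a rate constant in min^-1."""
    k_s = (BOLTZMANN_KB * T / PLANCK_H) * np.exp(-dG * 1000.0 / (R_GAS * T))
    return float(k_s * 60.0)


def bcm_from_spectrum(wavelengths, intensities) -> float:
    """Barycentric mean of a fluorescence spectrum, nm."""
    wl = np.asarray(wavelengths, dtype=float)
    inten = np.asarray(intensities, dtype=float)
    if np.any(inten < 0):
        raise KineticsError("intensities must be non-negative")
    total = inten.sum()
    if total == 0:
        raise KineticsError("BCM undefined for an all-zero spectrum")
    return float((wl * inten).sum() / total)


def mre_convert(theta_obs, Mw: float, n: int, c: float, l: float):
    """Mean residue ellipticity from observed ellipticity (degrees).

    MRE = theta_obs * Mw * 100 / (n * c * l) with Mw in g/mol, c in
    mg/mL and l in cm; the factor 100 converts the molecular weight
    to mg/dmol.
    """
    if min(Mw, n, c, l) <= 0:
        raise KineticsError("Mw, n, c and l must all be positive")
    return np.asarray(theta_obs, dtype=float) * Mw * 100.0 / (n * c * l)


def _logistic(x, lo, hi, x0, w):
    return lo + (hi - lo) / (1.0 + np.exp(-(x - x0) / w))


def curve_metrics(curve: ExperimentCurve, metric: str, window=None, k_onset: float = 5.0):
    """Scalar descriptors of a melt curve.

    metric:
      - ``tm_peak``: temperature of the signal maximum (DSC-style Tm).
      - ``tm_midpoint``: midpoint of a fitted four-parameter logistic
        (sigmoid melts, e.g. BCM or CD); raises a fit-failure error for
        non-sigmoidal data.
      - ``agg_max``: maximum signal within ``window`` (default 293.15 to
        353.15 K, i.e. the 20-80 degC SLS aggregation window).
      - ``t_onset``: first temperature where the signal exceeds the
        pre-transition baseline mean by ``k_onset`` standard deviations.
    """
    if curve.x.size < 5:
        raise KineticsError("need at least 5 points")
    x, y = curve.x, curve.y
    if metric == "tm_peak":
        return float(x[int(np.argmax(y))])
    if metric == "tm_midpoint":
        lo0, hi0 = float(y[0]), float(y[-1])
        p0 = [lo0, hi0, float(x[int(np.argmax(np.abs(np.gradient(y, x))))]),
              (x[-1] - x[0]) / 20.0]
        try:
            popt, _ = curve_fit(_logistic, x, y, p0=p0, maxfev=10000)
        except RuntimeError as exc:
            raise KineticsError(f"sigmoid fit failed: {exc}") from exc
        resid = y - _logistic(x, *popt)
        amp = abs(popt[1] - popt[0])
        if amp < 1e-12 or np.sqrt(np.mean(resid**2)) > 0.25 * amp:
            raise KineticsError("curve is not sigmoidal enough for a midpoint")
        if not (x[0] <= popt[2] <= x[-1]):
            raise KineticsError("fitted midpoint outside the data range")
        return float(popt[2])
    if metric == "agg_max":
        if window is None:
            window = (293.15, 353.15)
        mask = (x >= window[0]) & (x <= window[1])
        if not mask.any():
            raise KineticsError("window contains no data")
        return float(np.max(y[mask]))
    if metric == "t_onset":
        n_base = max(5, x.size // 10)
        mu, sd = float(np.mean(y[:n_base])), float(np.std(y[:n_base]))
        sd = max(sd, 1e-12)
        above = np.nonzero(y > mu + k_onset * sd)[0]
        if above.size == 0:
            raise KineticsError("signal never exceeds the onset criterion")
        return float(x[above[0]])
    raise KineticsError(f"unknown metric {metric!r}")


def reversibility_ratio(first_scan: ExperimentCurve, reheat_scan: ExperimentCurve):
    """Percent unfolding reversibility: 100 * integral(reheat)/integral(first).

    Both curves must be baseline-subtracted DSC scans over the same
    temperature window; trapezoidal integration.  Returns
    ``(percent, clipped_flag)`` — the flag marks ratios above 100 %.
    """
    if not np.allclose(first_scan.x[[0, -1]], reheat_scan.x[[0, -1]]):
        raise KineticsError("scans must share the temperature window")
    area_first = np.trapezoid(first_scan.y, first_scan.x)
    if area_first == 0:
        raise KineticsError("first-scan integral is zero; ratio undefined")
    area_reheat = np.trapezoid(reheat_scan.y, reheat_scan.x)
    pct = 100.0 * area_reheat / area_first
    return float(pct), bool(pct > 100.0)


def state_fraction_sls_correlation(
    params: KineticParams,
    v: float,
    sls: ExperimentCurve,
    window: tuple[float, float] | None = None,
) -> dict:
    """Correlate a normalised SLS trace with the modelled state fractions.

    The SLS signal is min-max normalised within ``window`` and compared
    (Pearson r) against xI, xD and the cumulative xI + xD evaluated on
    the same temperatures; the best-matching candidate names the species
    whose accumulation the aggregation signal follows.
    """
    x, y = sls.x, sls.y
    if window is not None:
        m = (x >= window[0]) & (x <= window[1])
        x, y = x[m], y[m]
    if x.size < 3:
        raise KineticsError("too few SLS points in window")
    if np.ptp(y) == 0:
        raise KineticsError("SLS constant in window; correlation undefined")
    y_norm = (y - y.min()) / np.ptp(y)
    frac = propagate_scan(params, x[0], x[-1], v, grid=x)
    candidates = {"I": frac.xI, "D": frac.xD, "I+D": frac.xI + frac.xD}
    rs = {}
    for name, series in candidates.items():
        if np.ptp(series) == 0:
            rs[name] = np.nan
        else:
            rs[name] = float(pearsonr(y_norm, series)[0])
    valid = {k: v_ for k, v_ in rs.items() if np.isfinite(v_)}
    if not valid:
        raise KineticsError("all candidate fractions are constant in window")
    best = max(valid, key=valid.get)
    return {"r": rs, "best_match": best}
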