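"""Global weighted least-squares fitting of multi-technique unfolding data.

All thermal scans (DSC, BCM, CD) at every scan rate and all isothermal
traces share one set of kinetic parameters (Ea1, Tstar1, Ea2, Tstar2);
calorimetric enthalpies are shared across DSC datasets and per-state
linear baselines are local to each spectroscopic dataset.  Because the
model is linear in the enthalpies and baselines, those are solved
exactly by (bounded) linear least squares inside the residual — a
variable-projection scheme — leaving a four-dimensional nonlinear
problem attacked from multiple Latin-hypercube starts plus a
data-informed start.

The enthalpy dissection constraint mirrors standard practice for
scan-rate-limited data: either dHcal1 or dHcal2 is pinned to zero, or
("auto") both constraints are fitted and the lower-rss one retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lstsq as _lstsq
from scipy.optimize import least_squares, lsq_linear
from scipy.stats import qmc

from .kinetics import (
    ExperimentCurve,
    KineticParams,
    KineticsError,
    StateFractions,
    propagate_isothermal,
    propagate_scan,
    rate_constant,
)

_SPECTRO_SCAN = ("DSF_BCM", "CD")


@dataclass
class FitResult:
    """Outcome of a global fit.

    ``stderr`` maps free parameter names to asymptotic standard errors
    from the Jacobian at the solution; it is ``None`` (with a flag) when
    the Jacobian is rank deficient.
    """

    params: KineticParams
    per_dataset_baselines: dict
    rss: float
    stderr: dict | None
    constraint_used: str
    n_scan_rates: int
    flags: list = field(default_factory=list)
    success: bool = True

    def as_dict(self) -> dict:
        return {
            "params": self.params.as_dict(),
            "per_dataset_baselines": {
                k: {s: list(ab) for s, ab in v.items()}
                for k, v in self.per_dataset_baselines.items()
            },
            "rss": self.rss,
            "stderr": self.stderr,
            "constraint_used": self.constraint_used,
            "n_scan_rates": self.n_scan_rates,
            "flags": self.flags,
            "success": self.success,
        }


DEFAULT_BOUNDS = {
    "Ea1": (50.0, 800.0),
    "Tstar1": (300.0, 390.0),
    "Ea2": (50.0, 800.0),
    "Tstar2": (300.0, 390.0),
}


def _dataset_weights(datasets, scheme):
    """Per-dataset residual weights.

    ``inverse_variance`` estimates the noise level from linearly
    detrended pre-transition points (first 15 % of each curve) so that
    techniques with different units contribute comparably.
    """
    weights = []
    for d in datasets:
        if scheme == "uniform":
            weights.append(1.0)
            continue
        # second differences cancel smooth signal; their MAD estimates the
        # point noise robustly even where the curve itself is steep
        d2 = np.diff(d.y, n=2)
        sd = float(np.median(np.abs(d2)) / (np.sqrt(6.0) * 0.6744898))
        amp = float(np.ptp(d.y))
        sd = max(sd, 1e-4 * amp if amp > 0 else 1e-12, 1e-12)
        weights.append(1.0 / sd)
    return np.asarray(weights)


def _forward_fractions(p, datasets):
    """State fractions for every dataset at nonlinear params p.

    Scan datasets sharing a scan rate and grid (e.g. DSC and BCM curves
    from the same run) reuse a single propagation.
    """
    ea1, ts1, ea2, ts2 = p
    kp = KineticParams(Ea1=ea1, Tstar1=ts1, Ea2=ea2, Tstar2=ts2)
    out = []
    cache = {}
    for d in datasets:
        if d.technique == "ISOTHERMAL":
            out.append(propagate_isothermal(kp, d.hold_temperature, d.x))
        else:
            key = (d.scan_rate, d.x[0], d.x[-1], d.x.size)
            if key not in cache:
                cache[key] = propagate_scan(
                    kp, d.x[0], d.x[-1], d.scan_rate, grid=d.x)
            out.append(cache[key])
    return kp, out


def _linear_design(p, datasets, weights, constraint, fit_dsc_baseline, Tref):
    """Stacked weighted design matrix for the linear parameters.

    Global columns first (the free calorimetric enthalpies), then the
    per-dataset baseline blocks.  Returns the matrix, the weighted
    observation vector and bookkeeping of the column layout.
    """
    kp, fracs = _forward_fractions(p, datasets)
    free_dh = [s for s in ("dHcal1", "dHcal2")
               if constraint != f"fix_{s}"]
    has_dsc = any(d.technique == "DSC" for d in datasets)
    if not has_dsc:
        free_dh = []
    n_global = len(free_dh)
    blocks, cols_per_ds = [], []
    rows_total = sum(d.x.size for d in datasets)
    ncols = n_global
    for d in datasets:
        if d.technique == "DSC":
            nc = 2 if fit_dsc_baseline else 0
        elif d.technique in _SPECTRO_SCAN:
            nc = 6
        else:  # ISOTHERMAL
            nc = 3
        cols_per_ds.append(nc)
        ncols += nc
    A = np.zeros((rows_total, ncols))
    b = np.zeros(rows_total)
    row = 0
    col = n_global
    for d, fr, w, nc in zip(datasets, fracs, weights, cols_per_ds):
        n = d.x.size
        sl = slice(row, row + n)
        b[sl] = w * d.y
        if d.technique == "DSC":
            k1 = rate_constant(kp, 1, d.x)
            k2 = rate_constant(kp, 2, d.x)
            basis = {"dHcal1": k1 * fr.xN / d.scan_rate,
                     "dHcal2": k2 * fr.xI / d.scan_rate}
            for j, name in enumerate(free_dh):
                A[sl, j] = w * basis[name]
            if fit_dsc_baseline:
                A[sl, col] = w
                A[sl, col + 1] = w * (d.x - Tref)
        elif d.technique in _SPECTRO_SCAN:
            dx = d.x - Tref
            for j, xs in enumerate((fr.xN, fr.xI, fr.xD)):
                A[sl, col + 2 * j] = w * xs
                A[sl, col + 2 * j + 1] = w * xs * dx
        else:
            for j, xs in enumerate((fr.xN, fr.xI, fr.xD)):
                A[sl, col + j] = w * xs
        row += n
        col += nc
    return A, b, free_dh, cols_per_ds


def _solve_linear(A, b, n_dh):
    """Least squares with non-negativity on the leading enthalpy columns."""
    if A.shape[1] == 0:
        return np.zeros(0), b.copy()
    coef, *_ = _lstsq(A, b, lapack_driver="gelsy", check_finite=False)
    if n_dh and np.any(coef[:n_dh] < 0):
        lb = np.full(A.shape[1], -np.inf)
        ub = np.full(A.shape[1], np.inf)
        lb[:n_dh] = 0.0
        res = lsq_linear(A, b, bounds=(lb, ub))
        coef = res.x
    return coef, A @ coef - b


def _projected_residual(p, datasets, weights, constraint, fit_dsc_baseline, Tref):
    A, b, free_dh, _ = _linear_design(
        p, datasets, weights, constraint, fit_dsc_baseline, Tref)
    _, resid = _solve_linear(A, b, len(free_dh))
    return resid


def _heuristic_start(datasets):
    """Data-informed start: place both Tstar near the steepest transition."""
    t_trans = []
    for d in datasets:
        if d.technique == "ISOTHERMAL":
            continue
        dy = np.abs(np.gradient(d.y, d.x))
        t_trans.append(float(d.x[int(np.argmax(dy))]))
    t0 = float(np.median(t_trans)) if t_trans else 335.0
    t0 = min(max(t0, 302.0), 388.0)
    return np.array([250.0, min(max(t0 - 2.0, 300.0), 390.0),
                     250.0, min(max(t0 + 5.0, 300.0), 390.0)])


def _fit_one_constraint(datasets, weights, constraint, starts, bounds_arr,
                        fit_dsc_baseline, Tref, patience: int = 8):
    """Multi-start local optimisation; deterministic early stop.

    Starts are visited in order and the search stops once ``patience``
    consecutive starts fail to improve the best weighted rss by more
    than 0.1 % (ties keep the earliest solution).
    """
    best = None
    stale = 0
    args = (datasets, weights, constraint, fit_dsc_baseline, Tref)
    scale = [100.0, 5.0, 100.0, 5.0]
    for p0 in starts:
        p0c = np.clip(p0, bounds_arr[0] + 1e-9, bounds_arr[1] - 1e-9)
        try:
            sol = least_squares(
                _projected_residual, p0c, bounds=bounds_arr, args=args,
                method="trf", xtol=1e-9, ftol=1e-9, gtol=1e-9, x_scale=scale,
            )
        except (KineticsError, np.linalg.LinAlgError):
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[1] * (1.0 - 1e-3):
            best = (sol, rss)
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    if best is None:
        raise KineticsError("optimizer failed from every start")
    # polish the winner to full precision (refit-stable solution)
    sol = least_squares(
        _projected_residual, best[0].x, bounds=bounds_arr, args=args,
        method="trf", xtol=1e-13, ftol=1e-13, gtol=1e-13, x_scale=scale,
    )
    return sol, float(2.0 * sol.cost)


def _collect_result(p, datasets, weights, constraint, fit_dsc_baseline, Tref,
                    rss, n_scan_rates, flags):
    A, b, free_dh, cols_per_ds = _linear_design(
        p, datasets, weights, constraint, fit_dsc_baseline, Tref)
    coef, resid = _solve_linear(A, b, len(free_dh))
    dh = {"dHcal1": 0.0, "dHcal2": 0.0}
    for j, name in enumerate(free_dh):
        dh[name] = max(float(coef[j]), 0.0)
    params = KineticParams(Ea1=p[0], Tstar1=p[1], Ea2=p[2], Tstar2=p[3],
                           dHcal1=dh["dHcal1"], dHcal2=dh["dHcal2"])
    baselines = {}
    col = len(free_dh)
    for d, nc in zip(datasets, cols_per_ds):
        name = d.name or f"{d.technique}@{d.scan_rate or d.hold_temperature}"
        if d.technique == "DSC":
            if fit_dsc_baseline:
                baselines[name] = {"baseline": (float(coef[col]), float(coef[col + 1]))}
        elif d.technique in _SPECTRO_SCAN:
            baselines[name] = {
                s: (float(coef[col + 2 * j]), float(coef[col + 2 * j + 1]))
                for j, s in enumerate("NID")
            }
        else:
            baselines[name] = {
                s: (float(coef[col + j]), 0.0) for j, s in enumerate("NID")
            }
        col += nc

    # standard errors from the full finite-difference Jacobian
    theta = np.concatenate([p, coef])
    names = ["Ea1", "Tstar1", "Ea2", "Tstar2"] + free_dh + [
        f"linear_{i}" for i in range(coef.size - len(free_dh))]

    def full_resid(th):
        A2, b2, _, _ = _linear_design(
            th[:4], datasets, weights, constraint, fit_dsc_baseline, Tref)
        return A2 @ th[4:] - b2

    n, m = resid.size, theta.size
    J = np.empty((n, m))
    for j in range(m):
        eps = 1e-6 * max(abs(theta[j]), 1.0)
        tp = theta.copy(); tp[j] += eps
        tm = theta.copy(); tm[j] -= eps
        J[:, j] = (full_resid(tp) - full_resid(tm)) / (2 * eps)
    stderr = None
    sv = np.linalg.svd(J, compute_uv=False)
    if sv[0] > 0 and sv[-1] / sv[0] > 1e-10 and n > m:
        s2 = rss / (n - m)
        cov = np.linalg.inv(J.T @ J) * s2
        stderr = {nm: float(np.sqrt(max(cv, 0.0)))
                  for nm, cv in zip(names, np.diag(cov))}
        stderr = {k: v for k, v in stderr.items() if not k.startswith("linear_")}
    else:
        flags = flags + ["jacobian_rank_deficient"]
    return FitResult(
        params=params, per_dataset_baselines=baselines, rss=rss,
        stderr=stderr, constraint_used=constraint,
        n_scan_rates=n_scan_rates, flags=flags,
    )


def global_fit(
    datasets: list[ExperimentCurve],
    init: KineticParams | None = None,
    constraint: str = "auto",
    weights: str = "inverse_variance",
    n_starts: int = 20,
    seed: int = 1,
    bounds: dict | None = None,
    fit_dsc_baseline: bool = False,
    Tref: float = 298.15,
) -> FitResult:
    """Fit the three-state irreversible model globally across datasets.

    Parameters
    ----------
    datasets
        Thermal scans (DSC / DSF_BCM / CD) at one or more scan rates plus
        optional isothermal traces.  SLS curves are ignored with a flag:
        light scattering reports aggregation, not the unfolding states.
    constraint
        ``fix_dHcal1`` / ``fix_dHcal2`` pin one enthalpy to zero;
        ``auto`` fits both constraints and keeps the lower-rss solution;
        ``none`` leaves both free.
    weights
        ``inverse_variance`` (pre-transition noise based, default) or
        ``uniform``.
    n_starts
        Number of Latin-hypercube starts for the nonlinear stage (a
        data-informed start and ``init``, when given, are always added).
    """
    flags = []
    fit_sets = [d for d in datasets if d.technique != "SLS"]
    if len(fit_sets) < len(datasets):
        flags.append("sls_datasets_excluded")
    if not fit_sets:
        raise KineticsError("no fittable datasets")
    rates = sorted({d.scan_rate for d in fit_sets if d.scan_rate is not None})
    if len(rates) < 2:
        warnings.warn(
            "fewer than 2 scan rates: kinetic parameters are weakly "
            "identifiable from scan data alone", stacklevel=2)
        flags.append("identifiability_warning")

    w = _dataset_weights(fit_sets, weights)
    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    lo = np.array([bnds["Ea1"][0], bnds["Tstar1"][0], bnds["Ea2"][0], bnds["Tstar2"][0]])
    hi = np.array([bnds["Ea1"][1], bnds["Tstar1"][1], bnds["Ea2"][1], bnds["Tstar2"][1]])

    sampler = qmc.LatinHypercube(d=4, seed=seed)
    starts = [_heuristic_start(fit_sets)]
    if init is not None:
        starts.append(np.array([init.Ea1, init.Tstar1, init.Ea2, init.Tstar2]))
    starts += list(lo + sampler.random(n_starts) * (hi - lo))

    constraints = (["fix_dHcal1", "fix_dHcal2"] if constraint == "auto"
                   else [constraint])
    best = None
    for con in constraints:
        sol, rss = _fit_one_constraint(
            fit_sets, w, con, starts, (lo, hi), fit_dsc_baseline, Tref)
        if best is None or rss < best[2]:
            best = (con, sol, rss)
    con, sol, rss = best
    if not sol.success:
        flags.append("optimizer_not_converged")
    res = _collect_result(sol.x, fit_sets, w, con, fit_dsc_baseline, Tref,
                          rss, len(rates), flags)
    res.success = bool(sol.success)
    return res
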