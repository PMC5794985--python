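"""Global two-state fit of elastic scans, MSD decomposition, onset detection.

The central inference: at each pressure, all scattering curves of a
reduced scan are fitted *simultaneously* with the two-state elastic
intensity, sharing the thermodynamic parameters (dH, dS/R) and the
temperature-independent well separation d across temperatures, with one
free single-well MSD per temperature.  Populations follow the Arrhenius
law p2/p1 = exp(-dG/(RT)).

Least-squares machinery is lmfit (MINPACK Levenberg-Marquardt with
bound transformations, so positivity constraints are enforced in a
transformed parameter space); the model, residuals, multi-start
strategy and identifiability diagnostics live here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .forward_models import GAS_CONSTANT, ThermoParams, populations
from .model_free import fit_gaussian_msd
from .reduction_io import ElasticScan

__all__ = [
    "TwoStateParams",
    "FitReport",
    "MSDRecord",
    "FitOptions",
    "OnsetResult",
    "PressureSeriesResult",
    "global_fit",
    "decompose_msd",
    "onset_temperature",
    "pressure_series_fit",
]

logger = logging.getLogger(__name__)

# multi-start grid: d (A) x dH (kJ/mol)
_DEFAULT_STARTS = tuple(
    (d0, dh0) for d0 in (0.5, 1.0, 1.5, 2.0) for dh0 in (5.0, 15.0)
)


@dataclass
class TwoStateParams:
    """Converged global parameter set at one pressure."""

    thermo: ThermoParams
    d: float                       # A
    msd0_per_t: dict[float, float]  # T (K) -> <dx^2>_0 (A^2)
    P: float                       # bar


@dataclass
class FitReport:
    """Result of :func:`global_fit` with uncertainties and diagnostics."""

    params: TwoStateParams
    param_errs: dict               # same keys: dH, dS_R, d, msd0_per_t
    chi2_reduced: float
    n_iter: int
    converged: bool
    residuals_by_t: dict[float, float]   # per-curve weighted RMS
    d_identifiable: bool = True
    covar: np.ndarray | None = None
    var_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pressure_bar": self.params.P,
            "delta_h_kJ_mol": self.params.thermo.delta_h,
            "delta_h_err": self.param_errs.get("dH"),
            "delta_s_over_r": self.params.thermo.delta_s_over_r,
            "delta_s_over_r_err": self.param_errs.get("dS_R"),
            "d_A": self.params.d,
            "d_err": self.param_errs.get("d"),
            "d_identifiable": self.d_identifiable,
            "msd0_per_t": {str(k): v for k, v in self.params.msd0_per_t.items()},
            "msd0_err_per_t": {str(k): v
                               for k, v in self.param_errs["msd0_per_t"].items()},
            "chi2_reduced": self.chi2_reduced,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "residual_rms_by_t": {str(k): v
                                  for k, v in self.residuals_by_t.items()},
        }


@dataclass
class MSDRecord:
    """Per-temperature MSD decomposition (total vs single-well)."""

    T: float
    msd_total: float
    msd_single_well: float
    msd_total_err: float
    msd_single_well_err: float


@dataclass
class FitOptions:
    """Options for the global fit."""

    q_max: float | None = None        # restrict the fitted q window
    starts: tuple = _DEFAULT_STARTS   # multi-start (d0, dH0) grid
    ds_r_init: float = 2.0
    msd0_mode: str = "free"           # "free" or "linear"
    with_scale: bool = False          # per-curve free amplitude
    max_nfev: int | None = None


def _model_matrix(params: lmfit.Parameters, q: np.ndarray,
                  temps: np.ndarray, opts: FitOptions) -> np.ndarray:
    thermo = ThermoParams(params["dH"].value, params["dS_R"].value)
    pp = populations(temps, thermo).product
    d = params["d"].value
    sinc = np.sinc(q * d / np.pi)
    brace = 1.0 - 2.0 * pp[:, None] * (1.0 - sinc[None, :])
    if opts.msd0_mode == "linear":
        msd0 = params["msd0_slope"].value * (temps - temps[0])
    else:
        msd0 = np.array([params[f"msd0_{i}"].value for i in range(len(temps))])
    model = np.exp(-msd0[:, None] * q[None, :] ** 2) * brace
    if opts.with_scale:
        scale = np.array([params[f"scale_{i}"].value for i in range(len(temps))])
        model = scale[:, None] * model
    return model


def _anharmonic_term(thermo: ThermoParams, d: float, t: float,
                     report_covar, var_names: list[str], errs: dict):
    """Inter-well MSD term p1 p2 d^2/3 at T with first-order uncertainty."""
    pops = populations(t, thermo)
    pp = float(pops.product)
    value = pp * d**2 / 3.0
    dpp_dx = pp * (pops.p2 - pops.p1)  # x = dG/(RT)
    g = {
        "dH": dpp_dx * (1e3 / (GAS_CONSTANT * t)) * d**2 / 3.0,
        "dS_R": -dpp_dx * d**2 / 3.0,
        "d": 2.0 * pp * d / 3.0,
    }
    if report_covar is not None and var_names:
        idx = {n: i for i, n in enumerate(var_names)}
        gv = np.zeros(len(var_names))
        for name, val in g.items():
            if name in idx:
                gv[idx[name]] = val
        var = float(gv @ report_covar @ gv)
    else:
        var = float(np.nansum([(g[k] * errs.get(k, np.nan)) ** 2 for k in g]))
    return value, np.sqrt(max(var, 0.0))


def global_fit(scan: ElasticScan, opts: FitOptions | None = None) -> FitReport:
    """Global weighted least-squares fit of the two-state model.

    Free parameters: dH, dS/R and d shared across temperatures, plus
    one single-well MSD per temperature (all bounded non-negative where
    physical).  The fit is run from a fixed grid of 8 starting points
    (d x dH); the converged solution with the lowest reduced chi^2
    wins.  Non-convergence is reported, never silenced.  A fit where
    the upper well stays essentially unpopulated (max p1 p2 < 1e-4) or
    where d's uncertainty exceeds half its value flags d as
    unidentifiable.
    """
    opts = opts or FitOptions()
    temps = scan.temperatures
    if len(temps) < 5:
        raise ValueError(f"need >= 5 temperatures for a global fit, have {len(temps)}")
    q = scan.q
    qmask = np.ones_like(q, dtype=bool) if opts.q_max is None else q <= opts.q_max
    qfit = q[qmask]
    data = np.stack([c.intensity[qmask] for c in scan.curves])
    sig = np.stack([c.sigma[qmask] for c in scan.curves])
    # inverse-sigma weights; unit weights where sigma is degenerate (e.g.
    # the exactly-1 reference curve, or noiseless synthetic data)
    pos = sig > 0
    weights = np.ones_like(sig)
    weights[pos] = 1.0 / sig[pos]
    if pos.any() and not pos.all():
        weights[~pos] = np.median(weights[pos])

    # data-driven initial single-well MSDs from per-curve Gaussian fits
    msd0_init = []
    for c in scan.curves:
        try:
            g = fit_gaussian_msd(c, q_max=2.0)
            msd0_init.append(min(max(g.msd, 1e-4), 5.0))
        except ValueError:
            msd0_init.append(0.01)

    def residual(params):
        model = _model_matrix(params, qfit, temps, opts)
        return ((model - data) * weights).ravel()

    results = []
    for d0, dh0 in opts.starts:
        params = lmfit.Parameters()
        params.add("dH", value=dh0, min=1e-2, max=100.0)
        params.add("dS_R", value=opts.ds_r_init, min=-20.0, max=50.0)
        params.add("d", value=d0, min=0.0, max=10.0)
        if opts.msd0_mode == "linear":
            params.add("msd0_slope", value=1e-3, min=0.0, max=0.1)
        else:
            for i, v in enumerate(msd0_init):
                params.add(f"msd0_{i}", value=v, min=0.0, max=10.0)
        if opts.with_scale:
            for i in range(len(temps)):
                params.add(f"scale_{i}", value=1.0, min=0.1, max=10.0)
        res = lmfit.minimize(residual, params, method="leastsq",
                             max_nfev=opts.max_nfev)
        results.append(res)

    converged = [r for r in results if r.success]
    pool = converged or results
    best = min(pool, key=lambda r: r.redchi)
    if not converged:
        logger.warning("global_fit: no start converged (P=%s bar)", scan.P)

    bp = best.params
    if opts.msd0_mode == "linear":
        slope = bp["msd0_slope"].value
        slope_err = bp["msd0_slope"].stderr or np.nan
        msd0_map = {float(t): slope * (t - temps[0]) for t in temps}
        msd0_err_map = {float(t): slope_err * (t - temps[0]) for t in temps}
    else:
        msd0_map = {float(t): bp[f"msd0_{i}"].value for i, t in enumerate(temps)}
        msd0_err_map = {
            float(t): (bp[f"msd0_{i}"].stderr if bp[f"msd0_{i}"].stderr is not None
                       else np.nan)
            for i, t in enumerate(temps)
        }

    thermo = ThermoParams(bp["dH"].value, bp["dS_R"].value)
    params_out = TwoStateParams(thermo=thermo, d=bp["d"].value,
                                msd0_per_t=msd0_map, P=scan.P)
    errs = {
        "dH": bp["dH"].stderr if bp["dH"].stderr is not None else np.nan,
        "dS_R": bp["dS_R"].stderr if bp["dS_R"].stderr is not None else np.nan,
        "d": bp["d"].stderr if bp["d"].stderr is not None else np.nan,
        "msd0_per_t": msd0_err_map,
    }

    model = _model_matrix(bp, qfit, temps, opts)
    wres = (model - data) * weights
    residuals_by_t = {float(t): float(np.sqrt(np.mean(wres[i] ** 2)))
                      for i, t in enumerate(temps)}

    # d is identified only when the fitted inter-well MSD term is itself
    # significant: an essentially frozen scan (p1 p2 ~ 0 everywhere) or a
    # term smaller than twice its propagated uncertainty cannot pin d
    pp_max = float(np.max(populations(temps, thermo).product))
    t_hi = float(temps[-1])
    anh, anh_err = _anharmonic_term(thermo, params_out.d, t_hi,
                                    report_covar=getattr(best, "covar", None),
                                    var_names=list(best.var_names), errs=errs)
    d_identifiable = bool(pp_max >= 1e-4 and np.isfinite(errs["d"])
                          and (anh_err == 0.0 or anh > 2.0 * anh_err))
    if not d_identifiable:
        logger.warning("global_fit: well separation d poorly identified "
                       "(max p1p2=%.2e, anharmonic term %.3g +- %.3g A^2)",
                       pp_max, anh, anh_err)

    return FitReport(
        params=params_out,
        param_errs=errs,
        chi2_reduced=float(best.redchi),
        n_iter=int(best.nfev),
        converged=bool(best.success),
        residuals_by_t=residuals_by_t,
        d_identifiable=d_identifiable,
        covar=getattr(best, "covar", None),
        var_names=list(best.var_names),
    )


def decompose_msd(report: FitReport) -> list[MSDRecord]:
    """Split the fitted MSD into single-well and total (Arrhenius-weighted).

    msd_single_well(T) is the fitted <dx^2>_0(T); msd_total adds the
    inter-well term p1 p2 d^2 / 3 at the fitted thermodynamics.  Errors
    are first-order propagation through the analytic gradient, using the
    full fit covariance when available.
    """
    p = report.params
    thermo = p.thermo
    out = []
    name_to_idx = {n: i for i, n in enumerate(report.var_names)}
    for i, (t, msd0) in enumerate(sorted(p.msd0_per_t.items())):
        pops = populations(t, thermo)
        pp = float(pops.product)
        total = msd0 + pp * p.d**2 / 3.0
        # analytic gradient of the inter-well term
        dpp_dx = pp * (pops.p2 - pops.p1)     # x = dG/(RT)
        g = {
            "dH": dpp_dx * (1e3 / (GAS_CONSTANT * t)) * p.d**2 / 3.0,
            "dS_R": -dpp_dx * p.d**2 / 3.0,
            "d": 2.0 * pp * p.d / 3.0,
            f"msd0_{i}": 1.0,
        }
        msd0_err = report.param_errs["msd0_per_t"].get(t, np.nan)
        if report.covar is not None and name_to_idx:
            gv = np.zeros(len(report.var_names))
            for name, val in g.items():
                if name in name_to_idx:
                    gv[name_to_idx[name]] = val
            var = float(gv @ report.covar @ gv)
            total_err = np.sqrt(max(var, 0.0))
        else:
            e = report.param_errs
            total_err = np.sqrt(
                np.nansum([
                    (g["dH"] * e["dH"]) ** 2,
                    (g["dS_R"] * e["dS_R"]) ** 2,
                    (g["d"] * e["d"]) ** 2,
                    msd0_err**2,
                ])
            )
        out.append(MSDRecord(T=float(t), msd_total=float(total),
                             msd_single_well=float(msd0),
                             msd_total_err=float(total_err),
                             msd_single_well_err=float(msd0_err)))
    return out


@dataclass
class OnsetResult:
    """Onset temperature of the dynamical transition."""

    t_on: float | None
    t_on_err: float | None
    detected: bool
    method: str


def _two_segment_sse(t: np.ndarray, y: np.ndarray, tb: float):
    X = np.column_stack([np.ones_like(t), t, np.maximum(t - tb, 0.0)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef, resid


def onset_temperature(records: list[MSDRecord], method: str = "breakpoint",
                      n_boot: int = 200, seed: int = 0,
                      threshold: float = 0.05) -> OnsetResult:
    """Estimate the dynamical-transition onset temperature T_on.

    ``breakpoint`` (default): exhaustive search over measured grid
    temperatures for the best continuous two-segment piecewise-linear
    fit of msd_total(T); a breakpoint is reported only when the
    two-segment model beats a single line (F-test at 5%, requiring an
    actual SSE reduction), otherwise the result is flagged "none
    detected".  The uncertainty is a seeded residual bootstrap.

    ``threshold``: the smallest T where the inter-well (anharmonic) MSD
    term exceeds ``threshold`` of the low-temperature harmonic
    extrapolation of msd_total.
    """
    recs = sorted(records, key=lambda r: r.T)
    t = np.array([r.T for r in recs])
    y = np.array([r.msd_total for r in recs])
    n = len(recs)
    if n < 6:
        raise ValueError(f"need >= 6 temperatures, have {n}")

    if method == "threshold":
        n_harm = max(3, n // 3)
        coef = np.polyfit(t[:n_harm], y[:n_harm], 1)
        harm = np.polyval(coef, t)
        anh = np.array([r.msd_total - r.msd_single_well for r in recs])
        floor = max(1e-3, float(np.max(np.abs(harm))) * 1e-3)
        exceeds = anh > threshold * np.maximum(harm, floor)
        if not exceeds.any():
            return OnsetResult(None, None, False, method)
        idx = int(np.argmax(exceeds))
        err = (t[min(idx + 1, n - 1)] - t[max(idx - 1, 0)]) / 2.0
        return OnsetResult(float(t[idx]), float(err), True, method)

    if method != "breakpoint":
        raise ValueError(f"unknown method {method!r}")

    candidates = t[2:n - 2]
    fits = [(_two_segment_sse(t, y, tb), tb) for tb in candidates]
    (sse_best, coef_best, resid_best), tb_best = min(fits, key=lambda f: f[0][0])

    line = np.polyfit(t, y, 1)
    sse_line = float(np.sum((y - np.polyval(line, t)) ** 2))

    dof = n - 3
    improvement = sse_line - sse_best
    if improvement <= max(1e-12, 1e-9 * sse_line) or dof <= 1:
        return OnsetResult(None, None, False, "breakpoint")
    if sse_best > 0:
        f_stat = (improvement / 1.0) / (sse_best / dof)
        p_val = stats.f.sf(f_stat, 1, dof)
        if p_val > 0.05:
            return OnsetResult(None, None, False, "breakpoint")

    yhat = y - resid_best
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        yb = yhat + rng.choice(resid_best, size=n, replace=True)
        _, tb = min(((_two_segment_sse(t, yb, c)[0], c) for c in candidates),
                    key=lambda f: f[0])
        boots.append(tb)
    return OnsetResult(float(tb_best), float(np.std(boots)), True, "breakpoint")


@dataclass
class PressureSeriesResult:
    """Per-pressure fit table plus the pressure-independence verdict."""

    table: pd.DataFrame
    thermo_pressure_dependent: bool
    reports: dict[float, FitReport] = field(default_factory=dict)


def pressure_series_fit(scans: list[ElasticScan],
                        opts: FitOptions | None = None) -> PressureSeriesResult:
    """Independent global fit per pressure; d(P) table + thermo check.

    Each scan is fitted on its own.  A per-row ``failed`` flag records
    fit errors without aborting the series.  The thermodynamic
    parameters are flagged pressure-dependent when any pair differs by
    more than twice its joint standard error.
    """
    rows = []
    reports: dict[float, FitReport] = {}
    for scan in scans:
        try:
            rep = global_fit(scan, opts)
        except Exception as exc:  # row-level failure, not a pipeline abort
            logger.warning("pressure_series_fit: fit failed at P=%s bar: %s",
                           scan.P, exc)
            rows.append({"pressure_bar": scan.P, "d_A": np.nan, "d_err": np.nan,
                         "delta_h_kJ_mol": np.nan, "delta_h_err": np.nan,
                         "delta_s_over_r": np.nan, "delta_s_over_r_err": np.nan,
                         "chi2_reduced": np.nan, "converged": False,
                         "d_identifiable": False, "failed": True})
            continue
        reports[float(scan.P)] = rep
        rows.append({
            "pressure_bar": scan.P,
            "d_A": rep.params.d, "d_err": rep.param_errs["d"],
            "delta_h_kJ_mol": rep.params.thermo.delta_h,
            "delta_h_err": rep.param_errs["dH"],
            "delta_s_over_r": rep.params.thermo.delta_s_over_r,
            "delta_s_over_r_err": rep.param_errs["dS_R"],
            "chi2_reduced": rep.chi2_reduced,
            "converged": rep.converged,
            "d_identifiable": rep.d_identifiable,
            "failed": False,
        })
    table = pd.DataFrame(rows).sort_values("pressure_bar").reset_index(drop=True)

    flag = False
    ok = table[~table["failed"]]
    n = len(ok)
    n_pairs = max(n * (n - 1), 1)  # two parameters x n(n-1)/2 pairs
    z_crit = float(stats.norm.ppf(1.0 - 0.05 / (2 * n_pairs)))  # family-wise 5%
    for col, err_col in (("delta_h_kJ_mol", "delta_h_err"),
                         ("delta_s_over_r", "delta_s_over_r_err")):
        v = ok[col].to_numpy()
        e = ok[err_col].to_numpy()
        for i in range(len(v)):
            for j in range(i + 1, len(v)):
                joint = np.sqrt(e[i] ** 2 + e[j] ** 2)
                if np.isfinite(joint) and abs(v[i] - v[j]) > z_crit * joint:
                    flag = True
    return PressureSeriesResult(table=table, thermo_pressure_dependent=flag,
                                reports=reports)
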