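"""Model-independent analyses.

Two classic EINS summaries that require no landscape model:

* the Gaussian-approximation MSD per curve — the slope of -ln I versus
  q^2 over a low-q window (0-2 1/A by default), and
* the total-intensity master curve: summed elastic intensity versus
  temperature, min-max normalized as
  I_N(T) = [I(T) - I(T_max)] / [I(T_min) - I(T_max)],
  whose collapse across pressures signals a pressure-independent
  dynamical-transition onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .reduction_io import ElasticScan, ScatteringCurve

__all__ = [
    "InsufficientDataError",
    "NormalizationError",
    "GaussianFitResult",
    "MasterCurve",
    "fit_gaussian_msd",
    "total_intensity",
    "normalize_master",
    "collapse_metric",
]

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Too few usable points for a fit."""


class NormalizationError(ValueError):
    """Degenerate (constant) master curve cannot be min-max normalized."""


@dataclass
class GaussianFitResult:
    """Gaussian-approximation MSD from one curve."""

    msd: float            # A^2
    msd_err: float        # A^2
    q2_range: tuple       # (q2_min, q2_max) of fitted window, 1/A^2
    n_points: int
    residual_rms: float


@dataclass
class MasterCurve:
    """Summed elastic intensity vs T at one pressure, optionally normalized."""

    T: np.ndarray
    I_tot: np.ndarray
    P: float
    I_tot_err: np.ndarray | None = None
    I_N: np.ndarray | None = None
    I_N_err: np.ndarray | None = None


def fit_gaussian_msd(curve: ScatteringCurve, q_max: float = 2.0) -> GaussianFitResult:
    """Weighted linear regression of -ln I on q^2 over q <= q_max.

    Points with non-positive intensity are excluded (and counted in the
    log); the slope is the total MSD in the Gaussian approximation.
    Weights are inverse-variance from the sigma column when available.
    """
    mask = (curve.q <= q_max) & (curve.intensity > 0)
    n_dropped = int(np.sum((curve.q <= q_max) & ~(curve.intensity > 0)))
    if n_dropped:
        logger.info("fit_gaussian_msd: excluded %d non-positive point(s)", n_dropped)
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 usable points with q <= {q_max}, have {int(mask.sum())}"
        )
    x = curve.q[mask] ** 2
    y = -np.log(curve.intensity[mask])
    sig_y = curve.sigma[mask] / curve.intensity[mask]
    X = sm.add_constant(x)
    if np.all(sig_y > 0):
        res = sm.WLS(y, X, weights=1.0 / sig_y**2).fit()
    else:
        res = sm.OLS(y, X).fit()
    return GaussianFitResult(
        msd=float(res.params[1]),
        msd_err=float(res.bse[1]),
        q2_range=(float(x.min()), float(x.max())),
        n_points=int(mask.sum()),
        residual_rms=float(np.sqrt(np.mean(res.resid**2))),
    )


def total_intensity(scan: ElasticScan, mode: str = "sum") -> MasterCurve:
    """Total scattered intensity per temperature.

    ``mode='sum'`` (default) sums the intensity over the q grid;
    ``mode='trapezoid'`` integrates with trapezoidal weights in q.  The
    two differ only by fixed positive weights and normalize away in the
    master curve.  Propagated uncertainties ride along.
    """
    t = scan.temperatures
    if mode == "sum":
        i_tot = np.array([c.intensity.sum() for c in scan.curves])
        i_err = np.array([np.sqrt(np.sum(c.sigma**2)) for c in scan.curves])
    elif mode == "trapezoid":
        q = scan.q
        w = np.gradient(q)  # trapezoid weights on a general grid
        i_tot = np.array([np.trapezoid(c.intensity, q) for c in scan.curves])
        i_err = np.array([np.sqrt(np.sum((w * c.sigma) ** 2)) for c in scan.curves])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return MasterCurve(T=t, I_tot=i_tot, P=scan.P, I_tot_err=i_err)


def normalize_master(mc: MasterCurve) -> MasterCurve:
    """Min-max normalization between the lowest and highest temperature.

    I_N = (I(T) - I(T_max)) / (I(T_min) - I(T_max)); by construction 1
    at the lowest and 0 at the highest measured temperature.  Invariant
    under affine rescaling of the input intensities.
    """
    if len(mc.T) < 2:
        raise NormalizationError("need >= 2 temperatures")
    lo, hi = mc.I_tot[0], mc.I_tot[-1]
    denom = lo - hi
    if denom == 0 or not np.isfinite(denom):
        raise NormalizationError("constant master curve cannot be normalized")
    i_n = (mc.I_tot - hi) / denom
    i_n_err = None
    if mc.I_tot_err is not None:
        i_n_err = mc.I_tot_err / abs(denom)
    return MasterCurve(T=mc.T, I_tot=mc.I_tot, P=mc.P,
                       I_tot_err=mc.I_tot_err, I_N=i_n, I_N_err=i_n_err)


def collapse_metric(mcs: list[MasterCurve]) -> float:
    """RMS deviation of normalized master curves from their mean.

    Curves are linearly interpolated onto the first curve's temperature
    grid when grids differ.  A single curve collapses trivially (0).
    """
    if not mcs:
        raise ValueError("no master curves")
    for mc in mcs:
        if mc.I_N is None:
            raise ValueError("master curves must be normalized first")
    if len(mcs) == 1:
        logger.info("collapse_metric: single curve, metric is 0 by definition")
        return 0.0
    t_grid = mcs[0].T
    stack = np.stack([
        mc.I_N if mc is mcs[0] else np.interp(t_grid, mc.T, mc.I_N)
        for mc in mcs
    ])
    mean = stack.mean(axis=0)
    return float(np.sqrt(np.mean((stack - mean) ** 2)))
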