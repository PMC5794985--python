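"""Scattering-data containers, the TSV dialect, and the reduction chain.

The reduction chain mirrors standard elastic-scan practice on a
backscattering spectrometer: subtract the empty-cell signal, bin the
slow temperature ramp, then normalize every curve point-wise to the
lowest-temperature (20 K) reference curve.

File dialect: long-format TSV, one row per (pressure, temperature, q)
point, header exactly ``pressure_bar  temperature_K  q_invA  intensity
sigma``; comment lines start with ``#``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "FormatError",
    "AlignmentError",
    "DegenerateReferenceError",
    "ScatteringCurve",
    "ElasticScan",
    "read_scan",
    "read_all_scans",
    "write_scan",
    "write_scans",
    "subtract_cell",
    "normalize_to_reference",
    "bin_temperatures",
    "reduce_scan",
]

logger = logging.getLogger(__name__)

COLUMNS = ["pressure_bar", "temperature_K", "q_invA", "intensity", "sigma"]


class FormatError(ValueError):
    """Malformed scattering table (missing column, bad cell, ragged q grid)."""


class AlignmentError(ValueError):
    """Operands do not share a common q grid."""


class DegenerateReferenceError(ValueError):
    """Reference curve has non-positive intensity and cannot normalize."""


@dataclass
class ScatteringCurve:
    """One elastic profile I(q) at a single (temperature, pressure).

    ``q`` in 1/A (strictly increasing), ``intensity`` dimensionless,
    ``sigma`` the per-point 1-sigma uncertainty, ``T`` in K, ``P`` in bar.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    T: float
    P: float

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.q) == len(self.intensity) == len(self.sigma)):
            raise ValueError("q, intensity, sigma must have equal length")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be >= 0")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")


@dataclass
class ElasticScan:
    """Ordered set of :class:`ScatteringCurve` over T at fixed pressure."""

    curves: list[ScatteringCurve]
    P: float
    meta: object = None

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValueError("scan must contain at least one curve")
        self.curves = sorted(self.curves, key=lambda c: c.T)
        q0 = self.curves[0].q
        for c in self.curves:
            if not np.allclose(c.q, q0):
                raise ValueError(f"curve at T={c.T} K has a different q grid")
            if not np.isclose(c.P, self.P):
                raise ValueError(f"curve at T={c.T} K has pressure {c.P}, scan has {self.P}")

    @property
    def q(self) -> np.ndarray:
        return self.curves[0].q

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([c.T for c in self.curves])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.curves:
            rows.append(
                pd.DataFrame(
                    {
                        "pressure_bar": c.P,
                        "temperature_K": c.T,
                        "q_invA": c.q,
                        "intensity": c.intensity,
                        "sigma": c.sigma,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = df[COLUMNS]
    for col in COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            row = int(np.argmax((vals.isna()).to_numpy()))
            raise FormatError(f"{path}: non-numeric or empty cell in column "
                              f"'{col}' at data row {row}")
        df[col] = vals
    return df


def _scan_from_frame(df: pd.DataFrame, pressure: float, meta=None) -> ElasticScan:
    curves = []
    ref_q = None
    for t, grp in df.groupby("temperature_K", sort=True):
        grp = grp.sort_values("q_invA")
        q = grp["q_invA"].to_numpy()
        if ref_q is None:
            ref_q = q
        elif len(q) != len(ref_q) or not np.allclose(q, ref_q):
            raise FormatError(
                f"inconsistent q grid at pressure={pressure} bar, T={t} K "
                f"(first offending row index {grp.index[0]})"
            )
        curves.append(
            ScatteringCurve(q, grp["intensity"].to_numpy(), grp["sigma"].to_numpy(),
                            T=float(t), P=float(pressure))
        )
    return ElasticScan(curves, P=float(pressure), meta=meta)


def read_scan(path, pressure: float | None = None) -> ElasticScan:
    """Read one single-pressure scan from a long-format TSV file.

    If the file contains several pressures, ``pressure`` selects one;
    omitting it is then an error listing the available values.
    """
    df = _read_table(path)
    pressures = np.sort(df["pressure_bar"].unique())
    if pressure is None:
        if len(pressures) > 1:
            raise FormatError(
                f"{path}: contains {len(pressures)} pressures {pressures.tolist()}; "
                "pass pressure= to select one or use read_all_scans()"
            )
        pressure = float(pressures[0])
    sel = df[np.isclose(df["pressure_bar"], pressure)]
    if sel.empty:
        raise FormatError(f"{path}: no rows at pressure {pressure} bar")
    return _scan_from_frame(sel, pressure)


def read_all_scans(path) -> list[ElasticScan]:
    """Read every pressure in the file as its own :class:`ElasticScan`."""
    df = _read_table(path)
    return [
        _scan_from_frame(grp, float(p))
        for p, grp in df.groupby("pressure_bar", sort=True)
    ]


def write_scan(scan: ElasticScan, path, header_comments: Sequence[str] = ()) -> None:
    write_scans([scan], path, header_comments)


def write_scans(scans: Iterable[ElasticScan], path,
                header_comments: Sequence[str] = ()) -> None:
    """Write one or more scans to a single long-format TSV file."""
    frames = [s.to_frame() for s in scans]
    df = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Reduction chain
# ---------------------------------------------------------------------------

def subtract_cell(sample: ElasticScan, cell: ElasticScan,
                  transmission: float = 1.0) -> ElasticScan:
    """Subtract the empty-cell signal: I_out = I_sample - tr * I_cell.

    The cell scan may carry a single temperature (a T-independent
    background) or a full ramp; each sample curve is paired with the
    cell curve nearest in temperature.  Uncertainties combine in
    quadrature.  Negative results are retained (not clipped) but
    counted in the log so the reduction stays auditable.
    """
    if not 0 < transmission <= 1:
        raise ValueError(f"transmission must be in (0, 1], got {transmission}")
    if len(sample.q) != len(cell.q) or not np.allclose(sample.q, cell.q):
        raise AlignmentError("sample and cell q grids differ")
    cell_t = cell.temperatures
    n_negative = 0
    out = []
    for c in sample.curves:
        cc = cell.curves[int(np.argmin(np.abs(cell_t - c.T)))]
        inten = c.intensity - transmission * cc.intensity
        sig = np.sqrt(c.sigma**2 + (transmission * cc.sigma) ** 2)
        n_negative += int(np.sum(inten < 0))
        out.append(ScatteringCurve(c.q, inten, sig, T=c.T, P=c.P))
    if n_negative:
        logger.warning("subtract_cell: %d point(s) went negative (retained)",
                       n_negative)
    return ElasticScan(out, P=sample.P, meta=sample.meta)


def normalize_to_reference(scan: ElasticScan, t_ref: float = 20.0,
                           tol: float = 2.0) -> ElasticScan:
    """Divide every curve point-wise by the curve at (nearest) ``t_ref``.

    The reference curve becomes exactly 1 at all q with zero
    uncertainty (it is perfectly correlated with itself); other curves
    get quotient-rule uncertainties.  Raises
    :class:`DegenerateReferenceError` if the reference has non-positive
    intensity anywhere.
    """
    temps = scan.temperatures
    i_ref = int(np.argmin(np.abs(temps - t_ref)))
    if abs(temps[i_ref] - t_ref) > tol:
        raise ValueError(
            f"no curve within {tol} K of reference temperature {t_ref} K "
            f"(nearest is {temps[i_ref]} K)"
        )
    ref = scan.curves[i_ref]
    if np.any(ref.intensity <= 0):
        raise DegenerateReferenceError(
            f"reference curve at T={ref.T} K has non-positive intensity"
        )
    out = []
    for c in scan.curves:
        vals = c.intensity / ref.intensity
        if c is ref:
            sig = np.zeros_like(vals)
            vals = np.ones_like(vals)
        else:
            # var(a/b) = (sigma_a/b)^2 + (a sigma_b / b^2)^2 -- safe when a <= 0
            sig = np.sqrt(
                (c.sigma / ref.intensity) ** 2
                + (c.intensity * ref.sigma / ref.intensity**2) ** 2
            )
        out.append(ScatteringCurve(c.q, vals, sig, T=c.T, P=c.P))
    return ElasticScan(out, P=scan.P, meta=scan.meta)


def bin_temperatures(curves, bin_width: float = 10.0) -> ElasticScan:
    """Bin ramp curves in temperature.

    Curves whose T falls in the same ``bin_width``-wide bin are
    averaged point-wise with inverse-variance weights and assigned the
    arithmetic mean temperature of the members.  ``curves`` may be an
    :class:`ElasticScan` or a list of :class:`ScatteringCurve`.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if isinstance(curves, ElasticScan):
        curve_list = curves.curves
        pressure, meta = curves.P, curves.meta
    else:
        curve_list = list(curves)
        if not curve_list:
            raise ValueError("no curves to bin")
        pressure, meta = curve_list[0].P, None
    if not curve_list:
        raise ValueError("no curves to bin")

    # bins centered on multiples of bin_width, so a ramp jittered around
    # nominal set-points lands in the bin of its set-point
    bins: dict[int, list[ScatteringCurve]] = {}
    for c in curve_list:
        bins.setdefault(int(np.round(c.T / bin_width)), []).append(c)

    out = []
    for _, members in sorted(bins.items()):
        if len(members) == 1:  # identity, bit-exact
            out.append(members[0])
            continue
        t_mean = float(np.mean([c.T for c in members]))
        inten = np.stack([c.intensity for c in members])
        sig = np.stack([c.sigma for c in members])
        if np.all(sig > 0):
            w = 1.0 / sig**2
            avg = np.sum(w * inten, axis=0) / np.sum(w, axis=0)
            avg_sig = np.sqrt(1.0 / np.sum(w, axis=0))
        else:  # degenerate sigmas: plain mean
            avg = inten.mean(axis=0)
            avg_sig = np.sqrt(np.sum(sig**2, axis=0)) / len(members)
        out.append(ScatteringCurve(members[0].q, avg, avg_sig,
                                   T=t_mean, P=pressure))
    return ElasticScan(out, P=pressure, meta=meta)


def reduce_scan(sample: ElasticScan, cell: ElasticScan | None = None,
                transmission: float = 1.0, bin_width: float | None = None,
                t_ref: float = 20.0) -> ElasticScan:
    """Full reduction chain: subtract cell, bin the ramp, normalize to T_ref."""
    scan = sample
    if cell is not None:
        scan = subtract_cell(scan, cell, transmission)
    tol = 2.0
    if bin_width is not None:
        scan = bin_temperatures(scan, bin_width)
        # binned ramp: the reference bin's mean T can sit anywhere in its bin
        tol = max(2.0, bin_width / 2.0 + 2.0)
    return normalize_to_reference(scan, t_ref=t_ref, tol=tol)
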