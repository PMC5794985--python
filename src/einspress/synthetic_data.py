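"""Seeded IN13-like synthetic elastic scans.

Emulates high-pressure elastic scans on a thermal backscattering
spectrometer (q = 0.2-4.9 1/A, 24 detectors, T = 20-300 K ramp,
resolution time ~100 ps): a two-state elastic structure factor on a
harmonic single-well baseline, multiplicative counting noise, an
additive empty-cell background, and a pressure-dependent well
separation d(P) that shrinks with pressure and jumps upward at a
configurable denaturation pressure.

The generator is the pipeline's testing ground: every reduction and
fitting stage can be exercised against known ground truth without any
instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward_models import (
    ThermoParams,
    WellGeometry,
    populations,
    two_state_intensity,
)
from .reduction_io import ElasticScan, ScatteringCurve

__all__ = [
    "InstrumentConfig",
    "PressureProfile",
    "DEFAULT_THERMO",
    "simulate_curve",
    "simulate_scan",
    "simulate_empty_cell",
    "add_cell",
    "ground_truth",
]

#: Thermodynamics of the low-pressure myoglobin-glycerol-water sample:
#: dH = 9.7 kJ/mol, dS/R = 2.5.
DEFAULT_THERMO = ThermoParams(delta_h=9.7, delta_s_over_r=2.5)


def _default_q_grid() -> np.ndarray:
    return np.linspace(0.2, 4.9, 24)


def _default_t_list() -> np.ndarray:
    return np.linspace(20.0, 300.0, 29)


def _default_d_of_p() -> dict[float, float]:
    # ~1.5 A at low pressure, declining ~30% by 3 kbar, upward jump at
    # the denaturation pressure; generator convention, not measured truth
    return {20.0: 1.50, 1000.0: 1.30, 2000.0: 1.05,
            3000.0: 1.45, 4000.0: 1.35, 5000.0: 1.25}


@dataclass
class InstrumentConfig:
    """Instrument grid, noise model and seed for the generator."""

    q_grid: np.ndarray = field(default_factory=_default_q_grid)
    tau: float = 100.0          # resolution time, ps
    T_list: np.ndarray = field(default_factory=_default_t_list)
    noise_rel: float = 0.01     # relative (multiplicative) Gaussian noise
    cell_level: float = 0.3     # empty-cell intensity as fraction of sample
    seed: int = 0

    def __post_init__(self) -> None:
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        self.T_list = np.asarray(self.T_list, dtype=float)
        if np.any(self.q_grid <= 0) or np.any(np.diff(self.q_grid) <= 0):
            raise ValueError("q_grid must be positive and strictly increasing")
        if np.any(np.diff(self.T_list) <= 0):
            raise ValueError("T_list must be strictly increasing")
        if self.noise_rel < 0 or self.cell_level < 0:
            raise ValueError("noise_rel and cell_level must be >= 0")


@dataclass
class PressureProfile:
    """Pressure series and the pressure dependence of the landscape.

    ``d_of_p`` tabulates the well separation (A) per pressure (bar);
    by default it is monotone non-increasing up to ``p_denat`` and
    jumps upward there (pressure-induced partial unfolding).  The
    single-well baseline is harmonic, <dx^2>_0(T) = b (T - T_ref) with
    ``harmonic_slope`` b in A^2/K; it passes through zero at the 20 K
    reference because all data are normalized there.
    """

    pressures: tuple = (20.0, 1000.0, 2000.0, 3000.0, 4000.0, 5000.0)
    d_of_p: dict[float, float] = field(default_factory=_default_d_of_p)
    p_denat: float = 3000.0
    harmonic_slope: float = 0.00125   # A^2/K
    t_ref: float = 20.0

    def __post_init__(self) -> None:
        p = np.asarray(self.pressures, dtype=float)
        if np.any(p <= 0) or np.any(np.diff(p) <= 0):
            raise ValueError("pressures must be positive and increasing")
        if any(v < 0 for v in self.d_of_p.values()):
            raise ValueError("well separations must be >= 0")
        if self.harmonic_slope < 0:
            raise ValueError("harmonic_slope must be >= 0")

    def d_at(self, pressure: float) -> float:
        for p, d in self.d_of_p.items():
            if np.isclose(p, pressure):
                return d
        raise LookupError(f"pressure {pressure} bar not in profile "
                          f"{sorted(self.d_of_p)}")

    def msd0_at(self, temperature: float) -> float:
        return max(self.harmonic_slope * (temperature - self.t_ref), 0.0)


def _rng_for(seed: int, pressure: float, temperature: float,
             tag: int = 0) -> np.random.Generator:
    # per-(T, P) substream: each curve is independently reproducible
    key = [int(seed), tag, int(round(pressure * 1000)),
           int(round(temperature * 1000))]
    return np.random.default_rng(np.random.SeedSequence(key))


def simulate_curve(temperature: float, pressure: float,
                   config: InstrumentConfig, profile: PressureProfile,
                   thermo: ThermoParams = DEFAULT_THERMO) -> ScatteringCurve:
    """One noisy elastic profile at (T, P) from the two-state model.

    Noise is multiplicative Gaussian N(1, noise_rel^2) per point; the
    sigma column carries noise_rel times the noiseless model intensity.
    """
    geom = WellGeometry(d=profile.d_at(pressure),
                        msd0=profile.msd0_at(temperature))
    pops = populations(temperature, thermo)
    model = two_state_intensity(config.q_grid, geom, pops)
    sigma = config.noise_rel * model
    if config.noise_rel > 0:
        rng = _rng_for(config.seed, pressure, temperature)
        noisy = model * (1.0 + config.noise_rel * rng.standard_normal(model.shape))
    else:
        noisy = model.copy()
    return ScatteringCurve(config.q_grid, noisy, sigma,
                           T=float(temperature), P=float(pressure))


def simulate_scan(pressure: float, config: InstrumentConfig,
                  profile: PressureProfile,
                  thermo: ThermoParams = DEFAULT_THERMO,
                  ramp: bool = False, n_sub: int = 3,
                  spread: float = 3.0) -> ElasticScan:
    """Full temperature scan at one pressure.

    With ``ramp=True`` each nominal temperature is replaced by
    ``n_sub`` sub-measurements jittered within +-``spread`` K,
    emulating continuous acquisition during a slow heating ramp; the
    raw curves are meant to be re-binned by the reduction chain.
    """
    curves = []
    for t in config.T_list:
        if ramp:
            rng = _rng_for(config.seed, pressure, t, tag=1)
            offsets = np.sort(rng.uniform(-spread, spread, size=n_sub))
            for dt in offsets:
                curves.append(simulate_curve(t + dt, pressure, config,
                                             profile, thermo))
        else:
            curves.append(simulate_curve(t, pressure, config, profile, thermo))
    return ElasticScan(curves, P=float(pressure), meta=config)


def simulate_empty_cell(config: InstrumentConfig,
                        pressure: float = 0.0) -> ElasticScan:
    """Empty-cell scan: smooth q-dependent, T-independent background.

    The cell contributes ``cell_level`` of the sample's low-T signal
    with a gentle q decay, plus its own counting noise.
    """
    base = cell_background(config)
    curves = []
    for t in config.T_list:
        sigma = config.noise_rel * base
        if config.noise_rel > 0:
            rng = _rng_for(config.seed, pressure, t, tag=2)
            inten = base * (1.0 + config.noise_rel * rng.standard_normal(base.shape))
        else:
            inten = base.copy()
        curves.append(ScatteringCurve(config.q_grid, inten, sigma,
                                      T=float(t), P=float(pressure)))
    return ElasticScan(curves, P=float(pressure), meta=config)


def cell_background(config: InstrumentConfig) -> np.ndarray:
    """Noiseless empty-cell background on the instrument q grid."""
    return config.cell_level * np.exp(-0.02 * config.q_grid**2)


def add_cell(sample: ElasticScan, config: InstrumentConfig) -> ElasticScan:
    """Add the cell background to a sample scan, as measured in-beam.

    The sample-in-cell measurement carries its *own* counting noise on
    the cell contribution (substream distinct from the empty-cell
    scan's), so subtracting an independently measured empty cell leaves
    statistically correct residual noise rather than an exact
    cancellation.  Sigmas combine in quadrature.
    """
    base = cell_background(config)
    out = []
    for c in sample.curves:
        sig_cell = config.noise_rel * base
        if config.noise_rel > 0:
            rng = _rng_for(config.seed, c.P, c.T, tag=3)
            bg = base * (1.0 + config.noise_rel * rng.standard_normal(base.shape))
        else:
            bg = base
        out.append(ScatteringCurve(
            c.q, c.intensity + bg,
            np.sqrt(c.sigma**2 + sig_cell**2), T=c.T, P=c.P))
    return ElasticScan(out, P=sample.P, meta=sample.meta)


def ground_truth(profile: PressureProfile,
                 thermo: ThermoParams = DEFAULT_THERMO) -> dict:
    """Generator parameters as a plain dict (sidecar for recovery checks)."""
    return {
        "delta_h_kJ_mol": thermo.delta_h,
        "delta_s_over_r": thermo.delta_s_over_r,
        "d_of_p_A": {str(k): v for k, v in profile.d_of_p.items()},
        "p_denat_bar": profile.p_denat,
        "harmonic_slope_A2_per_K": profile.harmonic_slope,
        "t_ref_K": profile.t_ref,
    }
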