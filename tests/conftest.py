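"""Shared fixtures: synthetic scans and the 20-seed recovery experiment."""

from __future__ import annotations

import numpy as np
import pytest

import einspress as ep

TRUE_DH = 9.7       # kJ/mol
TRUE_DS_R = 2.5
TRUE_D_LOW_P = 1.5  # A, low-pressure well separation


@pytest.fixture(scope="session")
def profile() -> ep.PressureProfile:
    return ep.PressureProfile()


@pytest.fixture(scope="session")
def thermo() -> ep.ThermoParams:
    return ep.ThermoParams(delta_h=TRUE_DH, delta_s_over_r=TRUE_DS_R)


@pytest.fixture(scope="session")
def noiseless_instrument() -> ep.InstrumentConfig:
    return ep.InstrumentConfig(noise_rel=0.0, seed=0)


@pytest.fixture(scope="session")
def noiseless_reduced_scan(noiseless_instrument, profile) -> ep.ElasticScan:
    """Noiseless low-pressure scan, normalized to the 20 K reference."""
    scan = ep.simulate_scan(20.0, noiseless_instrument, profile)
    return ep.reduce_scan(scan)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_reduced_scan) -> ep.FitReport:
    """Global two-state fit of the noiseless low-pressure scan."""
    return ep.global_fit(noiseless_reduced_scan)


def run_recovery_experiment(master_seed: int | None = None, n_seeds: int = 20):
    """The 20-seed low-pressure parameter-recovery experiment.

    Simulate a 29-temperature, 24-q scan at 1% relative noise with the
    reference thermodynamics, reduce, fit globally; repeat over seeds.
    Returns arrays of recovered (dH, dS/R, d) and reduced chi^2.
    """
    if master_seed is None:
        seeds = list(range(1, n_seeds + 1))
    else:
        children = np.random.SeedSequence(master_seed).spawn(n_seeds)
        seeds = [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children]
    prof = ep.PressureProfile()
    dh, ds, d, chi2 = [], [], [], []
    for seed in seeds:
        inst = ep.InstrumentConfig(noise_rel=0.01, seed=seed)
        red = ep.reduce_scan(ep.simulate_scan(20.0, inst, prof))
        rep = ep.global_fit(red)
        dh.append(rep.params.thermo.delta_h)
        ds.append(rep.params.thermo.delta_s_over_r)
        d.append(rep.params.d)
        chi2.append(rep.chi2_reduced)
    return np.array(dh), np.array(ds), np.array(d), np.array(chi2)


@pytest.fixture(scope="session")
def recovery_experiment():
    return run_recovery_experiment()
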