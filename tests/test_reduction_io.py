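"""Tests for the TSV dialect and the reduction chain."""

import numpy as np
import pytest

import einspress as ep
from einspress.reduction_io import (
    COLUMNS,
    DegenerateReferenceError,
    FormatError,
    AlignmentError,
)


def make_curve(T=100.0, P=20.0, q=None, intensity=None, sigma=None):
    q = np.linspace(0.2, 2.0, 5) if q is None else np.asarray(q, float)
    intensity = np.exp(-0.1 * q**2) if intensity is None else np.asarray(intensity, float)
    sigma = 0.01 * intensity if sigma is None else np.asarray(sigma, float)
    return ep.ScatteringCurve(q, intensity, sigma, T=T, P=P)


class TestContainers:
    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            make_curve(sigma=[-0.01, 0.01, 0.01, 0.01, 0.01])

    def test_non_increasing_q_rejected(self):
        with pytest.raises(ValueError):
            make_curve(q=[0.2, 0.5, 0.5, 1.0, 2.0])

    def test_scan_sorts_curves_by_temperature(self):
        scan = ep.ElasticScan([make_curve(T=t) for t in (300.0, 20.0, 150.0)],
                              P=20.0)
        np.testing.assert_array_equal(scan.temperatures, [20.0, 150.0, 300.0])

    def test_mixed_pressure_rejected(self):
        with pytest.raises(ValueError):
            ep.ElasticScan([make_curve(T=20.0, P=20.0),
                            make_curve(T=30.0, P=100.0)], P=20.0)


class TestIO:
    def test_write_read_roundtrip(self, tmp_path, profile, thermo):
        inst = ep.InstrumentConfig(noise_rel=0.01, seed=9)
        scan = ep.simulate_scan(20.0, inst, profile, thermo)
        path = tmp_path / "scan.tsv"
        ep.write_scan(scan, path, header_comments=["test header"])
        back = ep.read_scan(path)
        assert back.P == scan.P
        for c, c0 in zip(back.curves, scan.curves):
            np.testing.assert_allclose(c.intensity, c0.intensity, rtol=1e-9)
            np.testing.assert_allclose(c.sigma, c0.sigma, rtol=1e-9)

    def test_shuffled_temperatures_accepted_and_sorted(self, tmp_path):
        scan = ep.ElasticScan([make_curve(T=t) for t in (20.0, 150.0, 300.0)],
                              P=20.0)
        df = scan.to_frame().sample(frac=1.0, random_state=1)  # shuffle rows
        path = tmp_path / "shuffled.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = ep.read_scan(path)
        np.testing.assert_array_equal(back.temperatures, [20.0, 150.0, 300.0])
        assert np.all(np.diff(back.q) > 0)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("pressure_bar\ttemperature_K\tq_invA\tintensity\n"
                        "20\t20\t0.2\t1.0\n")
        with pytest.raises(FormatError, match="sigma"):
            ep.read_scan(path)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        rows = "\t".join(COLUMNS) + "\n20\t20\t0.2\toops\t0.01\n"
        path.write_text(rows)
        with pytest.raises(FormatError, match="intensity"):
            ep.read_scan(path)

    def test_negative_sigma_in_file_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        body = "\n".join(
            f"20\t20\t{q}\t1.0\t{s}" for q, s in
            [(0.2, 0.01), (0.4, -0.01), (0.6, 0.01)]
        )
        path.write_text("\t".join(COLUMNS) + "\n" + body + "\n")
        with pytest.raises(ValueError, match="sigma"):
            ep.read_scan(path)

    def test_inconsistent_q_grid_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        lines = ["\t".join(COLUMNS)]
        for q in (0.2, 0.4, 0.6):
            lines.append(f"20\t20\t{q}\t1.0\t0.01")
        for q in (0.2, 0.5, 0.6):  # different grid at the next temperature
            lines.append(f"20\t30\t{q}\t1.0\t0.01")
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match="q grid"):
            ep.read_scan(path)

    def test_multi_pressure_file(self, tmp_path, profile, thermo):
        inst = ep.InstrumentConfig(noise_rel=0.0)
        scans = [ep.simulate_scan(p, inst, profile, thermo)
                 for p in (20.0, 2000.0)]
        path = tmp_path / "multi.tsv"
        ep.write_scans(scans, path)
        with pytest.raises(FormatError, match="pressures"):
            ep.read_scan(path)
        back = ep.read_all_scans(path)
        assert [s.P for s in back] == [20.0, 2000.0]
        one = ep.read_scan(path, pressure=2000.0)
        assert one.P == 2000.0


class TestSubtractCell:
    def test_self_subtraction_is_zero(self):
        scan = ep.ElasticScan([make_curve(T=t) for t in (20.0, 150.0)], P=20.0)
        out = ep.subtract_cell(scan, scan, transmission=1.0)
        for c in out.curves:
            np.testing.assert_allclose(c.intensity, 0.0, atol=1e-15)

    def test_zero_cell_is_identity(self):
        scan = ep.ElasticScan([make_curve(T=20.0)], P=20.0)
        zero = ep.ElasticScan([make_curve(T=20.0, intensity=np.zeros(5),
                                          sigma=np.zeros(5))], P=20.0)
        out = ep.subtract_cell(scan, zero)
        np.testing.assert_array_equal(out.curves[0].intensity,
                                      scan.curves[0].intensity)

    def test_grid_mismatch_rejected(self):
        a = ep.ElasticScan([make_curve()], P=20.0)
        b = ep.ElasticScan([make_curve(q=np.linspace(0.3, 2.0, 5))], P=20.0)
        with pytest.raises(AlignmentError):
            ep.subtract_cell(a, b)

    def test_noisy_roundtrip_within_noise(self, profile, thermo):
        inst = ep.InstrumentConfig(noise_rel=0.01, seed=3)
        clean = ep.simulate_scan(20.0, ep.InstrumentConfig(noise_rel=0.0),
                                 profile, thermo)
        sample = ep.add_cell(ep.simulate_scan(20.0, inst, profile, thermo), inst)
        cell = ep.simulate_empty_cell(inst)
        rec = ep.subtract_cell(sample, cell)
        resid = np.concatenate([c.intensity - c0.intensity
                                for c, c0 in zip(rec.curves, clean.curves)])
        noise = np.concatenate([c.sigma for c in rec.curves])
        assert np.sqrt(np.mean(resid**2)) < 2 * np.sqrt(np.mean(noise**2))


class TestNormalize:
    def test_reference_becomes_unity(self, profile, thermo):
        inst = ep.InstrumentConfig(noise_rel=0.01, seed=4)
        scan = ep.simulate_scan(20.0, inst, profile, thermo)
        norm = ep.normalize_to_reference(scan, t_ref=20.0)
        np.testing.assert_array_equal(norm.curves[0].intensity, 1.0)
        np.testing.assert_array_equal(norm.curves[0].sigma, 0.0)

    def test_noiseless_normalization_matches_model_ratio(self, profile, thermo):
        inst = ep.InstrumentConfig(noise_rel=0.0)
        scan = ep.simulate_scan(20.0, inst, profile, thermo)
        norm = ep.normalize_to_reference(scan)
        ref = scan.curves[0]
        for c, cn in zip(scan.curves, norm.curves):
            np.testing.assert_allclose(cn.intensity,
                                       c.intensity / ref.intensity, rtol=1e-12)

    def test_idempotent(self, profile, thermo):
        inst = ep.InstrumentConfig(noise_rel=0.01, seed=6)
        once = ep.normalize_to_reference(
            ep.simulate_scan(20.0, inst, profile, thermo))
        twice = ep.normalize_to_reference(once)
        for c1, c2 in zip(once.curves, twice.curves):
            np.testing.assert_allclose(c2.intensity, c1.intensity, rtol=1e-12)
            np.testing.assert_allclose(c2.sigma, c1.sigma, rtol=1e-12)

    def test_nonpositive_reference_rejected(self):
        bad = ep.ElasticScan(
            [make_curve(T=20.0, intensity=[1.0, -0.5, 1.0, 1.0, 1.0],
                        sigma=[0.01] * 5),
             make_curve(T=150.0)], P=20.0)
        with pytest.raises(DegenerateReferenceError):
            ep.normalize_to_reference(bad)

    def test_missing_reference_rejected(self):
        scan = ep.ElasticScan([make_curve(T=t) for t in (100.0, 200.0)], P=20.0)
        with pytest.raises(ValueError, match="reference"):
            ep.normalize_to_reference(scan, t_ref=20.0)


class TestBinning:
    def test_mean_temperature_assigned(self):
        curves = [make_curve(T=100.1), make_curve(T=100.3)]
        out = ep.bin_temperatures(curves, bin_width=10.0)
        assert len(out.curves) == 1
        assert out.curves[0].T == pytest.approx(100.2)

    def test_single_curve_identity(self):
        c = make_curve(T=150.0)
        out = ep.bin_temperatures([c], bin_width=10.0)
        np.testing.assert_array_equal(out.curves[0].intensity, c.intensity)
        assert out.curves[0].T == 150.0

    def test_replicate_averaging_shrinks_sigma(self):
        rng = np.random.default_rng(0)
        q = np.linspace(0.2, 2.0, 5)
        sigma = np.full(5, 0.02)
        curves = [
            ep.ScatteringCurve(q, 1.0 + 0.02 * rng.standard_normal(5), sigma,
                               T=100.0 + 0.1 * i, P=20.0)
            for i in range(3)
        ]
        out = ep.bin_temperatures(curves, bin_width=10.0)
        np.testing.assert_allclose(out.curves[0].sigma, 0.02 / np.sqrt(3),
                                   rtol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ep.bin_temperatures([], bin_width=10.0)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            ep.bin_temperatures([make_curve()], bin_width=0.0)


class TestUncertaintyPropagation:
    """Quotient and difference rules against a Monte-Carlo oracle."""

    N_DRAWS = 10_000

    def _mc_sigma(self, f, mus, sigmas, rng):
        draws = [rng.normal(m, s, self.N_DRAWS) for m, s in zip(mus, sigmas)]
        return np.std(f(*draws), ddof=1)

    def test_difference_rule(self):
        rng = np.random.default_rng(11)
        q = np.linspace(0.2, 2.0, 3)
        a = ep.ElasticScan([ep.ScatteringCurve(q, [1.0] * 3, [0.05] * 3,
                                               T=20.0, P=20.0)], P=20.0)
        b = ep.ElasticScan([ep.ScatteringCurve(q, [0.3] * 3, [0.02] * 3,
                                               T=20.0, P=20.0)], P=20.0)
        out = ep.subtract_cell(a, b, transmission=1.0)
        mc = self._mc_sigma(lambda x, y: x - y, [1.0, 0.3], [0.05, 0.02], rng)
        np.testing.assert_allclose(out.curves[0].sigma, mc, rtol=0.10)

    def test_quotient_rule(self):
        rng = np.random.default_rng(12)
        q = np.linspace(0.2, 2.0, 3)
        ref = ep.ScatteringCurve(q, [1.0] * 3, [0.02] * 3, T=20.0, P=20.0)
        cur = ep.ScatteringCurve(q, [0.8] * 3, [0.03] * 3, T=150.0, P=20.0)
        scan = ep.ElasticScan([ref, cur], P=20.0)
        norm = ep.normalize_to_reference(scan, t_ref=20.0)
        mc = self._mc_sigma(lambda x, y: x / y, [0.8, 1.0], [0.03, 0.02], rng)
        np.testing.assert_allclose(norm.curves[1].sigma, mc, rtol=0.10)


class TestFullChain:
    def test_ramp_reduction_matches_noiseless_model(self, profile, thermo,
                                                    noiseless_reduced_scan):
        inst = ep.InstrumentConfig(noise_rel=0.01, seed=2)
        raw = ep.add_cell(
            ep.simulate_scan(20.0, inst, profile, thermo, ramp=True, n_sub=3),
            inst)
        cell = ep.simulate_empty_cell(inst)
        red = ep.reduce_scan(raw, cell=cell, bin_width=10.0)
        rms = np.sqrt(np.mean([
            np.mean((c.intensity - c0.intensity) ** 2)
            for c, c0 in zip(red.curves, noiseless_reduced_scan.curves)
        ]))
        expected = np.sqrt(np.mean([np.mean(c.sigma**2) for c in red.curves]))
        assert rms < 2 * expected
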