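"""Effective point source: fluence recovery, forward model, emission sampling."""
import numpy as np
import pytest
from scipy import stats as sps

from kvbeam import physdata
from kvbeam.source_model import (FluenceMap, InAirScan, SourceModel,
                                 build_source, fluence_from_inair,
                                 load_source, save_source)
from kvbeam.spectra import EnergySpectrum, kerma_integral


def line_spectrum(energy):
    centers = (np.arange(200) + 0.5) * 0.5
    f = np.zeros_like(centers)
    f[np.argmin(np.abs(centers - energy))] = 1.0
    return EnergySpectrum(centers, f, 100.0)


def make_scan(axis, positions, dose, aperture=5.0, ssd=15.0):
    return InAirScan(axis=axis, positions=np.asarray(positions, float),
                     relative_dose=np.asarray(dose, float),
                     applicator_diameter=aperture, ssd=ssd)


class TestFluenceFromInair:
    def test_identical_spectra_reduce_to_the_dose_scan(self):
        pos = np.linspace(-2.5, 2.5, 11)
        dose = 1.0 - 0.02 * np.abs(pos)
        scan = make_scan("inline", pos, dose)
        spec = line_spectrum(60.0)
        p, v = fluence_from_inair(scan, [(x, spec) for x in (-2.0, 0.0, 2.0)])
        assert np.allclose(v, dose / dose[5], rtol=0, atol=1e-15)

    def test_unity_at_center_by_construction(self, heel_truth):
        from kvbeam.fixtures import synthetic_inair_scan
        scan = synthetic_inair_scan(heel_truth, "inline", noise_sd=0.002,
                                    seed=9)
        _, v = fluence_from_inair(scan, list(heel_truth.source.spectra))
        assert v[np.argmin(np.abs(scan.positions))] == 1.0

    def test_two_position_toy_against_hand_integral(self):
        # D(x)/D(0)=0.9; U(0) a 60 keV line, U(x) an 80 keV line:
        # X(x) = 0.9 * [muen_air(60)*60] / [muen_air(80)*80]
        scan = make_scan("inline", [0.0, 2.0], [1.0, 0.9])
        specs = [(0.0, line_spectrum(60.25)), (2.0, line_spectrum(80.25))]
        _, v = fluence_from_inair(scan, specs)
        k60 = physdata.mass_energy_absorption("air", 60.25) * 60.25
        k80 = physdata.mass_energy_absorption("air", 80.25) * 80.25
        assert v[1] == pytest.approx(0.9 * k60 / k80, rel=1e-12)

    def test_missing_spectra_rejected(self):
        with pytest.raises(ValueError, match="spectrum"):
            fluence_from_inair(make_scan("inline", [0.0, 1.0], [1.0, 0.9]),
                               [])


class TestForwardModel:
    def test_center_dose_is_central_kerma_integral(self, uniform_source):
        expect = kerma_integral(uniform_source.spectrum_at(0.0))
        assert uniform_source.inair_dose_at(0.0, 0.0) == pytest.approx(expect)

    def test_eq_roundtrip_is_identity_on_x(self, heel_truth):
        # scan the forward model, invert it: X must come back to 1e-6
        src = heel_truth.source
        pos = np.arange(-7.0, 7.5, 0.5)
        dose = np.array([src.inair_dose_at(x, 0.0) for x in pos])
        scan = make_scan("inline", pos, dose,
                         aperture=src.applicator_diameter, ssd=src.ssd)
        p, v = fluence_from_inair(scan, list(src.spectra))
        truth = np.array([src.fluence.x(x) for x in p])
        assert np.max(np.abs(v - truth / truth[np.argmin(np.abs(p))])) < 1e-6

    def test_separability_identity(self, heel_truth):
        src = heel_truth.source
        x, y = 3.0, 2.0
        lhs = src.inair_dose_at(x, y) * src.inair_dose_at(0.0, 0.0)
        rhs = src.inair_dose_at(x, 0.0) * src.inair_dose_at(0.0, y)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_heel_asymmetry_sign_matches_truth(self, heel_truth):
        # anode side (+x) carries less fluence
        src = heel_truth.source
        assert src.inair_dose_at(5.0, 0.0) < src.inair_dose_at(-5.0, 0.0)

    def test_point_outside_aperture_tail_rejected(self, uniform_source):
        with pytest.raises(ValueError, match="outside"):
            uniform_source.inair_dose_at(4.0, 0.0)


class TestSampling:
    def test_uniform_source_fills_disk_uniformly(self, uniform_source, rng):
        n = 100_000
        d, _, w = uniform_source.sample_emission(rng, n)
        assert np.all(w == 1.0)
        # plane positions from directions
        x = d[:, 0] / d[:, 2] * uniform_source.ssd
        y = d[:, 1] / d[:, 2] * uniform_source.ssd
        R = uniform_source.aperture_radius
        assert np.all(x**2 + y**2 <= R**2 * (1 + 1e-9))
        # chi^2 of the x-marginal against the chord-length density
        edges = np.linspace(-R, R, 21)
        obs, _ = np.histogram(x, edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        exp = 2 * np.sqrt(np.maximum(R**2 - centers**2, 0))
        exp = exp / exp.sum() * n
        p = sps.chisquare(obs, exp, sum_check=False).pvalue
        assert p > 0.01

    def test_marginal_follows_fluence_times_chord(self, heel_truth, rng):
        src = heel_truth.source
        n = 100_000
        d, _, _ = src.sample_emission(rng, n)
        x = d[:, 0] / d[:, 2] * src.ssd
        R = src.aperture_radius
        edges = np.linspace(-R, R, 17)
        obs, _ = np.histogram(x, edges)
        # numeric integration of X(x) * integral of Y over the chord
        fine = np.linspace(-R, R, 2001)
        chord_y = np.array([
            np.trapezoid(src.fluence.y(np.linspace(-c, c, 101)),
                         np.linspace(-c, c, 101)) if (c := np.sqrt(
                             max(R**2 - xi**2, 0.0))) > 0 else 0.0
            for xi in fine])
        dens = src.fluence.x(fine) * chord_y
        exp = np.array([
            np.trapezoid(dens[(fine >= lo) & (fine <= hi)],
                         fine[(fine >= lo) & (fine <= hi)])
            for lo, hi in zip(edges[:-1], edges[1:])])
        exp = exp / exp.sum() * n
        p = sps.chisquare(obs, exp, sum_check=False).pvalue
        assert p > 0.01

    def test_energies_bounded_by_kvp(self, heel_truth, rng):
        _, e, _ = heel_truth.source.sample_emission(rng, 20_000)
        assert np.all(e <= heel_truth.kvp)
        assert np.all(e > 0)

    def test_delta_fluence_pins_all_rays(self, spec120, rng):
        fm = FluenceMap([-0.1, 0.0, 0.1], [0, 1, 0],
                        [-0.1, 0.0, 0.1], [0, 1, 0])
        src = SourceModel(ssd=15.0, applicator_diameter=5.0, fluence=fm,
                          spectra=((0.0, spec120),))
        d, _, _ = src.sample_emission(rng, 2000)
        x = d[:, 0] / d[:, 2] * 15.0
        y = d[:, 1] / d[:, 2] * 15.0
        assert np.all(np.abs(x) <= 0.1 + 1e-9)
        assert np.all(np.abs(y) <= 0.1 + 1e-9)

    def test_small_cone_geometry(self, spec120, rng):
        # 2 cm applicator at SSD 15: every ray inside the 1 cm radius disk
        fm = FluenceMap([-1, 0, 1], [1, 1, 1], [-1, 0, 1], [1, 1, 1])
        src = SourceModel(ssd=15.0, applicator_diameter=2.0, fluence=fm,
                          spectra=((0.0, spec120),))
        d, _, _ = src.sample_emission(rng, 10_000)
        r = np.hypot(d[:, 0], d[:, 1]) / d[:, 2] * 15.0
        assert np.all(r <= 1.0 + 1e-9)


class TestBuildAndSerialize:
    def test_scan_narrower_than_aperture_rejected(self, spec120):
        inline = make_scan("inline", np.arange(-1.0, 1.1, 0.5),
                           np.ones(5), aperture=5.0)
        cross = make_scan("crossline", np.arange(-3.0, 3.1, 0.5),
                          np.ones(13), aperture=5.0)
        with pytest.raises(ValueError, match="narrower"):
            build_source(120, 15.0, 5.0, inline, cross, [(0.0, spec120)])

    def test_save_load_round_trip(self, heel_truth, tmp_path):
        src = heel_truth.source
        save_source(src, tmp_path / "src.json")
        back = load_source(tmp_path / "src.json")
        assert back.ssd == src.ssd
        assert back.applicator_diameter == src.applicator_diameter
        g = np.linspace(-7, 7, 29)
        assert np.allclose([back.inair_dose_at(x, 0.0) for x in g],
                           [src.inair_dose_at(x, 0.0) for x in g],
                           rtol=1e-12)
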