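"""Monte Carlo transport: analytic oracles, distributions, bookkeeping."""
import numpy as np
import pytest
from scipy import stats as sps

from kvbeam import physdata, transport
from kvbeam.phantom import VoxelPhantom, build_water_phantom
from kvbeam.source_model import FluenceMap, SourceModel
from kvbeam.spectra import EnergySpectrum

M_E = 510.99895


def mono_spectrum(energy):
    centers = (np.arange(int(np.ceil((energy + 1) / 0.5))) + 0.5) * 0.5
    f = np.zeros_like(centers)
    f[np.argmin(np.abs(centers - energy))] = 1.0
    return EnergySpectrum(centers, f, energy + 1.0)


def pencil_source(energy, ssd=15.0):
    fm = FluenceMap([-0.05, 0, 0.05], [1, 1, 1], [-0.05, 0, 0.05], [1, 1, 1])
    return SourceModel(ssd=ssd, applicator_diameter=0.1, fluence=fm,
                       spectra=((0.0, mono_spectrum(energy)),))


class TestAnalyticOracles:
    def test_primary_slab_transmission_matches_beer_lambert(self):
        # pencil beam, interactions disabled beyond the first: the energy
        # escaping a t-thick water slab is exp(-mu t) of what was launched
        t_cm = 3.0
        src = pencil_source(60.25)
        ph = build_water_phantom(dims=(25, 25, 10),
                                 voxel_size=(0.4, 0.4, t_cm / 10), ssd=15.0)
        n = 100_000
        res = transport.compute_dose(src, ph, [], n, seed=11,
                                     primary_only=True)
        trans = res.escaped_energy / res.launched_energy
        expect = np.exp(-physdata.mass_attenuation("water", 60.25) * t_cm)
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(trans - expect) < 3 * se

    def test_inverse_square_in_near_transparent_medium(self):
        # kerma from a diverging cone in a medium with negligible attenuation
        # falls as 1/z^2 between two small on-axis tallies
        fm = FluenceMap([-2, 0, 2], [1, 1, 1], [-2, 0, 2], [1, 1, 1])
        src = SourceModel(ssd=10.0, applicator_diameter=4.0, fluence=fm,
                          spectra=((0.0, mono_spectrum(60.25)),))
        ph = build_water_phantom(dims=(31, 31, 60),
                                 voxel_size=(0.4, 0.4, 0.4), ssd=10.0)
        ph.density[:] = 1e-4  # nearly transparent, track-length scoring
        z1, z2 = 12.0, 30.0
        tallies = [transport.Tally((0, 0, z1), size=(1.0, 1.0, 0.4)),
                   transport.Tally((0, 0, z2), size=(1.0, 1.0, 0.4))]
        res = transport.compute_dose(src, ph, tallies, 200_000, seed=12,
                                     score="tracklength")
        ratio = res.dose[1] / res.dose[0]
        expect = (z1 / z2) ** 2
        se = ratio * np.sqrt(np.sum(res.relative_stderr() ** 2))
        assert abs(ratio - expect) < 3 * se + 1e-4

    def test_two_slab_crossing_probability(self):
        # water on top of aluminum: P(cross both) = exp(-mu1 t1 - mu2 t2)
        mat = np.zeros((15, 15, 10), dtype=np.uint8)
        mat[:, :, 5:] = 1
        rho = np.where(mat == 0, 1.0, 2.699).astype(np.float32)
        ph = VoxelPhantom(mat, rho, (0.4, 0.4, 0.3), (-2.8, -2.8, 15.15),
                          ("water", "aluminum"))
        src = pencil_source(60.25)
        n = 100_000
        res = transport.compute_dose(src, ph, [], n, seed=13,
                                     primary_only=True)
        trans = res.escaped_energy / res.launched_energy
        mu_w = physdata.mass_attenuation("water", 60.25) * 1.0
        mu_al = physdata.mass_attenuation("aluminum", 60.25) * 2.699
        expect = np.exp(-mu_w * 1.5 - mu_al * 1.5)
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(trans - expect) < 3 * se


class TestFreePaths:
    def test_exponential_distribution_in_homogeneous_water(self, water_phantom):
        st = transport.pcg_state(99)
        mu = physdata.mass_attenuation("water", 60.25)
        n = 30_000
        paths = []
        for _ in range(n):
            site, path = transport.sample_free_path(
                (0.0, 0.0, 15.0), (0.0, 0.0, 1.0), 60.25, water_phantom, st)
            if site is not None:  # exits are right-censored; drop them
                paths.append(path)
        # censor both sample and reference at the phantom depth
        depth = water_phantom.extent[2]
        ks = sps.kstest(np.array(paths),
                        lambda x: (1 - np.exp(-mu * x)) /
                                  (1 - np.exp(-mu * depth)))
        assert ks.pvalue > 0.01

    def test_chord_lengths_sum_to_geometric_chord(self, water_phantom):
        direction = np.array([0.3, 0.2, 0.93])
        direction /= np.linalg.norm(direction)
        lengths, _ = transport.voxel_chord_lengths((0.0, 0.0, 0.0),
                                                   direction, water_phantom)
        # geometric chord from entry to exit of the box along this ray
        (x0, x1), (y0, y1), (z0, z1) = water_phantom.bounds()
        t_in = z0 / direction[2]
        t_out = min((x1 - 0) / direction[0], (y1 - 0) / direction[1],
                    z1 / direction[2])
        assert lengths.sum() == pytest.approx(t_out - t_in, abs=1e-6)


class TestInteractionSampling:
    def test_incoherent_energy_within_compton_kinematic_bounds(self):
        st = transport.pcg_state(5)
        for energy in (20.0, 60.0, 100.0, 150.0):
            k = energy / M_E
            lo = energy / (1 + 2 * k)
            for _ in range(300):
                kind, e_out, cos_t = transport.sample_interaction(
                    energy, "water", st)
                if kind == "incoherent":
                    assert lo - 1e-9 <= e_out <= energy + 1e-9
                    assert -1.0 <= cos_t <= 1.0

    def test_coherent_preserves_energy_exactly(self):
        st = transport.pcg_state(6)
        seen = 0
        while seen < 50:
            kind, e_out, _ = transport.sample_interaction(30.0, "water", st)
            if kind == "coherent":
                assert e_out == 30.0
                seen += 1

    def test_klein_nishina_angular_distribution(self):
        # chi^2 of sampled cos(theta) at 100 keV against the numerically
        # integrated Klein-Nishina pdf
        st = transport.pcg_state(7)
        n = 100_000
        cs = []
        while len(cs) < n:
            kind, _, cos_t = transport.sample_interaction(100.0, "water", st)
            if kind == "incoherent":
                cs.append(cos_t)
        cs = np.array(cs[:n])
        k = 100.0 / M_E
        mu = np.linspace(-1, 1, 4001)
        r = 1.0 / (1.0 + k * (1.0 - mu))
        pdf = 0.5 * r**2 * (r + 1.0 / r - (1.0 - mu**2))
        edges = np.linspace(-1, 1, 21)
        cdf = np.concatenate([[0], np.cumsum(
            0.5 * (pdf[1:] + pdf[:-1]) * np.diff(mu))])
        cdf /= cdf[-1]
        exp = np.diff(np.interp(edges, mu, cdf)) * n
        obs, _ = np.histogram(cs, edges)
        p = sps.chisquare(obs, exp, sum_check=False).pvalue
        assert p > 0.01

    def test_event_fractions_follow_partial_cross_sections(self):
        st = transport.pcg_state(8)
        n = 20_000
        kinds = [transport.sample_interaction(30.0, "water", st)[0]
                 for _ in range(n)]
        pe, coh, inc = physdata.partial_coefficients("water", 30.0)
        tot = pe + coh + inc
        frac_pe = kinds.count("photoelectric") / n
        assert frac_pe == pytest.approx(pe / tot, abs=3 * np.sqrt(0.25 / n) + 0.01)


class TestBookkeeping:
    def test_energy_conservation_exact_per_history(self, uniform_source,
                                                   water_phantom):
        res = transport.compute_dose(uniform_source, water_phantom,
                                     [transport.Tally((0, 0, 16.0))],
                                     5000, seed=21, keep_history=True)
        resid = (res.launched_per_history - res.deposited_per_history
                 - res.escaped_per_history)
        assert np.max(np.abs(resid)) < 1e-9 * np.max(res.launched_per_history)

    def test_bit_identical_for_identical_seed(self, uniform_source,
                                              water_phantom):
        tallies = [transport.Tally((0, 0, 16.0))]
        a = transport.compute_dose(uniform_source, water_phantom, tallies,
                                   5000, seed=22)
        b = transport.compute_dose(uniform_source, water_phantom, tallies,
                                   5000, seed=22)
        assert np.array_equal(a.dose, b.dose)
        assert np.array_equal(a.stderr, b.stderr)
        assert a.launched_energy == b.launched_energy

    def test_stderr_shrinks_as_root_two_when_doubling_histories(
            self, uniform_source, water_phantom):
        t = [transport.Tally((0, 0, 16.0), size=(2.0, 2.0, 0.3))]
        a = transport.compute_dose(uniform_source, water_phantom, t,
                                   60_000, seed=23, score="tracklength")
        b = transport.compute_dose(uniform_source, water_phantom, t,
                                   120_000, seed=24, score="tracklength")
        ratio = a.stderr[0] / b.stderr[0]
        assert ratio == pytest.approx(np.sqrt(2), rel=0.20)


class TestValidation:
    def test_source_aimed_outside_phantom(self, uniform_source):
        ph = build_water_phantom(dims=(10, 10, 10),
                                 voxel_size=(0.4, 0.4, 0.3), ssd=15.0)
        ph.origin = (50.0, 50.0, 15.15)  # box far off axis
        with pytest.raises(ValueError, match="outside phantom"):
            transport.compute_dose(uniform_source, ph,
                                   [transport.Tally((50.0, 50.0, 16.0))],
                                   1000, seed=1)

    def test_tally_outside_phantom(self, uniform_source, water_phantom):
        with pytest.raises(ValueError, match="outside"):
            transport.compute_dose(uniform_source, water_phantom,
                                   [transport.Tally((0, 0, 100.0))],
                                   1000, seed=1)

    def test_minimum_history_count(self, uniform_source, water_phantom):
        with pytest.raises(ValueError, match="histories"):
            transport.compute_dose(uniform_source, water_phantom, [],
                                   10, seed=1)
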