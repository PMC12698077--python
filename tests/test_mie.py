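"""Mie scattering matrices, phase tables and density scaling."""

import numpy as np
import pytest
from numpy.testing import assert_allclose
from scipy.special import spherical_jn, spherical_yn

from muellermc import mie


def mie_ab_oracle(x, m):
    """Independent Mie coefficients built directly from Riccati-Bessel
    functions (scipy spherical Bessel), no logarithmic-derivative
    recurrence."""
    nmax = int(np.round(x + 4 * x ** (1 / 3) + 2))
    n = np.arange(1, nmax + 1)
    jx = spherical_jn(n, x)
    jxp = spherical_jn(n, x, derivative=True)
    yx = spherical_yn(n, x)
    yxp = spherical_yn(n, x, derivative=True)
    jmx = spherical_jn(n, m * x)
    jmxp = spherical_jn(n, m * x, derivative=True)
    psix = x * jx
    psixp = jx + x * jxp
    psimx = m * x * jmx
    psimxp = jmx + m * x * jmxp
    xix = x * (jx + 1j * yx)
    xixp = (jx + x * jxp) + 1j * (yx + x * yxp)
    a = (m * psimx * psixp - psix * psimxp) / (m * psimx * xixp - xix * psimxp)
    b = (psimx * psixp - m * psix * psimxp) / (psimx * xixp - m * xix * psimxp)
    return a, b


class TestMieSeries:
    def test_rayleigh_polarization_at_90(self):
        th = np.array([np.pi / 2])
        s11, s12, _, _ = mie.mie_scattering_matrix(0.01, 1.2, th)
        assert -s12[0] / s11[0] == pytest.approx(1.0, abs=1e-3)

    def test_rayleigh_phase_function(self):
        th = np.radians([0.0, 60.0, 90.0, 120.0])
        s11, _, _, _ = mie.mie_scattering_matrix(0.01, 1.2, th)
        expected = (1 + np.cos(th) ** 2) / 2
        assert_allclose(s11 / s11[0], expected, atol=1e-3)

    def test_against_independent_series_oracle(self):
        # 50 nm sphere, n_p = 1.59 in n = 1.33 at 633 nm
        x = np.pi * 50 * 1.33 / 633
        m = 1.59 / 1.33
        a, b = mie.mie_ab(x, m)
        a0, b0 = mie_ab_oracle(x, m)
        assert np.abs(a - a0).max() / np.abs(a0).max() < 1e-8
        assert np.abs(b - b0).max() / np.abs(b0).max() < 1e-8
        th = np.linspace(0, np.pi, 181)
        for got, want in zip(
            mie.mie_scattering_matrix(x, m, th),
            _matrix_from_ab(a0, b0, th),
        ):
            scale = np.abs(want).max()
            assert np.abs(got - want).max() / scale < 1e-8

    def test_energy_conservation_nonabsorbing(self):
        x = np.pi * 50 * 1.33 / 633
        csca, cext = mie.mie_cross_sections(x, 1.59 / 1.33, 633, 1.33)
        assert csca == pytest.approx(cext, rel=1e-10)

    def test_invalid_size_parameter(self):
        with pytest.raises(ValueError):
            mie.mie_ab(-1.0, 1.2)


def _matrix_from_ab(a, b, theta):
    nmax = a.size
    mu = np.cos(theta)
    s1 = np.zeros_like(mu, dtype=complex)
    s2 = np.zeros_like(mu, dtype=complex)
    pi_nm1 = np.zeros_like(mu)
    pi_n = np.ones_like(mu)
    for n in range(1, nmax + 1):
        tau = n * mu * pi_n - (n + 1) * pi_nm1
        f = (2 * n + 1) / (n * (n + 1))
        s1 += f * (a[n - 1] * pi_n + b[n - 1] * tau)
        s2 += f * (a[n - 1] * tau + b[n - 1] * pi_n)
        pi_nm1, pi_n = pi_n, ((2 * n + 1) * mu * pi_n - (n + 1) * pi_nm1) / n
    cross = s2 * np.conj(s1)
    return (
        0.5 * (np.abs(s2) ** 2 + np.abs(s1) ** 2),
        0.5 * (np.abs(s2) ** 2 - np.abs(s1) ** 2),
        np.real(cross),
        np.imag(cross),
    )


class TestPhaseTable:
    def test_grid_and_cdf(self, phase_table):
        assert phase_table.angles_deg.size == 9001
        assert phase_table.angles_deg[1] - phase_table.angles_deg[0] == pytest.approx(0.02)
        assert phase_table.cdf[0] == 0.0
        assert phase_table.cdf[-1] == pytest.approx(1.0)
        assert np.all(np.diff(phase_table.cdf) >= 0)
        assert np.all(phase_table.s11 > 0)
        assert np.all(np.abs(phase_table.s12) <= phase_table.s11 + 1e-30)

    def test_s34_vanishes_at_end_points(self, phase_table):
        assert phase_table.s34[0] == pytest.approx(0.0, abs=1e-12 * phase_table.s11[0])
        assert phase_table.s34[-1] == pytest.approx(0.0, abs=1e-12 * phase_table.s11[0])

    def test_rayleigh_regime_anisotropy(self, phase_table):
        assert abs(phase_table.anisotropy) < 0.2

    def test_monodisperse_table_matches_single_sphere(self):
        g = [mie.ScattererGroup(50.0, 1.59, number_density=1e12)]
        t = mie.build_phase_table(g, 633.0, 1.33)
        x = np.pi * 50 * 1.33 / 633
        k = 2 * np.pi * 1.33 / (633e-7)
        th = np.radians(t.angles_deg[::1000])
        s11, s12, s33, s34 = mie.mie_scattering_matrix(x, 1.59 / 1.33, th, wavenumber=k)
        assert_allclose(t.s11[::1000], s11, rtol=1e-12)
        assert_allclose(t.s12[::1000], s12, rtol=1e-12)

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            mie.build_phase_table([], 633.0, 1.33)


class TestDensityScaling:
    def test_target_mus_reached(self):
        groups = mie.density_for_target_mus(mie.gaussian_size_groups(), 633, 1.33, 400.0)
        total = 0.0
        for g in groups:
            x = np.pi * g.diameter_nm * 1.33 / 633
            csca, _ = mie.mie_cross_sections(x, g.n_particle / 1.33, 633, 1.33)
            total += g.number_density * csca
        assert total == pytest.approx(400.0, rel=1e-9)

    def test_mean_free_path_25_um(self):
        # mu_s = 400 cm^-1 <-> l_s = 25 um
        assert 1.0 / 400.0 == pytest.approx(25e-4)

    def test_linearity(self):
        g1 = mie.density_for_target_mus(mie.gaussian_size_groups(), 633, 1.33, 400.0)
        g2 = mie.density_for_target_mus(mie.gaussian_size_groups(), 633, 1.33, 800.0)
        for a, b in zip(g1, g2):
            assert b.number_density == pytest.approx(2 * a.number_density, rel=1e-12)

    def test_tumor_setting(self):
        groups = mie.density_for_target_mus(mie.gaussian_size_groups(), 633, 1.33, 120.0)
        total = sum(
            g.number_density
            * mie.mie_cross_sections(np.pi * g.diameter_nm * 1.33 / 633, g.n_particle / 1.33, 633, 1.33)[0]
            for g in groups
        )
        assert total == pytest.approx(120.0, rel=1e-9)

    def test_group_discretization(self):
        groups = mie.gaussian_size_groups()
        assert len(groups) == 5
        d = [g.diameter_nm for g in groups]
        assert d == sorted(d)
        assert np.mean(d) == pytest.approx(50.0, rel=1e-6)
        assert sum(g.weight for g in groups) == pytest.approx(1.0)


class TestAngleSampling:
    def test_end_points(self, phase_table):
        assert mie.sample_scattering_angle(phase_table, 0.0) == 0.0
        assert mie.sample_scattering_angle(phase_table, 1.0 - 1e-12) == pytest.approx(np.pi, abs=1e-3)

    def test_histogram_matches_density(self, phase_table, rng):
        # chi-square goodness of fit of 1e6 samples against s11 sin(theta)
        from scipy.stats import chisquare

        u = rng.random(1_000_000)
        th = np.interp(u, phase_table.cdf, np.radians(phase_table.angles_deg))
        edges = np.linspace(0, np.pi, 41)
        obs, _ = np.histogram(th, bins=edges)
        grid = np.radians(phase_table.angles_deg)
        pdf = phase_table.s11 * np.sin(grid)
        cdf = np.concatenate(([0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))))
        cdf /= cdf[-1]
        expect = np.diff(np.interp(edges, grid, cdf)) * len(th)
        _, p = chisquare(obs, expect * obs.sum() / expect.sum())
        assert p > 0.01
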