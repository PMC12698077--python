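"""Detector binning, Mueller estimation, maps and ROI statistics."""

import numpy as np
import pytest
from numpy.testing import assert_allclose

from muellermc import imaging
from muellermc.imaging import (
    D_ANALYTIC,
    PolarimetricMaps,
    active_mask,
    circular_mean_azimuth,
    convergence_check,
    estimate_mueller,
    estimate_mueller_field,
    make_maps,
    normalize_m11,
    pixel_centers,
    roi_masks,
)
from muellermc.phantoms import build_tumor_phantom
from muellermc.polarization import rotated_retarder
from muellermc.transport import NPIX, TransportConfig, TransportResult, launch_stokes


def _oracle_active_count():
    # independent geometric oracle: brute-force corner test per pixel
    n = 0
    for j in range(NPIX):
        for i in range(NPIX):
            x0 = -0.5 + 0.01 * i
            y0 = -0.5 + 0.01 * j
            corners = [(x0, y0), (x0 + 0.01, y0), (x0, y0 + 0.01), (x0 + 0.01, y0 + 0.01)]
            if all(x * x + y * y <= 0.25 + 1e-12 for x, y in corners):
                n += 1
    return n


class TestGeometry:
    def test_active_mask_matches_oracle(self):
        assert int(active_mask().sum()) == _oracle_active_count()

    def test_center_pixel_coordinates(self):
        c = pixel_centers()
        assert c[50] == pytest.approx(0.005)  # first pixel right of center
        assert c[49] == pytest.approx(-0.005)
        assert len(c) == 100


def _records(m_true, n, rng):
    s_in = np.stack(
        [launch_stokes(t, p) for t, p in zip(rng.uniform(0, np.pi, n), rng.uniform(0, 2 * np.pi, n))]
    )
    s_out = s_in @ m_true.T
    g = s_out.T @ s_in
    d = s_in.T @ s_in
    return g, d


class TestEstimator:
    def test_exact_recovery(self, rng):
        m_true = np.diag([1.0, 0.8, 0.7, 0.65]) @ rotated_retarder(0.5, 0.3)
        g, d = _records(m_true, 50, rng)
        m = estimate_mueller(g, d, 50, min_count=10)
        assert np.abs(m - m_true).max() < 1e-10

    def test_exact_recovery_minimal_rank(self, rng):
        m_true = rotated_retarder(1.1, 0.9)
        g, d = _records(m_true, 6, rng)
        m = estimate_mueller(g, d, 6, min_count=4)
        assert np.abs(m - m_true).max() < 1e-9

    def test_below_min_count(self, rng):
        g, d = _records(np.eye(4), 5, rng)
        assert estimate_mueller(g, d, 5, min_count=100) is None

    def test_degenerate_inputs_fall_back_to_analytic_d(self):
        # all S_in identical: rank-1 D-hat triggers the analytic fallback
        s = launch_stokes(0.3, 1.0)
        n = 200
        g = np.outer(s, s) * n  # S_out = S_in (identity medium)
        d = np.outer(s, s) * n
        m = estimate_mueller(g, d, n, min_count=10)
        expected = np.outer(s, s) @ np.linalg.inv(D_ANALYTIC)
        assert_allclose(m, expected, atol=1e-9)

    def test_empirical_d_matches_analytic(self, rng):
        # second moments of 1e5 Poincare-uniform states
        n = 100_000
        _, d = _records(np.eye(4), n, rng)
        assert np.abs(d / n - D_ANALYTIC).max() < 3 * 3.0 / np.sqrt(n)


class TestNormalization:
    def test_scale_removed(self):
        assert_allclose(normalize_m11(2.0 * np.eye(4)), np.eye(4))

    def test_idempotent(self, rng):
        m = rng.normal(size=(4, 4))
        m[0, 0] = abs(m[0, 0]) + 1.0
        once = normalize_m11(m)
        assert_allclose(normalize_m11(once), once)

    def test_nonpositive_rejected(self):
        m = np.eye(4)
        m[0, 0] = 0.0
        with pytest.raises(ValueError):
            normalize_m11(m)


def _fake_result(g_batches, d_batches, c_batches):
    cfg = TransportConfig(photons=1, batches=len(g_batches), seed=0)
    return TransportResult(
        np.stack(g_batches),
        np.stack(d_batches),
        np.stack(c_batches),
        np.zeros((len(g_batches), 6), dtype=np.int64),
        cfg,
        build_tumor_phantom(1.0),
    )


def _full_grid_records(m_true, per_pixel, rng):
    g = np.zeros((NPIX, NPIX, 4, 4))
    d = np.zeros((NPIX, NPIX, 4, 4))
    c = np.full((NPIX, NPIX), per_pixel, dtype=np.int64)
    gg, dd = _records(m_true, per_pixel, rng)
    g[:, :] = gg
    d[:, :] = dd
    return g, d, c


class TestConvergence:
    def test_identical_batches_converged(self, rng):
        g, d, c = _full_grid_records(np.eye(4), 30, rng)
        res = _fake_result([g, g, g], [d, d, d], [c, c, c])
        ok, max_se = convergence_check(res)
        assert ok
        assert max_se == pytest.approx(0.0, abs=1e-12)

    def test_discrepant_batches_not_converged(self, rng):
        g1, d1, c1 = _full_grid_records(np.eye(4), 30, rng)
        m2 = np.eye(4)
        m2[1, 1] = 0.8  # differs by 0.2 in one normalized element
        g2, d2, c2 = _full_grid_records(m2, 30, rng)
        ok, max_se = convergence_check(res := _fake_result([g1, g2], [d1, d2], [c1, c2]))
        assert not ok
        assert max_se > 0.015


class TestMapsAndRois:
    def test_maps_recover_known_matrix(self, rng):
        m_true = np.diag([1.0, 0.8, 0.8, 0.7]) @ rotated_retarder(np.radians(40), np.radians(30))
        g, d, c = _full_grid_records(m_true, 40, rng)
        maps = make_maps(g, d, c, min_count=10)
        sel = maps.valid
        assert sel.sum() == maps.active.sum()
        assert np.nanmax(np.abs(maps.depolarization[sel] - (1 - (0.8 + 0.8 + 0.7) / 3))) < 1e-8
        assert np.nanmax(np.abs(maps.retardance[sel] - 40.0)) < 1e-6
        assert np.nanmax(np.abs(maps.azimuth[sel] - 30.0)) < 1e-6

    def test_unphysical_pixels_masked(self, rng):
        g, d, c = _full_grid_records(np.eye(4), 40, rng)
        bad = np.diag([1.0, 1.5, 1.5, 1.5])  # gain > 1: fails Cloude
        gg, dd = _records(bad, 40, rng)
        g[50, 50] = gg
        d[50, 50] = dd
        maps = make_maps(g, d, c, min_count=10)
        assert not maps.valid[50, 50]
        assert np.isnan(maps.depolarization[50, 50])

    def test_roi_masks_geometry(self):
        ph = build_tumor_phantom(1.0)
        incl, host = roi_masks(ph)
        c = pixel_centers()
        xx, yy = np.meshgrid(c, c)
        assert np.all(np.abs(xx[incl]) <= 0.6 * ph.inclusion_half_cm)
        assert np.all(np.maximum(np.abs(xx[host]), np.abs(yy[host])) >= ph.inclusion_half_cm + 0.1 - 1e-12)
        assert not (incl & host).any()

    def test_roi_mean_of_constant_map(self, rng):
        m_true = np.diag([1.0, 0.5, 0.5, 0.5])
        g, d, c = _full_grid_records(m_true, 40, rng)
        maps = make_maps(g, d, c, min_count=10)
        ph = build_tumor_phantom(1.0)
        incl, host = roi_masks(ph)
        stats = imaging.roi_statistics(maps, incl)
        assert stats["depolarization"] == pytest.approx(0.5, abs=1e-9)
        contrast = imaging.roi_contrast(maps, incl, host)
        assert contrast["contrast_pp"] == pytest.approx(0.0, abs=1e-7)


class TestCircularMean:
    def test_wraparound(self):
        assert circular_mean_azimuth(np.array([179.0, 1.0])) == pytest.approx(0.0, abs=1e-9)

    def test_plain_mean(self):
        assert circular_mean_azimuth(np.array([40.0, 60.0])) == pytest.approx(50.0)

    def test_empty(self):
        assert np.isnan(circular_mean_azimuth(np.array([])))
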