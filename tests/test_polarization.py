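"""Stokes/Mueller algebra and Lu-Chipman decomposition."""

import numpy as np
import pytest
from numpy.testing import assert_allclose

from muellermc.polarization import (
    cloude_filter,
    linear_retardance,
    lu_chipman,
    optic_axis_azimuth,
    retarder_mueller,
    rotated_retarder,
    stokes_rotation,
    total_depolarization,
)


class TestRetarderAndRotation:
    def test_zero_retardation_is_identity(self):
        assert_allclose(retarder_mueller(0.0), np.eye(4), atol=1e-15)

    def test_half_wave(self):
        assert_allclose(retarder_mueller(np.pi), np.diag([1, 1, -1, -1]), atol=1e-12)

    def test_sixty_degree_block(self):
        m = retarder_mueller(np.pi / 3)
        c, s = np.cos(np.pi / 3), np.sin(np.pi / 3)
        assert_allclose(m[2:, 2:], [[c, s], [-s, c]], atol=1e-15)
        assert_allclose(np.linalg.det(m), 1.0, atol=1e-12)

    def test_rotation_inverse(self):
        r = stokes_rotation(0.3) @ stokes_rotation(-0.3)
        assert_allclose(r, np.eye(4), atol=1e-12)

    def test_rotation_quarter_turn(self):
        assert_allclose(stokes_rotation(np.pi / 2), np.diag([1, -1, -1, 1]), atol=1e-12)

    def test_rotated_retarder_beta_zero(self):
        assert_allclose(rotated_retarder(0.7, 0.0), retarder_mueller(0.7), atol=1e-15)

    @pytest.mark.parametrize("delta,beta", [(0.4, 0.1), (2.0, 1.0), (np.pi / 2, np.pi / 8)])
    def test_rotated_retarder_trace(self, delta, beta):
        # similarity transform preserves the trace 2 + 2 cos(delta)
        m = rotated_retarder(delta, beta)
        assert_allclose(np.trace(m), 2 + 2 * np.cos(delta), atol=1e-12)

    def test_rotated_retarder_element_ratio(self):
        # quarter-wave at 22.5 degrees: |m[1,3] / m[3,2]| = tan(pi/4) = 1
        m = rotated_retarder(np.pi / 2, np.pi / 8)
        assert_allclose(abs(m[1, 3] / m[3, 2]), 1.0, atol=1e-12)


class TestScalarObservables:
    def test_depolarization_limits(self):
        assert total_depolarization(np.eye(4)) == pytest.approx(0.0)
        assert total_depolarization(np.diag([1.0, 0, 0, 0])) == pytest.approx(1.0)
        assert total_depolarization(np.diag([1.0, 0.5, 0.5, 0.5])) == pytest.approx(0.5)

    def test_retardance_reads_delta(self):
        assert linear_retardance(retarder_mueller(np.radians(30))) == pytest.approx(30.0)
        assert linear_retardance(np.eye(4)) == pytest.approx(0.0)

    @pytest.mark.parametrize("beta_deg", [0.0, 17.0, 45.0, 90.0, 135.0])
    def test_retardance_invariant_under_axis_rotation(self, beta_deg):
        m = rotated_retarder(np.radians(30), np.radians(beta_deg))
        assert linear_retardance(m) == pytest.approx(30.0, abs=1e-9)

    @pytest.mark.parametrize("beta_deg", [0.0, 22.5, 60.0, 90.0, 170.0])
    def test_azimuth_round_trip(self, beta_deg):
        m = rotated_retarder(np.radians(90), np.radians(beta_deg))
        assert optic_axis_azimuth(m) == pytest.approx(beta_deg, abs=1e-9)

    def test_azimuth_invariant_under_retardance_sign(self):
        # delta -> -delta flips both defining elements; the axis the
        # extractor reports moves to the orthogonal branch, i.e. the same
        # physical axis pair
        m_pos = rotated_retarder(np.radians(40), np.radians(30))
        m_neg = rotated_retarder(np.radians(-40), np.radians(30))
        a, b = optic_axis_azimuth(m_pos), optic_axis_azimuth(m_neg)
        assert min(abs(a - b), 180 - abs(a - b)) == pytest.approx(90.0, abs=1e-9)
        # and the ratio of the printed elements is identical
        assert m_pos[1, 3] / m_pos[3, 1] == pytest.approx(m_neg[1, 3] / m_neg[3, 1])

    def test_azimuth_undefined_without_retardance(self):
        assert np.isnan(optic_axis_azimuth(np.eye(4)))


class TestCloude:
    def test_identity_is_pure(self):
        ok, ev = cloude_filter(np.eye(4))
        assert ok
        assert_allclose(ev, [1, 0, 0, 0], atol=1e-12)

    def test_ideal_depolarizer(self):
        ok, ev = cloude_filter(np.diag([1.0, 0, 0, 0]))
        assert ok
        assert_allclose(ev, [0.25] * 4, atol=1e-12)

    def test_overpolarizing_matrix_rejected(self):
        ok, ev = cloude_filter(np.diag([1.0, 1.2, 1.2, 1.2]))
        assert not ok
        assert ev.min() < 0

    def test_eigenvalues_normalized(self, rng):
        for _ in range(20):
            d = rng.uniform(0.2, 1.0, size=3)
            m = np.diag([1.0, *d]) @ rotated_retarder(rng.uniform(0, np.pi), rng.uniform(0, np.pi))
            _, ev = cloude_filter(m)
            assert ev.sum() == pytest.approx(1.0, abs=1e-12)


class TestLuChipman:
    def test_identity(self):
        dec = lu_chipman(np.eye(4))
        assert dec.total_depolarization == pytest.approx(0.0, abs=1e-12)
        assert dec.linear_retardance == pytest.approx(0.0, abs=1e-9)
        assert_allclose(dec.depolarizer, np.eye(4), atol=1e-9)
        assert_allclose(dec.diattenuator, np.eye(4), atol=1e-12)

    def test_ideal_depolarizer(self):
        dec = lu_chipman(np.diag([1.0, 0, 0, 0]))
        assert dec.total_depolarization == pytest.approx(1.0)

    def test_synthesized_factors_recovered(self):
        m = np.diag([1.0, 0.7, 0.7, 0.6]) @ rotated_retarder(np.radians(40), np.radians(30))
        dec = lu_chipman(m)
        assert dec.total_depolarization == pytest.approx(1 - (0.7 + 0.7 + 0.6) / 3, abs=1e-6)
        assert dec.linear_retardance == pytest.approx(40.0, abs=1e-6)
        assert dec.azimuth == pytest.approx(30.0, abs=1e-6)
        assert dec.valid

    def test_reconstruction(self, rng):
        for _ in range(50):
            m = np.diag([1.0, *rng.uniform(0.2, 1.0, 3)]) @ rotated_retarder(
                rng.uniform(0.01, np.pi - 0.01), rng.uniform(0, np.pi)
            )
            dec = lu_chipman(m)
            assert np.abs(dec.reconstruct() - m).max() < 1e-6

    def test_parameter_recovery_1000_random_triples(self, rng):
        # depolarizer diagonal in [0.2, 1], retardance in (0, 180),
        # azimuth in [0, 180): all three scalars recovered to 1e-6
        for _ in range(1000):
            diag = rng.uniform(0.2, 1.0, size=3)
            delta = rng.uniform(1e-3, np.pi - 1e-3)
            beta = rng.uniform(0.0, np.pi - 1e-9)
            m = np.diag([1.0, *diag]) @ rotated_retarder(delta, beta)
            dec = lu_chipman(m)
            assert dec.total_depolarization == pytest.approx(1 - np.abs(diag).sum() / 3, abs=1e-6)
            assert dec.linear_retardance == pytest.approx(np.degrees(delta), abs=1e-6)
            err = abs(dec.azimuth - np.degrees(beta)) % 180.0
            assert min(err, 180.0 - err) < 1e-6

    def test_diattenuating_input(self):
        # pure diattenuator from the first row survives the round trip
        d = np.array([0.3, 0.1, -0.2])
        m = np.eye(4)
        m[0, 1:] = d
        m[1:, 0] = d
        dmag = np.linalg.norm(d)
        a = np.sqrt(1 - dmag**2)
        m[1:, 1:] = a * np.eye(3) + (1 - a) * np.outer(d / dmag, d / dmag)
        dec = lu_chipman(m)
        assert np.abs(dec.reconstruct() - m).max() < 1e-9
        assert_allclose(dec.diattenuator, m, atol=1e-9)

    def test_nonfinite_input_rejected(self):
        m = np.eye(4)
        m[2, 2] = np.nan
        with pytest.raises(ValueError):
            lu_chipman(m)

    def test_degenerate_diattenuation_short_circuits(self):
        m = np.eye(4)
        m[0, 1] = 1.0
        m[1, 0] = 1.0
        dec = lu_chipman(m)
        assert dec.degenerate
        assert_allclose(dec.retarder, np.eye(4), atol=1e-12)
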