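"""Descriptor algebra: hand examples, invariances, and a brute-force DFT oracle."""

import numpy as np
import pytest

from leafcat import contour_extraction as ce
from leafcat import fourier_descriptor as fd
from leafcat.contour import Contour


def dft_oracle(z):
    """O(N^2) direct evaluation of Z[k] = (1/N) sum z[n] e^{-j2pi kn/N}."""
    n = len(z)
    out = np.empty(n, dtype=complex)
    for k in range(n):
        out[k] = np.sum(z * np.exp(-2j * np.pi * k * np.arange(n) / n)) / n
    return out


class TestSlopeSignal:
    def test_square_slopes(self, square_contour):
        r = ce.resample_contour(square_contour, 8, mode="linear")
        s = fd.slope_signal(r)
        expected = np.array([1, 1, 1j, 1j, -1, -1, -1j, -1j])
        np.testing.assert_allclose(s.values, expected, atol=1e-12)

    def test_unit_modulus_and_closure(self, leaf_fixtures):
        for c in leaf_fixtures[:5]:
            s = fd.slope_signal(c)
            np.testing.assert_allclose(np.abs(s.values), 1.0, atol=1e-9)
            assert abs(np.sum(s.values)) * s.step_length < 1e-3 * c.perimeter

    def test_rotation_multiplies_slopes(self, leaf_fixtures):
        c = leaf_fixtures[0]
        theta = 0.7
        s0 = fd.slope_signal(c)
        s1 = fd.slope_signal(c.rotated(theta))
        np.testing.assert_allclose(s1.values, s0.values * np.exp(1j * theta),
                                   atol=1e-9)

    def test_scale_invariant(self, leaf_fixtures):
        c = leaf_fixtures[0]
        s0 = fd.slope_signal(c)
        s1 = fd.slope_signal(c.scaled(3.7))
        np.testing.assert_allclose(s1.values, s0.values, atol=1e-9)

    def test_coincident_points_rejected(self):
        # the contour container already refuses exact duplicates; the slope
        # stage keeps its own guard as defense in depth
        v = np.array([[0, 0], [1, 0], [1, 0], [1, 1], [0, 1],
                      [0, 0.5], [0, 0.25], [0, 0.1]])
        with pytest.raises(ValueError, match="distinct|coincident"):
            fd.slope_signal(Contour(v))
        fake = Contour(np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]]))
        fake.vertices = np.array([[0, 0], [1, 0], [1, 0], [0, 1.0]])
        with pytest.raises(ValueError):
            fd.slope_signal(fake)


class TestCft:
    def test_ideal_circle_tangents(self):
        n = 64
        zhat = 1j * np.exp(2j * np.pi * np.arange(n) / n)
        s = fd.SlopeSignal(zhat, step_length=2 * np.pi / n)
        spectrum = fd.cft(s)
        assert abs(spectrum[1] - 1j) < 1e-12
        rest = np.delete(spectrum, 1)
        assert np.max(np.abs(rest)) < 1e-12

    def test_constant_signal(self):
        s = fd.SlopeSignal(np.ones(32, dtype=complex), 1.0)
        spectrum = fd.cft(s)
        assert abs(spectrum[0] - 1) < 1e-12
        assert np.max(np.abs(spectrum[1:])) < 1e-12

    def test_parseval(self, leaf_fixtures):
        for c in leaf_fixtures[:5]:
            spectrum = fd.cft(fd.slope_signal(c))
            assert abs(np.sum(np.abs(spectrum) ** 2) - 1.0) < 1e-9

    @pytest.mark.parametrize("n", [8, 17, 64])
    def test_matches_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        phases = rng.uniform(0, 2 * np.pi, n)
        s = fd.SlopeSignal(np.exp(1j * phases), 1.0)
        np.testing.assert_allclose(fd.cft(s), dft_oracle(s.values),
                                   atol=1e-10)

    def test_inverse_recovers_slopes(self, leaf_fixtures):
        s = fd.slope_signal(leaf_fixtures[0])
        spectrum = fd.cft(s)
        back = np.fft.ifft(spectrum * s.n)
        np.testing.assert_allclose(back, s.values, atol=1e-9)


class TestTruncate:
    def test_default_band_is_symmetric_11(self, leaf_fixtures):
        s = fd.slope_signal(leaf_fixtures[0])
        d = fd.truncate(fd.cft(s), s, q=22)
        assert sorted(d.band.tolist()) == sorted(
            list(range(-11, 0)) + list(range(1, 12)))
        assert len(d.coefficients) == 22
        assert d.energy <= 1.0 + 1e-12

    def test_one_sided_band(self, leaf_fixtures):
        s = fd.slope_signal(leaf_fixtures[0])
        d = fd.truncate(fd.cft(s), s, q=22, band="one-sided")
        assert d.band.tolist() == list(range(1, 23))

    def test_circle_energy_complete(self):
        n = 128
        zhat = 1j * np.exp(2j * np.pi * np.arange(n) / n)
        s = fd.SlopeSignal(zhat, 2 * np.pi / n)
        for q in (2, 8, 22):
            d = fd.truncate(fd.cft(s), s, q=q)
            assert abs(d.energy - 1.0) < 1e-12

    @pytest.mark.parametrize("q", [3, 0, 600])
    def test_invalid_q_rejected(self, q, leaf_fixtures):
        s = fd.slope_signal(leaf_fixtures[0])
        with pytest.raises(ValueError):
            fd.truncate(fd.cft(s), s, q=q)


class TestReconstruct:
    def test_full_spectrum_identity(self, leaf_fixtures):
        c = leaf_fixtures[0]
        s = fd.slope_signal(c)
        d = fd.truncate(fd.cft(s), s, q=len(c) - 2)
        rec = fd.reconstruct(d)
        err = np.max(np.linalg.norm(rec.vertices - c.vertices, axis=1))
        assert err < 1e-6 * c.perimeter

    def test_circle_q22_error_tiny(self, circle_contour):
        s = fd.slope_signal(circle_contour)
        d = fd.truncate(fd.cft(s), s, q=22)
        rec = fd.reconstruct(d)
        assert fd.rms_difference(circle_contour, rec) < 1e-3  # percent

    def test_error_nonincreasing_in_q(self, leaf_fixtures):
        for c in leaf_fixtures[:4]:
            s = fd.slope_signal(c)
            spectrum = fd.cft(s)
            errs = [fd.rms_difference(c, fd.reconstruct(
                fd.truncate(spectrum, s, q=q))) for q in (4, 8, 16, 22, 64)]
            assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))


class TestRmsDifference:
    def test_identical_is_zero(self, circle_contour):
        assert fd.rms_difference(circle_contour, circle_contour) == 0.0

    def test_uniform_displacement_closed_form(self, circle_contour):
        v = circle_contour.vertices
        r = np.sqrt(np.mean(np.sum((v - v.mean(0)) ** 2, axis=1)))
        shifted = circle_contour.translated(0.01 * r, 0.0)
        assert abs(fd.rms_difference(circle_contour, shifted) - 1.0) < 1e-9

    def test_length_mismatch_rejected(self, circle_contour, square_contour):
        with pytest.raises(ValueError, match="equal"):
            fd.rms_difference(circle_contour, square_contour)


class TestEquivariances:
    def test_translation_leaves_descriptor_unchanged(self, leaf_fixtures):
        c = leaf_fixtures[2]
        d0 = fd.describe(c)
        d1 = fd.describe(c.translated(37.0, -12.5))
        np.testing.assert_allclose(d1.coefficients, d0.coefficients,
                                   atol=1e-12)

    def test_rotation_phase_factor(self, leaf_fixtures):
        c = leaf_fixtures[2]
        theta = 1.1
        z0 = fd.cft(fd.slope_signal(c))
        z1 = fd.cft(fd.slope_signal(c.rotated(theta)))
        np.testing.assert_allclose(z1, z0 * np.exp(1j * theta), atol=1e-9)
        np.testing.assert_allclose(np.abs(z1), np.abs(z0), atol=1e-9)

    def test_start_point_shift_phase_factor(self, leaf_fixtures):
        c = leaf_fixtures[3]
        n = len(c)
        n0 = 57
        shifted = Contour(np.roll(c.vertices, -n0, axis=0))
        z0 = fd.cft(fd.slope_signal(c))
        z1 = fd.cft(fd.slope_signal(shifted))
        k = fd.signed_frequencies(n)
        np.testing.assert_allclose(
            z1, z0 * np.exp(-2j * np.pi * k * (-n0) / n), atol=1e-9)
        np.testing.assert_allclose(np.abs(z1), np.abs(z0), atol=1e-9)

    def test_canonical_phase_removes_rotation(self, leaf_fixtures):
        """Rotation gauge is removed exactly; the start-point gauge has a
        half-circuit ambiguity, so only rotation equality is guaranteed."""
        c = leaf_fixtures[4]
        a = fd.canonical_phase(fd.cft(fd.slope_signal(c)))
        b = fd.canonical_phase(fd.cft(fd.slope_signal(c.rotated(0.9))))
        assert abs(np.angle(a[1]) - np.pi / 2) < 1e-9
        assert abs(np.angle(b[1]) - np.pi / 2) < 1e-9
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_canonical_phase_aligns_fundamentals_after_shift(self, leaf_fixtures):
        c = leaf_fixtures[4]
        moved = Contour(np.roll(c.vertices, -31, axis=0))
        a = fd.canonical_phase(fd.cft(fd.slope_signal(c)))
        b = fd.canonical_phase(fd.cft(fd.slope_signal(moved)))
        np.testing.assert_allclose(np.abs(a), np.abs(b), atol=1e-9)
        assert abs(np.angle(b[1]) - np.pi / 2) < 1e-9
        assert abs(np.angle(b[-1]) - np.pi / 2) < 1e-9
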