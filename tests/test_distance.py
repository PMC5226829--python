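"""Quantum catches, von Kries correction, Weber fractions, and the
receptor-noise chromatic distance — including the independent generic-n
oracle and the model's invariance properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

import dichroma as dc
from dichroma.distance import ZeroCatchError
from tests.conftest import gaussian_reflectance


def oracle_jnd(delta_f, webers):
    """Independent receptor-noise distance: the noise-weighted distance of
    the signal vector from the achromatic (equal-signal) axis, found by
    numerically minimizing over the achromatic offset."""
    delta_f = np.asarray(delta_f)
    webers = np.asarray(webers)

    def cost(c):
        return float(np.sum(((delta_f - c) / webers) ** 2))

    res = minimize_scalar(cost, bounds=(-50, 50), method="bounded")
    return float(np.sqrt(res.fun))


class TestQuantumCatch:
    def test_zero_reflectance_zero_catch(self, grid, ideal, uvs_sensitivities):
        zero = dc.SpectralCurve(grid, np.zeros(len(grid)))
        assert dc.quantum_catch(zero, ideal, uvs_sensitivities[0]) == 0.0

    def test_unit_reflectance_ideal_gives_sensitivity_mass(self, grid, ideal, uvs_sensitivities):
        one = dc.SpectralCurve(grid, np.ones(len(grid)))
        for s in uvs_sensitivities:
            assert dc.quantum_catch(one, ideal, s) == pytest.approx(
                s.values.sum() * grid.step, rel=1e-12
            )

    def test_matches_term_by_term_oracle(self, grid, ideal, uvs_sensitivities):
        rng = np.random.default_rng(11)
        refl = dc.SpectralCurve(grid, rng.uniform(0, 1, len(grid)))
        for s in uvs_sensitivities:
            acc = 0.0
            for r_i, i_i, s_i in zip(refl.values, ideal.curve.values, s.values):
                acc += r_i * i_i * s_i * grid.step
            assert dc.quantum_catch(refl, ideal, s) == pytest.approx(acc, rel=1e-10)

    def test_all_zero_sensitivity_rejected(self, grid, ideal):
        zero = dc.SpectralCurve(grid, np.zeros(len(grid)))
        refl = dc.SpectralCurve(grid, np.ones(len(grid)))
        with pytest.raises(ValueError, match="zero"):
            dc.quantum_catch(refl, ideal, zero)


class TestVonKries:
    def test_flat_reflectance_gives_constant_q(self, grid, uvs_sensitivities):
        illum = dc.builtin_illuminant("D65", grid)
        c = 0.37
        refl = dc.SpectralCurve(grid, np.full(len(grid), c))
        q = dc.von_kries(
            dc.quantum_catches(refl, illum, uvs_sensitivities), illum, uvs_sensitivities
        )
        np.testing.assert_allclose(q, c, rtol=1e-12)

    def test_illuminant_scaling_cancels(self, grid, uvs_sensitivities):
        illum = dc.builtin_illuminant("D65", grid)
        scaled = dc.Illuminant("D65x10", illum.curve.scaled(10.0))
        refl = gaussian_reflectance(grid, 480.0)
        frac = dc.SpectralCurve(grid, refl.values / 100.0)
        q1 = dc.von_kries(
            dc.quantum_catches(frac, illum, uvs_sensitivities), illum, uvs_sensitivities
        )
        q2 = dc.von_kries(
            dc.quantum_catches(frac, scaled, uvs_sensitivities), scaled, uvs_sensitivities
        )
        np.testing.assert_allclose(q1, q2, rtol=1e-10)


class TestWeberFractions:
    def test_pekin_robin_ratio(self):
        nm = dc.NoiseModel((1, 2, 2, 4), 0.05)
        np.testing.assert_allclose(
            dc.weber_fractions(nm), [0.1, 0.05 * np.sqrt(2), 0.05 * np.sqrt(2), 0.05]
        )

    def test_equal_densities_all_reference(self):
        nm = dc.NoiseModel((3, 3, 3, 3), 0.05)
        np.testing.assert_allclose(dc.weber_fractions(nm), 0.05)

    def test_most_abundant_channel_pinned(self):
        # black noddy densities: MWS most abundant
        nm = dc.NoiseModel((1.00, 9.59, 16.82, 14.29), 0.05)
        webers = dc.weber_fractions(nm)
        assert webers[2] == pytest.approx(0.05)
        assert np.argmin(webers) == 2

    def test_ties_break_toward_lws(self):
        nm = dc.NoiseModel((1, 4, 4, 4), 0.05)
        assert nm.reference_index == 3

    def test_non_positive_density_rejected(self):
        with pytest.raises(ValueError):
            dc.NoiseModel((0, 1, 1, 1), 0.05)


class TestJndDistance:
    WEBERS = np.array([0.1, 0.05 * np.sqrt(2), 0.05 * np.sqrt(2), 0.05])

    def test_identical_catches_zero(self):
        q = np.array([0.2, 0.4, 0.3, 0.8])
        assert dc.jnd_distance(q, q, self.WEBERS).delta_s == 0.0

    def test_weber_doubling_halves_jnd(self):
        # construct an arbitrary pair, rescale it to exactly 6 JND, then
        # double and quadruple all Weber fractions: 6 -> 3 -> 1.5
        qa = np.array([0.2, 0.5, 0.3, 0.7])
        qb = np.array([0.25, 0.4, 0.35, 0.6])
        base = dc.jnd_distance(qa, qb, self.WEBERS).delta_s
        scale = base / 6.0
        webers6 = self.WEBERS * scale  # noise scaled so the pair sits at 6 JND
        assert dc.jnd_distance(qa, qb, webers6).delta_s == pytest.approx(6.0)
        assert dc.jnd_distance(qa, qb, 2 * webers6).delta_s == pytest.approx(3.0)
        assert dc.jnd_distance(qa, qb, 4 * webers6).delta_s == pytest.approx(1.5)

    def test_zero_catch_raises_typed_error(self):
        q = np.array([0.0, 0.4, 0.3, 0.8])
        with pytest.raises(ZeroCatchError):
            dc.jnd_distance(q, np.ones(4), self.WEBERS)

    def test_matches_generic_oracle_on_random_vectors(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            qa = rng.uniform(0.01, 2.0, 4)
            qb = rng.uniform(0.01, 2.0, 4)
            webers = rng.uniform(0.02, 0.3, 4)
            got = dc.jnd_distance(qa, qb, webers).delta_s
            expected = oracle_jnd(np.log(qa / qb), webers)
            assert got == pytest.approx(expected, rel=1e-6, abs=1e-9)


@st.composite
def catch_vectors(draw):
    vals = st.floats(0.01, 10.0, allow_nan=False, allow_infinity=False)
    return np.array([draw(vals) for _ in range(4)])


@st.composite
def weber_vectors(draw):
    vals = st.floats(0.01, 0.5, allow_nan=False, allow_infinity=False)
    return np.array([draw(vals) for _ in range(4)])


class TestInvariances:
    @given(qa=catch_vectors(), qb=catch_vectors(), w=weber_vectors())
    @settings(max_examples=200, deadline=None)
    def test_symmetry(self, qa, qb, w):
        assert dc.jnd_distance(qa, qb, w).delta_s == pytest.approx(
            dc.jnd_distance(qb, qa, w).delta_s, rel=1e-12, abs=1e-12
        )

    @given(qa=catch_vectors(), qb=catch_vectors(), w=weber_vectors(),
           k=st.floats(0.1, 10.0))
    @settings(max_examples=200, deadline=None)
    def test_noise_homogeneity(self, qa, qb, w, k):
        base = dc.jnd_distance(qa, qb, w).delta_s
        scaled = dc.jnd_distance(qa, qb, k * w).delta_s
        assert scaled * k == pytest.approx(base, rel=1e-9, abs=1e-12)

    @given(ca=st.floats(0.05, 1.0), cb=st.floats(0.05, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_two_grey_levels_are_indistinct(self, grid, ideal, uvs_sensitivities, ca, cb):
        # any two flat (achromatic) spectra differ only in intensity
        webers = self.webers()
        qa = dc.von_kries(
            dc.quantum_catches(dc.SpectralCurve(grid, np.full(len(grid), ca)), ideal, uvs_sensitivities),
            ideal, uvs_sensitivities,
        )
        qb = dc.von_kries(
            dc.quantum_catches(dc.SpectralCurve(grid, np.full(len(grid), cb)), ideal, uvs_sensitivities),
            ideal, uvs_sensitivities,
        )
        assert dc.jnd_distance(qa, qb, webers).delta_s == pytest.approx(0.0, abs=1e-9)

    @staticmethod
    def webers():
        return dc.NoiseModel((1, 2, 2, 4)).webers

    def test_single_channel_sensitivity_scaling_leaves_jnd(self, grid, ideal, uvs_sensitivities):
        webers = self.webers()
        ra = gaussian_reflectance(grid, 420.0)
        rb = gaussian_reflectance(grid, 470.0)
        fa = dc.SpectralCurve(grid, ra.values / 100)
        fb = dc.SpectralCurve(grid, rb.values / 100)

        def jnd(sens):
            qa = dc.von_kries(dc.quantum_catches(fa, ideal, sens), ideal, sens)
            qb = dc.von_kries(dc.quantum_catches(fb, ideal, sens), ideal, sens)
            return dc.jnd_distance(qa, qb, webers).delta_s

        base = jnd(uvs_sensitivities)
        for i in range(4):
            scaled = list(uvs_sensitivities)
            scaled[i] = scaled[i].scaled(3.7)
            assert jnd(scaled) == pytest.approx(base, rel=1e-10)

    def test_illuminant_intensity_invariance_end_to_end(self, grid, uvs_sensitivities):
        webers = self.webers()
        illum = dc.builtin_illuminant("forest_shade", grid)
        bright = dc.Illuminant("bright", illum.curve.scaled(13.0))
        fa = dc.SpectralCurve(grid, gaussian_reflectance(grid, 360.0).values / 100)
        fb = dc.SpectralCurve(grid, gaussian_reflectance(grid, 620.0).values / 100)

        def jnd(ill):
            qa = dc.von_kries(dc.quantum_catches(fa, ill, uvs_sensitivities), ill, uvs_sensitivities)
            qb = dc.von_kries(dc.quantum_catches(fb, ill, uvs_sensitivities), ill, uvs_sensitivities)
            return dc.jnd_distance(qa, qb, webers).delta_s

        assert jnd(illum) == pytest.approx(jnd(bright), rel=1e-10)
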