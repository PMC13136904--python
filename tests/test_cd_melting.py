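"""SVD melting analysis, three-state thermodynamics, RSQ dissimilarity."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quadstack.cd_melting import (CDMeltingMatrix, CDSpectrum, fit_three_state,
                                  rsq, significant_components, svd_decompose,
                                  three_state_fractions)
from quadstack.synth import SyntheticCDSpec, gen_cd_melt


def spectrum(values):
    values = np.asarray(values, dtype=float)
    return CDSpectrum(wavelengths=220.0 + np.arange(len(values)), ellipticity=values)


class TestSVD:
    def test_reconstruction_at_full_rank(self):
        mat, _ = gen_cd_melt(SyntheticCDSpec(rng_seed=1))
        res = svd_decompose(mat)
        rebuilt = res.U @ np.diag(res.S) @ res.V.T
        assert np.allclose(rebuilt, mat.ellipticity, atol=1e-10 * np.abs(mat.ellipticity).max())

    def test_rank_one_matrix(self):
        lam = np.linspace(220, 330, 50)
        temp = np.linspace(24, 100, 20)
        spec_shape = np.exp(-0.5 * ((lam - 280) / 15)**2)
        melt = 1.0 / (1.0 + np.exp((temp - 60) / 5))
        mat = CDMeltingMatrix(lam, temp, np.outer(spec_shape, melt))
        res = svd_decompose(mat)
        assert res.S[1] < 1e-10 * res.S[0]
        assert significant_components(res) == 1

    def test_noiseless_three_state_is_rank_three(self):
        mat, _ = gen_cd_melt(SyntheticCDSpec(noise_mdeg=0.0, rng_seed=2))
        res = svd_decompose(mat)
        assert res.S[3] < 1e-8 * res.S[0]

    def test_sign_convention(self):
        mat, _ = gen_cd_melt(SyntheticCDSpec(rng_seed=3))
        res = svd_decompose(mat)
        for j in range(res.U.shape[1]):
            assert res.U[np.argmax(np.abs(res.U[:, j])), j] > 0

    def test_non_finite_rejected(self):
        lam = np.linspace(220, 330, 10)
        temp = np.linspace(24, 100, 8)
        bad = np.ones((10, 8))
        bad[3, 4] = np.nan
        with pytest.raises(ValueError):
            svd_decompose(CDMeltingMatrix(lam, temp, bad))


class TestSignificance:
    def test_three_state_with_noise_gives_three(self):
        mat, _ = gen_cd_melt(SyntheticCDSpec(rng_seed=4))
        assert significant_components(svd_decompose(mat)) == 3

    def test_pure_noise_gives_zero(self, rng):
        lam = np.linspace(220, 330, 111)
        temp = np.linspace(24, 100, 39)
        mat = CDMeltingMatrix(lam, temp, rng.normal(size=(111, 39)))
        assert significant_components(svd_decompose(mat)) == 0

    def test_invariant_under_overall_scaling(self):
        mat, _ = gen_cd_melt(SyntheticCDSpec(rng_seed=5))
        res1 = svd_decompose(mat)
        scaled = CDMeltingMatrix(mat.wavelengths, mat.temperatures,
                                 37.5 * mat.ellipticity)
        res2 = svd_decompose(scaled)
        assert significant_components(res1) == significant_components(res2)


class TestThreeStateFractions:
    @given(st.floats(50, 400), st.floats(30, 90), st.floats(50, 400), st.floats(30, 95))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_fractions_sum_to_one_and_are_monotone(self, dh1, tm1, dh2, tm2):
        t = np.linspace(10, 110, 60)
        f = three_state_fractions(t, dh1, min(tm1, tm2), dh2, max(tm1, tm2))
        assert np.allclose(f.sum(axis=0), 1.0, atol=1e-12)
        assert np.all(f >= 0) and np.all(f <= 1)
        assert np.all(np.diff(f[0]) <= 1e-12)       # folded never increases
        assert np.all(np.diff(f[2]) >= -1e-12)      # unfolded never decreases


class TestThreeStateFit:
    def test_parameter_recovery(self):
        spec = SyntheticCDSpec(dH1=200.0, Tm1=55.0, dH2=250.0, Tm2=70.0,
                               noise_mdeg=0.15, rng_seed=6)
        mat, truth = gen_cd_melt(spec)
        fit = fit_three_state(svd_decompose(mat), n_components=3)
        assert abs(fit.Tm1 - truth["Tm1"]) < 1.0
        assert abs(fit.Tm2 - truth["Tm2"]) < 1.0
        assert fit.dH1 == pytest.approx(truth["dH1"], rel=0.15)
        assert fit.dH2 == pytest.approx(truth["dH2"], rel=0.15)

    def test_median_tm_error_across_replicates(self):
        errs = []
        for s in range(50):
            mat, truth = gen_cd_melt(SyntheticCDSpec(rng_seed=700 + s))
            fit = fit_three_state(svd_decompose(mat), n_components=3)
            errs.append(abs(fit.Tm1 - truth["Tm1"]))
        assert np.median(errs) <= 0.5

    def test_two_state_degenerate_input(self):
        """With the intermediate amplitude suppressed, the model collapses to
        a clean two-state melt and the headline Tm matches the generator."""
        lam = np.arange(220.0, 331.0)
        temp = np.arange(24.0, 101.0, 2.0)
        folded = 10 * np.exp(-0.5 * ((lam - 290) / 9)**2) - 8 * np.exp(-0.5 * ((lam - 240) / 8)**2)
        unfolded = 1.5 * np.exp(-0.5 * ((lam - 275) / 20)**2)
        tm_true, dh = 62.0, 250.0
        k = np.exp(-dh / 8.31446e-3 * (1 / (temp + 273.15) - 1 / (tm_true + 273.15)))
        f_f = 1 / (1 + k)
        d = np.outer(folded, f_f) + np.outer(unfolded, 1 - f_f)
        d += np.random.default_rng(8).normal(0, 0.1, d.shape)
        fit = fit_three_state(svd_decompose(CDMeltingMatrix(lam, temp, d)),
                              n_components=2)
        # the three-state model nests the two-state melt: one transition must
        # sit at the true Tm, and the fitted fractions must reproduce the
        # true folded curve through a linear combination (the extra
        # transition is spectroscopically silent)
        assert min(abs(fit.Tm1 - tm_true), abs(fit.Tm2 - tm_true)) < 1.0
        k_true = np.exp(-dh / 8.31446e-3 * (1 / (temp + 273.15) - 1 / (tm_true + 273.15)))
        f_true = 1 / (1 + k_true)
        coef, *_ = np.linalg.lstsq(fit.fractions.T, f_true, rcond=None)
        assert np.abs(fit.fractions.T @ coef - f_true).max() < 0.01

    def test_headline_tm_is_half_folded_crossing(self):
        mat, truth = gen_cd_melt(SyntheticCDSpec(rng_seed=9))
        fit = fit_three_state(svd_decompose(mat), n_components=3)
        f = three_state_fractions(np.array([fit.headline_Tm]),
                                  fit.dH1, fit.Tm1, fit.dH2, fit.Tm2)
        assert f[0, 0] == pytest.approx(0.5, abs=0.01)


class TestRSQ:
    def test_identical_spectra(self):
        a = spectrum([1.0, -2.0, 3.0, 0.5])
        assert rsq(a, a) == 0.0

    def test_constant_offset_closed_form(self):
        n, c = 25, 0.7
        a = spectrum(np.linspace(-5, 5, n))
        b = spectrum(np.linspace(-5, 5, n) + c)
        assert rsq(a, b) == pytest.approx(c * math.sqrt(n), rel=1e-12)

    def test_hand_computed_example(self):
        assert rsq(spectrum([1, 2, 2]), spectrum([0, 0, 0])) == pytest.approx(3.0)

    def test_grid_mismatch_requires_resample(self):
        a = spectrum([1, 2, 3])
        b = CDSpectrum(wavelengths=np.array([220.5, 221.5, 222.5]),
                       ellipticity=np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            rsq(a, b)
        assert rsq(a, b, resample=True) >= 0.0

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=12),
           st.lists(st.floats(-50, 50), min_size=3, max_size=12),
           st.lists(st.floats(-50, 50), min_size=3, max_size=12))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_metric_properties(self, xs, ys, zs):
        n = min(len(xs), len(ys), len(zs))
        a, b, c = spectrum(xs[:n]), spectrum(ys[:n]), spectrum(zs[:n])
        assert rsq(a, b) == rsq(b, a)
        assert rsq(a, b) >= 0
        if np.allclose(a.ellipticity, b.ellipticity):
            assert rsq(a, b) == pytest.approx(0.0, abs=1e-9)
        assert rsq(a, c) <= rsq(a, b) + rsq(b, c) + 1e-9
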