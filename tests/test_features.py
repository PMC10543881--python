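import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fraglift.features import (
    FOURIER_WINDOW,
    detrend_window,
    extract_features,
    feature_names,
    fourier_features,
    wavelet_features,
)
from fraglift.io_profiles import LengthHistogram, normalize

from conftest import profile_from_density, profile_from_logp


def quadratic_logp(beta0=-6.0, beta1=0.02, beta2=-1e-4, extra=None):
    """logp exactly quadratic in fragment length over the whole support
    (plus an optional additive term inside the Fourier window)."""
    j = np.arange(50, 401, dtype=float)
    logp = beta0 + beta1 * j + beta2 * j * j
    if extra is not None:
        lo, hi = FOURIER_WINDOW
        logp[lo - 50: hi - 50 + 1] += extra
    return profile_from_logp(logp)


def ols_normal_equations(j, y):
    """Independent least-squares oracle: solve the 3x3 normal equations."""
    A = np.column_stack([np.ones_like(j), j, j**2])
    return np.linalg.solve(A.T @ A, A.T @ y)


def naive_dft(x):
    """O(N^2) direct-summation DFT oracle."""
    N = len(x)
    k = np.arange(N)
    return np.array(
        [np.sum(x * np.exp(-2j * np.pi * kk * k / N)) for kk in range(N)]
    )


class TestDetrend:
    def test_quadratic_input_gives_zero_residuals(self):
        fit = detrend_window(quadratic_logp())
        assert fit.residuals.shape == (61,)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-10)

    def test_residuals_sum_to_zero(self, rng):
        # OLS with an intercept forces zero-mean residuals for any input
        for _ in range(5):
            noise = 0.3 * rng.normal(size=351)
            prof = profile_from_logp(quadratic_logp().logp + noise)
            assert abs(detrend_window(prof).residuals.sum()) < 1e-9

    def test_cosine_survives_detrending(self):
        # cosine at an exact DFT frequency over 61 points is orthogonal to
        # the constant regressor and nearly orthogonal to j and j^2
        n = np.arange(61)
        cosine = np.cos(2 * np.pi * 6 * n / 61)
        prof = quadratic_logp(extra=0.1 * cosine)
        fit = detrend_window(prof)
        # approximately the cosine (the quadratic absorbs a small part)...
        np.testing.assert_allclose(fit.residuals, 0.1 * cosine, atol=0.01)
        # ...and exactly the residuals of the normal-equations oracle
        j, logp = prof.window(*FOURIER_WINDOW)
        beta = ols_normal_equations(j.astype(float), logp)
        np.testing.assert_allclose(
            fit.residuals,
            logp - beta[0] - beta[1] * j - beta[2] * j**2,
            atol=1e-9,
        )

    def test_matches_normal_equations_oracle(self, rng):
        noise = 0.2 * rng.normal(size=351)
        prof = profile_from_logp(quadratic_logp().logp + noise)
        fit = detrend_window(prof)
        j, logp = prof.window(*FOURIER_WINDOW)
        beta = ols_normal_equations(j.astype(float), logp)
        np.testing.assert_allclose(
            [fit.beta0, fit.beta1, fit.beta2], beta, rtol=1e-6
        )
        np.testing.assert_allclose(
            fit.residuals,
            logp - beta[0] - beta[1] * j - beta[2] * j**2,
            atol=1e-9,
        )


class TestFourier:
    def test_zero_residuals_give_zero_magnitudes(self):
        fit = detrend_window(quadratic_logp())
        ff = fourier_features(fit)
        assert all(v < 1e-9 for v in ff.magnitudes.values())

    def test_exact_frequency_cosine(self):
        # sum_n cos(2*pi*6n/61) e^{-2*pi*ikn/61} has magnitude 61/2 at k=6
        n = np.arange(61)
        residuals = np.cos(2 * np.pi * 6 * n / 61)
        fit = detrend_window(quadratic_logp())
        ff = fourier_features(
            type(fit)(fit.beta0, fit.beta1, fit.beta2, residuals)
        )
        assert ff.magnitudes["F6"] == pytest.approx(30.5, abs=1e-9)
        others = [v for k, v in ff.magnitudes.items() if k != "F6"]
        assert max(others) < 1e-9

    def test_f0_vanishes_on_detrended_profiles(self, rng):
        for theta in (0.0, 0.2, 0.6):
            prof = profile_from_density(theta)
            ff = fourier_features(detrend_window(prof))
            assert abs(ff.F[0]) < 1e-9

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_conjugate_symmetry_and_parseval(self, seed):
        rng = np.random.default_rng(seed)
        residuals = rng.normal(size=61)
        residuals -= residuals.mean()
        fit = detrend_window(quadratic_logp())
        ff = fourier_features(
            type(fit)(fit.beta0, fit.beta1, fit.beta2, residuals)
        )
        F = ff.F
        for k in range(1, 31):
            assert abs(abs(F[61 - k]) - abs(F[k])) < 1e-9
        parseval = np.sum(np.abs(F) ** 2)
        assert parseval == pytest.approx(61 * np.sum(residuals**2), rel=1e-6)

    def test_matches_naive_dft_oracle(self, rng):
        for _ in range(10):
            residuals = rng.normal(size=61)
            residuals -= residuals.mean()
            fit = detrend_window(quadratic_logp())
            ff = fourier_features(
                type(fit)(fit.beta0, fit.beta1, fit.beta2, residuals)
            )
            np.testing.assert_allclose(ff.F, naive_dft(residuals), atol=1e-9)

    def test_wrong_length_rejected(self):
        fit = detrend_window(quadratic_logp())
        with pytest.raises(ValueError, match="61"):
            fourier_features(
                type(fit)(fit.beta0, fit.beta1, fit.beta2, np.zeros(60))
            )


# published 10-tap Daubechies scaling filter (5 vanishing moments)
DB5_FILTER = np.array(
    [
        0.16010239797419293,
        0.6038292697971896,
        0.7243085284377729,
        0.13842814590132074,
        -0.24229488706638203,
        -0.032244869584638375,
        0.07757149384004572,
        -0.006241490212798274,
        -0.012580751999081999,
        0.0033357252854737712,
    ]
)
DB5_QMF = np.array([(-1) ** n * DB5_FILTER[9 - n] for n in range(10)])


def filter_bank_dwt(x, levels):
    """Independent periodized filter-bank oracle.

    One analysis step: circular correlation with the scaling / wavelet
    filter followed by dyadic decimation,
    ``a_k = sum_n c_n x_{(2k - 4 + n) mod N}`` (the -4 shift aligns the
    even-length filter symmetrically around the retained samples).
    """
    details = []
    a = np.asarray(x, dtype=float)
    for _ in range(levels):
        N = a.size
        idx = (2 * np.arange(N // 2)[:, None] - 4 + np.arange(10)) % N
        details.append(a[idx] @ DB5_QMF)
        a = a[idx] @ DB5_FILTER
    return a, details


class TestWavelet:
    def test_constant_input_has_zero_details(self):
        prof = profile_from_logp(np.full(351, -5.0) + 1e-12)
        wf = wavelet_features(prof)
        details = {k: v for k, v in wf.coefficients.items()
                   if not k.startswith("W7_")}
        approx = {k: v for k, v in wf.coefficients.items()
                  if k.startswith("W7_")}
        assert max(abs(v) for v in details.values()) < 1e-9
        total = sum(v**2 for v in wf.coefficients.values())
        assert sum(v**2 for v in approx.values()) == pytest.approx(total)

    def test_energy_conservation(self, rng):
        for theta in (0.0, 0.3):
            prof = profile_from_density(theta)
            _, logp = prof.window(81, 336)
            wf = wavelet_features(prof)
            energy = sum(v**2 for v in wf.coefficients.values())
            assert energy == pytest.approx(np.sum(logp**2), abs=1e-9)

    def test_coefficient_count_and_names(self):
        prof = profile_from_density(0.1)
        wf = wavelet_features(prof)
        assert len(wf.coefficients) == 256
        # dyadic sizes: 128 + 64 + 32 + 16 + 8 + 4 details + 4 approx
        for scale, size in [(1, 128), (2, 64), (3, 32), (4, 16), (5, 8),
                            (6, 4), (7, 4)]:
            names = [k for k in wf.coefficients if k.startswith(f"W{scale}_")]
            assert len(names) == size

    def test_degree4_polynomial_interior_details_vanish(self):
        # db5 has 5 vanishing moments: interior level-1 detail coefficients
        # annihilate polynomials up to degree 4 exactly
        j = np.arange(50, 401, dtype=float)
        u = (j - 208.0) / 128.0
        logp = -6.0 + u + u**2 - 0.5 * u**3 + 0.25 * u**4
        prof = profile_from_logp(logp)
        wf = wavelet_features(prof, levels=1)
        scale = max(abs(v) for v in wf.coefficients.values())
        # interior coefficients: supports [2k-4, 2k+5] within [0, 255]
        interior = [
            wf.coefficients[f"W1_{k + 1}"] for k in range(2, 125)
        ]
        assert max(abs(v) for v in interior) < 1e-8 * scale

    def test_matches_filter_bank_oracle(self, rng):
        for _ in range(10):
            logp = -6.0 + 0.5 * rng.normal(size=351)
            prof = profile_from_logp(logp)
            _, x = prof.window(81, 336)
            wf = wavelet_features(prof, levels=6)
            approx, details = filter_bank_dwt(x, 6)
            for scale, det in enumerate(details, start=1):
                got = np.array(
                    [wf.coefficients[f"W{scale}_{k + 1}"]
                     for k in range(det.size)]
                )
                np.testing.assert_allclose(got, det, atol=1e-9)
            got_a = np.array(
                [wf.coefficients[f"W7_{k + 1}"] for k in range(approx.size)]
            )
            np.testing.assert_allclose(got_a, approx, atol=1e-9)

    def test_too_many_levels_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            wavelet_features(profile_from_density(0.1), levels=9)


class TestFeatureVector:
    def test_feature_count_and_determinism(self):
        prof = profile_from_density(0.25)
        fv1 = extract_features(prof)
        fv2 = extract_features(prof)
        assert len(fv1.values) == 286  # 30 Fourier + 256 wavelet
        assert list(fv1.values) == feature_names()
        assert fv1.values == fv2.values

    def test_count_scale_invariance(self, small_sim_config):
        from fraglift.synthetic import simulate_sample

        sample = simulate_sample(
            0.3, small_sim_config, seed=11, cohort="dilution"
        )
        # add one fragment per bin so every count is positive and the
        # pseudocount can be switched off (exact invariance regime)
        vec = sample.histogram.count_vector() + 1
        lo = sample.histogram.support[0]
        hist = LengthHistogram(
            sample.sample_id,
            {lo + i: int(c) for i, c in enumerate(vec)},
            sample.histogram.support,
        )
        scaled = LengthHistogram(
            hist.sample_id,
            {k: 10 * v for k, v in hist.counts.items()},
            hist.support,
        )
        fv1 = extract_features(normalize(hist, pseudocount=0.0))
        fv2 = extract_features(normalize(scaled, pseudocount=0.0))
        np.testing.assert_allclose(
            list(fv1.values.values()), list(fv2.values.values()), atol=1e-9
        )
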