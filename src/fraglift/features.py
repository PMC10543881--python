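"""Fourier and wavelet features of the cfDNA fragment-length profile.

Two complementary feature families are extracted from the log-proportion
profile of each sample:

* **Fourier magnitudes** of the ~10 bp oscillation in the 81-141 bp window.
  A second-degree polynomial in fragment length is fitted to ``log(p_j)``
  by ordinary least squares and removed; the discrete Fourier transform of
  the 61 residuals yields coefficients ``F_k = sum_n e_n exp(-2*pi*i*k*n/61)``
  whose magnitudes ``|F_1| .. |F_30|`` are the features (the remaining half
  is redundant by conjugate symmetry, and ``F_0 = 0`` because OLS residuals
  with an intercept sum to zero).
* **Wavelet coefficients** of ``log(p_j)`` over 81-336 bp (256 points): a
  decimated orthonormal discrete wavelet transform with the 10-tap
  Daubechies filter (five vanishing moments), chosen because its support
  matches the 10 bp nucleosomal oscillation period. All detail coefficients
  plus the final approximation are emitted, named ``W{scale}_{location}``
  with scale 1 the finest detail level and the approximation labelled
  ``levels + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .io_profiles import FragmentProfile

FOURIER_WINDOW = (81, 141)
WAVELET_WINDOW = (81, 336)

#: 10-tap Daubechies filter (pywt naming: db5 = 5 vanishing moments)
WAVELET_NAME = "db5"


@dataclass(frozen=True)
class DetrendFit:
    """Quadratic OLS fit of logp on fragment length over 81-141 bp."""

    beta0: float
    beta1: float
    beta2: float
    residuals: np.ndarray  # e_n, n = j - 81, length 61
    window: tuple[int, int] = FOURIER_WINDOW


@dataclass(frozen=True)
class FourierFeatures:
    """Complex DFT coefficients F_0..F_60 and the magnitudes |F_1|..|F_30|."""

    F: np.ndarray  # complex, length 61
    magnitudes: dict[str, float]


@dataclass(frozen=True)
class WaveletFeatures:
    """Named orthonormal DWT coefficients of logp over 81-336 bp."""

    coefficients: dict[str, float]
    filter: str
    levels: int
    boundary: str


@dataclass(frozen=True)
class FeatureVector:
    """All named features for one sample, in a fixed deterministic order."""

    sample_id: str
    values: dict[str, float]


def detrend_window(profile: FragmentProfile) -> DetrendFit:
    """Remove a quadratic trend from logp over 81-141 bp by OLS.

    Returns the fit coefficients and the 61 residuals indexed ``n = j - 81``.
    """
    lengths, logp = profile.window(*FOURIER_WINDOW)
    if not np.all(np.isfinite(logp)):
        raise ValueError("non-finite log-proportions in the 81-141 bp window")
    j = lengths.astype(float)
    design = np.column_stack([np.ones_like(j), j, j * j])
    beta, *_ = np.linalg.lstsq(design, logp, rcond=None)
    residuals = logp - design @ beta
    return DetrendFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]),
        residuals=residuals,
    )


def fourier_features(fit: DetrendFit) -> FourierFeatures:
    """Unnormalized negative-exponent DFT of the detrend residuals.

    ``F_k = sum_{n=0}^{60} e_n exp(-2*pi*i*k*n/61)``; magnitudes are
    reported for k = 1..30 only, as the upper half mirrors them.
    """
    residuals = np.asarray(fit.residuals, dtype=float)
    if residuals.shape != (61,):
        raise ValueError(f"expected 61 residuals, got {residuals.shape}")
    F = np.fft.fft(residuals)  # negative-exponent, unnormalized
    magnitudes = {f"F{k}": float(np.abs(F[k])) for k in range(1, 31)}
    return FourierFeatures(F=F, magnitudes=magnitudes)


def wavelet_features(
    profile: FragmentProfile,
    levels: int = 6,
    boundary: str = "periodization",
) -> WaveletFeatures:
    """Decimated orthonormal DWT of logp over the 256-point 81-336 bp window.

    With periodic boundary handling the transform is orthonormal: the 256
    output coefficients conserve the energy of the input exactly. Detail
    coefficients for scales ``1..levels`` (scale 1 finest) and the final
    approximation (labelled ``levels + 1``) are all emitted.
    """
    _, logp = profile.window(*WAVELET_WINDOW)
    n = logp.size
    if n != 256:
        raise ValueError(f"wavelet window must span 256 points, got {n}")
    max_levels = int(np.log2(n))
    if not 1 <= levels <= max_levels:
        raise ValueError(f"levels must be in [1, {max_levels}]")
    import warnings

    with warnings.catch_warnings():
        # at 6 levels on 256 points every coefficient sees the periodic
        # boundary; that is intentional, so silence pywt's depth warning
        warnings.filterwarnings("ignore", message="Level value .* too high")
        coeffs = pywt.wavedec(logp, WAVELET_NAME, mode=boundary, level=levels)
    # wavedec returns [cA_L, cD_L, ..., cD_1]; scale 1 is the finest detail
    named: dict[str, float] = {}
    approx, details = coeffs[0], coeffs[1:]
    for scale, detail in zip(range(levels, 0, -1), details):
        for loc, value in enumerate(detail, start=1):
            named[f"W{scale}_{loc}"] = float(value)
    for loc, value in enumerate(approx, start=1):
        named[f"W{levels + 1}_{loc}"] = float(value)
    return WaveletFeatures(
        coefficients=named,
        filter=WAVELET_NAME,
        levels=levels,
        boundary=boundary,
    )


def feature_names(levels: int = 6) -> list[str]:
    """Canonical feature order: Fourier block then wavelet block,
    lexicographically sorted within each block."""
    fourier = sorted(f"F{k}" for k in range(1, 31))
    n = 256
    wavelet = []
    size = n
    for scale in range(1, levels + 1):
        size //= 2
        wavelet.extend(f"W{scale}_{loc}" for loc in range(1, size + 1))
    wavelet.extend(f"W{levels + 1}_{loc}" for loc in range(1, size + 1))
    return fourier + sorted(wavelet)


def extract_features(profile: FragmentProfile, levels: int = 6) -> FeatureVector:
    """Concatenate Fourier magnitudes and wavelet coefficients for a sample."""
    fourier = fourier_features(detrend_window(profile)).magnitudes
    wavelet = wavelet_features(profile, levels=levels).coefficients
    combined = {**fourier, **wavelet}
    ordered = {name: combined[name] for name in feature_names(levels)}
    return FeatureVector(sample_id=profile.sample_id, values=ordered)


def feature_matrix(profiles: list[FragmentProfile], levels: int = 6):
    """Stack per-sample feature vectors into a DataFrame (rows = samples)."""
    import pandas as pd

    rows = [extract_features(p, levels=levels) for p in profiles]
    frame = pd.DataFrame(
        [fv.values for fv in rows], index=[fv.sample_id for fv in rows]
    )
    frame.index.name = "sample_id"
    return frame
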