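"""Steady-state Fourier analysis of entrained trial waveforms.

Implements the analysis chain used for flicker-evoked pupil and EEG
responses: fixed-window epoching, amplitude-calibrated Fourier
decomposition, coherent (complex-domain) averaging with Mahalanobis
outlier exclusion, complex-domain hypothesis tests (T2circ and its
factorial extension), dB summation ratios, and bootstrap standard errors.

Spectral scaling convention: one-sided spectrum scaled 2/N (DC scaled 1/N,
Nyquist 1/N), so that a sinusoid A*sin(2*pi*f*t + phi) completing an
integer number of cycles in the window appears with |bin(f)| == A.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Epoch",
    "SpectralEstimate",
    "CircStatResult",
    "epoch_trial",
    "amplitude_spectrum",
    "coherent_mean",
    "mahalanobis_filter",
    "tcirc2",
    "anova2circ",
    "ratio_db",
    "bootstrap_se",
]


@dataclass(frozen=True)
class Epoch:
    """A fixed-duration analysis window cut from one trial."""

    samples: np.ndarray
    rate: float
    t0: float = 0.0  # seconds skipped after stimulus onset

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass(frozen=True)
class SpectralEstimate:
    """One-sided complex amplitude spectrum of an epoch.

    ``bins[k]`` is the complex amplitude at frequency ``k * resolution``;
    resolution is 1/duration (0.1 Hz for 10-s epochs).
    """

    bins: np.ndarray
    resolution: float
    scaling: str = "sine-amplitude"

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(len(self.bins)) * self.resolution

    def at(self, freq_hz: float) -> complex:
        """Complex amplitude at a frequency (must sit on the bin grid)."""
        k = freq_hz / self.resolution
        ki = int(round(k))
        if abs(k - ki) > 1e-6 or not 0 <= ki < len(self.bins):
            raise ValueError(f"{freq_hz} Hz is not on the {self.resolution} Hz bin grid")
        return complex(self.bins[ki])


@dataclass(frozen=True)
class CircStatResult:
    """An F-distributed statistic on complex-valued data."""

    statistic: float
    df1: int
    df2: int
    p: float


def epoch_trial(raw: np.ndarray, rate: float, skip_s: float = 2.0, keep_s: float = 10.0) -> Epoch:
    """Extract the steady-state window of a trial, omitting the onset.

    The first ``skip_s`` seconds (onset transient) are discarded and exactly
    ``keep_s`` seconds are kept.
    """
    raw = np.asarray(raw, dtype=float)
    start = int(round(skip_s * rate))
    n = int(round(keep_s * rate))
    if len(raw) < start + n:
        raise ValueError(
            f"trial too short: need {start + n} samples ({skip_s}+{keep_s} s at "
            f"{rate} Hz), got {len(raw)}"
        )
    return Epoch(samples=raw[start : start + n], rate=rate, t0=skip_s)


def amplitude_spectrum(epoch: Epoch) -> SpectralEstimate:
    """Complex one-sided spectrum in sine-amplitude units.

    The phase convention follows numpy's rfft of the raw samples; only
    relative phase across trials/conditions is meaningful downstream.
    """
    x = np.asarray(epoch.samples, dtype=float)
    n = len(x)
    spec = np.fft.rfft(x)
    scale = np.full(len(spec), 2.0 / n)
    scale[0] = 1.0 / n
    if n % 2 == 0:
        scale[-1] = 1.0 / n  # Nyquist bin is not duplicated in the two-sided spectrum
    return SpectralEstimate(bins=spec * scale, resolution=epoch.rate / n)


def coherent_mean(values: Sequence[complex]) -> complex:
    """Arithmetic mean of complex amplitudes (phase-retaining average)."""
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("coherent_mean of an empty set")
    return complex(values.mean())


def mahalanobis_filter(
    values: Sequence[complex], threshold: float = 3.0, min_points: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass Mahalanobis outlier exclusion in the complex plane.

    Each point's distance from the sample mean is computed in the
    (real, imag) plane under the sample covariance; points with D >
    ``threshold`` are excluded. Groups smaller than ``min_points`` are
    passed through unchanged (the covariance estimate is too unstable).
    A singular covariance falls back to pooled isotropic variance.

    Returns
    -------
    retained : complex array
    excluded : int array of excluded indices
    """
    values = np.asarray(values, dtype=complex)
    if values.size < min_points:
        return values, np.array([], dtype=int)
    xy = np.column_stack([values.real, values.imag])
    mu = xy.mean(axis=0)
    dev = xy - mu
    cov = np.cov(xy, rowvar=False)
    try:
        cov_inv = np.linalg.inv(cov)
        if not np.all(np.isfinite(cov_inv)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        pooled = float(np.mean(dev**2))  # isotropic fallback: pooled mean square
        if pooled == 0:
            return values, np.array([], dtype=int)
        cov_inv = np.eye(2) / pooled
    d2 = np.einsum("ij,jk,ik->i", dev, cov_inv, dev)
    keep = np.sqrt(np.maximum(d2, 0.0)) <= threshold
    return values[keep], np.flatnonzero(~keep)


def tcirc2(values: Sequence[complex]) -> CircStatResult:
    """Test of zero mean for complex data with isotropic Gaussian noise.

    For M complex samples with equal, independent real/imaginary variance,

        T2circ = M * (M - 1) * |mean|^2 / sum |x_i - mean|^2

    is F(2, 2M-2) under the null hypothesis of zero population mean.
    """
    values = np.asarray(values, dtype=complex)
    M = values.size
    if M < 2:
        raise ValueError("tcirc2 needs at least 2 values")
    mean = values.mean()
    ss = float(np.sum(np.abs(values - mean) ** 2))
    if ss == 0:
        if abs(mean) == 0:
            raise ValueError("degenerate input: all values identically zero")
        return CircStatResult(statistic=np.inf, df1=2, df2=2 * M - 2, p=0.0)
    stat = M * (M - 1) * abs(mean) ** 2 / ss
    p = float(stats.f.sf(stat, 2, 2 * M - 2))
    return CircStatResult(statistic=float(stat), df1=2, df2=2 * M - 2, p=p)


def anova2circ(amplitudes: np.ndarray, factors: Sequence[str] = ("condition", "contrast")) -> dict[str, CircStatResult]:
    """Factorial extension of T2circ for complex-valued repeated measures.

    Parameters
    ----------
    amplitudes : complex array, shape (a, b, N) for a two-factor design or
        (b, N) for a one-factor design — the last axis is participants.
    factors : names for the design factors, outermost first.

    Notes
    -----
    The real and imaginary Fourier components are treated as a bivariate
    response with equal variance: each effect's sum of squares is computed
    on the complex cell means and tested against the pooled within-cell
    variability, with numerator and denominator degrees of freedom doubled
    relative to the corresponding univariate ANOVA. Participants enter as
    replicates within cells (error df = 2 * (n_obs - n_cells)); for the
    2 (condition) x 5 (contrast) x N=30 design this gives a contrast-effect
    df pair of (8, 580).
    """
    amps = np.asarray(amplitudes, dtype=complex)
    if amps.ndim == 2:
        amps = amps[None, :, :]
        factors = ("_dummy",) + tuple(factors[-1:])
    if amps.ndim != 3:
        raise ValueError("amplitudes must be (levels_A, levels_B, N) or (levels, N)")
    a, b, N = amps.shape
    if N < 2:
        raise ValueError("need at least 2 participants per cell")
    cell_means = amps.mean(axis=2)
    grand = amps.mean()
    mA = amps.mean(axis=(1, 2))
    mB = amps.mean(axis=(0, 2))
    ss_err = float(np.sum(np.abs(amps - cell_means[:, :, None]) ** 2))
    df_err = 2 * (a * b * N - a * b)
    if ss_err == 0:
        raise ValueError("zero within-cell variance; statistic undefined")
    ms_err = ss_err / df_err

    def effect(ss: float, df: int) -> CircStatResult:
        stat = (ss / df) / ms_err
        return CircStatResult(
            statistic=float(stat), df1=df, df2=df_err, p=float(stats.f.sf(stat, df, df_err))
        )

    out: dict[str, CircStatResult] = {}
    ss_B = float(N * a * np.sum(np.abs(mB - grand) ** 2))
    if a > 1:
        ss_A = float(N * b * np.sum(np.abs(mA - grand) ** 2))
        inter = cell_means - mA[:, None] - mB[None, :] + grand
        ss_AB = float(N * np.sum(np.abs(inter) ** 2))
        out[factors[0]] = effect(ss_A, 2 * (a - 1))
        out[factors[1]] = effect(ss_B, 2 * (b - 1))
        out[f"{factors[0]}:{factors[1]}"] = effect(ss_AB, 2 * (a - 1) * (b - 1))
    else:
        out[factors[-1]] = effect(ss_B, 2 * (b - 1))
    return out


def ratio_db(binoc: float, monoc: float) -> float:
    """Binocular:monocular amplitude ratio in decibels, 20*log10(b/m)."""
    if monoc <= 0:
        raise ValueError("monocular amplitude must be positive for a dB ratio")
    if binoc <= 0:
        raise ValueError("binocular amplitude must be positive for a dB ratio")
    return 20.0 * np.log10(binoc / monoc)


def bootstrap_se(
    values: Sequence[float] | np.ndarray,
    iterations: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Bootstrap standard error of the across-participant mean.

    Participants are resampled with replacement at the top level;
    the SE is the SD of the resampled means. Works on real or complex
    values (complex values are averaged coherently and the SD is taken
    over the resampled complex means' moduli deviations).
    """
    values = np.asarray(values)
    if values.shape[0] < 2:
        raise ValueError("bootstrap_se needs at least 2 participants")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, values.shape[0], size=(iterations, values.shape[0]))
    means = values[idx].mean(axis=1)
    if np.iscomplexobj(means):
        return float(np.abs(means - means.mean()).std())
    return float(means.std())
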