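"""Noise spectra, bandwidth-limited sigma, SNR and blockade fractions.

The current noise of a docked-sphere recording has a white floor plus a
low-frequency 1/f-type excess attributed to mechanical fluctuations of the
sphere; locking the sphere to the lipid coat suppresses the excess.  These
metrics quantify that: Welch power spectral densities, the RMS current
noise in a stated bandwidth, the signal-to-noise ratio (I_open - I_dock)
over sigma, and relative blockade fractions of current levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.signal

from .trace_synthesis import CurrentTrace

__all__ = [
    "NoiseSpectrum",
    "NoiseSummary",
    "psd",
    "sigma_at_bandwidth",
    "snr",
    "blockade_fraction",
    "fit_noise_model",
]


@dataclass
class NoiseSpectrum:
    """One-sided Welch PSD: frequencies (Hz) and density (pA^2/Hz)."""

    frequencies: np.ndarray
    density: np.ndarray
    segment_length: int
    n_averages: int

    def band_power(self, f_lo: float, f_hi: float) -> float:
        """Integrated power (pA^2) between two frequencies."""
        m = (self.frequencies >= f_lo) & (self.frequencies <= f_hi)
        return float(np.trapezoid(self.density[m], self.frequencies[m]))


@dataclass(frozen=True)
class NoiseSummary:
    """sigma in a stated bandwidth, SNR, and the pink/white decomposition
    S(f) = A/f^alpha + B."""

    sigma_pA: float
    bandwidth_hz: float
    snr: float
    pink_A: float
    white_B: float
    alpha: float


def _as_samples(trace) -> tuple[np.ndarray, float]:
    if isinstance(trace, CurrentTrace):
        return trace.samples, trace.sample_rate
    raise TypeError("psd/sigma metrics need a CurrentTrace (sample rate required)")


def psd(trace, segment_length: int = 2**14) -> NoiseSpectrum:
    """Averaged-periodogram (Welch) PSD with a Hann window and half overlap."""
    x, fs = _as_samples(trace)
    if segment_length > len(x):
        raise ValueError("segment longer than the trace")
    f, s = scipy.signal.welch(
        x, fs=fs, window="hann", nperseg=segment_length,
        noverlap=segment_length // 2, detrend="constant",
    )
    n_avg = max(1, (len(x) - segment_length // 2) // (segment_length // 2))
    return NoiseSpectrum(frequencies=f, density=s, segment_length=segment_length, n_averages=n_avg)


def sigma_at_bandwidth(trace, cutoff_hz: float) -> float:
    """RMS current noise (pA) after an ideal low-pass at ``cutoff_hz``.

    Implemented as a zero-phase brick-wall filter in the frequency domain
    (the mean is removed first), so white noise obeys the exact
    sqrt(bandwidth) scaling.
    """
    x, fs = _as_samples(trace)
    if not (0 < cutoff_hz <= fs / 2):
        raise ValueError("cutoff must lie in (0, Nyquist]")
    acq_cut = trace.acquisition.cutoff_hz
    if acq_cut and cutoff_hz > acq_cut * 1.0001:
        raise ValueError("cutoff exceeds the acquisition filter bandwidth")
    spec = np.fft.rfft(x - x.mean())
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    spec[freqs > cutoff_hz] = 0.0
    y = np.fft.irfft(spec, n=len(x))
    return float(y.std())


def snr(i_open_pA: float, i_dock_pA: float, sigma_pA: float) -> float:
    """Signal-to-noise ratio (I_open - I_dock) / sigma of the docking step."""
    if sigma_pA <= 0:
        raise ValueError("sigma must be positive")
    return (i_open_pA - i_dock_pA) / sigma_pA


def blockade_fraction(i_level_pA: float, i_open_pA: float) -> float:
    """Relative blockade 1 - I_level/I_open of a current level."""
    if i_open_pA == 0:
        raise ValueError("open-pore current must be nonzero")
    return 1.0 - i_level_pA / i_open_pA


def fit_noise_model(
    spectrum: NoiseSpectrum,
    f_lo: float = 1.0,
    f_hi: float = 1000.0,
    alpha: float | None = None,
) -> tuple[float, float, float]:
    """Least-squares pink/white decomposition S(f) = A/f^alpha + B.

    Fitted on log S over [f_lo, f_hi] (the band where the 1/f excess
    lives); ``alpha`` fixed if given, otherwise fitted.  Returns
    (A, B, alpha).
    """
    m = (spectrum.frequencies >= f_lo) & (spectrum.frequencies <= f_hi) & (spectrum.density > 0)
    f = spectrum.frequencies[m]
    s = spectrum.density[m]
    if len(f) < 4:
        raise ValueError("too few PSD points in the fit band")
    b0 = max(np.median(s[f > 0.5 * f_hi]), 1e-30)
    a0 = max((s[0] - b0) * f[0], 1e-30)

    if alpha is None:
        def model(fq, la, lb, al):
            return np.log(np.exp(la) / fq**al + np.exp(lb))
        p0 = [np.log(a0), np.log(b0), 1.0]
        bounds = ([-60, -60, 0.5], [60, 60, 1.5])
    else:
        def model(fq, la, lb):
            return np.log(np.exp(la) / fq**alpha + np.exp(lb))
        p0 = [np.log(a0), np.log(b0)]
        bounds = ([-60, -60], [60, 60])
    popt, _ = scipy.optimize.curve_fit(model, f, np.log(s), p0=p0, bounds=bounds, maxfev=20000)
    A = float(np.exp(popt[0]))
    B = float(np.exp(popt[1]))
    al = float(popt[2]) if alpha is None else float(alpha)
    return A, B, al


def summarize(
    trace,
    i_open_pA: float,
    i_dock_pA: float,
    bandwidth_hz: float = 10e3,
    segment_length: int = 2**14,
) -> NoiseSummary:
    """Convenience bundle: sigma at bandwidth, SNR and the PSD decomposition."""
    sigma = sigma_at_bandwidth(trace, bandwidth_hz)
    spec = psd(trace, segment_length=segment_length)
    A, B, al = fit_noise_model(spec)
    return NoiseSummary(
        sigma_pA=sigma,
        bandwidth_hz=bandwidth_hz,
        snr=snr(i_open_pA, i_dock_pA, sigma),
        pink_A=A,
        white_B=B,
        alpha=al,
    )
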