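"""Continuous-wavelet primitives shared by the spectral, EEG and coupling stages.

All time-frequency quantities in the pipeline are built on the analytic
Morlet wavelet (centre angular frequency omega0 = 6), evaluated in the
frequency domain on a geometric frequency grid (default 12 voices per
octave).  The cone of influence uses the standard e-folding time
sqrt(2) * scale.
"""

from __future__ import annotations

import numpy as np

OMEGA0 = 6.0
#: Fourier factor: scale s (seconds) for centre frequency f is FOURIER_FACTOR / f.
FOURIER_FACTOR = (OMEGA0 + np.sqrt(2.0 + OMEGA0**2)) / (4.0 * np.pi)


def freq_grid(f_lo: float, f_hi: float, voices_per_octave: int = 12) -> np.ndarray:
    """Geometric frequency grid covering (f_lo, f_hi], descending from f_hi.

    Returned ascending in frequency.  Always contains at least 2 points.
    """
    if not (0 < f_lo < f_hi):
        raise ValueError("need 0 < f_lo < f_hi")
    n_oct = np.log2(f_hi / f_lo)
    n = max(2, int(np.ceil(n_oct * voices_per_octave)) + 1)
    return f_hi * 2.0 ** (-np.linspace(n_oct, 0.0, n))


def cwt_morlet(x: np.ndarray, rate: float, freqs: np.ndarray) -> np.ndarray:
    """Analytic-Morlet CWT of one or several signals.

    Parameters
    ----------
    x : (n,) or (m, n) array
    rate : sampling rate, Hz
    freqs : (k,) centre frequencies, Hz

    Returns
    -------
    W : complex array (k, n) or (m, k, n)
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    m, n = X.shape
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    Fx = np.fft.fft(X - X.mean(axis=1, keepdims=True), nfft, axis=1)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, d=1.0 / rate)
    scales = FOURIER_FACTOR / np.asarray(freqs, dtype=float)  # seconds
    W = np.empty((m, scales.size, n), dtype=complex)
    pos = omega > 0
    for i, s in enumerate(scales):
        psi_hat = np.zeros(nfft)
        # L2-normalized analytic Morlet in the frequency domain
        psi_hat[pos] = (np.pi ** -0.25) * np.sqrt(2.0 * np.pi * s * rate) * np.exp(
            -0.5 * (s * omega[pos] - OMEGA0) ** 2
        )
        W[:, i, :] = np.fft.ifft(Fx * psi_hat, axis=1)[:, :n]
    return W[0] if single else W


def coi_mask(n: int, rate: float, freqs: np.ndarray) -> np.ndarray:
    """Boolean (k, n) mask, True where the sample is OUTSIDE the cone of
    influence (i.e. usable, not contaminated by the edges)."""
    t = np.arange(n) / rate
    edge = np.minimum(t, t[::-1])                       # distance to nearest edge, s
    efold = np.sqrt(2.0) * FOURIER_FACTOR / np.asarray(freqs, dtype=float)
    return edge[None, :] >= efold[:, None]


def band_indices(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Indices of grid frequencies inside the half-open band (lo, hi]."""
    lo, hi = band
    idx = np.where((freqs > lo) & (freqs <= hi + 1e-12))[0]
    if idx.size == 0:
        raise ValueError(f"no grid frequencies inside band ({lo}, {hi}]")
    return idx


def _smooth_time_real(row: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian time smoothing of (..., n) real data, approximated by three
    boxcar passes (matched total variance); O(n) regardless of sigma."""
    from scipy.ndimage import uniform_filter1d

    w = max(1, int(round(2.0 * sigma / np.sqrt(3.0))))
    if w <= 1:
        return row
    out = row
    for _ in range(3):
        out = uniform_filter1d(out, w, axis=-1, mode="reflect")
    return out


def smooth_scalogram(S: np.ndarray, rate: float, freqs: np.ndarray) -> np.ndarray:
    """Smoothing operator for coherence: scale-proportional Gaussian in time
    (sigma = one scale, triple-boxcar approximation) and a 3-point boxcar
    across scales.

    ``S`` has shape (..., k, n); smoothing is applied over the last two axes.
    """
    from scipy.ndimage import uniform_filter1d

    S = np.asarray(S)
    scales = FOURIER_FACTOR / np.asarray(freqs, dtype=float)
    out = np.empty_like(S)
    for i, s in enumerate(scales):
        sigma = s * rate
        row = S[..., i, :]
        if np.iscomplexobj(S):
            out[..., i, :] = _smooth_time_real(row.real, sigma) \
                + 1j * _smooth_time_real(row.imag, sigma)
        else:
            out[..., i, :] = _smooth_time_real(row, sigma)
    if S.shape[-2] >= 3:
        if np.iscomplexobj(S):
            out = uniform_filter1d(out.real, 3, axis=-2, mode="nearest") \
                + 1j * uniform_filter1d(out.imag, 3, axis=-2, mode="nearest")
        else:
            out = uniform_filter1d(out, 3, axis=-2, mode="nearest")
    return out
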