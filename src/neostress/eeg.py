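"""EEG features: delta-band CWT power and wavelet-leader multifractal
log-cumulants.

The multifractal summary follows the wavelet-leader formalism: the input
is integrated (cumulative sum) so that signals with increment-like
regularity — fractional Gaussian noise, band-passed EEG — acquire positive
Holder exponents, then a Daubechies-3 discrete wavelet transform is taken,
leaders are formed as suprema of coefficient magnitudes over the
3-neighbourhood at all finer scales, and the first two sample cumulants of
the log-leaders are regressed on scale (weights = number of leaders per
scale).  c1 estimates the dominant Hurst exponent; c2 (typically <= 0) the
width of the singularity spectrum, i.e. the amount of multifractality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt

from .records import UniformSeries, ValidationError
from .wavelets import band_indices, coi_mask, cwt_morlet, freq_grid

__all__ = ["LogCumulants", "DeltaPowerSeries", "delta_power",
           "eeg_epoch_stats", "log_cumulants"]

BAND_DELTA = (0.5, 4.0)


@dataclass(frozen=True)
class LogCumulants:
    c1: float
    c2: float
    j1: int
    j2: int
    n_leaders: tuple[int, ...]

    @property
    def missing(self) -> bool:
        return not (np.isfinite(self.c1) and np.isfinite(self.c2))


@dataclass
class DeltaPowerSeries:
    """Instantaneous power in the (0.5-4] Hz band of one EEG channel."""
    values: np.ndarray
    rate: float
    valid: np.ndarray     # True outside the cone of influence

    def as_series(self, t0: float = 0.0) -> UniformSeries:
        return UniformSeries(self.values, self.rate, t0)


def delta_power(eeg_channel: np.ndarray, rate: float,
                voices_per_octave: int = 12) -> DeltaPowerSeries:
    """|CWT|^2 summed over delta-band scales, per sample."""
    x = np.asarray(eeg_channel, dtype=float)
    if rate < 64.0:
        raise ValidationError("EEG rate must be >= 64 Hz for delta-band analysis")
    if x.size < 4 * rate:
        raise ValidationError("EEG segment too short for delta-band CWT")
    freqs = freq_grid(*BAND_DELTA, voices_per_octave)
    idx = band_indices(freqs, BAND_DELTA)
    W = cwt_morlet(x, rate, freqs)
    P = (np.abs(W[idx]) ** 2).sum(axis=0)
    valid = coi_mask(x.size, rate, freqs)[idx].all(axis=0)
    return DeltaPowerSeries(P, rate, valid)


def eeg_epoch_stats(values, valid=None) -> tuple[float, float]:
    """(mean, sample SD) of the slice, restricted to valid samples."""
    x = np.asarray(values, dtype=float)
    if valid is not None:
        x = x[np.asarray(valid, dtype=bool)]
    x = x[np.isfinite(x)]
    if x.size < 2:
        return (math.nan, math.nan)
    return (float(np.mean(x)), float(np.std(x, ddof=1)))


def _wavelet_leaders(x: np.ndarray, wavelet: str = "db3",
                     level: int | None = None) -> list[np.ndarray]:
    """Leaders per dyadic scale j = 1 (finest) .. level, from an L1-normalized DWT."""
    n = x.size
    J = int(np.floor(np.log2(n)))
    n2 = 2 ** J
    x = x[:n2]
    if level is None:
        level = max(3, J - 3)
    level = min(level, J)
    coeffs = pywt.wavedec(x, wavelet, mode="periodization", level=level)
    details = coeffs[1:][::-1]          # details[j-1] = scale j (finest first)
    leaders: list[np.ndarray] = []
    sup = None
    for j, d in enumerate(details, start=1):
        a = np.abs(d) * 2.0 ** (-j / 2.0)      # L2 -> L1 normalization
        if sup is None:
            sup = a
        else:
            prev = sup
            if prev.size % 2:
                prev = prev[:-1]
            child = np.maximum(prev[0::2], prev[1::2])
            m = min(child.size, a.size)
            sup = np.maximum(a[:m], child[:m])
        if sup.size >= 3:
            lead = np.maximum(np.maximum(sup[:-2], sup[1:-1]), sup[2:])
            leaders.append(lead)
        else:
            leaders.append(np.array([]))
    return leaders


def log_cumulants(signal, rate: float | None = None, j1: int = 3,
                  j2: int | None = None, wavelet: str = "db3") -> LogCumulants:
    """Wavelet-leader log-cumulants c1 (Hurst) and c2 (multifractality).

    The signal is demeaned and integrated before the transform; estimates
    come from a weighted linear regression of the per-scale cumulants of
    log-leaders against j*ln(2), over octaves ``j1 .. j2`` (default
    ``j2 = floor(log2 n) - 3``).  Returns NaN cumulants (flagged missing)
    when fewer than 3 usable scales are available.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 2 ** 10:
        return LogCumulants(math.nan, math.nan, j1, j1, ())
    walk = np.cumsum(x - x.mean())
    J = int(np.floor(np.log2(walk.size)))
    if j2 is None:
        j2 = J - 3
    j2 = min(j2, J)
    leaders = _wavelet_leaders(walk, wavelet, level=j2)
    if j2 - j1 + 1 < 3:
        return LogCumulants(math.nan, math.nan, j1, j2, ())
    js, C1, C2, nj = [], [], [], []
    for j in range(j1, j2 + 1):
        lead = leaders[j - 1]
        lead = lead[lead > 0]
        if lead.size < 4:
            continue
        ll = np.log(lead)
        js.append(j)
        C1.append(ll.mean())
        C2.append(ll.var())
        nj.append(lead.size)
    if len(js) < 3:
        return LogCumulants(math.nan, math.nan, j1, j2, ())
    js_a = np.asarray(js, dtype=float)
    w = np.asarray(nj, dtype=float)
    def wslope(y):
        y = np.asarray(y)
        W = w.sum()
        xm = (w * js_a).sum() / W
        ym = (w * y).sum() / W
        return float(((w * (js_a - xm) * (y - ym)).sum())
                     / ((w * (js_a - xm) ** 2).sum()))
    # cumulants grow linearly in j*ln2; regress on j, then divide by ln2
    c1 = wslope(C1) / math.log(2.0)
    c2 = wslope(C2) / math.log(2.0)
    return LogCumulants(float(c1), float(c2), j1, j2, tuple(nj))
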