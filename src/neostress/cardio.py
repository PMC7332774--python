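"""HRV and SpO2 features: temporal stats, CWT band powers, Poincare
descriptors and phase-rectified signal averaging (PRSA).

The tachogram is linearly interpolated onto a uniform 8 Hz grid before any
time-frequency analysis, so the high-frequency band (0.2-4] Hz stays below
Nyquist.  Spectral powers are |CWT|^2 sums over in-band scales of an
analytic Morlet transform; the mean and standard deviation of the HF and
LF powers, of the normalized HF fraction HF/(LF+HF) and of the LF/HF ratio
are taken per epoch over samples outside the cone of influence.

PRSA searches the whole event window for anchor points where the local
T-second mean decreases (or increases), averages 120-s fragments centred
on the anchors, and summarizes the averaged curve by its overall
least-squares slope and the slope over [anchor, anchor + T].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .records import Tachogram, UniformSeries, ValidationError
from .wavelets import band_indices, coi_mask, cwt_morlet, freq_grid

__all__ = [
    "SpectralSeries", "PoincareDescriptor", "PRSAProfile",
    "temporal_stats", "resample_uniform", "cwt_band_power",
    "spectral_epoch_features", "acf_first_zero", "poincare_features",
    "prsa", "prsa_feature_set",
]

BANDS_HRV = {"HF": (0.2, 4.0), "LF": (0.08, 0.2)}


@dataclass
class SpectralSeries:
    """Per-sample band powers on a uniform grid plus a validity mask."""
    rate: float
    t0: float
    hf: np.ndarray
    lf: np.ndarray
    valid: np.ndarray      # True outside the cone of influence (both bands)

    @property
    def hfnu(self) -> np.ndarray:
        tot = self.hf + self.lf
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.hf / tot, np.nan)

    @property
    def lfhf(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.hf > 0, self.lf / self.hf, np.nan)

    def index_range(self, start_s: float, end_s: float) -> tuple[int, int]:
        i0 = max(0, int(np.ceil((start_s - self.t0) * self.rate - 1e-9)))
        i1 = min(self.hf.size, int(np.ceil((end_s - self.t0) * self.rate - 1e-9)))
        return i0, max(i0, i1)


@dataclass(frozen=True)
class PoincareDescriptor:
    tau_lag: int
    sd1: float
    sd2: float
    cx: float
    cy: float


@dataclass
class PRSAProfile:
    T_s: float
    direction: str
    n_anchors: int
    curve: np.ndarray | None     # 120 s * rate + 1 samples, None when no anchors
    rate: float
    slope_ov: float = np.nan
    slope_ap: float = np.nan

    @property
    def missing(self) -> bool:
        return self.n_anchors == 0


def temporal_stats(values) -> tuple[float, float]:
    """(mean, sample SD). NaN pair when fewer than 2 samples."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return (math.nan, math.nan)
    return (float(np.mean(x)), float(np.std(x, ddof=1)))


def resample_uniform(source, rate: float = 8.0) -> UniformSeries:
    """Linear interpolation onto a uniform grid.

    Tachograms are interpreted as the function RR(t) sampled at the beat
    times; uniform series are interpolated from their own grid.
    """
    if isinstance(source, Tachogram):
        t, v = source.beat_times, source.rr
    elif isinstance(source, UniformSeries):
        t, v = source.times, source.values
    else:
        raise TypeError("expected Tachogram or UniformSeries")
    if t.size < 2:
        raise ValidationError("need at least 2 samples to resample")
    t0 = float(t[0])
    n = int(np.floor((t[-1] - t0) * rate)) + 1
    grid = t0 + np.arange(n) / rate
    return UniformSeries(np.interp(grid, t, v), rate=rate, t0=t0)


def cwt_band_power(series: UniformSeries, bands: dict | None = None,
                   voices_per_octave: int = 12) -> SpectralSeries:
    """Instantaneous HF and LF power of a uniform series via analytic-Morlet CWT."""
    bands = bands or BANDS_HRV
    if series.values.size < 64:
        raise ValidationError("series too short for CWT band power (need >= 64 samples)")
    nyq = series.rate / 2.0
    for name, (lo, hi) in bands.items():
        if hi > nyq:
            raise ValidationError(f"band {name} upper edge {hi} Hz above Nyquist {nyq} Hz")
    f_lo = min(lo for lo, _ in bands.values())
    f_hi = max(hi for _, hi in bands.values())
    freqs = freq_grid(f_lo, f_hi, voices_per_octave)
    W = cwt_morlet(series.values, series.rate, freqs)
    P = np.abs(W) ** 2
    valid = coi_mask(series.values.size, series.rate, freqs)
    out = {}
    band_valid = np.ones(series.values.size, dtype=bool)
    for name, band in bands.items():
        idx = band_indices(freqs, band)
        out[name] = P[idx].sum(axis=0)
        band_valid &= valid[idx].all(axis=0)
    return SpectralSeries(rate=series.rate, t0=series.t0,
                          hf=out["HF"], lf=out["LF"], valid=band_valid)


def spectral_epoch_features(spectral: SpectralSeries, start_s: float,
                            end_s: float) -> dict[str, float]:
    """Mean and SD of HF, LF, HFnu and LF/HF over in-epoch, non-cone samples."""
    i0, i1 = spectral.index_range(start_s, end_s)
    sel = spectral.valid[i0:i1]
    out = {}
    for name, arr in (("hf", spectral.hf), ("lf", spectral.lf),
                      ("hfnu", spectral.hfnu), ("lfhf", spectral.lfhf)):
        mu, sd = temporal_stats(arr[i0:i1][sel])
        out[f"mu_{name}"], out[f"sd_{name}"] = mu, sd
    return out


def acf_first_zero(values) -> tuple[int, bool]:
    """Smallest positive lag with non-positive unbiased sample ACF.

    Returns (lag, flagged); flagged means no crossing within n/2 and the
    lag was capped there.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 16:
        raise ValidationError("need >= 16 samples for the autocorrelation lag")
    x = x - x.mean()
    if np.allclose(x, 0):
        raise ValidationError("constant series has no autocorrelation zero")
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    acov = np.fft.irfft(np.abs(np.fft.rfft(x, nfft)) ** 2)[: n // 2 + 1]
    acov = acov / (n - np.arange(acov.size))        # unbiased
    nonpos = np.flatnonzero(acov[1:] <= 0)
    if nonpos.size:
        return int(nonpos[0] + 1), False
    return n // 2, True


def poincare_features(values) -> PoincareDescriptor:
    """Poincare-plot descriptors of a series against its tau-lagged copy.

    tau is the first zero of the autocorrelation; SD1/SD2 are the singular
    values of the column-centred matrix [x(t), x(t+tau)] scaled by
    1/sqrt(n-1) (minor / major axis SDs); Cx/Cy are the uncentred column
    means.  Constant series return all-zero SDs with centroid = constant.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 16:
        raise ValidationError("need >= 16 samples for Poincare analysis")
    if np.allclose(x, x[0]):
        return PoincareDescriptor(1, 0.0, 0.0, float(x[0]), float(x[0]))
    tau, _ = acf_first_zero(x)
    tau = max(1, min(tau, x.size - 2))
    X = np.column_stack((x[:-tau], x[tau:]))
    cx, cy = X.mean(axis=0)
    Xc = X - X.mean(axis=0)
    sv = np.linalg.svd(Xc, compute_uv=False) / np.sqrt(X.shape[0] - 1)
    return PoincareDescriptor(int(tau), float(sv[1]), float(sv[0]), float(cx), float(cy))


def prsa(series: UniformSeries, T_s: float, direction: str = "down",
         fragment_half_s: float = 60.0) -> PRSAProfile:
    """Phase-rectified signal average of a uniform series.

    Anchors sit at samples i where mean(x[i : i+T]) < mean(x[i-T : i]) for
    ``direction='down'`` (> for 'up'); 120-s fragments centred on the
    anchors (edge-crossing fragments dropped) are averaged.
    """
    if direction not in ("down", "up"):
        raise ValidationError("direction must be 'down' or 'up'")
    x = series.values
    rate = series.rate
    if x.size < 360 * rate:
        raise ValidationError("PRSA needs at least 360 s of signal")
    T = max(1, int(round(T_s * rate)))
    csum = np.concatenate(([0.0], np.cumsum(x)))
    i = np.arange(T, x.size - T + 1)
    after = csum[i + T] - csum[i]
    before = csum[i] - csum[i - T]
    anchors = i[after < before] if direction == "down" else i[after > before]
    half = int(round(fragment_half_s * rate))
    anchors = anchors[(anchors >= half) & (anchors + half < x.size)]
    L = 2 * half + 1
    if anchors.size == 0:
        return PRSAProfile(T_s, direction, 0, None, rate)
    idx = anchors[:, None] + np.arange(-half, half + 1)[None, :]
    curve = x[idx].mean(axis=0)
    t = np.arange(L) / rate
    slope_ov = float(np.polyfit(t, curve, 1)[0])
    j0, j1 = half, min(L - 1, half + T)
    slope_ap = float(np.polyfit(t[j0:j1 + 1], curve[j0:j1 + 1], 1)[0]) if j1 > j0 else math.nan
    return PRSAProfile(T_s, direction, int(anchors.size), curve, rate,
                       slope_ov=slope_ov, slope_ap=slope_ap)


def prsa_feature_set(series: UniformSeries, T_list, direction: str = "down") -> dict[str, float]:
    """(Slope_OV, Slope_AP) per T over the whole event window: 2*len(T_list) values."""
    out: dict[str, float] = {}
    for T_s in T_list:
        prof = prsa(series, T_s, direction)
        key = f"T{T_s:g}"
        out[f"slope_ov_{key}"] = prof.slope_ov if not prof.missing else math.nan
        out[f"slope_ap_{key}"] = prof.slope_ap if not prof.missing else math.nan
    return out
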