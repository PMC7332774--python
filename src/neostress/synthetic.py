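"""Synthetic neonatal cohorts with controllable stress effect sizes.

The clinical recordings this pipeline was designed for are not publicly
deposited, so this module generates cohorts of
:class:`~neostress.records.PolygraphicRecord` objects that reproduce the
statistical structure the analysis relies on:

* a tachogram with low- and high-frequency autonomic modulation and
  injected raised-cosine bradycardias;
* SpO2 with slow oximeter noise (AR(1)) and V-shaped desaturations
  co-timed with the bradycardias;
* 8-channel EEG made of a fractional (scale-free) background plus a
  delta-band oscillation whose amplitude envelope shares a band-limited
  random process with the RR modulation, at a 90-degree phase offset so
  that the coupling has a purely imaginary coherence signature.

Stress effects are injected through four independent dials
(:class:`EffectSpec`): deeper desaturations, a higher EEG self-similarity
(Hurst) exponent, stronger EEG-RR coupling, and (for the PSG group) a
relative change of high-frequency RR power.  Setting all four to zero
yields a null cohort in which stressed and non-stressed records are
statistically indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .records import (
    EEG_CHANNELS,
    GROUPS,
    PolygraphicRecord,
    Tachogram,
    UniformSeries,
    ValidationError,
)

__all__ = [
    "EffectSpec",
    "CohortSpec",
    "OverlapError",
    "generate_fractional_signal",
    "generate_mrw",
    "inject_bradycardia",
    "inject_desaturation",
    "generate_subject",
    "generate_cohort",
]


class OverlapError(ValueError):
    """An injected event would overlap an existing excursion."""


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------

@dataclass
class EffectSpec:
    """Stress effect sizes; all zero produces a null cohort.

    desat_depth_shift_pct
        Extra desaturation depth (percentage points) in stressed subjects.
    eeg_hurst_shift
        Increase of the EEG background Hurst exponent under stress.
    coupling_shift
        Increase of the shared-envelope weight linking the EEG delta
        amplitude to the RR modulation band under stress.
    hf_power_shift
        Relative change of high-frequency RR modulation power under
        stress, applied in the PSG group only.
    """

    desat_depth_shift_pct: float = 4.0
    eeg_hurst_shift: float = 0.15
    coupling_shift: float = 0.2
    hf_power_shift: float = 0.5

    def __post_init__(self) -> None:
        for name in ("desat_depth_shift_pct", "eeg_hurst_shift",
                     "coupling_shift", "hf_power_shift"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")

    @classmethod
    def null(cls) -> "EffectSpec":
        return cls(0.0, 0.0, 0.0, 0.0)

    def scaled(self, factor: float) -> "EffectSpec":
        return EffectSpec(self.desat_depth_shift_pct * factor,
                          self.eeg_hurst_shift * factor,
                          self.coupling_shift * factor,
                          self.hf_power_shift * factor)


@dataclass
class CohortSpec:
    """Cohort-level structure: sizes, durations, event frequency, baselines."""

    n_subjects_per_group: int = 10
    record_duration_s: float = 3600.0
    events_per_subject_mean: float = 8.0
    baseline_rr_s: float = 0.42
    baseline_spo2_pct: float = 96.0
    eeg_rate_hz: float = 256.0
    window_half_s: float = 180.0
    # baseline (non-stressed) physiology
    eeg_hurst_base: float = 0.55
    coupling_base: float = 0.35
    desat_depth_base_pct: float = 12.0
    desat_depth_sd_pct: float = 2.0
    spo2_noise_sd_pct: float = 0.3
    spo2_noise_rho: float = 0.9
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.record_duration_s < 360.0:
            raise ValidationError("record_duration_s must be >= 360 s")
        if self.events_per_subject_mean <= 0:
            raise ValidationError("events_per_subject_mean must be positive")


# --------------------------------------------------------------------------
# Scale-free generators
# --------------------------------------------------------------------------

def _circulant_gaussian(autocov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Stationary Gaussian series with the given autocovariance (Davies-Harte
    circulant embedding; tiny negative embedding eigenvalues are clipped)."""
    n = autocov.size
    m = int(2 ** np.ceil(np.log2(2 * max(n - 1, 1))))
    row = np.zeros(m)
    row[:n] = autocov
    row[m - n + 1:] = autocov[1:][::-1]
    lam = np.clip(np.fft.fft(row).real, 0.0, None)
    u = rng.standard_normal(m // 2 + 1)
    v = rng.standard_normal(m // 2 + 1)
    a = np.zeros(m, dtype=complex)
    a[0] = u[0] * np.sqrt(lam[0] / m)
    a[m // 2] = u[m // 2] * np.sqrt(lam[m // 2] / m)
    j = np.arange(1, m // 2)
    a[j] = (u[j] + 1j * v[j]) * np.sqrt(lam[j] / (2 * m))
    a[m - j] = np.conj(a[j])
    return np.fft.fft(a).real[:n]


def _fgn(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise by circulant embedding (unit variance)."""
    if not 0.0 < hurst < 1.0:
        raise ValidationError(f"hurst must lie in (0, 1), got {hurst}")
    if abs(hurst - 0.5) < 1e-12:
        return rng.standard_normal(n)
    k = np.arange(n)
    gamma = 0.5 * (np.abs(k + 1) ** (2 * hurst) - 2 * np.abs(k) ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    return _circulant_gaussian(gamma, rng)


def generate_fractional_signal(n_samples: int, hurst: float, seed,
                               rate: float = 1.0) -> UniformSeries:
    """Fractional Gaussian noise whose wavelet-leader c1 estimate converges
    to ``hurst`` and whose c2 is ~0 (monofractal)."""
    if n_samples < 1024:
        raise ValidationError("n_samples must be >= 1024")
    rng = np.random.default_rng(seed)
    return UniformSeries(_fgn(int(n_samples), hurst, rng), rate=rate)


def generate_mrw(n_samples: int, lambda2: float, seed,
                 rate: float = 1.0, corr_length: int | None = None) -> UniformSeries:
    """Multifractal-random-walk increments: Gaussian noise modulated by a
    log-normal cascade with intermittency ``lambda2`` (expected c2 = -lambda2)."""
    n = int(n_samples)
    rng = np.random.default_rng(seed)
    L = corr_length if corr_length is not None else n
    k = np.arange(n, dtype=float)
    cov = np.clip(np.where(k < L, lambda2 * np.log(L / (1.0 + k)), 0.0), 0.0, None)
    omega = _circulant_gaussian(cov, rng)
    omega -= omega.mean()
    eps = rng.standard_normal(n) * np.exp(omega)
    return UniformSeries(eps, rate=rate)


def _band_noise(n: int, rate: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to (lo, hi] Hz."""
    lo, hi = band
    w = rng.standard_normal(n)
    F = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    F[(f <= lo) | (f > hi)] = 0.0
    x = np.fft.irfft(F, n)
    sd = x.std()
    return x / sd if sd > 0 else x


# --------------------------------------------------------------------------
# Event injection
# --------------------------------------------------------------------------

def inject_bradycardia(tachogram: Tachogram, t_peak: float, depth_factor: float,
                       duration_s: float) -> Tachogram:
    """Inject a raised-cosine RR elongation peaking at ``depth_factor`` times
    the local RR, centred at ``t_peak``, and re-time all subsequent beats.

    The record's total duration grows by the added RR mass
    (depth_factor - 1) * mean_rr_local * duration_s / 2 (the raised-cosine
    integral), so downstream invariants on beat-time/RR consistency hold.
    """
    if depth_factor <= 1.0:
        raise ValidationError("depth_factor must exceed 1")
    t0, t1 = t_peak - duration_s / 2.0, t_peak + duration_s / 2.0
    if t0 <= tachogram.beat_times[0] or t1 >= tachogram.beat_times[-1]:
        raise ValidationError("bradycardia window falls outside the record")
    inside = (tachogram.beat_times >= t0) & (tachogram.beat_times <= t1)
    if not np.any(inside):
        raise ValidationError("no beats inside the bradycardia window")
    if np.max(tachogram.rr[inside]) > 1.25 * np.median(tachogram.rr):
        raise OverlapError("window already contains an RR excursion")
    profile = np.zeros_like(tachogram.rr)
    tb = tachogram.beat_times[inside]
    profile[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * (tb - t_peak) / duration_s))
    rr_new = tachogram.rr * (1.0 + (depth_factor - 1.0) * profile)
    start = tachogram.beat_times[0] - tachogram.rr[0]
    beat_times = start + rr_new[0] + np.concatenate(([0.0], np.cumsum(rr_new[1:])))
    return Tachogram(beat_times, rr_new)


def inject_desaturation(spo2: UniformSeries, t_nadir: float, depth_pct: float,
                        duration_s: float) -> UniformSeries:
    """Subtract a V-shaped dip of ``depth_pct`` below the running signal,
    clipped to stay >= 0.  ``depth_pct = 0`` is the identity."""
    if depth_pct < 0:
        raise ValidationError("depth_pct must be >= 0")
    if depth_pct == 0:
        return UniformSeries(spo2.values.copy(), spo2.rate, spo2.t0)
    t = spo2.times
    if t_nadir - duration_s / 2 < t[0] or t_nadir + duration_s / 2 > t[-1]:
        raise ValidationError("desaturation window falls outside the record")
    inside = np.abs(t - t_nadir) < duration_s / 2.0
    if np.min(spo2.values[inside]) < np.median(spo2.values) - 2.0:
        raise OverlapError("window already contains a desaturation")
    dip = np.zeros_like(spo2.values)
    dip[inside] = depth_pct * (1.0 - np.abs(t[inside] - t_nadir) / (duration_s / 2.0))
    return UniformSeries(np.clip(spo2.values - dip, 0.0, 100.0), spo2.rate, spo2.t0)


# --------------------------------------------------------------------------
# Subject / cohort generation
# --------------------------------------------------------------------------

#: PMA draws per monitoring group (weeks): mean, sd — anchored at typical
#: preterm demographics at each measuring point.
_PMA_BY_GROUP = {"5days": (32.1, 1.5), "34weeks": (34.1, 0.5), "PSG": (38.4, 1.0)}
_COUPLING_BAND_BY_GROUP = {"5days": (0.033, 0.08), "34weeks": (0.08, 0.2),
                           "PSG": (0.08, 0.2)}


def _event_times(duration_s: float, n_events: int, window_half_s: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Well-separated event peak times: margin window_half+30 at the edges,
    minimum spacing 2*window_half."""
    margin = window_half_s + 30.0
    spacing = 2.0 * window_half_s
    lo, hi = margin, duration_s - margin
    if hi <= lo:
        raise ValidationError("record too short for any event")
    capacity = int((hi - lo) // spacing) + 1
    n = min(n_events, capacity)
    for _ in range(200):
        t = np.sort(rng.uniform(lo, hi, size=n))
        if n == 1 or np.min(np.diff(t)) >= spacing:
            return t
    return lo + np.arange(n) * (hi - lo) / max(n - 1, 1)  # even fallback


def generate_subject(cohort_spec: CohortSpec, effect_spec: EffectSpec,
                     stressed: bool, group: str, seed,
                     n_events: int | None = None) -> PolygraphicRecord:
    """Generate one subject's PolygraphicRecord.

    ``n_events`` overrides the Poisson draw (0 gives an injection-free
    record, useful for specificity checks).
    """
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    D = cohort_spec.record_duration_s
    fs8 = 8.0
    n8 = int(round(D * fs8))
    t8 = np.arange(n8) / fs8

    # shared coupling process (group band) and its 90-degree shifted copy
    band = _COUPLING_BAND_BY_GROUP[group]
    s = _band_noise(n8, fs8, band, rng)
    s_lag = np.imag(hilbert(s))          # quarter-period lag -> imaginary coherence

    # --- tachogram ----------------------------------------------------
    hf_amp = 0.015
    if stressed and group == "PSG":
        hf_amp *= (1.0 + effect_spec.hf_power_shift)
    h = _band_noise(n8, fs8, (0.2, 0.5), rng)
    rr_mod = 1.0 + 0.02 * s + hf_amp * h
    rr_mod = np.clip(rr_mod, 0.5, 1.5)
    beats = []
    t = cohort_spec.baseline_rr_s
    while t < D:
        k = min(int(t * fs8), n8 - 1)
        rr_t = cohort_spec.baseline_rr_s * rr_mod[k]
        beats.append((t, rr_t))
        t += rr_t
    beat_times = np.array([b[0] for b in beats])
    rr = np.empty_like(beat_times)
    rr[0] = beat_times[0]
    rr[1:] = np.diff(beat_times)
    tach = Tachogram(beat_times, rr)

    # --- events -------------------------------------------------------
    if n_events is None:
        n_events = max(1, int(rng.poisson(cohort_spec.events_per_subject_mean)))
    peaks = (_event_times(D, n_events, cohort_spec.window_half_s, rng)
             if n_events > 0 else np.array([]))
    for tp in peaks:
        depth = rng.uniform(1.8, 2.2)
        dur = rng.uniform(6.0, 12.0)
        tach = inject_bradycardia(tach, tp, depth, dur)

    # --- SpO2 ---------------------------------------------------------
    n1 = int(round(D))
    ar = np.empty(n1)
    ar[0] = rng.standard_normal() * cohort_spec.spo2_noise_sd_pct
    innov_sd = cohort_spec.spo2_noise_sd_pct * np.sqrt(1 - cohort_spec.spo2_noise_rho**2)
    eps = rng.standard_normal(n1) * innov_sd
    for i in range(1, n1):
        ar[i] = cohort_spec.spo2_noise_rho * ar[i - 1] + eps[i]
    spo2 = UniformSeries(np.clip(cohort_spec.baseline_spo2_pct + ar, 0, 100), 1.0)
    for tp in peaks:
        depth = rng.normal(cohort_spec.desat_depth_base_pct,
                           cohort_spec.desat_depth_sd_pct)
        if stressed:
            depth += effect_spec.desat_depth_shift_pct
        depth = float(np.clip(depth, 4.0, 40.0))
        t_nadir = tp + rng.uniform(2.0, 8.0)
        dur = rng.uniform(30.0, 50.0)
        spo2 = inject_desaturation(spo2, t_nadir, depth, dur)

    # --- EEG ----------------------------------------------------------
    fs = cohort_spec.eeg_rate_hz
    n_eeg = int(round(D * fs))
    hurst = cohort_spec.eeg_hurst_base + (effect_spec.eeg_hurst_shift if stressed else 0.0)
    if not 0.0 < hurst < 1.0:
        raise ValidationError(f"effective EEG Hurst {hurst} outside (0, 1)")
    k_couple = cohort_spec.coupling_base + (effect_spec.coupling_shift if stressed else 0.0)
    env = np.clip(1.0 + k_couple * np.interp(np.arange(n_eeg) / fs, t8, s_lag), 0.05, None)
    eeg = np.empty((len(EEG_CHANNELS), n_eeg))
    for c in range(len(EEG_CHANNELS)):
        background = 20.0 * _fgn(n_eeg, hurst, rng)
        carrier = _band_noise(n_eeg, fs, (0.5, 4.0), rng)
        eeg[c] = background + 6.0 * carrier * env

    pma_mu, pma_sd = _PMA_BY_GROUP[group]
    pma = float(np.clip(rng.normal(pma_mu, pma_sd), 24.0, 45.0))
    return PolygraphicRecord(
        subject_id=str(seed) if not isinstance(seed, (int, np.integer)) else f"S{seed}",
        eeg=eeg, channel_names=EEG_CHANNELS, eeg_rate=fs,
        tachogram=tach, spo2=spo2, pma_weeks=pma, group=group,
        stress_label=bool(stressed),
    )


def generate_cohort(cohort_spec: CohortSpec, effect_spec: EffectSpec,
                    seed) -> list[PolygraphicRecord]:
    """Generate all three monitoring groups, half stressed per group
    (rounded down for odd sizes); per-subject seeds derive deterministically
    from the master seed."""
    n = cohort_spec.n_subjects_per_group
    if n < 2:
        raise ValidationError("need at least 2 subjects per group")
    root = np.random.SeedSequence(seed)
    records: list[PolygraphicRecord] = []
    idx = 0
    for group in GROUPS:
        n_stressed = n // 2
        for j in range(n):
            stressed = j < n_stressed
            child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(idx,))
            rec = generate_subject(cohort_spec, effect_spec, stressed, group, child)
            rec.subject_id = f"{group}_{j:02d}"
            records.append(rec)
            idx += 1
    return records
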