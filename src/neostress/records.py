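"""Core data model for neonatal polygraphic recordings.

A recording couples three simultaneously acquired signals: an 8-channel
monopolar EEG (referenced to Cz), the RR tachogram derived from the ECG,
and pulse-oximetry SpO2, together with the clinical metadata needed by the
stress classifier (post-menstrual age, monitoring group, and the stress
label, i.e. any non-zero pain score the day before the recording).

Conventions
-----------
* Time is in seconds from record start; sample indices are 0-based.
* An RR interval ``rr[i]`` ends at ``beat_times[i]``, so successive
  beat-time differences equal the RR intervals.
* All epoch/window intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("neostress")

#: Canonical EEG montage order (Cz-referenced monopolar channels).
EEG_CHANNELS = ("Fp1", "Fp2", "C3", "C4", "T3", "T4", "O1", "O2")

#: Monitoring groups: around day 5 of life, around 34 weeks PMA, and the
#: pre-discharge polysomnography.
GROUPS = ("5days", "34weeks", "PSG")

#: Physiologically plausible RR range (s); beats outside are treated as
#: artifacts and dropped at ingest.
RR_RANGE_S = (0.2, 2.0)


class ValidationError(ValueError):
    """A record or configuration violates a structural invariant."""


@dataclass
class Tachogram:
    """RR-interval series: ``rr[i]`` (s) is the interval ending at ``beat_times[i]`` (s)."""

    beat_times: np.ndarray
    rr: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.beat_times.shape != self.rr.shape or self.beat_times.ndim != 1:
            raise ValidationError("beat_times and rr must be 1-D arrays of equal length")
        if self.beat_times.size and not np.all(np.diff(self.beat_times) > 0):
            raise ValidationError("beat_times must be strictly increasing")
        if np.any(self.rr <= 0):
            raise ValidationError("RR intervals must be positive")
        if self.beat_times.size > 1:
            drift = np.abs(np.diff(self.beat_times) - self.rr[1:])
            if np.max(drift) > 1e-3:
                raise ValidationError(
                    f"beat-time differences deviate from RR by {np.max(drift):.4g} s (> 1 ms)"
                )

    @property
    def mean_rr(self) -> float:
        """Mean RR interval of the entire tachogram (s)."""
        return float(np.mean(self.rr))

    @property
    def duration_s(self) -> float:
        return float(self.beat_times[-1]) if self.beat_times.size else 0.0

    def copy(self) -> "Tachogram":
        return Tachogram(self.beat_times.copy(), self.rr.copy())

    @classmethod
    def from_rr(cls, rr, t0: float = 0.0) -> "Tachogram":
        """Build a tachogram from RR intervals alone; the first beat falls at ``t0 + rr[0]``."""
        rr = np.asarray(rr, dtype=float)
        return cls(t0 + np.cumsum(rr), rr)


@dataclass
class UniformSeries:
    """A uniformly sampled signal: ``values[k]`` is taken at ``t0 + k / rate`` seconds."""

    values: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValidationError("rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("series values must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate

    def slice_time(self, start_s: float, end_s: float) -> np.ndarray:
        """Values in the half-open time interval [start_s, end_s)."""
        i0 = max(0, int(np.ceil((start_s - self.t0) * self.rate - 1e-9)))
        i1 = min(self.values.size, int(np.ceil((end_s - self.t0) * self.rate - 1e-9)))
        return self.values[i0:max(i0, i1)]

    def index_range(self, start_s: float, end_s: float) -> tuple[int, int]:
        i0 = max(0, int(np.ceil((start_s - self.t0) * self.rate - 1e-9)))
        i1 = min(self.values.size, int(np.ceil((end_s - self.t0) * self.rate - 1e-9)))
        return i0, max(i0, i1)


@dataclass
class PolygraphicRecord:
    """One subject's synchronized EEG / tachogram / SpO2 recording plus metadata."""

    subject_id: str
    eeg: np.ndarray                      # (8, n_samples), microvolts
    channel_names: tuple[str, ...]
    eeg_rate: float
    tachogram: Tachogram
    spo2: UniformSeries                  # percent, 1 Hz
    pma_weeks: float
    group: str
    stress_label: bool

    MIN_DURATION_S = 360.0

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.eeg.ndim != 2 or self.eeg.shape[0] != len(EEG_CHANNELS):
            missing = [c for c in EEG_CHANNELS if c not in self.channel_names]
            raise ValidationError(
                f"EEG must have {len(EEG_CHANNELS)} channels; missing: {missing or self.eeg.shape}"
            )
        if set(self.channel_names) != set(EEG_CHANNELS):
            missing = [c for c in EEG_CHANNELS if c not in self.channel_names]
            raise ValidationError(f"missing EEG channels: {missing}")
        if self.channel_names != EEG_CHANNELS:
            order = [self.channel_names.index(c) for c in EEG_CHANNELS]
            self.eeg = self.eeg[order]
            self.channel_names = EEG_CHANNELS
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not (24.0 <= self.pma_weeks <= 45.0):
            raise ValidationError(f"pma_weeks {self.pma_weeks} outside [24, 45]")
        if np.any(self.spo2.values < 0) or np.any(self.spo2.values > 100):
            raise ValidationError("SpO2 values must lie in [0, 100]")
        if self.common_duration_s < self.MIN_DURATION_S:
            raise ValidationError(
                f"signals must cover >= {self.MIN_DURATION_S:.0f} s, got {self.common_duration_s:.1f} s"
            )

    @property
    def eeg_duration_s(self) -> float:
        return self.eeg.shape[1] / self.eeg_rate

    @property
    def common_duration_s(self) -> float:
        return min(self.eeg_duration_s, self.tachogram.duration_s, self.spo2.duration_s)


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

#: Frequency bands (Hz, half-open (lo, hi]) used across the pipeline.
BAND_DELTA = (0.5, 4.0)
BAND_HF = (0.2, 4.0)
BAND_LF = (0.08, 0.2)
BAND_VLF = (0.033, 0.08)

#: Coupling band per monitoring group: the autonomic rhythms shift from the
#: very-low- to the low-frequency band as the nervous system matures.
GROUP_COUPLING_BAND = {"5days": BAND_VLF, "34weeks": BAND_LF, "PSG": BAND_LF}


@dataclass
class PipelineConfig:
    """Tunable parameters of the event-detection / feature / classifier pipeline.

    Defaults follow the study protocol: bradycardia = RR elongation above
    1.5x the record-mean RR sustained for at least 4 s; desaturation depth
    thresholds of 3, 5 or 10 %; a 3-minute window on each side of the
    bradycardia peak; 19 amplitude-adjusted Fourier-transform surrogates
    (one-sided alpha = 0.05); and an LDA subspace ensemble whose per-learner
    feature count is capped at one tenth of the training events.
    """

    desat_thresholds_pct: tuple[float, ...] = (3.0, 5.0, 10.0)
    brady_factor: float = 1.5
    brady_min_dur_s: float = 4.0
    brady_merge_gap_beats: int = 5
    stationarity_factor: float = 1.1
    stationarity_beats: int = 5
    window_half_s: float = 180.0
    pair_before_s: float = 30.0
    pair_after_s: float = 60.0
    desat_baseline_window_s: float = 60.0
    eeg_band: tuple[float, float] = (1.0, 20.0)
    prsa_T_list: tuple[float, ...] = (1.0, 5.0, 10.0, 20.0, 50.0, 100.0)
    resample_rate_hz: float = 8.0
    n_surrogates: int = 19
    voices_per_octave: int = 12
    eeg_node_kind: str = "delta_power"   # or "delta_bandpass"
    nsup_objective: str = "H+E"          # or "H-E"
    rng_seed: int = 0
    # classifier settings
    ensemble_size: int = 30
    ensemble_grid: tuple[int, ...] = (15, 30, 60)
    tune_ensemble: bool = True
    subspace_fraction: float = 0.1
    correlation_cap: float = 0.9
    preselect_multiple: int = 3
    cv_folds: int = 10
    lda_shrinkage: float = 0.1
    kappa_threshold: float = 0.5

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.desat_thresholds_pct):
            raise ValidationError("desaturation thresholds must be positive")
        if self.brady_factor <= 1.0 or self.brady_min_dur_s <= 0:
            raise ValidationError("bradycardia thresholds must be positive (factor > 1)")
        lo, hi = self.eeg_band
        if not (0 < lo < hi):
            raise ValidationError("eeg_band must satisfy 0 < lo < hi")
        if self.nsup_objective not in ("H+E", "H-E"):
            raise ValidationError("nsup_objective must be 'H+E' or 'H-E'")

    def coupling_band(self, group: str) -> tuple[float, float]:
        return GROUP_COUPLING_BAND[group]

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            data = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key, value in data.items():
            if isinstance(value, list):
                data[key] = tuple(value)
        return cls(**data)
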