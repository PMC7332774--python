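"""Bradycardia / desaturation detection, pairing, and epoch segmentation.

A bradycardia is a maximal run of beats whose RR interval exceeds
``brady_factor`` (default 1.5) times the record-mean RR, with summed RR
duration of at least ``brady_min_dur_s`` (default 4 s).  A desaturation is
a drop of SpO2 below a 60-s running-median baseline by a configurable
threshold (3, 5 or 10 percentage points).  A hypoxic event is a
bradycardia paired with a concomitant desaturation; all feature extractors
operate on the pre / during / post epochs of a 3-minute window on each
side of the bradycardia peak.

All intervals are half-open [start, end) in seconds from record start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .records import (
    RR_RANGE_S,
    PipelineConfig,
    PolygraphicRecord,
    Tachogram,
    UniformSeries,
    ValidationError,
)

logger = logging.getLogger("neostress")

__all__ = [
    "BradycardiaEvent", "DesaturationEvent", "HypoxicEvent", "EpochSlice",
    "mean_rr", "detect_bradycardias", "detect_desaturations",
    "pair_events", "segment_epochs", "preprocess_eeg",
]


@dataclass(frozen=True)
class BradycardiaEvent:
    t_onset: float
    t_peak: float
    t_offset: float
    max_rr_s: float
    duration_s: float
    i_start: int = -1    # first / last supra-threshold beat index
    i_end: int = -1


@dataclass(frozen=True)
class DesaturationEvent:
    t_onset: float
    t_nadir: float
    t_offset: float
    baseline_pct: float
    nadir_pct: float

    @property
    def depth_pct(self) -> float:
        return self.baseline_pct - self.nadir_pct


@dataclass(frozen=True)
class EpochSlice:
    """One epoch of a hypoxic-event window: a half-open time interval."""
    role: str                  # pre | during | post | whole
    start_s: float
    end_s: float
    truncated: bool = False

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class HypoxicEvent:
    brady: BradycardiaEvent
    desat: DesaturationEvent
    window: tuple[float, float]
    truncated: bool
    epochs: dict            # role -> EpochSlice keyed on the bradycardia
    spo2_epochs: dict       # pre/post keyed on the desaturation

    @property
    def t_peak(self) -> float:
        return self.brady.t_peak


def mean_rr(tachogram: Tachogram) -> float:
    """Arithmetic mean RR of the entire tachogram, event beats included (s)."""
    if tachogram.rr.size < 2:
        raise ValidationError("tachogram must contain at least 2 beats")
    return float(np.mean(tachogram.rr))


def detect_bradycardias(tachogram: Tachogram,
                        config: PipelineConfig | None = None) -> list[BradycardiaEvent]:
    """Maximal supra-threshold RR runs with summed duration >= 4 s.

    Runs separated by fewer than ``brady_merge_gap_beats`` sub-threshold
    beats are merged.  The offset extends past the run to the first beat
    where RR stays <= ``stationarity_factor`` x mean RR for
    ``stationarity_beats`` consecutive beats (capped at the next event's
    onset), operationalizing the return to stationarity.
    """
    cfg = config or PipelineConfig()
    rr, bt = tachogram.rr, tachogram.beat_times
    rbar = mean_rr(tachogram)
    thr = cfg.brady_factor * rbar
    above = rr > thr
    if not np.any(above):
        return []
    # maximal runs
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    runs = list(zip(edges[::2], edges[1::2] - 1))  # inclusive beat-index runs
    # merge runs separated by short sub-threshold gaps
    merged = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] - 1 < cfg.brady_merge_gap_beats:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    # duration criterion: summed RR of supra-threshold beats in the run
    kept = []
    for s, e in merged:
        if np.sum(rr[s:e + 1][above[s:e + 1]]) >= cfg.brady_min_dur_s:
            kept.append((s, e))
    events: list[BradycardiaEvent] = []
    stat_thr = cfg.stationarity_factor * rbar
    below = rr <= stat_thr
    for n, (s, e) in enumerate(kept):
        seg = rr[s:e + 1]
        imax = s + int(np.argmax(seg))           # earliest max on ties
        t_onset = bt[s] - rr[s]                  # start of first supra-threshold interval
        # return to stationarity after the peak
        limit = kept[n + 1][0] if n + 1 < len(kept) else rr.size
        t_offset = None
        w = cfg.stationarity_beats
        for k in range(e + 1, limit - w + 1):
            if np.all(below[k:k + w]):
                t_offset = bt[k]
                break
        if t_offset is None:
            t_offset = bt[min(limit - 1, rr.size - 1)]
        t_offset = max(t_offset, bt[e])          # never before the run end
        if t_offset <= bt[imax]:
            t_offset = bt[e] + 1e-6
        events.append(BradycardiaEvent(
            t_onset=float(t_onset), t_peak=float(bt[imax]), t_offset=float(t_offset),
            max_rr_s=float(rr[imax]), duration_s=float(np.sum(seg[above[s:e + 1]])),
            i_start=int(s), i_end=int(e)))
    return events


def detect_desaturations(spo2: UniformSeries, threshold_pct: float,
                         config: PipelineConfig | None = None) -> list[DesaturationEvent]:
    """Drops below a preceding-60-s running-median baseline by the threshold,
    extended outward to the re-crossing of baseline - threshold/2."""
    cfg = config or PipelineConfig()
    x = spo2.values
    n = x.size
    if n < 360 * spo2.rate:
        raise ValidationError("SpO2 series must cover at least 6 min")
    w = max(1, int(round(cfg.desat_baseline_window_s * spo2.rate)))
    baseline = np.empty(n)
    for i in range(n):                      # causal running median over (i-w, i]
        lo = max(0, i - w)
        baseline[i] = np.median(x[lo:i]) if i > lo else x[0]
    candidate = x < baseline - threshold_pct
    if not np.any(candidate):
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], candidate.view(np.int8), [0]))))
    events: list[DesaturationEvent] = []
    last_end = -1
    for s, e in zip(edges[::2], edges[1::2] - 1):
        b0 = baseline[s]
        half = b0 - threshold_pct / 2.0
        lo = s
        while lo > 0 and x[lo - 1] < half:
            lo -= 1
        hi = e
        while hi < n - 1 and x[hi + 1] < half:
            hi += 1
        if lo <= last_end:                  # merge with the previous event
            prev = events.pop()
            lo = int(round((prev.t_onset - spo2.t0) * spo2.rate))
            b0 = prev.baseline_pct
        inad = lo + int(np.argmin(x[lo:hi + 1]))
        events.append(DesaturationEvent(
            t_onset=spo2.t0 + lo / spo2.rate,
            t_nadir=spo2.t0 + inad / spo2.rate,
            t_offset=spo2.t0 + (hi + 1) / spo2.rate,
            baseline_pct=float(b0), nadir_pct=float(x[inad])))
        last_end = hi
    return [ev for ev in events if ev.depth_pct >= threshold_pct]


def pair_events(bradys: list[BradycardiaEvent],
                desats: list[DesaturationEvent],
                config: PipelineConfig | None = None) -> list[tuple[BradycardiaEvent, DesaturationEvent]]:
    """Pair each bradycardia with a concomitant desaturation.

    A desaturation is a candidate when its interval intersects
    [brady.t_onset - 30 s, brady.t_offset + 60 s].  Assignment is greedy by
    nadir-to-peak distance; each desaturation is used at most once, and
    unpaired bradycardias are dropped.
    """
    cfg = config or PipelineConfig()
    candidates = []
    for i, b in enumerate(bradys):
        lo, hi = b.t_onset - cfg.pair_before_s, b.t_offset + cfg.pair_after_s
        for j, d in enumerate(desats):
            if d.t_offset > lo and d.t_onset < hi:
                candidates.append((abs(d.t_nadir - b.t_peak), i, j))
    pairs: dict[int, int] = {}
    used: set[int] = set()
    for _, i, j in sorted(candidates):
        if i not in pairs and j not in used:
            pairs[i] = j
            used.add(j)
    return [(bradys[i], desats[pairs[i]]) for i in sorted(pairs)]


def segment_epochs(brady: BradycardiaEvent, desat: DesaturationEvent,
                   record_duration_s: float,
                   config: PipelineConfig | None = None) -> HypoxicEvent:
    """Cut the 3-min-per-side window around the bradycardia peak into
    pre / during / post epochs (and desaturation-keyed SpO2 pre/post)."""
    cfg = config or PipelineConfig()
    w0 = brady.t_peak - cfg.window_half_s
    w1 = brady.t_peak + cfg.window_half_s
    truncated = w0 < 0 or w1 > record_duration_s
    w0c, w1c = max(0.0, w0), min(record_duration_s, w1)
    on = float(np.clip(brady.t_onset, w0c, w1c))
    off = float(np.clip(brady.t_offset, on, w1c))
    epochs = {
        "pre": EpochSlice("pre", w0c, on, truncated),
        "during": EpochSlice("during", on, off, truncated),
        "post": EpochSlice("post", off, w1c, truncated),
        "whole": EpochSlice("whole", w0c, w1c, truncated),
    }
    d_on = float(np.clip(desat.t_onset, w0c, w1c))
    d_off = float(np.clip(desat.t_offset, d_on, w1c))
    spo2_epochs = {
        "pre": EpochSlice("pre", w0c, d_on, truncated),
        "post": EpochSlice("post", d_off, w1c, truncated),
    }
    return HypoxicEvent(brady=brady, desat=desat, window=(w0c, w1c),
                        truncated=truncated, epochs=epochs, spo2_epochs=spo2_epochs)


def detect_hypoxic_events(record: PolygraphicRecord, threshold_pct: float,
                          config: PipelineConfig | None = None) -> list[HypoxicEvent]:
    """Convenience chain: detect, pair, segment."""
    cfg = config or PipelineConfig()
    bradys = detect_bradycardias(record.tachogram, cfg)
    desats = detect_desaturations(record.spo2, threshold_pct, cfg)
    out = [segment_epochs(b, d, record.common_duration_s, cfg)
           for b, d in pair_events(bradys, desats, cfg)]
    logger.info("detect %s thr=%g: %d bradycardias, %d desaturations, %d hypoxic events",
                record.subject_id, threshold_pct, len(bradys), len(desats), len(out))
    return out


def preprocess_eeg(eeg: np.ndarray, rate: float,
                   band: tuple[float, float] = (1.0, 20.0)) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (default 1-20 Hz)."""
    if rate <= 40.0:
        raise ValidationError("EEG rate must exceed 40 Hz for the 1-20 Hz band-pass")
    sos = butter(4, band, btype="bandpass", fs=rate, output="sos")
    return sosfiltfilt(sos, np.asarray(eeg, dtype=float), axis=-1)
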