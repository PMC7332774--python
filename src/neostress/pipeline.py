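"""End-to-end orchestration: detection -> feature extraction -> LOPO
classification, with one structured log line per stage.

Feature naming follows ``<signal>__<feature>__<epoch>`` (e.g.
``rr__mu__pre``, ``spo2__sd1__whole``, ``eeg_C3__c1_raw__post``,
``net_eeg_rr__path_length__mu__during``).  Per event the extractors yield:

* HRV: mean/SD of RR per epoch; mean/SD of HF, LF, HFnu and LF/HF band
  power per epoch (8 Hz resampled tachogram); Poincare tau/SD1/SD2 and
  centroids on the whole window; PRSA overall/anchor slopes for
  T in {1, 5, 10, 20, 50, 100} s ('up' anchors: RR lengthening).
* SpO2: mean/SD on the desaturation-keyed pre/post epochs; Poincare and
  PRSA ('down' anchors) on the whole window.
* EEG (8 channels): amplitude and delta-power mean/SD per epoch;
  wavelet-leader c1/c2 of the band-passed channel and of its 8 Hz
  delta-power envelope on the pre and post epochs.
* Network: mean/SD per epoch of path length, efficiency, clustering,
  eccentricity and the redundancy optimum on the 4 adjacency partitions.

Bradycardia-window features are cached across desaturation thresholds;
only the SpO2 pre/post temporal statistics depend on the desaturation
boundaries and are recomputed per threshold.
"""

from __future__ import annotations

import logging
import math
import os
import zlib

import numpy as np
import pandas as pd

from . import cardio, eeg as eegmod, network
from .classify import ClassifierReport, assemble_features, lopo_evaluate
from .events import HypoxicEvent, detect_hypoxic_events, preprocess_eeg
from .records import EEG_CHANNELS, PipelineConfig, PolygraphicRecord, ValidationError

logger = logging.getLogger("neostress")

__all__ = ["extract_event_features", "extract_cohort_features",
           "eeg_fractal_features", "run_pipeline"]


def _event_seed(base_seed: int, subject_id: str, k: int) -> int:
    return (int(base_seed) * 1000003 + zlib.crc32(subject_id.encode()) + 97 * k) % (2**31)


class _RecordContext:
    """Per-record precomputations shared by all of its events."""

    def __init__(self, record: PolygraphicRecord, cfg: PipelineConfig):
        self.record = record
        self.cfg = cfg
        self.eeg_filt = preprocess_eeg(record.eeg, record.eeg_rate, cfg.eeg_band)
        self.rr8 = cardio.resample_uniform(record.tachogram, cfg.resample_rate_hz)
        self.spo2_8 = cardio.resample_uniform(record.spo2, cfg.resample_rate_hz)

    def eeg_slice(self, start_s: float, end_s: float) -> tuple[np.ndarray, int]:
        rate = self.record.eeg_rate
        i0 = max(0, int(round(start_s * rate)))
        i1 = min(self.eeg_filt.shape[1], int(round(end_s * rate)))
        return self.eeg_filt[:, i0:i1], i0


def _uniform_window(series, start_s, end_s):
    i0, i1 = series.index_range(start_s, end_s)
    from .records import UniformSeries
    return UniformSeries(series.values[i0:i1], series.rate,
                         series.t0 + i0 / series.rate)


def _block_mean(x: np.ndarray, factor: int) -> np.ndarray:
    n = (x.size // factor) * factor
    return x[:n].reshape(-1, factor).mean(axis=1)


def _brady_window_features(ctx: _RecordContext, event: HypoxicEvent,
                           seed: int) -> dict[str, float]:
    """Features that depend only on the bradycardia window/epochs."""
    cfg = ctx.cfg
    rec = ctx.record
    out: dict[str, float] = {}
    w0, w1 = event.window
    ep3 = {k: v for k, v in event.epochs.items() if k != "whole"}

    # ---- HRV temporal per epoch (beat domain) ------------------------
    bt, rr = rec.tachogram.beat_times, rec.tachogram.rr
    for role, ep in ep3.items():
        sel = (bt >= ep.start_s) & (bt < ep.end_s)
        mu, sd = cardio.temporal_stats(rr[sel])
        out[f"rr__mu__{role}"], out[f"rr__sd__{role}"] = mu, sd

    # ---- HRV spectral per epoch --------------------------------------
    rr_win = _uniform_window(ctx.rr8, w0, w1)
    if rr_win.values.size >= 64:
        spec = cardio.cwt_band_power(rr_win, voices_per_octave=cfg.voices_per_octave)
        for role, ep in ep3.items():
            for name, val in cardio.spectral_epoch_features(
                    spec, ep.start_s, ep.end_s).items():
                out[f"rr__{name}__{role}"] = val

    # ---- Poincare on the whole window (beat domain) ------------------
    sel = (bt >= w0) & (bt < w1)
    try:
        pc = cardio.poincare_features(rr[sel])
        out.update({"rr__sd1__whole": pc.sd1, "rr__sd2__whole": pc.sd2,
                    "rr__cx__whole": pc.cx, "rr__cy__whole": pc.cy})
    except ValidationError:
        pass

    # ---- PRSA on the whole window ------------------------------------
    if rr_win.duration_s >= 360:
        for name, val in cardio.prsa_feature_set(
                rr_win, cfg.prsa_T_list, direction="up").items():
            out[f"rr__{name}__whole"] = val
    spo2_win = _uniform_window(ctx.spo2_8, w0, w1)
    if spo2_win.duration_s >= 360:
        for name, val in cardio.prsa_feature_set(
                spo2_win, cfg.prsa_T_list, direction="down").items():
            out[f"spo2__{name}__whole"] = val

    # ---- SpO2 Poincare on the whole window (1 Hz) --------------------
    sp = rec.spo2.slice_time(w0, w1)
    try:
        pc = cardio.poincare_features(sp)
        out.update({"spo2__sd1__whole": pc.sd1, "spo2__sd2__whole": pc.sd2,
                    "spo2__cx__whole": pc.cx, "spo2__cy__whole": pc.cy})
    except ValidationError:
        pass

    # ---- EEG amplitude / delta power per channel ---------------------
    eeg_win, i0 = ctx.eeg_slice(w0, w1)
    rate = rec.eeg_rate
    t0_win = i0 / rate
    factor = int(round(rate / cfg.resample_rate_hz))
    delta8 = {}
    for c, ch in enumerate(EEG_CHANNELS):
        dp = eegmod.delta_power(eeg_win[c], rate, cfg.voices_per_octave)
        dp8 = _block_mean(dp.values, factor)
        delta8[ch] = dp8
        for role, ep in ep3.items():
            j0 = max(0, int(round((ep.start_s - t0_win) * rate)))
            j1 = min(eeg_win.shape[1], int(round((ep.end_s - t0_win) * rate)))
            mu, sd = eegmod.eeg_epoch_stats(eeg_win[c, j0:j1])
            out[f"eeg_{ch}__mu__{role}"], out[f"eeg_{ch}__sd__{role}"] = mu, sd
            mu, sd = eegmod.eeg_epoch_stats(dp.values[j0:j1], dp.valid[j0:j1])
            out[f"eeg_{ch}__mu_pdelta__{role}"] = mu
            out[f"eeg_{ch}__sd_pdelta__{role}"] = sd

    # ---- fractality (pre / post only) --------------------------------
    out.update(_fractal_features(eeg_win, t0_win, rate, delta8, ep3, cfg))

    # ---- coupling graph & topology -----------------------------------
    n8 = min(min(x.size for x in delta8.values()),
             rr_win.values.size, spo2_win.values.size)
    if n8 >= 512:
        nodes = np.vstack([delta8[ch][:n8] for ch in EEG_CHANNELS]
                          + [rr_win.values[:n8], spo2_win.values[:n8]])
        band = cfg.coupling_band(rec.group)
        try:
            graph = network.build_coupling_graph(
                nodes, band, rate=cfg.resample_rate_hz, t0=max(w0, rr_win.t0),
                n_surr=cfg.n_surrogates, seed=seed,
                voices_per_octave=max(4, cfg.voices_per_octave // 2))
            out.update(network.topology_features(graph, ep3, cfg.nsup_objective))
        except ValidationError:
            logger.info("coupling graph skipped for %s (degenerate node series)",
                        rec.subject_id)
    return out


def _fractal_features(eeg_win: np.ndarray, t0_win: float, rate: float,
                      delta8: dict, ep3: dict, cfg: PipelineConfig) -> dict[str, float]:
    """Wavelet-leader c1/c2 of each band-passed channel and of its 8 Hz
    delta-power envelope, on the pre and post epochs ("during" is too short
    for scale-free analysis)."""
    # band-aware octave range: the 1-20 Hz band-pass removes the coarse
    # scales the default regression range would use
    j_hi = int(math.floor(math.log2(0.8 * rate / (1.5 * cfg.eeg_band[0]))))
    j_lo = max(2, int(math.ceil(math.log2(0.8 * rate / cfg.eeg_band[1]))))
    out: dict[str, float] = {}
    for c, ch in enumerate(EEG_CHANNELS):
        for role in ("pre", "post"):
            ep = ep3[role]
            j0 = max(0, int(round((ep.start_s - t0_win) * rate)))
            j1 = min(eeg_win.shape[1], int(round((ep.end_s - t0_win) * rate)))
            lc = eegmod.log_cumulants(eeg_win[c, j0:j1], rate, j1=j_lo, j2=j_hi)
            out[f"eeg_{ch}__c1_raw__{role}"] = lc.c1
            out[f"eeg_{ch}__c2_raw__{role}"] = lc.c2
            k0 = max(0, int(round((ep.start_s - t0_win) * cfg.resample_rate_hz)))
            k1 = min(delta8[ch].size,
                     int(round((ep.end_s - t0_win) * cfg.resample_rate_hz)))
            lc = eegmod.log_cumulants(delta8[ch][k0:k1], cfg.resample_rate_hz)
            out[f"eeg_{ch}__c1_delta__{role}"] = lc.c1
            out[f"eeg_{ch}__c2_delta__{role}"] = lc.c2
    return out


def eeg_fractal_features(record: PolygraphicRecord, event: HypoxicEvent,
                         config: PipelineConfig | None = None) -> dict[str, float]:
    """Standalone multifractal feature block for one event: 4 quantities
    (c1/c2 of the raw channel and of its delta-power envelope) x 8 channels
    per epoch, for the pre and post epochs."""
    cfg = config or PipelineConfig()
    ctx = _RecordContext(record, cfg)
    w0, w1 = event.window
    ep3 = {k: v for k, v in event.epochs.items() if k != "whole"}
    eeg_win, i0 = ctx.eeg_slice(w0, w1)
    rate = record.eeg_rate
    factor = int(round(rate / cfg.resample_rate_hz))
    delta8 = {ch: _block_mean(eegmod.delta_power(eeg_win[c], rate,
                                                 cfg.voices_per_octave).values,
                              factor)
              for c, ch in enumerate(EEG_CHANNELS)}
    return _fractal_features(eeg_win, i0 / rate, rate, delta8, ep3, cfg)


def _spo2_epoch_features(rec: PolygraphicRecord, event: HypoxicEvent) -> dict[str, float]:
    out = {}
    for role, ep in event.spo2_epochs.items():
        mu, sd = cardio.temporal_stats(rec.spo2.slice_time(ep.start_s, ep.end_s))
        out[f"spo2__mu__{role}"], out[f"spo2__sd__{role}"] = mu, sd
    return out


def extract_event_features(record: PolygraphicRecord, event: HypoxicEvent,
                           config: PipelineConfig | None = None,
                           ctx: _RecordContext | None = None,
                           seed: int | None = None,
                           brady_cache: dict | None = None) -> dict[str, float]:
    """The full per-event feature vector (no metadata columns)."""
    cfg = config or PipelineConfig()
    ctx = ctx or _RecordContext(record, cfg)
    if seed is None:
        seed = _event_seed(cfg.rng_seed, record.subject_id, int(event.t_peak))
    key = round(event.t_peak, 3)
    if brady_cache is not None and key in brady_cache:
        feats = dict(brady_cache[key])
    else:
        feats = _brady_window_features(ctx, event, seed)
        if brady_cache is not None:
            brady_cache[key] = dict(feats)
    feats.update(_spo2_epoch_features(record, event))
    return feats


def extract_cohort_features(records: list[PolygraphicRecord],
                            config: PipelineConfig | None = None) -> pd.DataFrame:
    """Detect events at every configured threshold and build the feature table."""
    cfg = config or PipelineConfig()
    rows: list[dict] = []
    for rec in records:
        ctx = _RecordContext(rec, cfg)
        cache: dict = {}
        n_rec = 0
        for thr in cfg.desat_thresholds_pct:
            events = detect_hypoxic_events(rec, thr, cfg)
            for k, ev in enumerate(events):
                seed = _event_seed(cfg.rng_seed, rec.subject_id, int(ev.t_peak))
                feats = extract_event_features(rec, ev, cfg, ctx=ctx, seed=seed,
                                               brady_cache=cache)
                row = {"subject_id": rec.subject_id, "group": rec.group,
                       "event_id": f"{rec.subject_id}_t{ev.t_peak:.0f}",
                       "label": rec.stress_label, "pma_weeks": rec.pma_weeks,
                       "desat_threshold_pct": float(thr)}
                row.update(feats)
                rows.append(row)
                n_rec += 1
        logger.info("features %s: %d event rows", rec.subject_id, n_rec)
    return assemble_features(rows)


def run_pipeline(records: list[PolygraphicRecord],
                 config: PipelineConfig | None = None,
                 seed: int | None = None,
                 out_dir: str | None = None) -> tuple[ClassifierReport, pd.DataFrame]:
    """Detect, extract and classify a cohort; optionally persist outputs.

    Returns the LOPO classifier report and the per-event feature table.
    Fully reproducible from the configuration and seed.
    """
    cfg = config or PipelineConfig()
    if seed is not None:
        cfg = PipelineConfig(**{**cfg.__dict__, "rng_seed": int(seed)})
    table = extract_cohort_features(records, cfg)
    logger.info("pipeline: %d subjects, %d event rows, %d features",
                len(records), len(table),
                max(0, table.shape[1] - 6))
    report = lopo_evaluate(table, cfg, seed=cfg.rng_seed,
                           expected_groups={r.group for r in records})
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        table.to_csv(os.path.join(out_dir, "features.csv"), index=False,
                     float_format="%.10g", lineterminator="\n")
        scores = report.pooled_scores()
        scores.to_csv(os.path.join(out_dir, "pooled_scores.csv"), index=False,
                      float_format="%.10g", lineterminator="\n")
        import json
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report, table
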