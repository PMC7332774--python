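"""Reading and writing record bundles.

The canonical interchange is a directory of plain-text files per subject:

* ``eeg.csv`` — header ``time_s,Fp1,Fp2,C3,C4,T3,T4,O1,O2`` (microvolts);
* ``tachogram.csv`` — header ``beat_time_s,rr_s``;
* ``spo2.csv`` — header ``time_s,spo2_pct`` (1 Hz);
* ``meta.json`` — ``{subject_id, pma_weeks, group, lps_prev_day}``.

EDF input for the EEG is supported read-only when ``mne`` is installed.
Writes are deterministic: identical records produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from .records import (
    EEG_CHANNELS,
    RR_RANGE_S,
    PipelineConfig,
    PolygraphicRecord,
    Tachogram,
    UniformSeries,
    ValidationError,
)

logger = logging.getLogger("neostress")

__all__ = ["read_record", "write_record"]

_FLOAT_FMT = "%.13g"


def write_record(record: PolygraphicRecord, out_dir: str) -> dict[str, str]:
    """Write the CSV/JSON bundle for one record; returns the path map."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {k: os.path.join(out_dir, f"{k}.csv")
             for k in ("eeg", "tachogram", "spo2")}
    paths["meta"] = os.path.join(out_dir, "meta.json")

    t = np.arange(record.eeg.shape[1]) / record.eeg_rate
    eeg_df = pd.DataFrame({"time_s": t})
    for c, name in enumerate(record.channel_names):
        eeg_df[name] = record.eeg[c]
    eeg_df.to_csv(paths["eeg"], index=False, float_format=_FLOAT_FMT,
                  lineterminator="\n")
    pd.DataFrame({"beat_time_s": record.tachogram.beat_times,
                  "rr_s": record.tachogram.rr}).to_csv(
        paths["tachogram"], index=False, float_format=_FLOAT_FMT,
        lineterminator="\n")
    pd.DataFrame({"time_s": record.spo2.times,
                  "spo2_pct": record.spo2.values}).to_csv(
        paths["spo2"], index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    meta = {"subject_id": record.subject_id,
            "pma_weeks": record.pma_weeks,
            "group": record.group,
            "lps_prev_day": 1 if record.stress_label else 0,
            "eeg_rate_hz": record.eeg_rate}
    with open(paths["meta"], "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def _read_eeg_csv(path: str) -> tuple[np.ndarray, tuple[str, ...], float]:
    df = pd.read_csv(path)
    missing = [c for c in EEG_CHANNELS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing EEG channels: {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValidationError("EEG file too short")
    dt = np.diff(t)
    if np.ptp(dt) > 1e-6:
        raise ValidationError("EEG time grid is not uniform")
    rate = 1.0 / float(np.mean(dt))
    names = tuple(c for c in df.columns if c != "time_s")
    return df[list(names)].to_numpy(dtype=float).T, names, rate


def _read_eeg_edf(path: str) -> tuple[np.ndarray, tuple[str, ...], float]:
    try:
        import mne
    except ImportError as exc:                      # pragma: no cover
        raise ValidationError("EDF input requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = tuple(raw.ch_names)
    missing = [c for c in EEG_CHANNELS if c not in names]
    if missing:
        raise ValidationError(f"missing EEG channels: {missing}")
    data = raw.get_data(picks=list(EEG_CHANNELS)) * 1e6   # volts -> microvolts
    return data, EEG_CHANNELS, float(raw.info["sfreq"])


def read_record(path_bundle, config: PipelineConfig | None = None) -> PolygraphicRecord:
    """Read a record bundle.

    ``path_bundle`` is either a directory containing the canonical file
    names or a dict with keys ``eeg``, ``tachogram``, ``spo2``, ``meta``.
    Beats with RR outside the physiological range are dropped (RR then
    re-derived from the remaining beat times).
    """
    if isinstance(path_bundle, (str, os.PathLike)):
        d = os.fspath(path_bundle)
        eeg_path = os.path.join(d, "eeg.csv")
        if not os.path.exists(eeg_path) and os.path.exists(os.path.join(d, "eeg.edf")):
            eeg_path = os.path.join(d, "eeg.edf")
        bundle = {"eeg": eeg_path,
                  "tachogram": os.path.join(d, "tachogram.csv"),
                  "spo2": os.path.join(d, "spo2.csv"),
                  "meta": os.path.join(d, "meta.json")}
    else:
        bundle = dict(path_bundle)

    if str(bundle["eeg"]).lower().endswith(".edf"):
        eeg, names, rate = _read_eeg_edf(bundle["eeg"])
    else:
        eeg, names, rate = _read_eeg_csv(bundle["eeg"])

    tdf = pd.read_csv(bundle["tachogram"])
    bt = tdf["beat_time_s"].to_numpy(dtype=float)
    if np.any(np.diff(bt) <= 0):
        raise ValidationError("beat times must be strictly increasing")
    rr = tdf["rr_s"].to_numpy(dtype=float)
    good = (rr >= RR_RANGE_S[0]) & (rr <= RR_RANGE_S[1])
    if not np.all(good):
        logger.info("dropping %d out-of-range beats", int((~good).sum()))
        bt = bt[good]
        rr = np.empty_like(bt)
        rr[0] = bt[0]
        rr[1:] = np.diff(bt)
    tach = Tachogram(bt, rr)

    sdf = pd.read_csv(bundle["spo2"])
    st = sdf["time_s"].to_numpy(dtype=float)
    dt = np.diff(st)
    if st.size < 2 or np.ptp(dt) > 1e-6:
        raise ValidationError("SpO2 must be uniformly sampled")
    srate = 1.0 / float(np.mean(dt))
    if abs(srate - 1.0) > 1e-6:
        raise ValidationError(f"SpO2 must be sampled at 1 Hz, got {srate:g} Hz")
    spo2 = UniformSeries(sdf["spo2_pct"].to_numpy(dtype=float), srate, float(st[0]))

    with open(bundle["meta"]) as fh:
        meta = json.load(fh)
    return PolygraphicRecord(
        subject_id=str(meta["subject_id"]), eeg=eeg, channel_names=names,
        eeg_rate=rate, tachogram=tach, spo2=spo2,
        pma_weeks=float(meta["pma_weeks"]), group=str(meta["group"]),
        stress_label=bool(meta["lps_prev_day"]))
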