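"""Reading and writing recordings as plain-text CSV.

Two-file convention: a waveform CSV (``time_s, abp_mmhg, cvp_mmhg``) and
an annotation CSV (``time_s, avd_ms``), plus an optional ground-truth
sidecar.  ``write_bundle``/``read_bundle`` wrap the pair in a
self-describing directory with a JSON metadata file.  Floats are written
with full round-trip precision, so a write/read cycle is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .records import GroundTruth, HaemoRecord

__all__ = ["read_record", "write_record", "write_bundle", "read_bundle"]

_FLOAT_FMT = "%.17g"  # exact float64 round-trip

WAVEFORM_COLUMNS = ["time_s", "abp_mmhg", "cvp_mmhg"]
ANNOTATION_COLUMNS = ["time_s", "avd_ms"]


def write_record(
    record: HaemoRecord,
    waveform_path: str | Path,
    annotation_path: str | Path,
    truth_path: str | Path | None = None,
) -> None:
    """Write the two-file CSV pair (and optionally the truth sidecar)."""
    wf = pd.DataFrame(
        {"time_s": record.time, "abp_mmhg": record.abp, "cvp_mmhg": record.cvp}
    )
    wf.to_csv(waveform_path, index=False, float_format=_FLOAT_FMT)
    ann = pd.DataFrame(record.events, columns=ANNOTATION_COLUMNS)
    ann.to_csv(annotation_path, index=False, float_format=_FLOAT_FMT)
    if truth_path is not None and record.truth is not None:
        t = record.truth
        rows = pd.DataFrame(
            {
                "beat_onset_time_s": t.beat_onset_times_s,
                "beat_avd_ms": t.beat_avd_ms,
                "peak_time_abp_s": t.beat_peak_times_abp_s,
                "peak_abp_mmhg": t.beat_peaks_abp_mmhg,
                "peak_time_cvp_s": t.beat_peak_times_cvp_s,
                "peak_cvp_mmhg": t.beat_peaks_cvp_mmhg,
            }
        )
        rows.to_csv(truth_path, index=False, float_format=_FLOAT_FMT)


def read_record(
    waveform_path: str | Path, annotation_path: str | Path
) -> HaemoRecord:
    """Read and validate a two-file CSV pair into a :class:`HaemoRecord`.

    Enforces a uniform sample grid (maximum jitter below half a sample
    period, reported with the first offending index), sorted in-span
    events, and the exact column contract.
    """
    wf = pd.read_csv(waveform_path, float_precision="round_trip")
    missing = [c for c in WAVEFORM_COLUMNS if c not in wf.columns]
    if missing:
        raise ValueError(f"waveform file missing column(s): {missing}")
    ann = pd.read_csv(annotation_path, float_precision="round_trip")
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation file missing column(s): {missing}")

    time = wf["time_s"].to_numpy(dtype=float)
    if time.size < 2:
        raise ValueError("waveform must contain at least 2 samples")
    period = (time[-1] - time[0]) / (time.size - 1)
    if period <= 0:
        raise ValueError("waveform time must be increasing")
    expected = time[0] + np.arange(time.size) * period
    jitter = np.abs(time - expected)
    if jitter.max() >= 0.5 * period:
        i = int(np.argmax(jitter >= 0.5 * period))
        raise ValueError(
            f"non-uniform time grid: sample {i} at t={time[i]:.6f}s deviates "
            f"{jitter[i]:.6f}s from the uniform grid (period {period:.6f}s)"
        )
    record = HaemoRecord(
        time=time,
        abp=wf["abp_mmhg"].to_numpy(dtype=float),
        cvp=wf["cvp_mmhg"].to_numpy(dtype=float),
        sample_rate_hz=1.0 / period,
        events=[(float(t), float(a)) for t, a in
                zip(ann["time_s"], ann["avd_ms"])],
    )
    record.validate()
    return record


def write_bundle(record: HaemoRecord, bundle_dir: str | Path,
                 metadata: dict | None = None) -> Path:
    """Write a self-describing bundle directory for one subject."""
    d = Path(bundle_dir)
    d.mkdir(parents=True, exist_ok=True)
    write_record(
        record,
        d / "waveform.csv",
        d / "annotations.csv",
        d / "truth.csv" if record.truth is not None else None,
    )
    meta = {
        "sample_rate_hz": record.sample_rate_hz,
        "n_samples": int(record.n_samples),
        "n_events": len(record.events),
    }
    if record.truth is not None:
        meta["true_optimum_abp_ms"] = record.truth.true_optimum_abp_ms
        meta["true_optimum_cvp_ms"] = record.truth.true_optimum_cvp_ms
    if metadata:
        meta.update(metadata)
    (d / "metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
    return d


def read_bundle(bundle_dir: str | Path) -> HaemoRecord:
    """Read a bundle directory written by :func:`write_bundle`."""
    d = Path(bundle_dir)
    record = read_record(d / "waveform.csv", d / "annotations.csv")
    meta_path = d / "metadata.json"
    truth_path = d / "truth.csv"
    if truth_path.exists() and meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if "true_optimum_abp_ms" in meta:
            t = pd.read_csv(truth_path, float_precision="round_trip")
            record.truth = GroundTruth(
                true_optimum_abp_ms=meta["true_optimum_abp_ms"],
                true_optimum_cvp_ms=meta["true_optimum_cvp_ms"],
                resp_trace_abp=np.array([]),
                resp_trace_cvp=np.array([]),
                beat_onset_times_s=t["beat_onset_time_s"].to_numpy(),
                beat_avd_ms=t["beat_avd_ms"].to_numpy(),
                beat_peak_times_abp_s=t["peak_time_abp_s"].to_numpy(),
                beat_peaks_abp_mmhg=t["peak_abp_mmhg"].to_numpy(),
                beat_peak_times_cvp_s=t["peak_time_cvp_s"].to_numpy(),
                beat_peaks_cvp_mmhg=t["peak_cvp_mmhg"].to_numpy(),
            )
    return record
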