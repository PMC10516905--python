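"""Recording and manifest I/O.

Waveform channels are stored one CSV per channel with a
``time_s,value`` header; the sampling rate is recovered from the time
column, which must be uniform and monotone.  A cohort manifest is a
CSV with one row per (subject, condition) referencing the three
channel files, plus the sampling rate, the induction end time and the
self-reported trance intensity (0-10, SICT only).  Ground truth of
synthetic cohorts is written as JSON next to the manifest.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import ROLES, WaveformChannel
from .synth import RespirationTruth, SyntheticRecording, ConditionProfile

MANIFEST_COLUMNS = (
    "subject_id", "condition", "ecg_path", "thoracic_path", "abdominal_path",
    "fs", "induction_end_s", "trance_intensity",
)


def write_waveform_csv(channel: WaveformChannel, path: str | Path) -> None:
    """Write a channel as ``time_s,value`` CSV."""
    df = pd.DataFrame({"time_s": channel.times, "value": channel.samples})
    df.to_csv(path, index=False, float_format="%.6f")


def read_waveform_csv(path: str | Path, role: str) -> WaveformChannel:
    """Read a ``time_s,value`` CSV back into a channel.

    Rejects files with a non-monotone or non-uniform time base.
    """
    df = pd.read_csv(path)
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    if np.max(np.abs(dt - dt[0])) > 1e-4:
        raise ValueError(f"{path}: time base is not uniform")
    fs = 1.0 / float(np.median(dt))
    return WaveformChannel(df["value"].to_numpy(float), fs=round(fs, 6), role=role)


def read_recording(row: dict | pd.Series, base_dir: str | Path = ".") -> dict:
    """Load the three channels referenced by one manifest row.

    Returns a dict with ``ecg``, ``thoracic``, ``abdominal`` channels
    plus the manifest metadata.
    """
    base = Path(base_dir)
    out = {
        "subject_id": str(row["subject_id"]),
        "condition": str(row["condition"]),
        "induction_end_s": float(row.get("induction_end_s", 0.0) or 0.0),
        "trance_intensity": row.get("trance_intensity"),
    }
    for role in ROLES:
        p = base / str(row[f"{role}_path"])
        if not p.exists():
            raise FileNotFoundError(f"manifest references missing file {p}")
        out[role] = read_waveform_csv(p, role)
    return out


def write_cohort(
    recordings: list[SyntheticRecording],
    out_dir: str | Path,
) -> Path:
    """Write a synthetic cohort: channel CSVs, manifest and truth JSON.

    Returns the manifest path.  Requires waveform channels (generate
    the cohort with ``waveforms=True``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    truth: dict[str, dict] = {}
    for rec in recordings:
        if rec.ecg is None:
            raise ValueError("cannot write an events-only cohort; need waveforms")
        stem = f"{rec.subject_id}_{rec.condition}"
        paths = {}
        for role in ROLES:
            rel = f"{stem}_{role}.csv"
            write_waveform_csv(getattr(rec, role), out / rel)
            paths[f"{role}_path"] = rel
        rows.append(
            {
                "subject_id": rec.subject_id,
                "condition": rec.condition,
                **paths,
                "fs": rec.ecg.fs,
                "induction_end_s": rec.induction_end_s,
                "trance_intensity": rec.trance_intensity,
            }
        )
        truth[stem] = {
            "r_times": rec.truth_r_times.tolist(),
            "breath_peaks": rec.truth_resp.peak_times.tolist(),
            "breath_troughs": rec.truth_resp.trough_times.tolist(),
            "breath_amplitudes": rec.truth_resp.amplitudes.tolist(),
            "profile": dataclasses.asdict(rec.profile_used),
        }
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh)
    return manifest_path


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate a cohort manifest."""
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and c != "trance_intensity"]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    dup = df.duplicated(subset=["subject_id", "condition"])
    if dup.any():
        raise ValueError(
            f"duplicate (subject_id, condition) rows in manifest: "
            f"{df.loc[dup, ['subject_id', 'condition']].to_dict('records')}"
        )
    if "trance_intensity" in df.columns:
        ti = df["trance_intensity"].dropna()
        if ((ti < 0) | (ti > 10)).any():
            raise ValueError("trance_intensity must lie in [0, 10]")
    return df


def read_ground_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
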