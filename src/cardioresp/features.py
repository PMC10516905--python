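"""Feature extraction: recordings -> the 27-feature table.

The registry has 16 cardiac metrics (time domain, Welch spectral with
raw and heart-rate-corrected variants, approximate entropy) and 11
respiratory metrics (rate, amplitude, phase-duration ratio, SDBB and
RMSSD-BB for each of the two belts, plus the belt-averaged rate).

Two extraction paths produce identical feature semantics:

* the **raw path** (:func:`extract_features`) runs full signal
  processing — ECG filtering, R-peak detection, artifact correction,
  belt preprocessing and breath detection;
* the **truth path** (:func:`extract_features_from_truth`) starts from
  the generator's ground-truth event series, skipping detection.  It
  is used for simulation studies of the feature/decoding layers, where
  the detection stages (validated separately to recover truth events
  exactly) would only add compute time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cardiac, resp
from .channels import RRSeries, BreathEvents, UnusableRecordingError, WaveformChannel
from .config import AnalysisConfig
from .synth import SyntheticRecording, _ABDOMINAL_GAIN

#: the full 27-feature registry
RESP_FEATURES = tuple(
    f"{name}_{belt}"
    for belt in ("thoracic", "abdominal")
    for name in resp.RESP_FEATURES_PER_CHANNEL
) + ("resp_rate_mean",)
ALL_FEATURES = cardiac.CARDIAC_FEATURES + RESP_FEATURES


def cardiac_features_from_rr(
    rr: RRSeries, config: AnalysisConfig
) -> dict[str, float | None]:
    """16 cardiac metrics from a corrected, segmented RR series."""
    td = cardiac.hrv_time_domain(rr)
    fd = cardiac.hrv_frequency_domain(
        rr,
        resample_hz=config.resample_hz,
        welch_segment_s=config.welch_segment_s,
        lf_band=config.lf_band,
        hf_band=config.hf_band,
        total_band=config.total_band,
    )
    corrected = cardiac.sacha_correction(fd, td["rr_mean"])
    apen = cardiac.approximate_entropy(
        rr.intervals,
        m=config.apen_m,
        r=config.apen_r_factor * float(np.std(rr.intervals)),
    )
    return {**td, "apen": apen, **fd, **corrected}


def resp_features_from_events(
    events: BreathEvents,
    belt: str,
    sig: WaveformChannel | None = None,
    amplitude: float | None = None,
) -> dict[str, float]:
    """Per-belt respiratory metrics with the belt-name qualifier.

    ``amplitude`` overrides the signal-derived excursion (used on the
    truth path, where per-breath amplitudes are known exactly).
    """
    feats = resp.resp_features(events, sig)
    if amplitude is not None:
        feats["amplitude"] = amplitude
    return {f"{k}_{belt}": v for k, v in feats.items()}


def _segment_events(times: np.ndarray, start: float, length: float) -> np.ndarray:
    return times[(times >= start) & (times <= start + length)]


def extract_features(
    recording,
    config: AnalysisConfig | None = None,
) -> dict[str, float | None]:
    """Raw-path extraction from the three waveform channels.

    ``recording`` needs ``ecg``, ``thoracic`` and ``abdominal``
    :class:`WaveformChannel` attributes plus ``induction_end_s``.
    Raises :class:`UnusableRecordingError` when any quality rule fails.
    """
    config = config or AnalysisConfig()
    start = config.segment_start_s + getattr(recording, "induction_end_s", 0.0)

    filtered = cardiac.filter_ecg(
        recording.ecg,
        highpass_hz=config.ecg_highpass_hz,
        order=config.ecg_filter_order,
        mains_hz=config.mains_hz,
        notch_q=config.notch_q,
    )
    peaks = cardiac.detect_r_peaks(filtered)
    if peaks.n < 10:
        raise UnusableRecordingError("too_few_beats", f"only {peaks.n} R peaks detected")
    rr = RRSeries.from_beat_times(peaks.times)
    rr = cardiac.correct_rr_intervals(
        rr,
        bounds=config.rr_bounds_ms,
        deviation=config.rr_deviation,
        max_flag_fraction=config.max_flag_fraction,
    )
    rr = cardiac.select_segment(rr, length=config.segment_length_s, start=start)
    row: dict[str, float | None] = cardiac_features_from_rr(rr, config)

    rates = []
    for belt in ("thoracic", "abdominal"):
        raw = getattr(recording, belt)
        clean = resp.preprocess_respiration(
            raw, lowpass_hz=config.resp_lowpass_hz, order=config.resp_filter_order
        )
        detected = resp.detect_breaths(clean, min_period_s=config.min_breath_period_s)
        detected = _window_events(detected, start, config.segment_length_s)
        # geometric features (amplitude, phase ratio) come from the
        # detected events, which stay aligned with the waveform; the
        # interval-variability features come from the artifact-corrected
        # BB series, whose event times may drift off the signal
        geom = resp.resp_features(detected, clean)
        corrected = resp.correct_bb_intervals(
            detected,
            bounds=config.bb_bounds_ms,
            deviation=config.bb_deviation,
            max_flag_fraction=config.max_flag_fraction,
        )
        var = resp.resp_features(corrected)
        feats = {
            f"resp_rate_{belt}": var["resp_rate"],
            f"amplitude_{belt}": geom["amplitude"],
            f"phase_ratio_{belt}": geom["phase_ratio"],
            f"sdbb_{belt}": var["sdbb"],
            f"rmssd_bb_{belt}": var["rmssd_bb"],
        }
        rates.append(feats[f"resp_rate_{belt}"])
        row.update(feats)
    row["resp_rate_mean"] = float(np.mean(rates))
    return row


def _window_events(events: BreathEvents, start: float, length: float) -> BreathEvents:
    pk = _segment_events(events.peak_times, start, length)
    on = _segment_events(events.inhale_onsets, start, length)
    if pk.size < 4:
        raise UnusableRecordingError(
            "too_few_breaths", f"only {pk.size} breaths inside the analysis window"
        )
    return BreathEvents(inhale_onsets=on, peak_times=pk)


def extract_features_from_truth(
    recording: SyntheticRecording,
    config: AnalysisConfig | None = None,
) -> dict[str, float | None]:
    """Truth-path extraction from ground-truth event series."""
    config = config or AnalysisConfig()
    start = config.segment_start_s + recording.induction_end_s
    length = config.segment_length_s

    rr_full = RRSeries.from_beat_times(recording.truth_r_times)
    rr = cardiac.select_segment(rr_full, length=length, start=start)
    row: dict[str, float | None] = cardiac_features_from_rr(rr, config)

    truth = recording.truth_resp
    for belt, scale in (("thoracic", 1.0), ("abdominal", _ABDOMINAL_GAIN)):
        mask = (truth.peak_times >= start) & (truth.peak_times <= start + length)
        events = BreathEvents(
            inhale_onsets=_segment_events(truth.trough_times, start, length),
            peak_times=truth.peak_times[mask],
        )
        amp = float(np.mean(truth.amplitudes[mask])) * scale
        row.update(resp_features_from_events(events, belt, amplitude=amp))
    row["resp_rate_mean"] = float(
        np.mean([row["resp_rate_thoracic"], row["resp_rate_abdominal"]])
    )
    return row


def feature_table(
    recordings: list,
    config: AnalysisConfig | None = None,
    path: str = "auto",
) -> tuple[pd.DataFrame, list[dict]]:
    """Build the long-format feature table for a cohort.

    ``path`` selects ``"raw"`` (full signal processing), ``"truth"``
    (ground-truth events) or ``"auto"`` (raw when waveforms are
    present).  Unusable recordings are excluded, each with a
    machine-readable reason in the returned exclusion log.
    """
    config = config or AnalysisConfig()
    rows = []
    exclusions = []
    for rec in recordings:
        use_raw = path == "raw" or (path == "auto" and rec.ecg is not None)
        try:
            feats = (
                extract_features(rec, config)
                if use_raw
                else extract_features_from_truth(rec, config)
            )
        except UnusableRecordingError as err:
            exclusions.append(
                {
                    "subject_id": rec.subject_id,
                    "condition": rec.condition,
                    "reason": err.reason,
                    "detail": str(err),
                }
            )
            continue
        rows.append({"subject_id": rec.subject_id, "condition": rec.condition, **feats})
    cols = ["subject_id", "condition", *ALL_FEATURES]
    table = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    return table, exclusions
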