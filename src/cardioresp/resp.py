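"""Respiration pipeline: belt signal -> breath events -> RRV features.

The belt signal is linearly detrended and low-passed (order-5
Butterworth at 2 Hz, zero phase), breath landmarks are located as
alternating local extrema (inhalation onset at the trough, B peak at
the inhalation maximum marking exhalation onset) with a 1.5 s minimum
breath period, and breath-to-breath (BB) intervals are measured
between successive B peaks.  Features: mean respiratory rate, mean
per-breath amplitude (peak minus preceding trough), phase-duration
ratio (mean inspiratory over mean expiratory duration), and the BB
variability metrics SDBB and RMSSD-BB.

Both belts (thoracic, abdominal) run through the identical code path;
all timing features are invariant under amplitude scaling of the
signal, while the amplitude feature is strictly linear in it.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .channels import BreathEvents, UnusableRecordingError, WaveformChannel
from .cardiac import _correct_intervals

#: minimum breath period enforced during detection, s
MIN_BREATH_PERIOD = 1.5
#: BB plausibility bounds, ms
BB_BOUNDS = (1500.0, 20000.0)
#: relative deviation from the running median that flags a BB interval
BB_DEVIATION = 0.40

RESP_FEATURES_PER_CHANNEL = ("resp_rate", "amplitude", "phase_ratio", "sdbb", "rmssd_bb")


def preprocess_respiration(
    raw: WaveformChannel, lowpass_hz: float = 2.0, order: int = 5
) -> WaveformChannel:
    """Linear detrend followed by zero-phase order-5 low-pass at 2 Hz."""
    if raw.fs <= 4:
        raise ValueError(f"fs must exceed 4 Hz, got {raw.fs}")
    if raw.duration < 60:
        raise ValueError(f"recording must be >= 60 s, got {raw.duration:.1f} s")
    x = signal.detrend(raw.samples, type="linear")
    sos = signal.butter(order, lowpass_hz, btype="lowpass", fs=raw.fs, output="sos")
    return raw.with_samples(signal.sosfiltfilt(sos, x))


def detect_breaths(
    sig: WaveformChannel,
    min_period_s: float = MIN_BREATH_PERIOD,
    prominence_factor: float = 0.3,
) -> BreathEvents:
    """Locate breath landmarks on a preprocessed belt signal.

    Peaks (inhalation maxima / B peaks) and troughs (inhalation onsets)
    are local extrema with a prominence of at least
    ``prominence_factor`` times the signal SD — a relative criterion,
    so detection is invariant to amplitude scaling — separated by at
    least the minimum breath period.  The sequences are then pruned to
    strictly alternate trough/peak.  Fewer than 3 detected breaths
    raises :class:`UnusableRecordingError`.
    """
    x = sig.samples
    fs = sig.fs
    sd = float(np.std(x))
    if sd == 0:
        raise UnusableRecordingError(
            reason="flat_respiration", message="constant belt signal; no breaths"
        )
    dist = max(int(min_period_s * fs), 1)
    prom = prominence_factor * sd
    peaks, _ = signal.find_peaks(x, distance=dist, prominence=prom)
    troughs, _ = signal.find_peaks(-x, distance=dist, prominence=prom)
    if peaks.size < 3:
        raise UnusableRecordingError(
            reason="too_few_breaths", message=f"only {peaks.size} breaths detected"
        )

    # keep, for each peak, the nearest preceding trough (alternation)
    onsets = []
    kept_peaks = []
    for p in peaks:
        prev = troughs[troughs < p]
        if prev.size == 0:
            continue
        t = prev[-1]
        if kept_peaks and t <= kept_peaks[-1]:
            # two peaks share a trough: keep the taller peak
            if x[p] > x[kept_peaks[-1]]:
                kept_peaks[-1] = p
            continue
        kept_peaks.append(p)
        onsets.append(t)
    if len(kept_peaks) < 3:
        raise UnusableRecordingError(
            reason="too_few_breaths", message=f"only {len(kept_peaks)} usable breaths"
        )
    return BreathEvents(
        inhale_onsets=np.asarray(onsets, float) / fs,
        peak_times=np.asarray(kept_peaks, float) / fs,
    )


def correct_bb_intervals(
    events: BreathEvents,
    bounds: tuple[float, float] = BB_BOUNDS,
    deviation: float = BB_DEVIATION,
    max_flag_fraction: float = 0.20,
) -> BreathEvents:
    """Automated BB artifact correction (same rule family as RR).

    Implausibly long intervals (missed breaths) are split, implausibly
    short ones (doubled detections) merged, and deviant intervals
    interpolated; more than 20 % flagged intervals marks the recording
    unusable.  Inhalation onsets are re-derived by keeping, for each
    surviving peak, the original onset where one exists.
    """
    if events.bb_intervals.size < 3:
        raise ValueError("need at least 3 BB intervals")
    try:
        corrected = _correct_intervals(
            events.peak_times,
            bounds=bounds,
            deviation=deviation,
            max_flag_fraction=max_flag_fraction,
            min_intervals=3,
            split_threshold=1.8,
            merge_threshold=0.55,
            kind="BB",
        )
    except UnusableRecordingError:
        raise
    new_peaks = corrected.beat_times
    # map original onsets onto surviving peaks; synthesize onsets for
    # inserted peaks at the median inspiratory lead
    leads = events.peak_times - events.inhale_onsets[: events.peak_times.size]
    med_lead = float(np.median(leads)) if leads.size else 1.0
    onsets = []
    for p in new_peaks:
        j = int(np.argmin(np.abs(events.peak_times - p)))
        if abs(events.peak_times[j] - p) < 1e-6:
            onsets.append(events.inhale_onsets[j] if j < events.inhale_onsets.size else p - med_lead)
        else:
            onsets.append(p - med_lead)
    onsets = np.maximum.accumulate(np.asarray(onsets))
    return BreathEvents(
        inhale_onsets=onsets,
        peak_times=new_peaks,
        corrected_flags=corrected.corrected_flags,
    )


def resp_features(
    events: BreathEvents, sig: WaveformChannel | None = None
) -> dict[str, float]:
    """Respiratory feature vector from corrected breath events.

    * ``resp_rate`` = 60000 / mean BB interval (breaths/min)
    * ``amplitude`` = mean per-breath excursion (peak value minus the
      preceding trough value) in channel units; requires ``sig``
    * ``phase_ratio`` = mean inspiratory duration (trough -> peak) over
      mean expiratory duration (peak -> next trough)
    * ``sdbb`` / ``rmssd_bb`` = SD and RMS of successive differences of
      the BB intervals, ms
    """
    bb = events.bb_intervals
    if bb.size < 2:
        raise ValueError("need at least 2 BB intervals")
    peaks, onsets = events.peak_times, events.inhale_onsets

    # pair each peak with its preceding onset and following onset
    insp, exp = [], []
    for i, p in enumerate(peaks):
        prev = onsets[onsets < p]
        nxt = onsets[onsets > p]
        if prev.size:
            insp.append(p - prev[-1])
        if nxt.size:
            exp.append(nxt[0] - p)
    phase_ratio = float(np.mean(insp) / np.mean(exp)) if insp and exp else np.nan

    amplitude = np.nan
    if sig is not None:
        idx_peak = np.clip(np.round(peaks * sig.fs).astype(int), 0, sig.n - 1)
        exc = []
        for i, p in enumerate(peaks):
            prev = onsets[onsets < p]
            if not prev.size:
                continue
            j = int(np.clip(round(prev[-1] * sig.fs), 0, sig.n - 1))
            exc.append(sig.samples[idx_peak[i]] - sig.samples[j])
        if exc:
            amplitude = float(np.mean(exc))

    diffs = np.diff(bb)
    return {
        "resp_rate": float(60000.0 / np.mean(bb)),
        "amplitude": amplitude,
        "phase_ratio": phase_ratio,
        "sdbb": float(np.std(bb, ddof=1)),
        "rmssd_bb": float(np.sqrt(np.mean(diffs**2))) if diffs.size else 0.0,
    }
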