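"""Cardiac pipeline: raw ECG -> corrected RR series -> HRV features.

Stages
------
1. :func:`filter_ecg` — zero-phase 0.5 Hz high-pass Butterworth
   (order 5) followed by a mains notch.
2. :func:`detect_r_peaks` — derivative / square / moving-window
   integration with an adaptive threshold and a 200 ms refractory
   period; polarity-insensitive peak refinement.
3. :func:`correct_rr_intervals` — automated stand-in for manual
   artifact review: implausible intervals are flagged, split, merged or
   interpolated; recordings with more than 20 % flagged intervals are
   declared unusable.
4. :func:`select_segment` — a contiguous analysis window (default
   11 min = 660 s) taken after the configured induction offset.
5. Features: time-domain (:func:`hrv_time_domain`), Welch spectral
   (:func:`hrv_frequency_domain`), approximate entropy
   (:func:`approximate_entropy`) and the multiplicative heart-rate
   correction of the spectral metrics (:func:`sacha_correction`).

Spectral conventions: the RR tachogram (ms vs beat time) is cubically
interpolated onto a uniform 4 Hz grid and analysed with Welch
(120 s Hann segments, 50 % overlap); LF = [0.04, 0.15) Hz,
HF = [0.15, 0.4) Hz; normalized powers divide by total power over
[0.04, 0.4) Hz so VLF is excluded.  Raw band powers are in ms^2; the
heart-rate-corrected variants multiply each spectral metric by the
segment mean RR expressed in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal
from scipy.spatial.distance import cdist

from .channels import EventSeries, RRSeries, UnusableRecordingError, WaveformChannel

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
TOTAL_BAND = (0.04, 0.40)

#: artifact plausibility bounds for RR intervals, ms
RR_BOUNDS = (300.0, 2000.0)
#: relative deviation from running median that flags an interval
RR_DEVIATION = 0.30
#: running-median window (intervals)
MEDIAN_WINDOW = 11
#: fraction of flagged intervals above which a recording is unusable
MAX_FLAG_FRACTION = 0.20


@dataclass(frozen=True)
class CardiacFeatures:
    """HRV feature vector for one recording segment.

    Spectral powers are raw (ms^2) with heart-rate-corrected variants
    (suffix ``_c``) obtained by multiplying by the mean RR interval in
    seconds.  ``None`` marks an undefined value (e.g. ln HF when the HF
    power is zero) — never infinity.
    """

    heart_rate: float
    rr_mean: float
    sdnn: float
    rmssd: float
    pnn50: float
    apen: float | None = None
    lf: float | None = None
    hf: float | None = None
    lfn: float | None = None
    hfn: float | None = None
    ln_hf: float | None = None
    lf_hf_ratio: float | None = None
    lf_c: float | None = None
    hf_c: float | None = None
    ln_hf_c: float | None = None
    lf_hf_ratio_c: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {k: getattr(self, k) for k in CARDIAC_FEATURES}


#: the 16-metric cardiac registry
CARDIAC_FEATURES = (
    "heart_rate", "rr_mean", "sdnn", "rmssd", "pnn50", "apen",
    "lf", "hf", "lfn", "hfn", "ln_hf", "lf_hf_ratio",
    "lf_c", "hf_c", "ln_hf_c", "lf_hf_ratio_c",
)


# ---------------------------------------------------------------------------
# Preprocessing and detection

def filter_ecg(
    raw: WaveformChannel,
    highpass_hz: float = 0.5,
    order: int = 5,
    mains_hz: float = 50.0,
    notch_q: float = 30.0,
) -> WaveformChannel:
    """Zero-phase high-pass plus mains notch filtering of a raw ECG."""
    if raw.fs < 100:
        raise ValueError(f"fs must be >= 100 Hz, got {raw.fs}")
    if raw.duration < 10:
        raise ValueError(f"recording must be >= 10 s, got {raw.duration:.1f} s")
    if mains_hz >= raw.fs / 2:
        raise ValueError(
            f"mains frequency {mains_hz} Hz is not below Nyquist ({raw.fs / 2} Hz)"
        )
    sos = signal.butter(order, highpass_hz, btype="highpass", fs=raw.fs, output="sos")
    x = signal.sosfiltfilt(sos, raw.samples)
    b, a = signal.iirnotch(mains_hz, notch_q, fs=raw.fs)
    x = signal.filtfilt(b, a, x)
    return raw.with_samples(x)


def detect_r_peaks(
    ecg: WaveformChannel,
    refractory_s: float = 0.2,
    integration_window_s: float = 0.15,
    edge_margin_s: float = 0.5,
) -> EventSeries:
    """Locate R peaks in a (filtered) ECG.

    Derivative -> squaring -> moving-window integration produces an
    energy envelope; candidate beats are envelope peaks above an
    adaptive threshold separated by at least the refractory period.
    Each candidate is then refined to the local maximum of the absolute
    filtered signal, which makes detection insensitive to electrode
    polarity.  Peaks within ``edge_margin_s`` of either recording
    boundary are discarded: zero-phase filter transients and truncated
    complexes there are not reliably localizable.  Returns an empty
    series when no plausible beat is found.
    """
    x = ecg.samples
    fs = ecg.fs
    if x.size < int(fs):
        return EventSeries(np.empty(0))
    deriv = np.gradient(x) * fs
    energy = deriv**2
    win = max(int(integration_window_s * fs), 1)
    mwi = np.convolve(energy, np.ones(win) / win, mode="same")
    peak_level = np.quantile(mwi, 0.99)
    if peak_level <= 0 or not np.isfinite(peak_level):
        return EventSeries(np.empty(0))
    threshold = 0.25 * peak_level
    dist = max(int(refractory_s * fs), 1)
    cand, _ = signal.find_peaks(mwi, height=threshold, distance=dist)
    if cand.size == 0:
        return EventSeries(np.empty(0))

    # refine each candidate to the extremum of |ecg| nearby
    half = int(0.1 * fs)
    refined = np.empty(cand.size, dtype=int)
    absx = np.abs(x)
    for i, c in enumerate(cand):
        lo, hi = max(c - half, 0), min(c + half + 1, x.size)
        refined[i] = lo + int(np.argmax(absx[lo:hi]))
    refined = np.unique(refined)
    # enforce the refractory period after refinement: keep the larger peak
    keep: list[int] = []
    for idx in refined:
        if keep and (idx - keep[-1]) < dist:
            if absx[idx] > absx[keep[-1]]:
                keep[-1] = idx
        else:
            keep.append(idx)
    times = np.asarray(keep, dtype=float) / fs
    lo_t, hi_t = edge_margin_s, ecg.duration - edge_margin_s
    return EventSeries(times[(times >= lo_t) & (times <= hi_t)])


# ---------------------------------------------------------------------------
# Artifact correction

def _running_median(values: np.ndarray, window: int = MEDIAN_WINDOW) -> np.ndarray:
    half = window // 2
    out = np.empty_like(values)
    for i in range(values.size):
        lo, hi = max(i - half, 0), min(i + half + 1, values.size)
        out[i] = np.median(values[lo:hi])
    return out


def correct_rr_intervals(
    rr: RRSeries,
    bounds: tuple[float, float] = RR_BOUNDS,
    deviation: float = RR_DEVIATION,
    max_flag_fraction: float = MAX_FLAG_FRACTION,
) -> RRSeries:
    """Automated replacement for manual RR artifact review.

    Rules (applied against a running median of 11 intervals):

    * interval > 1.65x the local median -> missed beat(s): split into
      ``round(interval / median)`` equal parts (new beats inserted);
    * interval < 0.55x the local median -> spurious detection: merged
      with its successor (beat removed);
    * outside ``bounds`` or deviating more than ``deviation`` from the
      local median -> replaced by cubic interpolation of the interval
      profile over the neighbouring clean beats.

    Raises :class:`UnusableRecordingError` when more than
    ``max_flag_fraction`` of the intervals had to be touched.
    """
    return _correct_intervals(
        rr.beat_times,
        bounds=bounds,
        deviation=deviation,
        max_flag_fraction=max_flag_fraction,
        min_intervals=10,
        split_threshold=1.65,
        merge_threshold=0.55,
        kind="RR",
    )


def _correct_intervals(
    event_times: np.ndarray,
    *,
    bounds: tuple[float, float],
    deviation: float,
    max_flag_fraction: float,
    min_intervals: int,
    split_threshold: float,
    merge_threshold: float,
    kind: str,
) -> RRSeries:
    times = np.asarray(event_times, dtype=float)
    iv = np.diff(times) * 1000.0
    if iv.size < min_intervals:
        raise ValueError(f"need at least {min_intervals} intervals, got {iv.size}")
    n_original = iv.size
    med = _running_median(iv)

    # pass 1: structural fixes (split long intervals, merge short ones)
    new_times: list[float] = [times[0]]
    flags: list[bool] = []
    n_struct = 0
    i = 0
    while i < iv.size:
        interval, local = iv[i], med[i]
        ratio = interval / local if local > 0 else np.inf
        if ratio > split_threshold:
            parts = int(np.clip(np.round(ratio), 2, 10))
            step = interval / parts / 1000.0
            for p in range(parts):
                new_times.append(times[i] + (p + 1) * step)
                flags.append(True)
            n_struct += 1
            i += 1
        elif ratio < merge_threshold and i + 1 < iv.size:
            new_times.append(times[i + 2])
            flags.append(True)
            n_struct += 1
            i += 2
        else:
            new_times.append(times[i + 1])
            flags.append(False)
            i += 1

    times2 = np.asarray(new_times)
    flags2 = np.asarray(flags, dtype=bool)
    iv2 = np.diff(times2) * 1000.0
    med2 = _running_median(iv2)

    # pass 2: replace out-of-bounds / deviant intervals by interpolation
    bad = (
        (iv2 < bounds[0])
        | (iv2 > bounds[1])
        | (np.abs(iv2 - med2) > deviation * med2)
    ) & ~flags2
    if np.any(bad) and np.sum(~bad) >= 4:
        idx = np.arange(iv2.size)
        spline = interpolate.CubicSpline(idx[~bad], iv2[~bad])
        iv2 = iv2.copy()
        iv2[bad] = spline(idx[bad])
        iv2 = np.clip(iv2, bounds[0] * 0.5, bounds[1] * 1.5)
        times2 = np.concatenate([[times2[0]], times2[0] + np.cumsum(iv2) / 1000.0])
        flags2 = flags2 | bad

    n_flagged = n_struct + int(np.sum(bad)) if np.any(bad) else n_struct
    if n_flagged / n_original > max_flag_fraction:
        raise UnusableRecordingError(
            reason=f"excessive_{kind.lower()}_artifacts",
            message=(
                f"{n_flagged}/{n_original} {kind} intervals flagged "
                f"(> {max_flag_fraction:.0%}); recording unusable"
            ),
        )
    return RRSeries(beat_times=times2, intervals=np.diff(times2) * 1000.0,
                    corrected_flags=flags2)


def select_segment(
    rr: RRSeries,
    length: float = 660.0,
    start: float = 0.0,
) -> RRSeries:
    """Contiguous analysis window of exactly ``length`` seconds.

    ``start`` is the segment offset in seconds (typically the end of
    the trance-induction period).  Rejects recordings shorter than
    ``start + length``.
    """
    available = float(rr.beat_times[-1])
    if available < start + length:
        raise ValueError(
            f"recording too short: need {start + length:.0f} s "
            f"(offset {start:.0f} + window {length:.0f}), have {available:.1f} s"
        )
    mask = (rr.beat_times >= start) & (rr.beat_times <= start + length)
    times = rr.beat_times[mask]
    idx = np.flatnonzero(mask)[:-1]
    return RRSeries(
        beat_times=times,
        intervals=np.diff(times) * 1000.0,
        corrected_flags=rr.corrected_flags[idx] if idx.size else np.empty(0, bool),
    )


# ---------------------------------------------------------------------------
# Feature computation

def hrv_time_domain(rr: RRSeries) -> dict[str, float]:
    """Time-domain HRV metrics.

    heart_rate is the mean instantaneous rate (mean of 60000/RR_i),
    sdnn the SD of the intervals, rmssd the root-mean-square of
    successive differences and pnn50 the percentage of successive
    differences exceeding 50 ms.
    """
    iv = rr.intervals
    if iv.size < 2:
        raise ValueError("need at least 2 intervals")
    diffs = np.diff(iv)
    return {
        "heart_rate": float(np.mean(60000.0 / iv)),
        "rr_mean": float(np.mean(iv)),
        "sdnn": float(np.std(iv, ddof=1)),
        "rmssd": float(np.sqrt(np.mean(diffs**2))),
        "pnn50": float(100.0 * np.mean(np.abs(diffs) > 50.0)),
    }


def rr_tachogram(
    rr: RRSeries, resample_hz: float = 4.0
) -> tuple[np.ndarray, float]:
    """Cubic interpolation of the RR tachogram onto a uniform grid."""
    t, v = rr.beat_times[1:], rr.intervals
    if t.size < 4:
        raise ValueError("need at least 4 intervals for spectral analysis")
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    spline = interpolate.CubicSpline(t, v)
    return spline(grid), resample_hz


def hrv_frequency_domain(
    rr: RRSeries,
    resample_hz: float = 4.0,
    welch_segment_s: float = 120.0,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
    total_band: tuple[float, float] = TOTAL_BAND,
) -> dict[str, float | None]:
    """Welch spectral HRV of the interpolated tachogram.

    Returns raw band powers in ms^2 (``lf``, ``hf``), powers normalized
    by total power over ``total_band`` (``lfn``, ``hfn``), the natural
    log of HF and the LF/HF ratio.  When HF is zero, ln HF and the
    ratio are returned as ``None`` (undefined, never infinite).
    """
    if rr.duration < 120:
        raise ValueError(
            f"segment must be >= 120 s for spectral HRV, got {rr.duration:.1f} s"
        )
    x, fs = rr_tachogram(rr, resample_hz)
    nperseg = min(int(welch_segment_s * fs), x.size)
    freqs, psd = signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend="constant",
    )

    def band_power(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs < hi)
        return float(np.trapezoid(psd[mask], freqs[mask])) if np.any(mask) else 0.0

    lf = band_power(*lf_band)
    hf = band_power(*hf_band)
    total = band_power(*total_band)
    lfn = lf / total if total > 0 else None
    hfn = hf / total if total > 0 else None
    return {
        "lf": lf,
        "hf": hf,
        "lfn": lfn,
        "hfn": hfn,
        "ln_hf": float(np.log(hf)) if hf > 0 else None,
        "lf_hf_ratio": lf / hf if hf > 0 else None,
    }


def approximate_entropy(
    values: np.ndarray | RRSeries,
    m: int = 2,
    r: float | None = None,
) -> float:
    """Approximate entropy ApEn(m, r) of a series.

    Template matches use the Chebyshev distance and include
    self-matches; ``r`` defaults to 0.2 x SD of the series.  ApEn is
    ``Phi_m - Phi_{m+1}`` with ``Phi_m`` the mean log fraction of
    templates within tolerance.
    """
    x = values.intervals if isinstance(values, RRSeries) else np.asarray(values, float)
    n = x.size
    if n < 50:
        raise ValueError(f"need at least 50 points for ApEn, got {n}")
    if n < m + 2:
        raise ValueError("series shorter than m + 1")
    if r is None:
        r = 0.2 * float(np.std(x, ddof=0))
    if r <= 0:
        return 0.0  # constant series: every template matches at any tolerance

    def phi(mm: int) -> float:
        k = n - mm + 1
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = cdist(emb, emb, metric="chebyshev")
        counts = np.sum(d <= r, axis=1) / k
        return float(np.mean(np.log(counts)))

    return phi(m) - phi(m + 1)


def sacha_correction(
    spectral: dict[str, float | None], rr_mean_ms: float
) -> dict[str, float | None]:
    """Heart-rate correction of spectral HRV: multiply each raw
    spectral power by the segment mean RR interval (in seconds).

    This removes the mathematical dependence of spectral HRV on heart
    rate: power scales with the square of cycle length, so dividing out
    one factor of mean RR decorrelates the metric from rate.  The
    normalized powers and the LF/HF ratio are scale-invariant, so only
    their values recomputed from the corrected powers are returned for
    completeness (they equal the raw ones).
    """
    if rr_mean_ms <= 0:
        raise ValueError("mean RR must be positive")
    mult = rr_mean_ms / 1000.0
    lf, hf = spectral.get("lf"), spectral.get("hf")
    lf_c = lf * mult if lf is not None else None
    hf_c = hf * mult if hf is not None else None
    return {
        "lf_c": lf_c,
        "hf_c": hf_c,
        "ln_hf_c": float(np.log(hf_c)) if hf_c else None,
        "lf_hf_ratio_c": (lf_c / hf_c) if (lf_c is not None and hf_c) else None,
    }


def cardiac_features(
    rr: RRSeries,
    apen_m: int = 2,
    apen_r_factor: float = 0.2,
    **spectral_kwargs,
) -> CardiacFeatures:
    """Full 16-metric cardiac feature vector for one RR segment."""
    td = hrv_time_domain(rr)
    fd = hrv_frequency_domain(rr, **spectral_kwargs)
    corrected = sacha_correction(fd, td["rr_mean"])
    apen = approximate_entropy(
        rr.intervals, m=apen_m, r=apen_r_factor * float(np.std(rr.intervals))
    )
    return CardiacFeatures(**td, apen=apen, **fd, **corrected)
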