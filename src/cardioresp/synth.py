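"""Synthetic cohort generator for cardio-respiratory recordings.

Generates raw ECG and respiration-belt waveforms with known ground
truth (beat times, breath landmarks, injected condition effects) so the
whole extraction/decoding pipeline can be exercised and validated
without access to human recordings.  The generator emulates a
three-condition within-subject study design — quiet rest (``Rest``), a
mental-imagery control task (``Imag``) and self-induced cognitive
trance (``SICT``) — in which the trance condition raises heart rate and
overall RR variability while withdrawing respiratory-band (vagal) RR
modulation, and deepens/slows the breathing pattern (larger amplitude,
longer relative inspiration, more breath-to-breath jitter).

Model
-----
RR intervals are generated by direct interval modulation evaluated at
beat times::

    RR_i = mean_rr + lf_depth * sin(2*pi*f_LF*t_i + phi_LF)
                   + hf_depth * sin(2*pi*f_HF*t_i + phi_HF) + e_i

where ``f_LF`` defaults to 0.10 Hz, ``f_HF`` to the respiratory
frequency, and ``e_i`` mixes a broadband (white, high-entropy) and an
AR(1) (smooth, low-entropy) component in proportion ``hr_entropy_mix``.
This is deliberately not an integral-pulse-frequency-modulation model:
band powers and their ground truth are what downstream stages consume,
not beat-generation physiology.

Respiration is a piecewise raised-cosine per breath whose inspiratory
and expiratory segment durations are in exact ratio ``ie_ratio``, so
the phase-duration ratio is known by construction; breath-to-breath
jitter is injected directly on the B-peak (exhalation-onset) times so
SDBB ground truth equals ``bb_jitter_sd``.

Determinism: every stream is seeded through
``numpy.random.SeedSequence(master_seed, spawn_key=(subject, condition,
channel))`` — identical configuration and master seed give bit-identical
recordings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .channels import (
    ROLE_ABDOMINAL,
    ROLE_ECG,
    ROLE_THORACIC,
    EventSeries,
    WaveformChannel,
)

CONDITIONS = ("Rest", "Imag", "SICT")

#: AR(1) coefficient of the smooth noise component
_AR1_PHI = 0.9
#: per-breath amplitude jitter (coefficient of variation)
_AMP_CV = 0.10
#: abdominal belt gain relative to thoracic
_ABDOMINAL_GAIN = 0.75


class ProfileError(ValueError):
    """A condition profile violates its physiological invariants."""


@dataclass(frozen=True)
class ConditionProfile:
    """Generative parameters for one experimental condition.

    All interval quantities are in ms, rates in breaths/min,
    frequencies in Hz.  ``hr_entropy_mix`` is the fraction of RR noise
    variance assigned to the broadband (white) component; the remainder
    is AR(1) with coefficient 0.9, so higher values produce a more
    irregular (higher approximate entropy) tachogram.
    """

    name: str
    mean_rr: float = 874.0
    lf_depth: float = 35.0
    hf_depth: float = 40.0
    rr_noise_sd: float = 28.0
    hr_entropy_mix: float = 0.85
    resp_rate: float = 15.4
    resp_amp: float = 210.0
    ie_ratio: float = 0.74
    bb_jitter_sd: float = 350.0
    lf_freq: float = 0.10
    hf_freq: float | None = None  # default: resp_rate / 60

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not (300.0 <= self.mean_rr <= 2000.0):
            raise ProfileError(f"mean_rr must be in [300, 2000] ms, got {self.mean_rr}")
        if self.resp_rate <= 0:
            raise ProfileError(f"resp_rate must be positive, got {self.resp_rate}")
        if self.ie_ratio <= 0:
            raise ProfileError(f"ie_ratio must be positive, got {self.ie_ratio}")
        for name in ("lf_depth", "hf_depth", "rr_noise_sd", "resp_amp", "bb_jitter_sd"):
            if getattr(self, name) < 0:
                raise ProfileError(f"{name} must be non-negative")
        if not (0.0 <= self.hr_entropy_mix <= 1.0):
            raise ProfileError("hr_entropy_mix must be in [0, 1]")
        if self.lf_depth + self.hf_depth + self.rr_noise_sd >= self.mean_rr / 2:
            raise ProfileError(
                "lf_depth + hf_depth + rr_noise_sd must stay below mean_rr/2 "
                "to avoid non-physiological intervals"
            )

    @property
    def resolved_hf_freq(self) -> float:
        return self.resp_rate / 60.0 if self.hf_freq is None else self.hf_freq

    def scaled(self, factors: dict[str, float]) -> "ConditionProfile":
        """Return a copy with multiplicative offsets applied to fields
        (used for per-subject random effects)."""
        updates = {k: getattr(self, k) * v for k, v in factors.items()}
        return dataclasses.replace(self, **updates)


@dataclass(frozen=True)
class RespirationTruth:
    """Ground-truth breath landmarks for one synthetic belt signal."""

    peak_times: np.ndarray      # B peaks (inhalation maxima / exhalation onsets), s
    trough_times: np.ndarray    # inhalation onsets, s
    amplitudes: np.ndarray      # per-breath trough-to-peak excursion, channel units

    @property
    def bb_intervals(self) -> np.ndarray:
        return np.diff(self.peak_times) * 1000.0


@dataclass
class SyntheticRecording:
    """One subject-condition recording with its generation ground truth.

    The waveform channels may be ``None`` when a cohort is generated in
    events-only mode (``waveforms=False``), which is faster and
    sufficient for studies of the feature/decoding layers; the truth
    event series are always populated.
    """

    subject_id: str
    condition: str
    profile_used: ConditionProfile
    truth_r_times: np.ndarray
    truth_resp: RespirationTruth
    ecg: WaveformChannel | None = None
    thoracic: WaveformChannel | None = None
    abdominal: WaveformChannel | None = None
    trance_intensity: float | None = None
    induction_end_s: float = 0.0

    @property
    def truth_breath_times(self) -> np.ndarray:
        return self.truth_resp.peak_times

    @property
    def truth_rr(self) -> EventSeries:
        return EventSeries(self.truth_r_times)


# ---------------------------------------------------------------------------
# RR-series generation

def generate_rr_series(
    profile: ConditionProfile,
    duration: float,
    seed: int | np.random.Generator = 0,
) -> EventSeries:
    """Generate beat times whose RR intervals follow the profile.

    Parameters
    ----------
    profile : ConditionProfile
    duration : float
        Recording duration in seconds (>= 120 s).
    seed : int or Generator
        Seed (or generator) for the noise and modulation phases.

    Returns
    -------
    EventSeries
        Beat times in seconds starting at 0; the cumulative sum of the
        RR intervals never exceeds ``duration``.
    """
    profile.validate()
    if duration < 120:
        raise ValueError(f"duration must be >= 120 s, got {duration}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    # worst-case beat count to pre-draw the noise sequences
    rr_floor = profile.mean_rr - profile.lf_depth - profile.hf_depth
    n_max = int(np.ceil(duration * 1000.0 / max(rr_floor - 5 * profile.rr_noise_sd, 250.0))) + 8

    deterministic = (
        profile.lf_depth == 0 and profile.hf_depth == 0 and profile.rr_noise_sd == 0
    )
    phi_lf, phi_hf = (0.0, 0.0) if deterministic else tuple(rng.uniform(0, 2 * np.pi, 2))

    white_sd = np.sqrt(profile.hr_entropy_mix) * profile.rr_noise_sd
    ar_sd = np.sqrt(1.0 - profile.hr_entropy_mix) * profile.rr_noise_sd
    white = rng.normal(0.0, 1.0, n_max) * white_sd
    ar = np.zeros(n_max)
    innov = rng.normal(0.0, 1.0, n_max)
    if ar_sd > 0:
        # stationary AR(1) with marginal sd ar_sd
        ar[0] = innov[0] * ar_sd
        c = ar_sd * np.sqrt(1.0 - _AR1_PHI**2)
        for i in range(1, n_max):
            ar[i] = _AR1_PHI * ar[i - 1] + c * innov[i]
    noise = white + ar

    f_lf, f_hf = profile.lf_freq, profile.resolved_hf_freq
    times = np.empty(n_max + 1)
    times[0] = 0.0
    t = 0.0
    n = 0
    for i in range(n_max):
        rr = (
            profile.mean_rr
            + profile.lf_depth * np.sin(2 * np.pi * f_lf * t + phi_lf)
            + profile.hf_depth * np.sin(2 * np.pi * f_hf * t + phi_hf)
            + noise[i]
        )
        rr = max(rr, 250.0)  # hard physiological floor; unreachable for valid profiles
        if t + rr / 1000.0 > duration:
            break
        t += rr / 1000.0
        n += 1
        times[n] = t
    return EventSeries(times[: n + 1])


# ---------------------------------------------------------------------------
# ECG synthesis

def _qrs_kernel(tau: np.ndarray) -> np.ndarray:
    """Fixed biphasic QRS-like kernel, global maximum exactly at tau=0."""
    return (
        np.exp(-((tau / 0.012) ** 2))
        - 0.30 * np.exp(-(((tau - 0.028) / 0.014) ** 2))
        - 0.22 * np.exp(-(((tau + 0.028) / 0.014) ** 2))
    )


def synthesize_ecg(
    r_times: np.ndarray,
    fs: float = 250.0,
    *,
    baseline_wander: bool = False,
    powerline: bool = False,
    powerline_freq: float = 50.0,
    noise_sd: float = 0.0,
    duration: float | None = None,
    seed: int | np.random.Generator = 0,
) -> WaveformChannel:
    """Render an ECG waveform with one QRS complex per R time.

    The kernel is a fixed biphasic template whose maximum sits exactly
    on the R time, so a correct detector recovers each truth event to
    within one sample.  Optional baseline wander (0.25 Hz) and mains
    contamination can be toggled on to exercise the filtering stages.
    """
    r_times = np.asarray(r_times, dtype=float)
    if r_times.size == 0:
        raise ValueError("r_times must contain at least one event")
    if np.any(np.diff(r_times) <= 0):
        raise ValueError("r_times must be strictly increasing")
    if fs < 100:
        raise ValueError(f"fs must be >= 100 Hz, got {fs}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    if duration is None:
        duration = float(r_times[-1]) + 0.5
    n = int(np.round(duration * fs))
    sig = np.zeros(n)
    half = int(np.round(0.12 * fs))  # kernel support: +-120 ms
    for rt in r_times:
        c = int(np.round(rt * fs))
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        if lo >= hi:
            continue
        tau = np.arange(lo, hi) / fs - rt
        sig[lo:hi] += _qrs_kernel(tau)

    t = np.arange(n) / fs
    if baseline_wander:
        sig += 0.25 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    if powerline:
        sig += 0.10 * np.sin(2 * np.pi * powerline_freq * t)
    if noise_sd > 0:
        sig += rng.normal(0.0, noise_sd, n)
    return WaveformChannel(sig, fs, ROLE_ECG)


# ---------------------------------------------------------------------------
# Respiration synthesis

def generate_breath_truth(
    profile: ConditionProfile,
    duration: float,
    seed: int | np.random.Generator = 0,
    amplitude_scale: float = 1.0,
) -> RespirationTruth:
    """Draw ground-truth breath landmarks for one belt channel.

    B-peak times carry white jitter of SD ``bb_jitter_sd`` directly on
    the inter-peak interval, so the ground-truth SDBB equals the
    configured jitter.  The trough (inhalation-onset) between two B
    peaks divides the interval so that inspiration:expiration durations
    are in exact ratio ``ie_ratio``.
    """
    profile.validate()
    if duration < 120:
        raise ValueError(f"duration must be >= 120 s, got {duration}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    period = 60.0 / profile.resp_rate  # s
    r = profile.ie_ratio
    n_max = int(np.ceil(duration / max(period - 3 * profile.bb_jitter_sd / 1000.0, 1.6))) + 4

    bb = period + rng.normal(0.0, profile.bb_jitter_sd / 1000.0, n_max)
    bb = np.maximum(bb, 1.6)  # enforce the minimum breath period
    # lead-in keeps the first trough clear of the recording edge (and of
    # zero-phase filter transients); trailing room leaves space for the
    # final expiratory trough so every peak is a detectable extremum
    lead_in = 0.8
    peaks = lead_in + period * r / (1.0 + r) + np.concatenate([[0.0], np.cumsum(bb)])
    peaks = peaks[peaks <= duration - period / (1.0 + r) - 0.2]
    if peaks.size < 2:
        raise ValueError("duration too short for the configured respiratory rate")

    # troughs at the I:E split point between peaks, plus the leading
    # (inhalation-onset) and trailing (expiration-end) troughs
    troughs = peaks[:-1] + np.diff(peaks) / (1.0 + r)
    lead_trough = peaks[0] - period * r / (1.0 + r)
    tail_trough = min(peaks[-1] + period / (1.0 + r), duration)
    troughs = np.concatenate([[lead_trough], troughs, [tail_trough]])

    amps = amplitude_scale * profile.resp_amp * (
        1.0 + _AMP_CV * rng.standard_normal(peaks.size)
    )
    amps = np.maximum(amps, 0.05 * profile.resp_amp * amplitude_scale)
    return RespirationTruth(peak_times=peaks, trough_times=troughs, amplitudes=amps)


def render_respiration(
    truth: RespirationTruth,
    duration: float,
    fs: float = 250.0,
    role: str = ROLE_THORACIC,
) -> WaveformChannel:
    """Render the piecewise raised-cosine belt waveform for given truth."""
    peaks, troughs, amps = truth.peak_times, truth.trough_times, truth.amplitudes
    # interleave extrema (time, value) in temporal order
    ev_t = np.concatenate([troughs, peaks])
    # trough k precedes peak k when a leading trough exists
    trough_vals = np.empty(troughs.size)
    for k, tt in enumerate(troughs):
        nxt = np.searchsorted(peaks, tt)
        ref = amps[min(nxt, amps.size - 1)]
        trough_vals[k] = -ref / 2.0
    ev_v = np.concatenate([trough_vals, amps / 2.0])
    order = np.argsort(ev_t)
    ev_t, ev_v = ev_t[order], ev_v[order]

    n = int(np.round(duration * fs))
    t = np.arange(n) / fs
    sig = np.empty(n)
    # raised-cosine interpolation between consecutive extrema
    idx = np.searchsorted(ev_t, t, side="right") - 1
    idx = np.clip(idx, 0, ev_t.size - 2)
    t0, t1 = ev_t[idx], ev_t[idx + 1]
    v0, v1 = ev_v[idx], ev_v[idx + 1]
    frac = np.clip((t - t0) / np.maximum(t1 - t0, 1e-9), 0.0, 1.0)
    sig = v0 + (v1 - v0) * (1.0 - np.cos(np.pi * frac)) / 2.0
    # boundary approaches: half-cosine from/to the midline so the first
    # and last extrema remain detectable local extrema, not plateaus
    pre = t < ev_t[0]
    if np.any(pre) and ev_t[0] > 0:
        f = t[pre] / ev_t[0]
        sig[pre] = ev_v[0] * (1.0 - np.cos(np.pi * f)) / 2.0
    post = t > ev_t[-1]
    if np.any(post) and duration > ev_t[-1]:
        f = np.clip((t[post] - ev_t[-1]) / max(duration - ev_t[-1], 1e-9), 0, 1)
        sig[post] = ev_v[-1] * (1.0 + np.cos(np.pi * f)) / 2.0
    return WaveformChannel(sig, fs, role)


def synthesize_respiration(
    profile: ConditionProfile,
    duration: float,
    seed: int | np.random.Generator = 0,
    fs: float = 250.0,
    role: str = ROLE_THORACIC,
) -> WaveformChannel:
    """Generate a quasi-periodic respiration-belt waveform."""
    truth = generate_breath_truth(profile, duration, seed)
    return render_respiration(truth, duration, fs, role)


# ---------------------------------------------------------------------------
# Cohort generation

#: Default study-condition profiles.  Heart-rate targets follow the
#: reported group means (Rest 69.25 bpm, SICT 81.07 bpm; the mean_rr
#: values include the small Jensen correction for the curvature of
#: 60000/RR).  Imag is generated identically to Rest.  The trance
#: condition raises heart rate, slow (LF) RR modulation and broadband
#: RR noise, withdraws respiratory-band (HF) modulation, lowers the
#: entropy mix (more regular tachogram), and deepens breathing:
#: larger amplitude, inspiration longer relative to expiration
#: (phase ratio 0.74 -> 1.04) and larger breath-to-breath jitter.
DEFAULT_PROFILES: dict[str, ConditionProfile] = {
    "Rest": ConditionProfile(
        name="Rest", mean_rr=874.0, lf_depth=35.0, hf_depth=40.0, rr_noise_sd=28.0,
        hr_entropy_mix=0.85, resp_rate=15.41, resp_amp=210.0, ie_ratio=0.74,
        bb_jitter_sd=350.0,
    ),
    "Imag": ConditionProfile(
        name="Imag", mean_rr=874.0, lf_depth=35.0, hf_depth=40.0, rr_noise_sd=28.0,
        hr_entropy_mix=0.85, resp_rate=15.41, resp_amp=210.0, ie_ratio=0.74,
        bb_jitter_sd=350.0,
    ),
    "SICT": ConditionProfile(
        name="SICT", mean_rr=750.0, lf_depth=65.0, hf_depth=12.0, rr_noise_sd=42.0,
        hr_entropy_mix=0.05, resp_rate=14.96, resp_amp=375.0, ie_ratio=1.04,
        bb_jitter_sd=900.0,
    ),
}

#: Per-subject multiplicative random-effect CVs (shared across the
#: subject's three conditions, preserving the within-subject pairing).
DEFAULT_SUBJECT_EFFECT_CV: dict[str, float] = {
    "mean_rr": 0.08,
    "lf_depth": 0.25,
    "hf_depth": 0.25,
    "rr_noise_sd": 0.15,
    "resp_rate": 0.15,
    "resp_amp": 0.30,
    "ie_ratio": 0.15,
    "bb_jitter_sd": 0.30,
}


@dataclass(frozen=True)
class SubjectSpec:
    """Per-subject draw: identifier plus multiplicative offsets applied
    to every condition profile of that subject."""

    subject_id: str
    random_effects: dict[str, float]
    seed: int


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic cohort."""

    n_subjects: int = 26
    duration: float = 720.0  # ~12 min recorded; an 11-min segment is analyzed
    fs: float = 250.0
    profiles: dict[str, ConditionProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    subject_effect_cv: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBJECT_EFFECT_CV)
    )
    master_seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")


#: reserved condition-slot indices for subject-level streams
_EFFECTS_STREAM = 1000
_INTENSITY_STREAM = 1001


def _subject_rng(master_seed: int, subject: int, condition: int, channel: int = 0):
    """Documented seed-splitting rule: one independent stream per
    (subject, condition, channel) via SeedSequence spawn keys; the
    reserved condition slots 1000/1001 carry the subject-level
    random-effects and self-report streams."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(subject, condition, channel))
    )


def draw_subject_specs(config: CohortConfig) -> list[SubjectSpec]:
    """Draw per-subject random effects (deterministic under master_seed).

    Effects are truncated-normal multipliers around 1 (clipped at
    +-2.5 CV) so that group means stay close to the profile targets.
    """
    specs = []
    for s in range(config.n_subjects):
        rng = _subject_rng(config.master_seed, s, _EFFECTS_STREAM)
        effects = {}
        for fname, cv in config.subject_effect_cv.items():
            g = 1.0 + cv * float(np.clip(rng.standard_normal(), -2.5, 2.5))
            effects[fname] = max(g, 0.05)
        specs.append(
            SubjectSpec(subject_id=f"S{s + 1:02d}", random_effects=effects, seed=s)
        )
    return specs


def generate_recording(
    profile: ConditionProfile,
    *,
    subject_id: str,
    condition: str,
    duration: float,
    fs: float,
    master_seed: int,
    subject_index: int,
    condition_index: int,
    waveforms: bool = True,
    trance_intensity: float | None = None,
) -> SyntheticRecording:
    """Generate one subject-condition recording (all three channels)."""
    rr_rng = _subject_rng(master_seed, subject_index, condition_index, 0)
    resp_rng = _subject_rng(master_seed, subject_index, condition_index, 1)

    rr = generate_rr_series(profile, duration, rr_rng)
    truth_resp = generate_breath_truth(profile, duration, resp_rng)
    abdominal_truth = RespirationTruth(
        peak_times=truth_resp.peak_times,
        trough_times=truth_resp.trough_times,
        amplitudes=truth_resp.amplitudes * _ABDOMINAL_GAIN,
    )

    ecg = thoracic = abdominal = None
    if waveforms:
        ecg_rng = _subject_rng(master_seed, subject_index, condition_index, 2)
        ecg = synthesize_ecg(rr.times, fs, duration=duration, seed=ecg_rng)
        thoracic = render_respiration(truth_resp, duration, fs, ROLE_THORACIC)
        abdominal = render_respiration(abdominal_truth, duration, fs, ROLE_ABDOMINAL)

    return SyntheticRecording(
        subject_id=subject_id,
        condition=condition,
        profile_used=profile,
        truth_r_times=rr.times,
        truth_resp=truth_resp,
        ecg=ecg,
        thoracic=thoracic,
        abdominal=abdominal,
        trance_intensity=trance_intensity,
    )


def generate_cohort(
    config: CohortConfig | None = None,
    *,
    waveforms: bool = True,
) -> list[SyntheticRecording]:
    """Generate the full synthetic cohort (all subjects x conditions).

    With ``waveforms=False`` only ground-truth event series are
    produced, which is much faster and sufficient for studying the
    feature and decoding layers (the waveform path is validated
    separately against the same truth).
    """
    config = config or CohortConfig()
    specs = draw_subject_specs(config)
    seen = set()
    recordings: list[SyntheticRecording] = []
    for s, spec in enumerate(specs):
        if spec.subject_id in seen:
            raise ValueError(f"duplicate subject_id {spec.subject_id!r}")
        seen.add(spec.subject_id)
        intensity_rng = _subject_rng(config.master_seed, s, _INTENSITY_STREAM)
        for c, (cond, base_profile) in enumerate(config.profiles.items()):
            profile = base_profile.scaled(spec.random_effects)
            intensity = (
                float(np.clip(np.round(intensity_rng.normal(6.69, 1.89)), 0, 10))
                if cond == "SICT"
                else None
            )
            recordings.append(
                generate_recording(
                    profile,
                    subject_id=spec.subject_id,
                    condition=cond,
                    duration=config.duration,
                    fs=config.fs,
                    master_seed=config.master_seed,
                    subject_index=s,
                    condition_index=c,
                    waveforms=waveforms,
                    trance_intensity=intensity,
                )
            )
    return recordings


# ---------------------------------------------------------------------------
# Heart-rate-dependence cohort (for validating the spectral-HRV correction)

def hr_dependent_profiles(
    n_subjects: int = 26,
    seed: int = 0,
    base_mean_rr: float = 850.0,
    base_hf_depth: float = 40.0,
) -> dict[tuple[str, str], ConditionProfile]:
    """Profiles with a built-in heart-rate -> HF-power dependence.

    The HF modulation depth scales as ``sqrt(base_mean_rr / mean_rr)``
    so that raw HF power is proportional to 1/mean_rr (faster heart
    rates carry *more* raw HF power) while HF multiplied by the mean RR
    interval is independent of heart rate up to a per-subject factor.
    This is the configuration under which the multiplicative
    heart-rate correction of spectral HRV should abolish the HF-vs-HR
    correlation.
    """
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, str], ConditionProfile] = {}
    cond_scale = {"Rest": 1.0, "Imag": 0.95, "SICT": 1.05}
    for s in range(n_subjects):
        subj_rr = base_mean_rr * np.exp(rng.normal(0.0, 0.18))
        subj_factor = np.exp(rng.normal(0.0, 0.05))
        for cond, k in cond_scale.items():
            mean_rr = float(np.clip(subj_rr * k, 450.0, 1600.0))
            hf_depth = base_hf_depth * np.sqrt(base_mean_rr / mean_rr) * subj_factor
            out[(f"S{s + 1:02d}", cond)] = ConditionProfile(
                name=cond,
                mean_rr=mean_rr,
                lf_depth=20.0,
                hf_depth=float(hf_depth),
                rr_noise_sd=6.0,
                hr_entropy_mix=0.5,
                resp_rate=15.0,
            )
    return out
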