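"""Analysis configuration: every tunable of the pipeline in one place.

Defaults follow the study constants where stated (0.5 Hz order-5 ECG
high-pass, 2 Hz order-5 belt low-pass, 11-min segments, LF 0.04-0.15 Hz,
HF 0.15-0.4 Hz, 1000 permutations, alpha 0.05) and documented package
choices elsewhere (4 Hz tachogram resampling, 120 s Welch segments,
ApEn m=2 / r=0.2 SD, artifact rules, within-subject permutation
scheme, 50 Hz mains).  Outputs embed a hash of the resolved
configuration so any result can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


@dataclass(frozen=True)
class AnalysisConfig:
    # ECG preprocessing
    ecg_highpass_hz: float = 0.5
    ecg_filter_order: int = 5
    mains_hz: float = 50.0  # Belgian mains; set 60 for North America
    notch_q: float = 30.0
    # segmenting
    segment_length_s: float = 660.0  # 11 min
    segment_start_s: float = 0.0     # offset after induction end
    # RR artifact rule
    rr_bounds_ms: tuple[float, float] = (300.0, 2000.0)
    rr_deviation: float = 0.30
    max_flag_fraction: float = 0.20
    # spectral HRV
    resample_hz: float = 4.0
    welch_segment_s: float = 120.0
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    total_band: tuple[float, float] = (0.04, 0.40)
    # ApEn
    apen_m: int = 2
    apen_r_factor: float = 0.2
    # respiration
    resp_lowpass_hz: float = 2.0
    resp_filter_order: int = 5
    min_breath_period_s: float = 1.5
    bb_bounds_ms: tuple[float, float] = (1500.0, 20000.0)
    bb_deviation: float = 0.40
    # decoding
    n_perm: int = 1000
    alpha: float = 0.05
    permutation_scheme: str = "within_subject"
    decode_seed: int = 0
    # phasic analysis
    phasic_metrics: tuple[str, ...] = ("hf", "hf_c")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @property
    def hash(self) -> str:
        """Short stable hash of the resolved configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise KeyError(f"unknown configuration key {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    @classmethod
    def from_json_file(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
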