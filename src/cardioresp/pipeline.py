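"""End-to-end pipeline: manifest -> features -> decoding + phasic reports.

Orchestrates the full analysis over a cohort: feature extraction for
every (subject, condition) recording, the three pairwise decoding
analyses with permutation maximum statistics, the phasic/tonic
analysis for the configured metrics, and the heart-rate /
respiration-rate dependence checks of the corrected spectral metrics.
Unusable recordings are excluded with machine-readable reasons; the
analysis proceeds while at least 3 subjects remain complete.  Every
output embeds the resolved configuration hash for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import features as feat
from .channels import UnusableRecordingError
from .config import AnalysisConfig
from .decode import CONDITION_PAIRS, ConditionDecoder, DecodingResults
from .io import read_manifest, read_recording
from .phasic import PhasicTonicAnalysis, PhasicTonicResults, dependence_check

log = logging.getLogger("cardioresp")


@dataclass
class PipelineResult:
    """All outputs of one pipeline run."""

    table: pd.DataFrame
    exclusions: list[dict]
    decoding: dict[tuple[str, str], DecodingResults]
    phasic: dict[str, PhasicTonicResults]
    dependence: list[dict]
    config: AnalysisConfig

    def decoding_frame(self) -> pd.DataFrame:
        frames = [res.summary() for res in self.decoding.values()]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config.hash,
            "n_feature_rows": len(self.table),
            "exclusions": self.exclusions,
            "decoding": {
                f"{a}_vs_{b}": res.to_dict() for (a, b), res in self.decoding.items()
            },
            "phasic": {m: res.to_dict() for m, res in self.phasic.items()},
            "dependence_checks": self.dependence,
        }

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "feature_table.csv", index=False)
        self.decoding_frame().to_csv(out / "decoding_report.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        with open(out / "config.json", "w") as fh:
            fh.write(self.config.to_json())
        with open(out / "exclusions.json", "w") as fh:
            json.dump(self.exclusions, fh, indent=2)


def analyze_table(
    table: pd.DataFrame,
    config: AnalysisConfig | None = None,
    exclusions: list[dict] | None = None,
    features: list[str] | None = None,
) -> PipelineResult:
    """Decoding + phasic + dependence analyses of a feature table."""
    config = config or AnalysisConfig()
    exclusions = list(exclusions or [])

    complete = (
        table.groupby("subject_id")["condition"].nunique()
        if len(table)
        else pd.Series(dtype=int)
    )
    n_complete = int((complete == 3).sum()) if len(complete) else 0
    if n_complete < 3:
        raise UnusableRecordingError(
            "too_few_complete_subjects",
            f"only {n_complete} subjects have all three conditions",
        )

    decoding: dict[tuple[str, str], DecodingResults] = {}
    for pair in CONDITION_PAIRS:
        model = ConditionDecoder(table, pair, features)
        decoding[pair] = model.fit(
            n_perm=config.n_perm,
            alpha=config.alpha,
            seed=config.decode_seed,
            scheme=config.permutation_scheme,
        )

    phasic_results: dict[str, PhasicTonicResults] = {}
    for metric in config.phasic_metrics:
        if metric in table.columns:
            phasic_results[metric] = PhasicTonicAnalysis(table, metric).fit()

    dependence = []
    for metric in ("hf", "hf_c"):
        for cov in ("heart_rate", "resp_rate_mean"):
            if metric in table.columns and cov in table.columns:
                dependence.append(dependence_check(table, metric, cov))

    return PipelineResult(
        table=table,
        exclusions=exclusions,
        decoding=decoding,
        phasic=phasic_results,
        dependence=dependence,
        config=config,
    )


def run_pipeline(
    manifest_path: str | Path,
    config: AnalysisConfig | None = None,
    base_dir: str | Path | None = None,
) -> PipelineResult:
    """Full run from a cohort manifest on disk."""
    config = config or AnalysisConfig()
    manifest = read_manifest(manifest_path)
    base = Path(base_dir) if base_dir is not None else Path(manifest_path).parent

    rows = []
    exclusions = []
    for _, mrow in manifest.iterrows():
        sid, cond = str(mrow["subject_id"]), str(mrow["condition"])
        try:
            rec = read_recording(mrow, base)
            row = feat.extract_features(_RecordingView(**rec), config)
        except UnusableRecordingError as err:
            log.warning("excluding %s/%s: %s", sid, cond, err)
            exclusions.append(
                {"subject_id": sid, "condition": cond,
                 "reason": err.reason, "detail": str(err)}
            )
            continue
        rows.append({"subject_id": sid, "condition": cond, **row})

    cols = ["subject_id", "condition", *feat.ALL_FEATURES]
    table = pd.DataFrame(rows, columns=cols)
    return analyze_table(table, config, exclusions)


@dataclass
class _RecordingView:
    """Adapter giving manifest-loaded channels the attribute layout the
    feature extractor expects."""

    subject_id: str
    condition: str
    ecg: object
    thoracic: object
    abdominal: object
    induction_end_s: float = 0.0
    trance_intensity: float | None = None
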