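"""Phasic (task-minus-rest) vagal analysis and dependence checks.

For a chosen HRV metric, the *tonic* value is the Rest-condition value
and the *phasic* values are the exact within-subject differences
``task - Rest`` for each task condition (Imag, SICT).  Spearman rank
correlations between tonic and phasic values quantify how strongly the
reactivity depends on the resting level.

A caution that the reporting layer repeats: because the phasic value
is defined as (task - tonic), it is mathematically anti-correlated with
the tonic value even when the task value is independent of rest
(regression to the mean of a difference score); strongly negative
tonic-phasic correlations therefore partially reflect the construction
itself.  :func:`phasic_tonic_correlation` documents this in its output.

The module also houses the Pearson dependence check used to validate
the heart-rate correction of spectral HRV: across all subject-condition
observations, corrected metrics should show no significant correlation
with heart rate or respiratory rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _permutations

import numpy as np
import pandas as pd
from scipy import stats

#: exact-permutation cutoff for the Spearman p-value (8! = 40320)
EXACT_PERMUTATION_MAX_N = 8


@dataclass(frozen=True)
class PhasicTonicRecord:
    """Per-subject tonic value and phasic (task - rest) differences."""

    subject_id: str
    metric: str
    tonic: float
    phasic_imag: float | None
    phasic_sict: float | None


def compute_phasic(
    table: pd.DataFrame,
    metric: str,
    rest: str = "Rest",
    tasks: tuple[str, ...] = ("Imag", "SICT"),
) -> list[PhasicTonicRecord]:
    """Exact per-subject phasic differences for one metric.

    Subjects lacking the Rest condition are excluded; a missing task
    condition yields ``None`` for that phasic entry.  The arithmetic is
    exact: ``phasic = value(task) - value(rest)`` with no tolerance.
    """
    if metric not in table.columns:
        raise KeyError(f"metric {metric!r} not present in the feature table")
    wide = table.pivot_table(
        index="subject_id", columns="condition", values=metric, aggfunc="first"
    )
    if rest not in wide.columns:
        raise ValueError(f"no {rest!r} condition in the table")
    records = []
    for sid, row in wide.iterrows():
        tonic = row.get(rest)
        if pd.isna(tonic):
            continue
        phasic = {}
        for task in tasks:
            v = row.get(task)
            phasic[task] = None if pd.isna(v) else float(v) - float(tonic)
        records.append(
            PhasicTonicRecord(
                subject_id=str(sid),
                metric=metric,
                tonic=float(tonic),
                phasic_imag=phasic.get("Imag"),
                phasic_sict=phasic.get("SICT"),
            )
        )
    return records


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = x.size
    count = 0
    total = 0
    for perm in _permutations(range(n)):
        r = _spearman_from_ranks(rx, ry[list(perm)])
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def _spearman_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    return float(np.sum(rx * ry) / denom) if denom > 0 else np.nan


def phasic_tonic_correlation(
    records: list[PhasicTonicRecord], task: str = "SICT"
) -> dict:
    """Spearman correlation of tonic vs phasic values across subjects.

    Uses an exact permutation p-value for n <= 8 and the
    t-approximation otherwise.  A constant tonic or phasic vector makes
    the correlation undefined: rho and p are reported as missing (NaN),
    never as an error or infinity.
    """
    attr = {"SICT": "phasic_sict", "Imag": "phasic_imag"}[task]
    pairs = [(r.tonic, getattr(r, attr)) for r in records if getattr(r, attr) is not None]
    if len(pairs) < 5:
        raise ValueError(f"need at least 5 paired records, got {len(pairs)}")
    tonic = np.array([p[0] for p in pairs])
    phasic = np.array([p[1] for p in pairs])
    out = {
        "task": task,
        "n": len(pairs),
        "note": (
            "phasic = task - tonic: the difference construction induces "
            "negative tonic-phasic correlation even under independence"
        ),
    }
    if np.ptp(tonic) == 0 or np.ptp(phasic) == 0:
        out.update(rho=float("nan"), p=float("nan"), method="undefined")
        return out
    rho = _spearman_from_ranks(stats.rankdata(tonic), stats.rankdata(phasic))
    if len(pairs) <= EXACT_PERMUTATION_MAX_N:
        p = _spearman_exact_p(tonic, phasic, rho)
        method = "exact_permutation"
    else:
        p = float(stats.spearmanr(tonic, phasic).pvalue)
        method = "t_approximation"
    out.update(rho=float(rho), p=float(p), method=method)
    return out


def dependence_check(
    table: pd.DataFrame, metric: str, covariate: str = "heart_rate"
) -> dict:
    """Pearson dependence of an HRV metric on a rate covariate.

    Pools all subject-condition observations.  Used to verify that the
    multiplicative heart-rate correction abolishes the mathematical
    HRV-heart-rate dependence (corrected metrics should give p > 0.05).
    """
    for col in (metric, covariate):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not present in the feature table")
    sub = table[[metric, covariate]].dropna()
    if len(sub) < 5:
        raise ValueError(f"need at least 5 paired observations, got {len(sub)}")
    x = sub[metric].to_numpy(float)
    y = sub[covariate].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"metric": metric, "covariate": covariate, "n": len(sub),
                "r": float("nan"), "p": float("nan")}
    r, p = stats.pearsonr(x, y)
    return {"metric": metric, "covariate": covariate, "n": len(sub),
            "r": float(r), "p": float(p)}


# ---------------------------------------------------------------------------
# Model / Results interface

class PhasicTonicAnalysis:
    """Phasic/tonic analysis of one metric from a feature table."""

    def __init__(self, table: pd.DataFrame, metric: str = "hf"):
        self.table = table
        self.metric = metric
        self.records = compute_phasic(table, metric)

    @classmethod
    def from_dataframe(cls, table, metric="hf"):
        return cls(table, metric)

    def fit(self, tasks: tuple[str, ...] = ("SICT", "Imag")) -> "PhasicTonicResults":
        correlations = {}
        for task in tasks:
            attr = {"SICT": "phasic_sict", "Imag": "phasic_imag"}[task]
            if sum(getattr(r, attr) is not None for r in self.records) >= 5:
                correlations[task] = phasic_tonic_correlation(self.records, task)
        return PhasicTonicResults(
            metric=self.metric, records=self.records, correlations=correlations
        )


@dataclass
class PhasicTonicResults:
    metric: str
    records: list[PhasicTonicRecord]
    correlations: dict[str, dict]

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "tonic": [r.tonic for r in self.records],
                "phasic_imag": [r.phasic_imag for r in self.records],
                "phasic_sict": [r.phasic_sict for r in self.records],
            }
        )
        df.attrs["metric"] = self.metric
        df.attrs["correlations"] = self.correlations
        return df

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "correlations": self.correlations,
            "records": [
                {
                    "subject_id": r.subject_id,
                    "tonic": r.tonic,
                    "phasic_imag": r.phasic_imag,
                    "phasic_sict": r.phasic_sict,
                }
                for r in self.records
            ],
        }
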