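"""Per-feature condition decoding with permutation maximum statistics.

For every feature, a two-class linear discriminant is evaluated under
leave-one-subject-out (LOSO) cross-validation: the classifier is
trained on the paired observations of all remaining subjects and
predicts the two held-out observations; decoding accuracy (DA) is the
percentage of correctly classified held-out observations across folds.

Significance is assessed non-parametrically.  Each permutation swaps
the two condition labels within each subject with probability 1/2
(respecting the paired design; a global label shuffle is available by
option), the full LOSO decoding is re-run, and the familywise
threshold at level alpha is the (1 - alpha) empirical quantile of the
per-permutation *maximum* DA across all features — so a feature is
declared significant only if its observed DA exceeds what the best of
all features achieves under the null.  The same permutation resamples
are shared across features so the maximum is taken over a coherent
joint null.

The model/results interface follows the conventions of statistical
modelling packages: build a :class:`ConditionDecoder` from a feature
table, call :meth:`~ConditionDecoder.fit`, inspect the returned
:class:`DecodingResults` (``summary()``, ``da_``, ``threshold_``,
``significant_``).

Numerical conventions: with a single feature, pooled-variance linear
discriminant analysis with equal priors reduces to a midpoint
threshold between the class means; observations exactly on the
boundary (and the degenerate case of identical class means) are
assigned to the lexicographically lower class label, which keeps the
whole observed path deterministic.  The familywise threshold uses the
'higher' empirical quantile and the comparison is strict (DA >
threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CONDITION_PAIRS = (("Rest", "SICT"), ("Rest", "Imag"), ("Imag", "SICT"))


# ---------------------------------------------------------------------------
# Closed-form single-feature linear discriminant

@dataclass(frozen=True)
class LinearDiscriminant1D:
    """Two-class pooled-variance discriminant on one feature.

    With equal priors the decision boundary is the midpoint of the two
    class means; ``predict`` assigns each value to the class with the
    nearer mean, breaking exact ties (and the degenerate identical-mean
    case) toward the lexicographically lower label.
    """

    class_a: str
    class_b: str
    mean_a: float
    mean_b: float

    @property
    def boundary(self) -> float:
        return 0.5 * (self.mean_a + self.mean_b)

    @property
    def _tie_label(self) -> str:
        return min(self.class_a, self.class_b)

    def predict(self, values: np.ndarray) -> np.ndarray:
        values = np.atleast_1d(np.asarray(values, dtype=float))
        d = self.mean_a - self.mean_b
        out = np.empty(values.size, dtype=object)
        if d == 0:
            out[:] = self._tie_label
            return out
        score = (values - self.boundary) * d
        out[score > 0] = self.class_a
        out[score < 0] = self.class_b
        out[score == 0] = self._tie_label
        return out


def fit_linear_discriminant(
    train_values: np.ndarray, train_labels: np.ndarray
) -> LinearDiscriminant1D:
    """Fit the closed-form two-class discriminant on one feature."""
    values = np.asarray(train_values, dtype=float)
    labels = np.asarray(train_labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required in training data, got {classes}")
    a, b = classes
    return LinearDiscriminant1D(
        class_a=a,
        class_b=b,
        mean_a=float(np.mean(values[labels == a])),
        mean_b=float(np.mean(values[labels == b])),
    )


# ---------------------------------------------------------------------------
# Decoding task container

@dataclass(frozen=True)
class DecodingTask:
    """Paired observations of one feature for a two-condition contrast.

    ``values_a[i]`` and ``values_b[i]`` are subject i's observations
    under conditions ``pair[0]`` and ``pair[1]`` (exactly one each:
    paired design).
    """

    pair: tuple[str, str]
    feature: str
    subject_ids: tuple[str, ...]
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self):
        va = np.asarray(self.values_a, dtype=float)
        vb = np.asarray(self.values_b, dtype=float)
        if va.size != vb.size or va.size != len(self.subject_ids):
            raise ValueError("paired design requires one observation per subject per condition")
        if np.any(~np.isfinite(va)) or np.any(~np.isfinite(vb)):
            raise ValueError(f"non-finite values in decoding task for {self.feature!r}")
        object.__setattr__(self, "values_a", va)
        object.__setattr__(self, "values_b", vb)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def tasks_from_table(
    table: pd.DataFrame,
    pair: tuple[str, str],
    features: list[str] | None = None,
) -> list[DecodingTask]:
    """Build paired decoding tasks from a long-format feature table.

    ``table`` must carry ``subject_id`` and ``condition`` columns plus
    one column per feature.  Subjects missing either condition of the
    pair, and features with missing values, are dropped.
    """
    a, b = pair
    cols = [c for c in table.columns if c not in ("subject_id", "condition")]
    features = features or cols
    wide_a = table[table["condition"] == a].set_index("subject_id")
    wide_b = table[table["condition"] == b].set_index("subject_id")
    common = sorted(set(wide_a.index) & set(wide_b.index))
    tasks = []
    for feat in features:
        if feat not in table.columns:
            raise KeyError(f"feature {feat!r} not present in the table")
        va = wide_a.loc[common, feat].to_numpy(dtype=float)
        vb = wide_b.loc[common, feat].to_numpy(dtype=float)
        ok = np.isfinite(va) & np.isfinite(vb)
        if ok.sum() < 3:
            continue
        tasks.append(
            DecodingTask(
                pair=pair,
                feature=feat,
                subject_ids=tuple(np.asarray(common)[ok].tolist()),
                values_a=va[ok],
                values_b=vb[ok],
            )
        )
    return tasks


# ---------------------------------------------------------------------------
# LOSO decoding

def loso_decode(task: DecodingTask) -> tuple[float, pd.DataFrame]:
    """Leave-one-subject-out decoding accuracy for one task.

    Each fold trains on the paired observations of all other subjects
    and predicts the held-out subject's two observations.  Returns the
    DA in percent and the per-fold predictions.
    """
    n = task.n_subjects
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    a, b = task.pair
    rows = []
    correct = 0
    for j in range(n):
        mask = np.arange(n) != j
        train_vals = np.concatenate([task.values_a[mask], task.values_b[mask]])
        train_labels = np.asarray([a] * (n - 1) + [b] * (n - 1))
        model = fit_linear_discriminant(train_vals, train_labels)
        preds = model.predict([task.values_a[j], task.values_b[j]])
        correct += int(preds[0] == a) + int(preds[1] == b)
        rows.append(
            {
                "subject_id": task.subject_ids[j],
                "pred_a": preds[0],
                "pred_b": preds[1],
                "true_a": a,
                "true_b": b,
            }
        )
    da = 100.0 * correct / (2 * n)
    return da, pd.DataFrame(rows)


def _loso_da_paired(
    values_a: np.ndarray, values_b: np.ndarray, swaps: np.ndarray,
    lower_is_a: bool,
) -> np.ndarray:
    """Vectorized LOSO DA for a batch of within-subject label swaps.

    ``swaps`` is (P, n) boolean; row p exchanges the two observations
    of subject i where ``swaps[p, i]`` is True.  Implements exactly the
    same midpoint rule and lexicographic tie-break as
    :func:`loso_decode` (``lower_is_a`` says whether class A is the
    lexicographically lower label).  Returns (P,) DAs in percent.
    """
    a = values_a[None, :]
    b = values_b[None, :]
    xa = np.where(swaps, b, a)  # observation carrying label A
    xb = np.where(swaps, a, b)
    n = values_a.size
    sum_a = xa.sum(axis=1, keepdims=True)
    sum_b = xb.sum(axis=1, keepdims=True)
    mean_a = (sum_a - xa) / (n - 1)  # training mean of class A per fold
    mean_b = (sum_b - xb) / (n - 1)
    d = mean_a - mean_b
    mid = 0.5 * (mean_a + mean_b)
    score_a = (xa - mid) * d  # > 0 iff held-out A obs predicted A
    score_b = (xb - mid) * d
    tie_to_a = lower_is_a
    correct = (
        (score_a > 0).sum(axis=1)
        + (score_b < 0).sum(axis=1)
        + (tie_to_a * ((score_a == 0).sum(axis=1)))
        + ((not tie_to_a) * ((score_b == 0).sum(axis=1)))
    )
    return 100.0 * correct / (2 * n)


def observed_da(task: DecodingTask) -> float:
    """Observed LOSO DA via the vectorized path (identical result to
    :func:`loso_decode`)."""
    swaps = np.zeros((1, task.n_subjects), dtype=bool)
    lower_is_a = task.pair[0] == min(task.pair)
    return float(_loso_da_paired(task.values_a, task.values_b, swaps, lower_is_a)[0])


def permutation_null(
    task: DecodingTask,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    scheme: str = "within_subject",
) -> np.ndarray:
    """Null distribution of the LOSO DA under label permutation.

    ``within_subject`` (default) swaps the two condition labels inside
    each subject with probability 1/2, preserving the paired design;
    ``global`` shuffles all 2n labels jointly (subjects may then carry
    two identical labels, in which case folds with a missing training
    class are skipped — provided for comparison only).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = task.n_subjects
    if scheme == "within_subject":
        swaps = rng.random((n_perm, n)) < 0.5
        lower_is_a = task.pair[0] == min(task.pair)
        return _loso_da_paired(task.values_a, task.values_b, swaps, lower_is_a)
    if scheme == "global":
        a, b = task.pair
        das = np.empty(n_perm)
        pooled = np.concatenate([task.values_a, task.values_b])
        base_labels = np.asarray([a] * n + [b] * n)
        for p in range(n_perm):
            labels = rng.permutation(base_labels)
            das[p] = _global_loso_da(pooled, labels, n, task.pair)
        return das
    raise ValueError(f"unknown permutation scheme {scheme!r}")


def _global_loso_da(pooled: np.ndarray, labels: np.ndarray, n: int, pair) -> float:
    correct = 0
    total = 0
    for j in range(n):
        mask = np.ones(2 * n, dtype=bool)
        mask[[j, j + n]] = False
        train_l = labels[mask]
        if len(set(train_l.tolist())) < 2:
            continue
        model = fit_linear_discriminant(pooled[mask], train_l)
        preds = model.predict(pooled[[j, j + n]])
        correct += int(preds[0] == labels[j]) + int(preds[1] == labels[j + n])
        total += 2
    return 100.0 * correct / total if total else np.nan


def shared_swaps(
    n_subjects: int, n_perm: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw the within-subject swap matrix shared across all features
    of one condition-pair analysis (coherent joint null)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.random((n_perm, n_subjects)) < 0.5


def max_statistic_threshold(
    null_matrix: np.ndarray, alpha: float = 0.05
) -> tuple[float, np.ndarray]:
    """Familywise threshold from the permutation maximum statistic.

    ``null_matrix`` is (n_features, n_perm) of permuted DAs computed on
    the *same* resamples.  Returns the (1 - alpha) 'higher'-method
    quantile of the per-permutation maxima, together with the maxima.
    """
    nulls = np.asarray(null_matrix, dtype=float)
    if nulls.ndim != 2:
        raise ValueError("null matrix must be 2-D (features x permutations)")
    maxima = np.max(nulls, axis=0)
    threshold = float(np.quantile(maxima, 1.0 - alpha, method="higher"))
    return threshold, maxima


# ---------------------------------------------------------------------------
# Model / Results interface

class ConditionDecoder:
    """Per-feature decoding of one condition pair from a feature table.

    Parameters
    ----------
    table : DataFrame
        Long format: ``subject_id``, ``condition`` plus feature columns.
    pair : (str, str)
        The two condition labels to contrast.
    features : list of str, optional
        Features to decode; defaults to every feature column.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        pair: tuple[str, str],
        features: list[str] | None = None,
    ):
        self.pair = tuple(pair)
        self.tasks = tasks_from_table(table, self.pair, features)
        if not self.tasks:
            raise ValueError(f"no decodable features for pair {pair}")
        ns = {t.n_subjects for t in self.tasks}
        if len(ns) != 1:
            # keep only features with the full paired subject set
            n_full = max(ns)
            self.tasks = [t for t in self.tasks if t.n_subjects == n_full]
        self.n_subjects = self.tasks[0].n_subjects

    @classmethod
    def from_dataframe(cls, table, pair, features=None):
        return cls(table, pair, features)

    def fit(
        self,
        n_perm: int = 1000,
        alpha: float = 0.05,
        seed: int | np.random.Generator = 0,
        scheme: str = "within_subject",
    ) -> "DecodingResults":
        """Run LOSO decoding plus the permutation max-statistic test."""
        das = np.array([observed_da(t) for t in self.tasks])
        if scheme == "within_subject":
            swaps = shared_swaps(self.n_subjects, n_perm, seed)
            lower_is_a = self.pair[0] == min(self.pair)
            nulls = np.vstack(
                [
                    _loso_da_paired(t.values_a, t.values_b, swaps, lower_is_a)
                    for t in self.tasks
                ]
            )
        else:
            rng = np.random.default_rng(seed)
            state = rng.bit_generator.state
            rows = []
            for t in self.tasks:
                r = np.random.default_rng(0)
                r.bit_generator.state = state  # same resamples for every feature
                rows.append(permutation_null(t, n_perm, r, scheme=scheme))
            nulls = np.vstack(rows)
        threshold, maxima = max_statistic_threshold(nulls, alpha)
        return DecodingResults(
            pair=self.pair,
            features=[t.feature for t in self.tasks],
            n_subjects=self.n_subjects,
            da=das,
            null_matrix=nulls,
            max_null=maxima,
            threshold=threshold,
            alpha=alpha,
            n_perm=n_perm,
            scheme=scheme,
        )


@dataclass
class DecodingResults:
    """Results of a per-feature decoding analysis of one condition pair."""

    pair: tuple[str, str]
    features: list[str]
    n_subjects: int
    da: np.ndarray
    null_matrix: np.ndarray
    max_null: np.ndarray
    threshold: float
    alpha: float
    n_perm: int
    scheme: str

    @property
    def significant(self) -> np.ndarray:
        """Strict comparison against the familywise threshold."""
        return self.da > self.threshold

    @property
    def n_observations(self) -> int:
        """Held-out observations entering each DA (2 per subject)."""
        return 2 * self.n_subjects

    def summary(self) -> pd.DataFrame:
        """Per-feature table: observed DA, familywise threshold and
        significance flag, sorted by DA."""
        df = pd.DataFrame(
            {
                "feature": self.features,
                "da": self.da,
                "threshold": self.threshold,
                "significant": self.significant,
            }
        )
        df["pair"] = f"{self.pair[0]} vs {self.pair[1]}"
        df["n_subjects"] = self.n_subjects
        df["n_observations"] = self.n_observations
        return df.sort_values("da", ascending=False).reset_index(drop=True)

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "alpha": self.alpha,
            "n_perm": self.n_perm,
            "n_subjects": self.n_subjects,
            "n_observations": self.n_observations,
            "scheme": self.scheme,
            "threshold": self.threshold,
            "features": {
                f: {"da": float(d), "significant": bool(s)}
                for f, d, s in zip(self.features, self.da, self.significant)
            },
        }

    def plot(self, ax=None):
        """Bar chart of per-feature DA with the familywise threshold."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 4))
        order = np.argsort(self.da)[::-1]
        colors = ["tab:purple" if s else "tab:gray" for s in self.significant[order]]
        ax.bar(np.arange(len(order)), self.da[order], color=colors)
        ax.axhline(self.threshold, color="k", ls="--", lw=1,
                   label=f"max-statistic threshold ({1 - self.alpha:.0%})")
        ax.axhline(50, color="k", ls=":", lw=0.8)
        ax.set_xticks(np.arange(len(order)))
        ax.set_xticklabels([self.features[i] for i in order], rotation=90)
        ax.set_ylabel("decoding accuracy (%)")
        ax.set_title(f"{self.pair[0]} vs {self.pair[1]}")
        ax.legend()
        return ax
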