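"""Metrics and reporting: AUROC with bootstrap CIs, sensitivity/
specificity/F1, per-sign mean aggregation, cohort prevalence tables and
patient-level splits.

Percent formatting is exact rational arithmetic rounded half-up to two
decimals only at the formatting layer, so printed prevalences are a pure
function of the underlying counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score

from .synthetic import SIGNS, CohortManifest


@dataclass
class MetricRow:
    """One Table-style row: per-sign AUROC/sensitivity/specificity/F1."""

    sign: str
    auroc: Optional[float] = None
    auroc_ci: Optional[Tuple[float, float]] = None
    sensitivity: Optional[float] = None
    sensitivity_ci: Optional[Tuple[float, float]] = None
    specificity: Optional[float] = None
    specificity_ci: Optional[Tuple[float, float]] = None
    f1: Optional[float] = None
    flagged: bool = False

    def __post_init__(self):
        for point, ci in ((self.auroc, self.auroc_ci),
                          (self.sensitivity, self.sensitivity_ci),
                          (self.specificity, self.specificity_ci)):
            if point is not None and ci is not None:
                lo, hi = ci
                if not (lo - 1e-12 <= point <= hi + 1e-12):
                    raise ValueError(f"CI ({lo}, {hi}) does not bracket point {point}")


@dataclass
class PrevalenceRow:
    """Yes/no counts for one cohort variable with an exact percentage."""

    variable: str
    count_yes: int
    count_no: int

    @property
    def percent_yes(self) -> str:
        return format_percent(self.count_yes, self.count_yes + self.count_no)


def format_percent(numerator: int, denominator: int, places: int = 2) -> str:
    """Exact percentage, rounded half-up at ``places`` decimals.

    Rounding happens once, at formatting time, on the exact rational value.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    q = Decimal(numerator) * 100 / Decimal(denominator)
    return str(q.quantize(Decimal(1).scaleb(-places), rounding=ROUND_HALF_UP))


def _validate_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return scores, labels


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUROC by the rank (Mann-Whitney) statistic, ties counting 1/2."""
    scores, labels = _validate_scores_labels(scores, labels)
    return float(roc_auc_score(labels, scores))


def sens_spec_f1(scores: Sequence[float], labels: Sequence[int],
                 threshold: float = 0.5) -> Tuple[float, float, float]:
    """Sensitivity, specificity and F1 from the 2x2 table at a threshold.

    Positive call: score >= threshold.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return sens, spec, f1


def youden_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Operating threshold maximizing sensitivity + specificity - 1.

    Candidate thresholds are the midpoints between consecutive unique
    scores (the ROC convention, which generalizes better than cutting
    exactly at an observed score); ties broken toward the smallest
    threshold (higher sensitivity).
    """
    scores, labels = _validate_scores_labels(scores, labels)
    uniq = np.unique(scores)
    candidates = np.concatenate([[uniq[0]], (uniq[1:] + uniq[:-1]) / 2.0])
    best_t, best_j = 0.5, -np.inf
    for t in candidates:
        sens, spec, _ = sens_spec_f1(scores, labels, t)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    return best_t


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> Tuple[float, float]:
    """Stratified percentile bootstrap CI for a score/label metric.

    Resampling is within each class so every resample keeps both classes;
    resamples on which the metric is undefined are redrawn (bounded) and
    counted.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    scores, labels = _validate_scores_labels(scores, labels)
    rng = np.random.default_rng(seed)
    pos = np.nonzero(labels == 1)[0]
    neg = np.nonzero(labels == 0)[0]
    stats = []
    redraws = 0
    while len(stats) < n_boot:
        idx = np.concatenate([rng.choice(pos, len(pos)), rng.choice(neg, len(neg))])
        try:
            stats.append(metric(scores[idx], labels[idx]))
        except ValueError:
            redraws += 1
            if redraws > 10 * n_boot:
                raise RuntimeError("metric undefined on too many bootstrap resamples")
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def metric_row(
    sign: str,
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
    n_boot: int = 2000,
    seed: int = 0,
    flagged: bool = False,
) -> MetricRow:
    """Full per-sign row: point metrics at a threshold plus bootstrap CIs.

    Returns a row of None metrics when only one class is present (the
    metrics are undefined there; the row still appears in reports).
    """
    try:
        scores, labels = _validate_scores_labels(scores, labels)
    except ValueError:
        return MetricRow(sign, flagged=flagged)
    auc = roc_auc(scores, labels)
    sens, spec, f1 = sens_spec_f1(scores, labels, threshold)
    auc_ci = bootstrap_ci(lambda s, l: roc_auc(s, l), scores, labels, n_boot, seed)
    se_ci = bootstrap_ci(lambda s, l: sens_spec_f1(s, l, threshold)[0], scores, labels, n_boot, seed)
    sp_ci = bootstrap_ci(lambda s, l: sens_spec_f1(s, l, threshold)[1], scores, labels, n_boot, seed)
    return MetricRow(sign, auc, auc_ci, sens, se_ci, spec, sp_ci, f1, flagged=flagged)


def aggregate_mean_row(rows: Sequence[MetricRow], include_flagged: bool = True) -> MetricRow:
    """Unweighted arithmetic mean across sign rows (CIs omitted).

    Rows with missing metrics are skipped per metric; ``include_flagged``
    False drops flagged (unsupported-baseline) rows entirely.
    """
    rows = [r for r in rows if include_flagged or not r.flagged]
    if not rows:
        raise ValueError("aggregate_mean_row needs at least one row")

    def _mean(attr):
        vals = [getattr(r, attr) for r in rows if getattr(r, attr) is not None]
        return float(np.mean(vals)) if vals else None

    return MetricRow("mean", auroc=_mean("auroc"), sensitivity=_mean("sensitivity"),
                     specificity=_mean("specificity"), f1=_mean("f1"))


def manifest_prevalences(manifest: CohortManifest) -> list:
    """Per-sign yes/no counts and exact percentages over patients."""
    rows = []
    for sign in SIGNS:
        yes, no = manifest.counts(sign)
        rows.append(PrevalenceRow(sign, yes, no))
    return rows


def split_cohort(
    manifest_or_ids,
    fractions: Tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> Tuple[list, list, list]:
    """Patient-level train/validation/test split.

    All of a patient's images share a split by construction (the split is
    over patient ids).  Sizes follow the largest-remainder rule so they sum
    exactly to the cohort size.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if isinstance(manifest_or_ids, CohortManifest):
        ids = list(manifest_or_ids.patients["patient_id"])
    else:
        ids = list(manifest_or_ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(x)) for x in raw]
    remainder = n - sum(sizes)
    by_frac = sorted(range(3), key=lambda i: raw[i] - sizes[i], reverse=True)
    for i in range(remainder):
        sizes[by_frac[i % 3]] += 1
    shuffled = [ids[i] for i in order]
    train = shuffled[: sizes[0]]
    val = shuffled[sizes[0] : sizes[0] + sizes[1]]
    test = shuffled[sizes[0] + sizes[1] :]
    return train, val, test
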