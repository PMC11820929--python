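"""Validation statistics: confusion matrices, class proportions, rate tests.

Predictions are compared against ground truth over the three coded states.
Accuracy is pooled (micro) and therefore identical to micro recall;
precision is support-weighted one-vs-rest, which is why it can differ from
recall; the correlation coefficient is Pearson's r on the paired numeric
codes (the codes form an ordinal activity scale), with Matthews'
multiclass correlation available for those who prefer a chance-corrected
association measure.

For frame-rate comparisons, class proportions from two runs are compared
with exact two-sided binomial tests (the high-rate run anchors the null),
and per-window mean state codes are compared with a classical paired
t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "ValidationMetrics",
    "ProportionRow",
    "confusion",
    "metrics",
    "matthews_corr",
    "class_proportions",
    "binomial_class_test",
    "PairedTestResult",
    "paired_fps_test",
]

STATES = (1, 2, 3)

#: Above this trial count the exact binomial tail summation gives way to a
#: normal approximation with continuity correction.
EXACT_BINOMIAL_LIMIT = 1_000_000


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 counts indexed (true_state, predicted_state) over states 1..3."""

    counts: np.ndarray
    n_dropped: int = 0  # pairs excluded because either side was UNKNOWN

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3) or (c < 0).any():
            raise ValueError("counts must be a non-negative 3x3 array")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __getitem__(self, key: tuple[int, int]) -> int:
        t, p = key
        return int(self.counts[t - 1, p - 1])


@dataclass(frozen=True)
class ValidationMetrics:
    accuracy: float
    precision: float  # support-weighted one-vs-rest
    recall: float  # micro == accuracy
    correlation: float  # Pearson r on paired codes
    per_class_precision: tuple[float, float, float]
    per_class_recall: tuple[float, float, float]


def confusion(
    truth: Sequence[int | None], predicted: Sequence[int | None]
) -> ConfusionMatrix:
    """Count paired (true, predicted) states, dropping UNKNOWN pairs."""
    if len(truth) != len(predicted):
        raise ValueError(f"length mismatch: {len(truth)} vs {len(predicted)}")
    counts = np.zeros((3, 3), dtype=np.int64)
    dropped = 0
    for t, p in zip(truth, predicted):
        if t is None or p is None:
            dropped += 1
            continue
        counts[int(t) - 1, int(p) - 1] += 1
    return ConfusionMatrix(counts, n_dropped=dropped)


def metrics(cm: ConfusionMatrix) -> ValidationMetrics:
    """Pooled metrics from a confusion matrix.

    accuracy = trace/total = micro recall.  Support-weighted precision
    weights each class's one-vs-rest precision by its true-class share; a
    class never predicted contributes precision 0 at its support weight.
    Correlation is Pearson's r between the paired codes, computed from the
    joint counts.
    """
    c = cm.counts.astype(np.float64)
    total = c.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(c)
    support = c.sum(axis=1)
    predicted = c.sum(axis=0)
    accuracy = float(diag.sum() / total)

    with np.errstate(invalid="ignore", divide="ignore"):
        prec_c = np.where(predicted > 0, diag / np.where(predicted > 0, predicted, 1), 0.0)
        rec_c = np.where(support > 0, diag / np.where(support > 0, support, 1), 0.0)
    precision = float(np.sum(support / total * prec_c))

    codes = np.array(STATES, dtype=np.float64)
    p_joint = c / total
    mu_t = float(codes @ p_joint.sum(axis=1))
    mu_p = float(codes @ p_joint.sum(axis=0))
    var_t = float((codes - mu_t) ** 2 @ p_joint.sum(axis=1))
    var_p = float((codes - mu_p) ** 2 @ p_joint.sum(axis=0))
    cov = float((codes - mu_t) @ p_joint @ (codes - mu_p))
    if var_t > 0 and var_p > 0:
        correlation = cov / math.sqrt(var_t * var_p)
    else:
        correlation = math.nan

    return ValidationMetrics(
        accuracy=accuracy,
        precision=precision,
        recall=accuracy,
        correlation=correlation,
        per_class_precision=tuple(float(x) for x in prec_c),
        per_class_recall=tuple(float(x) for x in rec_c),
    )


def matthews_corr(cm: ConfusionMatrix) -> float:
    """Multiclass Matthews correlation coefficient (chance-corrected)."""
    c = cm.counts.astype(np.float64)
    n = c.sum()
    t_k = c.sum(axis=1)
    p_k = c.sum(axis=0)
    cov_tp = float(np.trace(c) * n - t_k @ p_k)
    cov_tt = float(n**2 - t_k @ t_k)
    cov_pp = float(n**2 - p_k @ p_k)
    if cov_tt <= 0 or cov_pp <= 0:
        return math.nan
    return cov_tp / math.sqrt(cov_tt * cov_pp)


# -- class proportions and rate tests ---------------------------------------


@dataclass(frozen=True)
class ProportionRow:
    fps_label: str
    class_state: int
    count: int
    total: int
    proportion: float  # count/total rounded to reporting precision (3 dp)
    p_value: float | None = None


def class_proportions(
    records_or_counts: Sequence | Mapping[int, int],
    *,
    fps_label: str = "",
    total: int | None = None,
) -> list[ProportionRow]:
    """Per-class counts and proportions (reported to 3 decimals).

    Accepts activity records or a {state: count} mapping.  If an explicit
    ``total`` disagrees with the summed counts, the discrepancy is reported
    as a warning and the stated total is used as the denominator — printed
    tables are validated, never silently corrected.
    """
    if isinstance(records_or_counts, Mapping):
        counts = {int(k): int(v) for k, v in records_or_counts.items()}
    else:
        counts = {s: 0 for s in STATES}
        for r in records_or_counts:
            state = getattr(r, "state", r)
            if state is None:
                continue
            counts[int(state)] = counts.get(int(state), 0) + 1
    summed = sum(counts.values())
    if total is None:
        total = summed
    elif total != summed:
        warnings.warn(
            f"stated total {total} != summed class counts {summed}; "
            "using the stated total as denominator",
            stacklevel=2,
        )
    if total <= 0:
        raise ValueError("total must be positive")
    return [
        ProportionRow(
            fps_label=fps_label,
            class_state=state,
            count=count,
            total=total,
            proportion=round(count / total, 3),
        )
        for state, count in sorted(counts.items())
    ]


def binomial_class_test(count: int, total: int, p0: float) -> float:
    """Two-sided test of ``count`` successes in ``total`` against null p0.

    Exact tail summation (no normal approximation) up to 10^6 trials,
    beyond which a normal approximation with continuity correction is used.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"degenerate null proportion {p0}")
    if not 0 <= count <= total:
        raise ValueError("count outside [0, total]")
    if total <= EXACT_BINOMIAL_LIMIT:
        return float(stats.binomtest(count, total, p0).pvalue)
    mean = total * p0
    sd = math.sqrt(total * p0 * (1.0 - p0))
    z = (abs(count - mean) - 0.5) / sd
    return float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))


@dataclass(frozen=True)
class PairedTestResult:
    mean_diff: float
    ci_95: tuple[float, float]
    p_value: float
    t_statistic: float
    dof: int
    degenerate: bool  # zero-variance differences; CI has zero width


def paired_fps_test(
    series_a: Sequence[float], series_b: Sequence[float]
) -> PairedTestResult:
    """Classical paired t-test on matched per-window means.

    The pairing unit is whatever the caller matched the windows on
    (per-minute mean state codes in the fps comparison).  Identical series
    give mean_diff 0 with p 1; a constant offset gives a zero-width CI with
    the degenerate flag set.
    """
    a = np.asarray(series_a, dtype=np.float64)
    b = np.asarray(series_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("series length mismatch")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 paired windows")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    dof = n - 1
    if sd == 0.0:
        return PairedTestResult(
            mean_diff=mean,
            ci_95=(mean, mean),
            p_value=1.0 if mean == 0.0 else 0.0,
            t_statistic=math.inf if mean else 0.0,
            dof=dof,
            degenerate=True,
        )
    se = sd / math.sqrt(n)
    t = mean / se
    p = float(2.0 * stats.t.sf(abs(t), dof))
    half = float(stats.t.ppf(0.975, dof)) * se
    return PairedTestResult(
        mean_diff=mean,
        ci_95=(mean - half, mean + half),
        p_value=p,
        t_statistic=t,
        dof=dof,
        degenerate=False,
    )
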