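"""Per-arena metrics and replicate-level statistics.

Three per-arena measures summarize a quadrant count vector
``(q1, q2, q3, q4)`` with total ``n``:

dispersal
    Base-2 Shannon entropy of the occupancy proportions,
    ``-sum(p_i * log2(p_i))`` with the ``0*log2(0) = 0`` convention.
    Ranges 0 (all worms in one quadrant) to 2 bits (uniform spread).
response ratio
    Fraction of worms committed to either extreme quadrant,
    ``(q1 + q4) / n``; direction-blind.
chemotaxis index
    Normalized difference between the extreme quadrants,
    ``(q4 - q1) / (q4 + q1)``; +1 is full attraction to the odorant end,
    -1 full aversion. Undefined (``None``) when both extremes are empty.

Replicate-level statistics use the sample (n-1) standard deviation, a
t-distribution confidence interval on the mean, a two-sample t-test
(pooled-variance Student by default, Welch optional) and Cohen's *d* with
the two group variances averaged with equal weight regardless of group
sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median as _median
from typing import Sequence

import numpy as np
from scipy import stats

from .assay_data import ArenaRecord, ExperimentSet, QuadrantCounts, canonicalize
from .errors import InfiniteEffectError, InsufficientDataError, UndefinedInputError

__all__ = [
    "MetricsResult",
    "GroupSummary",
    "EffectReport",
    "OrientationComparison",
    "compute_dispersal",
    "compute_response_ratio",
    "compute_chemotaxis_index",
    "compute_metrics",
    "compute_effect_size",
    "unpaired_t_test",
    "summarize_group",
    "orientation_consistency",
]


@dataclass(frozen=True)
class MetricsResult:
    """Per-arena metric bundle; ``chemotaxis_index`` is None when undefined."""

    dispersal: float
    response_ratio: float
    chemotaxis_index: float | None
    n_total: int

    def to_dict(self) -> dict:
        return {
            "dispersal": self.dispersal,
            "response_ratio": self.response_ratio,
            "chemotaxis_index": self.chemotaxis_index,
            "n_total": self.n_total,
        }


@dataclass(frozen=True)
class GroupSummary:
    """Replicate-level summary of one metric across arenas.

    ``sd``, ``ci95_low`` and ``ci95_high`` are None when fewer than two
    values are available.
    """

    values: tuple[float, ...]
    mean: float
    sd: float | None
    median: float
    ci95_low: float | None
    ci95_high: float | None
    n_arenas: int
    confidence: float = 0.95

    def to_dict(self) -> dict:
        return {
            "values": list(self.values),
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "ci95_low": self.ci95_low,
            "ci95_high": self.ci95_high,
            "n_arenas": self.n_arenas,
            "confidence": self.confidence,
        }


@dataclass(frozen=True)
class EffectReport:
    """Effect size and/or test statistics for test vs control groups."""

    cohens_d: float | None = None
    t_statistic: float | None = None
    degrees_of_freedom: float | None = None
    p_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "cohens_d": self.cohens_d,
            "t_statistic": self.t_statistic,
            "degrees_of_freedom": self.degrees_of_freedom,
            "p_value": self.p_value,
        }


def compute_dispersal(counts: QuadrantCounts) -> float:
    """Base-2 entropy of quadrant occupancy proportions, in bits.

    Zero counts contribute zero. Raises :class:`UndefinedInputError` when
    the arena is empty.
    """
    n = counts.n_total
    if n == 0:
        raise UndefinedInputError("dispersal undefined for an empty arena (n_total = 0)")
    total = 0.0
    for q in counts.as_tuple():
        if q > 0:
            p = q / n
            total -= p * math.log2(p)
    # clamp -0.0 from the single-quadrant case
    return 0.0 if total == 0.0 else total


def compute_response_ratio(counts: QuadrantCounts) -> float:
    """Fraction of worms in the two extreme quadrants, ``(q1+q4)/n``."""
    n = counts.n_total
    if n == 0:
        raise UndefinedInputError("response ratio undefined for an empty arena (n_total = 0)")
    return (counts.q1 + counts.q4) / n


def compute_chemotaxis_index(counts: QuadrantCounts) -> float | None:
    """Normalized extreme-quadrant difference ``(q4-q1)/(q4+q1)``.

    Returns None (undefined) when both extreme quadrants are empty, which
    legitimately happens on arenas where worms stay central; downstream
    treats None as non-interpretable rather than an error.
    """
    denominator = counts.q1 + counts.q4
    if denominator == 0:
        return None
    return (counts.q4 - counts.q1) / denominator


def compute_metrics(source: QuadrantCounts | ArenaRecord) -> MetricsResult:
    """All three per-arena metrics from canonical counts (records are canonicalized)."""
    counts = canonicalize(source) if isinstance(source, ArenaRecord) else source
    return MetricsResult(
        dispersal=compute_dispersal(counts),
        response_ratio=compute_response_ratio(counts),
        chemotaxis_index=compute_chemotaxis_index(counts),
        n_total=counts.n_total,
    )


def _as_array(values: Sequence[float], name: str, minimum: int) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.ndim != 1 or arr.size < minimum:
        raise InsufficientDataError(
            f"{name} group needs at least {minimum} value(s), got {arr.size}"
        )
    return arr


def compute_effect_size(test: Sequence[float], control: Sequence[float]) -> EffectReport:
    """Cohen's *d* with equal-weight averaging of the two sample variances.

    ``d = (mean_test - mean_control) / sqrt((sd_test^2 + sd_control^2) / 2)``
    with sample (n-1) standard deviations. Group sizes do not enter the
    denominator. Raises :class:`InfiniteEffectError` when both sds are zero
    but the means differ; identical constant groups give ``d = 0``.
    """
    t = _as_array(test, "test", 2)
    c = _as_array(control, "control", 2)
    sd_t = float(np.std(t, ddof=1))
    sd_c = float(np.std(c, ddof=1))
    diff = float(np.mean(t) - np.mean(c))
    denom = math.sqrt((sd_t**2 + sd_c**2) / 2.0)
    if denom == 0.0:
        if diff == 0.0:
            return EffectReport(cohens_d=0.0)
        raise InfiniteEffectError(
            "both group standard deviations are zero but the means differ; "
            "effect size is infinite"
        )
    return EffectReport(cohens_d=diff / denom)


def unpaired_t_test(
    test: Sequence[float], control: Sequence[float], *, welch: bool = False
) -> EffectReport:
    """Two-sided two-sample t-test of test vs control.

    Student's pooled-variance test by default; pass ``welch=True`` for the
    unequal-variance variant. Degenerate case of two identical constant
    groups returns ``t = 0, p = 1``.
    """
    t = _as_array(test, "test", 2)
    c = _as_array(control, "control", 2)
    if np.std(t, ddof=1) == 0.0 and np.std(c, ddof=1) == 0.0 and np.mean(t) == np.mean(c):
        df = float(t.size + c.size - 2)
        return EffectReport(t_statistic=0.0, degrees_of_freedom=df, p_value=1.0)
    result = stats.ttest_ind(t, c, equal_var=not welch)
    return EffectReport(
        t_statistic=float(result.statistic),
        degrees_of_freedom=float(result.df),
        p_value=float(result.pvalue),
    )


def summarize_group(values: Sequence[float], confidence: float = 0.95) -> GroupSummary:
    """Mean, sample sd, median and t-distribution CI on the mean.

    With a single value the sd and CI are None. A constant sequence yields
    sd 0 and a zero-width interval.
    """
    arr = _as_array(values, "summary", 1)
    mean = float(np.mean(arr))
    med = float(_median(arr.tolist()))
    if arr.size < 2:
        return GroupSummary(
            values=tuple(arr.tolist()),
            mean=mean,
            sd=None,
            median=med,
            ci95_low=None,
            ci95_high=None,
            n_arenas=int(arr.size),
            confidence=confidence,
        )
    sd = float(np.std(arr, ddof=1))
    t_quantile = float(stats.t.ppf(0.5 + confidence / 2.0, df=arr.size - 1))
    half_width = t_quantile * sd / math.sqrt(arr.size)
    return GroupSummary(
        values=tuple(arr.tolist()),
        mean=mean,
        sd=sd,
        median=med,
        ci95_low=mean - half_width,
        ci95_high=mean + half_width,
        n_arenas=int(arr.size),
        confidence=confidence,
    )


@dataclass(frozen=True)
class OrientationComparison:
    """Canonical chemotaxis indices compared between physical orientations.

    A significant difference between orientations (after canonicalization,
    which should make them exchangeable) flags an external gradient in the
    lab frame.
    """

    mean_a: float
    mean_b: float
    difference: float
    n_a: int
    n_b: int
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    alpha: float
    flagged: bool

    def to_dict(self) -> dict:
        return {
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "difference": self.difference,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "t_statistic": self.t_statistic,
            "degrees_of_freedom": self.degrees_of_freedom,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "flagged": self.flagged,
        }


def orientation_consistency(
    exp: ExperimentSet, alpha: float = 0.05, *, welch: bool = False
) -> OrientationComparison:
    """Test whether canonical chemotaxis indices agree across orientations.

    Groups the defined canonical indices of chemotaxis arenas by physical
    orientation and runs an unpaired t-test A vs B. Requires at least two
    defined indices per orientation.
    """
    groups: dict[str, list[float]] = {"A": [], "B": []}
    for arena in exp.chemotaxis_arenas:
        ci = compute_chemotaxis_index(canonicalize(arena))
        if ci is not None:
            groups[arena.orientation].append(ci)
    for orientation, vals in groups.items():
        if len(vals) < 2:
            raise InsufficientDataError(
                f"orientation {orientation} has {len(vals)} defined chemotaxis "
                "index value(s); need at least 2 per orientation"
            )
    a, b = groups["A"], groups["B"]
    mean_a = float(np.mean(a))
    mean_b = float(np.mean(b))
    report = unpaired_t_test(a, b, welch=welch)
    return OrientationComparison(
        mean_a=mean_a,
        mean_b=mean_b,
        difference=mean_a - mean_b,
        n_a=len(a),
        n_b=len(b),
        t_statistic=report.t_statistic,
        degrees_of_freedom=report.degrees_of_freedom,
        p_value=report.p_value,
        alpha=alpha,
        flagged=bool(report.p_value < alpha),
    )
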