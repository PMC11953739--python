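"""Decision-chart preconditions and the eight-row inference rubric.

A chemotaxis experiment is interpretable only when every plate holds
sufficient worms (strictly more than 100 by default) and the paired
no-odorant dispersal controls spread uniformly (dispersal near 2 bits).
Failed controls are classified by regime: dispersal near 1 bit means the
worms stayed central (locomotion defect and/or attraction to the origin);
near 0 bits means they piled into one quadrant (response to an unknown
gradient within the arena).

Interpretable experiments are then classified high/low on replicate-median
dispersal, response ratio and |chemotaxis index|, and the (2 x 2 x 2)
combination is looked up in a fixed verdict table, with the chemotaxis-index
sign resolving attraction (positive) vs aversion (negative). The high/low
cut-offs are researcher-settable conventions, not measured constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Mapping, Sequence

import yaml

from .assay_data import ArenaRecord, ExperimentSet
from .errors import ConfigError, InsufficientDataError
from .metrics import MetricsResult, compute_metrics

__all__ = [
    "Thresholds",
    "Levels",
    "InferenceResult",
    "classify_levels",
    "classify_dispersal_regime",
    "check_preconditions",
    "infer_table1",
    "run_decision_chart",
    "VERDICT_TABLE",
]

HIGH = "high"
LOW = "low"
POSITIVE = "positive"
NEGATIVE = "negative"
NONE = "none"

REGIME_UNIFORM = "uniform~2"
REGIME_CENTRAL = "central~1"
REGIME_SINGLE = "single-quadrant~0"


@dataclass(frozen=True)
class Thresholds:
    """High/low cut-offs and the worms-per-plate minimum.

    Defaults classify the canonical regimes correctly (uniform controls as
    high dispersal; response ratios 0.1 low and 0.5 high; |index| above 0.5
    high) but are conventions the researcher may tighten or relax.
    """

    dispersal_high_min: float = 1.8
    response_ratio_high_min: float = 0.4
    ci_high_min_abs: float = 0.5
    min_worms: int = 101

    def __post_init__(self) -> None:
        if not (0.0 <= self.dispersal_high_min <= 2.0):
            raise ConfigError("dispersal_high_min must be within [0, 2] bits")
        if not (0.0 <= self.response_ratio_high_min <= 1.0):
            raise ConfigError("response_ratio_high_min must be within [0, 1]")
        if not (0.0 <= self.ci_high_min_abs <= 1.0):
            raise ConfigError("ci_high_min_abs must be within [0, 1]")
        if self.min_worms < 1:
            raise ConfigError("min_worms must be at least 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "Thresholds":
        """Load thresholds from a plain-text ``key: value`` file."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected key: value pairs")
        known = {"dispersal_high_min", "response_ratio_high_min", "ci_high_min_abs", "min_worms"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown threshold key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "dispersal_high_min": self.dispersal_high_min,
            "response_ratio_high_min": self.response_ratio_high_min,
            "ci_high_min_abs": self.ci_high_min_abs,
            "min_worms": self.min_worms,
        }


@dataclass(frozen=True)
class Levels:
    """High/low classification of the three metrics plus index sign."""

    dispersal_level: str
    rr_level: str
    ci_level: str
    ci_sign: str

    def to_dict(self) -> dict:
        return {
            "dispersal_level": self.dispersal_level,
            "rr_level": self.rr_level,
            "ci_level": self.ci_level,
            "ci_sign": self.ci_sign,
        }


# Verdict statements for the eight (dispersal, response ratio, |index|)
# combinations. "{response}"/"{sign}" slots resolve by the index sign:
# positive -> attraction, negative -> aversion.
VERDICT_TABLE: dict[tuple[str, str, str], str] = {
    (HIGH, HIGH, HIGH): "{response} ({sign} chemotaxis index) to the odorant",
    (HIGH, HIGH, LOW): (
        "no locomotion defect (high dispersal), aversion to the origin on "
        "chemotaxis plates only and/or attraction to the vehicle "
        "(low chemotaxis index and high response ratio)"
    ),
    (HIGH, LOW, HIGH): (
        "no locomotion defect (high dispersal), attraction to the origin "
        "and/or aversion to vehicle on chemotaxis plates only "
        "(low response ratio) overcome by {response} ({sign} chemotaxis "
        "index) to the odorant"
    ),
    (LOW, HIGH, HIGH): (
        "locomotion defect and/or attraction to the origin on dispersal "
        "plates only overcome (high response ratio) by {response} "
        "({sign} chemotaxis index) to the odorant"
    ),
    (HIGH, LOW, LOW): (
        "no locomotion defect (high dispersal), attraction to the origin on "
        "chemotaxis plates only and/or aversion to the vehicle "
        "(low chemotaxis index and low response ratio)"
    ),
    (LOW, LOW, HIGH): (
        "locomotion defect and/or attraction to the origin across all "
        "plates with {response} ({sign} chemotaxis index) to the odorant"
    ),
    (LOW, HIGH, LOW): (
        "locomotion defect and/or attraction to the origin on dispersal "
        "plates overcome by aversion to origin and/or attraction to the "
        "vehicle (low chemotaxis index but high response ratio)"
    ),
    (LOW, LOW, LOW): "locomotion defect and/or attraction to the origin across all plates",
}


@dataclass
class InferenceResult:
    """Outcome of the decision chart for one experiment."""

    interpretable: bool
    precondition_failures: list[str]
    dispersal_level: str | None = None
    rr_level: str | None = None
    ci_level: str | None = None
    ci_sign: str | None = None
    verdict: str | None = None
    dispersal_regime: str | None = None
    median_metrics: dict = field(default_factory=dict)
    per_arena_verdicts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "interpretable": self.interpretable,
            "precondition_failures": list(self.precondition_failures),
            "dispersal_level": self.dispersal_level,
            "rr_level": self.rr_level,
            "ci_level": self.ci_level,
            "ci_sign": self.ci_sign,
            "verdict": self.verdict,
            "dispersal_regime": self.dispersal_regime,
            "median_metrics": dict(self.median_metrics),
            "per_arena_verdicts": dict(self.per_arena_verdicts),
        }


def classify_dispersal_regime(dispersal: float) -> str:
    """Assign a dispersal value to its nearest anchor regime.

    Anchors sit at 2 (uniform), 1 (central accumulation) and 0
    (single-quadrant); boundaries at 1.5 and 0.5 bits are a convention.
    """
    if dispersal >= 1.5:
        return REGIME_UNIFORM
    if dispersal >= 0.5:
        return REGIME_CENTRAL
    return REGIME_SINGLE


def classify_levels(
    dispersal: float,
    response_ratio: float,
    chemotaxis_index: float | None,
    thresholds: Thresholds = Thresholds(),
) -> Levels:
    """Label each metric high/low against its threshold.

    The chemotaxis index is classified on magnitude; an undefined index is
    low with sign ``none``, as is an exact zero.
    """
    d_level = HIGH if dispersal >= thresholds.dispersal_high_min else LOW
    r_level = HIGH if response_ratio >= thresholds.response_ratio_high_min else LOW
    if chemotaxis_index is None:
        return Levels(d_level, r_level, LOW, NONE)
    c_level = HIGH if abs(chemotaxis_index) >= thresholds.ci_high_min_abs else LOW
    if chemotaxis_index > 0:
        sign = POSITIVE
    elif chemotaxis_index < 0:
        sign = NEGATIVE
    else:
        sign = NONE
    return Levels(d_level, r_level, c_level, sign)


def classify_metrics(metrics: MetricsResult, thresholds: Thresholds = Thresholds()) -> Levels:
    return classify_levels(
        metrics.dispersal, metrics.response_ratio, metrics.chemotaxis_index, thresholds
    )


def infer_table1(levels: Levels) -> str:
    """Look up the verdict for a level combination; total over all eight rows.

    Rows whose statement depends on the direction of the response resolve
    ``{response}``/``{sign}`` from ``ci_sign``; a high index level requires a
    definite sign.
    """
    template = VERDICT_TABLE[(levels.dispersal_level, levels.rr_level, levels.ci_level)]
    if "{response}" in template:
        if levels.ci_sign == POSITIVE:
            return template.format(response="attraction", sign="positive")
        if levels.ci_sign == NEGATIVE:
            return template.format(response="aversion", sign="negative")
        raise ValueError("a high chemotaxis-index level requires a definite sign")
    return template


def check_preconditions(
    exp: ExperimentSet,
    metrics: Mapping[str, MetricsResult],
    thresholds: Thresholds = Thresholds(),
) -> tuple[bool, list[str]]:
    """Decide interpretability before any verdict is attempted.

    Interpretable iff every arena carries at least ``min_worms`` worms and
    every dispersal-control arena reaches the high-dispersal cut-off.
    Control failures name the regime: central accumulation points to
    attraction to the center and/or defective locomotion; single-quadrant
    accumulation points to a response to an unknown gradient in the arena.

    Raises :class:`InsufficientDataError` when the experiment has no
    dispersal arenas at all.
    """
    if not exp.dispersal_arenas:
        raise InsufficientDataError(
            "no paired dispersal arenas: interpretability cannot be assessed"
        )
    reasons: list[str] = []
    for arena in exp.arenas:
        m = metrics[arena.plate_id]
        if m.n_total < thresholds.min_worms:
            reasons.append(
                f"plate {arena.plate_id}: n_total={m.n_total} below the "
                f"required minimum of {thresholds.min_worms} worms per plate"
            )
    for arena in exp.dispersal_arenas:
        d = metrics[arena.plate_id].dispersal
        if d < thresholds.dispersal_high_min:
            regime = classify_dispersal_regime(d)
            if regime == REGIME_CENTRAL:
                why = "attraction to center and/or defective locomotion"
            elif regime == REGIME_SINGLE:
                why = "response to an unknown gradient in the arena"
            else:
                why = "dispersal below the uniform-spread requirement"
            reasons.append(
                f"plate {arena.plate_id}: dispersal control at {d:.2f} bits "
                f"(< {thresholds.dispersal_high_min}); {why}"
            )
    return (not reasons, reasons)


def _median_metrics(
    arenas: Sequence[ArenaRecord], metrics: Mapping[str, MetricsResult]
) -> tuple[float, float | None]:
    """Median response ratio and median defined chemotaxis index."""
    rrs = [metrics[a.plate_id].response_ratio for a in arenas]
    cis = [
        metrics[a.plate_id].chemotaxis_index
        for a in arenas
        if metrics[a.plate_id].chemotaxis_index is not None
    ]
    return median(rrs), (median(cis) if cis else None)


def run_decision_chart(
    exp: ExperimentSet, thresholds: Thresholds = Thresholds()
) -> InferenceResult:
    """Full chart: metrics -> preconditions -> level classification -> verdict.

    Levels are classified on replicate medians: dispersal over the
    no-odorant control arenas (the quantity the chart gates on), response
    ratio and chemotaxis index over the chemotaxis arenas. Per-arena
    verdicts are also emitted for diagnostics. Non-interpretable
    experiments carry their failure reasons and no verdict.
    """
    metrics = {a.plate_id: compute_metrics(a) for a in exp.arenas}
    interpretable, reasons = check_preconditions(exp, metrics, thresholds)

    chem = exp.chemotaxis_arenas
    if not chem:
        reasons = reasons + ["no chemotaxis arenas present; nothing to infer"]
        return InferenceResult(
            interpretable=False,
            precondition_failures=reasons,
            median_metrics={k: m.to_dict() for k, m in metrics.items()},
        )

    control_dispersal = median(
        [metrics[a.plate_id].dispersal for a in exp.dispersal_arenas]
    )
    median_rr, median_ci = _median_metrics(chem, metrics)
    levels = classify_levels(control_dispersal, median_rr, median_ci, thresholds)
    regime = classify_dispersal_regime(control_dispersal)

    per_arena: dict[str, str] = {}
    for arena in chem:
        m = metrics[arena.plate_id]
        arena_levels = classify_levels(
            control_dispersal, m.response_ratio, m.chemotaxis_index, thresholds
        )
        try:
            per_arena[arena.plate_id] = infer_table1(arena_levels)
        except ValueError:
            per_arena[arena.plate_id] = "index sign indeterminate"

    summary = {
        "control_dispersal_median": control_dispersal,
        "response_ratio_median": median_rr,
        "chemotaxis_index_median": median_ci,
    }
    if not interpretable:
        return InferenceResult(
            interpretable=False,
            precondition_failures=reasons,
            dispersal_level=levels.dispersal_level,
            rr_level=levels.rr_level,
            ci_level=levels.ci_level,
            ci_sign=levels.ci_sign,
            dispersal_regime=regime,
            median_metrics=summary,
            per_arena_verdicts=per_arena,
        )
    try:
        verdict = infer_table1(levels)
    except ValueError:
        # defined index exactly zero at a high level cannot occur with a
        # positive cut-off; guard anyway
        return InferenceResult(
            interpretable=False,
            precondition_failures=["chemotaxis index sign indeterminate"],
            dispersal_level=levels.dispersal_level,
            rr_level=levels.rr_level,
            ci_level=levels.ci_level,
            ci_sign=levels.ci_sign,
            dispersal_regime=regime,
            median_metrics=summary,
            per_arena_verdicts=per_arena,
        )
    return InferenceResult(
        interpretable=True,
        precondition_failures=[],
        dispersal_level=levels.dispersal_level,
        rr_level=levels.rr_level,
        ci_level=levels.ci_level,
        ci_sign=levels.ci_sign,
        verdict=verdict,
        dispersal_regime=regime,
        median_metrics=summary,
        per_arena_verdicts=per_arena,
    )
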