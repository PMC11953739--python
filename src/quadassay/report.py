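"""Assembly of the full analysis report and its serializations.

The report is a plain JSON-serializable dict so that
``json.loads(json.dumps(report)) == report`` holds exactly: per-arena
metric rows, per-odorant replicate summaries (chemotaxis index and
response ratio), an effect-size comparison of each odorant's indices
against the cohort-paired no-odorant controls' apparent indices, the
orientation-consistency check, the decision-chart outcome, and
provenance (input hash, seed, timestamp).
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

from . import __version__
from .assay_data import ArenaRecord, ExperimentSet, canonicalize, validate_experiment
from .errors import InsufficientDataError
from .inference import Thresholds, run_decision_chart
from .metrics import (
    compute_chemotaxis_index,
    compute_effect_size,
    compute_metrics,
    orientation_consistency,
    summarize_group,
    unpaired_t_test,
)

logger = logging.getLogger(__name__)

METRIC_CSV_COLUMNS = (
    "plate_id",
    "assay_type",
    "odorant",
    "n_total",
    "dispersal",
    "response_ratio",
    "chemotaxis_index",
)


def per_arena_rows(records: Sequence[ArenaRecord]) -> list[dict]:
    """Per-arena metric rows (canonical frame), JSON/CSV friendly."""
    rows = []
    for record in records:
        m = compute_metrics(record)
        rows.append(
            {
                "plate_id": record.plate_id,
                "assay_type": record.assay_type,
                "orientation": record.orientation,
                "odorant": record.odorant,
                "vehicle": record.vehicle,
                "cohort": record.cohort,
                "n_total": m.n_total,
                "dispersal": m.dispersal,
                "response_ratio": m.response_ratio,
                "chemotaxis_index": m.chemotaxis_index,
            }
        )
    return rows


def write_metrics_csv(records: Sequence[ArenaRecord], path: str | Path) -> None:
    """Write the metric output table; undefined chemotaxis index is an empty cell."""
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(METRIC_CSV_COLUMNS)
        for row in per_arena_rows(records):
            ci = row["chemotaxis_index"]
            writer.writerow(
                [
                    row["plate_id"],
                    row["assay_type"],
                    row["odorant"],
                    row["n_total"],
                    repr(row["dispersal"]),
                    repr(row["response_ratio"]),
                    "" if ci is None else repr(ci),
                ]
            )


def _defined_cis(arenas: Sequence[ArenaRecord]) -> list[float]:
    out = []
    for arena in arenas:
        ci = compute_chemotaxis_index(canonicalize(arena))
        if ci is not None:
            out.append(ci)
    return out


def _odorant_block(exp: ExperimentSet, thresholds: Thresholds, welch: bool) -> dict:
    chem = exp.chemotaxis_arenas
    block: dict = {"n_chemotaxis_arenas": len(chem), "n_dispersal_arenas": len(exp.dispersal_arenas)}

    cis = _defined_cis(chem)
    block["chemotaxis_index_summary"] = summarize_group(cis).to_dict() if cis else None
    rrs = [compute_metrics(a).response_ratio for a in chem]
    block["response_ratio_summary"] = summarize_group(rrs).to_dict() if rrs else None

    # apparent chemotaxis on cohort-paired no-odorant controls
    paired_cohorts = {a.cohort for a in chem}
    paired_controls = [d for d in exp.dispersal_arenas if d.cohort in paired_cohorts]
    unpaired = [d.plate_id for d in exp.dispersal_arenas if d.cohort not in paired_cohorts]
    if unpaired:
        logger.warning(
            "odorant %s: dispersal arena(s) %s have no cohort-matched chemotaxis "
            "arena and are excluded from the effect-size control group",
            exp.odorant,
            ", ".join(unpaired),
        )
    control_cis = _defined_cis(paired_controls)
    block["control_apparent_ci_summary"] = (
        summarize_group(control_cis).to_dict() if control_cis else None
    )

    if len(cis) >= 2 and len(control_cis) >= 2:
        ttest = unpaired_t_test(cis, control_cis, welch=welch)
        block["effect_vs_control"] = {
            "cohens_d": compute_effect_size(cis, control_cis).cohens_d,
            "t_statistic": ttest.t_statistic,
            "degrees_of_freedom": ttest.degrees_of_freedom,
            "p_value": ttest.p_value,
        }
    else:
        block["effect_vs_control"] = None

    try:
        block["orientation_consistency"] = orientation_consistency(exp).to_dict()
    except InsufficientDataError as err:
        block["orientation_consistency"] = None
        logger.info("odorant %s: orientation check skipped (%s)", exp.odorant, err)

    try:
        block["inference"] = run_decision_chart(exp, thresholds).to_dict()
    except InsufficientDataError as err:
        block["inference"] = {
            "interpretable": False,
            "precondition_failures": [str(err)],
            "verdict": None,
        }
    return block


def build_analysis_report(
    records: Sequence[ArenaRecord],
    thresholds: Thresholds = Thresholds(),
    *,
    welch: bool = False,
    seed: int | None = None,
    config_info: dict | None = None,
) -> dict:
    """Assemble the complete analysis report for a set of arena records."""
    odorants = sorted({r.odorant for r in records if r.assay_type == "chemotaxis"})
    odorant_blocks: dict[str, dict] = {}
    violations: list[dict] = []
    for odorant in odorants:
        exp = ExperimentSet.from_records(records, odorant=odorant)
        for violation in validate_experiment(exp, thresholds.min_worms - 1):
            entry = violation.to_dict()
            entry["odorant"] = odorant
            violations.append(entry)
        odorant_blocks[odorant] = _odorant_block(exp, thresholds, welch)

    digest_source = json.dumps(
        [per_arena_rows(records), thresholds.to_dict(), config_info], sort_keys=True
    ).encode()
    return {
        "per_arena": per_arena_rows(records),
        "odorants": odorant_blocks,
        "violations": violations,
        "thresholds": thresholds.to_dict(),
        "provenance": {
            "package_version": __version__,
            "config_hash": hashlib.sha256(digest_source).hexdigest(),
            "seed": seed,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "config": config_info,
        },
    }


def interpretable(report: dict) -> bool:
    """True iff every odorant block in the report reached a verdict."""
    blocks = report["odorants"].values()
    return bool(blocks) and all(b["inference"].get("interpretable") for b in blocks)


def render_text(report: dict) -> str:
    """Human-readable rendering of an analysis report."""
    lines: list[str] = []
    lines.append(f"quadassay report (package {report['provenance']['package_version']})")
    lines.append(f"arenas analyzed: {len(report['per_arena'])}")
    if report["violations"]:
        lines.append("validation violations:")
        for v in report["violations"]:
            lines.append(f"  - [{v['rule']}] plate {v['plate_id']}: {v['detail']}")
    else:
        lines.append("validation violations: none")
    for odorant, block in report["odorants"].items():
        lines.append(f"\nodorant: {odorant}")
        ci = block["chemotaxis_index_summary"]
        if ci:
            lines.append(
                f"  chemotaxis index: median {ci['median']:+.3f} "
                f"(mean {ci['mean']:+.3f}, N={ci['n_arenas']})"
            )
        rr = block["response_ratio_summary"]
        if rr:
            lines.append(f"  response ratio:   median {rr['median']:.3f}")
        effect = block["effect_vs_control"]
        if effect:
            star = "*" if effect["p_value"] is not None and effect["p_value"] < 0.05 else ""
            lines.append(
                f"  effect vs paired controls: d={effect['cohens_d']:.2f}, "
                f"p={effect['p_value']:.3g}{star}"
            )
        oc = block["orientation_consistency"]
        if oc:
            status = "FLAGGED: possible lab-frame gradient" if oc["flagged"] else "consistent"
            lines.append(
                f"  orientation check: A vs B difference {oc['difference']:+.3f} "
                f"(p={oc['p_value']:.3g}) -> {status}"
            )
        inference = block["inference"]
        if inference.get("interpretable"):
            lines.append(f"  verdict: {inference['verdict']}")
        else:
            lines.append("  NOT INTERPRETABLE:")
            for reason in inference.get("precondition_failures", []):
                lines.append(f"    - {reason}")
    return "\n".join(lines) + "\n"


def make_figure(report: dict):
    """Two-panel summary figure: index per odorant, and commitment to extremes.

    Mirrors the shape of the usual assay figure (index on top, proportions
    underneath); cosmetic fidelity is not a goal. Returns a matplotlib
    Figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_top, ax_bottom) = plt.subplots(2, 1, figsize=(6, 6), sharex=True)
    odorants = list(report["odorants"])
    for pos, odorant in enumerate(odorants):
        block = report["odorants"][odorant]
        ci = block["chemotaxis_index_summary"]
        control = block["control_apparent_ci_summary"]
        if control:
            ax_top.scatter(
                [pos - 0.15] * len(control["values"]),
                control["values"],
                color="grey",
                alpha=0.6,
                label="no odorant" if pos == 0 else None,
            )
        if ci:
            ax_top.scatter([pos + 0.15] * len(ci["values"]), ci["values"], color="C1")
            if ci["ci95_low"] is not None:
                ax_top.errorbar(
                    [pos + 0.15],
                    [ci["mean"]],
                    yerr=[[ci["mean"] - ci["ci95_low"]], [ci["ci95_high"] - ci["mean"]]],
                    fmt="none",
                    ecolor="black",
                )
        rr = block["response_ratio_summary"]
        if rr:
            ax_bottom.scatter([pos] * len(rr["values"]), rr["values"], color="C0")
    ax_top.axhline(0.0, color="black", linewidth=0.5)
    ax_top.set_ylabel("chemotaxis index")
    ax_top.set_ylim(-1.1, 1.1)
    ax_bottom.set_ylabel("response ratio")
    ax_bottom.set_ylim(0, 1.05)
    ax_bottom.set_xticks(range(len(odorants)))
    ax_bottom.set_xticklabels(odorants, rotation=20)
    if odorants:
        ax_top.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    return fig
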