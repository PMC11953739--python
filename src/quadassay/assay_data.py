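"""Data model, validation and I/O for quadrant-count assay data.

An arena is a rectangular lane divided into four equal quadrants along its
long axis. Worms are released at the center (between the two middle
quadrants) and counted per quadrant after the assay. Raw files record
counts *left-to-right in the lab frame*; the canonical frame puts the
vehicle end at ``q1`` and the odorant end at ``q4``, so arenas run in
orientation ``B`` (odorant end on the left) are reversed on
canonicalization.

CSV schema (UTF-8, header required)::

    plate_id,assay_type,orientation,odorant,vehicle,cohort,c_left,c_midleft,c_midright,c_right

``assay_type`` is ``dispersal`` or ``chemotaxis``; ``orientation`` is ``A``
or ``B``; the four ``c_*`` columns are non-negative integers. Unknown extra
columns are preserved verbatim and round-trip through
:func:`write_counts_table`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import CountValidationError, SchemaError

__all__ = [
    "QuadrantCounts",
    "ArenaRecord",
    "ExperimentSet",
    "Violation",
    "read_counts_table",
    "write_counts_table",
    "canonicalize",
    "validate_experiment",
    "REQUIRED_COLUMNS",
]

REQUIRED_COLUMNS = (
    "plate_id",
    "assay_type",
    "orientation",
    "odorant",
    "vehicle",
    "cohort",
    "c_left",
    "c_midleft",
    "c_midright",
    "c_right",
)

ASSAY_TYPES = ("dispersal", "chemotaxis")
ORIENTATIONS = ("A", "B")

#: Default interpretability threshold on worms per plate: strictly more than 100.
MIN_WORMS_EXCLUSIVE = 100


@dataclass(frozen=True)
class QuadrantCounts:
    """Worm counts per quadrant in the canonical frame.

    ``q1`` is the extreme quadrant at the vehicle end, ``q4`` the extreme
    quadrant at the odorant end; ``q2`` and ``q3`` flank the central origin.
    """

    q1: int
    q2: int
    q3: int
    q4: int

    def __post_init__(self) -> None:
        for name in ("q1", "q2", "q3", "q4"):
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool):
                raise CountValidationError(f"{name} must be an integer, got {value!r}")
            if value < 0:
                raise CountValidationError(f"{name} must be non-negative, got {value}")

    @property
    def n_total(self) -> int:
        return self.q1 + self.q2 + self.q3 + self.q4

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.q1, self.q2, self.q3, self.q4)


@dataclass(frozen=True)
class ArenaRecord:
    """One arena's lab-frame counts plus assay metadata.

    ``physical_counts`` are listed left-to-right in the lab frame and are
    orientation-agnostic; use :func:`canonicalize` to obtain
    :class:`QuadrantCounts` in the vehicle-to-odorant frame.
    """

    plate_id: str
    assay_type: str
    orientation: str
    odorant: str
    vehicle: str
    cohort: str
    physical_counts: tuple[int, int, int, int]
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.assay_type not in ASSAY_TYPES:
            raise CountValidationError(
                f"assay_type must be one of {ASSAY_TYPES}, got {self.assay_type!r}"
            )
        if self.orientation not in ORIENTATIONS:
            raise CountValidationError(
                f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}"
            )
        # reuse QuadrantCounts validation for the count invariants
        QuadrantCounts(*self.physical_counts)

    @property
    def n_total(self) -> int:
        return sum(self.physical_counts)


@dataclass
class ExperimentSet:
    """Paired dispersal-control and chemotaxis arenas for one odorant.

    Pairing is by ``cohort`` label: a chemotaxis arena is paired with every
    dispersal arena sharing its cohort.
    """

    odorant: str
    arenas: list[ArenaRecord]

    @property
    def chemotaxis_arenas(self) -> list[ArenaRecord]:
        return [a for a in self.arenas if a.assay_type == "chemotaxis"]

    @property
    def dispersal_arenas(self) -> list[ArenaRecord]:
        return [a for a in self.arenas if a.assay_type == "dispersal"]

    def paired_dispersal(self, arena: ArenaRecord) -> list[ArenaRecord]:
        """Dispersal arenas from the same cohort as ``arena``."""
        return [d for d in self.dispersal_arenas if d.cohort == arena.cohort]

    @classmethod
    def from_records(
        cls, records: Iterable[ArenaRecord], odorant: str | None = None
    ) -> "ExperimentSet":
        """Build a set from records, optionally restricted to one odorant.

        Dispersal arenas (odorant ``none``) are always included; chemotaxis
        arenas are filtered to ``odorant`` when given. When ``odorant`` is
        None and the records hold a single odorant, that odorant is used.
        """
        records = list(records)
        odorants = sorted({r.odorant for r in records if r.assay_type == "chemotaxis"})
        if odorant is None:
            if len(odorants) > 1:
                raise CountValidationError(
                    f"records contain multiple odorants {odorants}; pass odorant= to select one"
                )
            odorant = odorants[0] if odorants else "none"
        arenas = [
            r
            for r in records
            if r.assay_type == "dispersal"
            or (r.assay_type == "chemotaxis" and r.odorant == odorant)
        ]
        return cls(odorant=odorant, arenas=arenas)


@dataclass(frozen=True)
class Violation:
    """One experiment-validation failure (data, not an exception)."""

    plate_id: str
    rule: str
    detail: str

    def to_dict(self) -> dict:
        return {"plate_id": self.plate_id, "rule": self.rule, "detail": self.detail}


def _parse_count(raw: str, column: str, row: int) -> int:
    text = raw.strip()
    try:
        value = int(text)
    except ValueError:
        raise CountValidationError(
            f"column {column!r} must be an integer count, got {raw!r}", row=row
        ) from None
    if value < 0:
        raise CountValidationError(
            f"column {column!r} must be non-negative, got {value}", row=row
        )
    return value


def read_counts_table(path: str | Path) -> list[ArenaRecord]:
    """Read a counts CSV into :class:`ArenaRecord` objects.

    Raises
    ------
    SchemaError
        If a required column is missing from the header.
    CountValidationError
        If any row is malformed; the message lists every bad row (1-based,
        header excluded) and nothing is returned on failure — there is no
        partial load.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
        extra_columns = [c for c in reader.fieldnames if c not in REQUIRED_COLUMNS]

        records: list[ArenaRecord] = []
        problems: list[str] = []
        for row_index, row in enumerate(reader, start=1):
            try:
                counts = tuple(
                    _parse_count(row[c] or "", c, row_index)
                    for c in ("c_left", "c_midleft", "c_midright", "c_right")
                )
                record = ArenaRecord(
                    plate_id=(row["plate_id"] or "").strip(),
                    assay_type=(row["assay_type"] or "").strip(),
                    orientation=(row["orientation"] or "").strip(),
                    odorant=(row["odorant"] or "").strip(),
                    vehicle=(row["vehicle"] or "").strip(),
                    cohort=(row["cohort"] or "").strip(),
                    physical_counts=counts,  # type: ignore[arg-type]
                    extra={c: row[c] for c in extra_columns},
                )
            except CountValidationError as err:
                if err.row is None:
                    problems.append(f"row {row_index}: {err}")
                else:
                    problems.append(str(err))
                continue
            records.append(record)

    if problems:
        raise CountValidationError(
            f"{path}: {len(problems)} malformed row(s); no records loaded:\n  "
            + "\n  ".join(problems)
        )
    return records


def write_counts_table(records: Sequence[ArenaRecord], path: str | Path) -> None:
    """Write records to CSV in the canonical schema, preserving extra columns."""
    path = Path(path)
    extra_columns: list[str] = []
    for record in records:
        for key in record.extra:
            if key not in extra_columns:
                extra_columns.append(key)
    fieldnames = list(REQUIRED_COLUMNS) + extra_columns
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.DictWriter(handle, fieldnames=fieldnames)
        writer.writeheader()
        for record in records:
            row = {
                "plate_id": record.plate_id,
                "assay_type": record.assay_type,
                "orientation": record.orientation,
                "odorant": record.odorant,
                "vehicle": record.vehicle,
                "cohort": record.cohort,
                "c_left": record.physical_counts[0],
                "c_midleft": record.physical_counts[1],
                "c_midright": record.physical_counts[2],
                "c_right": record.physical_counts[3],
            }
            row.update(record.extra)
            writer.writerow(row)


def canonicalize(record: ArenaRecord) -> QuadrantCounts:
    """Map lab-frame counts to the canonical vehicle(q1)→odorant(q4) frame.

    Orientation ``A`` keeps counts as-is; orientation ``B`` (odorant end on
    the left) reverses them. Dispersal records carry orientation ``A`` by
    convention, so they pass through unchanged — their dispersal and
    response-ratio metrics are invariant under reversal anyway.
    """
    counts = record.physical_counts
    if record.orientation == "B":
        counts = counts[::-1]
    return QuadrantCounts(*counts)


def validate_experiment(
    exp: ExperimentSet, min_worms_exclusive: int = MIN_WORMS_EXCLUSIVE
) -> list[Violation]:
    """Check experiment-level interpretability rules; violations are data.

    Rules checked:

    - every arena holds strictly more than ``min_worms_exclusive`` worms;
    - chemotaxis arenas cover both physical orientations (controls for
      lab-frame external gradients);
    - every chemotaxis arena has at least one cohort-matched dispersal arena.
    """
    violations: list[Violation] = []
    for arena in exp.arenas:
        if arena.n_total <= min_worms_exclusive:
            violations.append(
                Violation(
                    plate_id=arena.plate_id,
                    rule="min_worms",
                    detail=(
                        f"n_total={arena.n_total} does not exceed the "
                        f">{min_worms_exclusive} worms-per-plate requirement"
                    ),
                )
            )
    chem = exp.chemotaxis_arenas
    if chem:
        present = {a.orientation for a in chem}
        missing = set(ORIENTATIONS) - present
        if missing:
            violations.append(
                Violation(
                    plate_id="*",
                    rule="opposing_orientations",
                    detail=(
                        "chemotaxis arenas cover orientation(s) "
                        f"{sorted(present)} only; opposing orientation "
                        f"{sorted(missing)} missing"
                    ),
                )
            )
    for arena in chem:
        if not exp.paired_dispersal(arena):
            violations.append(
                Violation(
                    plate_id=arena.plate_id,
                    rule="paired_dispersal",
                    detail=f"no dispersal arena from cohort {arena.cohort!r}",
                )
            )
    return violations


def violations_to_json(violations: Sequence[Violation]) -> str:
    return json.dumps([v.to_dict() for v in violations], indent=2)
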