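"""Domain types and deterministic schedule construction for multi-dimensional
incomplete stepped-wedge cluster-randomised trials (M-DISW-CRT).

A trial enrols health facilities (clusters), each of which conducts a
sequence of standards-based audit (S-BA) cycles.  One audit cycle for a
care standard spans three consecutive months:

* month 1 — assess compliance under the current standard of care (control),
* month 2 — review findings and act on deficiencies (transition, no data),
* month 3 — re-assess compliance after action (intervention).

Two scheduling variants are supported.  In variant A each facility audits
two standards in consecutive, non-overlapping three-month phases; facilities
are randomised to one of three start-month strata so that the step is not
confounded with the intervention.  In variant B each facility audits six
standards in overlapping phases — the intervention month of one cycle is the
control month of the next — preceded by a baseline month and closed by an
endline month in which every standard is assessed; two start-month strata
are used.

Months are abstract 1-based integers, not calendar dates.  In variant B the
baseline month of a stratum-1 facility is month 1, so its audit phases
occupy months 2-4, 4-6, ..., 12-14 and the endline falls in month 15 for
stratum 2; month labels are arbitrary because the analysis treats month as
categorical.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ExposureState",
    "Standard",
    "AuditCycle",
    "CollectionEvent",
    "FacilitySchedule",
    "DesignMatrix",
    "build_schedule_A",
    "build_schedule_B",
    "design_matrix",
    "validate_schedule",
    "schedules_to_json",
    "schedules_from_json",
    "schedules_to_csv",
    "schedules_from_csv",
    "ScheduleError",
]


class ScheduleError(ValueError):
    """Raised for structurally invalid schedule inputs."""


class ExposureState(str, Enum):
    """Status of a standard at a facility in a given month.

    CONTROL (code 0) and INTERVENTION (code 1) months collect compliance
    data; TRANSITION months review findings and implement change but collect
    no data; ABSENT marks months outside the data-collection pattern.
    A standard at a facility only ever moves CONTROL -> TRANSITION ->
    INTERVENTION, never backwards.
    """

    CONTROL = "control"
    TRANSITION = "transition"
    INTERVENTION = "intervention"
    ABSENT = "absent"

    @property
    def code(self) -> int:
        """Integer pattern code: 0 control, 1 intervention, -1 no data."""
        return _STATE_CODES[self]


_STATE_CODES = {
    ExposureState.CONTROL: 0,
    ExposureState.INTERVENTION: 1,
    ExposureState.TRANSITION: -1,
    ExposureState.ABSENT: -1,
}


@dataclass(frozen=True)
class Standard:
    """A care standard against which client-level compliance is audited."""

    id: str
    label: str = ""


@dataclass(frozen=True)
class AuditCycle:
    """One three-month audit cycle of a single standard.

    The transition month is always control_month + 1 and the intervention
    month control_month + 2.
    """

    standard: str
    control_month: int

    @property
    def transition_month(self) -> int:
        return self.control_month + 1

    @property
    def intervention_month(self) -> int:
        return self.control_month + 2


@dataclass(frozen=True)
class CollectionEvent:
    """A single data-collection occasion: one facility, month and standard.

    ``months_since_intervention`` is 0 for control assessments and for the
    intervention assessment that closes an audit cycle; endline re-assessments
    count the months elapsed since that closing assessment.
    """

    month: int
    standard: str
    state: ExposureState
    months_since_intervention: int = 0

    @property
    def exposure(self) -> int:
        return 1 if self.state is ExposureState.INTERVENTION else 0


@dataclass
class FacilitySchedule:
    """A facility's month-by-month plan of audit cycles and extra assessments.

    ``extra_assessments`` holds baseline/endline data-collection occasions
    that fall outside the audit cycles, as (month, standard, state) with
    state CONTROL or INTERVENTION.
    """

    facility_id: str
    stratum: int
    cycles: list[AuditCycle]
    extra_assessments: list[tuple[int, str, ExposureState]] = field(default_factory=list)

    def collection_events(self) -> list[CollectionEvent]:
        """All data-collection occasions, in month order.

        Transition months contribute no events.  Endline re-assessments of a
        standard already in the intervention state carry the months elapsed
        since its cycle's intervention assessment.
        """
        intervention_month = {c.standard: c.intervention_month for c in self.cycles}
        events: list[CollectionEvent] = []
        for c in self.cycles:
            events.append(CollectionEvent(c.control_month, c.standard, ExposureState.CONTROL))
            events.append(
                CollectionEvent(c.intervention_month, c.standard, ExposureState.INTERVENTION)
            )
        for month, std, state in self.extra_assessments:
            lag = 0
            if state is ExposureState.INTERVENTION and std in intervention_month:
                lag = month - intervention_month[std]
            events.append(CollectionEvent(month, std, state, lag))
        events.sort(key=lambda e: (e.month, e.standard, e.state.value))
        return events

    def collection_months(self, standard: str) -> list[int]:
        """Months in which compliance data are collected for ``standard``."""
        return sorted({e.month for e in self.collection_events() if e.standard == standard})

    def standards(self) -> list[str]:
        """Audited standards, in cycle order."""
        return [c.standard for c in self.cycles]

    @property
    def first_month(self) -> int:
        return min(e.month for e in self.collection_events())

    @property
    def last_month(self) -> int:
        return max(e.month for e in self.collection_events())

    @property
    def window(self) -> int:
        """Number of calendar months spanned by data collection."""
        return self.last_month - self.first_month + 1

    def state_sequence(self, standard: str) -> list[tuple[int, ExposureState]]:
        """(month, state) pairs for one standard, in month order, data months only."""
        return sorted(
            (e.month, e.state) for e in self.collection_events() if e.standard == standard
        )


@dataclass
class DesignMatrix:
    """Per-standard pattern of sequences over trial months.

    ``rows`` is an (n_sequences, n_months) int8 array with entries
    0 = control assessment, 1 = intervention assessment, -1 = no data
    collection for this standard in that month.  ``clusters_per_sequence``
    counts the facilities following each row; ``labels`` carries
    (stratum, cycle position) for each row where known.
    """

    standard: str
    months: list[int]
    rows: np.ndarray
    clusters_per_sequence: np.ndarray
    labels: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_sequences(self) -> int:
        return self.rows.shape[0]

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int8)
        self.clusters_per_sequence = np.asarray(self.clusters_per_sequence, dtype=int)
        if self.rows.ndim != 2 or self.rows.shape[1] != len(self.months):
            raise ScheduleError("design matrix rows must cover every trial month")
        if self.rows.shape[0] != len(self.clusters_per_sequence):
            raise ScheduleError("one cluster count required per sequence")


# ---------------------------------------------------------------------------
# Schedule builders
# ---------------------------------------------------------------------------


def build_schedule_A(
    allocation: Iterable[tuple[str, str, str, int]],
) -> list[FacilitySchedule]:
    """Build variant-A schedules from (facility, first, second, stratum) rows.

    Each facility audits its first standard in months s..s+2 and its second
    in months s+3..s+5, where s is its stratum (1, 2 or 3).  In the first
    collection month the second standard is additionally assessed at control,
    and in the last month the first standard is re-assessed at intervention,
    so every audited standard has exactly three collection months and the
    facility completes six collection events inside a six-month window.
    """
    schedules: list[FacilitySchedule] = []
    seen: set[str] = set()
    for facility_id, first, second, stratum in allocation:
        stratum = int(stratum)
        if stratum not in (1, 2, 3):
            raise ScheduleError(f"stratum must be 1, 2 or 3, got {stratum!r}")
        if first == second:
            raise ScheduleError(f"facility {facility_id!r} must audit two distinct standards")
        if facility_id in seen:
            raise ScheduleError(f"duplicate facility id {facility_id!r}")
        seen.add(facility_id)
        start = stratum
        schedules.append(
            FacilitySchedule(
                facility_id=str(facility_id),
                stratum=stratum,
                cycles=[
                    AuditCycle(first, control_month=start),
                    AuditCycle(second, control_month=start + 3),
                ],
                extra_assessments=[
                    (start, second, ExposureState.CONTROL),
                    (start + 5, first, ExposureState.INTERVENTION),
                ],
            )
        )
    return schedules


def build_schedule_B(
    row_assignment: Iterable[tuple[str, Sequence[str], int]],
) -> list[FacilitySchedule]:
    """Build variant-B schedules from (facility, standard order, stratum) rows.

    With baseline month b equal to the stratum (1 or 2), the six audit
    cycles occupy months (b+1..b+3), (b+3..b+5), ..., (b+11..b+13): the
    intervention month of each cycle is the control month of the next.  The
    baseline month assesses all six standards at control; the endline month
    b+13 re-assesses at intervention the five standards whose cycles closed
    earlier (the final-phase standard's own intervention assessment already
    falls there), giving 23 collection events per facility.
    """
    schedules: list[FacilitySchedule] = []
    seen: set[str] = set()
    for facility_id, order, stratum in row_assignment:
        stratum = int(stratum)
        if stratum not in (1, 2):
            raise ScheduleError(f"stratum must be 1 or 2, got {stratum!r}")
        order = list(order)
        if len(order) != 6 or len(set(order)) != 6:
            raise ScheduleError(
                f"facility {facility_id!r} needs an ordering of 6 distinct standards"
            )
        if facility_id in seen:
            raise ScheduleError(f"duplicate facility id {facility_id!r}")
        seen.add(facility_id)
        b = stratum
        cycles = [
            AuditCycle(std, control_month=b + 2 * k + 1) for k, std in enumerate(order)
        ]
        extra = [(b, std, ExposureState.CONTROL) for std in order]
        endline = b + 13
        extra += [(endline, std, ExposureState.INTERVENTION) for std in order[:-1]]
        schedules.append(
            FacilitySchedule(
                facility_id=str(facility_id),
                stratum=stratum,
                cycles=cycles,
                extra_assessments=extra,
            )
        )
    return schedules


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


def design_matrix(schedules: Sequence[FacilitySchedule], standard: str) -> DesignMatrix:
    """Collapse facility schedules into the sequence pattern for one standard.

    Rows are the distinct month-by-month collection patterns observed for the
    standard (one per occupied stratum x cycle-position combination);
    ``clusters_per_sequence`` counts the facilities following each row.
    Columns span the full trial (month 1 through the latest collection month
    of any schedule), with -1 in months where the standard collects no data.
    """
    if not schedules:
        raise ScheduleError("no schedules supplied")
    t_max = max(s.last_month for s in schedules)
    months = list(range(1, t_max + 1))
    patterns: dict[tuple[int, ...], int] = {}
    labels: dict[tuple[int, ...], tuple[int, int]] = {}
    found = False
    for sched in schedules:
        seq = sched.state_sequence(standard)
        if not seq:
            continue
        found = True
        row = np.full(t_max, -1, dtype=np.int8)
        for month, state in seq:
            row[month - 1] = state.code
        key = tuple(int(v) for v in row)
        patterns[key] = patterns.get(key, 0) + 1
        position = next(
            (k for k, c in enumerate(sched.cycles) if c.standard == standard), -1
        )
        labels.setdefault(key, (sched.stratum, position + 1))
    if not found:
        raise ScheduleError(f"no schedule audits standard {standard!r}")
    # deterministic order: by first collection month, then pattern
    ordered = sorted(patterns, key=lambda k: (next(i for i, v in enumerate(k) if v >= 0), k))
    rows = np.array(ordered, dtype=np.int8)
    counts = np.array([patterns[k] for k in ordered], dtype=int)
    return DesignMatrix(
        standard=standard,
        months=months,
        rows=rows,
        clusters_per_sequence=counts,
        labels=[labels[k] for k in ordered],
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_schedule(schedule: FacilitySchedule) -> list[str]:
    """Check a schedule against the structural invariants; return violations.

    An empty list means the schedule is valid.  Checked: audit cycles cover
    distinct standards; consecutive cycles either abut (variant A) or overlap
    by exactly one month (variant B); no (month, standard) collection occasion
    is duplicated; and per standard the exposure states are monotone — every
    control assessment precedes every intervention assessment.
    """
    violations: list[str] = []
    stds = [c.standard for c in schedule.cycles]
    if len(set(stds)) != len(stds):
        violations.append("cycles must audit distinct standards")
    for prev, nxt in zip(schedule.cycles, schedule.cycles[1:]):
        gap = nxt.control_month - prev.intervention_month
        if gap not in (0, 1):
            violations.append(
                "cycle-spacing: cycle starting month "
                f"{nxt.control_month} neither abuts nor overlaps the cycle "
                f"ending month {prev.intervention_month}"
            )
    seen_events: set[tuple[int, str, ExposureState]] = set()
    for c in schedule.cycles:
        for month, state in (
            (c.control_month, ExposureState.CONTROL),
            (c.intervention_month, ExposureState.INTERVENTION),
        ):
            key = (month, c.standard, state)
            if key in seen_events:
                violations.append(f"duplicate collection of {c.standard} in month {month}")
            seen_events.add(key)
    for month, std, state in schedule.extra_assessments:
        if state not in (ExposureState.CONTROL, ExposureState.INTERVENTION):
            violations.append(f"extra assessment in month {month} must be control or intervention")
        key = (month, std, state)
        if key in seen_events:
            violations.append(f"duplicate collection of {std} in month {month}")
        seen_events.add(key)
    by_std: dict[str, list[tuple[int, ExposureState]]] = {}
    for month, std, state in seen_events:
        by_std.setdefault(std, []).append((month, state))
    for std, seq in by_std.items():
        seq.sort()
        last_intervention = None
        for month, state in seq:
            if state is ExposureState.INTERVENTION and last_intervention is None:
                last_intervention = month
            if state is ExposureState.CONTROL and last_intervention is not None:
                violations.append(
                    f"monotone-state: control assessment of {std} in month {month} "
                    f"follows intervention assessment in month {last_intervention}"
                )
    return violations


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------


def schedules_to_json(schedules: Sequence[FacilitySchedule]) -> str:
    payload = [
        {
            "facility_id": s.facility_id,
            "stratum": s.stratum,
            "cycles": [
                {"standard": c.standard, "control_month": c.control_month} for c in s.cycles
            ],
            "extra_assessments": [
                {"month": m, "standard": std, "state": state.value}
                for m, std, state in s.extra_assessments
            ],
        }
        for s in schedules
    ]
    return json.dumps(payload, indent=2)


def schedules_from_json(text: str) -> list[FacilitySchedule]:
    payload = json.loads(text)
    return [
        FacilitySchedule(
            facility_id=item["facility_id"],
            stratum=int(item["stratum"]),
            cycles=[
                AuditCycle(c["standard"], int(c["control_month"])) for c in item["cycles"]
            ],
            extra_assessments=[
                (int(e["month"]), e["standard"], ExposureState(e["state"]))
                for e in item["extra_assessments"]
            ],
        )
        for item in payload
    ]


def schedules_to_csv(schedules: Sequence[FacilitySchedule]) -> str:
    """Long-format (facility_id, month, standard, state) listing for review.

    Transition months are included so that the full audit-cycle structure is
    visible; they carry no data collection.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["facility_id", "month", "standard", "state"])
    for s in schedules:
        rows = [
            (s.facility_id, e.month, e.standard, e.state.value) for e in s.collection_events()
        ]
        rows += [
            (s.facility_id, c.transition_month, c.standard, ExposureState.TRANSITION.value)
            for c in s.cycles
        ]
        for row in sorted(rows, key=lambda r: (r[1], r[2], r[3])):
            writer.writerow(row)
    return buf.getvalue()


def schedules_from_csv(text: str) -> list[dict]:
    """Parse the long-format CSV back into row dicts (for review tooling)."""
    reader = csv.DictReader(io.StringIO(text))
    return [
        {
            "facility_id": row["facility_id"],
            "month": int(row["month"]),
            "standard": row["standard"],
            "state": ExposureState(row["state"]),
        }
        for row in reader
    ]
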