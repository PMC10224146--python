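"""Environmental/process monitoring: verdicts, control schedule, media fill.

The unit's QAS prescribes periodic microbiological and particulate controls:

* every two weeks — settle plates (1 h inside the hood, 4 h in the room),
  surface swabs of the hood's working area, and glove prints (left, right,
  and a control plate; fingers pressed ~10 s on TSA);
* every 6 months — airborne-particle counts and a process-requalification
  media-fill test;
* per operator — media-fill campaigns: in triplicate once per year for newly
  hired staff (one per day for 3 days or 3 in a day), single test every six
  months for experienced staff, plus triplicate initial qualification.

Sample results are compared with grade-dependent limits (Annex 1 of the EU
GMP guide). A three-valued verdict is reported: ``pass`` (no growth),
``pass_with_growth_below_limit`` (growth detected but within limits — still
highlighted in reports), ``fail``. Numeric limit cells the guideline owns are
shipped as editable config, with no-growth mode for Grade A.
"""

from __future__ import annotations

import datetime
import enum
from typing import Iterable, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class MonitoringError(Exception):
    pass


class SampleKind(str, enum.Enum):
    settle_plate_hood_1h = "settle_plate_hood_1h"
    settle_plate_room_4h = "settle_plate_room_4h"
    surface_swab = "surface_swab"
    glove_print_left = "glove_print_left"
    glove_print_right = "glove_print_right"
    glove_print_control = "glove_print_control"
    particle_count = "particle_count"


class Medium(str, enum.Enum):
    TSA = "TSA"  # trypticase soy agar, general growth
    SDA = "SDA"  # Sabouraud dextrose agar, yeasts and fungi
    none = "none"


class Grade(str, enum.Enum):
    A = "A"
    C = "C"
    D = "D"


class MonitoringSample(BaseModel):
    model_config = ConfigDict(frozen=True)

    kind: SampleKind
    medium: Medium
    grade_context: Grade
    value: float = Field(..., ge=0)  # CFU, or particles for particle_count
    date: datetime.date

    @model_validator(mode="after")
    def _medium_consistent(self) -> "MonitoringSample":
        is_particle = self.kind is SampleKind.particle_count
        if is_particle != (self.medium is Medium.none):
            raise ValueError("medium must be 'none' exactly for particle counts")
        return self


class LimitMode(str, enum.Enum):
    no_growth = "no_growth"
    le_limit = "le_limit"


class Limit(BaseModel):
    model_config = ConfigDict(frozen=True)

    mode: LimitMode
    value: float = 0.0


#: (kind, grade) -> limit. Grade A cells use no-growth; the Grade C settle
#: plate cell carries the 50 CFU/4 h value; remaining numeric cells are
#: placeholders pending the site's Annex 1 transcription.
DEFAULT_LIMITS: dict[tuple[SampleKind, Grade], Limit] = {
    **{
        (kind, Grade.A): Limit(mode=LimitMode.no_growth)
        for kind in SampleKind
        if kind is not SampleKind.particle_count
    },
    (SampleKind.particle_count, Grade.A): Limit(mode=LimitMode.le_limit, value=3520),
    (SampleKind.settle_plate_room_4h, Grade.C): Limit(mode=LimitMode.le_limit, value=50),
    (SampleKind.surface_swab, Grade.C): Limit(mode=LimitMode.le_limit, value=25),       # placeholder
    (SampleKind.particle_count, Grade.C): Limit(mode=LimitMode.le_limit, value=352000),
    (SampleKind.settle_plate_room_4h, Grade.D): Limit(mode=LimitMode.le_limit, value=100),  # placeholder
}


class Verdict(str, enum.Enum):
    passed = "pass"
    pass_with_growth_below_limit = "pass_with_growth_below_limit"
    fail = "fail"


def check_sample(
    sample: MonitoringSample,
    limits: Optional[dict[tuple[SampleKind, Grade], Limit]] = None,
) -> Verdict:
    """Three-valued verdict for one sample against the configured limits.

    Growth below the limit still counts as a distinct verdict so reports can
    highlight every detection, not only exceedances.
    """
    if limits is None:
        limits = DEFAULT_LIMITS
    try:
        limit = limits[(sample.kind, sample.grade_context)]
    except KeyError:
        raise MonitoringError(
            f"no limit configured for ({sample.kind.value}, grade {sample.grade_context.value})"
        ) from None
    if limit.mode is LimitMode.no_growth:
        return Verdict.passed if sample.value == 0 else Verdict.fail
    if sample.value > limit.value:
        return Verdict.fail
    if sample.value > 0:
        return Verdict.pass_with_growth_below_limit
    return Verdict.passed


def check_log(
    samples: Iterable[MonitoringSample],
    limits: Optional[dict[tuple[SampleKind, Grade], Limit]] = None,
) -> list[tuple[MonitoringSample, Verdict]]:
    """Check a whole log; aborts listing *all* limit gaps before any verdict."""
    if limits is None:
        limits = DEFAULT_LIMITS
    samples = list(samples)
    gaps = sorted(
        {
            (s.kind.value, s.grade_context.value)
            for s in samples
            if (s.kind, s.grade_context) not in limits
        }
    )
    if gaps:
        raise MonitoringError(f"missing limit entries for: {gaps}")
    return [(s, check_sample(s, limits)) for s in samples]


class OperatorStatus(str, enum.Enum):
    new_hire = "new_hire"
    experienced = "experienced"


class Operator(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    status: OperatorStatus
    initial_qualification_due: bool = False


class IncubationStage(BaseModel):
    model_config = ConfigDict(frozen=True)

    duration_h: float
    temperature_range_C: str


class MediaFillProtocol(BaseModel):
    model_config = ConfigDict(frozen=True)

    operator_status: OperatorStatus
    items: dict[str, int]
    notes: dict[str, str] = {}
    incubation: tuple[IncubationStage, ...]


#: Units each operator prepares in one media-fill test, medium replacing drug.
DEFAULT_MEDIA_FILL_ITEMS: dict[str, int] = {
    "bottle": 1,
    "bags": 10,
    "syringes": 5,
    "mother_bag": 1,
    "satellite_bags": 3,
    "glove_fingerprint_plates": 3,   # left, right, control
    "hood_operator_control_plates": 2,
    "environmental_control_plates": 2,
}

DEFAULT_INCUBATION = (
    IncubationStage(duration_h=168.0, temperature_range_C="20-25"),
    IncubationStage(duration_h=168.0, temperature_range_C="30-35"),
)


def media_fill_protocol(
    operator_status: OperatorStatus | str,
    item_overrides: Optional[dict[str, int]] = None,
) -> MediaFillProtocol:
    """Item list and two-stage incubation plan for one media-fill test.

    Incubation is 7 days at 20-25 degC immediately followed by 7 days at
    30-35 degC; the stage order is fixed.
    """
    items = dict(DEFAULT_MEDIA_FILL_ITEMS)
    if item_overrides:
        items.update(item_overrides)
    return MediaFillProtocol(
        operator_status=OperatorStatus(operator_status),
        items=items,
        notes={"satellite_bags": "with scalar dilutions"},
        incubation=DEFAULT_INCUBATION,
    )


class ScheduleEntry(BaseModel):
    model_config = ConfigDict(frozen=True)

    date: datetime.date
    kind: str
    detail: str = ""


class Schedule(BaseModel):
    model_config = ConfigDict(frozen=True)

    year: int
    entries: tuple[ScheduleEntry, ...]

    def count(self, kind: str) -> int:
        return sum(1 for e in self.entries if e.kind == kind)


def _first_monday(year: int) -> datetime.date:
    d = datetime.date(year, 1, 1)
    return d + datetime.timedelta(days=(7 - d.weekday()) % 7)


def build_schedule(year: int, operators: Iterable[Operator] = ()) -> Schedule:
    """Annual control schedule for the unit.

    Biweekly environmental controls run every 14 days from the year's first
    Monday (26 sessions/year); particle counts and the process-requalification
    media fill every 6 months; operator media fills at the seniority-dependent
    frequency (experienced: single test every 6 months; new hire: one annual
    triplicate campaign on consecutive days), plus a triplicate initial
    qualification when flagged.
    """
    entries: list[ScheduleEntry] = []
    start = _first_monday(year)

    # 26 biweekly sessions cover the 52-week year exactly.
    for i in range(26):
        entries.append(
            ScheduleEntry(
                date=start + datetime.timedelta(days=14 * i),
                kind="environmental_control",
                detail="settle plates (hood 1 h, room 4 h), surface swab, glove prints",
            )
        )

    for offset in (0, 182):
        d6 = start + datetime.timedelta(days=offset)
        entries.append(
            ScheduleEntry(date=d6, kind="particle_count", detail="airborne particulate, Annex 1 limits")
        )
        entries.append(
            ScheduleEntry(date=d6, kind="requalification_media_fill", detail="process requalification, single test")
        )

    for op in operators:
        if op.initial_qualification_due:
            for day in range(3):
                entries.append(
                    ScheduleEntry(
                        date=start + datetime.timedelta(days=day),
                        kind="operator_media_fill",
                        detail=f"{op.name}: initial qualification, test {day + 1}/3",
                    )
                )
        if op.status is OperatorStatus.experienced:
            for offset in (0, 182):
                entries.append(
                    ScheduleEntry(
                        date=start + datetime.timedelta(days=offset),
                        kind="operator_media_fill",
                        detail=f"{op.name}: experienced, single test",
                    )
                )
        else:
            for day in range(3):
                entries.append(
                    ScheduleEntry(
                        date=start + datetime.timedelta(days=day),
                        kind="operator_media_fill",
                        detail=f"{op.name}: annual triplicate campaign, test {day + 1}/3",
                    )
                )

    entries.sort(key=lambda e: (e.date, e.kind, e.detail))
    return Schedule(year=year, entries=tuple(entries))


def schedule_to_csv(schedule: Schedule) -> str:
    lines = ["date,kind,detail"]
    for e in schedule.entries:
        detail = e.detail.replace('"', "'")
        lines.append(f'{e.date.isoformat()},{e.kind},"{detail}"')
    return "\n".join(lines) + "\n"


def schedule_to_ics(schedule: Schedule) -> str:
    """Minimal iCalendar-compatible text export (all-day events)."""
    out = ["BEGIN:VCALENDAR", "VERSION:2.0", "PRODID:-//rbpes//monitoring//EN"]
    for i, e in enumerate(schedule.entries):
        out += [
            "BEGIN:VEVENT",
            f"UID:rbpes-{schedule.year}-{i}",
            f"DTSTART;VALUE=DATE:{e.date.strftime('%Y%m%d')}",
            f"SUMMARY:{e.kind}: {e.detail}",
            "END:VEVENT",
        ]
    out.append("END:VCALENDAR")
    return "\n".join(out) + "\n"
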