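"""Typed domain model for the trial: protocol, rosters, and raw records.

The evaluation consumes five kinds of input:

* a :class:`ProtocolSpec` — the planned intervention: components, the
  per-participant session plan with durations and success criteria, and the
  required team-representation schedule for team-mode sessions;
* a :class:`Roster` — participants, their teams, workplaces and trial step;
* :class:`SessionRecord` rows — the concrete session instances scheduled for
  delivery units (a team, a merged working group, or a training group), each
  marked held or canceled;
* :class:`LogbookEntry` rows — one deliverer record per held session;
* :class:`QuestionnaireResponse` rows — the end-of-intervention participant
  questionnaire (satisfaction and social support).

Sessions are delivered to *delivery units*, not to the whole organization:
unit membership defines who can attend. A participant's trial step is a
property of their randomization group and is inherited by that group's
sessions. All ordinal responses are stored as canonical category tokens.

:func:`validate_dataset` cross-checks the pieces and returns a structured
violation report; it raises only on structurally unusable input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Component",
    "SessionPlan",
    "RepresentationBand",
    "ProtocolSpec",
    "Participant",
    "Team",
    "Roster",
    "DeliveryUnit",
    "SessionRecord",
    "LogbookEntry",
    "QuestionnaireResponse",
    "Dataset",
    "Violation",
    "ValidationReport",
    "DatasetError",
    "validate_dataset",
    "reference_protocol",
    "SATISFACTION_ITEMS",
    "OVERALL_SATISFACTION_ITEMS",
    "SUPPORT_ITEM_COUNT",
]


class DatasetError(ValueError):
    """Structurally unusable input (no sessions, empty roster, broken protocol)."""


class Component(BaseModel):
    model_config = ConfigDict(frozen=True)
    id: str
    label: str = ""


class SessionPlan(BaseModel):
    """One planned per-participant session of the protocol."""

    model_config = ConfigDict(frozen=True)

    session_id: str
    component_id: str
    duration: float = Field(gt=0, description="duration in hours")
    receipt_mode: Literal["individual", "team"] = "individual"
    criteria_ids: Tuple[str, ...] = ()
    has_intensity: bool = False


class RepresentationBand(BaseModel):
    """Required representative count for one interval of team sizes."""

    model_config = ConfigDict(frozen=True)

    min_size: int = Field(ge=1)
    max_size: Optional[int] = None  # None = open-ended
    required: int = Field(ge=1)


class ProtocolSpec(BaseModel):
    """The planned intervention against which delivery and receipt are scored."""

    model_config = ConfigDict(frozen=True)

    components: Tuple[Component, ...]
    sessions: Tuple[SessionPlan, ...]
    total_hours: float
    representation_schedule: Tuple[RepresentationBand, ...]

    @model_validator(mode="after")
    def _check(self) -> "ProtocolSpec":
        comp_ids = {c.id for c in self.components}
        if len(comp_ids) != len(self.components):
            raise ValueError("duplicate component ids in protocol")
        for s in self.sessions:
            if s.component_id not in comp_ids:
                raise ValueError(
                    f"session {s.session_id!r} references undeclared component "
                    f"{s.component_id!r}"
                )
        plan_ids = [s.session_id for s in self.sessions]
        if len(set(plan_ids)) != len(plan_ids):
            raise ValueError("duplicate session ids in protocol")
        total = sum(s.duration for s in self.sessions)
        if abs(total - self.total_hours) > 1e-9:
            raise ValueError(
                f"total_hours={self.total_hours} but session durations sum to {total}"
            )
        # representation schedule must tile [1, inf) with no gaps or overlaps
        bands = sorted(self.representation_schedule, key=lambda b: b.min_size)
        if not bands or bands[0].min_size != 1:
            raise ValueError("representation schedule must start at team size 1")
        for a, b in zip(bands, bands[1:]):
            if a.max_size is None:
                raise ValueError("open-ended representation band must be last")
            if b.min_size != a.max_size + 1:
                raise ValueError(
                    f"representation schedule gap/overlap between sizes "
                    f"{a.max_size} and {b.min_size}"
                )
        if bands[-1].max_size is not None:
            raise ValueError("representation schedule must cover all team sizes (last band open-ended)")
        return self

    # -- convenience lookups -------------------------------------------------
    def plan(self, session_id: str) -> SessionPlan:
        for s in self.sessions:
            if s.session_id == session_id:
                return s
        raise KeyError(session_id)

    def component_hours(self, component_id: str) -> float:
        return sum(s.duration for s in self.sessions if s.component_id == component_id)

    def required_representatives(self, team_size: int) -> int:
        if team_size < 1:
            raise ValueError(f"team size must be >= 1, got {team_size}")
        for band in self.representation_schedule:
            if team_size >= band.min_size and (band.max_size is None or team_size <= band.max_size):
                return band.required
        raise ValueError(f"no representation band covers team size {team_size}")


class Participant(BaseModel):
    model_config = ConfigDict(frozen=True)
    participant_id: str
    team_id: str
    workplace_id: str
    step: str


class Team(BaseModel):
    model_config = ConfigDict(frozen=True)
    team_id: str
    workplace_id: str
    member_ids: Tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.member_ids)


class Roster(BaseModel):
    model_config = ConfigDict(frozen=True)
    participants: Tuple[Participant, ...]
    teams: Tuple[Team, ...]
    steps: Tuple[str, ...]

    @model_validator(mode="after")
    def _check(self) -> "Roster":
        teams = {t.team_id: t for t in self.teams}
        if len(teams) != len(self.teams):
            raise ValueError("duplicate team ids")
        pids = [p.participant_id for p in self.participants]
        if len(set(pids)) != len(pids):
            raise ValueError("duplicate participant ids")
        membership: Dict[str, set] = {tid: set(t.member_ids) for tid, t in teams.items()}
        for p in self.participants:
            t = teams.get(p.team_id)
            if t is None:
                raise ValueError(f"participant {p.participant_id} assigned to unknown team {p.team_id}")
            if t.workplace_id != p.workplace_id:
                raise ValueError(
                    f"participant {p.participant_id} workplace {p.workplace_id} "
                    f"does not match team {t.team_id} workplace {t.workplace_id}"
                )
            if p.participant_id not in membership[p.team_id]:
                raise ValueError(f"participant {p.participant_id} missing from team {p.team_id} members")
            if p.step not in self.steps:
                raise ValueError(f"participant {p.participant_id} has undeclared step {p.step}")
        return self

    def team(self, team_id: str) -> Team:
        for t in self.teams:
            if t.team_id == team_id:
                return t
        raise KeyError(team_id)


class DeliveryUnit(BaseModel):
    """The audience of a scheduled session instance (team, working group, training group)."""

    model_config = ConfigDict(frozen=True)
    unit_id: str
    component_id: str
    member_ids: Tuple[str, ...]
    team_ids: Tuple[str, ...] = ()


class SessionRecord(BaseModel):
    """One scheduled session instance for one delivery unit."""

    model_config = ConfigDict(frozen=True)
    session_id: str
    plan_id: str
    workplace_id: str
    unit_id: str
    step: str
    held: bool
    deliverer_id: str = ""


#: Questionnaire satisfaction item keys; the first three are component-specific.
SATISFACTION_ITEMS: tuple[str, ...] = (
    "sat_pt",
    "sat_cbt",
    "sat_pe",
    "sat_overall",
    "sat_relevant",
    "sat_interesting",
)
OVERALL_SATISFACTION_ITEMS: tuple[str, ...] = ("sat_overall", "sat_relevant", "sat_interesting")
SUPPORT_ITEM_COUNT = 4


class LogbookEntry(BaseModel):
    """Deliverer record filled in after one held session."""

    model_config = ConfigDict(frozen=True)

    session_id: str
    criterion_ratings: Dict[str, Optional[str]] = Field(default_factory=dict)
    understanding_items: Tuple[Optional[str], ...] = (None,) * 4
    contribution_items: Tuple[Optional[str], ...] = (None,) * 4
    self_rated_performance: Optional[int] = None
    intensity: Optional[int] = None
    motivation_rating: Optional[str] = None
    attendee_ids: Tuple[str, ...] = ()


class QuestionnaireResponse(BaseModel):
    """End-of-intervention participant questionnaire."""

    model_config = ConfigDict(frozen=True)

    participant_id: str
    satisfaction_items: Dict[str, Optional[str]] = Field(default_factory=dict)
    support_items: Tuple[Optional[str], ...] = (None,) * SUPPORT_ITEM_COUNT


class Dataset(BaseModel):
    """Everything one evaluation run consumes, bundled."""

    model_config = ConfigDict(frozen=True)

    protocol: ProtocolSpec
    roster: Roster
    units: Tuple[DeliveryUnit, ...]
    sessions: Tuple[SessionRecord, ...]
    logbooks: Tuple[LogbookEntry, ...]
    questionnaires: Tuple[QuestionnaireResponse, ...]


@dataclass(frozen=True)
class Violation:
    kind: str
    subject: str
    detail: str = ""


@dataclass
class ValidationReport:
    violations: List[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def of_kind(self, kind: str) -> List[Violation]:
        return [v for v in self.violations if v.kind == kind]

    def summary(self) -> str:
        if self.ok:
            return "dataset valid: no violations"
        counts: Dict[str, int] = {}
        for v in self.violations:
            counts[v.kind] = counts.get(v.kind, 0) + 1
        lines = [f"{len(self.violations)} violation(s):"]
        lines += [f"  {k}: {n}" for k, n in sorted(counts.items())]
        return "\n".join(lines)


def validate_dataset(dataset: Dataset) -> ValidationReport:
    """Cross-check protocol, roster and records; return a violation report.

    Raises :class:`DatasetError` only when the input is structurally unusable
    (no sessions or an empty roster); everything else is reported as a
    violation so a run can decide its own severity threshold. The input is
    never mutated and repeated calls return identical reports.
    """
    if not dataset.sessions:
        raise DatasetError("no sessions: nothing to evaluate")
    if not dataset.roster.participants:
        raise DatasetError("empty roster: no participants")

    report = ValidationReport()
    add = report.violations.append

    plan_ids = {s.session_id for s in dataset.protocol.sessions}
    unit_by_id = {u.unit_id: u for u in dataset.units}
    pids = {p.participant_id for p in dataset.roster.participants}
    session_by_id: Dict[str, SessionRecord] = {}

    for rec in dataset.sessions:
        if rec.session_id in session_by_id:
            add(Violation("duplicate_session", rec.session_id))
        session_by_id[rec.session_id] = rec
        if rec.plan_id not in plan_ids:
            add(Violation("unknown_plan", rec.session_id, f"plan {rec.plan_id!r} not in protocol"))
        unit = unit_by_id.get(rec.unit_id)
        if unit is None:
            add(Violation("unknown_unit", rec.session_id, f"unit {rec.unit_id!r} not declared"))
        if rec.step not in dataset.roster.steps:
            add(Violation("unknown_step", rec.session_id, f"step {rec.step!r} not declared"))

    for unit in dataset.units:
        for pid in unit.member_ids:
            if pid not in pids:
                add(Violation("unknown_participant", unit.unit_id, f"unit member {pid!r} not in roster"))

    logged = set()
    for lb in dataset.logbooks:
        rec = session_by_id.get(lb.session_id)
        if rec is None:
            add(Violation("unknown_session", lb.session_id, "logbook for unscheduled session"))
            continue
        if lb.session_id in logged:
            add(Violation("duplicate_logbook", lb.session_id))
        logged.add(lb.session_id)
        if not rec.held:
            add(Violation("logbook_for_canceled", lb.session_id))
        if rec.plan_id in plan_ids:
            plan = dataset.protocol.plan(rec.plan_id)
            missing = set(plan.criteria_ids) - set(lb.criterion_ratings)
            extra = set(lb.criterion_ratings) - set(plan.criteria_ids)
            for cid in sorted(missing):
                add(Violation("missing_criterion", lb.session_id, cid))
            for cid in sorted(extra):
                add(Violation("unexpected_criterion", lb.session_id, cid))
            if plan.has_intensity and lb.intensity is None:
                add(Violation("missing_intensity", lb.session_id))
            if not plan.has_intensity and lb.intensity is not None:
                add(Violation("unexpected_intensity", lb.session_id))
        unit = unit_by_id.get(rec.unit_id)
        for pid in lb.attendee_ids:
            if pid not in pids:
                add(Violation("unknown_participant", lb.session_id, f"attendee {pid!r} not in roster"))
            elif unit is not None and pid not in unit.member_ids:
                add(Violation("attendee_not_in_unit", lb.session_id, pid))

    for rec in dataset.sessions:
        if rec.held and rec.session_id not in logged:
            add(Violation("missing_logbook", rec.session_id))

    seen_q = set()
    for q in dataset.questionnaires:
        if q.participant_id in seen_q:
            add(Violation("duplicate_questionnaire", q.participant_id))
        seen_q.add(q.participant_id)
        if q.participant_id not in pids:
            add(Violation("unknown_participant", q.participant_id, "questionnaire from non-participant"))

    return report


# ---------------------------------------------------------------------------
# Reference protocol: 19 sessions / 27 h across three components
# ---------------------------------------------------------------------------

def reference_protocol() -> ProtocolSpec:
    """The packaged reference protocol: 19 sessions / 27 h.

    Participatory ergonomics (PE, 5 sessions / 9 h: a 1-h kick-off open to
    everyone, two 3-h working-group workshops and two 1-h evaluation meetings
    received at team level), physical training (PT, 12 weekly 1-h sessions
    with an intensity target) and cognitive behavioural training (CBT, two 3-h
    workshops). 55 success criteria in total across the sessions.
    """
    comps = (
        Component(id="PE", label="participatory ergonomics"),
        Component(id="PT", label="physical training"),
        Component(id="CBT", label="cognitive behavioural training"),
    )
    sessions: list[SessionPlan] = []

    def crit(prefix: str, n: int) -> tuple[str, ...]:
        return tuple(f"{prefix}_c{i}" for i in range(1, n + 1))

    sessions.append(SessionPlan(session_id="pe_kickoff", component_id="PE", duration=1,
                                receipt_mode="individual", criteria_ids=crit("pe_kickoff", 4)))
    for sid, dur, n in (("pe_ws1", 3, 4), ("pe_ws2", 3, 4), ("pe_ev1", 1, 3), ("pe_ev2", 1, 3)):
        sessions.append(SessionPlan(session_id=sid, component_id="PE", duration=dur,
                                    receipt_mode="team", criteria_ids=crit(sid, n)))
    for i in range(1, 13):
        sid = f"pt_{i:02d}"
        sessions.append(SessionPlan(session_id=sid, component_id="PT", duration=1,
                                    criteria_ids=crit(sid, 2), has_intensity=True))
    for sid, n in (("cbt_1", 6), ("cbt_2", 7)):
        sessions.append(SessionPlan(session_id=sid, component_id="CBT", duration=3,
                                    criteria_ids=crit(sid, n)))

    schedule = (
        RepresentationBand(min_size=1, max_size=4, required=2),
        RepresentationBand(min_size=5, max_size=9, required=3),
        RepresentationBand(min_size=10, max_size=14, required=4),
        RepresentationBand(min_size=15, max_size=19, required=5),
        RepresentationBand(min_size=20, max_size=None, required=6),
    )
    return ProtocolSpec(components=comps, sessions=tuple(sessions),
                        total_hours=27, representation_schedule=schedule)
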