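"""Receipt-side scoring: participation and responsiveness.

Participation is the duration-weighted fraction of the planned protocol a
participant was present for. For individually received sessions presence is
0/1 attendance. The team-received participatory-ergonomics sessions are scored
at team level — the intervention is expected to spill over ("contaminate")
from the attending representatives to the rest of the team — and the team
value is broadcast to every member:

* per session, team participation = attending members / required
  representatives (capped at 1), where the required count depends on team
  size (<5 → 2, 5–9 → 3, 10–14 → 4, 15–19 → 5, ≥20 → 6);
* the team participation score is the duration-weighted mean of those
  per-session values over held team-mode sessions;
* the continuity score rewards the *same* representatives attending
  throughout: members present at every held team-mode session / required,
  capped at 1 (an optional leniency allows a number of missed sessions);
* the combined team score is the mean of participation and continuity and
  becomes each member's presence for those sessions.

A session canceled by the organization contributes presence 0 — a participant
cannot gain a session their organization never held.

Responsiveness R is the mean of the available sub-indexes: satisfaction (six
questionnaire items), intervention-related social support (four items) and
motivation (the deliverer-rated group motivation of the sessions the
participant personally attended, duration-weighted). Participants without a
questionnaire have missing R. Component-level responsiveness uses the
component-specific satisfaction item together with the three overall items,
reuses the support index unchanged, and restricts motivation to the
component's sessions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .protocol_model import (
    OVERALL_SATISFACTION_ITEMS,
    SATISFACTION_ITEMS,
    Dataset,
    QuestionnaireResponse,
    RepresentationBand,
)
from .scoring import LIKERT5_FREQUENCY, score_index, score_likert5

__all__ = [
    "TeamPEScore",
    "Responsiveness",
    "required_representatives",
    "team_session_participation",
    "team_continuity",
    "team_pe_scores",
    "participation_weight",
    "presence_table",
    "individual_participation",
    "satisfaction_index",
    "support_index",
    "responsiveness_table",
]

#: Component id → its specific satisfaction item key.
COMPONENT_SATISFACTION_ITEM = {"PT": "sat_pt", "CBT": "sat_cbt", "PE": "sat_pe"}


@dataclass(frozen=True)
class TeamPEScore:
    team_id: str
    participation_score: Optional[float]
    continuity_score: Optional[float]

    @property
    def combined(self) -> Optional[float]:
        if self.participation_score is None or self.continuity_score is None:
            return None
        return (self.participation_score + self.continuity_score) / 2


@dataclass(frozen=True)
class Responsiveness:
    participant_id: str
    satisfaction: Optional[float]
    support: Optional[float]
    motivation: Optional[float]

    @property
    def r(self) -> Optional[float]:
        return score_index([self.satisfaction, self.support, self.motivation])


def required_representatives(team_size: int, schedule: Sequence[RepresentationBand] | None = None) -> int:
    """Required representative count for a team of the given size.

    Defaults to the reference schedule: <5 → 2, 5–9 → 3, 10–14 → 4,
    15–19 → 5, ≥20 → 6.
    """
    if team_size < 1:
        raise ValueError(f"team size must be >= 1, got {team_size}")
    if schedule is None:
        bounds = ((1, 4, 2), (5, 9, 3), (10, 14, 4), (15, 19, 5), (20, None, 6))
        schedule = [RepresentationBand(min_size=a, max_size=b, required=r) for a, b, r in bounds]
    for band in schedule:
        if team_size >= band.min_size and (band.max_size is None or team_size <= band.max_size):
            return band.required
    raise ValueError(f"no representation band covers team size {team_size}")


def team_session_participation(attending: int, required: int) -> float:
    """Per-session team participation: attending members / required, capped at 1."""
    if required < 1:
        raise ValueError("required representative count must be >= 1")
    if attending < 0:
        raise ValueError("attending count must be >= 0")
    return min(attending / required, 1.0)


def team_continuity(
    attendance_by_session: Sequence[Set[str]],
    required: int,
    max_missed: int = 0,
) -> Optional[float]:
    """Continuity: members attending (all − ``max_missed``) held sessions / required.

    ``attendance_by_session`` holds, for each held team-mode session, the set
    of team members who attended. Returns None when no session was held.
    """
    if not attendance_by_session:
        return None
    n = len(attendance_by_session)
    need = max(n - max_missed, 1)
    counts: Dict[str, int] = {}
    for attendees in attendance_by_session:
        for pid in attendees:
            counts[pid] = counts.get(pid, 0) + 1
    persistent = sum(1 for c in counts.values() if c >= need)
    return min(persistent / required, 1.0)


def participation_weight(presence: float, duration: float, total_hours: float) -> float:
    """Session participation weight P^s = presence × duration / total protocol hours."""
    if total_hours <= 0:
        raise ValueError("total protocol hours must be > 0")
    if not 0 <= presence <= 1:
        raise ValueError(f"presence must be in [0, 1], got {presence}")
    return presence * duration / total_hours


def _attendance_sets(dataset: Dataset) -> Dict[str, Set[str]]:
    return {lb.session_id: set(lb.attendee_ids) for lb in dataset.logbooks}


def team_pe_scores(dataset: Dataset, max_missed: int = 0) -> pd.DataFrame:
    """Team-mode participation, continuity and combined score per team.

    Returns a DataFrame with one row per roster team: ``team_id``,
    ``required``, ``participation_score``, ``continuity_score``, ``combined``
    (NaN where the team had no held team-mode session).
    """
    schedule = dataset.protocol.representation_schedule
    attendance = _attendance_sets(dataset)
    unit_teams: Dict[str, tuple] = {u.unit_id: u.team_ids for u in dataset.units}
    team_sessions: Dict[str, list] = {t.team_id: [] for t in dataset.roster.teams}
    for rec in dataset.sessions:
        plan = dataset.protocol.plan(rec.plan_id)
        if plan.receipt_mode != "team" or not rec.held:
            continue
        for tid in unit_teams.get(rec.unit_id, ()):
            if tid in team_sessions:
                team_sessions[tid].append((rec.session_id, plan.duration))

    rows = []
    for team in dataset.roster.teams:
        required = required_representatives(team.size, schedule)
        members = set(team.member_ids)
        held = team_sessions[team.team_id]
        if not held:
            rows.append({"team_id": team.team_id, "required": required,
                         "participation_score": np.nan, "continuity_score": np.nan,
                         "combined": np.nan})
            continue
        att_sets = [attendance.get(sid, set()) & members for sid, _ in held]
        durations = np.array([dur for _, dur in held], dtype=float)
        per_session = np.array(
            [team_session_participation(len(a), required) for a in att_sets]
        )
        participation = float(np.average(per_session, weights=durations))
        continuity = team_continuity(att_sets, required, max_missed=max_missed)
        score = TeamPEScore(team.team_id, participation, continuity)
        rows.append({"team_id": team.team_id, "required": required,
                     "participation_score": participation,
                     "continuity_score": continuity,
                     "combined": score.combined})
    return pd.DataFrame(rows)


def presence_table(dataset: Dataset, team_scores: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Per (participant, scheduled session) presence.

    One row per member of each session's delivery unit with columns
    ``participant_id, session_id, plan_id, component, duration, held,
    receipt_mode, team_id, workplace, step, attended, presence``.
    ``attended`` is personal attendance (0/1 from the logbook attendee list);
    ``presence`` is what participation uses — attendance for individual-mode
    sessions, the team's combined score broadcast to all members for team-mode
    sessions, and 0 for canceled sessions.
    """
    if team_scores is None:
        team_scores = team_pe_scores(dataset)
    combined = team_scores.set_index("team_id")["combined"].to_dict()
    attendance = _attendance_sets(dataset)
    units = {u.unit_id: u for u in dataset.units}
    p_team = {p.participant_id: p.team_id for p in dataset.roster.participants}

    rows = []
    for rec in dataset.sessions:
        plan = dataset.protocol.plan(rec.plan_id)
        unit = units.get(rec.unit_id)
        if unit is None:
            continue
        attended_set = attendance.get(rec.session_id, set()) if rec.held else set()
        team_mode = plan.receipt_mode == "team"
        for pid in unit.member_ids:
            attended = 1.0 if pid in attended_set else 0.0
            if not rec.held:
                presence = 0.0
            elif team_mode:
                c = combined.get(p_team.get(pid), np.nan)
                presence = 0.0 if pd.isna(c) else float(c)
            else:
                presence = attended
            rows.append((pid, rec.session_id, rec.plan_id, plan.component_id,
                         plan.duration, rec.held, plan.receipt_mode,
                         p_team.get(pid), rec.workplace_id, rec.step,
                         attended, presence))
    return pd.DataFrame(rows, columns=[
        "participant_id", "session_id", "plan_id", "component", "duration",
        "held", "receipt_mode", "team_id", "workplace", "step",
        "attended", "presence",
    ])


def individual_participation(presence: pd.DataFrame, total_hours: float) -> pd.Series:
    """Total participation per participant: Σ presence × duration / total hours."""
    w = presence["presence"] * presence["duration"] / total_hours
    return w.groupby(presence["participant_id"]).sum().rename("participation")


def satisfaction_index(q: QuestionnaireResponse, items: Sequence[str] = SATISFACTION_ITEMS) -> Optional[float]:
    """Mean score of the given satisfaction items (available-item mean)."""
    return score_index(
        [score_likert5(r) for k in items if (r := q.satisfaction_items.get(k)) is not None]
    )


def support_index(q: QuestionnaireResponse) -> Optional[float]:
    """Mean score of the four social-support items (always/often/… scale)."""
    return score_index(
        [score_likert5(r, LIKERT5_FREQUENCY) for r in q.support_items if r is not None]
    )


def _weighted_motivation(attended: pd.DataFrame) -> float:
    """Duration-weighted mean motivation over personally attended, scored sessions."""
    g = attended.dropna(subset=["motivation"])
    if g.empty:
        return np.nan
    return float(np.average(g["motivation"], weights=g["duration"]))


def responsiveness_table(
    dataset: Dataset,
    presence: pd.DataFrame,
    session_scores: pd.DataFrame,
) -> pd.DataFrame:
    """Responsiveness per participant, overall and per component.

    One row per roster participant: ``satisfaction``, ``support``,
    ``motivation``, ``responsiveness`` (R, mean of the available sub-indexes;
    NaN for questionnaire non-responders) plus ``satisfaction_<comp>``,
    ``motivation_<comp>``, ``responsiveness_<comp>`` for every component. The
    support index is shared unchanged across components. Motivation is
    computed for everyone with attendance, questionnaire or not.
    """
    mot = session_scores.set_index("session_id")["motivation"]
    att = presence[presence["attended"] > 0].copy()
    att["motivation"] = att["session_id"].map(mot)

    motivation_all = att.groupby("participant_id").apply(_weighted_motivation, include_groups=False)
    motivation_comp = {
        comp: g.groupby("participant_id").apply(_weighted_motivation, include_groups=False)
        for comp, g in att.groupby("component")
    }

    responses = {q.participant_id: q for q in dataset.questionnaires}
    components = [c.id for c in dataset.protocol.components]
    rows = []
    for p in dataset.roster.participants:
        pid = p.participant_id
        q = responses.get(pid)
        m = motivation_all.get(pid, np.nan)
        row: dict = {"participant_id": pid, "motivation": m}
        if q is None:
            row.update(satisfaction=np.nan, support=np.nan, responsiveness=np.nan)
            for comp in components:
                row[f"satisfaction_{comp}"] = np.nan
                row[f"motivation_{comp}"] = _get(motivation_comp, comp, pid)
                row[f"responsiveness_{comp}"] = np.nan
            rows.append(row)
            continue
        sat = satisfaction_index(q)
        sup = support_index(q)
        resp = Responsiveness(pid, sat, sup, None if pd.isna(m) else float(m))
        row.update(satisfaction=_num(sat), support=_num(sup), responsiveness=_num(resp.r))
        for comp in components:
            item = COMPONENT_SATISFACTION_ITEM.get(comp)
            comp_items = ((item,) if item else ()) + OVERALL_SATISFACTION_ITEMS
            csat = satisfaction_index(q, comp_items)
            cmot = _get(motivation_comp, comp, pid)
            r = score_index([csat, sup, None if pd.isna(cmot) else float(cmot)])
            row[f"satisfaction_{comp}"] = _num(csat)
            row[f"motivation_{comp}"] = cmot
            row[f"responsiveness_{comp}"] = _num(r)
        rows.append(row)
    return pd.DataFrame(rows)


def _num(x: Optional[float]) -> float:
    return np.nan if x is None else float(x)


def _get(comp_map: Dict[str, pd.Series], comp: str, pid: str) -> float:
    s = comp_map.get(comp)
    if s is None:
        return np.nan
    return float(s.get(pid, np.nan))
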