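"""Shared fixtures: generated trials and a hand-built miniature dataset."""

from __future__ import annotations

import pytest
from hypothesis import settings as hyp_settings

from impquant.implementation import score_trial

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None, database=None)
hyp_settings.load_profile("deterministic")
from impquant.protocol_model import (
    Dataset,
    DeliveryUnit,
    LogbookEntry,
    Participant,
    QuestionnaireResponse,
    Roster,
    Team,
    reference_protocol,
)
from impquant.synthetic_data import SimulationConfig, generate_trial

#: small but structurally complete trial for fast end-to-end tests
SMALL_CONFIG = SimulationConfig(
    seed=7,
    step_sizes=(20, 24),
    workplace_sizes=(22, 22),
    n_teams=8,
    pe_working_groups=4,
    pt_groups=4,
    cbt_groups=4,
    pt_trimmed_sessions=0,
    canceled_sessions={"PE": 1, "PT": 2, "CBT": 1},
)


@pytest.fixture(scope="session")
def small_trial():
    return generate_trial(SMALL_CONFIG)


@pytest.fixture(scope="session")
def reference_trial():
    """Default reference-shaped trial: 594 participants, 753 intended sessions."""
    return generate_trial(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def reference_scores(reference_trial):
    dataset, _ = reference_trial
    return score_trial(dataset)


def perfect_logbook(plan, attendees) -> LogbookEntry:
    """A logbook with every rating at the top of its scale."""
    return LogbookEntry(
        session_id="",  # set by caller via model_copy
        criterion_ratings={cid: "completely" for cid in plan.criteria_ids},
        understanding_items=("to a very large extent",) * 4,
        contribution_items=("to a very large extent",) * 4,
        self_rated_performance=10,
        intensity=9 if plan.has_intensity else None,
        motivation_rating="to a very large extent",
        attendee_ids=tuple(attendees),
    )


def make_mini_dataset(
    n_members: int = 6,
    attend: dict[str, tuple[str, ...]] | None = None,
    canceled: tuple[str, ...] = (),
    questionnaires: tuple[QuestionnaireResponse, ...] | None = None,
) -> Dataset:
    """One team, one delivery unit per component, full 19-session schedule.

    Defaults to perfect delivery and full attendance; ``attend`` overrides the
    attendee list per plan id, ``canceled`` lists plan ids not held.
    """
    protocol = reference_protocol()
    members = tuple(f"P{i}" for i in range(1, n_members + 1))
    team = Team(team_id="T1", workplace_id="W1", member_ids=members)
    roster = Roster(
        participants=tuple(
            Participant(participant_id=m, team_id="T1", workplace_id="W1", step="step1")
            for m in members
        ),
        teams=(team,),
        steps=("step1",),
    )
    units = tuple(
        DeliveryUnit(unit_id=f"U_{comp}", component_id=comp, member_ids=members,
                     team_ids=("T1",) if comp == "PE" else ())
        for comp in ("PE", "PT", "CBT")
    )
    sessions, logbooks = [], []
    from impquant.protocol_model import SessionRecord

    for plan in protocol.sessions:
        sid = f"S_{plan.session_id}"
        held = plan.session_id not in canceled
        sessions.append(SessionRecord(
            session_id=sid, plan_id=plan.session_id, workplace_id="W1",
            unit_id=f"U_{plan.component_id}", step="step1", held=held, deliverer_id="D1"))
        if held:
            attendees = (attend or {}).get(plan.session_id, members)
            lb = perfect_logbook(plan, attendees).model_copy(update={"session_id": sid})
            logbooks.append(lb)

    if questionnaires is None:
        questionnaires = tuple(
            QuestionnaireResponse(
                participant_id=m,
                satisfaction_items={k: "to a very large extent" for k in (
                    "sat_pt", "sat_cbt", "sat_pe", "sat_overall", "sat_relevant", "sat_interesting")},
                support_items=("always",) * 4,
            )
            for m in members
        )
    return Dataset(protocol=protocol, roster=roster, units=units,
                   sessions=tuple(sessions), logbooks=tuple(logbooks),
                   questionnaires=questionnaires)


@pytest.fixture
def mini_dataset() -> Dataset:
    return make_mini_dataset()
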