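"""Participation, team-level PE scoring and responsiveness."""

import numpy as np
import pytest

from impquant import receipt
from impquant.implementation import score_trial
from impquant.protocol_model import QuestionnaireResponse
from impquant.scoring import score_index

from conftest import make_mini_dataset


@pytest.mark.parametrize("size, required", [(4, 2), (12, 4), (20, 6), (7, 3), (17, 5)])
def test_required_representatives(size, required):
    assert receipt.required_representatives(size) == required


def test_required_representatives_rejects_empty_team():
    with pytest.raises(ValueError):
        receipt.required_representatives(0)


class TestTeamSessionParticipation:
    def test_full_quota(self):
        assert receipt.team_session_participation(3, 3) == 1.0

    def test_partial_quota(self):
        assert receipt.team_session_participation(2, 3) == pytest.approx(2 / 3)

    def test_capped_above_quota(self):
        assert receipt.team_session_participation(5, 3) == 1.0


class TestTeamContinuity:
    def test_same_representatives_throughout(self):
        sets = [{"a", "b", "c"}] * 4
        assert receipt.team_continuity(sets, required=3) == 1.0

    def test_rotating_attendees(self):
        sets = [{"a"}, {"b"}, {"c"}, {"d"}]
        assert receipt.team_continuity(sets, required=3) == 0.0

    def test_partial_persistence(self):
        sets = [{"a", "b", "c"}, {"a", "b", "d"}, {"a", "b"}]
        assert receipt.team_continuity(sets, required=4) == 0.5

    def test_leniency_allows_missed_sessions(self):
        sets = [{"a", "b"}, {"a"}, {"a", "b"}, {"a", "b"}]
        assert receipt.team_continuity(sets, required=2) == 0.5
        assert receipt.team_continuity(sets, required=2, max_missed=1) == 1.0

    def test_no_held_sessions_is_missing(self):
        assert receipt.team_continuity([], required=3) is None

    def test_continuity_bounded_by_best_session_participation(self):
        # persistent attendees attend every session, so continuity can never
        # exceed the best per-session participation
        rng = np.random.default_rng(5)
        for _ in range(50):
            members = list("abcdefgh")
            sets = [set(rng.choice(members, size=rng.integers(0, 9), replace=False))
                    for _ in range(4)]
            req = int(rng.integers(1, 5))
            cont = receipt.team_continuity(sets, required=req)
            best = max(receipt.team_session_participation(len(s), req) for s in sets)
            assert cont <= best + 1e-12


def test_participation_weight_worked_example():
    w = receipt.participation_weight(1, 3, 27)
    assert round(w, 2) == 0.11
    assert w == pytest.approx(1 / 9)


class TestMiniTrialReceipt:
    def test_full_attendance_scores_one(self, mini_dataset):
        scores = score_trial(mini_dataset)
        assert np.allclose(scores.individuals["participation"], 1.0)
        team = scores.team_scores.iloc[0]
        assert team["participation_score"] == 1.0
        assert team["continuity_score"] == 1.0
        assert team["combined"] == 1.0

    def test_combined_is_mean_of_participation_and_continuity(self):
        # only 2 of the 3 required representatives attend; the same 2 always
        ds = make_mini_dataset(attend={
            "pe_ws1": ("P1", "P2"), "pe_ws2": ("P1", "P2"),
            "pe_ev1": ("P1", "P2"), "pe_ev2": ("P1", "P2"),
        })
        scores = score_trial(ds)
        team = scores.team_scores.iloc[0]
        assert team["required"] == 3  # team of 6
        assert team["participation_score"] == pytest.approx(2 / 3)
        assert team["continuity_score"] == pytest.approx(2 / 3)
        assert team["combined"] == pytest.approx(2 / 3)

    def test_team_score_broadcast_to_all_members(self):
        ds = make_mini_dataset(attend={
            "pe_ws1": ("P1", "P2"), "pe_ws2": ("P1", "P3"),
            "pe_ev1": ("P2", "P3"), "pe_ev2": ("P1", "P2"),
        })
        scores = score_trial(ds)
        pe_rows = scores.participant_sessions.query("receipt_mode == 'team'")
        for _, g in pe_rows.groupby("session_id"):
            assert g["presence"].nunique() == 1  # identical for every member

    def test_canceled_pe_session_contributes_zero(self):
        ds = make_mini_dataset(canceled=("pe_ws2",))
        scores = score_trial(ds)
        # 3 h of the 27 lost: everything else perfect
        assert np.allclose(scores.individuals["participation"], 24 / 27)

    def test_single_attended_session_participation(self):
        # P6 attends only the first CBT workshop (3 h of 27) and the team-mode
        # sessions are attended by nobody, so the broadcast adds nothing
        nobody: tuple = ()
        ds = make_mini_dataset(attend={
            "pe_kickoff": ("P1",), "pe_ws1": nobody, "pe_ws2": nobody,
            "pe_ev1": nobody, "pe_ev2": nobody,
            **{f"pt_{i:02d}": nobody for i in range(1, 13)},
            "cbt_1": ("P6",), "cbt_2": nobody,
        })
        scores = score_trial(ds)
        ind = scores.individuals.set_index("participant_id")
        assert ind.loc["P6", "participation"] == pytest.approx(3 / 27)

    def test_pt_hours_only(self):
        nobody: tuple = ()
        ds = make_mini_dataset(attend={
            "pe_kickoff": nobody, "pe_ws1": nobody, "pe_ws2": nobody,
            "pe_ev1": nobody, "pe_ev2": nobody,
            **{f"pt_{i:02d}": ("P1",) for i in range(1, 13)},
            "cbt_1": nobody, "cbt_2": nobody,
        })
        ind = score_trial(ds).individuals.set_index("participant_id")
        assert ind.loc["P1", "participation"] == pytest.approx(12 / 27)

    def test_participation_monotone_in_attendance(self):
        base = make_mini_dataset(attend={"cbt_1": ("P1",), "cbt_2": ()})
        more = make_mini_dataset(attend={"cbt_1": ("P1",), "cbt_2": ("P1",)})
        p_base = score_trial(base).individuals.set_index("participant_id")
        p_more = score_trial(more).individuals.set_index("participant_id")
        assert p_more.loc["P1", "participation"] >= p_base.loc["P1", "participation"]


class TestResponsiveness:
    def test_mean_of_subindexes(self):
        assert score_index([83, 93, 92]) == pytest.approx(89.33, abs=0.01)

    def test_all_top_categories_score_100(self, mini_dataset):
        scores = score_trial(mini_dataset)
        assert np.allclose(scores.individuals["responsiveness"], 100.0)

    def test_missing_subindex_uses_available_mean(self):
        assert score_index([50, None, 100]) == 75

    def test_non_responder_has_missing_r_but_participation(self, mini_dataset):
        ds = mini_dataset.model_copy(update={"questionnaires": mini_dataset.questionnaires[1:]})
        ind = score_trial(ds).individuals.set_index("participant_id")
        dropped = mini_dataset.questionnaires[0].participant_id
        assert np.isnan(ind.loc[dropped, "responsiveness"])
        assert np.isnan(ind.loc[dropped, "implementation"])
        assert ind.loc[dropped, "participation"] == 1.0
        assert ind.loc[dropped, "exposure"] > 0

    def test_support_index_shared_across_components(self, reference_scores):
        ind = reference_scores.individuals
        resp = ind[ind["responder"]]
        # component responsiveness reuses the same support index: with equal
        # satisfaction propensities the components differ only via motivation
        assert {"responsiveness_PE", "responsiveness_PT", "responsiveness_CBT"} <= set(ind.columns)
        assert resp["responsiveness_PE"].notna().any()

    def test_component_satisfaction_uses_component_item(self):
        q = QuestionnaireResponse(
            participant_id="P1",
            satisfaction_items={
                "sat_pt": "to a very small extent",  # 0
                "sat_cbt": "to a very large extent",  # 100
                "sat_pe": "to a very large extent",
                "sat_overall": "to a very large extent",
                "sat_relevant": "to a very large extent",
                "sat_interesting": "to a very large extent",
            },
        )
        from impquant.receipt import satisfaction_index
        from impquant.protocol_model import OVERALL_SATISFACTION_ITEMS

        assert satisfaction_index(q, ("sat_pt",) + OVERALL_SATISFACTION_ITEMS) == 75
        assert satisfaction_index(q, ("sat_cbt",) + OVERALL_SATISFACTION_ITEMS) == 100
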