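"""Dose, content, quality and fidelity scoring."""

import math

import numpy as np
import pytest

from impquant import delivery
from impquant.protocol_model import LogbookEntry, SessionPlan
from impquant.reporting import percent


def _plan(criteria=("c1", "c2"), has_intensity=False):
    return SessionPlan(session_id="s", component_id="PT" if has_intensity else "CBT",
                       duration=1, criteria_ids=tuple(criteria), has_intensity=has_intensity)


def _logbook(ratings, intensity=None, **kwargs):
    return LogbookEntry(session_id="x", criterion_ratings=ratings, intensity=intensity, **kwargs)


class TestContent:
    def test_mean_of_criterion_scores(self):
        lb = _logbook({"c1": "completely", "c2": "partly"})
        assert delivery.content_score(lb, _plan()) == 75

    def test_all_completely_is_100(self):
        lb = _logbook({"c1": "completely", "c2": "completely"})
        assert delivery.content_score(lb, _plan()) == 100

    def test_intensity_enters_as_one_extra_element(self):
        lb = _logbook({"c1": "completely", "c2": "completely"}, intensity=5)
        c = delivery.content_score(lb, _plan(has_intensity=True))
        assert c == pytest.approx(250 / 3)  # mean of {100, 100, 50}

    def test_empty_criterion_set_is_missing(self):
        lb = _logbook({})
        assert delivery.content_score(lb, _plan(criteria=())) is None


class TestQuality:
    def test_mean_of_three_subscores(self):
        lb = LogbookEntry(
            session_id="x",
            understanding_items=("to a large extent",) * 3 + ("somewhat",),  # 87.5
            contribution_items=("to a large extent",) * 4,  # 100
            self_rated_performance=6,  # 50
        )
        q = delivery.quality_score(lb)
        assert q.understanding == 87.5
        assert q.contribution == 100
        assert q.performance == 50
        assert q.quality == pytest.approx((87.5 + 100 + 50) / 3)

    def test_subscore_aggregation_92_92_80(self):
        # quality is the plain mean of its three sub-scores
        from impquant.scoring import score_index

        assert score_index([92, 92, 80]) == pytest.approx(88)
        assert score_index([100, 100, 50]) == pytest.approx(83.33, abs=0.01)

    def test_all_missing_quality_is_missing(self):
        lb = LogbookEntry(session_id="x")
        assert delivery.quality_score(lb).quality is None


class TestFidelity:
    def test_worked_example_fractions(self):
        assert delivery.session_fidelity(0.5, 0.8) == pytest.approx(0.65)

    @pytest.mark.parametrize("c, q", [(1, 1), (0, 0), (30, 90), (100, 40)])
    def test_fidelity_between_content_and_quality(self, c, q):
        f = delivery.session_fidelity(c, q)
        assert min(c, q) <= f <= max(c, q)

    def test_missing_part_gives_missing_fidelity(self):
        assert delivery.session_fidelity(None, 80) is None


class TestDose:
    def test_worked_example(self):
        assert delivery.dose(700, 800) == 0.875

    def test_total_intervention_dose(self):
        d = delivery.dose(713, 753)
        assert math.isclose(d, 713 / 753)
        assert percent(d) == 95

    def test_nothing_delivered(self):
        assert delivery.dose(0, 10) == 0

    def test_errors(self):
        with pytest.raises(delivery.DoseError):
            delivery.dose(1, 0)
        with pytest.raises(delivery.DoseError):
            delivery.dose(5, 4)


def test_fidelity_of_intended_is_product():
    assert delivery.fidelity_of_intended(0.91, 713 / 753) == pytest.approx(0.8617, abs=5e-4)
    assert delivery.fidelity_of_intended(1, 1) == 1
    assert delivery.fidelity_of_intended(0.9, 0.5) == pytest.approx(0.45)


def test_organizational_implementation_worked_example():
    assert delivery.organizational_implementation(0.875, 0.65) == 0.7625
    assert delivery.organizational_implementation(1, 1) == 1
    assert delivery.organizational_implementation(0, 0) == 0


class TestSummarize:
    def test_single_session_stratum(self, reference_scores):
        sessions = reference_scores.session_scores
        one = sessions[sessions["held"]].iloc[[0]]
        row = delivery.summarize_delivery(one, by="organization").iloc[-1]
        assert row["n_intended"] == 1 and row["n_held"] == 1
        assert row["fidelity_mean"] == pytest.approx(one["fidelity"].iloc[0])
        assert row["fidelity_sd"] == 0.0

    def test_two_session_mean_and_sample_sd(self, reference_scores):
        sessions = reference_scores.session_scores.copy()
        two = sessions[sessions["held"]].iloc[:2].copy()
        two["fidelity"] = [80.0, 100.0]
        row = delivery.summarize_delivery(two, by="organization").iloc[-1]
        assert row["fidelity_mean"] == pytest.approx(90)
        assert row["fidelity_sd"] == pytest.approx(np.std([80, 100], ddof=1))
        assert row["fidelity_sd"] == pytest.approx(14.1421, abs=1e-4)

    def test_mean_preserved_when_adding_average_session(self, reference_scores):
        sessions = reference_scores.session_scores
        held = sessions[sessions["held"]].copy()
        before = delivery.summarize_delivery(held, by="organization").iloc[-1]
        clone = held.iloc[[0]].copy()
        for col in ("content", "understanding", "contribution", "performance",
                    "quality", "fidelity"):
            clone[col] = before[f"{col}_mean"]
        import pandas as pd

        grown = pd.concat([held, clone], ignore_index=True)
        after = delivery.summarize_delivery(grown, by="organization").iloc[-1]
        assert after["fidelity_mean"] == pytest.approx(before["fidelity_mean"])

    def test_fidelity_of_intended_equals_fidelity_at_full_dose(self, reference_scores):
        held = reference_scores.session_scores[reference_scores.session_scores["held"]]
        row = delivery.summarize_delivery(held, by="organization").iloc[-1]
        assert row["dose"] == 1
        assert row["fidelity_of_intended"] == pytest.approx(row["fidelity_mean"])
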