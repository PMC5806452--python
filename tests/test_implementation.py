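"""Exposure/implementation chain, totals and stratified summaries."""

import numpy as np
import pandas as pd
import pytest

from impquant import implementation as impl
from impquant.implementation import score_trial, stratified_summary
from impquant.receipt import participation_weight
from impquant.synthetic_data import SimulationConfig, generate_trial

from conftest import SMALL_CONFIG, make_mini_dataset


class TestSessionChain:
    def test_worked_example_chain(self):
        p = participation_weight(1, 3, 27)
        e = impl.session_exposure(0.65, p)
        assert round(e, 3) == 0.072
        i = impl.session_implementation(0.072, 0.8)
        assert i == pytest.approx(0.0576)

    def test_full_fidelity_identity(self):
        assert impl.session_exposure(1.0, 0.25) == 0.25

    def test_zero_presence_propagates(self):
        assert impl.session_exposure(0.9, 0.0) == 0.0
        assert impl.session_implementation(0.0, 0.8) == 0.0

    def test_missing_responsiveness_gives_missing_implementation(self):
        assert impl.session_implementation(0.072, None) is None
        assert impl.session_implementation(0.072, 1.0) == pytest.approx(0.072)


class TestIndividualTotals:
    def test_perfect_trial_scores_one(self, mini_dataset):
        ind = score_trial(mini_dataset).individuals
        assert np.allclose(ind["exposure"], 1.0)
        assert np.allclose(ind["implementation"], 1.0)

    def test_single_session_totals(self):
        nobody: tuple = ()
        ds = make_mini_dataset(attend={
            **{p.session_id: nobody for p in make_mini_dataset().protocol.sessions},
            "cbt_1": ("P1",),
        })
        ind = score_trial(ds).individuals.set_index("participant_id")
        # perfect fidelity and responsiveness: E_all = P = 3/27, I_all = E_all
        assert ind.loc["P1", "exposure"] == pytest.approx(3 / 27)
        assert ind.loc["P1", "implementation"] == pytest.approx(3 / 27)

    def test_chain_inequality_everywhere(self, reference_scores):
        ind = reference_scores.individuals
        assert (ind["exposure"] <= ind["participation"] + 1e-9).all()
        resp = ind.dropna(subset=["implementation"])
        assert (resp["implementation"] <= resp["exposure"] + 1e-9).all()
        assert ind["participation"].between(0, 1).all()

    def test_zero_propagation(self):
        # nobody attends anything: exposure and implementation are exactly 0
        nobody: tuple = ()
        ds = make_mini_dataset(attend={
            p.session_id: nobody for p in make_mini_dataset().protocol.sessions
        })
        ind = score_trial(ds).individuals
        assert (ind["participation"] == 0).all()
        assert (ind["exposure"] == 0).all()
        assert (ind["implementation"] == 0).all()

    def test_factorization_under_constant_fidelity(self):
        # content = quality = 0.5 makes every rating the middle category, so
        # session fidelity is exactly 50 and E_all = 0.5 × participation
        behavior = {
            comp: b.model_copy(update={"content": 0.5, "quality": 0.5})
            for comp, b in SMALL_CONFIG.behavior.items()
        }
        cfg = SMALL_CONFIG.model_copy(update={"behavior": behavior})
        ds, _ = generate_trial(cfg, seed=3)
        ind = score_trial(ds).individuals
        assert np.allclose(ind["exposure"], 0.5 * ind["participation"], atol=1e-12)

    def test_monotone_in_responsiveness(self, reference_scores):
        ind = reference_scores.individuals.dropna(subset=["implementation"])
        # I = E × R/100 exactly, hence increasing R never decreases I
        assert np.allclose(ind["implementation"],
                           ind["exposure"] * ind["responsiveness"] / 100)


class TestStratifiedSummary:
    def test_uniform_scores_reproduced(self, mini_dataset):
        ind = score_trial(mini_dataset).individuals
        total = stratified_summary(ind, by="total")
        means = total.set_index("measure")["mean"]
        assert means["participation"] == pytest.approx(100)
        assert means["implementation"] == pytest.approx(100)
        assert means["fidelity"] == pytest.approx(100)

    def test_two_strata_means(self):
        ind = pd.DataFrame({
            "participation": [0.4, 0.6, 0.8],
            "fidelity": [90.0, 90.0, 90.0],
            "exposure": [0.4, 0.6, 0.8],
            "responsiveness": [80.0, 80.0, 80.0],
            "implementation": [0.32, 0.48, 0.64],
            "step": ["s1", "s1", "s2"],
        })
        out = stratified_summary(ind, by="step")
        part = out[out["measure"] == "participation"].set_index("stratum")
        assert part.loc["s1", "mean"] == pytest.approx(50)
        assert part.loc["s2", "mean"] == pytest.approx(80)
        assert part.loc["s1", "n"] == 2

    def test_n_counts_non_missing_only(self, reference_scores):
        ind = reference_scores.individuals
        out = stratified_summary(ind, by="total").set_index("measure")
        assert out.loc["implementation", "n"] == ind["implementation"].notna().sum()
        assert out.loc["participation", "n"] == len(ind)

    def test_component_strata_use_component_scores(self, reference_scores):
        out = reference_scores.summary(by="component")
        comps = set(out["stratum"])
        assert comps == {"PE", "PT", "CBT"}
        part = out[out["measure"] == "participation"].set_index("stratum")["mean"]
        # PT is weekly short sessions with the lowest attendance propensity
        assert part["PT"] < part["PE"]

    def test_empty_stratum_rejected_gracefully(self):
        with pytest.raises(ValueError):
            stratified_summary(pd.DataFrame({"participation": []}), by="nonsense")


class TestOrgVsIndividual:
    def test_exact_coincidence_under_full_attendance(self, mini_dataset):
        report = impl.org_vs_individual_consistency(score_trial(mini_dataset))
        assert report["dose"] == 1
        assert report["absolute_difference"] == pytest.approx(0, abs=1e-12)

    def test_random_scenario_reports_finite_difference(self, reference_scores):
        report = impl.org_vs_individual_consistency(reference_scores)
        assert 0 <= report["organizational_implementation"] <= 1
        assert np.isfinite(report["absolute_difference"])
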