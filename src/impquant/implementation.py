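"""Exposure and implementation scores at session, individual and population level.

The chain, per participant and planned session:

* ``P^s`` — presence × session duration / total protocol hours;
* ``E^s = F^s × P^s`` — the fidelity the participant was actually exposed to
  (``F^s`` as a fraction);
* ``I^s = E^s × R`` — exposure discounted by the participant's responsiveness.

Totals sum over the planned sessions: ``E_all = Σ E^s``, ``I_all = Σ I^s``,
participation ``= Σ P^s``; all lie in [0, 1] and obey
``I_all ≤ E_all ≤ participation``. If any factor (fidelity, presence,
exposure or responsiveness) is 0, the corresponding implementation is 0. A
canceled session has presence 0, hence contributes 0. Responsiveness is
measured once, at the end of the intervention, and is applied as a constant
per participant; implementation is therefore computed only for questionnaire
responders, while participation and exposure are computed for everyone.

Component-level scores recompute the sums restricted to the component's
sessions, with the component's planned hours as the denominator, and use the
component-specific responsiveness.

Internally ratio-type quantities (participation, exposure, implementation)
are fractions; :func:`stratified_summary` reports them on 0–100 alongside the
0–100 fidelity and responsiveness scores, mirroring how such summaries are
conventionally tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import delivery, receipt
from .protocol_model import Dataset

__all__ = [
    "TrialScores",
    "session_exposure",
    "session_implementation",
    "score_trial",
    "individual_totals",
    "stratified_summary",
    "org_vs_individual_consistency",
]


def session_exposure(fidelity: float, participation: float) -> float:
    """Session exposure E^s = F^s × P^s (both fractions)."""
    return fidelity * participation


def session_implementation(exposure: float, responsiveness: Optional[float]) -> Optional[float]:
    """Session implementation I^s = E^s × R; missing if R is missing."""
    if responsiveness is None:
        return None
    return exposure * responsiveness


@dataclass
class TrialScores:
    """All derived tables for one scored trial."""

    dataset: Dataset
    session_scores: pd.DataFrame  # one row per scheduled session (delivery side)
    team_scores: pd.DataFrame  # team-mode participation/continuity/combined
    participant_sessions: pd.DataFrame  # one row per (participant, session)
    individuals: pd.DataFrame  # one row per participant

    def delivery_summary(self, by: str = "component") -> pd.DataFrame:
        return delivery.summarize_delivery(self.session_scores, by=by)

    def summary(self, by: str = "total") -> pd.DataFrame:
        return stratified_summary(self.individuals, by=by)


def score_trial(
    dataset: Dataset,
    missing_logbook: delivery.MissingLogbookPolicy = "as_missing",
    max_missed: int = 0,
) -> TrialScores:
    """Run the full scoring pipeline on a validated dataset.

    ``missing_logbook`` controls how held-but-unlogged sessions enter the
    fidelity means; ``max_missed`` is the continuity leniency (sessions a
    representative may miss while still counting as continuous).
    """
    sessions = delivery.score_sessions(dataset, missing_logbook=missing_logbook)
    teams = receipt.team_pe_scores(dataset, max_missed=max_missed)
    presence = receipt.presence_table(dataset, teams)
    responsiveness = receipt.responsiveness_table(dataset, presence, sessions)

    total_hours = dataset.protocol.total_hours
    ps = presence.merge(
        sessions[["session_id", "fidelity"]], on="session_id", how="left"
    )
    ps["p_s"] = ps["presence"] * ps["duration"] / total_hours
    ps["f_s"] = ps["fidelity"] / 100.0
    # a session with unknown fidelity cannot contribute exposure
    ps["e_s"] = (ps["f_s"] * ps["p_s"]).fillna(0.0)
    r_map = responsiveness.set_index("participant_id")["responsiveness"] / 100.0
    ps["r"] = ps["participant_id"].map(r_map)
    ps["i_s"] = ps["e_s"] * ps["r"]

    individuals = individual_totals(dataset, ps, responsiveness)
    return TrialScores(dataset, sessions, teams, ps, individuals)


def individual_totals(
    dataset: Dataset,
    participant_sessions: pd.DataFrame,
    responsiveness: pd.DataFrame,
) -> pd.DataFrame:
    """Per-participant totals: participation, fidelity, E_all, R, I_all.

    Overall and per-component columns; fractions for participation/exposure/
    implementation, 0–100 for fidelity and responsiveness. Individual fidelity
    is the duration-weighted mean of session fidelity over the participant's
    planned held (scored) sessions.
    """
    ps = participant_sessions
    total_hours = dataset.protocol.total_hours
    components = [c.id for c in dataset.protocol.components]

    def totals(g: pd.DataFrame, hours: float) -> pd.Series:
        held = g[g["held"] & g["fidelity"].notna()]
        fid = (
            float(np.average(held["fidelity"], weights=held["duration"]))
            if len(held)
            else np.nan
        )
        return pd.Series({
            "participation": g["p_s"].sum() * total_hours / hours,
            "fidelity": fid,
            "exposure": g["e_s"].sum() * total_hours / hours,
            "implementation": g["i_s"].sum() * total_hours / hours,
        })

    overall = ps.groupby("participant_id").apply(totals, hours=total_hours, include_groups=False)

    comp_frames = []
    for comp in components:
        hours = dataset.protocol.component_hours(comp)
        g = ps[ps["component"] == comp]
        t = g.groupby("participant_id").apply(totals, hours=hours, include_groups=False)
        # component implementation pairs component exposure with component R
        comp_frames.append(t.add_suffix(f"_{comp}"))

    roster = pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "team_id": p.team_id,
                "workplace": p.workplace_id,
                "step": p.step,
            }
            for p in dataset.roster.participants
        ]
    ).set_index("participant_id")

    resp = responsiveness.set_index("participant_id")
    out = roster.join([overall] + comp_frames).join(resp)

    # a participant scheduled for nothing has zero participation and exposure
    zero_cols = [c for c in out.columns if c.split("_")[0] in ("participation", "exposure")]
    out[zero_cols] = out[zero_cols].fillna(0.0)

    # implementation uses component-specific responsiveness at component level
    for comp in components:
        out[f"implementation_{comp}"] = (
            out[f"exposure_{comp}"] * out[f"responsiveness_{comp}"] / 100.0
        )
    out["implementation"] = out["exposure"] * out["responsiveness"] / 100.0
    out["responder"] = out.index.isin({q.participant_id for q in dataset.questionnaires})
    return out.reset_index()


#: measures reported by stratified_summary, with their individual-table column
#: and the factor that puts them on the 0–100 reporting scale.
_MEASURES = (
    ("fidelity", 1.0),
    ("exposure", 100.0),
    ("participation", 100.0),
    ("responsiveness", 1.0),
    ("implementation", 100.0),
)


def stratified_summary(individuals: pd.DataFrame, by: str = "total") -> pd.DataFrame:
    """n / mean / SD of each measure per stratum, on the 0–100 scale.

    ``by`` is ``total``, ``step``, ``workplace`` or ``component``. n counts the
    non-missing contributing participants; SD is the sample SD (n−1). For
    ``component`` the component-restricted scores are reported.
    """
    rows = []

    def emit(stratum_kind: str, stratum: str, g: pd.DataFrame, suffix: str = "") -> None:
        for measure, scale in _MEASURES:
            vals = g[f"{measure}{suffix}"].dropna() * scale
            rows.append({
                "level": "individual",
                "stratum_kind": stratum_kind,
                "stratum": stratum,
                "measure": measure,
                "n": int(len(vals)),
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else (0.0 if len(vals) == 1 else np.nan),
            })

    if by == "total":
        emit("total", "all", individuals)
    elif by in ("step", "workplace"):
        for label, g in individuals.groupby(by, sort=True):
            emit(by, str(label), g)
    elif by == "component":
        comps = sorted(
            c.rsplit("_", 1)[1] for c in individuals.columns if c.startswith("participation_")
        )
        for comp in comps:
            emit("component", comp, individuals, suffix=f"_{comp}")
    else:
        raise ValueError(f"cannot stratify by {by!r}")
    return pd.DataFrame(rows)


def org_vs_individual_consistency(scores: TrialScores) -> Dict[str, float]:
    """Compare organizational-level implementation with the mean individual score.

    The organizational score is the mean of dose and held-session fidelity;
    the individual side is the mean total implementation over responders. The
    two coincide exactly only under full attendance and responsiveness; the
    report states both and their absolute difference without asserting
    closeness.
    """
    sessions = scores.session_scores
    d = delivery.dose(int(sessions["held"].sum()), len(sessions))
    f = sessions.loc[sessions["held"], "fidelity"].dropna().mean() / 100.0
    org = delivery.organizational_implementation(d, f)
    ind = scores.individuals["implementation"].dropna().mean()
    ind = float(ind) if not pd.isna(ind) else np.nan
    return {
        "dose": d,
        "fidelity_held": f,
        "organizational_implementation": org,
        "mean_individual_implementation": ind,
        "absolute_difference": abs(org - ind),
    }
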