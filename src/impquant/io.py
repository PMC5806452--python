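"""Tabular readers and writers.

A dataset on disk is a directory of plain-text files:

* ``protocol.yaml`` — the protocol specification;
* ``participants.csv`` — participant_id, team_id, workplace_id, step;
* ``teams.csv`` — team_id, workplace_id (membership derives from participants);
* ``units.csv`` — unit_id, component_id, team_ids (``;``-joined, may be empty);
* ``unit_members.csv`` — unit_id, participant_id (long);
* ``sessions.csv`` — session_id, plan_id, workplace_id, unit_id, step, held,
  deliverer_id;
* ``logbooks.csv`` — one row per held session: session_id, ``crit_<id>``
  columns for every protocol criterion, understanding_1..4, contribution_1..4,
  performance, intensity, motivation;
* ``attendance.csv`` — session_id, participant_id (long);
* ``questionnaires.csv`` — participant_id, the six satisfaction items,
  support_1..4.

Dialect: UTF-8, comma-separated, header row required, ``NA`` for missing.
Writing then re-reading a dataset yields identical records.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .protocol_model import (
    SATISFACTION_ITEMS,
    SUPPORT_ITEM_COUNT,
    Dataset,
    DeliveryUnit,
    LogbookEntry,
    Participant,
    ProtocolSpec,
    QuestionnaireResponse,
    Roster,
    SessionRecord,
    Team,
)

__all__ = [
    "write_protocol",
    "read_protocol",
    "write_dataset",
    "read_dataset",
    "read_simulation_config",
    "write_scores",
    "packaged_protocol_path",
    "packaged_sim_config_path",
]

NA = "NA"
PathLike = Union[str, Path]


def packaged_protocol_path() -> Path:
    """Path of the packaged 19-session / 27-hour reference protocol."""
    return Path(__file__).parent / "data" / "reference_protocol.yaml"


def packaged_sim_config_path() -> Path:
    """Path of the packaged reference-trial simulation configuration."""
    return Path(__file__).parent / "data" / "reference_trial.yaml"


# --- protocol ---------------------------------------------------------------

def write_protocol(protocol: ProtocolSpec, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(protocol.model_dump(mode="json"), fh, sort_keys=False)


def read_protocol(path: PathLike) -> ProtocolSpec:
    with open(path, encoding="utf-8") as fh:
        return ProtocolSpec.model_validate(yaml.safe_load(fh))


def read_simulation_config(path: PathLike):
    from .synthetic_data import SimulationConfig

    with open(path, encoding="utf-8") as fh:
        return SimulationConfig.model_validate(yaml.safe_load(fh) or {})


# --- dataset ----------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, na_rep=NA)


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, na_values=[NA, ""], dtype=str)


def write_dataset(dataset: Dataset, outdir: PathLike) -> Path:
    """Write every table of a dataset into ``outdir`` (created if needed)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_protocol(dataset.protocol, out / "protocol.yaml")

    _write_csv(pd.DataFrame(
        [{"participant_id": p.participant_id, "team_id": p.team_id,
          "workplace_id": p.workplace_id, "step": p.step}
         for p in dataset.roster.participants]), out / "participants.csv")
    _write_csv(pd.DataFrame(
        [{"team_id": t.team_id, "workplace_id": t.workplace_id} for t in dataset.roster.teams]),
        out / "teams.csv")
    _write_csv(pd.DataFrame(
        [{"unit_id": u.unit_id, "component_id": u.component_id,
          "team_ids": ";".join(u.team_ids)} for u in dataset.units]), out / "units.csv")
    _write_csv(pd.DataFrame(
        [{"unit_id": u.unit_id, "participant_id": m}
         for u in dataset.units for m in u.member_ids]), out / "unit_members.csv")
    _write_csv(pd.DataFrame(
        [{"session_id": s.session_id, "plan_id": s.plan_id, "workplace_id": s.workplace_id,
          "unit_id": s.unit_id, "step": s.step, "held": "true" if s.held else "false",
          "deliverer_id": s.deliverer_id} for s in dataset.sessions]), out / "sessions.csv")

    crit_ids = [cid for plan in dataset.protocol.sessions for cid in plan.criteria_ids]
    lb_rows = []
    att_rows = []
    for lb in dataset.logbooks:
        row = {"session_id": lb.session_id}
        for cid in crit_ids:
            row[f"crit_{cid}"] = lb.criterion_ratings.get(cid)
        for i, r in enumerate(lb.understanding_items, 1):
            row[f"understanding_{i}"] = r
        for i, r in enumerate(lb.contribution_items, 1):
            row[f"contribution_{i}"] = r
        row["performance"] = lb.self_rated_performance
        row["intensity"] = lb.intensity
        row["motivation"] = lb.motivation_rating
        lb_rows.append(row)
        att_rows += [{"session_id": lb.session_id, "participant_id": m} for m in lb.attendee_ids]
    lb_cols = (["session_id"] + [f"crit_{c}" for c in crit_ids]
               + [f"understanding_{i}" for i in range(1, 5)]
               + [f"contribution_{i}" for i in range(1, 5)]
               + ["performance", "intensity", "motivation"])
    _write_csv(pd.DataFrame(lb_rows, columns=lb_cols), out / "logbooks.csv")
    _write_csv(pd.DataFrame(att_rows, columns=["session_id", "participant_id"]),
               out / "attendance.csv")

    q_rows = []
    for q in dataset.questionnaires:
        row = {"participant_id": q.participant_id}
        for k in SATISFACTION_ITEMS:
            row[k] = q.satisfaction_items.get(k)
        for i, r in enumerate(q.support_items, 1):
            row[f"support_{i}"] = r
        q_rows.append(row)
    _write_csv(pd.DataFrame(q_rows, columns=["participant_id", *SATISFACTION_ITEMS,
                                             *(f"support_{i}" for i in range(1, SUPPORT_ITEM_COUNT + 1))]),
               out / "questionnaires.csv")
    return out


def _opt_int(v) -> Optional[int]:
    return None if pd.isna(v) else int(float(v))


def _opt_str(v) -> Optional[str]:
    return None if pd.isna(v) else str(v)


def read_dataset(indir: PathLike) -> Dataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    d = Path(indir)
    protocol = read_protocol(d / "protocol.yaml")

    pdf = _read_csv(d / "participants.csv")
    participants = tuple(
        Participant(participant_id=r.participant_id, team_id=r.team_id,
                    workplace_id=r.workplace_id, step=r.step)
        for r in pdf.itertuples()
    )
    members: dict[str, list[str]] = {}
    for r in pdf.itertuples():
        members.setdefault(r.team_id, []).append(r.participant_id)
    tdf = _read_csv(d / "teams.csv")
    teams = tuple(
        Team(team_id=r.team_id, workplace_id=r.workplace_id,
             member_ids=tuple(members.get(r.team_id, ())))
        for r in tdf.itertuples()
    )
    steps = tuple(dict.fromkeys(pdf["step"]))
    roster = Roster(participants=participants, teams=teams, steps=steps)

    udf = _read_csv(d / "units.csv")
    umdf = _read_csv(d / "unit_members.csv")
    unit_members: dict[str, list[str]] = {}
    for r in umdf.itertuples():
        unit_members.setdefault(r.unit_id, []).append(r.participant_id)
    units = tuple(
        DeliveryUnit(unit_id=r.unit_id, component_id=r.component_id,
                     member_ids=tuple(unit_members.get(r.unit_id, ())),
                     team_ids=tuple(t for t in str(r.team_ids).split(";") if t and not pd.isna(r.team_ids)))
        for r in udf.itertuples()
    )

    sdf = _read_csv(d / "sessions.csv")
    sessions = tuple(
        SessionRecord(session_id=r.session_id, plan_id=r.plan_id, workplace_id=r.workplace_id,
                      unit_id=r.unit_id, step=r.step, held=str(r.held).lower() == "true",
                      deliverer_id="" if pd.isna(r.deliverer_id) else r.deliverer_id)
        for r in sdf.itertuples()
    )

    att = _read_csv(d / "attendance.csv")
    attendance: dict[str, list[str]] = {}
    for r in att.itertuples():
        attendance.setdefault(r.session_id, []).append(r.participant_id)

    plan_by_session = {s.session_id: s.plan_id for s in sessions}
    plans = {p.session_id: p for p in protocol.sessions}
    ldf = _read_csv(d / "logbooks.csv")
    logbooks = []
    for _, row in ldf.iterrows():
        sid = row["session_id"]
        plan = plans.get(plan_by_session.get(sid, ""), None)
        crit_ids = plan.criteria_ids if plan else ()
        ratings = {cid: _opt_str(row.get(f"crit_{cid}")) for cid in crit_ids
                   if f"crit_{cid}" in row and not pd.isna(row.get(f"crit_{cid}"))}
        logbooks.append(LogbookEntry(
            session_id=sid,
            criterion_ratings=ratings,
            understanding_items=tuple(_opt_str(row.get(f"understanding_{i}")) for i in range(1, 5)),
            contribution_items=tuple(_opt_str(row.get(f"contribution_{i}")) for i in range(1, 5)),
            self_rated_performance=_opt_int(row.get("performance")),
            intensity=_opt_int(row.get("intensity")),
            motivation_rating=_opt_str(row.get("motivation")),
            attendee_ids=tuple(attendance.get(sid, ())),
        ))

    qdf = _read_csv(d / "questionnaires.csv")
    questionnaires = tuple(
        QuestionnaireResponse(
            participant_id=row["participant_id"],
            satisfaction_items={k: _opt_str(row.get(k)) for k in SATISFACTION_ITEMS},
            support_items=tuple(_opt_str(row.get(f"support_{i}"))
                                for i in range(1, SUPPORT_ITEM_COUNT + 1)),
        )
        for _, row in qdf.iterrows()
    )

    return Dataset(protocol=protocol, roster=roster, units=units,
                   sessions=tuple(sessions), logbooks=tuple(logbooks),
                   questionnaires=questionnaires)


# --- score outputs ------------------------------------------------------------

def write_scores(scores, outdir: PathLike, run_info: Optional[dict] = None) -> Path:
    """Write all derived tables of a scored trial to ``outdir``.

    Produces ``delivery_summary.csv`` (all scopes stacked), ``receipt_team.csv``,
    ``receipt_individual.csv``, ``individual_scores.csv``,
    ``summary_by_{total,component,step,workplace}.csv`` and ``run.json``.
    """
    from . import __version__

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    delivery_all = pd.concat(
        [scores.delivery_summary(by=b) for b in ("component", "workplace", "step")],
        ignore_index=True,
    )
    _write_csv(delivery_all, out / "delivery_summary.csv")
    _write_csv(scores.team_scores, out / "receipt_team.csv")

    ind = scores.individuals
    receipt_cols = ["participant_id", "participation", "satisfaction", "support",
                    "motivation", "responsiveness"]
    receipt_cols += [c for c in ind.columns
                     if c.split("_")[0] in ("participation", "satisfaction", "motivation", "responsiveness")
                     and "_" in c]
    _write_csv(ind[receipt_cols], out / "receipt_individual.csv")
    _write_csv(ind, out / "individual_scores.csv")

    for by in ("total", "component", "step", "workplace"):
        _write_csv(scores.summary(by=by), out / f"summary_by_{by}.csv")

    info = {
        "impquant_version": __version__,
        "n_participants": int(len(ind)),
        "n_sessions_intended": int(len(scores.session_scores)),
        "n_sessions_held": int(scores.session_scores["held"].sum()),
        "n_responders": int(ind["responder"].sum()),
    }
    info.update(run_info or {})
    (out / "run.json").write_text(json.dumps(info, indent=2, sort_keys=True))
    return out
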