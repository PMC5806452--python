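"""Delivery-side scoring: dose, content, quality and fidelity.

Delivery is how faithfully the organization and its deliverers executed the
protocol, independent of who attended:

* dose ``D = D_d / D_i`` — fraction of intended sessions actually held;
* content ``C`` — mean score of the session's pre-specified success criteria
  (for physical-training sessions the scored intensity enters the mean as one
  additional element);
* quality ``Q`` — mean of the understanding index, the contribution index and
  the scored self-rated performance;
* session fidelity ``F = (C + Q) / 2``;
* fidelity of intended sessions = fidelity of held sessions × dose;
* organizational implementation = ``(D + F) / 2``.

Content, quality and fidelity are on 0–100; dose is a fraction in [0, 1].
Held sessions with no logbook contribute to dose but are missing for the
fidelity means by default (absence of measurement is not zero fidelity); pass
``missing_logbook="as_zero"`` to score them 0 instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .protocol_model import Dataset, LogbookEntry, SessionPlan
from .scoring import (
    score_criterion4,
    score_index,
    score_intensity10,
    score_likert5,
    score_performance10,
)

__all__ = [
    "QualityScores",
    "DoseError",
    "content_score",
    "quality_score",
    "session_fidelity",
    "dose",
    "fidelity_of_intended",
    "organizational_implementation",
    "score_sessions",
    "summarize_delivery",
]


class DoseError(ValueError):
    """Dose undefined or inconsistent (intended = 0 or delivered > intended)."""


@dataclass(frozen=True)
class QualityScores:
    """Quality Q with its three sub-scores, each on 0–100 (None = missing)."""

    understanding: Optional[float]
    contribution: Optional[float]
    performance: Optional[float]
    quality: Optional[float]


def content_score(logbook: LogbookEntry, plan: SessionPlan) -> Optional[float]:
    """Content C: mean of the scored success-criterion ratings, on 0–100.

    For sessions with an intensity target the scored intensity is averaged in
    as one additional element with the same weight as each criterion. Missing
    ratings are left out; a session with nothing rated has missing content.
    """
    items = [
        score_criterion4(rating)
        for cid in plan.criteria_ids
        if (rating := logbook.criterion_ratings.get(cid)) is not None
    ]
    if plan.has_intensity and logbook.intensity is not None:
        items.append(score_intensity10(logbook.intensity))
    return score_index(items)


def quality_score(logbook: LogbookEntry) -> QualityScores:
    """Quality Q: mean of understanding index, contribution index and performance."""
    understanding = score_index(
        [score_likert5(r) for r in logbook.understanding_items if r is not None]
    )
    contribution = score_index(
        [score_likert5(r) for r in logbook.contribution_items if r is not None]
    )
    performance = (
        float(score_performance10(logbook.self_rated_performance))
        if logbook.self_rated_performance is not None
        else None
    )
    quality = score_index([understanding, contribution, performance])
    return QualityScores(understanding, contribution, performance, quality)


def session_fidelity(content: Optional[float], quality: Optional[float]) -> Optional[float]:
    """Session fidelity F = (C + Q) / 2; missing if either part is missing.

    Scale-agnostic: returns the mean on whatever (consistent) scale the inputs
    use, so it serves both the 0–100 pipeline and fraction-scale examples.
    """
    if content is None or quality is None:
        return None
    return (content + quality) / 2


def dose(delivered: int, intended: int) -> float:
    """Dose D = delivered / intended, as an exact fraction in [0, 1]."""
    if intended <= 0:
        raise DoseError(f"dose undefined: intended session count must be > 0, got {intended}")
    if delivered < 0 or delivered > intended:
        raise DoseError(
            f"inconsistent counts: delivered={delivered} must be in [0, intended={intended}]"
        )
    return delivered / intended


def fidelity_of_intended(fidelity_held: float, dose_fraction: float) -> float:
    """Fidelity of the intended protocol: fidelity of held sessions × dose."""
    return fidelity_held * dose_fraction


def organizational_implementation(dose_fraction: float, fidelity: float) -> float:
    """Organizational-level implementation: mean of dose and fidelity (fractions)."""
    return (dose_fraction + fidelity) / 2


MissingLogbookPolicy = Literal["as_missing", "as_zero"]


def score_sessions(
    dataset: Dataset, missing_logbook: MissingLogbookPolicy = "as_missing"
) -> pd.DataFrame:
    """Score every scheduled session instance.

    Returns one row per session with identifiers (plan, component, unit,
    workplace, step, deliverer), the held flag, duration and the delivery
    scores ``content``, ``understanding``, ``contribution``, ``performance``,
    ``quality``, ``fidelity`` plus the scored group ``motivation`` (all 0–100,
    NaN where missing).
    """
    logbooks = {lb.session_id: lb for lb in dataset.logbooks}
    rows = []
    for rec in dataset.sessions:
        plan = dataset.protocol.plan(rec.plan_id)
        row = {
            "session_id": rec.session_id,
            "plan_id": rec.plan_id,
            "component": plan.component_id,
            "unit_id": rec.unit_id,
            "workplace": rec.workplace_id,
            "step": rec.step,
            "deliverer": rec.deliverer_id,
            "held": rec.held,
            "receipt_mode": plan.receipt_mode,
            "duration": plan.duration,
            "content": np.nan,
            "understanding": np.nan,
            "contribution": np.nan,
            "performance": np.nan,
            "quality": np.nan,
            "fidelity": np.nan,
            "motivation": np.nan,
        }
        lb = logbooks.get(rec.session_id) if rec.held else None
        if lb is not None:
            c = content_score(lb, plan)
            q = quality_score(lb)
            f = session_fidelity(c, q.quality)
            mot = float(score_likert5(lb.motivation_rating)) if lb.motivation_rating else None
            row.update(
                content=_nan(c),
                understanding=_nan(q.understanding),
                contribution=_nan(q.contribution),
                performance=_nan(q.performance),
                quality=_nan(q.quality),
                fidelity=_nan(f),
                motivation=_nan(mot),
            )
        elif rec.held and missing_logbook == "as_zero":
            for col in ("content", "understanding", "contribution", "performance",
                        "quality", "fidelity"):
                row[col] = 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def _nan(x: Optional[float]) -> float:
    return np.nan if x is None else float(x)


_SCORE_COLS = ["content", "understanding", "contribution", "performance", "quality", "fidelity"]


def summarize_delivery(session_scores: pd.DataFrame, by: str = "component") -> pd.DataFrame:
    """Delivery summary per stratum: counts, dose, score means/SDs.

    ``by`` is one of ``component``, ``workplace``, ``step``, ``organization``.
    Means and sample SDs (n−1) are over held sessions; ``fidelity_of_intended``
    is the held-session fidelity times the dose. A row for the whole
    organization (stratum ``all``) is always appended.
    """
    if by not in ("component", "workplace", "step", "organization"):
        raise ValueError(f"cannot group delivery by {by!r}")

    def one(label: str, g: pd.DataFrame) -> dict:
        intended = len(g)
        held = int(g["held"].sum())
        d = dose(held, intended) if intended else np.nan
        out = {"stratum": label, "n_intended": intended, "n_held": held, "dose": d}
        hg = g[g["held"]]
        for col in _SCORE_COLS:
            vals = hg[col].dropna()
            out[f"{col}_mean"] = vals.mean() if len(vals) else np.nan
            out[f"{col}_sd"] = vals.std(ddof=1) if len(vals) > 1 else (0.0 if len(vals) == 1 else np.nan)
        f = out["fidelity_mean"]
        out["fidelity_of_intended"] = fidelity_of_intended(f, d) if not np.isnan(f) else np.nan
        return out

    rows = []
    if by != "organization":
        for label, g in session_scores.groupby(by, sort=True):
            rows.append(one(str(label), g))
    rows.append(one("all", session_scores))
    df = pd.DataFrame(rows)
    df.insert(0, "scope", by)
    return df
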