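"""Mapping of raw response categories onto the 0–100 score scale.

Every instrument item used in the evaluation — success-criterion ratings,
deliverer quality items, self-rated performance, training intensity,
satisfaction, social support and motivation — is recorded on a small ordinal
scale and rescored onto 0–100 before any aggregation:

* 5-point extent/frequency scales: the two most positive categories score 100,
  the middle category 50, the two most negative 0.
* 4-point success-criterion scale: ``completely`` and ``more_in_depth`` score
  100, ``partly`` 50, ``not`` 0 (in-depth delivery is not rewarded beyond
  complete delivery).
* self-rated performance 0–10: 0–4 → 0, 5–7 → 50, 8–10 → 100.
* physical-training intensity 0–10: 0–3 → 0, 4–5 → 50, 6–7 → 75, 8–10 → 100.

Indexes (e.g. the four understanding items) are plain arithmetic means of the
available item scores; an index with no answered items is missing.

All maps are total on their declared domains and pure; scores are carried at
full float precision and only rounded at the reporting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Iterable, Optional, Sequence, Union

__all__ = [
    "ScoreValue",
    "CategoricalValueError",
    "ScoreRangeError",
    "LIKERT5_EXTENT",
    "LIKERT5_FREQUENCY",
    "CRITERION4_TOKENS",
    "score_likert5",
    "score_criterion4",
    "score_performance10",
    "score_intensity10",
    "score_index",
]


class CategoricalValueError(ValueError):
    """An ordinal response token outside the declared category set."""


class ScoreRangeError(ValueError):
    """A numeric response outside its declared 0–10 range."""


@dataclass(frozen=True)
class ScoreValue:
    """A single rescored item: value on 0–100 plus the scale it came from."""

    value: float
    source_scale: str

    def __float__(self) -> float:  # allows mixing with plain numbers
        return float(self.value)


#: 5-point extent scale, most positive first.
LIKERT5_EXTENT: tuple[str, ...] = (
    "to a very large extent",
    "to a large extent",
    "somewhat",
    "to a small extent",
    "to a very small extent",
)

#: 5-point frequency scale used by the social-support items, most positive first.
LIKERT5_FREQUENCY: tuple[str, ...] = (
    "always",
    "often",
    "sometimes",
    "seldom",
    "never",
)

#: Canonical 4-point success-criterion tokens.
CRITERION4_TOKENS: tuple[str, ...] = ("not", "partly", "completely", "more_in_depth")

# Long-form synonyms accepted by the readers ("partly implemented" etc.).
_CRITERION4_SYNONYMS = {
    "not implemented": "not",
    "partly implemented": "partly",
    "completely implemented": "completely",
    "implemented more in depth": "more_in_depth",
    "more in depth": "more_in_depth",
}

_CRITERION4_SCORES = {"not": 0.0, "partly": 50.0, "completely": 100.0, "more_in_depth": 100.0}

# Positional scores for any 5-category scale ordered most → least positive.
_LIKERT5_POSITIONAL = (100.0, 100.0, 50.0, 0.0, 0.0)


def _canon(token: str) -> str:
    return " ".join(token.strip().lower().replace("-", " ").split())


def score_likert5(rating: str, tokens: Sequence[str] = LIKERT5_EXTENT) -> ScoreValue:
    """Score a 5-category ordinal response.

    ``tokens`` lists the five categories from most to least positive; the two
    most positive score 100, the middle 50, the two most negative 0.
    """
    canon = _canon(rating)
    canon_tokens = [_canon(t) for t in tokens]
    if len(canon_tokens) != 5:
        raise ValueError(f"likert5 scale needs exactly 5 tokens, got {len(canon_tokens)}")
    try:
        idx = canon_tokens.index(canon)
    except ValueError:
        raise CategoricalValueError(
            f"unknown 5-point response {rating!r}; expected one of {list(tokens)}"
        ) from None
    return ScoreValue(_LIKERT5_POSITIONAL[idx], "likert5")


def score_criterion4(rating: str) -> ScoreValue:
    """Score a success-criterion rating on the 4-point implementation scale."""
    canon = _canon(rating)
    canon = _CRITERION4_SYNONYMS.get(canon, canon).replace(" ", "_")
    if canon not in _CRITERION4_SCORES:
        raise CategoricalValueError(
            f"unknown success-criterion response {rating!r}; "
            f"expected one of {list(CRITERION4_TOKENS)}"
        )
    return ScoreValue(_CRITERION4_SCORES[canon], "criterion4")


def score_performance10(value: int) -> ScoreValue:
    """Score deliverer self-rated performance (0–10): 0–4→0, 5–7→50, 8–10→100."""
    v = _check_0_10(value, "self-rated performance")
    score = 0.0 if v <= 4 else 50.0 if v <= 7 else 100.0
    return ScoreValue(score, "performance10")


def score_intensity10(value: int) -> ScoreValue:
    """Score physical-training intensity (0–10): 0–3→0, 4–5→50, 6–7→75, 8–10→100."""
    v = _check_0_10(value, "intensity")
    score = 0.0 if v <= 3 else 50.0 if v <= 5 else 75.0 if v <= 7 else 100.0
    return ScoreValue(score, "intensity10")


def _check_0_10(value: int, what: str) -> int:
    try:
        v = int(value)
    except (TypeError, ValueError):
        raise ScoreRangeError(f"{what} must be an integer in [0, 10], got {value!r}") from None
    if v != value or not 0 <= v <= 10:
        raise ScoreRangeError(f"{what} must be an integer in [0, 10], got {value!r}")
    return v


Item = Union[ScoreValue, float, int, None]


def score_index(items: Iterable[Item]) -> Optional[float]:
    """Mean of the non-missing item scores of one index; ``None`` if all missing.

    Missing items are simply left out of the mean (available-item mean); an
    index is missing only when every constituent item is missing.
    """
    values = [float(x) for x in items if x is not None]
    if not values:
        return None
    return fmean(values)
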