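"""Report-boundary formatting.

Scores are carried at full precision everywhere; rounding to whole percent
happens only here, half away from zero (0.875 → 88, 713/753 → 95, 4/9 → 44).
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = ["percent", "round_score", "format_table"]


def percent(fraction: float) -> int:
    """Whole-percent rendering of a fraction, rounding half away from zero."""
    return round_score(100.0 * fraction)


def round_score(score: float) -> int:
    """Round a 0–100 score to a whole number, half away from zero."""
    return int(math.floor(score + 0.5)) if score >= 0 else -int(math.floor(-score + 0.5))


def format_table(df: pd.DataFrame, floatfmt: str = "{:.1f}") -> str:
    """Plain-text rendering of a summary DataFrame for console output."""
    shown = df.copy()
    for col in shown.columns:
        if pd.api.types.is_float_dtype(shown[col]):
            shown[col] = shown[col].map(
                lambda v: "NA" if pd.isna(v) else floatfmt.format(v)
            )
    return shown.to_string(index=False)
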