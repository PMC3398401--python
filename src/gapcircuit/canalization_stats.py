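"""Positional-variance summaries and filtration rates.

Canalization is quantified by comparing the across-embryo spread of an
output position (the hb border, or the initial-Hb/basin-boundary
intersection) with the spread of the input position (where each embryo's
Bcd gradient crosses a reference threshold).  The filtration rate
1 - sd_out/sd_in is the fraction of positional variance removed by the
network.  Summaries report the full range (max - min) and the sample
standard deviation (n-1 denominator), stratified by Bcd family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PositionalSummary",
    "positional_summary",
    "filtration_rate",
    "family_stratified_summary",
    "correlate_positions",
]

ROW_LABELS = ("intersection", "hb_border", "bcd_threshold")
COLUMN_LABELS = ("I", "II", "full")


@dataclass(frozen=True)
class PositionalSummary:
    n: int
    full_range: float  # max - min, %EL
    sd: float  # sample sd (n-1), %EL


def positional_summary(positions) -> PositionalSummary:
    """Full range and sample standard deviation of a set of positions."""
    p = np.asarray(list(positions), dtype=float)
    if len(p) < 2:
        raise ValueError("need at least 2 positions for a summary")
    return PositionalSummary(len(p), float(p.max() - p.min()), float(np.std(p, ddof=1)))


def filtration_rate(output_sd: float, input_sd: float) -> float:
    """Fraction of positional variance filtered: 1 - output_sd / input_sd."""
    if input_sd <= 0:
        raise ValueError("input_sd must be positive")
    return 1.0 - output_sd / input_sd


def family_stratified_summary(
    records: list[dict],
) -> dict[str, dict[str, PositionalSummary | None]]:
    """Positional-variance table: three position kinds x (Family I, II, full set).

    Each record carries ``family`` ("I" | "II" | other) and any of the keys
    ``intersection``, ``hb_border``, ``bcd_threshold`` (positions in %EL).
    Strata with fewer than two values are marked absent (None).
    """
    out: dict[str, dict[str, PositionalSummary | None]] = {}
    for row in ROW_LABELS:
        out[row] = {}
        for col in COLUMN_LABELS:
            vals = [
                r[row]
                for r in records
                if row in r and r[row] is not None and (col == "full" or r.get("family") == col)
            ]
            out[row][col] = positional_summary(vals) if len(vals) >= 2 else None
    return out


def correlate_positions(xs, ys) -> float:
    """Pearson correlation between two matched position sets."""
    x = np.asarray(list(xs), dtype=float)
    y = np.asarray(list(ys), dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched samples, n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in one of the position sets")
    return float(np.corrcoef(x, y)[0, 1])
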