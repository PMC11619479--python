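"""Small numeric helpers shared across modules."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero, matching clinical-report convention.

    Python's built-in ``round`` uses banker's rounding (96.45 -> 96.4); reported
    percentages here follow half-up (96.45 -> 96.5).
    """
    if x is None:
        return x
    x = float(x)
    if math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float) -> float | None:
    """Percentage ``100 * numerator / denominator``; ``None`` when undefined."""
    if denominator == 0:
        return None
    return 100.0 * numerator / denominator


def frame_to_markdown(df, index: bool = False) -> str:
    """Minimal GitHub-flavoured markdown table from a DataFrame."""
    headers = ([str(df.index.name or "")] if index else []) + [str(c) for c in df.columns]
    rows = []
    for idx, row in df.iterrows():
        cells = ([str(idx)] if index else []) + ["" if v is None else str(v) for v in row]
        rows.append(cells)
    lines = [
        "| " + " | ".join(headers) + " |",
        "| " + " | ".join("---" for _ in headers) + " |",
    ]
    lines += ["| " + " | ".join(r) + " |" for r in rows]
    return "\n".join(lines)
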