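"""Climate-table summary utility.

Reads the monthly temperature table (park, month, four temperature columns in
degrees Celsius) and reports per-column arithmetic means rounded half-up to
one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .errors import ParseError, ValidationError

TEMPERATURE_COLUMNS = ("mean_daily_min", "cold_nights", "mean_daily_max", "hot_days")
VALID_MONTHS = ("Nov", "Dec")


@dataclass(frozen=True)
class ClimateRow:
    park: str
    month: str
    mean_daily_min: float
    cold_nights: float
    mean_daily_max: float
    hot_days: float

    def __post_init__(self) -> None:
        if self.month not in VALID_MONTHS:
            raise ValidationError(f"month {self.month!r} not in {VALID_MONTHS}")
        for col in TEMPERATURE_COLUMNS:
            v = getattr(self, col)
            if not (v == v and abs(v) != float("inf")):
                raise ValidationError(f"non-finite temperature in column {col}")


class ClimateTable:
    def __init__(self, rows: list[ClimateRow]):
        self.rows = list(rows)

    def __len__(self) -> int:
        return len(self.rows)


def load_climate_table(path: str | Path) -> ClimateTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"park", "month", *TEMPERATURE_COLUMNS}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: climate table needs columns {sorted(required)}")
    rows = [
        ClimateRow(
            str(r["park"]),
            str(r["month"]),
            float(r["mean_daily_min"]),
            float(r["cold_nights"]),
            float(r["mean_daily_max"]),
            float(r["hot_days"]),
        )
        for _, r in df.iterrows()
    ]
    return ClimateTable(rows)


def _round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def climate_summary(table: ClimateTable) -> dict[str, float]:
    """Per-column mean over all rows, rounded half-up to one decimal."""
    if len(table) == 0:
        raise ValidationError("climate table is empty")
    out = {}
    for col in TEMPERATURE_COLUMNS:
        vals = [getattr(r, col) for r in table.rows]
        out[col] = _round_half_up(sum(vals) / len(vals))
    return out
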