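"""Hourly presence categories and station-month summaries.

Each reviewed hour is placed in exactly one category:

* ``HWS1`` -- complex song: the vocalization bout is organized in at least
  two different themes.
* ``HWS2`` -- preliminary song: no two distinct themes, but at least three
  consecutive repeated phrases of one phrase type.
* ``SOCIAL`` -- vocalizations present without phrase/theme structure
  qualifying as song.
* ``ABSENT`` -- no vocalizations.

Precedence is exactly HWS1 > HWS2 > SOCIAL > ABSENT.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import _PHRASE_CODE_RE

__all__ = [
    "HourCategory",
    "AnnotatedHour",
    "classify_hour",
    "even_hour_schedule",
    "monthly_proportions",
]


class HourCategory(str, Enum):
    ABSENT = "ABSENT"
    SOCIAL = "SOCIAL"
    HWS2 = "HWS2"
    HWS1 = "HWS1"


@dataclass(frozen=True)
class AnnotatedHour:
    """One reviewed hour: the ordered phrase codes of any song bout plus a
    count of non-phrase vocalizations (social calls)."""

    station: str
    start: datetime
    phrase_codes: tuple[str, ...] = ()
    n_calls: int = 0
    category: Optional[HourCategory] = None

    def classified(self, catalogue: Optional[set[str]] = None) -> "AnnotatedHour":
        cat = classify_hour(self.phrase_codes, self.n_calls, catalogue)
        return AnnotatedHour(self.station, self.start, self.phrase_codes,
                             self.n_calls, cat)


def classify_hour(
    phrase_codes: Sequence[str],
    n_calls: int = 0,
    catalogue: Optional[set[str]] = None,
) -> HourCategory:
    """Classify one hour from its ordered phrase codes and call count.

    A theme is a maximal run of one phrase type; two distinct phrase types
    anywhere in the bout therefore yield two distinct themes (HWS1).
    Otherwise a run of >= 3 consecutive identical phrases yields HWS2.
    Any remaining vocalization yields SOCIAL, else ABSENT.

    ``catalogue``, if given, validates phrase codes against the known
    phrase types.
    """
    for code in phrase_codes:
        if not _PHRASE_CODE_RE.match(code):
            raise ValueError(f"invalid phrase code {code!r}")
        if catalogue is not None and code not in catalogue:
            raise ValueError(f"unknown phrase type {code!r}")
    if len(set(phrase_codes)) >= 2:
        return HourCategory.HWS1
    if _max_run(phrase_codes) >= 3:
        return HourCategory.HWS2
    if n_calls > 0 or len(phrase_codes) > 0:
        return HourCategory.SOCIAL
    return HourCategory.ABSENT


def _max_run(codes: Sequence[str]) -> int:
    best = run = 0
    prev = None
    for c in codes:
        run = run + 1 if c == prev else 1
        prev = c
        best = max(best, run)
    return best


def even_hour_schedule(hours: Iterable[AnnotatedHour]) -> list[AnnotatedHour]:
    """Keep hours whose hour-of-day is even (0, 2, ..., 22), emulating the
    even-hour review subsampling."""
    return [h for h in hours if h.start.hour % 2 == 0]


def monthly_proportions(hours: Iterable[AnnotatedHour]) -> pd.DataFrame:
    """Per station-month proportions of SOCIAL / HWS2 / HWS1 hours.

    The denominator is all classified hours in the station-month (ABSENT
    contributes to the denominator only), so the three proportions sum to
    <= 1.  Station-months with zero recorded hours do not appear in the
    output -- absence of a row flags no-data rather than a zero.
    """
    rows = []
    for h in hours:
        cat = h.category
        if cat is None:
            cat = classify_hour(h.phrase_codes, h.n_calls)
        rows.append(
            {
                "station": h.station,
                "month": pd.Period(h.start, freq="M"),
                "category": HourCategory(cat).value,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["station", "month", "n_hours",
                     "prop_social", "prop_hws2", "prop_hws1"]
        )
    df = pd.DataFrame(rows)
    out = []
    for (station, month), grp in df.groupby(["station", "month"]):
        n = len(grp)
        counts = grp["category"].value_counts()
        out.append(
            {
                "station": station,
                "month": month,
                "n_hours": n,
                "prop_social": counts.get("SOCIAL", 0) / n,
                "prop_hws2": counts.get("HWS2", 0) / n,
                "prop_hws1": counts.get("HWS1", 0) / n,
            }
        )
    return pd.DataFrame(out).sort_values(["station", "month"]).reset_index(drop=True)
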