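"""Length and complexity measures of songs, and their covariate correlations.

Five measures per singer: mean/sd session length, mean/sd song length (both
in vocalization units), and three complexity ratios -- unit complexity
(unique unit types / total units per song), phrase complexity (unique phrase
types / total phrases per song), and song complexity (their product).
Complexities are computed per song and averaged per singer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import Singer, SongSequence, Station
from .sequences import SongSession

__all__ = [
    "ElaboratenessRecord",
    "sequence_length",
    "unit_complexity",
    "phrase_complexity",
    "song_complexity",
    "correlate",
    "CorrelationResult",
    "singer_records",
    "correlation_report",
]


@dataclass(frozen=True)
class ElaboratenessRecord:
    singer: str
    day_of_year: int
    latitude: float
    mean_session_length: float
    sd_session_length: float
    mean_song_length: float
    sd_song_length: float
    unit_complexity: float
    phrase_complexity: float
    song_complexity: float

    def __post_init__(self) -> None:
        if not 1 <= self.day_of_year <= 366:
            raise ValueError("day_of_year must be in 1..366")
        for name in ("unit_complexity", "phrase_complexity", "song_complexity"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.mean_session_length < 1 or self.mean_song_length < 1:
            raise ValueError("mean lengths must be >= 1 unit")
        if self.sd_session_length < 0 or self.sd_song_length < 0:
            raise ValueError("standard deviations must be >= 0")


def sequence_length(seq: Union[SongSequence, SongSession, Sequence]) -> int:
    """Length of a song or session as its number of vocalization units."""
    if isinstance(seq, (SongSequence, SongSession)):
        n = len(seq.units)
    else:
        n = len(seq)
    if n == 0:
        raise ValueError("empty sequence has no length")
    return n


def unit_complexity(song: SongSequence) -> float:
    """Unique unit types divided by total units in the song; in (0, 1]."""
    if not song.units:
        raise ValueError("empty song")
    types = {u.unit_type for u in song.units}
    return len(types) / len(song.units)


def phrase_complexity(song: SongSequence) -> float:
    """Unique phrase types divided by total phrases in the song; in (0, 1]."""
    if not song.phrases:
        raise ValueError("song has no phrases")
    types = {p.phrase_type for p in song.phrases}
    return len(types) / len(song.phrases)


def song_complexity(song: SongSequence) -> float:
    """Unit complexity times phrase complexity."""
    return unit_complexity(song) * phrase_complexity(song)


@dataclass(frozen=True)
class CorrelationResult:
    r: Optional[float]
    n: int
    defined: bool
    reason: Optional[str] = None


def correlate(values: Sequence[float], covariate: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation between a measure and a covariate.

    Requires >= 3 finite pairs; a constant covariate (or constant values)
    makes r undefined and is reported as such rather than NaN.
    """
    x = np.asarray(covariate, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("values and covariate must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        return CorrelationResult(None, n, False, "fewer than 3 finite pairs")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(np.dot(dx, dx))
    syy = float(np.dot(dy, dy))
    if sxx == 0.0:
        return CorrelationResult(None, n, False, "constant covariate")
    if syy == 0.0:
        return CorrelationResult(None, n, False, "constant values")
    r = float(np.dot(dx, dy) / math.sqrt(sxx * syy))
    return CorrelationResult(max(-1.0, min(1.0, r)), n, True)


def singer_records(
    singers: Iterable[Singer],
    sessions_by_singer: dict[str, list[SongSession]],
    stations: dict[str, Station],
) -> list[ElaboratenessRecord]:
    """One record per singer.

    Session and song lengths (partials retained) are averaged per singer
    with population (ddof=0) standard deviations; complexities are computed
    per song and averaged per singer.
    """
    records = []
    for singer in singers:
        sessions = sessions_by_singer.get(singer.id, [])
        songs = singer.songs
        if not sessions or not songs:
            continue
        sess_len = np.array([sequence_length(s) for s in sessions], float)
        song_len = np.array([sequence_length(s) for s in songs], float)
        records.append(
            ElaboratenessRecord(
                singer=singer.id,
                day_of_year=singer.date.timetuple().tm_yday,
                latitude=stations[singer.station].latitude,
                mean_session_length=float(sess_len.mean()),
                sd_session_length=float(sess_len.std()),
                mean_song_length=float(song_len.mean()),
                sd_song_length=float(song_len.std()),
                unit_complexity=float(
                    np.mean([unit_complexity(s) for s in songs])
                ),
                phrase_complexity=float(
                    np.mean([phrase_complexity(s) for s in songs])
                ),
                song_complexity=float(
                    np.mean([song_complexity(s) for s in songs])
                ),
            )
        )
    return records


_MEASURES = (
    "mean_session_length",
    "mean_song_length",
    "unit_complexity",
    "phrase_complexity",
    "song_complexity",
)


def correlation_report(records: Sequence[ElaboratenessRecord]) -> pd.DataFrame:
    """Pearson r of each elaborateness measure against day of year and
    latitude, one row per (measure, covariate)."""
    df = pd.DataFrame([vars(r) for r in records])
    rows = []
    for covariate in ("day_of_year", "latitude"):
        for measure in _MEASURES:
            res = correlate(df[measure], df[covariate]) if len(df) else (
                CorrelationResult(None, 0, False, "no records")
            )
            rows.append(
                {
                    "measure": measure,
                    "covariate": covariate,
                    "r": res.r,
                    "n": res.n,
                    "defined": res.defined,
                }
            )
    return pd.DataFrame(rows)
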