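"""Singer attribution, quality filtering, and session/song segmentation.

Attribution rules: recordings at distinct stations belong to distinct
singers (stations sit > 200 km apart, beyond a day's travel at typical swim
speeds); within one station, a gap of more than 24 h between song-bearing
hours starts a new presumed singer.

A song session runs until a silence gap of more than one minute.  Within a
session, a song ends each time the full set of the session's unique theme
types has been rendered since the previous song boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    Phrase,
    SongSequence,
    ThemeSequence,
    Unit,
    format_singer_id,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AttributionConfig",
    "SongSession",
    "assign_singers",
    "quality_filter",
    "extend_to_neighbours",
    "split_sessions",
    "delineate_songs",
]


@dataclass(frozen=True)
class AttributionConfig:
    """Parameters of the singer-attribution heuristic."""

    singer_gap_h: float = 24.0
    min_station_distance_km: float = 200.0
    swim_speed_kmh: float = 4.0
    travel_rate_km_day: tuple[float, float] = (17.0, 75.0)

    def __post_init__(self) -> None:
        if (
            self.singer_gap_h <= 0
            or self.min_station_distance_km <= 0
            or self.swim_speed_kmh <= 0
            or any(r <= 0 for r in self.travel_rate_km_day)
        ):
            raise ValueError("all attribution parameters must be positive")


@dataclass
class SongSession:
    """Continuous singing of one singer, bounded by > 60 s silence gaps."""

    singer: str
    phrases: tuple[Phrase, ...]
    songs: list[SongSequence] = field(default_factory=list)

    @property
    def units(self) -> tuple[Unit, ...]:
        return tuple(u for p in self.phrases for u in p.units)

    @property
    def theme_sequence(self) -> ThemeSequence:
        return ThemeSequence.from_phrase_codes(
            p.phrase_type for p in self.phrases
        )


def assign_singers(
    song_hours: Iterable[tuple[str, datetime]],
    config: AttributionConfig = AttributionConfig(),
) -> dict[tuple[str, datetime], str]:
    """Map each (station, hour) to a presumed singer id.

    Input is sorted internally, so the assignment is stable under input
    permutation; duplicate (station, timestamp) pairs collapse to one hour.
    Within a station a new singer starts whenever the gap to the previous
    song hour exceeds ``config.singer_gap_h``; distinct stations are always
    distinct singers.  Singer id = station + date of the singer's first hour.
    """
    hours = sorted(set(song_hours))
    gap = timedelta(hours=config.singer_gap_h)
    assignment: dict[tuple[str, datetime], str] = {}
    prev_station: Optional[str] = None
    prev_time: Optional[datetime] = None
    current_id: Optional[str] = None
    for station, t in hours:
        new = (
            station != prev_station
            or prev_time is None
            or (t - prev_time) > gap
        )
        if new:
            current_id = format_singer_id(station, t.date())
        assignment[(station, t)] = current_id  # type: ignore[assignment]
        prev_station, prev_time = station, t
    return assignment


def quality_filter(
    sequences: Iterable[SongSequence],
    min_snr_db: float = 10.0,
    min_themes: int = 2,
) -> list[SongSequence]:
    """Keep high-quality sequences: SNR >= 10 dB and >= 2 distinct themes.

    Sequences without an SNR are excluded with a logged warning.
    """
    kept = []
    for seq in sequences:
        if seq.snr is None:
            logger.warning(
                "sequence of singer %s excluded: missing SNR", seq.singer
            )
            continue
        if seq.snr >= min_snr_db and len(set(seq.theme_sequence.tokens)) >= min_themes:
            kept.append(seq)
    return kept


def extend_to_neighbours(
    even_hour: datetime,
    quality_by_hour: Mapping[datetime, bool],
) -> list[datetime]:
    """Extend an analysed even hour to its odd neighbours when those also
    contain high-quality song, yielding a contiguous 1-3 hour window."""
    if even_hour.hour % 2 != 0:
        raise ValueError(f"{even_hour} is not an even hour")
    window = [even_hour]
    before = even_hour - timedelta(hours=1)
    after = even_hour + timedelta(hours=1)
    if quality_by_hour.get(before, False):
        window.insert(0, before)
    if quality_by_hour.get(after, False):
        window.append(after)
    return window


def split_sessions(
    singer: str,
    phrases: Sequence[Phrase],
    max_gap_s: float = 60.0,
) -> list[SongSession]:
    """Split a singer's time-ordered phrases into sessions at silence gaps
    strictly exceeding ``max_gap_s`` (gap measured end-to-start between
    consecutive units).  Unit count is conserved across sessions.
    """
    units = [u for p in phrases for u in p.units]
    for prev, nxt in zip(units, units[1:]):
        if nxt.start < prev.start:
            raise ValueError("units are not time-ordered")
        if nxt.start < prev.end:
            raise ValueError(
                f"overlapping units at t={nxt.start} (previous ends {prev.end})"
            )
    if not phrases:
        return []

    # Boundaries fall between phrases (a phrase is atomic); with strictly
    # positive unit durations the widest silence around a phrase boundary is
    # the end-to-start gap between its flanking units.
    sessions: list[SongSession] = []
    current: list[Phrase] = [phrases[0]]
    for prev, nxt in zip(phrases, phrases[1:]):
        gap = nxt.units[0].start - prev.units[-1].end
        if gap > max_gap_s:
            sessions.append(SongSession(singer, tuple(current)))
            current = [nxt]
        else:
            current.append(nxt)
    sessions.append(SongSession(singer, tuple(current)))
    return sessions


def delineate_songs(session: SongSession) -> list[SongSequence]:
    """Cut a session into songs: scanning theme tokens left to right, a song
    boundary is emitted each time the set of theme types seen since the last
    boundary equals the session's full unique theme-type set.  A trailing
    incomplete segment is kept and flagged ``partial``.  Concatenating the
    returned songs reproduces the session's phrases.
    """
    tokens = session.theme_sequence.tokens
    if not tokens:
        logger.info("session of %s has no themes; no songs", session.singer)
        return []
    full_set = set(tokens)

    # map each theme token to its phrase run
    runs: list[list[Phrase]] = []
    for p in session.phrases:
        if runs and runs[-1][0].phrase_type == p.phrase_type:
            runs[-1].append(p)
        else:
            runs.append([p])
    assert len(runs) == len(tokens)

    songs: list[SongSequence] = []
    seen: set[str] = set()
    current: list[Phrase] = []
    for tok, run in zip(tokens, runs):
        current.extend(run)
        seen.add(tok)
        if seen == full_set:
            songs.append(SongSequence.from_phrases(session.singer, current))
            current = []
            seen = set()
    if current:
        songs.append(
            SongSequence.from_phrases(session.singer, current, partial=True)
        )
    session.songs = songs
    return songs
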