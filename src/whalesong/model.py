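"""Domain types for the song hierarchy and I/O for annotation tables.

The song hierarchy, from the bottom up:

* **unit** -- a single discrete vocal element, typed by a call-type label
  (``CT`` followed by an integer).
* **phrase** -- a stereotyped combination of units.  A phrase type is coded
  with an uppercase letter (the first unit type) plus a lowercase letter
  (the combination of following unit types); per-unit repetition counts let
  the original unit sequence be reconstructed.
* **theme** -- consecutive repetitions of one phrase type.  Transcribing a
  phrase sequence to a theme sequence collapses adjacent repeats.
* **song / session** -- ordered phrases attributed to one singer.

Singers are identified by recording-station prefix plus a dd/MM/YY date.
"""

from __future__ import annotations

import csv
import hashlib
import re
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import datetime
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "Station",
    "UnitType",
    "Unit",
    "PhraseType",
    "Phrase",
    "ThemeSequence",
    "Singer",
    "SongSequence",
    "SelectionRecord",
    "Table1Row",
    "SingerIdError",
    "ThemeSequenceError",
    "SelectionTableError",
    "FixtureError",
    "parse_singer_id",
    "format_singer_id",
    "parse_theme_sequence",
    "read_selection_table",
    "write_selection_table",
    "read_table1_fixture",
    "TABLE1_SHA256",
]


class SingerIdError(ValueError):
    """Raised when a singer id cannot be parsed."""


class ThemeSequenceError(ValueError):
    """Raised when a theme-sequence string contains an invalid token."""


class SelectionTableError(ValueError):
    """Raised on schema or invariant violations in selection tables."""


class FixtureError(RuntimeError):
    """Raised when the packaged fixture fails its checksum."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Station:
    """A recording position (mooring)."""

    id: str
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("station id must be non-empty")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


_UNIT_TYPE_RE = re.compile(r"^CT\d+$")


@dataclass(frozen=True)
class UnitType:
    """A call type: the template for one kind of vocal unit."""

    id: str
    tonal: bool
    nominal_duration: float
    freq_low: float
    freq_high: float
    slope_sign: int = 0

    def __post_init__(self) -> None:
        if not _UNIT_TYPE_RE.match(self.id):
            raise ValueError(f"unit-type id {self.id!r} must match 'CT<int>'")
        if self.nominal_duration <= 0:
            raise ValueError("nominal_duration must be positive")
        if not self.freq_low < self.freq_high:
            raise ValueError("freq_low must be below freq_high")
        if self.slope_sign not in (-1, 0, 1):
            raise ValueError("slope_sign must be one of -1, 0, +1")


@dataclass(frozen=True)
class Unit:
    """One annotated vocal unit.

    ``start`` is seconds from the recording origin; the unit occupies the
    half-open interval ``[start, start + duration)``.
    """

    start: float
    duration: float
    unit_type: str
    snr: Optional[float] = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("unit duration must be positive")

    @property
    def end(self) -> float:
        return self.start + self.duration


_PHRASE_CODE_RE = re.compile(r"^[A-Z][a-z]$")


@dataclass(frozen=True)
class PhraseType:
    """A phrase template: code plus the ordered unit types it expands to.

    The uppercase letter of the code denotes the first unit type; the
    lowercase letter denotes the combination of following unit types.
    """

    code: str
    unit_template: tuple[str, ...]

    def __post_init__(self) -> None:
        if not _PHRASE_CODE_RE.match(self.code):
            raise ValueError(f"phrase code {self.code!r} must match [A-Z][a-z]")
        if not self.unit_template:
            raise ValueError("unit_template must be non-empty")


@dataclass(frozen=True)
class Phrase:
    """A realized phrase: type code, per-template-slot repetition counts,
    and the concrete units."""

    phrase_type: str
    repetitions: tuple[int, ...]
    units: tuple[Unit, ...]

    def __post_init__(self) -> None:
        if any(r < 1 for r in self.repetitions):
            raise ValueError("repetition counts must all be >= 1")

    def expanded_types(self, template: Sequence[str]) -> tuple[str, ...]:
        """Expand ``template`` by this phrase's repetition counts."""
        if len(template) != len(self.repetitions):
            raise ValueError(
                f"template length {len(template)} != repetition count "
                f"{len(self.repetitions)} for phrase {self.phrase_type}"
            )
        out: list[str] = []
        for ut, r in zip(template, self.repetitions):
            out.extend([ut] * r)
        return tuple(out)

    def validate_against(self, phrase_type: PhraseType) -> None:
        """Check that expanding the template reproduces the unit sequence."""
        expected = self.expanded_types(phrase_type.unit_template)
        actual = tuple(u.unit_type for u in self.units)
        if expected != actual:
            raise ValueError(
                f"phrase {self.phrase_type}: expanded template {expected} "
                f"does not match unit sequence {actual}"
            )


@dataclass(frozen=True)
class ThemeSequence:
    """An ordered sequence of phrase-type codes with adjacent repeats collapsed.

    Each token stands for one theme (a maximal run of one phrase type).
    """

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        for tok in self.tokens:
            if not _PHRASE_CODE_RE.match(tok):
                raise ThemeSequenceError(f"invalid theme token {tok!r}")
        for a, b in zip(self.tokens, self.tokens[1:]):
            if a == b:
                raise ThemeSequenceError(
                    f"consecutive equal tokens {a!r}; collapse first"
                )

    @classmethod
    def from_phrase_codes(cls, codes: Iterable[str]) -> "ThemeSequence":
        """Collapse a phrase-code sequence into themes (idempotent)."""
        out: list[str] = []
        for c in codes:
            if not out or out[-1] != c:
                out.append(c)
        return cls(tuple(out))

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    def __str__(self) -> str:
        return " ".join(self.tokens)


@dataclass(frozen=True)
class SongSequence:
    """One song: ordered units partitioned into phrases, plus the derived
    theme sequence.  ``partial`` marks a trailing segment that did not
    complete a full rendition of the session's theme set."""

    singer: str
    units: tuple[Unit, ...]
    phrases: tuple[Phrase, ...]
    theme_sequence: ThemeSequence
    partial: bool = False

    def __post_init__(self) -> None:
        n_phrase_units = sum(len(p.units) for p in self.phrases)
        if self.phrases and n_phrase_units != len(self.units):
            raise ValueError(
                f"phrases hold {n_phrase_units} units but song has "
                f"{len(self.units)}"
            )
        derived = ThemeSequence.from_phrase_codes(
            p.phrase_type for p in self.phrases
        )
        if self.phrases and derived.tokens != self.theme_sequence.tokens:
            raise ValueError(
                "theme_sequence is not derivable from the phrase sequence"
            )

    @property
    def snr(self) -> Optional[float]:
        """Minimum SNR over units, or None if any unit lacks one."""
        vals = [u.snr for u in self.units]
        if not vals or any(v is None for v in vals):
            return None
        return min(vals)  # type: ignore[type-var]

    @classmethod
    def from_phrases(
        cls, singer: str, phrases: Sequence[Phrase], partial: bool = False
    ) -> "SongSequence":
        units = tuple(u for p in phrases for u in p.units)
        themes = ThemeSequence.from_phrase_codes(p.phrase_type for p in phrases)
        return cls(singer, units, tuple(phrases), themes, partial)


@dataclass
class Singer:
    """A presumed individual singer: station + date, owning songs."""

    id: str
    station: str
    date: Date
    songs: list[SongSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        st, dt = parse_singer_id(self.id)
        if st != self.station or dt != self.date:
            raise SingerIdError(
                f"singer id {self.id!r} does not parse to "
                f"({self.station!r}, {self.date})"
            )

    @property
    def repertoire(self) -> frozenset[str]:
        """Union of phrase-type codes over all songs."""
        return frozenset(
            p.phrase_type for s in self.songs for p in s.phrases
        )

    @classmethod
    def create(cls, station: str, date: Date,
               songs: Optional[list[SongSequence]] = None) -> "Singer":
        return cls(format_singer_id(station, date), station, date, songs or [])


# ---------------------------------------------------------------------------
# Singer-id and theme-sequence parsing
# ---------------------------------------------------------------------------

# Station prefix is 2-3 characters (letters then optional digits), followed,
# with or without a space, by dd/MM/YY.
_SINGER_ID_RE = re.compile(
    r"^(?P<station>[A-Z][A-Za-z0-9]{1,2}?) ?(?P<d>\d{2})/(?P<m>\d{2})/(?P<y>\d{2})$"
)


def parse_singer_id(singer_id: str) -> tuple[str, Date]:
    """Parse ``'<station><dd/MM/YY>'`` (space optional) into station and date.

    Two-digit years map into 2000-2099.  Raises :class:`SingerIdError`
    naming the offending token on malformed input.
    """
    m = _SINGER_ID_RE.match(singer_id.strip())
    if m is None:
        raise SingerIdError(f"cannot parse singer id {singer_id!r}")
    station = m.group("station")
    dd, mm, yy = m.group("d"), m.group("m"), m.group("y")
    try:
        parsed = datetime.strptime(f"{dd}/{mm}/20{yy}", "%d/%m/%Y").date()
    except ValueError as exc:
        raise SingerIdError(
            f"malformed date {dd}/{mm}/{yy!s} in singer id {singer_id!r}"
        ) from exc
    return station, parsed


def format_singer_id(station: str, date: Date) -> str:
    """Canonical (spaced) singer id: ``'G3 13/04/11'``."""
    if not station or not re.match(r"^[A-Z][A-Za-z0-9]{1,2}$", station):
        raise SingerIdError(f"invalid station prefix {station!r}")
    return f"{station} {date.strftime('%d/%m/%y')}"


_TRAILING_COUNT_RE = re.compile(r"^\((\d+)\)$")


def parse_theme_sequence(text: str) -> tuple[ThemeSequence, Optional[int]]:
    """Parse a whitespace-separated theme-sequence string.

    A trailing parenthesized count, if present, is returned separately as
    the number of analysed sequences, e.g. ``"Cb Cc (17)"`` -> tokens
    ``(Cb, Cc)``, n = 17.
    """
    parts = text.split()
    if not parts:
        raise ThemeSequenceError("empty theme sequence")
    n: Optional[int] = None
    m = _TRAILING_COUNT_RE.match(parts[-1])
    if m is not None:
        n = int(m.group(1))
        parts = parts[:-1]
    for tok in parts:
        if not _PHRASE_CODE_RE.match(tok):
            raise ThemeSequenceError(f"invalid theme token {tok!r} in {text!r}")
    return ThemeSequence(tuple(parts)), n


# ---------------------------------------------------------------------------
# Selection tables (Raven-style, tab-separated)
# ---------------------------------------------------------------------------

SELECTION_COLUMNS = (
    "Selection",
    "Begin Time (s)",
    "End Time (s)",
    "Low Freq (Hz)",
    "High Freq (Hz)",
    "unit_type",
    "phrase_code",
    "phrase_reps",
    "snr_db",
)


@dataclass(frozen=True)
class SelectionRecord:
    """One selection-table row: a unit plus its phrase annotation."""

    unit: Unit
    low_freq: float
    high_freq: float
    phrase_code: str
    phrase_reps: tuple[int, ...]


def read_selection_table(path: str | Path) -> list[SelectionRecord]:
    """Read a tab-separated Raven-style selection table.

    Rows are returned ordered by begin time.  Raises
    :class:`SelectionTableError` listing missing columns, or naming the
    first row whose end time precedes its begin time.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in SELECTION_COLUMNS if c not in header]
        if missing:
            raise SelectionTableError(
                f"{path.name}: missing required columns: {', '.join(missing)}"
            )
        records: list[SelectionRecord] = []
        for i, row in enumerate(reader, start=1):
            begin = float(row["Begin Time (s)"])
            end = float(row["End Time (s)"])
            if end <= begin:
                raise SelectionTableError(
                    f"{path.name}: row {i}: End Time {end} <= Begin Time {begin}"
                )
            snr_raw = row["snr_db"].strip()
            reps_raw = row["phrase_reps"].strip()
            records.append(
                SelectionRecord(
                    unit=Unit(
                        start=begin,
                        duration=end - begin,
                        unit_type=row["unit_type"],
                        snr=float(snr_raw) if snr_raw else None,
                    ),
                    low_freq=float(row["Low Freq (Hz)"]),
                    high_freq=float(row["High Freq (Hz)"]),
                    phrase_code=row["phrase_code"],
                    phrase_reps=tuple(
                        int(x) for x in reps_raw.split(",") if x
                    ),
                )
            )
    records.sort(key=lambda r: r.unit.start)
    return records


def write_selection_table(path: str | Path,
                          records: Sequence[SelectionRecord]) -> None:
    """Write records as a tab-separated selection table.

    Numeric fields use ``repr``-faithful formatting so a read/write cycle
    round-trips bit-identically on the fields this writer owns.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SELECTION_COLUMNS)
        for i, rec in enumerate(records, start=1):
            writer.writerow(
                [
                    i,
                    repr(rec.unit.start),
                    repr(rec.unit.end),
                    repr(rec.low_freq),
                    repr(rec.high_freq),
                    rec.unit.unit_type,
                    rec.phrase_code,
                    ",".join(str(r) for r in rec.phrase_reps),
                    "" if rec.unit.snr is None else repr(rec.unit.snr),
                ]
            )


# ---------------------------------------------------------------------------
# Packaged set-median fixture
# ---------------------------------------------------------------------------

#: SHA-256 of the packaged set-median sequence table (77 singer rows).
TABLE1_SHA256 = "da79e0c18136a142e957c5f1267aebd1e6aebd334cb5550136830b73f06602f9"


@dataclass(frozen=True)
class Table1Row:
    singer_id: str
    station: str
    date: Date
    theme_sequence: ThemeSequence
    n_sequences: int

    @property
    def repertoire(self) -> frozenset[str]:
        """Phrase-type set of the set-median sequence (repertoire proxy)."""
        return frozenset(self.theme_sequence.tokens)


def read_table1_fixture() -> list[Table1Row]:
    """Load the packaged table of set-median theme sequences (one row per
    singer), verifying its checksum.

    The phrase-type set of each median sequence serves as that singer's
    repertoire proxy when no raw annotations are available.
    """
    data = (resources.files("whalesong") / "data" / "table1.csv").read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != TABLE1_SHA256:
        raise FixtureError(
            f"fixture checksum mismatch: expected {TABLE1_SHA256}, got {digest}"
        )
    rows: list[Table1Row] = []
    reader = csv.DictReader(data.decode("utf-8").splitlines())
    for row in reader:
        themes, _ = parse_theme_sequence(row["theme_sequence"])
        rows.append(
            Table1Row(
                singer_id=row["singer_id"],
                station=row["station"],
                date=Date.fromisoformat(row["date"]),
                theme_sequence=themes,
                n_sequences=int(row["n_sequences"]),
            )
        )
    return rows
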