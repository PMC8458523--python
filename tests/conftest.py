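from __future__ import annotations

import pytest

from whalesong.model import Phrase, SongSequence, Unit, read_table1_fixture


@pytest.fixture(scope="session")
def table1():
    return read_table1_fixture()


@pytest.fixture(scope="session")
def table1_by_id(table1):
    return {row.singer_id: row for row in table1}


def mk_phrase(code: str, start: float, n_units: int = 2, unit_type: str = "CT1",
              dur: float = 1.0, gap: float = 0.5, snr: float = 15.0) -> Phrase:
    """A phrase of ``n_units`` repeats of one unit type, starting at ``start``."""
    units = tuple(
        Unit(start=start + i * (dur + gap), duration=dur,
             unit_type=unit_type, snr=snr)
        for i in range(n_units)
    )
    return Phrase(code, (n_units,), units)


def mk_song(codes: list[str], singer: str = "G1 01/05/13", t0: float = 0.0,
            snr: float = 15.0, unit_types: dict[str, str] | None = None,
            phrase_gap: float = 3.0) -> SongSequence:
    """A song with one phrase per code; unit types default to one per code."""
    phrases = []
    t = t0
    for code in codes:
        ut = (unit_types or {}).get(code, f"CT{ord(code[0]) - 64}")
        p = mk_phrase(code, t, unit_type=ut, snr=snr)
        phrases.append(p)
        t = p.units[-1].end + phrase_gap
    return SongSequence.from_phrases(singer, phrases)
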