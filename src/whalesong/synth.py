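"""Synthetic study generator.

Produces every input the pipeline consumes -- singers with songs, phrases
and units; hourly presence tables; daily sea-ice grids; and labelled unit
feature tables -- with the statistical structure the analysis assumes:

* ``n_groups`` song groups whose phrase catalogues share a configurable
  fraction of types (0 = disjoint);
* within a group-year, singers draw repertoires from a common pool and the
  first two singers share theirs exactly (so some pairs are 100% similar);
* per-year catalogue turnover emulating era drift;
* song presence peaking at a configurable month;
* sinusoidal sea-ice cycles with a closed form retrievable for tests;
* separable Gaussian unit-feature clusters.

Everything is a pure function of (config, seed): equal configs give
bit-identical output.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass
from datetime import date as Date
from datetime import timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    Phrase,
    PhraseType,
    Singer,
    SongSequence,
    Station,
    Unit,
    UnitType,
    format_singer_id,
)
from .seaice import IceGrid
from .validation import FeatureTable

__all__ = [
    "SynthConfig",
    "SyntheticStudy",
    "DEFAULT_STATIONS",
    "generate_song_groups",
    "generate_hour_table",
    "generate_ice",
    "ice_closed_form",
    "generate_unit_features",
]

DEFAULT_STATIONS: tuple[Station, ...] = (
    Station("G1", -59.05, 0.10),
    Station("G2", -61.00, 0.05),
    Station("G3", -63.00, 0.00),
    Station("G4", -64.05, 0.05),
    Station("G5", -69.00, 0.00),
    Station("W13", -61.20, -55.50),
    Station("W6", -63.50, -50.00),
    Station("W9", -66.00, -45.00),
)


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic study.  ``seed`` is mandatory."""

    seed: int
    n_groups: int = 2
    catalog_sizes: tuple[int, ...] = (10, 8)
    group_overlap: float = 0.0
    years: tuple[int, ...] = (2013,)
    era_drift: float = 0.0
    singers_per_group_year: int = 6
    songs_per_singer: int = 5
    theme_seq_length: tuple[int, int] = (3, 7)
    stations: tuple[Station, ...] = DEFAULT_STATIONS
    season_peak_month: int = 5
    hours_per_day: int = 12
    ice_mean: float = 50.0
    ice_amplitude: float = 45.0
    ice_phase_day: float = 250.0
    ice_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.group_overlap <= 1.0:
            raise ValueError("group_overlap must lie in [0, 1]")
        if not 0.0 <= self.era_drift <= 1.0:
            raise ValueError("era_drift must lie in [0, 1]")
        if self.n_groups < 1 or len(self.catalog_sizes) != self.n_groups:
            raise ValueError("catalog_sizes must have one entry per group")
        if any(s < 2 for s in self.catalog_sizes):
            raise ValueError("each group catalogue needs >= 2 phrase types")
        if (
            self.singers_per_group_year < 1
            or self.songs_per_singer < 1
            or not self.years
            or self.hours_per_day < 1
        ):
            raise ValueError("all counts must be positive")
        lo, hi = self.theme_seq_length
        if not 2 <= lo <= hi:
            raise ValueError("theme_seq_length range must satisfy 2 <= lo <= hi")
        n_shared = round(self.group_overlap * min(self.catalog_sizes))
        if n_shared > min(self.catalog_sizes):
            raise ValueError("infeasible overlap/size combination")
        if not 1 <= self.season_peak_month <= 12:
            raise ValueError("season_peak_month must be a calendar month")

    @property
    def n_shared_types(self) -> int:
        return round(self.group_overlap * min(self.catalog_sizes))

    @property
    def southernmost_station(self) -> Station:
        return min(self.stations, key=lambda s: s.latitude)


@dataclass
class SyntheticStudy:
    """The generated ground truth."""

    config: SynthConfig
    singers: list[Singer]
    group_of: dict[str, int]
    catalogues: dict[tuple[int, int], tuple[str, ...]]  # (group, year) -> codes
    phrase_types: dict[str, PhraseType]
    unit_types: dict[str, UnitType]

    def songs_by_singer(self) -> dict[str, list[tuple[str, ...]]]:
        return {
            s.id: [song.theme_sequence.tokens for song in s.songs]
            for s in self.singers
        }

    def repertoires(self) -> dict[str, frozenset[str]]:
        return {s.id: s.repertoire for s in self.singers}


# ---------------------------------------------------------------------------
# Song groups
# ---------------------------------------------------------------------------

def _code_stream():
    for upper, lower in itertools.product(string.ascii_uppercase,
                                          string.ascii_lowercase):
        yield upper + lower


def _build_registries(codes: Sequence[str], rng: np.random.Generator
                      ) -> tuple[dict[str, PhraseType], dict[str, UnitType]]:
    """Phrase templates honouring the coding convention: the uppercase
    letter fixes the first unit type; the lowercase letter stands for the
    combination of following unit types."""
    unit_types: dict[str, UnitType] = {}
    first_ct: dict[str, str] = {}
    next_ct = 1

    def new_unit_type() -> str:
        nonlocal next_ct
        ct = f"CT{next_ct}"
        f_low = float(rng.uniform(50, 800))
        unit_types[ct] = UnitType(
            id=ct,
            tonal=bool(rng.integers(0, 2)),
            nominal_duration=float(rng.uniform(0.3, 2.5)),
            freq_low=f_low,
            freq_high=f_low + float(rng.uniform(100, 1200)),
            slope_sign=int(rng.integers(-1, 2)),
        )
        next_ct += 1
        return ct

    phrase_types: dict[str, PhraseType] = {}
    for code in codes:
        upper = code[0]
        if upper not in first_ct:
            first_ct[upper] = new_unit_type()
        n_follow = int(rng.integers(1, 4))
        follow = []
        for _ in range(n_follow):
            # reuse an existing type half the time to create shared units
            if unit_types and rng.random() < 0.5:
                follow.append(str(rng.choice(sorted(unit_types))))
            else:
                follow.append(new_unit_type())
        phrase_types[code] = PhraseType(code, (first_ct[upper], *follow))
    return phrase_types, unit_types


def _markov_theme_sequence(repertoire: Sequence[str], length: int,
                           rng: np.random.Generator) -> list[str]:
    """First-order chain over the repertoire with no immediate repeats."""
    seq = [str(rng.choice(repertoire))]
    while len(seq) < length:
        choices = [c for c in repertoire if c != seq[-1]]
        seq.append(str(rng.choice(choices)))
    return seq


def generate_song_groups(config: SynthConfig) -> SyntheticStudy:
    """Generate singers with full song/phrase/unit structure.

    Group catalogues share exactly ``round(group_overlap * min(size))``
    phrase types; within each group-year the first two singers use an
    identical repertoire; successive years replace ``round(era_drift *
    size)`` of the previous year's types with fresh ones.
    """
    rng = np.random.default_rng(config.seed)
    stream = _code_stream()

    n_shared = config.n_shared_types
    shared = [next(stream) for _ in range(n_shared)]
    base: dict[int, list[str]] = {}
    for g, size in enumerate(config.catalog_sizes):
        own = [next(stream) for _ in range(size - n_shared)]
        base[g] = shared + own

    years = tuple(sorted(config.years))
    catalogues: dict[tuple[int, int], tuple[str, ...]] = {}
    for g, size in enumerate(config.catalog_sizes):
        current = list(base[g])
        n_turn = round(config.era_drift * size)
        for yi, year in enumerate(years):
            if yi > 0 and n_turn > 0:
                # replace only group-exclusive types, keeping shared ones
                replace_pool = [c for c in current if c not in shared]
                n_rep = min(n_turn, len(replace_pool))
                doomed = set(
                    rng.choice(replace_pool, size=n_rep, replace=False)
                )
                current = [c for c in current if c not in doomed]
                current += [next(stream) for _ in range(n_rep)]
            catalogues[(g, year)] = tuple(current)

    all_codes = sorted({c for cat in catalogues.values() for c in cat})
    phrase_types, unit_types = _build_registries(all_codes, rng)

    south = config.southernmost_station.id
    song_stations = [s.id for s in config.stations if s.id != south]
    station_pools = [song_stations[g::config.n_groups] or [song_stations[g % len(song_stations)]]
                     for g in range(config.n_groups)]

    singers: list[Singer] = []
    group_of: dict[str, int] = {}
    used_ids: set[str] = set()
    for g in range(config.n_groups):
        for year in years:
            pool = list(catalogues[(g, year)])
            n_pool = len(pool)
            modal_size = max(2, n_pool // 2 + 1)
            modal = sorted(
                rng.choice(pool, size=modal_size, replace=False)
            )
            for si in range(config.singers_per_group_year):
                if si < 2:
                    repertoire = list(modal)
                else:
                    k = int(rng.integers(n_pool // 2 + 1, n_pool + 1))
                    repertoire = sorted(
                        rng.choice(pool, size=k, replace=False)
                    )
                station = str(rng.choice(station_pools[g]))
                # unique (station, date) within the season (Mar-Jun)
                while True:
                    doy = int(rng.integers(60, 182))
                    date = Date(year, 1, 1) + timedelta(days=doy - 1)
                    sid = format_singer_id(station, date)
                    if sid not in used_ids:
                        used_ids.add(sid)
                        break
                singer = Singer.create(station, date)
                clock = 0.0
                lo, hi = config.theme_seq_length
                for _ in range(config.songs_per_singer):
                    length = int(rng.integers(lo, hi + 1))
                    tokens = _markov_theme_sequence(repertoire, length, rng)
                    phrases: list[Phrase] = []
                    for tok in tokens:
                        for _ in range(int(rng.integers(1, 4))):
                            phrase, clock = _realize_phrase(
                                phrase_types[tok], unit_types, clock, rng
                            )
                            phrases.append(phrase)
                            clock += float(rng.uniform(2.0, 5.0))
                    singer.songs.append(
                        SongSequence.from_phrases(singer.id, phrases)
                    )
                    clock += 120.0  # silence gap: one session per song
                singers.append(singer)
                group_of[singer.id] = g

    return SyntheticStudy(
        config=config,
        singers=singers,
        group_of=group_of,
        catalogues=catalogues,
        phrase_types=phrase_types,
        unit_types=unit_types,
    )


def _realize_phrase(
    ptype: PhraseType,
    unit_types: dict[str, UnitType],
    clock: float,
    rng: np.random.Generator,
) -> tuple[Phrase, float]:
    reps = tuple(int(rng.integers(1, 3)) for _ in ptype.unit_template)
    units: list[Unit] = []
    for ut_id, r in zip(ptype.unit_template, reps):
        ut = unit_types[ut_id]
        for _ in range(r):
            dur = ut.nominal_duration * float(rng.uniform(0.9, 1.1))
            units.append(
                Unit(
                    start=clock,
                    duration=dur,
                    unit_type=ut_id,
                    snr=float(rng.uniform(11.0, 20.0)),
                )
            )
            clock += dur + float(rng.uniform(0.5, 2.0))
    return Phrase(ptype.code, reps, tuple(units)), clock


# ---------------------------------------------------------------------------
# Hour table
# ---------------------------------------------------------------------------

def _month_probs(month: int, peak: int) -> tuple[float, float, float]:
    """(p_hws1, p_hws2, p_social) for one calendar month."""
    dm = min(abs(month - peak), 12 - abs(month - peak))  # circular distance
    p_hws1 = 0.05 + 0.55 * float(np.exp(-(dm ** 2) / 2.0))
    return p_hws1, 0.3 * p_hws1, 0.15


def generate_hour_table(config: SynthConfig) -> pd.DataFrame:
    """Hourly categories for every station over the first configured year.

    Category probabilities depend on month and peak at
    ``season_peak_month``; the southernmost station emits social calls only.
    Columns: station, hour_start_iso, category.
    """
    rng = np.random.default_rng(config.seed + 1)
    year = min(config.years)
    south = config.southernmost_station.id
    start = pd.Timestamp(year=year, month=1, day=1)
    n_days = 366 if pd.Timestamp(year=year, month=12, day=31).dayofyear == 366 else 365
    step = max(1, 24 // config.hours_per_day)
    rows = []
    for st in config.stations:
        for day in range(n_days):
            base = start + pd.Timedelta(days=day)
            p1, p2, ps = _month_probs(base.month, config.season_peak_month)
            if st.id == south:
                p1, p2, ps = 0.0, 0.0, 0.20
            for hour in range(0, 24, step):
                u = rng.random()
                if u < p1:
                    cat = "HWS1"
                elif u < p1 + p2:
                    cat = "HWS2"
                elif u < p1 + p2 + ps:
                    cat = "SOCIAL"
                else:
                    cat = "ABSENT"
                rows.append(
                    {
                        "station": st.id,
                        "hour_start_iso": (base + pd.Timedelta(hours=hour)).isoformat(),
                        "category": cat,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sea ice
# ---------------------------------------------------------------------------

def ice_closed_form(config: SynthConfig, day_of_year) -> np.ndarray:
    """Noise-free concentration at a given day of year."""
    doy = np.asarray(day_of_year, dtype=float)
    raw = config.ice_mean + config.ice_amplitude * np.cos(
        2.0 * np.pi * (doy - config.ice_phase_day) / 365.25
    )
    return np.clip(raw, 0.0, 100.0)


def generate_ice(config: SynthConfig) -> IceGrid:
    """Daily grid: a handful of cells within 50 km of each station (plus
    distant decoys), all following the configured sinusoid plus noise."""
    rng = np.random.default_rng(config.seed + 2)
    offsets_near = [(0.0, 0.0), (0.2, 0.0), (-0.2, 0.0), (0.0, 0.4), (0.0, -0.4)]
    offsets_far = [(2.0, 0.0), (0.0, 8.0)]
    year_min, year_max = min(config.years), max(config.years)
    dates = pd.date_range(f"{year_min}-01-01", f"{year_max}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(float)
    base = ice_closed_form(config, doy)

    frames = []
    for st in config.stations:
        for dlat, dlon in offsets_near + offsets_far:
            lat = st.latitude + dlat
            lon = st.longitude + dlon
            noise = (
                rng.normal(0.0, config.ice_noise_sd, size=len(dates))
                if config.ice_noise_sd > 0
                else np.zeros(len(dates))
            )
            sic = np.clip(base + noise, 0.0, 100.0)
            frames.append(
                pd.DataFrame(
                    {"date": dates, "lat": lat, "lon": lon, "sic": sic}
                )
            )
    return IceGrid(pd.concat(frames, ignore_index=True), resolution_km=25.0)


# ---------------------------------------------------------------------------
# Unit features
# ---------------------------------------------------------------------------

def generate_unit_features(
    seed: int,
    n_classes: int = 4,
    exemplars_per_class: int = 50,
    separation: float = 10.0,
    n_features: int = 44,
) -> FeatureTable:
    """Gaussian unit-feature clusters: class i's mean sits ``separation``
    standard deviations along feature axis i; unit covariance."""
    if n_classes < 2 or exemplars_per_class < 2:
        raise ValueError("need >= 2 classes with >= 2 exemplars each")
    if n_features < n_classes:
        raise ValueError("need at least as many features as classes")
    rng = np.random.default_rng(seed)
    blocks = []
    labels = []
    for i in range(n_classes):
        mean = np.zeros(n_features)
        mean[i] = separation
        blocks.append(rng.normal(mean, 1.0, size=(exemplars_per_class, n_features)))
        labels += [f"CT{i + 1}"] * exemplars_per_class
    x = np.vstack(blocks)
    df = pd.DataFrame(x, columns=[f"f{j + 1}" for j in range(n_features)])
    return FeatureTable(df, pd.Series(labels, name="label"))
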