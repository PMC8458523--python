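"""Reusable synthetic benchmarks: two-group AU recovery and end-to-end
group-assignment recovery.

These are the reference constructions used by both the test suite and the
acceptance report, kept in the package so they are computed one way only.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .cluster import DEFAULT_SCALES, au_support_dci, single_linkage
from .sequences import delineate_songs, quality_filter, split_sessions
from .similarity import dci_matrix
from .synth import SynthConfig, generate_song_groups

__all__ = ["two_group_au", "rand_recovery", "rand_index"]


def two_group_au(
    seed: int,
    n_boot: int = 1000,
    n_per_group: int = 10,
    catalog_size: int = 8,
    scales: Sequence[float] = DEFAULT_SCALES,
) -> float:
    """AU support (0-1) of the division separating two synthetic song groups
    with disjoint phrase catalogues.

    Each group has ``catalog_size`` exclusive phrase types; every singer's
    repertoire is a random subset of 6-8 of its group's types, so any two
    same-group repertoires share at least half their types while cross-group
    similarity is exactly zero.
    """
    rng = np.random.default_rng(seed)
    catalogs = [
        [f"A{c}" for c in "abcdefghijklmnop"[:catalog_size]],
        [f"B{c}" for c in "abcdefghijklmnop"[:catalog_size]],
    ]
    stations = ("G1", "W13")
    repertoires: dict[str, set[str]] = {}
    groups: dict[str, int] = {}
    for g, catalog in enumerate(catalogs):
        lo = max(2, catalog_size - 2)
        for i in range(n_per_group):
            k = int(rng.integers(lo, catalog_size + 1))
            label = f"{stations[g]} {i + 1:02d}/04/13"
            repertoires[label] = set(
                str(c) for c in rng.choice(catalog, size=k, replace=False)
            )
            groups[label] = g

    dendro, supports = au_support_dci(
        repertoires, n_boot=n_boot, scales=scales, seed=seed
    )
    group0 = frozenset(lab for lab, g in groups.items() if g == 0)
    group1 = frozenset(lab for lab, g in groups.items() if g == 1)
    aus = [s.au for s in supports if s.cluster in (group0, group1)
           and s.au is not None]
    if not aus:
        return 0.0
    return float(min(aus))


def rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Plain Rand index between two partitions given as label sequences."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("partitions must label the same items")
    n = len(a)
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(n, k=1)
    agree = (same_a[iu] == same_b[iu]).sum()
    return float(agree / len(iu[0]))


def rand_recovery(seed: int, config: Optional[SynthConfig] = None) -> float:
    """Rand index between the true group assignment and the two-cluster cut
    of the pipeline's DCI dendrogram on a synthetic study.

    The pipeline path is exercised end to end: the generated phrase streams
    are re-segmented into sessions and songs, quality-filtered, reduced to
    repertoires, compared with DCI, and clustered with single linkage; the
    final merge defines the two-group cut.
    """
    if config is None:
        config = SynthConfig(seed=seed)
    else:
        if config.seed != seed:
            raise ValueError("config.seed must equal seed")
    study = generate_song_groups(config)

    repertoires: dict[str, frozenset[str]] = {}
    for singer in study.singers:
        phrases = [p for song in singer.songs for p in song.phrases]
        sessions = split_sessions(singer.id, phrases)
        songs = [s for sess in sessions for s in delineate_songs(sess)]
        kept = quality_filter(songs)
        rep = frozenset(p.phrase_type for s in kept for p in s.phrases)
        if rep:
            repertoires[singer.id] = rep

    matrix = dci_matrix(repertoires)
    dendro = single_linkage(matrix)
    leafsets = dendro.node_leafsets()
    last = dendro.merges[-1]
    left = leafsets[last.left]
    predicted = [0 if i in left else 1 for i in range(dendro.n_leaves)]
    truth = [study.group_of[lab] for lab in dendro.labels]
    return rand_index(truth, predicted)
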