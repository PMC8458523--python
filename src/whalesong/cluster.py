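"""Single-linkage clustering of similarity matrices with multiscale-bootstrap
approximately-unbiased (AU) support, and Newick export.

Similarities s are converted to distances d = 1 - s and merged with
nearest-neighbour (single) linkage.  Support for each dendrogram division is
estimated by resampling the raw observations beneath the similarity at a
range of sample-size scales r: the bootstrap proportion BP_r of replicates
containing the division is recorded per scale, the normal quantile of
(1 - BP_r) is regressed on (sqrt(r), 1/sqrt(r)) to estimate a signed
distance v and curvature c, and AU = 1 - Phi(v - c).

What gets resampled is method-specific:

* DCI -- singers' repertoires form a binary singer x phrase-type matrix and
  phrase-type columns are drawn with replacement (round(r * m) of m columns)
  per replicate, after which Dice similarities and the clustering are
  recomputed.
* LSI -- each singer's set of songs is resampled with replacement
  (round(r * k) of k songs, at least one) and the set median recomputed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm

from .similarity import SimilarityMatrix, lsi, set_median

__all__ = [
    "Merge",
    "Dendrogram",
    "ClusterSupport",
    "DEFAULT_SCALES",
    "single_linkage",
    "au_support_dci",
    "au_support_lsi",
    "export_newick",
]

#: Default resampling scales, 0.5 .. 1.4 in steps of 0.1.
DEFAULT_SCALES: tuple[float, ...] = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))


@dataclass(frozen=True)
class Merge:
    """One agglomeration step.  Node ids follow the scipy convention:
    leaves are 0..n-1, the k-th merge creates node n+k."""

    left: int
    right: int
    height: float


@dataclass(frozen=True)
class Dendrogram:
    labels: tuple[str, ...]
    merges: tuple[Merge, ...]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise ValueError(f"{n} leaves require {n - 1} merges")
        heights = [m.height for m in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def node_leafsets(self) -> dict[int, frozenset[int]]:
        """Leaf-index set of every node (leaves and internal)."""
        n = self.n_leaves
        sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        for k, m in enumerate(self.merges):
            sets[n + k] = sets[m.left] | sets[m.right]
        return sets

    def internal_clusters(self) -> list[frozenset[str]]:
        """Leaf-label sets of the internal nodes, in merge order."""
        sets = self.node_leafsets()
        n = self.n_leaves
        return [
            frozenset(self.labels[i] for i in sets[n + k])
            for k in range(len(self.merges))
        ]

    def node_heights(self) -> dict[int, float]:
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        for k, m in enumerate(self.merges):
            heights[n + k] = m.height
        return heights


def single_linkage(matrix: SimilarityMatrix) -> Dendrogram:
    """Agglomerative single-linkage (nearest neighbour) clustering on
    d = 1 - s.

    Deterministic: among equally distant cluster pairs, the pair whose
    (lexicographically smallest member labels) sort first is merged.
    """
    n = len(matrix.labels)
    if n < 2:
        raise ValueError("clustering needs at least 2 singers")
    d = matrix.to_distance().astype(float).copy()

    active: dict[int, int] = {i: i for i in range(n)}  # cluster id -> node id
    min_label: dict[int, str] = {i: matrix.labels[i] for i in range(n)}
    merges: list[Merge] = []
    next_node = n
    # cluster-to-cluster distance matrix indexed by original leaf slots;
    # row/col of a merged-away cluster is retired
    dist = d.copy()
    np.fill_diagonal(dist, np.inf)

    for _ in range(n - 1):
        ids = sorted(active)
        best: Optional[tuple[str, str]] = None
        best_pair: Optional[tuple[int, int]] = None
        dmin = np.inf
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                dd = dist[a, b]
                if dd < dmin - 1e-12:
                    dmin = dd
                    best_pair = (a, b)
                    best = tuple(sorted((min_label[a], min_label[b])))  # type: ignore
                elif abs(dd - dmin) <= 1e-12:
                    key = tuple(sorted((min_label[a], min_label[b])))
                    if best is None or key < best:
                        best = key  # type: ignore[assignment]
                        best_pair = (a, b)
        assert best_pair is not None
        a, b = best_pair
        merges.append(Merge(active[a], active[b], float(dmin)))
        # single linkage: new cluster distance = min of the two rows
        merged_row = np.minimum(dist[a], dist[b])
        dist[a, :] = merged_row
        dist[:, a] = merged_row
        dist[a, a] = np.inf
        dist[b, :] = np.inf
        dist[:, b] = np.inf
        min_label[a] = min(min_label[a], min_label[b])
        active[a] = next_node
        del active[b]
        next_node += 1

    return Dendrogram(matrix.labels, tuple(merges))


# ---------------------------------------------------------------------------
# Multiscale bootstrap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterSupport:
    """Bootstrap support for one dendrogram division."""

    cluster: frozenset[str]
    bp_by_scale: dict[float, float]
    au: Optional[float]
    n_boot: int
    flag: Optional[str] = None

    def __post_init__(self) -> None:
        for r, bp in self.bp_by_scale.items():
            if not 0.0 <= bp <= 1.0:
                raise ValueError(f"BP at scale {r} outside [0, 1]")
        if self.au is not None and not 0.0 <= self.au <= 1.0:
            raise ValueError("AU outside [0, 1]")


def _replicate_clusters(sim: np.ndarray) -> set[frozenset[int]]:
    """Internal-node leaf-index sets of a single-linkage tree on 1 - sim.

    scipy's C implementation is used here for speed; tie-breaking may
    differ from :func:`single_linkage`, which only perturbs replicates with
    exactly tied merge distances and leaves BP estimates unbiased.
    """
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    z = _scipy_linkage(squareform(d, checks=False), method="single")
    n = sim.shape[0]
    sets: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    out: set[frozenset[int]] = set()
    for left, right, _, _ in z:
        s = sets[int(left)] | sets[int(right)]
        sets.append(s)
        out.add(s)
    return out


def _fit_au(scales: Sequence[float], bps: Sequence[float], n_boot: int
            ) -> tuple[Optional[float], Optional[str]]:
    """Fit the multiscale-bootstrap model and return (AU, flag)."""
    bps = np.asarray(bps, dtype=float)
    if np.all(bps >= 1.0):
        return 1.0, "degenerate_all_one"
    if np.all(bps <= 0.0):
        return 0.0, "degenerate_all_zero"
    if len(scales) < 2:
        return None, "au_unavailable_single_scale"
    eps = 1.0 / (2.0 * n_boot)
    bp_c = np.clip(bps, eps, 1.0 - eps)
    z = norm.ppf(1.0 - bp_c)
    r = np.asarray(scales, dtype=float)
    design = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    # delta-method weights: Var(z-hat) = BP(1-BP) / (n_boot * phi(z)^2)
    w = n_boot * norm.pdf(z) ** 2 / (bp_c * (1.0 - bp_c))
    wx = design * w[:, None]
    coef, *_ = np.linalg.lstsq(wx.T @ design, wx.T @ z, rcond=None)
    v, c = float(coef[0]), float(coef[1])
    au = float(1.0 - norm.cdf(v - c))
    return au, None


def _multiscale_au(
    observed: Dendrogram,
    replicate_sim: Callable[[np.random.Generator, float], np.ndarray],
    n_boot: int,
    scales: Sequence[float],
    seed: int,
) -> list[ClusterSupport]:
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if len(scales) < 5 or min(scales) >= 1.0 or max(scales) <= 1.0:
        if tuple(scales) != (1.0,):
            warnings.warn(
                "scales should span both sides of 1.0 with >= 5 values for a "
                "stable AU fit", stacklevel=2
            )
    rng = np.random.default_rng(seed)
    label_index = {lab: i for i, lab in enumerate(observed.labels)}
    targets = [
        frozenset(label_index[lab] for lab in cl)
        for cl in observed.internal_clusters()
    ]
    counts = np.zeros((len(scales), len(targets)), dtype=np.int64)
    for si, r in enumerate(scales):
        for _ in range(n_boot):
            clusters = _replicate_clusters(replicate_sim(rng, r))
            for ti, t in enumerate(targets):
                if t in clusters:
                    counts[si, ti] += 1
    bps = counts / float(n_boot)

    supports: list[ClusterSupport] = []
    observed_label_sets = observed.internal_clusters()
    for ti, cl in enumerate(observed_label_sets):
        bp_by_scale = {float(r): float(bps[si, ti]) for si, r in enumerate(scales)}
        au, flag = _fit_au(list(scales), bps[:, ti], n_boot)
        supports.append(ClusterSupport(cl, bp_by_scale, au, n_boot, flag))
    return supports


def _dice_from_binary(x: np.ndarray) -> np.ndarray:
    """Dice similarity between rows of a binary (or multiplicity-weighted)
    indicator matrix; rows with no features get similarity 0 off-diagonal."""
    inter = x @ x.T
    sizes = x.sum(axis=1)
    denom = sizes[:, None] + sizes[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(denom > 0, 2.0 * inter / np.where(denom == 0, 1, denom), 0.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def binary_repertoire_matrix(
    repertoires: Mapping[str, Iterable[str]]
) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """(labels, phrase types, binary singer x phrase-type matrix)."""
    labels = tuple(repertoires.keys())
    sets = [frozenset(repertoires[lab]) for lab in labels]
    types = tuple(sorted(set().union(*sets))) if sets else ()
    x = np.zeros((len(labels), len(types)), dtype=float)
    tindex = {t: j for j, t in enumerate(types)}
    for i, s in enumerate(sets):
        for t in s:
            x[i, tindex[t]] = 1.0
    return labels, types, x


def au_support_dci(
    repertoires: Mapping[str, Iterable[str]],
    n_boot: int = 1000,
    scales: Sequence[float] = DEFAULT_SCALES,
    seed: int = 0,
) -> tuple[Dendrogram, list[ClusterSupport]]:
    """Single-linkage tree on DCI similarities with AU support per division.

    Phrase-type columns of the binary repertoire matrix are the resampling
    unit (round(r * m) columns with replacement per replicate).
    """
    from .similarity import dci_matrix

    labels, types, x = binary_repertoire_matrix(repertoires)
    observed = single_linkage(dci_matrix(repertoires))
    m = x.shape[1]

    def replicate(rng: np.random.Generator, r: float) -> np.ndarray:
        m_r = max(1, round(r * m))
        cols = rng.integers(0, m, size=m_r)
        return _dice_from_binary(x[:, cols])

    supports = _multiscale_au(observed, replicate, n_boot, scales, seed)
    return observed, supports


def au_support_lsi(
    songs_by_singer: Mapping[str, Sequence[Sequence[str]]],
    n_boot: int = 1000,
    scales: Sequence[float] = DEFAULT_SCALES,
    seed: int = 0,
) -> tuple[Dendrogram, list[ClusterSupport]]:
    """Single-linkage tree on LSI of set-median theme sequences with AU
    support per division.

    Each singer's song set is the resampling unit: round(r * k) songs (at
    least one) are drawn with replacement and the set median recomputed per
    replicate.
    """
    from .similarity import lsi_matrix

    labels = tuple(songs_by_singer.keys())
    song_lists = [
        [tuple(s) for s in songs_by_singer[lab]] for lab in labels
    ]
    for lab, sl in zip(labels, song_lists):
        if not sl:
            raise ValueError(f"singer {lab!r} has no songs")
    medians = {lab: set_median(sl) for lab, sl in zip(labels, song_lists)}
    observed = single_linkage(lsi_matrix(medians))
    n = len(labels)

    def replicate(rng: np.random.Generator, r: float) -> np.ndarray:
        meds = []
        for sl in song_lists:
            k = len(sl)
            k_r = max(1, round(r * k))
            sample = [sl[i] for i in rng.integers(0, k, size=k_r)]
            meds.append(set_median(sample))
        sim = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                sim[i, j] = sim[j, i] = lsi(meds[i], meds[j])
        return sim

    supports = _multiscale_au(observed, replicate, n_boot, scales, seed)
    return observed, supports


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

_SAFE_LABEL_RE = re.compile(r"^[A-Za-z0-9_.|-]+$")


def _newick_label(label: str) -> str:
    if _SAFE_LABEL_RE.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def export_newick(
    dendrogram: Dendrogram,
    supports: Optional[Sequence[ClusterSupport]] = None,
) -> str:
    """Newick string with branch lengths equal to merge-height differences
    and AU x 100 as internal-node labels when supports are supplied."""
    au_by_cluster: dict[frozenset[str], float] = {}
    if supports:
        for s in supports:
            if s.au is not None:
                au_by_cluster[s.cluster] = s.au * 100.0

    n = dendrogram.n_leaves
    heights = dendrogram.node_heights()
    leafsets = dendrogram.node_leafsets()
    children: dict[int, tuple[int, int]] = {
        n + k: (m.left, m.right) for k, m in enumerate(dendrogram.merges)
    }
    root = n + len(dendrogram.merges) - 1

    def render(node: int, parent_height: Optional[float]) -> str:
        if node < n:
            body = _newick_label(dendrogram.labels[node])
        else:
            left, right = children[node]
            h = heights[node]
            body = f"({render(left, h)},{render(right, h)})"
            cluster = frozenset(dendrogram.labels[i] for i in leafsets[node])
            if cluster in au_by_cluster:
                body += f"{au_by_cluster[cluster]:g}"
        if parent_height is None:
            return body
        return f"{body}:{max(0.0, parent_height - heights[node]):g}"

    return render(root, None) + ";"
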