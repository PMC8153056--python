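"""Spatio-temporal cluster-mass permutation statistics.

Mass-univariate t-maps over (channel, time) points are thresholded at a
two-tailed pointwise alpha, suprathreshold points are clustered by sensor
adjacency and temporal contiguity (split by t-value sign), each cluster is
scored by the sum of its t-values (the cluster mass), and family-wise
inference comes from a permutation null of the maximum absolute cluster
mass.  Paired designs permute by per-subject condition swaps (sign flips
of the difference maps); independent designs shuffle group labels.  When
the full permutation set is small enough it is enumerated exhaustively.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist

from .containers import Evoked, SensorLayout

#: permutation sets at most this large are enumerated exhaustively
EXHAUSTIVE_LIMIT = 2 ** 14

#: analysis windows (seconds post-R) used by the paradigm.  The R-locked
#: window ends at the first percentile of the short-delay R-to-sound
#: intervals (before 99% of anticipated tones); the omission-locked windows
#: cover 0-213 ms after the scheduled onset of the omitted sound.
WINDOWS_POST_R = {
    ("R_locked", "short"): (0.0, 0.229),
    ("R_locked", "long"): (0.0, 0.229),
    ("omission_locked", "short"): (0.287, 0.500),
    ("omission_locked", "long"): (0.587, 0.800),
}
OMISSION_WINDOW = (0.0, 0.213)


@dataclass
class AdjacencyGraph:
    """Symmetric, irreflexive channel neighborhood relation."""

    ch_names: list[str]
    neighbors: np.ndarray          # boolean n x n

    def __post_init__(self) -> None:
        self.neighbors = np.asarray(self.neighbors, dtype=bool)
        n = len(self.ch_names)
        if self.neighbors.shape != (n, n):
            raise ValueError("adjacency shape mismatch")
        if np.any(np.diag(self.neighbors)):
            raise ValueError("adjacency must be irreflexive")
        if not np.array_equal(self.neighbors, self.neighbors.T):
            raise ValueError("adjacency must be symmetric")

    @property
    def degrees(self) -> np.ndarray:
        return self.neighbors.sum(axis=1)


def build_adjacency(layout: SensorLayout, dist: float = 0.15) -> AdjacencyGraph:
    """Neighbors are channel pairs closer than ``dist`` in layout units."""
    d = np.linalg.norm(layout.pos[:, None] - layout.pos[None, :], axis=2)
    neigh = d < dist
    np.fill_diagonal(neigh, False)
    return AdjacencyGraph(list(layout.ch_names), neigh)


def condition_windows(analysis: str, condition: str,
                      relative_to_omission: bool = False) -> tuple[float, float]:
    """Analysis window in seconds for a (lock, delay-condition) pair."""
    if relative_to_omission:
        if analysis != "omission_locked":
            raise ValueError("omission-relative windows exist for omission_locked only")
        return OMISSION_WINDOW
    try:
        return WINDOWS_POST_R[(analysis, condition)]
    except KeyError:
        raise ValueError(f"unknown analysis/condition {(analysis, condition)!r}")


# ---------------------------------------------------------------------------
# pointwise statistics

def pointwise_t(condA: np.ndarray, condB: Optional[np.ndarray],
                design: str = "paired") -> tuple[np.ndarray, np.ndarray]:
    """Per-(channel, time) t statistic and two-tailed p.

    ``paired``: dependent-samples t on A - B (or a one-sample t on A alone
    when ``condB`` is None).  ``independent``: pooled-variance two-sample t.
    """
    condA = np.asarray(condA, dtype=float)
    if design == "paired":
        d = condA if condB is None else condA - np.asarray(condB, dtype=float)
        n = d.shape[0]
        if n < 2:
            raise ValueError("paired design needs at least 2 subjects")
        if condB is not None and np.asarray(condB).shape[0] != n:
            raise ValueError("paired design requires aligned subject counts")
        m = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = m / (sd / np.sqrt(n))
        t = np.where(np.isfinite(t), t, 0.0)
        df = n - 1
    elif design == "independent":
        condB = np.asarray(condB, dtype=float)
        na, nb = condA.shape[0], condB.shape[0]
        if min(na, nb) < 2:
            raise ValueError("need at least 2 subjects per group")
        va = condA.var(axis=0, ddof=1)
        vb = condB.var(axis=0, ddof=1)
        sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (condA.mean(axis=0) - condB.mean(axis=0)) / \
                np.sqrt(sp * (1 / na + 1 / nb))
        t = np.where(np.isfinite(t), t, 0.0)
        df = na + nb - 2
    else:
        raise ValueError(f"unknown design {design!r}")
    p = 2 * t_dist.sf(np.abs(t), df)
    return t, p


# ---------------------------------------------------------------------------
# clustering

@dataclass
class Cluster:
    channels: np.ndarray       # member channel indices
    times: np.ndarray          # member time indices (same length)
    polarity: int              # +1 / -1
    mass: float
    p: float = np.nan

    @property
    def members(self) -> list[tuple[int, int]]:
        return list(zip(self.channels.tolist(), self.times.tolist()))

    @property
    def n_channels(self) -> int:
        return len(np.unique(self.channels))

    @property
    def time_extent(self) -> int:
        return len(np.unique(self.times))


class _SpatioTemporalGraph:
    """Precomputed sparse adjacency over all (channel, time) nodes."""

    def __init__(self, adjacency: AdjacencyGraph, n_times: int):
        n_ch = len(adjacency.ch_names)
        self.n_ch, self.n_times = n_ch, n_times
        rows, cols = [], []
        ci, cj = np.nonzero(adjacency.neighbors)
        for t in range(n_times):
            base = t
            rows.append(ci * n_times + base)
            cols.append(cj * n_times + base)
        # temporal contiguity: consecutive samples within a channel
        node = np.arange(n_ch * n_times).reshape(n_ch, n_times)
        rows.append(node[:, :-1].ravel())
        cols.append(node[:, 1:].ravel())
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        n = n_ch * n_times
        self.graph = sparse.csr_matrix(
            (np.ones(rows.size + cols.size, dtype=np.int8),
             (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
            shape=(n, n))

    def components(self, mask_flat: np.ndarray) -> list[np.ndarray]:
        """Connected components of suprathreshold nodes (flat indices)."""
        idx = np.flatnonzero(mask_flat)
        if idx.size == 0:
            return []
        sub = self.graph[idx][:, idx]
        n_comp, labels = connected_components(sub, directed=False)
        return [idx[labels == c] for c in range(n_comp)]


def _clusters_from_mask(tmap: np.ndarray, mask: np.ndarray,
                        graph: _SpatioTemporalGraph, polarity: int,
                        min_channels: int, min_times: int) -> list[Cluster]:
    n_times = tmap.shape[1]
    out = []
    for comp in graph.components(mask.ravel()):
        ch = comp // n_times
        tt = comp % n_times
        if len(np.unique(tt)) < min_times or len(np.unique(ch)) < min_channels:
            continue
        out.append(Cluster(ch, tt, polarity, float(tmap[ch, tt].sum())))
    return out


def form_clusters(t_map: np.ndarray, p_map: np.ndarray,
                  adjacency: AdjacencyGraph, alpha: float = 0.05,
                  min_channels: int = 4, min_times: int = 2,
                  graph: Optional[_SpatioTemporalGraph] = None,
                  neighbor_rule: str = "extent") -> list[Cluster]:
    """Cluster suprathreshold points, split by polarity.

    Points with p < ``alpha`` are connected through sensor adjacency at the
    same sample and through temporal contiguity within a channel.  With the
    default ``neighbor_rule="extent"`` a cluster is kept only if it spans
    at least ``min_times`` samples and ``min_channels`` distinct channels.
    ``neighbor_rule="minnbchan"`` instead prunes, before clustering, every
    point whose channel has fewer than ``min_channels - 1`` suprathreshold
    neighboring channels at the same sample.
    """
    if t_map.shape != p_map.shape:
        raise ValueError("t and p maps must share a shape")
    if t_map.shape[0] != len(adjacency.ch_names):
        raise ValueError("adjacency does not cover the data channels")
    if graph is None:
        graph = _SpatioTemporalGraph(adjacency, t_map.shape[1])
    supra = p_map < alpha
    if neighbor_rule == "minnbchan":
        counts = adjacency.neighbors.astype(int) @ supra
        supra = supra & (counts >= min_channels - 1)
        min_ch_eff, min_t_eff = 1, min_times
    elif neighbor_rule == "extent":
        min_ch_eff, min_t_eff = min_channels, min_times
    else:
        raise ValueError(f"unknown neighbor_rule {neighbor_rule!r}")
    clusters = []
    for polarity in (1, -1):
        mask = supra & ((t_map > 0) if polarity > 0 else (t_map < 0))
        clusters.extend(_clusters_from_mask(
            t_map, mask, graph, polarity, min_ch_eff, min_t_eff))
    return sorted(clusters, key=lambda c: -abs(c.mass))


# ---------------------------------------------------------------------------
# permutation machinery

@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    t_map: np.ndarray
    p_map: np.ndarray
    n_perm: int
    method: str                 # "exhaustive" | "montecarlo"
    null_max: np.ndarray
    seed: Optional[int] = None

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]


def _paired_perm_tmaps(d_flat: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t-maps for sign-flip permutations of difference maps.

    ``d_flat``: subjects x points; ``signs``: perms x subjects (+/-1).
    The per-subject sum of squares is flip-invariant, so each permutation
    t-map needs only one matrix product.
    """
    n = d_flat.shape[0]
    ssq = (d_flat ** 2).sum(axis=0)
    m = signs @ d_flat / n
    var = (ssq - n * m ** 2) / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m / np.sqrt(var / n)
    return np.where(np.isfinite(t), t, 0.0)


def _max_cluster_mass(tmaps: np.ndarray, df: int, shape: tuple[int, int],
                      graph: _SpatioTemporalGraph, adjacency: AdjacencyGraph,
                      alpha: float, min_channels: int, min_times: int,
                      neighbor_rule: str) -> np.ndarray:
    tcrit = t_dist.ppf(1 - alpha / 2, df)
    out = np.zeros(tmaps.shape[0])
    for i, tm in enumerate(tmaps):
        tm = tm.reshape(shape)
        supra = np.abs(tm) > tcrit
        if neighbor_rule == "minnbchan":
            counts = adjacency.neighbors.astype(int) @ supra
            supra = supra & (counts >= min_channels - 1)
            mce, mte = 1, min_times
        else:
            mce, mte = min_channels, min_times
        best = 0.0
        for polarity in (1, -1):
            mask = supra & ((tm > 0) if polarity > 0 else (tm < 0))
            for cl in _clusters_from_mask(tm, mask, graph, polarity, mce, mte):
                best = max(best, abs(cl.mass))
        out[i] = best
    return out


def cluster_permutation_test(
    condA: np.ndarray,
    condB: Optional[np.ndarray],
    design: str,
    adjacency: AdjacencyGraph,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    min_channels: int = 4,
    min_times: int = 2,
    neighbor_rule: str = "extent",
    permutations: Optional[np.ndarray] = None,
) -> ClusterTestResult:
    """Cluster-mass permutation test on subjects x channels x time data.

    Paired designs exchange condition labels per subject (sign flips of the
    difference maps); independent designs shuffle group membership.  The
    null is the distribution of the maximum absolute cluster mass; each
    observed cluster's p is (b + 1)/(n_perm + 1) where b counts null maxima
    at least as large.  When the complete permutation set has at most
    2^14 elements it is enumerated instead (the identity permutation is
    then part of the null and the +1 correction is dropped).  An explicit
    ``permutations`` array (perms x subjects sign matrix for paired
    designs) is treated as an enumerated set.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives coarse p-values")
    condA = np.asarray(condA, dtype=float)
    shape = condA.shape[1:]
    t_obs, p_obs = pointwise_t(condA, condB, design)
    graph = _SpatioTemporalGraph(adjacency, shape[1])
    clusters = form_clusters(t_obs, p_obs, adjacency, alpha,
                             min_channels, min_times, graph, neighbor_rule)
    rng = np.random.default_rng(seed)

    if design == "paired":
        d = condA if condB is None else condA - np.asarray(condB, dtype=float)
        n = d.shape[0]
        d_flat = d.reshape(n, -1)
        df = n - 1
        if permutations is not None:
            signs = np.asarray(permutations, dtype=float)
            method = "exhaustive"
        elif 2 ** n <= EXHAUSTIVE_LIMIT:
            bits = np.arange(2 ** n)
            signs = 1.0 - 2.0 * ((bits[:, None] >> np.arange(n)) & 1)
            method = "exhaustive"
        else:
            signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
            method = "montecarlo"
        tmaps = _paired_perm_tmaps(d_flat, signs)
    elif design == "independent":
        condB = np.asarray(condB, dtype=float)
        na, nb = condA.shape[0], condB.shape[0]
        X = np.concatenate([condA, condB]).reshape(na + nb, -1)
        df = na + nb - 2
        total = math.comb(na + nb, na)
        if permutations is not None:
            groupings = np.asarray(permutations, dtype=bool)
            method = "exhaustive"
        elif total <= EXHAUSTIVE_LIMIT:
            groupings = np.zeros((total, na + nb), dtype=bool)
            for i, comb in enumerate(itertools.combinations(range(na + nb), na)):
                groupings[i, list(comb)] = True
            method = "exhaustive"
        else:
            groupings = np.zeros((n_perm, na + nb), dtype=bool)
            for i in range(n_perm):
                groupings[i, rng.permutation(na + nb)[:na]] = True
            method = "montecarlo"
        tmaps = np.empty((groupings.shape[0], X.shape[1]))
        for i, g in enumerate(groupings):
            tmaps[i] = pointwise_t(X[g].reshape(-1, *shape),
                                   X[~g].reshape(-1, *shape), "independent")[0].ravel()
    else:
        raise ValueError(f"unknown design {design!r}")

    null_max = _max_cluster_mass(tmaps, df, shape, graph, adjacency,
                                 alpha, min_channels, min_times, neighbor_rule)
    n_eff = null_max.size
    add = 0 if method == "exhaustive" else 1
    for cl in clusters:
        b = int(np.sum(null_max >= abs(cl.mass)))
        cl.p = (b + add) / (n_eff + add)
    return ClusterTestResult(clusters, t_obs, p_obs, n_eff, method,
                             null_max, seed)


# ---------------------------------------------------------------------------
# paradigm-level contrasts

@dataclass
class InteractionResult:
    interaction: ClusterTestResult
    simple_internal: Optional[ClusterTestResult]
    simple_external: Optional[ClusterTestResult]


def interaction_contrast(
    cells: np.ndarray,
    adjacency: AdjacencyGraph,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    run_simple_effects: Optional[bool] = None,
    **cluster_kw,
) -> InteractionResult:
    """Attention x delay double-subtraction interaction, plus simple effects.

    ``cells``: subjects x attention(internal, external) x delay(short, long)
    x channels x time.  The per-subject double difference
    (short - long)_internal - (short - long)_external is tested against
    zero with the paired machinery; if any interaction cluster is
    significant (or ``run_simple_effects=True``), short vs long is then
    tested separately within each attention level.
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 5 or cells.shape[1:3] != (2, 2):
        raise ValueError("cells must be subjects x 2 x 2 x channels x time")
    if not np.all(np.isfinite(cells)):
        raise ValueError("missing cell data")
    dd = (cells[:, 0, 0] - cells[:, 0, 1]) - (cells[:, 1, 0] - cells[:, 1, 1])
    inter = cluster_permutation_test(dd, None, "paired", adjacency,
                                     n_perm=n_perm, seed=seed, alpha=alpha,
                                     **cluster_kw)
    do_simple = (run_simple_effects if run_simple_effects is not None
                 else bool(inter.significant(alpha)))
    simple_int = simple_ext = None
    if do_simple:
        sseed = None if seed is None else seed + 1
        simple_int = cluster_permutation_test(
            cells[:, 0, 0], cells[:, 0, 1], "paired", adjacency,
            n_perm=n_perm, seed=sseed, alpha=alpha, **cluster_kw)
        simple_ext = cluster_permutation_test(
            cells[:, 1, 0], cells[:, 1, 1], "paired", adjacency,
            n_perm=n_perm, seed=None if seed is None else seed + 2,
            alpha=alpha, **cluster_kw)
    return InteractionResult(inter, simple_int, simple_ext)


def extract_cluster_mean(evoked: Evoked, members) -> float:
    """Mean voltage over a cluster's (channel, time) member points."""
    if isinstance(members, Cluster):
        ch, tt = members.channels, members.times
    else:
        pairs = list(members)
        if not pairs:
            raise ValueError("empty member set")
        ch = np.array([p[0] for p in pairs], dtype=int)
        tt = np.array([p[1] for p in pairs], dtype=int)
    if len(ch) == 0:
        raise ValueError("empty member set")
    if ch.max() >= evoked.data.shape[0] or tt.max() >= evoked.data.shape[1]:
        raise ValueError("member indices outside evoked dimensions")
    return float(evoked.data[ch, tt].mean())
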