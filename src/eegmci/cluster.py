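"""2-D cluster-based permutation statistics on channel x frequency and
channel x time grids.

The procedure: (1) a first-level two-sided t test at every grid cell
(pooled-variance two-sample t between groups, or a paired t on within-
subject differences); (2) cells with p below the first-level threshold
(default 0.01) are grouped into connected components of matching t sign
under edge connectivity — cells are neighbours when they share one grid
dimension and are adjacent in the other; (3) components smaller than the
minimum size (2 cells on channel-frequency grids, 20 on channel-time grids)
are discarded; each surviving cluster records its geometric ``size`` (cell
count) and statistical size ``tsize`` (sum of member t values); (4) a
max-statistic permutation null — relabelling participants, or randomly
sign-flipping pairs in the paired design, 1000 times by default — collects
the largest |tsize| per iteration; (5) a cluster is significant when its
|tsize| reaches the 95th percentile of that null distribution.  A cluster's
per-subject summary is the cluster-based aggregated (CBA) measure: the
unweighted mean of the subject's grid values over the cluster cells.

Channel adjacency defaults to consecutive rows in the fixed montage
ordering; an explicit channel-neighbourhood matrix may be supplied since
scalp channels have no canonical linear order.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "StatGrid", "Cluster", "NullDistribution", "ClusterAnalysis",
    "first_level", "form_clusters", "permutation_null", "assess_significance",
    "extract_cba", "cluster_analysis", "DEFAULT_MIN_SIZE",
]

DEFAULT_ALPHA = 0.01
DEFAULT_MIN_SIZE = {"channel_frequency": 2, "channel_time": 20}
SIGNIFICANCE_PERCENTILE = 95.0
_PLUS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class StatGrid:
    """First-level statistics over a channels x bins grid."""

    t: np.ndarray
    p: np.ndarray
    space: str                       # "channel_frequency" or "channel_time"
    design: str                      # "independent" or "paired"
    df: int

    def __post_init__(self) -> None:
        if self.t.shape != self.p.shape:
            raise ValueError("t and p grids must share a shape")
        if self.space not in DEFAULT_MIN_SIZE:
            raise ValueError("space must be 'channel_frequency' or 'channel_time'")


@dataclass
class Cluster:
    """A connected set of same-sign suprathreshold grid cells."""

    cells: np.ndarray                # (n_cells, 2) of (channel, bin) indices
    size: int
    tsize: float
    sign: int                        # +1 or -1
    space: str
    percentile: float | None = None
    significant: bool = False

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.cells[:, 0], self.cells[:, 1]] = True
        return m

    @property
    def channel_set(self) -> np.ndarray:
        return np.unique(self.cells[:, 0])

    @property
    def bin_window(self) -> tuple[int, int]:
        return int(self.cells[:, 1].min()), int(self.cells[:, 1].max())

    def to_dict(self) -> dict:
        return {
            "size": self.size, "tsize": self.tsize, "sign": self.sign,
            "space": self.space, "percentile": self.percentile,
            "significant": self.significant,
            "channels": self.channel_set.tolist(),
            "bin_window": list(self.bin_window),
            "cells": self.cells.tolist(),
        }


@dataclass
class NullDistribution:
    """Max-|tsize| permutation null; iterations with no cluster contribute 0."""

    max_tsizes: np.ndarray
    n_permutations: int
    seed: int | None
    exact: bool = False

    def __post_init__(self) -> None:
        if self.max_tsizes.size != self.n_permutations:
            raise ValueError("null length must equal the permutation count")


# ---------------------------------------------------------------------------
# first level
# ---------------------------------------------------------------------------


def _t_independent(x: np.ndarray, in_b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t (group B minus group A) per column.

    ``x`` is (n_subjects, n_cells); ``in_b`` is a boolean row mask, or a
    (n_perm, n_subjects) boolean matrix for batched permutations.
    """
    in_b = np.atleast_2d(in_b)
    n_b = in_b.sum(axis=1, keepdims=True).astype(float)
    n_a = in_b.shape[1] - n_b
    s = x.sum(axis=0)
    s2 = (x * x).sum(axis=0)
    sb = in_b @ x
    sb2 = in_b @ (x * x)
    mb = sb / n_b
    ma = (s - sb) / n_a
    ssb = sb2 - sb**2 / n_b
    ssa = (s2 - sb2) - (s - sb) ** 2 / n_a
    df = n_a + n_b - 2
    sp2 = (ssa + ssb) / df
    denom = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mb - ma) / denom
    return np.where(denom > 0, t, 0.0)


def _t_paired(d: np.ndarray, signs: np.ndarray | None = None) -> np.ndarray:
    """Paired t of within-subject differences vs 0, optionally sign-flipped.

    ``d`` is (n_pairs, n_cells); ``signs`` is (n_perm, n_pairs) of +-1.
    """
    n = d.shape[0]
    if signs is None:
        signs = np.ones((1, n))
    m = (signs @ d) / n
    v = ((signs**2) @ (d * d)) / n - m**2      # signs^2 == 1; E[x^2]-m^2
    sd = np.sqrt(v * n / (n - 1))
    denom = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / denom
    return np.where(denom > 0, t, 0.0)


def _as_matrix(grids: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    grids = np.asarray(grids, dtype=float)
    if grids.ndim != 3:
        raise ValueError("grids must be (n_subjects, n_channels, n_bins)")
    shape = grids.shape[1:]
    return grids.reshape(grids.shape[0], -1), shape


def first_level(grids: np.ndarray, labels: np.ndarray | None, design: str,
                space: str = "channel_frequency",
                groups: tuple[str, str] = ("HC", "MCI")) -> StatGrid:
    """Per-cell two-sided t map between groups (or of paired differences).

    Independent design: ``grids`` holds one grid per subject and ``labels``
    their group names; t is positive where the second group of ``groups``
    (the patient group by default) has the larger mean.  Paired design:
    ``grids`` holds within-subject difference grids and ``labels`` is
    ignored.  Zero-variance cells yield t = 0, p = 1 with a warning.
    """
    x, shape = _as_matrix(grids)
    if design == "independent":
        labels = np.asarray(labels)
        in_b = labels == groups[1]
        n_b, n_a = int(in_b.sum()), int((~in_b).sum())
        if n_a < 2 or n_b < 2:
            raise ValueError("need at least 2 subjects per group")
        t = _t_independent(x, in_b)[0]
        df = n_a + n_b - 2
    elif design == "paired":
        if x.shape[0] < 2:
            raise ValueError("need at least 2 pairs")
        t = _t_paired(x)[0]
        df = x.shape[0] - 1
    else:
        raise ValueError("design must be 'independent' or 'paired'")
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_var = np.std(x, axis=0) == 0
    if zero_var.any():
        warnings.warn("zero-variance cells set to t=0, p=1")
        p[zero_var] = 1.0
        t[zero_var] = 0.0
    return StatGrid(t.reshape(shape), p.reshape(shape), space, design, df)


# ---------------------------------------------------------------------------
# cluster formation
# ---------------------------------------------------------------------------


def _components_chain(mask: np.ndarray) -> list[np.ndarray]:
    """Connected components under 4-neighbour (edge) adjacency."""
    labeled, n = ndimage.label(mask, structure=_PLUS)
    return [np.argwhere(labeled == k) for k in range(1, n + 1)]


def _components_graph(mask: np.ndarray, channel_adjacency: np.ndarray,
                      ) -> list[np.ndarray]:
    """Connected components with an arbitrary channel-neighbour matrix.

    Cells are neighbours when identical in one dimension and adjacent in the
    other — bin adjacency is +-1, channel adjacency comes from the matrix.
    """
    cells = np.argwhere(mask)
    if cells.size == 0:
        return []
    index = -np.ones(mask.shape, dtype=int)
    index[cells[:, 0], cells[:, 1]] = np.arange(len(cells))
    parent = np.arange(len(cells))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    n_ch, n_bins = mask.shape
    for k, (c, b) in enumerate(cells):
        if b + 1 < n_bins and index[c, b + 1] >= 0:
            union(k, index[c, b + 1])
        for c2 in np.where(channel_adjacency[c])[0]:
            if index[c2, b] >= 0:
                union(k, index[c2, b])
    roots = np.array([find(k) for k in range(len(cells))])
    return [cells[roots == r] for r in np.unique(roots)]


def form_clusters(stat_grid: StatGrid, alpha: float = DEFAULT_ALPHA,
                  min_size: int | None = None,
                  channel_adjacency: np.ndarray | None = None,
                  ) -> list[Cluster]:
    """Group same-sign suprathreshold cells into clusters and drop those
    below the minimum size.  An empty list is a valid outcome."""
    if min_size is None:
        min_size = DEFAULT_MIN_SIZE[stat_grid.space]
    supra = stat_grid.p < alpha
    clusters: list[Cluster] = []
    for sign in (+1, -1):
        mask = supra & ((stat_grid.t > 0) if sign > 0 else (stat_grid.t < 0))
        comps = (_components_chain(mask) if channel_adjacency is None
                 else _components_graph(mask, channel_adjacency))
        for cells in comps:
            if len(cells) < min_size:
                continue
            tsize = float(stat_grid.t[cells[:, 0], cells[:, 1]].sum())
            clusters.append(Cluster(cells=cells, size=len(cells), tsize=tsize,
                                    sign=sign, space=stat_grid.space))
    clusters.sort(key=lambda c: -abs(c.tsize))
    return clusters


def _max_tsize(t_map: np.ndarray, t_crit: float, min_size: int,
               channel_adjacency: np.ndarray | None) -> float:
    """Largest |tsize| among clusters of one permuted t map (0 when none)."""
    best = 0.0
    for sign in (+1, -1):
        mask = (t_map > t_crit) if sign > 0 else (t_map < -t_crit)
        if not mask.any():
            continue
        if channel_adjacency is None:
            labeled, n = ndimage.label(mask, structure=_PLUS)
            if n == 0:
                continue
            sizes = ndimage.sum_labels(np.ones_like(t_map), labeled,
                                       index=np.arange(1, n + 1))
            tsums = ndimage.sum_labels(t_map, labeled,
                                       index=np.arange(1, n + 1))
            ok = sizes >= min_size
            if ok.any():
                best = max(best, float(np.abs(tsums[ok]).max()))
        else:
            for cells in _components_graph(mask, channel_adjacency):
                if len(cells) >= min_size:
                    best = max(best, abs(float(
                        t_map[cells[:, 0], cells[:, 1]].sum())))
    return best


def permutation_null(grids: np.ndarray, labels: np.ndarray | None, design: str,
                     space: str = "channel_frequency",
                     alpha: float = DEFAULT_ALPHA, min_size: int | None = None,
                     n_perm: int = 1000, seed: int = 0,
                     channel_adjacency: np.ndarray | None = None,
                     exact: bool | None = None) -> NullDistribution:
    """Max-statistic null distribution of the cluster procedure.

    Each iteration relabels participants (independent design, preserving
    group sizes) or flips each pair's sign (paired design), recomputes the
    first level and cluster formation with identical parameters, and records
    the largest |tsize| (0 when no cluster forms).  For 10 or fewer
    subjects/pairs the full assignment set is enumerated instead (with a
    warning), since so few units admit only a handful of distinct shuffles.
    """
    x, shape = _as_matrix(grids)
    n = x.shape[0]
    if min_size is None:
        min_size = DEFAULT_MIN_SIZE[space]
    if design == "independent":
        labels = np.asarray(labels)
        groups = np.unique(labels)
        if groups.size != 2:
            raise ValueError("independent design requires exactly 2 groups")
        n_b = int((labels == groups[1]).sum())
        df = n - 2
    elif design == "paired":
        df = n - 1
    else:
        raise ValueError("design must be 'independent' or 'paired'")
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    if exact is None:
        exact = n <= 10
        if exact:
            warnings.warn(
                f"only {n} subjects: using exact enumeration of assignments")
    rng = np.random.default_rng(seed)
    if design == "independent":
        if exact:
            combos = list(itertools.combinations(range(n), n_b))
            masks = np.zeros((len(combos), n), dtype=float)
            for i, combo in enumerate(combos):
                masks[i, list(combo)] = 1.0
        else:
            masks = np.zeros((n_perm, n), dtype=float)
            for i in range(n_perm):
                masks[i, rng.permutation(n)[:n_b]] = 1.0
        t_maps = _t_independent(x, masks.astype(bool))
    else:
        if exact:
            signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        else:
            signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        t_maps = _t_paired(x, signs)
    maxes = np.array([
        _max_tsize(t_maps[i].reshape(shape), t_crit, min_size,
                   channel_adjacency)
        for i in range(t_maps.shape[0])
    ])
    return NullDistribution(maxes, maxes.size, seed, exact=exact)


def assess_significance(clusters: list[Cluster], null: NullDistribution,
                        ) -> list[Cluster]:
    """Attach each cluster's percentile in the max-|tsize| null and the
    95th-percentile significance verdict.

    The percentile is the fraction of null values less than or equal to the
    cluster's |tsize| (ties count as below)."""
    if null.max_tsizes.size == 0:
        raise ValueError("empty null distribution")
    out = []
    for c in clusters:
        pct = float(100.0 * np.count_nonzero(
            null.max_tsizes <= abs(c.tsize)) / null.max_tsizes.size)
        out.append(replace(c, percentile=pct,
                           significant=bool(pct >= SIGNIFICANCE_PERCENTILE)))
    return out


def extract_cba(subject_grid: np.ndarray, cluster: Cluster) -> float:
    """Cluster-based aggregated measure: the unweighted mean of one
    subject's grid values over the cluster's cells."""
    if cluster.size == 0:
        raise ValueError("empty cluster")
    subject_grid = np.asarray(subject_grid)
    return float(subject_grid[cluster.cells[:, 0], cluster.cells[:, 1]].mean())


# ---------------------------------------------------------------------------
# one-call analysis
# ---------------------------------------------------------------------------


@dataclass
class ClusterAnalysis:
    """Full cluster-permutation analysis of one modality."""

    stat_grid: StatGrid
    clusters: list[Cluster]
    null: NullDistribution
    grids: np.ndarray = field(repr=False)
    labels: np.ndarray | None = field(default=None, repr=False)

    def cba(self, cluster: Cluster) -> np.ndarray:
        """Per-subject CBA values for one cluster."""
        return np.array([extract_cba(g, cluster) for g in self.grids])

    def top_clusters(self, k: int) -> list[Cluster]:
        """Best k clusters: significant ones first, then by percentile and
        |tsize| (the fallback selection when nothing reaches significance)."""
        ranked = sorted(self.clusters,
                        key=lambda c: (-int(c.significant),
                                       -(c.percentile or 0.0),
                                       -abs(c.tsize)))
        return ranked[:k]


def cluster_analysis(grids: np.ndarray, labels: np.ndarray | None, design: str,
                     space: str, alpha: float = DEFAULT_ALPHA,
                     min_size: int | None = None, n_perm: int = 1000,
                     seed: int = 0,
                     channel_adjacency: np.ndarray | None = None,
                     ) -> ClusterAnalysis:
    """First level -> clusters -> permutation null -> significance."""
    grid = first_level(grids, labels, design, space)
    clusters = form_clusters(grid, alpha, min_size, channel_adjacency)
    null = permutation_null(grids, labels, design, space, alpha, min_size,
                            n_perm, seed, channel_adjacency)
    clusters = assess_significance(clusters, null)
    return ClusterAnalysis(grid, clusters, null, np.asarray(grids), labels)
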