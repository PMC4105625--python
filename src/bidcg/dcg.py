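"""DCG-tree clustering: regulated random walks on a temperature-scanned
potential graph, cluster counts over a temperature grid, critical
temperatures, and the nested ultrametric tree.

The empirical distance matrix is turned into a weighted graph with edge
weight exp(-d(i,j)/T). At high temperature a Markov walk moves freely; at
low temperature it is trapped in potential wells. A *regulated* walk retires
each node after a fixed number of visits, so the order in which nodes are
retired — and the spikes in the time between retirements — reveal the wells
(clusters) at that temperature. Repeated walks are aggregated into a
co-occurrence (ensemble) matrix, from which the cluster count K(T) and the
memberships are read off. Plateaus of K(T) mark critical temperatures,
which become the merge heights of the ultrametric DCG-tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from ._walk import walk_kernel
from .core import Partition
from .distances import DistanceMatrix

__all__ = [
    "DCGConfig",
    "TemperatureGrid",
    "WalkRecord",
    "EnsembleMatrix",
    "ClusterCountProfile",
    "DCGTree",
    "build_transition_matrix",
    "make_temperature_grid",
    "regulated_random_walk",
    "segment_walk",
    "ensemble_from_walks",
    "estimate_cluster_count",
    "scan_temperatures",
    "find_critical_temperatures",
    "build_dcg_tree",
    "ultrametric_distance",
    "tree_to_newick",
]


@dataclass(frozen=True)
class DCGConfig:
    """Tunables of the DCG-tree build.

    Temperatures form a geometric grid of `n_temps` values between
    f_low * q_low-quantile and f_high * q_high-quantile of the positive
    off-diagonal distances. At each temperature `walks_per_temp` regulated
    walks (node retired after `removal_threshold` visits) are aggregated
    into a co-occurrence matrix; edges with co-occurrence >= theta define
    the clusters. K(T) is median-smoothed over 3 points and plateaus
    shorter than `min_plateau_len` grid points are ignored.

    The potential on edge (i, j) is d(i,j)**kernel_power, so the default
    transition weight is the heat kernel exp(-d^2/T); kernel_power=1 gives
    the plain exponential kernel. Temperatures (and hence tree heights) are
    in units of the transformed distance.
    """

    n_temps: int = 15
    kernel_power: float = 2.0
    f_low: float = 0.1
    f_high: float = 2.0
    q_low: float = 0.05
    q_high: float = 0.95
    walks_per_temp: int = 40
    removal_threshold: int = 5
    theta: float = 0.45
    silhouette_floor: float = 0.1
    min_plateau_len: int = 1
    min_block_size: int = 1
    seed: int = 0


@dataclass(frozen=True)
class TemperatureGrid:
    temperatures: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        object.__setattr__(self, "temperatures", t)
        if t.size < 2:
            raise ValueError("temperature grid needs at least 2 values")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be positive and strictly increasing")

    def __len__(self) -> int:
        return self.temperatures.size


@dataclass(frozen=True)
class WalkRecord:
    """One regulated walk: node removal order and inter-removal step counts."""

    removal_order: np.ndarray  # int indices, permutation of range(n)
    recurrence_times: np.ndarray
    temperature: float
    removal_threshold: int = 5

    @property
    def n(self) -> int:
        return self.removal_order.size


@dataclass(frozen=True)
class EnsembleMatrix:
    """Co-occurrence fractions over repeated walks at one temperature."""

    items: tuple
    co_occurrence: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.co_occurrence, dtype=float)
        object.__setattr__(self, "co_occurrence", c)
        if c.shape != (len(self.items), len(self.items)):
            raise ValueError("co-occurrence shape mismatch")
        if np.any(c < -1e-9) or np.any(c > 1 + 1e-9):
            raise ValueError("co-occurrence entries must lie in [0, 1]")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("co-occurrence diagonal must be 1")


@dataclass(frozen=True)
class ClusterCountProfile:
    temperatures: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        k = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "counts", k)
        if t.size != k.size:
            raise ValueError("profile lengths differ")
        if np.any(np.diff(t) <= 0):
            raise ValueError("profile temperatures must increase")
        if np.any(k < 1):
            raise ValueError("cluster counts must be >= 1")

    @property
    def points(self) -> list[tuple[float, int]]:
        return list(zip(self.temperatures.tolist(), self.counts.tolist()))


@dataclass
class DCGTree:
    """Nested partitions (finest -> coarsest) at increasing merge heights."""

    items: list[str]
    levels: list[Partition]
    level_heights: list[float]

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.level_heights):
            raise ValueError("one height per level required")
        if len(self.levels) == 0:
            raise ValueError("tree needs at least one level")
        h = np.asarray(self.level_heights, dtype=float)
        if np.any(h <= 0) or np.any(np.diff(h) <= 0):
            raise ValueError("level heights must be positive and strictly increasing")
        item_set = set(self.items)
        for p in self.levels:
            if set(p.items) != item_set:
                raise ValueError("level item set mismatch")
        # nestedness: every block at level l is inside one block at level l+1
        for fine, coarse in zip(self.levels, self.levels[1:]):
            for b in fine.blocks:
                if not any(b <= c for c in coarse.blocks):
                    raise ValueError("levels are not nested")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_blocks(self) -> list[frozenset]:
        """All distinct blocks across all levels, finest level first."""
        seen: list[frozenset] = []
        for p in self.levels:
            for b in sorted(p.blocks, key=lambda s: (-len(s), sorted(s))):
                if b not in seen:
                    seen.append(b)
        return seen


# ---------------------------------------------------------------------------


def _potential_weights(d: np.ndarray, t: float,
                       kernel_power: float = 2.0) -> np.ndarray:
    """Edge weights exp(-d(i,j)**kernel_power / t), row-stabilized.

    Each row's off-diagonal minimum potential is subtracted inside the
    exponent; the factor cancels under row normalization but keeps the
    nearest neighbour's weight at 1, so low temperatures freeze the walk
    onto its local well instead of underflowing to zero mass.
    """
    n = d.shape[0]
    pot = d ** kernel_power if kernel_power != 1.0 else d.copy()
    off = pot + np.diag(np.full(n, np.inf))
    rowmin = off.min(axis=1)
    np.fill_diagonal(pot, rowmin)  # keeps the exponent bounded on the diagonal
    W = np.exp(-(pot - rowmin[:, None]) / t)
    np.fill_diagonal(W, 0.0)
    return W


def build_transition_matrix(d: DistanceMatrix, t: float,
                            kernel_power: float = 2.0) -> np.ndarray:
    """Row-stochastic transition matrix, P(i -> j) ∝ exp(-d(i,j)^p / t)."""
    if t <= 0:
        raise ValueError("temperature must be positive")
    if len(d) < 2:
        raise ValueError("need at least 2 items")
    W = _potential_weights(d.values, t, kernel_power)
    row = W.sum(axis=1)
    return W / row[:, None]


def make_temperature_grid(d: DistanceMatrix, n_temps: int = 15,
                          f_low: float = 0.1, f_high: float = 2.0,
                          q_low: float = 0.05, q_high: float = 0.95,
                          kernel_power: float = 2.0) -> TemperatureGrid:
    """Geometric grid spanning scaled quantiles of the positive potentials
    (distances raised to kernel_power)."""
    if n_temps < 2:
        raise ValueError("n_temps must be >= 2")
    off = d.values[np.triu_indices(len(d), k=1)] ** kernel_power
    pos = off[off > 0]
    if pos.size == 0:
        raise ValueError("all distances are zero: degenerate data cloud")
    lo = f_low * float(np.quantile(pos, q_low))
    hi = f_high * float(np.quantile(pos, q_high))
    if lo <= 0:
        lo = f_low * float(pos.min())
    if hi <= lo:
        hi = lo * 10.0
    return TemperatureGrid(np.geomspace(lo, hi, n_temps))


def regulated_random_walk(p: np.ndarray, removal_threshold: int,
                          rng_seed: int, temperature: float = 1.0) -> WalkRecord:
    """Run one regulated walk on a weight (or transition) matrix.

    The walk retires a node once it has accumulated `removal_threshold`
    visits; recurrence times are the step counts between retirements.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1] or p.shape[0] < 2:
        raise ValueError("need a square matrix over >= 2 nodes")
    if removal_threshold < 1:
        raise ValueError("removal_threshold must be >= 1")
    order, rec = walk_kernel(np.ascontiguousarray(p), int(removal_threshold),
                             int(rng_seed) % 2**31)
    return WalkRecord(order, rec, float(temperature), int(removal_threshold))


SPIKE_MEAN_RATIO = 3.0


def _spike_threshold(rt: np.ndarray) -> float | None:
    """Two-group split of the recurrence times by minimising within-group
    variance (1-D Otsu), restricted so the spike group is the minority.
    Returns the spike cutoff, or None when the groups are not separated by
    at least SPIKE_MEAN_RATIO in their means (a free, unimodal walk)."""
    n = rt.size
    srt = np.sort(rt)
    c1 = np.cumsum(srt)
    c2 = np.cumsum(srt**2)
    best, best_i = np.inf, None
    for i in range(max(n // 2, 1), n):  # bottom group gets >= half the values
        n_lo, n_hi = i, n - i
        s_lo, s_hi = c1[i - 1], c1[-1] - c1[i - 1]
        v_lo = c2[i - 1] - s_lo**2 / n_lo
        v_hi = (c2[-1] - c2[i - 1]) - s_hi**2 / n_hi
        if v_lo + v_hi < best:
            best, best_i = v_lo + v_hi, i
    if best_i is None or best_i == n:
        return None
    mean_lo = c1[best_i - 1] / best_i
    mean_hi = (c1[-1] - c1[best_i - 1]) / (n - best_i)
    if mean_hi < SPIKE_MEAN_RATIO * max(mean_lo, 1.0):
        return None
    return float(srt[best_i])


_NULL_QUANTILE = 0.995
_null_cache: dict[tuple[int, int], np.ndarray] = {}


def _null_recurrence_profile(n: int, removal_threshold: int) -> np.ndarray:
    """Per-position recurrence-time quantiles of the structureless walk.

    Simulated once per (n, removal_threshold) on the uniform-weight graph
    (fixed internal seed, cached): the free walk's recurrence times depend
    strongly on removal position (the first removals carry the
    coupon-collector warm-up), so spike detection must be position-matched.
    """
    key = (n, removal_threshold)
    if key not in _null_cache:
        W = np.ones((n, n))
        np.fill_diagonal(W, 0.0)
        seeds = np.random.SeedSequence(771177).generate_state(200) % 2**31
        rts = np.empty((200, n))
        for k, s in enumerate(seeds):
            _, rec = walk_kernel(W, removal_threshold, int(s))
            rts[k] = rec
        _null_cache[key] = np.quantile(rts, _NULL_QUANTILE, axis=0)
    return _null_cache[key]


def segment_walk(w: WalkRecord) -> np.ndarray:
    """Segment labels per node from recurrence-time spikes.

    Entering a fresh potential well is slow (the first removal there needs
    `removal_threshold` fresh visits) while removals inside an occupied
    well come quickly, so trapping by cluster structure shows up as
    recurrence times far above what a free (structureless) walk would
    produce. The removal order is cut before every removal whose recurrence
    time exceeds the free-walk null's position-matched 99.5% quantile, and
    additionally before removals in the spike group of a two-group variance
    split when the walk's recurrence times are clearly bimodal. The first
    removal never opens a new segment: its recurrence time is warm-up, not
    an escape.
    """
    rt = w.recurrence_times.astype(float)
    n = rt.size
    labels = np.empty(w.n, dtype=np.int64)
    if n < 2:
        labels[:] = 0
        return labels
    thr = _spike_threshold(rt[1:])
    cut = np.zeros(n, dtype=bool) if thr is None else rt >= thr
    cut[0] = False
    seg_of_rank = np.cumsum(cut)
    labels[w.removal_order] = seg_of_rank
    return labels


def ensemble_from_walks(walks: list[WalkRecord],
                        d: DistanceMatrix | None = None,
                        items: tuple | None = None) -> EnsembleMatrix:
    """Co-occurrence fractions: how often each pair shares a walk segment."""
    if not walks:
        raise ValueError("need at least one walk")
    n = walks[0].n
    if any(w.n != n for w in walks):
        raise ValueError("inconsistent node sets across walks")
    if items is None:
        items = tuple(d.items) if d is not None else tuple(range(n))
    if len(items) != n:
        raise ValueError("item labels do not match walk size")
    co = np.zeros((n, n), dtype=float)
    for w in walks:
        lab = segment_walk(w)
        co += lab[:, None] == lab[None, :]
    co /= len(walks)
    np.fill_diagonal(co, 1.0)
    return EnsembleMatrix(items, co)


SPLIT_GAP_RATIO = 1.5
SILHOUETTE_FLOOR = 0.1
MAX_CANDIDATE_K = 20


def estimate_cluster_count(e: EnsembleMatrix, theta: float = 0.45,
                           d: DistanceMatrix | None = None,
                           silhouette_floor: float = 0.1) -> int:
    """Cluster count from the co-occurrence matrix.

    The co-occurrence dissimilarities (1 - co) are merged by average
    linkage, giving a family of candidate flat clusterings (one per merge
    whose height is at least 1 - theta: clusters must disagree in at least
    that fraction of walks). When the original distances are supplied, the
    candidate with the highest silhouette on them is selected, and K = 1 is
    returned when no candidate reaches a minimal silhouette — a walk with
    no structure at this temperature dilutes co-occurrence uniformly.
    Without distances the tree is cut at the largest relative gap between
    consecutive merge heights. Average linkage keeps both readouts robust
    to isolated borderline edges between well-separated groups.
    """
    return int(_components(e, theta, None if d is None else d.values,
                           silhouette_floor)[0])


def _components(e: EnsembleMatrix, theta: float,
                dvals: np.ndarray | None = None,
                silhouette_floor: float = SILHOUETTE_FLOOR) -> tuple[int, np.ndarray]:
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform as _sqf

    n = e.co_occurrence.shape[0]
    dis = 1.0 - e.co_occurrence
    np.fill_diagonal(dis, 0.0)
    dis = np.clip((dis + dis.T) / 2.0, 0.0, None)
    Z = linkage(_sqf(dis, checks=False), method="average")
    h = Z[:, 2]
    cut_positions = [m for m in range(n - 1) if h[m] >= 1.0 - theta]
    one = np.zeros(n, dtype=np.int64)
    if not cut_positions:
        return 1, one
    if dvals is not None:
        from scipy.cluster.hierarchy import cut_tree

        # candidate cluster counts: bounded below n/2 (frozen-regime
        # fragmentation is never a level) and above by a practical ceiling
        ks = [n - m for m in cut_positions
              if 2 <= n - m <= min(max(n // 2, 1), MAX_CANDIDATE_K)]
        if not ks:
            return 1, one
        cuts = cut_tree(Z, n_clusters=ks)  # one pass for every candidate
        best_fit, best_lab = -np.inf, None
        seen: set[bytes] = set()
        for col in range(cuts.shape[1]):
            lab = cuts[:, col].astype(np.int64)
            # silhouette rewards shaving off singletons; absorb runts into
            # their highest-affinity sibling before scoring
            lab = _absorb_runts(lab, e.co_occurrence, 2)
            key = lab.tobytes()
            if key in seen:
                continue
            seen.add(key)
            # structure gate on the original distances: a free walk's
            # random cuts must not read as clusters
            if level_silhouette(dvals, lab) <= silhouette_floor:
                continue
            # selection by fit to this temperature's walk evidence, so a
            # better-separated coarse reading cannot shadow genuine fine
            # structure at a low temperature
            fit = level_silhouette(dis, lab)
            if fit > best_fit:
                best_fit, best_lab = fit, lab
        if best_lab is None:
            return 1, one
        # outliers removed in walk tails can co-occur into phantom groups
        # the linkage tree cannot undo; polish memberships by nearest mean
        # distance
        best_lab = _polish_membership(best_lab, dvals)
        return int(best_lab.max() + 1), best_lab
    best_gap, best_m = SPLIT_GAP_RATIO, None
    for m in cut_positions:
        lower = h[m - 1] if m > 0 else 0.0
        gap = h[m] / max(lower, 0.05)
        if gap > best_gap:
            best_gap, best_m = gap, m
    if best_m is None:
        return 1, one
    labels = fcluster(Z, t=n - best_m, criterion="maxclust") - 1
    return int(labels.max() + 1), labels.astype(np.int64)


def scan_temperatures(
    d: DistanceMatrix,
    grid: TemperatureGrid,
    walks_per_temp: int = 40,
    removal_threshold: int = 5,
    rng_seed: int = 0,
    kernel_power: float = 2.0,
    silhouette_floor: float = 0.1,
) -> tuple[ClusterCountProfile, list[EnsembleMatrix]]:
    """K(T) profile and per-temperature ensemble, deterministic in rng_seed."""
    if walks_per_temp < 1:
        raise ValueError("walks_per_temp must be >= 1")
    n_t = len(grid)
    child = np.random.SeedSequence(rng_seed).generate_state(n_t * walks_per_temp)
    seeds = (child % 2**31).reshape(n_t, walks_per_temp)
    counts = np.empty(n_t, dtype=int)
    ensembles: list[EnsembleMatrix] = []
    for ti, t in enumerate(grid.temperatures):
        W = _potential_weights(d.values, t, kernel_power)
        walks = [
            regulated_random_walk(W, removal_threshold, int(seeds[ti, k]), t)
            for k in range(walks_per_temp)
        ]
        e = ensemble_from_walks(walks, d)
        ensembles.append(e)
        counts[ti] = estimate_cluster_count(e, d=d,
                                            silhouette_floor=silhouette_floor)
    return ClusterCountProfile(grid.temperatures, counts), ensembles


def _plateau_runs(profile: ClusterCountProfile,
                  min_plateau_len: int = 2) -> list[tuple[int, int]]:
    """Maximal runs (start index, length) of the 3-point-median-smoothed
    K(T), dropping runs shorter than min_plateau_len (falling back to the
    longest run when nothing qualifies)."""
    k_s = _median3(profile.counts)
    runs: list[tuple[int, int]] = []
    start = 0
    for i in range(1, k_s.size + 1):
        if i == k_s.size or k_s[i] != k_s[start]:
            runs.append((start, i - start))
            start = i
    kept = [r for r in runs if r[1] >= min_plateau_len]
    if not kept:
        kept = [max(runs, key=lambda r: r[1])]
    return kept


def find_critical_temperatures(profile: ClusterCountProfile,
                               min_plateau_len: int = 2) -> list[float]:
    """First temperature of each retained plateau of the smoothed K(T)."""
    if profile.temperatures.size < 2:
        raise ValueError("profile needs at least 2 points")
    return [float(profile.temperatures[s])
            for s, _ in _plateau_runs(profile, min_plateau_len)]


def _median3(k: np.ndarray) -> np.ndarray:
    if k.size < 3:
        return k.copy()
    out = k.copy()
    for i in range(1, k.size - 1):
        out[i] = np.median(k[i - 1 : i + 2])
    return out


def build_dcg_tree(d: DistanceMatrix, config: DCGConfig | None = None) -> DCGTree:
    """Full pipeline: temperature scan -> critical temperatures -> nested
    ultrametric tree with critical temperatures as merge heights.

    Candidate levels (one per plateau of K(T)) are screened by silhouette,
    deduplicated, and reconciled finest-first: the finest level is kept
    verbatim and each coarser level is rebuilt as a majority-vote grouping
    of the finer blocks, realizing the self-correcting membership across
    levels while guaranteeing nestedness.
    """
    cfg = config or DCGConfig()
    if len(d) < 2:
        raise ValueError("need at least 2 items")
    grid = make_temperature_grid(d, cfg.n_temps, cfg.f_low, cfg.f_high,
                                 cfg.q_low, cfg.q_high, cfg.kernel_power)
    profile, ensembles = scan_temperatures(
        d, grid, cfg.walks_per_temp, cfg.removal_threshold, cfg.seed,
        cfg.kernel_power, cfg.silhouette_floor,
    )
    runs = _plateau_runs(profile, cfg.min_plateau_len)
    items = list(d.items)
    n = len(items)
    # membership per plateau from the plateau-averaged ensemble (more stable
    # than any single grid point); the critical temperature itself is the
    # plateau onset
    raw: list[tuple[float, np.ndarray, np.ndarray]] = []
    for start, length in runs:
        co = np.mean([ensembles[i].co_occurrence
                      for i in range(start, start + length)], axis=0)
        e = EnsembleMatrix(tuple(items), co)
        _, labels = _components(e, cfg.theta, d.values, cfg.silhouette_floor)
        raw.append((float(grid.temperatures[start]), labels, co))
    # frozen-regime fragmentation (more blocks than half the items) is
    # walk freezing, not structure
    cand = [x for x in raw if x[1].max() + 1 <= max(n // 2, 1)] or [raw[-1]]
    cand = _filter_levels(cand, d.values)
    cand = _dedup_levels(cand, d.values)
    # keep a chain of strictly increasing K moving from the coarsest
    # (highest-temperature) plateau downwards
    kept: list[tuple[float, np.ndarray, np.ndarray]] = []
    for tc, labels, co in reversed(cand):  # high T -> low T
        k = labels.max() + 1
        if not kept or k > kept[-1][1].max() + 1:
            kept.append((tc, labels, co))
    kept.reverse()  # back to fine -> coarse
    # reconcile finest-first: the finest level is kept verbatim and every
    # coarser level is rebuilt as a grouping of the finer blocks by
    # majority membership. Fine-scale evidence thereby corrects stray
    # assignments made at coarser temperatures (the self-correction of
    # memberships across tree levels), and nestedness holds by
    # construction.
    nested_labels: list[np.ndarray] = []
    current = kept[0][1]
    nested_labels.append(current)
    for tc, labels, co in kept[1:]:  # fine -> coarse
        current = _coarsen_by_majority(current, labels)
        nested_labels.append(current)
    levels: list[Partition] = []
    heights: list[float] = []
    prev_labels: np.ndarray | None = None
    for (tc, _, _), lab in zip(kept, nested_labels):
        if prev_labels is not None and _same_partition(prev_labels, lab):
            continue
        levels.append(Partition.from_labels(items, lab.tolist()))
        heights.append(tc)
        prev_labels = lab
    if len(levels[-1]) > 1:
        # closing root level so every pair has a finite ultrametric height
        levels.append(Partition(items, [frozenset(items)]))
        heights.append(max(heights[-1] * 2.0, float(grid.temperatures[-1]) * 2.0))
    return DCGTree(items, levels, heights)


def level_silhouette(dvals: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette of a flat labelling on a precomputed distance matrix
    (singleton clusters contribute 0); -inf when undefined (fewer than 2 or
    more than n-1 clusters)."""
    n = dvals.shape[0]
    labels = np.asarray(labels)
    ids, inv, counts = np.unique(labels, return_inverse=True, return_counts=True)
    k = ids.size
    if not 2 <= k <= n - 1:
        return -np.inf
    H = np.zeros((n, k))
    H[np.arange(n), inv] = 1.0
    S = dvals @ H  # per-item sums of distances to each cluster
    own = counts[inv] - 1
    a = np.where(own > 0, S[np.arange(n), inv] / np.maximum(own, 1), 0.0)
    mean_other = S / counts[None, :]
    mean_other[np.arange(n), inv] = np.inf
    b = mean_other.min(axis=1)
    denom = np.maximum(np.maximum(a, b), 1e-300)
    sil = np.where(own > 0, (b - a) / denom, 0.0)
    return float(sil.mean())


def _filter_levels(kept, dvals: np.ndarray):
    """Discard badly-separated candidate levels.

    Two artefacts can masquerade as plateaus of K(T): nearest-neighbour
    freezing at temperatures below the data's mixing scale (spuriously fine
    levels) and Monte-Carlo blips (spuriously coarse intermediate levels).
    Both separate their blocks far worse than the real structure, so any
    level whose silhouette on the original distances is under 80% of
    the best level's is dropped.
    """
    if len(kept) < 2:
        return kept
    sil = [level_silhouette(dvals, lab) for _, lab, _ in kept]
    finite = [x for x in sil if np.isfinite(x)]
    if not finite:
        return kept
    cutoff = 0.8 * max(finite)
    out = [entry for entry, x in zip(kept, sil)
           if np.isfinite(x) and x >= cutoff]
    return out or kept


def _dedup_levels(cand, dvals: np.ndarray):
    """Merge near-identical candidate levels, keeping the better one.

    A coarse temperature grid often produces several plateaus whose
    partitions differ only by the placement of one or two items (e.g. an
    11-cluster and a 10-cluster reading of the same structure). Adjacent
    candidates with adjusted Rand index > 0.9 are collapsed onto the
    representative with the higher silhouette.
    """
    if len(cand) < 2:
        return cand
    from sklearn.metrics import adjusted_rand_score

    out = [cand[0]]
    out_sil = [level_silhouette(dvals, cand[0][1])]
    for entry in cand[1:]:
        s = level_silhouette(dvals, entry[1])
        if adjusted_rand_score(out[-1][1], entry[1]) > 0.9:
            if s > out_sil[-1]:
                out[-1], out_sil[-1] = entry, s
        else:
            out.append(entry)
            out_sil.append(s)
    return out


def _polish_membership(labels: np.ndarray, dvals: np.ndarray,
                       n_rounds: int = 2) -> np.ndarray:
    """Reassign every item to the cluster with the smallest mean distance
    to it (excluding itself), synchronously, for a few rounds. Clusters may
    empty out; labels are recompacted."""
    labels = np.asarray(labels)
    n = labels.size
    for _ in range(n_rounds):
        ids, inv, counts = np.unique(labels, return_inverse=True,
                                     return_counts=True)
        k = ids.size
        if k == 1:
            break
        H = np.zeros((n, k))
        H[np.arange(n), inv] = 1.0
        S = dvals @ H
        denom = counts[None, :] - (inv[:, None] == np.arange(k)[None, :])
        M = np.where(denom > 0, S / np.maximum(denom, 1), np.inf)
        new = M.argmin(axis=1)
        if np.array_equal(new, inv):
            labels = inv
            break
        labels = new
    _, labels = np.unique(labels, return_inverse=True)
    return labels.astype(np.int64)


def _coarsen_by_majority(fine: np.ndarray, coarse_raw: np.ndarray) -> np.ndarray:
    """Group the blocks of `fine` according to the raw coarser labelling:
    each fine block goes, whole, to the raw coarse label held by the
    majority of its members (ties to the smaller label). Returns a compact
    label vector whose blocks are unions of fine blocks."""
    out = np.empty_like(fine)
    for b in np.unique(fine):
        members = fine == b
        votes = np.bincount(coarse_raw[members])
        out[members] = int(votes.argmax())
    _, out = np.unique(out, return_inverse=True)
    return out


def _absorb_runts(labels: np.ndarray, co: np.ndarray, min_size: int) -> np.ndarray:
    if min_size <= 1:
        return labels
    if (np.bincount(labels) >= min_size).all():
        return labels  # fast path: nothing to absorb
    labels = labels.copy()
    while True:
        ids, counts = np.unique(labels, return_counts=True)
        runts = ids[counts < min_size]
        if runts.size == 0 or ids.size == 1:
            break
        r = runts[0]
        members = labels == r
        best, best_aff = None, -1.0
        for other in ids:
            if other == r:
                continue
            aff = float(co[np.ix_(members, labels == other)].mean())
            if aff > best_aff:
                best, best_aff = other, aff
        labels[members] = best
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    key_a = {}
    key_b = {}
    for x, y in zip(a, b):
        if key_a.setdefault(x, y) != y or key_b.setdefault(y, x) != x:
            return False
    return True


def ultrametric_distance(tree: DCGTree, i: str, j: str) -> float:
    """Height of the lowest level where i and j share a block (0 at finest)."""
    if i not in set(tree.items) or j not in set(tree.items):
        raise KeyError("unknown identifier")
    if i == j:
        return 0.0
    for level, p in enumerate(tree.levels):
        for b in p.blocks:
            if i in b:
                if j in b:
                    return 0.0 if level == 0 else float(tree.level_heights[level])
                break
    raise ValueError(f"items {i!r} and {j!r} never share a block")


def tree_to_newick(tree: DCGTree) -> str:
    """Newick export with branch lengths from level-height differences."""

    def h(level: int) -> float:
        return 0.0 if level == 0 else float(tree.level_heights[level])

    def render(block: frozenset, level: int) -> str:
        if level == 0:
            if len(block) == 1:
                return next(iter(block))
            kids = ",".join(f"{x}:0" for x in sorted(block))
            return f"({kids})"
        children = [b for b in tree.levels[level - 1].blocks if b <= block]
        if len(children) == 1:
            return render(children[0], level - 1)
        parts = []
        for c in sorted(children, key=lambda s: sorted(s)):
            sub = render(c, level - 1)
            parts.append(f"{sub}:{h(level) - h(level - 1):g}")
        return "(" + ",".join(parts) + ")"

    top = tree.levels[-1]
    L = tree.n_levels - 1
    if len(top) == 1:
        return render(next(iter(top.blocks)), L) + ";"
    parts = [render(b, L) + ":0" for b in sorted(top.blocks, key=lambda s: sorted(s))]
    return "(" + ",".join(parts) + ");"


def export_levels_tsv(tree: DCGTree, path) -> None:
    """Flat per-level membership table: item, level index, block index."""
    with open(path, "w") as fh:
        fh.write("item\tlevel\theight\tblock\n")
        for li, (p, h) in enumerate(zip(tree.levels, tree.level_heights)):
            lab = p.as_labels()
            for item in tree.items:
                fh.write(f"{item}\t{li}\t{h:g}\t{lab[item]}\n")
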