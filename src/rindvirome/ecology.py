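"""Diversity, ordination, permutation tests, correlation and clustering.

All statistics are implemented here from their definitions: Shannon
entropy, Bray-Curtis dissimilarity, classical multidimensional scaling
(PCoA), one-factor PERMANOVA with a freely permuted label null, the
Mantel test (Spearman by default), Kruskal-Wallis with tie correction,
Spearman correlation matrices, agglomerative complete-linkage clustering
with deterministic tie-breaking, and the within-cluster sum-of-squares
elbow used to choose the number of abundance-profile clusters.

Permutation p-values use the (1 + exceedances) / (1 + permutations)
estimator, so p = 0 is impossible; every stochastic routine takes a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.stats import chi2, rankdata

logger = logging.getLogger("rindvirome")


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape inconsistent with ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int


# ---------------------------------------------------------------------------
# diversity and dissimilarity
# ---------------------------------------------------------------------------

def shannon(p: np.ndarray | pd.Series, base: float | None = None) -> float:
    """Shannon entropy H = -sum p ln p of a relative-abundance vector.

    Natural log by default (the conventional scale for community
    diversity); pass ``base`` to change it. Zeros contribute nothing.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("relative abundances must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("relative-abundance vector must sum to 1")
    pos = p[p > 0]
    h = float(-(pos * np.log(pos)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity: sum |x - y| / sum (x + y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis over the rows (samples) of an abundance table."""
    x = table.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("all-zero sample rows")
    diff = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    sums = totals[:, None] + totals[None, :]
    d = diff / sums
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(table.index), d)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def pcoa(d: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling of a distance matrix.

    Double-centers -d^2/2, eigendecomposes, and keeps the positive-
    eigenvalue axes in decreasing order. Returns the sample coordinates
    and the explained-variance fraction per axis (eigenvalue over the sum
    of positive eigenvalues). Bray-Curtis is semi-metric, so negative
    eigenvalues can occur and are dropped.
    """
    n = d.n
    d2 = d.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > max(1e-10, 1e-10 * abs(eigvals).max() if eigvals.size else 0)
    if not positive.any():
        logger.warning("degenerate distance matrix: no positive PCoA axes")
        return pd.DataFrame(np.zeros((n, 0)), index=d.ids), np.empty(0)
    vals = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(vals)
    explained = vals / vals.sum()
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=d.ids, columns=cols), explained


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and integer group labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.nonzero(labels == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return ss_total, ss_within


def permanova(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA with freely permuted group labels.

    pseudo-F = (SS_between / (a - 1)) / (SS_within / (n - a)) computed from
    sums of squared inter-point distances; R^2 = SS_between / SS_total.
    """
    groups = pd.Series(list(groups))
    if len(groups) != d.n:
        raise ValueError("group labels must match distance matrix samples")
    labels, uniques = pd.factorize(groups)
    a = len(uniques)
    if a < 2:
        raise ValueError("need at least two groups")
    counts = np.bincount(labels)
    if (counts == 0).any():
        raise ValueError("empty group")
    n = d.n
    d2 = d.values ** 2
    ss_total, ss_within = _permanova_ss(d2, labels)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(labels) for _ in range(n_perm)])
    # vectorized within-group SS over all permutations
    ss_w = np.zeros(n_perm)
    for g in range(a):
        mask = (perms == g).astype(float)            # (n_perm, n)
        ss_w += np.einsum("pi,ij,pj->p", mask, d2, mask) / (2.0 * counts[g])
    f_perm = ((ss_total - ss_w) / (a - 1)) / (ss_w / (n - a))
    p = (1.0 + np.count_nonzero(f_perm >= f_obs)) / (1.0 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm)


def _rank_rows(x: np.ndarray) -> np.ndarray:
    """Average ranks along the last axis (vectorized, tie-aware)."""
    return rankdata(x, axis=-1)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "spearman",
) -> MantelResult:
    """Mantel test between two distance matrices over the same samples.

    The statistic is the (rank) correlation of the strictly-lower-triangle
    entries; the null permutes the rows and columns of the second matrix
    jointly. One-sided (greater) p-value.
    """
    if d1.ids != d2.ids:
        raise ValueError("distance matrices must share ids and order")
    n = d1.n
    if n < 3:
        raise ValueError("mantel test needs at least 3 samples")
    il = np.tril_indices(n, k=-1)
    v1 = d1.values[il]
    if method == "spearman":
        v1s = rankdata(v1)
    elif method == "pearson":
        v1s = v1
    else:
        raise ValueError(f"unknown method {method!r}")

    def corr_with(v2: np.ndarray) -> np.ndarray:
        v2s = _rank_rows(v2) if method == "spearman" else v2
        a = v1s - v1s.mean()
        b = v2s - v2s.mean(axis=-1, keepdims=True)
        num = (a * b).sum(axis=-1)
        den = np.sqrt((a * a).sum() * (b * b).sum(axis=-1))
        return num / den

    r_obs = float(corr_with(d2.values[il][None, :])[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    rows = perms[:, il[0]]
    cols = perms[:, il[1]]
    v2_perm = d2.values[rows, cols]
    r_perm = corr_with(v2_perm)
    p = (1.0 + np.count_nonzero(r_perm >= r_obs)) / (1.0 + n_perm)
    return MantelResult(r_obs, float(p), n_perm)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from the chi-square approximation."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    n = pooled.size
    if np.unique(pooled).size == 1:
        return 0.0, 1.0
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g in arrays:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_correction = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (n ** 3 - n)
    if tie_correction > 0:
        h /= tie_correction
    p = float(chi2.sf(h, len(arrays) - 1))
    return float(h), p


def spearman_matrix(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Spearman r for every (column of a, column of b) pair over shared samples.

    Zero-variance columns yield NaN (undefined, distinct from r = 0).
    """
    if list(a.index) != list(b.index):
        raise ValueError("tables must share samples in the same order")
    ra = rankdata(a.to_numpy(dtype=float), axis=0)
    rb = rankdata(b.to_numpy(dtype=float), axis=0)

    def centered(x: np.ndarray) -> np.ndarray:
        return x - x.mean(axis=0)

    ca, cb = centered(ra), centered(rb)
    sa = np.sqrt((ca ** 2).sum(axis=0))
    sb = np.sqrt((cb ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ca.T @ cb) / np.outer(sa, sb)
    r[np.outer(sa == 0, np.ones_like(sb, dtype=bool))] = np.nan
    r[np.outer(np.ones_like(sa, dtype=bool), sb == 0)] = np.nan
    return pd.DataFrame(r, index=a.columns, columns=b.columns)


# ---------------------------------------------------------------------------
# hierarchical clustering and the WSS elbow
# ---------------------------------------------------------------------------

def hclust_complete(profiles: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Agglomerative complete-linkage clustering of the rows of ``profiles``.

    Distances are Euclidean (feed log-transformed abundances for the
    heatmap ordering). Ties break on the smallest pair of cluster indices,
    making the result deterministic and invariant to row input order once
    rows are identified by label. Returns a linkage matrix in the usual
    (left, right, height, size) layout plus the leaf order from a
    left-before-right traversal.
    """
    ids = list(profiles.index)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two profiles")
    x = profiles.to_numpy(dtype=float)
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))

    active = {i: [i] for i in range(n)}          # cluster index -> leaf members
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]
    merges = np.zeros((n - 1, 4))
    children: dict[int, tuple[int, int]] = {}
    next_idx = n
    for step in range(n - 1):
        (ci, cj), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        members = active[ci] + active[cj]
        merges[step] = (ci, cj, h, len(members))
        children[next_idx] = (ci, cj)
        del active[ci], active[cj]
        dist = {k: v for k, v in dist.items() if ci not in k and cj not in k}
        for ck, mk in active.items():
            pair = (min(ck, next_idx), max(ck, next_idx))
            dist[pair] = max(d[a, b] for a in members for b in mk)
        active[next_idx] = members
        next_idx += 1

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        left, right = children[node]
        return leaves(left) + leaves(right)

    order = leaves(next_idx - 1)
    return merges, [ids[i] for i in order]


def cut_clusters(merges: np.ndarray, n_leaves: int, k: int) -> np.ndarray:
    """Cluster labels for the k-cluster cut of a linkage matrix."""
    if not 1 <= k <= n_leaves:
        raise ValueError("k out of range")
    parent = list(range(n_leaves + len(merges)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for step in range(n_leaves - k):
        left, right, _, _ = merges[step]
        new = n_leaves + step
        parent[find(int(left))] = new
        parent[find(int(right))] = new
    roots = {}
    labels = np.zeros(n_leaves, dtype=int)
    for i in range(n_leaves):
        r = find(i)
        labels[i] = roots.setdefault(r, len(roots))
    return labels


def wss_cluster_count(profiles: pd.DataFrame, k_max: int = 10) -> tuple[np.ndarray, int]:
    """Within-cluster sum of squares for dendrogram cuts k = 1..k_max.

    The chosen k is a scree-style elbow on the log(WSS) curve: structural
    splits produce log-WSS drops well above the noise level of the curve's
    tail, so the rule keeps the largest k whose drop both (a) exceeds a
    baseline estimated from the tail drops and (b) clearly dominates the
    following drop. On data with no cluster structure every drop looks
    like tail noise and the rule returns k = 1; on well-separated planted
    clusters it returns the planted count exactly.
    """
    n = len(profiles)
    if k_max >= n:
        raise ValueError("k_max must be smaller than the number of profiles")
    merges, _ = hclust_complete(profiles)
    x = profiles.to_numpy(dtype=float)
    wss = np.zeros(k_max)
    for k in range(1, k_max + 1):
        labels = cut_clusters(merges, n, k)
        total = 0.0
        for g in np.unique(labels):
            sub = x[labels == g]
            total += ((sub - sub.mean(axis=0)) ** 2).sum()
        wss[k - 1] = total
    if k_max < 3:
        return wss, int(np.argmin(wss) + 1)
    floor = max(wss[0], 1.0) * 1e-12
    drops = -np.diff(np.log(np.maximum(wss, floor)))  # drop at k = 2..k_max
    tail = drops[drops.size // 2:]
    threshold = max(2.2 * float(np.median(tail)), 0.25 * float(drops.max()))
    candidates = [
        i + 2
        for i, d in enumerate(drops)
        if d > threshold
        and d > 1.3 * (drops[i + 1] if i + 1 < drops.size else float(tail.min()))
    ]
    chosen = candidates[-1] if candidates else 1
    return wss, chosen


def linkage_to_newick(merges: np.ndarray, ids: list[str]) -> str:
    """Serialize a linkage matrix as a Newick string (heights as branch lengths)."""
    n = len(ids)
    height = {i: 0.0 for i in range(n)}
    node = {i: ids[i] for i in range(n)}
    for step, (left, right, h, _) in enumerate(merges):
        left, right = int(left), int(right)
        bl = h - height[left]
        br = h - height[right]
        idx = n + step
        node[idx] = f"({node[left]}:{bl:.6g},{node[right]}:{br:.6g})"
        height[idx] = h
    return node[n + len(merges) - 1] + ";"
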