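"""Reusable components (RCs) for representative-based clustering.

A clustering algorithm in this framework is assembled from one RC per
subproblem:

* **initialization** — DIANA, RANDOM, XMEANS, GMEANS, PCA, KMEANS++, SPSS
* **distance** — EUCLIDEAN, CITY, CORREL, COSINE
* **representative update** — MEAN, MEDIAN, ONLINE
* **cluster evaluation** — AIC, BIC, SILHOU, COMPACT, XB, CONN

Each vocabulary is an addressable registry so a variant can be substituted
without touching the engine.  Tokens are case-insensitive on input and
canonical uppercase everywhere else.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import anderson

logger = logging.getLogger(__name__)

__all__ = [
    "INIT_TOKENS",
    "DISTANCE_TOKENS",
    "UPDATE_TOKENS",
    "EVALUATE_TOKENS",
    "EVALUATION_ORIENTATION",
    "compute_distance",
    "pairwise_distances",
    "initialize_representatives",
    "update_representatives",
    "internal_score",
    "all_internal_scores",
    "CONNECTIVITY_NEIGHBORS",
]

#: Handl–Knowles connectivity neighbourhood size (clipped to n-1 at use).
CONNECTIVITY_NEIGHBORS = 10

_EPS = 1e-12


def canonical(token: str) -> str:
    return str(token).upper()


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _pairwise_correlation(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1)
    yn = np.linalg.norm(yc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (xc @ yc.T) / np.outer(xn, yn)
    dist = 1.0 - np.clip(corr, -1.0, 1.0)
    # constant vectors have undefined correlation: maximal-dissimilarity convention
    degenerate = (xn < _EPS)[:, None] | (yn < _EPS)[None, :]
    if degenerate.any():
        logger.info("CORREL: %d degenerate (constant-vector) pairs mapped to 1", degenerate.sum())
        dist[degenerate] = 1.0
    return dist


def _pairwise_cosine(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xn = np.linalg.norm(x, axis=1)
    yn = np.linalg.norm(y, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = (x @ y.T) / np.outer(xn, yn)
    dist = 1.0 - np.clip(cos, -1.0, 1.0)
    degenerate = (xn < _EPS)[:, None] | (yn < _EPS)[None, :]
    if degenerate.any():
        logger.info("COSINE: %d zero-vector pairs mapped to 1", degenerate.sum())
        dist[degenerate] = 1.0
    return dist


_DISTANCES = {
    "EUCLIDEAN": lambda x, y: cdist(x, y, metric="euclidean"),
    "CITY": lambda x, y: cdist(x, y, metric="cityblock"),
    "CORREL": _pairwise_correlation,
    "COSINE": _pairwise_cosine,
}

DISTANCE_TOKENS = tuple(sorted(_DISTANCES))


def pairwise_distances(x: np.ndarray, y: np.ndarray, kind: str) -> np.ndarray:
    """Distance matrix between the rows of ``x`` and the rows of ``y``."""
    kind = canonical(kind)
    if kind not in _DISTANCES:
        raise ValueError(f"unknown distance RC: {kind}")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ValueError(f"dimension mismatch: {x.shape[1]} vs {y.shape[1]}")
    d = _DISTANCES[kind](x, y)
    return np.maximum(d, 0.0)


def compute_distance(x, y, kind: str) -> float:
    """Distance between two vectors under the given distance RC."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.size < 1:
        raise ValueError("vectors must have length >= 1")
    if canonical(kind) == "CORREL" and x.size < 2:
        raise ValueError("CORREL requires vectors of length >= 2")
    return float(pairwise_distances(x[None, :], y[None, :], kind)[0, 0])


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _farthest_point_fill(x, centers, distance, n_needed):
    """Greedily add instances maximizing the min distance to current centers."""
    centers = list(centers)
    for _ in range(n_needed):
        d = pairwise_distances(x, np.asarray(centers), distance).min(axis=1)
        centers.append(x[int(np.argmax(d))])
    return centers


def _init_random(x, k, distance, rng):
    idx = rng.choice(x.shape[0], size=k, replace=False)
    return x[idx].copy()


def _init_kmeanspp(x, k, distance, rng):
    n = x.shape[0]
    centers = [x[int(rng.integers(n))]]
    for _ in range(k - 1):
        d2 = pairwise_distances(x, np.asarray(centers), distance).min(axis=1) ** 2
        total = d2.sum()
        if total <= 0:  # all mass on existing centers: fall back to uniform
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centers.append(x[idx])
    return np.asarray(centers)


def _diana_split(members, dmat):
    """Split one cluster by the classic splinter-group rule.

    The object with the largest average dissimilarity seeds the splinter
    group; objects then migrate while they are on average closer to the
    splinter group than to the remainder.
    """
    members = list(members)
    sub = dmat[np.ix_(members, members)]
    m = len(members)
    avg = sub.sum(axis=1) / (m - 1)
    seed = int(np.argmax(avg))
    in_splinter = np.zeros(m, dtype=bool)
    in_splinter[seed] = True
    moved = True
    while moved and not in_splinter.all():
        moved = False
        rest = np.nonzero(~in_splinter)[0]
        if len(rest) == 1:
            break
        spl = np.nonzero(in_splinter)[0]
        a = sub[np.ix_(rest, spl)].mean(axis=1)
        b = sub[np.ix_(rest, rest)].sum(axis=1) / (len(rest) - 1)
        gain = b - a
        j = int(np.argmax(gain))
        if gain[j] > 0:
            in_splinter[rest[j]] = True
            moved = True
    group_a = [members[i] for i in np.nonzero(in_splinter)[0]]
    group_b = [members[i] for i in np.nonzero(~in_splinter)[0]]
    return group_a, group_b


def _init_diana(x, k, distance, rng):
    dmat = pairwise_distances(x, x, distance)
    clusters = [list(range(x.shape[0]))]
    while len(clusters) < k:
        diameters = [
            dmat[np.ix_(c, c)].max() if len(c) > 1 else -1.0 for c in clusters
        ]
        target = int(np.argmax(diameters))
        if diameters[target] <= 0:  # only singletons/duplicates left
            big = max(range(len(clusters)), key=lambda i: len(clusters[i]))
            c = clusters.pop(big)
            clusters.extend([c[:1], c[1:]])
            continue
        c = clusters.pop(target)
        a, b = _diana_split(c, dmat)
        clusters.extend([a, b])
    return np.asarray([x[c].mean(axis=0) for c in clusters])


def _init_pca(x, k, distance, rng):
    xc = x - x.mean(axis=0)
    # first right singular vector = leading principal axis
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    proj = xc @ vt[0]
    lo, hi = proj.min(), proj.max()
    if hi - lo <= 0:
        return np.asarray(_farthest_point_fill(x, [x.mean(axis=0)], distance, k - 1))
    edges = np.linspace(lo, hi, k + 1)
    bins = np.clip(np.digitize(proj, edges[1:-1]), 0, k - 1)
    centers = [x[bins == b].mean(axis=0) for b in range(k) if (bins == b).any()]
    if len(centers) < k:
        centers = _farthest_point_fill(x, centers, distance, k - len(centers))
    return np.asarray(centers)


def _local_two_means(subset, distance, rng, n_iter=20):
    """A short 2-means run on a subset, used by the splitting initializers."""
    if subset.shape[0] < 2:
        return np.vstack([subset[0], subset[0]]), np.zeros(subset.shape[0], dtype=int)
    centers = _init_kmeanspp(subset, 2, distance, rng)
    assign = np.zeros(subset.shape[0], dtype=int)
    for _ in range(n_iter):
        new_assign = pairwise_distances(subset, centers, distance).argmin(axis=1)
        for c in range(2):
            if (new_assign == c).any():
                centers[c] = subset[new_assign == c].mean(axis=0)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    return centers, assign


def _spherical_bic(subset, centers, assign, distance):
    d = subset.shape[1]
    k = centers.shape[0]
    n = subset.shape[0]
    dist = pairwise_distances(subset, centers, distance)[np.arange(n), assign]
    ssq = float((dist**2).sum())
    sigma2 = max(ssq / max(n - k, 1), _EPS)
    sizes = np.bincount(assign, minlength=k)
    ll = 0.0
    for nj in sizes:
        if nj > 0:
            ll += nj * math.log(nj / n)
    ll -= 0.5 * n * d * math.log(2 * math.pi * sigma2)
    ll -= 0.5 * max(n - k, 0)
    p = k * d + 1
    return -2.0 * ll + p * math.log(n)


def _split_until_k(x, k, distance, rng, should_split):
    """Shared x-means / g-means skeleton: grow from 2 centers to exactly k.

    ``should_split(subset, children, child_assign, parent_center)`` returns a
    score; the positive-scoring cluster with the largest score is split.  If
    no criterion fires before k centers exist, farthest-point splits are
    forced so exactly k centers always result.
    """
    centers, _ = _local_two_means(x, distance, rng)
    centers = list(centers)
    while len(centers) < k:
        assign = pairwise_distances(x, np.asarray(centers), distance).argmin(axis=1)
        best_score, best = -np.inf, None
        for c in range(len(centers)):
            subset = x[assign == c]
            if subset.shape[0] < 2 or np.allclose(subset, subset[0]):
                continue
            children, child_assign = _local_two_means(subset, distance, rng)
            score = should_split(subset, children, child_assign, np.asarray(centers[c]))
            if score > best_score:
                best_score, best = score, (c, children)
        if best is not None and best_score > 0:
            c, children = best
            centers[c] = children[0]
            centers.append(children[1])
        else:  # criterion stopped early: force a farthest-point split
            d = pairwise_distances(x, np.asarray(centers), distance).min(axis=1)
            centers.append(x[int(np.argmax(d))])
    return np.asarray(centers[:k])


def _init_xmeans(x, k, distance, rng):
    def bic_gain(subset, children, child_assign, parent):
        one = _spherical_bic(subset, parent[None, :], np.zeros(len(subset), dtype=int), distance)
        two = _spherical_bic(subset, children, child_assign, distance)
        return one - two  # positive when the 2-center model has lower BIC

    return _split_until_k(x, k, distance, rng, bic_gain)


def _init_gmeans(x, k, distance, rng):
    def ad_excess(subset, children, child_assign, parent):
        v = children[1] - children[0]
        norm = np.linalg.norm(v)
        if norm < _EPS:
            return -1.0
        proj = subset @ (v / norm)
        if np.std(proj) < _EPS or len(proj) < 8:
            return -1.0
        try:
            res = anderson(proj, dist="norm", method="interpolate")
            return float(0.05 - res.pvalue)  # >0: reject normality at 5%, split
        except TypeError:  # scipy < 1.17: critical-value interface
            res = anderson(proj, dist="norm")
            crit = res.critical_values[res.significance_level == 5.0][0]
            return float(res.statistic - crit)

    return _split_until_k(x, k, distance, rng, ad_excess)


def _init_spss(x, k, distance, rng):
    """QUICK-CLUSTER-style streaming selection of k well-separated seeds."""
    centers = x[:k].copy()
    for i in range(k, x.shape[0]):
        xi = x[i : i + 1]
        d_to_centers = pairwise_distances(xi, centers, distance)[0]
        cc = pairwise_distances(centers, centers, distance)
        np.fill_diagonal(cc, np.inf)
        a, b = np.unravel_index(np.argmin(cc), cc.shape)
        if d_to_centers.min() > cc[a, b]:
            victim = a if d_to_centers[a] <= d_to_centers[b] else b
            centers[victim] = xi[0]
    return centers


_INITIALIZERS = {
    "DIANA": _init_diana,
    "RANDOM": _init_random,
    "XMEANS": _init_xmeans,
    "GMEANS": _init_gmeans,
    "PCA": _init_pca,
    "KMEANS++": _init_kmeanspp,
    "SPSS": _init_spss,
}

INIT_TOKENS = tuple(sorted(_INITIALIZERS))


def initialize_representatives(x, k, kind, distance, seed=0):
    """Return k initial representatives under the chosen initialization RC.

    Deterministic given ``(x, k, kind, seed)``; seed-free RCs (DIANA, PCA,
    SPSS) ignore the seed entirely.
    """
    kind = canonical(kind)
    if kind not in _INITIALIZERS:
        raise ValueError(f"unknown initialization RC: {kind}")
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("initialization requires a fully observed, finite matrix")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds the number of instances ({x.shape[0]})")
    rng = np.random.default_rng(seed)
    centers = np.asarray(_INITIALIZERS[kind](x, k, canonical(distance), rng), dtype=float)
    assert centers.shape == (k, x.shape[1])
    return centers


# ---------------------------------------------------------------------------
# Representative updates
# ---------------------------------------------------------------------------

def _update_mean(x, assign, k, prev, distance, rng):
    out = prev.copy()
    for c in range(k):
        members = assign == c
        if members.any():
            out[c] = x[members].mean(axis=0)
    return out


def _update_median(x, assign, k, prev, distance, rng):
    out = prev.copy()
    for c in range(k):
        members = assign == c
        if members.any():
            out[c] = np.median(x[members], axis=0)
    return out


def _update_online(x, assign, k, prev, distance, rng):
    # One MacQueen pass in seeded random order: the prior center counts as
    # one pseudo-observation, so after the pass each center is the running
    # mean of (prev_center, its instances in visit order).
    out = prev.copy()
    counts = np.ones(k)
    for i in rng.permutation(x.shape[0]):
        c = assign[i]
        counts[c] += 1
        out[c] += (x[i] - out[c]) / counts[c]
    return out


_UPDATES = {"MEAN": _update_mean, "MEDIAN": _update_median, "ONLINE": _update_online}

UPDATE_TOKENS = tuple(sorted(_UPDATES))


def update_representatives(x, assignment, reps, kind, distance, seed=0):
    """Recompute representatives from the current assignment."""
    kind = canonical(kind)
    if kind not in _UPDATES:
        raise ValueError(f"unknown update RC: {kind}")
    x = np.asarray(x, dtype=float)
    assignment = np.asarray(assignment, dtype=int)
    reps = np.asarray(reps, dtype=float)
    k = reps.shape[0]
    if assignment.min() < 0 or assignment.max() >= k:
        raise ValueError("cluster index out of range")
    rng = np.random.default_rng(seed)
    return _UPDATES[kind](x, assignment, k, reps, canonical(distance), rng)


# ---------------------------------------------------------------------------
# Internal evaluation measures
# ---------------------------------------------------------------------------

def _score_compact(x, assign, centers, distance):
    n = x.shape[0]
    d = pairwise_distances(x, centers, distance)[np.arange(n), assign]
    return float(d.mean())


def _score_silhouette(x, assign, centers, distance):
    n = x.shape[0]
    labels = np.unique(assign)
    if len(labels) < 2:
        raise ValueError("SILHOU is undefined for a single cluster")
    dmat = pairwise_distances(x, x, distance)
    s = np.zeros(n)
    sizes = {c: int((assign == c).sum()) for c in labels}
    for i in range(n):
        own = assign[i]
        if sizes[own] == 1:
            s[i] = 0.0
            continue
        same = assign == own
        a = dmat[i, same].sum() / (sizes[own] - 1)
        b = min(dmat[i, assign == c].mean() for c in labels if c != own)
        denom = max(a, b)
        s[i] = 0.0 if denom <= 0 else (b - a) / denom
    return float(s.mean())


def _loglik_spherical(x, assign, centers, distance):
    """x-means spherical identical-variance Gaussian log-likelihood.

    The squared chosen distance stands in for squared Euclidean deviations so
    the measure composes with every distance RC.
    """
    n, d = x.shape
    k = centers.shape[0]
    dist = pairwise_distances(x, centers, distance)[np.arange(n), assign]
    sigma2 = max(float((dist**2).sum()) / max(n - k, 1), _EPS)
    sizes = np.bincount(assign, minlength=k)
    ll = sum(nj * math.log(nj / n) for nj in sizes if nj > 0)
    ll -= 0.5 * n * d * math.log(2 * math.pi * sigma2)
    ll -= 0.5 * max(n - k, 0)
    return ll, k * d + 1


def _score_aic(x, assign, centers, distance):
    ll, p = _loglik_spherical(x, assign, centers, distance)
    return -2.0 * ll + 2.0 * p


def _score_bic(x, assign, centers, distance):
    ll, p = _loglik_spherical(x, assign, centers, distance)
    return -2.0 * ll + p * math.log(x.shape[0])


def _score_xb(x, assign, centers, distance):
    if centers.shape[0] < 2:
        raise ValueError("XB is undefined for a single cluster")
    n = x.shape[0]
    dist = pairwise_distances(x, centers, distance)[np.arange(n), assign]
    cc = pairwise_distances(centers, centers, distance)
    np.fill_diagonal(cc, np.inf)
    min_sep2 = max(float(cc.min()) ** 2, _EPS)
    return float((dist**2).sum()) / (n * min_sep2)


def _score_connectivity(x, assign, centers, distance):
    n = x.shape[0]
    length = min(CONNECTIVITY_NEIGHBORS, n - 1)
    dmat = pairwise_distances(x, x, distance)
    np.fill_diagonal(dmat, np.inf)
    order = np.argsort(dmat, axis=1, kind="stable")[:, :length]
    weights = 1.0 / np.arange(1, length + 1)
    violations = assign[order] != assign[:, None]
    return float((violations * weights).sum())


_EVALUATIONS = {
    "AIC": _score_aic,
    "BIC": _score_bic,
    "SILHOU": _score_silhouette,
    "COMPACT": _score_compact,
    "XB": _score_xb,
    "CONN": _score_connectivity,
}

EVALUATE_TOKENS = tuple(sorted(_EVALUATIONS))

EVALUATION_ORIENTATION = {
    "AIC": "lower_better",
    "BIC": "lower_better",
    "SILHOU": "higher_better",
    "COMPACT": "lower_better",
    "XB": "lower_better",
    "CONN": "lower_better",
}


def internal_score(x, assignment, reps, kind, distance):
    """Evaluate a partition with one internal validity RC.

    Returns ``(score, orientation)`` where orientation is ``"lower_better"``
    or ``"higher_better"``.
    """
    kind = canonical(kind)
    if kind not in _EVALUATIONS:
        raise ValueError(f"unknown evaluation RC: {kind}")
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("internal scores require a fully observed, finite matrix")
    assignment = np.asarray(assignment, dtype=int)
    reps = np.asarray(reps, dtype=float)
    score = _EVALUATIONS[kind](x, assignment, reps, canonical(distance))
    return float(score), EVALUATION_ORIENTATION[kind]


def all_internal_scores(x, assignment, reps, distance):
    """All six internal measures for one solution (dict token -> score)."""
    return {
        kind: internal_score(x, assignment, reps, kind, distance)[0]
        for kind in EVALUATE_TOKENS
    }
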