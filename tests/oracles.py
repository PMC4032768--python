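"""Independent reference implementations used only as test oracles.

Everything here is deliberately written from first principles (exact
arithmetic, brute-force enumeration, textbook pseudocode) and shares no code
with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def set_partitions(n: int):
    """All partitions of n items as canonical label tuples (restricted growth)."""

    def rec(prefix, n_blocks):
        i = len(prefix)
        if i == n:
            yield tuple(prefix)
            return
        for b in range(n_blocks + 1):
            yield from rec(prefix + [b], max(n_blocks, b + 1))

    yield from rec([0], 1)


def _counts(labels):
    out = {}
    for lab in labels:
        out[lab] = out.get(lab, 0) + 1
    return out


def brute_force_mi(a, b) -> float:
    """Plug-in mutual information (nats) from raw joint counts."""
    n = len(a)
    joint = _counts(list(zip(a, b)))
    ca, cb = _counts(a), _counts(b)
    mi = 0.0
    for (la, lb), nij in joint.items():
        mi += (nij / n) * math.log(n * nij / (ca[la] * cb[lb]))
    return mi


def brute_force_emi(a, b) -> float:
    """Exact E[MI] under the hypergeometric model, exact-rational pmf.

    The hypergeometric probabilities are summed as Fractions; only the final
    logarithm terms are floats.
    """
    n = len(a)
    ca, cb = _counts(a), _counts(b)
    emi = 0.0
    for ai in ca.values():
        for bj in cb.values():
            denom = math.comb(n, bj)
            for nij in range(max(1, ai + bj - n), min(ai, bj) + 1):
                p = Fraction(math.comb(ai, nij) * math.comb(n - ai, bj - nij), denom)
                emi += float(p) * (nij / n) * math.log(n * nij / (ai * bj))
    return emi


def brute_force_ami(a, b) -> float:
    """AMI with arithmetic-mean normalizer from the brute-force pieces."""

    def h(labels):
        n = len(labels)
        return -sum((c / n) * math.log(c / n) for c in _counts(labels).values())

    normalizer = 0.5 * (h(a) + h(b))
    if normalizer <= 0:
        return 0.0
    if h(a) == 0.0 or h(b) == 0.0:
        return 0.0
    # identical up to relabeling -> exactly 1 (covers the degenerate
    # all-singletons case where the chance adjustment denominator vanishes)
    fwd = {}
    bwd = {}
    consistent = True
    for la, lb in zip(a, b):
        if fwd.setdefault(la, lb) != lb or bwd.setdefault(lb, la) != la:
            consistent = False
            break
    if consistent:
        return 1.0
    emi = brute_force_emi(a, b)
    denom = normalizer - emi
    if abs(denom) < 1e-15:
        denom = math.copysign(1e-15, denom)
    return min((brute_force_mi(a, b) - emi) / denom, 1.0)


def permutation_emi(a, b) -> float:
    """E[MI] as the literal average over every relabeling permutation of b."""
    n = len(a)
    b = list(b)
    total = 0.0
    count = 0
    for perm in itertools.permutations(range(n)):
        total += brute_force_mi(a, [b[i] for i in perm])
        count += 1
    return total / count


def reference_lloyd(x: np.ndarray, centers: np.ndarray, max_iter: int = 100):
    """Textbook Lloyd k-means from shared initial centers.

    Conventions match the documented engine behavior: squared-Euclidean
    argmin assignment with lowest-index tie break, per-cluster mean update,
    empty clusters reseeded at the instance farthest from its representative,
    stop when assignments repeat.
    """
    x = np.asarray(x, dtype=float)
    centers = np.array(centers, dtype=float, copy=True)
    k = centers.shape[0]
    assign = None
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
        new = d2.argmin(axis=1)
        reseeded = False
        for c in range(k):
            if not (new == c).any():
                own = d2[np.arange(len(x)), new]
                i = int(own.argmax())
                centers[c] = x[i]
                new[i] = c
                reseeded = True
        if assign is not None and not reseeded and np.array_equal(new, assign):
            break
        assign = new
        for c in range(k):
            if (assign == c).any():
                centers[c] = x[assign == c].mean(axis=0)
    return assign, centers
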