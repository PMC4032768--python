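"""External clustering validation by adjusted mutual information (AMI).

AMI corrects mutual information between two partitions for chance agreement
under the permutation (hypergeometric) model with fixed marginals:

    AMI = (MI - E[MI]) / (normalizer - E[MI])

where E[MI] is the *exact* expected mutual information and the normalizer is,
by default, the arithmetic mean of the two partition entropies.  AMI is 1 for
identical partitions (up to relabeling) and ~0 for independent ones.
Natural logarithms throughout; the index is scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "contingency_table",
    "entropy",
    "mutual_information",
    "expected_mutual_information",
    "ami",
    "AMI_NORMALIZERS",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Joint label counts of two partitions of the same instances."""

    counts: np.ndarray
    n: int

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if (counts < 0).any():
            raise ValueError("contingency counts must be nonnegative")
        if counts.sum() != self.n:
            raise ValueError("contingency counts do not sum to n")


def contingency_table(a, b) -> ContingencyTable:
    """Cross-tabulate two label vectors (any hashable label values)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"label vectors must be 1-D and of equal length "
                         f"({a.shape} vs {b.shape})")
    if a.size < 1:
        raise ValueError("label vectors must be non-empty")
    counts = pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b")).to_numpy()
    return ContingencyTable(counts=counts, n=int(a.size))


def entropy(counts: np.ndarray) -> float:
    """Shannon entropy (nats) of a count vector."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def mutual_information(ct: ContingencyTable) -> float:
    """Mutual information (nats) of the joint partition counts."""
    counts = ct.counts.astype(float)
    n = float(ct.n)
    a = counts.sum(axis=1)
    b = counts.sum(axis=0)
    nz = counts > 0
    nij = counts[nz]
    outer = np.outer(a, b)[nz]
    return float((nij / n * (np.log(nij * n) - np.log(outer))).sum())


def expected_mutual_information(ct: ContingencyTable) -> float:
    """Exact E[MI] under the fixed-marginal hypergeometric model.

    The sum over admissible cell counts is evaluated with log-space
    factorials (gammaln) for numeric safety.
    """
    counts = ct.counts
    n = ct.n
    a = counts.sum(axis=1)
    b = counts.sum(axis=0)
    log_n = np.log(n)
    base = gammaln(n - a + 1)[:, None] + gammaln(n - b + 1)[None, :] - gammaln(n + 1)
    emi = 0.0
    for i, ai in enumerate(a):
        for j, bj in enumerate(b):
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1)
            log_p = (
                gammaln(ai + 1)
                + gammaln(bj + 1)
                + base[i, j]
                - gammaln(nij + 1)
                - gammaln(ai - nij + 1)
                - gammaln(bj - nij + 1)
                - gammaln(n - ai - bj + nij + 1)
            )
            term = nij / n * (np.log(nij) + log_n - np.log(ai) - np.log(bj))
            emi += float((term * np.exp(log_p)).sum())
    return emi


AMI_NORMALIZERS = {
    "arithmetic": lambda ha, hb: 0.5 * (ha + hb),
    "max": max,
    "min": min,
    "geometric": lambda ha, hb: float(np.sqrt(ha * hb)),
}


def ami(a, b, average_method: str = "arithmetic") -> float:
    """Adjusted mutual information between two label vectors.

    Returns 1 for identical partitions up to relabeling and 0 when the
    normalizer is 0 (both partitions trivial).  The default normalizer is the
    arithmetic mean of the entropies; alternatives live in
    :data:`AMI_NORMALIZERS`.
    """
    if average_method not in AMI_NORMALIZERS:
        raise ValueError(f"unknown AMI normalizer: {average_method!r}")
    ct = contingency_table(a, b)
    ha = entropy(ct.counts.sum(axis=1))
    hb = entropy(ct.counts.sum(axis=0))
    normalizer = AMI_NORMALIZERS[average_method](ha, hb)
    if normalizer <= 0:
        return 0.0  # both partitions put everything in one cluster
    if ha == 0.0 or hb == 0.0:
        return 0.0  # one side trivial: MI = E[MI] = 0 analytically
    counts = ct.counts
    if (
        counts.shape[0] == counts.shape[1]
        and ((counts > 0).sum(axis=0) == 1).all()
        and ((counts > 0).sum(axis=1) == 1).all()
    ):
        # identical up to relabeling: exactly 1, even where the adjustment
        # denominator degenerates (e.g. two all-singleton partitions)
        return 1.0
    mi = mutual_information(ct)
    emi = expected_mutual_information(ct)
    denom = normalizer - emi
    if abs(denom) < 1e-15:
        denom = 1e-15 if denom >= 0 else -1e-15
    # AMI <= 1 analytically; guard against float overshoot at exact agreement
    return float(min((mi - emi) / denom, 1.0))
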