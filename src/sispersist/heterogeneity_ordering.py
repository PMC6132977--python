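"""Weighted majorization and convex order: 'more heterogeneous than'.

``x1`` is p-majorized by ``x2`` (x1 is the less heterogeneous vector) when
some permutation sigma sorts both vectors non-increasingly at once, the
p-weighted means agree, and every p-weighted partial sum of x1 along sigma
is dominated by that of x2.  For finite integer-supported distributions the
analogous comparison is the convex order, checked through cumulative sums of
the distribution functions.  Both are partial orders, so "incomparable" is a
first-class verdict rather than an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import permutations, product
from math import factorial

import numpy as np

MEAN_TOL = 1e-9
SUM_TOL = 1e-9


class Verdict(str, Enum):
    ORDERED = "ordered"            # x1 below x2 (x1 less heterogeneous)
    REVERSE_ORDERED = "reverse-ordered"
    INCOMPARABLE = "incomparable"


@dataclass(frozen=True)
class OrderedPair:
    x1: np.ndarray
    x2: np.ndarray
    p: np.ndarray
    verdict: Verdict


def _validate_weights(p, n: int) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (n,):
        raise ValueError("weight vector p must match the vectors' length")
    if np.any(p <= 0) or abs(p.sum() - 1.0) > MEAN_TOL:
        raise ValueError("p must be positive and sum to 1")
    return p


def _tied_blocks(order: np.ndarray, x1: np.ndarray, x2: np.ndarray
                 ) -> list[list[int]]:
    """Maximal runs of positions where both vectors tie (the only freedom
    left in the shared sorting permutation)."""
    blocks, cur = [], [order[0]]
    for a, b in zip(order[:-1], order[1:]):
        if x1[a] == x1[b] and x2[a] == x2[b]:
            cur.append(b)
        else:
            blocks.append(cur)
            cur = [b]
    blocks.append(cur)
    return blocks


def _dominates(x1, x2, p, order) -> bool:
    s1 = np.cumsum(p[order] * x1[order])[:-1]
    s2 = np.cumsum(p[order] * x2[order])[:-1]
    return bool(np.all(s1 <= s2 + SUM_TOL))


def _one_sided(x1: np.ndarray, x2: np.ndarray, p: np.ndarray,
               max_enum: int = 20000) -> bool:
    """Does a shared non-increasing permutation with partial-sum dominance
    of x2 over x1 exist?"""
    # sort by x1 desc, tie-break x2 desc: the only candidate up to joint ties
    order = np.lexsort((-x2, -x1))
    for x in (x1, x2):
        if np.any(np.diff(x[order]) > 0):
            return False        # no simultaneous non-increasing permutation
    if _dominates(x1, x2, p, order):
        return True
    blocks = _tied_blocks(order, x1, x2)
    free = [b for b in blocks if len(b) > 1]
    n_enum = int(np.prod([factorial(len(b)) for b in free])) if free else 1
    if not free or n_enum > max_enum:
        # within a joint-tied block both vectors are constant, so reordering
        # only permutes the weights; beyond the enumeration cap fall back to
        # the canonical order alone
        return False
    for perm_choice in product(*(permutations(b) for b in blocks)):
        candidate = np.concatenate([np.asarray(c, dtype=int) for c in perm_choice])
        if _dominates(x1, x2, p, candidate):
            return True
    return False


def p_majorizes(x1, x2, p) -> OrderedPair:
    """Compare vectors under p-majorization.

    ``ORDERED`` means x1 is p-majorized by x2 (x1 is the flatter vector);
    vectors with differing p-weighted means are ``INCOMPARABLE`` by
    definition.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("x1 and x2 must be 1-d vectors of equal length")
    p = _validate_weights(p, x1.size)
    if abs(p @ x1 - p @ x2) > MEAN_TOL * max(1.0, abs(p @ x1)):
        return OrderedPair(x1, x2, p, Verdict.INCOMPARABLE)
    below = _one_sided(x1, x2, p)
    above = _one_sided(x2, x1, p)
    if below:
        verdict = Verdict.ORDERED
    elif above:
        verdict = Verdict.REVERSE_ORDERED
    else:
        verdict = Verdict.INCOMPARABLE
    return OrderedPair(x1, x2, p, verdict)


def convex_order_le(dist1: dict[int, float], dist2: dict[int, float]
                    ) -> Verdict:
    """Convex order on finite distributions over {1, ..., d_max}.

    ``ORDERED`` means dist1 <=_cv dist2 (dist2 more variable), via the
    cumulative characterisation: partial sums of the CDF of dist1 dominated
    by those of dist2 at every threshold.  Unequal means -> INCOMPARABLE.
    """
    support = sorted(set(dist1) | set(dist2))
    if not support or min(support) < 1:
        raise ValueError("supports must be subsets of {1, 2, ...}")
    d_max = max(support)
    grid = np.arange(1, d_max + 1)
    p1 = np.array([dist1.get(int(i), 0.0) for i in grid])
    p2 = np.array([dist2.get(int(i), 0.0) for i in grid])
    for p in (p1, p2):
        if abs(p.sum() - 1.0) > MEAN_TOL or np.any(p < 0):
            raise ValueError("each distribution must be a probability vector")
    if abs(grid @ p1 - grid @ p2) > MEAN_TOL * max(1.0, grid @ p1):
        return Verdict.INCOMPARABLE
    c1 = np.cumsum(np.cumsum(p1))       # sum_{i<=j} P(X <= i)
    c2 = np.cumsum(np.cumsum(p2))
    below = bool(np.all(c1 <= c2 + SUM_TOL))
    above = bool(np.all(c2 <= c1 + SUM_TOL))
    if below:
        return Verdict.ORDERED
    if above:
        return Verdict.REVERSE_ORDERED
    return Verdict.INCOMPARABLE


def robin_hood_pair(x, p, amount: float, donor: int, recipient: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Mean-preserving transfer reducing heterogeneity: returns (x, x')
    with x' p-majorized by x.

    A p-weighted amount is moved from the larger entry (donor) to the
    smaller (recipient): x'_donor = x_donor - amount/p_donor and
    x'_recipient = x_recipient + amount/p_recipient, keeping the p-weighted
    mean fixed.  The transfer must not overshoot (donor stays >= recipient)
    nor drive any entry non-positive.
    """
    x = np.asarray(x, dtype=float)
    p = _validate_weights(p, x.size)
    if donor == recipient:
        raise ValueError("donor and recipient must differ")
    if amount < 0:
        raise ValueError("amount must be nonnegative")
    if x[donor] < x[recipient]:
        raise ValueError("donor entry must be at least the recipient entry")
    xp = x.copy()
    xp[donor] -= amount / p[donor]
    xp[recipient] += amount / p[recipient]
    if xp[donor] <= 0:
        raise ValueError("transfer would drive the donor entry non-positive")
    if xp[donor] < xp[recipient] - SUM_TOL:
        raise ValueError("transfer overshoots: donor would fall below recipient")
    # a transfer crossing a third entry strictly between the old and new
    # values destroys the shared sorting permutation: the resulting pair is
    # incomparable under p-majorization even though convex sums still order
    for m in range(x.size):
        if m in (donor, recipient):
            continue
        if xp[donor] < x[m] < x[donor] or x[recipient] < x[m] < xp[recipient]:
            raise ValueError(
                "transfer crosses an intermediate entry; the pair would not "
                "be p-majorization comparable")
    return x, xp


def max_safe_amount(x, p, donor: int, recipient: int) -> float:
    """Largest transfer amount keeping the Robin-Hood pair comparable:
    no donor/recipient overshoot and no crossing of intermediate entries."""
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    gap = x[donor] - x[recipient]
    if gap < 0:
        raise ValueError("donor entry must be at least the recipient entry")
    cap = gap / (1.0 / p[donor] + 1.0 / p[recipient])
    between = [x[m] for m in range(x.size)
               if m not in (donor, recipient)
               and x[recipient] < x[m] < x[donor]]
    if between:
        cap = min(cap,
                  p[donor] * (x[donor] - max(between)),
                  p[recipient] * (min(between) - x[recipient]))
    return float(cap)
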