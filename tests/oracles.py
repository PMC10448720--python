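"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's own code paths (and scipy/sklearn
shortcuts) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def fisher_two_sided(table) -> Fraction:
    """Exact two-sided Fisher p by full hypergeometric enumeration.

    Conditional on the margins, sums the probabilities of all tables no more
    probable than the observed one.  Exact rational arithmetic throughout.
    """
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)
    observed = Fraction(comb(r1, a) * comb(n - r1, c1 - a), denom)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    total = Fraction(0)
    for k in range(lo, hi + 1):
        pk = Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
        if pk <= observed:
            total += pk
    return total


def roc_auc_pairwise(scores, labels) -> float:
    """ROC AUC as exhaustive pairwise concordance with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    if not pos or not neg:
        raise ValueError("need both classes")
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def butina_reference(sims: dict, ids: list, cutoff: float) -> list[tuple[str, tuple[str, ...]]]:
    """Straightforward sphere-exclusion clustering.

    ``sims`` maps unordered id pairs (frozenset) to similarity.  Returns
    (centroid, members) tuples in formation order; same rules as the package
    claims: closed neighborhoods at >= cutoff, centroid = unassigned id with
    the most unassigned neighbors, ties to the smallest id.
    """

    def sim(a, b):
        return 1.0 if a == b else sims[frozenset((a, b))]

    remaining = set(ids)
    out = []
    while remaining:
        best = None
        best_count = -1
        for cand in sorted(remaining):
            count = sum(1 for other in remaining if sim(cand, other) >= cutoff)
            if count > best_count:
                best, best_count = cand, count
        members = tuple(sorted(o for o in remaining if sim(best, o) >= cutoff))
        out.append((best, members))
        remaining.difference_update(members)
    return out


def fine_grid_trapezoid(values, log10_points, refine: int = 1000) -> float:
    """Trapezoidal AUC of the piecewise-linear curve on a ``refine``x finer grid,
    normalized by the total log10 width."""
    x = np.asarray(log10_points, dtype=float)
    v = np.asarray(values, dtype=float)
    fine_x = np.linspace(x[0], x[-1], (len(x) - 1) * refine + 1)
    fine_v = np.interp(fine_x, x, v)
    area = 0.0
    for i in range(len(fine_x) - 1):
        area += 0.5 * (fine_v[i] + fine_v[i + 1]) * (fine_x[i + 1] - fine_x[i])
    return area / (x[-1] - x[0])


def restricted_fine_trapezoid(values, log10_points, x_cut: float, refine: int = 1000) -> float:
    """As :func:`fine_grid_trapezoid` but integrating only up to ``x_cut``."""
    x = np.asarray(log10_points, dtype=float)
    v = np.asarray(values, dtype=float)
    if x_cut <= x[0]:
        return 0.0
    x_cut = min(x_cut, x[-1])
    fine_x = np.linspace(x[0], x_cut, (len(x) - 1) * refine + 1)
    fine_v = np.interp(fine_x, x, v)
    area = 0.0
    for i in range(len(fine_x) - 1):
        area += 0.5 * (fine_v[i] + fine_v[i + 1]) * (fine_x[i + 1] - fine_x[i])
    return area / (x[-1] - x[0])
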