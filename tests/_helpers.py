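"""Independent oracles shared by the unit and acceptance suites.

These deliberately avoid the code paths they check: the Fisher oracle
enumerates margin-fixed tables with exact rational arithmetic, the vote
oracle counts ballots with collections.Counter, and the SMOTE check
scans candidate segments directly.
"""

from __future__ import annotations

import itertools
from collections import Counter
from fractions import Fraction
from math import comb

import numpy as np


def fisher_oracle_one_sided(tp: int, fp: int, fn: int, tn: int) -> float:
    """Exact one-sided enrichment p by brute-force hypergeometric enumeration.

    Margins fixed: K = tp+fn actives, m = tp+fp carriers, N total. Sums
    the point mass of every margin-consistent table with tp' >= tp,
    using exact rationals until the final float conversion.
    """
    n_total = tp + fp + fn + tn
    k_active = tp + fn
    m_carrier = tp + fp
    if n_total == 0:
        return 1.0
    denom = comb(n_total, m_carrier)
    total = Fraction(0)
    for t in range(tp, min(k_active, m_carrier) + 1):
        if m_carrier - t > n_total - k_active:
            continue
        total += Fraction(comb(k_active, t) * comb(n_total - k_active, m_carrier - t),
                          denom)
    return float(total)


def all_tables(n_max: int):
    """Every non-negative 2x2 table (tp, fp, fn, tn) with total <= n_max."""
    for n in range(n_max + 1):
        for tp in range(n + 1):
            for fp in range(n - tp + 1):
                for fn in range(n - tp - fp + 1):
                    yield tp, fp, fn, n - tp - fp - fn


def vote_oracle(prediction_matrix: np.ndarray) -> np.ndarray:
    """Majority vote by explicit ballot counting; ties go positive."""
    out = []
    for column in prediction_matrix.T:
        tally = Counter(int(v) for v in column)
        if tally[1] > tally[0]:
            out.append(1)
        elif tally[1] < tally[0]:
            out.append(0)
        else:
            out.append(1)
    return np.array(out, dtype=int)


def all_vote_patterns(n_members: int):
    """Every possible single-compound ballot for a member count."""
    return list(itertools.product((0, 1), repeat=n_members))


def on_segment_of_some_pair(
    point: np.ndarray, originals: np.ndarray, tol: float = 1e-9
) -> bool:
    """True iff ``point`` is a convex combination of two original rows."""
    for i, j in itertools.combinations(range(len(originals)), 2):
        a, b = originals[i], originals[j]
        d = b - a
        denom = float(d @ d)
        if denom == 0:
            if np.allclose(point, a, atol=tol):
                return True
            continue
        u = float((point - a) @ d) / denom
        if -tol <= u <= 1 + tol and np.allclose(a + u * d, point, atol=tol):
            return True
    return False
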