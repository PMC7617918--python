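"""Shared fixtures and independent oracles.

The enumeration oracles here deliberately avoid the package's vectorised
code paths: they walk every ordered with-replacement draw with
itertools.product and use statistics.median / fractions.Fraction, so they
can serve as ground truth for the bootstrap engine.
"""

from __future__ import annotations

import itertools
import statistics
from collections import Counter
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from delphi_stabilize import LikertScale, RatingsMatrix


def make_matrix(rows, k=9, participant_ids=None, item_ids=None) -> RatingsMatrix:
    """Build a RatingsMatrix from a list of per-participant rating rows."""
    rows = [list(r) for r in rows]
    n, j = len(rows), len(rows[0])
    pids = participant_ids or [f"p{i+1}" for i in range(n)]
    iids = item_ids or [f"q{c+1}" for c in range(j)]
    frame = pd.DataFrame(rows, index=pids, columns=iids, dtype=float)
    return RatingsMatrix(frame, LikertScale(k))


# -- enumeration oracles -------------------------------------------------------


def enumerate_match_counts(pool_rows, n) -> Counter:
    """Exact distribution of the item-median match count over all N^n draws.

    ``pool_rows`` is a list of per-participant rating tuples.  Returns
    Counter {match_count: number_of_ordered_draws}.
    """
    j = len(pool_rows[0])
    full_medians = [
        statistics.median(row[col] for row in pool_rows) for col in range(j)
    ]
    counts = Counter()
    for draw in itertools.product(pool_rows, repeat=n):
        sub_medians = [statistics.median(r[col] for r in draw) for col in range(j)]
        matched = sum(
            1 for a, b in zip(sub_medians, full_medians) if abs(a - b) < 1e-9
        )
        counts[matched] += 1
    return counts


def oracle_consensus_status(ratings, critical=(7, 9), not_important=(1, 3),
                            inclusion_min=Fraction(7, 10), veto_max=Fraction(3, 20)) -> str:
    """Reference consensus classifier using exact Fractions."""
    n = len(ratings)
    c = sum(1 for r in ratings if critical[0] <= r <= critical[1])
    ni = sum(1 for r in ratings if not_important[0] <= r <= not_important[1])
    if Fraction(c, n) >= inclusion_min and Fraction(ni, n) < veto_max:
        return "inclusion"
    if Fraction(ni, n) >= inclusion_min and Fraction(c, n) < veto_max:
        return "exclusion"
    return "none"


def enumerate_consensus_counts(pool_rows, n, **crit_kwargs) -> Counter:
    """Exact distribution of the per-draw consensus count over all N^n draws."""
    j = len(pool_rows[0])
    counts = Counter()
    for draw in itertools.product(pool_rows, repeat=n):
        reached = sum(
            1
            for col in range(j)
            if oracle_consensus_status([r[col] for r in draw], **crit_kwargs) != "none"
        )
        counts[reached] += 1
    return counts


def dist_median_iqr(counter: Counter) -> tuple[float, float]:
    """Median and linear-interpolation IQR of an exact discrete distribution."""
    expanded = np.repeat(
        list(counter.keys()), list(counter.values())
    ).astype(float)
    q1, med, q3 = np.quantile(expanded, [0.25, 0.5, 0.75])
    return float(med), float(q3 - q1)


# -- fixtures ------------------------------------------------------------------


@pytest.fixture
def tiny_pool() -> RatingsMatrix:
    """3 participants x 2 items; small enough to enumerate all draws."""
    return make_matrix([[7, 2], [8, 2], [9, 5]])


@pytest.fixture
def degenerate_pool() -> RatingsMatrix:
    """Every participant rates every item identically (zero variance)."""
    return make_matrix([[9, 7, 8]] * 6)


@pytest.fixture
def wide_csv(tmp_path):
    path = tmp_path / "ratings_wide.csv"
    path.write_text(
        "participant_id,q1,q2\n"
        "a,7,8\n"
        "b,9,9\n"
        "c,1,2\n"
    )
    return path


@pytest.fixture
def long_csv(tmp_path):
    path = tmp_path / "ratings_long.csv"
    path.write_text(
        "participant,item,rating\n"
        "a,q1,7\na,q2,8\n"
        "b,q1,9\nb,q2,9\n"
        "c,q1,1\nc,q2,2\n"
    )
    return path
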