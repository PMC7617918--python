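"""A-priori consensus criteria and consensus-count replication curves.

Reporting-guideline and core-outcome-set Delphi surveys typically fix
consensus rules before seeing the data.  The standard pair implemented
here:

* consensus for inclusion — at least 70% of participants rate the item in
  the *critical* band (7-9 on a 9-point scale) AND fewer than 15% rate it
  *not important* (1-3);
* consensus for exclusion — the mirror image (>= 70% not-important,
  < 15% critical).

Shares are compared as exact rationals (count out of n raters), never as
rounded percentages, because the rules are thresholds rather than
reported summaries.  The bootstrap then asks how the *number of items
reaching consensus* behaves as the sample grows, exactly parallel to the
median-replicability curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .io import LikertScale, RatingsMatrix
from .resampling import (
    MatchDistribution,
    ResampleConfig,
    _rng_for_size,
    percent,
    summarize_counts,
)

__all__ = [
    "ConsensusCriteria",
    "ConsensusCurve",
    "consensus_status",
    "consensus_counts",
    "full_pool_consensus_count",
    "consensus_curve",
]


def _as_fraction(x) -> Fraction:
    # via str() so a float literal like 0.70 becomes exactly 7/10
    return x if isinstance(x, Fraction) else Fraction(str(x))


@dataclass(frozen=True)
class ConsensusCriteria:
    """Inclusion/exclusion threshold rules over two rating bands.

    Bands are inclusive integer ranges on the scale; ``inclusion_min`` is
    the share required in the favouring band (>=) and ``veto_max`` the
    share in the opposing band that blocks consensus (strict <).
    """

    critical_band: tuple[int, int] = (7, 9)
    not_important_band: tuple[int, int] = (1, 3)
    inclusion_min: Fraction = Fraction(7, 10)
    veto_max: Fraction = Fraction(3, 20)

    def __post_init__(self) -> None:
        object.__setattr__(self, "inclusion_min", _as_fraction(self.inclusion_min))
        object.__setattr__(self, "veto_max", _as_fraction(self.veto_max))
        lo_c, hi_c = self.critical_band
        lo_n, hi_n = self.not_important_band
        if not (lo_c <= hi_c and lo_n <= hi_n):
            raise ValueError("bands must be (low, high) with low <= high")
        if not (hi_n < lo_c or hi_c < lo_n):
            raise ValueError("critical and not-important bands must be disjoint")
        if not 0 < self.inclusion_min <= 1 or not 0 <= self.veto_max < 1:
            raise ValueError("thresholds must be proportions in (0,1]/[0,1)")
        if self.inclusion_min <= self.veto_max:
            raise ValueError("inclusion_min must exceed veto_max")

    @classmethod
    def default_for_scale(cls, scale: LikertScale | int) -> "ConsensusCriteria":
        """Top-3 / bottom-3 category bands for a k-point scale.

        Gives (7-9, 1-3) on 9 points and (8-10, 1-3) on 10 points.  The
        10-point choice is a convention this package fixes (and records in
        the run manifest): published rules are usually phrased for 9-point
        scales only.
        """
        k = scale.k if isinstance(scale, LikertScale) else int(scale)
        if k < 7:
            raise ValueError(f"default top-3/bottom-3 bands need k >= 7, got {k}")
        return cls(critical_band=(k - 2, k), not_important_band=(1, 3))

    def validate_scale(self, scale: LikertScale) -> None:
        for lo, hi in (self.critical_band, self.not_important_band):
            if lo < 1 or hi > scale.k:
                raise ValueError(
                    f"band ({lo},{hi}) falls outside the {scale.k}-point scale"
                )


# -- single-item classification ------------------------------------------------


def consensus_status(ratings_for_item, crit: ConsensusCriteria) -> str:
    """Classify one item's rating vector: 'inclusion', 'exclusion' or 'none'.

    The two outcomes are mutually exclusive by construction: both require
    a >= 70% share, and two disjoint bands cannot both hold >= 70%.
    """
    r = np.asarray(ratings_for_item)
    if r.size == 0:
        raise ValueError("empty rating vector")
    n = r.size
    c = int(((r >= crit.critical_band[0]) & (r <= crit.critical_band[1])).sum())
    ni = int(((r >= crit.not_important_band[0]) & (r <= crit.not_important_band[1])).sum())
    if Fraction(c, n) >= crit.inclusion_min and Fraction(ni, n) < crit.veto_max:
        return "inclusion"
    if Fraction(ni, n) >= crit.inclusion_min and Fraction(c, n) < crit.veto_max:
        return "exclusion"
    return "none"


# -- vectorized counting over bootstrap draws ----------------------------------


def _band_counts(sub: np.ndarray, band: tuple[int, int]) -> np.ndarray:
    return ((sub >= band[0]) & (sub <= band[1])).sum(axis=1)


def consensus_counts(sub: np.ndarray, crit: ConsensusCriteria) -> np.ndarray:
    """Per-draw number of items reaching consensus (either direction).

    ``sub`` is a (B, n, J) block of ratings.  Threshold comparisons are
    done in integer arithmetic (count * denominator vs numerator * n), so
    they are exact for any rational threshold.
    """
    _, n, _ = sub.shape
    c = _band_counts(sub, crit.critical_band)  # (B, J)
    ni = _band_counts(sub, crit.not_important_band)
    p, q = crit.inclusion_min.numerator, crit.inclusion_min.denominator
    v, w = crit.veto_max.numerator, crit.veto_max.denominator
    inclusion = (c * q >= p * n) & (ni * w < v * n)
    exclusion = (ni * q >= p * n) & (c * w < v * n)
    return (inclusion | exclusion).sum(axis=1)


def full_pool_consensus_count(rm: RatingsMatrix, crit: ConsensusCriteria) -> int:
    """Items reaching consensus in the complete participant pool."""
    rm.require_complete()
    crit.validate_scale(rm.scale)
    sub = rm.values[None, :, :]
    return int(consensus_counts(sub, crit)[0])


# -- the consensus curve -------------------------------------------------------


@dataclass
class ConsensusCurve:
    """Per-size summaries of the consensus-count distributions.

    Same summary conventions as the replicability curve; the count being
    summarised is "items reaching consensus in the draw" instead of
    "item medians matching the pool".
    """

    table: pd.DataFrame
    j_items: int
    n_pool: int
    n_draws: int
    seed: int
    central_stat: str = "consensus"

    COLUMNS = (
        "n",
        "median_matches",
        "iqr_matches",
        "mean_matches",
        "pct_replicability",
        "pct_variability",
    )

    def __post_init__(self) -> None:
        missing = [col for col in self.COLUMNS if col not in self.table.columns]
        if missing:
            raise ValueError(f"curve table lacks columns {missing}")
        self.table = self.table.loc[:, list(self.COLUMNS)].reset_index(drop=True)

    @property
    def sizes(self) -> list[int]:
        return [int(n) for n in self.table["n"]]

    def at(self, n: int) -> pd.Series:
        row = self.table.loc[self.table["n"] == n]
        if row.empty:
            raise KeyError(f"sample size {n} not on the curve grid")
        return row.iloc[0]

    def pct_at(self, n: int) -> int:
        return int(self.at(n)["pct_replicability"])

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConsensusCurve):
            return NotImplemented
        return (
            self.table.equals(other.table)
            and (self.j_items, self.n_pool, self.n_draws, self.seed)
            == (other.j_items, other.n_pool, other.n_draws, other.seed)
        )


def consensus_curve(
    rm: RatingsMatrix,
    crit: ConsensusCriteria | None = None,
    cfg: ResampleConfig = ResampleConfig(),
) -> tuple[ConsensusCurve, list[MatchDistribution]]:
    """Bootstrap the consensus-count curve.

    Per size n, B with-replacement subsamples are drawn with the same
    per-size substreams as :func:`replicability_curve` (same seed => the
    same participants are drawn), each draw's items are classified against
    ``crit``, and the per-draw consensus counts are summarised by
    median/IQR/mean and percentages of J.
    """
    rm.require_complete()
    if crit is None:
        crit = ConsensusCriteria.default_for_scale(rm.scale)
    crit.validate_scale(rm.scale)
    # same id-sorted canonical order as the replicability engine
    order = np.argsort(np.asarray(rm.participant_ids))
    values = rm.values[order].astype(np.int16)
    n_pool, j_items = values.shape

    rows = []
    dists = []
    for n in cfg.sizes:
        rng = _rng_for_size(cfg.seed, n)
        counts = np.empty(cfg.n_draws, dtype=int)
        chunk = max(1, min(cfg.n_draws, 200_000_000 // max(1, n * j_items)))
        done = 0
        while done < cfg.n_draws:
            b = min(chunk, cfg.n_draws - done)
            idx = rng.integers(0, n_pool, size=(b, n))
            counts[done : done + b] = consensus_counts(values[idx], crit)
            done += b
        rows.append({"n": n, **summarize_counts(counts, j_items, cfg.quantile_method)})
        dists.append(MatchDistribution(size=n, counts=counts))

    curve = ConsensusCurve(
        table=pd.DataFrame(rows),
        j_items=j_items,
        n_pool=n_pool,
        n_draws=cfg.n_draws,
        seed=cfg.seed,
    )
    return curve, dists
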