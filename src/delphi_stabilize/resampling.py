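"""Bootstrap subsampling engine: item-median match counts and replicability curves.

The central question: if a Delphi survey had recruited only n of its N
participants, how many of the J item medians would have come out the same?
For each sample size n on a grid, B subsamples of n participants are drawn
with replacement from the pool; per draw, the per-item central statistic
(median by default) of the subsample is compared with the full pool's, and
the number of items that agree is the draw's match count.  The B match
counts per size are summarised by their median, IQR (Q3 - Q1) and mean,
and expressed as percentages of J:

    % replicability = round(100 * median_matches / J)
    % variability   = round(100 * iqr_matches / J)

Replicability bands: < 60 below-moderate, 60-<80 moderate, 80-<90 high,
>= 90 very high.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import RatingsMatrix

__all__ = [
    "ResampleConfig",
    "ReplicabilityCurve",
    "MatchDistribution",
    "size_grid",
    "percent",
    "item_central",
    "match_count",
    "replicability_curve",
    "classify_replicability",
    "min_size_for",
]

#: numbers of latent draws kept in memory at once (chunking guard)
_MAX_CHUNK_ELEMENTS = 200_000_000

DEFAULT_SIZES = tuple(range(20, 501, 10))
SUBGROUP_SIZES = tuple(range(20, 101, 10))


def size_grid(start: int, stop: int, step: int) -> tuple[int, ...]:
    """Inclusive sample-size grid, e.g. size_grid(20, 500, 10)."""
    return tuple(range(start, stop + 1, step))


def percent(count: float, total: int) -> int:
    """Integer percentage, rounding half away from zero (18/22 -> 82, 2/22 -> 9)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(math.floor(100.0 * count / total + 0.5))


@dataclass(frozen=True)
class ResampleConfig:
    """Resampling plan: size grid, draws per size, seed, and match conventions.

    ``sizes`` defaults to 20..500 step 10 and ``n_draws`` to 1000 — the
    standard design for this analysis.  ``central_stat`` switches the whole
    pipeline between item medians and item means; means are compared after
    rounding both sides to ``mean_match_decimals`` places (exact equality
    of continuous means is almost surely never attained).
    ``quantile_method`` is the estimator used for the Q1/Q3 of the match
    counts (any method accepted by numpy's quantile).
    """

    sizes: tuple[int, ...] = DEFAULT_SIZES
    n_draws: int = 1000
    seed: int = 0
    central_stat: Literal["median", "mean"] = "median"
    mean_match_decimals: int = 1
    quantile_method: str = "linear"

    def __post_init__(self) -> None:
        sizes = tuple(int(n) for n in self.sizes)
        if not sizes:
            raise ValueError("sizes grid is empty")
        if any(n < 1 for n in sizes):
            raise ValueError("all sample sizes must be >= 1")
        if list(sizes) != sorted(sizes):
            raise ValueError("sizes must be sorted ascending")
        object.__setattr__(self, "sizes", sizes)
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.central_stat not in ("median", "mean"):
            raise ValueError(f"unknown central_stat {self.central_stat!r}")
        if self.mean_match_decimals < 0:
            raise ValueError("mean_match_decimals must be >= 0")


@dataclass
class ReplicabilityCurve:
    """Per-sample-size summaries of the match-count distributions.

    ``table`` has one row per size n with columns n, median_matches,
    iqr_matches, mean_matches, pct_replicability, pct_variability.
    Percent columns are integer-rounded; the match-count columns retain
    full precision.
    """

    table: pd.DataFrame
    j_items: int
    n_pool: int
    n_draws: int
    seed: int
    central_stat: str = "median"

    COLUMNS = (
        "n",
        "median_matches",
        "iqr_matches",
        "mean_matches",
        "pct_replicability",
        "pct_variability",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
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

    def __eq__(self, other) -> bool:  # value semantics, used by round-trip tests
        if not isinstance(other, ReplicabilityCurve):
            return NotImplemented
        return (
            self.table.equals(other.table)
            and (self.j_items, self.n_pool, self.n_draws, self.seed, self.central_stat)
            == (other.j_items, other.n_pool, other.n_draws, other.seed, other.central_stat)
        )


@dataclass
class MatchDistribution:
    """The raw B match counts for one sample size."""

    size: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)


# -- per-item central statistic ------------------------------------------------


def item_central(rm: RatingsMatrix, stat: str = "median") -> np.ndarray:
    """Per-item median (midpoint convention on even counts) or mean.

    With an even number of raters the median is the midpoint of the two
    central order statistics, so half-integers arise on integer data.
    """
    rm.require_complete()
    values = rm.values
    if stat == "median":
        return np.median(values, axis=0)
    if stat == "mean":
        return values.mean(axis=0)
    raise ValueError(f"unknown stat {stat!r}")


def match_count(
    sub_central: np.ndarray,
    full_central: np.ndarray,
    stat: str = "median",
    decimals: int = 1,
) -> int:
    """Number of items whose subsample central value replicates the pool's.

    Median mode counts exact equalities (half-integers included; the 1e-9
    tolerance only absorbs float representation).  Mean mode rounds both
    sides to ``decimals`` places first.
    """
    sub_central = np.asarray(sub_central, dtype=float)
    full_central = np.asarray(full_central, dtype=float)
    if sub_central.shape != full_central.shape:
        raise ValueError(
            f"length mismatch: {sub_central.shape} vs {full_central.shape}"
        )
    return int(_match_matrix(sub_central[None, :], full_central, stat, decimals).sum())


def _match_matrix(
    sub_central: np.ndarray, full_central: np.ndarray, stat: str, decimals: int
) -> np.ndarray:
    """Boolean (B, J) matrix of item matches for a block of draws."""
    if stat == "median":
        return np.abs(sub_central - full_central[None, :]) < 1e-9
    if stat == "mean":
        return np.round(sub_central, decimals) == np.round(full_central, decimals)[None, :]
    raise ValueError(f"unknown stat {stat!r}")


# -- the bootstrap loop --------------------------------------------------------


def _rng_for_size(seed: int, n: int) -> np.random.Generator:
    # one substream per sample size, keyed by n: editing the grid never
    # perturbs the draws taken at other sizes
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(n,)))


def draw_match_counts(
    values: np.ndarray,
    full_central: np.ndarray,
    n: int,
    n_draws: int,
    rng: np.random.Generator,
    stat: str = "median",
    decimals: int = 1,
) -> np.ndarray:
    """Match counts for ``n_draws`` with-replacement subsamples of size n."""
    n_pool, j_items = values.shape
    counts = np.empty(n_draws, dtype=int)
    chunk = max(1, min(n_draws, _MAX_CHUNK_ELEMENTS // max(1, n * j_items)))
    done = 0
    while done < n_draws:
        b = min(chunk, n_draws - done)
        idx = rng.integers(0, n_pool, size=(b, n))
        sub = values[idx]  # (b, n, J)
        if stat == "median":
            cen = np.median(sub, axis=1)
        else:
            cen = sub.mean(axis=1)
        counts[done : done + b] = _match_matrix(cen, full_central, stat, decimals).sum(axis=1)
        done += b
    return counts


def summarize_counts(
    counts: np.ndarray, j_items: int, quantile_method: str = "linear"
) -> dict[str, float]:
    """Median/IQR/mean of the B match counts plus integer percentages of J."""
    q1, med, q3 = np.quantile(counts, [0.25, 0.5, 0.75], method=quantile_method)
    iqr = q3 - q1
    return {
        "median_matches": float(med),
        "iqr_matches": float(iqr),
        "mean_matches": float(np.mean(counts)),
        "pct_replicability": percent(float(med), j_items),
        "pct_variability": percent(float(iqr), j_items),
    }


def replicability_curve(
    rm: RatingsMatrix,
    cfg: ResampleConfig = ResampleConfig(),
    reference_central: np.ndarray | None = None,
) -> tuple[ReplicabilityCurve, list[MatchDistribution]]:
    """Bootstrap the replicability curve of a complete ratings pool.

    For each n on ``cfg.sizes`` draws ``cfg.n_draws`` with-replacement
    subsamples of n participants, counts per draw how many item centrals
    equal the reference (the pool's own centrals unless
    ``reference_central`` overrides them, as the subgroup analysis does),
    and summarises the counts.  n may exceed the pool size N: with
    replacement the draw stays well defined, and small stakeholder pools
    are routinely probed past their size.  Deterministic given cfg.seed.
    """
    rm.require_complete()
    # draws index participants in id-sorted order, so the row order of the
    # input can never affect any downstream statistic
    order = np.argsort(np.asarray(rm.participant_ids))
    values = rm.values[order]
    n_pool, j_items = values.shape
    if reference_central is None:
        full_central = item_central(rm, cfg.central_stat)
    else:
        full_central = np.asarray(reference_central, dtype=float)
        if full_central.shape != (j_items,):
            raise ValueError(
                f"reference_central has shape {full_central.shape}, expected ({j_items},)"
            )
    if any(n > n_pool for n in cfg.sizes):
        warnings.warn(
            f"grid exceeds pool size ({max(cfg.sizes)} > {n_pool}); "
            "with-replacement draws remain defined",
            stacklevel=2,
        )

    rows = []
    dists = []
    for n in cfg.sizes:
        rng = _rng_for_size(cfg.seed, n)
        counts = draw_match_counts(
            values, full_central, n, cfg.n_draws, rng,
            cfg.central_stat, cfg.mean_match_decimals,
        )
        rows.append({"n": n, **summarize_counts(counts, j_items, cfg.quantile_method)})
        dists.append(MatchDistribution(size=n, counts=counts))

    curve = ReplicabilityCurve(
        table=pd.DataFrame(rows),
        j_items=j_items,
        n_pool=n_pool,
        n_draws=cfg.n_draws,
        seed=cfg.seed,
        central_stat=cfg.central_stat,
    )
    return curve, dists


# -- interpretation ------------------------------------------------------------


def classify_replicability(pct: float) -> str:
    """Band a replicability percentage.

    [0, 60) below_moderate; [60, 80) moderate; [80, 90) high;
    [90, 100] very_high.
    """
    if not 0 <= pct <= 100:
        raise ValueError(f"percentage {pct!r} outside [0, 100]")
    if pct < 60:
        return "below_moderate"
    if pct < 80:
        return "moderate"
    if pct < 90:
        return "high"
    return "very_high"


def min_size_for(curve: ReplicabilityCurve, threshold: float = 80) -> int | None:
    """Smallest grid size whose % replicability reaches ``threshold``; None if never."""
    if curve.table.empty:
        raise ValueError("empty curve")
    hit = curve.table.loc[curve.table["pct_replicability"] >= threshold, "n"]
    return int(hit.iloc[0]) if not hit.empty else None
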