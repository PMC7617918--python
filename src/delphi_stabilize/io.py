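"""Ratings data model, CSV readers/writers, and the completeness filter.

A Delphi round-1 dataset is a participants x items matrix of integer
Likert ratings.  Cells where a participant answered "unsure"/"no opinion"
or skipped the item are stored as missing (NaN); the analysis excludes
any participant with at least one missing cell, mirroring the standard
practice of analysing complete raters only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LikertScale",
    "RatingsMatrix",
    "DEFAULT_MISSING_TOKENS",
    "read_ratings",
    "read_meta",
    "align_meta",
    "filter_complete",
    "write_curve",
    "read_curve",
    "write_manifest",
]

#: Cell values treated as "no usable rating" (case-insensitive, stripped).
DEFAULT_MISSING_TOKENS = frozenset({"", "na", "nan", "unsure", "no opinion", "unsure/no opinion"})

META_COLUMNS = (
    "participant_id",
    "gender",
    "age_years",
    "role_raw",
    "years_experience",
    "country",
    "income_group",
)


@dataclass(frozen=True)
class LikertScale:
    """A k-point ordinal rating scale; valid ratings are integers in [1, k].

    The surveys this package targets use 9- or 10-point scales, but any
    k >= 3 is accepted.
    """

    k: int
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if int(self.k) != self.k or self.k < 3:
            raise ValueError(f"Likert scale needs an integer k >= 3, got {self.k!r}")
        object.__setattr__(self, "k", int(self.k))
        if self.labels is not None:
            labels = tuple(str(x) for x in self.labels)
            if len(labels) != self.k:
                raise ValueError(
                    f"scale has k={self.k} points but {len(labels)} labels"
                )
            object.__setattr__(self, "labels", labels)

    def contains(self, r: float) -> bool:
        return float(r).is_integer() and 1 <= r <= self.k


@dataclass
class RatingsMatrix:
    """Participants x items integer ratings with NaN marking missing cells.

    ``data`` is a DataFrame indexed by participant id with one column per
    item id; values are float64 (integers where present, NaN where the
    participant gave no usable rating).
    """

    data: pd.DataFrame
    scale: LikertScale

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate participant ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate item ids: {dupes}")
        values = self.data.to_numpy(dtype=float)
        present = ~np.isnan(values)
        bad = present & (
            (values < 1) | (values > self.scale.k) | (values != np.round(values))
        )
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"rating {values[i, j]!r} at participant "
                f"{self.data.index[i]!r}, item {self.data.columns[j]!r} "
                f"is outside the {self.scale.k}-point scale"
            )
        self.data = pd.DataFrame(
            values, index=self.data.index.astype(str), columns=self.data.columns.astype(str)
        )

    # -- convenience accessors -------------------------------------------------

    @property
    def participant_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def item_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        """Ratings as a float (N, J) array, NaN = missing."""
        return self.data.to_numpy(dtype=float)

    @property
    def is_complete(self) -> bool:
        return not self.data.isna().to_numpy().any()

    def require_complete(self) -> None:
        if self.n_participants == 0 or self.n_items == 0:
            raise ValueError("empty ratings matrix")
        if not self.is_complete:
            raise ValueError(
                "ratings matrix still contains missing cells; run filter_complete first"
            )

    def subset(self, participant_ids: Sequence[str]) -> "RatingsMatrix":
        """Restrict to the given participants (order as given)."""
        missing = [p for p in participant_ids if p not in self.data.index]
        if missing:
            raise KeyError(f"unknown participant ids: {missing}")
        return RatingsMatrix(self.data.loc[list(participant_ids)], self.scale)


# -- readers -------------------------------------------------------------------


def _parse_cell(
    raw: str,
    scale: LikertScale,
    missing_tokens: frozenset[str],
    where: str,
) -> float:
    token = raw.strip()
    if token.lower() in missing_tokens:
        return np.nan
    try:
        value = float(token)
    except ValueError:
        raise ValueError(f"unparseable rating {raw!r} at {where}") from None
    if not scale.contains(value):
        raise ValueError(
            f"rating {raw!r} at {where} is outside the {scale.k}-point scale [1, {scale.k}]"
        )
    return value


def read_ratings(
    path: str | Path,
    dialect: str = "wide",
    scale: LikertScale = LikertScale(9),
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
) -> RatingsMatrix:
    """Read a ratings CSV in ``wide`` or ``long`` dialect.

    wide: one row per participant; first column is the participant id and
    each remaining column is one item.  long: three columns
    (participant, item, rating), one row per rated cell.

    Tokens in ``missing_tokens`` (matched case-insensitively after
    stripping) become missing cells — this is how "unsure / no opinion"
    answers enter the matrix.  Numeric cells outside [1, k] raise, naming
    the offending cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tokens = frozenset(t.strip().lower() for t in missing_tokens)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)

    if dialect == "wide":
        if raw.shape[1] < 2:
            raise ValueError("wide ratings CSV needs an id column plus >=1 item column")
        ids = raw.iloc[:, 0].astype(str).str.strip()
        items = [str(c) for c in raw.columns[1:]]
        out = np.empty((len(raw), len(items)))
        for j, col in enumerate(raw.columns[1:]):
            for i, cell in enumerate(raw[col]):
                out[i, j] = _parse_cell(
                    cell, scale, tokens, f"participant {ids.iloc[i]!r}, item {items[j]!r}"
                )
        frame = pd.DataFrame(out, index=pd.Index(ids, name="participant_id"), columns=items)
        return RatingsMatrix(frame, scale)

    if dialect == "long":
        if raw.shape[1] != 3:
            raise ValueError(
                "long ratings CSV needs exactly 3 columns (participant, item, rating)"
            )
        part = raw.iloc[:, 0].astype(str).str.strip()
        item = raw.iloc[:, 1].astype(str).str.strip()
        pairs = pd.MultiIndex.from_arrays([part, item])
        if pairs.has_duplicates:
            dup = pairs[pairs.duplicated()][0]
            raise ValueError(f"duplicate (participant, item) pair {tuple(dup)!r}")
        vals = [
            _parse_cell(c, scale, tokens, f"participant {p!r}, item {it!r}")
            for p, it, c in zip(part, item, raw.iloc[:, 2])
        ]
        frame = (
            pd.DataFrame({"participant_id": part, "item": item, "rating": vals})
            .pivot(index="participant_id", columns="item", values="rating")
        )
        # preserve first-appearance order rather than pivot's lexical sort
        frame = frame.reindex(index=part.unique(), columns=item.unique())
        frame.columns.name = None
        return RatingsMatrix(frame, scale)

    raise ValueError(f"unknown dialect {dialect!r}; expected 'wide' or 'long'")


def read_meta(path: str | Path) -> pd.DataFrame:
    """Read a participant-metadata CSV keyed by ``participant_id``."""
    meta = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "participant_id" not in meta.columns:
        raise ValueError("metadata CSV must have a participant_id column")
    meta["participant_id"] = meta["participant_id"].str.strip()
    if meta["participant_id"].duplicated().any():
        dupes = meta.loc[meta["participant_id"].duplicated(), "participant_id"].tolist()
        raise ValueError(f"duplicate participant_id in metadata: {dupes}")
    for col in ("age_years", "years_experience"):
        if col in meta.columns:
            meta[col] = pd.to_numeric(meta[col], errors="coerce")
    return meta


def align_meta(
    rm: RatingsMatrix,
    meta: pd.DataFrame,
    allow_partial: bool = False,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Join metadata 1:1 onto the ratings rows.

    Returns the metadata restricted and reordered to the ratings
    participants, plus a report of ids present on only one side.  Real
    survey exports are messy, so mismatches are reported rather than
    silently dropped; proceeding on the intersection requires an explicit
    ``allow_partial=True``.
    """
    meta = meta.set_index(meta["participant_id"].astype(str), drop=False)
    ratings_ids = pd.Index(rm.participant_ids)
    unmatched_ratings = [p for p in ratings_ids if p not in meta.index]
    unmatched_meta = [p for p in meta.index if p not in set(ratings_ids)]
    report = {
        "ratings_without_meta": unmatched_ratings,
        "meta_without_ratings": unmatched_meta,
    }
    if unmatched_ratings and not allow_partial:
        raise ValueError(
            f"{len(unmatched_ratings)} rated participants have no metadata row "
            f"(e.g. {unmatched_ratings[:5]}); pass allow_partial=True to analyse "
            "the intersection"
        )
    keep = [p for p in ratings_ids if p in meta.index]
    aligned = meta.loc[keep].reset_index(drop=True)
    return aligned, report


# -- completeness filter -------------------------------------------------------


def filter_complete(rm: RatingsMatrix) -> tuple[RatingsMatrix, list[str]]:
    """Drop every participant with >=1 missing cell.

    Participants who answered "unsure/no opinion" anywhere or who did not
    rate all items are excluded wholly; the item set is unchanged.
    Returns the filtered matrix and the excluded participant ids.
    Raises if no participant survives (all downstream statistics would be
    undefined).
    """
    complete = ~rm.data.isna().any(axis=1)
    excluded = [str(p) for p in rm.data.index[~complete]]
    if not complete.any():
        raise ValueError("no participant rated all items; nothing to analyse")
    filtered = RatingsMatrix(rm.data.loc[complete], rm.scale)
    return filtered, excluded


# -- curve serialization -------------------------------------------------------

_CURVE_META_PREFIX = "# "


def write_curve(curve, path: str | Path) -> None:
    """Write a replicability/consensus curve as tidy CSV.

    One data row per sample size; curve-level metadata (J, N, B, seed,
    statistic) goes in ``# key=value`` header comment lines so a write →
    read round trip reconstructs the curve exactly.
    """
    table: pd.DataFrame = curve.table
    if table.empty:
        raise ValueError("refusing to write an empty curve")
    path = Path(path)
    meta = {
        "kind": type(curve).__name__,
        "j_items": curve.j_items,
        "n_pool": curve.n_pool,
        "n_draws": curve.n_draws,
        "seed": curve.seed,
        "central_stat": getattr(curve, "central_stat", "median"),
    }
    with open(path, "w", newline="") as fh:
        for key, value in meta.items():
            fh.write(f"{_CURVE_META_PREFIX}{key}={value}\n")
        table.to_csv(fh, index=False)


def read_curve(path: str | Path):
    """Inverse of :func:`write_curve`."""
    from .resampling import ReplicabilityCurve
    from .consensus import ConsensusCurve

    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith(_CURVE_META_PREFIX):
            key, _, value = line[len(_CURVE_META_PREFIX):].strip().partition("=")
            meta[key] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh)
    kinds = {"ReplicabilityCurve": ReplicabilityCurve, "ConsensusCurve": ConsensusCurve}
    cls = kinds[meta.get("kind", "ReplicabilityCurve")]
    return cls(
        table=table,
        j_items=int(meta["j_items"]),
        n_pool=int(meta["n_pool"]),
        n_draws=int(meta["n_draws"]),
        seed=int(meta["seed"]),
        central_stat=meta.get("central_stat", "median"),
    )


def write_manifest(manifest: dict, path: str | Path) -> None:
    """Write a JSON run manifest (seed, grids, filter counts, versions)."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
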