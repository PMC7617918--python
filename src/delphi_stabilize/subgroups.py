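"""Stakeholder groupings and per-group replicability curves.

Multistakeholder Delphi panels mix researchers, methodologists,
clinicians, patients and carers from many countries.  This module builds
the standard partitions of a panel —

* ``gender``            men / women
* ``role3``             Researchers (epidemiologists + trial investigators),
                        Methodologists (statisticians + trial methodologists),
                        Clinicians (clinical and allied health professionals)
* ``experience15``      < 15 vs >= 15 years in current role
* ``age44``             <= 44 vs >= 45 years old
* ``region2``           Europe vs Rest of the World (editable country table)
* ``participant_type``  patient and carer vs clinician / health care professional
* ``income4``           four World Bank country-income classes (year-versioned table)

— and reruns the bootstrap replicability analysis inside each group,
typically on a reduced grid (20..100 step 10) because stakeholder pools
are small.  With-replacement draws stay defined past the group size, so a
34-person group can still be probed at n = 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import RatingsMatrix
from .resampling import (
    SUBGROUP_SIZES,
    MatchDistribution,
    ReplicabilityCurve,
    ResampleConfig,
    item_central,
    replicability_curve,
)

__all__ = [
    "GroupingSpec",
    "UNCLASSIFIED",
    "builtin_specs",
    "build_groups",
    "subgroup_curves",
    "load_region_table",
    "load_income_table",
]

#: Bucket for participants a rule cannot place; always reported, never dropped.
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class GroupingSpec:
    """A named rule mapping participant metadata to group labels.

    ``rule`` receives the metadata DataFrame and returns one label per row
    (a Series aligned to it); rows it cannot classify should get
    ``UNCLASSIFIED``.  ``grid`` is the sample-size grid used when curves
    are computed per group.
    """

    name: str
    rule: Callable[[pd.DataFrame], pd.Series]
    grid: tuple[int, ...] = SUBGROUP_SIZES


def _norm(series: pd.Series) -> pd.Series:
    return series.astype(str).str.strip().str.lower()


def load_region_table() -> pd.DataFrame:
    """Country -> Europe / Rest of the World mapping shipped with the package."""
    with resources.files("delphi_stabilize.data").joinpath("regions.csv").open() as fh:
        return pd.read_csv(fh)


def load_income_table() -> pd.DataFrame:
    """Country -> World Bank income-class mapping (2024 vintage)."""
    path = resources.files("delphi_stabilize.data").joinpath("income_groups_2024.csv")
    with path.open() as fh:
        return pd.read_csv(fh)


# -- built-in rules ------------------------------------------------------------

_ROLE3 = {
    "epidemiologist": "Researchers",
    "trial investigator": "Researchers",
    "statistician": "Methodologists",
    "trial methodologist": "Methodologists",
    "clinician/health and allied health professional": "Clinicians",
    "clinician": "Clinicians",
    "health professional": "Clinicians",
    "allied health professional": "Clinicians",
}

_GENDER = {"man": "Men", "men": "Men", "male": "Men",
           "woman": "Women", "women": "Women", "female": "Women"}

_PARTICIPANT_TYPE = {
    "patient and carer": "Patients/Carers",
    "patient": "Patients/Carers",
    "carer": "Patients/Carers",
    "clinician/health care professional": "Clinicians/Health professionals",
    "clinician": "Clinicians/Health professionals",
    "health care professional": "Clinicians/Health professionals",
}

_INCOME_CLASSES = (
    "High Income Country",
    "High Middle-Income Country",
    "Low Middle-Income Country",
    "Low Income Country",
)


def _map_rule(column: str, mapping: Mapping[str, str]) -> Callable[[pd.DataFrame], pd.Series]:
    def rule(meta: pd.DataFrame) -> pd.Series:
        if column not in meta.columns:
            raise KeyError(f"metadata lacks column {column!r}")
        return _norm(meta[column]).map(mapping).fillna(UNCLASSIFIED)

    return rule


def _numeric_cut(
    column: str, boundary: float, low_label: str, high_label: str
) -> Callable[[pd.DataFrame], pd.Series]:
    # low_label for values < boundary, high_label for values >= boundary
    def rule(meta: pd.DataFrame) -> pd.Series:
        if column not in meta.columns:
            raise KeyError(f"metadata lacks column {column!r}")
        x = pd.to_numeric(meta[column], errors="coerce")
        out = pd.Series(UNCLASSIFIED, index=meta.index, dtype=object)
        out[x < boundary] = low_label
        out[x >= boundary] = high_label
        return out

    return rule


def _region2_rule(meta: pd.DataFrame) -> pd.Series:
    if "region" in meta.columns:
        reg = meta["region"].astype(str).str.strip()
        return reg.where(reg.isin(["Europe", "Rest of the World"]), UNCLASSIFIED)
    table = load_region_table()
    lut = dict(zip(_norm(table["country"]), table["region"]))
    return _norm(meta["country"]).map(lut).fillna(UNCLASSIFIED)


def _income4_rule(meta: pd.DataFrame) -> pd.Series:
    if "income_group" in meta.columns:
        inc = meta["income_group"].astype(str).str.strip()
        return inc.where(inc.isin(_INCOME_CLASSES), UNCLASSIFIED)
    table = load_income_table()
    lut = dict(zip(_norm(table["country"]), table["income_group"]))
    return _norm(meta["country"]).map(lut).fillna(UNCLASSIFIED)


def builtin_specs() -> dict[str, GroupingSpec]:
    """The standard stakeholder groupings, keyed by name."""
    return {
        "gender": GroupingSpec("gender", _map_rule("gender", _GENDER)),
        "role3": GroupingSpec("role3", _map_rule("role_raw", _ROLE3)),
        "experience15": GroupingSpec(
            "experience15",
            _numeric_cut("years_experience", 15, "<15 years", ">=15 years"),
        ),
        "age44": GroupingSpec(
            "age44", _numeric_cut("age_years", 45, "<=44 years", ">44 years")
        ),
        "region2": GroupingSpec("region2", _region2_rule),
        "participant_type": GroupingSpec(
            "participant_type", _map_rule("participant_type", _PARTICIPANT_TYPE)
        ),
        "income4": GroupingSpec("income4", _income4_rule),
    }


# -- building and analysing groups --------------------------------------------


def build_groups(
    meta: pd.DataFrame, spec: GroupingSpec
) -> dict[str, list[str]]:
    """Partition participants into labelled groups under ``spec``.

    Every participant receives exactly one label; rule outputs that are
    lists/sets (overlapping membership) raise.  The ``unclassified``
    bucket appears in the result whenever the rule could not place
    someone, so nothing is silently dropped.
    """
    if "participant_id" not in meta.columns:
        raise ValueError("metadata lacks participant_id")
    labels = spec.rule(meta)
    if len(labels) != len(meta):
        raise ValueError(f"rule {spec.name!r} returned {len(labels)} labels for {len(meta)} rows")
    bad = [lab for lab in labels if isinstance(lab, (list, set, tuple))]
    if bad:
        raise ValueError(f"rule {spec.name!r} assigned overlapping labels: {bad[:3]}")
    groups: dict[str, list[str]] = {}
    for pid, lab in zip(meta["participant_id"].astype(str), labels):
        groups.setdefault(str(lab), []).append(pid)
    return groups


def subgroup_curves(
    rm: RatingsMatrix,
    groups: Mapping[str, Sequence[str]],
    cfg: ResampleConfig | None = None,
    reference: str = "own_pool",
    include_unclassified: bool = False,
) -> dict[str, tuple[ReplicabilityCurve, list[MatchDistribution]]]:
    """Replicability curves computed inside each stakeholder group.

    Under ``own_pool`` (default) each group's resamples are compared
    against that group's own full-pool item centrals — the natural
    reading when a group's replicability is expected to approach 100% as
    n approaches the group size.  Under ``overall_pool`` they are compared
    against the whole filtered sample's centrals, measuring how well a
    single stakeholder group alone reproduces the panel-wide result.
    """
    if cfg is None:
        cfg = ResampleConfig(sizes=SUBGROUP_SIZES)
    if reference not in ("own_pool", "overall_pool"):
        raise ValueError(f"unknown reference {reference!r}")
    overall = item_central(rm, cfg.central_stat) if reference == "overall_pool" else None

    out: dict[str, tuple[ReplicabilityCurve, list[MatchDistribution]]] = {}
    for label, members in groups.items():
        if label == UNCLASSIFIED and not include_unclassified:
            continue
        if len(members) == 0:
            raise ValueError(f"group {label!r} is empty")
        sub = rm.subset(list(members))
        out[label] = replicability_curve(sub, cfg, reference_central=overall)
    return out
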