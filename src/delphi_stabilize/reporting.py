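"""End-to-end orchestration: full-sample, subgroup and consensus analyses,
publication-shaped tables, boxplot figures, and a reproducibility manifest.

The emitted tables mirror the standard presentation of this analysis:

* a percent table across sample sizes — "% median replicability
  (variability)" per dataset;
* per-grouping comparison tables with "median replicability (IQR)" and
  "% replicability (%variability)" columns, one column pair per group;
* a consensus table — "% median number of items reaching consensus
  (variability)";
* boxplots of the match-count distributions (sample size on the x-axis,
  matches on the y-axis), whiskers drawn with the same quantile
  convention as the tabulated IQRs.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .consensus import ConsensusCriteria, ConsensusCurve, consensus_curve
from .io import RatingsMatrix, filter_complete, write_curve, write_manifest
from .resampling import (
    MatchDistribution,
    ReplicabilityCurve,
    ResampleConfig,
    classify_replicability,
    min_size_for,
    percent,
    replicability_curve,
)
from .subgroups import GroupingSpec, build_groups, builtin_specs, subgroup_curves

__all__ = [
    "AnalysisBundle",
    "run_full_analysis",
    "percent_table",
    "subgroup_table",
    "boxplot_matches",
    "stability_monitor",
    "write_bundle",
]


@dataclass
class AnalysisBundle:
    """Everything one end-to-end run produced."""

    curve: ReplicabilityCurve
    dists: list[MatchDistribution]
    consensus: ConsensusCurve | None
    consensus_dists: list[MatchDistribution]
    subgroup: dict[str, dict[str, ReplicabilityCurve]]
    excluded_ids: list[str]
    manifest: dict


def _ratings_hash(rm: RatingsMatrix) -> str:
    payload = rm.data.to_csv().encode()
    return hashlib.sha256(payload).hexdigest()


def run_full_analysis(
    rm: RatingsMatrix,
    meta: pd.DataFrame | None = None,
    cfg: ResampleConfig = ResampleConfig(),
    criteria: ConsensusCriteria | None = None,
    grouping_specs: Sequence[GroupingSpec] | None = None,
    subgroup_cfg: ResampleConfig | None = None,
    subgroup_reference: str = "own_pool",
    run_consensus: bool = True,
) -> AnalysisBundle:
    """Filter, bootstrap, classify, and assemble one analysis bundle.

    Applies the completeness filter, computes the full-sample
    replicability curve, the consensus-count curve (unless disabled), and
    — when metadata and grouping specs are given — per-group curves on
    the subgroup grid.  The manifest records every convention the numbers
    depend on, so any published cell is reproducible from it alone.
    """
    filtered, excluded = filter_complete(rm)
    curve, dists = replicability_curve(filtered, cfg)

    cons_curve = None
    cons_dists: list[MatchDistribution] = []
    if run_consensus:
        crit = criteria or ConsensusCriteria.default_for_scale(filtered.scale)
        cons_curve, cons_dists = consensus_curve(filtered, crit, cfg)
    else:
        crit = criteria

    sub_results: dict[str, dict[str, ReplicabilityCurve]] = {}
    if meta is not None and grouping_specs:
        kept = meta[meta["participant_id"].astype(str).isin(filtered.participant_ids)]
        for spec in grouping_specs:
            groups = build_groups(kept, spec)
            scfg = subgroup_cfg or ResampleConfig(
                sizes=spec.grid,
                n_draws=cfg.n_draws,
                seed=cfg.seed,
                central_stat=cfg.central_stat,
                mean_match_decimals=cfg.mean_match_decimals,
                quantile_method=cfg.quantile_method,
            )
            curves = subgroup_curves(filtered, groups, scfg, reference=subgroup_reference)
            sub_results[spec.name] = {lab: c for lab, (c, _) in curves.items()}

    manifest = {
        "package_version": __version__,
        "timestamp_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        "ratings_sha256": _ratings_hash(rm),
        "n_pool_raw": rm.n_participants,
        "n_pool_filtered": filtered.n_participants,
        "n_excluded_incomplete": len(excluded),
        "j_items": filtered.n_items,
        "scale_k": filtered.scale.k,
        "sizes": list(cfg.sizes),
        "n_draws": cfg.n_draws,
        "seed": cfg.seed,
        "central_stat": cfg.central_stat,
        "mean_match_decimals": cfg.mean_match_decimals,
        "quantile_method": cfg.quantile_method,
        "consensus_criteria": None
        if crit is None
        else {
            "critical_band": list(crit.critical_band),
            "not_important_band": list(crit.not_important_band),
            "inclusion_min": str(crit.inclusion_min),
            "veto_max": str(crit.veto_max),
        },
        "subgroup_reference": subgroup_reference if sub_results else None,
        "grouping_specs": sorted(sub_results),
    }
    return AnalysisBundle(
        curve=curve,
        dists=dists,
        consensus=cons_curve,
        consensus_dists=cons_dists,
        subgroup=sub_results,
        excluded_ids=excluded,
        manifest=manifest,
    )


# -- table emitters ------------------------------------------------------------


def percent_table(curves: Mapping[str, ReplicabilityCurve | ConsensusCurve]) -> pd.DataFrame:
    """'% replicability (variability)' across sizes, one column per dataset."""
    out = None
    for name, curve in curves.items():
        col = curve.table.apply(
            lambda r: f"{int(r['pct_replicability'])}% ({int(r['pct_variability'])}%)",
            axis=1,
        )
        frame = pd.DataFrame({"n": curve.table["n"].astype(int), name: col})
        out = frame if out is None else out.merge(frame, on="n", how="outer")
    if out is None:
        raise ValueError("no curves given")
    return out


def _fmt_number(x: float) -> str:
    return f"{x:g}"


def subgroup_table(curves: Mapping[str, ReplicabilityCurve]) -> pd.DataFrame:
    """Comparison table: per group, 'median (IQR)' and '% (%)' column pair."""
    if not curves:
        raise ValueError("no subgroup curves given")
    out = None
    for label, curve in curves.items():
        med = curve.table.apply(
            lambda r: f"{_fmt_number(r['median_matches'])} ({_fmt_number(r['iqr_matches'])})",
            axis=1,
        )
        pct = curve.table.apply(
            lambda r: f"{int(r['pct_replicability'])}% ({int(r['pct_variability'])}%)",
            axis=1,
        )
        frame = pd.DataFrame(
            {
                "n": curve.table["n"].astype(int),
                f"{label} | median replicability (IQR)": med,
                f"{label} | % replicability (%variability)": pct,
            }
        )
        out = frame if out is None else out.merge(frame, on="n", how="outer")
    return out


def check_percent_consistency(curve: ReplicabilityCurve | ConsensusCurve) -> None:
    """Assert percent cells equal round(100*count/J) of the count cells."""
    for _, row in curve.table.iterrows():
        assert int(row["pct_replicability"]) == percent(row["median_matches"], curve.j_items)
        assert int(row["pct_variability"]) == percent(row["iqr_matches"], curve.j_items)


# -- figures -------------------------------------------------------------------


def boxplot_matches(
    dists: Sequence[MatchDistribution],
    j_items: int,
    title: str = "",
    path: str | Path | None = None,
    quantile_method: str = "linear",
):
    """Boxplots of match counts by sample size (whiskers use the IQR convention)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, 0.28 * len(dists)), 4))
    data = [d.counts for d in dists]
    stats = []
    for d in dists:
        q1, med, q3 = np.quantile(d.counts, [0.25, 0.5, 0.75], method=quantile_method)
        stats.append(
            {
                "label": str(d.size),
                "mean": float(np.mean(d.counts)),
                "med": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "whislo": float(np.min(d.counts)),
                "whishi": float(np.max(d.counts)),
                "fliers": [],
            }
        )
    ax.bxp(stats, showfliers=False)
    ax.set_xlabel("resampled sample size n")
    ax.set_ylabel("item medians replicated")
    ax.set_ylim(0, j_items)
    if title:
        ax.set_title(title)
    step = max(1, len(dists) // 12)
    for i, lab in enumerate(ax.get_xticklabels()):
        lab.set_visible(i % step == 0)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


# -- accrual monitoring --------------------------------------------------------


def stability_monitor(
    snapshots: Sequence[RatingsMatrix],
    cfg: ResampleConfig = ResampleConfig(),
    threshold: float = 80,
) -> pd.DataFrame:
    """Track replicability while a panel accrues participants.

    ``snapshots`` must be nested participant sets (each later snapshot
    contains every earlier participant).  For each snapshot the curve is
    recomputed after filtering, and the summary row reports the largest
    grid size not exceeding the snapshot's filtered pool (the largest
    feasible probe of the data so far) with its replicability band; the
    ``flag`` column marks the first snapshot whose feasible replicability
    enters the high band (>= ``threshold``).
    """
    if not snapshots:
        raise ValueError("no snapshots given")
    prev: set[str] = set()
    for s, rm in enumerate(snapshots):
        ids = set(rm.participant_ids)
        if not prev.issubset(ids):
            raise ValueError(f"snapshot {s} is not a superset of snapshot {s - 1}")
        prev = ids

    rows = []
    flagged = False
    for s, rm in enumerate(snapshots):
        filtered, excluded = filter_complete(rm)
        feasible = [n for n in cfg.sizes if n <= filtered.n_participants]
        probe = max(feasible) if feasible else min(cfg.sizes)
        curve, _ = replicability_curve(filtered, cfg)
        pct = curve.pct_at(probe)
        flag = (not flagged) and pct >= threshold
        flagged = flagged or flag
        rows.append(
            {
                "snapshot": s,
                "n_raw": rm.n_participants,
                "n_complete": filtered.n_participants,
                "probe_n": probe,
                "pct_replicability": pct,
                "band": classify_replicability(pct),
                "high_band_entered": flag,
            }
        )
    return pd.DataFrame(rows)


# -- output bundle -------------------------------------------------------------


def write_bundle(bundle: AnalysisBundle, outdir: str | Path, name: str = "survey") -> None:
    """Write curves, tables, figures and the manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_curve(bundle.curve, outdir / f"{name}_replicability_curve.csv")
    percent_table({name: bundle.curve}).to_csv(
        outdir / f"{name}_percent_table.csv", index=False
    )
    boxplot_matches(
        bundle.dists,
        bundle.curve.j_items,
        title=f"{name}: median replicability by sample size",
        path=outdir / f"{name}_replicability_boxplot.png",
        quantile_method=bundle.manifest["quantile_method"],
    )
    if bundle.consensus is not None:
        write_curve(bundle.consensus, outdir / f"{name}_consensus_curve.csv")
        percent_table({name: bundle.consensus}).to_csv(
            outdir / f"{name}_consensus_table.csv", index=False
        )
    for spec_name, curves in bundle.subgroup.items():
        subgroup_table(curves).to_csv(
            outdir / f"{name}_subgroups_{spec_name}.csv", index=False
        )
    write_manifest(bundle.manifest, outdir / f"{name}_manifest.json")
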