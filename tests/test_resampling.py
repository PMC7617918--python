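"""The bootstrap engine: central statistics, match counting, curves, bands."""

from contextlib import nullcontext as _nullcontext

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from delphi_stabilize import (
    ResampleConfig,
    SyntheticConfig,
    classify_replicability,
    filter_complete,
    generate,
    item_central,
    match_count,
    min_size_for,
    percent,
    replicability_curve,
)

from conftest import dist_median_iqr, enumerate_match_counts, make_matrix


class TestItemCentral:
    def test_odd_median(self):
        rm = make_matrix([[1], [9], [9]])
        assert item_central(rm, "median")[0] == 9

    def test_even_median_midpoint(self):
        rm = make_matrix([[7], [8]])
        assert item_central(rm, "median")[0] == 7.5

    def test_mean(self):
        rm = make_matrix([[2], [4], [4], [6]])
        assert item_central(rm, "mean")[0] == 4.0

    def test_incomplete_matrix_rejected(self):
        rm = make_matrix([[7, np.nan], [8, 9]])
        with pytest.raises(ValueError, match="missing"):
            item_central(rm)


class TestMatchCount:
    def test_identity_vector(self):
        v = np.arange(22, dtype=float) % 9 + 1
        assert match_count(v, v) == 22

    def test_half_integer_mismatch(self):
        assert match_count([7, 8.5, 9], [7, 8, 9], stat="median") == 2

    def test_mean_mode_rounds_both_sides(self):
        # 7.14 -> 7.1 vs 7.12 -> 7.1 (match); 8.31 -> 8.3 vs 8.26 -> 8.3 (match)
        assert match_count([7.14, 8.31], [7.12, 8.26], stat="mean", decimals=1) == 2
        # at 2 decimals neither pair agrees
        assert match_count([7.14, 8.31], [7.12, 8.26], stat="mean", decimals=2) == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            match_count([1, 2], [1, 2, 3])


class TestReplicabilityCurve:
    def test_degenerate_pool_laws(self, degenerate_pool):
        cfg = ResampleConfig(sizes=(2, 5, 9), n_draws=100, seed=0)
        with pytest.warns(UserWarning, match="exceeds pool"):
            curve, dists = replicability_curve(degenerate_pool, cfg)
        assert (curve.table["pct_replicability"] == 100).all()
        assert (curve.table["pct_variability"] == 0).all()
        assert (curve.table["median_matches"] == 3).all()
        assert all((d.counts == 3).all() for d in dists)

    def test_monte_carlo_matches_enumeration(self, tiny_pool):
        pool_rows = [tuple(r) for r in tiny_pool.values]
        exact = enumerate_match_counts(pool_rows, n=2)
        exact_med, exact_iqr = dist_median_iqr(exact)
        cfg = ResampleConfig(sizes=(2,), n_draws=10_000, seed=42)
        curve, dists = replicability_curve(tiny_pool, cfg)
        row = curve.at(2)
        assert row["median_matches"] == exact_med
        assert abs(row["iqr_matches"] - exact_iqr) <= 1.0  # IQR of ints, MC jitter
        # full distributional agreement at larger B
        cfg_big = ResampleConfig(sizes=(3,), n_draws=50_000, seed=7)
        _, dists_big = replicability_curve(
            make_matrix([[7, 2], [8, 2], [9, 5], [7, 5]]), cfg_big
        )
        exact4 = enumerate_match_counts(
            [(7, 2), (8, 2), (9, 5), (7, 5)], n=3
        )
        total = sum(exact4.values())
        counts = dists_big[0].counts
        tv = 0.5 * sum(
            abs(exact4.get(k, 0) / total - np.mean(counts == k))
            for k in range(3)
        )
        assert tv < 0.02

    def test_seeded_determinism(self, tiny_pool):
        cfg = ResampleConfig(sizes=(2, 3), n_draws=200, seed=5)
        c1, d1 = replicability_curve(tiny_pool, cfg)
        c2, d2 = replicability_curve(tiny_pool, cfg)
        pd.testing.assert_frame_equal(c1.table, c2.table)
        for a, b in zip(d1, d2):
            np.testing.assert_array_equal(a.counts, b.counts)

    def test_grid_extension_preserves_earlier_sizes(self, tiny_pool):
        short = ResampleConfig(sizes=(2, 3), n_draws=100, seed=5)
        long = ResampleConfig(sizes=(1, 2, 3, 4), n_draws=100, seed=5)
        _, d_short = replicability_curve(tiny_pool, short)
        with pytest.warns(UserWarning):
            _, d_long = replicability_curve(tiny_pool, long)
        by_size = {d.size: d.counts for d in d_long}
        for d in d_short:
            np.testing.assert_array_equal(d.counts, by_size[d.size])

    def test_participant_order_invariance(self):
        cfg = SyntheticConfig(n_participants=40, n_items=8, seed=3)
        rm, _, _ = generate(cfg)
        rcfg = ResampleConfig(sizes=(10, 20), n_draws=300, seed=1)
        c1, _ = replicability_curve(rm, rcfg)
        rng = np.random.default_rng(0)
        perm = rng.permutation(rm.n_participants)
        shuffled = make_matrix(
            rm.values[perm],
            k=rm.scale.k,
            participant_ids=[rm.participant_ids[i] for i in perm],
            item_ids=rm.item_ids,
        )
        c2, _ = replicability_curve(shuffled, rcfg)
        pd.testing.assert_frame_equal(c1.table, c2.table)

    def test_n_may_exceed_pool(self, tiny_pool):
        cfg = ResampleConfig(sizes=(100,), n_draws=50, seed=0)
        with pytest.warns(UserWarning, match="exceeds pool"):
            curve, _ = replicability_curve(tiny_pool, cfg)
        assert 0 <= curve.at(100)["median_matches"] <= 2

    def test_mean_stat_curve_runs(self, tiny_pool):
        cfg = ResampleConfig(
            sizes=(2,), n_draws=100, seed=0, central_stat="mean", mean_match_decimals=1
        )
        curve, _ = replicability_curve(tiny_pool, cfg)
        assert curve.central_stat == "mean"
        assert 0 <= curve.at(2)["median_matches"] <= 2

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(1, 9), min_size=2, max_size=4),
            min_size=2,
            max_size=6,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1),
        st.integers(0, 2**20),
    )
    def test_summary_bounds(self, rows, seed):
        rm = make_matrix(rows)
        j = rm.n_items
        cfg = ResampleConfig(sizes=(2, 3), n_draws=40, seed=seed)
        with pytest.warns(UserWarning) if rm.n_participants < 3 else _nullcontext():
            curve, dists = replicability_curve(rm, cfg)
        assert ((curve.table["median_matches"] >= 0) & (curve.table["median_matches"] <= j)).all()
        assert ((curve.table["mean_matches"] >= 0) & (curve.table["mean_matches"] <= j)).all()
        assert ((curve.table["iqr_matches"] >= 0) & (curve.table["iqr_matches"] <= j)).all()
        for d in dists:
            assert d.counts.min() >= 0 and d.counts.max() <= j

    def test_stochastic_monotonicity(self):
        # statistical, not hard: growing subsamples replicate at least as well
        wins = 0
        reps = 8
        for seed in range(reps):
            rm, _, _ = generate(
                SyntheticConfig(n_participants=80, n_items=20, seed=seed)
            )
            cfg = ResampleConfig(sizes=(20, 160), n_draws=200, seed=seed)
            with pytest.warns(UserWarning):
                curve, _ = replicability_curve(rm, cfg)
            if curve.at(160)["mean_matches"] >= curve.at(20)["mean_matches"]:
                wins += 1
        assert wins >= reps - 1


class TestInterpretation:
    @pytest.mark.parametrize(
        "pct,band",
        [
            (0, "below_moderate"),
            (59, "below_moderate"),
            (60, "moderate"),
            (79, "moderate"),
            (80, "high"),
            (89, "high"),
            (90, "very_high"),
            (100, "very_high"),
        ],
    )
    def test_bands(self, pct, band):
        assert classify_replicability(pct) == band

    def test_band_input_validated(self):
        with pytest.raises(ValueError):
            classify_replicability(101)

    def test_min_size_threshold_crossing(self, tiny_pool):
        cfg = ResampleConfig(sizes=(2, 3), n_draws=100, seed=0)
        curve, _ = replicability_curve(tiny_pool, cfg)
        curve.table.loc[:, "pct_replicability"] = [77, 82]
        assert min_size_for(curve, 80) == 3
        curve.table.loc[:, "pct_replicability"] = [100, 100]
        assert min_size_for(curve, 80) == 2
        curve.table.loc[:, "pct_replicability"] = [70, 79]
        assert min_size_for(curve, 80) is None

    def test_percent_rounding_examples(self):
        assert percent(18, 22) == 82
        assert percent(2, 22) == 9
        assert percent(0, 5) == 0
        assert percent(5, 5) == 100


class TestConfigValidation:
    def test_rejects_empty_grid(self):
        with pytest.raises(ValueError):
            ResampleConfig(sizes=())

    def test_rejects_unsorted_grid(self):
        with pytest.raises(ValueError):
            ResampleConfig(sizes=(30, 20))

    def test_rejects_bad_stat(self):
        with pytest.raises(ValueError):
            ResampleConfig(central_stat="mode")
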