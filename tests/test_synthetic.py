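"""Ground-truth properties of the latent-opinion rating generator."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from delphi_stabilize import (
    ResampleConfig,
    SyntheticConfig,
    filter_complete,
    generate,
    replicability_curve,
    scenario_presets,
)
from delphi_stabilize.synthetic import discretize, latent_window


class TestGenerate:
    def test_noise_free_single_group_is_degenerate(self):
        cfg = SyntheticConfig(
            n_participants=30,
            n_items=8,
            group_mix={"only": (1.0, 0.5)},
            participant_sd=0.0,
            residual_sd=0.0,
            knife_edge_fraction=0.0,
            seed=3,
        )
        rm, _, _ = generate(cfg)
        values = rm.values
        assert (values == values[0]).all()  # every rater identical
        rcfg = ResampleConfig(sizes=(5, 20), n_draws=100, seed=0)
        curve, _ = replicability_curve(rm, rcfg)
        assert (curve.table["pct_replicability"] == 100).all()

    def test_filter_removes_exactly_the_flagged_incomplete(self):
        cfg = SyntheticConfig(
            n_participants=200, n_items=12, incomplete_rate=0.1, seed=17
        )
        rm, _, truth = generate(cfg)
        assert len(truth.incomplete_ids) == 20
        filtered, excluded = filter_complete(rm)
        assert sorted(excluded) == sorted(truth.incomplete_ids)
        assert filtered.n_participants == 180

    def test_seeded_determinism(self):
        cfg = SyntheticConfig(n_participants=50, n_items=9, incomplete_rate=0.1, seed=5)
        rm1, meta1, t1 = generate(cfg)
        rm2, meta2, t2 = generate(cfg)
        pd.testing.assert_frame_equal(rm1.data, rm2.data)
        pd.testing.assert_frame_equal(meta1, meta2)
        np.testing.assert_array_equal(t1.item_locations, t2.item_locations)
        assert t1.incomplete_ids == t2.incomplete_ids

    @pytest.mark.parametrize("k", [3, 5, 9, 10])
    def test_ratings_within_scale(self, k):
        cfg = SyntheticConfig(n_participants=80, n_items=10, k=k, seed=k)
        rm, _, _ = generate(cfg)
        values = rm.values
        assert values.min() >= 1 and values.max() <= k

    def test_marginal_shifts_monotonically_with_item_location(self):
        cfg = SyntheticConfig(
            n_participants=4000, n_items=30, knife_edge_fraction=0.0, seed=9
        )
        rm, _, truth = generate(cfg)
        item_means = rm.values.mean(axis=0)
        order = np.argsort(truth.item_locations)
        # item means must increase with mu_j (allowing sampling jitter between
        # near-ties): rank correlation close to 1
        rho = np.corrcoef(
            np.argsort(np.argsort(truth.item_locations)),
            np.argsort(np.argsort(item_means)),
        )[0, 1]
        assert rho > 0.95
        assert item_means[order[-1]] > item_means[order[0]]

    def test_knife_edge_items_depress_small_sample_replicability(self):
        base = dict(n_participants=150, n_items=30, seed=21)
        sharp, _, _ = generate(SyntheticConfig(knife_edge_fraction=1.0, **base))
        smooth, _, _ = generate(SyntheticConfig(knife_edge_fraction=0.0, **base))
        rcfg = ResampleConfig(sizes=(20,), n_draws=400, seed=2)
        c_sharp, _ = replicability_curve(sharp, rcfg)
        c_smooth, _ = replicability_curve(smooth, rcfg)
        assert c_sharp.pct_at(20) < c_smooth.pct_at(20)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticConfig(group_mix={"a": (0.5, 0.0), "b": (0.3, 1.0)})

    def test_group_shift_recovered_through_discretization(self):
        """Between-group rating difference matches a numerical-integration oracle.

        The discretization map attenuates latent shifts; the oracle
        integrates rating(z) against each group's latent Gaussian and
        predicts the between-group difference in item means, which the
        simulated data must reproduce within 5%.
        """
        from scipy.stats import norm

        sigma_e = 1.0
        cfg = SyntheticConfig(
            n_participants=10_000,
            n_items=12,
            group_mix={"lo": (0.5, 0.0), "hi": (0.5, 2.0 * sigma_e)},
            participant_sd=0.6,
            residual_sd=sigma_e,
            knife_edge_fraction=0.0,
            seed=31,
        )
        rm, meta, truth = generate(cfg)
        sigma_w = np.hypot(cfg.participant_sd, cfg.residual_sd)

        def expected_rating(mu_eff: float) -> float:
            # E[rating] = 1 + sum_t P(z > t), z ~ N(mu_eff, sigma_w)
            return 1.0 + norm.sf((truth.thresholds - mu_eff) / sigma_w).sum()

        predicted = np.array(
            [
                expected_rating(mu + 2.0 * sigma_e) - expected_rating(mu)
                for mu in truth.item_locations
            ]
        )
        lo_ids = meta.loc[meta["stakeholder_group"] == "lo", "participant_id"]
        hi_ids = meta.loc[meta["stakeholder_group"] == "hi", "participant_id"]
        measured = (
            rm.data.loc[hi_ids].mean(axis=0) - rm.data.loc[lo_ids].mean(axis=0)
        ).to_numpy()
        assert predicted.mean() > 0
        assert abs(measured.mean() - predicted.mean()) / predicted.mean() < 0.05


class TestPresets:
    def test_preset_shapes(self):
        presets = scenario_presets()
        shapes = {
            name: (c.n_participants, c.n_items, c.k) for name, c in presets.items()
        }
        assert shapes["surrogate-like"] == (175, 22, 9)
        assert shapes["spi-like"] == (333, 77, 10)
        assert shapes["cosb-like"] == (553, 88, 9)

    def test_preset_determinism(self):
        cfg = scenario_presets()["surrogate-like"]
        rm1, _, _ = generate(cfg)
        rm2, _, _ = generate(cfg)
        pd.testing.assert_frame_equal(rm1.data, rm2.data)

    def test_presets_start_in_moderate_band(self):
        # the generator's defaults ARE the study conditions: small panels
        # (n = 20) replicate moderately, not perfectly
        for name, cfg in scenario_presets().items():
            rm, _, _ = generate(cfg)
            complete, _ = filter_complete(rm)
            rcfg = ResampleConfig(sizes=(20,), n_draws=300, seed=1)
            curve, _ = replicability_curve(complete, rcfg)
            assert 60 <= curve.pct_at(20) < 80, name


class TestLatentMap:
    def test_window_and_thresholds(self):
        cfg = SyntheticConfig(n_participants=10, n_items=2, k=9, seed=0)
        lo, hi = latent_window(cfg)
        assert lo == pytest.approx(cfg.item_loc_mean - 4 * cfg.total_sd)
        assert hi == pytest.approx(cfg.item_loc_mean + 4 * cfg.total_sd)
        _, _, truth = generate(cfg)
        assert len(truth.thresholds) == 8
        steps = np.diff(truth.thresholds)
        np.testing.assert_allclose(steps, steps[0])

    def test_discretize_edges(self):
        thresholds = np.array([0.0, 1.0, 2.0])
        z = np.array([-5.0, 0.5, 1.0, 5.0])
        np.testing.assert_array_equal(discretize(z, thresholds), [1, 2, 3, 4])

    def test_knife_edge_latent_median_on_threshold(self):
        cfg = SyntheticConfig(
            n_participants=10, n_items=20, knife_edge_fraction=0.5, seed=44
        )
        _, _, truth = generate(cfg)
        mean_shift = sum(p * g for p, g in cfg.group_mix.values())
        for item in truth.knife_edge_items:
            j = int(item.replace("item", "")) - 1
            latent_median = truth.item_locations[j] + mean_shift
            assert np.min(np.abs(truth.thresholds - latent_median)) < 1e-9
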