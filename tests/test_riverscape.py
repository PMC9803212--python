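"""Synthetic riverscape: network topology, predictors, truth, presences."""

import numpy as np
import pandas as pd
import pytest

import riverpart as rp
from riverpart.errors import (
    DegenerateInputError,
    EmptyPresenceError,
    InvalidArgumentError,
)
from riverpart.riverscape import NATIONAL_RANGES, SUBSTITUTED_PREDICTORS


class TestGenerateNetwork:
    def test_degenerate_single_reach(self):
        net = rp.generate_network(1, n_outlets=1, seed=0)
        assert len(net) == 1
        assert net.downstream_id(int(net.reach_ids[0])) is None

    def test_forest_structure(self):
        net = rp.generate_network(100, n_outlets=3, seed=1)
        assert len(net) == 100
        assert net.n_components == 3
        assert len(set(net.reach_ids)) == 100
        # following downstream links terminates at an outlet for every reach
        for rid in net.reach_ids:
            seen = set()
            cur = int(rid)
            while cur is not None:
                assert cur not in seen, "cycle detected"
                seen.add(cur)
                cur = net.downstream_id(cur)

    def test_mean_length_matches_configured_distribution(self):
        net = rp.generate_network(10_000, n_outlets=5, mean_length_m=700.0, seed=2)
        assert net.lengths_m.mean() == pytest.approx(700.0, rel=0.05)

    def test_too_many_outlets_rejected(self):
        with pytest.raises(InvalidArgumentError):
            rp.generate_network(3, n_outlets=5, seed=0)

    def test_deterministic_given_seed(self):
        a = rp.generate_network(80, n_outlets=2, seed=11).to_frame()
        b = rp.generate_network(80, n_outlets=2, seed=11).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_csv_round_trip(self, small_network, tmp_path):
        path = tmp_path / "reaches.csv"
        small_network.to_csv(path)
        again = rp.RiverNetwork.from_csv(path)
        pd.testing.assert_frame_equal(small_network.to_frame(), again.to_frame())


class TestGeneratePredictors:
    def test_zero_conversion_gives_identical_epochs(self, small_network):
        cfg = rp.GeneratorConfig(conversion_fraction=0.0)
        pair = rp.generate_predictors(small_network, cfg, seed=4)
        pd.testing.assert_frame_equal(pair.contemporary, pair.prehuman)

    def test_conversion_only_lowers_forest(self, epoch_pair):
        assert (
            epoch_pair.prehuman["segIndigenousForest"]
            >= epoch_pair.contemporary["segIndigenousForest"] - 1e-12
        ).all()

    def test_nonsubstituted_columns_identical_between_epochs(self, epoch_pair):
        for col in epoch_pair.contemporary.columns:
            if col not in SUBSTITUTED_PREDICTORS:
                pd.testing.assert_series_equal(
                    epoch_pair.contemporary[col], epoch_pair.prehuman[col]
                )

    def test_upstream_forest_matches_traversal_oracle(self, small_network, epoch_pair):
        forest = epoch_pair.contemporary["segIndigenousForest"]
        lengths = small_network.lengths_m
        us = epoch_pair.contemporary["usIndigenousForest"]
        for rid in small_network.reach_ids[::7]:
            ids = sorted(small_network.upstream_ids(int(rid)))
            expected = float(
                (forest.loc[ids] * lengths.loc[ids]).sum() / lengths.loc[ids].sum()
            )
            assert us.loc[rid] == pytest.approx(expected, abs=1e-12)

    def test_medians_inside_national_ranges(self, epoch_pair):
        med = epoch_pair.contemporary.median()
        for name, (lo, hi) in NATIONAL_RANGES.items():
            assert lo <= med[name] <= hi, name

    def test_deterministic_given_seed(self, small_network):
        a = rp.generate_predictors(small_network, seed=9)
        b = rp.generate_predictors(small_network, seed=9)
        pd.testing.assert_frame_equal(a.contemporary, b.contemporary)
        pd.testing.assert_frame_equal(a.prehuman, b.prehuman)


class TestTempSeasonality:
    def test_identical_zscores_cancel(self):
        out = rp.temp_seasonality([1, 2, 3], [4, 5, 6])
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_hand_case(self):
        out = rp.temp_seasonality([1, 2, 3], [6, 5, 4])
        assert out[0] == pytest.approx(-2.0)

    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        W = rng.normal(10, 3, 50)
        S = rng.normal(20, 2, 50)
        np.testing.assert_allclose(
            rp.temp_seasonality(W + 10.0, S), rp.temp_seasonality(W, S), atol=1e-9
        )
        np.testing.assert_allclose(
            rp.temp_seasonality(W, S - 5.0), rp.temp_seasonality(W, S), atol=1e-9
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            rp.temp_seasonality([1.0, 1.0, 1.0], [4, 5, 6])


class TestOccupancyTruth:
    def test_regimes_are_nested(self, truth):
        p = truth.probs
        assert (p["predation"] <= p["converted"] + 1e-12).all()
        assert (p["converted"] <= p["pristine"] + 1e-12).all()

    def test_zero_coefficients_give_half(self, small_network, epoch_pair):
        cfg = rp.GeneratorConfig(
            suitability_coefs={}, suitability_threshold=0.0, refuge_mode="none"
        )
        t = rp.build_truth(epoch_pair, small_network, cfg, seed=0)
        np.testing.assert_allclose(t.probs["pristine"], 0.5)
        np.testing.assert_allclose(t.probs["predation"], 0.5)

    def test_covariate_refuge_excludes_low_slopes(self, small_network, epoch_pair):
        cfg = rp.GeneratorConfig(refuge_mode="covariate")
        t = rp.build_truth(epoch_pair, small_network, cfg, seed=0)
        slope = epoch_pair.contemporary["segSlopeCatchment"]
        thr = slope.quantile(cfg.refuge_slope_quantile)
        presences = rp.simulate_presences(t, "predation", 2000, seed=1)
        assert len(presences) > 0
        assert (slope.loc[sorted(presences)] >= thr).all()


class TestSimulatePresences:
    def test_support_nesting_across_regimes(self, truth):
        # reaches that can never produce a presence under a stricter regime
        zero_pred = truth.probs.index[truth.probs["predation"] == 0]
        pres = rp.simulate_presences(truth, "predation", 5000, seed=2)
        assert pres.isdisjoint(set(zero_pred))

    def test_empty_occupancy_raises(self, truth):
        empty = rp.OccupancyTruth(
            probs=truth.probs * 0.0, coefficients={}, refuge_ids=frozenset()
        )
        with pytest.raises(EmptyPresenceError, match="zero everywhere"):
            rp.simulate_presences(empty, "pristine", 10, seed=0)

    def test_record_frequencies_match_probabilities(self, truth):
        # single-record draws land on reach i with probability p_i / sum(p)
        p = truth.probs["pristine"].to_numpy()
        expected = p / p.sum()
        n_draws = 4000
        counts = pd.Series(0, index=truth.probs.index, dtype=float)
        for s in range(n_draws):
            (rid,) = rp.simulate_presences(truth, "pristine", 1, seed=s)
            counts.loc[rid] += 1
        tv = 0.5 * np.abs(counts.to_numpy() / n_draws - expected).sum()
        assert tv < 0.08  # total-variation distance shrinks as draws grow

    def test_unknown_regime_rejected(self, truth):
        with pytest.raises(InvalidArgumentError):
            rp.simulate_presences(truth, "apocalypse", 10, seed=0)
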