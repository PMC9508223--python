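import numpy as np
import pandas as pd
import pytest
from itertools import combinations
from scipy.stats import norm

from celltraffic.datasets import LocalisationDataset
from celltraffic.synthetic import (
    DEFAULT_TIME_GRID,
    NegativeNoiseError,
    NoiseConfig,
    add_noise,
    censor_organs,
    default_truth,
    make_dataset,
    negative_multiplier_probability,
    subsample_times,
)
from celltraffic.diagnostics import timescale_table


class TestDefaultTruth:
    def test_deterministic_under_seed(self, rat_system):
        a = default_truth(rat_system, 7)
        b = default_truth(rat_system, 7)
        np.testing.assert_array_equal(a.to_vector(), b.to_vector())
        c = default_truth(rat_system, 8)
        assert not np.array_equal(a.to_vector(), c.to_vector())

    @pytest.mark.parametrize("seed", range(5))
    def test_domains_and_spread(self, rat_system, seed):
        params = default_truth(rat_system, seed)
        assert np.all(params.e > 0) and np.all(params.e <= 1)
        assert np.all(params.mu > 0) and np.all(params.mu <= 1)
        # e spans roughly two orders of magnitude
        assert params.e.max() / params.e.min() > 20

    @pytest.mark.parametrize("seed", range(5))
    def test_flagged_timescales_present(self, rat_system, seed):
        """At least one timescale faster than the first datum and one
        slower than the last, for every seed."""
        params = default_truth(rat_system, seed)
        table = timescale_table(rat_system, params).table
        all_flags = list(table["flag_e"]) + list(table["flag_mu"])
        assert "below_first_datum" in all_flags
        assert "above_last_datum" in all_flags


class TestMakeDataset:
    def test_initial_row_all_cells_in_blood(self, noise_free_dataset):
        row0 = noise_free_dataset.data[noise_free_dataset.data.time_h == 0.0]
        blood = row0[row0.curve == "Blood"]["value"].iloc[0]
        organs = row0[row0.curve != "Blood"]["value"]
        assert blood == 1.0
        assert (organs == 0.0).all()

    def test_rows_sum_to_one_with_full_observation(self, noise_free_dataset):
        sums = noise_free_dataset.wide().sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_bit_identical_regeneration(self, rat_system, truth):
        a = make_dataset(rat_system, truth)
        b = make_dataset(rat_system, truth)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_default_grid(self, noise_free_dataset):
        np.testing.assert_array_equal(
            noise_free_dataset.times(), np.asarray(DEFAULT_TIME_GRID)
        )


class TestAddNoise:
    def test_sigma_zero_is_identity(self, noise_free_dataset):
        noised = add_noise(noise_free_dataset, NoiseConfig(0.0, seed=1))
        pd.testing.assert_frame_equal(noised.data, noise_free_dataset.data)

    def test_initial_row_exempt(self, noise_free_dataset):
        noised = add_noise(noise_free_dataset, NoiseConfig(0.3, seed=1))
        a = noised.data[noised.data.time_h == 0.0]["value"].to_numpy()
        b = noise_free_dataset.data[
            noise_free_dataset.data.time_h == 0.0
        ]["value"].to_numpy()
        np.testing.assert_array_equal(a, b)

    def test_negative_tail_probability_closed_form(self):
        """P(N(1, 0.2) < 0) = Phi(-5) = 2.9e-7."""
        p = negative_multiplier_probability(0.2)
        assert p == pytest.approx(norm.cdf(-5.0))
        assert p == pytest.approx(2.9e-7, rel=0.02)

    def test_multiplier_moments(self):
        """1e5 draws at sigma=0.1: mean within 1 +- 0.002, sd within 0.1 +- 0.003."""
        rng = np.random.default_rng(0)
        base = pd.DataFrame(
            {
                "curve": ["Blood"] * 100_001,
                "time_h": np.arange(100_001, dtype=float),
                "value": np.ones(100_001),
            }
        )
        ds = LocalisationDataset(base)
        noised = add_noise(ds, NoiseConfig(0.1, seed=11))
        m = noised.data[noised.data.time_h > 0]["value"]
        assert m.mean() == pytest.approx(1.0, abs=0.002)
        assert m.std() == pytest.approx(0.1, abs=0.003)

    def test_negative_value_refused_with_location(self, noise_free_dataset):
        with pytest.raises(NegativeNoiseError):
            # sd 5: negatives essentially guaranteed among 64 draws
            add_noise(noise_free_dataset, NoiseConfig(5.0, seed=0))

    def test_noise_composes_and_is_seed_deterministic(self, noise_free_dataset):
        once = add_noise(noise_free_dataset, NoiseConfig(0.1, seed=3))
        again = add_noise(noise_free_dataset, NoiseConfig(0.1, seed=3))
        pd.testing.assert_frame_equal(once.data, again.data)
        twice = add_noise(once, NoiseConfig(0.05, seed=4))
        assert isinstance(twice.provenance["noise"], list)


class TestSubsample:
    def test_identity_when_keeping_all(self, noise_free_dataset):
        sub = subsample_times(noise_free_dataset, 8)
        np.testing.assert_array_equal(
            sub.times(), noise_free_dataset.times()
        )

    def test_k3_matches_brute_force_max_min_spacing(self, noise_free_dataset):
        """Exhaustive oracle over C(8,3) subsets containing the final time."""
        post = [0.5, 1, 2, 4, 8, 12, 18, 24]
        best = max(
            (c for c in combinations(post, 3) if c[-1] == 24),
            key=lambda c: (min(np.diff(c)), c),
        )
        assert best == (0.5, 12, 24)
        sub = subsample_times(noise_free_dataset, 3)
        np.testing.assert_array_equal(sub.times(), [0.0, 0.5, 12.0, 24.0])

    def test_k1_keeps_final_point(self, noise_free_dataset):
        sub = subsample_times(noise_free_dataset, 1)
        np.testing.assert_array_equal(sub.times(), [0.0, 24.0])

    def test_k_out_of_range(self, noise_free_dataset):
        with pytest.raises(ValueError):
            subsample_times(noise_free_dataset, 9)


class TestCensoring:
    def test_keep_all_is_identity(self, noise_free_dataset):
        kept = censor_organs(noise_free_dataset, noise_free_dataset.curves)
        pd.testing.assert_frame_equal(
            kept.data.reset_index(drop=True),
            noise_free_dataset.data.reset_index(drop=True),
        )

    def test_dropping_skin_breaks_row_sums(self, noise_free_dataset):
        censored = censor_organs(
            noise_free_dataset,
            [c for c in noise_free_dataset.curves if c != "Skin"],
        )
        assert "Skin" not in censored.curves
        sums = censored.wide().sum(axis=1)
        assert (sums.iloc[1:] < 1.0 - 1e-6).all()
        assert censored.provenance["censored"] == ["Skin"]

    def test_blood_always_kept_and_empty_keep_rejected(self, noise_free_dataset):
        censored = censor_organs(noise_free_dataset, ["Spleen"])
        assert "Blood" in censored.curves
        with pytest.raises(ValueError):
            censor_organs(noise_free_dataset, [])

    def test_censoring_and_subsampling_commute(self, noise_free_dataset):
        keep = ["Spleen", "Liver", "Lungs"]
        a = subsample_times(censor_organs(noise_free_dataset, keep), 4)
        b = censor_organs(subsample_times(noise_free_dataset, 4), keep)
        pd.testing.assert_frame_equal(
            a.data.reset_index(drop=True), b.data.reset_index(drop=True)
        )
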