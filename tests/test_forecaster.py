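"""The stacked ensemble and its walk-forward engine."""

import dataclasses
import warnings

import numpy as np
import pytest

from wearcast.synthetic import (
    SyntheticCohortConfig, HeartRateSeries, generate_participant,
)
from wearcast import forecaster as fc
from wearcast.evaluation import compute_auc


@pytest.fixture(scope="module")
def tiny_config():
    return dataclasses.replace(
        fc.scaled_config(), n_trees=50, n_folds=2, lstm_epochs=10,
        retrain_days=21.0)


@pytest.fixture(scope="module")
def hourly_trace(default_participant_module, tiny_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fc.walk_forward_run(
            default_participant_module, "hourly", config=tiny_config, seed=3)


@pytest.fixture(scope="module")
def default_participant_module():
    cfg = SyntheticCohortConfig(
        duration_days=150.0, seizure_rate=8.0 / 30.0,
        locking_kappa=(0.0, 3.0), seed=42)
    return generate_participant(cfg)


class TestOversampling:
    def test_rebalances_to_one_to_one(self):
        rng = np.random.default_rng(0)
        X = np.arange(110, dtype=float)[:, None]
        y = np.r_[np.ones(10), np.zeros(100)]
        Xb, yb = fc.oversample_minority(X, y, rng)
        assert (yb == 1).sum() == (yb == 0).sum() == 100

    def test_balanced_input_is_identity(self):
        X = np.arange(20, dtype=float)[:, None]
        y = np.r_[np.ones(10), np.zeros(10)]
        Xb, yb = fc.oversample_minority(X, np.asarray(y), np.random.default_rng(0))
        assert Xb.shape == X.shape

    def test_duplicates_are_exact_copies(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 3))
        y = np.r_[np.ones(5), np.zeros(45)]
        Xb, yb = fc.oversample_minority(X, y, rng)
        originals = {tuple(row) for row in X[:5]}
        for row in Xb[50:]:
            assert tuple(row) in originals

    def test_single_class_warns_and_passes_through(self):
        X = np.ones((5, 2))
        with pytest.warns(UserWarning, match="one class"):
            Xb, yb = fc.oversample_minority(X, np.zeros(5), np.random.default_rng(0))
        assert Xb.shape == X.shape


class TestStacker:
    def test_identical_bases_preserve_ranking(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(0, 1, 300)
        y = (rng.random(300) < base).astype(int)
        B = np.column_stack([base, base])
        stack = fc.train_stacker(B, y, np.ones(300, bool))
        out = stack(B)
        assert compute_auc(out, y) == pytest.approx(compute_auc(base, y))

    def test_informative_base_survives_noise_partner(self):
        rng = np.random.default_rng(3)
        signal = rng.uniform(0, 1, 800)
        y = (rng.random(800) < signal ** 2).astype(int)
        noise = rng.uniform(0, 1, 800)
        B = np.column_stack([signal, noise])
        stack = fc.train_stacker(B, y, np.ones(800, bool))
        assert compute_auc(stack(B), y) >= compute_auc(signal, y) - 0.02

    def test_few_positives_fall_back_to_rank_average(self):
        rng = np.random.default_rng(4)
        B = rng.uniform(0, 1, (40, 2))
        y = np.r_[np.ones(3), np.zeros(37)].astype(int)
        stack = fc.train_stacker(B, y, np.ones(40, bool))
        assert stack.fallback
        out = stack(B)
        assert np.all((out >= 0) & (out <= 1))

    def test_adjacency_removal_drops_flanking_steps(self):
        times = np.arange(10) * 60.0
        labels = np.zeros(10, int)
        labels[5] = 1
        keep = fc.adjacency_keep_mask(times, labels, np.array([5 * 60.0 + 10]))
        assert not keep[4] and not keep[6]
        assert keep[5] and keep[3] and keep[7]


class TestSleepHistory:
    def test_tensor_shape_and_order(self, default_participant_module, tiny_config):
        prep = fc.PreparedParticipant(default_participant_module, tiny_config)
        assert prep.tensors.shape[1:] == (7, 7)
        assert prep.tensors.shape[0] == len(prep.wake_times)
        # the last history row is the most recent night: for consecutive
        # nights, history k of wake i equals the features of wake i-7+k
        feats = prep.sleep_df[list(
            __import__("wearcast.preprocess", fromlist=["SLEEP_FEATURES"]).SLEEP_FEATURES
        )].to_numpy()
        i = 40
        assert np.allclose(prep.tensors[i, -1], feats[i - 1])
        assert np.allclose(prep.tensors[i, 0], feats[i - 7])


class TestWalkForward:
    def test_trace_tiles_the_testing_span(self, hourly_trace):
        t = hourly_trace.times_min
        assert np.all(np.diff(t) == 60.0)
        assert np.all((hourly_trace.likelihood >= 0) & (hourly_trace.likelihood <= 1))

    def test_tiers_consistent_with_active_thresholds(self, hourly_trace):
        lik = hourly_trace.likelihood
        med = hourly_trace.theta_med
        high = hourly_trace.theta_high
        tier = hourly_trace.tier
        assert np.all(med <= high)
        assert np.all((lik < med) == (tier == "low"))
        assert np.all((lik >= high) == (tier == "high"))

    def test_deterministic_given_seed(self, default_participant_module, tiny_config):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fc.walk_forward_run(default_participant_module, "hourly",
                                    config=tiny_config, seed=3)
        b_prep = fc.PreparedParticipant(default_participant_module, tiny_config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b = fc.walk_forward_run(b_prep, "hourly", config=tiny_config, seed=3)
        assert np.array_equal(a.likelihood, b.likelihood)
        assert np.array_equal(a.tier, b.tier)

    def test_daily_horizon_runs_and_uses_multiday_only(self,
                                                       default_participant_module,
                                                       tiny_config):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tr = fc.walk_forward_run(default_participant_module, "daily",
                                     config=tiny_config, seed=3)
        assert tr.labels.size == tr.likelihood.size
        for periods in tr.retained_cycles:
            assert all(p >= 36.0 for p in periods)

    def test_future_data_cannot_reach_the_first_block(
            self, default_participant_module, tiny_config, hourly_trace):
        """Leakage audit: rewriting everything after the first block leaves
        the first block's likelihoods untouched."""
        p = default_participant_module
        first_epoch = hourly_trace.epoch == 0
        cut_t = hourly_trace.times_min[first_epoch][-1] + 60.0
        cut5 = int(cut_t * 12)
        bpm = p.hr.bpm.copy()
        rng = np.random.default_rng(9)
        bpm[cut5:] = rng.normal(90, 15, bpm.size - cut5)
        diary_keep = p.diary.times_min < cut_t
        q = dataclasses.replace(
            p,
            hr=HeartRateSeries(bpm, p.hr.missing_mask.copy(), 5, p.hr.start),
            diary=dataclasses.replace(
                p.diary,
                times_min=np.append(p.diary.times_min[diary_keep],
                                    p.diary.times_min[~diary_keep] + 7.0),
                types=list(p.diary.types)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tr_q = fc.walk_forward_run(q, "hourly", config=tiny_config, seed=3)
        a = hourly_trace.likelihood[first_epoch]
        b = tr_q.likelihood[tr_q.epoch == 0][: a.size]
        assert np.allclose(a[: b.size], b)

    def test_frozen_model_close_to_retrained_on_stationary_data(
            self, default_participant_module, tiny_config, hourly_trace):
        # the generator's cycles are stationary, so freezing the initial fit
        # should cost little versus weekly-style refits (the retrain switch)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            frozen = fc.walk_forward_run(default_participant_module, "hourly",
                                         config=tiny_config, seed=3,
                                         retrain=False)
        a = compute_auc(hourly_trace.likelihood, hourly_trace.labels)
        b = compute_auc(frozen.likelihood, frozen.labels)
        assert abs(a - b) < 0.2
        assert frozen.labels.size == hourly_trace.labels.size

    def test_excluding_groups_removes_their_columns(
            self, default_participant_module, tiny_config):
        prep = fc.PreparedParticipant(default_participant_module, tiny_config)
        times, dur, labels, _ = prep.grid("hourly")
        cutoff = 100 * 1440.0
        rows = np.flatnonzero(times + dur <= cutoff)
        _, _, names, groups, _ = fc._epoch_features(
            prep, "hourly", cutoff, rows, rows[:5], ("cycles",), tiny_config)
        assert "cycles" not in groups
        _, _, names2, groups2, _ = fc._epoch_features(
            prep, "hourly", cutoff, rows, rows[:5], (), tiny_config)
        assert "cycles" in groups2 and "heart_rate" in groups2
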