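"""Generator behaviour: templates, epochs, datasets, continuous mode, raters."""

from dataclasses import replace

import numpy as np
import pytest

from mrcprel import (
    CONDITIONS,
    HEALTHY_IMAGINED,
    HEALTHY_VOLUNTARY,
    STROKE_VOLUNTARY,
    RaterProfile,
    SimulationConfig,
    average_included,
    default_condition_params,
    default_rater_profiles,
    make_template,
    similarity_table,
    simulate_continuous,
    simulate_dataset,
    simulate_epoch,
    simulate_rater_decisions,
    simulate_rater_label,
)
from mrcprel.epoch_metrics import AverageMRCP
from mrcprel.preprocessing import bandpass_recording, extract_epochs, large_laplacian
from mrcprel.reliability import RatingsMatrix, icc_a1
from mrcprel.synthetic import child_rng

FS, PRE, POST = 500.0, 3.0, 1.5


class TestTemplate:
    def test_planted_extremum_with_zero_spread(self, clean_params):
        params = replace(clean_params, pn_amplitude_mean=-15.0, pn_latency_mean_ms=100.0)
        t = make_template(params, FS, PRE, POST, np.random.default_rng(0))
        assert t.true_pn_amplitude == pytest.approx(-15.0)
        assert t.true_pn_index == 1500 + int(0.1 * FS)
        assert t.samples[t.true_pn_index] == pytest.approx(-15.0)
        assert t.samples[t.true_pn_index] == t.samples.min()

    def test_default_amplitude_within_physiological_range(self):
        params = default_condition_params()[HEALTHY_VOLUNTARY]
        for seed in range(30):
            t = make_template(params, FS, PRE, POST, np.random.default_rng(seed))
            assert -30.0 <= t.true_pn_amplitude <= -5.0

    def test_baseline_flat_before_ramp_onset(self):
        params = default_condition_params()[HEALTHY_VOLUNTARY]
        t = make_template(params, FS, PRE, POST, np.random.default_rng(3))
        onset_idx = t.cue_index + int(params.ramp_onset_ms * FS / 1000.0)
        baseline = t.samples[: onset_idx]
        assert np.abs(baseline).max() < 0.1 * abs(params.pn_amplitude_mean)

    def test_latency_outside_window_raises(self, clean_params):
        params = replace(clean_params, pn_latency_mean_ms=2000.0)
        with pytest.raises(ValueError, match="outside the epoch window"):
            make_template(params, FS, PRE, POST, np.random.default_rng(0))


class TestEpoch:
    def test_zero_noise_epoch_equals_template(self, clean_params):
        t = make_template(clean_params, FS, PRE, POST, np.random.default_rng(1))
        epoch, flag = simulate_epoch(t, clean_params, np.random.default_rng(2))
        assert not flag
        assert np.array_equal(epoch, t.samples)

    def test_artefact_probability_one_always_flags(self, clean_params):
        params = replace(clean_params, artefact_prob=1.0)
        t = make_template(params, FS, PRE, POST, np.random.default_rng(1))
        flags = [simulate_epoch(t, params, np.random.default_rng(s))[1] for s in range(20)]
        assert all(flags)

    def test_fixed_seed_reproducible(self):
        params = default_condition_params()[HEALTHY_VOLUNTARY]
        t = make_template(params, FS, PRE, POST, np.random.default_rng(5))
        a, fa = simulate_epoch(t, params, np.random.default_rng(42))
        b, fb = simulate_epoch(t, params, np.random.default_rng(42))
        assert fa == fb
        assert np.array_equal(a, b)


class TestDataset:
    def test_default_config_gives_50_epochs_of_2250_samples(self):
        ds = simulate_dataset(HEALTHY_VOLUNTARY, 0, SimulationConfig(seed=1))
        assert ds.epochs.epochs.shape == (50, 2250)
        assert ds.epochs.cue_index == 1500

    def test_zero_noise_dataset_similarity_exactly_one(self, clean_params):
        cfg = SimulationConfig(seed=2, n_epochs=10)
        cfg.condition_params[HEALTHY_VOLUNTARY] = clean_params
        ds = simulate_dataset(HEALTHY_VOLUNTARY, 0, cfg)
        tab = similarity_table(ds.epochs)
        assert np.allclose(tab["cs"], 1.0)

    def test_condition_ordering_of_similarity_means(self):
        cfg = SimulationConfig(seed=6)
        means = {}
        for cond in CONDITIONS:
            cs = np.concatenate([
                similarity_table(simulate_dataset(cond, pid, cfg).epochs)["cs"].values
                for pid in range(5)
            ])
            means[cond] = cs.mean()
        assert means[HEALTHY_VOLUNTARY] > means[HEALTHY_IMAGINED]
        assert means[STROKE_VOLUNTARY] > means[HEALTHY_IMAGINED]

    def test_streams_independent_of_added_raters(self):
        # dataset content depends only on (seed, condition, participant)
        a = simulate_dataset(HEALTHY_VOLUNTARY, 3, SimulationConfig(seed=9, n_raters=2))
        b = simulate_dataset(HEALTHY_VOLUNTARY, 3, SimulationConfig(seed=9, n_raters=5))
        assert np.array_equal(a.epochs.epochs, b.epochs.epochs)

    def test_unknown_condition_raises(self):
        with pytest.raises(ValueError, match="no parameters"):
            simulate_dataset("sitting", 0, SimulationConfig(seed=1))


class TestContinuous:
    def test_cue_count_and_monotonicity_and_gaps(self):
        cfg = SimulationConfig(seed=3)
        _, cues = simulate_continuous(HEALTHY_VOLUNTARY, cfg)
        assert len(cues) == 50
        gaps = np.diff(cues)
        assert (gaps > 0).all()
        # focus (2-3 s) + 1 s hold + rest (6-8 s)
        assert (gaps >= 9.0).all() and (gaps <= 12.0).all()

    def test_zero_noise_round_trip_recovers_template(self, clean_params):
        params = replace(
            default_condition_params()[HEALTHY_VOLUNTARY],
            background_noise_sd=0.0, artefact_prob=0.0,
            pn_latency_jitter_sd_ms=0.0, epoch_scale_sd=0.0,
        )
        cfg = SimulationConfig(seed=4, n_epochs=10)
        cfg.condition_params[HEALTHY_VOLUNTARY] = params
        rec, cues = simulate_continuous(HEALTHY_VOLUNTARY, cfg)
        virtual = large_laplacian(bandpass_recording(rec))
        es = extract_epochs(virtual, rec.fs, cues)
        tmpl = make_template(
            params, cfg.fs, cfg.pre_s, cfg.post_s,
            child_rng(cfg.seed, "continuous", HEALTHY_VOLUNTARY, 0),
        )
        r = np.corrcoef(es.epochs.mean(axis=0), tmpl.samples)[0, 1]
        assert r > 0.99


class TestRaters:
    def _epochs(self, n=400):
        cfg = SimulationConfig(seed=5, n_epochs=n)
        return simulate_dataset(HEALTHY_VOLUNTARY, 0, cfg).epochs

    def test_zero_slope_accept_rate_approaches_logistic_intercept(self):
        es = self._epochs(2000)
        profile = RaterProfile("E1", 4.0, accept_intercept=-1.0, accept_cs_slope=0.0)
        cs = np.zeros(2000)
        acc = simulate_rater_decisions(es, cs, profile, 1, np.random.default_rng(0))
        expected = 1.0 / (1.0 + np.exp(1.0))
        assert acc["accept"].mean() == pytest.approx(expected, abs=0.03)

    def test_saturated_intercept_accepts_everything(self):
        es = self._epochs(100)
        profile = RaterProfile("E1", 4.0, accept_intercept=10.0, accept_cs_slope=0.0)
        acc = simulate_rater_decisions(es, np.zeros(100), profile, 1, np.random.default_rng(1))
        assert acc["accept"].all()

    def test_two_session_match_probability_increases_with_similarity(self):
        # Monte-Carlo P(matched | cs) against the logistic^2 curve
        profile = RaterProfile("E1", 4.0, accept_intercept=-1.0, accept_cs_slope=6.0)
        es = self._epochs(100)
        grid = np.array([0.0, 0.3, 0.6, 0.9])
        probs = []
        for cs_val in grid:
            cs = np.full(100, cs_val)
            matched = np.zeros(100, dtype=int)
            for rep in range(40):
                a1 = simulate_rater_decisions(es, cs, profile, 1, np.random.default_rng(2 * rep))
                a2 = simulate_rater_decisions(es, cs, profile, 2, np.random.default_rng(2 * rep + 1))
                matched += (a1["accept"].values & a2["accept"].values).astype(int)
            p_emp = matched.sum() / (100 * 40)
            p_theory = (1.0 / (1.0 + np.exp(-(-1.0 + 6.0 * cs_val)))) ** 2
            assert p_emp == pytest.approx(p_theory, abs=0.03)
            probs.append(p_emp)
        assert all(np.diff(probs) > 0)

    def test_zero_noise_label_equals_automated_pn(self, clean_params):
        cfg = SimulationConfig(seed=8, n_epochs=5)
        cfg.condition_params[HEALTHY_VOLUNTARY] = clean_params
        ds = simulate_dataset(HEALTHY_VOLUNTARY, 0, cfg)
        avg = average_included(ds.epochs, np.ones(5, bool))
        profile = RaterProfile("E1", 4.0, 0.0, 0.0, pn_bias_ms=0.0, pn_noise_sd_ms=0.0)
        lab = simulate_rater_label(avg, profile, np.random.default_rng(0))
        assert lab == pytest.approx(ds.true_pn_latency_ms)

    def test_label_determinism(self):
        cfg = SimulationConfig(seed=8, n_epochs=5)
        ds = simulate_dataset(HEALTHY_VOLUNTARY, 0, cfg)
        avg = average_included(ds.epochs, np.ones(5, bool))
        profile = default_rater_profiles()[0]
        a = simulate_rater_label(avg, profile, np.random.default_rng(7))
        b = simulate_rater_label(avg, profile, np.random.default_rng(7))
        assert a == b

    def test_degenerate_average_raises(self):
        avg = AverageMRCP("d0", np.zeros(2250), 1, FS, 1500)
        profile = default_rater_profiles()[0]
        with pytest.raises(ValueError, match="no defined PN"):
            simulate_rater_label(avg, profile, np.random.default_rng(0))

    def test_label_variance_components_imply_expected_icc(self, clean_params):
        # sigma2_dataset = 100^2 ms^2, sigma2_bias = 0, sigma2_noise = 10^2
        # -> theoretical ICC = 10000 / 10100 = 0.990
        params = replace(clean_params, pn_latency_dataset_sd_ms=100.0)
        cfg = SimulationConfig(seed=3, n_epochs=5)
        cfg.condition_params[HEALTHY_VOLUNTARY] = params
        mat = np.empty((10, 5))
        for pid in range(10):
            ds = simulate_dataset(HEALTHY_VOLUNTARY, pid, cfg)
            avg = average_included(ds.epochs, np.ones(5, bool))
            for j in range(5):
                profile = RaterProfile(f"E{j}", 4.0, 0.0, 0.0,
                                       pn_bias_ms=0.0, pn_noise_sd_ms=10.0)
                mat[pid, j] = simulate_rater_label(
                    avg, profile, child_rng(cfg.seed, "label", pid, j)
                )
        res = icc_a1(RatingsMatrix(mat))
        assert res.ci_low <= 0.990 <= res.ci_high
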