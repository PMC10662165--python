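"""Generator tests: determinism, degenerate limits, and recovery of the
ground-truth parameters by direct sample statistics."""

import numpy as np
import pandas as pd
import pytest

import chronosynd as cs
from chronosynd import synthetic


class TestChronotypeGenerator:
    def test_noise_free_limit_wake_exactly_at_offset(self):
        cfg = cs.ChronoSimConfig(n_individuals=3, n_days=4,
                                 sd_wake_between=0, sd_wake_within=0,
                                 sd_rest_between=0, sd_rest_within=0, seed=1)
        _, _, truth = cs.gen_chronotype_dataset(cfg)
        assert np.allclose(truth.realized_wake, cfg.mu_wake)
        assert np.allclose(truth.realized_rest, cfg.mu_rest)

    def test_degenerate_emission_all_zero_counts(self):
        cfg = cs.ChronoSimConfig(n_individuals=2, n_days=2,
                                 lambda_active=1e-12, pi_zero_active=0.0, seed=1)
        det, _, _ = cs.gen_chronotype_dataset(cfg)
        assert len(det) == 0

    def test_between_individual_sd_recovery(self):
        cfg = cs.ChronoSimConfig(n_individuals=30, n_days=14, seed=1)
        _, _, truth = cs.gen_chronotype_dataset(cfg)
        sd_hat = truth.wake_offsets.std(ddof=1)
        # SE of a sample SD of n normal draws ~ sd / sqrt(2(n-1))
        se = cfg.sd_wake_between / np.sqrt(2 * (cfg.n_individuals - 1))
        assert abs(sd_hat - cfg.sd_wake_between) < 3 * se

    def test_same_seed_identical_output(self):
        a = cs.gen_chronotype_dataset(cs.ChronoSimConfig(n_individuals=4, n_days=3, seed=9))
        b = cs.gen_chronotype_dataset(cs.ChronoSimConfig(n_individuals=4, n_days=3, seed=9))
        assert a[0].equals(b[0])
        assert a[1].equals(b[1])

    def test_zip_marginal_mean_in_active_bins(self):
        cfg = cs.ChronoSimConfig(n_individuals=5, n_days=15, seed=4)
        det, _, truth = cs.gen_chronotype_dataset(cfg)
        from chronosynd import hmm
        start = pd.Timestamp(cfg.start_date)
        active_counts = []
        for ind, seq in truth.state_sequences.items():
            b = hmm.bin_detections(det[det.individual_id == ind].timestamp,
                                   start, start + pd.Timedelta(days=cfg.n_days))
            active_counts.append(b.counts[seq == 1])
        counts = np.concatenate(active_counts)
        assert counts.size > 10_000
        expected = (1 - cfg.pi_zero_active) * cfg.lambda_active
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - expected) < 4 * se

    def test_degenerate_schedule_rejected(self):
        cfg = cs.ChronoSimConfig(n_individuals=2, n_days=2,
                                 mu_wake=500.0, mu_rest=-300.0,
                                 sd_wake_between=60.0, seed=1)
        with pytest.raises(ValueError, match="degenerate schedule"):
            cs.gen_chronotype_dataset(cfg)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            cs.ChronoSimConfig(lambda_active=0.0).validate()
        with pytest.raises(ValueError):
            cs.ChronoSimConfig(pi_zero_active=1.0).validate()
        with pytest.raises(ValueError):
            cs.ChronoSimConfig(bin_minutes=7).validate()


class TestMarkovSeries:
    def test_reproducible_and_rest_silent(self):
        c1, s1 = cs.gen_markov_series(500, seed=3)
        c2, s2 = cs.gen_markov_series(500, seed=3)
        assert np.array_equal(c1, c2) and np.array_equal(s1, s2)
        assert c1[s1 == 0].sum() == 0

    def test_diagonal_persistence(self):
        _, s = cs.gen_markov_series(20_000, diag=0.9, seed=0)
        stay = np.mean(s[1:] == s[:-1])
        assert stay == pytest.approx(0.9, abs=0.01)


class TestPersonalityGenerator:
    def test_row_count_and_no_missing_cells(self):
        cfg = cs.TraitSimConfig(n_individuals=10, n_trials=3, seed=2)
        table, _ = cs.gen_personality_dataset(cfg)
        assert len(table) == 10 * 3 * 4
        assert not table["value"].isna().any()

    def test_zero_between_covariance_collapses_intercepts(self):
        cfg = cs.TraitSimConfig(n_individuals=40, n_trials=4,
                                trait_names=("a", "b"),
                                Sigma_ind=np.zeros((2, 2)),
                                Sigma_e=np.eye(2), sd_batch=0.0, seed=5)
        _, truth = cs.gen_personality_dataset(cfg)
        assert np.allclose(truth.u, 0.0)

    def test_same_seed_byte_identical_tables(self, tmp_path):
        cfg = cs.TraitSimConfig(n_individuals=6, n_trials=2, seed=8)
        t1, _ = cs.gen_personality_dataset(cfg)
        t2, _ = cs.gen_personality_dataset(cs.TraitSimConfig(
            n_individuals=6, n_trials=2, seed=8))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        synthetic.write_trials_csv(t1, p1)
        synthetic.write_trials_csv(t2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_true_intercept_correlation_matches_target(self):
        r = 0.7
        S = np.array([[1.0, r], [r, 1.0]])
        cfg = cs.TraitSimConfig(n_individuals=200, n_trials=4,
                                trait_names=("a", "b"), Sigma_ind=S,
                                Sigma_e=np.eye(2), sd_batch=0.0, seed=6)
        _, truth = cs.gen_personality_dataset(cfg)
        r_hat = np.corrcoef(truth.u[:, 0], truth.u[:, 1])[0, 1]
        assert abs(r_hat - r) < 0.05 + 3 * (1 - r ** 2) / np.sqrt(200)

    def test_non_psd_covariance_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        cfg = cs.TraitSimConfig(trait_names=("a", "b"), Sigma_ind=bad,
                                Sigma_e=np.eye(2))
        with pytest.raises(ValueError, match="positive semi-definite"):
            cfg.validate()


class TestTrajectoryGenerator:
    def test_buried_from_start_never_detected(self):
        cfg = cs.TrajSimConfig(p_bury=1.0, p_emerge=0.0, start_buried=True,
                               duration_min=5, seed=1)
        traj = cs.gen_trajectory(cfg)
        assert traj.n_detected == 0

    def test_zero_step_is_stationary(self):
        cfg = cs.TrajSimConfig(step_mean_cm=0.0, p_bury=0.0, duration_min=5, seed=2)
        traj = cs.gen_trajectory(cfg)
        xy = traj.detected_xy()
        assert np.allclose(xy, xy[0])

    def test_positions_stay_inside_arena(self):
        cfg = cs.TrajSimConfig(step_mean_cm=15.0, p_bury=0.0, duration_min=60, seed=3)
        traj = cs.gen_trajectory(cfg)
        xy = traj.detected_xy()
        assert xy[:, 0].min() >= 0 and xy[:, 0].max() <= cfg.arena_width_cm
        assert xy[:, 1].min() >= 0 and xy[:, 1].max() <= cfg.arena_height_cm

    def test_turning_concentration_recovery(self):
        # huge arena so wall reflections never distort the turn distribution
        cfg = cs.TrajSimConfig(arena_width_cm=1e6, arena_height_cm=1e6,
                               kappa_turn=5.0, p_bury=0.0,
                               duration_min=10_000 / 6, seed=2)
        traj = cs.gen_trajectory(cfg)
        pos = pd.DataFrame({"minute": np.arange(traj.n_detected),
                            "x_cm": traj.x_cm[traj.detected],
                            "y_cm": traj.y_cm[traj.detected]})
        angles = cs.turning_angles(pos)
        assert cs.vonmises_kappa(angles) == pytest.approx(5.0, rel=0.10)

    def test_object_outside_arena_rejected(self):
        with pytest.raises(ValueError, match="inside the arena"):
            cs.TrajSimConfig(object_xy=(100.0, 100.0)).validate()


class TestJointGenerator:
    def _configs(self, n, coupling_seed=0):
        ch = cs.ChronoSimConfig(n_individuals=n, n_days=7, seed=coupling_seed)
        tr = cs.TraitSimConfig(n_individuals=n, seed=coupling_seed + 1)
        return ch, tr

    def test_mismatched_counts_rejected(self):
        ch = cs.ChronoSimConfig(n_individuals=5)
        tr = cs.TraitSimConfig(n_individuals=6)
        with pytest.raises(ValueError, match="n_individuals"):
            cs.gen_joint_dataset(ch, tr)

    def test_uncoupled_correlation_near_zero(self):
        ch, tr = self._configs(150)
        _, _, _, truth = cs.gen_joint_dataset(ch, tr, coupling_beta=0.0)
        k = truth.trait_names.index("aggressiveness")
        r = np.corrcoef(truth.wake_offsets, truth.u[:, k])[0, 1]
        assert abs(r) < 3 / np.sqrt(150)

    def test_coupling_approaches_one_in_noise_free_limit(self):
        ch = cs.ChronoSimConfig(n_individuals=80, n_days=7, seed=3)
        tr = cs.TraitSimConfig(n_individuals=80,
                               Sigma_ind=1e-8 * np.eye(4),
                               Sigma_e=np.eye(4), sd_batch=0.0, seed=4)
        _, _, _, truth = cs.gen_joint_dataset(ch, tr, coupling_beta=0.1)
        k = truth.trait_names.index("aggressiveness")
        r = np.corrcoef(truth.wake_offsets, truth.u[:, k])[0, 1]
        assert r > 0.999

    def test_realized_correlation_matches_closed_form(self):
        # analytic: r = b*sd_wake / sqrt(b^2 sd_wake^2 + V_ind_aggr)
        b = 0.05
        ch = cs.ChronoSimConfig(n_individuals=100, n_days=7, seed=11)
        tr = cs.TraitSimConfig(n_individuals=100, seed=12)
        _, _, _, truth = cs.gen_joint_dataset(ch, tr, coupling_beta=b)
        k = truth.trait_names.index("aggressiveness")
        v_ind = tr.Sigma_ind[k, k]
        sd_w = ch.sd_wake_between
        r_true = b * sd_w / np.sqrt(b ** 2 * sd_w ** 2 + v_ind)
        r_hat = np.corrcoef(truth.wake_offsets, truth.u[:, k])[0, 1]
        se = (1 - r_true ** 2) / np.sqrt(100)
        assert abs(r_hat - r_true) < 3 * se


def test_writers_roundtrip(tmp_path):
    cfg = cs.ChronoSimConfig(n_individuals=2, n_days=2, seed=1)
    det, env, truth = cs.gen_chronotype_dataset(cfg)
    synthetic.write_detections_csv(det, tmp_path / "det.csv")
    synthetic.write_env_csv(env, tmp_path / "env.csv")
    synthetic.write_ground_truth_json(truth, tmp_path / "truth.json")
    back = pd.read_csv(tmp_path / "det.csv", parse_dates=["timestamp"])
    assert len(back) == len(det)
    assert (back.timestamp - det.timestamp).abs().max() < pd.Timedelta("1ms")
    import json
    payload = json.loads((tmp_path / "truth.json").read_text())
    assert "wake_offsets" in payload and len(payload["wake_offsets"]) == 2
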