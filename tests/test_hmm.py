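"""ZIP-HMM unit tests: binning, emissions, forward/Viterbi, EM, chronotype."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

import chronosynd as cs
from chronosynd import hmm


def brute_force_loglik(params, counts):
    """Independent oracle: sum over all 2^T state paths."""
    T = len(counts)
    total = -np.inf
    logd = np.log(params.delta)
    logg = np.log(params.gamma)
    emis = np.array([[hmm.zip_log_pmf(int(c), params.lam[s], params.pi_zero[s])
                      for s in (0, 1)] for c in counts])
    for path in product((0, 1), repeat=T):
        ll = logd[path[0]] + emis[0, path[0]]
        for t in range(1, T):
            ll += logg[path[t - 1], path[t]] + emis[t, path[t]]
        total = np.logaddexp(total, ll)
    return total


def random_params(rng):
    g = rng.uniform(0.05, 0.95, size=2)
    return cs.ZipHmmParams(
        delta=np.array([0.5, 0.5]),
        gamma=np.array([[g[0], 1 - g[0]], [1 - g[1], g[1]]]),
        lam=rng.uniform(0.2, 6.0, size=2),
        pi_zero=rng.uniform(0.0, 0.6, size=2),
    )


class TestBinning:
    def test_empty_input_gives_zero_counts(self):
        b = hmm.bin_detections([], "2022-05-01", "2022-05-02")
        assert len(b.counts) == 288
        assert b.counts.sum() == 0

    def test_direct_counting_example(self):
        ts = pd.to_datetime(["2022-05-01 00:00:30", "2022-05-01 00:01:40",
                             "2022-05-01 00:05:10"])
        b = hmm.bin_detections(ts, "2022-05-01", "2022-05-02")
        assert list(b.counts[:2]) == [2, 1]
        assert b.counts.sum() == 3

    def test_conservation_against_histogram_oracle(self, rng):
        secs = rng.uniform(0, 86400, size=10_000)
        base = pd.Timestamp("2022-05-01")
        ts = base + pd.to_timedelta(secs, unit="s")
        b = hmm.bin_detections(ts, base, base + pd.Timedelta(days=1))
        assert b.counts.sum() == 10_000
        oracle, _ = np.histogram(secs, bins=np.arange(0, 86401, 300))
        assert np.array_equal(b.counts, oracle)

    def test_out_of_window_dropped_and_logged(self):
        ts = pd.to_datetime(["2022-04-30 23:59:00", "2022-05-01 01:00:00"])
        b = hmm.bin_detections(ts, "2022-05-01", "2022-05-02")
        assert b.n_dropped == 1
        assert b.counts.sum() == 1

    def test_bins_aligned_to_midnight(self):
        b = hmm.bin_detections([], "2022-05-01 06:17", "2022-05-01 12:00")
        assert b.bin_starts[0].minute % 5 == 0


class TestZipPmf:
    def test_reduces_to_poisson_when_no_inflation(self):
        for c in (0, 1, 5):
            assert hmm.zip_log_pmf(c, 3.0, 0.0) == pytest.approx(
                poisson.logpmf(c, 3.0), abs=1e-12)

    def test_zero_count_large_lambda_limit(self):
        assert hmm.zip_log_pmf(0, 700.0, 0.3) == pytest.approx(np.log(0.3), abs=1e-9)

    @pytest.mark.parametrize("lam,pz", [(0.5, 0.0), (4.0, 0.2), (8.0, 0.7)])
    def test_normalisation(self, lam, pz):
        counts = np.arange(0, 200)
        total = np.exp([hmm.zip_log_pmf(int(c), lam, pz) for c in counts]).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            hmm.zip_log_pmf(1, -1.0, 0.2)
        with pytest.raises(ValueError):
            hmm.zip_log_pmf(1, 1.0, 1.0)


class TestForward:
    def test_single_bin_is_delta_weighted_mixture(self):
        p = cs.ZipHmmParams(delta=[0.3, 0.7], gamma=[[0.9, 0.1], [0.2, 0.8]],
                            lam=[0.5, 4.0], pi_zero=[0.0, 0.2])
        expected = np.logaddexp(
            np.log(0.3) + hmm.zip_log_pmf(2, 0.5, 0.0),
            np.log(0.7) + hmm.zip_log_pmf(2, 4.0, 0.2))
        assert cs.forward_loglik(p, [2]) == pytest.approx(expected, abs=1e-10)

    def test_identical_emissions_ignore_transitions(self, rng):
        counts = rng.poisson(2, size=30)
        lls = []
        for diag in (0.5, 0.9, 0.99):
            p = cs.ZipHmmParams(delta=[0.5, 0.5],
                                gamma=[[diag, 1 - diag], [1 - diag, diag]],
                                lam=[2.0, 2.0], pi_zero=[0.1, 0.1])
            lls.append(cs.forward_loglik(p, counts))
        assert np.ptp(lls) < 1e-9
        iid = sum(hmm.zip_log_pmf(int(c), 2.0, 0.1) for c in counts)
        assert lls[0] == pytest.approx(iid, abs=1e-9)

    def test_matches_path_enumeration(self, rng):
        for _ in range(10):
            p = random_params(rng)
            T = int(rng.integers(2, 9))
            counts = rng.poisson(rng.uniform(0.5, 4.0), size=T)
            assert cs.forward_loglik(p, counts) == pytest.approx(
                brute_force_loglik(p, counts), abs=1e-8)

    def test_label_permutation_invariance(self, rng):
        p = random_params(rng)
        counts = rng.poisson(2, size=40)
        perm = cs.ZipHmmParams(delta=p.delta[::-1].copy(),
                               gamma=p.gamma[::-1, ::-1].copy(),
                               lam=p.lam[::-1].copy(),
                               pi_zero=p.pi_zero[::-1].copy())
        assert cs.forward_loglik(p, counts) == pytest.approx(
            cs.forward_loglik(perm, counts), abs=1e-9)


class TestViterbi:
    def test_certain_emissions_threshold_counts(self):
        p = cs.ZipHmmParams(delta=[0.5, 0.5], gamma=[[0.5, 0.5], [0.5, 0.5]],
                            lam=[1e-8, 5.0], pi_zero=[0.0, 0.0])
        counts = np.array([0, 3, 0, 0, 7, 1, 0])
        path = cs.viterbi_decode(p, counts)
        assert np.array_equal(path.states, (counts > 0).astype(int))

    def test_beats_random_paths(self, rng):
        p = random_params(rng)
        counts = rng.poisson(2, size=25)

        def path_ll(states):
            ll = np.log(p.delta[states[0]]) + hmm.zip_log_pmf(
                int(counts[0]), p.lam[states[0]], p.pi_zero[states[0]])
            for t in range(1, len(counts)):
                ll += np.log(p.gamma[states[t - 1], states[t]])
                ll += hmm.zip_log_pmf(int(counts[t]), p.lam[states[t]],
                                      p.pi_zero[states[t]])
            return ll

        vit = cs.viterbi_decode(p.ordered(), counts)
        ll_vit = path_ll(vit.states)
        for _ in range(1000):
            assert ll_vit >= path_ll(rng.integers(0, 2, size=len(counts))) - 1e-9

    def test_palindromic_posteriors_under_symmetric_model(self):
        p = cs.ZipHmmParams(delta=[0.5, 0.5], gamma=[[0.9, 0.1], [0.1, 0.9]],
                            lam=[0.3, 4.0], pi_zero=[0.0, 0.0])
        counts = np.array([0, 0, 3, 5, 3, 0, 0])
        path = cs.viterbi_decode(p, counts)
        assert np.allclose(path.posterior_active,
                           path.posterior_active[::-1], atol=1e-9)


class TestEm:
    def test_loglik_nondecreasing(self):
        counts, _ = cs.gen_markov_series(400, seed=5)
        fit = cs.fit_zip_hmm(counts, n_starts=1, seed=0)
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs > -1e-8)

    def test_recovery_from_markov_series(self):
        counts, _ = cs.gen_markov_series(2000, lam_active=4.0,
                                         pi_zero_active=0.2, diag=0.95, seed=1)
        fit = cs.fit_zip_hmm(counts, seed=0)
        p = fit.params
        assert abs(p.lam[1] - 4.0) / 4.0 < 0.10
        assert abs(p.gamma[0, 0] - 0.95) < 0.03
        assert abs(p.gamma[1, 1] - 0.95) < 0.03

    def test_init_at_truth_converges_quickly(self):
        counts, _ = cs.gen_markov_series(1000, seed=2)
        truth = cs.ZipHmmParams(delta=[0.5, 0.5],
                                gamma=[[0.95, 0.05], [0.05, 0.95]],
                                lam=[1e-6, 4.0], pi_zero=[0.0, 0.2])
        fit = cs.fit_zip_hmm(counts, init=truth, n_starts=1, max_iter=200,
                             tol=1e-6, seed=0)
        assert fit.converged
        assert abs(fit.params.lam[1] - 4.0) / 4.0 < 0.10

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cs.fit_zip_hmm(np.zeros(200, dtype=int))

    def test_active_label_ordering(self):
        counts, _ = cs.gen_markov_series(1000, seed=3)
        fit = cs.fit_zip_hmm(counts, seed=0)
        ec = fit.params.expected_counts
        assert ec[1] >= ec[0]


class TestChronotypeExtraction:
    def _binned_day(self, states, date="2022-05-01"):
        start = pd.Timestamp(date)
        bins = pd.DatetimeIndex([start + pd.Timedelta(minutes=5 * i)
                                 for i in range(len(states))])
        binned = hmm.BinnedSeries(individual_id="F0", bin_starts=bins,
                                  counts=np.zeros(len(states), dtype=int))
        path = hmm.StatePath(states=np.asarray(states),
                             posterior_active=np.asarray(states, dtype=float))
        return path, binned

    def test_awakening_arithmetic(self):
        # Rest until 06:35, then Active until 18:30, Rest after
        states = np.zeros(288, dtype=int)
        states[79:222] = 1          # bin 79 starts 06:35; bin 222 starts 18:30
        path, binned = self._binned_day(states)
        solar = pd.DataFrame({"date": ["2022-05-01"], "sunrise": ["06:00"],
                              "sunset": ["19:00"]})
        obs = hmm.extract_daily_chronotype(path, binned, solar)
        assert len(obs) == 1
        assert obs[0].awakening_min == pytest.approx(35.0)
        assert obs[0].rest_onset_min == pytest.approx(-30.0)

    def test_all_active_day_yields_no_observation(self):
        states = np.ones(288, dtype=int)
        path, binned = self._binned_day(states)
        solar = pd.DataFrame({"date": ["2022-05-01"], "sunrise": ["06:00"],
                              "sunset": ["19:00"]})
        assert hmm.extract_daily_chronotype(path, binned, solar) == []

    def test_missing_solar_entry_names_date(self):
        states = np.zeros(288, dtype=int)
        states[80:200] = 1
        path, binned = self._binned_day(states)
        solar = pd.DataFrame({"date": ["2022-06-01"], "sunrise": ["06:00"],
                              "sunset": ["19:00"]})
        with pytest.raises(KeyError, match="2022-05-01"):
            hmm.extract_daily_chronotype(path, binned, solar)


def test_solar_helper_is_plausible_for_mallorca():
    out = hmm.solar_events(["2022-06-21"], latitude_deg=39.5, longitude_deg=2.6,
                           utc_offset_hours=2.0)
    sunrise = out.loc[0, "sunrise"]
    sunset = out.loc[0, "sunset"]
    assert 5 <= sunrise.hour <= 7
    assert 20 <= sunset.hour <= 22
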