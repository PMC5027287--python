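"""HMM idealization, transition densities and transition-probability rates."""

import numpy as np
import pytest

import casfret as cf
from casfret.idealize import IdealizedTrajectory

from conftest import make_fret_trajectory

MEANS = np.array([0.0, 0.42, 0.92])


def _labels_with_dwells(rng, n_frames, p_stay=0.9):
    labels = np.zeros(n_frames, dtype=np.int8)
    state = 0
    for i in range(n_frames):
        if rng.random() > p_stay:
            state = rng.integers(0, 3)
        labels[i] = state
    return labels


def _ideal(tp, molecule_id="m0"):
    """Minimal IdealizedTrajectory with a prescribed transition matrix."""
    return IdealizedTrajectory(
        molecule_id=molecule_id,
        states=np.array([0, 1], dtype=np.int8),
        state_means=MEANS.copy(),
        state_sds=np.zeros(3),
        transition_matrix=np.asarray(tp, dtype=float),
        log_likelihood=0.0,
        occupancy=np.array([1, 1, 0]),
        degenerate=np.array([False, False, True]),
        fret=MEANS[[0, 1]],
    )


class TestFretHmm:
    def test_noiseless_viterbi_recovers_path_exactly(self):
        rng = np.random.default_rng(1)
        labels = _labels_with_dwells(rng, 500)
        est = cf.FretHmm().fit(MEANS[labels])
        assert np.array_equal(est.labels_, labels)

    def test_low_noise_misclassification_below_one_percent(self):
        rng = np.random.default_rng(2)
        labels = _labels_with_dwells(rng, 3000)
        fret = MEANS[labels] + rng.normal(0, 0.05, labels.size)
        est = cf.FretHmm().fit(fret)
        assert np.mean(est.labels_ != labels) < 0.01

    def test_viterbi_invariant_to_intensity_rescaling(self, analysis_config):
        ds = cf.generate_dataset("5-20_mm", n_molecules=1, duration=60, seed=6)
        trace = ds.traces[0]
        cfg = cf.AnalysisConfig.from_manifest(ds.manifest)
        scale = 2.5
        scaled = cf.IntensityTrace(
            molecule_id=trace.molecule_id,
            time_s=trace.time_s,
            donor=cfg.background_donor + scale * (trace.donor - cfg.background_donor),
            acceptor=cfg.background_acceptor
            + scale * (trace.acceptor - cfg.background_acceptor),
            frame_interval=trace.frame_interval,
        )
        t1 = cf.correct_trace(trace, cfg)
        t2 = cf.correct_trace(scaled, cfg)
        i1 = cf.fit_hmm(t1)
        i2 = cf.fit_hmm(t2)
        assert np.array_equal(i1.states, i2.states)

    def test_high_mean_recovered_on_cognate_traces(self):
        """Free-mean EM on bound cognate traces returns the high-state mean
        within 0.03 of the emission truth."""
        ds = cf.generate_dataset("cognate", n_molecules=30, duration=60, seed=8)
        cfg = cf.AnalysisConfig.from_manifest(ds.manifest)
        trajs = [cf.correct_trace(t, cfg) for t in ds.traces]
        ideal = cf.idealize_trajectories(trajs)
        means = cf.aggregate_state_means(ideal)
        assert means[2] == pytest.approx(0.92, abs=0.03)

    def test_degenerate_states_flagged_not_raised(self):
        rng = np.random.default_rng(3)
        est = cf.FretHmm().fit(0.92 + rng.normal(0, 0.03, 200))
        assert est.degenerate_[0] and est.degenerate_[1]
        assert not est.degenerate_[2]
        assert est.occupancy_[2] == 200

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            cf.FretHmm().fit(np.zeros(10))

    def test_transition_probability_matches_discretized_ctmc(self):
        """Slow-binding two-state chain observed at frame instants:
        geometric-mean T_p(high->zero) matches the exact discretized-CTMC
        entry expm(Q dt)[H, U] -- which approximates 1 - exp(-k dt) in this
        regime -- within 15% over 100 molecules."""
        from scipy.linalg import expm

        scheme = cf.KineticScheme(
            rate_constants={
                ("U", "H"): cf.RateConstant(0.2),
                ("H", "U"): cf.RateConstant(2.0),
            }
        )
        rng = np.random.default_rng(20)
        frame_times = np.arange(600) * 0.1
        ideal = []
        for seed in range(100):
            path = cf.simulate_state_path(scheme, 60.001, seed=seed, initial_state="H")
            states = path.state_at(frame_times)
            fret = MEANS[states] + rng.normal(0, 0.04, states.size)
            ideal.append(cf.fit_hmm(fret))
        rates = cf.estimate_transition_rates(ideal, 0.1)
        exact = expm(scheme.rate_matrix() * 0.1)[2, 0]
        assert exact == pytest.approx(1 - np.exp(-2.0 * 0.1), rel=0.02)
        assert rates.mean_probabilities[2, 0] == pytest.approx(exact, rel=0.15)


class TestTransitionRates:
    def test_saturated_probability_gives_sampling_rate(self):
        """T_p = 1 at 0.1 s frames converts to 10 per second."""
        rates = cf.estimate_transition_rates(
            [_ideal([[0, 1, 0], [1, 0, 0], [0, 0, 1]])], 0.1, conversion="linear"
        )
        assert rates.rates[0, 1] == pytest.approx(10.0)
        assert rates.rates[1, 0] == pytest.approx(10.0)

    def test_unobserved_pair_reported_as_zero(self):
        rates = cf.estimate_transition_rates(
            [_ideal([[0.5, 0.5, 0], [0.5, 0.5, 0], [0, 0, 1]])], 0.1
        )
        assert rates.rates[0, 2] == 0.0
        assert not rates.observed[0, 2]
        assert rates.observed[0, 1]

    def test_geometric_mean_equals_arithmetic_when_equal(self):
        tp = [[0.8, 0.2, 0], [0.3, 0.7, 0], [0, 0, 1]]
        rates = cf.estimate_transition_rates([_ideal(tp), _ideal(tp, "m1")], 0.1)
        assert rates.mean_probabilities[0, 1] == pytest.approx(0.2)
        assert rates.mean_probabilities[1, 0] == pytest.approx(0.3)

    def test_fast_exit_recovered_with_log_conversion(self):
        """A sampling-state exit at 10/s (comparable to the sampling rate) is
        recovered within 20% using the exact discrete-observation inversion;
        the linear (published) conversion saturates and cannot."""
        scheme = cf.get_preset("no_pam").scheme
        rng = np.random.default_rng(15)
        frame_times = np.arange(600) * 0.1
        ideal = []
        for seed in range(80):
            path = cf.simulate_state_path(scheme, 60.001, seed=seed)
            states = path.state_at(frame_times)
            fret = MEANS[states] + rng.normal(0, 0.04, states.size)
            ideal.append(cf.fit_hmm(fret))
        log_rates = cf.estimate_transition_rates(ideal, 0.1, conversion="log")
        lin_rates = cf.estimate_transition_rates(ideal, 0.1, conversion="linear")
        assert log_rates.rates[1, 0] == pytest.approx(10.0, rel=0.2)
        assert lin_rates.rates[1, 0] < 8.0

    def test_invalid_frame_interval_rejected(self):
        with pytest.raises(ValueError):
            cf.estimate_transition_rates([_ideal(np.eye(3))], 0.0)


class TestTransitionDensity:
    def test_two_state_data_peaks_at_corners(self):
        rng = np.random.default_rng(4)
        labels = np.repeat(rng.integers(0, 2, 60) * 2, 10)[:500]
        fret = MEANS[labels] + rng.normal(0, 0.03, labels.size)
        ideal = cf.fit_hmm(fret)
        tdp = cf.transition_density([ideal])
        assert tdp.n_transitions > 0
        centers = (tdp.bin_edges[:-1] + tdp.bin_edges[1:]) / 2
        bx, by = np.meshgrid(centers, centers, indexing="ij")
        corner = ((np.abs(bx - 0) < 0.15) & (np.abs(by - 0.92) < 0.15)) | (
            (np.abs(bx - 0.92) < 0.15) & (np.abs(by - 0) < 0.15)
        )
        assert tdp.hist[corner].sum() / tdp.hist.sum() > 0.95

    def test_mismatch_preset_shows_mid_and_high_clusters(self, dataset_9_20):
        ds, cfg, trajs, _ = dataset_9_20
        ideal = cf.idealize_trajectories(trajs[:40])
        tdp = cf.transition_density(ideal)
        centers = (tdp.bin_edges[:-1] + tdp.bin_edges[1:]) / 2
        bx, by = np.meshgrid(centers, centers, indexing="ij")
        zero_to_mid = tdp.hist[(np.abs(bx) < 0.15) & (np.abs(by - 0.42) < 0.2)].sum()
        zero_to_high = tdp.hist[(np.abs(bx) < 0.15) & (np.abs(by - 0.92) < 0.2)].sum()
        assert zero_to_mid > 0
        assert zero_to_high > 0

    def test_single_dwell_trace_has_no_transitions(self):
        rng = np.random.default_rng(5)
        ideal = cf.fit_hmm(0.92 + rng.normal(0, 0.03, 100))
        tdp = cf.transition_density([ideal])
        assert tdp.n_transitions == 0
        assert tdp.hist.sum() == 0
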