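"""Hidden-Markov behavioral classifier: windows, features, training, decoding."""

import json

import numpy as np
import pytest

import flyseize as fz
from flyseize import hmm as H
from flyseize.arena import AnalysisInterval

from conftest import line_traj, make_traj


def _noisy_walk_traj(seed, duration_s=60.0, fps=30.0):
    rng = np.random.default_rng(seed)
    n = int(duration_s * fps)
    steps = rng.normal(0.3, 0.1, size=(n, 2))
    xy = np.cumsum(steps, axis=0)
    return make_traj(xy[:, 0], xy[:, 1], fps=fps)


class TestSegmentWindows:
    def test_sequential_window_count(self):
        traj = _noisy_walk_traj(0, 120.0)
        assert len(fz.segment_windows(traj)) == 60

    def test_sliding_window_count(self):
        traj = _noisy_walk_traj(0, 120.0)
        assert len(fz.segment_windows(traj, stride_frames=1)) == 3600 - 60 + 1

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            fz.segment_windows(make_traj(np.zeros(30), np.zeros(30)))

    def test_bad_stride_rejected(self):
        with pytest.raises(ValueError):
            fz.segment_windows(_noisy_walk_traj(0), stride_frames=0)

    def test_gappy_windows_dropped(self):
        traj = _noisy_walk_traj(1, 10.0)
        gap = np.zeros(len(traj), bool)
        gap[:30] = True  # 50 % of the first window interpolated
        traj.gap_mask = gap
        wins = fz.segment_windows(traj, max_interp_fraction=0.25)
        assert wins[0].start_frame == 60


class TestFeatureModel:
    def _straight_windows(self, n=300, W=60, noise=1e-3, seed=0):
        rng = np.random.default_rng(seed)
        wins = []
        for i in range(n):
            speed = rng.uniform(1.0, 10.0)
            x = speed / 30.0 * np.arange(W)
            y = rng.normal(0, noise, W)
            wins.append(fz.TrajectoryWindow("f", 0, np.column_stack([x, y])))
        return wins

    def test_stationary_training_set_degenerate(self):
        wins = [fz.TrajectoryWindow("f", 0, np.zeros((60, 2)))
                for _ in range(300)]
        with pytest.raises(ValueError, match="degenerate"):
            fz.fit_feature_model(wins, n_components=2,
                                 min_windows_per_component=10)

    def test_straight_segments_concentrate_variance(self):
        wins = self._straight_windows()
        fm = fz.fit_feature_model(wins, n_components=2,
                                  min_windows_per_component=10)
        X = H.align_windows(np.stack([w.xy for w in wins]))
        total = X.reshape(len(wins), -1).var(axis=0, ddof=1).sum()
        assert fm.scale[0] ** 2 / total >= 0.99

    def test_training_features_have_unit_variance(self):
        wins = self._straight_windows(noise=0.05)
        fm = fz.fit_feature_model(wins, n_components=3,
                                  min_windows_per_component=10)
        feats = H.window_features(np.stack([w.xy for w in wins]), fm)
        assert np.allclose(feats.var(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_rotation_invariant_features(self):
        wins = self._straight_windows(noise=0.05)
        fm = fz.fit_feature_model(wins, n_components=3,
                                  min_windows_per_component=10)
        w = wins[0].xy
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rotated = w @ R.T + np.array([4.0, -2.0])
        f0 = H.window_features(w, fm)
        f1 = H.window_features(rotated, fm)
        assert np.allclose(f0, f1, atol=1e-8)

    def test_mean_window_maps_near_zero(self):
        wins = self._straight_windows(noise=0.05)
        fm = fz.fit_feature_model(wins, n_components=3,
                                  min_windows_per_component=10)
        mean_win = fm.mean.reshape(-1, 2)
        f = H.window_features(mean_win, fm)
        assert np.all(np.abs(f) < 1e-6)

    def test_window_length_mismatch_rejected(self):
        wins = self._straight_windows(noise=0.05)
        fm = fz.fit_feature_model(wins, n_components=2,
                                  min_windows_per_component=10)
        with pytest.raises(ValueError, match="length"):
            H.window_features(np.zeros((30, 2)), fm)

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="windows"):
            fz.fit_feature_model(self._straight_windows(n=40), n_components=5)


def _simulate_hmm_features(seed, n_seq=6, seq_len=80):
    """Sequences from a known, well-separated 3-state Gaussian HMM plus
    matched per-window motion values for the labeling rule."""
    rng = np.random.default_rng(seed)
    A = np.array([[0.8, 0.15, 0.05], [0.4, 0.5, 0.1], [0.05, 0.05, 0.9]])
    means = np.array([[4.0, 0.0], [0.0, 4.0], [-4.0, -4.0]])
    feats, disps = [], []
    for _ in range(n_seq):
        z = [0]
        for _ in range(seq_len - 1):
            z.append(rng.choice(3, p=A[z[-1]]))
        z = np.array(z)
        feats.append(means[z] + 0.3 * rng.normal(size=(seq_len, 2)))
        disps.append(np.array([12.0, 0.6, 0.9])[z]
                     + 0.05 * rng.normal(size=seq_len))
    return A, feats, disps


class TestTraining:
    def test_identical_seed_and_data_identical_model(self):
        _, feats, _ = _simulate_hmm_features(1)
        m1 = fz.train_classifier(feats, seed=5, n_restarts=3)
        m2 = fz.train_classifier(feats, seed=5, n_restarts=3)
        assert np.array_equal(m1.transmat, m2.transmat)
        assert np.array_equal(m1.means, m2.means)
        assert np.array_equal(m1.covars, m2.covars)

    def test_loglik_trace_monotone(self):
        # EM guarantees a non-decreasing log-likelihood; the covariance ridge
        # can introduce sub-tolerance oscillation, hence the relative slack
        _, feats, _ = _simulate_hmm_features(2)
        m = fz.train_classifier(feats, seed=0, n_restarts=2)
        trace = np.asarray(m.metadata["loglik_trace"])
        assert np.all(np.diff(trace) >= -1e-4 * (1.0 + np.abs(trace[:-1])))

    def test_too_few_flies_rejected(self):
        _, feats, _ = _simulate_hmm_features(3)
        with pytest.raises(ValueError, match="2 flies"):
            fz.train_classifier(feats[:1])


class TestStateLabeling:
    def test_constructed_model_labels_recovered(self):
        _, feats, disps = _simulate_hmm_features(4)
        model = fz.train_classifier(feats, seed=0, n_restarts=3)
        model = fz.assign_state_labels(model, feats, disps)
        # the state whose mean is nearest each generating mean gets its label
        gen_means = {"walking": [4.0, 0.0], "pausing": [0.0, 4.0],
                     "immobilized": [-4.0, -4.0]}
        for name, mu in gen_means.items():
            s = int(np.argmin(((model.means - mu) ** 2).sum(axis=1)))
            assert model.state_names[s] == name

    def test_equal_self_transition_tie_break_by_index(self):
        model = fz.HmmModel(
            startprob=np.array([1 / 3, 1 / 3, 1 / 3]),
            transmat=np.full((3, 3), 1 / 3),
            means=np.array([[5.0], [0.0], [0.1]]),
            covars=np.full((3, 1), 0.01),
        )
        rng = np.random.default_rng(0)
        feats = [rng.choice([5.0, 0.0, 0.1], size=(50, 1)) for _ in range(2)]
        disps = [np.where(f[:, 0] > 2, 10.0, 0.5) for f in feats]
        labeled = fz.assign_state_labels(model, feats, disps)
        assert labeled.state_names == ("walking", "immobilized", "pausing")

    def test_collapsed_regime_warns(self):
        rng = np.random.default_rng(1)
        model = fz.HmmModel(
            startprob=np.array([0.5, 0.25, 0.25]),
            transmat=np.array([[0.9, 0.05, 0.05],
                               [0.45, 0.45, 0.1],
                               [0.45, 0.1, 0.45]]),
            means=np.array([[0.0], [50.0], [-50.0]]),
            covars=np.full((3, 1), 0.5),
        )
        feats = [rng.normal(0.0, 0.7, size=(60, 1)) for _ in range(2)]
        disps = [np.abs(rng.normal(1, 0.1, 60)) for _ in range(2)]
        with pytest.warns(UserWarning, match="collapse"):
            fz.assign_state_labels(model, feats, disps)


class TestDecoding:
    def test_posteriors_sum_to_one(self, separated_cohort, separated_model):
        model, fm = separated_model
        seq = fz.decode_states(model, separated_cohort[0].trajectory, fm)
        assert np.allclose(seq.posteriors.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((seq.confidence >= 0) & (seq.confidence <= 1))

    def test_decode_matches_generating_labels_away_from_transitions(
            self, separated_cohort, separated_model):
        model, fm = separated_model
        lab = separated_cohort[1]
        seq = fz.decode_states(model, lab.trajectory, fm)
        # score only frames > 1.5 s from any ground-truth state change
        z = lab.labels
        change = np.flatnonzero(np.diff(z) != 0)
        far = np.ones(len(z), bool)
        for c in change:
            far[max(0, c - 45):c + 46] = False
        assert (seq.states[far] == z[far]).mean() >= 0.97

    def test_decoding_invariant_under_rigid_motion(
            self, separated_cohort, separated_model):
        model, fm = separated_model
        traj = separated_cohort[2].trajectory
        th = 0.5
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        xy = traj.xy @ R.T + np.array([3.0, 1.0])
        moved = make_traj(xy[:, 0], xy[:, 1])
        s0 = fz.decode_states(model, traj, fm)
        s1 = fz.decode_states(model, moved, fm)
        assert (s0.states == s1.states).mean() > 0.999

    def test_short_trajectory_rejected(self, separated_model):
        model, fm = separated_model
        with pytest.raises(ValueError, match="shorter"):
            fz.decode_states(model, make_traj(np.zeros(30), np.zeros(30)), fm)

    def test_unlabeled_model_rejected(self, separated_model):
        model, fm = separated_model
        from dataclasses import replace
        with pytest.raises(ValueError, match="labeled"):
            fz.decode_states(replace(model, state_names=None),
                             _noisy_walk_traj(0), fm)


class TestSerialization:
    def test_roundtrip_reproduces_decoding(self, tmp_path, separated_cohort,
                                           separated_model):
        model, fm = separated_model
        path = tmp_path / "model.json"
        fz.save_model(path, model, fm)
        model2, fm2 = fz.load_model(path)
        assert np.array_equal(model.transmat, model2.transmat)
        assert np.array_equal(fm.components, fm2.components)
        traj = separated_cohort[3].trajectory
        s0 = fz.decode_states(model, traj, fm)
        s1 = fz.decode_states(model2, traj, fm2)
        assert np.array_equal(s0.states, s1.states)
        assert np.array_equal(s0.confidence, s1.confidence)

    def test_version_mismatch_refused(self, tmp_path, separated_model):
        model, fm = separated_model
        path = tmp_path / "model.json"
        fz.save_model(path, model, fm)
        doc = json.loads(path.read_text())
        doc["version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="version"):
            fz.load_model(path)


def _sequence_from_runs(runs, fps=30.0):
    """StateSequence from (state, seconds) run-length pairs."""
    states = np.concatenate([
        np.full(int(round(sec * fps)), fz.STATES.index(name), dtype=np.int8)
        for name, sec in runs
    ])
    t = np.arange(len(states)) / fps
    return fz.StateSequence("fly", fps, t, states, np.ones(len(states)))


class TestImmobilizationSummary:
    IV = AnalysisInterval("high_temp", 0.0, 120.0)

    def test_single_long_bout(self):
        seq = _sequence_from_runs([("walking", 40), ("immobilized", 49),
                                   ("walking", 31)])
        s = fz.immobilization_summary(seq, self.IV)
        assert s.total_immobilized_s == pytest.approx(49.0)
        assert s.longest_bout_s == pytest.approx(49.0)
        assert s.incidence and s.onset_time_s == pytest.approx(40.0)

    def test_all_walking(self):
        seq = _sequence_from_runs([("walking", 120)])
        s = fz.immobilization_summary(seq, self.IV)
        assert s.total_immobilized_s == 0.0 and not s.incidence
        assert s.onset_time_s is None

    def test_three_short_bouts_no_incidence(self):
        runs = [("walking", 30), ("immobilized", 1), ("walking", 30),
                ("immobilized", 1), ("walking", 30), ("immobilized", 1),
                ("walking", 27)]
        s = fz.immobilization_summary(_sequence_from_runs(runs), self.IV)
        assert s.total_immobilized_s == pytest.approx(3.0)
        assert not s.incidence  # no single bout reaches the 2-s criterion

    def test_cumulative_onset_curve(self):
        seqs = [
            _sequence_from_runs([("walking", 10), ("immobilized", 110)]),
            _sequence_from_runs([("walking", 60), ("immobilized", 60)]),
            _sequence_from_runs([("walking", 120)]),
        ]
        summaries = [fz.immobilization_summary(s, self.IV) for s in seqs]
        t, frac = fz.cumulative_onset_curve(summaries, self.IV)
        assert frac[0] == 0.0
        assert frac[-1] == pytest.approx(2 / 3)
        assert np.all(np.diff(frac) >= 0)
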