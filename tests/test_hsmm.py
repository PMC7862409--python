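"""Duration-dependent HSMM: training, Viterbi optimality, segmentation."""
import numpy as np
import pytest

from radarhrv import train_hsmm, viterbi_segment
from radarhrv.beats import match_beats, scores, states_to_beats
from radarhrv.errors import (
    HeartRateOutOfRangeError,
    InvalidTrainingDataError,
)
from radarhrv.hsmm import HsmmModel, path_score
from radarhrv.types import FeatureTrack, StateSequence

FEATURE_FS = 50.0


def _make_track(features, hr=60.0):
    features = np.asarray(features, dtype=float)
    return FeatureTrack(features=features, feature_fs=FEATURE_FS,
                        hr_bpm=np.full(len(features), hr),
                        norm_mean=np.zeros(features.shape[1]),
                        norm_std=np.ones(features.shape[1]))


def _labelled_gaussian_track(rng, state_means, durations, n_cycles,
                             noise=0.1, hr=60.0):
    """Synthetic feature track with known per-state Gaussian emissions."""
    states, feats = [], []
    for _ in range(n_cycles):
        for s in range(4):
            for _ in range(durations[s]):
                states.append(s)
                feats.append(state_means[s] + noise * rng.normal(size=len(state_means[s])))
    track = _make_track(np.array(feats), hr=hr)
    labels = StateSequence(states=np.array(states), feature_fs=FEATURE_FS)
    return track, labels


STATE_MEANS = np.array([
    [3.0, 3.0, 2.0, 0.0],
    [0.5, 0.5, 0.3, 0.0],
    [2.0, 2.0, 1.5, 0.0],
    [-0.5, -0.5, -0.3, 0.0],
])
DUR_60BPM = [5, 9, 4, 32]  # frames at 50 Hz: 0.1 s, 0.18 s, 0.08 s, 0.64 s


class TestTraining:
    def test_emission_means_recovered(self, rng):
        track, labels = _labelled_gaussian_track(rng, STATE_MEANS, DUR_60BPM, 30)
        model = train_hsmm([track], [labels])
        # non-zero generating means recovered within 5%
        nz = STATE_MEANS != 0
        assert np.allclose(model.means[nz], STATE_MEANS[nz], rtol=0.05)

    def test_training_is_deterministic_under_duplication(self, rng):
        track, labels = _labelled_gaussian_track(rng, STATE_MEANS, DUR_60BPM, 20)
        m1 = train_hsmm([track], [labels])
        m2 = train_hsmm([track, track], [labels, labels])
        assert np.allclose(m1.means, m2.means)
        assert np.allclose(m1.dur_mean, m2.dur_mean)

    def test_missing_state_rejected(self, rng):
        track, labels = _labelled_gaussian_track(rng, STATE_MEANS, DUR_60BPM, 10)
        no_dia = labels.states.copy()
        no_dia[no_dia == 3] = 1  # relabel diastole as systole
        with pytest.raises(InvalidTrainingDataError):
            train_hsmm([track], [StateSequence(states=no_dia,
                                               feature_fs=FEATURE_FS)])

    def test_duration_model_scales_with_heart_rate(self, rng):
        track, labels = _labelled_gaussian_track(rng, STATE_MEANS, DUR_60BPM, 20)
        model = train_hsmm([track], [labels])
        dia60 = model.duration_frames(3, 60.0)[0]
        dia120 = model.duration_frames(3, 120.0)[0]
        assert dia60 == pytest.approx(2 * dia120, rel=1e-6)
        s1_60 = model.duration_frames(0, 60.0)[0]
        s1_120 = model.duration_frames(0, 120.0)[0]
        assert s1_60 == pytest.approx(s1_120, rel=1e-6)


def _brute_force_best(model, track, hr):
    """Exhaustive enumeration over all legal cyclic segmentations."""
    T = track.n_frames
    logpmf = [model.duration_logpmf(s, hr) for s in range(4)]
    em = model.emission_loglik(track.features)
    cum = np.vstack([np.r_[0.0, np.cumsum(em[:, s])] for s in range(4)])
    nxt = [1, 2, 3, 0]
    best = [-np.inf, None]

    def recurse(t, s, score, path):
        for d in range(1, len(logpmf[s])):
            if t + d > T:
                break
            seg = score + logpmf[s][d] + (cum[s, t + d] - cum[s, t])
            if not np.isfinite(seg):
                continue
            if t + d == T:
                if seg > best[0]:
                    best[0] = seg
                    best[1] = path + [(s, d)]
            else:
                recurse(t + d, nxt[s], seg, path + [(s, d)])

    for s0 in range(4):
        recurse(0, s0, -np.log(4), [])
    states = np.concatenate([[s] * d for s, d in best[1]])
    return best[0], states


class TestViterbi:
    def test_matches_exhaustive_enumeration_on_toy_instances(self, rng):
        toy_means = STATE_MEANS
        for trial in range(2):
            track, labels = _labelled_gaussian_track(
                rng, toy_means, [4, 5, 3, 13], n_cycles=1, noise=0.6)
            model = train_hsmm(*zip(*[_labelled_gaussian_track(
                rng, toy_means, [4, 5, 3, 13], 10, noise=0.6)]))
            hr = 60.0 / (25 / FEATURE_FS)  # cycle of 25 frames -> 120 bpm
            seq = viterbi_segment(model, track, hr_bpm=hr)
            bf_score, bf_states = _brute_force_best(model, track, hr)
            vit_score = path_score(model, track, seq.states, hr)
            assert vit_score == pytest.approx(bf_score, abs=1e-9)
            assert np.array_equal(seq.states, bf_states)

    def test_decoded_score_dominates_ground_truth_path(self, rng):
        track, labels = _labelled_gaussian_track(rng, STATE_MEANS,
                                                 [4, 5, 3, 13], 2, noise=0.8)
        model = train_hsmm(*zip(*[_labelled_gaussian_track(
            rng, STATE_MEANS, [4, 5, 3, 13], 10, noise=0.8)]))
        hr = 60.0 / (25 / FEATURE_FS)
        seq = viterbi_segment(model, track, hr_bpm=hr)
        assert (path_score(model, track, seq.states, hr)
                >= path_score(model, track, labels.states, hr) - 1e-9)

    def test_output_is_always_cyclic(self, hsmm_subjects, trained_hsmm):
        track, _, _, _ = hsmm_subjects[5]
        seq = viterbi_segment(trained_hsmm, track)
        assert seq.is_cyclic()
        assert np.all(np.bincount(seq.states, minlength=4) > 0)

    def test_heart_rate_out_of_range_rejected(self, hsmm_subjects,
                                              trained_hsmm):
        track = hsmm_subjects[5][0]
        with pytest.raises(HeartRateOutOfRangeError):
            viterbi_segment(trained_hsmm, track, hr_bpm=150.0)

    def test_cycle_period_consistent_with_heart_rate(self, hsmm_subjects,
                                                     trained_hsmm):
        track, _, truth, _ = hsmm_subjects[5]
        seq = viterbi_segment(trained_hsmm, track)
        beats = states_to_beats(seq)
        period = np.mean(np.diff(beats.times))
        true_period = np.mean(truth.rr_intervals)
        assert abs(period / true_period - 1.0) < 0.2


class TestSegmentationQuality:
    def test_held_out_subject_frame_accuracy(self, hsmm_subjects,
                                             trained_hsmm):
        track, labels, _, _ = hsmm_subjects[5]
        seq = viterbi_segment(trained_hsmm, track)
        assert np.mean(seq.states == labels.states) >= 0.95

    def test_held_out_subject_beat_f1(self, hsmm_subjects, trained_hsmm):
        track, _, truth, _ = hsmm_subjects[5]
        seq = viterbi_segment(trained_hsmm, track)
        m = match_beats(truth.beats, states_to_beats(seq))
        assert scores(m)["f1"] >= 0.95

    def test_accuracy_degrades_gracefully_with_noise(self, hsmm_subjects,
                                                     trained_hsmm, rng):
        track, labels, _, _ = hsmm_subjects[5]
        accs = []
        for sigma in (0.0, 1.0, 4.0):
            noisy = FeatureTrack(
                features=track.features + sigma * rng.normal(
                    size=track.features.shape),
                feature_fs=track.feature_fs, hr_bpm=track.hr_bpm,
                norm_mean=track.norm_mean, norm_std=track.norm_std)
            seq = viterbi_segment(trained_hsmm, noisy)
            accs.append(np.mean(seq.states == labels.states))
        assert accs[0] >= accs[-1]  # monotone on average; no crash at any SNR


def test_model_json_roundtrip(tmp_path, rng):
    track, labels = _labelled_gaussian_track(rng, STATE_MEANS, DUR_60BPM, 10)
    model = train_hsmm([track], [labels])
    path = tmp_path / "model.json"
    model.save(path)
    loaded = HsmmModel.load(path)
    assert np.allclose(loaded.means, model.means)
    assert np.allclose(loaded.covs, model.covs)
    assert loaded.feature_fs == model.feature_fs
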