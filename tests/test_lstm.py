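"""Bidirectional LSTM segmenter: training, determinism, cycle repair."""
import numpy as np
import pytest

from radarhrv import LstmConfig, predict_states, train_lstm
from radarhrv.errors import InvalidInputError
from radarhrv.lstm import losocv_evaluate, repair_cycle
from radarhrv.types import FeatureTrack, StateSequence

FEATURE_FS = 50.0

TINY = dict(hidden_units=(16, 8), epochs=3, window_s=2.0, seed=0)


def _toy_subject(rng, n_cycles=40, noise=0.3):
    means = np.array([[3.0, 3.0, 2.0, 0.0], [0.5, 0.5, 0.3, 0.0],
                      [2.0, 2.0, 1.5, 0.0], [-0.5, -0.5, -0.3, 0.0]])
    durs = [5, 9, 4, 32]
    states, feats = [], []
    for _ in range(n_cycles):
        for s in range(4):
            for _ in range(durs[s]):
                states.append(s)
                feats.append(means[s] + noise * rng.normal(size=4))
    track = FeatureTrack(features=np.array(feats), feature_fs=FEATURE_FS,
                         hr_bpm=np.full(len(states), 60.0),
                         norm_mean=np.zeros(4), norm_std=np.ones(4))
    return track, StateSequence(states=np.array(states), feature_fs=FEATURE_FS)


class TestConfig:
    def test_learning_rate_schedule_matches_stated_steps(self):
        cfg = LstmConfig()  # full-scale config: 0.001, x0.1 every 20 epochs
        assert cfg.lr_at_epoch(1) == pytest.approx(1e-3)
        assert cfg.lr_at_epoch(20) == pytest.approx(1e-3)
        assert cfg.lr_at_epoch(21) == pytest.approx(1e-4)
        assert cfg.lr_at_epoch(41) == pytest.approx(1e-5)

    def test_full_scale_architecture_defaults(self):
        cfg = LstmConfig()
        assert cfg.hidden_units == (400, 200)
        assert cfg.dropout == 0.2
        assert cfg.epochs == 50
        assert cfg.batch_size == 64

    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidInputError):
            LstmConfig(dropout=1.0)
        with pytest.raises(InvalidInputError):
            LstmConfig(hidden_units=(0, 10))


class TestTraining:
    def test_same_seed_gives_bit_identical_histories(self, rng):
        track, labels = _toy_subject(rng)
        n1 = train_lstm([track], [labels], LstmConfig(**TINY))
        n2 = train_lstm([track], [labels], LstmConfig(**TINY))
        assert n1.history == n2.history
        assert all(np.array_equal(a["fwd"]["W"], b["fwd"]["W"])
                   for a, b in zip(n1.layers, n2.layers))

    def test_loss_decreases_without_dropout(self, rng):
        track, labels = _toy_subject(rng)
        cfg = LstmConfig(hidden_units=(16, 8), epochs=5, window_s=2.0,
                         dropout=0.0, seed=1)
        net = train_lstm([track], [labels], cfg)
        assert net.history[-1] < net.history[0]
        assert all(b <= a * 1.05 for a, b in zip(net.history, net.history[1:]))

    def test_label_length_mismatch_rejected(self, rng):
        track, labels = _toy_subject(rng)
        bad = StateSequence(states=labels.states[:-10], feature_fs=FEATURE_FS)
        with pytest.raises(InvalidInputError):
            train_lstm([track], [bad], LstmConfig(**TINY))

    def test_toy_subject_learnable(self, rng):
        # one short subject yields few windows; a smaller batch keeps the
        # number of gradient updates adequate
        track, labels = _toy_subject(rng)
        cfg = LstmConfig(hidden_units=(32, 16), epochs=30, window_s=2.0,
                         batch_size=8, seed=2)
        net = train_lstm([track], [labels], cfg)
        _, seq = predict_states(net, track)
        assert np.mean(seq.states == labels.states) > 0.9


class TestPrediction:
    def test_probability_rows_sum_to_one(self, rng):
        track, labels = _toy_subject(rng, n_cycles=10)
        net = train_lstm([track], [labels], LstmConfig(**TINY))
        probs, seq = predict_states(net, track)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert seq.is_cyclic()

    def test_feature_dimension_mismatch_rejected(self, rng):
        track, labels = _toy_subject(rng, n_cycles=10)
        net = train_lstm([track], [labels], LstmConfig(**TINY))
        bad = FeatureTrack(features=track.features[:, :3],
                           feature_fs=FEATURE_FS,
                           hr_bpm=track.hr_bpm, norm_mean=np.zeros(3),
                           norm_std=np.ones(3))
        with pytest.raises(InvalidInputError):
            predict_states(net, bad)


class TestCycleRepair:
    def test_isolated_flip_removed(self):
        # a clean cyclic path with one diastole frame flipped to S2
        states = np.concatenate([np.full(5, 0), np.full(9, 1), np.full(4, 2),
                                 np.full(32, 3), np.full(5, 0), np.full(9, 1),
                                 np.full(4, 2), np.full(32, 3)])
        flipped = states.copy()
        flipped[60] = 2
        logp = np.full((len(states), 4), np.log(0.05))
        logp[np.arange(len(states)), flipped] = np.log(0.85)
        repaired = repair_cycle(logp, FEATURE_FS)
        assert np.array_equal(repaired, states)
        seq = StateSequence(states=repaired, feature_fs=FEATURE_FS)
        assert seq.is_cyclic()

    def test_repair_preserves_clean_path(self):
        states = np.concatenate([np.full(5, 0), np.full(9, 1), np.full(4, 2),
                                 np.full(30, 3)] * 3)
        logp = np.full((len(states), 4), np.log(0.02))
        logp[np.arange(len(states)), states] = np.log(0.94)
        assert np.array_equal(repair_cycle(logp, FEATURE_FS), states)


class TestLosocv:
    def test_fold_structure_and_score_ranges(self, rng):
        subjects = []
        from radarhrv.beats import states_to_beats

        for _ in range(5):
            track, labels = _toy_subject(rng, n_cycles=20)
            subjects.append((track, labels, states_to_beats(labels)))
        table, mean = losocv_evaluate(subjects, LstmConfig(
            hidden_units=(16, 8), epochs=4, window_s=2.0, seed=3))
        assert len(table) == 5
        assert sorted(table.index) == [0, 1, 2, 3, 4]
        assert ((table["f1"] >= 0) & (table["f1"] <= 1)).all()
        assert mean["f1"] == pytest.approx(table["f1"].mean())

    def test_too_few_subjects_rejected(self, rng):
        track, labels = _toy_subject(rng, n_cycles=5)
        from radarhrv.beats import states_to_beats

        subj = (track, labels, states_to_beats(labels))
        with pytest.raises(InvalidInputError):
            losocv_evaluate([subj, subj], LstmConfig(**TINY))


def test_checkpoint_roundtrip(tmp_path, rng):
    track, labels = _toy_subject(rng, n_cycles=10)
    net = train_lstm([track], [labels], LstmConfig(**TINY))
    path = tmp_path / "ckpt.npz"
    net.save(path)
    from radarhrv.lstm import TrainedSegmenter

    loaded = TrainedSegmenter.load(path)
    p1, _ = predict_states(net, track)
    p2, _ = predict_states(loaded, track)
    assert np.allclose(p1, p2)
    assert loaded.config.hidden_units == net.config.hidden_units
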