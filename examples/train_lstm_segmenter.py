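"""Train the bidirectional LSTM segmenter (reduced desk-tier configuration).

Trains on three simulated subjects and evaluates beat detection on a
fourth. The full-scale configuration (400/200 hidden units, 50 epochs)
is `LstmConfig()`; the desk tier keeps this example to ~10 s of CPU.
"""
import numpy as np

from radarhrv import (
    LstmConfig,
    SimulationConfig,
    demodulate,
    extract_features,
    match_beats,
    predict_states,
    scores,
    simulate_record,
    train_lstm,
)
from radarhrv.beats import states_to_beats
from radarhrv.pipeline import truth_feature_labels


def make_subject(seed, mean_rr):
    cfg = SimulationConfig(duration=120.0, mean_rr=mean_rr, seed=seed)
    record, truth = simulate_record(cfg)
    track, _ = extract_features(demodulate(record, cfg.wavelength))
    labels = truth_feature_labels(truth, track.feature_fs, track.n_frames)
    return track, labels, truth


subjects = [make_subject(40 + i, 0.75 + 0.07 * i) for i in range(4)]

config = LstmConfig.desk(seed=0)
net = train_lstm([s[0] for s in subjects[:3]], [s[1] for s in subjects[:3]],
                 config)
print(f"trained {config.hidden_units} BiLSTM for {config.epochs} epochs; "
      f"loss {net.history[0]:.3f} -> {net.history[-1]:.3f}")

track, labels, truth = subjects[3]
probs, seq = predict_states(net, track)
m = match_beats(truth.beats, states_to_beats(seq), tolerance=0.075)
print(f"held-out frame accuracy: {np.mean(seq.states == labels.states):.3f}")
print(f"held-out beat F1:        {scores(m)['f1']:.3f} "
      f"(TP/FP/FN {m.tp}/{m.fp}/{m.fn})")
print("Per-frame softmax posteriors are projected onto the nearest legal "
      "cyclic state path before S1 onsets are read off as beats.")
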