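"""Compute HRV indices from beat times.

Builds a 5-minute tachogram with respiratory (0.25 Hz) and low-frequency
(0.1 Hz) modulation, corrupts it with a missed and a spurious beat,
repairs it with the artefact filter, and reports the indices.
"""
import numpy as np

from radarhrv import (
    BeatList,
    SimulationConfig,
    beats_to_rr,
    hrv_indices,
    remove_artefacts,
    simulate_tachogram,
)

cfg = SimulationConfig(duration=300.0, mean_rr=0.9, seed=5)
beats, _ = simulate_tachogram(cfg)

# corrupt: drop beat 100 (missed), add a spurious beat near t of beat 200
times = np.delete(beats.times, 100)
times = np.sort(np.r_[times, beats.times[200] + 0.31])
rr = remove_artefacts(beats_to_rr(BeatList(times)))
print(f"{len(rr)} intervals after artefact repair "
      f"({np.sum(~rr.valid)} flagged invalid, low quality: {rr.low_quality})")

idx = hrv_indices(rr, window=90.0)
print(f"heart rate : {idx.heart_rate:6.2f} bpm")
print(f"LF power   : {idx.lf_power:6.2f}   HF power: {idx.hf_power:6.2f} "
      "(standardised-signal units)")
print(f"LF norm    : {idx.lf_norm:6.2f}   HF norm : {idx.hf_norm:6.2f} n.u.")
print(f"LF/HF ratio: {idx.lf_hf_ratio:6.3f}")
print(f"TRI        : {idx.tri:6.3f}")
print("HF norm is the share of respiratory-band power in the combined "
      "LF+HF power; TRI is the interval count over the modal histogram "
      "bin count (1/128 s bins).")
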