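"""Recover chest displacement from four-channel Six-Port baseband signals.

Simulates a 30 s radar recording of a breathing subject with heartbeats,
demodulates it back to displacement, and reports the reconstruction error.
"""
import numpy as np

from radarhrv import (
    SimulationConfig,
    demodulate,
    detect_clipping,
    simulate_displacement,
    simulate_record,
    simulate_tachogram,
)

cfg = SimulationConfig(duration=30.0, noise_sd=0.0, seed=1)
record, truth = simulate_record(cfg)

clip = detect_clipping(record)
print(f"clipping flagged: {clip.flagged} "
      f"(worst rail fraction {clip.worst_fraction:.4f})")

disp = demodulate(record, cfg.wavelength)

# reference displacement from the same generating process
beats, _ = simulate_tachogram(cfg)
x_true, _ = simulate_displacement(beats, cfg)
rmse = np.sqrt(np.mean((disp.x - (x_true.x - x_true.x[0])) ** 2))

print(f"samples: {len(disp.x)} at {disp.fs:g} Hz")
print(f"displacement span: {1e3 * (disp.x.max() - disp.x.min()):.2f} mm "
      "(respiration dominates; heart sounds are tens of microns)")
print(f"round-trip RMSE: {rmse * 1e9:.3f} nm")
print("The arctangent demodulation is exact for a noiseless, unclipped "
      "record: the error is numerical precision only.")
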