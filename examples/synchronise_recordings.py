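"""Align two recordings sampled by unsynchronised clocks.

Generates one Gold-code watermark sampled by two devices whose clocks
differ by 1.3% and whose recordings start 0.85 s apart, then recovers both
parameters from the sequences alone.
"""
from radarhrv import generate_sync_pair
from radarhrv.sync import solve_sync

FS = 2000.0
TRUE_FACTOR = 1.013
TRUE_LAG_S = 0.85

seq_a, seq_b = generate_sync_pair(FS, 60.0, TRUE_FACTOR, TRUE_LAG_S, seed=3)
solution = solve_sync(seq_a, seq_b)

print(f"true clock ratio:      {TRUE_FACTOR:.6f}")
print(f"estimated ratio:       {solution.resampling_factor:.6f} "
      f"(relative error "
      f"{abs(solution.resampling_factor / TRUE_FACTOR - 1):.2e})")
print(f"true latency:          {TRUE_LAG_S * FS:.1f} samples at {FS:g} Hz")
print(f"estimated latency:     {solution.latency_samples} samples")
print(f"peak correlation:      {solution.peak_correlation:.3f}")
print("A relative clock error below 1e-4 and a latency within one sample "
      "keep beat timings aligned to well under the 75 ms scoring tolerance "
      "over a full recording.")
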