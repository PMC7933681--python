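"""Dynamic vs static fixed point on a random weight matrix.

Shows the per-tensor fractional-length choice, the fault-tolerant zeroing
of near-zero entries, and the saturating static baseline.  The dynamic
format spends all its bits on the fraction when the weights are small,
which is why 16 dynamic bits can match a 22-bit static format.
"""

import numpy as np

from dendep import dynamic_quantize, fx_quantize_matrix

rng = np.random.default_rng(0)
W = rng.normal(0.0, 0.1, (6, 6))
W[0, 0] = 1e-4  # a weight close to zero

q16 = dynamic_quantize(W, total_bits=16, r_max=0.2)
print(f"dynamic 16-bit: FL={q16.fmt.frac_length} "
      f"(LSB 2^-{q16.fmt.frac_length} = {q16.fmt.lsb:.2e}), "
      f"zeroed entries: {int(q16.zero_mask.sum())}")
print(f"  max |error| = {np.max(np.abs(q16.decode() - W)):.2e}")

q8 = dynamic_quantize(W, total_bits=8, r_max=0.2)
print(f"dynamic  8-bit: FL={q8.fmt.frac_length}, "
      f"zeroed entries: {int(q8.zero_mask.sum())} "
      f"(coarse LSB pushes more weights past the 20% error bound)")

s = fx_quantize_matrix(W * 10_000, integer_bits=8, fractional_bits=4)
sat = (2 ** (8 + 4) - 1) / 2.0**4
n_sat = int(np.sum(np.abs(s.decode()) == sat))
print(f"static 8.4 on x10000-scaled weights: {n_sat} entries saturate at "
      f"+/-{sat} (largest representable magnitude)")
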