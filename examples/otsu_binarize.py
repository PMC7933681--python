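"""Binarize filtered spike traces with Otsu's threshold.

Synaptic traces from a half-silent input population are bimodal; the
between-class-variance maximum lands between the modes, so the 1-bit
version of the trace preserves exactly the active/silent distinction the
weight update needs.
"""

import numpy as np

from dendep import GrayHistogram, binarize_trace, otsu_statistics

rng = np.random.default_rng(1)
# traces of 300 silent synapses near 0.02 and 150 active ones near 0.15
traces = np.concatenate([rng.normal(0.02, 0.005, 300),
                         rng.normal(0.15, 0.01, 150)])

binary, degenerate = binarize_trace(traces, bins=64)
print(f"degenerate: {degenerate}")
print(f"fraction mapped to 1: {binary.mean():.3f}  (true active fraction "
      f"{150 / 450:.3f})")

counts, _ = np.histogram(traces, bins=64)
stats = otsu_statistics(GrayHistogram(counts / counts.sum()))
t_best = int(stats["t"][np.argmax(stats["lambda_b2"])])
print(f"between-class variance peaks at level {t_best} of 64; "
      f"lambda_b2 + lambda_w2 = total variance "
      f"({stats['lambda_b2'][t_best-1] + stats['lambda_w2'][t_best-1]:.4f} "
      f"= {stats['total_var']:.4f})")
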