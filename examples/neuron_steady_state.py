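"""Three-compartment neuron: simulated vs closed-form steady states.

Holds the dendritic potentials constant and integrates the soma; the
Euler trajectory settles onto the conductance-weighted average of the
dendritic drives, which is the fixed point the learning rule's k_b
coupling factor comes from.
"""

import numpy as np

from dendep import (
    NetworkConfig,
    coupling_factor_kb,
    hidden_fixed_point,
    step_hidden_soma,
)

cfg = NetworkConfig(n_input=1, hidden_sizes=(1,), n_output=1)
v0b, v0a = np.array([1.0]), np.array([-0.5])

v = np.zeros(1)
for _ in range(int(50 * cfg.tau / cfg.dt)):
    v = step_hidden_soma(v, v0b, v0a, cfg)

expected = hidden_fixed_point(v0b, v0a, cfg)
print(f"simulated steady state : {v[0]:.8f}")
print(f"closed form            : {expected[0]:.8f}   "
      f"(= (g_b*V0b + g_a*V0a) / (g_l+g_b+g_a))")
kb = coupling_factor_kb(cfg.g_l, cfg.g_b, cfg.g_a)
print(f"basal coupling k_b     : {kb:.4f}   "
      f"(fraction of basal drive reaching the soma)")
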