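"""Shift-and-add sigmoid: evaluate the shipped tables and fit a new one.

Prints the shipped coefficient table, its worst-case deviation from the
exact sigmoid, and the slope an exhaustive power-of-two fit picks for the
central segment — the quarter slope means hardware computes sigma(x) near
zero as (x >> 2) + 0.5.
"""

import numpy as np

from dendep import cf_re, fit_pwl, pwl_eval, sigmoid, sigmoid_pwl_spec

spec = sigmoid_pwl_spec()
print("shipped PWL sigmoid table:")
print(spec.to_table())

xs = np.arange(-6, 6 + 1e-9, 0.01)
err = np.abs(pwl_eval(spec, xs) - sigmoid(xs))
print(f"sigma_PWL(0)      = {pwl_eval(spec, 0.0)}   (exact sigma(0) = 0.5)")
print(f"max |PWL - exact| = {err.max():.4f} on [-6, 6]")
print(f"CF_RE             = {cf_re(sigmoid(xs), pwl_eval(spec, xs)):.5f}")

fitted = fit_pwl(sigmoid, (-1.3, 1.3), cf_threshold=1.0,
                 slope_candidates=[2.0**k for k in range(-7, 1)],
                 breakpoint_grid=[], initial_segments=1, max_segments=1,
                 fixed_intercept=0.5)
print(f"\nexhaustive fit on (-1.3, 1.3], intercept 0.5 -> slope "
      f"{fitted.segments[0].slope}  (a power of two: x * 0.25 is x >> 2)")
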