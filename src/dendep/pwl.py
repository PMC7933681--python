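"""Piecewise-linear (PWL) approximation with power-of-two slopes.

On digital neuromorphic hardware a multiplication by a power of two reduces
to a bit shift, so a nonlinearity approximated by linear segments whose
slopes are all ``±2^k`` (or zero) can be evaluated with shifts and adds
only.  This module provides

* :class:`PWLSegment` / :class:`PWLSpec` — a validated, ordered list of
  segments covering the whole real line, with output clamps;
* :func:`pwl_eval` — evaluation (vectorised);
* :func:`cf_re` — the mean squared *relative* error criterion used to
  accept a fit;
* :func:`fit_pwl` — exhaustive search over candidate breakpoints and
  power-of-two slopes;
* :func:`sigmoid_pwl_spec` / :func:`dsigmoid_pwl_spec` — the shipped
  shift-and-add coefficient tables for the logistic sigmoid
  ``σ(x) = 1/(1+e^(−x))`` and its derivative.

Segment membership uses half-open intervals ``(s_{i−1}, s_i]``; the last
segment is unbounded above.  Segments are independent affine pieces — the
shipped tables are *not* continuous at the breakpoints (the jumps are a few
thousandths and are part of the coefficient design).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PWLSegment",
    "PWLSpec",
    "PWLFitError",
    "pwl_eval",
    "cf_re",
    "fit_pwl",
    "sigmoid_pwl_spec",
    "dsigmoid_pwl_spec",
    "sigmoid",
    "dsigmoid",
]


def sigmoid(x):
    """Logistic sigmoid ``1/(1+e^(−x))``.

    Computed as ``(1 + tanh(x/2))/2``, which is the same function and
    stable for large |x|.
    """
    x = np.asarray(x, dtype=float)
    out = 0.5 * (1.0 + np.tanh(0.5 * x))
    if out.ndim == 0:
        return float(out)
    return out


def dsigmoid(x):
    """Derivative of the logistic sigmoid, ``σ(x)(1−σ(x))``."""
    s = sigmoid(x)
    return s * (1.0 - s)


def _is_power_of_two_or_zero(a: float) -> bool:
    if a == 0.0:
        return True
    m, e = math.frexp(abs(a))
    return m == 0.5


@dataclass(frozen=True)
class PWLSegment:
    """One affine piece ``a·x + b`` valid on ``(previous break, upper_break]``.

    ``slope`` must be zero or ``±2^k`` for integer ``k`` so that hardware can
    realise the product as a shift.  The last segment of a spec has
    ``upper_break = +inf``.
    """

    slope: float
    intercept: float
    upper_break: float = math.inf

    def __post_init__(self):
        if not _is_power_of_two_or_zero(self.slope):
            raise ValueError(
                f"segment slope {self.slope!r} is not 0 or ±2^k"
            )


@dataclass(frozen=True)
class PWLSpec:
    """An ordered piecewise-linear function with output clamps.

    Evaluation picks the unique segment whose half-open interval contains
    ``x``, computes ``a·x + b`` and clamps the result to
    ``[clamp_low, clamp_high]``.
    """

    segments: tuple[PWLSegment, ...]
    clamp_low: float = -math.inf
    clamp_high: float = math.inf

    def __post_init__(self):
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("spec needs at least one segment")
        breaks = [s.upper_break for s in segs]
        if breaks[-1] != math.inf:
            raise ValueError("last segment must be unbounded (upper_break=inf)")
        for lo, hi in zip(breaks, breaks[1:]):
            if not lo < hi:
                raise ValueError(f"breakpoints not strictly increasing: {breaks}")
        if not self.clamp_low < self.clamp_high:
            raise ValueError("clamp_low must be < clamp_high")

    @property
    def breakpoints(self) -> np.ndarray:
        """Interior breakpoints ``s_1 < … < s_{n−1}`` (no trailing inf)."""
        return np.array([s.upper_break for s in self.segments[:-1]])

    def __call__(self, x):
        return pwl_eval(self, x)

    # -- plain-text (de)serialisation -------------------------------------
    def to_table(self) -> str:
        """Render as a plain-text coefficient table (i, a, b, condition)."""
        lines = ["i\ta\tb\tcondition"]
        prev = -math.inf
        for i, s in enumerate(self.segments, start=1):
            if prev == -math.inf:
                cond = f"x <= {s.upper_break:g}"
            elif s.upper_break == math.inf:
                cond = f"x > {prev:g}"
            else:
                cond = f"{prev:g} < x <= {s.upper_break:g}"
            lines.append(f"{i}\t{s.slope!r}\t{s.intercept!r}\t{cond}")
            prev = s.upper_break
        lines.append(f"clamp\t{self.clamp_low!r}\t{self.clamp_high!r}\toutput")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str) -> "PWLSpec":
        segs = []
        clamp_low, clamp_high = -math.inf, math.inf
        for line in text.strip().splitlines():
            parts = line.split("\t")
            if parts[0] == "i":
                continue
            if parts[0] == "clamp":
                clamp_low, clamp_high = float(parts[1]), float(parts[2])
                continue
            a, b, cond = float(parts[1]), float(parts[2]), parts[3]
            upper = math.inf
            if "<=" in cond:
                upper = float(cond.rsplit("<=", 1)[1])
            segs.append(PWLSegment(a, b, upper))
        return cls(tuple(segs), clamp_low, clamp_high)


def pwl_eval(spec: PWLSpec, x):
    """Evaluate ``spec`` at ``x`` (scalar or array).

    The segment for ``x`` is the one with the smallest ``upper_break ≥ x``
    (half-open membership ``s_{i−1} < x ≤ s_i``); the affine value is then
    clamped to ``[clamp_low, clamp_high]``.
    """
    x_arr = np.asarray(x, dtype=float)
    breaks = spec.breakpoints
    # side='left' puts x == s_i into segment i (interval (s_{i-1}, s_i])
    idx = np.searchsorted(breaks, x_arr, side="left")
    slopes = np.array([s.slope for s in spec.segments])
    intercepts = np.array([s.intercept for s in spec.segments])
    y = slopes[idx] * x_arr + intercepts[idx]
    y = np.clip(y, spec.clamp_low, spec.clamp_high)
    if y.ndim == 0:
        return float(y)
    return y


def cf_re(f_ori_samples, f_pwl_samples) -> float:
    """Mean squared relative error between original and PWL samples.

    ``CF_RE = (1/n) Σ (f_ori − f_pwl)² / f_ori²``.  Undefined when any
    original sample is zero.
    """
    f_ori = np.asarray(f_ori_samples, dtype=float)
    f_pwl = np.asarray(f_pwl_samples, dtype=float)
    if f_ori.shape != f_pwl.shape or f_ori.size == 0:
        raise ValueError("sample lists must be non-empty and equal length")
    if np.any(f_ori == 0.0):
        raise ValueError("relative error undefined for zero-valued original sample")
    return float(np.mean(((f_ori - f_pwl) / f_ori) ** 2))


class PWLFitError(RuntimeError):
    """Raised when no candidate spec meets the error threshold.

    Carries ``best_spec`` and ``best_cf`` so callers can inspect the
    closest miss.
    """

    def __init__(self, msg, best_spec: PWLSpec, best_cf: float):
        super().__init__(msg)
        self.best_spec = best_spec
        self.best_cf = best_cf


def _power_of_two_slopes(min_exp: int = -7, max_exp: int = 0,
                         signed: bool = True, with_zero: bool = False):
    pos = [2.0 ** k for k in range(min_exp, max_exp + 1)]
    out = list(pos)
    if signed:
        out += [-a for a in pos]
    if with_zero:
        out.append(0.0)
    return sorted(out)


def fit_pwl(
    f_ori: Callable[[np.ndarray], np.ndarray],
    domain: tuple[float, float],
    cf_threshold: float,
    slope_candidates: Sequence[float] | None = None,
    breakpoint_grid: Sequence[float] | None = None,
    initial_segments: int = 1,
    max_segments: int = 8,
    fixed_intercept: float | None = None,
    sample_step: float = 0.01,
) -> PWLSpec:
    """Fit a PWL spec to ``f_ori`` by exhaustive search.

    For each segment count ``k`` (starting at ``initial_segments``) every
    increasing choice of ``k−1`` interior breakpoints from
    ``breakpoint_grid`` is tried; on each segment every candidate slope is
    tried, the intercept chosen by relative-error-weighted least squares on
    that segment's samples (or pinned to ``fixed_intercept``).  Because the
    criterion :func:`cf_re` is a sum over sample points, the best slope and
    intercept per segment are independent given the breakpoints, so the
    search is exhaustive yet tractable.  If the best spec at ``k`` segments
    misses ``cf_threshold`` the segment count is incremented, up to
    ``max_segments``; exhausting the cap raises :class:`PWLFitError` with
    the best spec found.

    Ties are broken by fewer segments, then by smaller sum of |slope|
    (deterministic result).
    """
    if cf_threshold <= 0:
        raise ValueError("cf_threshold must be > 0")
    lo, hi = domain
    xs = np.arange(lo + sample_step, hi + sample_step / 2, sample_step)
    fs = np.asarray(f_ori(xs), dtype=float)
    if np.any(fs == 0.0):
        raise ValueError("f_ori must be nonzero on the sample grid")
    w = 1.0 / fs**2  # relative-error weights

    if slope_candidates is None:
        slope_candidates = _power_of_two_slopes()
    slope_candidates = sorted(set(slope_candidates))
    if breakpoint_grid is None:
        breakpoint_grid = np.round(np.arange(lo + 0.5, hi, 0.5), 6).tolist()
    breakpoint_grid = [b for b in breakpoint_grid if lo < b < hi]

    n = xs.size
    best = None  # (cf, n_segments, abs_slope_sum, spec)

    def segment_best(mask: np.ndarray):
        """Best (slope, intercept, sse) on the masked samples."""
        xseg, fseg, wseg = xs[mask], fs[mask], w[mask]
        best_local = None
        for a in slope_candidates:
            if fixed_intercept is not None:
                b = fixed_intercept
            else:
                # weighted least squares for b given a
                b = float(np.sum(wseg * (fseg - a * xseg)) / np.sum(wseg))
            sse = float(np.sum(wseg * (a * xseg + b - fseg) ** 2))
            key = (sse, abs(a))
            if best_local is None or key < best_local[0]:
                best_local = (key, a, b)
        return best_local[1], best_local[2], best_local[0][0]

    for k in range(initial_segments, max_segments + 1):
        for interior in itertools.combinations(breakpoint_grid, k - 1):
            bounds = (-math.inf,) + interior + (math.inf,)
            segs = []
            total_sse = 0.0
            ok = True
            for lo_b, hi_b in zip(bounds, bounds[1:]):
                mask = (xs > lo_b) & (xs <= hi_b)
                if not np.any(mask):
                    ok = False
                    break
                a, b, sse = segment_best(mask)
                segs.append(PWLSegment(a, b, hi_b))
                total_sse += sse
            if not ok:
                continue
            cf = total_sse / n
            cand = (cf, k, sum(abs(s.slope) for s in segs),
                    PWLSpec(tuple(segs)))
            if best is None or cand[:3] < best[:3]:
                best = cand
        if best is not None and best[0] <= cf_threshold:
            return best[3]
    raise PWLFitError(
        f"no spec met cf_re <= {cf_threshold} within {max_segments} segments "
        f"(best {best[0]:.3g})",
        best_spec=best[3],
        best_cf=best[0],
    )


# -- shipped shift-and-add coefficient tables ------------------------------

def sigmoid_pwl_spec() -> PWLSpec:
    """Shift-and-add approximation of the logistic sigmoid.

    Five affine segments with power-of-two slopes plus output clamps that
    keep every value inside ``[0.0001, 0.9999]`` (so the approximation never
    saturates to exactly 0 or 1, which would kill the derivative signal in
    downstream learning).  Maximum absolute error against ``σ`` on
    ``[−6, 6]`` is below 0.05.
    """
    return PWLSpec(
        segments=(
            PWLSegment(0.0078125, 0.05, -3.4),
            PWLSegment(0.0625, 0.24, -1.3),
            PWLSegment(0.25, 0.5, 1.3),
            PWLSegment(0.0625, 0.76, 3.4),
            PWLSegment(0.0078125, 0.95, math.inf),
        ),
        clamp_low=0.0001,
        clamp_high=0.9999,
    )


def dsigmoid_pwl_spec() -> PWLSpec:
    """Shift-and-add approximation of the sigmoid derivative ``σ′``.

    Six affine segments, mirror-symmetric about 0 (odd-symmetric slopes),
    with a floor clamp of 0.0001 so the approximated derivative never
    vanishes; the ceiling 0.25 is σ′'s true maximum and is attained only at
    x = 0.  Maximum absolute error against ``σ′`` on ``[−6, 6]`` is below
    0.03.
    """
    return PWLSpec(
        segments=(
            PWLSegment(0.0078125, 0.05, -3.2),
            PWLSegment(0.03125, 0.15, -2.0),
            PWLSegment(0.0625, 0.25, 0.0),
            PWLSegment(-0.0625, 0.25, 2.0),
            PWLSegment(-0.03125, 0.15, 3.2),
            PWLSegment(-0.0078125, 0.05, math.inf),
        ),
        clamp_low=0.0001,
        clamp_high=0.25,
    )
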