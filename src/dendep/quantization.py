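"""Dynamic fixed-point weight representation and Otsu trace binarization.

Two hardware-efficiency layers live here:

* **Dynamic fixed point** — every number is stored as a signed ``B``-bit
  mantissa scaled by ``2^(−FL)``; the fractional length ``FL`` is chosen
  per tensor from its value range, so no integer/fractional split has to
  be fixed in advance.  A *fault-tolerant ratio* ``R_max`` zeroes entries
  whose best representable relative error exceeds the bound — these are
  exactly the values close to 0, whose relative error after rounding is
  large but whose contribution is negligible.
  A *static* fixed-point baseline (fixed integer/fractional split with
  hardware-style saturation) is provided for comparison experiments.

* **Otsu binarization** — filtered spike trains are histogrammed and
  split at the threshold maximising the between-class variance
  ``λ_b²(t) = q1(1−q1)(μ1−μ2)²``, turning real-valued synaptic traces into
  1-bit events during learning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DfxFormat",
    "QuantizedMatrix",
    "GrayHistogram",
    "dfx_encode",
    "dfx_decode",
    "select_fractional_length",
    "dfx_quantize_matrix",
    "dynamic_quantize",
    "fx_quantize_matrix",
    "otsu_threshold",
    "otsu_statistics",
    "binarize_trace",
]


@dataclass(frozen=True)
class DfxFormat:
    """A dynamic fixed-point number format.

    ``total_bits`` includes the sign bit; ``frac_length`` is the power of
    two the mantissa is scaled by (value = sign · mantissa · 2^(−FL));
    ``r_max`` is the fault-tolerant ratio: a value whose best representable
    relative error exceeds ``r_max`` is stored as 0.
    """

    total_bits: int
    frac_length: int
    r_max: float = 0.2

    def __post_init__(self):
        if self.total_bits < 2:
            raise ValueError("total_bits must be >= 2")
        if not 0 <= self.frac_length <= self.total_bits - 1:
            raise ValueError("frac_length must be in [0, total_bits-1]")
        if self.r_max <= 0:
            raise ValueError("r_max must be > 0")

    @property
    def lsb(self) -> float:
        return 2.0 ** (-self.frac_length)

    @property
    def max_mantissa(self) -> int:
        return 2 ** (self.total_bits - 1) - 1


@dataclass
class QuantizedMatrix:
    """A weight matrix stored as integer mantissas with a shared scale.

    ``mantissas`` are signed integers with magnitude < 2^(B−1);
    ``zero_mask`` marks entries forced to zero by the ``r_max`` rule.
    """

    mantissas: np.ndarray
    fmt: DfxFormat
    zero_mask: np.ndarray = None

    def __post_init__(self):
        self.mantissas = np.asarray(self.mantissas, dtype=np.int64)
        if np.any(np.abs(self.mantissas) > self.fmt.max_mantissa):
            raise ValueError("mantissa magnitude exceeds 2^(B-1)-1")
        if self.zero_mask is None:
            self.zero_mask = np.zeros(self.mantissas.shape, dtype=bool)

    def decode(self) -> np.ndarray:
        """Real-valued matrix ``W_new`` this container represents."""
        return self.mantissas * self.fmt.lsb

    # runtime container: integer mantissas + a small text header
    def save(self, path):
        np.savez(path, mantissas=self.mantissas, zero_mask=self.zero_mask,
                 header=np.array([self.fmt.total_bits, self.fmt.frac_length]),
                 r_max=np.array([self.fmt.r_max]))

    @classmethod
    def load(cls, path) -> "QuantizedMatrix":
        with np.load(path) as z:
            b, fl = (int(v) for v in z["header"])
            fmt = DfxFormat(b, fl, float(z["r_max"][0]))
            return cls(z["mantissas"], fmt, z["zero_mask"].astype(bool))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (sign-symmetric)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def dfx_encode(value: float, fmt: DfxFormat) -> tuple[int, bool]:
    """Encode a scalar into (signed mantissa, zeroed flag).

    The mantissa is the nearest representable (round half away from zero).
    If the relative error of the nearest representable exceeds ``r_max``
    the value is stored as 0 with ``zeroed=True``.  Values too large for
    the mantissa range raise ``OverflowError`` — saturation is never
    applied silently in the dynamic format.
    """
    m = float(_round_half_away(np.array(value * 2.0**fmt.frac_length)))
    if abs(m) > fmt.max_mantissa:
        raise OverflowError(
            f"value {value} overflows {fmt.total_bits}-bit mantissa at "
            f"FL={fmt.frac_length}"
        )
    m = int(m)
    if value != 0.0:
        rel_err = abs(m * fmt.lsb - value) / abs(value)
        if rel_err > fmt.r_max:
            return 0, True
    return m, False


def dfx_decode(mantissa: int, fmt: DfxFormat) -> float:
    """Decode a signed mantissa: ``(−1)^s · |mantissa| · 2^(−FL)``."""
    if abs(mantissa) > fmt.max_mantissa:
        raise ValueError("mantissa out of range for format")
    return mantissa * fmt.lsb


def select_fractional_length(values: np.ndarray, total_bits: int) -> int:
    """Largest fractional length that represents every value without overflow.

    This is the "dynamic" step: the scale is read off the tensor itself.
    All-zero input returns the maximum ``B−1`` (pure fraction).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0 or not np.all(np.isfinite(values)):
        raise ValueError("need at least one finite value")
    vmax = float(np.max(np.abs(values)))
    max_mant = 2 ** (total_bits - 1) - 1
    if vmax == 0.0:
        return total_bits - 1
    for fl in range(total_bits - 1, -1, -1):
        if _round_half_away(np.array(vmax * 2.0**fl)) <= max_mant:
            return fl
    raise OverflowError(
        f"max |value| = {vmax} does not fit in {total_bits} bits at FL=0"
    )


def dfx_quantize_matrix(W: np.ndarray, fmt: DfxFormat) -> QuantizedMatrix:
    """Quantize a whole matrix into the dynamic fixed-point container.

    Vectorised equivalent of applying :func:`dfx_encode` entry by entry
    (sign bit first, nearest ``B``-bit mantissa, then the fault-tolerant
    zeroing judgment).  Raises ``OverflowError`` naming the first
    offending entry if any value does not fit at the format's FL.
    """
    W = np.asarray(W, dtype=float)
    scaled = _round_half_away(W * 2.0**fmt.frac_length)
    over = np.abs(scaled) > fmt.max_mantissa
    if np.any(over):
        idx = tuple(int(i) for i in np.argwhere(over)[0])
        raise OverflowError(
            f"entry {idx} = {W[idx]} overflows at FL={fmt.frac_length}"
        )
    mant = scaled.astype(np.int64)
    decoded = mant * fmt.lsb
    nonzero = W != 0.0
    rel_err = np.zeros_like(W)
    rel_err[nonzero] = np.abs(decoded[nonzero] - W[nonzero]) / np.abs(W[nonzero])
    zero_mask = nonzero & (rel_err > fmt.r_max)
    mant[zero_mask] = 0
    return QuantizedMatrix(mant, fmt, zero_mask)


def dynamic_quantize(W: np.ndarray, total_bits: int,
                     r_max: float = 0.2) -> QuantizedMatrix:
    """Pick the per-tensor fractional length, then quantize (the full
    dynamic fixed-point step used after each weight update)."""
    fl = select_fractional_length(W, total_bits)
    return dfx_quantize_matrix(W, DfxFormat(total_bits, fl, r_max))


def fx_quantize_matrix(W: np.ndarray, integer_bits: int,
                       fractional_bits: int) -> QuantizedMatrix:
    """Static fixed-point baseline with hardware-style saturation.

    The fractional length is fixed at ``fractional_bits`` for every matrix
    regardless of content; magnitudes beyond the integer range saturate to
    the largest representable value (mirroring a saturating datapath — no
    error, unlike the dynamic format).  No fault-tolerant zeroing.
    """
    if integer_bits < 0 or fractional_bits < 0 or integer_bits + fractional_bits < 1:
        raise ValueError("need at least one magnitude bit")
    W = np.asarray(W, dtype=float)
    total_bits = 1 + integer_bits + fractional_bits
    fmt = DfxFormat(total_bits, fractional_bits, r_max=np.inf)  # no zeroing rule
    scaled = _round_half_away(W * 2.0**fractional_bits)
    mant = np.clip(scaled, -fmt.max_mantissa, fmt.max_mantissa).astype(np.int64)
    return QuantizedMatrix(mant, fmt)


# -- Otsu thresholding -----------------------------------------------------

@dataclass(frozen=True)
class GrayHistogram:
    """A normalised gray-level histogram ``p(i)``, levels ``1 … L``."""

    probabilities: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.ndim != 1 or p.size < 2:
            raise ValueError("histogram needs at least two levels")
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("probabilities must be non-negative and sum to 1")

    @property
    def levels(self) -> int:
        return self.probabilities.size


def otsu_statistics(hist: GrayHistogram):
    """Per-candidate-threshold Otsu statistics.

    For each candidate threshold ``t`` (cluster 1 = levels ``1…t``,
    cluster 2 = levels ``t+1…L``) returns arrays over ``t = 1 … L−1`` of
    the cluster masses ``q1, q2``, means ``μ1, μ2``, within-class variance
    ``λ_w²`` and between-class variance ``λ_b² = q1(1−q1)(μ1−μ2)²``.
    Degenerate thresholds (an empty cluster) get ``λ_b² = 0``.
    """
    p = hist.probabilities
    L = p.size
    levels = np.arange(1, L + 1, dtype=float)
    csum = np.cumsum(p)
    cmean = np.cumsum(levels * p)
    total_mean = cmean[-1]
    total_var = float(np.sum((levels - total_mean) ** 2 * p))

    q1 = csum[:-1]                       # t = 1 … L-1
    q2 = 1.0 - q1
    with np.errstate(invalid="ignore", divide="ignore"):
        mu1 = np.where(q1 > 0, cmean[:-1] / q1, 0.0)
        mu2 = np.where(q2 > 0, (total_mean - cmean[:-1]) / q2, 0.0)
    valid = (q1 > 0) & (q2 > 0)
    lam_b = np.where(valid, q1 * (1.0 - q1) * (mu1 - mu2) ** 2, 0.0)
    lam_w = total_var - lam_b
    return {
        "t": np.arange(1, L), "q1": q1, "q2": q2, "mu1": mu1, "mu2": mu2,
        "lambda_b2": lam_b, "lambda_w2": lam_w, "total_var": total_var,
        "valid": valid,
    }


def otsu_threshold(hist: GrayHistogram) -> int:
    """Threshold level ``t*`` maximising the between-class variance.

    Cluster 1 is levels ``1…t``, cluster 2 is ``t+1…L`` (1-indexed levels,
    matching the histogram convention).  Ties resolve to the smallest
    ``t``.  A histogram with a single occupied level has no valid split
    and raises ``ValueError``.
    """
    stats = otsu_statistics(hist)
    if not np.any(stats["valid"]):
        raise ValueError("degenerate histogram: only one occupied level")
    return int(stats["t"][int(np.argmax(stats["lambda_b2"]))])


def binarize_trace(values: np.ndarray, bins: int = 256
                   ) -> tuple[np.ndarray, bool]:
    """Binarize real-valued filtered spike traces via Otsu's threshold.

    The values are histogrammed into ``bins`` levels over their range, the
    between-class-variance-maximising level is found, and each value maps
    to 1 iff it lies above the threshold level's upper edge.  Constant
    input is degenerate: returns all zeros with the flag set.
    """
    values = np.asarray(values, dtype=float)
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        return np.zeros_like(values), True
    counts, edges = np.histogram(values, bins=bins, range=(vmin, vmax))
    hist = GrayHistogram(counts / counts.sum())
    t = otsu_threshold(hist)
    cut = edges[t]  # upper edge of level t (levels are 1-indexed)
    return (values > cut).astype(float), False
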