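"""Discrete-time dynamics of the segregated-dendrite spiking network.

The network is simulated with a forward-Euler scheme at step ``dt`` (ms).
Input neurons are Poisson units whose rate encodes pixel intensity.
Hidden neurons have three functional compartments: a basal dendrite
receiving bottom-up input (``V0b = W0·s_input + b0``), an apical dendrite
receiving top-down feedback through fixed random weights
(``V0a = Y·s1``), and a soma integrating both::

    τ dV0/dt = −V0 + (g_b/g_l)(V0b − V0) + (g_a/g_l)(V0a − V0)

Output neurons integrate their basal drive plus a somatic teaching
current ``I`` (zero in the forward phase)::

    τ dV1/dt = −V1 + I + (g_d/g_l)(V1b − V1)

The dendritic compartments are algebraic weighted sums — only somata
carry state.  Somatic spiking is an inhomogeneous Poisson process with
rate ``Φ = Φ_max·σ(V)``; presynaptic spike trains are low-pass filtered
with the double-exponential kernel

    κ(t) = (e^(−t/τ_L) − e^(−t/τ_s)) Θ(t) / (τ_L − τ_s),

which integrates to 1, so a steady rate ``r`` produces a steady trace
``s ≈ r``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pwl import PWLSpec, sigmoid

__all__ = [
    "NetworkConfig",
    "HiddenState",
    "OutputState",
    "SpikeTrain",
    "ExpTraceFilter",
    "response_kernel",
    "dendrite_potentials",
    "step_hidden_soma",
    "step_output_soma",
    "hidden_fixed_point",
    "output_fixed_point",
    "rate_from_potential",
    "sample_poisson_spikes",
    "export_raster",
]


@dataclass(frozen=True)
class NetworkConfig:
    """All sizes, conductances and time constants of the network.

    Conductances are relative (only ratios to ``g_l`` enter the dynamics).
    ``phi_max`` is the maximum firing rate in spikes/ms; with ``dt`` in ms
    the per-step spike probability is ``rate·dt``.  ``ipi_mean`` /
    ``ipi_shape`` parameterise the inverse-Gaussian distribution of phase
    (inter-plateau) durations.  ``i_teach`` is the magnitude of the
    somatic teaching current: the correct output neuron receives
    ``+i_teach``, all others ``−i_teach`` during the target phase.
    """

    n_input: int
    hidden_sizes: tuple[int, ...]
    n_output: int
    g_l: float = 0.1
    g_b: float = 1.0
    g_a: float = 0.05
    g_d: float = 1.0
    tau: float = 10.0          # ms, = C_m / g_l
    dt: float = 1.0            # ms
    phi_max: float = 0.2       # spikes per ms
    tau_l: float = 10.0        # ms, long kernel constant
    tau_s: float = 3.0         # ms, short kernel constant
    settle_ms: float = 30.0    # Δt_s before phase averaging starts
    ipi_mean: float = 50.0     # ms, inverse-Gaussian mean phase length
    ipi_shape: float = 500.0   # ms, inverse-Gaussian shape
    i_teach: float = 50.0
    refractory_ms: float = 0.0

    def __post_init__(self):
        if not (self.tau_l > self.tau_s > 0):
            raise ValueError("need tau_l > tau_s > 0")
        if min(self.g_l, self.g_b, self.g_a, self.g_d) < 0:
            raise ValueError("conductances must be >= 0")
        if self.dt <= 0 or self.tau <= 0:
            raise ValueError("dt and tau must be > 0")
        if not 0 < self.phi_max <= 1:
            raise ValueError("phi_max must be in (0, 1]")
        if self.settle_ms <= 0 or self.ipi_mean <= 0 or self.ipi_shape <= 0:
            raise ValueError("settle_ms, ipi_mean, ipi_shape must be > 0")

    @property
    def n_hidden_layers(self) -> int:
        return len(self.hidden_sizes)


@dataclass
class HiddenState:
    """Per-step state of one hidden layer (vectors over its neurons)."""

    v_soma: np.ndarray
    v_basal: np.ndarray
    v_apical: np.ndarray
    trace: "ExpTraceFilter"          # filtered own spikes, s0
    spike_count: np.ndarray          # accumulator over the current phase
    refractory_left: np.ndarray

    @classmethod
    def zeros(cls, n: int, cfg: NetworkConfig) -> "HiddenState":
        z = np.zeros(n)
        return cls(z.copy(), z.copy(), z.copy(),
                   ExpTraceFilter(n, cfg.dt, cfg.tau_l, cfg.tau_s),
                   np.zeros(n, dtype=np.int64), np.zeros(n))


@dataclass
class OutputState:
    """Per-step state of the output layer."""

    v_soma: np.ndarray
    v_basal: np.ndarray
    i_teach: np.ndarray              # 0 throughout the forward phase
    trace: "ExpTraceFilter"          # filtered output spikes, s1
    spike_count: np.ndarray
    refractory_left: np.ndarray

    @classmethod
    def zeros(cls, p: int, cfg: NetworkConfig) -> "OutputState":
        z = np.zeros(p)
        return cls(z.copy(), z.copy(), z.copy(),
                   ExpTraceFilter(p, cfg.dt, cfg.tau_l, cfg.tau_s),
                   np.zeros(p, dtype=np.int64), np.zeros(p))


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (ms) of one neuron."""

    neuron: int
    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")


def response_kernel(t, tau_l: float, tau_s: float):
    """Double-exponential synaptic kernel κ(t); zero for t ≤ 0.

    Normalised so that ``∫₀^∞ κ dt = 1``.
    """
    if not tau_l > tau_s > 0:
        raise ValueError("need tau_l > tau_s > 0")
    t = np.asarray(t, dtype=float)
    out = np.where(
        t > 0,
        (np.exp(-t / tau_l) - np.exp(-t / tau_s)) / (tau_l - tau_s),
        0.0,
    )
    if out.ndim == 0:
        return float(out)
    return out


class ExpTraceFilter:
    """O(1)-per-step recursive implementation of the κ-filtered spike sum.

    Maintains two exponential accumulators ``A = Σ_k e^(−(t−t_k)/τ_L)`` and
    ``B = Σ_k e^(−(t−t_k)/τ_s)``; the trace is ``s = (A − B)/(τ_L − τ_s)``,
    identical to summing ``κ(t − t_k)`` over the entire spike history.
    A spike registered at the current step contributes κ(0) = 0 now and
    rises on subsequent steps, matching the causal kernel.
    """

    def __init__(self, n: int, dt: float, tau_l: float, tau_s: float):
        if not tau_l > tau_s > 0:
            raise ValueError("need tau_l > tau_s > 0")
        self._decay_l = np.exp(-dt / tau_l)
        self._decay_s = np.exp(-dt / tau_s)
        self._norm = 1.0 / (tau_l - tau_s)
        self._a = np.zeros(n)
        self._b = np.zeros(n)

    def step(self, spikes) -> np.ndarray:
        """Advance one step, add this step's spike counts, return s(t)."""
        self._a *= self._decay_l
        self._b *= self._decay_s
        if spikes is not None:
            self._a += spikes
            self._b += spikes
        return (self._a - self._b) * self._norm

    @property
    def value(self) -> np.ndarray:
        return (self._a - self._b) * self._norm

    def reset(self):
        self._a[:] = 0.0
        self._b[:] = 0.0


def dendrite_potentials(W0, b0, s_input, Y, s1):
    """Algebraic dendritic potentials of a hidden layer.

    ``V0b = W0·s_input + b0`` (basal, bottom-up) and ``V0a = Y·s1``
    (apical, top-down feedback through the fixed random weights).
    """
    W0, Y = np.asarray(W0), np.asarray(Y)
    s_input, s1, b0 = np.asarray(s_input), np.asarray(s1), np.asarray(b0)
    if W0.shape[1] != s_input.shape[0] or W0.shape[0] != b0.shape[0]:
        raise ValueError("W0/b0/s_input shapes disagree")
    if Y.shape[1] != s1.shape[0] or Y.shape[0] != W0.shape[0]:
        raise ValueError("Y/s1 shapes disagree")
    return W0 @ s_input + b0, Y @ s1


def step_hidden_soma(v0, v0b, v0a, cfg: NetworkConfig):
    """One Euler step of the hidden soma potential."""
    g = cfg.dt / cfg.tau
    return v0 + g * (-v0 + (cfg.g_b / cfg.g_l) * (v0b - v0)
                     + (cfg.g_a / cfg.g_l) * (v0a - v0))


def step_output_soma(v1, v1b, i_teach, cfg: NetworkConfig):
    """One Euler step of the output soma potential (with teaching current)."""
    g = cfg.dt / cfg.tau
    return v1 + g * (-v1 + i_teach + (cfg.g_d / cfg.g_l) * (v1b - v1))


def hidden_fixed_point(v0b, v0a, cfg: NetworkConfig):
    """Steady state of the hidden soma under constant dendritic drive."""
    return (cfg.g_b * np.asarray(v0b) + cfg.g_a * np.asarray(v0a)) / (
        cfg.g_l + cfg.g_b + cfg.g_a)


def output_fixed_point(v1b, i_teach, cfg: NetworkConfig):
    """Steady state of the output soma under constant drive and current."""
    return (cfg.g_l * np.asarray(i_teach) + cfg.g_d * np.asarray(v1b)) / (
        cfg.g_l + cfg.g_d)


def rate_from_potential(v, phi_max: float, sigmoid_impl: PWLSpec | None = None):
    """Instantaneous Poisson rate ``Φ = Φ_max·σ(V)``.

    ``sigmoid_impl=None`` uses the exact logistic sigmoid; passing a
    :class:`~dendep.pwl.PWLSpec` evaluates the shift-and-add approximation
    instead.
    """
    if not 0 < phi_max <= 1:
        raise ValueError("phi_max must be in (0, 1]")
    if sigmoid_impl is None:
        return phi_max * sigmoid(v)
    return phi_max * sigmoid_impl(np.asarray(v, dtype=float))


def sample_poisson_spikes(rates, dt: float, rng: np.random.Generator):
    """Bernoulli spike indicators: each neuron fires with prob ``rate·dt``."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    p = np.minimum(rates * dt, 1.0)
    return (rng.random(rates.shape) < p).astype(np.int8)


def export_raster(trains: list[SpikeTrain], path):
    """Write spike trains as two-column text (neuron_id, time_ms)."""
    with open(path, "w") as fh:
        fh.write("# neuron_id\ttime_ms\n")
        for tr in trains:
            for t in tr.times:
                fh.write(f"{tr.neuron}\t{t:.6g}\n")
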