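"""Two-phase plateau-potential learning with fixed random feedback.

Each training trial presents one image twice:

* **forward phase** — the image drives the input layer, no teaching
  current (``I = 0``).  After a settling time ``Δt_s`` the network's
  phase averages are accumulated over a window ``Δt1``; at its end each
  hidden neuron computes a plateau potential
  ``α_f = σ(⟨V0a⟩_forward)`` from its time-averaged apical potential.
* **target phase** — the same image plus a somatic teaching current at
  the output layer: the correct neuron receives ``+I`` (driving it
  toward its maximum rate), all others ``−I`` (silencing them).  After
  settling, averages over ``Δt2`` yield ``α_t = σ(⟨V0a⟩_target)``.

The difference ``α_t − α_f`` is the per-neuron credit signal: because the
apical compartment sees the output layer only through *fixed random*
feedback weights ``Y``, no weight transport is needed, and learning relies
on feedback alignment.  The hidden update descends an approximation of
the loss ``L0 = ‖φ0* − Φ_max σ(V̄0f)‖²`` with target rate
``φ0* = Φ̄0f + α_t − α_f``::

    ∂L0/∂W0 ≈ −k_b (α_t − α_f) Φ_max σ′(V̄0f) ∘ s̄input_f,
    k_b = g_b / (g_l + g_b + g_a),

applied as ``W0 ← W0 − η0·P0·∂L0/∂W0`` (the constant factor from the
squared norm is absorbed into ``η0·P0``).  The output layer uses a delta
rule on its phase-averaged rates, with the teaching current defining the
targets.  Phase durations are drawn from an inverse-Gaussian
distribution; the schedule is robust to their exact lengths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import quantization as qz
from .data import LabeledImage
from .dynamics import (
    ExpTraceFilter,
    NetworkConfig,
    rate_from_potential,
    step_hidden_soma,
    step_output_soma,
)
from .pwl import PWLSpec, dsigmoid, dsigmoid_pwl_spec, sigmoid, sigmoid_pwl_spec

__all__ = [
    "SynapseSet",
    "PhaseRecord",
    "PlateauSet",
    "LearningConfig",
    "TrialLog",
    "compute_plateau",
    "coupling_factor_kb",
    "target_rate",
    "hidden_update",
    "output_update",
    "sample_interphase_interval",
    "run_two_phase_trial",
]


@dataclass
class SynapseSet:
    """All synaptic weights of a 0/1/2-hidden-layer network.

    ``weights[l]`` maps layer ``l`` activity to layer ``l+1`` dendrites;
    ``feedbacks[l]`` is the fixed random feedback matrix from the output
    layer to hidden layer ``l``'s apical dendrites (direct feedback for
    every hidden layer).  Feedback weights are never modified by training.
    For the canonical one-hidden-layer network the aliases ``W0, b0, W1,
    b1, Y`` are exposed.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feedbacks: list[np.ndarray]

    # canonical one-hidden-layer aliases
    @property
    def W0(self) -> np.ndarray:
        return self.weights[0]

    @property
    def b0(self) -> np.ndarray:
        return self.biases[0]

    @property
    def W1(self) -> np.ndarray:
        return self.weights[-1]

    @property
    def b1(self) -> np.ndarray:
        return self.biases[-1]

    @property
    def Y(self) -> np.ndarray:
        if not self.feedbacks:
            raise AttributeError("network has no hidden layer, hence no Y")
        return self.feedbacks[0]

    @classmethod
    def initialize(cls, cfg: NetworkConfig,
                   rng: np.random.Generator) -> "SynapseSet":
        """Uniform(±1/√fan-in) feed-forward weights, Uniform(±1) fixed
        feedback, zero biases."""
        sizes = (cfg.n_input, *cfg.hidden_sizes, cfg.n_output)
        weights, biases = [], []
        for fan_in, fan_out in zip(sizes, sizes[1:]):
            lim = 1.0 / np.sqrt(fan_in)
            weights.append(rng.uniform(-lim, lim, size=(fan_out, fan_in)))
            biases.append(np.zeros(fan_out))
        feedbacks = [rng.uniform(-1.0, 1.0, size=(n, cfg.n_output))
                     for n in cfg.hidden_sizes]
        return cls(weights, biases, feedbacks)

    def copy(self) -> "SynapseSet":
        return SynapseSet([w.copy() for w in self.weights],
                          [b.copy() for b in self.biases],
                          [y.copy() for y in self.feedbacks])


@dataclass(frozen=True)
class LearningConfig:
    """Learning rates, scaling constants and the efficiency-layer switches.

    ``eta_hidden·p_hidden`` (η0·P0) scales the hidden plateau updates and
    ``eta_output·p_output`` the output delta rule.  ``sigmoid_mode`` picks
    exact σ/σ′ or their shift-and-add PWL approximations throughout the
    rate and update paths; ``binarize_traces`` applies Otsu binarization
    to the phase-averaged traces entering the weight updates;
    ``weight_mode`` selects full-precision, static fixed-point
    (saturating, fixed integer/fraction split) or dynamic fixed-point
    (per-tensor fractional length, fault-tolerant zeroing) storage of the
    trained weights after every update.
    """

    eta_hidden: float = 60.0
    eta_output: float = 2.0
    p_hidden: float = 1.0
    p_output: float = 1.0
    sigmoid_mode: str = "exact"          # "exact" | "pwl"
    binarize_traces: bool = False
    weight_mode: str = "float"           # "float" | "static" | "dynamic"
    dynamic_bits: int = 16
    static_integer_bits: int = 8
    static_fractional_bits: int = 14
    r_max: float = 0.2

    def __post_init__(self):
        if self.eta_hidden < 0 or self.eta_output < 0:
            raise ValueError("learning rates must be >= 0")
        if self.sigmoid_mode not in ("exact", "pwl"):
            raise ValueError("sigmoid_mode must be 'exact' or 'pwl'")
        if self.weight_mode not in ("float", "static", "dynamic"):
            raise ValueError("weight_mode must be float/static/dynamic")

    def sigma(self):
        """(σ, σ′) callables for the configured implementation."""
        if self.sigmoid_mode == "pwl":
            return sigmoid_pwl_spec(), dsigmoid_pwl_spec()
        return sigmoid, dsigmoid


@dataclass
class PhaseRecord:
    """Phase boundary times and the phase-averaged quantities.

    Per-hidden-layer quantities are lists (index = hidden layer).  Times
    are in ms from trial onset; ``dt1``/``dt2`` are the averaging-window
    lengths of the forward and target phases (``Δt1 = t1 − (t0 + Δt_s)``).
    """

    t0: float
    t1: float
    t2: float
    dt1: float
    dt2: float
    apical_f: list[np.ndarray]       # ⟨V0a⟩ per hidden layer, forward
    apical_t: list[np.ndarray]       # ⟨V0a⟩ per hidden layer, target
    v_hidden_f: list[np.ndarray]     # V̄0f per hidden layer
    s_input_f: np.ndarray            # s̄input_f
    s_hidden_f: list[np.ndarray]     # s̄0_f per hidden layer
    rate_hidden_f: list[np.ndarray]  # Φ̄0f per hidden layer
    v_output_f: np.ndarray           # V̄1f
    rate_output_f: np.ndarray        # Φ̄1f
    rate_output_t: np.ndarray        # Φ̄1 target phase

    def __post_init__(self):
        if not (self.t0 < self.t1 < self.t2):
            raise ValueError("phase times must satisfy t0 < t1 < t2")
        if self.dt1 <= 0 or self.dt2 <= 0:
            raise ValueError("averaging windows must be positive")


@dataclass(frozen=True)
class PlateauSet:
    """Plateau potentials at the two phase ends, per hidden neuron.

    Values are sigmoid outputs, strictly inside (0, 1).
    """

    alpha_f: np.ndarray
    alpha_t: np.ndarray

    def __post_init__(self):
        for a in (self.alpha_f, self.alpha_t):
            if np.any(a <= 0) or np.any(a >= 1):
                raise ValueError("plateau potentials must lie in (0, 1)")


@dataclass
class TrialLog:
    """Per-trial bookkeeping: spikes, SynOps, loss proxy, phase record."""

    label: int
    phase: PhaseRecord
    plateaus: list[PlateauSet]
    spike_counts: dict
    synops: int
    loss: float
    first_output_spike_ms: float | None = None
    predicted: int | None = None
    alignment_deg: float | None = None

    def to_json(self) -> str:
        return json.dumps({
            "label": self.label,
            "t0": self.phase.t0, "t1": self.phase.t1, "t2": self.phase.t2,
            "spike_counts": {k: int(np.sum(v)) if not isinstance(v, list)
                             else [int(np.sum(x)) for x in v]
                             for k, v in self.spike_counts.items()},
            "synops": int(self.synops),
            "loss": float(self.loss),
            "first_output_spike_ms": self.first_output_spike_ms,
            "predicted": self.predicted,
            "alignment_deg": self.alignment_deg,
        })


def compute_plateau(apical_trace: np.ndarray, window: tuple[int, int],
                    sigmoid_impl: PWLSpec | None = None) -> np.ndarray:
    """Plateau potentials from a recorded apical time series.

    ``apical_trace`` has shape (steps, neurons); the plateau is the
    sigmoid of the time average over ``window = (start, end)`` (end
    exclusive, in steps).
    """
    start, end = window
    if not 0 <= start < end <= apical_trace.shape[0]:
        raise ValueError("empty or out-of-range plateau window")
    mean_v = np.mean(np.asarray(apical_trace, dtype=float)[start:end], axis=0)
    s = sigmoid if sigmoid_impl is None else sigmoid_impl
    return np.asarray(s(mean_v))


def coupling_factor_kb(g_l: float, g_b: float, g_a: float) -> float:
    """Basal-to-soma coupling ``k_b = g_b/(g_l + g_b + g_a)``."""
    denom = g_l + g_b + g_a
    if denom <= 0:
        raise ValueError("conductances sum to zero")
    return g_b / denom


def target_rate(rate_forward: np.ndarray, alpha_t: np.ndarray,
                alpha_f: np.ndarray) -> np.ndarray:
    """Hidden target rate ``φ0* = Φ̄0f + α_t − α_f``."""
    rate_forward, alpha_t, alpha_f = map(np.asarray,
                                         (rate_forward, alpha_t, alpha_f))
    if not rate_forward.shape == alpha_t.shape == alpha_f.shape:
        raise ValueError("inputs must have the same length")
    return rate_forward + alpha_t - alpha_f


def _maybe_binarize(trace_mean: np.ndarray, lcfg: LearningConfig) -> np.ndarray:
    if not lcfg.binarize_traces:
        return trace_mean
    binary, _degenerate = qz.binarize_trace(trace_mean)
    return binary


def hidden_update(phase: PhaseRecord, plateaus: PlateauSet, syn: SynapseSet,
                  cfg: NetworkConfig, lcfg: LearningConfig, layer: int = 0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Plateau-driven weight increment for one hidden layer.

    Returns ``(ΔW, Δb)`` to be *added* to the layer's weights, i.e.
    ``−η0·P0·∂L0/∂W``.  The presynaptic factor is the phase-averaged
    trace of the layer below (the raw input traces for the first hidden
    layer), optionally Otsu-binarized.
    """
    _, sprime = lcfg.sigma()
    kb = coupling_factor_kb(cfg.g_l, cfg.g_b, cfg.g_a)
    delta = (kb * (plateaus.alpha_t - plateaus.alpha_f)
             * cfg.phi_max * np.asarray(sprime(phase.v_hidden_f[layer])))
    pre = phase.s_input_f if layer == 0 else phase.s_hidden_f[layer - 1]
    pre = _maybe_binarize(np.asarray(pre), lcfg)
    scale = lcfg.eta_hidden * lcfg.p_hidden
    if delta.shape[0] != syn.weights[layer].shape[0] or \
            pre.shape[0] != syn.weights[layer].shape[1]:
        raise ValueError("update shapes disagree with the synapse matrix")
    return scale * np.outer(delta, pre), scale * delta


def output_update(phase: PhaseRecord, syn: SynapseSet, cfg: NetworkConfig,
                  lcfg: LearningConfig) -> tuple[np.ndarray, np.ndarray]:
    """Delta-rule increment for the output layer.

    The teaching current defines the targets: the update is proportional
    to ``(Φ̄1_target − Φ̄1_forward)·σ′(V̄1f) ∘ s̄_pre_f``.  The feedback
    matrices are never touched.
    """
    _, sprime = lcfg.sigma()
    delta = ((phase.rate_output_t - phase.rate_output_f)
             * np.asarray(sprime(phase.v_output_f)))
    pre = (phase.s_hidden_f[-1] if phase.s_hidden_f else phase.s_input_f)
    pre = _maybe_binarize(np.asarray(pre), lcfg)
    scale = lcfg.eta_output * lcfg.p_output
    if delta.shape[0] != syn.weights[-1].shape[0] or \
            pre.shape[0] != syn.weights[-1].shape[1]:
        raise ValueError("update shapes disagree with the synapse matrix")
    return scale * np.outer(delta, pre), scale * delta


def sample_interphase_interval(rng: np.random.Generator, mean: float,
                               shape: float) -> float:
    """One inverse-Gaussian (Wald) draw of a phase duration (ms)."""
    if mean <= 0 or shape <= 0:
        raise ValueError("mean and shape must be > 0")
    return float(rng.wald(mean, shape))


def _quantize_weights(syn: SynapseSet, lcfg: LearningConfig) -> None:
    """Re-store the trained weights in the configured fixed-point format.

    Applied in place after every update step; feedback matrices stay in
    full precision (they are fixed, so a one-time quantization would be a
    constant offset — kept exact so float and quantized runs share Y).
    """
    if lcfg.weight_mode == "float":
        return
    for arrs in (syn.weights, syn.biases):
        for i, a in enumerate(arrs):
            if lcfg.weight_mode == "dynamic":
                q = qz.dynamic_quantize(a, lcfg.dynamic_bits, lcfg.r_max)
            else:
                q = qz.fx_quantize_matrix(a, lcfg.static_integer_bits,
                                          lcfg.static_fractional_bits)
            arrs[i] = q.decode()


class _PhaseAccumulator:
    """Running sums of the per-step quantities a phase average needs."""

    def __init__(self, cfg: NetworkConfig):
        self.n = 0
        self.apical = [np.zeros(h) for h in cfg.hidden_sizes]
        self.v_hidden = [np.zeros(h) for h in cfg.hidden_sizes]
        self.s_hidden = [np.zeros(h) for h in cfg.hidden_sizes]
        self.rate_hidden = [np.zeros(h) for h in cfg.hidden_sizes]
        self.s_input = np.zeros(cfg.n_input)
        self.v_output = np.zeros(cfg.n_output)
        self.rate_output = np.zeros(cfg.n_output)

    def mean(self, attr):
        v = getattr(self, attr)
        if isinstance(v, list):
            return [x / self.n for x in v]
        return v / self.n


class _NetworkSim:
    """Stateful step-by-step simulator of the layered network.

    Holds the trace filters and somatic potentials; one ``run`` call
    advances a block of steps with fixed teaching current, optionally
    accumulating phase averages and spike logs.
    """

    def __init__(self, syn: SynapseSet, cfg: NetworkConfig,
                 lcfg: LearningConfig, rng: np.random.Generator):
        self.syn, self.cfg, self.rng = syn, cfg, rng
        sig, _ = lcfg.sigma()
        self._sigma = sig
        self.input_trace = ExpTraceFilter(cfg.n_input, cfg.dt, cfg.tau_l,
                                          cfg.tau_s)
        self.hidden_v = [np.zeros(h) for h in cfg.hidden_sizes]
        self.hidden_traces = [ExpTraceFilter(h, cfg.dt, cfg.tau_l, cfg.tau_s)
                              for h in cfg.hidden_sizes]
        self.hidden_refrac = [np.zeros(h) for h in cfg.hidden_sizes]
        self.output_v = np.zeros(cfg.n_output)
        self.output_trace = ExpTraceFilter(cfg.n_output, cfg.dt, cfg.tau_l,
                                           cfg.tau_s)
        self.output_refrac = np.zeros(cfg.n_output)
        self.s_out = np.zeros(cfg.n_output)
        self.time_ms = 0.0

    def _bernoulli(self, rates, u, refrac):
        p = np.minimum(rates * self.cfg.dt, 1.0)
        if self.cfg.refractory_ms > 0:
            p = np.where(refrac > 0, 0.0, p)
        spk = (u < p).astype(np.int8)
        if self.cfg.refractory_ms > 0:
            refrac -= self.cfg.dt
            np.maximum(refrac, 0.0, out=refrac)
            refrac[spk > 0] = self.cfg.refractory_ms
        return spk

    def run(self, input_rates: np.ndarray, n_steps: int, i_teach: np.ndarray,
            accum: _PhaseAccumulator | None = None,
            spike_totals: dict | None = None,
            output_spike_steps: list | None = None):
        """Advance ``n_steps`` with constant teaching current.

        ``accum`` collects phase-average sums; ``spike_totals`` collects
        per-layer spike counts (for SynOps); ``output_spike_steps``
        records (absolute time, neuron) of every output spike.
        """
        cfg, syn = self.cfg, self.syn
        L = cfg.n_hidden_layers
        sigma = self._sigma
        phi_max, dt = cfg.phi_max, cfg.dt
        refractory = cfg.refractory_ms > 0
        # Euler coefficients: v' = c_self·v + c_b·v_b (+ c_a·v_a | c_i·I)
        g = dt / cfg.tau
        h_self = 1.0 - g * (1.0 + cfg.g_b / cfg.g_l + cfg.g_a / cfg.g_l)
        h_b, h_a = g * cfg.g_b / cfg.g_l, g * cfg.g_a / cfg.g_l
        o_self = 1.0 - g * (1.0 + cfg.g_d / cfg.g_l)
        o_d = g * cfg.g_d / cfg.g_l
        gi_teach = g * i_teach

        in_spikes_all = (self.rng.random((n_steps, cfg.n_input))
                         < np.minimum(input_rates * dt, 1.0)[None, :]
                         ).astype(np.int8)
        u_hid = [self.rng.random((n_steps, h)) for h in cfg.hidden_sizes]
        u_out = self.rng.random((n_steps, cfg.n_output))
        hid_counts = [np.zeros(h, dtype=np.int64) for h in cfg.hidden_sizes]
        out_spikes_all = np.zeros((n_steps, cfg.n_output), dtype=np.int8)
        t_start = self.time_ms

        weights, biases, feedbacks = syn.weights, syn.biases, syn.feedbacks
        for n in range(n_steps):
            s_input = self.input_trace.step(in_spikes_all[n])
            s_prev = s_input
            for l in range(L):
                v_b = weights[l] @ s_prev + biases[l]
                v_a = feedbacks[l] @ self.s_out
                v = h_self * self.hidden_v[l] + h_b * v_b + h_a * v_a
                self.hidden_v[l] = v
                rates = phi_max * sigma(v)
                if refractory:
                    spk = self._bernoulli(rates, u_hid[l][n],
                                          self.hidden_refrac[l])
                else:
                    spk = (u_hid[l][n] < rates * dt).astype(np.int8)
                hid_counts[l] += spk
                s_prev = self.hidden_traces[l].step(spk)
                if accum is not None:
                    accum.apical[l] += v_a
                    accum.v_hidden[l] += v
                    accum.s_hidden[l] += s_prev
                    accum.rate_hidden[l] += rates
            v1b = weights[-1] @ s_prev + biases[-1]
            v1 = o_self * self.output_v + gi_teach + o_d * v1b
            self.output_v = v1
            rates1 = phi_max * sigma(v1)
            if refractory:
                out_spikes = self._bernoulli(rates1, u_out[n],
                                             self.output_refrac)
            else:
                out_spikes = (u_out[n] < rates1 * dt).astype(np.int8)
            out_spikes_all[n] = out_spikes
            self.s_out = self.output_trace.step(out_spikes)

            if accum is not None:
                accum.n += 1
                accum.s_input += s_input
                accum.v_output += v1
                accum.rate_output += rates1
        self.time_ms = t_start + n_steps * dt

        if spike_totals is not None:
            spike_totals["input"] += int(in_spikes_all.sum())
            for l in range(L):
                spike_totals["hidden"][l] += int(hid_counts[l].sum())
            spike_totals["output"] += int(out_spikes_all.sum())
        if output_spike_steps is not None:
            for n, j in zip(*np.nonzero(out_spikes_all)):
                output_spike_steps.append((t_start + (n + 1) * dt, int(j)))


def _fan_outs(cfg: NetworkConfig) -> dict:
    """Efferent synapse counts per layer (feedback synapses included)."""
    sizes = (cfg.n_input, *cfg.hidden_sizes, cfg.n_output)
    return {
        "input": sizes[1],
        "hidden": [sizes[l + 2] for l in range(cfg.n_hidden_layers)],
        "output": int(sum(cfg.hidden_sizes)),
    }


def _backprop_gradient_w0(phase: PhaseRecord, syn: SynapseSet,
                          cfg: NetworkConfig, lcfg: LearningConfig
                          ) -> np.ndarray:
    """True-backpropagation counterpart of the first hidden update
    (error routed through W1ᵀ instead of the random feedback)."""
    _, sprime = lcfg.sigma()
    e1 = ((phase.rate_output_t - phase.rate_output_f)
          * np.asarray(sprime(phase.v_output_f)))
    delta = syn.weights[-1].T @ e1
    for l in range(len(cfg.hidden_sizes) - 1, 0, -1):
        delta = delta * np.asarray(sprime(phase.v_hidden_f[l]))
        delta = syn.weights[l].T @ delta
    delta = delta * np.asarray(sprime(phase.v_hidden_f[0]))
    return np.outer(delta, phase.s_input_f)


def run_two_phase_trial(image: LabeledImage, syn: SynapseSet,
                        cfg: NetworkConfig, lcfg: LearningConfig,
                        rng: np.random.Generator,
                        update: bool = True,
                        teaching: bool = True,
                        log_alignment: bool = False) -> TrialLog:
    """Simulate one forward+target trial and apply the weight updates.

    The network state starts from rest at each trial.  Phase averaging
    windows ``Δt1, Δt2`` are inverse-Gaussian draws floored at the
    settling time.  With ``teaching=False`` the target phase runs without
    teaching current (a control in which ``α_t ≈ α_f`` and updates carry
    no systematic signal); with ``update=False`` the computed updates are
    not applied.  ``log_alignment`` additionally records the angle
    between the first hidden layer's update and the true-backprop
    gradient routed through ``W1ᵀ``.
    """
    if image.flat.shape[0] != cfg.n_input:
        raise ValueError("image size disagrees with cfg.n_input")
    sig, _ = lcfg.sigma()
    sim = _NetworkSim(syn, cfg, lcfg, rng)
    input_rates = image.flat * cfg.phi_max
    settle_steps = int(round(cfg.settle_ms / cfg.dt))
    if settle_steps < 1:
        raise ValueError("settling time shorter than one step")

    dt1 = max(sample_interphase_interval(rng, cfg.ipi_mean, cfg.ipi_shape),
              cfg.settle_ms)
    dt2 = max(sample_interphase_interval(rng, cfg.ipi_mean, cfg.ipi_shape),
              cfg.settle_ms)
    n1 = int(round(dt1 / cfg.dt))
    n2 = int(round(dt2 / cfg.dt))

    spike_totals = {"input": 0,
                    "hidden": [0] * cfg.n_hidden_layers,
                    "output": 0}
    out_spike_log: list = []
    zero_i = np.zeros(cfg.n_output)

    # forward phase: settle, then average
    sim.run(input_rates, settle_steps, zero_i, spike_totals=spike_totals,
            output_spike_steps=out_spike_log)
    acc_f = _PhaseAccumulator(cfg)
    sim.run(input_rates, n1, zero_i, accum=acc_f, spike_totals=spike_totals,
            output_spike_steps=out_spike_log)

    alpha_f = [np.asarray(sig(a)) for a in acc_f.mean("apical")]

    # target phase: teaching current on
    i_vec = zero_i
    if teaching:
        i_vec = np.full(cfg.n_output, -cfg.i_teach)
        i_vec[image.label] = cfg.i_teach
    sim.run(input_rates, settle_steps, i_vec, spike_totals=spike_totals)
    acc_t = _PhaseAccumulator(cfg)
    sim.run(input_rates, n2, i_vec, accum=acc_t, spike_totals=spike_totals)

    alpha_t = [np.asarray(sig(a)) for a in acc_t.mean("apical")]

    t0 = 0.0
    t1 = t0 + cfg.settle_ms + n1 * cfg.dt
    t2 = t1 + cfg.settle_ms + n2 * cfg.dt
    phase = PhaseRecord(
        t0=t0, t1=t1, t2=t2, dt1=n1 * cfg.dt, dt2=n2 * cfg.dt,
        apical_f=acc_f.mean("apical"), apical_t=acc_t.mean("apical"),
        v_hidden_f=acc_f.mean("v_hidden"),
        s_input_f=acc_f.mean("s_input"),
        s_hidden_f=acc_f.mean("s_hidden"),
        rate_hidden_f=acc_f.mean("rate_hidden"),
        v_output_f=acc_f.mean("v_output"),
        rate_output_f=acc_f.mean("rate_output"),
        rate_output_t=acc_t.mean("rate_output"),
    )
    plateaus = [PlateauSet(np.clip(f, 1e-12, 1 - 1e-12),
                           np.clip(t, 1e-12, 1 - 1e-12))
                for f, t in zip(alpha_f, alpha_t)]

    alignment_deg = None
    d_hidden = [hidden_update(phase, plateaus[l], syn, cfg, lcfg, layer=l)
                for l in range(cfg.n_hidden_layers)]
    d_out = output_update(phase, syn, cfg, lcfg)
    if log_alignment and cfg.n_hidden_layers >= 1:
        from .experiment import alignment_angle
        bp = _backprop_gradient_w0(phase, syn, cfg, lcfg)
        dep = d_hidden[0][0]
        if np.linalg.norm(bp) > 0 and np.linalg.norm(dep) > 0:
            alignment_deg = alignment_angle(dep, bp)

    if update:
        for l, (dW, db) in enumerate(d_hidden):
            syn.weights[l] += dW
            syn.biases[l] += db
        syn.weights[-1] += d_out[0]
        syn.biases[-1] += d_out[1]
        _quantize_weights(syn, lcfg)

    fan = _fan_outs(cfg)
    synops = (spike_totals["input"] * fan["input"]
              + sum(s * f for s, f in zip(spike_totals["hidden"],
                                          fan["hidden"]))
              + spike_totals["output"] * fan["output"])
    loss = float(sum(np.sum((p.alpha_t - p.alpha_f) ** 2) for p in plateaus))
    forward_spikes = [t for t, _ in out_spike_log]
    return TrialLog(
        label=image.label, phase=phase, plateaus=plateaus,
        spike_counts=spike_totals, synops=int(synops), loss=loss,
        first_output_spike_ms=(min(forward_spikes) if forward_spikes else None),
        alignment_deg=alignment_deg,
    )
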