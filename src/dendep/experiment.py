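"""Training/evaluation loops, SynOps accounting and spike-based readouts.

:func:`train_network` runs the two-phase trial over a shuffled training
set each epoch and evaluates on a held-out set, producing a
:class:`TrainingHistory` (accuracy, plateau-loss proxy, cumulative
synaptic-operation counts, feedback-alignment angles).  Everything is
reproducible from a single integer seed.

SynOps is the event-driven cost metric: every spike costs one operation
per efferent synapse of the spiking neuron, so only active connections
consume anything.  Readouts are spike-based: either the argmax of output
spike counts over the forward window (rate readout) or the identity of
the earliest output spike (first-spike readout).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from .data import LabeledImage
from .dynamics import NetworkConfig
from .learning import (
    LearningConfig,
    SynapseSet,
    TrialLog,
    _fan_outs,
    _NetworkSim,
    _PhaseAccumulator,
    run_two_phase_trial,
)

__all__ = [
    "TrainingHistory",
    "train_network",
    "evaluate_accuracy",
    "count_synops",
    "neuron_selectivity",
    "alignment_angle",
    "spike_time_histogram",
]


@dataclass
class TrainingHistory:
    """Per-epoch learning curves plus per-trial diagnostics.

    ``synops`` is the cumulative count at each epoch end (non-decreasing);
    ``alignment_deg`` holds per-trial feedback-alignment angles when they
    were logged (one flat list, ``trials_per_epoch`` long per epoch).
    """

    accuracy: list[float] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    synops: list[int] = field(default_factory=list)
    trials: int = 0
    trials_per_epoch: int = 0
    alignment_deg: list[float] = field(default_factory=list)

    def last_epoch_alignment(self) -> np.ndarray:
        """Alignment angles of the final epoch's trials."""
        if not self.alignment_deg or self.trials_per_epoch == 0:
            return np.array([])
        return np.asarray(self.alignment_deg[-self.trials_per_epoch:])

    def to_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "accuracy_percent", "loss", "synops"])
            for e, (a, l, s) in enumerate(zip(self.accuracy, self.loss,
                                              self.synops), start=1):
                w.writerow([e, a, l, s])

    def to_jsonl(self, path):
        with open(path, "w") as fh:
            for e, (a, l, s) in enumerate(zip(self.accuracy, self.loss,
                                              self.synops), start=1):
                fh.write(json.dumps({"epoch": e, "accuracy_percent": a,
                                     "loss": l, "synops": s}) + "\n")


def train_network(
    train_set: list[LabeledImage],
    test_set: list[LabeledImage],
    cfg: NetworkConfig,
    lcfg: LearningConfig,
    epochs: int,
    seed: int,
    readout: str = "rate",
    log_alignment: bool = False,
    trial_hook=None,
) -> tuple[SynapseSet, TrainingHistory]:
    """Train with the two-phase schedule and evaluate every epoch.

    Training images are reshuffled each epoch; the test evaluation and
    weight initialisation derive from the same seed, so the whole run is
    reproducible.  ``trial_hook(trial_log)``, if given, is called after
    every trial (e.g. to stream JSON-lines logs).
    """
    if not train_set:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    syn = SynapseSet.initialize(cfg, rng)
    hist = TrainingHistory(trials_per_epoch=len(train_set))
    cum_synops = 0
    for _epoch in range(epochs):
        order = rng.permutation(len(train_set))
        epoch_loss = 0.0
        for i in order:
            log = run_two_phase_trial(train_set[i], syn, cfg, lcfg, rng,
                                      log_alignment=log_alignment)
            cum_synops += log.synops
            epoch_loss += log.loss
            hist.trials += 1
            if log.alignment_deg is not None:
                hist.alignment_deg.append(log.alignment_deg)
            if trial_hook is not None:
                trial_hook(log)
        acc = evaluate_accuracy(syn, test_set, cfg, readout=readout,
                                rng=rng, lcfg=lcfg)
        hist.accuracy.append(acc)
        hist.loss.append(epoch_loss / len(train_set))
        hist.synops.append(cum_synops)
    return syn, hist


def evaluate_accuracy(
    syn: SynapseSet,
    dataset: list[LabeledImage],
    cfg: NetworkConfig,
    readout: str = "rate",
    rng: np.random.Generator | None = None,
    lcfg: LearningConfig | None = None,
    eval_ms: float = 100.0,
    collect: bool = False,
):
    """Percent of images classified correctly from output spikes.

    Each image is presented for ``settle + eval_ms`` ms with no teaching
    current; the decision is the output neuron with the most spikes in
    the evaluation window (``readout="rate"``, ties to the lowest index)
    or the neuron that spikes first (``readout="first_spike"``).  Images
    producing no output spike at all count as incorrect and are tallied.
    With ``collect=True`` returns ``(percent, details)`` where details
    holds per-image first-spike times, spike counts and hidden spike
    flags.
    """
    if readout not in ("rate", "first_spike"):
        raise ValueError("readout must be 'rate' or 'first_spike'")
    rng = rng if rng is not None else np.random.default_rng(0)
    lcfg = lcfg if lcfg is not None else LearningConfig()
    settle_steps = int(round(cfg.settle_ms / cfg.dt))
    n_eval = int(round(eval_ms / cfg.dt))
    correct = 0
    no_spike = 0
    details = {"first_spike_ms": [], "spike_counts": [], "correct": [],
               "no_spike_images": 0}
    for img in dataset:
        sim = _NetworkSim(syn, cfg, lcfg, rng)
        rates = img.flat * cfg.phi_max
        totals = {"input": 0, "hidden": [0] * cfg.n_hidden_layers,
                  "output": 0}
        out_log: list = []
        zero_i = np.zeros(cfg.n_output)
        sim.run(rates, settle_steps, zero_i)
        acc = _PhaseAccumulator(cfg)
        # output spikes are counted only inside the evaluation window
        sim.run(rates, n_eval, zero_i, accum=acc, spike_totals=totals,
                output_spike_steps=out_log)
        counts = np.zeros(cfg.n_output, dtype=np.int64)
        first = {}
        for t, j in out_log:
            counts[j] += 1
            first.setdefault(j, t)
        if counts.sum() == 0:
            no_spike += 1
            ok = False
            pred = -1
        else:
            if readout == "rate":
                pred = int(np.argmax(counts))  # argmax ties -> lowest index
            else:
                pred = min(first, key=lambda j: (first[j], j))
            ok = pred == img.label
        correct += ok
        if collect:
            details["first_spike_ms"].append(min(first.values())
                                             if first else np.nan)
            details["spike_counts"].append(counts)
            details["correct"].append(ok)
    pct = 100.0 * correct / len(dataset)
    if collect:
        details["no_spike_images"] = no_spike
        return pct, details
    return pct


def count_synops(trial_log: TrialLog, cfg: NetworkConfig) -> int:
    """Recompute SynOps from a trial's raw spike counts.

    One operation per spike per efferent synapse of the spiking neuron:
    input spikes fan out to the first hidden layer (or the output layer
    in a 0-hidden network), hidden spikes to the next layer, output
    spikes to the feedback synapses.
    """
    fan = _fan_outs(cfg)
    s = trial_log.spike_counts
    return (s["input"] * fan["input"]
            + sum(h * f for h, f in zip(s["hidden"], fan["hidden"]))
            + s["output"] * fan["output"])


def neuron_selectivity(
    syn: SynapseSet,
    dataset: list[LabeledImage],
    cfg: NetworkConfig,
    neuron_sample: np.ndarray,
    rng: np.random.Generator | None = None,
    lcfg: LearningConfig | None = None,
    layer: int = 0,
    eval_ms: float = 100.0,
) -> np.ndarray:
    """−log spike probability of sampled hidden neurons per class.

    For each sampled neuron and each class, the probability of emitting
    at least one spike during the presentation of a class image is
    estimated over the dataset; probabilities are floored at 1/n_images
    of the class so the negative log stays finite.  Returns a
    ``(len(neuron_sample), n_classes)`` matrix.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    lcfg = lcfg if lcfg is not None else LearningConfig()
    neuron_sample = np.asarray(neuron_sample, dtype=int)
    n_classes = cfg.n_output
    spikes_by_class = {c: [] for c in range(n_classes)}
    settle_steps = int(round(cfg.settle_ms / cfg.dt))
    n_eval = int(round(eval_ms / cfg.dt))
    for img in dataset:
        sim = _NetworkSim(syn, cfg, lcfg, rng)
        rates = img.flat * cfg.phi_max
        zero_i = np.zeros(cfg.n_output)
        sim.run(rates, settle_steps, zero_i)
        hook_counts = _per_neuron_hidden_spikes(sim, rates, n_eval, layer)
        spikes_by_class[img.label].append(hook_counts[neuron_sample] > 0)
    out = np.empty((neuron_sample.size, n_classes))
    for c in range(n_classes):
        flags = np.asarray(spikes_by_class[c], dtype=float)
        if flags.size == 0:
            out[:, c] = np.nan
            continue
        p = flags.mean(axis=0)
        p = np.maximum(p, 1.0 / flags.shape[0])
        out[:, c] = -np.log(p)
    return out


def _per_neuron_hidden_spikes(sim: _NetworkSim, rates, n_steps: int,
                              layer: int) -> np.ndarray:
    """Run ``n_steps`` recording per-neuron spike counts in one hidden
    layer (simple re-implementation of the step loop with a counter)."""
    cfg, syn = sim.cfg, sim.syn
    counts = np.zeros(cfg.hidden_sizes[layer], dtype=np.int64)
    from .dynamics import step_hidden_soma, step_output_soma
    zero_i = np.zeros(cfg.n_output)
    for _ in range(n_steps):
        in_spikes = (sim.rng.random(cfg.n_input)
                     < np.minimum(rates * cfg.dt, 1.0)).astype(np.int8)
        s_prev = sim.input_trace.step(in_spikes)
        for l in range(cfg.n_hidden_layers):
            v_b = syn.weights[l] @ s_prev + syn.biases[l]
            v_a = syn.feedbacks[l] @ sim.s_out
            sim.hidden_v[l] = step_hidden_soma(sim.hidden_v[l], v_b, v_a, cfg)
            r = cfg.phi_max * np.asarray(sim._sigma(sim.hidden_v[l]))
            spk = (sim.rng.random(r.shape)
                   < np.minimum(r * cfg.dt, 1.0)).astype(np.int8)
            if l == layer:
                counts += spk
            s_prev = sim.hidden_traces[l].step(spk)
        v1b = syn.weights[-1] @ s_prev + syn.biases[-1]
        sim.output_v = step_output_soma(sim.output_v, v1b, zero_i, cfg)
        r1 = cfg.phi_max * np.asarray(sim._sigma(sim.output_v))
        out_spk = (sim.rng.random(r1.shape)
                   < np.minimum(r1 * cfg.dt, 1.0)).astype(np.int8)
        sim.s_out = sim.output_trace.step(out_spk)
    return counts


def alignment_angle(dep_update: np.ndarray, backprop_update: np.ndarray
                    ) -> float:
    """Angle (degrees) between two update matrices, flattened.

    90° means orthogonal (no useful error information in the feedback
    path); angles < 90° indicate feedback alignment.
    """
    a = np.asarray(dep_update, dtype=float).ravel()
    b = np.asarray(backprop_update, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("update shapes disagree")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("angle undefined for zero-norm update")
    cos = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def spike_time_histogram(first_spike_times_ms, bin_ms: float = 5.0):
    """Histogram of per-image first-decision times.

    ``first_spike_times_ms`` may contain NaN for images that produced no
    output spike; those are dropped, so the histogram total equals the
    number of images with at least one output spike.  Returns
    ``(bin_edges, counts)``.
    """
    t = np.asarray(first_spike_times_ms, dtype=float)
    t = t[np.isfinite(t)]
    if t.size == 0:
        return np.array([0.0, bin_ms]), np.array([0])
    hi = np.ceil(t.max() / bin_ms) * bin_ms
    edges = np.arange(0.0, hi + bin_ms, bin_ms)
    counts, edges = np.histogram(t, bins=edges)
    return edges, counts
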