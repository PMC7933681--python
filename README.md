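# dendep

Spike-driven credit assignment with segregated dendrites, packaged for
neuromorphic-style experiments: a discrete-time spiking network whose hidden
neurons separate bottom-up input (basal dendrite) from top-down feedback
(apical dendrite), trained with a two-phase plateau-potential rule and fixed
random feedback weights — plus the hardware-efficiency layers that make the
whole loop shift-and-add friendly: a piecewise-linear sigmoid with
power-of-two slopes, Otsu binarization of synaptic traces, and dynamic
fixed-point weight storage.

## Who this is for

Researchers in computational neuroscience and neuromorphic engineering who
want a tested, reproducible reference implementation of dendritic
event-based learning: how far a spiking network gets on a classification
task *without* weight transport, and how little arithmetic precision the
training loop actually needs.

## The model

Hidden neurons have three functional compartments. Dendrites are algebraic
weighted sums; only somata integrate (forward Euler, step ΔT):

```
V0b = W0·s_input + b0              (basal, bottom-up)
V0a = Y·s1                         (apical, fixed random feedback Y)
τ dV0/dt = −V0 + (g_b/g_l)(V0b − V0) + (g_a/g_l)(V0a − V0)
τ dV1/dt = −V1 + I + (g_d/g_l)(V1b − V1)     (output, teaching current I)
```

Spiking is Poisson with rate Φ = Φ_max·σ(V); presynaptic spikes are filtered
by the double-exponential kernel κ(t) = (e^(−t/τ_L) − e^(−t/τ_s))Θ(t)/(τ_L−τ_s).
Each trial runs a **forward phase** (I = 0) and a **target phase** (the
correct output neuron driven to its maximum rate, the others silenced). At
each phase end, every hidden neuron computes a plateau potential — the
sigmoid of its time-averaged apical potential — and the difference drives
the update

```
ΔW0 ∝ k_b (α_t − α_f) Φ_max σ′(V̄0f) ∘ s̄input_f,   k_b = g_b/(g_l+g_b+g_a),
```

with the feedback matrix Y never trained (feedback alignment). Phase
lengths are inverse-Gaussian draws; the schedule is robust to their exact
values.

Efficiency layers (each individually switchable in `LearningConfig`):

* **PWL sigmoid** — σ and σ′ replaced by piecewise-linear tables whose
  slopes are all ±2^k, so multiplication becomes a shift (`pwl` module,
  exhaustive fitter included, accepted under the mean squared relative
  error CF_RE).
* **Trace binarization** — phase-averaged traces Otsu-thresholded to 1 bit
  before entering the updates.
* **Dynamic fixed point** — weights stored as signed B-bit mantissas with a
  per-tensor fractional length chosen from the value range; entries whose
  best representable relative error exceeds a fault-tolerant ratio R_max
  are zeroed.

## Worked example

`examples/train_orientation.py` trains a 729–50–8 network for 3 epochs on
the generated oriented-bar task (27×27 images, 8 orientations in 22.5°
steps, 10% of pixels Gaussian-perturbed) and prints:

```
epoch 1: accuracy  22.5%  plateau loss 0.0429  cumulative SynOps 3.339e+07
epoch 2: accuracy  32.5%  plateau loss 0.0358  cumulative SynOps 6.628e+07
epoch 3: accuracy  65.0%  plateau loss 0.0312  cumulative SynOps 9.917e+07
median alignment angle, last epoch: 53.4 deg (90 deg = no error information in the feedback path)
```

Accuracy is the spike-count readout on a held-out set (chance is 12.5%);
the plateau loss is the mean ‖α_t − α_f‖², the quantity the hidden rule
descends; SynOps counts one operation per spike per efferent synapse (the
event-driven cost metric); and the alignment angle compares the plateau
update with the true backpropagation gradient — it starts near 90°
(orthogonal) and falls as the feed-forward weights align with the fixed
feedback. A 100-hidden-neuron run over 10 epochs reaches high accuracy;
see `tests/test_acceptance.py` for the full study conditions.

Other examples: `pwl_sigmoid.py` (tables, fit, CF_RE), `quantize_weights.py`
(dynamic vs static fixed point), `otsu_binarize.py`, `neuron_steady_state.py`.

There is also a thin CLI:

```
dendep train --task bars --hidden 1 --epochs 10 --seed 0 --weights dynamic:16
dendep fit-pwl --target sigmoid --threshold 0.05
dendep quantize weights.csv --bits 16 --rmax 0.2
```

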