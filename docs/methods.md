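# Methods

## Model

The network is a feed-forward chain of Poisson spiking layers simulated in
discrete time (forward Euler, default ΔT = 1 ms). Input neurons encode
pixel intensity v ∈ [0,1] as a Poisson rate v·Φ_max. Hidden neurons carry
three functional compartments: the basal dendrite receives the bottom-up
weighted sum `V0b = W0·s_input + b0`, the apical dendrite receives top-down
feedback `V0a = Y·s1` through a *fixed random* matrix Y, and the soma
integrates both with conductance ratios

    τ dV0/dt = −V0 + (g_b/g_l)(V0b − V0) + (g_a/g_l)(V0a − V0).

Dendritic compartments are algebraic (they carry no state of their own);
only somata integrate. Output somata follow
`τ dV1/dt = −V1 + I + (g_d/g_l)(V1b − V1)` with a somatic teaching current
I that is zero outside the target phase. Under constant drive the somata
settle onto the conductance-weighted fixed points
`(g_b V0b + g_a V0a)/(g_l+g_b+g_a)` and `(g_l I + g_d V1b)/(g_l+g_d)`,
which the test suite verifies against simulation to 1e−6.

Somatic spiking is an inhomogeneous Bernoulli approximation of a Poisson
process: spike probability rate·ΔT per step, rate Φ = Φ_max·σ(V).
Presynaptic spike trains are filtered with the double-exponential kernel
κ(t) = (e^(−t/τ_L) − e^(−t/τ_s))Θ(t)/(τ_L − τ_s), which has unit area, so a
steady rate r yields a steady trace ≈ r. The filter is implemented as two
exponential accumulators (O(1) per step) and is exactly equal to the
direct convolution over the full spike history; the tests check agreement
to 1e−10 on random rasters. A spike registered at step t contributes
κ(0) = 0 at its own step and rises afterwards (causal kernel).

## Two-phase learning

Each trial presents one image twice. Forward phase: settle Δt_s, then
average network quantities over a window Δt1. Target phase: teaching
current on (+I to the correct output neuron, −I to all others), settle
Δt_s, average over Δt2. At each phase end every hidden neuron computes a
plateau potential α = σ(⟨V0a⟩); the difference α_t − α_f is the credit
signal. Writing the target rate φ0* = Φ̄0f + α_t − α_f, the hidden update
descends the approximation of L0 = ‖φ0* − Φ_max σ(V̄0f)‖²:

    ΔW0 = η0·P0 · k_b (α_t − α_f) Φ_max σ′(V̄0f) ∘ s̄input_f,
    Δb0 = η0·P0 · k_b (α_t − α_f) Φ_max σ′(V̄0f),

with k_b = g_b/(g_l+g_b+g_a) the basal-to-soma coupling at steady state.
The constant 2 from differentiating the squared norm is absorbed into
η0·P0; the finite-difference test accounts for this factor explicitly.
The target is treated as fixed (no derivatives through φ0*). The output
layer uses a delta rule on phase-averaged rates,
ΔW1 ∝ (Φ̄1_target − Φ̄1_forward)·σ′(V̄1f) ∘ s̄0_f, with the teaching
current defining the targets. Y is never modified.

Phase averaging windows are drawn per trial from an inverse-Gaussian
(Wald) distribution (mean 50 ms, shape 500 ms), floored at the settling
time; the scheme does not depend on their exact lengths. Network state is
reset at each trial onset; it persists across the two phases within a
trial. Updates are applied once per trial, hidden layer(s) first, then
the output layer, after the target phase ends.

With more than one hidden layer each layer has its own fixed feedback
matrix direct from the output layer, and each computes its own plateau
pair. A zero-hidden-layer network degenerates to the output delta rule
alone.

## Parameters, units, defaults

| parameter | meaning | default | why |
|---|---|---|---|
| g_l, g_b, g_a, g_d | leak / basal / apical / output-dendrite conductances (relative) | 0.1, 1.0, 0.05, 1.0 | strong basal coupling, weak apical coupling — mostly-segregated feedback; g_a is the segregation knob (0 = full segregation) |
| τ | membrane time constant (ms) | 10 | C_m never appears independently; τ = C_m/g_l is the stored quantity |
| ΔT | Euler step (ms) | 1 | step refinement changes trajectories < 1e−2; tests check monotone convergence under ΔT → ΔT/10 |
| Φ_max | maximum rate (spikes/ms) | 0.2 | keeps per-step spike probabilities ≤ 0.2 |
| τ_L, τ_s | kernel constants (ms) | 10, 3 | trace settles within tens of ms, inside a phase window |
| Δt_s | settling time (ms) | 30 | ≈ 3τ before averages are trusted |
| phase mean, shape | inverse-Gaussian window (ms) | 50, 500 | windows of 30–80 ms; ~100 Poisson samples per average |
| I (teach) | teaching current | ±50 | a somatic current reaches the soma attenuated by g_l/(g_l+g_d) = 1/11, so ±50 drives V1 to ±4.5, i.e. rates 0.99/0.01 of maximum — the teaching signal is *defined* as max-rate/silent, and weaker currents (e.g. ±10 → rates 0.71/0.29 of max) do not implement it |
| η0, η1 | learning rates | 60, 2.0 | per-trial updates on phase-averaged traces (which are ≲0.2 in magnitude); chosen so the 729–100–8 network converges on the bar task within a few epochs |
| P0, P1 | scaling constants | 1.0 | only the products η·P enter the updates |
| R_max | fault-tolerant ratio | 0.2 | zeroes only entries within a few LSB of zero at 16 bits; larger values would zero mid-range weights |
| refractory | absolute refractory (ms) | 0 (off) | the rate model has no reset; an optional 2 ms refractory can be enabled |

Weight initialisation: W uniform ±1/√fan-in, Y uniform ±1 (fixed),
biases 0.

## Efficiency layers

**PWL sigmoid.** σ and σ′ are replaced by piecewise-linear tables whose
slopes are 0 or ±2^k (shift-and-add hardware). Segment membership is
half-open, (s_{i−1}, s_i]; segments are independent affine pieces and the
shipped tables are intentionally discontinuous by a few thousandths at
breakpoints. Outputs are clamped to [0.0001, 0.9999] (σ) and
[0.0001, 0.25] (σ′) — the floors keep rates and derivative signals from
vanishing exactly. The shipped σ table deviates from the exact sigmoid by
at most 0.0554 on [−6, 6] (worst near x = ∓1.3, where the outer segment
extends past the point at which the central segment's line would be
closer); the σ′ table by at most 0.020. The exhaustive fitter searches
every breakpoint combination from a grid and every candidate slope per
segment, with the intercept free (relative-error-weighted least squares)
or pinned; because the CF_RE criterion sums over sample points, per-segment
choices are independent given breakpoints, so the search is exhaustive yet
tractable. Fit acceptance uses CF_RE = (1/n)Σ(f_ori − f_PWL)²/f_ori² on a
0.01-step grid; if the threshold is missed the segment count grows by one,
up to a cap. Ties: lower CF_RE, then fewer segments, then smaller Σ|slope|.

**Otsu trace binarization.** Phase-averaged traces are histogrammed
(default 256 levels) and split at the level maximising the between-class
variance λ_b²(t) = q1(1−q1)(μ1−μ2)²; values above the threshold edge map
to 1. Ties resolve to the smallest level; the identity
λ² = λ_w²(t) + λ_b²(t) is verified to 1e−9. Constant traces are a
degenerate input: all zeros plus a flag. When the switch is on, the
binarized traces replace the real-valued ones wherever traces enter a
weight update (both the input traces in hidden updates and the hidden
traces in the output update) — the forward dynamics are untouched.

**Dynamic fixed point.** A value is stored as (−1)^s·mantissa·2^(−FL) with
a B-bit signed mantissa. The fractional length is chosen per tensor as
the largest FL whose rounded mantissas still fit (all-zero tensors get
B−1), recomputed after every weight update; this is the "dynamic" step —
no integer/fraction split is fixed in advance. Rounding is half away from
zero (sign-symmetric). Values whose rounded mantissa would exceed the
range raise an overflow error — this deliberately includes the half-LSB
edge zone just below 2^(B−1−FL), so the round-trip bound
|decode(encode(v)) − v| ≤ 2^(−FL−1) holds for *every* accepted value.
A nonzero value whose encoded relative error exceeds R_max is stored as
zero and flagged; these are exactly the values near zero. The quantized
training protocol re-stores W and b in the quantized format after each
update; somatic potentials, traces and the fixed Y stay full-precision
(keeping Y exact means float and quantized runs share the same feedback,
so accuracy differences isolate the weight-storage effect). The static
baseline fixes the integer/fraction split for every tensor and saturates
instead of erroring, mirroring a saturating datapath.

## Synthetic data

The generator renders a bright bar of width 3 px through the centre of a
27×27 image at one of eight orientations (0°–157.5° in 22.5° steps),
anti-aliased (intensity falls linearly to 0 over one pixel beyond the
half-width), with a per-sample sub-pixel perpendicular offset drawn from
Uniform(−0.5, 0.5) so no two samples coincide. Optionally exactly
round(0.10·729) = 73 distinct pixels are perturbed with N(0, 0.3²) noise
and clipped back to [0,1]. Train and test sets are independent draws from
the generator, not a fixed split.

What this emulates: a low-level feature-detection stream with stimulus
jitter and pixel noise, small enough that full training studies run on
one CPU in minutes. What it does not emulate: the within-class diversity
of handwritten digits — the bar classes are close to linearly separable,
so absolute accuracies here are far higher than digit benchmarks at equal
architecture, and passing tests demonstrate the learning mechanism works,
not that its absolute accuracy transfers to harder data. An IDX
reader/writer is included for running the same pipeline on the standard
digit archives when they are available locally.

## Study conditions used by the scaled-down experiments

The training studies in the acceptance tests use a 729–100–8 network on
800 training / 200 test images (100/25 per class) with 10% pixel noise,
10 epochs, spike-count readout over a 100 ms forward window. The depth
comparison trains 0-hidden and 1-hidden networks on the same data over
three seeds; the quantized study compares float, 16-bit dynamic
fixed-point and 8-integer/8-fractional-bit static fixed-point weight
storage on one seed. These sizes were chosen so each study completes in
minutes on a single CPU while keeping ≥100 Poisson samples per phase
average and ≥25 test images per class.

## Numerical choices and degenerate inputs

* Euler stability: with the defaults the per-step contraction factors are
  |1 − (ΔT/τ)(1 + g_b/g_l + g_a/g_l)| = 0.15 (hidden) and 0.1 (output);
  both well inside the unit circle.
* Readout ties go to the lowest neuron index; images with no output spike
  in the window count as incorrect and are tallied separately.
* Plateau values are clipped to (0,1) open-interval bounds at 1e−12
  before constructing the plateau record (σ can round to exactly 1.0 in
  float under extreme drive).
* All-zero images are permitted (zero input rates, bias-driven updates
  only); all-zero weight tensors quantize with FL = B−1.
* Selectivity probabilities are floored at 1/n so −log p stays finite.
* Every random draw flows from one `numpy.random.Generator`; a (seed,
  config) pair reproduces training bit-identically.

## Known limitations

* The Bernoulli-per-step spike model cannot emit two spikes of one neuron
  in one step; at Φ_max·ΔT = 0.2 the distortion is negligible.
* Deep feedback is direct-from-output per hidden layer; other routings
  (layer-to-layer feedback) are not implemented.
* No momentum, learning-rate decay, or error-sensitivity scheduling.
* The PWL fitter's exhaustive search is exponential in segment count over
  the breakpoint grid; it is intended for the small grids typical of
  hardware tables.
* Gradients/updates are not themselves quantized in the fixed-point
  training protocol — only the stored weights are.
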