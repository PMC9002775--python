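# Methods

## Model

The classifier is a Gelenbe random neural network (RNN): a network of
queues in which each neuron *l* carries a nonnegative integer potential
k_l(t).  Excitatory spikes raise the potential by one, inhibitory spikes
lower it by one (floored at zero), and an excited neuron (k_l > 0) fires
after an exponential service time at rate r_l, routing the spike to
neuron *j* as excitatory with probability p⁺_{l,j}, as inhibitory with
probability p⁻_{l,j}, or out of the network with probability d(l).  With
Poisson exogenous arrivals Λ⁺_l, Λ⁻_l, the network is an open queueing
network with product-form steady state; the marginal probability that
neuron *l* is excited solves the fixed point

    f_l = (Σ_j f_j w⁺_{j,l} + Λ⁺_l) / (r_l + Σ_j f_j w⁻_{j,l} + Λ⁻_l)

with weight rates w±_{j,l} = r_j p±_{j,l}.  Firing rates are tied to the
outgoing weights, r_l = (1 − d(l))⁻¹ Σ_j (w⁺_{l,j} + w⁻_{l,j}), so the
routing probabilities sum to one with d(l) by construction; this identity
is maintained to machine precision through every training update because
the network is always *parameterized* by its weights.

Two conventions need stating because the classical presentation leaves
them open:

* **Exogenous arrivals.** The internal-traffic equations do not by
  themselves give the classifier a way to inject data; exogenous Poisson
  rates Λ± are therefore first-class citizens of the solver, as is
  standard in the Gelenbe-network literature.  The feature encoder maps a
  normalized feature x_i ∈ [0, 1] to Λ⁺ = 0.9·x_i on input neuron *i*
  (nothing else receives exogenous traffic).  The factor 0.9, together
  with initial firing rates near 1, keeps input activations below 1.
* **Output-layer rates.** Output neurons have d = 1 (their spikes always
  leave the network) and no outgoing weights, so the rate/weight relation
  leaves their firing rate free.  It is fixed at r_out = 1.0, which makes
  each output activation a bounded ratio in [0, 1) directly comparable
  across classes.

## Steady-state solver

The classifier network is strictly feedforward (76-100-80-4 by default:
76 moment features in, two hidden layers, four classes out), so the fixed
point is solved *exactly* in one topological pass — layer k depends only
on layers before it.  General topologies fall back to damped fixed-point
iteration (damping 0.5, tolerance 1e-10, max 10 000 iterations) and
report non-convergence explicitly on the result object rather than
silently.  Activations are capped at 1 − 1e-9 (they are probabilities of
a busy queue); a neuron that receives excitatory traffic with zero
service capacity is an unstable queue and raises an error naming it.

## Simulator oracle

`simulate_network` runs the spiking dynamics event by event (Gillespie:
exponential waiting times between exogenous arrivals and firings, then
categorical routing).  It measures the fraction of *time* each neuron is
excited.  The first 5% of events are discarded as warm-up because the
chain starts empty, and standard errors are estimated by batch means
(40 batches) since the busy/idle indicator is autocorrelated.  Solver and
simulator are developed independently and cross-checked in the tests —
agreement within 3 standard errors at 10^6 events on random small
networks — which is what certifies the algebra of both.

## Training

Learning minimizes half the mean per-sample squared error between the
four output activations and one-hot targets.  Because the feedforward
steady state is an explicit composition of rational maps, the gradient is
computed by exact backpropagation; each weight influences the loss both
through the receiving layer (numerator/denominator) and through its own
sender's firing rate, and both paths are chained.  Neurons pinned at the
activation cap contribute zero derivative (projected dynamics).  The
analytic gradient is verified against central differences to better than
1e-4 relative in the tests.  Updates are plain gradient descent with
projection onto the nonnegative orthant (negative components clipped to
zero), full-batch by default with an optional mini-batch mode.

Defaults — learning rate 0.5, 200 epochs, uniform [0, 1/fan-out] initial
weights with a fixed seed — were chosen once for stable convergence on
min-max-normalized features at input scale 0.9: that initialization puts
every non-output firing rate near 1, hence input activations near
0.9·x, and the loss then descends smoothly at this rate.  Plain gradient
descent is only guaranteed monotone for small steps; the monotonicity
check in the tests therefore runs at learning rate 0.05.

One representational constraint of the architecture is worth knowing:
all excitation flows from the inputs and there is no bias term, so every
activation vanishes as the input vector approaches zero, and a class
whose signature is "all features low" can only win by the tie-break.
Classes are therefore easiest to learn when each has some feature that is
*high* for it (the four moment features of distinct seizure types have
this structure, as does the anti-correlated two-feature task used in the
training tests).

## Features

Recordings are segmented into contiguous non-overlapping 1-second
windows (trailing partial window dropped); the uniform montage drops Cz
and Pz when present, leaving 19 channels at 500 Hz.  Each channel of a
window is summarized by population standard deviation (ddof 0), Fisher
excess kurtosis (bias-uncorrected), skewness (bias-uncorrected) and mean,
in channel-major order [std, kurtosis, skewness, mean] — the order is
fixed because trained weights depend on it.  A flat channel scores 0 for
std, skewness and kurtosis by convention (the moment ratios are 0/0).
Min-max normalization is fitted on training data only; out-of-range test
values are clipped to [0, 1] and a constant feature maps to 0.  In
cross-validation the normalizer is refit per fold (leak-free).

## Synthetic data

The generator emulates the *structure* of long-term epilepsy-monitoring
data — 19 channels, 500 Hz, labeled seconds, four classes with
configurable counts (defaults 3895/3034/705/111, the class sizes of the
recordings this emulates) — not physiological EEG.  Since the pipeline
only ever sees four moments per channel, each class is designed to be
identifiable in those moments over a shared stationary AR(2) background
(coefficients 0.5/−0.25, innovation scale 10 µV):

| class | component | moment signature |
|---|---|---|
| 0 normal | background only | baseline |
| 1 complex partial | ~3 Hz spike-wave bursts, 120 µV | std ↑, kurtosis ≫ 0 |
| 2 electrographic | sustained 7 Hz rhythm, 30 µV | std ↑, kurtosis < 0 |
| 3 video-detected | slow baseline drift, ~40–60 µV | mean ↑ |

Per-channel gains (uniform ±20%) spread the components across the
montage.  Effect sizes default to clearly separable so that pipeline
tests are stable; consequently a perfect synthetic score demonstrates
that the machinery (features → normalization → training → inference →
metrics) is correct, *not* that comparable accuracy would be reached on
clinical recordings, where class overlap is substantial.  What the
generator does not emulate: inter-subject variability, artifacts,
non-stationarity within a second, realistic spatial fields, or the
heavy class imbalance of real monitoring data.

## Evaluation

Confusion matrices use rows = true class, columns = predicted.
Per-class metrics are one-vs-rest; both the one-vs-rest accuracy
(TP+TN over all) and the class recall are reported because "per-class
accuracy" is used for either in this literature.  Overall accuracy is
trace/total; overall precision/recall/F1 are unweighted macro averages.
Ratios with zero denominators are reported as 0 and flagged.  Splits are
plain shuffled 90/10 by default (floor rule: 7790 segments → 7011/779);
k-fold and stratified k-fold splitters guarantee fold sizes within one
sample and, when stratified, per-class balance within one sample.

## Problem sizes and numerical choices

The test suite and the acceptance script run the end-to-end benchmark at
400 segments per class (1600 seconds total, 90/10 split and 10-fold CV)
— large enough that the four classes are estimated stably, small enough
to re-run routinely on one CPU.  Simulator cross-checks use 10^6 events
per network.  Tolerances: fixed-point residual 1e-10; probability
conservation 1e-12; gradient check 1e-4 relative; DCT round trip 1e-10;
EDF round trip one 16-bit quantization step.

## Known limitations

* Training is plain projected gradient descent; no momentum, adaptive
  steps or line search.  Loss curves at the default rate are not
  monotone, only convergent in practice.
* Recurrent (non-feedforward) topologies are solved but not trainable.
* The trainable CNN/ResNet comparison models require a deep-learning
  backend; without one, the package provides their exact architecture
  arithmetic and feature operators (GAP channel attention, DCT pair,
  residual-block semantics) and raises an informative error for
  training requests.
* The EDF writer covers the plain-EDF subset used here (uniform 1-s
  records, one sampling rate, 16-bit samples); EDF+ annotations are out
  of scope.
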