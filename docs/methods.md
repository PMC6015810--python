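# Methods

## Model

`polybind` simulates hierarchies of conductance-based leaky integrate-and-fire
(LIF) neurons with randomized axonal conduction delays and trace-based
spike-timing-dependent plasticity (STDP), to study how *polychronization* —
reproducible, time-staggered spike patterns — and three-neuron *binding
circuits* emerge when such networks are trained on visual stimuli.

### Membrane and synapse dynamics

Each neuron integrates

    tau_m dV/dt = (V_0 - V) + I / g_0,      I_i = sum_j g_ij (Vrev_j - V_i)

with tau_m = C_m / g_0 (pF/nS = ms; units are mV, ms, nS, pF, pA throughout,
which closes the equation dimensionally without conversion factors).
Cellular parameters are the standard cortical regular-spiking /
fast-spiking values: C_m = 500/214 pF, g_0 = 25/18 nS (so tau_m = 20 ms
excitatory; 214/18 = 11.89 ms inhibitory, printed as 12 ms in the source
literature — we derive it from C_m/g_0 and accept the ~1% rounding),
V_0 = -74/-82 mV, threshold -53 mV, after-spike hyperpolarization
-57/-58 mV, absolute refractory period 2 ms.

Synaptic conductances decay exponentially with class-specific tau_g
(150 ms for all excitatory->excitatory classes, 2 ms excitatory->inhibitory,
5 ms inhibitory->excitatory) and jump by lambda * dg_ij when a presynaptic
spike *arrives*, i.e. one axonal delay Delta_t_ij after its emission.
dg_ij in [0, 1] is the plastic weight; lambda is the class's conductance
scaling bound (0.4 nS Gabor->L1, 1.6 nS E->E, 40 nS E->I, 80 nS I->E).
Reversal potentials: 0 mV excitatory, -70 mV inhibitory.

Integration is forward Euler on a fixed grid (published step 0.02 ms; the
desk-scale experiments below use 0.1 ms, which changes first-spike times by
less than 0.05 ms in the convergence test). The conductance decay uses the
exact per-step factor exp(-dt/tau_g) rather than the Euler difference — it
is unconditionally stable and identical in the dt -> 0 limit. Spikes are
stamped on the step grid and delays rounded to the nearest step (the 0.1 ms
delay floor is five 0.02 ms steps). Within a step: conductance decay, spike
arrivals, membrane update, threshold detection, delivery scheduling — so an
arrival can fire its target in the same step. During the refractory period
the membrane is clamped at V_H while conductances keep evolving, the common
LIF convention.

### Plasticity

Two saturating traces drive the weight rule: a per-synapse presynaptic
trace C (neurotransmitter concentration; driven at spike *arrival* by
C <- C + alpha_C (1 - C), decay tau_C) and a per-neuron postsynaptic trace
D (NMDA-receptor unblocking; driven at postsynaptic spikes, decay tau_D).
Weight updates are event-driven and multiplicative:

* presynaptic arrival: dg <- dg - rho D dg (depression first), then C is
  driven;
* postsynaptic spike: dg <- dg + rho C (1 - dg) (potentiation first), then
  D is driven.

alpha_C = alpha_D = 0.5, rho = 0.1. Both factors keep dg in [0, 1] by
construction. The published rule names a weight time constant tau_dg
without a value; whether the rule is continuous-time in tau_dg or
event-driven in rho cannot be settled from the text, so both readings are
implemented behind `PlasticityParams.continuous_tau_dg_ms` (the
continuous reading replaces rho by 1/tau_dg at events); event-driven is
the default. When a pre arrival and a post spike land in the same step,
arrivals are processed first, mirroring the integration ordering.

### Visual front end

Images are encoded by a Gabor bank modelling V1 simple cells: 4
orientations x 2 phases (0, pi), wavelength 2 px, aspect ratio 0.5,
bandwidth 1.5 octaves; the envelope width follows the standard octave-
bandwidth relation sigma = (lambda/pi) sqrt(ln 2 / 2) (2^b + 1)/(2^b - 1).
One input unit exists per (retinal location, filter). Responses are
half-rectified and mapped to firing rates on [0, 100 Hz]. The printed form
of the rate-mapping equation is illegible in the source; we normalize the
rectified responses by the 99th percentile of the positive responses for
the image and clip at the 100 Hz ceiling, so the population of well-matched
filters — not only the single best one — saturates the ceiling. (The
alternative, normalizing by the single maximum response, leaves nearly all
input rates far below the ceiling and the four-layer network silent even at
full scale.) Input spikes are homogeneous Poisson realizations of these
rates; repeated presentations with fresh seeds are the "transforms" of a
stimulus.

The built-in stimuli are centered outline drawings of a circle, a heart and
a star. Outlines are drawn with a 3 px stroke at any grid size: the Gabor
wavelength is fixed at 2 px, so it is the stroke width in pixels, not
relative to the image, that sets the filter response; a 3 px stroke drives
the bank strongly and uniformly along the outline.

### Architectures

*Two-layer model* (polychronization experiments): a 1000-unit Poisson input
layer, all units at 50 Hz, projects to layer 1 (connection probability 0.2,
delays U[1, 10] ms) which projects to layer 2 (probability 0.02, delays
U[1, 30] ms); both projections plastic, no inhibition. The synchrony
control pins every layer-1 -> layer-2 delay to 1 ms.

*Four-layer model* (ventral-stream experiments): layers 1-4 (V2, V4, TEO,
TE) each hold a 64 x 64 excitatory and 32 x 32 inhibitory grid; the retina
is 128 x 128. Feedforward counts per excitatory neuron are {30, 100, 100,
100} with fan-in radii {1, 8, 12, 16} (pre-grid cells, Euclidean, no
wraparound — a retina has borders); optional feedback (10, radius 8) and
lateral (10, radius 4) excitatory connections; excitatory->inhibitory (30,
radius 1) and inhibitory->excitatory (30, radius 8) loops implement local
competition. All E->E classes are plastic with delays U[0.1, 10] ms.
Initial plastic weights are i.i.d. U[0, 1] (the source is silent; uniform
keeps the soft bounds meaningful from the first event); non-plastic weights
are fixed at 1 with strength carried by the 40/80 nS scaling bounds.
Afferents are sampled without replacement when the radius disc holds enough
candidates, otherwise with replacement (logged). Positions map
proportionally between grids of different sizes.

With two contacts per pair (M = 2), every plastic pre/post pair is
represented twice with independent delays drawn from [0, 10] ms and
independent initial weights, letting plasticity select between transmission
delays.

### Desk-scale configuration

The full four-layer model (151k units, 2.3M synapses) integrates ~55 s per
200 ms presentation on one CPU, so training studies run at reduced scale.
The scaled configuration shrinks every grid's linear dimension by `scale`
(default 1/4: 16 x 16 excitatory grids, 32 x 32 retina) while fan-in counts
and radii shrink by sqrt(scale) and the conductance scaling bounds grow by
1/sqrt(scale). Rationale: scaling counts fully proportionally would cut
each neuron's afferent sample four-fold and (after drive compensation)
quadruple unitary conductances; the square-root split keeps both the
fan-in sampling noise and the unitary synaptic strength closer to the
full-size model, and the 1/sqrt(scale) compensation preserves each
neuron's mean total drive. The two-layer experiments use the same reduced
protocol documented with the acceptance checks: 300 neurons per layer and
dt = 0.1 ms, all other parameters as published.

### Schedules and seeds

A presentation lasts 200 ms (the source never states a duration; 200 ms
comfortably spans the conductance build-up at tau_g = 150 ms and the
first-spike statistics of interest). Membrane, conductances, traces and
pending deliveries are reset between presentations; only weights persist.
Training presents stimuli in turn with plasticity on; testing runs with
plasticity off. The two-layer protocol is 10 pre-test trials, 10 training
presentations (tau_C = 100 ms, tau_D = 150 ms, rho = 0.1), 10 post-test
trials; pre- and post-test use matched Poisson seeds, so an untrained run
reproduces its pre-test exactly. Every random draw derives from the master
seed through per-role child seeds (wiring; test trial i; training
presentation i), so adding trials never perturbs earlier randomness.

## Analyses

*Single-cell stimulus information.* Firing rates per (cell, stimulus,
transform) are discretized into equal-width bins over [0, max rate] per
cell — bins are (low, high] with zero pinned to bin 0, so a rate exactly on
an interior boundary falls low and the cell's maximum lands in the top
bin — and I(s, R) = sum_r P(r|s) log2 P(r|s)/P(r) is computed per stimulus
with a uniform stimulus prior; a cell's score is the maximum over stimuli,
with ceiling log2(n stimuli) (1.58 bits for three). Default 10 bins.

*Spike-pair PNG information.* For every ordered neuron pair (i, j) and
1 ms interval bin d in [0, 10) ms, a pair is present in a transform if i
spikes within bin d after any spike of j; presence is binary per transform
(occurrence-frequency reading of the published probability table; the
absolute spike time t is marginalized within a presentation). The binary
presence table feeds the same information formula. The same 1.58-bit
ceiling applies.

*First-spike precision.* For neurons that respond (>= 1 spike) in every
trial, the mean and sample (n-1) standard deviation of first-spike times
across trials.

*Binding circuits.* The detector returns all ordered triples (low 1,
high 2, binder 3) whose synapses 1->2, 1->3, 2->3 all reach a weight
threshold (default half the maximum plastic weight) and whose delays
satisfy |Delta(3,1) - (Delta(2,1) + Delta(3,2))| <= 1 ms (one interval
bin). The dynamical probe embeds a triple in an isolated circuit with fast
synapses: external drive and the 1->2 path use a 0.5 ms conductance and
400 nS scale (each drive volley elicits exactly one spike, ~0.5-1 ms
latency); the binder's two afferents use 2 ms conductances at 60 nS each,
so one volley peaks ~12 mV below threshold while two volleys within the
~6 ms summation window cross it. The probe asserts the binder fires within
4 ms of t_1 + Delta(3,1) under causal drive (the allowance covers the
binder's near-threshold integration latency), and stays silent when the
two neurons are driven independently at offsets of +-9 and +-12 ms —
beyond the summation window set by the 20 ms membrane time constant — and
when neuron 2 is driven alone.

## What the synthetic stimuli do and do not probe

The generator reproduces the study conditions: flat 50 Hz input for the
two-layer experiments, and Poisson-encoded outline shapes for the
four-layer experiments. It does not model natural-image statistics,
translation or scale transforms, multiple simultaneous objects, or
retinal/LGN preprocessing beyond the Gabor bank. Passing tests therefore
demonstrate the mechanisms (delay-driven polychronization, arrival-locked
STDP, delay-consistent binding triples) under controlled drive, not
invariant object recognition on real imagery.

## Numerical and design notes

* Delays are rounded to the nearest integration step at scheduling; a
  delivered spike's arrival minus emission equals the stored delay to
  within one step by construction.
* The instability guard aborts integration with a diagnostic if any
  membrane potential becomes non-finite (step size too large).
* Duration not divisible by dt is rounded down with a logged warning.
* "Responded" means >= 1 spike within the presentation window.
* The pair-occurrence flag is binary per transform; spike-count weighting
  is intentionally not the default (the published probability is an
  occurrence frequency across transforms).
* Information at the exact ceiling requires a cell to respond in *every*
  transform of its preferred stimulus and in *none* of the others; with
  finitely many transforms this is a demanding event, so the experiment
  drivers report both exact-ceiling counts and counts above a high-
  information threshold.

## Known limitations

* The published E->E conductance time constant (150 ms) makes postsynaptic
  spike timing depend on conductance accumulated over tens of milliseconds,
  which weakens the causal specificity of the 5-25 ms STDP window — the
  source itself notes the value was a compromise and that faster synapses
  would sharpen coincidence detection. At desk scale and short training
  schedules this materially limits how much training sharpens stimulus
  selectivity in the four-layer model.
* A structural property of the event-driven multiplicative rule: when
  tau_C = tau_D, the equilibrium weight in the linear-trace regime is
  tau_C/(tau_C + tau_D) = 1/2 for every synapse — first-order rate
  correlations between pre and post cancel, and only genuine spike-timing
  structure can move weights away from 1/2. Afferents active only under
  non-preferred stimuli are frozen rather than depressed (no postsynaptic
  spikes for LTP, no postsynaptic trace for LTD). Both properties cap how
  fast stimulus selectivity and multi-contact delay selection can emerge at
  reduced scale; the four-layer experiment drivers report the measured
  counts and weight-gap statistics so this regime is visible in the
  outputs rather than hidden.
* Under the published two-layer drive (every input at 50 Hz, tau_g =
  150 ms, lambda = 1.6 nS), every wired neuron responds in every trial both
  before and after training, so the all-trial responder count is fixed at
  its wiring ceiling; the first-spike precision effects remain.
* No event-driven (off-grid) integration, no adaptive or NMDA
  voltage-dependent channels, no synaptic depression/facilitation, no
  population-oscillation modelling.
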