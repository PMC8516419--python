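# Methods

## Model

The network has two conductance-based populations: N_E = 4000 excitatory
exponential integrate-and-fire neurons and N_I = 1000 inhibitory
leaky integrate-and-fire neurons.  Every ordered pair of distinct neurons
is connected independently with probability p = 0.2.  Membrane parameters
(C = 300 pF, gL = C/τ_m = 15 nS, τ_m = 20 ms, ΔT = 2 mV, V_T = −52 mV,
V_peak = 20 mV, V_reset = −60 mV, τ_ref = 1 ms; resting potentials −70 mV
for E and −62 mV for I, reversal potentials 0 / −75 mV) and synaptic
parameters (kernels: E rise/decay 1/6 ms, I rise/decay 0.5/2 ms; initial
weights J0_EE = 2.76 pF, J0_EI = 48.7 pF; fixed weights J_IE = 1.27 pF,
J_II = 16.2 pF; external drive 4.5 kHz → E, 2.25 kHz → I, with 1.78 / 1.27
pF external weights) are the published table values and are the package
defaults; a YAML config can override any field, with unknown keys rejected.

Synaptic kernels are differences of exponentials normalized to unit time
integral, so a Poisson drive of rate r (kHz) through weight J (pF) yields a
mean conductance of exactly J·r (nS).  Each spike's weight is deposited
into a decay trace and a rise trace (both incremented by J/(τ_d − τ_r));
the instantaneous conductance is their difference.  Traces decay with exact
per-step exponential factors.

Plasticity acts on two classes.  E→E weights follow the all-to-all triplet
STDP rule: accumulators r1, r2 (presynaptic; τ+ = 16.8 ms, τx = 101 ms) and
o1, o2 (postsynaptic; τ− = 33.7 ms, τy = 125 ms) jump by one on their
neuron's spikes and decay otherwise.  A presynaptic spike changes each
existing synapse by −o1·(A2− + A3−·r2); a postsynaptic spike by
+r1·(A2+ + A3+·o2), with amplitudes A2+ = 7.5e−10, A3+ = 9.3e−3,
A2− = 7e−3, A3− = 2.3e−4 pF.  Updates use the accumulator values *before*
the current step's increments.  I→E weights follow the symmetric
homeostatic rule: traces y_I, y_E with a shared 20 ms time constant; an
inhibitory spike changes its synapses by η·(y_E − 2 r0 τ) and an excitatory
spike by η·y_I, with η = 1 pF and target rate r0 = 3 Hz.  In expectation
(independent trains) the drift is η·r_I·2τ·(r_E − r0), so the rule
potentiates inhibition onto E neurons firing above target and depresses it
below — the engine of both stabilization and adaptation.

Two additional homeostatic mechanisms bound the excitatory dynamics: hard
weight bounds ([1.78, 21.4] pF for E→E, [48.7, 243] pF for I→E), and
subtractive normalization every 20 ms, which subtracts the per-row deviation
of each E neuron's summed E→E input from its initial value, divided by its
in-degree, from every existing synapse (then re-clips).  Row sums are
conserved exactly whenever no bound binds; when clipping binds the row sum
drifts, which is tolerated and reported by the tests.

An optional adaptive-current variant (a_w = 4 nS, b_w = 80.5 pA,
τ_w = 150 ms) subtracts w_adapt from the EIF equation, integrates
τ_w dw/dt = −w + a_w (V − Vrest) and jumps by b_w on spikes.  It is used
only as a control (all synaptic plasticity frozen) to show that unspecific
spike-frequency adaptation cannot produce stimulus-specific adaptation.

## Stimulation

A stimulus is a fixed random subset of neurons (each E neuron joins with
probability 5%, each I neuron with 15%; subsets of different stimuli may
overlap) that receives extra Poisson drive while the stimulus is shown
(12 kHz to E members, 1.2 kHz to I members, 300 ms per presentation).
Protocols are declarative epoch lists:

* **pretraining** — every stimulus n times in random order, no pauses;
* **sequence blocks** — n contiguous repetitions of a short sequence
  (e.g. ABC); in the second-to-last repetition the last slot either becomes
  a novel stimulus (standard), swaps with its neighbour (swap control), or
  the block is order-shuffled under a no-immediate-repeat constraint
  (shuffle control); the novel stimulus's drive can be scaled (graded-drive
  experiments); blocks can be presented in multiple randomized rounds
  (the repeated-sequence paradigm) and analysed round-averaged;
* **oddball (SSA)** — stimulus A presented n times with pauses, the deviant
  B in the second-to-last slot; A and B share their excitatory subset
  while their inhibitory subsets overlap partially;
* **disinhibition** — during the deviant epoch the whole inhibitory
  population's external rate is reduced by a fraction of 1.5 kHz
  (floored at zero).

## Integration and engine

Forward Euler at dt = 0.1 ms.  Per step: conductance decay; delivery of the
previous step's network spikes (one-step causal delay) plus this step's
external Poisson counts; membrane update (EIF spikes at V_peak, LIF at
V_T; reset and 1 ms clamp); plasticity (decay → update with pre-increment
values → increment → clip; simultaneous pre/post updates are additive and
therefore order-free); normalization on its 20 ms schedule; recording.
External counts are drawn chunk-wise in the driver from a named random
substream (connectivity, membership, input and protocol randomness are
independent substreams of the master seed), so the numba kernel and the
pure-numpy reference backend consume identical randomness and produce
identical spike records — the equivalence is asserted in the tests, and the
rest of the suite exploits the compiled kernel's ~500x speed advantage.
NaN voltages abort with the step and neuron named.  Spike buffers are sized
by the refractory-period bound (at most one spike per neuron per 1.1 ms),
and weight snapshots (default every 1 s) store the full I→E matrix plus
scalar E→E summaries to keep memory bounded.

## Analysis

Population rates are binned spike counts per neuron per second (default
10 ms bins) with optional boxcar smoothing (50 ms) for peak detection.  Per
sequence block: the **baseline** is the mean rate over the stimulus epochs
of the last two full sequences preceding the probed (novel/swap) epoch; the
**onset amplitude** is the peak within the block's first sequence minus
baseline; the **novelty amplitude** is the peak within the probed epoch
minus baseline; the **adaptation level** is onset rate minus baseline.  The
novelty **z-score** compares the probed epoch's peak against the
distribution of per-sequence peaks over the preceding (adapted) sequences.
This null uses the same max statistic as the probe, so it is free of the
positive bias a smoothed-trace maximum has against a bin-level standard
deviation; an unremarkable slot (the swap control) scores near zero while a
genuine novelty response scores far above 2.  Multi-round protocols are
averaged per block (time-locked to block onset) before amplitude
extraction.  Exponential decay fits use multi-start least squares on
a·exp(−x/τ) + b with degenerate inputs flagged rather than defaulted;
linear fits are ordinary least squares with closed-form standard errors.

## Desk-scale experiments and synaptic-count compensation

Full-size quantitative reproduction (e.g. the growth constant of the
novelty amplitude with repetitions, τ ≈ 9, or the slope of decay constant
versus sequence length, m ≈ 1.6) requires the 5000-neuron network for many
minutes of simulated time and is out of desk-test range.  The
`novelnet.experiments` module instead re-creates every paradigm on a
10x-smaller network (400 E / 100 I) and checks the mechanism's qualitative
signatures.

Proportional down-scaling alone distorts the operating point in two ways
that are fatal to the mechanism.  First, with only ~20 inhibitory synapses
per E neuron, even bound-saturated I→E weights cannot carry enough
inhibitory current to balance a driven assembly, so responses cannot adapt
(the weights pin at j_max).  Second, twenty IPSC sources deliver inhibition
in rare large packets relative to the 2 ms inhibitory kernel, making the
mean inhibitory conductance unrepresentative.  The compensation mode
(`novelnet.io.scaled_compensation`, off by default) therefore (i) raises
the connection probability to preserve each class's in-degree as far as
the small populations allow, (ii) multiplies each class's weights — and the
plastic classes' initial values and bounds — by the residual in-degree
deficit, preserving the in-degree × weight product, and (iii) multiplies
the inhibitory learning rate η by the same I→E factor, preserving the drift
timescale of the *total* inhibitory input a neuron receives.  Triplet
amplitudes keep their table values: excitatory assembly formation is
secondary to the inhibitory mechanism, and faster eSTDP at small N promotes
spurious attractor ignition.  At scale 1 the compensation is the identity.
Scaled runs remain qualitative: relative finite-size fluctuations are
larger, E–I spike correlations of the denser graph shift the iSTDP fixed
point somewhat below 3 Hz, and absolute rates are not comparable to the
full model.

The frozen study conditions (chosen from the paradigm definitions, with
sizes set once for desk-scale statistics): 20 s of baseline settling; a
pretraining phase presenting *all* of a session's stimuli 5 times in random
order; six sequence blocks of length-3 sequences × 15 repetitions
(standard, swap, and four graded-drive blocks at 25/50/75/100% novel
drive), each presented in 5 randomized rounds and analysed round-averaged;
oddball runs of 20 presentations with 300 ms pauses and the deviant at
slot 18.  The inhibitory-membership overlap of the oddball stimuli defaults
to 0.3 (shared fraction of the union): inhibitory neurons shared between A
and B are potentiated during A *and* recruited by B, so large overlaps
suppress the deviant response along with the adapted one; 0.3 keeps the
deviant's inhibition dominated by its own unpotentiated pool.  The
parameter is exposed for sweeps.

What the desk-scale runs do show: a novelty peak far above the adapted
per-sequence response distribution, no such peak for the swap control,
monotone growth of the novelty amplitude with novel-stimulus drive,
assembly-specific inhibitory weights rising during their own block and
decaying during others, stimulus-specific adaptation that requires *tuned*
plastic inhibition (absent with untuned inhibition or with frozen synapses
plus adaptive currents), and disinhibition amplifying and densifying the
deviant response.  What they do not show: the full model's absolute rates,
time constants, or amplitudes.

## Numerical choices and edge cases

* Euler step 0.1 ms; conductance decay uses exact exponential factors.
* EIF spikes at the numeric cutoff V_peak (V_T is the soft threshold inside
  the exponential); LIF spikes at V_T.  Refractory neurons are clamped and
  do not integrate.
* Zero synaptic delay; spikes emitted at step t reach conductances at
  t + 1 (explicit one-step causality).
* External input is sampled as per-neuron Poisson counts per step
  (λ = rate·dt ≈ 0.45 at baseline, too large for a Bernoulli
  approximation).
* Simultaneous pre- and post-synaptic spikes within one step: both updates
  use pre-increment accumulator values; the updates are additive, so their
  order does not affect the result.
* Clipping runs after normalization; the resulting row-sum drift under
  binding bounds is documented and tested.
* Neurons with no incoming E→E synapses are skipped by normalization;
  empty neuron subsets and degenerate fits raise or flag instead of
  returning defaults.
* Exponential fits bound τ > 0 and report non-convergence; constant input
  is flagged as unidentifiable.

## Known limitations

* The scaled experiments validate mechanism signatures, not quantitative
  values; full-size runs are required for the published time constants.
* A single inhibitory population — no interneuron subtypes, no short-term
  plasticity, no NMDA-dependent mechanisms, no topographic assembly
  arrangement.
* The dense compensated graph at very small N increases shared-input
  correlations; the homeostatic plateau sits ~1 Hz below the nominal
  target there (the sparse 1000-neuron configuration converges to within
  1 Hz of target, as tested).
* Plasticity of E→I and I→I synapses is out of scope; those weights are
  fixed.
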