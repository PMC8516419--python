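# novelnet

A recurrent spiking-network model of how cortex generates **novelty
responses** — and the analysis pipeline to quantify them.

Sensory cortex responds strongly to a stimulus it has not seen recently and
weakly to one it has: responses *adapt* under repetition, and a rare
(deviant, novel) stimulus breaks through the adapted background.  `novelnet`
implements a mechanistic account of this in a plastic
excitatory–inhibitory network: spike-timing-dependent plasticity of
inhibitory-to-excitatory synapses (iSTDP) selectively raises inhibition onto
excitatory neurons tuned to recently shown stimuli, while inhibition onto
neurons tuned to unseen stimuli stays low.  Novelty responses are then
simply *un-adapted* responses.  The package is for computational
neuroscientists who want to simulate, perturb, and quantify this mechanism.

## Model

* 4000 excitatory exponential integrate-and-fire (EIF) neurons,
  `C dV/dt = -gL(V-Vrest) + gL ΔT exp((V-V_T)/ΔT) - gE(V-VrevE) - gI(V-VrevI)`,
  and 1000 inhibitory leaky integrate-and-fire (LIF) neurons, randomly
  recurrently connected (p = 0.2), conductance-based synapses with
  difference-of-exponentials kernels (normalized to unit integral).
* **Triplet eSTDP** on E→E synapses: four spike accumulators r1, r2, o1, o2
  (τ+ = 16.8, τx = 101, τ− = 33.7, τy = 125 ms); a presynaptic spike
  depresses by `o1 (A2- + A3- r2)`, a postsynaptic spike potentiates by
  `r1 (A2+ + A3+ o2)`, all-to-all, with pre-increment accumulator values.
* **Homeostatic iSTDP** on I→E synapses: symmetric pair rule with low-pass
  traces (τ = 20 ms); a presynaptic spike changes the synapse by
  `η (y_E - 2 r0 τ)`, a postsynaptic spike by `η y_I`.  Its fixed point is a
  postsynaptic target rate r0 = 3 Hz.
* **Subtractive normalization** keeps each E neuron's summed E→E input at
  its initial value (every 20 ms), and hard bounds clip both plastic
  classes.
* **Stimuli** are extra Poisson drive (12 kHz → tuned E, 1.2 kHz → tuned I)
  to random subsets (5% of E, 15% of I per stimulus); paradigms are built
  as data: pretraining, repeated stimulus sequences with a novel stimulus
  in the second-to-last repetition (plus swap / shuffle / graded-drive
  controls), oddball (SSA) stimulation, and top-down disinhibition.

The simulation engine is a forward-Euler loop (dt = 0.1 ms) compiled with
numba, with a pure-numpy serial reference backend that is tested to produce
identical spikes.

## Worked example

Simulate a small network (one sequence block with a novel stimulus) and
quantify the response:

```python
import novelnet as nn

config, conn, _ = nn.make_fixture_network(0.1, seed=1, compensate=True)
config["sim"].seed = 1
stimset = nn.assign_memberships(config["network"], config["stimulus"], 4, 1)

settle = nn.Protocol([nn.StimulusEpoch(0, 20_000.0, None, tag="blank")])
pre = nn.make_pretraining(4, 5, config["stimulus"], seed=1)
block = nn.make_sequence_paradigm([[0, 1, 2]], 15, [3], seed=1)
protocol = settle.concat(pre).concat(block)

res = nn.run_simulation(conn, stimset, protocol, config)
trace = nn.population_rate(res.spikes, "E", t_max=res.duration, smooth_ms=50)
summary = nn.response_amplitudes(trace, protocol, block=0)
print(f"baseline {summary.baseline:.2f} Hz, "
      f"novelty amplitude {summary.novelty_amplitude:.2f} Hz, "
      f"peak z {summary.novelty_z():.1f}")
```

```
baseline 1.20 Hz, novelty amplitude 2.05 Hz, peak z 2.3
```

The baseline is the adapted population rate over the last two sequences
before the novel stimulus; the novelty amplitude is the excess population
rate when the novel stimulus appears; the z-score compares that peak with
the per-sequence peaks of the adapted responses — values above 2 mean the
novel stimulus broke through an otherwise adapted response.  (This minimal
example pretrains only four stimuli; the fuller paradigm in
`novelnet.experiments`, with more stimuli and round-averaged repeated
blocks, separates the novelty peak much more sharply.)

A command-line interface wraps the same pipeline for shell use:

```bash
novelnet protocol sequence --n-blocks 1 --n-reps 15 --out proto.yaml
novelnet simulate --config examples/config_small.yaml \
    --protocol proto.yaml --out run.h5
novelnet analyze run.h5 --protocol proto.yaml --out summary.json
```

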