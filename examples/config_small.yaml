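# Desk-scale example configuration: a 20x-reduced network with all other
# parameters at their published defaults. Suitable for quick end-to-end
# runs (simulate -> analyze) on a laptop.
network:
  n_exc: 200
  n_inh: 50
sim:
  seed: 3
  weight_snapshot_ms: 500.0
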