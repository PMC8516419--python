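"""Serialization and test-fixture helpers.

Bulk simulation output goes to HDF5 (spikes, weight snapshots, a config
echo); connectivity and memberships can be saved alongside.  Small
summaries are written as JSON/CSV by the CLI.  ``make_fixture_network``
builds a proportionally scaled-down network for desk-scale paradigm runs;
scaling divides the population sizes only — weights are *not* rescaled, so
scaled runs exercise properties and contracts rather than reproduce
full-scale numbers quantitatively.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass

import h5py
import numpy as np
import yaml

from . import __version__
from .engine import SimResult, SpikeRecord, WeightTrace
from .network import (Connectivity, StimulusSet, assign_memberships,
                      build_connectivity)
from .params import Config, NetworkParams, _SECTIONS

__all__ = ["save_run", "load_run", "save_network", "load_network",
           "make_fixture_network", "scaled_compensation", "RunManifest"]


@dataclass
class RunManifest:
    """Provenance of one simulation output file."""

    config_hash: str
    seed: int
    code_version: str
    output_path: str
    wall_time_s: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


def _config_yaml(config: Config) -> str:
    doc = {name: dataclasses.asdict(config[name]) for name in _SECTIONS}
    return yaml.safe_dump(doc, sort_keys=True)


def save_run(path, result: SimResult, wall_time_s: float = 0.0) -> RunManifest:
    """Write spikes, weight snapshots and a config echo to HDF5."""
    cfg_yaml = _config_yaml(result.config) if result.config else ""
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_yaml.encode()).hexdigest()[:16],
        seed=result.config["sim"].seed if result.config else 0,
        code_version=__version__,
        output_path=str(path),
        wall_time_s=wall_time_s,
    )
    with h5py.File(path, "w") as f:
        g = f.create_group("spikes")
        g.create_dataset("t_ms", data=result.spikes.t)
        g.create_dataset("population", data=result.spikes.pop)
        g.create_dataset("index", data=result.spikes.idx)
        g = f.create_group("weights")
        g.create_dataset("times_ms", data=result.weights.times)
        g.create_dataset("w_ei", data=result.weights.w_ei)
        g.create_dataset("w_ee_mean", data=result.weights.w_ee_mean)
        g.create_dataset("w_ei_mean", data=result.weights.w_ei_mean)
        if result.weights.w_ee is not None:
            g.create_dataset("w_ee", data=result.weights.w_ee)
        f.attrs["config_yaml"] = cfg_yaml
        f.attrs["duration_ms"] = result.duration
        f.attrs["manifest"] = manifest.to_json()
    return manifest


def load_run(path) -> tuple[SpikeRecord, WeightTrace, float]:
    """Read back (spikes, weight trace, duration_ms) from an HDF5 run file."""
    with h5py.File(path, "r") as f:
        spikes = SpikeRecord(t=f["spikes/t_ms"][:],
                             pop=f["spikes/population"][:],
                             idx=f["spikes/index"][:])
        g = f["weights"]
        weights = WeightTrace(
            times=g["times_ms"][:], w_ei=g["w_ei"][:],
            w_ee_mean=g["w_ee_mean"][:], w_ei_mean=g["w_ei_mean"][:],
            w_ee=g["w_ee"][:] if "w_ee" in g else None)
        duration = float(f.attrs["duration_ms"])
    return spikes, weights, duration


def save_network(path, conn: Connectivity, stimset: StimulusSet | None = None) -> None:
    """Weights as dense arrays, memberships as index lists."""
    with h5py.File(path, "w") as f:
        g = f.create_group("connectivity")
        for name in ("w_ee", "w_ei", "w_ie", "w_ii",
                     "m_ee", "m_ei", "m_ie", "m_ii",
                     "row_sums_ee_init", "n_in_ee"):
            g.create_dataset(name, data=getattr(conn, name))
        if stimset is not None:
            g = f.create_group("stimuli")
            for s, idx in stimset.members_E.items():
                g.create_dataset(f"members_E/{s}", data=idx)
            for s, idx in stimset.members_I.items():
                g.create_dataset(f"members_I/{s}", data=idx)


def load_network(path) -> tuple[Connectivity, StimulusSet | None]:
    with h5py.File(path, "r") as f:
        g = f["connectivity"]
        conn = Connectivity(
            w_ee=g["w_ee"][:], w_ei=g["w_ei"][:], w_ie=g["w_ie"][:],
            w_ii=g["w_ii"][:], m_ee=g["m_ee"][:].astype(bool),
            m_ei=g["m_ei"][:].astype(bool), m_ie=g["m_ie"][:].astype(bool),
            m_ii=g["m_ii"][:].astype(bool),
            row_sums_ee_init=g["row_sums_ee_init"][:],
            n_in_ee=g["n_in_ee"][:])
        stimset = None
        if "stimuli" in f:
            stimset = StimulusSet()
            for s in f["stimuli/members_E"]:
                stimset.members_E[int(s)] = f[f"stimuli/members_E/{s}"][:]
            for s in f["stimuli/members_I"]:
                stimset.members_I[int(s)] = f[f"stimuli/members_I/{s}"][:]
    return conn, stimset


def scaled_compensation(config: Config, base: NetworkParams | None = None) -> Config:
    """Synaptic-count compensation for a scaled-down network.

    A proportionally scaled network has proportionally fewer synapses per
    neuron, which changes the operating point in two qualitative ways: the
    total recurrent input per neuron shrinks, and the *temporal* granularity
    of synaptic input coarsens (fewer, effectively larger input events).
    This mode preserves the full-size mean field per class as faithfully as
    small populations allow:

    * the connection probability is raised to ``min(1, K_target / N_pre)``
      so each neuron's in-degree gets as close to the full-size in-degree
      ``K_target = p * N_pre,full`` as the population permits,
    * each class's weights (and, for the plastic classes, their initial
      value and hard bounds) are multiplied by the residual in-degree
      deficit ``K_target / K_scaled``, preserving the in-degree x weight
      product,
    * the inhibitory learning rate is multiplied by the same I->E factor so
      the drift of the *total* inhibitory input onto a neuron — the
      quantity homeostasis and adaptation act through — keeps its
      full-size timescale.  Triplet amplitudes are left at their table
      values: excitatory assembly formation is secondary to the inhibitory
      mechanism and faster eSTDP promotes attractor ignition at small N.

    At scale 1 the compensation is the identity.  Scaled runs remain
    qualitative: relative input fluctuations are larger at small N.
    """
    base = base or NetworkParams()
    net = config["network"]
    syn = config["synapse"]
    pl = config["plasticity"]
    p = syn.p_conn
    k_ee = p * (base.n_exc - 1)
    k_ei = p * base.n_inh
    k_ie = p * base.n_exc
    k_ii = p * (base.n_inh - 1)
    p_new = min(1.0, max(k_ee / (net.n_exc - 1), k_ei / net.n_inh,
                         k_ie / net.n_exc, k_ii / (net.n_inh - 1)))
    c_ee = k_ee / (p_new * (net.n_exc - 1))
    c_ei = k_ei / (p_new * net.n_inh)
    c_ie = k_ie / (p_new * net.n_exc)
    c_ii = k_ii / (p_new * (net.n_inh - 1))
    out = dict(config)
    out["synapse"] = dataclasses.replace(
        syn, p_conn=p_new,
        j0_EE=syn.j0_EE * c_ee, j_min_EE=syn.j_min_EE * c_ee,
        j_max_EE=syn.j_max_EE * c_ee,
        j0_EI=syn.j0_EI * c_ei, j_min_EI=syn.j_min_EI * c_ei,
        j_max_EI=syn.j_max_EI * c_ei,
        j_IE=syn.j_IE * c_ie, j_II=syn.j_II * c_ii)
    out["plasticity"] = dataclasses.replace(pl, eta=pl.eta * c_ei)
    return out


def make_fixture_network(scale: float, seed: int, n_stimuli: int = 0,
                         config: Config | None = None,
                         compensate: bool = False,
                         ) -> tuple[Config, Connectivity, StimulusSet | None]:
    """Proportionally scaled network + optional memberships for tests.

    ``scale`` in (0, 1]; populations become ceil(scale * 4000) E and
    ceil(scale * 1000) I with all other parameters at their defaults (or
    taken from ``config``).  With ``compensate=False`` (default) weights
    are left untouched — such runs probe properties, not quantitative
    behavior.  ``compensate=True`` applies :func:`scaled_compensation`,
    which preserves the full-size operating point and is used for the
    scaled paradigm-contract runs.  Returns the adjusted config, the
    connectivity and a StimulusSet when ``n_stimuli > 0``.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    from .params import default_config
    config = {k: dataclasses.replace(v) for k, v in
              (config or default_config()).items()}
    base = NetworkParams()
    net = config["network"]
    net.n_exc = math.ceil(scale * base.n_exc)
    net.n_inh = math.ceil(scale * base.n_inh)
    if compensate:
        config = scaled_compensation(config, base)
    conn = build_connectivity(net, config["synapse"], seed)
    stimset = None
    if n_stimuli > 0:
        stimset = assign_memberships(net, config["stimulus"], n_stimuli, seed)
    return config, conn, stimset
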