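"""Model parameters and configuration handling.

All parameter bundles carry the published defaults of the cortical
excitatory/inhibitory spiking-network model: membrane dynamics of the
exponential integrate-and-fire (EIF, excitatory) and leaky integrate-and-fire
(LIF, inhibitory) populations, synaptic connectivity and kernels, plasticity
time constants and amplitudes, and the stimulation-paradigm rates.

Units follow the field convention used throughout the package:

* voltages in mV, capacitance in pF, conductance in nS,
* time in ms, rates in kHz (spikes per ms) unless a field name says Hz,
* synaptic weights in pF (weight times kernel, 1/ms, gives nS).

Configurations are read from and written to YAML; unknown keys are rejected
and invariant violations are reported collectively with field names.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from typing import Any

import numpy as np
import yaml

__all__ = [
    "NetworkParams",
    "SynapseParams",
    "StimulusParams",
    "PlasticityParams",
    "AdaptiveCurrentParams",
    "SimConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "default_config",
    "substream",
]


class ConfigError(ValueError):
    """Raised for malformed configuration files or invalid parameter values."""


# ---------------------------------------------------------------------------
# parameter bundles
# ---------------------------------------------------------------------------


@dataclass
class NetworkParams:
    """Membrane parameters of the EIF (E) and LIF (I) populations."""

    n_exc: int = 4000
    n_inh: int = 1000
    tau_mem_E: float = 20.0      # ms
    tau_mem_I: float = 20.0      # ms
    v_rest_E: float = -70.0      # mV
    v_rest_I: float = -62.0      # mV
    delta_T: float = 2.0         # mV, slope factor of the EIF exponential
    capacitance: float = 300.0   # pF
    v_rev_E: float = 0.0         # mV
    v_rev_I: float = -75.0       # mV
    v_thr: float = -52.0         # mV; EIF soft threshold V_T, LIF spike threshold
    v_peak: float = 20.0         # mV; EIF numeric spike cutoff
    v_reset: float = -60.0       # mV
    tau_refr: float = 1.0        # ms absolute refractory period

    @property
    def g_leak(self) -> float:
        """Leak conductance in nS (C / tau_mem_E)."""
        return self.capacitance / self.tau_mem_E

    def validate(self) -> list[str]:
        errs = []
        if self.n_exc <= 0:
            errs.append("n_exc: population size must be positive")
        if self.n_inh <= 0:
            errs.append("n_inh: population size must be positive")
        for name in ("tau_mem_E", "tau_mem_I", "tau_refr", "delta_T",
                     "capacitance"):
            if getattr(self, name) <= 0:
                errs.append(f"{name}: must be > 0")
        if not (self.v_reset < self.v_thr < self.v_peak):
            errs.append("v_reset < v_thr < v_peak violated")
        if not (self.v_rev_I < self.v_rest_E < self.v_rev_E):
            errs.append("v_rev_I < v_rest_E < v_rev_E violated")
        return errs


@dataclass
class SynapseParams:
    """Connectivity, synaptic kernels, weights and external drive."""

    p_conn: float = 0.2
    tau_rise_E: float = 1.0      # ms
    tau_decay_E: float = 6.0     # ms
    tau_rise_I: float = 0.5      # ms
    tau_decay_I: float = 2.0     # ms
    j_min_EE: float = 1.78       # pF
    j_max_EE: float = 21.4       # pF
    j0_EE: float = 2.76          # pF
    j_min_EI: float = 48.7       # pF (I -> E)
    j_max_EI: float = 243.0      # pF
    j0_EI: float = 48.7          # pF
    j_IE: float = 1.27           # pF (E -> I, fixed)
    j_II: float = 16.2           # pF (I -> I, fixed)
    j_EEx: float = 1.78          # pF external -> E
    j_IEx: float = 1.27          # pF external -> I
    r_ext_E: float = 4.5         # kHz external baseline onto E
    r_ext_I: float = 2.25        # kHz external baseline onto I

    def validate(self) -> list[str]:
        errs = []
        if not 0.0 <= self.p_conn <= 1.0:
            errs.append("p_conn: must lie in [0, 1]")
        if not self.tau_rise_E < self.tau_decay_E:
            errs.append("tau_rise_E: rise must be < decay for the E kernel")
        if not self.tau_rise_I < self.tau_decay_I:
            errs.append("tau_rise_I: rise must be < decay for the I kernel")
        if min(self.tau_rise_E, self.tau_rise_I) <= 0:
            errs.append("synaptic rise times must be > 0")
        if not self.j_min_EE <= self.j0_EE <= self.j_max_EE:
            errs.append("j_min_EE <= j0_EE <= j_max_EE violated")
        if not self.j_min_EI <= self.j0_EI <= self.j_max_EI:
            errs.append("j_min_EI <= j0_EI <= j_max_EI violated")
        if min(self.r_ext_E, self.r_ext_I) < 0:
            errs.append("external rates must be >= 0")
        return errs


@dataclass
class StimulusParams:
    """Stimulus tuning and drive of the stimulation paradigm."""

    r_stim_E: float = 12.0       # kHz extra drive to E members
    r_stim_I: float = 1.2        # kHz extra drive to I members
    r_disinh_I: float = -1.5     # kHz applied to all I during disinhibition
    p_member_E: float = 0.05
    p_member_I: float = 0.15
    stim_duration: float = 300.0  # ms per stimulus presentation

    def validate(self) -> list[str]:
        errs = []
        for name in ("p_member_E", "p_member_I"):
            if not 0.0 < getattr(self, name) < 1.0:
                errs.append(f"{name}: must lie in (0, 1)")
        if self.stim_duration <= 0:
            errs.append("stim_duration: must be > 0")
        if self.r_stim_E < 0 or self.r_stim_I < 0:
            errs.append("stimulus drives must be >= 0")
        return errs


@dataclass
class PlasticityParams:
    """Triplet eSTDP (E->E), symmetric iSTDP (I->E) and normalization.

    Accumulator mapping: r1 decays with ``tau_plus``, r2 with ``tau_x``
    (presynaptic detectors); o1 decays with ``tau_minus``, o2 with ``tau_y``
    (postsynaptic detectors).
    """

    tau_plus: float = 16.8       # ms, pairwise presynaptic accumulator r1
    tau_x: float = 101.0         # ms, triplet presynaptic accumulator r2
    tau_minus: float = 33.7      # ms, pairwise postsynaptic accumulator o1
    tau_y: float = 125.0         # ms, triplet postsynaptic accumulator o2
    a2_plus: float = 7.5e-10     # pF pairwise potentiation amplitude
    a3_plus: float = 9.3e-3      # pF triplet potentiation amplitude
    a2_minus: float = 7e-3       # pF pairwise depression amplitude
    a3_minus: float = 2.3e-4     # pF triplet depression amplitude
    tau_istdp: float = 20.0      # ms, low-pass spike traces y_E / y_I
    eta: float = 1.0             # pF inhibitory learning rate
    target_rate_hz: float = 3.0  # Hz homeostatic target of the E population
    norm_interval: float = 20.0  # ms between subtractive-normalization events

    @property
    def r0(self) -> float:
        """Target rate in spikes per ms."""
        return self.target_rate_hz / 1000.0

    @property
    def istdp_offset(self) -> float:
        """Depression offset 2 * r0 * tau_istdp of the iSTDP rule (dimensionless)."""
        return 2.0 * self.r0 * self.tau_istdp

    def validate(self) -> list[str]:
        errs = []
        for name in ("tau_plus", "tau_x", "tau_minus", "tau_y", "tau_istdp",
                     "norm_interval"):
            if getattr(self, name) <= 0:
                errs.append(f"{name}: must be > 0")
        for name in ("a2_plus", "a3_plus", "a2_minus", "a3_minus", "eta"):
            if getattr(self, name) < 0:
                errs.append(f"{name}: must be >= 0")
        if self.target_rate_hz < 0:
            errs.append("target_rate_hz: must be >= 0")
        return errs


@dataclass
class AdaptiveCurrentParams:
    """Adaptive-current control variant (spike-frequency adaptation).

    When enabled, w_adapt is subtracted from the EIF membrane equation;
    it integrates tau_w * dw/dt = -w + a_w (V - v_rest_E) and jumps by
    b_w on every spike.
    """

    a_w: float = 4.0             # nS subthreshold adaptation
    b_w: float = 80.5            # pA spike-triggered adaptation
    tau_w: float = 150.0         # ms
    enabled: bool = False

    def validate(self) -> list[str]:
        errs = []
        if self.tau_w <= 0:
            errs.append("tau_w: must be > 0")
        return errs


@dataclass
class SimConfig:
    """Euler-loop settings, plasticity switches and recording cadences."""

    dt: float = 0.1              # ms, forward-Euler step
    duration: float = 0.0        # ms; 0 means "span of the protocol"
    seed: int = 0
    triplet_on: bool = True
    istdp_on: bool = True
    normalization_on: bool = True
    adaptive_current_on: bool = False
    weight_snapshot_ms: float = 1000.0
    rate_bin_ms: float = 10.0
    chunk_steps: int = 10000     # steps per engine chunk (external-input draws)
    backend: str = "numba"       # "numba" (fast) or "numpy" (serial reference)

    def validate(self) -> list[str]:
        errs = []
        if self.dt <= 0:
            errs.append("dt: must be > 0")
        if self.duration < 0:
            errs.append("duration: must be >= 0")
        if self.weight_snapshot_ms <= 0:
            errs.append("weight_snapshot_ms: must be > 0")
        if self.rate_bin_ms <= 0:
            errs.append("rate_bin_ms: must be > 0")
        if self.chunk_steps <= 0:
            errs.append("chunk_steps: must be > 0")
        if self.backend not in ("numba", "numpy"):
            errs.append("backend: must be 'numba' or 'numpy'")
        return errs


# ---------------------------------------------------------------------------
# RNG substreams
# ---------------------------------------------------------------------------

# Named substreams so the connectivity draw, membership draw, external input
# and protocol randomization can be re-randomized independently of each other.
_SUBSTREAMS = {"connectivity": 1, "membership": 2, "input": 3, "protocol": 4}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return an independent generator for the named random substream."""
    try:
        key = _SUBSTREAMS[name]
    except KeyError:
        raise ValueError(f"unknown substream {name!r}; "
                         f"known: {sorted(_SUBSTREAMS)}") from None
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, key))))


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

_SECTIONS: dict[str, type] = {
    "network": NetworkParams,
    "synapse": SynapseParams,
    "stimulus": StimulusParams,
    "plasticity": PlasticityParams,
    "adaptation": AdaptiveCurrentParams,
    "sim": SimConfig,
}

Config = dict[str, Any]


def default_config() -> Config:
    """Full default parameter set (all published table values)."""
    return {name: cls() for name, cls in _SECTIONS.items()}


def _build_section(name: str, cls: type, data: dict, errs: list[str]):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    for key in sorted(unknown):
        errs.append(f"{name}.{key}: unknown key")
    kwargs = {k: v for k, v in data.items() if k in known}
    obj = cls(**kwargs)
    errs.extend(f"{name}.{e}" for e in obj.validate())
    return obj


def load_config(path) -> Config:
    """Load parameters from YAML; unspecified fields take the table defaults.

    Returns a dict with keys ``network``, ``synapse``, ``stimulus``,
    ``plasticity``, ``adaptation`` and ``sim``.  All invariant violations
    and unknown keys are collected and raised together.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    errs: list[str] = []
    for key in sorted(set(raw) - set(_SECTIONS)):
        errs.append(f"{key}: unknown section")
    cfg: Config = {}
    for name, cls in _SECTIONS.items():
        data = raw.get(name, {}) or {}
        if not isinstance(data, dict):
            errs.append(f"{name}: section must be a mapping")
            data = {}
        cfg[name] = _build_section(name, cls, data, errs)
    if errs:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errs))
    return cfg


def save_config(cfg: Config, path) -> None:
    """Write a parameter bundle back to YAML (round-trips with load_config)."""
    doc = {name: dataclasses.asdict(cfg[name]) for name in _SECTIONS}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
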