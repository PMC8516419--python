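"""Membrane and conductance dynamics (forward Euler, dt = 0.1 ms).

Excitatory neurons follow the exponential integrate-and-fire (EIF) model

    C dV/dt = -gL (V - VrestE) + gL dT exp((V - VT)/dT)
              - gE (V - VrevE) - gI (V - VrevI) [- w_adapt]

and spike when V crosses the numeric cutoff ``v_peak``; inhibitory neurons
are leaky integrate-and-fire (LIF) with the hard threshold ``v_thr``.  Both
are reset to ``v_reset`` and clamped there for the absolute refractory
period.

Synaptic conductances are a difference-of-exponentials kernel

    F(t) = (exp(-t/tau_decay) - exp(-t/tau_rise)) / (tau_decay - tau_rise)

realized as two exponential traces updated with exact per-step decay
factors; each arriving spike of weight J (pF) adds J/(tau_decay - tau_rise)
to both traces, so the instantaneous conductance (decay - rise, in nS)
equals the convolution of the spike train with J*F up to the dt
discretization of spike times.  The kernel integrates to exactly 1, so a
Poisson drive of rate r (kHz) and weight J (pF) gives mean conductance
J*r (nS).

These numpy implementations are the serial reference; the simulation engine
re-implements the identical arithmetic in a compiled kernel and is tested
against this path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import AdaptiveCurrentParams, NetworkParams

__all__ = ["synaptic_kernel_value", "kernel_peak_time", "ConductanceState",
           "NeuronState", "step_membranes"]


def synaptic_kernel_value(t, tau_rise: float, tau_decay: float):
    """Difference-of-exponentials synaptic kernel F(t), units 1/ms.

    Vectorized over ``t``.  F(0) = 0, F >= 0 for t >= 0 and the integral
    over [0, inf) is 1 for any valid time-constant pair.
    """
    if not 0 < tau_rise < tau_decay:
        raise ValueError("require 0 < tau_rise < tau_decay")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("kernel is causal; t must be >= 0")
    return (np.exp(-t / tau_decay) - np.exp(-t / tau_rise)) / (tau_decay - tau_rise)


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Argmax of the kernel: t* = tr*td/(td - tr) * ln(td/tr)."""
    if not 0 < tau_rise < tau_decay:
        raise ValueError("require 0 < tau_rise < tau_decay")
    return (tau_rise * tau_decay / (tau_decay - tau_rise)
            * np.log(tau_decay / tau_rise))


@dataclass
class ConductanceState:
    """Double-exponential conductance traces for one input class.

    ``g = x_decay - x_rise`` is the instantaneous conductance in nS.
    """

    tau_rise: float
    tau_decay: float
    x_decay: np.ndarray
    x_rise: np.ndarray

    @classmethod
    def zeros(cls, n: int, tau_rise: float, tau_decay: float) -> "ConductanceState":
        if not 0 < tau_rise < tau_decay:
            raise ValueError("require 0 < tau_rise < tau_decay")
        return cls(tau_rise, tau_decay,
                   np.zeros(n), np.zeros(n))

    @property
    def g(self) -> np.ndarray:
        return self.x_decay - self.x_rise

    def decay(self, dt: float) -> None:
        """Exact exponential decay of both traces over one step."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.x_decay *= np.exp(-dt / self.tau_decay)
        self.x_rise *= np.exp(-dt / self.tau_rise)

    def add(self, weighted_input: np.ndarray) -> None:
        """Deposit summed synaptic weight (pF) arriving at each neuron.

        ``weighted_input[i]`` is sum_j J_ij * (spikes of j this step), plus
        J_ext * (external count) for external drive.
        """
        inc = np.asarray(weighted_input) / (self.tau_decay - self.tau_rise)
        self.x_decay += inc
        self.x_rise += inc

    def step(self, weighted_input: np.ndarray, dt: float) -> None:
        """Decay then deposit: one conductance step."""
        self.decay(dt)
        self.add(weighted_input)


@dataclass
class NeuronState:
    """Voltages, refractory counters and the optional adaptive current."""

    v: np.ndarray                 # mV
    refr_steps: np.ndarray        # integer steps of clamp remaining
    w_adapt: np.ndarray | None = None  # pA, E population only

    @classmethod
    def at_rest(cls, n: int, v_rest: float, with_adapt: bool = False) -> "NeuronState":
        return cls(np.full(n, float(v_rest)), np.zeros(n, dtype=np.int64),
                   np.zeros(n) if with_adapt else None)


def step_membranes(state: NeuronState, g_exc: np.ndarray, g_inh: np.ndarray,
                   net: NetworkParams, population: str, dt: float,
                   adapt: AdaptiveCurrentParams | None = None) -> np.ndarray:
    """Advance one population's membranes by one Euler step; return spikes.

    ``population`` is "E" (EIF, spike at v_peak) or "I" (LIF, spike at
    v_thr).  Refractory neurons are clamped at v_reset and do not
    integrate.  The adaptive current, when enabled on the E population,
    integrates tau_w dw/dt = -w + a_w (V - VrestE) on time-t values and
    jumps by b_w on each spike.  Raises FloatingPointError on NaN voltages
    (diverged integration, dt too large).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if population not in ("E", "I"):
        raise ValueError("population must be 'E' or 'I'")
    v = state.v
    refr = state.refr_steps
    active = refr <= 0
    clamped = ~active
    use_adapt = (population == "E" and adapt is not None and adapt.enabled
                 and state.w_adapt is not None)

    if population == "E":
        v_rest = net.v_rest_E
        current = (-net.g_leak * (v - v_rest)
                   + net.g_leak * net.delta_T
                   * np.exp((v - net.v_thr) / net.delta_T)
                   - g_exc * (v - net.v_rev_E)
                   - g_inh * (v - net.v_rev_I))
        if use_adapt:
            current = current - state.w_adapt
        v_new = v + dt * current / net.capacitance
        if use_adapt:
            # integrate on the pre-step voltage, spike jump applied below
            state.w_adapt += dt * (-state.w_adapt
                                   + adapt.a_w * (v - v_rest)) / adapt.tau_w
        v = np.where(active, v_new, net.v_reset)
        spikes = active & (v >= net.v_peak)
    else:
        current = (-net.g_leak * (v - net.v_rest_I)
                   - g_exc * (v - net.v_rev_E)
                   - g_inh * (v - net.v_rev_I))
        v_new = v + dt * current / net.capacitance
        v = np.where(active, v_new, net.v_reset)
        spikes = active & (v >= net.v_thr)

    if np.any(np.isnan(v)):
        bad = int(np.flatnonzero(np.isnan(v))[0])
        raise FloatingPointError(
            f"membrane potential diverged (NaN) for {population} neuron {bad}; "
            "dt too large for the present conductances")

    refr_len = int(round(net.tau_refr / dt))
    v[spikes] = net.v_reset
    refr[clamped] -= 1
    refr[spikes] = refr_len
    if use_adapt:
        state.w_adapt[spikes] += adapt.b_w
    state.v = v
    return spikes
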