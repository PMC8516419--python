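"""Synaptic plasticity: triplet eSTDP, homeostatic iSTDP, normalization.

Triplet eSTDP (E -> E).  Four per-neuron spike accumulators decay
exponentially and jump by one on the owning neuron's spikes: presynaptic
r1 (tau_plus) and r2 (tau_x), postsynaptic o1 (tau_minus) and o2 (tau_y).
On a presynaptic spike of neuron j every existing synapse j -> i is
depressed by o1_i * (A2- + A3- * r2_j); on a postsynaptic spike of i every
synapse j -> i is potentiated by r1_j * (A2+ + A3+ * o2_i).  Updates use
the accumulator values *before* this step's increments (the epsilon
convention), and spike interactions are all-to-all in time.

Symmetric iSTDP (I -> E).  Two low-pass spike traces y_I (presynaptic
inhibitory) and y_E (postsynaptic excitatory) share one time constant.  An
inhibitory spike changes its outgoing synapses by eta * (y_E - 2 r0 tau_y);
an excitatory spike changes its incoming inhibitory synapses by eta * y_I.
Only spike timing, not order, matters; the constant offset makes the rule
homeostatic with fixed point at the postsynaptic target rate r0.

Subtractive normalization.  Every ``norm_interval`` (20 ms) the deviation of
each E neuron's incoming E->E weight sum from its initial value is shared
equally across its N_i existing synapses and subtracted, then weights are
re-clipped to the hard bounds.  Row sums are conserved exactly whenever no
bound binds; clipping introduces a tolerated drift.

Within-step ordering (mirrored by the engine): decay accumulators, apply
weight updates for this step's spikes with pre-increment values (ties
between a neuron acting as pre and post in the same step are additive and
therefore order-free), increment accumulators, clip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Connectivity
from .params import PlasticityParams

__all__ = ["TripletState", "ISTDPState", "decay_triplet", "decay_istdp",
           "apply_triplet_estdp", "apply_istdp", "increment_triplet",
           "increment_istdp", "normalize_incoming_ee", "clip_weights"]


@dataclass
class TripletState:
    """Per-E-neuron accumulators of the triplet rule (dimensionless)."""

    r1: np.ndarray
    r2: np.ndarray
    o1: np.ndarray
    o2: np.ndarray

    @classmethod
    def zeros(cls, n_exc: int) -> "TripletState":
        return cls(*(np.zeros(n_exc) for _ in range(4)))


@dataclass
class ISTDPState:
    """Low-pass spike traces of the inhibitory rule."""

    y_E: np.ndarray   # per E neuron
    y_I: np.ndarray   # per I neuron

    @classmethod
    def zeros(cls, n_exc: int, n_inh: int) -> "ISTDPState":
        return cls(np.zeros(n_exc), np.zeros(n_inh))


def decay_triplet(state: TripletState, par: PlasticityParams, dt: float) -> None:
    state.r1 *= np.exp(-dt / par.tau_plus)
    state.r2 *= np.exp(-dt / par.tau_x)
    state.o1 *= np.exp(-dt / par.tau_minus)
    state.o2 *= np.exp(-dt / par.tau_y)


def decay_istdp(state: ISTDPState, par: PlasticityParams, dt: float) -> None:
    f = np.exp(-dt / par.tau_istdp)
    state.y_E *= f
    state.y_I *= f


def apply_triplet_estdp(w_ee: np.ndarray, mask_ee: np.ndarray,
                        state: TripletState, par: PlasticityParams,
                        pre_spikes: np.ndarray, post_spikes: np.ndarray) -> None:
    """Weight updates for one step's E spikes (accumulators already decayed).

    ``pre_spikes`` / ``post_spikes`` are index arrays into the E population;
    both roles are played by the same spiking neurons in a recurrent
    network.  Accumulators are *not* incremented here — call
    :func:`increment_triplet` afterwards.
    """
    for j in np.asarray(pre_spikes, dtype=np.int64).ravel():
        dep = par.a2_minus + par.a3_minus * state.r2[j]
        col = mask_ee[:, j]
        w_ee[col, j] -= state.o1[col] * dep
    for i in np.asarray(post_spikes, dtype=np.int64).ravel():
        row = mask_ee[i, :]
        w_ee[i, row] += state.r1[row] * (par.a2_plus
                                         + par.a3_plus * state.o2[i])


def increment_triplet(state: TripletState, spikes: np.ndarray) -> None:
    """Post-update accumulator increments for this step's E spikes."""
    idx = np.asarray(spikes, dtype=np.int64).ravel()
    state.r1[idx] += 1.0
    state.r2[idx] += 1.0
    state.o1[idx] += 1.0
    state.o2[idx] += 1.0


def apply_istdp(w_ei: np.ndarray, mask_ei: np.ndarray, state: ISTDPState,
                par: PlasticityParams, pre_spikes_I: np.ndarray,
                post_spikes_E: np.ndarray) -> None:
    """Weight updates for one step's spikes (traces already decayed)."""
    offset = par.istdp_offset
    for j in np.asarray(pre_spikes_I, dtype=np.int64).ravel():
        col = mask_ei[:, j]
        w_ei[col, j] += par.eta * (state.y_E[col] - offset)
    for i in np.asarray(post_spikes_E, dtype=np.int64).ravel():
        row = mask_ei[i, :]
        w_ei[i, row] += par.eta * state.y_I[row]


def increment_istdp(state: ISTDPState, spikes_I: np.ndarray,
                    spikes_E: np.ndarray) -> None:
    state.y_I[np.asarray(spikes_I, dtype=np.int64).ravel()] += 1.0
    state.y_E[np.asarray(spikes_E, dtype=np.int64).ravel()] += 1.0


def normalize_incoming_ee(w_ee: np.ndarray, conn: Connectivity,
                          j_min: float, j_max: float) -> None:
    """Subtractive normalization of each E neuron's incoming E->E weights.

    Subtracts (sum_j J_ij(t) - sum_j J_ij(0)) / N_i from every existing
    synapse onto neuron i, then re-clips to [j_min, j_max].  Neurons with
    no incoming E synapses are skipped.
    """
    n_in = conn.n_in_ee
    ok = n_in > 0
    sums = np.where(conn.m_ee, w_ee, 0.0).sum(axis=1)
    delta = np.zeros_like(sums)
    delta[ok] = (sums[ok] - conn.row_sums_ee_init[ok]) / n_in[ok]
    w_ee -= delta[:, None] * conn.m_ee
    clip_weights(w_ee, conn.m_ee, j_min, j_max)


def clip_weights(w: np.ndarray, mask: np.ndarray, j_min: float,
                 j_max: float) -> None:
    """Clamp existing synapses into [j_min, j_max]; absent entries untouched."""
    if j_min > j_max:
        raise ValueError("j_min must be <= j_max")
    np.clip(w, j_min, j_max, out=w, where=mask)
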