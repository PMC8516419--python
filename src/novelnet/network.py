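"""Random recurrent connectivity and stimulus-membership structure.

The network is a sparse Erdos–Renyi graph over two populations: every ordered
pair of distinct neurons is connected independently with probability
``p_conn``.  Four weight classes exist, stored post x pre in pF:

* ``w_ee`` (E -> E)  plastic under triplet eSTDP + subtractive normalization,
* ``w_ei`` (I -> E)  plastic under homeostatic iSTDP,
* ``w_ie`` (E -> I)  fixed,
* ``w_ii`` (I -> I)  fixed.

Stimuli are abstract: a stimulus is simply the subset of E and I neurons that
receive elevated Poisson drive whenever it is shown.  Membership draws are
independent per stimulus, so one neuron may belong to several stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import NetworkParams, StimulusParams, SynapseParams, substream

__all__ = ["Connectivity", "StimulusSet", "build_connectivity",
           "assign_memberships", "build_ssa_memberships"]


@dataclass
class Connectivity:
    """Weight matrices (post x pre), adjacency masks and normalization refs."""

    w_ee: np.ndarray          # (nE, nE) pF, plastic
    w_ei: np.ndarray          # (nE, nI) pF, plastic (I -> E)
    w_ie: np.ndarray          # (nI, nE) pF, fixed
    w_ii: np.ndarray          # (nI, nI) pF, fixed
    m_ee: np.ndarray          # boolean masks, same shapes
    m_ei: np.ndarray
    m_ie: np.ndarray
    m_ii: np.ndarray
    row_sums_ee_init: np.ndarray  # (nE,) E->E in-sum at construction, pF
    n_in_ee: np.ndarray           # (nE,) number of E->E synapses per post neuron

    @property
    def n_exc(self) -> int:
        return self.w_ee.shape[0]

    @property
    def n_inh(self) -> int:
        return self.w_ii.shape[0]

    def copy(self) -> "Connectivity":
        return Connectivity(
            self.w_ee.copy(), self.w_ei.copy(), self.w_ie.copy(),
            self.w_ii.copy(), self.m_ee.copy(), self.m_ei.copy(),
            self.m_ie.copy(), self.m_ii.copy(),
            self.row_sums_ee_init.copy(), self.n_in_ee.copy())


@dataclass
class StimulusSet:
    """Stimulus-id -> member-index maps for the E and I populations."""

    members_E: dict[int, np.ndarray] = field(default_factory=dict)
    members_I: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_stimuli(self) -> int:
        return len(self.members_E)

    def stimulus_ids(self) -> list[int]:
        return sorted(self.members_E)


def _mask(rng: np.random.Generator, n_post: int, n_pre: int, p: float,
          no_self: bool) -> np.ndarray:
    m = rng.random((n_post, n_pre)) < p
    if no_self:
        np.fill_diagonal(m, False)
    return m


def build_connectivity(net: NetworkParams, syn: SynapseParams,
                       seed: int) -> Connectivity:
    """Draw the random recurrent network and initialize all weights.

    Plastic classes start at their initial table values (``j0_EE``,
    ``j0_EI``); fixed classes at their constant weights.  The per-neuron
    E->E in-degree and initial incoming weight sum are recorded as the
    reference for subtractive normalization.  Pure function of
    (parameters, seed).
    """
    errs = net.validate() + syn.validate()
    if errs:
        raise ValueError("invalid parameters:\n  " + "\n  ".join(errs))
    rng = substream(seed, "connectivity")
    nE, nI = net.n_exc, net.n_inh
    # draw order is fixed so each class is reproducible
    m_ee = _mask(rng, nE, nE, syn.p_conn, no_self=True)
    m_ei = _mask(rng, nE, nI, syn.p_conn, no_self=False)
    m_ie = _mask(rng, nI, nE, syn.p_conn, no_self=False)
    m_ii = _mask(rng, nI, nI, syn.p_conn, no_self=True)
    w_ee = np.where(m_ee, syn.j0_EE, 0.0)
    w_ei = np.where(m_ei, syn.j0_EI, 0.0)
    w_ie = np.where(m_ie, syn.j_IE, 0.0)
    w_ii = np.where(m_ii, syn.j_II, 0.0)
    return Connectivity(
        w_ee=w_ee, w_ei=w_ei, w_ie=w_ie, w_ii=w_ii,
        m_ee=m_ee, m_ei=m_ei, m_ie=m_ie, m_ii=m_ii,
        row_sums_ee_init=w_ee.sum(axis=1),
        n_in_ee=m_ee.sum(axis=1).astype(np.int64),
    )


def assign_memberships(net: NetworkParams, stim: StimulusParams,
                       n_stimuli: int, seed: int) -> StimulusSet:
    """Draw stimulus membership independently per (stimulus, neuron).

    Each E neuron joins a given stimulus with probability ``p_member_E``
    (expected assembly size 0.05 * 4000 = 200 at defaults) and each I neuron
    with ``p_member_I`` (expected 150).  Overlaps across stimuli are allowed.
    """
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    rng = substream(seed, "membership")
    sset = StimulusSet()
    for s in range(n_stimuli):
        sset.members_E[s] = np.flatnonzero(
            rng.random(net.n_exc) < stim.p_member_E).astype(np.int64)
        sset.members_I[s] = np.flatnonzero(
            rng.random(net.n_inh) < stim.p_member_I).astype(np.int64)
    return sset


def build_ssa_memberships(net: NetworkParams, stim: StimulusParams,
                          overlap_I: float = 0.3, seed: int = 0) -> StimulusSet:
    """Membership structure of the oddball (SSA) paradigm.

    Stimuli A (id 0) and B (id 1) drive the *same* excitatory neurons (one
    shared draw at ``p_member_E``).  The inhibitory memberships are partially
    overlapping: each is marginally Bernoulli(``p_member_I``) while the
    expected shared fraction of their union equals ``overlap_I``.  This is
    realized per neuron with the trinomial (both, A-only, B-only, neither)
    where p_both = 2 * p * overlap_I / (1 + overlap_I).

    The default overlap of 0.3 keeps the deviant's recruited inhibition
    dominated by its own (unpotentiated) tuned pool: inhibitory neurons
    shared between A and B are both potentiated during the frequent
    stimulus and driven by the deviant, so large overlaps suppress the
    oddball response along with the adapted one.
    """
    if not 0.0 <= overlap_I <= 1.0:
        raise ValueError("overlap_I must lie in [0, 1]")
    rng = substream(seed, "membership")
    shared_E = np.flatnonzero(
        rng.random(net.n_exc) < stim.p_member_E).astype(np.int64)
    p = stim.p_member_I
    p_both = 2.0 * p * overlap_I / (1.0 + overlap_I)
    p_only = p - p_both
    u = rng.random(net.n_inh)
    both = u < p_both
    only_a = (u >= p_both) & (u < p_both + p_only)
    only_b = (u >= p_both + p_only) & (u < p_both + 2 * p_only)
    mem_a = np.flatnonzero(both | only_a).astype(np.int64)
    mem_b = np.flatnonzero(both | only_b).astype(np.int64)
    return StimulusSet(
        members_E={0: shared_E, 1: shared_E.copy()},
        members_I={0: mem_a, 1: mem_b},
    )
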