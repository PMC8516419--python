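"""The main simulation loop.

One forward-Euler step (dt = 0.1 ms) performs, in order:

1. exact-exponential decay of all conductance traces,
2. delivery of the *previous* step's network spikes (one-step causal delay)
   and of this step's external Poisson counts into the traces,
3. membrane integration (EIF for E, LIF for I) and spike detection,
4. plasticity: decay of accumulators, weight updates for this step's spikes
   using pre-increment accumulator values, accumulator increments, clipping
   of the touched rows/columns,
5. subtractive normalization on its 20 ms schedule,
6. spike recording.

Two backends implement the identical arithmetic: a numba-compiled serial
kernel (default) and a pure-numpy reference built from the
:mod:`~novelnet.dynamics` and :mod:`~novelnet.plasticity` module functions.
External Poisson counts are drawn chunk-wise in the driver from the "input"
random substream, so both backends consume the same randomness and a fixed
seed yields identical spike records per backend.

Memory stays bounded for long runs: spikes go to per-chunk buffers sized by
the refractory-period bound on the spike count, and weight snapshots store
the full I->E matrix plus scalar summaries of the E->E matrix (full E->E
snapshots are optional).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

log = logging.getLogger("novelnet.engine")

from . import dynamics, plasticity
from .network import Connectivity, StimulusSet
from .params import (AdaptiveCurrentParams, Config, NetworkParams,
                     PlasticityParams, StimulusParams, SimConfig,
                     SynapseParams, substream)
from .protocols import Protocol, compile_rates

__all__ = ["SpikeRecord", "WeightTrace", "SimResult", "run_simulation"]


@dataclass
class SpikeRecord:
    """Time-sorted spikes: (time ms, population 0=E/1=I, neuron index)."""

    t: np.ndarray          # float64 ms
    pop: np.ndarray        # int8, 0 = E, 1 = I
    idx: np.ndarray        # int32

    def __len__(self) -> int:
        return len(self.t)

    def population(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, indices) of one population ("E" or "I")."""
        sel = self.pop == (0 if which == "E" else 1)
        return self.t[sel], self.idx[sel]


@dataclass
class WeightTrace:
    """Weight snapshots on a fixed cadence."""

    times: np.ndarray               # ms, strictly increasing
    w_ei: np.ndarray                # (n_snap, nE, nI) full I->E matrices
    w_ee_mean: np.ndarray           # mean over existing E->E synapses, pF
    w_ei_mean: np.ndarray           # mean over existing I->E synapses, pF
    w_ee: np.ndarray | None = None  # optional full E->E snapshots


@dataclass
class SimResult:
    spikes: SpikeRecord
    weights: WeightTrace
    conn: Connectivity              # final weights (input Connectivity is not mutated)
    duration: float                 # ms simulated
    config: Config = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------


@njit(cache=False)
def _run_chunk(n_steps, dt, step0,
               vE, vI, refE, refI, wad,
               xEe_d, xEe_r, xEi_d, xEi_r,
               xIe_d, xIe_r, xIi_d, xIi_r,
               r1, r2, o1, o2, yE, yI,
               prevE, prevI,
               w_ee, w_ei, w_ie, w_ii,
               m_ee, m_ei, m_ie, m_ii,
               row0, n_in,
               extE, extI,
               gL, C, vrestE, vrestI, DT, VT, vpeak, vthr, vreset,
               vrevE, vrevI, refr_len,
               dEd, dEr, dId, dIr, invE, invI, j_eex, j_iex,
               f_r1, f_r2, f_o1, f_o2, f_y,
               a2p, a3p, a2m, a3m, eta, alpha,
               jminEE, jmaxEE, jminEI, jmaxEI,
               aw, bw, tauw,
               triplet_on, istdp_on, norm_on, adapt_on,
               norm_every,
               spk_step, spk_pop, spk_idx):
    nE = vE.shape[0]
    nI = vI.shape[0]
    n_spk = 0
    sE = np.empty(nE, dtype=np.int64)
    sI = np.empty(nI, dtype=np.int64)
    for t in range(n_steps):
        # 1. decay conductance traces
        for i in range(nE):
            xEe_d[i] *= dEd
            xEe_r[i] *= dEr
            xEi_d[i] *= dId
            xEi_r[i] *= dIr
        for i in range(nI):
            xIe_d[i] *= dEd
            xIe_r[i] *= dEr
            xIi_d[i] *= dId
            xIi_r[i] *= dIr
        # 2. deliver previous step's network spikes and this step's external input
        for j in range(nE):
            if prevE[j]:
                for i in range(nE):
                    if m_ee[i, j]:
                        inc = w_ee[i, j] * invE
                        xEe_d[i] += inc
                        xEe_r[i] += inc
                for i in range(nI):
                    if m_ie[i, j]:
                        inc = w_ie[i, j] * invE
                        xIe_d[i] += inc
                        xIe_r[i] += inc
        for j in range(nI):
            if prevI[j]:
                for i in range(nE):
                    if m_ei[i, j]:
                        inc = w_ei[i, j] * invI
                        xEi_d[i] += inc
                        xEi_r[i] += inc
                for i in range(nI):
                    if m_ii[i, j]:
                        inc = w_ii[i, j] * invI
                        xIi_d[i] += inc
                        xIi_r[i] += inc
        for i in range(nE):
            c = extE[t, i]
            if c > 0:
                inc = c * j_eex * invE
                xEe_d[i] += inc
                xEe_r[i] += inc
        for i in range(nI):
            c = extI[t, i]
            if c > 0:
                inc = c * j_iex * invE
                xIe_d[i] += inc
                xIe_r[i] += inc
        # 3. membranes
        nsE = 0
        for i in range(nE):
            v = vE[i]
            if adapt_on:
                w_new = wad[i] + dt * (-wad[i] + aw * (v - vrestE)) / tauw
            if refE[i] > 0:
                refE[i] -= 1
                vE[i] = vreset
            else:
                gE = xEe_d[i] - xEe_r[i]
                gI = xEi_d[i] - xEi_r[i]
                cur = (-gL * (v - vrestE)
                       + gL * DT * np.exp((v - VT) / DT)
                       - gE * (v - vrevE) - gI * (v - vrevI))
                if adapt_on:
                    cur -= wad[i]
                v = v + dt * cur / C
                if v != v:  # NaN
                    return n_spk, step0 + t, i, 0
                if v >= vpeak:
                    vE[i] = vreset
                    refE[i] = refr_len
                    sE[nsE] = i
                    nsE += 1
                    if adapt_on:
                        w_new += bw
                else:
                    vE[i] = v
            if adapt_on:
                wad[i] = w_new
        nsI = 0
        for i in range(nI):
            if refI[i] > 0:
                refI[i] -= 1
                vI[i] = vreset
            else:
                v = vI[i]
                gE = xIe_d[i] - xIe_r[i]
                gI = xIi_d[i] - xIi_r[i]
                cur = (-gL * (v - vrestI)
                       - gE * (v - vrevE) - gI * (v - vrevI))
                v = v + dt * cur / C
                if v != v:
                    return n_spk, step0 + t, i, 1
                if v >= vthr:
                    vI[i] = vreset
                    refI[i] = refr_len
                    sI[nsI] = i
                    nsI += 1
                else:
                    vI[i] = v
        # 4. record spikes
        if n_spk + nsE + nsI > spk_step.shape[0]:
            return n_spk, step0 + t, -1, -2  # buffer overflow (cannot happen
            # with the refractory-bound capacity, kept as a guard)
        for k in range(nsE):
            spk_step[n_spk] = step0 + t
            spk_pop[n_spk] = 0
            spk_idx[n_spk] = sE[k]
            n_spk += 1
        for k in range(nsI):
            spk_step[n_spk] = step0 + t
            spk_pop[n_spk] = 1
            spk_idx[n_spk] = sI[k]
            n_spk += 1
        # 5. plasticity: decay -> update (pre-increment values) -> increment -> clip
        if triplet_on:
            for i in range(nE):
                r1[i] *= f_r1
                r2[i] *= f_r2
                o1[i] *= f_o1
                o2[i] *= f_o2
            for k in range(nsE):
                j = sE[k]
                dep = a2m + a3m * r2[j]
                for i in range(nE):
                    if m_ee[i, j]:
                        w_ee[i, j] -= o1[i] * dep
            for k in range(nsE):
                i = sE[k]
                pot = a2p + a3p * o2[i]
                for j in range(nE):
                    if m_ee[i, j]:
                        w_ee[i, j] += r1[j] * pot
            for k in range(nsE):
                i = sE[k]
                r1[i] += 1.0
                r2[i] += 1.0
                o1[i] += 1.0
                o2[i] += 1.0
            for k in range(nsE):
                j = sE[k]
                for i in range(nE):
                    if m_ee[i, j]:
                        w = w_ee[i, j]
                        if w < jminEE:
                            w_ee[i, j] = jminEE
                        elif w > jmaxEE:
                            w_ee[i, j] = jmaxEE
                for jj in range(nE):
                    if m_ee[j, jj]:
                        w = w_ee[j, jj]
                        if w < jminEE:
                            w_ee[j, jj] = jminEE
                        elif w > jmaxEE:
                            w_ee[j, jj] = jmaxEE
        if istdp_on:
            for i in range(nE):
                yE[i] *= f_y
            for j in range(nI):
                yI[j] *= f_y
            for k in range(nsI):
                j = sI[k]
                for i in range(nE):
                    if m_ei[i, j]:
                        w_ei[i, j] += eta * (yE[i] - alpha)
            for k in range(nsE):
                i = sE[k]
                for j in range(nI):
                    if m_ei[i, j]:
                        w_ei[i, j] += eta * yI[j]
            for k in range(nsI):
                yI[sI[k]] += 1.0
            for k in range(nsE):
                yE[sE[k]] += 1.0
            for k in range(nsI):
                j = sI[k]
                for i in range(nE):
                    if m_ei[i, j]:
                        w = w_ei[i, j]
                        if w < jminEI:
                            w_ei[i, j] = jminEI
                        elif w > jmaxEI:
                            w_ei[i, j] = jmaxEI
            for k in range(nsE):
                i = sE[k]
                for j in range(nI):
                    if m_ei[i, j]:
                        w = w_ei[i, j]
                        if w < jminEI:
                            w_ei[i, j] = jminEI
                        elif w > jmaxEI:
                            w_ei[i, j] = jmaxEI
        # 6. subtractive normalization every norm_every steps
        if norm_on and (step0 + t + 1) % norm_every == 0:
            for i in range(nE):
                if n_in[i] > 0:
                    s = 0.0
                    for j in range(nE):
                        if m_ee[i, j]:
                            s += w_ee[i, j]
                    d = (s - row0[i]) / n_in[i]
                    for j in range(nE):
                        if m_ee[i, j]:
                            w = w_ee[i, j] - d
                            if w < jminEE:
                                w = jminEE
                            elif w > jmaxEE:
                                w = jmaxEE
                            w_ee[i, j] = w
        # 7. hand spikes to the next step's conductance update
        for i in range(nE):
            prevE[i] = False
        for k in range(nsE):
            prevE[sE[k]] = True
        for i in range(nI):
            prevI[i] = False
        for k in range(nsI):
            prevI[sI[k]] = True
    return n_spk, -1, -1, -1


# ---------------------------------------------------------------------------
# numpy reference backend (serial reference mode)
# ---------------------------------------------------------------------------


class _NumpyStepper:
    """Readable per-step reference built on the dynamics/plasticity modules."""

    def __init__(self, conn: Connectivity, net: NetworkParams,
                 syn: SynapseParams, plast: PlasticityParams,
                 adapt: AdaptiveCurrentParams, cfg: SimConfig,
                 check_conservation: bool):
        nE, nI = conn.n_exc, conn.n_inh
        self.conn, self.net, self.syn = conn, net, syn
        self.plast, self.adapt, self.cfg = plast, adapt, cfg
        self.check = check_conservation
        self.stateE = dynamics.NeuronState.at_rest(nE, net.v_rest_E,
                                                   with_adapt=True)
        self.stateI = dynamics.NeuronState.at_rest(nI, net.v_rest_I)
        self.gEe = dynamics.ConductanceState.zeros(nE, syn.tau_rise_E, syn.tau_decay_E)
        self.gEi = dynamics.ConductanceState.zeros(nE, syn.tau_rise_I, syn.tau_decay_I)
        self.gIe = dynamics.ConductanceState.zeros(nI, syn.tau_rise_E, syn.tau_decay_E)
        self.gIi = dynamics.ConductanceState.zeros(nI, syn.tau_rise_I, syn.tau_decay_I)
        self.trip = plasticity.TripletState.zeros(nE)
        self.istdp = plasticity.ISTDPState.zeros(nE, nI)
        self.prevE = np.zeros(nE, dtype=bool)
        self.prevI = np.zeros(nI, dtype=bool)
        self.norm_every = max(1, int(round(plast.norm_interval / cfg.dt)))

    def step(self, global_step: int, extE: np.ndarray, extI: np.ndarray):
        conn, net, syn, plast, cfg = (self.conn, self.net, self.syn,
                                      self.plast, self.cfg)
        dt = cfg.dt
        in_E = conn.w_ee @ self.prevE + syn.j_EEx * extE
        in_I_onto_E = conn.w_ei @ self.prevI
        in_E_onto_I = conn.w_ie @ self.prevE + syn.j_IEx * extI
        in_I_onto_I = conn.w_ii @ self.prevI
        self.gEe.step(in_E, dt)
        self.gEi.step(in_I_onto_E, dt)
        self.gIe.step(in_E_onto_I, dt)
        self.gIi.step(in_I_onto_I, dt)
        spkE = dynamics.step_membranes(self.stateE, self.gEe.g, self.gEi.g,
                                       net, "E", dt, self.adapt)
        spkI = dynamics.step_membranes(self.stateI, self.gIe.g, self.gIi.g,
                                       net, "I", dt)
        idxE = np.flatnonzero(spkE)
        idxI = np.flatnonzero(spkI)
        if cfg.triplet_on:
            plasticity.decay_triplet(self.trip, plast, dt)
            plasticity.apply_triplet_estdp(conn.w_ee, conn.m_ee, self.trip,
                                           plast, idxE, idxE)
            plasticity.increment_triplet(self.trip, idxE)
            plasticity.clip_weights(conn.w_ee, conn.m_ee, syn.j_min_EE,
                                    syn.j_max_EE)
        if cfg.istdp_on:
            plasticity.decay_istdp(self.istdp, plast, dt)
            plasticity.apply_istdp(conn.w_ei, conn.m_ei, self.istdp, plast,
                                   idxI, idxE)
            plasticity.increment_istdp(self.istdp, idxI, idxE)
            plasticity.clip_weights(conn.w_ei, conn.m_ei, syn.j_min_EI,
                                    syn.j_max_EI)
        if cfg.normalization_on and (global_step + 1) % self.norm_every == 0:
            if self.check:
                before = np.where(conn.m_ee, conn.w_ee, 0.0).sum(axis=1)
            plasticity.normalize_incoming_ee(conn.w_ee, conn,
                                             syn.j_min_EE, syn.j_max_EE)
            if self.check:
                after = np.where(conn.m_ee, conn.w_ee, 0.0).sum(axis=1)
                at_bound = (np.isclose(conn.w_ee, syn.j_min_EE)
                            | np.isclose(conn.w_ee, syn.j_max_EE)) & conn.m_ee
                free = ~at_bound.any(axis=1) & (conn.n_in_ee > 0)
                drift = np.abs(after - conn.row_sums_ee_init)[free]
                if drift.size and drift.max() >= 1e-9:
                    raise AssertionError(
                        f"normalization failed to conserve a clip-free row "
                        f"sum (max drift {drift.max():.3e} pF) at step "
                        f"{global_step}")
        self.prevE = spkE
        self.prevI = spkI
        return idxE, idxI


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def run_simulation(conn: Connectivity, stimset: StimulusSet,
                   protocol: Protocol, config: Config,
                   duration: float | None = None,
                   store_w_ee_full: bool = False,
                   check_conservation: bool = False) -> SimResult:
    """Simulate the network under a stimulation protocol.

    ``config`` is the parameter bundle dict produced by
    :func:`novelnet.params.default_config` / ``load_config`` (keys
    ``network``, ``synapse``, ``stimulus``, ``plasticity``, ``adaptation``,
    ``sim``).  The input ``conn`` is copied; final weights are returned in
    ``SimResult.conn``.  Identical inputs and seed give identical outputs
    for a given backend.

    ``check_conservation`` asserts the normalization row-sum invariant at
    every normalization event and requires the numpy backend.
    """
    net: NetworkParams = config["network"]
    syn: SynapseParams = config["synapse"]
    stim: StimulusParams = config["stimulus"]
    plast: PlasticityParams = config["plasticity"]
    adapt: AdaptiveCurrentParams = config["adaptation"]
    cfg: SimConfig = config["sim"]
    errs = sum((b.validate() for b in (net, syn, stim, plast, adapt, cfg)), [])
    if errs:
        raise ValueError("invalid parameters:\n  " + "\n  ".join(errs))
    if check_conservation and cfg.backend != "numpy":
        raise ValueError("check_conservation requires the numpy backend")
    if conn.n_exc != net.n_exc or conn.n_inh != net.n_inh:
        raise ValueError("Connectivity shape disagrees with NetworkParams")

    conn = conn.copy()
    import dataclasses as _dc
    adapt = _dc.replace(adapt,
                        enabled=bool(adapt.enabled or cfg.adaptive_current_on))
    dt = cfg.dt
    if not protocol.epochs:
        raise ValueError("protocol has no epochs")
    if duration is None:
        duration = cfg.duration if cfg.duration > 0 else protocol.duration
    n_steps = int(round(duration / dt))
    rates_E, rates_I, bounds = compile_rates(protocol, stimset, net.n_exc,
                                             net.n_inh, syn, stim)
    if protocol.duration < duration - 1e-9:
        raise ValueError("protocol shorter than the requested duration")

    step_t = np.arange(n_steps) * dt
    ep_idx = np.clip(np.searchsorted(bounds, step_t, side="right") - 1,
                     0, len(rates_E) - 1).astype(np.int64)
    lamE_all = rates_E * dt
    lamI_all = rates_I * dt

    rng = substream(cfg.seed, "input")
    nE, nI = net.n_exc, net.n_inh
    refr_len = int(round(net.tau_refr / dt))
    norm_every = max(1, int(round(plast.norm_interval / dt)))
    snap_every = max(1, int(round(cfg.weight_snapshot_ms / dt)))

    # snapshot bookkeeping
    snap_times, snap_wei, snap_wee_mean, snap_wei_mean = [], [], [], []
    snap_wee_full = [] if store_w_ee_full else None

    def take_snapshot(step: int):
        snap_times.append(step * dt)
        snap_wei.append(conn.w_ei.copy())
        snap_wee_mean.append(float(conn.w_ee[conn.m_ee].mean())
                             if conn.m_ee.any() else 0.0)
        snap_wei_mean.append(float(conn.w_ei[conn.m_ei].mean())
                             if conn.m_ei.any() else 0.0)
        if snap_wee_full is not None:
            snap_wee_full.append(conn.w_ee.copy())

    spk_t_parts, spk_pop_parts, spk_idx_parts = [], [], []

    # chunk boundaries land on every snapshot time so snapshots always see
    # the state at their nominal step; identical partitioning in both
    # backends keeps the external Poisson draw sequence identical too
    chunk_bounds = [0]
    while chunk_bounds[-1] < n_steps:
        k0 = chunk_bounds[-1]
        k1 = min(k0 + cfg.chunk_steps, (k0 // snap_every + 1) * snap_every,
                 n_steps)
        chunk_bounds.append(k1)

    if cfg.backend == "numpy":
        stepper = _NumpyStepper(conn, net, syn, plast, adapt, cfg,
                                check_conservation)
        take_snapshot(0)
        for k0, k1 in zip(chunk_bounds, chunk_bounds[1:]):
            extE = rng.poisson(lamE_all[ep_idx[k0:k1]])
            extI = rng.poisson(lamI_all[ep_idx[k0:k1]])
            for k in range(k0, k1):
                idxE, idxI = stepper.step(k, extE[k - k0], extI[k - k0])
                for pop, idx in ((0, idxE), (1, idxI)):
                    if len(idx):
                        spk_t_parts.append(np.full(len(idx), k * dt))
                        spk_pop_parts.append(np.full(len(idx), pop, dtype=np.int8))
                        spk_idx_parts.append(idx.astype(np.int32))
            if k1 % snap_every == 0:
                take_snapshot(k1)
    else:
        state = _KernelState(conn, net, adapt)
        cap = ((cfg.chunk_steps // max(refr_len, 1)) + 2) * (nE + nI)
        spk_step = np.empty(cap, dtype=np.int64)
        spk_pop = np.empty(cap, dtype=np.int8)
        spk_idx = np.empty(cap, dtype=np.int32)
        take_snapshot(0)
        for k0, k1 in zip(chunk_bounds, chunk_bounds[1:]):
            extE = rng.poisson(lamE_all[ep_idx[k0:k1]]).astype(np.int16)
            extI = rng.poisson(lamI_all[ep_idx[k0:k1]]).astype(np.int16)
            n_spk, err_step, err_neuron, err_pop = _run_chunk(
                k1 - k0, dt, k0,
                state.vE, state.vI, state.refE, state.refI, state.wad,
                state.xEe_d, state.xEe_r, state.xEi_d, state.xEi_r,
                state.xIe_d, state.xIe_r, state.xIi_d, state.xIi_r,
                state.r1, state.r2, state.o1, state.o2, state.yE, state.yI,
                state.prevE, state.prevI,
                conn.w_ee, conn.w_ei, conn.w_ie, conn.w_ii,
                conn.m_ee, conn.m_ei, conn.m_ie, conn.m_ii,
                conn.row_sums_ee_init, conn.n_in_ee,
                extE, extI,
                net.g_leak, net.capacitance, net.v_rest_E, net.v_rest_I,
                net.delta_T, net.v_thr, net.v_peak, net.v_thr, net.v_reset,
                net.v_rev_E, net.v_rev_I, refr_len,
                np.exp(-dt / syn.tau_decay_E), np.exp(-dt / syn.tau_rise_E),
                np.exp(-dt / syn.tau_decay_I), np.exp(-dt / syn.tau_rise_I),
                1.0 / (syn.tau_decay_E - syn.tau_rise_E),
                1.0 / (syn.tau_decay_I - syn.tau_rise_I),
                syn.j_EEx, syn.j_IEx,
                np.exp(-dt / plast.tau_plus), np.exp(-dt / plast.tau_x),
                np.exp(-dt / plast.tau_minus), np.exp(-dt / plast.tau_y),
                np.exp(-dt / plast.tau_istdp),
                plast.a2_plus, plast.a3_plus, plast.a2_minus, plast.a3_minus,
                plast.eta, plast.istdp_offset,
                syn.j_min_EE, syn.j_max_EE, syn.j_min_EI, syn.j_max_EI,
                adapt.a_w, adapt.b_w, adapt.tau_w,
                cfg.triplet_on, cfg.istdp_on, cfg.normalization_on,
                bool(adapt.enabled or cfg.adaptive_current_on),
                norm_every,
                spk_step, spk_pop, spk_idx)
            if err_pop == -2:
                raise RuntimeError(f"spike buffer overflow at step {err_step}")
            if err_pop >= 0:
                pop = "E" if err_pop == 0 else "I"
                raise FloatingPointError(
                    f"membrane potential diverged (NaN) at step {err_step} "
                    f"(t = {err_step * dt:.1f} ms) for {pop} neuron "
                    f"{err_neuron}; dt too large")
            if n_spk:
                spk_t_parts.append(spk_step[:n_spk] * dt)
                spk_pop_parts.append(spk_pop[:n_spk].copy())
                spk_idx_parts.append(spk_idx[:n_spk].copy())
                e_rate = (spk_pop[:n_spk] == 0).sum() / nE \
                    / ((k1 - k0) * dt * 1e-3)
                log.info("t = %.1f s / %.1f s, running E rate %.2f Hz",
                         k1 * dt / 1000.0, n_steps * dt / 1000.0, e_rate)
            if k1 % snap_every == 0:
                take_snapshot(k1)

    spikes = SpikeRecord(
        t=np.concatenate(spk_t_parts) if spk_t_parts else np.empty(0),
        pop=np.concatenate(spk_pop_parts) if spk_pop_parts else
        np.empty(0, dtype=np.int8),
        idx=np.concatenate(spk_idx_parts) if spk_idx_parts else
        np.empty(0, dtype=np.int32),
    )
    weights = WeightTrace(
        times=np.asarray(snap_times),
        w_ei=np.stack(snap_wei) if snap_wei else np.empty((0, nE, nI)),
        w_ee_mean=np.asarray(snap_wee_mean),
        w_ei_mean=np.asarray(snap_wei_mean),
        w_ee=np.stack(snap_wee_full) if snap_wee_full else None,
    )
    return SimResult(spikes=spikes, weights=weights, conn=conn,
                     duration=n_steps * dt, config=config)


class _KernelState:
    """Flat per-neuron state arrays for the compiled kernel."""

    def __init__(self, conn: Connectivity, net: NetworkParams,
                 adapt: AdaptiveCurrentParams):
        nE, nI = conn.n_exc, conn.n_inh
        self.vE = np.full(nE, net.v_rest_E)
        self.vI = np.full(nI, net.v_rest_I)
        self.refE = np.zeros(nE, dtype=np.int64)
        self.refI = np.zeros(nI, dtype=np.int64)
        self.wad = np.zeros(nE)
        for name in ("xEe_d", "xEe_r", "xEi_d", "xEi_r"):
            setattr(self, name, np.zeros(nE))
        for name in ("xIe_d", "xIe_r", "xIi_d", "xIi_r"):
            setattr(self, name, np.zeros(nI))
        for name in ("r1", "r2", "o1", "o2", "yE"):
            setattr(self, name, np.zeros(nE))
        self.yI = np.zeros(nI)
        self.prevE = np.zeros(nE, dtype=np.bool_)
        self.prevI = np.zeros(nI, dtype=np.bool_)
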