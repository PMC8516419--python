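"""Stimulation timelines: pretraining, sequence blocks, oddball, disinhibition.

A protocol is pure data — a time-ordered list of epochs, each assigning extra
Poisson drive to the neurons tuned to one stimulus (and, optionally, an
inhibition of the inhibitory population modelling top-down disinhibition of
the excitatory network).  The engine compiles a protocol plus a
:class:`~novelnet.network.StimulusSet` into per-epoch external-rate vectors.

Paradigms
---------
* **Pretraining** — every stimulus repeated ``n_reps`` times in random order,
  300 ms each, no pauses; imprints assemblies and tuned inhibition before the
  actual stimulation phase.
* **Sequence paradigm** — blocks of ``n_reps`` contiguous repetitions of a
  short stimulus sequence (e.g. ABC); in the second-to-last repetition the
  last stimulus is replaced by a novel one (standard), swapped with its
  neighbour (swap control), or the whole block is order-shuffled under a
  no-immediate-repeat constraint (shuffle control).  Blocks follow each other
  without interruption; a multi-round block order re-randomizes the block
  sequence per round (the repeated-sequence paradigm).
* **Oddball / SSA** — one stimulus A presented ``n_reps`` times separated by
  pauses, with the deviant B in the second-to-last slot, optionally paired
  with disinhibition.

Epoch tags (``pretraining``, ``onset``, ``repeat``, ``novel``, ``swap``,
``pause``, ``blank``) plus block / repetition / slot coordinates are what the
analysis module keys on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .network import StimulusSet
from .params import StimulusParams, SynapseParams, substream

__all__ = ["StimulusEpoch", "Protocol", "make_pretraining",
           "make_sequence_paradigm", "make_ssa_paradigm", "external_rate"]


@dataclass
class StimulusEpoch:
    """One homogeneous slice of the stimulation timeline."""

    t_start: float                 # ms
    t_end: float                   # ms
    stimulus: int | None = None    # None: blank / pause
    drive_scale_E: float = 1.0     # fraction of r_stim_E for E members
    disinhibition_scale: float = 0.0  # fraction of |r_disinh_I| onto all I
    tag: str = "repeat"
    block: int = -1                # block index; -1 outside blocks
    rep: int = -1                  # sequence repetition within the block
    slot: int = -1                 # stimulus slot within the repetition
    round: int = 0                 # presentation round of the block

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def __post_init__(self):
        if self.t_start >= self.t_end:
            raise ValueError("epoch requires t_start < t_end")
        if self.drive_scale_E < 0 or self.disinhibition_scale < 0:
            raise ValueError("epoch scales must be >= 0")


@dataclass
class Protocol:
    """Time-ordered, non-overlapping epochs."""

    epochs: list[StimulusEpoch] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.epochs[-1].t_end if self.epochs else 0.0

    def stimulus_ids(self) -> list[int]:
        return sorted({e.stimulus for e in self.epochs if e.stimulus is not None})

    def blocks(self) -> list[int]:
        return sorted({e.block for e in self.epochs if e.block >= 0})

    def block_epochs(self, block: int) -> list[StimulusEpoch]:
        return [e for e in self.epochs if e.block == block]

    def tagged(self, tag: str, block: int | None = None) -> list[StimulusEpoch]:
        return [e for e in self.epochs
                if e.tag == tag and (block is None or e.block == block)]

    def epoch_at(self, t: float) -> StimulusEpoch:
        for e in self.epochs:
            if e.t_start <= t < e.t_end:
                return e
        raise ValueError(f"t={t} ms outside the protocol span")

    def shift(self, offset: float) -> "Protocol":
        """A copy with all epoch times translated by ``offset`` ms."""
        out = []
        for e in self.epochs:
            d = asdict(e)
            d["t_start"] += offset
            d["t_end"] += offset
            out.append(StimulusEpoch(**d))
        return Protocol(out)

    def concat(self, other: "Protocol") -> "Protocol":
        """This protocol followed immediately by ``other``."""
        return Protocol(self.epochs + other.shift(self.duration).epochs)

    def validate(self) -> None:
        for a, b in zip(self.epochs, self.epochs[1:]):
            if b.t_start < a.t_end - 1e-9:
                raise ValueError("epochs overlap")
            if b.t_start > a.t_end + 1e-9:
                raise ValueError("gap between epochs; insert an explicit "
                                 "pause/blank epoch")

    # -- YAML serialization -------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {"epochs": [asdict(e) for e in self.epochs]}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Protocol":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls([StimulusEpoch(**e) for e in doc["epochs"]])


# ---------------------------------------------------------------------------
# paradigm constructors
# ---------------------------------------------------------------------------


def make_pretraining(n_stimuli: int, n_reps: int, stim: StimulusParams,
                     seed: int, t_start: float = 0.0) -> Protocol:
    """Random-order presentation of every stimulus, ``n_reps`` times each.

    Zero repetitions (or zero stimuli) yields an empty protocol — the
    no-pretraining control.
    """
    if n_stimuli < 0 or n_reps < 0:
        raise ValueError("n_stimuli and n_reps must be >= 0")
    order = np.repeat(np.arange(n_stimuli), n_reps)
    substream(seed, "protocol").shuffle(order)
    epochs, t = [], t_start
    for s in order:
        epochs.append(StimulusEpoch(t, t + stim.stim_duration, int(s),
                                    tag="pretraining"))
        t += stim.stim_duration
    return Protocol(epochs)


def _shuffled_order(base: list[int], n_reps: int,
                    rng: np.random.Generator) -> list[list[int]]:
    """Per-repetition re-draws of the stimulus order, no immediate repeats.

    Preserves the multiset of stimuli within every repetition, so the
    distribution of presented stimuli is identical to the periodic case.
    """
    if len(set(base)) < 2:
        raise ValueError("shuffle variant needs >= 2 distinct stimuli")
    orders, prev_last = [], None
    for _ in range(n_reps):
        while True:
            cand = list(rng.permutation(base))
            if any(a == b for a, b in zip(cand, cand[1:])):
                continue
            if prev_last is not None and cand[0] == prev_last:
                continue
            break
        orders.append([int(x) for x in cand])
        prev_last = cand[-1]
    return orders


def make_sequence_paradigm(seq_stimuli: list[list[int]],
                           n_reps: int | list[int],
                           novel_stimuli: list[int | None],
                           variant: str | list[str] = "standard",
                           novel_drive_scale: float | list[float] = 1.0,
                           block_rounds: int = 1,
                           seed: int = 0,
                           stim: StimulusParams | None = None) -> Protocol:
    """Sequence blocks with a novelty manipulation in the second-to-last rep.

    Parameters
    ----------
    seq_stimuli : one stimulus-id list per block (the block's sequence).
    n_reps : repetitions per block (scalar or per-block; each >= 2).
    novel_stimuli : the novel id per block (ignored by the swap variant).
    variant : "standard" (novel replaces the last slot), "swap" (last two
        slots exchanged, no novel stimulus) or "shuffle" (standard novelty on
        a per-repetition re-shuffled order); scalar or per-block.
    novel_drive_scale : fraction of the full stimulus drive given to the
        novel stimulus (the graded-drive experiments); scalar or per-block.
    block_rounds : number of rounds; each round presents every block once in
        a freshly randomized order (the repeated-sequence paradigm).  One
        round preserves the given block order (the unique-sequence paradigm).
    """
    stim = stim or StimulusParams()
    n_blocks = len(seq_stimuli)
    reps = [n_reps] * n_blocks if np.isscalar(n_reps) else list(n_reps)
    variants = [variant] * n_blocks if isinstance(variant, str) else list(variant)
    drives = ([novel_drive_scale] * n_blocks if np.isscalar(novel_drive_scale)
              else list(novel_drive_scale))
    if not (len(reps) == len(variants) == len(novel_stimuli)
            == len(drives) == n_blocks):
        raise ValueError("per-block argument lengths disagree")
    for seq, r, var in zip(seq_stimuli, reps, variants):
        if len(seq) < 2:
            raise ValueError("sequence length must be >= 2")
        if r < 2:
            raise ValueError("n_reps must be >= 2")
        if var not in ("standard", "swap", "shuffle"):
            raise ValueError(f"unknown variant {var!r}")
    rng = substream(seed, "protocol")

    block_order: list[tuple[int, int]] = []
    for rnd in range(block_rounds):
        order = np.arange(n_blocks)
        if block_rounds > 1:
            rng.shuffle(order)
        block_order.extend((int(b), rnd) for b in order)

    epochs, t = [], 0.0
    dur = stim.stim_duration
    for b, rnd in block_order:
        seq, r, var, novel = seq_stimuli[b], reps[b], variants[b], novel_stimuli[b]
        L = len(seq)
        if var == "shuffle":
            rep_orders = _shuffled_order(list(seq), r, rng)
        else:
            rep_orders = [list(seq) for _ in range(r)]
        for rep in range(r):
            order = list(rep_orders[rep])
            scales = [1.0] * L
            tags = ["onset" if rep == 0 else "repeat"] * L
            if rep == r - 2:
                if var == "swap":
                    order[-1], order[-2] = order[-2], order[-1]
                    tags[-1] = tags[-2] = "swap"
                else:
                    if novel is None:
                        raise ValueError("standard/shuffle blocks need a "
                                         "novel stimulus id")
                    order[-1] = novel
                    scales[-1] = drives[b]
                    tags[-1] = "novel"
            for slot, (s, sc, tag) in enumerate(zip(order, scales, tags)):
                epochs.append(StimulusEpoch(t, t + dur, int(s),
                                            drive_scale_E=sc, tag=tag,
                                            block=b, rep=rep, slot=slot,
                                            round=rnd))
                t += dur
    return Protocol(epochs)


def make_ssa_paradigm(n_reps: int = 20, pause: float = 300.0,
                      oddball_position: int | None = None,
                      disinhibition_scale: float = 0.0,
                      stim: StimulusParams | None = None,
                      frequent: int = 0, deviant: int = 1) -> Protocol:
    """Oddball paradigm: A repeated with pauses, B in the oddball slot.

    ``oddball_position`` defaults to the second-to-last slot.  A positive
    ``disinhibition_scale`` suppresses the whole inhibitory population by
    that fraction of |r_disinh_I| during the oddball epoch only.
    """
    stim = stim or StimulusParams()
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    pos = n_reps - 2 if oddball_position is None else oddball_position
    if not 0 <= pos < n_reps:
        raise ValueError("oddball_position out of range")
    epochs, t = [], 0.0
    dur = stim.stim_duration
    for k in range(n_reps):
        odd = k == pos
        epochs.append(StimulusEpoch(
            t, t + dur,
            deviant if odd else frequent,
            disinhibition_scale=disinhibition_scale if odd else 0.0,
            tag="novel" if odd else ("onset" if k == 0 else "repeat"),
            block=0, rep=k, slot=0))
        t += dur
        if pause > 0 and k < n_reps - 1:
            epochs.append(StimulusEpoch(t, t + pause, None, tag="pause",
                                        block=0, rep=k, slot=1))
            t += pause
    return Protocol(epochs)


# ---------------------------------------------------------------------------
# rate lookup / compilation
# ---------------------------------------------------------------------------


def external_rate(protocol: Protocol, stimset: StimulusSet,
                  population: str, index: int, t: float,
                  syn: SynapseParams | None = None,
                  stim: StimulusParams | None = None) -> float:
    """External Poisson rate (kHz) seen by one neuron at time t.

    Baseline plus tuned stimulus drive for members of the active stimulus,
    minus the disinhibition reduction for inhibitory neurons; floored at 0.
    """
    syn = syn or SynapseParams()
    stim = stim or StimulusParams()
    ep = protocol.epoch_at(t)
    if population == "E":
        rate = syn.r_ext_E
        if ep.stimulus is not None and index in stimset.members_E.get(ep.stimulus, ()):
            rate += stim.r_stim_E * ep.drive_scale_E
    elif population == "I":
        rate = syn.r_ext_I
        if ep.stimulus is not None and index in stimset.members_I.get(ep.stimulus, ()):
            rate += stim.r_stim_I
        rate -= ep.disinhibition_scale * abs(stim.r_disinh_I)
    else:
        raise ValueError("population must be 'E' or 'I'")
    return max(rate, 0.0)


def compile_rates(protocol: Protocol, stimset: StimulusSet, n_exc: int,
                  n_inh: int, syn: SynapseParams,
                  stim: StimulusParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-epoch external-rate vectors for the engine.

    Returns ``(rates_E (n_epochs, nE), rates_I (n_epochs, nI),
    bounds (n_epochs + 1,))`` with rates in kHz and bounds in ms.
    """
    protocol.validate()
    n_ep = len(protocol.epochs)
    rates_E = np.full((n_ep, n_exc), syn.r_ext_E)
    rates_I = np.full((n_ep, n_inh), syn.r_ext_I)
    bounds = np.empty(n_ep + 1)
    for k, ep in enumerate(protocol.epochs):
        bounds[k] = ep.t_start
        if ep.stimulus is not None:
            mE = stimset.members_E.get(ep.stimulus)
            mI = stimset.members_I.get(ep.stimulus)
            if mE is not None and len(mE):
                rates_E[k, mE] += stim.r_stim_E * ep.drive_scale_E
            if mI is not None and len(mI):
                rates_I[k, mI] += stim.r_stim_I
        if ep.disinhibition_scale > 0:
            rates_I[k] -= ep.disinhibition_scale * abs(stim.r_disinh_I)
    bounds[-1] = protocol.epochs[-1].t_end if n_ep else 0.0
    np.clip(rates_E, 0.0, None, out=rates_E)
    np.clip(rates_I, 0.0, None, out=rates_I)
    return rates_E, rates_I, bounds
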