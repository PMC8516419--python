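"""Reference desk-scale experiments: the paradigm contracts at scale 0.1.

Quantitative reproduction of the full model (4000 E / 1000 I run for many
minutes of simulated time) is a long-running exercise; these experiments
re-create each stimulation paradigm on a 10x smaller network so that the
mechanism's qualitative signatures — novelty peaks, the absent swap
response, graded novel drive, assembly-specific inhibitory weight dynamics,
stimulus-specific adaptation and its controls, disinhibition — can be
checked in minutes.  Scaled runs use the synaptic-count compensation mode
(:func:`novelnet.io.scaled_compensation`), which preserves each connection
class's in-degree x weight product and the inhibitory learning timescale;
without it the reduced inhibitory in-degree saturates the I->E weight bound
and adaptation cannot develop.

Study conditions (chosen once; see the methods note):

* network: scale 0.1 (400 E / 100 I), compensated;
* settling: 20 s of baseline drive before any stimulation;
* pretraining: all stimuli of the session, 5 repetitions each, random order;
* sequence blocks: length-3 sequences, 15 repetitions per block, 6 blocks
  (standard, swap, and four graded-novel-drive blocks at 25/50/75/100%),
  each presented in 5 randomized rounds and analysed round-averaged;
* oddball: 20 presentations, 300 ms pauses, deviant at slot 18, inhibitory
  membership overlap 0.3.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import analysis
from .engine import SimResult, run_simulation
from .io import make_fixture_network
from .network import (StimulusSet, assign_memberships, build_ssa_memberships,
                      Connectivity)
from .params import Config
from .protocols import (Protocol, StimulusEpoch, make_pretraining,
                        make_sequence_paradigm, make_ssa_paradigm)

__all__ = ["settle_state", "run_sequence_experiment", "run_ssa_experiment",
           "SequenceExperiment", "SSAExperiment"]

SCALE = 0.1
SETTLE_MS = 20000.0
PRETRAIN_REPS = 5
SEQ_LEN = 3
N_REPS = 15
BLOCK_ROUNDS = 5
DRIVE_SCALES = (0.25, 0.5, 0.75, 1.0)
SSA_REPS = 20
SSA_PAUSE_MS = 300.0
SSA_OVERLAP_I = 0.3


def _dummy_stimset() -> StimulusSet:
    return StimulusSet(members_E={0: np.arange(1)},
                       members_I={0: np.empty(0, np.int64)})


def settle_state(seed: int, scale: float = SCALE,
                 duration_ms: float = SETTLE_MS
                 ) -> tuple[Config, Connectivity]:
    """Build the compensated scaled network and let it find its balance.

    Returns the configuration and the connectivity after ``duration_ms`` of
    baseline drive with all plasticity active; the settled weights are the
    common starting point of every paradigm run.
    """
    config, conn, _ = make_fixture_network(scale, seed=seed, compensate=True)
    config["sim"].seed = seed
    blank = Protocol([StimulusEpoch(0.0, duration_ms, None, tag="blank")])
    res = run_simulation(conn, _dummy_stimset(), blank, config)
    return config, res.conn


@dataclass
class SequenceExperiment:
    """Round-averaged summaries of the six-block sequence paradigm."""

    summaries: dict[int, analysis.ResponseSummary]
    probe_tags: dict[int, str]
    drive_blocks: dict[float, int]        # novel drive scale -> block id
    drive_spearman_rho: float
    assembly_weight_gain: float           # pF, within own block (mean/round)
    assembly_weight_decay: float          # pF, between own blocks (mean)
    result: SimResult = field(repr=False)
    protocol: Protocol = field(repr=False)
    stimset: StimulusSet = field(repr=False)


def run_sequence_experiment(seed: int, config: Config | None = None,
                            conn: Connectivity | None = None,
                            block_rounds: int = BLOCK_ROUNDS,
                            n_reps: int = N_REPS) -> SequenceExperiment:
    """Pretraining plus the standard / swap / graded-drive sequence blocks.

    Block 0 is the standard novelty block, block 1 the swap control and
    blocks 2-5 present their novel stimulus at 25/50/75/100% drive.  All
    stimuli (including the novel ones) appear in the pretraining phase, and
    blocks are presented in ``block_rounds`` randomized rounds whose
    responses are averaged per block.
    """
    if config is None or conn is None:
        config, conn = settle_state(seed)
    net, stim = config["network"], config["stimulus"]

    # stimulus ids: each block uses consecutive ids (3 sequence + 1 novel),
    # except the swap block which has no novel stimulus
    next_id = 0
    seqs, novels = [], []
    variants = ["standard", "swap"] + ["standard"] * len(DRIVE_SCALES)
    drives = [1.0, 1.0, *DRIVE_SCALES]
    for var in variants:
        seqs.append(list(range(next_id, next_id + SEQ_LEN)))
        next_id += SEQ_LEN
        if var == "swap":
            novels.append(None)
        else:
            novels.append(next_id)
            next_id += 1
    n_stim = next_id
    stimset = assign_memberships(net, stim, n_stim, seed)

    pre = make_pretraining(n_stim, PRETRAIN_REPS, stim, seed)
    blocks = make_sequence_paradigm(seqs, n_reps, novels, variant=variants,
                                    novel_drive_scale=drives,
                                    block_rounds=block_rounds, seed=seed)
    protocol = pre.concat(blocks)
    res = run_simulation(conn, stimset, protocol, config)

    trace = analysis.population_rate(res.spikes, "E",
                                     bin_ms=config["sim"].rate_bin_ms,
                                     t_max=res.duration, smooth_ms=50.0)
    summaries, probe_tags = {}, {}
    for b, var in enumerate(variants):
        tag = "swap" if var == "swap" else "novel"
        avg, local = analysis.block_round_average(trace, protocol, b)
        summaries[b] = analysis.response_amplitudes(avg, local, b,
                                                    probe_tag=tag)
        probe_tags[b] = tag
    drive_blocks = {d: 2 + k for k, d in enumerate(DRIVE_SCALES)}
    amps = [summaries[drive_blocks[d]].novelty_amplitude
            for d in DRIVE_SCALES]
    rho = float(stats.spearmanr(list(DRIVE_SCALES), amps).statistic)

    gain, decay = _assembly_weight_dynamics(res, protocol, stimset,
                                            block=0)
    return SequenceExperiment(summaries=summaries, probe_tags=probe_tags,
                              drive_blocks=drive_blocks,
                              drive_spearman_rho=rho,
                              assembly_weight_gain=gain,
                              assembly_weight_decay=decay,
                              result=res, protocol=protocol, stimset=stimset)


def _assembly_weight_dynamics(res: SimResult, protocol: Protocol,
                              stimset: StimulusSet, block: int
                              ) -> tuple[float, float]:
    """Mean I->E weight onto a block's assemblies: in-block gain and
    between-block decay (pF), averaged over rounds and the block's stimuli."""
    eps = protocol.block_epochs(block)
    rounds = sorted({e.round for e in eps})
    stimuli = sorted({e.stimulus for e in eps if e.tag in ("onset", "repeat")})
    w = res.weights
    traj = np.mean([[analysis.assembly_mean_weight(w.w_ei[k], res.conn,
                                                   stimset, s)
                     for k in range(len(w.times))] for s in stimuli], axis=0)

    def mean_at(t: float) -> float:
        return float(np.interp(t, w.times, traj))

    spans = []
    for r in rounds:
        r_eps = [e for e in eps if e.round == r]
        spans.append((min(e.t_start for e in r_eps),
                      max(e.t_end for e in r_eps)))
    gains = [mean_at(t1) - mean_at(t0) for t0, t1 in spans]
    decays = [mean_at(t0_next) - mean_at(t1)
              for (_, t1), (t0_next, _) in zip(spans, spans[1:])]
    return float(np.mean(gains)), float(np.mean(decays)) if decays else 0.0


@dataclass
class SSAExperiment:
    """Oddball-paradigm summary for one inhibition variant."""

    variant: str
    disinhibition: float
    subset_summary: analysis.ResponseSummary   # stimulated E subset trace
    population_summary: analysis.ResponseSummary  # all-E trace
    oddball_peak_rate: float        # Hz, all-E peak during the deviant epoch
    fraction_active: float          # E neurons spiking within 100 ms of deviant
    result: SimResult = field(repr=False)
    protocol: Protocol = field(repr=False)
    stimset: StimulusSet = field(repr=False)


def run_ssa_experiment(seed: int, variant: str = "tuned",
                       disinhibition: float = 0.0,
                       config: Config | None = None,
                       conn: Connectivity | None = None) -> SSAExperiment:
    """Oddball paradigm with tuned / untuned / adaptive-current variants.

    ``variant``:

    * ``"tuned"`` — plastic inhibition with tuned inhibitory neurons (the
      configuration that produces stimulus-specific adaptation),
    * ``"untuned"`` — plastic inhibition, but stimuli drive no inhibitory
      neurons,
    * ``"adaptive"`` — all plasticity frozen, spike-triggered adaptive
      currents enabled instead.

    ``disinhibition`` suppresses the whole inhibitory population by that
    fraction of |r_disinh_I| during the deviant epoch only.
    """
    if variant not in ("tuned", "untuned", "adaptive"):
        raise ValueError(f"unknown variant {variant!r}")
    if config is None or conn is None:
        config, conn = settle_state(seed)
    net, stim = config["network"], config["stimulus"]

    stimset = build_ssa_memberships(net, stim, overlap_I=SSA_OVERLAP_I,
                                    seed=seed)
    if variant == "untuned":
        stimset = StimulusSet(
            members_E=dict(stimset.members_E),
            members_I={0: np.empty(0, np.int64), 1: np.empty(0, np.int64)})
    cfg = {k: dataclasses.replace(v) for k, v in config.items()}
    if variant == "adaptive":
        cfg["sim"].triplet_on = False
        cfg["sim"].istdp_on = False
        cfg["sim"].normalization_on = False
        cfg["sim"].adaptive_current_on = True

    protocol = make_ssa_paradigm(n_reps=SSA_REPS, pause=SSA_PAUSE_MS,
                                 disinhibition_scale=disinhibition, stim=stim)
    res = run_simulation(conn, stimset, protocol, cfg)

    kw = dict(bin_ms=cfg["sim"].rate_bin_ms, t_max=res.duration,
              smooth_ms=50.0)
    sub_trace = analysis.population_rate(res.spikes, "E",
                                         subset=stimset.members_E[0], **kw)
    pop_trace = analysis.population_rate(res.spikes, "E", **kw)
    sub = analysis.response_amplitudes(sub_trace, protocol, 0)
    pop = analysis.response_amplitudes(pop_trace, protocol, 0)
    odd = protocol.tagged("novel")[0]
    frac = analysis.fraction_active(res.spikes, "E", np.arange(net.n_exc),
                                    odd.t_start, 100.0)
    return SSAExperiment(variant=variant, disinhibition=disinhibition,
                         subset_summary=sub, population_summary=pop,
                         oddball_peak_rate=pop_trace.max_in(odd.t_start,
                                                            odd.t_end),
                         fraction_active=frac, result=res, protocol=protocol,
                         stimset=stimset)
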