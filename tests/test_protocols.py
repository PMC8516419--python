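from collections import Counter

import numpy as np
import pytest

import novelnet as nn
from novelnet.params import StimulusParams, SynapseParams
from novelnet.protocols import (Protocol, StimulusEpoch, external_rate,
                                make_pretraining, make_sequence_paradigm,
                                make_ssa_paradigm)

STIM = StimulusParams()


def test_pretraining_counts_and_duration():
    proto = make_pretraining(65, 5, STIM, seed=0)
    assert proto.duration == pytest.approx(65 * 5 * 300.0)  # 97.5 s
    counts = Counter(e.stimulus for e in proto.epochs)
    assert all(counts[s] == 5 for s in range(65))
    assert all(e.tag == "pretraining" for e in proto.epochs)
    proto.validate()  # gap-free


def test_pretraining_zero_reps_is_empty():
    assert make_pretraining(10, 0, STIM, seed=0).epochs == []


def test_pretraining_order_is_seed_dependent_permutation():
    a = make_pretraining(10, 3, STIM, seed=1)
    b = make_pretraining(10, 3, STIM, seed=1)
    c = make_pretraining(10, 3, STIM, seed=2)
    assert [e.stimulus for e in a.epochs] == [e.stimulus for e in b.epochs]
    assert [e.stimulus for e in a.epochs] != [e.stimulus for e in c.epochs]


def test_standard_block_structure_and_novel_slot():
    # sequence ABC repeated 5 times: 15 slots; the novel stimulus replaces
    # the last slot of the second-to-last sequence, i.e. 0-based slot 11
    # (the oddball analog: slot 18 of 20 presentations)
    proto = make_sequence_paradigm([[0, 1, 2]], 5, [9], seed=0)
    assert len(proto.epochs) == 15
    assert proto.duration == pytest.approx(4500.0)
    novel = [k for k, e in enumerate(proto.epochs) if e.tag == "novel"]
    assert novel == [3 * 3 + 2]
    assert proto.epochs[11].stimulus == 9
    # all other slots follow the periodic sequence
    for k, e in enumerate(proto.epochs):
        if k != 11:
            assert e.stimulus == [0, 1, 2][k % 3]
    assert {e.tag for e in proto.epochs[:3]} == {"onset"}
    proto.validate()


def test_swap_block_exchanges_last_two_slots():
    proto = make_sequence_paradigm([[0, 1, 2]], 4, [None], variant="swap",
                                   seed=0)
    swap_rep = [e for e in proto.epochs if e.rep == 2]  # second-to-last
    assert [e.stimulus for e in swap_rep] == [0, 2, 1]  # ABC -> ACB
    assert not any(e.tag == "novel" for e in proto.epochs)
    assert sum(e.tag == "swap" for e in proto.epochs) == 2


def test_shuffle_preserves_multiset_and_forbids_repeats():
    proto = make_sequence_paradigm([[0, 1, 2, 3]], 6, [7], variant="shuffle",
                                   seed=3)
    stims = [e.stimulus for e in proto.epochs]
    for a, b in zip(stims, stims[1:]):
        assert a != b, "no stimulus may appear twice in a row"
    for rep in range(6):
        rep_stims = [e.stimulus for e in proto.epochs if e.rep == rep]
        if rep == 4:  # novel replaces the last slot
            assert rep_stims[-1] == 7
            assert Counter(rep_stims[:-1]) <= Counter([0, 1, 2, 3])
        else:
            assert Counter(rep_stims) == Counter([0, 1, 2, 3])
    with pytest.raises(ValueError):
        make_sequence_paradigm([[0, 0]], 3, [7], variant="shuffle", seed=0)


def test_novel_drive_scale_zero_and_per_block():
    proto = make_sequence_paradigm([[0, 1], [2, 3]], 3, [4, 5],
                                   novel_drive_scale=[0.0, 0.6], seed=0)
    novicks = {e.block: e.drive_scale_E for e in proto.epochs
               if e.tag == "novel"}
    assert novicks == {0: 0.0, 1: 0.6}
    assert all(e.drive_scale_E == 1.0 for e in proto.epochs
               if e.tag != "novel")


def test_block_rounds_randomize_and_tag_rounds():
    proto = make_sequence_paradigm([[0, 1], [2, 3]], 3, [4, 5],
                                   block_rounds=4, seed=1)
    assert len(proto.epochs) == 4 * 2 * 3 * 2
    for b in (0, 1):
        rounds = {e.round for e in proto.epochs if e.block == b}
        assert rounds == {0, 1, 2, 3}
        # exactly one novel tag per block and round
        for r in rounds:
            tags = [e.tag for e in proto.epochs
                    if e.block == b and e.round == r]
            assert tags.count("novel") == 1
    proto.validate()


def test_ssa_paradigm_layout_and_oddball():
    proto = make_ssa_paradigm(n_reps=20, pause=300.0, stim=STIM)
    stim_eps = [e for e in proto.epochs if e.stimulus is not None]
    assert len(stim_eps) == 20
    assert [e.stimulus for e in stim_eps].count(1) == 1
    assert stim_eps[18].stimulus == 1 and stim_eps[18].tag == "novel"
    pauses = [e for e in proto.epochs if e.stimulus is None]
    assert len(pauses) == 19
    proto.validate()
    # pause=0 gives contiguous presentation
    contig = make_ssa_paradigm(n_reps=5, pause=0.0, stim=STIM)
    assert len(contig.epochs) == 5
    contig.validate()
    with pytest.raises(ValueError):
        make_ssa_paradigm(n_reps=5, oddball_position=7)


def test_external_rate_examples():
    syn = SynapseParams()
    net_kw = dict(syn=syn, stim=STIM)
    stimset = nn.StimulusSet(members_E={0: np.array([3, 4])},
                             members_I={0: np.array([1])})
    proto = make_ssa_paradigm(n_reps=3, pause=0.0, stim=STIM,
                              disinhibition_scale=1.0)
    t_odd = [e for e in proto.epochs if e.tag == "novel"][0].t_start
    # non-member E neuron: baseline only
    assert external_rate(proto, stimset, "E", 0, 100.0, **net_kw) == 4.5
    # member E neuron during its stimulus: 4.5 + 12
    assert external_rate(proto, stimset, "E", 3, 100.0, **net_kw) == 16.5
    # member I neuron during its stimulus: 2.25 + 1.2
    assert external_rate(proto, stimset, "I", 1, 100.0, **net_kw) == 3.45
    # any I neuron during full disinhibition: 2.25 - 1.5
    assert external_rate(proto, stimset, "I", 0, t_odd + 1.0,
                         **net_kw) == pytest.approx(0.75)


def test_protocol_rejects_gaps_and_overlaps():
    with pytest.raises(ValueError, match="gap"):
        Protocol([StimulusEpoch(0, 300, 0), StimulusEpoch(400, 700, 1)]).validate()
    with pytest.raises(ValueError, match="overlap"):
        Protocol([StimulusEpoch(0, 300, 0), StimulusEpoch(200, 500, 1)]).validate()


def test_protocol_yaml_round_trip(tmp_path):
    proto = make_sequence_paradigm([[0, 1, 2]], 4, [3], seed=0)
    p = tmp_path / "proto.yaml"
    proto.to_yaml(p)
    loaded = Protocol.from_yaml(p)
    assert loaded == proto
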