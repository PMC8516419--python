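import numpy as np
import pytest

import novelnet as nn
from novelnet.analysis import (assembly_mean_weight, block_round_average,
                               fit_exponential_decay, fit_linear,
                               fraction_active, population_rate,
                               response_amplitudes)
from novelnet.engine import SpikeRecord
from novelnet.network import Connectivity, StimulusSet
from novelnet.protocols import Protocol, StimulusEpoch


def record(times, idx, pop=0):
    times = np.asarray(times, float)
    order = np.argsort(times, kind="stable")
    return SpikeRecord(t=times[order],
                       pop=np.full(len(times), pop, dtype=np.int8),
                       idx=np.asarray(idx, np.int32)[order])


def test_population_rate_counts_single_neuron():
    spikes = record(np.arange(10) * 100.0 + 50.0, [0] * 10)
    tr = population_rate(spikes, "E", subset=np.array([0]), bin_ms=100.0,
                        t_max=1000.0)
    assert tr.rate == pytest.approx(np.full(10, 10.0))  # 10 Hz every bin


def test_population_rate_conserves_spike_count(rng):
    n = 7
    times = rng.uniform(0, 2000, 400)
    idx = rng.integers(0, n, 400)
    spikes = record(times, idx)
    tr = population_rate(spikes, "E", subset=np.arange(n), bin_ms=25.0,
                        t_max=2000.0)
    total = tr.rate.sum() * (tr.bin_ms * 1e-3) * n
    assert total == pytest.approx(400)


def test_population_rate_no_spikes_and_empty_subset():
    empty = SpikeRecord(t=np.empty(0), pop=np.empty(0, np.int8),
                        idx=np.empty(0, np.int32))
    tr = population_rate(empty, "E", subset=np.arange(3), bin_ms=10.0,
                        t_max=100.0)
    assert (tr.rate == 0).all()
    with pytest.raises(ValueError):
        population_rate(empty, "E", subset=np.array([]), bin_ms=10.0)


def _toy_block(n_reps=8, seq_len=3, probe="novel"):
    epochs, t = [], 0.0
    for rep in range(n_reps):
        for slot in range(seq_len):
            tag = "onset" if rep == 0 else "repeat"
            stimulus = slot
            if rep == n_reps - 2 and slot == seq_len - 1:
                tag = probe
                stimulus = 99 if probe == "novel" else slot
            epochs.append(StimulusEpoch(t, t + 300.0, stimulus, tag=tag,
                                        block=0, rep=rep, slot=slot))
            t += 300.0
    return Protocol(epochs)


def _trace(proto, baseline=3.0, novelty_peak=None, onset_peak=None):
    bins = int(proto.duration / 10.0)
    rate = np.full(bins, baseline)
    t = (np.arange(bins) + 0.5) * 10.0
    if onset_peak is not None:
        rate[(t >= 100) & (t < 200)] = onset_peak
    if novelty_peak is not None:
        probe = [e for e in proto.epochs if e.tag == "novel"][0]
        rate[(t >= probe.t_start + 100) & (t < probe.t_start + 200)] = novelty_peak
    return nn.RateTrace(t=t, rate=rate, bin_ms=10.0)


def test_amplitudes_on_constant_trace_are_zero():
    proto = _toy_block()
    r = response_amplitudes(_trace(proto), proto, 0)
    assert r.onset_amplitude == 0.0
    assert r.novelty_amplitude == 0.0
    assert r.adaptation_level == 0.0
    assert r.baseline == pytest.approx(3.0)


def test_amplitudes_extract_crafted_peaks():
    proto = _toy_block()
    r = response_amplitudes(_trace(proto, 3.0, novelty_peak=9.0,
                                   onset_peak=5.0), proto, 0)
    assert r.novelty_amplitude == pytest.approx(6.0)
    assert r.onset_amplitude == pytest.approx(2.0)


def test_amplitudes_invariant_to_constant_shift():
    proto = _toy_block()
    tr = _trace(proto, 3.0, novelty_peak=9.0, onset_peak=5.0)
    shifted = nn.RateTrace(t=tr.t, rate=tr.rate + 11.0, bin_ms=tr.bin_ms)
    a = response_amplitudes(tr, proto, 0)
    b = response_amplitudes(shifted, proto, 0)
    assert b.novelty_amplitude == pytest.approx(a.novelty_amplitude)
    assert b.onset_amplitude == pytest.approx(a.onset_amplitude)
    assert b.adaptation_level == pytest.approx(a.adaptation_level)


def test_swap_block_has_no_novel_probe():
    proto = _toy_block(probe="swap")
    r = response_amplitudes(_trace(proto), proto, 0, probe_tag="novel")
    assert r.novelty_amplitude is None
    with pytest.raises(ValueError):
        r.novelty_z()
    r_swap = response_amplitudes(_trace(proto), proto, 0, probe_tag="swap")
    assert r_swap.novelty_amplitude is not None


def test_block_round_average_aligns_rounds():
    epochs = []
    t = 0.0
    for rnd in range(3):
        for rep in range(2):
            epochs.append(StimulusEpoch(t, t + 300.0, 0,
                                        tag="onset" if rep == 0 else "repeat",
                                        block=0, rep=rep, slot=0, round=rnd))
            t += 300.0
    proto = Protocol(epochs)
    bins = int(proto.duration / 10.0)
    rate = np.zeros(bins)
    for rnd in range(3):  # constant plateau per round: 1, 2, 3
        i0 = rnd * 60
        rate[i0:i0 + 60] = rnd + 1.0
    tr = nn.RateTrace(t=(np.arange(bins) + 0.5) * 10.0, rate=rate, bin_ms=10.0)
    avg, local = block_round_average(tr, proto, 0)
    assert avg.rate == pytest.approx(np.full(60, 2.0))
    assert local.epochs[0].t_start == 0.0
    assert local.duration == pytest.approx(600.0)


def test_exponential_fit_recovers_noiseless_parameters():
    x = np.arange(1, 31, dtype=float)
    y = 5.0 * np.exp(-x / 9.0) + 3.0
    fit = fit_exponential_decay(x, y)
    assert fit.ok
    assert fit.params["tau"] == pytest.approx(9.0, rel=1e-6)
    assert fit.params["amplitude"] == pytest.approx(5.0, rel=1e-6)
    assert fit.params["offset"] == pytest.approx(3.0, rel=1e-6)


def test_exponential_fit_flags_constant_input():
    fit = fit_exponential_decay(np.arange(6.0), np.full(6, 2.0))
    assert not fit.ok and "unidentifiable" in fit.message


def test_exponential_fit_with_noise_recovers_tau_within_3se(rng):
    x = np.arange(1, 51, dtype=float)
    y = 5.0 * np.exp(-x / 9.0) + 3.0
    y_noisy = y * (1 + 0.05 * rng.standard_normal(y.size))
    fit = fit_exponential_decay(x, y_noisy, n_restarts=50)
    assert fit.ok
    assert abs(fit.params["tau"] - 9.0) < 3 * fit.stderr["tau"]


def test_linear_fit_exact_and_two_point():
    x = np.arange(10, dtype=float)
    fit = fit_linear(x, 1.6 * x + 2.0)
    assert fit.params["slope"] == pytest.approx(1.6, rel=1e-12)
    assert fit.params["intercept"] == pytest.approx(2.0, rel=1e-12)
    two = fit_linear([0.0, 2.0], [1.0, 5.0])
    assert two.params["slope"] == pytest.approx(2.0)
    assert two.resid_norm == pytest.approx(0.0, abs=1e-12)
    assert not fit_linear([1.0, 1.0], [0.0, 1.0]).ok


def test_linear_fit_stderr_matches_closed_form(rng):
    x = np.linspace(0, 10, 40)
    y = 1.6 * x + 2.0 + rng.normal(0, 0.5, x.size)
    fit = fit_linear(x, y)
    resid = y - (fit.params["intercept"] + fit.params["slope"] * x)
    s2 = resid @ resid / (x.size - 2)
    se = np.sqrt(s2 / ((x - x.mean()) @ (x - x.mean())))
    assert fit.stderr["slope"] == pytest.approx(se, rel=1e-9)


def test_fraction_active_counts_window():
    # 30 of 100 neurons spike inside the window, others outside
    times = np.concatenate([np.full(30, 150.0), np.full(20, 500.0)])
    idx = np.concatenate([np.arange(30), np.arange(30, 50)])
    spikes = record(times, idx)
    subset = np.arange(100)
    assert fraction_active(spikes, "E", subset, 100.0, 100.0) == pytest.approx(0.30)
    assert fraction_active(spikes, "E", subset, 900.0, 100.0) == 0.0
    all_in = record(np.full(100, 120.0), np.arange(100))
    assert fraction_active(all_in, "E", subset, 100.0, 100.0) == 1.0


def _conn_ei(w, mask):
    nE, nI = w.shape
    return Connectivity(w_ee=np.zeros((nE, nE)), w_ei=w,
                        w_ie=np.zeros((nI, nE)), w_ii=np.zeros((nI, nI)),
                        m_ee=np.zeros((nE, nE), bool), m_ei=mask,
                        m_ie=np.zeros((nI, nE), bool),
                        m_ii=np.zeros((nI, nI), bool),
                        row_sums_ee_init=np.zeros(nE),
                        n_in_ee=np.zeros(nE, np.int64))


def test_assembly_mean_weight_selections():
    w = np.array([[48.7, 50.0], [48.7, 70.0]])
    mask = np.ones((2, 2), bool)
    conn = _conn_ei(w, mask)
    sset = StimulusSet(members_E={0: np.array([0, 1])},
                       members_I={0: np.array([1])})
    # uniform selection
    uni = _conn_ei(np.full((2, 2), 48.7), mask)
    assert assembly_mean_weight(uni.w_ei, uni, sset, 0) == pytest.approx(48.7)
    # stimulus-specific column {50, 70} -> 60
    assert assembly_mean_weight(w, conn, sset, 0,
                                "stimulus_specific_inhibitory") == pytest.approx(60.0)
    # single-synapse selection
    single = StimulusSet(members_E={0: np.array([1])},
                         members_I={0: np.array([1])})
    assert assembly_mean_weight(w, conn, single, 0,
                                "stimulus_specific_inhibitory") == pytest.approx(70.0)
    with pytest.raises(ValueError):
        assembly_mean_weight(w, conn, sset, 3)
    empty = StimulusSet(members_E={0: np.array([0])},
                        members_I={0: np.empty(0, np.int64)})
    with pytest.raises(ValueError):
        assembly_mean_weight(w, conn, empty, 0, "stimulus_specific_inhibitory")
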