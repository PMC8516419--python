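"""Summary quantities: population rates, response amplitudes, fits.

The analysis mirrors how population calcium/spike data are summarized in
sequence-novelty and oddball experiments:

* a binned population rate trace (Hz per neuron), optionally boxcar-smoothed
  for peak detection;
* per block, a *baseline* (mean rate over the stimulus epochs of the last
  two full sequences preceding the probed epoch), an *onset amplitude*
  (peak during the first sequence of the block minus baseline) and a
  *novelty amplitude* (peak during the novel/oddball epoch minus baseline);
* exponential decay fits y = a exp(-x / tau) + b of adaptation curves and
  ordinary least-squares fits of decay constant versus sequence length;
* the fraction of neurons with at least one spike in a 100 ms window (the
  density of a response);
* assembly-resolved mean inhibitory weights, either from the whole
  inhibitory population onto an assembly or restricted to the similarly
  tuned inhibitory neurons (the stimulus-specific weights of the oddball
  analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .engine import SpikeRecord
from .network import Connectivity, StimulusSet
from .protocols import Protocol, StimulusEpoch

__all__ = ["RateTrace", "ResponseSummary", "FitResult", "population_rate",
           "block_round_average", "response_amplitudes",
           "fit_exponential_decay", "fit_linear", "fraction_active",
           "assembly_mean_weight"]


@dataclass
class RateTrace:
    """Uniformly binned population-average firing rate."""

    t: np.ndarray        # bin centers, ms
    rate: np.ndarray     # Hz per neuron
    bin_ms: float

    def mean_in(self, t0: float, t1: float) -> float:
        sel = (self.t >= t0) & (self.t < t1)
        if not sel.any():
            raise ValueError(f"no rate bins in [{t0}, {t1}) ms")
        return float(self.rate[sel].mean())

    def max_in(self, t0: float, t1: float) -> float:
        sel = (self.t >= t0) & (self.t < t1)
        if not sel.any():
            raise ValueError(f"no rate bins in [{t0}, {t1}) ms")
        return float(self.rate[sel].max())


@dataclass
class ResponseSummary:
    """Block-level response decomposition (all rates in Hz)."""

    baseline: float
    baseline_sd: float          # SD across baseline bins
    onset_amplitude: float      # onset peak - baseline
    novelty_amplitude: float | None  # probe peak - baseline; None if no probe
    adaptation_level: float     # onset rate - baseline rate
    peak_null_mean: float = np.nan  # per-sequence peak height over baseline seqs
    peak_null_sd: float = np.nan

    def novelty_z(self) -> float:
        """Probe peak height relative to the per-sequence peak null.

        The probed epoch's peak is compared against the distribution of
        per-sequence peaks over the adapted sequences preceding it.  Using
        peaks as the null (rather than baseline bins) removes the positive
        bias of a max statistic, so an unremarkable slot — e.g. the swap
        control — scores near zero.
        """
        if self.novelty_amplitude is None:
            raise ValueError("block has no probed (novel/swap) epoch")
        sd = self.peak_null_sd if self.peak_null_sd > 0 else np.inf
        return (self.novelty_amplitude + self.baseline
                - self.peak_null_mean) / sd


@dataclass
class FitResult:
    params: dict[str, float]
    stderr: dict[str, float]
    resid_norm: float
    ok: bool = True
    message: str = ""


def population_rate(spikes: SpikeRecord, population: str = "E",
                    subset: np.ndarray | None = None, bin_ms: float = 10.0,
                    t_max: float | None = None,
                    smooth_ms: float = 0.0) -> RateTrace:
    """Population-average firing rate in Hz (spikes / neuron / s).

    ``subset`` restricts to the given neuron indices (default: the whole
    population); spike counts are divided by the subset size and the bin
    width.  ``smooth_ms`` applies a boxcar of that width (rounded to an odd
    number of bins) for peak detection.
    """
    if bin_ms <= 0:
        raise ValueError("bin must be > 0")
    t, idx = spikes.population(population)
    if subset is not None:
        subset = np.asarray(subset)
        if subset.size == 0:
            raise ValueError("empty neuron subset")
        sel = np.isin(idx, subset)
        t = t[sel]
        n = subset.size
    else:
        n = int(idx.max()) + 1 if len(idx) else 1
    if t_max is None:
        t_max = float(t.max()) + bin_ms if len(t) else bin_ms
    n_bins = int(np.ceil(t_max / bin_ms))
    counts, _ = np.histogram(t, bins=n_bins, range=(0.0, n_bins * bin_ms))
    rate = counts / (n * bin_ms * 1e-3)
    if smooth_ms > 0:
        w = max(1, int(round(smooth_ms / bin_ms)) | 1)
        rate = np.convolve(rate, np.ones(w) / w, mode="same")
    centers = (np.arange(n_bins) + 0.5) * bin_ms
    return RateTrace(t=centers, rate=rate, bin_ms=bin_ms)


def _baseline_window(trace: RateTrace, epochs: list[StimulusEpoch],
                     probe: StimulusEpoch, n_epochs: int) -> np.ndarray:
    """Rate bins inside the last ``n_epochs`` stimulus epochs before the probe."""
    before = [e for e in epochs
              if e.t_end <= probe.t_start + 1e-9 and e.stimulus is not None]
    window = before[-n_epochs:]
    if not window:
        raise ValueError("block too short to define a baseline")
    sel = np.zeros(len(trace.t), dtype=bool)
    for e in window:
        sel |= (trace.t >= e.t_start) & (trace.t < e.t_end)
    if not sel.any():
        raise ValueError("no rate bins inside the baseline window")
    return trace.rate[sel]


def block_round_average(trace: RateTrace, protocol: Protocol,
                        block: int) -> tuple[RateTrace, Protocol]:
    """Average a block's rate trace across its presentation rounds.

    In the repeated-sequence paradigm each block is presented several
    times in randomized order; responses are averaged across those rounds,
    time-locked to block onset.  Returns the averaged trace on a local time
    axis starting at 0 together with one round's epochs shifted likewise.
    """
    import dataclasses as _dc

    eps = protocol.block_epochs(block)
    if not eps:
        raise ValueError(f"protocol has no block {block}")
    rounds = sorted({e.round for e in eps})
    per_round = [[e for e in eps if e.round == r] for r in rounds]
    length = per_round[0][-1].t_end - per_round[0][0].t_start
    n_bins = int(round(length / trace.bin_ms))
    acc = np.zeros(n_bins)
    for reps in per_round:
        i0 = int(round(reps[0].t_start / trace.bin_ms))
        seg = trace.rate[i0:i0 + n_bins]
        if seg.size < n_bins:
            raise ValueError("trace shorter than the block span")
        acc += seg
    acc /= len(per_round)
    local = []
    t0 = per_round[0][0].t_start
    for e in per_round[0]:
        d = _dc.asdict(e)
        d["t_start"] -= t0
        d["t_end"] -= t0
        local.append(StimulusEpoch(**d))
    avg = RateTrace(t=(np.arange(n_bins) + 0.5) * trace.bin_ms, rate=acc,
                    bin_ms=trace.bin_ms)
    return avg, Protocol(local)


def response_amplitudes(trace: RateTrace, protocol: Protocol, block: int,
                        probe_tag: str = "novel",
                        baseline_sequences: int = 2,
                        null_sequences: int = 6) -> ResponseSummary:
    """Baseline, onset and novelty amplitudes of one sequence block.

    The baseline is the mean rate over the stimulus epochs of the last
    ``baseline_sequences`` full sequences preceding the probed epoch
    (excluding that epoch); the onset peak is searched within the first
    sequence of the block; the novelty peak within the probed epoch.  The
    per-sequence peaks of the last ``null_sequences`` sequences before the
    probe form the null distribution behind
    :meth:`ResponseSummary.novelty_z`.  For the swap control pass
    ``probe_tag="swap"`` — the probed epoch is then the last swapped slot,
    and the returned "novelty" amplitude quantifies the (absent) response
    there.  For multi-round protocols average first with
    :func:`block_round_average`.
    """
    epochs = protocol.block_epochs(block)
    if not epochs:
        raise ValueError(f"protocol has no block {block}")
    seq_len = max(e.slot for e in epochs if e.rep == 0) + 1
    probes = [e for e in epochs if e.tag == probe_tag]
    probe = probes[-1] if probes else None

    onset_eps = [e for e in epochs if e.rep == 0]
    onset_t0 = min(e.t_start for e in onset_eps)
    onset_t1 = max(e.t_end for e in onset_eps)

    if probe is not None:
        base = _baseline_window(trace, epochs, probe,
                                baseline_sequences * seq_len)
        ref = probe
    else:
        # no probed epoch: take the sequences before the block's end
        ref = epochs[-1]
        base = _baseline_window(trace, epochs + [ref], ref,
                                baseline_sequences * seq_len)
    baseline = float(base.mean())
    baseline_sd = float(base.std(ddof=1)) if base.size > 1 else 0.0

    # per-sequence peak null over the sequences preceding the probe
    null_reps = sorted({e.rep for e in epochs
                        if e.stimulus is not None
                        and e.t_end <= ref.t_start + 1e-9})[-null_sequences:]
    peaks = []
    for rep in null_reps:
        reps_eps = [e for e in epochs if e.rep == rep and e.stimulus is not None
                    and e.t_end <= ref.t_start + 1e-9]
        if reps_eps:
            peaks.append(trace.max_in(min(e.t_start for e in reps_eps),
                                      max(e.t_end for e in reps_eps)))
    peak_null_mean = float(np.mean(peaks)) if peaks else np.nan
    peak_null_sd = (float(np.std(peaks, ddof=1)) if len(peaks) > 1 else np.nan)

    onset_amp = trace.max_in(onset_t0, onset_t1) - baseline
    novelty_amp = (trace.max_in(probe.t_start, probe.t_end) - baseline
                   if probe is not None else None)
    onset_rate = trace.mean_in(onset_t0, onset_t1)
    return ResponseSummary(baseline=baseline, baseline_sd=baseline_sd,
                           onset_amplitude=onset_amp,
                           novelty_amplitude=novelty_amp,
                           adaptation_level=onset_rate - baseline,
                           peak_null_mean=peak_null_mean,
                           peak_null_sd=peak_null_sd)


def fit_exponential_decay(x, y, n_restarts: int = 20,
                          seed: int = 0) -> FitResult:
    """Least-squares fit of y = a exp(-x / tau) + b.

    Multi-start Levenberg–Marquardt; non-convergence and degenerate
    (constant) inputs are reported in ``ok`` / ``message`` rather than
    silently defaulted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points")
    if np.ptp(y) == 0:
        return FitResult({}, {}, 0.0, ok=False,
                         message="constant input: tau unidentifiable")

    def model(x, a, tau, b):
        return a * np.exp(-x / tau) + b

    rng = np.random.default_rng(seed)
    span = np.ptp(x) or 1.0
    best = None
    for k in range(n_restarts):
        if k == 0:
            p0 = (y[0] - y[-1], span / 3.0, y[-1])
        else:
            p0 = ((y[0] - y[-1]) * rng.uniform(0.3, 3.0),
                  span * rng.uniform(0.05, 2.0),
                  y[-1] + np.ptp(y) * rng.uniform(-0.5, 0.5))
        try:
            popt, pcov = optimize.curve_fit(model, x, y, p0=p0,
                                            bounds=([-np.inf, 1e-9, -np.inf],
                                                    [np.inf, np.inf, np.inf]),
                                            maxfev=10000)
        except (RuntimeError, ValueError):
            continue
        resid = float(np.linalg.norm(y - model(x, *popt)))
        if best is None or resid < best[2]:
            best = (popt, pcov, resid)
    if best is None:
        return FitResult({}, {}, np.inf, ok=False,
                         message="exponential fit did not converge")
    popt, pcov, resid = best
    err = np.sqrt(np.diag(pcov))
    return FitResult(
        params={"amplitude": popt[0], "tau": popt[1], "offset": popt[2]},
        stderr={"amplitude": err[0], "tau": err[1], "offset": err[2]},
        resid_norm=resid)


def fit_linear(x, y) -> FitResult:
    """Ordinary least squares y = m x + c with standard errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        return FitResult({}, {}, np.inf, ok=False, message="degenerate x")
    res = stats.linregress(x, y)
    pred = res.intercept + res.slope * x
    return FitResult(
        params={"slope": res.slope, "intercept": res.intercept},
        stderr={"slope": res.stderr, "intercept": res.intercept_stderr},
        resid_norm=float(np.linalg.norm(y - pred)))


def fraction_active(spikes: SpikeRecord, population: str,
                    subset: np.ndarray, t0: float,
                    window: float = 100.0) -> float:
    """Fraction of ``subset`` with >= 1 spike in [t0, t0 + window)."""
    if window <= 0:
        raise ValueError("window must be > 0")
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("empty neuron subset")
    t, idx = spikes.population(population)
    sel = (t >= t0) & (t < t0 + window)
    active = np.intersect1d(np.unique(idx[sel]), subset)
    return active.size / subset.size


def assembly_mean_weight(w_ei: np.ndarray, conn: Connectivity,
                         stimset: StimulusSet, stimulus: int,
                         kind: str = "inhibitory_onto_assembly") -> float:
    """Mean existing I->E weight onto a stimulus-specific assembly (pF).

    ``kind="inhibitory_onto_assembly"`` averages over all presynaptic
    inhibitory neurons; ``kind="stimulus_specific_inhibitory"`` restricts to
    inhibitory neurons tuned to the same stimulus (the A-onto-A weights of
    the oddball analysis).
    """
    if stimulus not in stimset.members_E:
        raise ValueError(f"unknown stimulus {stimulus}")
    post = stimset.members_E[stimulus]
    if kind == "inhibitory_onto_assembly":
        pre = np.arange(conn.n_inh)
    elif kind == "stimulus_specific_inhibitory":
        pre = np.asarray(stimset.members_I.get(stimulus, np.empty(0, int)))
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if post.size == 0 or pre.size == 0:
        raise ValueError("no synapses in the selection")
    sub_w = w_ei[np.ix_(post, pre)]
    sub_m = conn.m_ei[np.ix_(post, pre)]
    if not sub_m.any():
        raise ValueError("no synapses in the selection")
    return float(sub_w[sub_m].mean())
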