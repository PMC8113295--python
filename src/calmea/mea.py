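"""Spike, burst and network-burst detection for microelectrode-array data.

The detection cascade follows common practice for extracellular MEA
recordings of cultured neuronal networks:

* spikes: adaptive threshold at ``k`` times the local noise SD (default
  ``k = 5.5``), noise estimated robustly per window from the median
  absolute deviation (MAD);
* bursts: maximal runs of >= 5 spikes on one electrode with every
  inter-spike interval (ISI) <= 100 ms;
* network bursts: maximal runs of spikes pooled over all electrodes with
  ISI <= 100 ms, at least 50 spikes in total, and at least 60 % of the
  active electrodes contributing.

The "synchronicity coefficient" summary is implemented as the mean
pairwise zero-lag Pearson correlation of 0.1-s binned per-electrode spike
counts; it is a proxy for network coordination, not a vendor-defined
statistic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np

#: Gaussian consistency constant for the median absolute deviation.
MAD_TO_SD = 1.4826


@dataclass
class SpikeTrain:
    """Spike times (seconds, ascending) recorded on one electrode."""

    electrode_id: int
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.sort(np.asarray(self.times, dtype=float).ravel())

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass
class Burst:
    """A single-electrode burst: >= ``min_spikes`` spikes, all ISIs <= ``max_isi``."""

    electrode_id: int
    start: float
    end: float
    n_spikes: int


@dataclass
class NetworkBurst:
    """A pooled multi-electrode burst."""

    start: float
    end: float
    n_spikes: int
    participating_fraction: float


@dataclass
class MEAMetrics:
    """Network-level summary of one recording."""

    network_burst_frequency: float  # events per minute
    spikes_per_burst: float  # mean over bursts; NaN when no bursts
    synchronicity: float  # mean pairwise correlation of binned counts
    n_bursts: int = 0
    n_network_bursts: int = 0
    n_active_electrodes: int = 0


def estimate_noise_sd(trace, window: int = 1250) -> np.ndarray:
    """Robust per-window noise SD of a voltage trace.

    The SD is estimated per non-overlapping window as
    ``MAD_TO_SD * median(|v - median(v)|)``, which is insensitive to
    sparse large spikes riding on the noise.  A trace shorter than one
    window yields a single global estimate.

    Parameters
    ----------
    trace : array-like
        Sampled voltage.
    window : int
        Window length in samples (>= 100).

    Returns
    -------
    np.ndarray
        One SD estimate per window.
    """
    v = np.asarray(trace, dtype=float).ravel()
    if window < 100:
        raise ValueError("window must be >= 100 samples")
    if v.size == 0:
        raise ValueError("empty trace")
    if v.size < window:
        med = np.median(v)
        return np.array([MAD_TO_SD * np.median(np.abs(v - med))])
    n_win = v.size // window
    out = np.empty(n_win + (1 if v.size % window else 0))
    for i in range(n_win):
        seg = v[i * window : (i + 1) * window]
        out[i] = MAD_TO_SD * np.median(np.abs(seg - np.median(seg)))
    if v.size % window:
        seg = v[n_win * window :]
        out[-1] = MAD_TO_SD * np.median(np.abs(seg - np.median(seg)))
    return out


def _sd_per_sample(v: np.ndarray, window: int) -> np.ndarray:
    """Expand per-window SD estimates to a step function over samples."""
    sds = estimate_noise_sd(v, window=window)
    if sds.size == 1:
        return np.full(v.size, sds[0])
    per = np.repeat(sds[:-1], window)
    tail = v.size - per.size
    return np.concatenate([per, np.full(tail, sds[-1])]) if tail else per


def detect_spikes(
    trace,
    sampling_rate: float,
    electrode_id: int = 0,
    k: float = 5.5,
    refractory: float = 1e-3,
    window_s: float = 0.1,
) -> SpikeTrain:
    """Adaptive-threshold spike detection on a raw voltage trace.

    Samples with ``|v| > k * sd`` (``sd`` the local MAD-based noise SD)
    are grouped into events; groups separated by less than the refractory
    period are merged and each event is timed at its extremum sample.

    Parameters
    ----------
    trace : array-like
        Sampled voltage, noise in arbitrary units.
    sampling_rate : float
        Samples per second (must be > 0).
    k : float
        Threshold multiplier of the noise SD (the assay default is 5.5).
    refractory : float
        Minimum separation between distinct events, in seconds.
    window_s : float
        Length of the noise-estimation window, in seconds.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    v = np.asarray(trace, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage trace contains non-finite samples")
    if v.size == 0:
        return SpikeTrain(electrode_id, np.empty(0))
    window = max(100, int(round(window_s * sampling_rate)))
    sd = _sd_per_sample(v, window)
    above = np.abs(v) > k * sd
    if not above.any():
        return SpikeTrain(electrode_id, np.empty(0))
    idx = np.flatnonzero(above)
    gap = max(1, int(round(refractory * sampling_rate)))
    breaks = np.flatnonzero(np.diff(idx) > gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    peaks = []
    for s, e in zip(starts, ends):
        seg = idx[s : e + 1]
        peaks.append(seg[np.argmax(np.abs(v[seg]))])
    return SpikeTrain(electrode_id, np.asarray(peaks, dtype=float) / sampling_rate)


def _isi_runs(times: np.ndarray, max_isi: float) -> List[slice]:
    """Maximal runs of consecutive spikes with every ISI <= max_isi."""
    if times.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(times) > max_isi)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [times.size]])
    return [slice(int(s), int(e)) for s, e in zip(starts, ends)]


def detect_bursts(
    train: SpikeTrain, max_isi: float = 0.1, min_spikes: int = 5
) -> List[Burst]:
    """Single-electrode burst detection by the ISI rule.

    A burst is a maximal run of consecutive spikes in which every
    inter-spike interval is <= ``max_isi`` seconds; runs with fewer than
    ``min_spikes`` spikes are discarded.
    """
    bursts = []
    for run in _isi_runs(train.times, max_isi):
        n = run.stop - run.start
        if n >= min_spikes:
            bursts.append(
                Burst(
                    electrode_id=train.electrode_id,
                    start=float(train.times[run.start]),
                    end=float(train.times[run.stop - 1]),
                    n_spikes=n,
                )
            )
    return bursts


def active_electrodes(
    trains: Sequence[SpikeTrain],
    duration: Optional[float] = None,
    min_rate_per_min: float = 5.0,
) -> List[int]:
    """Electrodes considered active: >= ``min_rate_per_min`` spikes/min.

    ``duration`` defaults to the last spike time over all trains.
    """
    if duration is None:
        all_last = [t.times[-1] for t in trains if t.n_spikes]
        duration = max(all_last) if all_last else 0.0
    if duration <= 0:
        return []
    return [
        t.electrode_id
        for t in trains
        if t.n_spikes / duration * 60.0 >= min_rate_per_min
    ]


def detect_network_bursts(
    trains: Sequence[SpikeTrain],
    max_isi: float = 0.1,
    min_spikes: int = 50,
    min_fraction: float = 0.6,
    active: "str | Sequence[int]" = "rate",
    duration: Optional[float] = None,
    min_rate_per_min: float = 5.0,
) -> List[NetworkBurst]:
    """Network-burst detection on the pooled spike train.

    Spikes from all electrodes are pooled and segmented into maximal runs
    with pooled ISI <= ``max_isi``.  A run is emitted as a network burst
    when it contains >= ``min_spikes`` spikes in total and >=
    ``min_fraction`` of the active electrodes contribute at least one
    spike to it.

    Parameters
    ----------
    active : "rate", "all", or sequence of electrode ids
        How the set of active electrodes is determined.  ``"rate"``
        applies the >= 5 spikes/min rule; ``"all"`` counts every supplied
        train as active.
    """
    if not trains:
        raise ValueError("at least one spike train is required")
    if active == "rate":
        act = active_electrodes(trains, duration, min_rate_per_min)
    elif active == "all":
        act = [t.electrode_id for t in trains]
    else:
        act = list(active)
    act_set = set(act)
    if not act_set:
        return []
    pooled_t = np.concatenate([t.times for t in trains]) if trains else np.empty(0)
    pooled_e = np.concatenate(
        [np.full(t.n_spikes, t.electrode_id) for t in trains]
    ) if trains else np.empty(0)
    order = np.argsort(pooled_t, kind="stable")
    pooled_t, pooled_e = pooled_t[order], pooled_e[order]
    events = []
    for run in _isi_runs(pooled_t, max_isi):
        n = run.stop - run.start
        if n < min_spikes:
            continue
        contributing = set(pooled_e[run].astype(int)) & act_set
        frac = len(contributing) / len(act_set)
        if frac >= min_fraction:
            events.append(
                NetworkBurst(
                    start=float(pooled_t[run.start]),
                    end=float(pooled_t[run.stop - 1]),
                    n_spikes=n,
                    participating_fraction=frac,
                )
            )
    return events


def bin_spike_counts(
    trains: Sequence[SpikeTrain],
    bin_width: float = 0.1,
    duration: Optional[float] = None,
):
    """Spike counts in half-open bins ``[m*w, (m+1)*w)``.

    A spike falling exactly on a bin edge is counted in the right-hand
    bin (the bin whose left edge it sits on).

    Returns
    -------
    (edges, pooled, per_electrode)
        ``edges`` of length ``n_bins + 1``; ``pooled`` the summed counts;
        ``per_electrode`` an ``(n_electrodes, n_bins)`` array in the order
        of ``trains``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if duration is None:
        last = [t.times[-1] for t in trains if t.n_spikes]
        duration = (max(last) + bin_width) if last else bin_width
    n_bins = max(1, int(np.ceil(duration / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    per = np.zeros((len(trains), n_bins), dtype=int)
    for i, t in enumerate(trains):
        if t.n_spikes == 0:
            continue
        idx = np.floor(t.times / bin_width).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        np.add.at(per[i], idx, 1)
    return edges, per.sum(axis=0), per


def synchronicity_coefficient(
    trains: Sequence[SpikeTrain],
    bin_width: float = 0.1,
    duration: Optional[float] = None,
    active: "str | Sequence[int]" = "rate",
) -> float:
    """Mean pairwise Pearson correlation of binned per-electrode counts.

    Computed over active electrode pairs; NaN when fewer than two active
    electrodes or when a count series has zero variance.
    """
    if active == "rate":
        act = set(active_electrodes(trains, duration))
    elif active == "all":
        act = {t.electrode_id for t in trains}
    else:
        act = set(active)
    use = [t for t in trains if t.electrode_id in act]
    if len(use) < 2:
        return float("nan")
    _, _, per = bin_spike_counts(use, bin_width=bin_width, duration=duration)
    sds = per.std(axis=1)
    keep = sds > 0
    if keep.sum() < 2:
        return float("nan")
    corr = np.corrcoef(per[keep])
    iu = np.triu_indices_from(corr, k=1)
    return float(np.mean(corr[iu]))


def summarize_metrics(
    bursts: Sequence[Burst],
    network_bursts: Sequence[NetworkBurst],
    trains: Sequence[SpikeTrain],
    duration: float,
    bin_width: float = 0.1,
    active: "str | Sequence[int]" = "rate",
) -> MEAMetrics:
    """Network summary: network-burst frequency (per minute), mean spikes
    per burst, and the synchronicity coefficient."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    freq = len(network_bursts) / duration * 60.0
    spb = float(np.mean([b.n_spikes for b in bursts])) if bursts else float("nan")
    sync = synchronicity_coefficient(
        trains, bin_width=bin_width, duration=duration, active=active
    )
    if active == "rate":
        n_act = len(active_electrodes(trains, duration))
    elif active == "all":
        n_act = len(trains)
    else:
        n_act = len(set(active))
    return MEAMetrics(
        network_burst_frequency=freq,
        spikes_per_burst=spb,
        synchronicity=sync,
        n_bursts=len(bursts),
        n_network_bursts=len(network_bursts),
        n_active_electrodes=n_act,
    )


def acute_response_summary(pre_counts, post_counts, bin_width: float = 0.1) -> dict:
    """Compare binned spike counts before and after compound addition.

    Parameters
    ----------
    pre_counts, post_counts : array-like
        Pooled spike counts per ``bin_width`` bin for the baseline window
        and the treatment window.

    Returns
    -------
    dict with keys ``pre_rate``, ``post_rate`` (spikes/s), ``fold_change``
    (post/pre; NaN when the baseline rate is zero and the post rate is
    non-zero, 0 when the post window is empty), and ``series`` — a dict of
    the two aligned count arrays.
    """
    pre = np.asarray(pre_counts, dtype=float).ravel()
    post = np.asarray(post_counts, dtype=float).ravel()
    if pre.size == 0 or post.size == 0:
        raise ValueError("both windows must contain at least one bin")
    pre_rate = pre.mean() / bin_width
    post_rate = post.mean() / bin_width
    if post_rate == 0:
        fold = 0.0
    elif pre_rate == 0:
        fold = float("nan")
    else:
        fold = post_rate / pre_rate
    return {
        "pre_rate": float(pre_rate),
        "post_rate": float(post_rate),
        "fold_change": float(fold),
        "series": {"pre": pre, "post": post},
    }
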