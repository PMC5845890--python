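"""Per-neuron calcium event detection and population burst synchrony.

Spontaneous 180-s recordings of neuronal cultures show epochs in which a
large fraction of neurons fire together ("network bursts"). This module
detects per-neuron event onsets from ΔF/F0 traces and groups pooled onsets
into bursts with an explicit, parameterised synchrony definition: a sliding
window (default 1 s) in which at least a minimum fraction (default 20%) of
active neurons have an onset; overlapping qualifying windows are merged
into one burst.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .traces import TimeSeriesTrace

logger = logging.getLogger(__name__)

__all__ = [
    "NeuronEventTrain",
    "NetworkBurst",
    "NetworkMetrics",
    "detect_events",
    "detect_network_bursts",
    "network_metrics",
]


@dataclass
class NeuronEventTrain:
    """Detected calcium-event onsets for one neuron."""

    neuron_id: str
    onsets: np.ndarray  # seconds, strictly increasing

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.size > 1 and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def active(self) -> bool:
        return self.onsets.size > 0


@dataclass
class NetworkBurst:
    """One synchronized population event."""

    onset: float  # s
    window: float  # s, span of the merged cluster
    participants: frozenset
    participation_fraction: float  # of active neurons

    def __post_init__(self) -> None:
        if not 0.0 < self.participation_fraction <= 1.0:
            raise ValueError("participation_fraction must lie in (0, 1]")


@dataclass
class NetworkMetrics:
    """Population-level summary of one recording."""

    burst_frequency: float  # bursts per minute
    mean_participation: Optional[float]  # percent of active neurons, None if no bursts
    active_fraction: float  # percent of all recorded neurons with >= 1 event
    recording_length: float  # s
    n_neurons: int
    n_bursts: int


def detect_events(
    dff: TimeSeriesTrace,
    k: float = 3.0,
    refractory: float = 1.0,
    min_above: int = 3,
    baseline_window: Optional[tuple] = None,
) -> NeuronEventTrain:
    """Detect event onsets as upward threshold crossings of a ΔF/F0 trace.

    The threshold sits k noise SDs above the baseline level (default
    k = 3). The center is the median and the noise scale derives from the
    median absolute successive difference (σ = med|Δy| / (√2·Φ⁻¹(3/4))),
    both computed over the whole recording by default: spontaneous
    recordings have no event-free epoch, and while transients shift and
    inflate moment (or even MAD) estimates badly in busy recordings, they
    barely move the median level and contribute only slow decays to the
    successive differences. Pass ``baseline_window`` to restrict the
    estimate (e.g. a known pre-stimulus segment). A crossing only counts
    when the signal stays above threshold
    for ``min_above`` consecutive samples — a calcium transient outlasts
    many samples while an isolated noise spike does not — and crossings
    closer than ``refractory`` seconds to the previous accepted onset are
    discarded. Hysteresis guards slow transients: after an accepted onset
    the detector re-arms only once the signal has fallen back below half
    the threshold excess, so noise riding on a decaying tail cannot fire a
    second time.
    """
    v = dff.values
    if float(np.min(v)) < -1.0 or (
        float(np.min(v)) >= 0.0 and float(np.median(v)) > 1.0
    ):
        raise ValueError(
            "trace does not look like dF/F0 (values below -1, or strictly "
            "positive with median > 1 as raw fluorescence would be); "
            "normalize first"
        )
    if baseline_window is None:
        base = v
    else:
        base = v[dff.window_mask(*baseline_window)]
    center = float(np.median(base)) if base.size else 0.0
    # med|Δy| of iid Gaussian noise is √2·0.6745·σ
    sigma = float(np.median(np.abs(np.diff(base)))) / 0.95387 if base.size > 1 else 0.0
    excess = k * sigma if sigma > 0 else 0.5 * float(np.max(np.abs(v)) or 1.0)
    thr = center + excess
    rearm_level = center + 0.5 * excess

    above = v > thr
    below_rearm = np.cumsum(v < rearm_level)  # for fast "released since" checks
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    onsets: List[float] = []
    last = -math.inf
    last_idx = 0
    n = v.size
    for i in crossings:
        stop = min(i + min_above, n)
        if stop - i < min_above or not np.all(above[i:stop]):
            continue
        if onsets and below_rearm[i] == below_rearm[last_idx]:
            continue  # still riding the previous transient's tail
        t = float(dff.t[i])
        if t - last >= refractory:
            onsets.append(t)
            last = t
            last_idx = i
    return NeuronEventTrain(neuron_id=dff.trace_id, onsets=np.array(onsets))


def detect_network_bursts(
    trains: Sequence[NeuronEventTrain],
    sync_window: float = 1.0,
    min_participation: float = 0.2,
) -> List[NetworkBurst]:
    """Group pooled event onsets into synchronized network bursts.

    A candidate window is any ``sync_window``-long interval starting at an
    onset in which at least ``min_participation`` of the *active* neurons
    (those with ≥ 1 event anywhere in the recording) have an onset.
    Overlapping candidate windows merge into a single burst whose
    participant set is the union over the merged span.
    """
    active = [tr for tr in trains if tr.active]
    if not active:
        logger.warning("no active event trains: no bursts detectable")
        return []
    n_active = len(active)
    need = max(2, math.ceil(min_participation * n_active))

    times = np.concatenate([tr.onsets for tr in active])
    ids = np.concatenate(
        [np.full(tr.onsets.size, i) for i, tr in enumerate(active)]
    )
    order = np.argsort(times, kind="stable")
    times, ids = times[order], ids[order]

    # qualifying window start indices
    qual_spans: List[tuple] = []
    j = 0
    for i in range(times.size):
        if j < i:
            j = i
        while j + 1 < times.size and times[j + 1] <= times[i] + sync_window:
            j += 1
        if np.unique(ids[i : j + 1]).size >= need:
            qual_spans.append((times[i], times[j]))

    bursts: List[NetworkBurst] = []
    for start, stop in _merge_spans(qual_spans):
        mask = (times >= start) & (times <= stop)
        members = frozenset(active[int(i)].neuron_id for i in np.unique(ids[mask]))
        bursts.append(
            NetworkBurst(
                onset=float(start),
                window=float(stop - start) if stop > start else sync_window,
                participants=members,
                participation_fraction=len(members) / n_active,
            )
        )
    return bursts


def _merge_spans(spans: List[tuple]) -> List[tuple]:
    """Merge overlapping/abutting (start, stop) intervals (input sorted by start)."""
    merged: List[list] = []
    for start, stop in spans:
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], stop)
        else:
            merged.append([start, stop])
    return [tuple(m) for m in merged]


def network_metrics(
    bursts: Sequence[NetworkBurst],
    trains: Sequence[NeuronEventTrain],
    recording_length: float,
) -> NetworkMetrics:
    """Burst frequency (per minute), mean participation and active fraction."""
    if not recording_length > 0:
        raise ValueError("recording_length must be > 0")
    n = len(trains)
    n_active = sum(tr.active for tr in trains)
    freq = len(bursts) / (recording_length / 60.0)
    mean_part = (
        float(np.mean([b.participation_fraction for b in bursts])) * 100.0
        if bursts
        else None
    )
    return NetworkMetrics(
        burst_frequency=freq,
        mean_participation=mean_part,
        active_fraction=100.0 * n_active / n if n else 0.0,
        recording_length=float(recording_length),
        n_neurons=n,
        n_bursts=len(bursts),
    )
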