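"""Wingstroke segmentation and construction of the U and M matrices.

The unit of analysis is the wingstroke (~50 ms at a 20 Hz tethered wingbeat).
This module detects muscle spikes in EMG channels, segments the continuous
torque record into per-wingstroke windows aligned either to the ascending
zero crossing of the Hilbert phase ("phase-triggered") or to the reference
muscle's spike ("spike-triggered"), and assembles

* ``U`` -- the N x k matrix of spike times relative to cycle onset
  (one spike per muscle per wingstroke), column-standardised, and
* ``M`` -- the N x b matrix of torque waveforms (b samples per cycle),
  column-centred and scaled by a single overall factor ``s``.

It also provides the trial-inclusion filter (reference-channel mean spike
rate must exceed 18 spikes/s) and the decile partition of cycles by mean
torque used throughout the downstream reconstruction analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import signal

from .exceptions import DegenerateDataError, InputError

__all__ = [
    "SpikeTable",
    "MotorSignals",
    "WaveformEnsemble",
    "DecilePartition",
    "detect_spikes",
    "filter_trials",
    "hilbert_phase",
    "build_ensemble",
    "build_motor_signals",
    "decile_partition",
    "intersect_cycles",
]

logger = logging.getLogger("motorpls.ensemble")

#: wingstroke window defaults: 50 ms / 500 samples at 10 kHz
DEFAULT_WINDOW_MS = 50.0
DEFAULT_WINDOW_SAMPLES = 500
#: bandpass around the dominant wingstroke frequency, Hz
DEFAULT_BAND = (3.0, 35.0)
DEFAULT_FILTER_ORDER = 8
#: Chebyshev type II stopband attenuation (dB); the filter is applied
#: forward-backward so cycle onsets are not delayed
DEFAULT_STOP_ATTEN_DB = 40.0
#: minimum reference-channel rate for a trial to be analysed, spikes/s
DEFAULT_MIN_RATE = 18.0


@dataclass(frozen=True)
class SpikeTable:
    """Spike event times (seconds) per labelled channel."""

    channels: Mapping[str, np.ndarray]

    def __post_init__(self):
        clean = {}
        for label, times in self.channels.items():
            t = np.asarray(times, dtype=float).ravel()
            if t.size and np.any(np.diff(t) <= 0):
                raise InputError(f"spike times for {label!r} must be strictly increasing")
            clean[label] = t
        object.__setattr__(self, "channels", clean)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.channels[label]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def rate(self, label: str, duration: float) -> float:
        if duration <= 0:
            raise InputError("duration must be positive")
        return self.channels[label].size / duration


@dataclass(frozen=True)
class MotorSignals:
    """Per-cycle spike-timing matrix U with standardisation metadata.

    ``U`` holds the column-standardised timings (mean 0, unit variance,
    population scaling); ``raw`` keeps the unstandardised values in ms
    relative to cycle onset for reporting.
    """

    U: np.ndarray
    raw: np.ndarray
    labels: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    cycle_index: np.ndarray

    @classmethod
    def from_raw(cls, raw, labels, cycle_index=None) -> "MotorSignals":
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        if cycle_index is None:
            cycle_index = np.arange(raw.shape[0])
        center = raw.mean(axis=0)
        scale = raw.std(axis=0)  # population scaling: exact unit variance
        if np.any(scale == 0):
            bad = [labels[j] for j in np.flatnonzero(scale == 0)]
            raise DegenerateDataError(
                f"zero-variance timing column(s) {bad}: cannot standardise"
            )
        return cls(
            U=(raw - center) / scale,
            raw=raw,
            labels=tuple(labels),
            center=center,
            scale=scale,
            cycle_index=np.asarray(cycle_index),
        )

    @property
    def n_cycles(self) -> int:
        return self.U.shape[0]

    def take(self, rows) -> "MotorSignals":
        """Subset of cycles, re-standardised on that subset."""
        rows = np.asarray(rows)
        return MotorSignals.from_raw(self.raw[rows], self.labels, self.cycle_index[rows])

    def with_column(self, values, label: str) -> "MotorSignals":
        """Return a copy with an extra raw column appended (e.g. dt)."""
        raw = np.column_stack([self.raw, np.asarray(values, float)])
        return MotorSignals.from_raw(raw, self.labels + (label,), self.cycle_index)


@dataclass(frozen=True)
class WaveformEnsemble:
    """Aligned torque-waveform matrix M with its scaling metadata.

    ``M`` is column-centred and divided by the single overall scale ``s``
    (the square root of the mean per-element variance), so raw waveforms are
    recovered as ``M * s + sta``. ``sta`` is the pre-centring row mean (the
    ensemble/spike-triggered average) and ``mean_torque`` the per-cycle mean
    torque over the window.
    """

    M: np.ndarray
    sta: np.ndarray
    s: float
    mean_torque: np.ndarray
    onsets: np.ndarray
    mode: str
    window_ms: float
    sample_rate: float
    cycle_index: np.ndarray
    n_dropped: int = 0

    @property
    def n_cycles(self) -> int:
        return self.M.shape[0]

    @property
    def n_samples(self) -> int:
        return self.M.shape[1]

    def raw_rows(self) -> np.ndarray:
        """Uncentred, unscaled waveforms (N x b)."""
        return self.M * self.s + self.sta

    @classmethod
    def from_rows(
        cls,
        rows: np.ndarray,
        sample_rate: float = 10_000.0,
        onsets: np.ndarray | None = None,
        mode: str = "spike",
        cycle_index: np.ndarray | None = None,
        n_dropped: int = 0,
    ) -> "WaveformEnsemble":
        """Build the ensemble directly from extracted per-cycle waveforms."""
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if np.isnan(rows).any():
            raise InputError("waveform rows contain NaN")
        n, b = rows.shape
        sta = rows.mean(axis=0)
        centered = rows - sta
        s = float(np.sqrt(np.mean(centered**2)))
        if s == 0:
            logger.warning("degenerate ensemble: zero variance, scaling refused (s=1)")
            s = 1.0
        if onsets is None:
            onsets = np.arange(n) * b / sample_rate
        if cycle_index is None:
            cycle_index = np.arange(n)
        return cls(
            M=centered / s,
            sta=sta,
            s=s,
            mean_torque=rows.mean(axis=1),
            onsets=np.asarray(onsets, float),
            mode=mode,
            window_ms=b / sample_rate * 1000.0,
            sample_rate=sample_rate,
            cycle_index=np.asarray(cycle_index),
            n_dropped=n_dropped,
        )

    def take(self, rows) -> "WaveformEnsemble":
        """Subset of cycles, re-centred and re-scaled on that subset."""
        rows = np.asarray(rows)
        return WaveformEnsemble.from_rows(
            self.raw_rows()[rows],
            sample_rate=self.sample_rate,
            onsets=self.onsets[rows],
            mode=self.mode,
            cycle_index=self.cycle_index[rows],
        )


@dataclass(frozen=True)
class DecilePartition:
    """Assignment of cycles to groups ordered by per-cycle mean torque."""

    labels: np.ndarray  # group index per cycle, 0 = most negative mean torque
    group_means: np.ndarray  # G x b mean waveforms on uncentred data
    group_mean_torque: np.ndarray  # G
    n_groups: int = 10

    def rows_in_group(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.labels == g)


def detect_spikes(
    emg: np.ndarray,
    sample_rate: float,
    threshold: float | None = None,
    refractory_ms: float = 5.0,
    auto_k: float = 4.0,
    label: str = "ch0",
) -> SpikeTable:
    """Threshold-crossing spike detection on a single EMG channel.

    Returns upward-crossing times; crossings within ``refractory_ms`` of an
    accepted spike are suppressed. With ``threshold=None`` the threshold is
    set automatically to mean + ``auto_k`` standard deviations.
    """
    x = np.asarray(emg, dtype=float)
    if x.ndim != 1:
        raise InputError("emg must be a 1-D series")
    if threshold is None:
        sd = x.std()
        if sd == 0:
            raise DegenerateDataError("flat EMG signal: automatic threshold undefined")
        threshold = x.mean() + auto_k * sd
    above = x >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    refractory = refractory_ms / 1000.0 * sample_rate
    kept = []
    last = -np.inf
    for idx in crossings:
        if idx - last > refractory:
            kept.append(idx)
            last = idx
    times = np.asarray(kept, dtype=float) / sample_rate
    return SpikeTable({label: times})


def filter_trials(
    spikes: SpikeTable,
    duration: float,
    min_rate: float = DEFAULT_MIN_RATE,
    channel: str | None = None,
) -> tuple[bool, float]:
    """Trial-inclusion filter: reference-channel rate must *exceed* min_rate.

    The comparison is a strict inequality, so a trial exactly at the
    threshold fails. Returns ``(passed, rate)``.
    """
    if channel is None:
        channel = spikes.labels[0]
    rate = spikes.rate(channel, duration)
    return rate > min_rate, rate


def hilbert_phase(
    torque: np.ndarray,
    sample_rate: float,
    band: tuple[float, float] = DEFAULT_BAND,
    order: int = DEFAULT_FILTER_ORDER,
    stop_atten_db: float = DEFAULT_STOP_ATTEN_DB,
) -> tuple[np.ndarray, np.ndarray]:
    """Wingstroke phase and cycle-onset times from the torque record.

    The record is band-passed around the dominant wingstroke frequency with
    a Chebyshev type II filter applied forward-backward (zero phase), the
    analytic-signal phase is taken, and cycle onsets are the ascending zero
    crossings of that phase (linearly interpolated between samples).

    Returns
    -------
    (phase, crossings)
        Phase in (-pi, pi] per sample, and onset times in seconds.
    """
    x = np.asarray(torque, dtype=float)
    if x.ndim != 1:
        raise InputError("torque must be a 1-D series")
    min_len = int(3 * sample_rate / band[0])
    if x.size < min_len:
        raise InputError(
            f"series too short for the {band[0]}-{band[1]} Hz band: "
            f"need >= {min_len} samples, got {x.size}"
        )
    sos = signal.cheby2(
        order, stop_atten_db, band, btype="bandpass", fs=sample_rate, output="sos"
    )
    # generous reflection padding: the narrow low band edge gives the filter
    # a long transient that would otherwise distort phase near the record ends
    padlen = int(min(x.size - 1, 10 * sample_rate / band[0]))
    filtered = signal.sosfiltfilt(sos, x, padlen=padlen)
    phase = np.angle(signal.hilbert(filtered))
    # ascending zero crossing: phase passes 0 from below, excluding +-pi wraps
    prev, nxt = phase[:-1], phase[1:]
    idx = np.flatnonzero((prev < 0) & (nxt >= 0) & (nxt - prev < np.pi))
    frac = -prev[idx] / (nxt[idx] - prev[idx])
    crossings = (idx + frac) / sample_rate
    return phase, crossings


def build_ensemble(
    torque: np.ndarray,
    sample_rate: float,
    onsets: np.ndarray,
    window_ms: float = DEFAULT_WINDOW_MS,
    n_samples: int = DEFAULT_WINDOW_SAMPLES,
    mode: str = "phase",
) -> WaveformEnsemble:
    """Extract fixed-length windows at each onset and assemble M.

    Each window starts at the onset (zero-phase crossing in ``phase`` mode,
    reference-channel spike time in ``spike`` mode) and spans ``n_samples``
    samples; the window duration is fixed even when the instantaneous cycle
    period deviates from the nominal wingbeat. Windows that overrun the
    record or contain NaN are dropped and counted.
    """
    x = np.asarray(torque, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    if np.any(np.diff(onsets) < 0):
        raise InputError("onsets must be sorted")
    if mode not in ("phase", "spike"):
        raise InputError(f"unknown alignment mode {mode!r}")
    starts = np.round(onsets * sample_rate).astype(int)
    rows, kept, kept_onsets = [], [], []
    for i, i0 in enumerate(starts):
        win = x[i0 : i0 + n_samples] if i0 >= 0 else np.empty(0)
        if win.size < n_samples or np.isnan(win).any():
            logger.warning("cycle %d dropped: window outside record or contains NaN", i)
            continue
        rows.append(win)
        kept.append(i)
        kept_onsets.append(onsets[i])
    if not rows:
        raise InputError("no complete windows could be extracted")
    n_dropped = len(onsets) - len(rows)
    if n_dropped:
        logger.info("build_ensemble: dropped %d of %d cycles", n_dropped, len(onsets))
    return WaveformEnsemble.from_rows(
        np.asarray(rows),
        sample_rate=sample_rate,
        onsets=np.asarray(kept_onsets),
        mode=mode,
        cycle_index=np.asarray(kept, dtype=int),
        n_dropped=n_dropped,
    )


def build_motor_signals(
    spikes: SpikeTable,
    onsets: np.ndarray,
    window_s: float | None = None,
    labels: tuple[str, ...] | None = None,
) -> MotorSignals:
    """Per-cycle spike times relative to cycle onset, standardised.

    A cycle is retained only when every channel has exactly one spike inside
    ``[onset, onset + window_s)``; others are dropped and logged. Raw values
    are in ms relative to onset.
    """
    onsets = np.asarray(onsets, dtype=float)
    if window_s is None:
        if onsets.size < 2:
            raise InputError("window_s is required with fewer than 2 onsets")
        window_s = float(np.median(np.diff(onsets)))
    if labels is None:
        labels = tuple(spikes.labels)
    raw_rows, kept = [], []
    for i, t0 in enumerate(onsets):
        row = []
        for label in labels:
            st = spikes[label]
            inside = st[(st >= t0) & (st < t0 + window_s)]
            if inside.size != 1:
                break
            row.append((inside[0] - t0) * 1000.0)
        else:
            raw_rows.append(row)
            kept.append(i)
            continue
        logger.warning("cycle %d dropped: channel without exactly one spike", i)
    if not raw_rows:
        raise InputError("no cycles with exactly one spike per channel")
    n_dropped = len(onsets) - len(raw_rows)
    if n_dropped:
        logger.info("build_motor_signals: dropped %d of %d cycles", n_dropped, len(onsets))
    return MotorSignals.from_raw(
        np.asarray(raw_rows), labels, cycle_index=np.asarray(kept, dtype=int)
    )


def intersect_cycles(
    ensemble: WaveformEnsemble, signals: MotorSignals
) -> tuple[WaveformEnsemble, MotorSignals]:
    """Restrict both containers to the cycles they share (by cycle_index)."""
    common = np.intersect1d(ensemble.cycle_index, signals.cycle_index)
    e_rows = np.flatnonzero(np.isin(ensemble.cycle_index, common))
    s_rows = np.flatnonzero(np.isin(signals.cycle_index, common))
    return ensemble.take(e_rows), signals.take(s_rows)


def decile_partition(ensemble: WaveformEnsemble, n_groups: int = 10) -> DecilePartition:
    """Partition cycles into groups ordered by per-cycle mean torque.

    Cycles are ranked by mean torque (ties broken by cycle order); the
    remainder when N is not divisible by ``n_groups`` is spread over the
    lowest-torque groups first, so group sizes differ by at most one. Group
    mean waveforms are computed on the uncentred data.
    """
    n = ensemble.n_cycles
    if n < n_groups:
        raise InputError(f"need at least {n_groups} cycles, got {n}")
    mt = ensemble.mean_torque
    if np.ptp(mt) == 0:
        logger.warning("all per-cycle mean torques equal: deciles formed by index order")
    order = np.argsort(mt, kind="stable")
    base, rem = divmod(n, n_groups)
    sizes = np.full(n_groups, base)
    sizes[:rem] += 1
    labels = np.empty(n, dtype=int)
    raw = ensemble.raw_rows()
    group_means = np.empty((n_groups, ensemble.n_samples))
    group_mt = np.empty(n_groups)
    start = 0
    for g, size in enumerate(sizes):
        rows = order[start : start + size]
        labels[rows] = g
        group_means[g] = raw[rows].mean(axis=0)
        group_mt[g] = mt[rows].mean()
        start += size
    return DecilePartition(
        labels=labels,
        group_means=group_means,
        group_mean_torque=group_mt,
        n_groups=n_groups,
    )
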