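"""Action-potential detection and feature extraction.

Definitions follow standard current-clamp practice: threshold is the
membrane potential at the last upward crossing of dV/dt = 10 V/s before
the spike peak (central differences, linear interpolation between
samples); amplitude is peak minus threshold; half-width is the time the
spike spends above threshold + amplitude/2.  Two single-AP traces are
averaged per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .io import RunConfig, ValidationError, VoltageSweep

__all__ = [
    "SpikeEvent",
    "APFeatureSet",
    "detect_spikes",
    "ap_threshold",
    "ap_amplitude",
    "ap_half_width",
    "extract_ap_features",
    "average_ap_features",
]

logger = logging.getLogger(__name__)

_DEFAULT = RunConfig()


@dataclass(frozen=True)
class SpikeEvent:
    """One detected action potential."""

    peak_index: int
    peak_mV: float
    threshold_index: int | None = None   # sample before the interpolated crossing
    threshold_mV: float | None = None

    def __post_init__(self) -> None:
        if self.threshold_index is not None and self.threshold_index > self.peak_index:
            raise ValidationError("threshold must precede the peak")
        if self.threshold_mV is not None and not self.threshold_mV < self.peak_mV:
            raise ValidationError("threshold must lie below the peak")


@dataclass
class APFeatureSet:
    """Per-AP (or repeat-averaged) threshold, amplitude and half-width."""

    threshold_mV: float | None
    amplitude_mV: float | None
    half_width_ms: float | None
    n_traces_averaged: int = 1

    @property
    def valid(self) -> bool:
        return (
            self.threshold_mV is not None
            and self.amplitude_mV is not None
            and self.half_width_ms is not None
            and self.amplitude_mV > 0
            and self.half_width_ms > 0
        )


def _dvdt(sweep: VoltageSweep) -> np.ndarray:
    """Central-difference dV/dt in V/s (== mV/ms) at the native rate."""
    return np.gradient(sweep.voltage, sweep.dt_ms)


def detect_spikes(sweep: VoltageSweep, config: RunConfig = _DEFAULT) -> list[SpikeEvent]:
    """Find APs as local maxima passing the amplitude/slope criterion.

    A candidate peak is kept when it reaches ``peak_floor_mv`` (0 mV by
    default) or when dV/dt exceeds the 10 V/s criterion in the preceding
    search window and the peak has at least ``peak_min_prominence_mv``
    of prominence.  Peaks closer than the refractory guard
    (``peak_min_separation_ms``) are merged by ``find_peaks``.  Returns
    an empty list for subthreshold sweeps.
    """
    v = sweep.voltage
    guard = max(1, int(round(config.peak_min_separation_ms / sweep.dt_ms)))
    idx, props = find_peaks(v, distance=guard, prominence=0.0)
    if idx.size == 0:
        return []
    dvdt = _dvdt(sweep)
    win = max(1, int(round(config.threshold_search_window_ms / sweep.dt_ms)))
    events = []
    for peak, prom in zip(idx, props["prominences"]):
        if v[peak] < config.peak_floor_mv:
            lo = max(0, peak - win)
            if prom < config.peak_min_prominence_mv or dvdt[lo : peak + 1].max() < config.dvdt_threshold_v_per_s:
                continue
        thr_idx, thr_mv = _threshold_for_peak(sweep, dvdt, int(peak), config)
        events.append(
            SpikeEvent(
                peak_index=int(peak),
                peak_mV=float(v[peak]),
                threshold_index=thr_idx,
                threshold_mV=thr_mv,
            )
        )
    return events


def _threshold_for_peak(
    sweep: VoltageSweep, dvdt: np.ndarray, peak: int, config: RunConfig
) -> tuple[int | None, float | None]:
    thr = config.dvdt_threshold_v_per_s
    win = max(1, int(round(config.threshold_search_window_ms / sweep.dt_ms)))
    lo = max(1, peak - win)
    v = sweep.voltage
    # last upward crossing of the dV/dt criterion before the peak
    for i in range(peak, lo - 1, -1):
        if dvdt[i] >= thr and dvdt[i - 1] < thr:
            f = (thr - dvdt[i - 1]) / (dvdt[i] - dvdt[i - 1])
            return i - 1, float(v[i - 1] + f * (v[i] - v[i - 1]))
    window = dvdt[lo : peak + 1]
    if window.size and np.all(window >= thr):
        # boundary case: the whole window is at/above criterion
        return lo, float(v[lo])
    return None, None


def ap_threshold(sweep: VoltageSweep, spike: SpikeEvent, config: RunConfig = _DEFAULT) -> float | None:
    """Threshold voltage (mV) of one spike, or None when no dV/dt crossing
    exists in the search window (feature-undefined)."""
    _, thr = _threshold_for_peak(sweep, _dvdt(sweep), spike.peak_index, config)
    return thr


def ap_amplitude(sweep: VoltageSweep, spike: SpikeEvent, config: RunConfig = _DEFAULT) -> float | None:
    """Peak voltage relative to threshold, mV."""
    thr = spike.threshold_mV if spike.threshold_mV is not None else ap_threshold(sweep, spike, config)
    if thr is None:
        return None
    return float(sweep.voltage[spike.peak_index] - thr)


def _cross_time_ms(v: np.ndarray, i: int, j: int, level: float, dt_ms: float) -> float:
    """Interpolated time (ms) where v crosses `level` between samples i and j."""
    f = (level - v[i]) / (v[j] - v[i])
    return (i + f * (j - i)) * dt_ms


def ap_half_width(sweep: VoltageSweep, spike: SpikeEvent, config: RunConfig = _DEFAULT) -> float | None:
    """Width (ms) at 50% of amplitude above threshold.

    Linearly interpolated upward and downward crossings of
    threshold + amplitude/2; None when the downstroke is truncated by
    the sweep end (feature-undefined).
    """
    thr = spike.threshold_mV if spike.threshold_mV is not None else ap_threshold(sweep, spike, config)
    if thr is None:
        return None
    v = sweep.voltage
    peak = spike.peak_index
    level = thr + (v[peak] - thr) / 2.0
    up = None
    for i in range(peak, 0, -1):
        if v[i] >= level and v[i - 1] < level:
            up = _cross_time_ms(v, i - 1, i, level, sweep.dt_ms)
            break
    down = None
    for i in range(peak, v.size - 1):
        if v[i] >= level and v[i + 1] < level:
            down = _cross_time_ms(v, i, i + 1, level, sweep.dt_ms)
            break
    if up is None or down is None:
        return None
    return float(down - up)


def extract_ap_features(sweep: VoltageSweep, config: RunConfig = _DEFAULT) -> APFeatureSet:
    """Features of the first AP in a single-AP sweep.

    All fields are None when no spike is detected.
    """
    events = detect_spikes(sweep, config)
    if not events:
        return APFeatureSet(None, None, None)
    spike = events[0]
    return APFeatureSet(
        threshold_mV=spike.threshold_mV,
        amplitude_mV=ap_amplitude(sweep, spike, config),
        half_width_ms=ap_half_width(sweep, spike, config),
    )


def average_ap_features(a: APFeatureSet, b: APFeatureSet | None = None) -> APFeatureSet:
    """Arithmetic mean of two repeat feature sets.

    A single valid input (or one undefined input) is passed through with
    a logged warning, per the two-repeat averaging convention.
    """
    if b is None or not b.valid:
        if b is not None:
            logger.warning("one feature set undefined; returning the other un-averaged")
        else:
            logger.warning("single-trace average requested")
        return APFeatureSet(a.threshold_mV, a.amplitude_mV, a.half_width_ms, n_traces_averaged=1)
    if not a.valid:
        logger.warning("one feature set undefined; returning the other un-averaged")
        return APFeatureSet(b.threshold_mV, b.amplitude_mV, b.half_width_ms, n_traces_averaged=1)
    return APFeatureSet(
        threshold_mV=(a.threshold_mV + b.threshold_mV) / 2.0,
        amplitude_mV=(a.amplitude_mV + b.amplitude_mV) / 2.0,
        half_width_ms=(a.half_width_ms + b.half_width_ms) / 2.0,
        n_traces_averaged=2,
    )
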