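"""I-F curves, evoked spike frequency per step, and maximum firing rate.

The two-repeat 1-s step protocol (-100 to +500 pA by 25) is summarised
as the per-level mean spike count over repeats; with 1-s steps the
evoked frequency in Hz equals the mean count.  "Maximum spike firing
frequency" is the maximum over current levels of the repeat-averaged
evoked frequency (whole-step mean rate); an inverse-minimum-ISI variant
is available through ``RunConfig.max_freq_method``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import RunConfig, ValidationError, VoltageSweep
from .spikes import detect_spikes

__all__ = ["IFCurve", "build_if_curve", "max_firing_frequency", "evoked_frequency_long_table"]

_DEFAULT = RunConfig()


@dataclass
class IFCurve:
    """Spike counts and evoked frequencies on the current-step grid."""

    current_levels_pA: np.ndarray
    counts_repeat1: np.ndarray      # NaN where the level is missing in that repeat
    counts_repeat2: np.ndarray
    step_duration_s: float
    missing_in_one_repeat: np.ndarray = field(default=None)  # bool per level
    min_isi_ms: np.ndarray = field(default=None)  # per level, over both repeats; NaN if < 2 spikes

    def __post_init__(self) -> None:
        n = self.current_levels_pA.size
        if self.counts_repeat1.size != n or self.counts_repeat2.size != n:
            raise ValidationError("count arrays must match the current grid")
        if self.missing_in_one_repeat is None:
            self.missing_in_one_repeat = np.isnan(self.counts_repeat1) | np.isnan(
                self.counts_repeat2
            )
        if self.min_isi_ms is None:
            self.min_isi_ms = np.full(n, np.nan)

    @property
    def evoked_freq_Hz(self) -> np.ndarray:
        counts = np.nanmean(np.vstack([self.counts_repeat1, self.counts_repeat2]), axis=0)
        return counts / self.step_duration_s

    @property
    def max_freq_Hz(self) -> float:
        return float(np.max(self.evoked_freq_Hz)) if self.current_levels_pA.size else 0.0


def _count_map(
    sweeps: Sequence[VoltageSweep], config: RunConfig
) -> tuple[dict[float, int], float, dict[float, float]]:
    counts: dict[float, int] = {}
    min_isi: dict[float, float] = {}
    durations = set()
    for sweep in sweeps:
        step = sweep.step
        if step is None:
            raise ValidationError(f"sweep {sweep.sweep_id} has no step descriptor")
        events = detect_spikes(sweep, config)
        counts[step.amplitude_pA] = len(events)
        durations.add(round(step.duration_s, 9))
        if len(events) >= 2:
            peaks = np.array([e.peak_index for e in events])
            min_isi[step.amplitude_pA] = float(np.min(np.diff(peaks)) * sweep.dt_ms)
    if len(durations) > 1:
        raise ValidationError(f"mixed step durations in one protocol: {sorted(durations)}")
    return counts, (durations.pop() if durations else 1.0), min_isi


def build_if_curve(
    repeat1: Sequence[VoltageSweep],
    repeat2: Sequence[VoltageSweep],
    config: RunConfig = _DEFAULT,
) -> IFCurve:
    """Per-level mean spike counts over the two protocol repeats.

    Levels present in only one repeat use that repeat alone and are
    flagged in ``missing_in_one_repeat``.
    """
    if not repeat1 and not repeat2:
        raise ValidationError("both repeats are empty")
    c1, d1, c1_isi = _count_map(repeat1, config)
    c2, d2, c2_isi = _count_map(repeat2, config)
    if repeat1 and repeat2 and abs(d1 - d2) > 1e-9:
        raise ValidationError("repeats use different step durations")
    grid = np.array(sorted(set(c1) | set(c2)))
    n1 = np.array([c1.get(a, np.nan) for a in grid], dtype=float)
    n2 = np.array([c2.get(a, np.nan) for a in grid], dtype=float)
    isi = np.array(
        [np.nanmin([c1_isi.get(a, np.nan), c2_isi.get(a, np.nan)]) if
         (a in c1_isi or a in c2_isi) else np.nan for a in grid],
        dtype=float,
    )
    return IFCurve(
        current_levels_pA=grid,
        counts_repeat1=n1,
        counts_repeat2=n2,
        step_duration_s=d1 if repeat1 else d2,
        min_isi_ms=isi,
    )


def max_firing_frequency(curve: IFCurve, config: RunConfig = _DEFAULT) -> tuple[float, float | None]:
    """Maximum evoked firing frequency and the current level attaining it.

    Ties resolve to the lowest current; an all-zero curve returns
    (0.0, None).
    """
    if config.max_freq_method == "inverse_min_isi":
        with np.errstate(invalid="ignore"):
            inst = 1000.0 / curve.min_isi_ms
        if np.all(np.isnan(inst)):
            return 0.0, None
        best = int(np.nanargmax(inst))
        return float(inst[best]), float(curve.current_levels_pA[best])
    freqs = curve.evoked_freq_Hz
    if curve.current_levels_pA.size == 0 or np.all(freqs == 0):
        return 0.0, None
    best = int(np.argmax(freqs))  # argmax takes the first (lowest-current) tie
    return float(freqs[best]), float(curve.current_levels_pA[best])


def evoked_frequency_long_table(
    curves: Mapping[str, IFCurve],
    cell_info: pd.DataFrame,
    outcome_name: str = "evoked_spike_freq",
) -> pd.DataFrame:
    """Long-format table feeding the current-adjusted hierarchical model.

    One row per positive current level per cell; zero-spike levels are
    retained (required by the log1p transform).  ``cell_info`` must be
    indexed by cell id and carry the factor columns.
    """
    rows = []
    for cell_id, curve in curves.items():
        if cell_id not in cell_info.index:
            raise ValidationError(f"no metadata for cell {cell_id!r}")
        meta = cell_info.loc[cell_id].to_dict()
        freqs = curve.evoked_freq_Hz
        for level, freq in zip(curve.current_levels_pA, freqs):
            if level <= 0:
                continue
            rows.append(
                dict(
                    cell_id=cell_id,
                    **meta,
                    current_pA=float(level),
                    outcome_name=outcome_name,
                    outcome_value=float(freq),
                )
            )
    return pd.DataFrame(rows)
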