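"""Readers and writers for sweeps, cell tables and run configuration.

All downstream modules consume the containers defined here; nothing else
in the package parses files.  Units are fixed pipeline-wide: voltage in
mV, current in pA, time in seconds for protocol metadata and in ms for
reported features, resistance in MΩ, capacitance in pF, lengths in µm,
volumes in mm³.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StepDescriptor",
    "VoltageSweep",
    "CellRecord",
    "RunConfig",
    "FormatError",
    "IntegrityError",
    "ValidationError",
    "InsufficientDataError",
    "read_sweeps",
    "write_sweeps",
    "read_cell_table",
    "write_cell_table",
    "FACTOR_LEVELS",
]


class FormatError(ValueError):
    """A file does not follow the declared on-disk format."""


class IntegrityError(ValueError):
    """Internally inconsistent data (e.g. mismatched array lengths)."""


class ValidationError(ValueError):
    """A value falls outside the documented domain."""


class InsufficientDataError(ValueError):
    """Fewer observations than an operation requires."""


@dataclass(frozen=True)
class StepDescriptor:
    """A rectangular current step riding on a constant baseline.

    Attributes
    ----------
    baseline_pA : float
        Holding current outside the step, pA.
    amplitude_pA : float
        Step amplitude relative to baseline, pA.
    onset_s, duration_s : float
        Step onset and duration in seconds from the sweep start.
    """

    baseline_pA: float
    amplitude_pA: float
    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValidationError(f"step duration must be > 0, got {self.duration_s}")
        if self.onset_s < 0:
            raise ValidationError(f"step onset must be >= 0, got {self.onset_s}")

    def waveform(self, n_samples: int, sampling_rate: float) -> np.ndarray:
        """Materialise the step as a per-sample current array in pA."""
        t_end = n_samples / sampling_rate
        if self.onset_s + self.duration_s > t_end + 1e-12:
            raise ValidationError("step extends past the end of the sweep")
        i = np.full(n_samples, self.baseline_pA, dtype=float)
        a = int(round(self.onset_s * sampling_rate))
        b = int(round((self.onset_s + self.duration_s) * sampling_rate))
        i[a:b] += self.amplitude_pA
        return i


@dataclass
class VoltageSweep:
    """One membrane-potential time series plus its injected current.

    ``current`` is either a per-sample array (pA, same length as
    ``voltage``) or a :class:`StepDescriptor`.
    """

    sweep_id: str
    sampling_rate: float  # Hz
    voltage: np.ndarray  # mV
    current: np.ndarray | StepDescriptor
    t0: float = 0.0  # s

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.voltage.ndim != 1 or self.voltage.size == 0:
            raise IntegrityError("voltage must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.voltage)):
            raise IntegrityError(f"sweep {self.sweep_id}: non-finite voltage samples")
        if not self.sampling_rate > 0:
            raise FormatError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not isinstance(self.current, StepDescriptor):
            self.current = np.asarray(self.current, dtype=float)
            if self.current.shape != self.voltage.shape:
                raise IntegrityError(
                    f"sweep {self.sweep_id}: voltage has {self.voltage.size} samples "
                    f"but current has {self.current.size}"
                )
            if not np.all(np.isfinite(self.current)):
                raise IntegrityError(f"sweep {self.sweep_id}: non-finite current samples")
        else:
            # validate the descriptor against the sweep duration
            self.current.waveform(self.voltage.size, self.sampling_rate)

    @property
    def n_samples(self) -> int:
        return int(self.voltage.size)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def time_s(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def current_waveform(self) -> np.ndarray:
        """Injected current as a per-sample array in pA."""
        if isinstance(self.current, StepDescriptor):
            return self.current.waveform(self.n_samples, self.sampling_rate)
        return self.current

    @property
    def step(self) -> StepDescriptor | None:
        return self.current if isinstance(self.current, StepDescriptor) else None


# --------------------------------------------------------------------------
# cell tables

FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "group": ("sham", "stroke"),
    "hemisphere": ("contralesional", "ipsilesional"),
    "layer": ("L2/3", "L5"),
    "sex": ("female", "male"),
    "gfp": ("negative", "positive", "unknown"),
}

# accepted spellings (lower-cased) -> canonical level
_SYNONYMS: dict[str, dict[str, str]] = {
    "hemisphere": {"ipsilateral": "ipsilesional", "peri-infarct": "ipsilesional"},
    "layer": {"2/3": "L2/3", "layer 2/3": "L2/3", "5": "L5", "layer 5": "L5"},
    "gfp": {"+": "positive", "-": "negative", "gfp+": "positive", "gfp-": "negative"},
}

REQUIRED_CELL_COLUMNS = (
    "animal_id",
    "group",
    "hemisphere",
    "layer",
    "sex",
    "outcome_name",
    "outcome_value",
)


@dataclass(frozen=True)
class CellRecord:
    """One measured outcome for one cell in the factorial design."""

    animal_id: str
    group: str
    hemisphere: str
    layer: str
    sex: str
    gfp: str
    outcome_name: str
    outcome_value: float

    def __post_init__(self) -> None:
        for factor in ("group", "hemisphere", "layer", "sex", "gfp"):
            value = getattr(self, factor)
            if value not in FACTOR_LEVELS[factor]:
                raise ValidationError(f"{factor}={value!r} not in {FACTOR_LEVELS[factor]}")
        if not np.isfinite(self.outcome_value):
            raise ValidationError("outcome_value must be finite")


def canonical_level(factor: str, value: str) -> str:
    """Map a case-insensitive spelling onto the canonical factor level."""
    text = str(value).strip()
    low = text.lower()
    for level in FACTOR_LEVELS[factor]:
        if low == level.lower():
            return level
    syn = _SYNONYMS.get(factor, {})
    if low in syn:
        return syn[low]
    raise ValidationError(f"unknown {factor} level {value!r}; expected one of {FACTOR_LEVELS[factor]}")


def validate_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    """Canonicalise factor levels and check the cell-table schema.

    Returns a copy with canonical levels; raises :class:`ValidationError`
    listing offending rows on any unknown level.
    """
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cell table missing required columns: {missing}")
    out = df.copy()
    if "gfp" not in out.columns:
        out["gfp"] = "unknown"
    bad: list[str] = []
    for factor in ("group", "hemisphere", "layer", "sex", "gfp"):
        canon = []
        for idx, value in out[factor].items():
            try:
                canon.append(canonical_level(factor, value))
            except ValidationError:
                bad.append(f"row {idx}: {factor}={value!r}")
                canon.append(None)
        out[factor] = canon
    if bad:
        raise ValidationError("invalid factor levels:\n  " + "\n  ".join(bad))
    out["outcome_value"] = out["outcome_value"].astype(float)
    if not np.all(np.isfinite(out["outcome_value"])):
        raise ValidationError("outcome_value contains non-finite entries")
    out["animal_id"] = out["animal_id"].astype(str)
    return out


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format cell table (CSV) and validate factor levels."""
    return validate_cell_table(pd.read_csv(path))


def write_cell_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_cell_table(df).to_csv(path, index=False)


def cell_records(df: pd.DataFrame) -> list[CellRecord]:
    """The validated table as a list of :class:`CellRecord`."""
    df = validate_cell_table(df)
    return [
        CellRecord(
            animal_id=r.animal_id,
            group=r.group,
            hemisphere=r.hemisphere,
            layer=r.layer,
            sex=r.sex,
            gfp=r.gfp,
            outcome_name=r.outcome_name,
            outcome_value=float(r.outcome_value),
        )
        for r in df.itertuples(index=False)
    ]


# --------------------------------------------------------------------------
# native sweep format
#
# A delimited text file.  '#'-prefixed header lines carry per-file and
# per-sweep metadata as key=value tokens; the body is a CSV in long
# format with columns sweep_id, voltage_mv [, current_pa].  Floats are
# printed with %.17g so the round trip is bit-for-bit for float64.

_MAGIC = "strokephys-sweeps v1"


def _format_float(x: float) -> str:
    return format(float(x), ".17g")


def write_sweeps(sweeps: Sequence[VoltageSweep], path: str | Path) -> None:
    """Write sweeps in the native delimited-text format.

    ``read_sweeps`` after ``write_sweeps`` is the identity, bit-for-bit.
    An empty collection produces a valid header-only file.
    """
    sweeps = list(sweeps)
    any_sampled = any(s.step is None for s in sweeps)
    lines = [f"# {_MAGIC}", f"# n_sweeps={len(sweeps)}"]
    for s in sweeps:
        kv = [
            f"id={s.sweep_id}",
            f"rate_hz={_format_float(s.sampling_rate)}",
            f"t0_s={_format_float(s.t0)}",
            f"n={s.n_samples}",
        ]
        if s.step is not None:
            d = s.step
            kv += [
                "current=step",
                f"baseline_pa={_format_float(d.baseline_pA)}",
                f"amplitude_pa={_format_float(d.amplitude_pA)}",
                f"onset_s={_format_float(d.onset_s)}",
                f"duration_s={_format_float(d.duration_s)}",
            ]
        else:
            kv.append("current=samples")
        lines.append("# sweep " + " ".join(kv))
    header = "\n".join(lines) + "\n"

    frames = []
    for s in sweeps:
        frame = {"sweep_id": s.sweep_id, "voltage_mv": s.voltage}
        if any_sampled:
            frame["current_pa"] = (
                s.current if s.step is None else np.full(s.n_samples, np.nan)
            )
        frames.append(pd.DataFrame(frame))
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(header)
        if sweeps:
            body = pd.concat(frames, ignore_index=True)
            body.to_csv(fh, index=False, float_format="%.17g")


def _parse_header(lines: list[str]) -> list[dict[str, str]]:
    if not lines or lines[0].strip() != f"# {_MAGIC}":
        raise FormatError(f"not a {_MAGIC} file")
    metas = []
    for line in lines[1:]:
        body = line.lstrip("#").strip()
        if body.startswith("sweep "):
            tokens = body[len("sweep "):].split()
            metas.append(dict(t.split("=", 1) for t in tokens))
    return metas


def read_sweeps(path: str | Path, format: str = "tabular") -> list[VoltageSweep]:
    """Read sweeps written by :func:`write_sweeps`.

    Parameters
    ----------
    path : path
        File in the native format.
    format : {"tabular"}
        On-disk representation; only the native delimited text format is
        implemented (vendor formats are an extension point).
    """
    if format != "tabular":
        raise FormatError(f"unknown sweep format {format!r}")
    path = Path(path)
    header_lines: list[str] = []
    with open(path) as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            header_lines.append(line.rstrip("\n"))
        rest = fh.read()
    metas = _parse_header(header_lines)
    if not metas:
        return []
    body = pd.read_csv(_io.StringIO(rest), dtype={"sweep_id": str}, float_precision="round_trip")
    if "voltage_mv" not in body.columns:
        raise FormatError("sweep file body missing voltage_mv column")

    sweeps: list[VoltageSweep] = []
    grouped = {k: g for k, g in body.groupby("sweep_id", sort=False)}
    for meta in metas:
        for key in ("id", "rate_hz", "t0_s", "n", "current"):
            if key not in meta:
                raise FormatError(f"sweep header missing field {key!r}")
        sid = meta["id"]
        if sid not in grouped:
            raise IntegrityError(f"no samples for sweep {sid!r}")
        g = grouped[sid]
        if len(g) != int(meta["n"]):
            raise IntegrityError(
                f"sweep {sid!r}: header declares {meta['n']} samples, file has {len(g)}"
            )
        voltage = g["voltage_mv"].to_numpy(dtype=float)
        current: np.ndarray | StepDescriptor
        if meta["current"] == "step":
            current = StepDescriptor(
                baseline_pA=float(meta["baseline_pa"]),
                amplitude_pA=float(meta["amplitude_pa"]),
                onset_s=float(meta["onset_s"]),
                duration_s=float(meta["duration_s"]),
            )
        elif meta["current"] == "samples":
            if "current_pa" not in g.columns:
                raise FormatError(f"sweep {sid!r} declares sampled current but column is absent")
            current = g["current_pa"].to_numpy(dtype=float)
        else:
            raise FormatError(f"unknown current kind {meta['current']!r}")
        sweeps.append(
            VoltageSweep(
                sweep_id=sid,
                sampling_rate=float(meta["rate_hz"]),
                voltage=voltage,
                current=current,
                t0=float(meta["t0_s"]),
            )
        )
    return sweeps


# --------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Every tunable in the pipeline, with documented defaults.

    Read from a ``key = value`` text file via :meth:`from_file`; unknown
    keys are an error.
    """

    # passive-property analysis
    baseline_window_ms: float = 100.0     # RMP window before any step
    steady_state_window_ms: float = 100.0  # tail of each 1-s step
    tau_fit_skip_samples: int = 2          # pipette transient skip after onset
    tau_fit_n_tau: float = 5.0             # fit-window length in estimated taus
    series_r_max_change: float = 0.20      # QC exclusion threshold

    # spike detection / AP features
    dvdt_threshold_v_per_s: float = 10.0
    threshold_search_window_ms: float = 5.0
    peak_min_separation_ms: float = 1.0    # refractory guard
    peak_floor_mv: float = 0.0
    peak_min_prominence_mv: float = 20.0

    # firing analysis
    max_freq_method: str = "mean_rate"     # or "inverse_min_isi"

    # AIS morphometry
    ais_threshold_fraction: float = 0.33
    ais_smooth_window_um: float = 1.0
    ais_baseline_flank_fraction: float = 0.10
    profile_spacing_um: float = 0.1
    min_stratum_n: int = 1

    # lesion volumetry
    section_thickness_um: float = 30.0
    series_factor: int = 3

    # estimation statistics
    n_boot: int = 5000
    ci_level: float = 0.95
    bootstrap_method: str = "percentile"   # or "bca"

    # Bayesian inference
    chains: int = 4
    iterations: int = 2000
    warmup: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_freq_method not in ("mean_rate", "inverse_min_isi"):
            raise ValidationError(f"unknown max_freq_method {self.max_freq_method!r}")
        if self.bootstrap_method not in ("percentile", "bca"):
            raise ValidationError(f"unknown bootstrap_method {self.bootstrap_method!r}")
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must be in (0, 1)")
        if self.warmup >= self.iterations:
            raise ValidationError("warmup must be smaller than iterations")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"line {lineno}: expected 'key = value', got {raw!r}")
            key, value = (t.strip() for t in line.split("=", 1))
            if key not in fields:
                raise ValidationError(f"unknown configuration key {key!r}")
            ftype = fields[key].type
            if ftype == "int":
                kwargs[key] = int(value)
            elif ftype == "float":
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")
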