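"""Axon-initial-segment morphometry and lesion volumetry.

The AIS is delimited on an Ankyrin-G fluorescence line profile as the
first and last points where intensity falls to a fixed fraction (0.33 by
default) of the maximum, after optional smoothing and baseline removal.
Lesion volume follows the standard serial-section estimator: traced area
per section x section thickness x sampling series factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .io import FormatError, IntegrityError, ValidationError

__all__ = [
    "FluorescenceProfile",
    "AISBounds",
    "LesionSeries",
    "SomaDistance",
    "read_profile",
    "write_profile",
    "sample_profile_from_image",
    "detect_ais_bounds",
    "distance_from_soma",
    "aggregate_per_stratum",
    "lesion_volume",
    "compare_projection_length",
]


@dataclass
class FluorescenceProfile:
    """Intensity versus arc length along a traced axon."""

    arc_length_um: np.ndarray
    intensity: np.ndarray
    source: str = "tabular"

    def __post_init__(self) -> None:
        self.arc_length_um = np.asarray(self.arc_length_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.arc_length_um.shape != self.intensity.shape or self.arc_length_um.ndim != 1:
            raise IntegrityError("arc_length_um and intensity must be equal-length 1-D arrays")
        if self.arc_length_um.size < 2:
            raise IntegrityError("profile needs at least two samples")
        if np.any(np.diff(self.arc_length_um) <= 0):
            raise IntegrityError("arc_length_um must be strictly increasing")
        if np.any(self.intensity < 0) or not np.all(np.isfinite(self.intensity)):
            raise IntegrityError("intensity must be finite and >= 0")


@dataclass(frozen=True)
class AISBounds:
    """Detected AIS start/end along the traced axon, in µm."""

    start_um: float
    end_um: float
    max_intensity: float
    threshold_fraction: float

    def __post_init__(self) -> None:
        if not self.start_um < self.end_um:
            raise ValidationError("AIS start must precede end")

    @property
    def length_um(self) -> float:
        return self.end_um - self.start_um


@dataclass(frozen=True)
class LesionSeries:
    """Per-section traced lesion areas from a 1-in-k section series."""

    section_areas_um2: tuple[float, ...]
    thickness_um: float = 30.0
    series_factor: int = 3

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.section_areas_um2):
            raise ValidationError("section areas must be >= 0")
        if not self.thickness_um > 0:
            raise ValidationError("section thickness must be > 0")
        if int(self.series_factor) != self.series_factor or self.series_factor < 1:
            raise ValidationError("series_factor must be an integer >= 1")


class SomaDistance(NamedTuple):
    distance_um: float
    overlaps_soma: bool


def read_profile(path: str | Path) -> FluorescenceProfile:
    """Read a 2-column (arc_length_um, intensity) CSV profile."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("arc_length_um", "intensity"):
        if col not in df.columns:
            raise FormatError(f"profile file missing column {col!r}")
    return FluorescenceProfile(df["arc_length_um"].to_numpy(), df["intensity"].to_numpy())


def write_profile(profile: FluorescenceProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"arc_length_um": profile.arc_length_um, "intensity": profile.intensity}
    ).to_csv(path, index=False, float_format="%.17g")


def _resample_polyline(points: np.ndarray, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Equal-arc-length resampling; returns (positions_um, xy points)."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise ValidationError("polyline has zero length")
    s = np.arange(0.0, total + spacing / 2, spacing)
    s[-1] = min(s[-1], total)
    x = np.interp(s, cum, points[:, 0])
    y = np.interp(s, cum, points[:, 1])
    return s, np.column_stack([x, y])


def sample_profile_from_image(
    image: np.ndarray | str | Path,
    polyline_um: np.ndarray,
    width_um: float = 0.0,
    pixel_size_um: float = 1.0,
    spacing_um: float = 0.1,
) -> FluorescenceProfile:
    """Sample intensity along a traced polyline on a max-projection image.

    Bilinear interpolation at fixed arc-length spacing; when
    ``width_um > 0`` the intensity is averaged across perpendicular
    offsets spanning that width.  Polyline coordinates are (x, y) in µm
    with the origin at the centre of pixel (0, 0).
    """
    if isinstance(image, (str, Path)):
        import tifffile

        image = tifffile.imread(image)
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValidationError("expected a single-channel 2-D image")
    polyline_um = np.asarray(polyline_um, dtype=float)
    if polyline_um.ndim != 2 or polyline_um.shape[0] < 2 or polyline_um.shape[1] != 2:
        raise ValidationError("polyline must be an (n >= 2, 2) array of (x, y) µm coordinates")

    s, pts = _resample_polyline(polyline_um, spacing_um)
    # unit tangents -> normals for the perpendicular averaging
    tangent = np.gradient(pts, axis=0)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])

    if width_um > 0:
        n_off = max(3, int(round(width_um / pixel_size_um)) * 2 + 1)
        offsets = np.linspace(-width_um / 2, width_um / 2, n_off)
    else:
        offsets = np.array([0.0])

    samples = np.empty((offsets.size, s.size))
    for k, off in enumerate(offsets):
        xy = pts + off * normal
        cols = xy[:, 0] / pixel_size_um
        rows = xy[:, 1] / pixel_size_um
        if (
            rows.min() < -1e-9
            or cols.min() < -1e-9
            or rows.max() > image.shape[0] - 1 + 1e-9
            or cols.max() > image.shape[1] - 1 + 1e-9
        ):
            raise ValidationError("polyline (or its width band) falls outside the image")
        samples[k] = map_coordinates(image, [rows, cols], order=1, mode="nearest")
    return FluorescenceProfile(s, samples.mean(axis=0), source="image+polyline")


def _moving_average(y: np.ndarray, window_samples: int) -> np.ndarray:
    if window_samples <= 1:
        return y
    kernel = np.ones(window_samples) / window_samples
    pad = window_samples // 2
    padded = np.pad(y, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + y.size]
    return out


def detect_ais_bounds(
    profile: FluorescenceProfile,
    threshold_fraction: float = 0.33,
    smooth_window_um: float = 0.0,
    baseline_flank_fraction: float = 0.10,
) -> AISBounds | None:
    """Locate AIS start/end as threshold crossings of the intensity profile.

    The profile is optionally smoothed with a moving average, a baseline
    (median of the flanking ``baseline_flank_fraction`` of samples at
    each end) is subtracted, and the AIS spans the first upward and last
    downward crossing of ``threshold_fraction`` x the maximum of the
    baseline-subtracted profile, linearly interpolated.  Interior dips
    below threshold are bridged (first-rise / last-fall rule).

    Returns ``None`` when the profile never exceeds the threshold
    (no-AIS flag).
    """
    if not 0 < threshold_fraction < 1:
        raise ValidationError("threshold_fraction must be in (0, 1)")
    x = profile.arc_length_um
    dx = float(np.median(np.diff(x)))
    window = int(round(smooth_window_um / dx)) if smooth_window_um > 0 else 0
    y = _moving_average(profile.intensity, window)

    n_flank = max(1, int(round(baseline_flank_fraction * y.size)))
    baseline = float(np.median(np.concatenate([y[:n_flank], y[-n_flank:]])))
    rel = y - baseline
    peak = float(rel.max())
    if peak <= 0:
        return None
    thr = threshold_fraction * peak
    above = rel >= thr
    if not above.any():
        return None

    first = int(np.argmax(above))
    last = int(y.size - 1 - np.argmax(above[::-1]))
    if first == 0:
        start = float(x[0])
    else:
        f = (thr - rel[first - 1]) / (rel[first] - rel[first - 1])
        start = float(x[first - 1] + f * (x[first] - x[first - 1]))
    if last == y.size - 1:
        end = float(x[-1])
    else:
        f = (rel[last] - thr) / (rel[last] - rel[last + 1])
        end = float(x[last] + f * (x[last + 1] - x[last]))
    return AISBounds(
        start_um=start,
        end_um=end,
        max_intensity=peak + baseline,
        threshold_fraction=threshold_fraction,
    )


def distance_from_soma(soma_end_um: float, ais_start_um: float) -> SomaDistance:
    """AIS start position relative to the end of the soma label.

    Negative distances (AIS overlapping the soma signal) are flagged,
    not rejected.
    """
    d = float(ais_start_um) - float(soma_end_um)
    return SomaDistance(distance_um=d, overlaps_soma=d < 0)


def aggregate_per_stratum(
    df: pd.DataFrame,
    value_col: str = "outcome_value",
    keys: Sequence[str] = ("animal_id", "hemisphere", "layer"),
    min_n: int = 1,
) -> pd.DataFrame:
    """Per-stratum (animal x hemisphere x layer) means of per-cell measures.

    Returns one row per non-empty stratum with columns ``mean``, ``n``
    and ``low_n`` (True when a stratum holds fewer than ``min_n`` cells).
    """
    grouped = df.groupby(list(keys), observed=True)[value_col]
    out = grouped.agg(mean="mean", n="size").reset_index()
    out["low_n"] = out["n"] < min_n
    return out


def lesion_volume(series: LesionSeries) -> float:
    """Total lesion volume in mm³ from a serial-section area series.

    sum(area_i x thickness) x series_factor / 1e9 (µm³ -> mm³).
    """
    total_um3 = float(np.sum(series.section_areas_um2)) * series.thickness_um
    return total_um3 * series.series_factor / 1e9


class ProjectionLengths(NamedTuple):
    length3d_um: float
    length2d_um: float


def compare_projection_length(path3d_um: np.ndarray) -> ProjectionLengths:
    """Arc length of a 3-D traced path and of its XY (max-projection) shadow."""
    pts = np.asarray(path3d_um, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValidationError("expected an (n >= 2, 3) array of µm coordinates")
    d3 = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    d2 = float(np.linalg.norm(np.diff(pts[:, :2], axis=0), axis=1).sum())
    return ProjectionLengths(length3d_um=d3, length2d_um=d2)
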