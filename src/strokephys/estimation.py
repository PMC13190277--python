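"""Two-group estimation statistics with bootstrap confidence intervals.

Implements the Gardner-Altman/Cumming style analysis: group descriptives
plus the unpaired mean difference with a seeded bootstrap CI (resampling
within groups, with replacement).  The percentile interval is the
default; a bias-corrected-and-accelerated (BCa) variant is available.
Orientation convention: the difference is group_b minus group_a, so with
(a, b) = (sham, stroke) positive differences mean larger values after
stroke (and likewise GFP+ minus GFP-).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import InsufficientDataError, ValidationError

__all__ = ["EstimationResult", "unpaired_mean_difference", "cumming_export"]


@dataclass
class EstimationResult:
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    mean_diff: float          # mean_b - mean_a
    ci_low: float
    ci_high: float
    n_boot: int
    ci_level: float
    seed: int | None
    method: str = "percentile"


def _boot_means(values: np.ndarray, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    return values[idx].mean(axis=1)


def unpaired_mean_difference(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_boot: int = 5000,
    ci: float = 0.95,
    seed: int | None = None,
    method: str = "percentile",
) -> EstimationResult:
    """Unpaired mean difference (b - a) with a bootstrap CI.

    Resamples each group independently with replacement ``n_boot`` times
    (5000 by default, matching common estimation-statistics practice)
    and takes the percentile (or BCa) interval of the resampled
    differences.  Deterministic for a given seed.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    if method not in ("percentile", "bca"):
        raise ValidationError(f"unknown bootstrap method {method!r}")
    rng = np.random.default_rng(seed)
    diffs = _boot_means(b, n_boot, rng) - _boot_means(a, n_boot, rng)
    observed = float(b.mean() - a.mean())
    alpha = 1.0 - ci
    if method == "percentile":
        lo, hi = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
    else:
        lo, hi = _bca_interval(a, b, diffs, observed, alpha)
    return EstimationResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=int(a.size),
        n_b=int(b.size),
        mean_diff=observed,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        ci_level=ci,
        seed=seed,
        method=method,
    )


def _bca_interval(
    a: np.ndarray, b: np.ndarray, diffs: np.ndarray, observed: float, alpha: float
) -> tuple[float, float]:
    # bias correction from the bootstrap distribution
    p0 = np.clip(np.mean(diffs < observed), 1e-9, 1 - 1e-9)
    z0 = norm.ppf(p0)
    # acceleration from jackknife influence values over both groups
    jack = []
    for i in range(a.size):
        jack.append(b.mean() - np.delete(a, i).mean())
    for i in range(b.size):
        jack.append(np.delete(b, i).mean() - a.mean())
    jack = np.asarray(jack)
    infl = jack.mean() - jack
    denom = 6.0 * np.sum(infl**2) ** 1.5
    acc = np.sum(infl**3) / denom if denom > 0 else 0.0
    out = []
    for q in (alpha / 2, 1 - alpha / 2):
        z = z0 + norm.ppf(q)
        adj = norm.cdf(z0 + z / (1 - acc * z))
        out.append(np.quantile(diffs, np.clip(adj, 0.0, 1.0)))
    return float(out[0]), float(out[1])


def cumming_export(
    results: Mapping[str, EstimationResult],
    raw: Mapping[str, tuple[Sequence[float], Sequence[float]]] | None = None,
    labels: tuple[str, str] = ("sham", "stroke"),
) -> pd.DataFrame:
    """Plot-ready tidy table for Cumming estimation graphics.

    Row kinds: ``raw`` (individual points, when provided),
    ``group_summary`` (mean, SD, n per group) and ``difference`` (the
    difference-axis row with bootstrap CI).  The column schema is stable
    across outcomes.
    """
    columns = [
        "outcome", "kind", "group", "value", "mean", "sd", "n",
        "mean_diff", "ci_low", "ci_high", "n_boot", "ci_level",
    ]
    rows: list[dict] = []
    for outcome, res in results.items():
        if raw and outcome in raw:
            for label, values in zip(labels, raw[outcome]):
                for v in values:
                    rows.append(dict(outcome=outcome, kind="raw", group=label, value=float(v)))
        for label, mean, sd, n in (
            (labels[0], res.mean_a, res.sd_a, res.n_a),
            (labels[1], res.mean_b, res.sd_b, res.n_b),
        ):
            rows.append(
                dict(outcome=outcome, kind="group_summary", group=label, mean=mean, sd=sd, n=n)
            )
        rows.append(
            dict(
                outcome=outcome,
                kind="difference",
                group=f"{labels[1]}-{labels[0]}",
                mean_diff=res.mean_diff,
                ci_low=res.ci_low,
                ci_high=res.ci_high,
                n_boot=res.n_boot,
                ci_level=res.ci_level,
            )
        )
    return pd.DataFrame(rows, columns=columns)
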