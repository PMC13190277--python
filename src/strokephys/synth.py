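"""Synthetic data with known ground truth for every analysis stage.

The generators emulate the study conditions: passive RC responses to 1-s
hyperpolarising steps, leaky-integrate-and-fire (LIF) spiking with a
piecewise-linear action-potential template (so threshold, amplitude and
half-width have closed forms), trapezoidal Ankyrin-G intensity profiles
with analytic 0.33-of-max crossings, serial lesion sections, and
hierarchical factorial cohorts with declared fixed effects and
animal-level random intercept + hemisphere slope.

Subthreshold dynamics use the exact exponential-update discretisation of
the linear membrane ODE (not Euler), so noiseless traces match the
closed form to machine precision.  Identical seeds give identical
outputs everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .design import design_matrix
from .io import StepDescriptor, ValidationError, VoltageSweep
from .morphometry import FluorescenceProfile, LesionSeries, lesion_volume

__all__ = [
    "PassiveModel",
    "SpikingModel",
    "CohortSpec",
    "simulate_passive",
    "simulate_spiking",
    "simulate_single_ap_protocol",
    "simulate_ais_profile",
    "simulate_cohort",
    "simulate_lesion_sections",
    "lif_rheobase",
    "lif_steady_rate",
    "if_step_grid",
    "SingleAPProtocolResult",
    "AISProfileTruth",
    "CohortTruth",
]

#: numerical tolerance (mV) for the threshold test V >= V_T.  At the exact
#: rheobase current the membrane approaches threshold only asymptotically,
#: so a strict comparison would leave the on-grid rheobase undefined.
THRESHOLD_TOL_MV = 1e-9


@dataclass(frozen=True)
class PassiveModel:
    """Passive RC membrane: resting potential, input resistance, time constant."""

    E_L: float = -70.0       # mV
    R_in: float = 150.0      # MΩ
    tau_m: float = 20.0      # ms
    noise_sd: float = 0.0    # mV, stationary SD of the OU process noise

    def __post_init__(self) -> None:
        if not self.R_in > 0:
            raise ValidationError("R_in must be > 0")
        if not self.tau_m > 0:
            raise ValidationError("tau_m must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def steady_state_mv(self, current_pA: float) -> float:
        """Asymptotic membrane potential under a constant current (pA)."""
        return self.E_L + current_pA * self.R_in / 1000.0


@dataclass(frozen=True)
class SpikingModel(PassiveModel):
    """LIF membrane with a piecewise-linear AP template.

    When the membrane reaches ``V_T`` a triangular spike is inserted:
    a linear rise over ``ap_rise_ms`` to ``V_T + ap_peak_amp``, then a
    linear fall that re-crosses threshold ``ap_fall_ms`` after the peak
    and continues at the same rate down to ``V_reset``, where the
    potential is clamped for the rest of ``t_ref`` before integration
    resumes.  The template makes the extracted features analytic:
    threshold ``V_T``, amplitude ``ap_peak_amp``, half-width exactly
    ``(ap_rise_ms + ap_fall_ms)/2``.
    """

    V_T: float = -45.0        # mV
    V_reset: float = -65.0    # mV
    t_ref: float = 3.0        # ms
    ap_peak_amp: float = 100.0  # mV above threshold
    ap_rise_ms: float = 0.4
    ap_fall_ms: float = 0.8

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.V_T > self.E_L:
            raise ValidationError("V_T must exceed E_L")
        if self.V_reset > self.V_T:
            raise ValidationError("V_reset must not exceed V_T")
        if self.ap_peak_amp / self.ap_rise_ms < 50.0:
            raise ValidationError(
                "template initial slope must be >= 50 V/s so the 10 V/s "
                "detector lands within one sample of V_T"
            )
        fall_total_ms = self.ap_fall_ms * (
            (self.ap_peak_amp + self.V_T - self.V_reset) / self.ap_peak_amp
        )
        if self.t_ref < self.ap_rise_ms + fall_total_ms:
            raise ValidationError("AP template longer than the refractory period")

    @property
    def half_width_ms(self) -> float:
        return (self.ap_rise_ms + self.ap_fall_ms) / 2.0


def _subthreshold(
    model: PassiveModel,
    v0: float,
    i_pA: np.ndarray,
    rate: float,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Exact-update trajectory V_{n+1} = V_ss + (V_n - V_ss) a (+ OU noise)."""
    dt_ms = 1000.0 / rate
    a = np.exp(-dt_ms / model.tau_m)
    v_ss = model.E_L + i_pA * model.R_in / 1000.0
    drive = (1.0 - a) * v_ss
    if model.noise_sd > 0 and rng is not None:
        drive = drive + model.noise_sd * np.sqrt(1.0 - a * a) * rng.standard_normal(i_pA.size)
    # recursion V_n = a V_{n-1} + drive_n, seeded with V_0 = v0 at index -1
    out, _ = lfilter([1.0], [1.0, -a], drive, zi=np.array([a * v0]))
    return out


def simulate_passive(
    model: PassiveModel,
    steps: Sequence[StepDescriptor],
    rate: float = 50_000.0,
    seed: int | None = None,
    tail_s: float = 0.1,
) -> list[VoltageSweep]:
    """Simulate the hyperpolarising step family on a passive membrane.

    Noiseless sweeps equal V(t) = E_L + I R (1 - exp(-t/tau)) during the
    step exactly.  Depolarising steps are refused: this model has no
    spike mechanism.
    """
    for s in steps:
        if s.amplitude_pA > 0 or s.baseline_pA > 0:
            raise ValidationError(
                "simulate_passive only accepts hyperpolarising or zero steps"
            )
    rng = np.random.default_rng(seed)
    sweeps = []
    for k, step in enumerate(steps):
        n = int(round((step.onset_s + step.duration_s + tail_s) * rate))
        i_pA = step.waveform(n, rate)
        v = _subthreshold(model, model.E_L, i_pA, rate, rng)
        sweeps.append(
            VoltageSweep(
                sweep_id=f"passive_{k:02d}_{int(step.amplitude_pA)}pA",
                sampling_rate=rate,
                voltage=v,
                current=step,
            )
        )
    return sweeps


@dataclass
class SpikingTruth:
    """Ground truth emitted alongside each simulated spiking sweep."""

    spike_start_indices: list[int]
    threshold_mV: float
    amplitude_mV: float
    half_width_ms: float

    @property
    def n_spikes(self) -> int:
        return len(self.spike_start_indices)


def _template(model: SpikingModel, rate: float) -> np.ndarray:
    dt_ms = 1000.0 / rate
    n_rise = max(1, int(round(model.ap_rise_ms / dt_ms)))
    peak = model.V_T + model.ap_peak_amp
    # fall re-crosses V_T ap_fall_ms after the peak and continues at the
    # same slope to V_reset, keeping the half-width closed form exact
    fall_total_ms = model.ap_fall_ms * ((peak - model.V_reset) / model.ap_peak_amp)
    n_fall = max(1, int(round(fall_total_ms / dt_ms)))
    rise = np.linspace(model.V_T, peak, n_rise + 1)
    fall = np.linspace(peak, model.V_reset, n_fall + 1)[1:]
    return np.concatenate([rise, fall])


def simulate_spiking(
    model: SpikingModel,
    steps: Sequence[StepDescriptor],
    rate: float = 50_000.0,
    seed: int | None = None,
    tail_s: float = 0.1,
) -> tuple[list[VoltageSweep], list[SpikingTruth]]:
    """LIF simulation of a current-step family with template APs.

    The spike count is deterministic for ``noise_sd = 0``; the per-sweep
    ground-truth record carries the template insertion points.
    """
    rng = np.random.default_rng(seed)
    template = _template(model, rate)
    n_ref = int(round(model.t_ref * rate / 1000.0))
    sweeps: list[VoltageSweep] = []
    truths: list[SpikingTruth] = []
    for k, step in enumerate(steps):
        n = int(round((step.onset_s + step.duration_s + tail_s) * rate))
        i_pA = step.waveform(n, rate)
        v = np.empty(n)
        spike_starts: list[int] = []
        pos = 0
        v_prev = model.E_L
        while pos < n:
            seg = _subthreshold(model, v_prev, i_pA[pos:], rate, rng)
            crossing = np.nonzero(seg >= model.V_T - THRESHOLD_TOL_MV)[0]
            if crossing.size == 0:
                v[pos:] = seg
                break
            c = pos + int(crossing[0])
            v[pos:c] = seg[: c - pos]
            t_end = min(c + template.size, n)
            v[c:t_end] = template[: t_end - c]
            r_end = min(c + max(n_ref, template.size), n)
            v[t_end:r_end] = model.V_reset
            spike_starts.append(c)
            v_prev = model.V_reset
            pos = r_end
        sweeps.append(
            VoltageSweep(
                sweep_id=f"step_{k:02d}_{int(step.amplitude_pA)}pA",
                sampling_rate=rate,
                voltage=v,
                current=step,
            )
        )
        truths.append(
            SpikingTruth(
                spike_start_indices=spike_starts,
                threshold_mV=model.V_T,
                amplitude_mV=model.ap_peak_amp,
                half_width_ms=model.half_width_ms,
            )
        )
    return sweeps, truths


def if_step_grid(
    start_pA: float = -100.0,
    stop_pA: float = 500.0,
    increment_pA: float = 25.0,
    onset_s: float = 0.1,
    duration_s: float = 1.0,
) -> list[StepDescriptor]:
    """The standard I-F protocol grid: 1-s steps, -100 to +500 pA by 25."""
    amps = np.arange(start_pA, stop_pA + increment_pA / 2, increment_pA)
    return [
        StepDescriptor(baseline_pA=0.0, amplitude_pA=float(a), onset_s=onset_s, duration_s=duration_s)
        for a in amps
    ]


def lif_rheobase(model: SpikingModel, grid_pA: Sequence[float]) -> float | None:
    """Smallest grid current whose steady state reaches threshold (long-step limit)."""
    needed = (model.V_T - model.E_L) * 1000.0 / model.R_in  # pA
    eligible = sorted(a for a in grid_pA if a >= needed - 1e-9)
    return float(eligible[0]) if eligible else None


def lif_steady_rate(model: SpikingModel, current_pA: float) -> float:
    """Closed-form LIF steady firing rate (Hz) at a suprathreshold current.

    f = 1000 / (t_ref + tau ln[(I R + E_L - V_reset) / (I R + E_L - V_T)])
    with I R in mV.  Returns 0 for currents at or below rheobase.
    """
    drive = model.E_L + current_pA * model.R_in / 1000.0
    if drive <= model.V_T:
        return 0.0
    isi_ms = model.t_ref + model.tau_m * np.log((drive - model.V_reset) / (drive - model.V_T))
    return 1000.0 / isi_ms


@dataclass
class SingleAPProtocolResult:
    sweeps: list[VoltageSweep]
    truths: list[SpikingTruth]
    amplitudes_pA: list[float]
    first_single_ap_index: int | None  # index into sweeps, None on failure
    protocol_failed: bool


def simulate_single_ap_protocol(
    model: SpikingModel,
    start_pA: float = 100.0,
    increment_pA: float = 25.0,
    pulse_ms: float = 2.0,
    rate: float = 50_000.0,
    seed: int | None = None,
    ceiling_pA: float = 3000.0,
) -> SingleAPProtocolResult:
    """Escalating 2-ms depolarising pulses until exactly one AP is evoked.

    Reaching ``ceiling_pA`` without a single-AP sweep sets the
    protocol-failure flag instead of raising.
    """
    if increment_pA <= 0:
        raise ValidationError("increment_pA must be > 0")
    rng = np.random.default_rng(seed)
    sweeps: list[VoltageSweep] = []
    truths: list[SpikingTruth] = []
    amps: list[float] = []
    first_single: int | None = None
    amp = start_pA
    while amp <= ceiling_pA:
        step = StepDescriptor(
            baseline_pA=0.0, amplitude_pA=amp, onset_s=0.01, duration_s=pulse_ms / 1000.0
        )
        child_seed = int(rng.integers(0, 2**31 - 1))
        sw, tr = simulate_spiking(model, [step], rate=rate, seed=child_seed, tail_s=0.05)
        sw[0].sweep_id = f"singleap_{int(amp)}pA"
        sweeps.append(sw[0])
        truths.append(tr[0])
        amps.append(amp)
        if first_single is None and tr[0].n_spikes == 1:
            first_single = len(sweeps) - 1
            break
        amp += increment_pA
    return SingleAPProtocolResult(
        sweeps=sweeps,
        truths=truths,
        amplitudes_pA=amps,
        first_single_ap_index=first_single,
        protocol_failed=first_single is None,
    )


@dataclass(frozen=True)
class AISProfileTruth:
    start_um: float   # analytic crossing of the threshold fraction, rising edge
    end_um: float     # analytic crossing, falling edge
    length_um: float


def simulate_ais_profile(
    start_um: float = 5.0,
    plateau_um: float = 20.0,
    edge_um: float = 1.0,
    f_max: float = 1000.0,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    dx_um: float = 0.1,
    seed: int | None = None,
    tail_um: float = 10.0,
    threshold_fraction: float = 0.33,
) -> tuple[FluorescenceProfile, AISProfileTruth]:
    """Trapezoidal Ankyrin-G intensity profile with analytic boundaries.

    The noiseless profile is ``baseline`` outside the trapezoid, rises
    linearly over ``edge_um`` to ``f_max``, holds for ``plateau_um`` and
    falls over ``edge_um``.  The threshold crossings of the
    baseline-subtracted profile sit at ``start + f*edge`` and
    ``start + edge + plateau + (1-f)*edge`` (f = threshold fraction),
    giving truth length ``plateau + 2(1-f) edge`` = plateau + 1.34 edge
    at the default fraction.
    """
    if edge_um < 0 or plateau_um <= 0:
        raise ValidationError("plateau_um must be > 0 and edge_um >= 0")
    if f_max <= baseline:
        raise ValidationError("f_max must exceed the baseline")
    total = start_um + 2 * edge_um + plateau_um + tail_um
    x = np.arange(0.0, total + dx_um / 2, dx_um)
    rise_end = start_um + edge_um
    fall_start = rise_end + plateau_um
    fall_end = fall_start + edge_um
    y = np.full(x.size, float(baseline))
    if edge_um > 0:
        on_rise = (x >= start_um) & (x < rise_end)
        y[on_rise] = baseline + (f_max - baseline) * (x[on_rise] - start_um) / edge_um
        on_fall = (x > fall_start) & (x <= fall_end)
        y[on_fall] = baseline + (f_max - baseline) * (fall_end - x[on_fall]) / edge_um
    y[(x >= rise_end) & (x <= fall_start)] = f_max
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + noise_sd * rng.standard_normal(x.size), 0.0, None)
    f = threshold_fraction
    truth = AISProfileTruth(
        start_um=start_um + f * edge_um,
        end_um=fall_start + (1 - f) * edge_um,
        length_um=plateau_um + 2 * (1 - f) * edge_um,
    )
    return FluorescenceProfile(x, y, source="tabular"), truth


def simulate_lesion_sections(
    true_volume_mm3: float,
    n_sections: int,
    thickness_um: float = 30.0,
    series_factor: int = 3,
    seed: int | None = None,
) -> LesionSeries:
    """Per-section lesion areas whose volume estimate recovers the truth.

    Areas follow a jittered spherical-cap-like (parabolic) profile and
    are rescaled so that the serial-section estimator returns
    ``true_volume_mm3`` exactly.
    """
    if true_volume_mm3 < 0:
        raise ValidationError("true_volume_mm3 must be >= 0")
    if n_sections == 0 or true_volume_mm3 == 0:
        return LesionSeries((), thickness_um=thickness_um, series_factor=series_factor)
    rng = np.random.default_rng(seed)
    u = np.linspace(-1, 1, n_sections + 2)[1:-1]
    weights = (1 - u * u) * (1 + 0.1 * rng.uniform(-1, 1, n_sections))
    weights = np.clip(weights, 1e-6, None)
    target_um3 = true_volume_mm3 * 1e9 / series_factor
    areas = weights / weights.sum() * target_um3 / thickness_um
    series = LesionSeries(tuple(float(a) for a in areas), thickness_um, series_factor)
    assert abs(lesion_volume(series) - true_volume_mm3) < 1e-9 * max(1.0, true_volume_mm3)
    return series


# --------------------------------------------------------------------------
# hierarchical cohorts


@dataclass
class CohortSpec:
    """Generative settings for a factorial cohort with animal random effects.

    ``fixed_effects`` maps design-matrix term names (see
    :func:`strokephys.design.term_names`) to effect sizes on the
    declared ``scale``; unnamed terms are zero.  Defaults mirror the
    study's electrophysiology cohort: 12 animals (3 per group x sex),
    cells in every hemisphere x layer stratum, correlated random
    intercept and hemisphere slope by animal.
    """

    outcome_name: str = "outcome"
    intercept: float = 0.0
    fixed_effects: Mapping[str, float] = field(default_factory=dict)
    scale: str = "identity"            # "identity" or "log"
    n_animals_per_cell: int = 3        # per group x sex cell
    cells_per_stratum: int = 2         # per hemisphere x layer per animal
    re_sd_intercept: float = 1.0
    re_sd_hemisphere: float = 0.5
    re_corr: float = 0.0
    residual_sd: float = 1.0
    factors: tuple[str, ...] = ("group", "hemisphere", "layer", "sex")
    interaction_order: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.re_sd_intercept, self.re_sd_hemisphere, self.residual_sd) < 0:
            raise ValidationError("standard deviations must be >= 0")
        if not -1.0 <= self.re_corr <= 1.0:
            raise ValidationError("re_corr must lie in [-1, 1]")
        if self.scale not in ("identity", "log"):
            raise ValidationError("scale must be 'identity' or 'log'")


@dataclass
class CohortTruth:
    """The generating parameters, for parameter-recovery tests."""

    beta: dict[str, float]
    re_sd_intercept: float
    re_sd_hemisphere: float
    re_corr: float
    residual_sd: float
    scale: str
    animal_effects: pd.DataFrame  # animal_id, b_intercept, b_hemisphere


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, CohortTruth]:
    """Draw a long-format cell table from the declared generative model.

    outcome = design . beta + b0[animal] + b1[animal] * 1{ipsilesional}
    + residual, on ``spec.scale`` (exponentiated for "log").
    """
    from .io import FACTOR_LEVELS, validate_cell_table

    rng = np.random.default_rng(spec.seed)
    rows = []
    animal_ids = []
    counter = 0
    for group in FACTOR_LEVELS["group"]:
        for sex in FACTOR_LEVELS["sex"]:
            for _ in range(spec.n_animals_per_cell):
                counter += 1
                aid = f"m{counter:03d}"
                animal_ids.append(aid)
                for hemisphere in FACTOR_LEVELS["hemisphere"]:
                    for layer in FACTOR_LEVELS["layer"]:
                        for _ in range(spec.cells_per_stratum):
                            rows.append(
                                dict(
                                    animal_id=aid,
                                    group=group,
                                    hemisphere=hemisphere,
                                    layer=layer,
                                    sex=sex,
                                    gfp="unknown",
                                    outcome_name=spec.outcome_name,
                                )
                            )
    df = pd.DataFrame(rows)
    X, names = design_matrix(df, spec.factors, spec.interaction_order)
    unknown = set(spec.fixed_effects) - set(names)
    if unknown:
        raise ValidationError(f"fixed_effects refer to unknown terms {sorted(unknown)}")
    beta = np.array(
        [spec.intercept if n == "(Intercept)" else spec.fixed_effects.get(n, 0.0) for n in names]
    )

    cov = np.array(
        [
            [spec.re_sd_intercept**2, spec.re_corr * spec.re_sd_intercept * spec.re_sd_hemisphere],
            [spec.re_corr * spec.re_sd_intercept * spec.re_sd_hemisphere, spec.re_sd_hemisphere**2],
        ]
    )
    b = rng.multivariate_normal(np.zeros(2), cov, size=len(animal_ids), method="svd")
    b_map = {aid: b[i] for i, aid in enumerate(animal_ids)}
    hemi = (df["hemisphere"] == "ipsilesional").to_numpy(dtype=float)
    ranef = np.array([b_map[a][0] for a in df["animal_id"]]) + hemi * np.array(
        [b_map[a][1] for a in df["animal_id"]]
    )
    linpred = X @ beta + ranef + spec.residual_sd * rng.standard_normal(len(df))
    df["outcome_value"] = np.exp(linpred) if spec.scale == "log" else linpred
    truth = CohortTruth(
        beta=dict(zip(names, beta)),
        re_sd_intercept=spec.re_sd_intercept,
        re_sd_hemisphere=spec.re_sd_hemisphere,
        re_corr=spec.re_corr,
        residual_sd=spec.residual_sd,
        scale=spec.scale,
        animal_effects=pd.DataFrame(
            {"animal_id": animal_ids, "b_intercept": b[:, 0], "b_hemisphere": b[:, 1]}
        ),
    )
    return validate_cell_table(df), truth
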