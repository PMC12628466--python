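"""Seeded synthetic data with the statistical structure of the crossover study.

The generator emulates a 20-participant, two-condition (control vs oxidative
stress) crossover with blood sampling at five timepoints (baseline, pre,
immediately / 10 min / 30 min post arm exercise):

* **Lactate incubation series** — for every participant × condition × timepoint,
  lactate (μM) at 0/30/60/90 min of incubation, a line of slope equal to the true
  glycolytic flux plus i.i.d. Gaussian measurement noise.
* **True fluxes** — a participant-level baseline flux (~21 μM/min at rest) scaled
  multiplicatively: ×1.4 under oxidative stress at the pre timepoint, ×2.74
  (control) or ×1.67 (oxidative stress) immediately post exercise, geometric
  midpoint at 10 min, back to the pre level by 30 min.
* **Blood-gas panels** — pH fall, 2,3-BPG rise (+14% control / +22% oxidative
  stress) and temperature 37 → 38.5 °C from pre to post, relaxing back by 30 min.
* **Redox biomarkers** — fractional shifts under oxidative stress at pre
  (+22% F2-isoprostanes, +28% protein carbonyls, −20% glutathione).
* **NIRS traces** — 10 Hz, three optodes: incremental exercise to exhaustion
  (O2Hb falls, HHb rises, recovery within 3 min) or a 5/5/3-min vascular
  occlusion protocol.

Every draw flows from one :class:`numpy.random.Generator`; identical seeds give
bit-identical tables. Negative simulated concentrations are resampled rather
than clipped so the Gaussian error model stays intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .flux import TIMEPOINT_ORDER, LactateSeries

__all__ = [
    "StudyDesign",
    "EffectSizeProfile",
    "BloodGasShifts",
    "NirsKinetics",
    "NirsTrace",
    "SyntheticStudy",
    "generate_lactate_series",
    "generate_study",
    "generate_nirs_trace",
]

NIRS_HZ = 10.0


@dataclass(frozen=True)
class StudyDesign:
    """Crossover layout: who is measured, when, and at which incubation times."""

    n_participants: int = 20
    conditions: tuple[str, ...] = ("control", "oxidative_stress")
    timepoints: tuple[str, ...] = TIMEPOINT_ORDER
    incubation_times: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise InvalidParameterError("n_participants must be >= 2")
        times = np.asarray(self.incubation_times, dtype=float)
        if times[0] != 0 or np.any(np.diff(times) <= 0):
            raise InvalidParameterError(
                "incubation_times must start at 0 and strictly increase"
            )


@dataclass(frozen=True)
class BloodGasShifts:
    """Pre → post-exercise blood-gas shifts applied by the generator."""

    ph_delta: float = -0.10          # plasma pH fall at exhaustion
    dpg_fraction_control: float = 0.14
    dpg_fraction_os: float = 0.22
    temp_rest_c: float = 37.0
    temp_exercise_c: float = 38.5

    def __post_init__(self) -> None:
        if self.temp_rest_c >= self.temp_exercise_c:
            raise InvalidParameterError("temp_rest_c must be below temp_exercise_c")


@dataclass(frozen=True)
class EffectSizeProfile:
    """Ground-truth effect sizes the generator embeds (and tests try to recover)."""

    baseline_flux_mean: float = 21.1       # μM/min at rest
    baseline_flux_sd: float = 4.0          # between-participant SD
    os_flux_multiplier: float = 1.4        # oxidative stress at the pre timepoint
    exercise_flux_multiplier_control: float = 2.74   # +174% immediately post
    exercise_flux_multiplier_os: float = 1.67        # +67% immediately post
    lactate_noise_sd: float = 50.0         # μM per assay point
    lactate_intercept_um: float = 150.0    # residual lactate in washed suspension
    lactate_intercept_jitter_sd: float = 30.0
    biomarker_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "f2_isoprostanes": 0.22,
            "protein_carbonyls": 0.28,
            "glutathione": -0.20,
        }
    )
    bloodgas_shifts: BloodGasShifts = field(default_factory=BloodGasShifts)
    ph_rest: float = 7.40
    dpg_rest_mm: float = 4.65
    dpg_between_sd_mm: float = 0.3

    def __post_init__(self) -> None:
        for name in (
            "os_flux_multiplier",
            "exercise_flux_multiplier_control",
            "exercise_flux_multiplier_os",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.lactate_noise_sd < 0:
            raise InvalidParameterError("lactate_noise_sd must be >= 0")
        if self.baseline_flux_sd < 0 or self.baseline_flux_mean <= 0:
            raise InvalidParameterError("baseline flux mean must be > 0, sd >= 0")


def _resample_nonnegative(rng: np.random.Generator, mean, sd) -> np.ndarray:
    """Draw Normal(mean, sd) elementwise, redrawing any negative values."""
    mean = np.asarray(mean, dtype=float)
    out = rng.normal(mean, sd)
    out = np.atleast_1d(out)
    mean_b = np.broadcast_to(mean, out.shape)
    for _ in range(1000):
        bad = out < 0
        if not bad.any():
            break
        out[bad] = rng.normal(mean_b[bad], sd)
    else:
        out[out < 0] = 0.0
    return out


def generate_lactate_series(
    true_flux: float,
    times: Sequence[float] = (0.0, 30.0, 60.0, 90.0),
    noise_sd: float = 50.0,
    seed: int | np.random.Generator = 0,
    intercept: float = 0.0,
    sample_id: str = "synthetic",
    meta: Mapping[str, object] | None = None,
) -> LactateSeries:
    """One incubation series: ``intercept + true_flux·t`` plus Gaussian noise.

    Negative draws are resampled so concentrations stay non-negative without
    truncating the error distribution elsewhere.
    """
    if true_flux < 0:
        raise InvalidParameterError("true_flux must be >= 0")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    t = np.asarray(times, dtype=float)
    if t.size == 0 or np.any(np.diff(t) <= 0):
        raise InvalidParameterError("times must be non-empty and increasing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    line = intercept + true_flux * t
    values = line if noise_sd == 0 else _resample_nonnegative(rng, line, noise_sd)
    return LactateSeries(
        sample_id=sample_id,
        incubation_min=tuple(t),
        lactate_um=tuple(float(v) for v in np.atleast_1d(values)),
        meta=dict(meta or {}),
    )


def _true_flux_multiplier(
    effects: EffectSizeProfile, condition: str, timepoint: str
) -> float:
    os_mult = effects.os_flux_multiplier if condition == "oxidative_stress" else 1.0
    ex_mult = (
        effects.exercise_flux_multiplier_os
        if condition == "oxidative_stress"
        else effects.exercise_flux_multiplier_control
    )
    if timepoint == "baseline":
        return 1.0
    pre_level = os_mult
    if timepoint == "pre":
        return pre_level
    if timepoint == "post0":
        return pre_level * ex_mult
    if timepoint == "post10":
        # midway (geometric mean) between post0 and pre
        return pre_level * float(np.sqrt(ex_mult))
    if timepoint == "post30":
        return pre_level
    raise InvalidParameterError(f"unknown timepoint {timepoint!r}")


@dataclass(frozen=True)
class NirsKinetics:
    """Shape parameters of a synthetic muscle-oximetry trace (all μM except s)."""

    o2hb_baseline: float = 25.0
    hhb_baseline: float = 15.0
    o2hb_drop: float = 10.0       # decline from baseline at exhaustion
    hhb_rise: float = 12.0        # rise from baseline at exhaustion
    recovery_tau_s: float = 30.0  # exponential recovery time constant
    noise_sd: float = 0.5         # per-optode white noise
    n_optodes: int = 3


@dataclass(frozen=True)
class NirsTrace:
    """A 10 Hz multi-optode trace with rest / work / recovery phase marks.

    ``o2hb`` and ``hhb`` have shape (n_optodes, n_samples); ``phase_marks``
    gives the (start, end) of each phase in seconds from trace start.
    """

    time_s: np.ndarray
    o2hb: np.ndarray
    hhb: np.ndarray
    phase_marks: Mapping[str, tuple[float, float]]
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dt = np.diff(self.time_s)
        if dt.size and not np.allclose(dt, 1.0 / NIRS_HZ, rtol=0.01):
            raise InvalidParameterError("trace must be sampled at 10 Hz (±1%)")
        if self.o2hb.shape != self.hhb.shape or self.o2hb.shape[-1] != self.time_s.size:
            raise InvalidParameterError("signal arrays must align with time_s")
        marks = list(self.phase_marks.values())
        for (a, b) in marks:
            if b <= a:
                raise InvalidParameterError("phase bounds must be increasing")
        for (_, b), (a2, _) in zip(marks, marks[1:]):
            if a2 < b - 1e-9:
                raise InvalidParameterError("phases must not overlap")

    @property
    def n_optodes(self) -> int:
        return self.o2hb.shape[0]


def _exercise_profile(t, work_start, work_end, amp, kin: NirsKinetics):
    """Monotone rise of `amp` over work, exponential return during recovery."""
    y = np.zeros_like(t)
    work = (t >= work_start) & (t < work_end)
    frac = (t[work] - work_start) / (work_end - work_start)
    y[work] = amp * frac
    rec = t >= work_end
    y[rec] = amp * np.exp(-(t[rec] - work_end) / kin.recovery_tau_s)
    return y


def _occlusion_profile(t, occ_start, occ_end, amp, kin: NirsKinetics):
    y = np.zeros_like(t)
    occ = (t >= occ_start) & (t < occ_end)
    y[occ] = amp * (t[occ] - occ_start) / (occ_end - occ_start)
    rec = t >= occ_end
    y[rec] = amp * np.exp(-(t[rec] - occ_end) / kin.recovery_tau_s)
    return y


def generate_nirs_trace(
    duration_s: float = 600.0,
    phase: str = "exercise",
    kinetics: NirsKinetics | None = None,
    seed: int | np.random.Generator = 0,
    rest_s: float = 300.0,
    recovery_s: float = 180.0,
    meta: Mapping[str, object] | None = None,
) -> NirsTrace:
    """Generate a 10 Hz three-optode trace.

    ``phase="exercise"``: ``rest_s`` of flat baseline, ``duration_s`` of work
    during which O2Hb falls and HHb rises monotonically to exhaustion, then
    ``recovery_s`` of exponential recovery toward baseline (within 3 min for the
    default time constant). ``phase="occlusion"``: 5 min rest, ``duration_s``
    (5 min) of linear drift (O2Hb down, HHb up), 3 min recovery.
    """
    if phase not in ("exercise", "occlusion"):
        raise InvalidParameterError(f"unknown phase {phase!r}")
    if duration_s <= 60:
        raise InvalidParameterError("duration_s must exceed 60 s")
    kin = kinetics or NirsKinetics()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    total = rest_s + duration_s + recovery_s
    n = int(round(total * NIRS_HZ)) + 1
    t = np.arange(n) / NIRS_HZ
    work_start, work_end = rest_s, rest_s + duration_s

    if phase == "exercise":
        o2hb_shift = -_exercise_profile(t, work_start, work_end, kin.o2hb_drop, kin)
        hhb_shift = _exercise_profile(t, work_start, work_end, kin.hhb_rise, kin)
    else:
        o2hb_shift = -_occlusion_profile(t, work_start, work_end, kin.o2hb_drop, kin)
        hhb_shift = _occlusion_profile(t, work_start, work_end, kin.hhb_rise, kin)

    shape = (kin.n_optodes, n)
    noise_o = rng.normal(0.0, kin.noise_sd, shape) if kin.noise_sd > 0 else np.zeros(shape)
    noise_h = rng.normal(0.0, kin.noise_sd, shape) if kin.noise_sd > 0 else np.zeros(shape)
    o2hb = kin.o2hb_baseline + o2hb_shift[None, :] + noise_o
    hhb = kin.hhb_baseline + hhb_shift[None, :] + noise_h

    marks = {
        "rest": (0.0, work_start),
        "work": (work_start, work_end),
        "recovery": (work_end, total),
    }
    return NirsTrace(time_s=t, o2hb=o2hb, hhb=hhb, phase_marks=marks, meta=dict(meta or {}))


@dataclass(frozen=True)
class SyntheticStudy:
    """A full simulated crossover dataset plus the ground truth that made it."""

    design: StudyDesign
    effects: EffectSizeProfile
    lactate_table: pd.DataFrame    # participant, condition, timepoint, incubation_min, lactate_um
    bloodgas_table: pd.DataFrame   # participant, condition, timepoint, po2..hb
    biomarker_table: pd.DataFrame  # participant, condition, timepoint, biomarker, value
    truth: pd.DataFrame            # participant, condition, timepoint, true_flux
    nirs_traces: tuple[NirsTrace, ...] = ()

    def lactate_series(self) -> list[LactateSeries]:
        """Split the long lactate table into per-sample :class:`LactateSeries`."""
        out = []
        for (p, c, tp), sub in self.lactate_table.groupby(
            ["participant", "condition", "timepoint"], sort=False
        ):
            sub = sub.sort_values("incubation_min")
            out.append(
                LactateSeries(
                    sample_id=f"P{p:02d}_{c}_{tp}",
                    incubation_min=tuple(sub["incubation_min"]),
                    lactate_um=tuple(sub["lactate_um"]),
                    meta={"participant": p, "condition": c, "timepoint": tp},
                )
            )
        return out


def generate_study(
    design: StudyDesign | None = None,
    effects: EffectSizeProfile | None = None,
    include_nirs: bool = False,
) -> SyntheticStudy:
    """Generate one complete crossover dataset.

    The truth table satisfies, by construction, ``mean(true pre flux under
    oxidative stress) / mean(true pre flux under control) ==
    os_flux_multiplier`` — only the lactate assay noise separates downstream
    estimates from the embedded multipliers. NIRS traces (one exercise trace per
    participant × condition, exhaustion drawn uniformly in 480–900 s) are
    generated only when ``include_nirs`` is set, since most analyses need only
    the lactate and blood-gas tables.
    """
    design = design or StudyDesign()
    effects = effects or EffectSizeProfile()
    rng = np.random.default_rng(design.rng_seed)

    baselines = _resample_nonnegative(
        rng, np.full(design.n_participants, effects.baseline_flux_mean),
        effects.baseline_flux_sd,
    )
    intercepts = _resample_nonnegative(
        rng, np.full(design.n_participants, effects.lactate_intercept_um),
        effects.lactate_intercept_jitter_sd,
    )
    dpg_rest = _resample_nonnegative(
        rng, np.full(design.n_participants, effects.dpg_rest_mm),
        effects.dpg_between_sd_mm,
    )

    shifts = effects.bloodgas_shifts
    lactate_rows, bloodgas_rows, biomarker_rows, truth_rows = [], [], [], []
    nirs_traces: list[NirsTrace] = []

    for p in range(design.n_participants):
        for condition in design.conditions:
            for timepoint in design.timepoints:
                mult = _true_flux_multiplier(effects, condition, timepoint)
                true_flux = float(baselines[p] * mult)
                truth_rows.append(
                    {
                        "participant": p,
                        "condition": condition,
                        "timepoint": timepoint,
                        "true_flux": true_flux,
                    }
                )
                series = generate_lactate_series(
                    true_flux,
                    design.incubation_times,
                    effects.lactate_noise_sd,
                    seed=rng,
                    intercept=float(intercepts[p]),
                )
                for t_min, lac in zip(series.incubation_min, series.lactate_um):
                    lactate_rows.append(
                        {
                            "participant": p,
                            "condition": condition,
                            "timepoint": timepoint,
                            "incubation_min": t_min,
                            "lactate_um": lac,
                        }
                    )

                exercised = timepoint in ("post0", "post10")
                # post10 relaxes halfway back toward rest values
                w = 1.0 if timepoint == "post0" else (0.5 if timepoint == "post10" else 0.0)
                dpg_frac = (
                    shifts.dpg_fraction_os
                    if condition == "oxidative_stress"
                    else shifts.dpg_fraction_control
                )
                bloodgas_rows.append(
                    {
                        "participant": p,
                        "condition": condition,
                        "timepoint": timepoint,
                        "po2": 100.0,
                        "pco2": 40.0,
                        "ph": effects.ph_rest + w * shifts.ph_delta,
                        "dpg": float(dpg_rest[p]) * (1.0 + w * dpg_frac),
                        "temp": shifts.temp_rest_c
                        + w * (shifts.temp_exercise_c - shifts.temp_rest_c),
                        "hct": 0.45,
                        "hb": 15.0,
                    }
                )

                stressed_now = condition == "oxidative_stress" and timepoint != "baseline"
                for biomarker, effect in effects.biomarker_effects.items():
                    level = 1.0 * (1.0 + effect if stressed_now else 1.0)
                    biomarker_rows.append(
                        {
                            "participant": p,
                            "condition": condition,
                            "timepoint": timepoint,
                            "biomarker": biomarker,
                            "value": float(
                                _resample_nonnegative(rng, level, 0.05)[0]
                            ),
                        }
                    )

            if include_nirs:
                duration = float(rng.uniform(480.0, 900.0))
                nirs_traces.append(
                    generate_nirs_trace(
                        duration_s=duration,
                        phase="exercise",
                        seed=rng,
                        meta={"participant": p, "condition": condition, "limb": "arm"},
                    )
                )

    return SyntheticStudy(
        design=design,
        effects=effects,
        lactate_table=pd.DataFrame(lactate_rows),
        bloodgas_table=pd.DataFrame(bloodgas_rows),
        biomarker_table=pd.DataFrame(biomarker_rows),
        truth=pd.DataFrame(truth_rows),
        nirs_traces=tuple(nirs_traces),
    )
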