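"""Ground-truthed synthetic study generation.

Emulates the statistical structure the readout chain assumes: stepwise
diabetic blood-glucose schedules (fasting 4, postprandial 12,
postabsorptive 6, hyperglycemic 20 mM), interstitial-fluid (ISF) glucose
lagging blood by a first-order ~20 min filter, needle swelling following
the calibrated chemo-mechanical kinetics, per-device baseline length
1.2 mm with ~20 um fabrication spread, and additive Gaussian measurement
noise on SR.  Every stochastic choice is keyed to one root seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chemo_mechanics import CalibratedModel, transient_sr
from .errors import InvalidInputError
from ._seeding import derive_seed, rng_for
from .ultrasound_sim import (
    NeedleGeometry,
    ProbeConfig,
    ScenePhantom,
    render_sequence,
    write_frames,
)

__all__ = [
    "GLUCOSE_STATE_LEVELS",
    "GlucoseProfile",
    "PhysiologyParams",
    "CohortSpec",
    "StudyBundle",
    "default_daily_schedule",
    "generate_profile",
    "isf_glucose",
    "forward_sr",
    "generate_study",
]

#: Blood glucose levels (mM) mimicking the diabetic daily states.
GLUCOSE_STATE_LEVELS = {
    "fasting": 4.0,
    "postprandial": 12.0,
    "postabsorptive": 6.0,
    "hyperglycemic": 20.0,
}


@dataclass(frozen=True)
class PhysiologyParams:
    """Timescales (minutes) of the glucose signal chain: blood rise ~10,
    ISF diffusion lag ~20, postprandial plateau 60-90."""

    blood_rise_time: float = 10.0
    isf_lag: float = 20.0
    postprandial_duration: float = 75.0

    def __post_init__(self):
        if min(self.blood_rise_time, self.isf_lag, self.postprandial_duration) <= 0:
            raise InvalidInputError("physiology timescales must be > 0")


@dataclass(frozen=True)
class GlucoseProfile:
    """Minute-resolved glucose series with per-sample state labels."""

    times: np.ndarray
    glucose: np.ndarray
    labels: tuple

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(self.glucose < 0):
            raise InvalidInputError("glucose must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort: device baseline spread and SR noise structure."""

    n_subjects: int = 8
    baseline_length_mean: float = 1.2    # mm
    baseline_length_sd: float = 0.02     # mm, fabrication spread
    intercept_sd: float = 0.7            # SR points, device-to-device offset
    noise_sd: float = 0.3                # SR points, per-reading cycle error
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise InvalidInputError("n_subjects must be >= 1")
        if min(self.baseline_length_sd, self.intercept_sd, self.noise_sd) < 0:
            raise InvalidInputError("spreads must be >= 0")
        if self.baseline_length_mean <= 0:
            raise InvalidInputError("baseline length must be > 0")


def default_daily_schedule(params: PhysiologyParams | None = None) -> list:
    """A diabetic day: fasting, meal, postabsorptive, a hyperglycemic
    excursion, recovery, and overnight fasting."""
    params = params or PhysiologyParams()
    return [
        ("fasting", 240.0),
        ("postprandial", params.postprandial_duration),
        ("postabsorptive", 120.0),
        ("hyperglycemic", params.postprandial_duration),
        ("postabsorptive", 120.0),
        ("fasting", 360.0),
    ]


def generate_profile(schedule, params: PhysiologyParams | None = None,
                     seed: int | None = None, dt: float = 1.0,
                     level_jitter_sd: float = 0.0) -> GlucoseProfile:
    """Blood glucose profile from an ordered (state, duration-minutes) list.

    Transitions between segment levels are linear ramps over
    ``blood_rise_time``; optional seeded Gaussian jitter perturbs segment
    levels.  Deterministic given the seed.
    """
    params = params or PhysiologyParams()
    if not schedule:
        raise InvalidInputError("schedule must be nonempty")
    rng = rng_for(seed, "profile") if seed is not None else None
    levels, bounds, labels = [], [0.0], []
    for state, duration in schedule:
        if duration <= 0:
            raise InvalidInputError("segment durations must be > 0")
        level = GLUCOSE_STATE_LEVELS[state]
        if rng is not None and level_jitter_sd > 0:
            level = max(0.0, level + rng.normal(0.0, level_jitter_sd))
        levels.append(level)
        bounds.append(bounds[-1] + float(duration))
        labels.append(state)

    times = np.arange(0.0, bounds[-1] + 0.5 * dt, dt)
    glucose = np.empty_like(times)
    sample_labels = []
    seg = 0
    for i, t in enumerate(times):
        while seg + 1 < len(levels) and t >= bounds[seg + 1]:
            seg += 1
        if seg == 0 or t >= bounds[seg] + params.blood_rise_time:
            glucose[i] = levels[seg]
        else:  # ramp from the previous level
            frac = (t - bounds[seg]) / params.blood_rise_time
            glucose[i] = levels[seg - 1] + frac * (levels[seg] - levels[seg - 1])
        sample_labels.append(labels[seg])
    return GlucoseProfile(times=times, glucose=glucose, labels=tuple(sample_labels))


def isf_glucose(profile: GlucoseProfile, isf_lag: float = 20.0) -> GlucoseProfile:
    """First-order lag filter of the blood profile (zero-order hold).

    ``isf' = (blood - isf) / isf_lag`` integrated exactly per step: the
    steady state equals the blood level, and a step reaches 63.2 % of its
    height at t = isf_lag.
    """
    if isf_lag <= 0:
        raise InvalidInputError("isf_lag must be > 0")
    blood = profile.glucose
    isf = np.empty_like(blood)
    isf[0] = blood[0]
    dts = np.diff(profile.times)
    decay = np.exp(-dts / isf_lag)
    for i in range(1, blood.size):
        isf[i] = blood[i] + (isf[i - 1] - blood[i]) * decay[i - 1]
    return GlucoseProfile(times=profile.times.copy(), glucose=isf,
                          labels=profile.labels)


def forward_sr(isf_profile: GlucoseProfile, model: CalibratedModel,
               sample_times=None, initial_sr: float = 0.0,
               confinement_stiffness: float = 0.0) -> np.ndarray:
    """SR (%) truth series for a needle exposed to an ISF glucose profile.

    The profile is treated as piecewise-constant at its own resolution and
    fed through the mode-superposition transient solver; identical
    consecutive levels are collapsed into single segments.  Cyclic
    schedules that reach equilibrium return SR to its cycle-start value
    (reversibility of the binding equilibrium).
    """
    g = np.round(isf_profile.glucose, 6)
    keep = np.concatenate([[True], np.diff(g) != 0])
    schedule = list(zip(isf_profile.times[keep], g[keep]))
    times = isf_profile.times if sample_times is None else np.asarray(sample_times, float)
    return transient_sr(model, schedule, times, initial_sr=initial_sr,
                        confinement_stiffness=confinement_stiffness)


# ---------------------------------------------------------------------------
# full study bundles
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """Frames + truth table + manifest for one synthetic study."""

    truth: pd.DataFrame
    frames: dict            # (subject, time_min) -> FrameSequence
    manifest: dict
    geometry: NeedleGeometry
    probe: ProbeConfig
    scene: ScenePhantom

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.truth.to_csv(out / "truth.csv", index=False)
        for (subject, t), seq in self.frames.items():
            write_frames(out / f"subject{subject:02d}_t{int(t):04d}.tif", seq)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return out


def _subject_glucose_levels(cohort: CohortSpec, span=(5.0, 22.0)) -> np.ndarray:
    """Evenly spread target glucose levels across the cohort span."""
    return np.linspace(span[0], span[1], cohort.n_subjects)


def generate_study(cohort: CohortSpec, schedule, model: CalibratedModel,
                   probe: ProbeConfig | None = None,
                   scene: ScenePhantom | None = None,
                   geometry: NeedleGeometry | None = None,
                   params: PhysiologyParams | None = None,
                   reading_time_min: float = 60.0,
                   frames_per_point: int = 3,
                   confinement_stiffness: float = 0.0) -> StudyBundle:
    """Generate a ground-truthed image study for a synthetic cohort.

    ``schedule`` is either a per-subject sequence of target glucose levels
    (single-reading animal-style design: a baseline acquisition at t = 0
    and a reading at ``reading_time_min``) or an ordered
    ``(state, duration)`` daily schedule sampled hourly for every subject.
    Per subject, the baseline needle length and a device SR offset are
    drawn once; each reading adds Gaussian SR noise; three frames are
    rendered per time point.
    """
    probe = probe or ProbeConfig()
    scene = scene or ScenePhantom()
    geometry = geometry or NeedleGeometry()
    params = params or PhysiologyParams()

    is_daily = (isinstance(schedule, (list, tuple)) and len(schedule) > 0
                and isinstance(schedule[0], (tuple, list))
                and isinstance(schedule[0][0], str))
    if is_daily:
        total = sum(d for _, d in schedule)
        sample_times = np.arange(0.0, total + 1.0, 60.0)
        per_subject_profiles = True
    else:
        levels = (np.asarray(schedule, dtype=float) if schedule is not None
                  else _subject_glucose_levels(cohort))
        if levels.size != cohort.n_subjects:
            raise InvalidInputError("one glucose level per subject required")
        sample_times = np.array([0.0, reading_time_min])
        per_subject_profiles = False

    rng = rng_for(cohort.seed, "cohort")
    rows, frames = [], {}
    for s in range(cohort.n_subjects):
        l0 = rng.normal(cohort.baseline_length_mean, cohort.baseline_length_sd)
        offset = rng.normal(0.0, cohort.intercept_sd)
        if per_subject_profiles:
            profile = generate_profile(schedule, params, seed=derive_seed(cohort.seed, "profile", s))
        else:
            profile = generate_profile([("fasting", reading_time_min + 60.0)], params)
            profile = GlucoseProfile(times=profile.times,
                                     glucose=np.full_like(profile.glucose, levels[s]),
                                     labels=profile.labels)
        isf = isf_glucose(profile, params.isf_lag)
        sr_clean = forward_sr(isf, model, sample_times=sample_times,
                              confinement_stiffness=confinement_stiffness)
        for t, sr_c in zip(sample_times, sr_clean):
            noise = rng.normal(0.0, cohort.noise_sd) if t > 0 else 0.0
            sr_true = sr_c + (offset + noise if t > 0 else 0.0)
            l_true = l0 * (1.0 + sr_true / 100.0)
            blood = float(np.interp(t, profile.times, profile.glucose))
            isf_g = float(np.interp(t, isf.times, isf.glucose))
            seq = render_sequence(
                scene, geometry, np.full(geometry.count, l_true), probe,
                n_frames=frames_per_point,
                seed=derive_seed(cohort.seed, "frames", s, int(round(t))))
            frames[(s, float(t))] = seq
            rows.append({"subject": s, "time_min": float(t), "blood_mM": blood,
                         "isf_mM": isf_g, "sr_truth": float(sr_true),
                         "l0_mm": float(l0), "l_true_mm": float(l_true)})
    truth = pd.DataFrame(rows)
    manifest = {
        "seed": cohort.seed,
        "n_subjects": cohort.n_subjects,
        "frames_per_point": frames_per_point,
        "reading_time_min": reading_time_min,
        "noise_sd": cohort.noise_sd,
        "intercept_sd": cohort.intercept_sd,
        "baseline_length_mean": cohort.baseline_length_mean,
        "baseline_length_sd": cohort.baseline_length_sd,
        "model_provenance": model.provenance,
        "design": "daily-schedule" if per_subject_profiles else "single-reading",
    }
    return StudyBundle(truth=truth, frames=frames, manifest=manifest,
                       geometry=geometry, probe=probe, scene=scene)
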