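"""End-to-end orchestration: forward simulation, readout, calibration,
validation and reporting.

``run_forward`` chains the synthetic cohort generator, the swelling model
and the B-mode renderer into a study bundle; ``run_readout`` chains edge
metrology and calibration into per-reading glucose estimates and summary
metrics.  ``validate_in_vivo_fixture`` reproduces the correlation
statistics of the shipped in vivo (glucose, SR) table.  All stages derive
their randomness from one root seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .chemo_mechanics import (
    CalibratedModel,
    load_default_model,
    relaxation_fraction,
)
from .errors import InvalidInputError, NoDataError, UndefinedCorrelationError
from .glucose_calibration import (
    HYPERGLYCEMIA_THRESHOLD_MM,
    CalibrationCurve,
    CorrelationReport,
    fit_curve,
    invert,
    pearson_validation,
)
from .needle_metrology import compute_sr, measure_sequence
from ._seeding import derive_seed
from .synthetic_data import CohortSpec, StudyBundle, generate_study
from .ultrasound_sim import NeedleGeometry, ProbeConfig, ScenePhantom, render_sequence

__all__ = [
    "PipelineConfig",
    "RunReport",
    "run_forward",
    "run_readout",
    "model_calibration_curve",
    "calibration_run",
    "load_in_vivo_fixture",
    "load_quasi_free_table",
    "validate_in_vivo_fixture",
]


@dataclass
class PipelineConfig:
    """Run configuration; file paths are optional and default to the
    shipped calibration and default probe/scene."""

    model_path: str | None = None
    out_dir: str | None = None
    seed: int = 0
    frames_per_point: int = 3
    reading_time_min: float = 60.0
    noise_sd: float = 0.3
    n_subjects: int = 8
    glucose_span: tuple = (5.0, 22.0)
    stages: tuple = ("simulate", "readout", "report")

    def load_model(self) -> CalibratedModel:
        if self.model_path:
            return CalibratedModel.from_json(self.model_path)
        return load_default_model()

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "glucose_span" in d:
            d["glucose_span"] = tuple(d["glucose_span"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


@dataclass
class RunReport:
    """Per-reading truth vs estimate rows plus summary metrics."""

    rows: pd.DataFrame
    rmse_mM: float
    hyperglycemia_recall: float
    correlation: CorrelationReport | None

    def to_json(self, path) -> None:
        payload = {
            "rows": self.rows.to_dict(orient="records"),
            "rmse_mM": self.rmse_mM,
            "hyperglycemia_recall": self.hyperglycemia_recall,
            "correlation": vars(self.correlation) if self.correlation else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def summary(self) -> str:
        lines = [
            f"readings: {len(self.rows)}",
            f"glucose RMSE: {self.rmse_mM:.2f} mM",
            f"hyperglycemia recall: {self.hyperglycemia_recall:.2f}",
        ]
        if self.correlation is not None:
            lines.append(self.correlation.summary())
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# fixtures shipped with the package
# ---------------------------------------------------------------------------

def _read_data_csv(name: str) -> pd.DataFrame:
    text = resources.files("sononeedle.data").joinpath(name).read_text()
    return pd.read_csv(StringIO(text))


def load_in_vivo_fixture() -> pd.DataFrame:
    """The eight in vivo (blood glucose mM, SR %) pairs."""
    return _read_data_csv("in_vivo_sr_glucose.csv")


def load_quasi_free_table(min_glucose: float = 0.0) -> pd.DataFrame:
    """The printed quasi-free (glucose mM, SR %) calibration table."""
    df = _read_data_csv("quasi_free_sr.csv")
    return df[df.glucose_mM >= min_glucose].reset_index(drop=True)


def validate_in_vivo_fixture(pairs: pd.DataFrame | None = None) -> CorrelationReport:
    """Correlation statistics of the shipped in vivo table (or a subset)."""
    df = pairs if pairs is not None else load_in_vivo_fixture()
    report = pearson_validation(df[["glucose_mM", "sr_percent"]].to_numpy())
    print(report.summary())
    return report


# ---------------------------------------------------------------------------
# forward and inverse runs
# ---------------------------------------------------------------------------

def run_forward(config: PipelineConfig, model: CalibratedModel | None = None,
                probe: ProbeConfig | None = None,
                scene: ScenePhantom | None = None,
                geometry: NeedleGeometry | None = None) -> StudyBundle:
    """Simulate a single-reading cohort study; deterministic per seed."""
    model = model or config.load_model()
    cohort = CohortSpec(n_subjects=config.n_subjects, noise_sd=config.noise_sd,
                        seed=config.seed)
    levels = np.linspace(*config.glucose_span, config.n_subjects)
    bundle = generate_study(cohort, levels, model, probe=probe, scene=scene,
                            geometry=geometry,
                            reading_time_min=config.reading_time_min,
                            frames_per_point=config.frames_per_point)
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle


def model_calibration_curve(model: CalibratedModel,
                            reading_time_min: float | None = 60.0,
                            glucose_range: tuple = (0.0, 20.0),
                            n_points: int = 11) -> CalibrationCurve:
    """Linear calibration derived from the model's own SR curve, evaluated
    at the reading time so that non-equilibrium readings invert without
    bias."""
    g = np.linspace(*glucose_range, n_points)
    sr = model.sr_percent(g, time_min=reading_time_min)
    return fit_curve(np.column_stack([g, sr]), glucose_range)


def run_readout(bundle: StudyBundle, config: PipelineConfig | None = None,
                curve: CalibrationCurve | None = None,
                model: CalibratedModel | None = None) -> RunReport:
    """Measure every frame sequence in a bundle and estimate glucose.

    Per subject, baseline lengths l0 come from the earliest time point
    (the acquisition made immediately after insertion); later time points
    yield per-needle SRs against each needle's own l0, averaged over the
    needles in view.  Estimates use the supplied calibration curve, or one
    derived from the model at the reading time.
    """
    config = config or PipelineConfig()
    if bundle.truth.empty or not bundle.frames:
        raise NoDataError("bundle contains no frames")
    if curve is None:
        model = model or config.load_model()
        curve = model_calibration_curve(model, config.reading_time_min)
    frac = (relaxation_fraction(config.reading_time_min, model.kinetics)
            if model is not None else 1.0)

    substrate_row = bundle.scene.substrate_row
    rows = []
    for subject, sub_truth in bundle.truth.groupby("subject"):
        times = sorted(sub_truth.time_min.unique())
        base_seq = bundle.frames[(subject, times[0])]
        baselines = {m.needle_id: m.length for m in measure_sequence(
            base_seq, bundle.geometry, substrate_row)}
        for t in times[1:]:
            seq = bundle.frames[(subject, t)]
            measurements = measure_sequence(seq, bundle.geometry, substrate_row)
            srs = [compute_sr(baselines[m.needle_id], m.length, timestamp=t).sr_percent
                   for m in measurements if m.needle_id in baselines]
            if not srs:
                continue
            sr_measured = float(np.mean(srs))
            est = invert(curve, sr_measured, model=model, response_fraction=frac)
            truth_row = sub_truth[sub_truth.time_min == t].iloc[0]
            rows.append({
                "subject": subject, "time_min": t,
                "glucose_truth_mM": truth_row.blood_mM,
                "glucose_est_mM": est.glucose_mM,
                "sr_truth": truth_row.sr_truth,
                "sr_measured": sr_measured,
                "extrapolated": est.extrapolated,
                "hyperglycemia_alert": est.hyperglycemia_alert,
            })
    if not rows:
        raise NoDataError("no reading could be measured")
    df = pd.DataFrame(rows)
    err = df.glucose_est_mM - df.glucose_truth_mM
    rmse = float(np.sqrt(np.mean(err**2)))
    hyper = df[df.glucose_truth_mM >= HYPERGLYCEMIA_THRESHOLD_MM]
    recall = float(hyper.hyperglycemia_alert.mean()) if len(hyper) else float("nan")
    try:
        corr = pearson_validation(df[["glucose_truth_mM", "sr_measured"]].to_numpy())
    except (InvalidInputError, UndefinedCorrelationError):
        corr = None  # fewer than three readings, or a degenerate design
    report = RunReport(rows=df, rmse_mM=rmse, hyperglycemia_recall=recall,
                       correlation=corr)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "readout.csv", index=False)
        report.to_json(out / "report.json")
    return report


def calibration_run(model: CalibratedModel, levels=None, seed: int = 0,
                    noise_sd: float = 0.3, frames_per_level: int = 3,
                    probe: ProbeConfig | None = None,
                    scene: ScenePhantom | None = None,
                    geometry: NeedleGeometry | None = None,
                    reading_time_min: float = 60.0) -> tuple:
    """Simulated bench calibration: render/measure a device at each glucose
    level and fit the measured SR-vs-glucose line over 0-20 mM.

    Returns ``(curve, pairs)`` where ``pairs`` is the measured
    (glucose, SR %) array.  Used to check that the pipeline recovers the
    generating model's sensitivity.
    """
    probe = probe or ProbeConfig()
    scene = scene or ScenePhantom()
    geometry = geometry or NeedleGeometry()
    if levels is None:
        levels = np.linspace(0.0, 22.0, 12)
    levels = np.asarray(levels, dtype=float)
    rng = np.random.default_rng(derive_seed(seed, "calibration-noise"))
    frac = relaxation_fraction(reading_time_min, model.kinetics)
    l0 = 1.2

    base_seq = render_sequence(scene, geometry, np.full(geometry.count, l0),
                               probe, frames_per_level,
                               seed=derive_seed(seed, "cal-baseline"))
    baselines = {m.needle_id: m.length for m in measure_sequence(
        base_seq, geometry, scene.substrate_row)}

    pairs = []
    sr_eq = model.sr_percent(levels)
    for i, (g, sr_e) in enumerate(zip(levels, sr_eq)):
        sr_true = sr_e * frac + rng.normal(0.0, noise_sd)
        l_true = l0 * (1.0 + sr_true / 100.0)
        seq = render_sequence(scene, geometry, np.full(geometry.count, l_true),
                              probe, frames_per_level,
                              seed=derive_seed(seed, "cal-level", i))
        ms = measure_sequence(seq, geometry, scene.substrate_row)
        srs = [compute_sr(baselines[m.needle_id], m.length).sr_percent
               for m in ms if m.needle_id in baselines]
        pairs.append((g, float(np.mean(srs))))
    pairs = np.asarray(pairs)
    curve = fit_curve(pairs, glucose_range=(0.0, 20.0))
    return curve, pairs
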