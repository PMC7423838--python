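"""Synthetic cohort generation.

Produces cohorts with the statistical structure the pipeline assumes:
smooth monotone cumulative DVHs whose Dx metrics are strongly collinear,
clinical covariates with realistic marginals (including a smoking-shifted
serum A2M distribution), and toxicity grades drawn from a *known* logistic
outcome model so downstream selection stages can be tested for parameter
recovery.

The DVH generative family is a normalized logistic sigmoid in dose: for a
patient-level midpoint ``m`` and steepness ``k``,

    raw(D) = 1 / (1 + exp(k (D - m)))
    V(D)   = (raw(D) - raw(Dmax)) / (raw(0) - raw(Dmax)),   Dmax = 1.2 Rx

which is exactly 1 at D = 0, exactly 0 at Dmax, and non-increasing.
Patient-to-patient variation enters through lognormal jitter on ``m`` and
``k``; because all Dx metrics of a curve move together with ``m``, adjacent
Dx columns are highly correlated across a cohort, as required.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dvh import DVHCurve
from .errors import ConfigurationError, ParameterError, ValidationError
from .io import build_feature_table
from .records import ClinicalRecord

_PROB_TOL = 1e-8


@dataclass(frozen=True)
class Fractionation:
    """One entry of the fractionation menu."""

    total_dose_gy: float
    fraction_number: int
    treatment_days: int
    modality: str = "conventional"

    def __post_init__(self) -> None:
        if self.total_dose_gy <= 0 or self.fraction_number < 1:
            raise ParameterError("invalid fractionation entry")
        if self.treatment_days < self.fraction_number:
            raise ValidationError(
                "treatment_days must be >= fraction_number "
                f"({self.treatment_days} < {self.fraction_number})"
            )


@dataclass(frozen=True)
class StructureShape:
    """DVH shape parameters for one structure.

    ``coverage_fraction`` places the sigmoid midpoint at
    ``coverage_fraction * prescription`` Gy; ``falloff_steepness`` is the
    dimensionless slope (per prescription dose).  The jitter standard
    deviations control patient-level lognormal variation.
    """

    falloff_steepness: float
    coverage_fraction: float
    midpoint_jitter_sd: float = 0.15
    steepness_jitter_sd: float = 0.30
    bin_width_gy: float = 0.5

    def __post_init__(self) -> None:
        if self.falloff_steepness <= 0:
            raise ParameterError("falloff_steepness must be positive")
        if not 0 < self.coverage_fraction <= 1:
            raise ParameterError("coverage_fraction must be in (0, 1]")
        if self.bin_width_gy <= 0:
            raise ParameterError("bin_width_gy must be positive")


@dataclass(frozen=True)
class ClinicalDists:
    """Marginal distributions for the clinical covariates.

    A2M (mg/dL) is lognormal with the given log-median and log-sigma, plus
    an additive shift for former/current smokers; defaults reproduce a
    median near 191 mg/dL with smokers shifted upward.
    """

    age_mean: float = 68.0
    age_sd: float = 11.0
    age_range: tuple[float, float] = (25.0, 93.0)
    female_p: float = 0.527
    kps_values: tuple[float, ...] = (70.0, 80.0, 90.0, 100.0)
    kps_probs: tuple[float, ...] = (0.15, 0.25, 0.40, 0.20)
    smoking_probs: tuple[float, float, float] = (0.182, 0.694, 0.124)  # never/former/current
    pack_years_log_mean: float = math.log(37.0)
    pack_years_log_sd: float = 0.7
    a2m_log_median: float = math.log(169.0)
    a2m_log_sd: float = 0.32
    a2m_smoker_shift: tuple[float, float] = (25.0, 35.0)  # former, current (mg/dL)
    chemo_timing_probs: tuple[float, float, float] = (0.232, 0.287, 0.481)
    subtype_names: tuple[str, ...] = ("NSCLC", "SCLC", "thymoma", "mesothelioma", "metastases")
    subtype_probs: tuple[float, ...] = (0.783, 0.066, 0.031, 0.097, 0.023)
    fractionation_menu: tuple[Fractionation, ...] = (
        Fractionation(60.0, 30, 40, "conventional"),
        Fractionation(54.0, 27, 37, "conventional"),
        Fractionation(50.0, 5, 10, "sbrt"),
    )
    fractionation_probs: tuple[float, ...] = (0.40, 0.35, 0.25)

    def __post_init__(self) -> None:
        for name, probs in (
            ("kps_probs", self.kps_probs),
            ("smoking_probs", self.smoking_probs),
            ("chemo_timing_probs", self.chemo_timing_probs),
            ("subtype_probs", self.subtype_probs),
            ("fractionation_probs", self.fractionation_probs),
        ):
            arr = np.asarray(probs, dtype=float)
            if np.any(arr < 0) or np.any(arr > 1):
                raise ParameterError(f"{name} entries must lie in [0, 1]")
            if abs(arr.sum() - 1.0) > _PROB_TOL:
                raise ParameterError(f"{name} must sum to 1, got {arr.sum()}")
        if not 0 <= self.female_p <= 1:
            raise ParameterError("female_p must lie in [0, 1]")
        if len(self.fractionation_menu) != len(self.fractionation_probs):
            raise ParameterError("fractionation menu and probabilities differ in length")


@dataclass(frozen=True)
class OutcomeModel:
    """Known logistic ground truth for one toxicity endpoint.

    ``logit(p_event) = intercept + sum_i coefficients[f_i] * feature[f_i]``;
    events receive CTCAE grade >= 2 and non-events grade < 2 according to
    the configured conditional splits.
    """

    endpoint: str
    coefficients: Mapping[str, float]
    intercept: float
    event_grade_probs: Mapping[int, float] = field(
        default_factory=lambda: {2: 53 / 61, 3: 8 / 61}
    )
    nonevent_grade_probs: Mapping[int, float] = field(default_factory=lambda: {0: 0.7, 1: 0.3})

    def __post_init__(self) -> None:
        for name, probs, valid in (
            ("event_grade_probs", self.event_grade_probs, {2, 3, 4, 5}),
            ("nonevent_grade_probs", self.nonevent_grade_probs, {0, 1}),
        ):
            if set(probs) - valid:
                raise ParameterError(f"{name} grades must be within {sorted(valid)}")
            total = sum(probs.values())
            if abs(total - 1.0) > _PROB_TOL or any(p < 0 for p in probs.values()):
                raise ParameterError(f"{name} must be non-negative and sum to 1")

    def linear_predictor(self, features: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.coefficients if f not in features.columns]
        if missing:
            raise ConfigurationError(
                f"outcome model for {self.endpoint!r} references missing features: {missing}"
            )
        eta = np.full(len(features), self.intercept, dtype=float)
        for name, beta in self.coefficients.items():
            eta += beta * features[name].to_numpy(dtype=float)
        return eta

    def event_probability(self, features: pd.DataFrame) -> np.ndarray:
        eta = self.linear_predictor(features)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    n_patients: int = 258
    seed: int = 0
    structure_names: tuple[str, ...] = ("esophagus", "lung", "heart")
    dvh_shapes: Mapping[str, StructureShape] = field(
        default_factory=lambda: dict(DEFAULT_DVH_SHAPES)
    )
    clinical_dists: ClinicalDists = field(default_factory=ClinicalDists)
    outcome_models: tuple[OutcomeModel, ...] = ()

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise ParameterError(f"n_patients must be >= 10, got {self.n_patients}")
        missing = [s for s in self.structure_names if s not in self.dvh_shapes]
        if missing:
            raise ConfigurationError(f"no DVH shape parameters for structures {missing}")


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated cohort plus the ground truth that produced its outcomes."""

    dvhs: tuple[DVHCurve, ...]
    clinical: tuple[ClinicalRecord, ...]
    grades: pd.DataFrame  # index patient_id, one column per endpoint
    truth: tuple[OutcomeModel, ...]
    seed: int

    def __post_init__(self) -> None:
        pids = {r.patient_id for r in self.clinical}
        if set(self.grades.index) != pids:
            raise ValidationError("grade table does not cover exactly the cohort patients")
        vals = self.grades.to_numpy()
        if vals.size and (vals.min() < 0 or vals.max() > 5):
            raise ValidationError("grades must lie in 0..5")


DEFAULT_DVH_SHAPES: dict[str, StructureShape] = {
    "esophagus": StructureShape(falloff_steepness=7.0, coverage_fraction=0.55),
    "lung": StructureShape(falloff_steepness=5.0, coverage_fraction=0.32),
    "heart": StructureShape(falloff_steepness=4.0, coverage_fraction=0.22),
}


def normalized_sigmoid(dose: np.ndarray, midpoint: float, slope: float, dmax: float) -> np.ndarray:
    """The generating DVH function; exposed so tests can invert it analytically."""
    raw = 1.0 / (1.0 + np.exp(np.clip(slope * (dose - midpoint), -700, 700)))
    head = 1.0 / (1.0 + math.exp(max(min(slope * (0.0 - midpoint), 700), -700)))
    tail = 1.0 / (1.0 + math.exp(max(min(slope * (dmax - midpoint), 700), -700)))
    return np.clip((raw - tail) / (head - tail), 0.0, 1.0)


def sample_dvh_curve(
    shape: StructureShape,
    fractionation: Fractionation,
    rng: np.random.Generator,
    patient_id: str = "p0",
    structure: str = "structure",
) -> DVHCurve:
    """Draw one cumulative DVH from the normalized-sigmoid family.

    The curve is 1.0 at 0 Gy, non-increasing, and reaches 0 at or before
    1.2x the prescription dose.
    """
    rx = fractionation.total_dose_gy
    dmax = 1.2 * rx
    midpoint = shape.coverage_fraction * rx * math.exp(
        rng.normal(0.0, shape.midpoint_jitter_sd)
    )
    midpoint = float(np.clip(midpoint, 0.02 * rx, 1.05 * rx))
    slope = shape.falloff_steepness / rx * math.exp(rng.normal(0.0, shape.steepness_jitter_sd))
    grid = np.arange(0.0, dmax + shape.bin_width_gy / 2, shape.bin_width_gy)
    if grid[-1] < dmax:
        grid = np.append(grid, dmax)
    vol = normalized_sigmoid(grid, midpoint, slope, dmax)
    vol[0] = 1.0
    vol[-1] = 0.0
    vol = np.minimum.accumulate(vol)
    return DVHCurve(
        patient_id=patient_id, structure=structure, dose_gy=grid, volume_fraction=vol
    )


def sample_clinical(
    dists: ClinicalDists, rng: np.random.Generator, patient_id: str = "p0"
) -> ClinicalRecord:
    """Draw one clinical record from the configured marginals.

    A2M is drawn lognormal and shifted additively for former/current
    smokers; pack-years are zero for never smokers.
    """
    age = float(np.clip(rng.normal(dists.age_mean, dists.age_sd), *dists.age_range))
    sex = "female" if rng.random() < dists.female_p else "male"
    kps = float(rng.choice(dists.kps_values, p=dists.kps_probs))
    smoking = ("never", "former", "current")[
        rng.choice(3, p=np.asarray(dists.smoking_probs, dtype=float))
    ]
    pack_years = (
        0.0
        if smoking == "never"
        else float(rng.lognormal(dists.pack_years_log_mean, dists.pack_years_log_sd))
    )
    a2m = float(rng.lognormal(dists.a2m_log_median, dists.a2m_log_sd))
    if smoking == "former":
        a2m += dists.a2m_smoker_shift[0]
    elif smoking == "current":
        a2m += dists.a2m_smoker_shift[1]
    chemo_timing = ("concurrent", "sequential", "none")[
        rng.choice(3, p=np.asarray(dists.chemo_timing_probs, dtype=float))
    ]
    subtype = str(
        dists.subtype_names[rng.choice(len(dists.subtype_names), p=dists.subtype_probs)]
    )
    frac = dists.fractionation_menu[
        rng.choice(len(dists.fractionation_menu), p=dists.fractionation_probs)
    ]
    return ClinicalRecord(
        patient_id=patient_id,
        age=age,
        sex=sex,
        kps=kps,
        smoking_status=smoking,
        pack_years=pack_years,
        a2m_mg_dl=a2m,
        chemo_timing=chemo_timing,
        rt_modality=frac.modality,
        total_dose_gy=frac.total_dose_gy,
        fraction_number=frac.fraction_number,
        treatment_days=frac.treatment_days,
        subtype=subtype,
    )


def assign_outcomes(
    features: pd.DataFrame, model: OutcomeModel, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-patient CTCAE grades from the logistic ground truth.

    The binary event is drawn first (Bernoulli on the model's event
    probability); the grade is then drawn conditional on event status.
    """
    p = model.event_probability(features)
    events = rng.random(len(features)) < p
    grades = np.zeros(len(features), dtype=int)

    ev_grades = np.array(sorted(model.event_grade_probs))
    ev_probs = np.array([model.event_grade_probs[g] for g in ev_grades])
    nev_grades = np.array(sorted(model.nonevent_grade_probs))
    nev_probs = np.array([model.nonevent_grade_probs[g] for g in nev_grades])

    n_ev = int(events.sum())
    if n_ev:
        grades[events] = rng.choice(ev_grades, size=n_ev, p=ev_probs)
    if n_ev < len(features):
        grades[~events] = rng.choice(nev_grades, size=len(features) - n_ev, p=nev_probs)
    return grades


def default_outcome_models() -> tuple[OutcomeModel, OutcomeModel]:
    """Ground-truth models used by the default cohort spec.

    Intercepts were calibrated once against the default generator so that
    event prevalence is ~23.6% (esophagitis) and ~14.0% (pneumonitis) at
    large n; coefficients act on EQD2 Gy, days, mg/dL and 0/1 indicators.
    """
    esoph = OutcomeModel(
        endpoint="esophagitis",
        coefficients={
            "esophagus_D50": 0.045,
            "treatment_days": 0.055,
            "chemo": 0.9,
            "a2m_mg_dl": -0.004,
        },
        intercept=-4.15,
        event_grade_probs={2: 53 / 61, 3: 8 / 61},
        nonevent_grade_probs={0: 0.7, 1: 0.3},
    )
    pneum = OutcomeModel(
        endpoint="pneumonitis",
        coefficients={
            "lung_D65": 0.10,
            "heart_max": 0.03,
            "treatment_days": 0.02,
            "sex": 0.5,
        },
        intercept=-7.87,
        event_grade_probs={2: 26 / 36, 3: 9 / 36, 4: 1 / 36},
        nonevent_grade_probs={0: 0.75, 1: 0.25},
    )
    return esoph, pneum


def default_spec(n_patients: int = 258, seed: int = 0) -> CohortSpec:
    """Default three-structure, two-endpoint cohort spec."""
    return CohortSpec(
        n_patients=n_patients,
        seed=seed,
        outcome_models=default_outcome_models(),
    )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full cohort: DVHs, clinical records and outcome grades.

    Deterministic given ``spec.seed``: a single generator seeded once is
    threaded through every sampling step in a fixed order.
    """
    rng = np.random.default_rng(spec.seed)
    width = max(3, len(str(spec.n_patients)))
    pids = [f"p{i:0{width}d}" for i in range(spec.n_patients)]

    clinical = [sample_clinical(spec.clinical_dists, rng, pid) for pid in pids]
    dvhs: list[DVHCurve] = []
    for rec in clinical:
        frac = Fractionation(
            rec.total_dose_gy, rec.fraction_number, rec.treatment_days, rec.rt_modality
        )
        for s in spec.structure_names:
            dvhs.append(
                sample_dvh_curve(
                    spec.dvh_shapes[s], frac, rng, patient_id=rec.patient_id, structure=s
                )
            )

    grades = pd.DataFrame(index=pd.Index(pids, name="patient_id"))
    if spec.outcome_models:
        table = build_feature_table(dvhs, clinical)
        feats = table.data.loc[pids]
        for model in spec.outcome_models:
            grades[model.endpoint] = assign_outcomes(feats, model, rng)

    return SyntheticCohort(
        dvhs=tuple(dvhs),
        clinical=tuple(clinical),
        grades=grades,
        truth=tuple(spec.outcome_models),
        seed=spec.seed,
    )


def write_truth_json(models: Sequence[OutcomeModel], path: str | Path) -> None:
    """Persist ground-truth coefficients for parameter-recovery tests."""
    payload = [
        {
            "endpoint": m.endpoint,
            "intercept": m.intercept,
            "coefficients": dict(m.coefficients),
            "event_grade_probs": {str(k): v for k, v in m.event_grade_probs.items()},
            "nonevent_grade_probs": {str(k): v for k, v in m.nonevent_grade_probs.items()},
        }
        for m in models
    ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
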