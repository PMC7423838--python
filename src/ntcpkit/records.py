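"""Per-patient clinical covariate records."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import ValidationError

SMOKING_LEVELS = ("never", "former", "current")
CHEMO_LEVELS = ("concurrent", "sequential", "none")
MODALITY_LEVELS = ("conventional", "sbrt")
SEX_LEVELS = ("male", "female")


@dataclass(frozen=True)
class ClinicalRecord:
    """Baseline covariates and treatment-schedule fields for one patient.

    ``a2m_mg_dl`` is the baseline serum alpha-2-macroglobulin level;
    ``treatment_days`` counts calendar days of the radiotherapy course
    including weekends.
    """

    patient_id: str
    age: float
    sex: str
    kps: float
    smoking_status: str
    pack_years: float
    a2m_mg_dl: float
    chemo_timing: str
    rt_modality: str
    total_dose_gy: float
    fraction_number: int
    treatment_days: int
    subtype: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", _level(self.sex, SEX_LEVELS, "sex", self.patient_id))
        object.__setattr__(
            self,
            "smoking_status",
            _level(self.smoking_status, SMOKING_LEVELS, "smoking_status", self.patient_id),
        )
        object.__setattr__(
            self,
            "chemo_timing",
            _level(self.chemo_timing, CHEMO_LEVELS, "chemo_timing", self.patient_id),
        )
        object.__setattr__(
            self,
            "rt_modality",
            _level(self.rt_modality, MODALITY_LEVELS, "rt_modality", self.patient_id),
        )
        if self.age <= 0:
            raise ValidationError(f"age must be positive (patient {self.patient_id!r})")
        if self.a2m_mg_dl <= 0:
            raise ValidationError(f"a2m_mg_dl must be positive (patient {self.patient_id!r})")
        if self.fraction_number < 1 or self.treatment_days < 1:
            raise ValidationError(
                f"fraction_number and treatment_days must be >= 1 (patient {self.patient_id!r})"
            )
        if self.treatment_days < self.fraction_number:
            warnings.warn(
                f"treatment_days < fraction_number for patient {self.patient_id!r}",
                stacklevel=2,
            )

    @property
    def has_chemo(self) -> bool:
        return self.chemo_timing != "none"

    @property
    def is_sbrt(self) -> bool:
        return self.rt_modality == "sbrt"

    @property
    def dose_per_fraction(self) -> float:
        return self.total_dose_gy / self.fraction_number

    @property
    def smoking_ordinal(self) -> int:
        """never < former < current encoded 0 < 1 < 2."""
        return SMOKING_LEVELS.index(self.smoking_status)


def _level(value: str, levels: tuple[str, ...], name: str, patient_id: str) -> str:
    norm = str(value).strip().lower()
    if norm not in levels:
        raise ValidationError(
            f"unknown {name} level {value!r} for patient {patient_id!r}; expected one of {levels}"
        )
    return norm
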