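"""Cumulative dose-volume histograms and dosimetric feature extraction.

A cumulative DVH gives, for each dose level ``D``, the fraction of a
structure's volume receiving at least ``D``.  All downstream dose metrics
(Dx, mean, max, fractional fDx) are read off this curve.  Physical doses
are converted to the equivalent dose in 2 Gy fractions (EQD2) under the
linear-quadratic model before metric extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ParameterError, StateError, ValidationError

PHYSICAL = "physical"
EQD2 = "EQD2"

#: Dx grid used throughout: x = 5%, 10%, ..., 100% of the structure volume.
DEFAULT_DX_GRID: tuple[int, ...] = tuple(range(5, 101, 5))

#: Uniform resampling grid width (Gy) applied before metric extraction.
DEFAULT_RESAMPLE_WIDTH = 0.1

#: Default linear-quadratic alpha/beta ratios (Gy) by structure.
DEFAULT_ALPHA_BETA: dict[str, float] = {"esophagus": 10.0, "lung": 3.0, "heart": 3.0}

_MONOTONE_TOL = 1e-9


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH for one patient and structure.

    Parameters
    ----------
    patient_id, structure
        Identifiers carried through to the feature table.
    dose_gy
        Strictly increasing dose grid starting at 0 Gy.
    volume_fraction
        Non-increasing values in [0, 1] with ``volume_fraction[0] == 1``.
    dose_kind
        ``"physical"`` for planned dose, ``"EQD2"`` after conversion.
    """

    patient_id: str
    structure: str
    dose_gy: np.ndarray
    volume_fraction: np.ndarray
    dose_kind: str = PHYSICAL

    def __post_init__(self) -> None:
        dose = np.asarray(self.dose_gy, dtype=float)
        vol = np.asarray(self.volume_fraction, dtype=float)
        object.__setattr__(self, "dose_gy", dose)
        object.__setattr__(self, "volume_fraction", vol)
        ctx = f"patient={self.patient_id!r} structure={self.structure!r}"
        if self.dose_kind not in (PHYSICAL, EQD2):
            raise ValidationError(f"unknown dose_kind {self.dose_kind!r} ({ctx})")
        if dose.ndim != 1 or vol.ndim != 1 or dose.size != vol.size:
            raise ValidationError(f"dose and volume arrays must be 1-D of equal length ({ctx})")
        if dose.size < 2:
            raise ValidationError(f"need at least two DVH bins ({ctx})")
        if dose[0] != 0.0:
            raise ValidationError(f"dose grid must start at 0 Gy, got {dose[0]} ({ctx})")
        if np.any(np.diff(dose) <= 0):
            raise ValidationError(f"dose bins out of order ({ctx})")
        if np.any(vol < -_MONOTONE_TOL) or np.any(vol > 1 + _MONOTONE_TOL):
            raise ValidationError(f"volume fractions outside [0, 1] ({ctx})")
        if abs(vol[0] - 1.0) > _MONOTONE_TOL:
            raise ValidationError(f"cumulative DVH must start at volume fraction 1.0 ({ctx})")
        if np.any(np.diff(vol) > _MONOTONE_TOL):
            raise ValidationError(f"volume fractions must be non-increasing ({ctx})")

    @property
    def n_bins(self) -> int:
        return int(self.dose_gy.size)

    def resample(self, bin_width: float = DEFAULT_RESAMPLE_WIDTH) -> "DVHCurve":
        """Linear resampling onto a uniform dose grid of the given width."""
        if bin_width <= 0:
            raise ParameterError("bin_width must be positive")
        dmax = float(self.dose_gy[-1])
        grid = np.arange(0.0, dmax + bin_width / 2, bin_width)
        if grid[-1] < dmax:
            grid = np.append(grid, dmax)
        vol = np.interp(grid, self.dose_gy, self.volume_fraction)
        vol[0] = 1.0
        return replace(self, dose_gy=grid, volume_fraction=vol)


@dataclass(frozen=True)
class EQD2Params:
    """Linear-quadratic conversion parameters for one treatment course."""

    alpha_beta: float
    fraction_number: int

    def __post_init__(self) -> None:
        if self.alpha_beta <= 0:
            raise ParameterError(f"alpha_beta must be positive, got {self.alpha_beta}")
        if self.fraction_number < 1:
            raise ParameterError(f"fraction_number must be >= 1, got {self.fraction_number}")


@dataclass(frozen=True)
class DoseMetricSet:
    """Dosimetric summary of one patient x structure.

    ``dx`` holds EQD2 doses on the x-grid; ``fdx`` holds the fractional
    variant (dose per treatment day) computed from the physical curve, or
    ``None`` for structures without fractional variables.
    """

    patient_id: str
    structure: str
    dx: Mapping[int, float]
    mean_dose: float
    max_dose: float
    treatment_days: int
    fdx: Mapping[int, float] | None = None
    fmean: float | None = None
    fmax: float | None = None


def eqd2_transform(curve: DVHCurve, params: EQD2Params) -> DVHCurve:
    """Convert a physical-dose DVH to EQD2.

    Each bin dose ``D`` maps to ``D * (d + a/b) / (2 + a/b)`` where the dose
    per fraction is ``d = D / fraction_number``.  The transform is strictly
    increasing in ``D``, so volume fractions are unchanged and the curve
    stays a valid cumulative DVH.
    """
    if curve.dose_kind != PHYSICAL:
        raise StateError("curve is already in EQD2")
    ab = params.alpha_beta
    d = curve.dose_gy / params.fraction_number
    dose = curve.dose_gy * (d + ab) / (2.0 + ab)
    return replace(curve, dose_gy=dose, dose_kind=EQD2)


def dose_at_volume(curve: DVHCurve, x: float) -> float:
    """Minimum dose (Gy) received by the hottest x% of the structure.

    Reads the cumulative DVH at volume fraction ``x/100`` with linear
    interpolation between bins.  Plateaus are resolved to the lowest dose
    achieving the target fraction.  If the target exceeds every tabulated
    fraction below 1.0, the largest dose still covering the full volume
    (the minimum structure dose) is returned.
    """
    if not 0 < x <= 100:
        raise ParameterError(f"x must be in (0, 100], got {x}")
    target = x / 100.0
    dose = curve.dose_gy
    vol = curve.volume_fraction

    if target >= 1.0 - _MONOTONE_TOL:
        # x = 100: minimum structure dose, the largest dose still covering
        # the full volume
        full = vol >= 1.0 - _MONOTONE_TOL
        return float(dose[full][-1])

    below = vol <= target + _MONOTONE_TOL
    if not below.any():
        # target above every tabulated fraction < 1: minimum structure dose
        full = vol >= 1.0 - _MONOTONE_TOL
        return float(dose[full][-1])
    i = int(np.argmax(below))  # first bin at or below the target
    if i == 0:
        return 0.0
    v_hi, v_lo = vol[i - 1], vol[i]
    if v_hi - v_lo <= _MONOTONE_TOL:
        return float(dose[i])
    frac = (v_hi - target) / (v_hi - v_lo)
    return float(dose[i - 1] + frac * (dose[i] - dose[i - 1]))


def mean_dose(curve: DVHCurve) -> float:
    """Mean structure dose: the integral of the cumulative DVH over dose."""
    return float(np.trapezoid(curve.volume_fraction, curve.dose_gy))


def max_dose(curve: DVHCurve) -> float:
    """Largest tabulated dose with non-zero covered volume."""
    nz = curve.volume_fraction > _MONOTONE_TOL
    return float(curve.dose_gy[nz][-1])


def fractional_metrics(
    dx: Mapping[int, float],
    mean: float,
    mx: float,
    treatment_days: int,
) -> tuple[dict[int, float], float, float]:
    """Divide every dose-valued metric by the number of treatment days.

    Treatment days count calendar days from the start to the end of the
    course, weekends included.  Units of the result are Gy/day.
    """
    if treatment_days < 1:
        raise ParameterError(f"treatment_days must be >= 1, got {treatment_days}")
    fdx = {x: v / treatment_days for x, v in dx.items()}
    return fdx, mean / treatment_days, mx / treatment_days


def summarize_structure(
    curve: DVHCurve,
    params: EQD2Params,
    treatment_days: int,
    dx_grid: Sequence[int] = DEFAULT_DX_GRID,
    include_fractional: bool = False,
    fractional_on_physical: bool = True,
    resample_width: float = DEFAULT_RESAMPLE_WIDTH,
) -> DoseMetricSet:
    """Full dosimetric metric set for one physical-dose DVH.

    The curve is resampled to a uniform grid, converted to EQD2, and the
    Dx grid, mean and max doses are extracted from the EQD2 curve.  When
    ``include_fractional`` is set, fDx/fmean/fmax are computed by dividing
    the metrics of the *physical* curve (default; switchable) by the number
    of treatment days.
    """
    if treatment_days < 1:
        raise ParameterError(f"treatment_days must be >= 1, got {treatment_days}")
    phys = curve.resample(resample_width)
    eq = eqd2_transform(phys, params)

    dx = {int(x): dose_at_volume(eq, x) for x in dx_grid}
    mean = mean_dose(eq)
    mx = max_dose(eq)

    fdx = fmean = fmx = None
    if include_fractional:
        base = phys if fractional_on_physical else eq
        base_dx = {int(x): dose_at_volume(base, x) for x in dx_grid}
        fdx, fmean, fmx = fractional_metrics(
            base_dx, mean_dose(base), max_dose(base), treatment_days
        )

    return DoseMetricSet(
        patient_id=curve.patient_id,
        structure=curve.structure,
        dx=dx,
        mean_dose=mean,
        max_dose=mx,
        treatment_days=treatment_days,
        fdx=fdx,
        fmean=fmean,
        fmax=fmx,
    )
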